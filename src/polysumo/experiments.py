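"""Ground-truth recovery experiments.

These functions define the package's standard validation experiments —
fixed synthetic study conditions, run end to end through the pipeline with
the truth nuclear masks as the external-segmentation fidelity path — and
return the recovered quantities.  The same definitions back the test
suite, the acceptance script and the analysis drivers, so every reported
number comes from one code path.

Scene sizes: detection experiments run at 512 x 512 with 6 cells per field
(identical optics to full-size fields; all parameters are in pixels), and
the localization experiment at the acquisition-native 1024 x 1024 with 30
cells so each field pools enough puncta for a stable percentage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pipeline import PipelineConfig, process_field
from .stress_stats import GroupComparisonResult, mann_whitney_u
from .synthetic_scenes import SceneSpec, derive_seed, generate_scene

# Easy-regime spot width: spots of 2-6 px diameter, reading "diameter" as
# the thresholded support of a Gaussian spot (about 3.6 sigma at the
# operating threshold), i.e. sigma in [0.6, 1.6] px.
EASY_SIGMA_RANGE = (0.6, 1.6)
EASY_LAMBDA = 8.0
LOCALIZATION_NUCLEAR_FRACTION = 0.9
LOCALIZATION_LAMBDA = 12.0
DIFFERENTIAL_LAMBDAS = {"control": 5.0, "as2o3": 15.0}


def easy_scene_spec(seed: int, **overrides) -> SceneSpec:
    """One easy-regime count-recovery field: 512^2, 6 cells, Poisson(8)
    spots of 2-6 px at peak SNR well above 10, centers >= 4 px apart."""
    defaults = dict(
        field_shape=(512, 512),
        n_nuclei=6,
        puncta_per_cell_lambda=EASY_LAMBDA,
        punctum_sigma_px=EASY_SIGMA_RANGE,
        seed=seed,
    )
    defaults.update(overrides)
    return SceneSpec(**defaults)


@dataclass
class CountRecoveryResult:
    n_cells: int
    n_cells_exact: int
    true_counts: list[int] = field(default_factory=list)
    detected_counts: list[int] = field(default_factory=list)

    @property
    def fraction_exact(self) -> float:
        return self.n_cells_exact / self.n_cells

    @property
    def mean_detected(self) -> float:
        return float(np.mean(self.detected_counts))

    @property
    def mean_true(self) -> float:
        return float(np.mean(self.true_counts))


def run_count_recovery(
    base_seed: int = 0, n_images: int = 9, config: PipelineConfig | None = None
) -> CountRecoveryResult:
    """Detected-vs-true per-cell punctum counts on easy-regime scenes."""
    config = config or PipelineConfig()
    result = CountRecoveryResult(0, 0)
    for i in range(n_images):
        spec = easy_scene_spec(derive_seed(base_seed, i))
        fld, truth = generate_scene(spec)
        res = process_field(
            fld, config, field_id=f"easy_{i:02d}", external_nuclei=truth.nuclei_mask
        )
        detected = {c.cell_id: c.n_puncta_total for c in res.cell_records}
        for cell_id, true_n in truth.per_cell_counts().items():
            det_n = detected.get(cell_id, 0)
            result.n_cells += 1
            result.n_cells_exact += int(det_n == int(true_n))
            result.true_counts.append(int(true_n))
            result.detected_counts.append(det_n)
    return result


@dataclass
class LocalizationRecoveryResult:
    true_fraction: float
    pct_nuclear_per_image: list[float]
    true_pct_per_image: list[float]

    @property
    def max_abs_error(self) -> float:
        """Largest per-image deviation from 100 * true placement fraction."""
        return max(
            abs(p - 100.0 * self.true_fraction) for p in self.pct_nuclear_per_image
        )

    @property
    def pooled_pct_nuclear(self) -> float:
        return float(np.mean(self.pct_nuclear_per_image))


def run_localization_recovery(
    base_seed: int = 0,
    n_images: int = 9,
    nuclear_fraction: float = LOCALIZATION_NUCLEAR_FRACTION,
    config: PipelineConfig | None = None,
) -> LocalizationRecoveryResult:
    """Recovered nuclear-localization percentage on predominantly nuclear
    scenes (full-size fields, 30 cells each, Poisson(12) spots)."""
    config = config or PipelineConfig()
    pct, true_pct = [], []
    for i in range(n_images):
        spec = easy_scene_spec(
            derive_seed(base_seed, 1000 + i),
            field_shape=(1024, 1024),
            n_nuclei=30,
            puncta_per_cell_lambda=LOCALIZATION_LAMBDA,
            nuclear_fraction=nuclear_fraction,
        )
        fld, truth = generate_scene(spec)
        res = process_field(
            fld, config, field_id=f"loc_{i:02d}", external_nuclei=truth.nuclei_mask
        )
        pct.append(res.summary.pct_nuclear)
        true_pct.append(truth.pct_nuclear())
    return LocalizationRecoveryResult(
        true_fraction=nuclear_fraction,
        pct_nuclear_per_image=pct,
        true_pct_per_image=true_pct,
    )


@dataclass
class DifferentialDetectionResult:
    control_means: list[float]
    stress_means: list[float]
    test: GroupComparisonResult


def run_differential_detection(
    base_seed: int = 0, n_images: int = 9, config: PipelineConfig | None = None
) -> DifferentialDetectionResult:
    """Control (lambda=5) versus arsenic-stress (lambda=15) conditions,
    compared by Mann-Whitney on per-image mean puncta per cell."""
    config = config or PipelineConfig()
    groups: dict[str, list[float]] = {}
    for g, (cond, lam) in enumerate(DIFFERENTIAL_LAMBDAS.items()):
        means = []
        for i in range(n_images):
            spec = easy_scene_spec(
                derive_seed(base_seed, 2000 + 100 * g + i),
                puncta_per_cell_lambda=lam,
            )
            fld, truth = generate_scene(spec)
            res = process_field(
                fld, config, field_id=f"{cond}_{i:02d}",
                external_nuclei=truth.nuclei_mask, condition=cond,
            )
            means.append(res.summary.mean_puncta_per_cell)
        groups[cond] = means
    test = mann_whitney_u(groups["control"], groups["as2o3"])
    return DifferentialDetectionResult(
        control_means=groups["control"], stress_means=groups["as2o3"], test=test
    )
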