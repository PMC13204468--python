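"""End-to-end orchestration: simulate -> segment -> detect -> quantify.

One YAML-serializable config carries every tunable parameter with the
pipeline defaults; outputs are label TIFFs plus three CSV tables and a
manifest with content hashes, so a re-run on identical inputs is
byte-identical and auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .compartments import CompartmentSet, SegmentationParams, segment_field
from .core_images import (
    FieldImage,
    LabelMask,
    Projection,
    average_z_projection,
    read_field,
    read_label_mask,
    rescale_to_unit,
    write_label_mask,
)
from .puncta import PunctaParams, PunctumRecord, assign_puncta, detect_puncta
from .quantify import (
    CellRecord,
    ImageSummary,
    cells_table,
    export_csv,
    images_table,
    measure_intensities,
    puncta_table,
    summarize_image,
)

logger = logging.getLogger("polysumo")


@dataclass
class StatsOptions:
    adjust: str = "sidak"  # or "holm"
    exact_cutoff: int = 16


@dataclass
class PipelineConfig:
    """Every pipeline parameter, with the published defaults, in one place."""

    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    puncta: PunctaParams = field(default_factory=PunctaParams)
    stats: StatsOptions = field(default_factory=StatsOptions)
    channel_order: tuple[str, ...] = ("dapi", "gfp", "rfp")
    condition: str = "control"
    construct: str = "WT"  # or "MT"
    nuclei_mask_name: str | None = None  # per-field external label TIFF
    seed: int = 0

    def to_yaml(self, path: str | Path | None = None) -> str:
        d = asdict(self)
        d["channel_order"] = list(d["channel_order"])
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        """Load a config; unknown keys anywhere in the document are
        rejected so typos never silently fall back to defaults."""
        src = str(source)
        text = Path(src).read_text() if "\n" not in src and Path(src).exists() else src
        data = yaml.safe_load(text) or {}
        return cls._from_dict(data)

    @classmethod
    def _from_dict(cls, data: dict) -> "PipelineConfig":
        def build(dc_type, payload: dict):
            names = {f.name for f in dataclasses.fields(dc_type)}
            unknown = set(payload) - names
            if unknown:
                raise ValueError(f"unknown config keys: {sorted(unknown)}")
            return dc_type(**payload)

        payload = dict(data)
        for key, dc_type in (
            ("segmentation", SegmentationParams),
            ("puncta", PunctaParams),
            ("stats", StatsOptions),
        ):
            if key in payload and isinstance(payload[key], dict):
                payload[key] = build(dc_type, payload[key])
        if "channel_order" in payload:
            payload["channel_order"] = tuple(payload["channel_order"])
        return build(cls, payload)


@dataclass
class FieldResult:
    field_id: str
    compartments: CompartmentSet
    puncta_mask: LabelMask
    punctum_records: list[PunctumRecord]
    cell_records: list[CellRecord]
    summary: ImageSummary
    projection: Projection


def process_field(
    fld: FieldImage,
    config: PipelineConfig,
    field_id: str = "field",
    external_nuclei: LabelMask | None = None,
    condition: str | None = None,
) -> FieldResult:
    """Run the full quantification chain on one in-memory field."""
    t0 = time.perf_counter()
    proj = average_z_projection(fld)
    comp = segment_field(proj, config.segmentation, external_nuclei)
    raw_gfp = proj.channels["gfp"]
    gfp_unit = rescale_to_unit(raw_gfp)
    puncta_mask = detect_puncta(gfp_unit, config.puncta)
    records = assign_puncta(puncta_mask, comp, field_id=field_id, params=config.puncta)
    records, cell_records = measure_intensities(
        records, puncta_mask, comp, raw_gfp, field_id=field_id
    )
    summary = summarize_image(
        cell_records, records,
        condition=condition or config.condition,
        construct=config.construct,
        field_id=field_id,
    )
    logger.info(
        "stage=quantify field=%s duration=%.2fs cells=%d puncta=%d",
        field_id, time.perf_counter() - t0, len(cell_records), len(records),
    )
    return FieldResult(
        field_id=field_id,
        compartments=comp,
        puncta_mask=puncta_mask,
        punctum_records=records,
        cell_records=cell_records,
        summary=summary,
        projection=proj,
    )


@dataclass
class PipelineReport:
    n_fields: int
    n_failed: int
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.n_failed == 0


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def discover_fields(input_dir: str | Path) -> list[tuple[str, Path, str | None]]:
    """Field directories under ``input_dir``: any subdirectory holding the
    three channel TIFFs.  Conditions come from a manifest.yaml when present."""
    input_dir = Path(input_dir)
    conditions: dict[str, str] = {}
    manifest = input_dir / "manifest.yaml"
    if manifest.exists():
        data = yaml.safe_load(manifest.read_text()) or {}
        for entry in data.get("fields", []):
            conditions[entry["field_id"]] = entry.get("condition")
    out = []
    for sub in sorted(p for p in input_dir.iterdir() if p.is_dir()):
        if (sub / "gfp.tif").exists():
            out.append((sub.name, sub, conditions.get(sub.name)))
    return out


def run_pipeline(
    config: PipelineConfig, input_dir: str | Path, out_dir: str | Path
) -> PipelineReport:
    """Process every field under ``input_dir`` into ``out_dir``.

    Per-field failures are isolated: the failing field is reported (stage +
    message) and the remaining fields still complete.  The manifest lists
    every artifact with its SHA-256 so determinism is checkable.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fields = discover_fields(input_dir)
    if not fields:
        raise FileNotFoundError(f"no field directories under {input_dir}")

    all_puncta: list[PunctumRecord] = []
    all_cells: list[CellRecord] = []
    all_images: list[ImageSummary] = []
    failures: dict[str, str] = {}
    for field_id, fdir, condition in fields:
        try:
            fld = read_field(
                {ch: fdir / f"{ch}.tif" for ch in config.channel_order}
            )
            external = None
            if config.nuclei_mask_name:
                mask_path = fdir / config.nuclei_mask_name
                if mask_path.exists():
                    external = read_label_mask(mask_path, kind="nuclei")
            result = process_field(
                fld, config, field_id=field_id,
                external_nuclei=external, condition=condition,
            )
        except Exception as exc:  # noqa: BLE001 - isolation contract
            failures[field_id] = f"{type(exc).__name__}: {exc}"
            logger.error("stage=failed field=%s error=%s", field_id, exc)
            continue
        mask_dir = out_dir / "masks" / field_id
        mask_dir.mkdir(parents=True, exist_ok=True)
        write_label_mask(result.compartments.nuclei, mask_dir / "nuclei.tif")
        write_label_mask(result.compartments.cells, mask_dir / "cells.tif")
        write_label_mask(result.compartments.cytoplasm, mask_dir / "cytoplasm.tif")
        write_label_mask(result.puncta_mask, mask_dir / "puncta.tif")
        all_puncta.extend(result.punctum_records)
        all_cells.extend(result.cell_records)
        all_images.append(result.summary)

    export_csv(puncta_table(all_puncta), out_dir / "puncta.csv")
    export_csv(cells_table(all_cells), out_dir / "cells.csv")
    export_csv(images_table(all_images), out_dir / "images.csv")

    manifest = {
        "config": yaml.safe_load(config.to_yaml()),
        "n_fields": len(fields),
        "failures": failures,
        "artifacts": {
            str(p.relative_to(out_dir)): _sha256(p)
            for p in sorted(out_dir.rglob("*"))
            if p.is_file() and p.name != "manifest.yaml"
        },
    }
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return PipelineReport(
        n_fields=len(fields), n_failed=len(failures), failures=failures
    )
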