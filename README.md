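# polysumo

Quantification of polySUMO reporter puncta in multi-channel fluorescence
microscopy fields.

Cells expressing a GFP-tagged tandem-SIM (polySIM) sensor derived from the
SUMO-targeted ubiquitin ligase RNF4 form bright sub-micron puncta wherever
polySUMO chains accumulate — predominantly in the nucleus under basal
conditions, with condition-specific shifts in number, intensity and
nuclear/cytoplasmic balance under oxidative, metabolic and genotoxic
stress.  `polysumo` turns three-channel confocal fields (DAPI, GFP
reporter, RFP/membrane counterstain) into per-punctum, per-cell and
per-image measurement tables, and provides the group statistics used to
compare conditions.  Because such studies rarely ship raw images, the
package includes a synthetic scene generator with exact ground truth, so
every stage is validated by recovery experiments rather than by eye.

## The pipeline

For each field (16-bit z-stacks or 2-D planes):

1. average z-projection per channel; unit rescaling
   `x ↦ (x − min)/(max − min)`;
2. nuclei from an external label mask (e.g. a dedicated nuclear
   segmentation model) or a classical DAPI fallback; nuclei with area
   < 1200 px² are discarded;
3. cell bodies by seeded watershed on the combined GFP+RFP image,
   foreground at `0.5 · t₁` where `t₁` is the lower three-class Otsu
   boundary (middle class as foreground); cytoplasm = cell ∖ nucleus;
4. GFP spot enhancement: `max(0, I − G_{σ=300}(I))`, smoothing `G_{σ=1}`,
   exact white top-hat (disk radius 2);
5. puncta at threshold `max(Otsu₂, 0.05)` on the projection's unit scale,
   declumped by shape-and-intensity watershed, gated to area-equivalent
   diameter `2·√(A/π) ∈ [1, 10]` px;
6. centroid-based assignment to nucleus or cytoplasm (outside cells →
   excluded); intensities measured on the raw projection; per-image
   pooling `pct_nuclear = 100·Σn_nuc/Σn_tot`.

Group comparison: exact/two-sided Mann–Whitney U for localization
percentages, two-way ANOVA (Type II SS) with Šidák-adjusted pairwise
contrasts for counts and intensities.

## Worked example

Simulate a three-condition experiment (control, arsenic stress, and the
binding-dead MT construct; 3 images each), quantify it, and compare:

```bash
python analysis/01_simulate_conditions.py
python analysis/02_quantify_conditions.py
python analysis/03_compare_conditions.py
```

The second step prints the per-condition means recovered by the pipeline:

```
              mean_puncta_per_cell  pct_nuclear
condition
as2o3                    15.500000    93.582251
control                   4.722222    87.021324
mt_construct              0.277778    83.333333
```

Reading: arsenic-stressed cells carry ~15.5 puncta per cell against ~4.7
in control (the simulated rates are 15 and 5; the truth tables in
`results/truth_summary.csv` give 15.6 and 4.8 for these seeds), puncta are
~90% nuclear, and the binding-dead construct yields almost none — the
0.28/cell it reports corresponds to the generator's residual rate, not
noise.  The third step writes `results/stats.csv` with the Mann–Whitney
comparisons of per-image mean puncta per cell.

The same stages are available as a CLI for externally acquired TIFFs:

```bash
polysumo simulate --preset control --n 9 --seed 7 --out fields/
polysumo run --in fields/ --config config.yaml --out out/
```

`out/` then holds nuclei/cells/cytoplasm/puncta label TIFFs per field,
three CSV tables (`puncta.csv`, `cells.csv`, `images.csv`) and a manifest
with content hashes; re-running with the same inputs reproduces the CSVs
byte for byte.

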