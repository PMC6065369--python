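# invadex

Quantitative analysis of tumor-cell invasion from tissue and live-cell
microscopy, built around the **Local Invasion Index (LII)**: treating
cancer-cell nuclei in a tumor section as a planar point pattern, each cell's
nearest-neighbor distance (NND) is the Euclidean distance to its most
proximal neighboring cancer cell, and

```
LII = mean NND over border-corrected cells        [um]
```

Cells are excluded from the mean when their *NND zone* — the closed disc
centered on the cell with radius equal to its NND — is not fully contained in
the analysis region, which removes the censoring bias of cells near the
region border whose true nearest neighbor may lie outside the imaged area.
Higher LII means cells are more scattered, i.e. more locally invasive; tumors
are binned as LII-low (≤ 7 µm) or LII-high (≥ 9 µm).

The package is aimed at quantitative cancer-biology groups who need the full
measurement stack around this index, exercisable end-to-end on synthetic data
with known ground truth:

- `invadex.synthgen` — generators for every input: Poisson / Thomas-cluster /
  hardcore point patterns, rendered cytokeratin + nuclei tissue images,
  confocal z-series, kymographs, DCIS sections, 2×2 contingency tables, and
  grouped expression matrices, each with its planted ground truth.
- `invadex.segmentation` — cytokeratin/nuclei thresholding, nucleus
  detection with watershed splitting, cancer-cell identification by
  cytokeratin positivity, invasion counting in 3D cultures, mask-restricted
  intensity quantification.
- `invadex.spatial` — NND (exactly equal to the all-pairs brute force), the
  NND-zone edge exclusion, LII, bin classification, per-cell population
  analyses (median split, bin histograms, Welch comparisons).
- `invadex.dcis` — the DCIS index for xenograft tumor sections:
  `n_structures × (cellular_area / tumor_area) / tumor_area`, i.e. intact
  in-situ structures per unit tumor area corrected for cellularity.
- `invadex.meta2x2` — per-study exact odds-ratio analysis of 2×2
  exposure × outcome tables (study inclusion filter of ≥ 10 patients per
  treatment group, sample OR with Haldane–Anscombe correction, two-sided
  Fisher exact p, conditional exact (Cornfield) 95% CI, optional
  Mantel–Haenszel pooling).
- `invadex.dynamics` — membrane-ruffle frequency and speed from kymographs,
  and marker quantification in a membrane-proximal band (default 3 µm) of
  the cell mask, built per z-slice from the distance transform.
- `invadex.gene_screen` — volcano screen of a curated gene list (hit =
  twofold change in either direction and p ≤ 0.05) with cross-dataset
  recurrence ranking.
- `invadex.validation` — end-to-end recovery checks of all of the above
  against planted ground truth and independent oracles.

## Worked example

Generate a synthetic tumor-cell point pattern and score it:

```bash
$ invadex synth pattern --seed 11 --out cells.csv
wrote cells.csv
$ invadex lii --cells cells.csv --region 0,0,500,500
{"lii_um": 4.9960638449664865, "bin": "low", "n": 2435, "n_included": 2346}
```

The default generator draws a homogeneous Poisson pattern at
λ = 0.01 cells/µm² in a 500 × 500 µm window: 2435 cells were realized, 89
were dropped by the NND-zone border correction, and the mean NND of the
remaining 2346 cells is 5.00 µm — matching the Poisson closed form
1/(2√λ) = 5 µm — which classifies this (cohesive, randomly mixed) pattern
as LII-low.

The same analysis runs from Python:

```python
from invadex import synthgen, analyze_pattern

cfg = synthgen.SimulationConfig(seed=11, window=(0, 0, 500, 500))
pattern, truth = synthgen.generate_point_pattern(cfg, "poisson", 0.01)
result = analyze_pattern(pattern)
print(result.lii, result.bin, result.n_included, result.n_total)
```

Other subcommands cover the rest of the stack: `invadex segment` (cells CSV
from a cytokeratin/nuclei TIFF), `invadex meta` (forest table from per-study
2×2 counts), `invadex dcis`, `invadex kymo`, `invadex band` and
`invadex screen`.

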