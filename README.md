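# stfd — spatio-temporal fractal dimension of source activations

`stfd` measures the spatio-temporal complexity of source-space activity
matrices (n_sources × n_samples, with 3D source coordinates). Each source is
binarized against its own epoch-wide threshold (mean + SD of the absolute
amplitudes, strict inequality); the active sources at each sample form a 3D
point cloud; stacking the clouds of each non-overlapping 1-s window along a
normalized time axis gives a 4D cloud, whose box-counting
(Minkowski–Bouligand) dimension is estimated as the log–log slope of
occupied-box counts over grid resolutions 1..128 (fit range 8..64 by
default). Per-subject mean dimensions feed a nonparametric statistical
battery (Mann–Whitney U, ROC AUC, Spearman with Bonferroni correction, PCA
of clinical scores, chi-squared demographics).

Because no recordings ship with the package, a synthetic-data module
provides (a) point clouds of analytically known dimension for estimator
validation and (b) a two-group cohort simulator whose groups differ in the
spatial dispersion of clustered activations.

## Library quick start

```python
from stfd import CohortSpec, simulate_epoch, fd_series, mann_whitney

spec = CohortSpec(seed=1)          # 27 + 15 subjects, desk scale
epoch = simulate_epoch(spec, 0)    # subject A01
series = fd_series(epoch)          # one 4D FD per 1-s window
print(series.mean_fd, len(series.values))
```

## Command line

```bash
stfd simulate --out epochs/ --seed 1          # write synthetic cohort (.h5 or .tsv)
stfd binarize epochs/A01.h5 --out mask.tsv    # run-length mask export
stfd fd epochs/A01.h5 --out A01_fd.tsv        # per-window FD series
stfd stats --summary out/cohort_summary.tsv --out report.json
stfd pipeline --out out/ --seed 1             # simulate -> binarize -> fd -> stats
stfd fixtures --out validation/               # fractal validation suite
```

`stfd pipeline` writes per-subject FD series TSVs, `cohort_summary.tsv`,
`report.json`/`report.txt`, and a `manifest.json` (config + SHA-256 +
library versions) sufficient to reproduce the run bit-identically. All
reference parameters are defaults and flags: `--window-seconds`,
`--fit-range MIN:MAX`, `--resolutions`, `--seed`, `--paper-scale` (restores
15,002 sources × 500 Hz × 120 s), plus `--config FILE` with a YAML mirror of
the full configuration.

Desk-scale defaults (2,000 sources, 100 Hz, 20 s) keep the full 42-subject
pipeline around two minutes on one CPU.

## Layout

- `src/stfd/activation.py` — epochs, thresholding, 3D/4D point clouds
- `src/stfd/boxcount.py` — box-counting kernel, FD regression, per-window series
- `src/stfd/group_stats.py` — U tests, AUC, Spearman/Bonferroni, PCA, demographics
- `src/stfd/synthetic_data.py` — fractal validation clouds, cohort and score simulators
- `src/stfd/cli_pipeline.py` — configuration, orchestration, `stfd` CLI
- `src/stfd/io.py` — HDF5/TSV epoch containers, mask and table exports
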