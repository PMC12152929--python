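# dropletquant

Quantification of protein condensates (liquid–liquid phase-separated
droplets) in fluorescence micrographs: particle segmentation with
equivalent-sphere volume statistics, bead-calibrated two-channel
registration, and object-based classification of **heterotypic**
(two-protein) versus **homotypic** (single-protein) droplets by a
nearest-neighbour distance criterion. A synthetic two-channel image
generator with full ground truth makes every stage verifiable without
any raw microscopy data.

The package is aimed at condensate biology — e.g. mixed
eGFP–α-synuclein / mCherry–S100A9 droplet populations imaged in
dual-view TIRF — but the pipeline applies to any two-channel
object-based colocalization problem.

## The analysis in brief

1. **Segmentation.** Automatic global threshold (exact integer-level
   Otsu by default, IsoData optional), 8-connected particle extraction,
   hole filling (a droplet with smaller droplets inside counts once),
   and removal of components of ≤ 4 px as artifacts. A particle of
   projected area *A* is assigned the volume of the sphere whose
   great-circle disk has that area:
   `r = √(A/π)`, `V = (4/3)πr³`.
2. **Registration.** The mCherry channel is aligned to the eGFP channel
   with a similarity (or translation/affine) transform estimated by
   least squares from sub-pixel-localized fluorescent beads imaged in
   both channels; droplet coordinates (not pixels) are transformed.
3. **Colocalization.** Euclidean distances between all green and red
   droplet centers are compared with a 500 nm criterion (strict `<`);
   sub-criterion pairs are matched one-to-one in ascending distance
   order and counted once as heterotypic droplets, the rest are
   channel-exclusive homotypic droplets. Percentages are averaged as
   mean ± sd across fields of view.
4. **Statistics.** Per-condition particle counts and mean volumes
   (design: thirty 500×500 px images per condition) are compared by
   one-way ANOVA with Bonferroni-corrected pooled-variance pairwise
   tests, including a disassembly contrast (count decrease with mean
   volume increase when small droplets dissolve first).

See `docs/methods.md` for models, defaults and limitations.

## Worked example

```python
from dropletquant.pipeline import RunConfig, run_synthetic_study

# six 1024x1024 px two-channel TIRF-like fields, ~420 droplets each,
# with a misregistration of 300 nm + 0.5 deg between the channels
cfg = RunConfig(seed=5, channel_shift_nm=(300.0, 0.0), channel_rotation_deg=0.5)
out = run_synthetic_study(cfg)

agg = out["aggregate_corrected"]
for cls in ("heterotypic", "greenOnly", "redOnly"):
    print(f"{cls:12s} {agg.mean_pct[cls]:5.1f} +/- {agg.sd_pct[cls]:4.1f} %")
print("n =", agg.n_pooled, "| uncorrected heterotypic:",
      round(out["aggregate_uncorrected"].mean_pct["heterotypic"], 1), "%")
```

prints

```
heterotypic   43.5 +/-  2.4 %
greenOnly     12.4 +/-  1.5 %
redOnly       44.1 +/-  1.7 %
n = 2511 | uncorrected heterotypic: 11.3 %
```

i.e. with the bead-estimated correction the pipeline recovers the
simulated composition (here 43.8 / 12.1 / 44.0 % ground truth) to
within half a percentage point per class, while ignoring the channel
misalignment would misclassify three quarters of the heterotypic
droplets as channel-exclusive.

The same stages run from the shell on TIFF/CSV inputs:

```sh
dropletquant run-all --seed 5 --out runs/demo      # synthetic end-to-end
dropletquant segment --config my.yaml --out runs/seg   # your own images
```

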