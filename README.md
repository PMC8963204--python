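# isletcoloc

Quantification of marker colocalization in pancreatic islets from
multiplex immunofluorescence images, with a synthetic tissue phantom
generator for end-to-end validation.

## The problem

In type 1 diabetes (T1D) research, multiplex immunofluorescence of
pancreatic tissue is used to ask which endocrine cell types express a
protein of interest — here MDA5 (IFIH1), a cytoplasmic viral dsRNA
sensor — and how that expression shifts with disease state.  The
standard readout is the per-islet **colocalization rate** between the
MDA5 channel and a hormone channel (insulin for β-cells, glucagon for
α-cells):

```
rate = 100 · A_coloc / A_fg ,    A_fg = A_ROI − A_bg
```

where, within one islet ROI, `A_coloc` is the area (pixel count) above
threshold in *both* channels, `A_bg` is the area below threshold in both,
and the foreground `A_fg` is the remainder of the ROI.  All areas are
exact integer pixel counts; a rate with empty foreground is flagged
undefined rather than set to 0.

On top of the rates, whole-slide sections are tabulated into five
structure categories: insulin-containing islets (ICI) and
insulin-deficient islets (IDI), each MDA5-positive or MDA5-negative,
plus chromogranin-A-positive / hormone-negative / MDA5-positive
**islet-like clusters** that appear in recent-onset T1D tissue.  Group
differences are tested nonparametrically (Mann–Whitney U; Kruskal–Wallis
with Dunn post-hoc and Holm adjustment), summarized as median with IQR.

Because donor images of this kind are generally not public, the package
includes a first-class synthetic tissue generator: islets as packed
disks of α/β/δ/other endocrine cells with per-cell marker levels and
per-cell MDA5 positivity, rendered through a Gaussian PSF with
background and noise into 6-channel OME-TIFFs (DAPI, INS, GCG, SST,
CHGA, MDA5) with complete per-pixel ground truth.  Cohort presets (ND,
AAB_POS, T1D_RO, T1D_LS) are calibrated to published cohort-level rate
distributions, so the whole pipeline — segmentation, rate computation,
classification, statistics — can be validated against known truth.

## Worked example

```python
from isletcoloc.pipeline import run_cohort, cohort_tables
from isletcoloc.stats import summarize, mann_whitney

results = run_cohort("ND", donors=10, seed=0, shape=(1024, 1024), islets_per_donor=15)
meas, recs = cohort_tables(results)
m = meas[meas["defined"]]
gcg = m.loc[m["pair"] == "MDA5-GCG", "rate_percent"]
ins = m.loc[m["pair"] == "MDA5-INS", "rate_percent"]
s_g, s_i = summarize(gcg), summarize(ins)
print(f"MDA5-GCG median {s_g.median:.1f}% (IQR {s_g.q1:.1f}-{s_g.q3:.1f}), n={s_g.n}")
print(f"MDA5-INS median {s_i.median:.1f}% (IQR {s_i.q1:.1f}-{s_i.q3:.1f}), n={s_i.n}")
print(f"Mann-Whitney p = {mann_whitney(gcg, ins).p_value:.4g}")
```

prints

```
MDA5-GCG median 21.4% (IQR 13.7-28.4), n=150
MDA5-INS median 16.7% (IQR 9.8-22.8), n=150
Mann-Whitney p = 0.0001066
```

i.e. in a simulated nondiabetic cohort of 10 donors (150 islets) the
MDA5–glucagon rate is higher than the MDA5–insulin rate — the
generator's α-cell positive fraction is higher — and the two-sided
Mann–Whitney test detects the difference.

The same pipeline is available from the shell:

```
isletcoloc simulate --preset T1D_RO --donors 3 --seed 1 --out cohort/
isletcoloc quantify --images cohort/ --group T1D_RO --out out/measurements.csv
isletcoloc classify --areas out/measurements_areas.csv --out out/records.csv
isletcoloc report   --measurements out/measurements.csv --records out/records.csv --out out/report/
isletcoloc sweep    --images cohort/ --out out/sweep.csv   # cutoff sensitivity
```

`report` writes the five-category distribution table (counts and
percentages per donor), per-group rate summaries, the full contrast set
with test statistics, and dot-plot/stacked-bar figures.

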