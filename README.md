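# cmrquant

Quantitative analysis of cardiovascular magnetic resonance (CMR) studies
of ischaemic heart disease, built for longitudinal cohorts that compare a
baseline examination against a follow-up (for example, before and six
months after an intramyocardial cell-therapy procedure).  Because
clinical CMR series of this kind are rarely shared, every stage ships
with a synthetic phantom generator carrying known ground truth, so the
whole pipeline is testable end to end without any external data.

## What it computes

**Myocardial blood flow and perfusion reserve.**  First-pass perfusion
series are reduced to an arterial input function (AIF, the LV blood-pool
signal on the basal slice) and per-segment tissue curves on the
standardized 16-segment model.  Tissue curves are deconvolved against the
AIF with a Fermi-shaped impulse response

&nbsp;&nbsp;&nbsp;&nbsp;h(t) = A·(1 + e^(−w/k)) / (1 + e^((t − t_d − w)/k)) for t ≥ t_d, else 0,

whose plateau estimates myocardial blood flow (MBF, mL/min/g).  The
myocardial perfusion reserve (MPR) is the ratio of MBF under adenosine
stress to resting MBF, aggregated over targeted (treated ischaemic) and
non-targeted territories.

**Infarct core and peri-infarct zone.**  Late gadolinium enhancement
(LGE) images are partitioned against a remote normal region on the same
slice: total scar is signal above the remote mean + 2 SD, core above
+ 3 SD, peri-infarct the 2–3 SD band.  Masses use voxel volume × 1.05
g/mL, reported absolutely, as a percentage of LV mass (%MDE_total), and
as core/peri percentages of total scar, plus a per-sector transmural
extent class (<50%, 50–75%, >75%).

**LV function.**  Simpson-summation volumetry from traced endo/epi
contours gives EDV, ESV, EF = 100·(EDV−ESV)/EDV, mass =
(epi − endo volume)·1.05 g/mL at end-diastole, and percent systolic wall
thickening per angular sector from centroid-ray wall thickness.

**Cohort statistics.**  Per-subject paired metrics are compared between
timepoints (and targeted vs non-targeted regions within timepoint) with
two-sided paired Student's t tests at α = 0.05, reported in the
conventional mean ± SD, P layout.

## Worked example

Recover flow from a noise-free phantom whose true rest/stress MBF are the
group means of a treated ischaemic territory at baseline:

```python
from cmrquant import (PhantomConfig, generate_aif, generate_tissue_curve,
                      fermi_deconvolve, compute_mpr)

cfg = PhantomConfig(seed=42)
t, aif = generate_aif(cfg)
rest = generate_tissue_curve(aif, cfg.frame_interval_s, true_mbf=0.67)
stress = generate_tissue_curve(aif, cfg.frame_interval_s, true_mbf=0.83)
fit_rest = fermi_deconvolve(aif, rest, cfg.frame_interval_s)
fit_stress = fermi_deconvolve(aif, stress, cfg.frame_interval_s)
print(f"rest MBF   = {fit_rest.mbf:.3f} mL/min/g")
print(f"stress MBF = {fit_stress.mbf:.3f} mL/min/g")
print(f"MPR        = {compute_mpr(fit_rest.mbf, fit_stress.mbf):.2f}")
```

prints

```
rest MBF   = 0.670 mL/min/g
stress MBF = 0.830 mL/min/g
MPR        = 1.24
```

— the planted flows are recovered exactly and their ratio, 1.24, is the
depressed perfusion reserve (≈1.2) typical of an ischaemic territory.
A virtual 12-subject paired cohort then reproduces the statistical
layout of a longitudinal study:

```python
from cmrquant.synthetic import PhantomConfig, generate_cohort
from cmrquant.stats import summarize_cohort, format_report

tab = generate_cohort(PhantomConfig(seed=42, n_subjects=12))
rep = summarize_cohort(tab, metrics=("ef_pct", "mpr_targeted",
                                     "mpr_nontargeted"))
print(format_report(rep))
```

```
Paired cohort comparisons (baseline vs 6-month follow-up)

ef_pct: 49.85 ± 9.46 versus 53.01 ± 5.87, P = 0.121  (n = 12)
mpr_targeted: 1.26 ± 0.25 versus 1.48 ± 0.35, P = 0.0132 *(n = 12)
mpr_nontargeted: 2.09 ± 0.82 versus 2.29 ± 0.62, P = 0.246  (n = 12)
mpr_targeted_vs_nontargeted_baseline: 1.26 ± 0.25 versus 2.09 ± 0.82, P = 0.00769 *(n = 12)
mpr_targeted_vs_nontargeted_followup: 1.48 ± 0.35 versus 2.29 ± 0.62, P = 0.00466 *(n = 12)

* significant at P < 0.05 (unadjusted)
```

The targeted-territory reserve improves significantly while the
non-targeted territory does not, and at baseline the targeted territory
is significantly more ischaemic than the non-targeted one — the pattern
the generator's default effect sizes encode.

## Command line

```bash
cmrquant simulate --seed 2 --out sim/        # phantom cohort + manifest
cmrquant perfusion --rest sim/S01_baseline_rest \
                   --stress sim/S01_baseline_stress --out perf.csv
cmrquant lge --image sim/S01_baseline_lge --lv-mass 150 --out lge.csv
cmrquant function --contours sim/S01_baseline_contours.json --out fn.csv
cmrquant cohort --table cohort.csv --out stats/
cmrquant run --seed 7 --out run/             # everything, with provenance
```

Exit codes: 0 ok, 1 validation error, 2 compute error.

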