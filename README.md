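# boldretest

Does the way you specify a first-level fMRI GLM change how reliable your
contrast maps are when the same subjects are scanned twice? `boldretest` is
a simulation laboratory for that question, aimed at methods researchers and
neuroimaging statisticians. It generates synthetic two-session BOLD cohorts
with *known* ground-truth reliability, fits four first-level modeling
pipelines, checks each model against its own error assumptions, and measures
voxelwise test-retest reliability — so every claim about a pipeline can be
validated against truth instead of anecdote.

The four pipelines:

| name | HRF model | physiological noise |
|---|---|---|
| `default` | canonical double-gamma, block design | — |
| `flexhrf` | + temporal & dispersion derivatives, mixed block/event | — |
| `mcompcor` | canonical, block design | single mCompCor regressor |
| `combined` | + derivatives, mixed block/event | single mCompCor regressor |

All pipelines share six motion covariates, a 128 s discrete-cosine high-pass
basis, an intercept, and global AR(1) prewhitening (two-pass, with an exact
correction for the projection bias of residual autocorrelation).

The core statistics:

- **mCompCor**: the mean time series over the union of the top-2%
  temporal-SD voxels and a WM/CSF mask, demeaned — a deliberately
  single-regressor simplification of CompCor.
- **Residual diagnostics**: per-voxel Shapiro–Wilk (normality),
  Breusch–Pagan (homoscedasticity), Durbin–Watson (independence, with exact
  design-conditional null moments); violations are p < 0.05.
- **Reliability**: consistency ICC from the two-way ANOVA with subjects
  random and sessions fixed,
  `ICC(3,1) = (BMS − EMS) / (BMS + (k−1)·EMS)`, summarized per region by the
  median voxelwise ICC (mvICC) with the usual qualitative labels
  (Poor < 0.40 ≤ Fair < 0.60 ≤ Good < 0.75 ≤ Excellent).
- **Pipeline comparison**: Friedman rank tests over matched voxels (or
  subjects, for violation proportions) with Nemenyi all-pairs post-hocs.

## Worked example

```python
import boldretest as bt

config = bt.StudyConfig(
    simulation=bt.SimulationConfig(n_subjects=12),
    voxel_p=0.005, min_extent=5, seed=0,
)
results = bt.run_study(config, write_outputs=False)
print(results.mvicc_table.round(3))
print((100 * results.violation_table).round(1))
print(results.comparisons["icc"])
```

prints (abridged to the visual overlap ROI):

```
                         mvicc  n_voxels category
roi            pipeline
visual_overlap default   0.297       130     Poor
visual_overlap flexhrf   0.130       130     Poor
visual_overlap mcompcor  0.530       130     Fair
visual_overlap combined  0.475       130     Fair

                         normality  homoscedasticity  independence
visual_overlap default         6.4              52.4           9.7
               flexhrf         5.2              37.6           8.6
               mcompcor        4.8               6.3          11.5
               combined        5.5               5.5           5.4

Friedman test on icc (130 voxel blocks): chi2(3) = 326.95, p = 1.46e-70
mean ranks: default=2.07, flexhrf=1.05, mcompcor=3.72, combined=3.16
```

Reading this: the phantom injected a shared physiological confound and
per-subject/session HRF jitter on top of a true ICC of 0.5. The default
pipeline leaves the confound in the data — its residuals fail the
homoscedasticity check in 52% of voxel fits and its mvICC lands in the Poor
range (0.30). Adding the mCompCor regressor removes the confound: violations
drop to ~5–6% and reliability rises into the Fair range (0.53 / 0.48 for the
combined model), with the Friedman test confirming the pipelines differ. The
derivative bases alone (`flexhrf`) reduce heteroscedasticity failures but
pay a contrast-variance penalty, so their mvICC does not improve — see
`docs/methods.md` for why that is expected in a block design. One cohort's
mvICC carries sampling noise of ±0.1; direction claims in the test suite are
averaged over cohorts.

A command-line interface covers the same ground:

```bash
boldretest simulate --out phantom/ --subjects 12 --seed 0   # write NIfTI cohort
boldretest run-all  --out study/   --subjects 12 --seed 0   # full analysis
boldretest icc --data phantom/ --out study2/                # stage-wise, from disk
```

`load_real_inputs` runs the identical pipeline stages on any cohort laid out
as NIfTI runs + BIDS-style events TSV + 6-column motion text files.

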