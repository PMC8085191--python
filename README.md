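# pbifpet

Quantitative dynamic brain PET with reversible tracers (here modeled on a
TSPO neuroinflammation ligand) estimates the total volume of distribution
V_T by kinetic modeling against the arterial input function — the
metabolite-corrected tracer concentration in arterial plasma over time.
Arterial catheterization is invasive and a major workflow bottleneck, so a
long-standing alternative is the **population-based input function
(PBIF)**: average the peak-aligned, normalized input functions of a cohort
(leave-one-out), then rescale the average to a new individual using scalar
factors such as body weight, injected dose, or one or two late blood
samples.

`pbifpet` is a library + CLI for researchers who want to build and stress
test that workflow end to end:

* a **synthetic cohort generator** (healthy volunteers and Parkinson
  disease subjects, high- and mixed-affinity TSPO binder genotypes, known
  ground truth) emulating automated early arterial sampling at 15-s
  intervals, late manual draws, parent-fraction assays, and
  two-tissue-compartment regional TACs on the 32-frame / 90-min schedule;
* **input-function processing**: tri-exponential fitting of the blood
  curve, Hill-type parent-fraction fitting, metabolite correction,
  resampling onto a 1-s grid with the peak aligned to 30 s;
* **leave-one-out PBIF construction** under three normalization schemes
  (weight x dose, AUC, weight x AUC) with late-sample tail scaling on the
  60–90 min window and a pseudo-time-point screen;
* **Logan graphical analysis** with automatic linearity-onset (t*)
  selection by the maximum-admissible-error criterion and goodness-of-fit
  diagnostics (R^2, AIC, %SE of the slope);
* **agreement statistics**: Bland-Altman bias and limits of agreement,
  coefficient of repeatability, ICC, ANOVA across normalization schemes
  with Bonferroni-corrected pairwise t-tests, Shapiro-Wilk normality, and
  optional gray-matter normalization.

## The model

For a reversible tracer the Logan transform linearizes the kinetics: for
t ≥ t*,

    ∫₀ᵗ C(T) dT / C(t)  =  V_T · ∫₀ᵗ C_p(T) dT / C(t)  +  const,

where C is the (blood-volume-corrected) tissue TAC, C_p the
metabolite-corrected plasma input, and the slope is V_T.  Ground-truth
tissue curves come from the two-tissue-compartment model with rate
constants K1, k2, k3, k4, for which V_T = (K1/k2)(1 + k3/k4); the measured
PET signal mixes in 5% whole blood.  t* is the earliest frame after which
every Logan point deviates from the fitted line by at most 10% (relative
to the fitted value).

Agreement between paired estimates uses two percent-difference
conventions: test-retest differences are normalized by the pair mean,
D = (retest − test)/((retest + test)/2) × 100, while PBIF-vs-PSAIF
differences are referenced to the arterial gold standard,
D = (P_PBIF − P_PSAIF)/P_PSAIF × 100.  Limits of agreement are
bias ± 1.96·SD (the coverage factor is configurable).

## Worked example

```python
from pbifpet import CohortConfig, RunConfig, run_full

config = RunConfig(cohort=CohortConfig(seed=20210429), outdir="demo_run")
result = run_full(config)

region = "thalamus"
tr = result.testretest.set_index("region").loc[region]
print(f"test-retest ({region}): bias {tr.mean_bias:+.2f}% +/- {tr.sd:.2f}, "
      f"LOA [{tr.loa_low:.2f}, {tr.loa_high:.2f}], ICC {tr.icc:.2f} (n={tr.n:.0f})")

pa = result.pbif_agreement["weight-auc"].set_index("region").loc[region]
print(f"PBIF vs PSAIF, weight x AUC ({region}): bias {pa.mean_bias:+.2f}% +/- {pa.sd:.2f}, "
      f"LOA [{pa.loa_low:.2f}, {pa.loa_high:.2f}] (n={pa.n:.0f})")

row = result.logan.query(
    "subject_id=='S01' and session=='test' and region=='thalamus' and if_source=='PSAIF'"
).iloc[0]
print(f"S01 thalamus (PSAIF): V_T {row.VT:.2f}, t* {row.t_star_min:.0f} min, R2 {row.R2:.4f}")
```

prints

```
test-retest (thalamus): bias +28.12% +/- 15.24, LOA [-1.74, 57.98], ICC 0.80 (n=5)
PBIF vs PSAIF, weight x AUC (thalamus): bias +4.59% +/- 25.05, LOA [-44.52, 53.69] (n=23)
S01 thalamus (PSAIF): V_T 2.07, t* 20 min, R2 0.9994
```

Reading: same-day test-retest with full arterial sampling carries a
systematic ~28% retest increase with limits of agreement spanning about
±30% around it — that is the repeatability floor any surrogate input
function has to be judged against.  Replacing the arterial curve with the
leave-one-out population curve (weight x AUC normalization, tail-scaled on
the 60–90 min samples) biases thalamic V_T by only +4.6%, well inside the
test-retest limits, which is the acceptance logic for declaring the PBIF a
usable substitute.  The last line shows one regional Logan fit: the plot
becomes linear at 20 min and the slope (V_T) is estimated with R² > 0.999.

The same workflow is scriptable from the shell:

```bash
pbifpet simulate --config examples/run_config.yaml --out demo_bundle
pbifpet validate demo_bundle
pbifpet run-full --config examples/run_config.yaml --out demo_run
```

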