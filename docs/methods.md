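# Methods

## Tracer kinetics model

The simulator describes Tc-99m mebrofenin with three compartments —
blood pool, hepatocytes, bile — and total activity normalised to 1 at
injection:

```
blood(t) = f + (1 − f) · exp(−k_upt · t)
liver′(t) = k_upt · (1 − f) · exp(−k_upt · t) − k_exc · liver(t) · 1[t > t_lag]
bile(t)  = 1 − blood(t) − liver(t)
```

`k_upt` (1/min) is the hepatic extraction rate, `f` the fraction of
dose never available for hepatic uptake (competing protein binding and
the renal route), `k_exc` (1/min) the canalicular excretion rate, and
`t_lag` (s) a hard onset delay for biliary excretion: hepatocytes
accumulate tracer for several minutes before canalicular transport
produces measurable biliary activity, which is why the 150–350 s
window shows pure uptake. A hard lag is the simplest mechanism that
reproduces this uptake-then-excretion shape, and it gives the system a
closed-form solution (piecewise exponentials, with the `k_upt = k_exc`
degeneracy handled by the limiting form), so no ODE integrator is
involved and conservation holds to machine precision.

**Default constants** — `k_upt = 0.13/min`, `f = 0.10`,
`t_lag = 400 s`, `k_exc = 0.10/min`, dose 200 MBq. These are
*synthetic*, not patient-derived: no published kinetic constants
accompany the clinical protocol this package targets. They were chosen
once so that the rendered studies land in the clinically reported
ranges (TL-F ≈ 8 %/min, TL-U ≈ 48 % at 350 s, hepatic peak just after
the 360 s dynamic phase, when the SPECT snapshot is taken). Because
blood + liver + bile must sum to 1, the model cannot independently
match every published median (e.g. a 50 % liver share forces a large
residual blood pool and hence a somewhat lower uptake-rate estimate
than the typical clinical 10–11 %/min); the defaults favour a correct
TL-U scale and a physically consistent blood curve.

## Rendering

Expected pixel counts are
`dose · sensitivity · frame_dur · activity(t_mid) · spatial_weight · µ_view`.
Blood-pool activity is spread uniformly over the blood-pool mask;
hepatic and biliary activity follow the phantom's `function_density`
(bile remains within the hepatobiliary silhouette — during the
dynamic phase it is zero anyway under the default lag). Attenuation is
a scalar per view (anterior 0.85, posterior 0.65 — the posterior view
sees the spine), which is exactly the situation the geometric mean
corrects: the Gmean image carries the view-independent factor
`sqrt(µ_ant · µ_post)`. The posterior view is emitted left-right
mirrored, as a rear camera head produces it; the consumer un-mirrors
it (`gmean_pixel(mirror_posterior=True)`, the default). The default
system sensitivity (250 counts/MBq/s) puts ≈2·10⁵ counts per frame in
the liver at peak, a realistic clinical count level. Poisson noise is
sampled from a `numpy` generator seeded explicitly per acquisition;
the seed is written into the output metadata, and identical seeds give
bit-identical data.

The SPECT volume is emitted as an already-reconstructed count volume
proportional to `liver(t_spect) · function_density`; projection and
tomographic reconstruction are out of scope, since the quantification
consumes reconstructed counts only. Not modelled anywhere: scatter,
collimator response, partial-volume effects, patient motion,
radioactive decay (Tc-99m decays < 1.2 % over the 360 s study; a
decay-correction switch exists in the config but defaults off).

## Estimators

**TL-F.** The uptake-rate estimator is the two-point form: the change
of the liver's fractional FOV share across the window, divided by the
time integral of the blood-pool curve normalised at the window start
(trapezoid rule; linear interpolation where 150/350 s fall between
frame mid-times; frame *mid*-times are the curve abscissa to keep
10 s frames unbiased for slope-type quantities). Several variants of
this clearance estimator circulate in the HBS literature; a
least-squares slope variant (`estimator="slope"`) is provided for
sensitivity analyses. Both are invariant to rescaling all curves by a
common factor (dose/sensitivity invariance). Negative TL-F, possible
under extreme noise, is flagged with a warning but never clamped.

**TL-U** is defined at the window end (350 s) by default; a
window-mean variant is available since the literature is not explicit
about the evaluation time. By convention TL-U uses ROI-ROI Gmean
curves and TL-F pixel-pixel Gmean curves — the pipeline wires these
modes by default and each is configurable. The blood-pool curve is
taken from the Gmean pathway in both modes.

**FLR-C** is a plain count ratio of the FLR VOI to the whole-liver VOI
on the SPECT volume (extrahepatic structures excluded by the VOI
definition). Noise-free it equals the phantom's function mass in the
FLR exactly; with Poisson noise it is a binomial proportion of the
liver count total, so its standard error at ≥10⁶ liver counts is
< 0.001.

## Outcome grading

ISGLS PHLF requires simultaneously elevated INR and bilirubin on some
postoperative day ≥ 5; severity is the management consequence
(A: none, B: noninvasive deviation, C: invasive procedure), evaluated
on the worst qualifying day. Upper normal limits are
institution-specific and therefore configuration values (defaults
INR > 1.2, bilirubin > 20.5 µmol/L). The 50–50 criteria are strict
inequalities on day 5 exactly (PT < 50 %, bilirubin > 50 µmol/L); when
both PT and INR are present, ISGLS uses INR and 50–50 uses PT, as each
criterion specifies. Bilirubin in mg/dL is converted on ingest
(× 17.104).

## Cohort statistics

The AUC is computed by midranks (Mann–Whitney probability, ties
counted half) and its confidence interval by the DeLong structural
components estimator; the package's AUC is cross-checked in the tests
against exhaustive positive×negative pair counting. Cutoffs are
searched on the midpoint grid between adjacent distinct scores plus
one candidate beyond each extreme, maximising Se + Sp with
deterministic tie-breaking (larger LR+, then smaller LR−, then smaller
cutoff). The positive test direction is `score ≤ cutoff`, inclusive —
low function predicts failure — and configurable. Quartiles use linear
interpolation (type 7), stated explicitly because IQR conventions
differ between packages. Reported percentages are rounded only at the
reporting layer; all internal values are full precision.

## Synthetic cohorts and the reference cohort

`generate_cohort` samples demographics (height/weight → DuBois BSA →
Vauthey sTLV), an FLR volumetric share (log-normal, median 0.35), a
functional share FLR-C that tracks the volumetric share with
log-normal scatter (producing the volume–function correlation seen
clinically), and global function TL-F/TL-U at normal-liver levels. The
PHLF grade is drawn from an ordinal-logistic model in the true FLR-F
with slope 2.5 per %/min/m²; the intercepts (4.95, 2.50) were
calibrated once against the generator's FLR-F distribution to yield
≈47 % any-grade and ≈16 % grade-B PHLF, typical of high-risk
major-hepatectomy series. Day-5 labs are then drawn from
grade-conditional ranges chosen so the ISGLS grader recovers the
sampled grade exactly, and so that most — not all — grade-B patients
also meet the 50–50 criteria.

`reference_cohort` is different in kind: a deterministic, synthetic
patient-level reconstruction of a published 38-patient diagnostic
structure (6 grade B / 12 grade A / 20 no-PHLF, FLR-F stratified at
1.59 / 1.85 / 2.79 %/min/m², four 50–50-positive patients). Only the
stratum memberships are informative; the individual score values
within a stratum are arbitrary placeholders. It exists so the
diagnostic-table code can be exercised against known printed metrics.

**What passing tests do and do not show.** The simulator has ideal
geometry, scalar attenuation and pure Poisson statistics; recovery of
TL-F to < 5 % median error there demonstrates the correctness of the
estimator chain, not its accuracy on real scanners, where scatter,
reconstruction artefacts and ROI placement dominate the error budget.
Patient-level medians, correlations and AUCs from any real cohort are
not reproducible from code and are not claimed.

## Problem sizes and determinism

Simulation-based checks use a 64×64 planar matrix, a 32×40×40 SPECT
grid and 200 seeded replicates — count levels per region are kept at
clinical scale (sensitivity unchanged), so the noise regime matches a
128 matrix study while the suite runs in seconds. All stochastic
stages take explicit integer seeds; the acceptance script derives
per-replicate seeds from its single `--seed` via `SeedSequence`.

## Known limitations

- The three-compartment closed form cannot represent intra-hepatic
  heterogeneity of kinetics; regional function enters only through the
  static `function_density`.
- The 50–50 criteria need PT; cohorts carrying only INR cannot
  evaluate that endpoint.
- `select_cutoff` returns midpoints, so on small cohorts the numeric
  cutoff differs from a published cutoff even when the induced
  classification is identical.
- DeLong intervals are asymptotic and clipped to [0, 1]; at n ≈ 38
  with AUC near 1 they are known to be anti-conservative.
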