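# Methods

## Scope and units

`theradose` computes internal dosimetry for preclinical biodistribution
studies of radiolabeled antibodies. All times are hours, activities MBq,
masses grams, doses mGy/MBq; unit conversions happen only at I/O
boundaries. Nuclide constants (half-life, mean electron and photon
energy per decay) ship in a CSV catalog with Cu-64 (T½ = 12.7006 h,
Ē_e = 0.121 MeV) and Lu-177 (T½ = 159.46 h, Ē_e = 0.147 MeV) entries
following the ICRP-107 compilation; because decay-data compilations
differ at the sub-percent level, the catalog is user-replaceable and no
constant is hard-coded elsewhere.

## From %IA/g to normalized activity

Gamma-counter biodistribution data arrive as %IA/g, conventionally
decay-corrected to injection time; the `decay_corrected` flag records
the convention and can be flipped for labs reporting raw values. Organ
normalized activity is nA = (%IA/g/100) × organ mass. The rest-of-body
source region uses the muscle concentration as representative background
uptake: nA_rob = (mouse mass − Σ source organ masses) × c_muscle.
Organs measured without a mass (blood, bone, the muscle sample itself)
contribute to uptake-ratio reporting but not to TIACs or doses. The
heart measurement is treated as a single blood-bearing source without
wall/content separation.

## Curve fitting

Fitting operates on *uncorrected* activities (physical decay re-applied
via exp(−λ_p t)), so the fitted rate is the effective constant
λ_eff = λ_bio + λ_p. This is the representation under which the
integration rule's comparison of λ_eff with λ_p is meaningful: λ_eff
below λ_p means the biological uptake is still rising.

The default objective is unweighted least squares on log-transformed
activities (log-linear regression): deterministic, needing no starting
values, and exact for two points. A nonlinear least-squares option on
the natural scale (`scale="linear"`, initialized from the log fit) is
provided because kinetic modules of dosimetry packages differ on this
point; with three nearly monoexponential time points the two differ by
well under the measurement uncertainty. Neither variant weights by the
group SDs — the SD enters through the envelope instead.

## TIAC integration

For λ_eff > λ_p the monoexponential integrates analytically to
infinity: TIAC = A₀/λ_eff. Otherwise extrapolating a slower-than-decay
curve to infinity would be unphysical (it implies unbounded biological
retention); the curve is integrated only to the last measurement t_last
and a pure physical-decay tail is attached:

    TIAC = A₀(1 − e^(−λ_eff t_last))/λ_eff + A₀ e^(−λ_eff t_last)/λ_p.

The first term uses the analytic limit A₀·t_last as λ_eff → 0 (switch at
|λ_eff·t_last| < 1e-12) and the same closed form remains valid for
negative λ_eff (net accumulation — tumor and uterus in practice). The
rule is continuous at λ_eff = λ_p, where both branches give A₀/λ_p, and
is verified in the tests against adaptive quadrature of the piecewise
curve.

The mean ± SD envelope re-runs fit + integration on the mean, mean+SD
and mean−SD series. It is a sensitivity band, not a confidence interval,
and is reported as such. When a mean−SD value is non-positive the bound
is reported as NaN with a warning rather than aborting the organ.

## Cross-radionuclide extrapolation

When the same conjugate is labeled with a different radionuclide and the
biology is assumed identical, uncorrected activities transfer via
SF(t) = e^(−λ_p,dest t)/e^(−λ_p,src t) applied per time point, followed
by a fresh fit and integration under the destination nuclide's λ_p. The
operation is exactly invertible (dest→src restores the input to machine
precision) and rejects decay-corrected input, for which the factor is
meaningless. Note the known limitation: for tissues whose uptake is
still rising at the last sample, extrapolating a long-lived nuclide's
tail from short-lived-nuclide data inflates the TIAC — the conditional
rule bounds but does not remove this.

## Absorbed dose

Sphere self-dose (tissues absent from a phantom: tumor, uterus,
ovaries) assumes local deposition of all electron/positron energy
(absorbed fraction φ = 1):

    D [mGy/MBq] = TIAC · 3.6e9 · Ē_e[MeV] · 1.602e-13 / (m·1e-3) · 1e3.

For sub-gram spheres the true electron absorbed fraction is below but
near 1, so the model overestimates by a small positive margin (≤15% in
the regression checks); `absorbed_fraction` is a hook for supplying
mass-dependent φ tables. Photon self-dose is neglected (sub-percent at
these masses). Phantom-organ doses require an S-value matrix file
(source, target, mGy per MBq·h), taken as already mass-adjusted; the
dose is the source-by-target double sum, with sphere-modelled tissues
folded into the remainder source first. No phantom S-values are bundled:
without a matrix the output is restricted to sphere-model tissues and
flagged as self-dose-only.

Reported tables carry full-precision columns plus display columns
rounded to 3 significant figures (doses/TIACs) or the nearest integer
(percent difference ratios); downstream arithmetic always uses the
full-precision columns.

## Synthetic studies

The generator emulates a destructive-sampling design: groups of mice per
time point, default 3 time points at 4.3/26.0/50.2 h, 3 mice per point,
11 source organs plus muscle and remainder, 17.8 g mouse. Organ kinetics
are washout (A·e^(−λ_bio t), λ_bio < 0 allowed for accumulation) or
uptake-washout (A(e^(−λ_bio t) − e^(−λ_up t))); defaults place the
noiseless %IA/g values where an anti-tumor antibody sits (liver ~16%IA/g
early with slow clearance, tumor peaking ~24 %IA/g near one day, muscle
~3 %IA/g). Measurement noise is multiplicative lognormal with mean 1 and
configurable CV (default 10%) — lognormal keeps activities positive; the
seed is mandatory.

The truth record stores each organ's analytic TIAC two ways: the 0→∞
integral of the generating curve (including physical decay), and — for
washout organs, where the monoexponential fit of noiseless data is exact
— the value the conditional rule returns for the exact parameters. The
latter is the right oracle for pipeline-recovery tests on accumulating
organs, where the rule intentionally deviates from the infinite
integral. Uptake-washout organs are not monoexponential, so the fitted
TIAC carries a small model bias (<5% at the default sampling).

What the generator does not emulate: inter-mouse covariance, tumor
growth over the study, counting statistics or background, blood/bone
compartments. Passing tests therefore demonstrate correctness of the
arithmetic and estimation chain under the stated noise model, not
robustness to every feature of real animal data.

## Problem sizes in the test suite

The property tests run a few hundred randomized instances per invariant;
the noisy-recovery check uses 200 replicate studies at CV 10% with 4
mice per time point (median organ-level TIAC error below 15%). The whole
suite completes in a few seconds on one core.

## Known limitations

- Monoexponential kinetics only; no compartmental or multi-exponential
  fitting, no Bayesian uncertainty.
- The mean±SD envelope understates uncertainty when fits are poor.
- Local deposition is an upper bound; supply absorbed-fraction tables or
  an S-matrix for tighter dose estimates.
- No human extrapolation; mouse-scale only.
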