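# Methods

## NM-MRI contrast quantification

An `ImageVolume` is a slice-first 3D grid with physical voxel sizes; the
default synthetic geometry uses the in-plane resolution of a 220 mm FOV /
512 matrix acquisition (≈ 0.4297 mm/pixel) with 3 mm slices.  A circular ROI
of area A mm² has radius √(A/π); a pixel belongs to the ROI iff its center
lies *strictly* inside the disc.  This rule is deterministic,
resolution-independent (the radius is computed in mm and tested per pixel)
and trivially matched by a brute-force enumeration oracle, at the cost of a
small discretization of the nominal area (a 2 mm² LC ROI covers 9 pixels at
the default resolution).  ROI standard deviations use the n−1 denominator so
CNR values are reproducible bit-exactly.

LC localization is an exhaustive grid search over pixel-center disc
placements within a per-side search box on three contiguous slices,
maximizing mean intensity; ties are broken by the lexicographically smallest
(row, col) center so the result is deterministic on flat inputs.  A disc must
fit entirely inside the search box.

CNR_LC uses one pontine-tegmentum reference per (session, slice) and CNR_SN
one cerebral-peduncle reference per (session, side); duplicated reference
values are accepted since protocols differ on whether references are redrawn.
Aggregates are plain arithmetic means over all per-measurement CNRs
(3 slices × 2 sides × sessions for LC; 3 subregions × 2 sides × sessions for
SN).  Bilateral SN averaging is unconditional.

Intra-rater reliability is the absolute-agreement single-measure ICC
computed from the two-way ANOVA mean squares,
ICC = (MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n) with k = 2 sessions.
The agreement (rather than consistency) form is the default because repeated
assessments by one rater should agree in level, not merely rank; the choice
is isolated in one function and easily swapped.

## BOLD conditioning

The chain order is fixed: drop → detrend → confound regression → band-pass.
All steps are node-wise independent, so they commute with node permutation.
The band-pass is an ideal rectangular DFT mask retaining |f| ∈ [0.04, 0.07]
Hz inclusive and zeroing everything else including DC: it is zero-phase,
idempotent, and introduces no order/ripple parameters.  An IIR design would
need those parameters and would distort phase; the DFT mask matches the
convention of resting-state toolchains that filter in the frequency domain.

Framewise displacement follows Jenkinson's RMS formulation: for the relative
rigid transform between consecutive volumes, decomposed as matrix residual
A = M − I and translation b, FD = √((1/5)R²·tr(AᵀA) + bᵀb), which is exactly
the RMS displacement of a point uniform in a solid sphere of radius R.  R is
fixed at the standard 80 mm.  Rotation matrices compose as Rx·Ry·Rz; the FD
of small motions is insensitive to this convention, and the sphere-sampling
oracle in the tests uses the same affines, so the check is
convention-independent.  The subject-level summary is the *mean* FD over
volumes (a `threshold` on mean FD is the common reading of a subject-level
"> 0.2 mm" exclusion); exclusion is strict, so a subject exactly at the
threshold is kept.  The 24-parameter motion expansion is the Friston set
[p, p₋₁, p², p₋₁²].

## Phase synchronization

Instantaneous phase is the four-quadrant angle of the analytic signal
s + iH[s], computed with the one-sided-spectrum discrete Hilbert transform
(half-weight at DC and, for even lengths, Nyquist).  The two-quadrant
arctan(H[s]/s) form loses the sign of s and cannot produce a continuous
phase; the four-quadrant angle is the standard resolution.  Phases are
wrapped to (−π, π]; unwrapping happens only inside tests.  Ten points are
trimmed from each end before the order parameter is taken (195 → 175 in the
reference configuration), because the DFT-based transform wraps around the
record ends.  The order parameter r(t) = (1/n)|Σ e^{iθ_j}| is bounded in
[0, 1], invariant to a common time-varying phase offset and to node
permutation; for n independent uniform phases E[r²] = 1/n exactly, which the
tests verify by Monte-Carlo at n = 33.

## Synthetic data

*Phantoms.*  Regions are painted as discs of the protocol ROI areas at
planted mean intensities over a uniform background, plus i.i.d. Gaussian
noise; the default grid is 3 slices of 96 × 96 pixels, enough to contain the
brainstem ROI geometry with realistic pixel counts (9 px LC, 109 px PT).
What this emulates: planted contrast, reference-region noise, repeated
assessments.  What it does not: field inhomogeneity, partial-volume edges,
anatomy-dependent placement ambiguity — so a passing localization test says
the search is correct, not that LC delineation on real scans is easy.  The
end-to-end CNR estimate has a small positive bias of order 3/(4·n_PT) from
the reciprocal of the sampled reference SD (~0.7% at 109 reference pixels),
well inside the 2% Monte-Carlo tolerance and shrinking with ROI size.

*Oscillators.*  The generative model is the mean-field Kuramoto system
dθ_j/dt = ω_j + (K/n)Σ_k sin(θ_k − θ_j), observed as sin θ_j + Gaussian
noise (SD 0.05 by default).  The sine observation — not the raw phases —
forces the pipeline's own Hilbert step to recover the phases, testing the
whole chain.  Natural frequencies are uniform in 0.04–0.07 Hz so the
band-pass is transparent to the signal and recovery tests isolate synchrony
estimation from filter distortion.  Integration is forward Euler at
sampling_interval/20 (0.1 s at TR = 2 s): at these frequencies the phase
advances ≲ 0.044 rad per substep, where Euler error is negligible; a
pairwise-sum reference integrator in the tests confirms the mean-field
shortcut.  With the default frequency spread the critical coupling is
K_c ≈ 0.12, so K = 0.1 is subcritical (⟨r⟩ ≈ 0.45) and K ≥ 0.5 is strongly
synchronized; seed-averaged ⟨r(t)⟩ is monotone in K over {0, 0.5, 1, 2, 4}.

*Cohorts.*  Covariates (age ~ N(61, 8²) years, medication duration
~ |N(4, 2.5²)| years, LEDD ~ N(450, 180²) mg clipped at 50) are standardized
internally; outcome residual innovations are jointly Gaussian with
corr(e_CNR, e_rate) = target_r (default 0.42, the reference effect size at
n = 57) and corr(e_CNR, e_syncrate) = target_r_sync (default −0.32), so the
population partial correlation after covariate removal equals the target
exactly.  UPDRS-III ON is derived as OFF·(1 − rate) so the rate of change is
reproduced exactly and scores stay non-negative; rates are truncated at 0.95
in the (vanishingly rare) upper tail.  CNR_SN gets covariate effects but an
independent innovation, so it is a true null predictor for the stepwise
model.  Between-subject variances of the synchrony values are free choices
(sync_OFF ~ N(0.55, 0.06²)); no published per-subject dispersion exists to
match, so absolute cohort-level sync numbers should not be over-interpreted.

## Inference

Partial correlation residualizes both variables on [1, covariates] by least
squares and takes the Pearson correlation of the residuals, with
p from t = r√(df/(1 − r²)), df = n − 2 − p_cov, two-sided.  Collinear
covariate columns are dropped with a warning.  With no covariates it reduces
to plain Pearson to machine precision, and it is invariant under invertible
affine maps of the covariate block.

Stepwise regression standardizes response and candidates, then alternates a
forward step (admit the candidate with the smallest partial-F p value if
≤ p_enter) with backward elimination (drop the retained predictor with the
largest p while it exceeds p_remove).  Defaults p_enter = 0.05,
p_remove = 0.10 follow the common convention of commercial statistics
packages; both are arguments.  With p_enter = p_remove = 1 the procedure
retains everything and equals full OLS.  Under a global null with five
candidates, the family entry rate is 1 − (1 − p_enter)⁵ ≈ 0.23, and with one
planted effect among five candidates the *exact* recovery rate is
≈ (1 − p_enter)⁴ ≈ 0.81 — chance co-entry of a null candidate is a property
of the procedure, not a defect.  Group comparisons use the pooled-variance
two-sample t test (continuous variables) and Pearson's chi-squared without
continuity correction (sex); both wrap scipy.  No multiple-testing
correction is applied; the cohort report counts the tests it ran.

The cohort report hard-codes the analysis pairings: CNR_LC/CNR_SN vs
UPDRS-III OFF and ON with age as covariate; CNR_LC/CNR_SN vs the rates of
change, and UPDRS rate vs sync rate, with age, medication duration and LEDD
as covariates; and the stepwise model of the UPDRS rate on CNR_LC, CNR_SN,
age, duration and LEDD.

## Problem sizes and determinism

The test suite and the acceptance script run the Monte-Carlo checks at 1000
phantoms (CNR recovery), 100 phantoms (localization), 10⁵ draws (null r²),
50 seeds per coupling (monotonicity), 500–1000 cohort replicates (partial-r
recovery, null entry rates) — sizes at which the binomial/standard-error
tolerances quoted in the tests are meaningful while the whole suite runs in
well under a minute per file.  Every generator takes an explicit integer
seed and uses a local `numpy.random.Generator`; nothing touches global
random state, so identical seeds give bit-identical outputs.

## Known limitations

- The ROI protocol assumes the operator-supplied search regions bracket the
  true LC; there is no automated brainstem segmentation.
- The ideal DFT band-pass assumes the record is representative of the
  process (implicit periodic extension); border effects are handled by the
  downstream trim, not by tapering.
- The phase measure is a single global order parameter; no time-resolved
  states or pairwise phase-locking structure.
- The cohort generator plants linear Gaussian relationships; it cannot probe
  robustness to outliers, floor effects in UPDRS scores, or non-linear
  dose–response structure.
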