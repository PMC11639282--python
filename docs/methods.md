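# Methods

## State space and master equation

One catalytic centre is described by a conformation (E_LS or E_HS) and the
isotope label (¹⁶O or ¹⁸O) of its slow and fast substrate-water sites —
eight states, indexed `4·conf + 2·slow + fast` (LS=0/HS=1, ¹⁶O=0/¹⁸O=1);
the indexing is fixed so serialized states are portable. The dynamics are a
continuous-time Markov chain: a site with exchange rate k acquires ¹⁸O at
k·α and loses it at k·(1−α), where α is the bulk ¹⁸O enrichment;
conformational conversion (k_c2 forward, k_c1 back) preserves the labels.
No transition changes two coordinates at once.

After the injection is reduced to a time shift (below), the bulk enrichment
is constant and the generator is time-independent, so the matrix
exponential propagates populations exactly; `propagate` is therefore the
normative backend. For repeated evaluation over many time points
(`propagate_times`) the generator is diagonalized once and
exp(Gt)p₀ = V e^{Λt} V⁻¹p₀ evaluated vectorized; if the eigenvector matrix
is ill conditioned (condition number above 1e8, e.g. near eigenvalue
degeneracies) the code falls back to one matrix exponential per time
point. An adaptive stiff ODE integration of the same generator serves as
an independent oracle in the tests only — the two routes agree to better
than 1e-10 in the yields.

Numerical tolerances: population sums are conserved to 1e-12 and tiny
negative populations from round-off are clipped at 0; both choices reflect
double precision on an 8-state system. When k_c1 = k_c2 = 0 the
conformational split is undefined and must be supplied explicitly —
assuming 50/50 silently would fabricate physics.

## Initial state and yields

At time zero the LS/HS equilibrium (HS fraction k_c2/(k_c1+k_c2)) is
assumed already established, and each site independently carries ¹⁸O with
probability α_in. Whether that equilibrium assumption also holds for long
incubations — where the labelled water is injected soon after the flash
that forms S₂ — is an open experimental question; the equilibrium-at-t₀
assumption is adopted uniformly here.

Yields are reported plateau-normalized by default: ³⁶Y = P(both ¹⁸O)/α_f²
and ³⁴Y = P(exactly one ¹⁸O)/(2α_f(1−α_f)), so both approach 1 at isotopic
equilibrium. Raw isotopologue probabilities are available behind
`normalized=False`.

## Eigen-structure

The yields are linear functionals of exp(Gt)p₀ and hence sums of
exponentials in the eigenvalues of G. The slow-site × conformation
marginal is itself autonomous (conversion is label-blind), which gives the
exact closed form for the slow pair λ₃± quoted in the README; the same
expression with the fast-site rates substituted matches another eigenvalue
pair of the full spectrum. That fast-pair correspondence is a numerical
hypothesis of this package, verified over 50 random rate sets to 1e-9
relative, not a transcribed derivation. The pure conformational relaxation
−(k_c1+k_c2) also appears in the spectrum.

Pre-exponential coefficients are computed by eigen-projection (project p₀
onto right eigenvectors, the yield functionals onto the same basis) rather
than by transcribing symbolic coefficient expressions. The structural
claim that the initial-enrichment correction enters the coefficients only
through q = 1 − α_in/α_f (linearly and quadratically) is checked by a test
showing the yields at fixed time are exactly quadratic polynomials in
α_in. Eigenvalue pairs are classified by nearest match to the closed
forms; when two targets compete for eigenvalues closer than 1e-6 relative
the system is flagged kinetically unresolvable — the regime where the
phases are not visually separable in data either.

One bookkeeping note: with all six rates positive the chain is irreducible,
so the spectrum is one zero eigenvalue (the plateau) plus seven decay
modes; per yield channel the constant term plus exponentials is what an
experimenter counts as "the exponential terms".

## Measurement corrections

Three instrumental effects are modelled; all are applied by default.

* **Initial enrichment** (α_in, default 0.007): bulk water carries ~0.7 %
  ¹⁸O before injection from natural abundance and syringe leakage. Enters
  through the initial state. Shifts curves to earlier times.
* **Non-instant injection** (t_m, default 6 ms): the enrichment ramps
  approximately linearly to α_f. For one site the piecewise solution is
  exact and, past the ramp, identical to the instant-mixing solution
  delayed by t_k = ln((e^{kt_m}−1)/(kt_m))/k; t_k → t_m/2 as k → 0
  (evaluated by series below k·t_m = 1e-4 for continuity) and rises above
  3.3 ms only for k ≳ 200 s⁻¹. Because the multi-site solution with
  time-dependent α has no closed form, the full model applies a fixed
  t_k = 3 ms shift, with incubation times clamped at zero (data never
  precede injection). A rate-derived per-curve shift (t_k evaluated at a
  caller-chosen k) is available behind `MixingSpec(shift_rate=...)` but off
  by default, since t_k stays near 3 ms over the relevant rates. Shifts
  curves to later times.
* **S₃ carryover** (default 10 ms at k_f = 19.5, k_s = 0.25 s⁻¹): between
  the last two flashes the sample sits in S₃ and keeps exchanging. The
  end-of-incubation populations are propagated for the extra duration
  under a generator whose site rates are the S₃ values in both
  conformations, assuming the fast/slow site identity carries over from
  S₂. Conformational interconversion is left active during the interval:
  its effect is bounded by k_c·0.01 and retaining it avoids a second
  special-case generator. Shifts curves to earlier times.

The enrichment and S₃ corrections push yields up at fixed time, the mixing
shift pushes them down; applied together they largely cancel (the combined
effect is smaller than the largest single effect on every bundled
parameter set).

## Empirical models

The traditional analysis treats the sites as independent exchangers:
³⁴Y = a(1−e^{−k_f t}) + (1−a)(1−e^{−k_s t}), ³⁶Y = 1−e^{−k_s t}, with the
fast amplitude fixed by the enrichments,
a = [α_f(1−α_in) + α_in(1−α_f)]/(2α_f(1−α_f)); a is fixed to that value by
default and can be freed by flag. When both conformations are populated an
intermediate phase with amplitude b appears in the slow bracket of both
channels. b reflects the conformational equilibrium but is left free by
default — constraining it to k_c2/(k_c1+k_c2) would presuppose the very
interpretation under test. A fitted k_f/k_s below 10 triggers an
ill-conditioning warning, since the biexponential decomposition assumes
k_f ≫ k_s. In the fast-conversion regime the two slow phases recovered by
the tri-exponential fit are the λ₃ eigenvalues, not the bare rate
constants; the tests demonstrate this to ≲0.1 % when the fast phases are
two decades above the slow pair, and the bias that appears when the
separation shrinks to a factor of a few is itself physically meaningful
(the fast eigen-modes no longer cancel within the slow window).

## Fitting and uncertainties

The objective is the summed squared residual over both channels, weighted
by per-point σ when supplied and unweighted otherwise (the original
experimental weighting is not public, so absolute chi² values are
comparable only between fits of the same data). The model is multimodal by
construction — the package's central point is that two distinct parameter
sets can fit one dataset equally well — so fits run bounded trust-region
least squares from the user's guess plus n_starts−1 log-uniformly
scattered starts (default 8, seeded); every start's outcome is kept in the
diagnostics. Default bounds are [1e-4, 1e4] s⁻¹ for rates and [0, 1] for
amplitudes.

Bootstrap errors use case resampling of (t, ³⁴Y, ³⁶Y) triplets (residual
resampling behind a flag), refitting each replicate from the point
estimate, and report 68 % percentile half-widths to mirror the ± convention
of published tables; whether published ± values are 68 % or 95 % intervals
is unstated, and 68 % is adopted here. Runs are bit-reproducible given the
seed; more than 20 % non-converged replicates raises an error.

## Synthetic data

`generate_synthetic` emulates a TR-MIMS experiment: 30 log-spaced
incubation times from 0.01 s to 100 s (the instrumental window between the
mixing dead time and substrate depletion), fully corrected yields, and
i.i.d. Gaussian noise (default σ = 0.02 per channel, matching the visual
scatter of published exchange data) added without clipping, since measured
normalized yields can stray outside [0, 1]. What it does not emulate:
time-correlated drift, channel-dependent or signal-dependent noise,
normalization uncertainty of the plateau, and flash-to-flash S-state
inhomogeneity (misses/double hits). Consequently parameter-recovery and
bootstrap results on synthetic data characterize the estimator under ideal
noise: recovered bootstrap intervals are narrower (by roughly a factor
2–3 for k_s2) than uncertainties published from experimental data, and
passing recovery tests bound the method's, not the instrument's, error.

## File formats and configuration

Exchange curves are plain comma-separated text (`time_s,y34,y36`, optional
`sigma34,sigma36`, `#` comments), times in seconds, yields pre-normalized
to plateau 1 — the normalization procedure applied to raw ion currents is
upstream of this package. Parse errors name the offending line. Presets
ship point estimates only; printed uncertainties are metadata and never
act as priors. The CLI logs package version, seed and a configuration hash
into every output header; output paths are excluded from the hash so
identical runs produce identical files.

## Known limitations

* The injection correction is a global time shift, not a per-site solution
  of the time-dependent-α master equation.
* The S₃ carryover uses a single fast/slow rate pair for both
  conformations; conformation-specific S₃ rates are not resolved by
  experiment.
* Only two conformations and two sites are representable.
* Absolute chi² values depend on the (unpublished) experimental weighting
  convention and should not be compared across datasets.
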