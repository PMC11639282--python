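# s2wex — substrate-water exchange kinetics for photosystem II

`s2wex` simulates and fits time-resolved membrane-inlet mass-spectrometry
(TR-MIMS) substrate-water exchange experiments on the S₂ state of the
oxygen-evolving complex of photosystem II. It is aimed at researchers who
measure ¹⁶O/¹⁸O isotope exchange of the two substrate waters — a
fast-exchanging site W_f and a slowly exchanging site W_s — and need to
decide which kinetic interpretation their data support.

## The model

The S₂-state cluster is modelled as two interconverting conformations, a
low-spin form E_LS and a high-spin form E_HS, each with two exchange sites.
With labels ¹⁶O/¹⁸O per site this gives an 8-state continuous-time Markov
chain governed by six rate constants (all s⁻¹): site-exchange rates k_f1,
k_s1 (in E_LS) and k_f2, k_s2 (in E_HS), and conversion rates k_c2
(E_LS → E_HS) and k_c1 (E_HS → E_LS). Exchange with bulk water of ¹⁸O
enrichment α replaces ¹⁶O at rate k·α and ¹⁸O at rate k·(1−α); the
normalized single- and double-labelled O₂ yields are

    ³⁴Y(t) = P(exactly one ¹⁸O) / (2 α_f (1−α_f)),
    ³⁶Y(t) = P(both ¹⁸O) / α_f².

Both are finite sums of exponentials in the eigenvalues of the generator.
The slow eigenvalue pair has the exact closed form

    λ₃± = ½ [ −(k_s1 + k_s2 + k_c1 + k_c2)
              ± √((−k_s1 + k_s2 + k_c1 − k_c2)² + 4 k_c1 k_c2) ],

whose approximation limits distinguish two physical readings of the slow
³⁶Y phase: slow-site exchange in E_LS (λ₃⁺ ≈ −k_s1, valid when conversion
is slow) versus the E_LS → E_HS conversion itself (λ₃⁺ ≈ −k_c2, valid when
E_LS is exchange-inert). Three measurement corrections are built in:
non-zero initial enrichment (~0.7 % ¹⁸O before injection), the ~6 ms linear
injection ramp (applied as a 3 ms time shift, t_k = ln((e^{kt_m}−1)/(kt_m))/k),
and the ~10 ms of additional exchange in the S₃ state between the final two
flashes. Fits minimize the summed squared residuals of both channels with
multi-start bounded least squares; uncertainties are 68 % percentile
half-widths of case-resampling bootstrap distributions.

## Worked example

Print the eigen-structure of the published Sr²⁺-substituted PSII pH 8.3
model (k_f1=120, k_f2=65, k_s1=1.0, k_s2=50, k_c1=3.6, k_c2=12 s⁻¹):

```sh
s2wex eigen --preset sr_pH8.3_hb
```

```
full spectrum (s^-1):
       +0.0000  zero
      -11.9625  lambda3+
      -15.6000  conformational
      -54.6375  lambda3-
      -67.9258  lambda2+
     -116.0512  lambda1+
     -132.6742  lambda2-
     -135.5488  lambda1-
slow pair closed form: lambda3+ = -11.96, lambda3- = -54.64 s^-1
  relaxed                    (-13.00, -53.60)  rel. deviation (8.7%, 1.9%)
  slow-conversion            (-1.00, -50.00)  rel. deviation (91.6%, 8.5%)
  fast-conversion-LS-inert   (-12.00, -50.00)  rel. deviation (0.3%, 8.5%)
```

The two slow phases visible in ³⁶Y decay at 11.96 and 54.64 s⁻¹. The
slower one sits within 0.3 % of −k_c2 = −12 s⁻¹ (conversion reading) but an
order of magnitude away from −k_s1 = −1 s⁻¹ (LS-exchange reading): for this
sample the slow ³⁶Y phase tracks the E_LS → E_HS conversion, not exchange
in E_LS. The same analysis is available in Python:

```python
import numpy as np
from s2wex import preset, lambda3_exact, generate_synthetic, FitSpec, fit

rates = preset("sr_pH6.0_tw")          # Sr-PSII pH 6.0 re-fit parameters
data = generate_synthetic(rates, noise_sd=0.02, seed=1)
spec = FitSpec(values=rates.as_dict(),
               free={"k_s2": True, "k_c1": True, "k_c2": True}, seed=1)
print(fit(data, spec).summary())
```

Simulating a noisy experiment at the published parameters
(k_s2 = 26, k_c1 = 1.1, k_c2 = 1.3 s⁻¹) and refitting recovers them to a
few percent; `bootstrap(data, spec, n_boot=500, seed=1)` adds the
percentile errors.

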