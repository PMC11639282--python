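"""Two-site, two-conformation isotope-exchange kinetics.

The oxygen-evolving complex in its S2 state is modelled as an enzyme with
two substrate-water binding sites — a fast-exchanging site (W_f) and a
slowly exchanging site (W_s) — and two interconverting conformations, a
low-spin form (E_LS) and a high-spin form (E_HS).  Each site holds either a
16O or an 18O label, giving an 8-state continuous-time Markov chain over
(conformation, slow-site label, fast-site label).

Six first-order rate constants define one model:

==========  =====================================================
``k_f1``    fast-site exchange in E_LS (s^-1)
``k_f2``    fast-site exchange in E_HS (s^-1)
``k_s1``    slow-site exchange in E_LS (s^-1)
``k_s2``    slow-site exchange in E_HS (s^-1)
``k_c1``    conformational conversion E_HS -> E_LS (s^-1)
``k_c2``    conformational conversion E_LS -> E_HS (s^-1)
==========  =====================================================

Site exchange with bulk water of 18O enrichment ``alpha`` replaces a 16O
label by 18O at rate ``k * alpha`` and an 18O label by 16O at rate
``k * (1 - alpha)``; conversions between conformations preserve the site
labels.  The generator of the chain is constant once the bulk enrichment is
constant, so the matrix exponential propagates populations exactly; an
adaptive ODE integration of the same generator is used as an independent
oracle in the test suite only.

State indexing is fixed for portability:
``index = 4*conformation + 2*slow_label + fast_label`` with LS=0, HS=1 and
16O=0, 18O=1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

__all__ = [
    "N_STATES",
    "LS",
    "HS",
    "RateConstants",
    "EnrichmentSpec",
    "IsotopologueState",
    "YieldCurve",
    "state_index",
    "build_generator",
    "equilibrium_initial_state",
    "stationary_state",
    "propagate",
    "propagate_times",
    "yields_from_state",
]

N_STATES = 8
LS, HS = 0, 1

#: population-sum conservation tolerance (double precision, 8 states)
SUM_TOL = 1e-12


def state_index(conformation: int, slow_label: int, fast_label: int) -> int:
    """Flat index of the (conformation, slow-site, fast-site) state.

    Labels are 0 for 16O and 1 for 18O; conformation is 0 (LS) or 1 (HS).
    """
    return 4 * conformation + 2 * slow_label + fast_label


def _check_rate(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be a finite non-negative rate, got {value!r}")
    return value


@dataclass(frozen=True)
class RateConstants:
    """The six apparent rate constants (s^-1) of one S2-state model."""

    k_f1: float
    k_f2: float
    k_s1: float
    k_s2: float
    k_c1: float
    k_c2: float

    def __post_init__(self) -> None:
        for name in ("k_f1", "k_f2", "k_s1", "k_s2", "k_c1", "k_c2"):
            object.__setattr__(self, name, _check_rate(name, getattr(self, name)))

    def as_dict(self) -> dict[str, float]:
        return {
            "k_f1": self.k_f1,
            "k_f2": self.k_f2,
            "k_s1": self.k_s1,
            "k_s2": self.k_s2,
            "k_c1": self.k_c1,
            "k_c2": self.k_c2,
        }

    @property
    def hs_equilibrium_fraction(self) -> float:
        """Equilibrium fraction in E_HS, k_c2 / (k_c1 + k_c2)."""
        total = self.k_c1 + self.k_c2
        if total == 0:
            raise ValueError(
                "conformational equilibrium undefined: k_c1 = k_c2 = 0; "
                "supply an explicit conformation split"
            )
        return self.k_c2 / total


@dataclass(frozen=True)
class EnrichmentSpec:
    """Bulk-water 18O context: initial and final enrichment.

    ``alpha_in`` is the 18O fraction of the bulk before labelled-water
    injection (natural abundance plus syringe leakage, about 0.7% in
    practice) and ``alpha_f`` the final fraction after injection.  Derived
    quantities follow the conventional ratio notation:
    ``r = (1-alpha_f)/alpha_f`` (H2-16O : H2-18O after injection), ``r0``
    the same ratio before injection (infinite when ``alpha_in == 0``), and
    ``q = 1 - alpha_in/alpha_f`` the initial-enrichment correction factor.
    """

    alpha_in: float = 0.007
    alpha_f: float = 0.25

    def __post_init__(self) -> None:
        a_in, a_f = float(self.alpha_in), float(self.alpha_f)
        if not (0.0 <= a_in <= a_f < 1.0):
            raise ValueError(
                f"require 0 <= alpha_in <= alpha_f < 1, got "
                f"alpha_in={a_in!r}, alpha_f={a_f!r}"
            )
        if a_f == 0.0:
            raise ValueError("alpha_f must be positive (yield normalization undefined)")
        object.__setattr__(self, "alpha_in", a_in)
        object.__setattr__(self, "alpha_f", a_f)

    @property
    def r(self) -> float:
        return (1.0 - self.alpha_f) / self.alpha_f

    @property
    def r0(self) -> float:
        """16O/18O ratio before injection; ``inf`` for alpha_in == 0."""
        if self.alpha_in == 0.0:
            return math.inf
        return (1.0 - self.alpha_in) / self.alpha_in

    @property
    def q(self) -> float:
        return 1.0 - self.alpha_in / self.alpha_f


@dataclass
class IsotopologueState:
    """Probability vector over the 8 (conformation, labels) states."""

    populations: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        p = np.asarray(self.populations, dtype=float)
        if p.shape != (N_STATES,):
            raise ValueError(f"populations must have shape ({N_STATES},), got {p.shape}")
        if not np.all(np.isfinite(p)):
            raise ValueError("populations must be finite")
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError("populations must lie in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"populations must sum to 1, got {p.sum()!r}")
        self.populations = p
        self.time = float(self.time)

    def p_both_18(self) -> float:
        """Probability that both sites carry 18O."""
        return float(self.populations[3] + self.populations[7])

    def p_exactly_one_18(self) -> float:
        """Probability that exactly one site carries 18O."""
        return float(
            self.populations[1] + self.populations[2]
            + self.populations[5] + self.populations[6]
        )

    def hs_fraction(self) -> float:
        return float(self.populations[4:].sum())


@dataclass
class YieldCurve:
    """Normalized 34/36 O2-yield channels sampled at increasing times."""

    times: np.ndarray
    y34: np.ndarray
    y36: np.ndarray
    normalized: bool = True

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y34 = np.asarray(self.y34, dtype=float)
        y36 = np.asarray(self.y36, dtype=float)
        if not (t.shape == y34.shape == y36.shape) or t.ndim != 1:
            raise ValueError("times, y34, y36 must be 1-D arrays of equal length")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        self.times, self.y34, self.y36 = t, y34, y36


def build_generator(rates: RateConstants, alpha: float) -> np.ndarray:
    """Generator matrix of the 8-state chain at bulk enrichment ``alpha``.

    Column convention: ``G[j, i]`` is the rate of the transition i -> j, so
    every column sums to zero and ``dp/dt = G @ p``.  Only single-coordinate
    transitions occur: one site label flips, or the conformation changes
    with labels preserved.
    """
    alpha = float(alpha)
    if not (0.0 <= alpha < 1.0) or not math.isfinite(alpha):
        raise ValueError(f"alpha must lie in [0, 1), got {alpha!r}")
    G = np.zeros((N_STATES, N_STATES))
    site_rates = {LS: (rates.k_s1, rates.k_f1), HS: (rates.k_s2, rates.k_f2)}
    for conf in (LS, HS):
        k_slow, k_fast = site_rates[conf]
        for slow in (0, 1):
            for fast in (0, 1):
                i = state_index(conf, slow, fast)
                # slow-site label flip
                j = state_index(conf, 1 - slow, fast)
                G[j, i] += k_slow * (alpha if slow == 0 else 1.0 - alpha)
                # fast-site label flip
                j = state_index(conf, slow, 1 - fast)
                G[j, i] += k_fast * (alpha if fast == 0 else 1.0 - alpha)
                # conformational conversion, labels preserved
                j = state_index(1 - conf, slow, fast)
                G[j, i] += rates.k_c2 if conf == LS else rates.k_c1
    np.fill_diagonal(G, G.diagonal() - G.sum(axis=0))
    return G


def _site_label_probs(alpha: float) -> np.ndarray:
    return np.array([1.0 - alpha, alpha])


def equilibrium_initial_state(
    rates: RateConstants,
    alpha_in: float,
    conformation_split: float | None = None,
) -> IsotopologueState:
    """State at time zero of the labelled-water incubation.

    The LS/HS conformational equilibrium is assumed established before the
    injection; each site independently carries 18O with probability
    ``alpha_in``.  ``conformation_split`` (fraction in HS) overrides the
    equilibrium and is required when ``k_c1 == k_c2 == 0``.
    """
    if not (0.0 <= alpha_in < 1.0):
        raise ValueError(f"alpha_in must lie in [0, 1), got {alpha_in!r}")
    if conformation_split is None:
        f_hs = rates.hs_equilibrium_fraction
    else:
        f_hs = float(conformation_split)
        if not (0.0 <= f_hs <= 1.0):
            raise ValueError("conformation_split must lie in [0, 1]")
    label = _site_label_probs(alpha_in)
    p = np.empty(N_STATES)
    for conf, f_conf in ((LS, 1.0 - f_hs), (HS, f_hs)):
        for slow in (0, 1):
            for fast in (0, 1):
                p[state_index(conf, slow, fast)] = f_conf * label[slow] * label[fast]
    return IsotopologueState(populations=p, time=0.0)


def stationary_state(
    rates: RateConstants,
    alpha: float,
    conformation_split: float | None = None,
) -> IsotopologueState:
    """Stationary distribution of the chain at bulk enrichment ``alpha``.

    Conformations settle at k_c2/(k_c1+k_c2) HS and each site carries 18O
    with probability ``alpha``; labels and conformation are independent at
    stationarity because conversion preserves labels.
    """
    state = equilibrium_initial_state(rates, alpha, conformation_split)
    return state


def propagate(
    state: IsotopologueState, generator: np.ndarray, dt: float
) -> IsotopologueState:
    """Advance a state by ``dt`` seconds under a constant generator.

    Uses the matrix exponential, which is exact for the time-independent
    generator.  Probability mass is conserved to 1e-12.
    """
    dt = float(dt)
    if dt < 0:
        raise ValueError(f"dt must be non-negative, got {dt!r}")
    G = np.asarray(generator, dtype=float)
    if not np.all(np.isfinite(G)):
        raise ValueError("generator contains non-finite entries")
    if dt == 0.0:
        return IsotopologueState(state.populations.copy(), state.time)
    p = expm(G * dt) @ state.populations
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    return IsotopologueState(populations=p, time=state.time + dt)


def propagate_times(
    p0: np.ndarray, generator: np.ndarray, times: np.ndarray
) -> np.ndarray:
    """Populations at many times: column k is exp(G t_k) @ p0.

    Uses the eigendecomposition of the generator when it is well
    conditioned (one diagonalization serves every time point), falling back
    to one matrix exponential per time otherwise.
    """
    G = np.asarray(generator, dtype=float)
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if not np.all(np.isfinite(G)):
        raise ValueError("generator contains non-finite entries")
    scale = max(np.abs(G).max(), 1.0)
    try:
        lam, V = np.linalg.eig(G)
        cond = np.linalg.cond(V)
    except np.linalg.LinAlgError:  # pragma: no cover - defensive
        cond = np.inf
    if cond < 1e8:
        coef = np.linalg.solve(V, np.asarray(p0, dtype=float).astype(complex))
        out = (V @ (np.exp(np.outer(lam, t)) * coef[:, None])).real
    else:
        out = np.column_stack([expm(G * tk) @ p0 for tk in t])
    out = np.clip(out, 0.0, None)
    out /= out.sum(axis=0, keepdims=True)
    return out


def yields_from_state(
    state: IsotopologueState,
    enrichment: EnrichmentSpec,
    normalized: bool = True,
) -> tuple[float, float]:
    """(34Y, 36Y) for one state.

    With the plateau-1 convention (default) the double-labelled yield is
    P(both sites 18O) / alpha_f^2 and the single-labelled yield is
    P(exactly one 18O) / (2 alpha_f (1 - alpha_f)); both approach 1 as the
    state equilibrates at the final enrichment.  With ``normalized=False``
    the raw isotopologue probabilities are returned instead.
    """
    a_f = enrichment.alpha_f
    p36 = state.p_both_18()
    p34 = state.p_exactly_one_18()
    if not normalized:
        return p34, p36
    return p34 / (2.0 * a_f * (1.0 - a_f)), p36 / (a_f * a_f)
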