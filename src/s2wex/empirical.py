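"""Empirical multi-exponential fit models for TR-MIMS exchange curves.

The traditional analysis treats the two substrate-water sites as
independent pseudo-first-order exchangers with rates k_f >> k_s:

    34Y(t) = a (1 - exp(-k_f t)) + (1 - a)(1 - exp(-k_s t))
    36Y(t) = 1 - exp(-k_s t)

where the fast-phase amplitude is fixed by the bulk enrichments,

    a = [alpha_f (1 - alpha_in) + alpha_in (1 - alpha_f)]
        / (2 alpha_f (1 - alpha_f)),

reducing to 0.5/(1 - alpha_f) when the initial enrichment is ignored.
When both S2 conformations are populated an intermediate phase with
amplitude b appears in the slow part of both channels:

    36Y(t) = b (1 - exp(-k_i t)) + (1 - b)(1 - exp(-k_s t))

with the same substitution inside the (1 - a) bracket of 34Y; b reflects
the conformational equilibrium ratio but is left free by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .kinetic_core import EnrichmentSpec

__all__ = [
    "BiexpParams",
    "TriexpParams",
    "biexp_yields",
    "triexp_yields",
    "a_from_enrichment",
]


def _check_fraction(name: str, value: float) -> float:
    value = float(value)
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class BiexpParams:
    """Fast amplitude and the two apparent rates of the bi-exponential model."""

    a: float
    k_f: float
    k_s: float

    def __post_init__(self) -> None:
        _check_fraction("a", self.a)
        if self.k_f < 0 or self.k_s < 0:
            raise ValueError("rates must be non-negative")
        if self.k_s > 0 and self.k_f / self.k_s < 10:
            warnings.warn(
                "biexponential decomposition assumes k_f >> k_s; "
                f"k_f/k_s = {self.k_f / self.k_s:.3g} is ill-conditioned",
                stacklevel=2,
            )


@dataclass(frozen=True)
class TriexpParams:
    """Tri-exponential (two-conformation) empirical model parameters."""

    a: float
    b: float
    k_f: float
    k_i: float
    k_s: float

    def __post_init__(self) -> None:
        _check_fraction("a", self.a)
        _check_fraction("b", self.b)
        if min(self.k_f, self.k_i, self.k_s) < 0:
            raise ValueError("rates must be non-negative")


def biexp_yields(t, p: BiexpParams) -> tuple[np.ndarray, np.ndarray]:
    """(34Y, 36Y) of the bi-exponential model at times ``t``."""
    t = np.asarray(t, dtype=float)
    fast = 1.0 - np.exp(-p.k_f * t)
    slow = 1.0 - np.exp(-p.k_s * t)
    return p.a * fast + (1.0 - p.a) * slow, slow


def triexp_yields(t, p: TriexpParams) -> tuple[np.ndarray, np.ndarray]:
    """(34Y, 36Y) of the tri-exponential model; b = 0 recovers the bi-exponential."""
    t = np.asarray(t, dtype=float)
    fast = 1.0 - np.exp(-p.k_f * t)
    mid = 1.0 - np.exp(-p.k_i * t)
    slow = 1.0 - np.exp(-p.k_s * t)
    y36 = p.b * mid + (1.0 - p.b) * slow
    y34 = p.a * fast + (1.0 - p.a) * y36
    return y34, y36


def a_from_enrichment(enrichment: EnrichmentSpec) -> float:
    """Fast-phase amplitude implied by the bulk enrichments.

    Equals 0.5/(1 - alpha_f) exactly when alpha_in = 0, and 1 when the
    initial and final enrichments coincide.
    """
    a_in, a_f = enrichment.alpha_in, enrichment.alpha_f
    if not (0.0 < a_f < 1.0):
        raise ValueError("alpha_f must lie strictly between 0 and 1")
    return (a_f * (1.0 - a_in) + a_in * (1.0 - a_f)) / (2.0 * a_f * (1.0 - a_f))
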