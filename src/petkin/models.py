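"""Closed-form model equations and elementary equilibrium quantities.

This is the pure math layer every other module evaluates:

* multi-exponential (optionally stretched) relaxations,
  ``F(t) = Y0 + sum_i A_i (1 - exp(-(k_i t)^beta_i))``,
  with the sign convention that a *negative* amplitude is a fluorescence
  decrease, i.e. a decrease of the inter-dye distance (docking / closing),
  and a positive amplitude an increase (undocking / opening);
* the biphasic single-turnover hydrolysis curve
  ``F = F0 + (Fmax - F0) e^{-k1 (t - t0)} + (Fmax - F0)(1 - e^{-k2 (t - t0)})``,
  where ``k1`` is the composite pre-commitment association/dissociation rate,
  ``k2`` the hydrolysis rate and ``t0`` the unobservable dead-time offset;
* the proximity-quenching map translating an inter-dye distance into relative
  fluorescence (PET quenching is essentially complete below ~5 A and absent
  above ~15 A);
* the exact single-site fraction-bound solution used to rescale observed
  amplitudes to per-complex amplitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import DegenerateModelError, InputError

__all__ = [
    "Phase",
    "MultiExpModel",
    "SingleTurnoverModel",
    "QuenchingModel",
    "BindingParams",
    "eval_multiexp",
    "eval_single_turnover",
    "quench",
    "fraction_bound",
]


@dataclass(frozen=True)
class Phase:
    """One exponential component of a relaxation.

    Parameters
    ----------
    amplitude : float
        Signed fluorescence change in instrument units (AU). Negative means
        the inter-dye distance decreases (docking, closing).
    rate : float
        First-order rate constant in 1/s. Must be positive.
    beta : float, default 1.0
        Stretching exponent in (0, 1]; 1 is a pure exponential. Values < 1
        describe kinetically heterogeneous (Kohlrausch) relaxations.
    """

    amplitude: float
    rate: float
    beta: float = 1.0

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise InputError(f"phase rate must be > 0, got {self.rate}")
        if not 0 < self.beta <= 1:
            raise InputError(f"stretching exponent must be in (0, 1], got {self.beta}")


@dataclass(frozen=True)
class MultiExpModel:
    """Baseline plus an ordered sum of 1-3 exponential phases.

    ``baseline`` is the extrapolated fluorescence at time zero (Y0, AU).
    Phases are stored sorted by descending rate (fastest first).
    """

    baseline: float
    phases: tuple[Phase, ...] = field(default=())

    def __post_init__(self) -> None:
        phases = tuple(sorted(self.phases, key=lambda p: -p.rate))
        if not 1 <= len(phases) <= 3:
            raise InputError(f"1 to 3 phases required, got {len(phases)}")
        object.__setattr__(self, "phases", phases)

    @property
    def total_amplitude(self) -> float:
        """Signed sum of phase amplitudes (the t -> infinity change from Y0)."""
        return float(sum(p.amplitude for p in self.phases))

    def __call__(self, times: Sequence[float] | np.ndarray) -> np.ndarray:
        return eval_multiexp(self, times)


@dataclass(frozen=True)
class SingleTurnoverModel:
    """Biphasic single-turnover hydrolysis model.

    ``F0`` is the quenched minimal fluorescence after nucleotide association,
    ``Fmax`` the final maximal fluorescence, ``k1`` the composite
    pre-commitment rate, ``k2`` the hydrolysis rate and ``t0`` the
    unobservable dead-time offset. For ``k1 > k2`` the curve starts at Fmax,
    dips to a unique minimum at ``t0 + ln(k1/k2)/(k1 - k2)`` and recovers to
    Fmax.
    """

    F0: float
    Fmax: float
    k1: float
    k2: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not self.Fmax > self.F0:
            raise InputError(f"Fmax ({self.Fmax}) must exceed F0 ({self.F0})")
        if not (self.k1 > 0 and self.k2 > 0):
            raise InputError("k1 and k2 must be positive")
        if math.isclose(self.k1, self.k2, rel_tol=1e-12):
            raise DegenerateModelError(
                "k1 == k2: the biphasic form is undefined in the confluent limit"
            )

    @property
    def t_min(self) -> float:
        """Time of the fluorescence minimum (only meaningful for k1 > k2)."""
        return self.t0 + math.log(self.k1 / self.k2) / (self.k1 - self.k2)

    def __call__(self, times: Sequence[float] | np.ndarray) -> np.ndarray:
        return eval_single_turnover(self, times)


@dataclass(frozen=True)
class QuenchingModel:
    """Distance -> relative fluorescence map for PET proximity quenching.

    Fluorescence is ``q_floor`` ("largely quenched", not zero) at or below
    ``d_quench`` and exactly 1 at or above ``d_free``. In between, a cubic
    smoothstep applied to the ``sharpness``-th power of the normalized
    distance gives a continuous, differentiable, monotone interpolation.
    ``sharpness > 1`` skews the transition towards the free limit, matching
    the short-range character of photoinduced electron transfer: quenching
    remains substantial up to a couple of Angstrom below the free distance
    (e.g. a pair at 14 A is still strongly quenched while 15 A is fully
    fluorescent); ``sharpness = 1`` recovers the symmetric smoothstep.
    Distances in Angstrom.
    """

    d_quench: float = 5.0
    d_free: float = 15.0
    q_floor: float = 0.05
    sharpness: float = 8.0

    def __post_init__(self) -> None:
        if not 0 < self.d_quench < self.d_free:
            raise InputError("require 0 < d_quench < d_free")
        if not 0 <= self.q_floor < 1:
            raise InputError("q_floor must be in [0, 1)")
        if not self.sharpness >= 1:
            raise InputError("sharpness must be >= 1")

    def __call__(self, distance):
        return quench(self, distance)


@dataclass(frozen=True)
class BindingParams:
    """Single-site equilibrium binding parameters (all in one common unit)."""

    chaperone_total: float
    client_total: float
    kd: float

    def __post_init__(self) -> None:
        if self.chaperone_total < 0 or self.client_total < 0:
            raise InputError("concentrations must be nonnegative")
        if not self.kd > 0:
            raise InputError("kd must be positive")


def _validated_times(times, allow_negative: bool = False) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim == 0:
        t = t[np.newaxis]
    if t.ndim != 1:
        raise InputError(f"time vector must be one-dimensional, got shape {t.shape}")
    if not allow_negative and t.size and np.min(t) < 0:
        raise InputError("time values must be nonnegative")
    if t.size > 1 and np.any(np.diff(t) < 0):
        raise InputError("time vector must be nondecreasing")
    return t


def eval_multiexp(model: MultiExpModel, times) -> np.ndarray:
    """Evaluate ``Y0 + sum_i A_i (1 - exp(-(k_i t)^beta_i))`` on a time grid.

    ``F(0) = Y0`` and ``F(inf) = Y0 + sum_i A_i``. Raises
    :class:`~petkin.exceptions.InputError` for negative or non-monotone times.
    """
    t = _validated_times(times)
    out = np.full(t.shape, model.baseline, dtype=float)
    for p in model.phases:
        out += p.amplitude * (1.0 - np.exp(-((p.rate * t) ** p.beta)))
    return out


def eval_single_turnover(model: SingleTurnoverModel, times) -> np.ndarray:
    """Evaluate the biphasic single-turnover curve; requires ``times >= t0``."""
    t = _validated_times(times, allow_negative=True)
    if t.size and np.min(t) < model.t0 - 1e-12:
        raise InputError("times must not precede the dead-time offset t0")
    tau = np.clip(t - model.t0, 0.0, None)
    span = model.Fmax - model.F0
    return model.F0 + span * np.exp(-model.k1 * tau) + span * (1.0 - np.exp(-model.k2 * tau))


def quench(qm: QuenchingModel, distance):
    """Relative fluorescence of a dye pair at the given inter-dye distance (A).

    Monotone nondecreasing; exactly ``qm.q_floor`` for ``d <= d_quench`` and
    exactly 1 for ``d >= d_free``; cubic smoothstep in between.
    """
    d = np.asarray(distance, dtype=float)
    if np.any(d <= 0):
        raise InputError("distance must be positive")
    x = np.clip((d - qm.d_quench) / (qm.d_free - qm.d_quench), 0.0, 1.0)
    u = np.power(x, qm.sharpness)
    s = u * u * (3.0 - 2.0 * u)
    q = qm.q_floor + (1.0 - qm.q_floor) * s
    if np.isscalar(distance) or np.ndim(distance) == 0:
        return float(q)
    return q


def fraction_bound(bp: BindingParams) -> float:
    """Fraction of chaperone in complex with client, exact single-site solution.

    Solves the mass-balance quadratic for the complex concentration; evaluated
    in the numerically stable form ``f = 2 L / (S + sqrt(S^2 - 4 K L))`` with
    ``S = K + L + Kd``, which avoids cancellation when ``K L << S^2``.
    """
    K, L, Kd = bp.chaperone_total, bp.client_total, bp.kd
    if K == 0:
        raise InputError("chaperone_total must be positive to define a bound fraction")
    if L == 0:
        return 0.0
    s = K + L + Kd
    disc = s * s - 4.0 * K * L
    f = 2.0 * L / (s + math.sqrt(max(disc, 0.0)))
    return float(min(f, 1.0))
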