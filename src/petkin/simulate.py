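"""Synthetic-data generation for the trace-analysis pipeline.

No raw stopped-flow or plate-reader recordings are deposited for this assay
family, so every input the pipeline analyzes is produced here from explicit
generative models:

* ATP-binding quench/de-quench traces from a weighted mixture of apo-state
  subpopulations feeding a shared sequential conformational chain
  (apo -> linker docked -> nucleotide-binding-cleft closed -> SBDbeta docked
  -> lid open), observed through the PET quenching map;
* paired short (0.25 s) / long (250 s) recordings for interface-destabilized
  variants whose final slow transition detaches the SBDbeta again
  (the slow fluorescence re-increase), with a seeded voltage offset between
  the two recordings so the splice step of the analysis does real work;
* plate-reader single-turnover hydrolysis traces following the biphasic
  hydrolysis model, plus flat nucleotide controls.

All randomness flows from the ``rng_seed`` of the acquisition spec; identical
seed and spec give a bit-identical trace.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import expm

from .exceptions import ConfigurationError, InputError
from .models import QuenchingModel, SingleTurnoverModel, eval_single_turnover, quench

__all__ = [
    "Subpopulation",
    "KineticScheme",
    "AcquisitionSpec",
    "Trace",
    "FlatTurnoverModel",
    "state_occupancies",
    "noiseless_binding_signal",
    "generate_binding_trace",
    "generate_long_trace_pair",
    "generate_single_turnover_trace",
]


@dataclass(frozen=True)
class Subpopulation:
    """One apo-state subpopulation of the conformational mixture.

    Each subpopulation shares the downstream chain but enters it with its own
    (ATP-association) rate. ``distance_overrides`` optionally replaces the
    per-state distance vector of one or more probes for this subpopulation,
    modelling "different starting conformation" heterogeneity.
    """

    weight: float
    entry_rate: float
    distance_overrides: Mapping[str, tuple[float, ...]] | None = None


@dataclass(frozen=True)
class KineticScheme:
    """Irreversible first-order chain S0 -> S1 -> ... -> Sn with a subpopulation mixture.

    Parameters
    ----------
    state_names : sequence of str
        Names of the conformational states, in chain order (>= 2 states).
    distances : mapping probe -> per-state distance vector (A)
        One inter-dye distance per state for every supported probe.
    step_rates : sequence of float
        Forward rate constants (1/s) between consecutive states; the first
        entry is the default entry rate, overridden per subpopulation.
    subpopulations : sequence of Subpopulation
        Weights must sum to 1 within 1e-9.
    """

    state_names: tuple[str, ...]
    distances: Mapping[str, tuple[float, ...]]
    step_rates: tuple[float, ...]
    subpopulations: tuple[Subpopulation, ...] = (Subpopulation(1.0, None),)  # type: ignore[arg-type]

    def __post_init__(self) -> None:
        object.__setattr__(self, "state_names", tuple(self.state_names))
        object.__setattr__(self, "step_rates", tuple(float(r) for r in self.step_rates))
        object.__setattr__(
            self,
            "distances",
            {p: tuple(float(d) for d in ds) for p, ds in dict(self.distances).items()},
        )
        n = len(self.state_names)
        if n < 2:
            raise InputError("a kinetic scheme needs at least 2 states")
        if len(self.step_rates) != n - 1:
            raise InputError(
                f"{n} states require {n - 1} step rates, got {len(self.step_rates)}"
            )
        subs = []
        for s in self.subpopulations:
            if s.entry_rate is None:
                s = replace(s, entry_rate=self.step_rates[0])
            subs.append(s)
        object.__setattr__(self, "subpopulations", tuple(subs))
        if any(r <= 0 for r in self.step_rates):
            raise InputError("all step rates must be positive")
        for probe, ds in self.distances.items():
            if len(ds) != n:
                raise ConfigurationError(
                    f"probe {probe!r} has {len(ds)} distances for {n} states"
                )
            if any(d <= 0 for d in ds):
                raise InputError("all distances must be positive")
        w = sum(s.weight for s in self.subpopulations)
        if abs(w - 1.0) > 1e-9:
            raise InputError(f"subpopulation weights must sum to 1, got {w}")
        for s in self.subpopulations:
            if s.entry_rate <= 0:
                raise InputError("subpopulation entry rates must be positive")
            if s.distance_overrides:
                for probe, ds in s.distance_overrides.items():
                    if len(ds) != n or any(d <= 0 for d in ds):
                        raise ConfigurationError(
                            f"bad distance override for probe {probe!r}"
                        )

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def probe_distances(self, probe: str, subpop_index: int = 0) -> np.ndarray:
        sub = self.subpopulations[subpop_index]
        if sub.distance_overrides and probe in sub.distance_overrides:
            return np.asarray(sub.distance_overrides[probe], dtype=float)
        if probe not in self.distances:
            raise ConfigurationError(
                f"probe {probe!r} has no distances in this scheme "
                f"(known: {sorted(self.distances)})"
            )
        return np.asarray(self.distances[probe], dtype=float)

    def chain_rates(self, subpop_index: int) -> np.ndarray:
        rates = np.asarray(self.step_rates, dtype=float)
        rates[0] = self.subpopulations[subpop_index].entry_rate
        return rates


@dataclass(frozen=True)
class AcquisitionSpec:
    """How a trace is sampled and how noisy it is.

    ``dead_time`` (default 2.3 ms) is the unobservable stopped-flow mixing
    interval; samples before it are discarded. ``noise_sigma`` defaults to
    0.3% of ``full_scale`` (the 10 V instrument convention). The grid is
    either ``n_samples`` points over [dead_time, duration] (linear or
    log-spaced), a fixed ``sampling_hz``, or an explicit ``time_grid``.
    """

    duration: float
    n_samples: int | None = None
    sampling_hz: float | None = None
    time_grid: tuple[float, ...] | None = None
    spacing: str = "linear"
    dead_time: float = 0.0023
    noise_sigma: float = 0.03
    full_scale: float = 10.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.time_grid is not None:
            object.__setattr__(self, "time_grid", tuple(float(t) for t in self.time_grid))
        if not self.duration > self.dead_time:
            raise InputError("duration must exceed the dead time")
        if self.noise_sigma < 0:
            raise InputError("noise_sigma must be nonnegative")
        if self.time_grid is None and self.n_samples is None and self.sampling_hz is None:
            raise InputError("provide n_samples, sampling_hz or an explicit time_grid")
        if self.sampling_hz is not None and self.sampling_hz <= 0:
            raise InputError("sampling rate must be positive")
        if self.spacing not in ("linear", "log"):
            raise InputError("spacing must be 'linear' or 'log'")

    def times(self) -> np.ndarray:
        """Resolved sample grid; strictly increasing, starting at dead_time."""
        if self.time_grid is not None:
            t = np.asarray(self.time_grid, dtype=float)
        elif self.sampling_hz is not None:
            t = np.arange(0.0, self.duration, 1.0 / self.sampling_hz)
        elif self.spacing == "log":
            t0 = max(self.dead_time, 1e-6)
            t = np.geomspace(t0, self.duration, self.n_samples)
        else:
            t = np.linspace(self.dead_time, self.duration, self.n_samples)
        t = t[t >= self.dead_time - 1e-15]
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise InputError("resolved time grid must be strictly increasing")
        return t


@dataclass
class Trace:
    """A sampled fluorescence time series with acquisition metadata."""

    times: np.ndarray
    fluorescence: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.times.shape != self.fluorescence.shape or self.times.ndim != 1:
            raise InputError("times and fluorescence must be 1-D arrays of equal length")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise InputError("trace times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def window(self, t_start: float, t_end: float) -> "Trace":
        """Sub-trace with t_start <= t <= t_end."""
        sel = (self.times >= t_start) & (self.times <= t_end)
        if sel.sum() < 2:
            raise InputError(f"window [{t_start}, {t_end}] contains fewer than 2 samples")
        meta = dict(self.metadata)
        meta["window"] = (float(t_start), float(t_end))
        return Trace(self.times[sel], self.fluorescence[sel], meta)

    def value_at(self, t: float) -> float:
        """Linear interpolation of the trace at time t; t must lie in the span."""
        if not self.times[0] <= t <= self.times[-1]:
            raise InputError(
                f"t={t} s outside the trace span [{self.times[0]}, {self.times[-1]}] s"
            )
        return float(np.interp(t, self.times, self.fluorescence))

    def to_json_metadata(self) -> str:
        return json.dumps(self.metadata, indent=2, sort_keys=True, default=str)


@dataclass(frozen=True)
class FlatTurnoverModel:
    """Null single-turnover control (ADP, AMPPNP): flat fluorescence, no turnover."""

    level: float


def _chain_occupancies(rates: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Occupancies (n_states x n_times) of the chain with the given step rates.

    Spectral solution of the triangular rate matrix when all rates are
    distinct; falls back to a matrix exponential per time point for confluent
    (repeated) rates.
    """
    n = rates.size + 1
    A = np.zeros((n, n))
    for i, r in enumerate(rates):
        A[i, i] = -r
        A[i + 1, i] = r
    e0 = np.zeros(n)
    e0[0] = 1.0
    scale = max(rates.max(), 1.0)
    distinct = np.min(np.abs(np.subtract.outer(rates, rates) + np.eye(rates.size) * scale)) > 1e-9 * scale
    if distinct:
        lam, V = np.linalg.eig(A)
        c = np.linalg.solve(V, e0)
        occ = (V * c) @ np.exp(np.outer(lam, times))
        occ = np.real(occ)
    else:
        occ = np.column_stack([expm(A * t) @ e0 for t in times])
    return np.clip(occ, 0.0, 1.0)


def state_occupancies(scheme: KineticScheme, subpop_index: int, times) -> np.ndarray:
    """Forward solution of the sequential chain for one subpopulation.

    Returns an (n_states x n_times) matrix; every column sums to 1 and the
    first state decays as ``exp(-k_entry t)``.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim == 0:
        t = t[np.newaxis]
    if np.any(t < 0):
        raise InputError("times must be nonnegative")
    return _chain_occupancies(scheme.chain_rates(subpop_index), t)


def noiseless_binding_signal(
    scheme: KineticScheme,
    probe: str,
    times,
    qm: QuenchingModel | None = None,
    full_scale: float = 10.0,
) -> np.ndarray:
    """Mixture-averaged noiseless fluorescence of a probe on the given grid."""
    qm = qm or QuenchingModel()
    t = np.asarray(times, dtype=float)
    signal = np.zeros_like(t)
    for j, sub in enumerate(scheme.subpopulations):
        occ = state_occupancies(scheme, j, t)
        q = quench(qm, scheme.probe_distances(probe, j))
        signal += sub.weight * (np.asarray(q) @ occ)
    return full_scale * signal


def generate_binding_trace(
    scheme: KineticScheme,
    probe: str,
    acq: AcquisitionSpec,
    qm: QuenchingModel | None = None,
) -> Trace:
    """Simulate one stopped-flow nucleotide-binding trace for a probe.

    Gaussian noise of ``acq.noise_sigma`` is added per sample; samples before
    the dead time are never produced. Deterministic given ``acq.rng_seed``.
    """
    qm = qm or QuenchingModel()
    t = acq.times()
    signal = noiseless_binding_signal(scheme, probe, t, qm, acq.full_scale)
    rng = np.random.default_rng(acq.rng_seed)
    noise = rng.normal(0.0, acq.noise_sigma, t.size) if acq.noise_sigma > 0 else 0.0
    meta = {
        "probe": probe,
        "kind": "binding",
        "seed": acq.rng_seed,
        "dead_time_s": acq.dead_time,
        "noise_sigma_au": acq.noise_sigma,
        "full_scale_au": acq.full_scale,
        "duration_s": acq.duration,
    }
    return Trace(t, signal + noise, meta)


def generate_long_trace_pair(
    scheme: KineticScheme,
    probe: str,
    acq_short: AcquisitionSpec,
    acq_long: AcquisitionSpec,
    qm: QuenchingModel | None = None,
    offset_range: float = 1.0,
) -> tuple[Trace, Trace]:
    """Simulate a paired short (dense) and long (coarse) recording.

    The long trace receives a seeded uniform voltage offset in
    ``+-offset_range`` AU, emulating the arbitrary baseline shift between two
    separately recorded kinetics; the analysis splice step must remove it.
    If the scheme's final (slow) step is not at least 100x slower than the
    fastest chain rate a non-separability warning is emitted.
    """
    qm = qm or QuenchingModel()
    slow = scheme.step_rates[-1]
    fastest = max(
        max(s.entry_rate for s in scheme.subpopulations),
        max(scheme.step_rates[:-1], default=slow),
    )
    if scheme.n_states > 2 and slow >= fastest / 100.0:
        warnings.warn(
            "final step is less than 100x slower than the fastest chain rate; "
            "fast and slow windows may not be separable",
            stacklevel=2,
        )
    short = generate_binding_trace(scheme, probe, acq_short, qm)
    t_long = acq_long.times()
    signal = noiseless_binding_signal(scheme, probe, t_long, qm, acq_long.full_scale)
    rng = np.random.default_rng(acq_long.rng_seed)
    offset = float(rng.uniform(-offset_range, offset_range))
    noise = rng.normal(0.0, acq_long.noise_sigma, t_long.size) if acq_long.noise_sigma > 0 else 0.0
    meta = {
        "probe": probe,
        "kind": "binding-long",
        "seed": acq_long.rng_seed,
        "dead_time_s": acq_long.dead_time,
        "noise_sigma_au": acq_long.noise_sigma,
        "full_scale_au": acq_long.full_scale,
        "duration_s": acq_long.duration,
        "voltage_offset_au": offset,
    }
    long = Trace(t_long, signal + offset + noise, meta)
    return short, long


def generate_single_turnover_trace(
    model: SingleTurnoverModel | FlatTurnoverModel,
    acq: AcquisitionSpec,
) -> Trace:
    """Simulate a plate-reader single-turnover trace (or a flat null control)."""
    t = acq.times()
    if isinstance(model, FlatTurnoverModel):
        signal = np.full(t.size, model.level)
        kind = "turnover-null"
    else:
        signal = eval_single_turnover(model, t)
        kind = "turnover"
    rng = np.random.default_rng(acq.rng_seed)
    noise = rng.normal(0.0, acq.noise_sigma, t.size) if acq.noise_sigma > 0 else 0.0
    meta = {
        "kind": kind,
        "seed": acq.rng_seed,
        "noise_sigma_au": acq.noise_sigma,
        "duration_s": acq.duration,
    }
    return Trace(t, signal + noise, meta)
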