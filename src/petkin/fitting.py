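"""Parameter estimation from fluorescence traces.

Two scikit-learn-style estimators do the numerical work:

* :class:`MultiExponentialRegressor` — 1-3 exponential (optionally stretched)
  phases plus a baseline, fitted by variable projection: for a candidate set
  of rates the baseline and amplitudes are solved linearly, and only the
  log-rates (and stretching exponents) are optimized nonlinearly. A fixed
  grid of log-spaced rate combinations provides deterministic multi-start;
  the best sum of squared errors wins, ties broken by first index.
* :class:`SingleTurnoverRegressor` — the biphasic single-turnover hydrolysis
  curve, with ``k1 > k2`` enforced through the parameterization
  ``k1 = k2 (1 + e^theta)``.

Module-level functions (``fit_multiexp``, ``select_model_order``,
``fit_single_turnover``, ``splice_long_trace``, ``analyze_two_windows``) wrap
the estimators and return the result containers the rest of the pipeline
consumes.

Rate bounds are identifiability-driven: components slower than about a
quarter of the reciprocal window span are indistinguishable from baseline
drift, and components whose amplitude has decayed by 1e4 before the first
sample of a late-starting window cannot be recovered from it.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy import stats as sstats
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import FitFailureError, InputError
from .models import MultiExpModel, Phase, SingleTurnoverModel
from .simulate import Trace

__all__ = [
    "MultiExponentialRegressor",
    "SingleTurnoverRegressor",
    "MultiExpFit",
    "SingleTurnoverFit",
    "TwoWindowSummary",
    "SLOW_MODEL_FAMILIES",
    "fit_multiexp",
    "select_model_order",
    "fit_single_turnover",
    "splice_long_trace",
    "analyze_two_windows",
    "runs_test_pvalue",
]

#: Rates above this (1/s) carry increased dead-time uncertainty.
RATE_UNCERTAIN_THRESHOLD = 1000.0

#: Slow-window model families: (number of phases, stretched flags fastest->slowest).
SLOW_MODEL_FAMILIES: dict[str, tuple[int, tuple[bool, ...]]] = {
    "biexp": (2, (False, False)),
    "biexp_stretched": (2, (False, True)),
    "triexp": (3, (False, False, False)),
}


def _as_times(X) -> np.ndarray:
    t = np.asarray(X, dtype=float)
    if t.ndim == 2 and t.shape[1] == 1:
        t = t[:, 0]
    if t.ndim != 1:
        raise InputError(f"expected a 1-D time vector, got shape {t.shape}")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise InputError("time vector must be strictly increasing")
    return t


def runs_test_pvalue(residuals) -> float:
    """Two-sided Wald-Wolfowitz runs test on residual signs.

    Small p-values indicate systematic residual structure (a misspecified
    model); this is the objective stand-in for "randomly distributed
    residuals" judged by eye.
    """
    s = np.sign(np.asarray(residuals, dtype=float))
    s = s[s != 0]
    n = s.size
    if n < 2:
        return 1.0
    n1 = int(np.count_nonzero(s > 0))
    n2 = n - n1
    if n1 == 0 or n2 == 0:
        return 0.0 if n >= 10 else 1.0
    runs = 1 + int(np.count_nonzero(s[1:] != s[:-1]))
    mu = 1.0 + 2.0 * n1 * n2 / n
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n * n * (n - 1.0))
    if var <= 0:
        return 1.0
    z = (runs - mu) / math.sqrt(var)
    return float(2.0 * sstats.norm.sf(abs(z)))


def _design_matrix(t: np.ndarray, rates: np.ndarray, betas: np.ndarray, drift: bool = False) -> np.ndarray:
    cols = [np.ones_like(t)]
    for k, b in zip(rates, betas):
        x = k * t
        cols.append(1.0 - np.exp(-np.power(x, b)))
    if drift:
        cols.append(t - t[0])
    return np.column_stack(cols)


def _project(t, y, rates, betas, weights=None, amp_cap=None, drift=False):
    """Solve baseline+amplitudes linearly for fixed rates; return (coef, resid, sse).

    ``amp_cap`` bounds each phase amplitude: nearly-degenerate rate sets can
    otherwise fit noise with huge mutually-cancelling amplitudes. The bounded
    solve is only invoked when the unconstrained solution violates the cap.
    With ``drift`` a linear background column (coefficient in AU/s) absorbs
    slow out-of-window processes; it is capped at ``amp_cap`` over the span.
    """
    B = _design_matrix(t, rates, betas, drift)
    if weights is not None:
        Bw = B * weights[:, None]
        yw = y * weights
    else:
        Bw, yw = B, y
    coef, *_ = np.linalg.lstsq(Bw, yw, rcond=None)
    if amp_cap is not None:
        caps = np.full(B.shape[1] - 1, amp_cap)
        if drift:
            caps[-1] = amp_cap / max(t[-1] - t[0], 1e-30)
        if not np.all(np.isfinite(coef)) or np.any(np.abs(coef[1:]) > caps):
            lb = np.concatenate([[-np.inf], -caps])
            ub = np.concatenate([[np.inf], caps])
            coef = optimize.lsq_linear(Bw, yw, bounds=(lb, ub), method="bvls").x
    resid = y - B @ coef
    wresid = resid if weights is None else resid * weights
    return coef, resid, float(wresid @ wresid)


class MultiExponentialRegressor(RegressorMixin, BaseEstimator):
    """Sum-of-exponentials regression of a fluorescence trace.

    Parameters
    ----------
    n_phases : int
        Number of exponential phases (1-3).
    stretched : sequence of bool or None
        Per-phase stretched-exponential flags in output order (fastest phase
        first). None means no stretching.
    rate_bounds : (float, float) or None
        Explicit rate bounds in 1/s; by default derived from the time window.
    n_rate_grid, n_refine : int
        Size of the fixed log-spaced rate start grid and how many of the best
        coarse starts are polished with a nonlinear optimizer.
    beta_min, beta_start : float
        Lower bound and start value for stretching exponents.

    Attributes
    ----------
    model_ : MultiExpModel
        Fitted model (phases sorted by descending rate).
    baseline_, phases_, sse_, residuals_, contributions_, total_amplitude_,
    runs_test_p_, rate_uncertain_ : fitted summaries, see :class:`MultiExpFit`.
    """

    def __init__(
        self,
        n_phases: int = 1,
        stretched: Sequence[bool] | None = None,
        rate_bounds: tuple[float, float] | None = None,
        n_rate_grid: int = 8,
        n_refine: int = 6,
        beta_min: float = 0.2,
        beta_start: float = 0.85,
        amp_cap_factor: float = 5.0,
        drift: bool = False,
    ) -> None:
        self.n_phases = n_phases
        self.stretched = stretched
        self.rate_bounds = rate_bounds
        self.n_rate_grid = n_rate_grid
        self.n_refine = n_refine
        self.beta_min = beta_min
        self.beta_start = beta_start
        self.amp_cap_factor = amp_cap_factor
        self.drift = drift

    # -- internals ---------------------------------------------------------
    def _default_rate_bounds(self, t: np.ndarray) -> tuple[float, float]:
        span = t[-1] - t[0]
        k_lo = 1.0 / (4.0 * span)
        k_hi = 1.0 / (2.0 * float(np.min(np.diff(t))))
        if t[0] > 0:
            k_hi = min(k_hi, math.log(1e4) / t[0])
        if k_hi <= k_lo * 10.0:
            k_hi = k_lo * 100.0
        return k_lo, k_hi

    def fit(self, X, y, sample_weight=None):
        t = _as_times(X)
        y = np.asarray(y, dtype=float)
        if y.shape != t.shape:
            raise InputError("X and y must have matching lengths")
        n = int(self.n_phases)
        if not 1 <= n <= 3:
            raise InputError("n_phases must be 1, 2 or 3")
        stretched_out = tuple(self.stretched) if self.stretched is not None else (False,) * n
        if len(stretched_out) != n:
            raise InputError("stretched must have one flag per phase")
        # Output order is fastest-first; the internal rate vector is ascending.
        stretched_asc = tuple(reversed(stretched_out))
        n_free = 1 + 2 * n + sum(stretched_asc) + (1 if self.drift else 0)
        if y.size < 10 * n_free:
            raise InputError(
                f"{y.size} samples are too few for {n_free} free parameters "
                f"(need at least {10 * n_free})"
            )
        weights = None if sample_weight is None else np.asarray(sample_weight, float)

        # Amplitudes larger than a few times the observed data range are
        # unphysical extrapolations; cap them (see _project).
        noise_scale = float(np.std(np.diff(y)) / math.sqrt(2.0)) if y.size > 2 else 0.0
        amp_cap = self.amp_cap_factor * max(float(np.ptp(y)), 10.0 * noise_scale, 1e-12)

        k_lo, k_hi = self.rate_bounds or self._default_rate_bounds(t)
        grid = np.geomspace(k_lo, k_hi, self.n_rate_grid)
        combos = list(itertools.combinations(range(self.n_rate_grid), n))
        beta0 = np.array([self.beta_start if s else 1.0 for s in stretched_asc])

        coarse = []
        for idx in combos:
            rates = grid[list(idx)]
            _, _, sse = _project(t, y, rates, beta0, weights, amp_cap, self.drift)
            coarse.append((sse, rates))
        coarse.sort(key=lambda c: c[0])

        n_beta = sum(stretched_asc)
        lo = np.concatenate([np.full(n, math.log(k_lo)), np.full(n_beta, self.beta_min)])
        hi = np.concatenate([np.full(n, math.log(k_hi)), np.full(n_beta, 1.0)])

        def unpack(x):
            rates = np.exp(x[:n])
            betas = np.ones(n)
            j = n
            for i, s in enumerate(stretched_asc):
                if s:
                    betas[i] = x[j]
                    j += 1
            return rates, betas

        def residual(x):
            rates, betas = unpack(x)
            _, resid, _ = _project(t, y, rates, betas, weights, amp_cap, self.drift)
            return resid if weights is None else resid * weights

        best = None
        for sse0, rates0 in coarse[: self.n_refine]:
            x0 = np.concatenate(
                [np.log(np.clip(rates0, k_lo, k_hi)), beta0[np.array(stretched_asc, bool)]]
            )
            try:
                res = optimize.least_squares(
                    residual, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14,
                    max_nfev=400,
                )
            except (ValueError, np.linalg.LinAlgError):
                continue
            sse = float(res.fun @ res.fun)
            if np.isfinite(sse) and (best is None or sse < best[0]):
                best = (sse, res.x)
        if best is None:
            raise FitFailureError("no optimizer start converged")
        sse, x = best
        rates, betas = unpack(x)
        coef, resid, sse = _project(t, y, rates, betas, weights, amp_cap, self.drift)

        order = np.argsort(-rates)  # fastest first
        self.baseline_ = float(coef[0])
        self.drift_ = float(coef[-1]) if self.drift else 0.0
        self.phases_ = tuple(
            Phase(amplitude=float(coef[1 + i]), rate=float(rates[i]), beta=float(betas[i]))
            for i in order
        )
        self.model_ = MultiExpModel(self.baseline_, self.phases_)
        self.residuals_ = resid
        self.sse_ = float(sse)
        amp = np.array([abs(p.amplitude) for p in self.phases_])
        total_abs = amp.sum()
        self.contributions_ = tuple(
            amp / total_abs if total_abs > 0 else np.full(n, 1.0 / n)
        )
        self.total_amplitude_ = float(sum(p.amplitude for p in self.phases_))
        self.runs_test_p_ = runs_test_pvalue(resid)
        self.rate_uncertain_ = tuple(p.rate > RATE_UNCERTAIN_THRESHOLD for p in self.phases_)
        self.window_ = (float(t[0]), float(t[-1]))
        self.n_samples_ = int(y.size)
        self.n_free_ = n_free
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        t = _as_times(X)
        return self.model_(t)


@dataclass
class MultiExpFit:
    """A fitted multi-exponential model plus its diagnostics."""

    model: MultiExpModel
    window: tuple[float, float]
    residuals: np.ndarray
    sse: float
    runs_test_p: float
    contributions: tuple[float, ...]
    total_amplitude: float
    rate_uncertain: tuple[bool, ...]
    n_samples: int
    n_free: int
    flags: tuple[str, ...] = ()
    drift: float = 0.0  # linear background (AU/s); excluded from amplitudes

    @property
    def n_phases(self) -> int:
        return len(self.model.phases)

    @property
    def rates(self) -> tuple[float, ...]:
        return tuple(p.rate for p in self.model.phases)

    @property
    def weighted_rate(self) -> float:
        """Contribution-weighted average rate (population-average statistic)."""
        return float(
            sum(c * p.rate for c, p in zip(self.contributions, self.model.phases))
        )

    def to_dict(self) -> dict:
        return {
            "baseline": self.model.baseline,
            "phases": [
                {
                    "amplitude": p.amplitude,
                    "rate": p.rate,
                    "beta": p.beta,
                    "contribution": c,
                    "rate_uncertain": u,
                }
                for p, c, u in zip(self.model.phases, self.contributions, self.rate_uncertain)
            ],
            "total_amplitude": self.total_amplitude,
            "weighted_rate": self.weighted_rate,
            "sse": self.sse,
            "runs_test_p": self.runs_test_p,
            "window_s": list(self.window),
            "n_samples": self.n_samples,
            "flags": list(self.flags),
        }


def _fit_from_estimator(est: MultiExponentialRegressor, flags: tuple[str, ...] = ()) -> MultiExpFit:
    return MultiExpFit(
        model=est.model_,
        window=est.window_,
        residuals=est.residuals_,
        sse=est.sse_,
        runs_test_p=est.runs_test_p_,
        contributions=tuple(float(c) for c in est.contributions_),
        total_amplitude=est.total_amplitude_,
        rate_uncertain=est.rate_uncertain_,
        n_samples=est.n_samples_,
        n_free=est.n_free_,
        flags=flags,
        drift=getattr(est, "drift_", 0.0),
    )


def fit_multiexp(
    trace: Trace,
    n_phases: int,
    allow_stretched: Sequence[bool] | None = None,
    window: tuple[float, float] | None = None,
    sample_weight=None,
    rate_bounds: tuple[float, float] | None = None,
    drift: bool = False,
) -> MultiExpFit:
    """Fit ``n_phases`` exponential phases to a trace (optionally windowed)."""
    if window is not None:
        trace = trace.window(*window)
    est = MultiExponentialRegressor(
        n_phases=n_phases, stretched=allow_stretched, rate_bounds=rate_bounds, drift=drift
    )
    est.fit(trace.times, trace.fluorescence, sample_weight=sample_weight)
    return _fit_from_estimator(est)


def select_model_order(
    trace: Trace,
    max_phases: int = 3,
    alpha: float = 0.01,
    min_contribution: float = 0.02,
    min_rate_separation: float = 1.5,
    window: tuple[float, float] | None = None,
    rate_bounds: tuple[float, float] | None = None,
    drift: bool = False,
) -> MultiExpFit:
    """Choose the number of phases by nested extra-sum-of-squares F-tests.

    ``n+1`` phases replace ``n`` only if the F-test is significant at
    ``alpha`` AND every contribution of the richer fit is at least
    ``min_contribution`` AND all its rates are mutually separated by at least
    ``min_rate_separation``-fold, so the chosen model never contains an
    unidentifiable rate pair.
    """
    if window is not None:
        trace = trace.window(*window)
    chosen = fit_multiexp(trace, 1, rate_bounds=rate_bounds, drift=drift)
    for n in range(2, max_phases + 1):
        try:
            candidate = fit_multiexp(trace, n, rate_bounds=rate_bounds, drift=drift)
        except (InputError, FitFailureError):
            break
        df_extra = candidate.n_free - chosen.n_free
        df_resid = candidate.n_samples - candidate.n_free
        if candidate.sse >= chosen.sse or df_resid <= 0:
            break
        f_stat = ((chosen.sse - candidate.sse) / df_extra) / (candidate.sse / df_resid)
        p_val = float(sstats.f.sf(f_stat, df_extra, df_resid))
        rates = np.sort(candidate.rates)
        separated = bool(np.all(rates[1:] / rates[:-1] >= min_rate_separation))
        if p_val < alpha and min(candidate.contributions) >= min_contribution and separated:
            chosen = candidate
        else:
            break
    return chosen


# -- single turnover -------------------------------------------------------


class SingleTurnoverRegressor(RegressorMixin, BaseEstimator):
    """Least-squares fit of the biphasic single-turnover hydrolysis curve.

    ``k1 > k2`` is enforced by the parameterization ``k1 = k2 (1 + e^theta)``;
    ``t0`` is fixed (default 0) unless ``fit_t0`` is set, reflecting that the
    dead-time offset is essentially unobservable. Only ``Fmax`` and ``k2``
    are flagged high-confidence: the fluorescence changes governing ``F0``,
    ``k1`` and ``t0`` partly fall into the unobserved dead time.
    """

    HIGH_CONFIDENCE = ("Fmax", "k2")

    def __init__(self, fit_t0: bool = False, n_ratio_grid: int = 10) -> None:
        self.fit_t0 = fit_t0
        self.n_ratio_grid = n_ratio_grid

    def fit(self, X, y):
        t = _as_times(X)
        y = np.asarray(y, dtype=float)
        if y.shape != t.shape:
            raise InputError("X and y must have matching lengths")
        if y.size < 40:
            raise InputError("too few samples for a single-turnover fit")
        noise = float(np.std(np.diff(y)) / math.sqrt(2.0)) if y.size > 2 else 0.0
        self.noise_estimate_ = noise

        # Smoothed peak-to-peak amplitude decides whether there is signal at all.
        win = max(5, y.size // 50)
        kernel = np.ones(win) / win
        smooth = np.convolve(y, kernel, mode="valid")
        signal_span = float(np.ptp(smooth))
        self.informative_ = signal_span >= 3.0 * max(noise, 1e-12)

        fmax0 = float(np.mean(y[-max(3, y.size // 20):]))
        span0 = max(signal_span, 10.0 * max(noise, 1e-12))
        # Tail estimate of k2 from the late single-exponential approach to Fmax.
        tail = slice(y.size // 2, None)
        u = fmax0 + max(3.0 * noise, 1e-9 * span0) - y[tail]
        ok = u > 0
        if ok.sum() >= 10:
            slope = np.polyfit(t[tail][ok], np.log(u[ok]), 1)[0]
            k2_init = max(-slope, 0.1 / (t[-1] - t[0]))
        else:
            k2_init = 2.0 / (t[-1] - t[0])

        def unpack(x):
            f0, fmax, lk2, theta = x[:4]
            k2 = math.exp(lk2)
            k1 = k2 * (1.0 + math.exp(theta))
            t0 = x[4] if self.fit_t0 else 0.0
            return f0, fmax, k1, k2, t0

        def residual(x):
            f0, fmax, k1, k2, t0 = unpack(x)
            tau = np.clip(t - t0, 0.0, None)
            span = fmax - f0
            model = f0 + span * np.exp(-k1 * tau) + span * (1.0 - np.exp(-k2 * tau))
            return model - y

        best = None
        for ratio in np.geomspace(1.5, 1e5, self.n_ratio_grid):
            x0 = [fmax0 - span0, fmax0, math.log(k2_init), math.log(ratio - 1.0)]
            if self.fit_t0:
                x0.append(0.0)
            try:
                res = optimize.least_squares(residual, x0, xtol=1e-14, ftol=1e-14, max_nfev=600)
            except (ValueError, np.linalg.LinAlgError):
                continue
            sse = float(res.fun @ res.fun)
            if np.isfinite(sse) and (best is None or sse < best[0]):
                best = (sse, res)
        if best is None:
            raise FitFailureError("single-turnover fit did not converge from any start")
        sse, res = best
        f0, fmax, k1, k2, t0 = unpack(res.x)
        self.F0_, self.Fmax_, self.k1_, self.k2_, self.t0_ = f0, fmax, k1, k2, t0
        self.sse_ = sse
        self.residuals_ = res.fun
        self.n_samples_ = int(y.size)

        # Asymptotic standard errors from the Jacobian at the optimum.
        dof = max(y.size - res.x.size, 1)
        try:
            cov = np.linalg.pinv(res.jac.T @ res.jac) * (sse / dof)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            se = np.full(res.x.size, np.nan)
        # Delta method for the log/ratio parameterization.
        self.stderr_ = {
            "F0": float(se[0]),
            "Fmax": float(se[1]),
            "k2": float(se[2] * k2),
            "k1": float(np.hypot(se[2] * k1, se[3] * (k1 - k2))),
            "t0": float(se[4]) if self.fit_t0 else 0.0,
        }
        flags = []
        if not self.informative_:
            flags.append("non_informative")
        dt_min = float(np.min(np.diff(t)))
        if k1 >= 0.5 / dt_min or (k1 > k2 and math.log(k1 / k2) / (k1 - k2) < t[0]):
            flags.append("k1_unresolved")
        self.flags_ = tuple(flags)
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        t = _as_times(X)
        tau = np.clip(t - self.t0_, 0.0, None)
        span = self.Fmax_ - self.F0_
        return self.F0_ + span * np.exp(-self.k1_ * tau) + span * (1.0 - np.exp(-self.k2_ * tau))


@dataclass
class SingleTurnoverFit:
    """Fitted single-turnover parameters with per-parameter confidence flags."""

    F0: float
    Fmax: float
    k1: float
    k2: float
    t0: float
    stderr: Mapping[str, float]
    high_confidence: Mapping[str, bool]
    sse: float
    residuals: np.ndarray
    n_samples: int
    flags: tuple[str, ...] = ()

    @property
    def model(self) -> SingleTurnoverModel:
        """The fitted model; raises if the fit is degenerate (Fmax <= F0)."""
        return SingleTurnoverModel(self.F0, self.Fmax, self.k1, self.k2, self.t0)

    def to_dict(self) -> dict:
        return {
            "F0": self.F0,
            "Fmax": self.Fmax,
            "k1": self.k1,
            "k2": self.k2,
            "t0": self.t0,
            "stderr": dict(self.stderr),
            "high_confidence": dict(self.high_confidence),
            "sse": self.sse,
            "n_samples": self.n_samples,
            "flags": list(self.flags),
        }


def fit_single_turnover(trace: Trace, fit_t0: bool = False) -> SingleTurnoverFit:
    """Fit the biphasic single-turnover curve to a plate-reader trace."""
    est = SingleTurnoverRegressor(fit_t0=fit_t0)
    est.fit(trace.times, trace.fluorescence)
    conf = {p: p in SingleTurnoverRegressor.HIGH_CONFIDENCE for p in ("F0", "Fmax", "k1", "k2", "t0")}
    return SingleTurnoverFit(
        F0=est.F0_,
        Fmax=est.Fmax_,
        k1=est.k1_,
        k2=est.k2_,
        t0=est.t0_,
        stderr=est.stderr_,
        high_confidence=conf,
        sse=est.sse_,
        residuals=est.residuals_,
        n_samples=est.n_samples_,
        flags=est.flags_,
    )


# -- long-trace splicing and two-window analysis ----------------------------


def splice_long_trace(
    short_fit: MultiExpFit,
    short_trace: Trace,
    long_trace: Trace,
    target_start: float = 10.0,
    t_ref: float = 0.025,
) -> Trace:
    """Y-transform the long recording onto the short recording's scale.

    The long trace is shifted by
    ``c = (target_start - Y0_short) + (y_short(t_ref) - y_long(t_ref))`` so
    the combined kinetics starts at ``target_start`` AU (the "10 V"
    convention) and the two recordings agree at the reference point
    (0.025 s). Both traces must cover ``t_ref`` (linear interpolation).
    """
    c = (target_start - short_fit.model.baseline) + (
        short_trace.value_at(t_ref) - long_trace.value_at(t_ref)
    )
    meta = dict(long_trace.metadata)
    meta["splice_constant_au"] = float(c)
    meta["splice_target_start_au"] = float(target_start)
    return Trace(long_trace.times, long_trace.fluorescence + c, meta)


@dataclass
class TwoWindowSummary:
    """Paired fast/slow analysis of a short and a spliced long recording."""

    fast_fit: MultiExpFit
    slow_fit: MultiExpFit
    amplitude_ratio: float
    rate_separation: float
    slow_family: str
    spliced_long: Trace
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "fast_fit": self.fast_fit.to_dict(),
            "slow_fit": self.slow_fit.to_dict(),
            "amplitude_ratio": self.amplitude_ratio,
            "rate_separation_orders": self.rate_separation,
            "slow_family": self.slow_family,
            "flags": list(self.flags),
        }


def analyze_two_windows(
    short_trace: Trace,
    long_trace: Trace,
    slow_model_family: str | Sequence[str] = ("biexp", "biexp_stretched", "triexp"),
    fast_window: tuple[float, float] | None = None,
    slow_window: tuple[float, float] = (10.0, 250.0),
    runs_alpha: float = 0.05,
    max_fast_phases: int = 3,
) -> TwoWindowSummary:
    """Fast fit, splice, slow-window fit, and the derived two-window summary.

    The slow families are tried in the given order; the first whose residual
    runs test exceeds ``runs_alpha`` is kept. If none passes, the one with
    the largest runs-test p-value is returned flagged ``residual-structure``.
    """
    families = [slow_model_family] if isinstance(slow_model_family, str) else list(slow_model_family)
    for fam in families:
        if fam not in SLOW_MODEL_FAMILIES:
            raise InputError(f"unknown slow model family {fam!r}")
    if fast_window is None:
        fast_window = (float(short_trace.times[0]), float(short_trace.times[-1]))
    if fast_window[1] > slow_window[0]:
        raise InputError("fast and slow windows must not overlap")

    fast_trace = short_trace.window(*fast_window)
    # Completeness bound: only phases that substantially finish inside the
    # fast window have trustworthy extrapolated amplitudes there; slower
    # structure (the onset of the slow rise) belongs to the slow window.
    tf = fast_trace.times
    fast_hi = min(1.0 / (2.0 * float(np.min(np.diff(tf)))), math.log(1e4) / tf[0]) if tf[0] > 0 else 1.0 / (2.0 * float(np.min(np.diff(tf))))
    fast_bounds = (2.0 / float(tf[-1] - tf[0]), fast_hi)
    # the linear drift column absorbs the in-window onset of the slow rise
    fast_fit = select_model_order(
        fast_trace, max_phases=max_fast_phases, rate_bounds=fast_bounds, drift=True
    )
    spliced = splice_long_trace(fast_fit, short_trace, long_trace)
    slow_trace = spliced.window(*slow_window)

    # Identifiability bounds for the late window: a component that has decayed
    # more than ~20-fold before the first sample cannot be recovered from it,
    # and allowing it lets noise acquire huge extrapolated amplitudes.
    t0 = float(slow_trace.times[0])
    span = float(slow_trace.times[-1] - t0)
    slow_bounds = (1.0 / span, math.log(20.0) / t0) if t0 > 0 else None

    slow_fit = None
    family_used = families[0]
    flags: tuple[str, ...] = ()
    tried: list[tuple[float, str, MultiExpFit]] = []
    for fam in families:
        n, stretched = SLOW_MODEL_FAMILIES[fam]
        try:
            cand = fit_multiexp(slow_trace, n, allow_stretched=stretched, rate_bounds=slow_bounds)
            if any(stretched):
                # A stretched term redistributes amplitude outside the window;
                # keep it only when it significantly beats the plain fit
                # (nested extra-sum-of-squares F-test, alpha 0.01).
                plain = fit_multiexp(slow_trace, n, rate_bounds=slow_bounds)
                df_resid = cand.n_samples - cand.n_free
                if cand.sse < plain.sse and df_resid > 0:
                    f_stat = (plain.sse - cand.sse) / (cand.sse / df_resid)
                    if float(sstats.f.sf(f_stat, 1, df_resid)) >= 0.01:
                        cand = plain
                else:
                    cand = plain
        except (InputError, FitFailureError):
            continue
        tried.append((cand.runs_test_p, fam, cand))
        if cand.runs_test_p > runs_alpha:
            slow_fit, family_used = cand, fam
            break
    if slow_fit is None:
        if not tried:
            raise FitFailureError("no slow-window model family produced a fit")
        _, family_used, slow_fit = max(tried, key=lambda x: x[0])
        flags = ("residual-structure",)

    fast_amp = abs(fast_fit.total_amplitude)
    slow_amp = abs(slow_fit.total_amplitude)
    amplitude_ratio = float(slow_amp / fast_amp) if fast_amp > 0 else math.inf
    rate_separation = float(math.log10(fast_fit.weighted_rate / slow_fit.weighted_rate))
    return TwoWindowSummary(
        fast_fit=fast_fit,
        slow_fit=slow_fit,
        amplitude_ratio=amplitude_ratio,
        rate_separation=rate_separation,
        slow_family=family_used,
        spliced_long=spliced,
        flags=flags,
    )
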