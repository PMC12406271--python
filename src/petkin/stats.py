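"""Population-level derived statistics.

* the contribution-weighted average rate, ``k_w = sum_i c_i k_i`` with
  ``c_i = |A_i| / sum_j |A_j|`` — the population-average kinetic statistic
  used to compare a perturbed reaction against its control;
* the equilibrium amplitude correction ``A_corr = A_obs / f_bound`` that
  rescales an observed amplitude to a per-complex amplitude when only a
  fraction of the chaperone is in complex with the client;
* descriptive variant-vs-reference fold-change tables (no hypothesis
  testing; the tidy CSV output is consumable by any stats environment).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import InputError, UndefinedRateError
from .fitting import MultiExpFit
from .models import BindingParams, fraction_bound

__all__ = [
    "WeightedRateResult",
    "VariantComparison",
    "weighted_rate",
    "correct_amplitude",
    "compare_variants",
]


@dataclass(frozen=True)
class WeightedRateResult:
    """Contribution-weighted average rate of a multi-exponential fit."""

    weighted_rate: float
    contributions: tuple[float, ...]
    rates: tuple[float, ...]
    source: MultiExpFit


def weighted_rate(fit: MultiExpFit) -> WeightedRateResult:
    """Average the phase rates weighted by their absolute-amplitude contribution.

    Always lies between the smallest and largest fitted rate. Raises
    :class:`UndefinedRateError` when every amplitude is zero (no signal, no
    weights).
    """
    amps = np.array([abs(p.amplitude) for p in fit.model.phases])
    if amps.sum() == 0:
        raise UndefinedRateError("all phase amplitudes are zero; weighted rate undefined")
    rates = np.array([p.rate for p in fit.model.phases])
    c = amps / amps.sum()
    return WeightedRateResult(
        weighted_rate=float(c @ rates),
        contributions=tuple(float(x) for x in c),
        rates=tuple(float(r) for r in rates),
        source=fit,
    )


def correct_amplitude(total_amplitude: float, bp: BindingParams) -> float:
    """Rescale an observed total amplitude by the fraction of chaperone in complex.

    ``A_corr = A_obs / fraction_bound(bp)``; raises :class:`InputError` when
    no complex forms (fraction bound is zero) since the correction is then a
    division by zero.
    """
    f = fraction_bound(bp)
    if f == 0:
        raise InputError(
            "no chaperone-client complex forms under these conditions "
            "(fraction bound = 0); the amplitude correction is undefined"
        )
    return float(total_amplitude) / f


@dataclass
class VariantComparison:
    """Per-probe fold changes of a variant against a reference."""

    table: pd.DataFrame
    rate_folds: dict[str, float]
    amplitude_folds: dict[str, float]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def compare_variants(
    variant_fits: Mapping[str, MultiExpFit],
    reference_fits: Mapping[str, MultiExpFit],
    variant_name: str = "variant",
    reference_name: str = "reference",
) -> VariantComparison:
    """Descriptive per-probe fold changes (weighted rate and signed total amplitude).

    Probes present in only one of the two sets are reported as absent rather
    than raising; a zero-valued reference yields an "undefined" marker (NaN
    fold), never an infinity.
    """
    rows = []
    rate_folds: dict[str, float] = {}
    amp_folds: dict[str, float] = {}
    for probe in sorted(set(variant_fits) | set(reference_fits)):
        v = variant_fits.get(probe)
        r = reference_fits.get(probe)
        if v is None or r is None:
            for quantity in ("weighted_rate", "total_amplitude"):
                rows.append(
                    dict(probe=probe, quantity=quantity, variant=np.nan, reference=np.nan,
                         fold=np.nan, flags="absent")
                )
            continue
        for quantity, vv, rv in (
            ("weighted_rate", weighted_rate(v).weighted_rate, weighted_rate(r).weighted_rate),
            ("total_amplitude", v.total_amplitude, r.total_amplitude),
        ):
            if rv == 0:
                fold, flag = np.nan, "undefined"
            else:
                fold, flag = vv / rv, ""
            rows.append(
                dict(probe=probe, quantity=quantity, variant=vv, reference=rv,
                     fold=fold, flags=flag)
            )
            if quantity == "weighted_rate":
                rate_folds[probe] = fold
            else:
                amp_folds[probe] = fold
    table = pd.DataFrame(rows)
    table.insert(0, "reference_name", reference_name)
    table.insert(0, "variant_name", variant_name)
    return VariantComparison(table=table, rate_folds=rate_folds, amplitude_folds=amp_folds)
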