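"""Named generative presets anchored to published values for this assay system.

The registry is loaded from the human-readable ``data/presets.yaml`` shipped
with the package. Binding presets describe ATP (or analog) association to a
labeled chaperone observed by stopped flow; the interface-variant presets
additionally carry a paired short/long (0.25 s / 250 s) scheme for the
SBDbeta-IB probe whose final slow step detaches the substrate-binding domain
again. Turnover presets describe the plate-reader single-turnover hydrolysis
assay.

Every preset number is tagged ``published`` (a published value for this
assay system) or ``synthetic`` (declared design value) in the YAML; fold-factor constraints
between presets (e.g. a variant's rate being an exact fraction of wild type)
are applied multiplicatively in code so they hold by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from importlib import resources
from typing import Mapping

import yaml

from .exceptions import RegistryError
from .models import QuenchingModel, SingleTurnoverModel
from .simulate import AcquisitionSpec, FlatTurnoverModel, KineticScheme, Subpopulation

__all__ = [
    "PresetRecord",
    "preset_library",
    "available_presets",
    "default_quenching_model",
    "binding_acquisition",
    "long_pair_acquisitions",
    "turnover_acquisition",
    "fold_constraints",
    "LONG_PAIR_PRESETS",
    "INTERFACE_VARIANTS",
]

#: Presets that carry a short/long trace-pair scheme.
LONG_PAIR_PRESETS = ("wt_ATP", "R151A", "D393A", "K414I", "D481A")
#: Interface variants showing the slow fluorescence re-increase.
INTERFACE_VARIANTS = ("R151A", "D393A", "K414I", "D481A")


@dataclass(frozen=True)
class PresetRecord:
    """One named entry of the preset registry."""

    name: str
    kind: str  # "binding" or "turnover"
    scheme: KineticScheme | None = None
    long_scheme: KineticScheme | None = None
    slow_family: str | None = None
    turnover_model: SingleTurnoverModel | FlatTurnoverModel | None = None
    rate_scale: float | None = None
    suggested_duration: float | None = None
    provenance: Mapping[str, str] | None = None


@lru_cache(maxsize=1)
def _registry_data() -> dict:
    text = resources.files("petkin.data").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def default_quenching_model() -> QuenchingModel:
    q = _registry_data()["quench_map"]
    return QuenchingModel(q["d_quench"], q["d_free"], q["q_floor"], q.get("sharpness", 1.0))


def _base_scheme() -> KineticScheme:
    base = _registry_data()["binding_base"]
    subs = tuple(
        Subpopulation(s["weight"], s["entry_rate"]) for s in base["subpopulations"]
    )
    return KineticScheme(
        state_names=tuple(base["state_names"]),
        distances={p: tuple(d) for p, d in base["distances"].items()},
        step_rates=tuple(base["step_rates"]),
        subpopulations=subs,
    )


def _weighted_entry_rate(scheme: KineticScheme) -> float:
    return sum(s.weight * s.entry_rate for s in scheme.subpopulations)


def _scaled_scheme(scheme: KineticScheme, scale: float) -> KineticScheme:
    subs = tuple(replace(s, entry_rate=s.entry_rate * scale) for s in scheme.subpopulations)
    return replace(
        scheme,
        step_rates=tuple(r * scale for r in scheme.step_rates),
        subpopulations=subs,
    )


def _binding_scheme(name: str, spec: dict) -> tuple[KineticScheme, float]:
    base = _base_scheme()
    distances = {p: list(d) for p, d in base.distances.items()}
    if "lid_open_distance" in spec:
        distances["lid"][-1] = float(spec["lid_open_distance"])
    base = replace(base, distances={p: tuple(d) for p, d in distances.items()})
    if spec.get("single_subpopulation"):
        fold = float(spec["weighted_rate_inverse_fold"])
        entry = _weighted_entry_rate(_base_scheme()) / fold
        scheme = replace(base, subpopulations=(Subpopulation(1.0, entry),))
        scale = entry / _weighted_entry_rate(_base_scheme())
        return scheme, scale
    scale = 1.0 / spec["inverse_fold"] if "inverse_fold" in spec else float(spec["rate_scale"])
    return _scaled_scheme(base, scale), scale


def _long_scheme(name: str) -> tuple[KineticScheme | None, str | None]:
    data = _registry_data()
    variants = data["long_pair_variants"]
    if name not in variants:
        return None, None
    base = data["long_pair_base"]
    spec = variants[name]
    d_apo, d_dock, d_open, d_s = base["sbdb_ib_distances"]
    entry = base["entry_rate"]
    hidden = base["hidden_entry_rate"]
    slow = tuple(base["slow_rates"])
    full_path = (d_apo, d_dock, d_open, d_s)
    mode = spec["mode"]
    if mode == "no_slow_state":
        # Wild-type-like: docking only, triphasic fast window, flat slow window.
        wt = _base_scheme()
        scheme = KineticScheme(
            state_names=("apo", "docked"),
            distances={"sbdb_ib": (d_apo, d_dock)},
            step_rates=(entry,),
            subpopulations=tuple(
                Subpopulation(s.weight, s.entry_rate) for s in wt.subpopulations
            ),
        )
    elif mode == "prerise_hidden":
        fold = float(spec["slow_to_fast_fold"])
        w_visible = 1.0 / fold
        pre_docked = {"sbdb_ib": (d_dock, d_dock, d_open, d_s)}
        scheme = KineticScheme(
            state_names=tuple(base["state_names"]),
            distances={"sbdb_ib": full_path},
            step_rates=(entry,) + slow,
            subpopulations=(
                Subpopulation(w_visible, entry),
                Subpopulation(1.0 - w_visible, hidden, pre_docked),
            ),
        )
    elif mode == "partial_rise":
        fold = float(spec["rise_to_drop_fold"])
        stuck = {"sbdb_ib": (d_apo, d_dock, d_dock, d_dock)}
        scheme = KineticScheme(
            state_names=tuple(base["state_names"]),
            distances={"sbdb_ib": full_path},
            step_rates=(entry,) + slow,
            subpopulations=(
                Subpopulation(fold, entry),
                Subpopulation(1.0 - fold, entry, stuck),
            ),
        )
    elif mode == "single":
        scheme = KineticScheme(
            state_names=tuple(base["state_names"]),
            distances={"sbdb_ib": full_path},
            step_rates=(entry,) + slow,
            subpopulations=(Subpopulation(1.0, entry),),
        )
    else:  # pragma: no cover - schema guard
        raise RegistryError(f"unknown long-pair mode {mode!r}")
    return scheme, spec.get("slow_family")


def _turnover_record(name: str, spec: dict) -> PresetRecord:
    base = _registry_data()["turnover_base"]
    if "flat_level" in spec:
        model: SingleTurnoverModel | FlatTurnoverModel = FlatTurnoverModel(spec["flat_level"])
        duration = 22000.0
    else:
        k1 = base["k1_fast"] if spec["k1"] == "fast" else base["k1_slow"]
        model = SingleTurnoverModel(
            F0=base["F0"], Fmax=base["Fmax"], k1=k1, k2=float(spec["k2"]), t0=base["t0"]
        )
        duration = math.ceil(3.5 / model.k2 / 100.0) * 100.0
    return PresetRecord(
        name=name,
        kind="turnover",
        turnover_model=model,
        suggested_duration=duration,
        provenance={"k2": spec.get("provenance", "synthetic")},
    )


@lru_cache(maxsize=None)
def preset_library(name: str) -> PresetRecord:
    """Look up a preset by name; unknown names raise :class:`RegistryError`."""
    data = _registry_data()
    if name in data["turnover_presets"]:
        return _turnover_record(name, data["turnover_presets"][name])
    if name in data["binding_variants"]:
        spec = data["binding_variants"][name]
        scheme, scale = _binding_scheme(name, spec)
        long_scheme, slow_family = _long_scheme(name)
        base_duration = data["binding_base"]["duration_s"]
        if spec.get("single_subpopulation"):
            duration = 5.0 / scheme.subpopulations[0].entry_rate
        else:
            duration = base_duration / scale
        return PresetRecord(
            name=name,
            kind="binding",
            scheme=scheme,
            long_scheme=long_scheme,
            slow_family=slow_family,
            rate_scale=scale,
            suggested_duration=duration,
            provenance={"summary": spec.get("provenance", "synthetic")},
        )
    raise RegistryError(
        f"unknown preset {name!r}; available: {', '.join(available_presets())}"
    )


def available_presets() -> tuple[str, ...]:
    data = _registry_data()
    return tuple(sorted(data["binding_variants"])) + tuple(sorted(data["turnover_presets"]))


def binding_acquisition(record: PresetRecord, seed: int, n_samples: int = 10000) -> AcquisitionSpec:
    """Default stopped-flow acquisition for a binding preset."""
    return AcquisitionSpec(
        duration=record.suggested_duration,
        n_samples=n_samples,
        spacing="linear",
        rng_seed=seed,
    )


def long_pair_acquisitions(seed: int) -> tuple[AcquisitionSpec, AcquisitionSpec]:
    """Default paired 0.25 s (dense linear) / 250 s (log-spaced) acquisitions.

    The two recordings get distinct deterministic seeds derived from ``seed``.
    """
    base = _registry_data()["long_pair_base"]
    short = AcquisitionSpec(
        duration=base["short_duration_s"], n_samples=10000, spacing="linear",
        rng_seed=2 * seed,
    )
    long = AcquisitionSpec(
        duration=base["long_duration_s"], n_samples=2000, spacing="log",
        rng_seed=2 * seed + 1,
    )
    return short, long


def turnover_acquisition(record: PresetRecord, seed: int, n_samples: int = 720) -> AcquisitionSpec:
    """Default plate-reader acquisition (regular cycles, no stopped-flow dead time)."""
    return AcquisitionSpec(
        duration=record.suggested_duration,
        n_samples=n_samples,
        spacing="linear",
        dead_time=0.0,
        rng_seed=seed,
    )


def fold_constraints() -> dict[str, tuple[float, float]]:
    """(stated, constructed) fold factors for every fold-constrained preset.

    Rate folds are wild-type weighted entry rate over the variant's; amplitude
    folds are the analytic slow/fast quench-amplitude ratios of the long-pair
    schemes. Constructed values must match the stated ones exactly.
    """
    data = _registry_data()
    qm = default_quenching_model()
    wt_rate = _weighted_entry_rate(_base_scheme())
    out: dict[str, tuple[float, float]] = {}
    for name, spec in data["binding_variants"].items():
        rec = preset_library(name)
        if "inverse_fold" in spec:
            out[f"{name}:rate_fold"] = (
                float(spec["inverse_fold"]),
                wt_rate / _weighted_entry_rate(rec.scheme),
            )
        elif spec.get("single_subpopulation"):
            out[f"{name}:rate_fold"] = (
                float(spec["weighted_rate_inverse_fold"]),
                wt_rate / rec.scheme.subpopulations[0].entry_rate,
            )
    for name, spec in data["long_pair_variants"].items():
        stated = spec.get("slow_to_fast_fold", spec.get("rise_to_drop_fold"))
        if stated is None:
            continue
        scheme = preset_library(name).long_scheme
        drop = rise = 0.0
        from .models import quench

        for j, sub in enumerate(scheme.subpopulations):
            d = scheme.probe_distances("sbdb_ib", j)
            drop += sub.weight * (quench(qm, d[1]) - quench(qm, d[0]))
            rise += sub.weight * (quench(qm, d[-1]) - quench(qm, d[1]))
        out[f"{name}:amplitude_fold"] = (float(stated), abs(rise) / abs(drop))
    return out
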