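"""Event-based vocabulary for three-population demographic scenarios.

A scenario relates three contemporary population clusters — ``A`` (Andean),
``B`` (northern Atlantic Forest) and ``C`` (central-southern Atlantic
Forest) — through an ordered set of demographic events: population splits,
instantaneous admixture pulses, size changes, bottlenecks and exponential
growth.  The default rooted shape is ``((A, B), C)``: A and B merge into an
ancestor ``AB`` at ``tdiv_AB``, which merges with C into ``ABC`` at
``tdiv_ABC``.

Candidate models are shipped as declarative YAML documents (one per model)
under :mod:`refugia.catalog`; event times, admixture fractions and sizes are
referenced there by parameter *symbol* and resolved against a parameter set
at simulation time.  Times are stored in **years** throughout and converted
to generations only inside the coalescent engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import yaml

__all__ = [
    "LEAF_POPULATIONS",
    "ANCESTOR_AB",
    "ANCESTOR_ABC",
    "EvolutionaryConstants",
    "Split",
    "Pulse",
    "SizeChange",
    "Bottleneck",
    "Growth",
    "DemographicModel",
    "ParameterSet",
    "years_to_generations",
    "generations_to_years",
    "count_free_parameters",
    "validate_model",
    "build_catalog",
    "available_profiles",
    "load_model",
    "save_model",
    "midpoint_parameters",
]

#: The three contemporary clusters.  For the ruficapillus/torquatus catalog
#: "A" denotes the torquatus cluster (the labelling is taxon-specific; the
#: topology is not).
LEAF_POPULATIONS = ("A", "B", "C")
ANCESTOR_AB = "AB"
ANCESTOR_ABC = "ABC"

ParameterSet = Mapping[str, float]
SymbolOrValue = Union[str, float]


@dataclass(frozen=True)
class EvolutionaryConstants:
    """Mutation rate (per site per generation) and generation time (years)."""

    mu: float = 2.5e-9
    gen_time: float = 2.33

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mutation rate must be positive")
        if self.gen_time <= 0:
            raise ValueError("generation time must be positive")


def years_to_generations(t: float, constants: EvolutionaryConstants) -> float:
    """Convert a time in years to generations (``t / gen_time``)."""
    if t < 0:
        raise ValueError("time must be non-negative")
    return t / constants.gen_time


def generations_to_years(g: float, constants: EvolutionaryConstants) -> float:
    """Inverse of :func:`years_to_generations`."""
    if g < 0:
        raise ValueError("time must be non-negative")
    return g * constants.gen_time


# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Split:
    """At ``time`` (backward) lineages of ``derived`` join ``ancestral``."""

    time: SymbolOrValue
    derived: str
    ancestral: str


@dataclass(frozen=True)
class Pulse:
    """Instantaneous admixture: forward in time, a ``fraction`` of ``dest``
    derives from ``source`` at ``time``.  Backward in time each lineage in
    ``dest`` moves to ``source`` independently with that probability."""

    time: SymbolOrValue
    source: str
    dest: str
    fraction: SymbolOrValue


@dataclass(frozen=True)
class SizeChange:
    """``pop`` has diploid size ``new_ne`` for all times older than ``time``."""

    time: SymbolOrValue
    pop: str
    new_ne: SymbolOrValue


@dataclass(frozen=True)
class Bottleneck:
    """At ``time`` the size of ``pop`` is multiplied by ``strength`` in (0, 1)
    for all older times (a historical contraction seen backward)."""

    time: SymbolOrValue
    pop: str
    strength: SymbolOrValue


@dataclass(frozen=True)
class Growth:
    """Exponential growth of ``pop`` at per-generation ``rate`` from the
    present: backward in time ``Ne(t) = Ne0 * exp(-rate * t)``."""

    pop: str
    rate: SymbolOrValue


Event = Union[Split, Pulse, SizeChange, Bottleneck, Growth]

_EVENT_KINDS = {
    "split": Split,
    "pulse": Pulse,
    "size_change": SizeChange,
    "bottleneck": Bottleneck,
    "growth": Growth,
}


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class DemographicModel:
    """A named three-population scenario.

    Parameters
    ----------
    name, model_type
        Catalog identity, e.g. ``"VI"`` / ``"Migrations and divergence"``.
    events
        Ordered event list; split times must define a valid rooted tree over
        the three leaves.
    bounds
        Per-symbol ``(lo, hi)`` box.  A symbol with ``lo == hi`` is fixed;
        free parameters are exactly the symbols with non-degenerate bounds.
    topology
        Rooted shape; only ``((A,B),C)`` is supported (relabel populations to
        express the alternatives).
    tie_ancestral_ne
        Symbol whose value the ancestral demes (AB, ABC) inherit unless the
        model declares ``Ne_AB`` / ``Ne_ABC`` explicitly.
    provenance
        ``"transcribed"`` for models pinned by the source tables,
        ``"inferred"`` for members reconstructed from the legend categories.
    """

    name: str
    model_type: str
    events: list = field(default_factory=list)
    bounds: dict = field(default_factory=dict)
    topology: str = "((A,B),C)"
    tie_ancestral_ne: str = "Ne_C"
    provenance: str = "inferred"

    @property
    def free_params(self) -> list[tuple[str, tuple[float, float]]]:
        return [(s, (lo, hi)) for s, (lo, hi) in self.bounds.items() if lo < hi]

    def symbols(self) -> list[str]:
        return list(self.bounds)

    def split_time_symbols(self) -> tuple[SymbolOrValue, SymbolOrValue]:
        """(tdiv_AB-like, tdiv_ABC-like) time references of the two splits."""
        t_ab = t_abc = None
        for ev in self.events:
            if isinstance(ev, Split):
                if ev.ancestral == ANCESTOR_AB:
                    t_ab = ev.time
                elif ev.ancestral == ANCESTOR_ABC:
                    t_abc = ev.time
        if t_ab is None or t_abc is None:
            raise ValueError(f"model {self.name!r} lacks a valid pair of splits")
        return t_ab, t_abc

    def resolve(self, ref: SymbolOrValue, params: ParameterSet) -> float:
        if isinstance(ref, str):
            try:
                return float(params[ref])
            except KeyError:
                raise KeyError(
                    f"model {self.name!r}: no value for symbol {ref!r}"
                ) from None
        return float(ref)


def count_free_parameters(model: DemographicModel) -> int:
    """Number of independently optimised scalars (``k`` in the AIC)."""
    return len(model.free_params)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _pulse_window(model: DemographicModel, ev: Pulse) -> str:
    """Which split bounds a pulse: A<->B pulses must predate the A/B split,
    anything touching C or the AB ancestor must predate the root split."""
    pops = {ev.source, ev.dest}
    if pops <= {"A", "B"}:
        return "AB"
    return "ABC"


def validate_model(model: DemographicModel, params: ParameterSet,
                   rtol: float = 1e-9) -> list[str]:
    """Check a parameter set against the model's invariants.

    Returns a list of human-readable violations (empty when valid).
    Violations are data, not exceptions.
    """
    out: list[str] = []
    get = lambda ref: model.resolve(ref, params)  # noqa: E731

    for sym, (lo, hi) in model.bounds.items():
        if sym not in params:
            out.append(f"missing value for {sym}")
            continue
        v = float(params[sym])
        slack = rtol * max(abs(lo), abs(hi), 1.0)
        if v < lo - slack or v > hi + slack:
            out.append(f"{sym}={v:g} outside bounds [{lo:g}, {hi:g}]")

    try:
        t_ab = get(model.split_time_symbols()[0])
        t_abc = get(model.split_time_symbols()[1])
    except (KeyError, ValueError) as exc:
        out.append(str(exc))
        return out
    if t_ab < 0 or t_abc < 0:
        out.append("split times must be non-negative")
    if t_ab > t_abc * (1 + rtol):
        out.append(f"tdiv(A/B)={t_ab:g} exceeds tdiv(AB/C)={t_abc:g}")

    for ev in model.events:
        try:
            if isinstance(ev, Pulse):
                t = get(ev.time)
                p = get(ev.fraction)
                if t < 0:
                    out.append(f"pulse time {t:g} is negative")
                if not (0.0 <= p <= 1.0):
                    out.append(f"pulse fraction {p:g} outside [0, 1]")
                limit = t_ab if _pulse_window(model, ev) == "AB" else t_abc
                if t > limit * (1 + rtol):
                    out.append(
                        f"pulse {ev.source}->{ev.dest} at {t:g} postdates the "
                        f"split that merges it ({limit:g})"
                    )
            elif isinstance(ev, (SizeChange, Bottleneck)):
                t = get(ev.time)
                if t < 0:
                    out.append(f"event time {t:g} is negative")
                limit = t_ab if ev.pop in ("A", "B") else t_abc
                if ev.pop in ("A", "B", "C") and t > limit * (1 + rtol):
                    out.append(f"event in {ev.pop} at {t:g} postdates the deme")
                if isinstance(ev, Bottleneck):
                    s = get(ev.strength)
                    if not (0.0 < s <= 1.0):
                        out.append(f"bottleneck strength {s:g} outside (0, 1]")
                else:
                    if get(ev.new_ne) <= 0:
                        out.append("size change to non-positive Ne")
        except KeyError as exc:
            out.append(str(exc))

    for sym in ("Ne_A", "Ne_B", "Ne_C"):
        if sym in params and float(params[sym]) <= 0:
            out.append(f"{sym} must be positive")
    return out


def midpoint_parameters(model: DemographicModel) -> dict[str, float]:
    """A canonical valid parameter point: the geometric midpoint of each
    symbol's bounds (arithmetic for ranges that include zero), with event
    times placed at 40% of the divergence that bounds them so the event
    ordering invariants hold by construction."""
    mid = {}
    for sym, (lo, hi) in model.bounds.items():
        if lo == hi:
            mid[sym] = lo
        elif lo > 0:
            mid[sym] = math.sqrt(lo * hi)
        else:
            mid[sym] = 0.5 * (lo + hi)
    t_ab, t_abc = model.split_time_symbols()
    for ev in model.events:
        window = None
        if isinstance(ev, Pulse):
            window = t_ab if {ev.source, ev.dest} <= {"A", "B"} else t_abc
        elif isinstance(ev, (SizeChange, Bottleneck)):
            window = t_ab if ev.pop in ("A", "B") else t_abc
        if window is not None and isinstance(ev.time, str):
            mid[ev.time] = 0.4 * (mid[window] if isinstance(window, str)
                                  else float(window))
    return mid


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _event_to_doc(ev: Event) -> dict:
    for kind, cls in _EVENT_KINDS.items():
        if isinstance(ev, cls):
            doc = {"kind": kind}
            doc.update(ev.__dict__)
            return doc
    raise TypeError(f"unknown event {ev!r}")


def _event_from_doc(doc: Mapping) -> Event:
    doc = dict(doc)
    kind = doc.pop("kind")
    try:
        cls = _EVENT_KINDS[kind]
    except KeyError:
        raise ValueError(f"unknown event kind {kind!r}") from None
    return cls(**doc)


def model_to_doc(model: DemographicModel) -> dict:
    return {
        "name": model.name,
        "model_type": model.model_type,
        "topology": model.topology,
        "provenance": model.provenance,
        "tie_ancestral_ne": model.tie_ancestral_ne,
        "events": [_event_to_doc(ev) for ev in model.events],
        "bounds": {s: [float(lo), float(hi)]
                   for s, (lo, hi) in model.bounds.items()},
    }


def model_from_doc(doc: Mapping) -> DemographicModel:
    return DemographicModel(
        name=str(doc["name"]),
        model_type=str(doc["model_type"]),
        topology=doc.get("topology", "((A,B),C)"),
        provenance=doc.get("provenance", "inferred"),
        tie_ancestral_ne=doc.get("tie_ancestral_ne", "Ne_C"),
        events=[_event_from_doc(e) for e in doc.get("events", [])],
        bounds={s: (float(b[0]), float(b[1]))
                for s, b in doc.get("bounds", {}).items()},
    )


def save_model(model: DemographicModel, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(model_to_doc(model), sort_keys=False))


def load_model(path: str | Path) -> DemographicModel:
    return model_from_doc(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Catalog
# ---------------------------------------------------------------------------

def _catalog_root():
    return resources.files("refugia") / "catalog"


def available_profiles() -> dict:
    with resources.as_file(_catalog_root() / "profiles.yaml") as p:
        return yaml.safe_load(p.read_text())


def _apply_overrides(model: DemographicModel, overrides: Mapping) -> DemographicModel:
    model = replace(model)
    for key, val in overrides.items():
        if key == "bounds":
            new_bounds = dict(model.bounds)
            for sym, b in val.items():
                if sym not in new_bounds:
                    raise ValueError(
                        f"override names unknown symbol {sym!r} in model {model.name!r}")
                new_bounds[sym] = (float(b[0]), float(b[1]))
            model.bounds = new_bounds
        elif key in ("model_type", "tie_ancestral_ne"):
            setattr(model, key, val)
        else:
            raise ValueError(f"malformed override field {key!r}")
    return model


def build_catalog(taxon_profile: str | Mapping) -> list[DemographicModel]:
    """Load the candidate-model catalog for a taxon profile.

    ``taxon_profile`` is either a profile name from ``catalog/profiles.yaml``
    (``"mentalis"``, ``"caerulescens"``, ``"palliatus"``, ``"ruficapillus"``,
    ``"full"``) or a mapping ``{"models": [...], "overrides": {name: {...}}}``.
    """
    if isinstance(taxon_profile, str):
        profiles = available_profiles()
        if taxon_profile not in profiles:
            raise ValueError(
                f"unknown profile {taxon_profile!r}; "
                f"known: {sorted(profiles)}")
        profile = profiles[taxon_profile]
    else:
        profile = dict(taxon_profile)

    names: Sequence[str] = profile["models"]
    overrides: Mapping = profile.get("overrides", {}) or {}
    root = _catalog_root()
    catalog = []
    for name in names:
        res = root / f"model_{name}.yaml"
        try:
            text = res.read_text()
        except FileNotFoundError:
            raise ValueError(f"unknown model name {name!r} in profile") from None
        model = model_from_doc(yaml.safe_load(text))
        if name in overrides:
            model = _apply_overrides(model, overrides[name])
        catalog.append(model)
    return catalog
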