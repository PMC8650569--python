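"""Synthetic cfu time-course generator for a four-species model biofilm.

The community comprises *Rhodocyclus* sp. (Rh), *Pseudomonas fluorescens*
(Pf), *Kocuria varians* (Kv) and *Bacillus cereus* (Bc) grown on
stainless-steel chips and enumerated by plate counts.  Each species follows
a lag-logistic trajectory whose parameters depend on which other community
members are present; interspecies interactions are emulated as
context-dependent parameter modifiers rather than coupled dynamics:

* Kv: its carrying capacity collapses a few-hundred-fold whenever Bc is
  present (thiocillin-mediated amensalism), an effect partially relieved
  ("mitigated") when Pf and/or Rh are also present.
* Pf: in any mixed community its development is delayed (lag 33 h) while
  growing faster and to a somewhat lower plateau once started.
* Rh: the other species facilitate its adhesion and early development
  (higher starting density, no lag); alone it starts below the detection
  limit and stays undetectable through 24 h.
* Bc: net growth in the biofilm is zero; its level is constant.

Observation noise is lognormal (normal on log10 counts) and observations
below the detection limit (default 1e3 cfu cm^-2) are recorded at the limit
with a censoring flag.  Every (context, replicate) pair owns an independent
RNG stream derived from the master seed, so adding contexts never perturbs
existing draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .growth import GrowthParams, logistic_value

__all__ = [
    "SpeciesSpec",
    "InteractionModifier",
    "Context",
    "ScenarioConfig",
    "SPECIES",
    "FULL_NAMES",
    "default_scenario",
    "delta_tcl_scenario",
    "planktonic_scenario",
    "undiluted_medium_scenario",
    "bc_dilution_scenario",
    "glass_scenario",
    "scenario",
    "list_scenarios",
    "effective_params",
    "simulate_counts",
    "simulate_planktonic",
    "scenario_to_yaml",
    "scenario_from_yaml",
]

SPECIES = ("Rh", "Pf", "Kv", "Bc")
FULL_NAMES = {
    "Rh": "Rhodocyclus sp.",
    "Pf": "Pseudomonas fluorescens",
    "Kv": "Kocuria varians",
    "Bc": "Bacillus cereus",
}

# Community-context anchor densities (cfu cm^-2).  Mono-culture parameters
# and the 72-h endpoint levels of K. varians under each omission design are
# the quantities the modifiers below are solved against.
_KV_MONO_K = 2.1e7
_KV_FULL = 5.4e4       # 72-h level, four-species community
_KV_NO_PF = 1.2e4      # 72-h level when Pf omitted
_KV_NO_RH = 3.5e3      # 72-h level when Rh omitted
_KV_MITIGATION_PF = _KV_FULL / _KV_NO_PF          # 4.5-fold relief by Pf
_KV_MITIGATION_RH = _KV_FULL / _KV_NO_RH          # ~15.4-fold relief by Rh
_KV_SUPPRESSION = _KV_FULL / (_KV_MONO_K * _KV_MITIGATION_PF * _KV_MITIGATION_RH)

_BC_MONO = 7.9e4       # constant Bc level alone
_BC_COMMUNITY = 2.3e5  # constant Bc level in any mixed biofilm


@dataclass(frozen=True)
class SpeciesSpec:
    """One community member: label, mono-culture growth parameters and the
    inoculum density used in the adhesion step (cfu ml^-1)."""

    name: str
    base_params: GrowthParams
    adhesion_input: float = 5e6

    def __post_init__(self) -> None:
        if self.adhesion_input <= 0:
            raise ValueError("adhesion_input must be positive")


@dataclass(frozen=True)
class InteractionModifier:
    """Context-dependent change of one growth parameter of ``target``.

    The modifier applies when the required ``source`` species are present
    alongside the target: with ``trigger='all'`` every source species must
    be present, with ``trigger='any'`` at least one.  Multiplicative
    modifiers compose by product and additive ones by sum, so application
    order never matters.
    """

    source: frozenset
    target: str
    parameter: str  # one of x0, mu, K, tau
    mode: str       # multiply | add
    value: float
    trigger: str = "all"  # all | any

    def __post_init__(self) -> None:
        object.__setattr__(self, "source", frozenset(self.source))
        if self.parameter not in ("x0", "mu", "K", "tau"):
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.mode not in ("multiply", "add"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.trigger not in ("all", "any"):
            raise ValueError(f"unknown trigger {self.trigger!r}")
        if self.mode == "multiply" and not self.value > 0:
            raise ValueError("multiplicative modifier value must be > 0")

    def applies(self, others: frozenset) -> bool:
        if self.trigger == "all":
            return self.source <= others
        return bool(self.source & others)


@dataclass(frozen=True)
class Context:
    """A labelled species subset to simulate (e.g. mono, omission, full)."""

    label: str
    members: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))


@dataclass(frozen=True)
class ScenarioConfig:
    species: tuple
    modifiers: tuple = ()
    contexts: tuple = ()
    times: tuple = (0.0, 24.0, 48.0, 72.0, 96.0)
    replicates: int = 5
    noise_sd: float = 0.1          # lognormal sigma in log10 units
    detection_limit: float = 1e3   # cfu cm^-2
    seed: int | None = None
    unit: str = "cfu_cm2"          # cfu_cm2 (biofilm) | cfu_ml (planktonic)
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        names = {s.name for s in self.species}
        for m in self.modifiers:
            unknown = (set(m.source) | {m.target}) - names
            if unknown:
                raise ValueError(f"modifier references unknown species {unknown}")
        for c in self.contexts:
            if not c.members <= names:
                raise ValueError(f"context {c.label!r} has unknown members")

    def species_spec(self, name: str) -> SpeciesSpec:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(f"unknown species {name!r}")

    @property
    def species_names(self) -> tuple:
        return tuple(s.name for s in self.species)


def _standard_contexts(names: Sequence[str]) -> tuple:
    all_members = frozenset(names)
    contexts = [Context(f"mono_{n}", frozenset({n})) for n in names]
    contexts += [Context(f"no_{n}", all_members - {n}) for n in names]
    contexts.append(Context("full", all_members))
    return tuple(contexts)


def default_scenario(seed: int | None = None, replicates: int = 5,
                     noise_sd: float = 0.1) -> ScenarioConfig:
    """Wild-type four-species biofilm: mono, omission and full contexts.

    Base parameters are the mono-culture estimates; modifiers reproduce the
    community-context estimates (Pf: mu 0.94 h^-1, K 5.8e6, lag 33 h;
    Rh: x0 2.9e3, mu 0.25, K 8.3e6, no lag) and the 72-h K. varians levels
    of the omission designs (5.4e4 full, 1.2e4 without Pf, 3.5e3 without
    Rh, 2.1e7 without Bc).
    """
    species = (
        # Alone, Rh adheres below the detection limit (preset 5e2) and is
        # still undetectable at 24 h; it then grows to a plateau of 1.5e7.
        SpeciesSpec("Rh", GrowthParams(x0=5e2, mu=0.5, K=1.5e7, tau=24.0)),
        SpeciesSpec("Pf", GrowthParams(x0=2.7e4, mu=0.25, K=1.7e7, tau=0.0)),
        SpeciesSpec("Kv", GrowthParams(x0=7.7e4, mu=1.93, K=_KV_MONO_K, tau=3.0)),
        # Zero net growth: constant at x0 (mu = 0).
        SpeciesSpec("Bc", GrowthParams(x0=_BC_MONO, mu=0.0, K=_BC_MONO, tau=0.0)),
    )
    others = lambda n: frozenset(SPECIES) - {n}  # noqa: E731
    modifiers = (
        # Rh: facilitation of adhesion and early development by any partner.
        InteractionModifier(others("Rh"), "Rh", "x0", "multiply", 2.9e3 / 5e2, "any"),
        InteractionModifier(others("Rh"), "Rh", "mu", "multiply", 0.25 / 0.5, "any"),
        InteractionModifier(others("Rh"), "Rh", "K", "multiply", 8.3e6 / 1.5e7, "any"),
        InteractionModifier(others("Rh"), "Rh", "tau", "add", -24.0, "any"),
        # Pf: delayed development in any mixed community.
        InteractionModifier(others("Pf"), "Pf", "mu", "multiply", 0.94 / 0.25, "any"),
        InteractionModifier(others("Pf"), "Pf", "K", "multiply", 5.8e6 / 1.7e7, "any"),
        InteractionModifier(others("Pf"), "Pf", "tau", "add", 33.0, "any"),
        # Bc: constant level, about threefold higher in mixed communities.
        InteractionModifier(others("Bc"), "Bc", "x0", "multiply",
                            _BC_COMMUNITY / _BC_MONO, "any"),
        InteractionModifier(others("Bc"), "Bc", "K", "multiply",
                            _BC_COMMUNITY / _BC_MONO, "any"),
        # Bc -> Kv amensalism: capacity suppression whenever Bc is present,
        # mitigated multiplicatively by the presence of Pf and of Rh.
        InteractionModifier(frozenset({"Bc"}), "Kv", "K", "multiply",
                            _KV_SUPPRESSION),
        InteractionModifier(frozenset({"Bc", "Pf"}), "Kv", "K", "multiply",
                            _KV_MITIGATION_PF),
        InteractionModifier(frozenset({"Bc", "Rh"}), "Kv", "K", "multiply",
                            _KV_MITIGATION_RH),
    )
    return ScenarioConfig(
        species=species, modifiers=modifiers,
        contexts=_standard_contexts(SPECIES),
        replicates=replicates, noise_sd=noise_sd, seed=seed, name="default",
    )


def delta_tcl_scenario(seed: int | None = None, replicates: int = 5,
                       noise_sd: float = 0.1) -> ScenarioConfig:
    """Thiocillin-null preset: the Bc strain lacking the thiocillin
    structural genes no longer suppresses K. varians, so every Bc-sourced
    modifier of Kv is removed and Kv keeps its mono-culture capacity in the
    community."""
    base = default_scenario(seed=seed, replicates=replicates, noise_sd=noise_sd)
    modifiers = tuple(
        m for m in base.modifiers
        if not (m.target == "Kv" and "Bc" in m.source)
    )
    return replace(base, modifiers=modifiers, name="delta_tclEH")


#: 72-h planktonic coculture composition (% of total counts).
PLANKTONIC_PROPORTIONS = {"Bc": 38.2, "Rh": 29.8, "Pf": 18.0, "Kv": 14.0}
_PLANKTONIC_TOTAL = 5e8  # cfu ml^-1 at 72 h


def planktonic_scenario(seed: int | None = None, replicates: int = 5,
                        noise_sd: float = 0.1) -> ScenarioConfig:
    """Liquid coculture preset: proportions are far more even than in the
    biofilm and the Bc -> Kv suppression is absent (the inhibitory activity
    stays cell-associated).  All species start from the 5e6 cfu ml^-1
    inoculum and reach their capacity well before 72 h."""
    species = tuple(
        SpeciesSpec(n, GrowthParams(
            x0=5e6, mu=0.5,
            K=_PLANKTONIC_TOTAL * PLANKTONIC_PROPORTIONS[n] / 100.0, tau=0.0))
        for n in SPECIES
    )
    return ScenarioConfig(
        species=species, modifiers=(),
        contexts=(Context("plk_full", frozenset(SPECIES)),),
        replicates=replicates, noise_sd=noise_sd, seed=seed,
        unit="cfu_ml", name="planktonic",
    )


def undiluted_medium_scenario(seed: int | None = None, replicates: int = 7,
                              noise_sd: float = 0.1) -> ScenarioConfig:
    """Continuous perturbation: undiluted growth medium (20x nutrients).

    The biofilm becomes Pf-dominated (6.2e7 cfu cm^-2), Bc rises about
    18-fold to 4.3e6, Kv stays a minority at 1.8e5 and Rh falls below the
    detection limit in every replicate (seven data sets in the source
    design, hence the default of 7 replicates).  Parameters here are
    community-effective values for the full context only.
    """
    species = (
        SpeciesSpec("Rh", GrowthParams(x0=5e2, mu=0.0, K=5e2, tau=0.0)),
        SpeciesSpec("Pf", GrowthParams(x0=2.7e4, mu=0.94, K=6.2e7, tau=0.0)),
        SpeciesSpec("Kv", GrowthParams(x0=7.7e4, mu=0.25, K=1.8e5, tau=0.0)),
        SpeciesSpec("Bc", GrowthParams(x0=7.9e4, mu=0.25, K=4.3e6, tau=0.0)),
    )
    return ScenarioConfig(
        species=species, modifiers=(),
        contexts=(Context("full", frozenset(SPECIES)),),
        replicates=replicates, noise_sd=noise_sd, seed=seed,
        name="undiluted_medium",
    )


def bc_dilution_scenario(seed: int | None = None, replicates: int = 5,
                         noise_sd: float = 0.1) -> ScenarioConfig:
    """Transient perturbation: B. cereus inoculum reduced 1000-fold.

    Bc adheres at ~2.5e3 cfu cm^-2 but regrows to the same equilibrium
    level as under standard conditions, so the 72-h composition is
    unchanged (the community is robust to this perturbation)."""
    base = default_scenario(seed=seed, replicates=replicates, noise_sd=noise_sd)
    species = tuple(
        replace(s, base_params=GrowthParams(x0=2.5e3, mu=0.5, K=_BC_MONO, tau=0.0))
        if s.name == "Bc" else s
        for s in base.species
    )
    return replace(base, species=species,
                   contexts=(Context("full", frozenset(SPECIES)),),
                   name="bc_dilution_1000")


def glass_scenario(seed: int | None = None, replicates: int = 5,
                   noise_sd: float = 0.1) -> ScenarioConfig:
    """Continuous perturbation: glass substratum instead of stainless steel.
    The Bc equilibrium proportion rises roughly tenfold; other species are
    little affected."""
    base = default_scenario(seed=seed, replicates=replicates, noise_sd=noise_sd)
    others = frozenset(SPECIES) - {"Bc"}
    extra = (
        InteractionModifier(others, "Bc", "x0", "multiply", 10.0, "any"),
        InteractionModifier(others, "Bc", "K", "multiply", 10.0, "any"),
    )
    return replace(base, modifiers=base.modifiers + extra,
                   contexts=(Context("full", frozenset(SPECIES)),),
                   name="glass")


_SCENARIOS = {
    "default": default_scenario,
    "wild_type": default_scenario,
    "delta_tclEH": delta_tcl_scenario,
    "planktonic": planktonic_scenario,
    "undiluted_medium": undiluted_medium_scenario,
    "bc_dilution_1000": bc_dilution_scenario,
    "glass": glass_scenario,
}


def scenario(name: str, **kwargs) -> ScenarioConfig:
    """Look up a named scenario preset."""
    try:
        return _SCENARIOS[name](**kwargs)
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(_SCENARIOS)}"
        ) from None


def list_scenarios() -> list:
    return sorted(_SCENARIOS)


def effective_params(species: str, context: Iterable[str],
                     config: ScenarioConfig) -> GrowthParams:
    """Growth parameters of ``species`` in a given community context.

    Every modifier triggered by the *other* members of the context is
    applied to the mono-culture base parameters; multiplicative modifiers
    compose by product and additive ones by sum (commutative), with
    multiplication applied before addition.
    """
    members = frozenset(context)
    if species not in members:
        raise ValueError(f"{species!r} not in context {sorted(members)}")
    spec = config.species_spec(species)
    others = members - {species}
    values = {"x0": spec.base_params.x0, "mu": spec.base_params.mu,
              "K": spec.base_params.K, "tau": spec.base_params.tau}
    mult = {k: 1.0 for k in values}
    add = {k: 0.0 for k in values}
    for m in config.modifiers:
        if m.target == species and m.applies(others):
            if m.mode == "multiply":
                mult[m.parameter] *= m.value
            else:
                add[m.parameter] += m.value
    out = {k: values[k] * mult[k] + add[k] for k in values}
    for k in ("tau", "mu"):
        if -1e-9 < out[k] < 0:
            out[k] = 0.0
    return GrowthParams(x0=out["x0"], mu=out["mu"], K=out["K"], tau=out["tau"])


def _stream(seed: int | None, context_label: str, replicate: int) -> np.random.Generator:
    entropy = [zlib.crc32(context_label.encode()), replicate]
    if seed is not None:
        entropy.insert(0, int(seed) % (2**31))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def simulate_counts(config: ScenarioConfig) -> pd.DataFrame:
    """Simulate a long-format count table for every configured context.

    For each (context, species, replicate, time) the expected value is the
    closed-form lag-logistic count under the context-effective parameters;
    the observation multiplies it by ``10**eps`` with
    ``eps ~ Normal(0, noise_sd)``.  Observations below the detection limit
    are stored at the limit with ``censored=True``.
    """
    rows = []
    times = np.asarray(config.times, dtype=float)
    for ctx in config.contexts:
        members = sorted(ctx.members, key=config.species_names.index)
        params = {s: effective_params(s, ctx.members, config) for s in members}
        truth = {}
        for s in members:
            p = params[s]
            if p.defined:
                truth[s] = np.asarray(logistic_value(times, p), dtype=float)
            else:  # pragma: no cover - presets always keep mu/tau defined
                truth[s] = np.full(times.shape, p.K)
        for rep in range(1, config.replicates + 1):
            rng = _stream(config.seed, ctx.label, rep)
            for s in members:
                eps = rng.standard_normal(times.size) * config.noise_sd
                obs = truth[s] * 10.0 ** eps
                cens = obs < config.detection_limit
                obs = np.where(cens, config.detection_limit, obs)
                for t, v, c in zip(times, obs, cens):
                    rows.append((ctx.label, s, rep, float(t), float(v), bool(c),
                                 config.detection_limit))
    return pd.DataFrame(rows, columns=[
        "context", "species", "replicate", "time_h", "cfu_per_cm2",
        "censored", "detection_limit",
    ])


def simulate_planktonic(config: ScenarioConfig | None = None,
                        seed: int | None = None) -> pd.DataFrame:
    """Simulate the liquid-coculture preset (counts in cfu ml^-1)."""
    if config is None:
        config = planktonic_scenario(seed=seed)
    elif config.unit != "cfu_ml":
        raise ValueError("planktonic simulation expects a cfu_ml scenario")
    return simulate_counts(config)


# --- YAML (de)serialisation -------------------------------------------------

def _params_dict(p: GrowthParams) -> dict:
    return {"x0": p.x0, "mu": p.mu, "K": p.K, "tau": p.tau}


def scenario_to_yaml(config: ScenarioConfig) -> str:
    doc = {
        "name": config.name,
        "unit": config.unit,
        "times": list(map(float, config.times)),
        "replicates": config.replicates,
        "noise_sd": config.noise_sd,
        "detection_limit": config.detection_limit,
        "seed": config.seed,
        "species": [
            {"name": s.name, "adhesion_input": s.adhesion_input,
             "params": _params_dict(s.base_params)}
            for s in config.species
        ],
        "modifiers": [
            {"source": sorted(m.source), "target": m.target,
             "parameter": m.parameter, "mode": m.mode, "value": m.value,
             "trigger": m.trigger}
            for m in config.modifiers
        ],
        "contexts": [
            {"label": c.label, "members": sorted(c.members)}
            for c in config.contexts
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def scenario_from_yaml(text: str) -> ScenarioConfig:
    doc = yaml.safe_load(text)
    species = tuple(
        SpeciesSpec(s["name"], GrowthParams(**s["params"]),
                    s.get("adhesion_input", 5e6))
        for s in doc["species"]
    )
    modifiers = tuple(
        InteractionModifier(frozenset(m["source"]), m["target"], m["parameter"],
                            m["mode"], m["value"], m.get("trigger", "all"))
        for m in doc.get("modifiers", [])
    )
    contexts = tuple(
        Context(c["label"], frozenset(c["members"])) for c in doc["contexts"]
    )
    return ScenarioConfig(
        species=species, modifiers=modifiers, contexts=contexts,
        times=tuple(doc["times"]), replicates=doc["replicates"],
        noise_sd=doc["noise_sd"], detection_limit=doc["detection_limit"],
        seed=doc.get("seed"), unit=doc.get("unit", "cfu_cm2"),
        name=doc.get("name", "custom"),
    )
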