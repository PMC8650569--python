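"""Signed interspecies-interaction inference from omission designs.

The experimental logic: grow each species alone, the full community, and
every community-minus-one ("omission") variant, then compare each target
species' endpoint abundance in the full community against each omission.

* Omitting X significantly *increases* target Y  =>  X -> Y negative.
  If X's own abundance is unaffected by the presence of Y (reciprocal
  check) the negative edge is amensalism, otherwise competition.
* Omitting Z significantly *decreases* Y while a negative W -> Y edge
  exists  =>  Z -> Y positive of type mitigation (Z relieves the W -> Y
  suppression); without such a conditioning edge the positive effect is
  facilitation.

Significance is judged by the two-sided Mann-Whitney test on endpoint
abundances at level ``alpha``; on top of that an effect-size floor (default
threefold, i.e. 0.5 log10) is required so that large designs cannot call
edges on significance without magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .growth import FitResult
from .stats import mann_whitney_compare, stars_from_p

__all__ = [
    "ContextEffect",
    "OmissionEffect",
    "InteractionEdge",
    "compare_contexts",
    "omission_design_effects",
    "classify_edges",
    "build_network",
    "write_dot",
]


@dataclass(frozen=True)
class ContextEffect:
    """Change of one quantity of ``target`` between two community contexts.

    ``fold_change`` is context_b relative to context_a for multiplicative
    quantities (x0, mu, K, endpoint_abundance) and a difference in hours
    for tau.  Only endpoint-abundance effects carry a p-value (fitted
    parameters are point estimates without replication).
    """

    target: str
    context_a: str
    context_b: str
    parameter: str          # x0 | mu | K | tau | endpoint_abundance
    fold_change: float
    p_value: float | None = None
    mean_a: float | None = None
    mean_b: float | None = None

    def __post_init__(self) -> None:
        if self.parameter != "tau" and not self.fold_change > 0:
            raise ValueError("fold_change must be > 0 for multiplicative "
                             "parameters")


def _endpoint_values(table: pd.DataFrame, context: str, target: str,
                     time: float) -> np.ndarray:
    sel = table[(table["context"] == context) & (table["species"] == target)
                & (table["time_h"] == time)]
    return sel["cfu_per_cm2"].to_numpy(float)


def compare_contexts(abundances: pd.DataFrame, target: str,
                     context_a: str, context_b: str,
                     fits: Mapping | None = None,
                     endpoint_time: float | None = None) -> list:
    """Fold changes of ``target`` between two contexts.

    Always returns the endpoint-abundance effect (arithmetic-mean fold with
    a Mann-Whitney p across replicates, >= 3 per context); when per-context
    ``fits`` are supplied (mapping ``(context, species) -> FitResult``) the
    fitted-parameter effects are appended: x0/mu/K as fold changes, tau as
    a difference in hours.  No-growth fits contribute only K (the mean
    population level).  Swapping the contexts inverts every fold change
    (tau difference negates) and preserves the p-value.
    """
    if endpoint_time is None:
        times_a = set(abundances.loc[abundances["context"] == context_a, "time_h"])
        times_b = set(abundances.loc[abundances["context"] == context_b, "time_h"])
        shared = times_a & times_b
        if not shared:
            raise ValueError("contexts share no sampling time")
        endpoint_time = max(shared)
    va = _endpoint_values(abundances, context_a, target, endpoint_time)
    vb = _endpoint_values(abundances, context_b, target, endpoint_time)
    if va.size == 0 or vb.size == 0:
        raise ValueError(
            f"target {target!r} absent from context "
            f"{context_a if va.size == 0 else context_b!r} at t={endpoint_time}")
    if np.array_equal(np.sort(va), np.sort(vb)):
        p = 1.0
    else:
        p = mann_whitney_compare(va, vb).p_retained
    effects = [ContextEffect(
        target=target, context_a=context_a, context_b=context_b,
        parameter="endpoint_abundance",
        fold_change=float(vb.mean() / va.mean()), p_value=float(p),
        mean_a=float(va.mean()), mean_b=float(vb.mean()),
    )]
    if fits is not None:
        fa: FitResult = fits[(context_a, target)]
        fb: FitResult = fits[(context_b, target)]
        usable = {"fitted": ("x0", "mu", "K", "tau"), "no_growth": ("K",)}
        params_a = usable.get(fa.status, ())
        params_b = usable.get(fb.status, ())
        for name in ("x0", "mu", "K", "tau"):
            if name not in params_a or name not in params_b:
                continue
            a = getattr(fa.params, name)
            b = getattr(fb.params, name)
            if name == "tau":
                effects.append(ContextEffect(target, context_a, context_b,
                                             "tau", b - a))
            else:
                effects.append(ContextEffect(target, context_a, context_b,
                                             name, b / a))
    return effects


@dataclass(frozen=True)
class OmissionEffect:
    """Endpoint effect on ``target`` of omitting ``omitted`` from the
    community (full community is context_a, omission is context_b)."""

    omitted: str
    target: str
    effect: ContextEffect


def omission_design_effects(table: pd.DataFrame,
                            endpoint_time: float | None = None) -> list:
    """Build all full-vs-omission endpoint effects from a count table.

    The full-community context is identified as the one containing every
    species present in the table; each omission context must contain
    exactly all-but-one species.  Raises when any single-species omission
    is missing.
    """
    members_by_context = {
        ctx: frozenset(sub["species"]) for ctx, sub in table.groupby("context")
    }
    all_species = frozenset(table["species"].unique())
    full = [c for c, m in members_by_context.items() if m == all_species]
    if not full:
        raise ValueError("no full-community context present")
    full_ctx = full[0]
    omissions = {}
    for ctx, m in members_by_context.items():
        if len(m) == len(all_species) - 1:
            (omitted,) = all_species - m
            omissions[omitted] = ctx
    missing = sorted(all_species - set(omissions))
    if missing:
        raise ValueError(
            "incomplete omission design; missing omission context(s) for: "
            + ", ".join(missing))
    effects = []
    for omitted, ctx in sorted(omissions.items()):
        for target in sorted(all_species - {omitted}):
            (eff,) = compare_contexts(table, target, full_ctx, ctx,
                                      endpoint_time=endpoint_time)
            effects.append(OmissionEffect(omitted, target, eff))
    return effects


@dataclass(frozen=True)
class InteractionEdge:
    """A signed, typed interaction from ``source`` to ``target``.

    ``magnitude`` is the endpoint fold change attributable to the source's
    presence (always >= 1; the direction is carried by ``sign``).
    Mitigation edges record the negative edge they relieve in
    ``conditioning`` (source, target).
    """

    source: str
    target: str
    sign: str               # positive | negative | neutral
    type: str               # amensalism | competition | facilitation | mitigation | delay | none
    magnitude: float
    p_value: float
    conditioning: tuple | None = None
    evidence: tuple = ()

    def __post_init__(self) -> None:
        if (self.sign == "neutral") != (self.type == "none"):
            raise ValueError("sign=neutral iff type=none")
        if self.type == "mitigation" and self.conditioning is None:
            raise ValueError("mitigation edges must reference the negative "
                             "edge they relieve")

    @property
    def stars(self) -> str:
        return stars_from_p(self.p_value)


def classify_edges(effects: Sequence[OmissionEffect], alpha: float = 0.05,
                   fold_floor: float = 3.0) -> list:
    """Turn full-vs-omission effects into a signed interaction edge list.

    An effect is called when its Mann-Whitney p is below ``alpha`` *and*
    its endpoint fold change is at least ``fold_floor`` in either
    direction.  The output is invariant under permutation of the input and
    only non-neutral edges are emitted.
    """
    by_pair = {(e.omitted, e.target): e for e in sorted(
        effects, key=lambda e: (e.omitted, e.target))}

    def called(e: OmissionEffect) -> bool:
        f = e.effect.fold_change
        return (e.effect.p_value is not None and e.effect.p_value < alpha
                and max(f, 1.0 / f) >= fold_floor)

    negatives = {}
    for (omitted, target), e in by_pair.items():
        if called(e) and e.effect.fold_change > 1:
            # omitting X increased Y: X suppresses Y
            recip = by_pair.get((target, omitted))
            unaffected = recip is None or not called(recip)
            negatives[(omitted, target)] = InteractionEdge(
                source=omitted, target=target, sign="negative",
                type="amensalism" if unaffected else "competition",
                magnitude=e.effect.fold_change, p_value=e.effect.p_value,
                evidence=(e.effect,) + (
                    (recip.effect,) if recip is not None else ()),
            )
    edges = list(negatives.values())
    for (omitted, target), e in by_pair.items():
        if called(e) and e.effect.fold_change < 1:
            # omitting Z decreased Y: Z supports Y
            conditioning = [
                (w, t) for (w, t) in negatives if t == target and w != omitted
            ]
            if conditioning:
                strongest = max(conditioning,
                                key=lambda k: negatives[k].magnitude)
                edges.append(InteractionEdge(
                    source=omitted, target=target, sign="positive",
                    type="mitigation",
                    magnitude=1.0 / e.effect.fold_change,
                    p_value=e.effect.p_value, conditioning=strongest,
                    evidence=(e.effect,)))
            else:
                edges.append(InteractionEdge(
                    source=omitted, target=target, sign="positive",
                    type="facilitation",
                    magnitude=1.0 / e.effect.fold_change,
                    p_value=e.effect.p_value, evidence=(e.effect,)))
    return sorted(edges, key=lambda e: (e.source, e.target))


def build_network(edges: Iterable[InteractionEdge]) -> pd.DataFrame:
    """Deterministically ordered edge-list table (source, target
    lexicographic); duplicate (source, target) pairs are an error."""
    edges = list(edges)
    keys = [(e.source, e.target) for e in edges]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(f"duplicate edge(s): {dupes}")
    rows = [
        {"source": e.source, "target": e.target, "sign": e.sign,
         "type": e.type, "magnitude": e.magnitude, "p_value": e.p_value,
         "stars": e.stars,
         "conditioned_on": ("%s->%s" % e.conditioning) if e.conditioning else ""}
        for e in sorted(edges, key=lambda e: (e.source, e.target))
    ]
    return pd.DataFrame(rows, columns=[
        "source", "target", "sign", "type", "magnitude", "p_value", "stars",
        "conditioned_on",
    ])


def write_dot(edges: Iterable[InteractionEdge], path) -> None:
    """Write the interaction network as a Graphviz DOT file."""
    lines = ["digraph interactions {", "  rankdir=LR;"]
    for e in sorted(edges, key=lambda e: (e.source, e.target)):
        color = {"negative": "red", "positive": "darkgreen"}.get(e.sign, "gray")
        arrow = "tee" if e.sign == "negative" else "normal"
        lines.append(
            f'  {e.source} -> {e.target} [color={color}, arrowhead={arrow}, '
            f'label="{e.type} ({e.magnitude:.3g}x)"];'
        )
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
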