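"""Community-composition analytics: proportions, steady-state detection and
perturbation-vs-standard robustness comparison.

Proportions are computed on replicate means: each species' arithmetic-mean
count at the requested (context, time) divided by the sum over species,
times 100.  Species whose every replicate is censored contribute 0% by
default (with an explicit flag) or, on request, the log-midpoint of the
imputation range.

Steady state ("equilibrium") is the earliest sampling time after which no
species' abundance changes significantly, judged by per-species Tukey HSD
contrasts on log10 counts across sampling times.  Two operationalisations
are offered: ``all_later`` (default, stricter) requires every contrast
between the candidate time and each later time to be nonsignificant;
``consecutive`` requires only the reading-to-next-reading contrasts from
the candidate onwards to be nonsignificant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .stats import (
    ImputationSpec,
    TestSummary,
    repeated_imputation_test,
    two_way_anova_tukey,
)

__all__ = [
    "CompositionSnapshot",
    "RobustnessReport",
    "proportions",
    "steady_state_time",
    "perturbation_response",
    "plot_composition",
]


@dataclass(frozen=True)
class CompositionSnapshot:
    """Per-species share of total counts at one (context, time)."""

    context: str
    time: float
    proportions: Mapping[str, float]  # percent, sums to 100 (within 0.1)
    total: float                      # summed mean counts
    censored_species: tuple = ()

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError("total must be positive")
        s = sum(self.proportions.values())
        if abs(s - 100.0) > 0.1:
            raise ValueError(f"proportions sum to {s}, not 100")


def proportions(table: pd.DataFrame, context: str, time: float,
                censored: str = "zero",
                imputation: ImputationSpec = ImputationSpec()) -> CompositionSnapshot:
    """Species proportions (%) at one context and time.

    ``censored='zero'`` assigns 0% to species whose replicates are all
    below detection (flagged in ``censored_species``);
    ``censored='midpoint'`` lets them contribute the log-midpoint of the
    imputation range instead.
    """
    sel = table[(table["context"] == context) & (table["time_h"] == time)]
    if sel.empty:
        raise ValueError(f"no rows at context={context!r} time={time}")
    means: dict[str, float] = {}
    flagged = []
    for sp, sub in sel.groupby("species"):
        obs = sub.loc[~sub["censored"], "cfu_per_cm2"]
        if obs.empty:
            flagged.append(sp)
            if censored == "midpoint":
                means[sp] = float(10 ** ((np.log10(imputation.low)
                                          + np.log10(imputation.high)) / 2))
            elif censored == "zero":
                means[sp] = 0.0
            else:
                raise ValueError(f"unknown censored policy {censored!r}")
        else:
            means[sp] = float(obs.mean())
    total = sum(means.values())
    if total <= 0:
        raise ValueError("zero total count; all species censored")
    props = {sp: 100.0 * m / total for sp, m in sorted(means.items())}
    return CompositionSnapshot(context=context, time=float(time),
                               proportions=props, total=total,
                               censored_species=tuple(sorted(flagged)))


def _per_species_time_significance(table: pd.DataFrame, alpha: float) -> dict:
    """Map (species, t_early, t_late) -> significant? from per-species Tukey
    contrasts across sampling times."""
    summaries = two_way_anova_tukey(table, factors=("species", "time_h"),
                                    family="within", alpha=alpha)
    sig = {}
    for s in summaries:
        species, pair = s.contrast.split("|")
        a, b = pair.split(" vs ")
        t1, t2 = sorted((float(a), float(b)))
        sig[(species, t1, t2)] = s.significant
    return sig


def steady_state_time(table: pd.DataFrame, alpha: float = 0.05,
                      mode: str = "all_later",
                      context: str | None = None) -> float | None:
    """Earliest sampling time at which the community is at equilibrium.

    Returns the earliest time T (strictly before the last sampling time)
    such that no species changes significantly after T under the chosen
    contrast mode, or None when no such time exists.  Needs >= 3 sampling
    times and >= 2 replicates per (species, time) cell.
    """
    if context is not None:
        table = table[table["context"] == context]
    elif table["context"].nunique() > 1:
        raise ValueError("table spans several contexts; pass context=...")
    times = np.sort(table["time_h"].unique())
    if times.size < 2:
        raise ValueError("need >= 2 sampling times")
    sig = _per_species_time_significance(table, alpha)
    species = table["species"].unique()

    def quiet(t1: float, t2: float) -> bool:
        return not any(sig[(sp, t1, t2)] for sp in species)

    for i, t in enumerate(times[:-1]):
        later = times[i + 1:]
        if mode == "all_later":
            ok = all(quiet(t, u) for u in later)
        elif mode == "consecutive":
            steps = list(zip(times[i:-1], times[i + 1:]))
            ok = all(quiet(a, b) for a, b in steps)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if ok:
            return float(t)
    return None


@dataclass(frozen=True)
class RobustnessReport:
    """Perturbation-vs-standard comparison at the endpoint.

    ``per_species`` maps species -> dict with keys fold_change (perturbed
    over standard, on mean counts), p, stars, significant.  ``verdict`` is
    "altered" iff at least one species is significant at alpha.
    """

    perturbation: str
    endpoint_time: float
    per_species: Mapping[str, dict]
    verdict: str
    alpha: float = 0.05

    def __post_init__(self) -> None:
        any_sig = any(v["significant"] for v in self.per_species.values())
        if (self.verdict == "altered") != any_sig:
            raise ValueError("verdict inconsistent with per-species calls")


def perturbation_response(standard: pd.DataFrame, perturbed: pd.DataFrame,
                          alpha: float = 0.05,
                          perturbation: str = "perturbed",
                          endpoint_time: float | None = None,
                          imputation: ImputationSpec = ImputationSpec(),
                          rng=None) -> RobustnessReport:
    """Compare a perturbed community against the standard one.

    Endpoint counts from both tables enter a species x condition Tukey HSD
    analysis (family: all interaction cells); when either table contains
    censored rows the analysis is routed through the repeated randomized
    imputation procedure and the retained p-values are used.  Only the
    same-species standard-vs-perturbed contrasts are reported.
    """
    sp_std = set(standard["species"].unique())
    sp_per = set(perturbed["species"].unique())
    if sp_std != sp_per:
        raise ValueError(f"species mismatch: {sorted(sp_std ^ sp_per)}")
    if endpoint_time is None:
        shared = set(standard["time_h"]) & set(perturbed["time_h"])
        if not shared:
            raise ValueError("tables share no sampling time")
        endpoint_time = max(shared)
    frames = []
    for label, tab in (("standard", standard), (perturbation, perturbed)):
        sub = tab[tab["time_h"] == endpoint_time].copy()
        sub["condition"] = label
        frames.append(sub)
    combined = pd.concat(frames, ignore_index=True)

    test = lambda t: two_way_anova_tukey(  # noqa: E731
        t, factors=("species", "condition"), family="cells", alpha=alpha)
    summaries = repeated_imputation_test(combined, imputation, test=test,
                                         rng=rng, alpha=alpha)
    wanted = {}
    for s in summaries:
        a, b = s.contrast.split(" vs ")
        sp_a, cond_a = a.rsplit(":", 1)
        sp_b, cond_b = b.rsplit(":", 1)
        if sp_a == sp_b and {cond_a, cond_b} == {"standard", perturbation}:
            wanted[sp_a] = s

    per_species = {}
    for sp in sorted(sp_std):
        m_std = combined[(combined["species"] == sp)
                         & (combined["condition"] == "standard")][
                             "cfu_per_cm2"].mean()
        m_per = combined[(combined["species"] == sp)
                         & (combined["condition"] == perturbation)][
                             "cfu_per_cm2"].mean()
        s = wanted.get(sp)
        if s is None:  # pragma: no cover - design always yields the contrast
            raise RuntimeError(f"missing contrast for species {sp}")
        per_species[sp] = {
            "fold_change": float(m_per / m_std),
            "p": s.p_retained,
            "stars": s.stars,
            "significant": s.significant,
            "n_repeats_used": s.n_repeats_used,
        }
    verdict = ("altered" if any(v["significant"] for v in per_species.values())
               else "robust")
    return RobustnessReport(perturbation=perturbation,
                            endpoint_time=float(endpoint_time),
                            per_species=per_species, verdict=verdict,
                            alpha=alpha)


def plot_composition(snapshots, path=None, ax=None):
    """Stacked-bar chart of composition snapshots (requires matplotlib)."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    snapshots = list(snapshots)
    species = sorted({sp for s in snapshots for sp in s.proportions})
    labels = [f"{s.context}@{s.time:g}h" for s in snapshots]
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(snapshots) + 2, 4))
    bottom = np.zeros(len(snapshots))
    for sp in species:
        vals = np.array([s.proportions.get(sp, 0.0) for s in snapshots])
        ax.bar(labels, vals, bottom=bottom, label=sp)
        bottom += vals
    ax.set_ylabel("% of total counts")
    ax.legend(fontsize=8)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
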