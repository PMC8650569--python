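"""Omission-design interaction inference and network assembly."""

import math

import numpy as np
import pandas as pd
import pytest

from biofilmnet.growth import FitResult, GrowthParams
from biofilmnet.interactions import (
    ContextEffect,
    InteractionEdge,
    OmissionEffect,
    build_network,
    classify_edges,
    compare_contexts,
    omission_design_effects,
    write_dot,
)
from biofilmnet.simulate import default_scenario, delta_tcl_scenario, simulate_counts
from conftest import make_table


def _two_context_table(level_a, level_b, species="Kv", noise_sd=0.05,
                       seeds=(1, 2)):
    a = make_table({species: level_a}, times=(72.0,), noise_sd=noise_sd,
                   seed=seeds[0], context="full")
    b = make_table({species: level_b}, times=(72.0,), noise_sd=noise_sd,
                   seed=seeds[1], context="no_Bc")
    return pd.concat([a, b], ignore_index=True)


class TestCompareContexts:
    def test_endpoint_fold_change_and_p(self):
        """K. varians released ~200-fold when B. cereus is omitted."""
        tab = _two_context_table(5.4e4, 1.1e7)
        (eff,) = compare_contexts(tab, "Kv", "full", "no_Bc")
        assert eff.parameter == "endpoint_abundance"
        assert eff.fold_change == pytest.approx(1.1e7 / 5.4e4, rel=0.25)
        assert eff.p_value == pytest.approx(2 / 252)

    def test_identical_contexts_unit_fold(self):
        a = make_table({"Kv": 1e5}, times=(72.0,), noise_sd=0.1, seed=3)
        b = a.copy()
        b["context"] = "other"
        tab = pd.concat([a, b], ignore_index=True)
        (eff,) = compare_contexts(tab, "Kv", "full", "other")
        assert eff.fold_change == pytest.approx(1.0)
        assert eff.p_value == 1.0

    def test_antisymmetry(self):
        tab = _two_context_table(5.4e4, 1.1e7)
        (fwd,) = compare_contexts(tab, "Kv", "full", "no_Bc")
        (rev,) = compare_contexts(tab, "Kv", "no_Bc", "full")
        assert fwd.fold_change == pytest.approx(1 / rev.fold_change)
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_fitted_parameter_effects(self):
        """P. fluorescens alone vs in community: same-order mu and K but a
        33 h lag difference."""
        tab = _two_context_table(1e7, 5e6, species="Pf")
        fits = {
            ("full", "Pf"): FitResult(
                GrowthParams(2.7e4, 0.25, 1.7e7, 0.0), "fitted", 0.1, 13),
            ("no_Bc", "Pf"): FitResult(
                GrowthParams(2.7e4, 0.94, 5.8e6, 33.0), "fitted", 0.1, 13),
        }
        effects = compare_contexts(tab, "Pf", "full", "no_Bc", fits=fits)
        by_param = {e.parameter: e for e in effects}
        assert by_param["tau"].fold_change == pytest.approx(33.0)
        assert 1 / 3 <= by_param["K"].fold_change <= 3
        assert by_param["mu"].fold_change == pytest.approx(0.94 / 0.25)

    def test_no_growth_fit_compares_k_only(self):
        tab = _two_context_table(2.3e5, 2.3e5, species="Bc")
        fits = {
            ("full", "Bc"): FitResult(
                GrowthParams(7.9e4, math.nan, 2.3e5, math.nan),
                "no_growth", 0.1, 5),
            ("no_Bc", "Bc"): FitResult(
                GrowthParams(7.9e4, math.nan, 2.4e5, math.nan),
                "no_growth", 0.1, 5),
        }
        effects = compare_contexts(tab, "Bc", "full", "no_Bc", fits=fits)
        params = {e.parameter for e in effects}
        assert params == {"endpoint_abundance", "K"}

    def test_absent_target_errors(self):
        tab = _two_context_table(1e5, 1e6)
        with pytest.raises(ValueError):
            compare_contexts(tab, "Pf", "full", "no_Bc")


def _fig6_effects(p_up=0.008, p_pf=0.03, p_rh=0.008):
    """Hand-built omission pattern: omitting Bc releases Kv ~200-fold while
    Bc itself is unaffected by Kv; omitting Pf or Rh lowers Kv."""
    def eff(omitted, target, fold, p):
        return OmissionEffect(omitted, target, ContextEffect(
            target, "full", f"no_{omitted}", "endpoint_abundance", fold, p))

    effects = [eff("Bc", "Kv", 204.0, p_up),
               eff("Pf", "Kv", 1.2e4 / 5.4e4, p_pf),
               eff("Rh", "Kv", 3.5e3 / 5.4e4, p_rh)]
    for omitted in ("Rh", "Pf", "Kv", "Bc"):
        for target in ("Rh", "Pf", "Kv", "Bc"):
            if omitted == target:
                continue
            if any(e.omitted == omitted and e.target == target
                   for e in effects):
                continue
            effects.append(eff(omitted, target, 1.05, 0.8))
    return effects


class TestClassifyEdges:
    def test_amensalism_and_mitigation_pattern(self):
        edges = classify_edges(_fig6_effects())
        by_pair = {(e.source, e.target): e for e in edges}
        assert set(by_pair) == {("Bc", "Kv"), ("Pf", "Kv"), ("Rh", "Kv")}
        bc_kv = by_pair[("Bc", "Kv")]
        assert bc_kv.sign == "negative" and bc_kv.type == "amensalism"
        for src in ("Pf", "Rh"):
            e = by_pair[(src, "Kv")]
            assert e.sign == "positive" and e.type == "mitigation"
            assert e.conditioning == ("Bc", "Kv")

    def test_reciprocal_effect_means_competition(self):
        effects = _fig6_effects()
        effects = [e for e in effects
                   if not (e.omitted == "Kv" and e.target == "Bc")]
        effects.append(OmissionEffect("Kv", "Bc", ContextEffect(
            "Bc", "full", "no_Kv", "endpoint_abundance", 8.0, 0.01)))
        edges = classify_edges(effects)
        bc_kv = {(e.source, e.target): e for e in edges}[("Bc", "Kv")]
        assert bc_kv.type == "competition"

    def test_all_nonsignificant_empty(self):
        effects = [OmissionEffect(o, t, ContextEffect(
            t, "full", f"no_{o}", "endpoint_abundance", 1.1, 0.6))
            for o in "AB" for t in "AB" if o != t]
        assert classify_edges(effects) == []

    def test_significance_without_magnitude_not_called(self):
        effects = [OmissionEffect("A", "B", ContextEffect(
            "B", "full", "no_A", "endpoint_abundance", 1.5, 0.001)),
            OmissionEffect("B", "A", ContextEffect(
                "A", "full", "no_B", "endpoint_abundance", 1.0, 0.9))]
        assert classify_edges(effects) == []

    def test_permutation_invariance(self):
        effects = _fig6_effects()
        rng = np.random.default_rng(0)
        for _ in range(3):
            shuffled = list(effects)
            rng.shuffle(shuffled)
            assert classify_edges(shuffled) == classify_edges(effects)


class TestOmissionDesign:
    def test_missing_omission_context_errors(self, default_table):
        incomplete = default_table[default_table.context != "no_Pf"]
        with pytest.raises(ValueError, match="Pf"):
            omission_design_effects(incomplete)

    def test_end_to_end_wild_type_network(self, default_table):
        edges = classify_edges(omission_design_effects(default_table))
        pairs = {(e.source, e.target, e.sign, e.type) for e in edges}
        assert ("Bc", "Kv", "negative", "amensalism") in pairs

    def test_end_to_end_mutant_has_no_suppression_edge(self):
        tab = simulate_counts(delta_tcl_scenario(seed=11))
        edges = classify_edges(omission_design_effects(tab))
        assert not any(e.source == "Bc" and e.target == "Kv" for e in edges)


class TestBuildNetwork:
    def _edges(self):
        return [
            InteractionEdge("Pf", "Kv", "positive", "mitigation", 4.5, 0.03,
                            conditioning=("Bc", "Kv")),
            InteractionEdge("Bc", "Kv", "negative", "amensalism", 204.0,
                            0.008),
        ]

    def test_deterministic_order(self):
        net = build_network(self._edges())
        assert list(net["source"]) == ["Bc", "Pf"]
        assert net.loc[0, "type"] == "amensalism"
        assert net.loc[1, "conditioned_on"] == "Bc->Kv"

    def test_duplicate_edges_rejected(self):
        edges = self._edges() + [InteractionEdge("Bc", "Kv", "negative",
                                                 "amensalism", 10.0, 0.01)]
        with pytest.raises(ValueError, match="duplicate"):
            build_network(edges)

    def test_empty_edge_list(self):
        net = build_network([])
        assert len(net) == 0
        assert "source" in net.columns

    def test_dot_output(self, tmp_path):
        path = tmp_path / "net.dot"
        write_dot(self._edges(), path)
        text = path.read_text()
        assert "Bc -> Kv" in text and "digraph" in text

    def test_edge_invariants(self):
        with pytest.raises(ValueError):
            InteractionEdge("A", "B", "neutral", "amensalism", 1.0, 0.5)
        with pytest.raises(ValueError):
            InteractionEdge("A", "B", "positive", "mitigation", 2.0, 0.01)
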