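"""DAG construction, d-separation basis sets and piecewise-SEM fitting."""

import itertools

import networkx as nx
import numpy as np
import pytest

from paceline.inference import prepare_analysis_table
from paceline.growth import add_birth_columns
from paceline.path import (
    DagSpec,
    PathModel,
    basis_set,
    build_dag,
    compare_direction_variants,
    fit_path_model,
)


class TestBuildDag:
    def test_default_structure(self):
        dag = build_dag(response="rmr")
        g = dag.graph()
        assert nx.is_directed_acyclic_graph(g)
        assert len(dag.correlated_errors) == 3
        assert dag.nodes["entry"] == "binomial-logit"
        assert ("birth_date", "rmr") in dag.edges
        assert ("body_mass", "rmr") in dag.edges
        assert ("entry", "rmr") in dag.edges

    def test_inverted_variant_acyclic_families_preserved(self):
        dag = build_dag(response="stress_max", direction="inverted")
        assert nx.is_directed_acyclic_graph(dag.graph())
        assert ("stress_max", "entry") in dag.edges
        assert dag.nodes["entry"] == "binomial-logit"

    def test_cycle_rejected(self):
        dag = build_dag(response="rmr")
        with pytest.raises(ValueError, match="cycle"):
            DagSpec(nodes=dag.nodes, edges=dag.edges + [("rmr", "birth_date")],
                    correlated_errors=dag.correlated_errors, exogenous=dag.exogenous)

    def test_correlated_error_on_directed_edge_rejected(self):
        with pytest.raises(ValueError, match="correlated-error"):
            DagSpec(nodes={"a": "gaussian", "b": "gaussian"}, edges=[("a", "b")],
                    correlated_errors=[("a", "b")])


class TestBasisSet:
    def test_chain_has_single_claim(self):
        dag = DagSpec(nodes={n: "gaussian" for n in "abc"},
                      edges=[("a", "b"), ("b", "c")], exogenous=["a"])
        claims = basis_set(dag)
        assert len(claims) == 1
        c = claims[0]
        assert {c.x, c.y} == {"a", "c"} and c.conditioning == ("b",)

    def test_saturated_dag_empty(self):
        nodes = list("abcd")
        edges = [(x, y) for i, x in enumerate(nodes) for y in nodes[i + 1:]]
        dag = DagSpec(nodes={n: "gaussian" for n in nodes}, edges=edges, exogenous=["a"])
        assert basis_set(dag) == []

    def test_default_dag_excludes_behaviour_pairs(self):
        claims = basis_set(build_dag(response="rmr"))
        pairs = {frozenset((c.x, c.y)) for c in claims}
        assert frozenset(("entry", "distance")) not in pairs
        assert frozenset(("entry", "exploration")) not in pairs
        assert frozenset(("distance", "exploration")) not in pairs
        # what remains is body mass against the three behaviours
        assert pairs == {frozenset(("body_mass", b))
                         for b in ("entry", "distance", "exploration")}

    def test_matches_dseparation_oracle_on_all_small_dags(self):
        # every upper-triangular DAG on 5 nodes (covers all shapes); each
        # claim must be d-separated and exactly the eligible pairs covered
        nodes = list("abcde")
        pos = list(itertools.combinations(range(5), 2))
        for mask in range(1 << len(pos)):
            edges = [(nodes[i], nodes[j]) for k, (i, j) in enumerate(pos)
                     if mask >> k & 1]
            g = nx.DiGraph()
            g.add_nodes_from(nodes)
            g.add_edges_from(edges)
            exog = [n for n in nodes if g.in_degree(n) == 0]
            dag = DagSpec(nodes={n: "gaussian" for n in nodes}, edges=edges,
                          exogenous=exog)
            claims = basis_set(dag)
            adjacent = {frozenset(e) for e in edges}
            expected_pairs = {
                frozenset((x, y)) for x, y in itertools.combinations(nodes, 2)
                if frozenset((x, y)) not in adjacent
                and not (x in exog and y in exog)
            }
            assert {frozenset((c.x, c.y)) for c in claims} == expected_pairs
            for c in claims:
                assert nx.is_d_separator(g, {c.x}, {c.y}, set(c.conditioning)), (
                    f"claim {c} not d-separated in {edges}")


class TestPathModelFitting:
    def test_saturated_model_fisher_c_zero(self, small_analysis):
        nodes = {"birth_date": "gaussian", "distance": "gaussian",
                 "exploration": "gaussian"}
        edges = [("birth_date", "distance"), ("birth_date", "exploration"),
                 ("distance", "exploration")]
        dag = DagSpec(nodes=nodes, edges=edges, exogenous=["birth_date"])
        res = fit_path_model(dag, small_analysis)
        assert res.fisher_c == 0.0
        assert res.fisher_df == 0
        assert res.fisher_p == 1.0

    def test_standardized_coefficients_affine_invariant(self, small_cohort):
        cohort, _ = small_cohort
        cohort = add_birth_columns(cohort, intervals=())
        a1 = prepare_analysis_table(cohort)
        scaled = cohort.copy()
        scaled["rmr"] = scaled["rmr"] * 3.7 + 5.0
        scaled["ambient_temp_C"] = scaled["ambient_temp_C"] / 2.0 - 1.0
        a2 = prepare_analysis_table(scaled)
        dag = build_dag(response="rmr")
        r1 = fit_path_model(dag, a1, compute_fit=False)
        r2 = fit_path_model(dag, a2, compute_fit=False)
        assert np.allclose(r1.coefficients["beta"], r2.coefficients["beta"], atol=1e-7)

    def test_marginal_r2_in_unit_interval(self, small_analysis):
        res = fit_path_model(build_dag(response="rmr"), small_analysis)
        for node, r2 in res.marginal_r2.items():
            assert 0.0 <= r2 <= 1.0, node
        assert set(res.marginal_r2) == {"entry", "distance", "exploration", "rmr"}

    def test_constant_covariate_dropped_and_reported(self, small_analysis):
        # two-session cohorts have a constant age class
        res = fit_path_model(build_dag(response="rmr"), small_analysis)
        assert all("age_class" in v for v in res.dropped_covariates.values())
        assert res.coefficients.query("source == 'age_class'").empty

    def test_correlated_error_table(self, small_analysis):
        res = fit_path_model(build_dag(response="rmr"), small_analysis)
        assert len(res.correlated_errors) == 3
        row = res.correlated_errors.query("a == 'distance' and b == 'exploration'")
        assert row["r"].iloc[0] > 0  # syndrome direction

    def test_missing_column_rejected(self, small_analysis):
        broken = small_analysis.drop(columns=["mass_z"])
        with pytest.raises(ValueError, match="mass_z"):
            PathModel(build_dag(response="rmr"), broken)

    def test_nan_rows_rejected(self, small_analysis):
        broken = small_analysis.copy()
        broken.loc[0, "rmr_z"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            PathModel(build_dag(response="rmr"), broken)

    def test_summary_and_edge_list(self, small_analysis):
        res = fit_path_model(build_dag(response="rmr"), small_analysis)
        text = res.summary()
        assert "Fisher's C" in text and "birth_date -> rmr" in text
        edges = res.edge_list()
        assert {"source", "target", "beta", "significant"} <= set(edges.columns)


def test_direction_variants_agree_on_default_data(small_analysis):
    out = compare_direction_variants(small_analysis, response="rmr", compute_fit=False)
    assert set(out) == {"forward", "inverted", "agreement", "details"}
    assert len(out["details"]) == 4  # three behaviours + the metabolic response
    assert isinstance(out["agreement"], bool)
    # birth-date signs at least must match between the two directions
    d = out["details"]
    assert (np.sign(d["beta_forward"]) == np.sign(d["beta_inverted"])).all()
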