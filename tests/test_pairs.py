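"""Hypergeometric shared-miRNA test, candidate filtering, co-expression gate."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lmmacnet import pairs
from lmmacnet.io import ExpressionMatrix, IdList, InteractionTable
from oracles import bh_stepup, enumerate_hypergeom_upper, exact_hypergeom_lower


def table(cls, edges):
    return InteractionTable("miRNA", cls, tuple(edges))


# ---------------------------------------------------------------- hypergeometric

class TestHypergeomSharedTest:
    def test_upper_matches_enumeration(self):
        h = pairs.HypergeomInputs(M=10, K=4, N=3, x=2)
        want = float(enumerate_hypergeom_upper(10, 4, 3, 2))
        assert pairs.hypergeom_shared_test(h, "upper") == pytest.approx(want, abs=1e-12)

    def test_x_zero_upper_is_one(self):
        h = pairs.HypergeomInputs(M=10, K=4, N=3, x=0)
        assert pairs.hypergeom_shared_test(h, "upper") == 1.0

    def test_full_cdf_is_one(self):
        h = pairs.HypergeomInputs(M=10, K=4, N=3, x=3)
        assert pairs.hypergeom_shared_test(h, "lower_as_printed") == pytest.approx(1.0, abs=1e-12)

    def test_printed_lower_tail_matches_term_sum(self):
        h = pairs.HypergeomInputs(M=12, K=5, N=4, x=2)
        want = float(exact_hypergeom_lower(12, 5, 4, 2))
        assert pairs.hypergeom_shared_test(h, "lower_as_printed") == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("kwargs", [
        {"M": 0, "K": 0, "N": 0, "x": 0},
        {"M": 5, "K": 6, "N": 2, "x": 1},
        {"M": 5, "K": 2, "N": 2, "x": 3},
        {"M": 5, "K": 2, "N": 2, "x": -1},
    ])
    def test_invariant_violations_rejected(self, kwargs):
        with pytest.raises(ValueError):
            pairs.HypergeomInputs(**kwargs)

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(data=st.data())
    def test_upper_lower_complement_identity(self, data):
        M = data.draw(st.integers(1, 40))
        K = data.draw(st.integers(0, M))
        N = data.draw(st.integers(0, M))
        x = data.draw(st.integers(1, max(1, min(K, N))))
        if x > min(K, N):
            x = min(K, N)
        if x < 1:
            return
        upper = pairs.hypergeom_shared_test(pairs.HypergeomInputs(M, K, N, x), "upper")
        lower = pairs.hypergeom_shared_test(pairs.HypergeomInputs(M, K, N, x - 1),
                                            "lower_as_printed")
        assert upper + lower == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------- candidates

class TestCandidateInteractions:
    MG = table("gene", [("m1", "g1"), ("m1", "g2"), ("m2", "g1"),
                        ("m3", "g3"), ("m4", "g1")])
    ML = table("lncRNA", [("m1", "l1"), ("m9", "l2")])

    def test_intersection_filter(self):
        mg, ml = pairs.candidate_interactions(
            self.MG, self.ML,
            IdList("risk_gene", ("g1", "g2")), IdList("risk_miRNA", ("m1", "m2")))
        assert set(mg.edges) == {("m1", "g1"), ("m1", "g2"), ("m2", "g1")}
        assert set(ml.edges) == {("m1", "l1")}

    def test_gene_in_module_but_mirna_not_risk_removed(self):
        mg, _ = pairs.candidate_interactions(
            self.MG, self.ML,
            IdList("risk_gene", ("g1",)), IdList("risk_miRNA", ("m1", "m4")))
        assert ("m2", "g1") not in mg.edges

    def test_disjoint_risk_mirnas_error(self):
        with pytest.raises(ValueError, match="no candidate"):
            pairs.candidate_interactions(
                self.MG, self.ML,
                IdList("risk_gene", ("g1",)), IdList("risk_miRNA", ("mX",)))


# ---------------------------------------------------------------- hypergeom stage

class TestScoreAllPairs:
    def test_full_overlap_small_p_retained(self):
        mirnas = [f"m{i}" for i in range(50)]
        mg = table("gene", [(m, "g1") for m in mirnas[:3]])
        ml = table("lncRNA", [(m, "l1") for m in mirnas[:3]])
        out = pairs.score_all_pairs(mg, ml, IdList("risk_miRNA", tuple(mirnas)),
                                    p_max=0.01, universe="curated")
        assert len(out) == 1
        want = float(enumerate_hypergeom_upper(50, 3, 3, 3))
        assert out[0].p_hyper == pytest.approx(want, rel=1e-9)

    def test_no_shared_mirnas_not_tested(self):
        mg = table("gene", [("m1", "g1")])
        ml = table("lncRNA", [("m2", "l1")])
        out = pairs.score_all_pairs(mg, ml, IdList("risk_miRNA", ("m1", "m2")), p_max=1.1)
        assert out == []

    def test_ties_break_lexicographically(self):
        mg = table("gene", [("m1", "gB"), ("m1", "gA")])
        ml = table("lncRNA", [("m1", "l1")])
        out = pairs.score_all_pairs(mg, ml, IdList("risk_miRNA", ("m1", "m2", "m3")),
                                    p_max=1.1)
        assert [cp.gene_id for cp in out] == ["gA", "gB"]

    def test_realized_universe_counts_present_mirnas(self):
        mg = table("gene", [("m1", "g1")])
        ml = table("lncRNA", [("m1", "l1")])
        out = pairs.score_all_pairs(mg, ml,
                                    IdList("risk_miRNA", ("m1", "m2", "m3")), p_max=1.1)
        assert out[0].hyper.M == 1  # only m1 is realized

    def test_empty_universe_rejected(self):
        mg = table("gene", [("m1", "g1")])
        ml = table("lncRNA", [("m1", "l1")])
        with pytest.raises(ValueError, match="universe"):
            pairs.score_all_pairs(mg, ml, IdList("risk_miRNA", ("mX",)))


# ---------------------------------------------------------------- co-expression

def expr_from_rows(rows: dict[str, np.ndarray]) -> ExpressionMatrix:
    ids = tuple(rows)
    vals = np.vstack([rows[t] for t in ids])
    return ExpressionMatrix(ids, tuple(f"s{i}" for i in range(vals.shape[1])), vals)


class TestPearsonWithFdr:
    def _pair(self, g, l):
        from conftest import make_pair
        return make_pair(g, l, {"m1"}, significant=False)

    def test_identical_rows_pcc_one(self, rng):
        x = rng.standard_normal(30)
        expr = expr_from_rows({"g1": x, "l1": x.copy()})
        out = pairs.pearson_with_fdr([self._pair("g1", "l1")], expr)
        assert len(out) == 1 and out[0].pcc == pytest.approx(1.0)
        assert out[0].significant

    def test_negative_correlation_rejected(self, rng):
        x = rng.standard_normal(40)
        expr = expr_from_rows({"g1": x, "l1": -x + 0.01 * rng.standard_normal(40)})
        out = pairs.pearson_with_fdr([self._pair("g1", "l1")], expr, return_all=True)
        assert out[0].pcc < -0.9 and not out[0].significant

    def test_zero_variance_pair_dropped(self, rng):
        expr = expr_from_rows({"g1": np.ones(10), "l1": rng.standard_normal(10)})
        assert pairs.pearson_with_fdr([self._pair("g1", "l1")], expr) == []

    def test_missing_transcript_dropped(self, rng):
        expr = expr_from_rows({"g1": rng.standard_normal(10),
                               "l9": rng.standard_normal(10)})
        assert pairs.pearson_with_fdr([self._pair("g1", "l1")], expr) == []

    def test_bh_adjustment_matches_hand_stepup(self):
        raw = [0.001, 0.002, 0.03, 0.4]
        got = pairs.bh_fdr(raw)
        assert np.allclose(got, [0.004, 0.004, 0.04, 0.4])
        assert np.allclose(got, bh_stepup(raw))

    def test_pcc_estimator_near_planted_rho(self):
        hits = 0
        for trial in range(100):
            r = np.random.default_rng(900 + trial)
            z = r.standard_normal(100)
            a = np.sqrt(0.8) * z + np.sqrt(0.2) * r.standard_normal(100)
            b = np.sqrt(0.8) * z + np.sqrt(0.2) * r.standard_normal(100)
            expr = expr_from_rows({"g1": a, "l1": b})
            out = pairs.pearson_with_fdr([self._pair("g1", "l1")], expr, return_all=True)
            hits += 0.68 <= out[0].pcc <= 0.88
        assert hits >= 95

    def test_threshold_monotonicity(self, rng):
        # shrinking p_max / raising pcc_min / shrinking fdr_max never adds a pair
        mirnas = tuple(f"m{i}" for i in range(30))
        mg = table("gene", [(m, f"g{i}") for i in range(6) for m in mirnas[i:i + 4]])
        ml = table("lncRNA", [(m, f"l{i}") for i in range(6) for m in mirnas[i:i + 4]])
        risk = IdList("risk_miRNA", mirnas)
        rows = {}
        for i in range(6):
            z = rng.standard_normal(50)
            rows[f"g{i}"] = np.sqrt(0.85) * z + np.sqrt(0.15) * rng.standard_normal(50)
            rows[f"l{i}"] = np.sqrt(0.85) * z + np.sqrt(0.15) * rng.standard_normal(50)
        expr = expr_from_rows(rows)

        def run(p_max, pcc_min, fdr_max):
            hyper = pairs.score_all_pairs(mg, ml, risk, p_max=p_max)
            final = pairs.pearson_with_fdr(hyper, expr, pcc_min=pcc_min, fdr_max=fdr_max)
            return {(cp.gene_id, cp.lncrna_id) for cp in final}

        base = run(0.05, 0.5, 0.1)
        assert run(0.01, 0.5, 0.1) <= base
        assert run(0.05, 0.8, 0.1) <= base
        assert run(0.05, 0.5, 0.01) <= base


def test_null_interactome_hyper_rate_controlled(rng):
    # uniform random wiring, no planted triplets: < 2% of tested pairs at p < 0.01
    n_tested = n_hits = 0
    for rep in range(50):
        r = np.random.default_rng(2000 + rep)
        mirnas = [f"m{i}" for i in range(30)]
        mg_edges = {(m, f"g{j}") for m in mirnas for j in range(20) if r.random() < 0.1}
        ml_edges = {(m, f"l{j}") for m in mirnas for j in range(20) if r.random() < 0.1}
        if not mg_edges or not ml_edges:
            continue
        out = pairs.score_all_pairs(table("gene", sorted(mg_edges)),
                                    table("lncRNA", sorted(ml_edges)),
                                    IdList("risk_miRNA", tuple(mirnas)), p_max=1.1)
        n_tested += len(out)
        n_hits += sum(cp.p_hyper < 0.01 for cp in out)
    assert n_tested > 0
    assert n_hits / n_tested <= 0.02
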