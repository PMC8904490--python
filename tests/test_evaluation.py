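"""Exact-test oracles and enrichment bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from cnmir.errors import ValidationError
from cnmir import evaluation as ev
from cnmir.stability_lasso import InteractionEdge
from cnmir.synthetic_data import GroundTruth


def _edge(m, g, sign="negative", count=90):
    coef = -0.5 if sign == "negative" else 0.5
    return InteractionEdge(m, g, ("r1",), count, coef, sign)


# ---------------------------------------------------------------------------
# hypergeometric / Fisher oracles

def hypergeom_upper_brute(k, n, K, N):
    """Direct enumeration of the upper tail with binomial coefficients."""
    total = comb(N, n, exact=True)
    return sum(
        comb(K, i, exact=True) * comb(N - K, n - i, exact=True)
        for i in range(k, min(n, K) + 1)
    ) / total


def fisher_two_sided_brute(a, b, c, d):
    row1, col1, total = a + b, a + c, a + b + c + d
    lo, hi = max(0, row1 + col1 - total), min(row1, col1)
    denom = comb(total, row1, exact=True)
    probs = [
        comb(col1, x, exact=True) * comb(total - col1, row1 - x, exact=True) / denom
        for x in range(lo, hi + 1)
    ]
    p_obs = probs[a - lo]
    return sum(p for p in probs if p <= p_obs * (1 + 1e-7))


def test_hypergeom_known_values():
    assert ev.hypergeom_upper(0, 4, 5, 10) == 1.0
    assert ev.hypergeom_upper(4, 4, 5, 10) == pytest.approx(5 / 210, abs=1e-12)
    assert ev.hypergeom_upper(2, 2, 2, 5) == pytest.approx(1 / 10, abs=1e-12)


def test_fisher_known_values():
    assert ev.fisher_two_sided(5, 5, 5, 5) == pytest.approx(1.0, abs=1e-12)
    assert ev.fisher_two_sided(3, 1, 1, 3) == pytest.approx(34 / 70, abs=1e-12)
    assert ev.fisher_two_sided(0, 0, 3, 4) == 1.0  # zero row: single table


def test_hypergeom_matches_enumeration_small_universes():
    for N in range(1, 16):
        for K in range(N + 1):
            for n in range(N + 1):
                for k in range(min(n, K) + 1):
                    assert ev.hypergeom_upper(k, n, K, N) == pytest.approx(
                        hypergeom_upper_brute(k, n, K, N), abs=1e-10
                    )


def test_fisher_matches_enumeration_small_tables(rng):
    tables = [(a, b, c, d)
              for a in range(6) for b in range(6)
              for c in range(6) for d in range(6)]
    for a, b, c, d in tables:
        assert ev.fisher_two_sided(a, b, c, d) == pytest.approx(
            fisher_two_sided_brute(a, b, c, d), abs=1e-10
        )


def test_fisher_agrees_with_scipy(rng):
    for _ in range(200):
        a, b, c, d = rng.integers(0, 12, size=4)
        ours = ev.fisher_two_sided(int(a), int(b), int(c), int(d))
        ref = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
        assert ours == pytest.approx(ref, abs=1e-9)


def test_fisher_rejects_negative_cells():
    with pytest.raises(ValidationError):
        ev.fisher_two_sided(-1, 2, 3, 4)


def test_hypergeom_rejects_bad_margins():
    with pytest.raises(ValidationError):
        ev.hypergeom_upper(3, 2, 5, 10)


# ---------------------------------------------------------------------------
# ground-truth expansion

def test_expand_ground_truth_tf_rule():
    tf = pd.DataFrame({"tf_id": ["TF1", "TF1"], "target_id": ["g1", "g2"]})
    gti = ev.expand_ground_truth({("miR-a", "TF1")}, tf)
    assert ("miR-a", "g1") in gti.pairs and ("miR-a", "g2") in gti.pairs
    assert gti.provenance[("miR-a", "g1")] == "tf_expanded"
    assert gti.provenance[("miR-a", "TF1")] == "direct"


def test_expand_ground_truth_no_tf_no_expansion():
    tf = pd.DataFrame({"tf_id": ["TF1"], "target_id": ["g1"]})
    gti = ev.expand_ground_truth({("miR-a", "gX")}, tf)
    assert gti.pairs == {("miR-a", "gX")}


def test_expand_keeps_direct_tag_over_expansion():
    tf = pd.DataFrame({"tf_id": ["TF1"], "target_id": ["g1"]})
    gti = ev.expand_ground_truth({("miR-a", "TF1"), ("miR-a", "g1")}, tf)
    assert gti.provenance[("miR-a", "g1")] == "direct"
    assert len(gti.pairs) == 2


# ---------------------------------------------------------------------------
# per-miRNA target enrichment and eligibility

def test_enrichment_eligibility_rules():
    truth = ev.GroundTruthInteractions(
        pairs={("m1", "g1"), ("m1", "g2"), ("m2", "g9")},
        provenance={},
    )
    universe = {f"g{i}" for i in range(1, 9)}
    edges = [_edge("m1", "g1"), _edge("m1", "g2"), _edge("m2", "g3")]
    res = {r.subject_id: r for r in ev.mirna_target_enrichment(edges, truth, universe)}
    # m1's computed targets are exactly its truth targets in a small universe
    assert res["m1"].eligible and res["m1"].k == 2
    assert res["m1"].p_value == pytest.approx(
        hypergeom_upper_brute(2, 2, 2, 8), abs=1e-12
    )
    assert res["m1"].significant == (res["m1"].p_value < 0.05)
    # m2 computed a target, but none of its known targets: not eligible
    assert not res["m2"].eligible and not res["m2"].significant


def test_enrichment_empty_edges():
    truth = ev.GroundTruthInteractions(pairs=set(), provenance={})
    assert ev.mirna_target_enrichment([], truth, {"g1"}) == []


def test_percent_significant():
    truth = ev.GroundTruthInteractions(
        pairs={("m1", "g1"), ("m1", "g2")}, provenance={})
    universe = {f"g{i}" for i in range(1, 30)}
    edges = [_edge("m1", "g1"), _edge("m1", "g2")]
    res = ev.mirna_target_enrichment(edges, truth, universe)
    assert ev.percent_significant(res) == 100.0


# ---------------------------------------------------------------------------
# oncogenic miRNA Fisher enrichment

def test_oncomirna_table_and_p():
    background = {f"m{i}" for i in range(20)}
    onco = {"m0", "m1", "m2", "m3", "m4"}
    computed = {"m0", "m1", "m2", "m3"}
    (a, b, c, d), p = ev.fisher_oncomirna_enrichment(computed, onco, background)
    assert (a, b, c, d) == (4, 0, 1, 15)
    assert p == pytest.approx(fisher_two_sided_brute(4, 0, 1, 15), abs=1e-12)
    assert p < 0.05


def test_oncomirna_disjoint_background_warns_p1():
    (_, p) = ev.fisher_oncomirna_enrichment({"m1"}, {"x"}, {"m1", "m2"})[1], None
    table, p = ev.fisher_oncomirna_enrichment({"m1"}, {"x"}, {"m1", "m2"})
    assert p == 1.0


def test_oncomirna_fisher_calibration(rng):
    """Uniformly drawn computed sets give a uniform p-value distribution."""
    background = [f"m{i}" for i in range(40)]
    onco = set(background[:12])
    hits = 0
    reps = 400
    for _ in range(reps):
        computed = set(rng.choice(background, size=10, replace=False))
        _, p = ev.fisher_oncomirna_enrichment(computed, onco, set(background))
        hits += p < 0.05
    # exact-test conservatism keeps the rate at or below nominal
    assert hits / reps <= 0.07


# ---------------------------------------------------------------------------
# method comparison

def _truth_and_universe():
    pairs = {("m1", "g1"), ("m2", "g2"), ("m3", "g3")}
    truth = ev.GroundTruthInteractions(pairs=pairs, provenance={})
    universe = {f"g{i}" for i in range(1, 40)}
    return truth, universe


def test_compare_methods_win_and_antisymmetry():
    truth, universe = _truth_and_universe()
    strong = {"m1": {"g1"}, "m2": {"g2"}}
    weak = {"m1": {"g1"} | {f"g{i}" for i in range(4, 30)},
            "m2": {"g2"} | {f"g{i}" for i in range(4, 30)}}
    fwd = ev.compare_methods(strong, weak, truth, universe)
    rev = ev.compare_methods(weak, strong, truth, universe)
    assert fwd["verdict"] == "a_wins" and rev["verdict"] == "b_wins"
    assert fwd["significant_a"] == rev["significant_b"]


def test_compare_methods_draw_on_identical_sets():
    truth, universe = _truth_and_universe()
    edges = {"m1": {"g1"}, "m3": {"g3"}}
    assert ev.compare_methods(edges, dict(edges), truth, universe)["verdict"] == "draw"


def test_compare_methods_no_overlap_not_comparable():
    truth, universe = _truth_and_universe()
    res = ev.compare_methods({"m1": {"g1"}}, {"m2": {"g2"}}, truth, universe)
    assert res["verdict"] == "not_comparable"


# ---------------------------------------------------------------------------
# ORA

def test_ora_exact_term_is_top_hit():
    universe = {f"g{i}" for i in range(50)}
    gene_set = {f"g{i}" for i in range(5)}
    annotation = {"hit": set(gene_set), "other": {f"g{i}" for i in range(20, 30)}}
    res = ev.ora(gene_set, annotation, universe)
    by_term = {r.subject_id: r for r in res}
    assert by_term["hit"].p_value < by_term["other"].p_value
    assert by_term["hit"].significant


def test_ora_empty_gene_set_all_p1():
    universe = {f"g{i}" for i in range(10)}
    res = ev.ora(set(), {"t": {"g1", "g2"}}, universe)
    assert all(r.p_value == 1.0 for r in res)


def test_ora_false_positive_control(rng):
    universe = [f"g{i}" for i in range(60)]
    terms = {f"t{j}": set(rng.choice(universe, size=10, replace=False))
             for j in range(12)}
    fp = 0
    reps = 300
    for _ in range(reps):
        gs = set(rng.choice(universe, size=8, replace=False))
        fp += sum(r.significant for r in ev.ora(gs, terms, set(universe)))
    # BH at alpha=0.05 over random sets: false positives are rare
    assert fp / reps < 0.2


# ---------------------------------------------------------------------------
# CN-expression correlation and recovery metrics

def test_spearman_signs():
    cn = pd.DataFrame([[0, 1, 2, 3]], index=["m1"], columns=list("abcd"))
    up = pd.DataFrame([[1, 2, 3, 4]], index=["m1"], columns=list("abcd"))
    down = pd.DataFrame([[4, 3, 2, 1]], index=["m1"], columns=list("abcd"))
    rho_up, med_up = ev.cn_expression_correlation(["m1"], cn, up)
    rho_dn, _ = ev.cn_expression_correlation(["m1"], cn, down)
    assert rho_up["m1"] == 1.0 and med_up == 1.0
    assert rho_dn["m1"] == -1.0


def test_spearman_constant_vector_is_missing():
    cn = pd.DataFrame([[1, 1, 1, 1]], index=["m1"], columns=list("abcd"))
    expr = pd.DataFrame([[1, 2, 3, 4]], index=["m1"], columns=list("abcd"))
    rho, med = ev.cn_expression_correlation(["m1"], cn, expr)
    assert np.isnan(rho["m1"]) and np.isnan(med)


def test_recovery_metrics_counts():
    truth = GroundTruth(
        true_edges={(f"m{i}", f"g{i}", "negative") for i in range(5)},
        true_regions=[], carrier_samples={}, true_de_genes={},
    )
    edges = [_edge(f"m{i}", f"g{i}") for i in range(4)] + [_edge("mX", "gX")]
    m = ev.recovery_metrics(edges, truth)
    assert m["precision"] == pytest.approx(0.8)
    assert m["recall"] == pytest.approx(0.8)
    assert m["sign_accuracy"] == 1.0


def test_recovery_metrics_empty_edges():
    truth = GroundTruth(true_edges={("m", "g", "negative")}, true_regions=[],
                        carrier_samples={}, true_de_genes={})
    m = ev.recovery_metrics([], truth)
    assert np.isnan(m["precision"]) and m["recall"] == 0.0
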