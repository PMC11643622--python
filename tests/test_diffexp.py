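"""Wilcoxon rank-sum DE, significance filtering, and hypergeometric ORA."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from vrcall.diffexp_enrich import (
    filter_significant,
    hypergeom_ora,
    read_gmt,
    wilcoxon_de,
)
from vrcall.errors import ValidationError
from vrcall.io_catalog import NormMatrix


def two_group_norm(values_a: list[list[float]], values_b: list[list[float]]):
    """NormMatrix with rows = cells of A then B; genes g0..g{k-1}."""
    arr = np.array(values_a + values_b, dtype=float)
    cells = [f"a{i}" for i in range(len(values_a))] + [
        f"b{i}" for i in range(len(values_b))
    ]
    genes = [f"g{j}" for j in range(arr.shape[1])]
    norm = NormMatrix(cells, genes, arr)
    return norm, cells[: len(values_a)], cells[len(values_a) :]


def brute_force_ranksum_p(x, y) -> float:
    """Independent oracle: full enumeration of group assignments."""
    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n_a, n = len(x), len(pooled)
    mu = n_a * (n + 1) / 2
    d_obs = abs(ranks[:n_a].sum() - mu)
    hits = total = 0
    for idx in combinations(range(n), n_a):
        total += 1
        if abs(sum(ranks[i] for i in idx) - mu) >= d_obs - 1e-9:
            hits += 1
    return hits / total


def test_identical_groups_give_null_result():
    rows = [[1.0, 2.0], [0.5, 1.5], [2.0, 0.0]]
    norm, a, b = two_group_norm(rows, rows)
    de = wilcoxon_de(norm, a, b, min_pct=0.0)
    assert de["log2FC"].abs().max() == 0.0
    assert (de["p_value"] == 1.0).all()


def test_p_matches_exact_permutation_oracle():
    a_vals = [5.1, 5.0, 5.2, 4.9, 5.05]
    b_vals = [0.0, 0.0, 0.1, 0.0, 0.05]
    norm, a, b = two_group_norm([[v] for v in a_vals], [[v] for v in b_vals])
    de = wilcoxon_de(norm, a, b, min_pct=0.0)
    expected = brute_force_ranksum_p(np.array(a_vals), np.array(b_vals))
    assert de.loc["g0", "p_value"] == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(2 / comb(10, 5))  # complete separation


def test_antisymmetric_under_group_swap():
    rng = np.random.default_rng(1)
    rows_a = rng.exponential(1.0, size=(20, 5)).tolist()
    rows_b = rng.exponential(2.0, size=(25, 5)).tolist()
    norm, a, b = two_group_norm(rows_a, rows_b)
    ab = wilcoxon_de(norm, a, b, min_pct=0.0)
    ba = wilcoxon_de(norm, b, a, min_pct=0.0)
    np.testing.assert_allclose(ab["log2FC"], -ba["log2FC"])
    np.testing.assert_allclose(ab["p_value"], ba["p_value"])


def test_group_validation():
    norm, a, b = two_group_norm([[1.0]] * 3, [[2.0]] * 3)
    with pytest.raises(ValidationError):
        wilcoxon_de(norm, a, a)  # overlap
    with pytest.raises(ValidationError):
        wilcoxon_de(norm, a[:2], b)  # too small


def test_bonferroni_bounds():
    rng = np.random.default_rng(2)
    rows_a = rng.normal(1.0, 1.0, size=(15, 40)).clip(min=0).tolist()
    rows_b = rng.normal(1.3, 1.0, size=(15, 40)).clip(min=0).tolist()
    norm, a, b = two_group_norm(rows_a, rows_b)
    de = wilcoxon_de(norm, a, b, min_pct=0.0)
    tested = de[de["tested"]]
    assert (tested["p_adj"] >= tested["p_value"] - 1e-15).all()
    assert (tested["p_adj"] <= 1.0).all()
    n_tested = int(de["tested"].sum())
    np.testing.assert_allclose(
        tested["p_adj"], np.minimum(tested["p_value"] * n_tested, 1.0)
    )


def test_exact_and_asymptotic_branches_agree_in_bulk():
    """For group sizes 8-10 the normal approximation tracks the exact
    permutation p closely away from the extreme tail (where the exact
    branch is the one actually used); assert 10% relative agreement for
    exact p >= 0.05."""
    rng = np.random.default_rng(3)
    checked = 0
    for n_a, n_b in [(8, 8), (9, 10), (10, 10)]:
        rows_a = rng.normal(1.0, 1.0, size=(n_a, 12)).clip(min=0).tolist()
        rows_b = rng.normal(1.2, 1.0, size=(n_b, 12)).clip(min=0).tolist()
        norm, a, b = two_group_norm(rows_a, rows_b)
        exact = wilcoxon_de(norm, a, b, min_pct=0.0, exact_max_n=10)
        approx = wilcoxon_de(norm, a, b, min_pct=0.0, exact_max_n=0)
        for g in exact.index:
            pe, pa = exact.loc[g, "p_value"], approx.loc[g, "p_value"]
            if pe >= 0.05:
                checked += 1
                assert abs(pa - pe) / pe <= 0.10, (g, pe, pa)
    assert checked >= 20


def test_filter_significant_criteria():
    de = pd.DataFrame(
        {
            "log2FC": [1.5, 0.9, -2.0, 1.2],
            "p_value": [1e-9, 1e-13, 1e-9, 1e-3],
            "p_adj": [1e-8, 1e-12, 1e-8, 1e-2],
        },
        index=["keep_up", "lfc_too_small", "keep_down", "p_too_big"],
    )
    out = filter_significant(de, lfc_cut=1.0, alpha=1e-6)
    assert list(out.index) == ["keep_up", "keep_down"]
    assert list(out["direction"]) == ["A_enriched", "B_enriched"]
    assert len(filter_significant(de.iloc[:0])) == 0


def hypergeom_tail_oracle(overlap, universe, set_size, query) -> float:
    """Exact combinatorial sum for P(X >= overlap)."""
    total = comb(universe, query)
    return sum(
        comb(set_size, k) * comb(universe - set_size, query - k)
        for k in range(overlap, min(set_size, query) + 1)
    ) / total


def test_ora_matches_combinatorial_oracle():
    universe = [f"u{i}" for i in range(100)]
    geneset = universe[:10]
    query = universe[5:15]  # overlap 5
    table = hypergeom_ora(query, {"s": ("", geneset)}, universe)
    expected = hypergeom_tail_oracle(5, 100, 10, 10)
    assert table.loc[0, "overlap"] == 5
    assert table.loc[0, "p_value"] == pytest.approx(expected, abs=1e-12)


def test_ora_degenerate_tails():
    universe = [f"u{i}" for i in range(30)]
    # overlap 0 -> P(X >= 0) = 1
    t0 = hypergeom_ora(universe[:5], {"s": ("", universe[20:25])}, universe)
    assert t0.loc[0, "overlap"] == 0
    assert t0.loc[0, "p_value"] == 1.0
    # query = set = universe -> overlap = |universe|, p = 1
    t1 = hypergeom_ora(universe, {"s": ("", universe)}, universe)
    assert t1.loc[0, "overlap"] == 30
    assert t1.loc[0, "p_value"] == 1.0


def test_ora_validation():
    with pytest.raises(ValidationError):
        hypergeom_ora(["g1"], {"s": ("", ["g1"])}, [])
    with pytest.raises(ValidationError):
        hypergeom_ora(["not_in_universe"], {"s": ("", ["g1"])}, ["g1"])


def test_gmt_round_trip(tmp_path):
    (tmp_path / "sets.gmt").write_text(
        "er_folding\tchaperones\tHspa5\tPdia6\tCreld2\n"
        "axon\tguidance\tRobo2\n"
    )
    sets = read_gmt(tmp_path / "sets.gmt")
    assert sets["er_folding"] == ("chaperones", ["Hspa5", "Pdia6", "Creld2"])
    assert sets["axon"][1] == ["Robo2"]
    with pytest.raises(ValidationError):
        (tmp_path / "bad.gmt").write_text("only_name\n")
        read_gmt(tmp_path / "bad.gmt")


def test_planted_er_genes_recovered_on_simulation(sim_norm, sim_bundle, sim_labels):
    """ER genes planted 4x higher in mature Gnao1 cells come out significant
    at the |log2FC|>1, adjusted p<1e-6 criteria; no background gene does."""
    _, catalog, _, truth = sim_bundle
    a = [b for b in sim_norm.barcodes if sim_labels[b] == "mature_Gnao1"]
    b_ = [b for b in sim_norm.barcodes if sim_labels[b] == "mature_Gnai2"]
    de = wilcoxon_de(sim_norm, a, b_)
    sig = filter_significant(de)
    er = set(catalog.genes_of_class("ER"))
    background = set(catalog.genes_of_class("other"))
    recovered = er & set(sig.index)
    assert len(recovered) / len(er) >= 0.9
    assert len(background & set(sig.index)) == 0
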