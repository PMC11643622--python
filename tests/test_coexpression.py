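"""Receptor calling, pattern enumeration, dosage, and Gnao1 subtypes."""

from collections import Counter
from itertools import chain

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vrcall.coexpression import (
    ReceptorCalls,
    call_receptors,
    classify_gnao1_subsets,
    count_per_cell,
    dosage_analysis,
    enumerate_patterns,
)
from vrcall.errors import ConfigurationError
from vrcall.io_catalog import NormMatrix

from conftest import make_catalog

V2R_CATALOG = make_catalog(
    {
        "Vmn2r1": ("V2R_C1", "C1"),
        "Vmn2r2": ("V2R_C2", "C2"),
        "Vmn2r3": ("V2R_C2", "C2"),
        "Vmn2r20": ("V2R_ABDE", "A"),
        "H2-M10.1": ("H2Mv", ""),
        "Vmn1r1": ("V1R", "A"),
    }
)
GENES = list(V2R_CATALOG.table.index)


def norm_of(rows: list[list[float]], barcodes=None) -> NormMatrix:
    barcodes = barcodes or [f"c{i}" for i in range(len(rows))]
    return NormMatrix(barcodes, GENES, np.array(rows))


def calls_of(per_cell: dict[str, dict[str, set]]) -> ReceptorCalls:
    cols = ("called_V1R", "called_ABD", "called_C1", "called_C2", "called_H2Mv")
    table = pd.DataFrame(
        {
            col: [frozenset(sets.get(col.removeprefix("called_"), set())) for sets in per_cell.values()]
            for col in cols
        },
        index=list(per_cell),
    )
    return ReceptorCalls(table)


def test_strict_threshold_exceedance():
    # value 1.30 surpasses the 1.25 V2R cutoff; exactly 1.25 does not
    norm = norm_of([[1.30, 1.25, 0.0, 0.0, 0.0, 0.0]])
    calls = call_receptors(norm, V2R_CATALOG, {"V2R": 1.25, "H2Mv": 1.25, "V1R": 2.5})
    assert calls.table.loc["c0", "called_C1"] == {"Vmn2r1"}
    assert calls.table.loc["c0", "called_C2"] == frozenset()


def test_cells_with_no_calls_are_retained():
    norm = norm_of([[0.0] * 6, [2.0, 0, 0, 0, 0, 0]])
    calls = call_receptors(norm, V2R_CATALOG, {"V2R": 1.25})
    assert list(calls.table.index) == ["c0", "c1"]
    hist = count_per_cell(calls, "C")
    assert hist.to_dict() == {0: 1, 1: 1}


def test_call_monotone_in_threshold(sim_norm, sim_bundle, sim_labels):
    _, catalog, _, _ = sim_bundle
    mature = [b for b in sim_norm.barcodes if str(sim_labels[b]).startswith("mature")]
    loose = call_receptors(sim_norm, catalog, {"V1R": 2.0, "V2R": 2.0, "H2Mv": 2.0}, cells=mature)
    strict = call_receptors(sim_norm, catalog, {"V1R": 3.0, "V2R": 3.0, "H2Mv": 3.0}, cells=mature)
    for col in loose.table.columns:
        for bc in mature:
            assert strict.table.loc[bc, col] <= loose.table.loc[bc, col]


def test_calls_recover_planted_truth(sim_norm, sim_bundle, sim_labels, sim_thresholds):
    _, catalog, _, truth = sim_bundle
    mature = [
        b
        for b in sim_norm.barcodes
        if sim_labels[b] in ("mature_Gnao1", "mature_Gnai2")
        and not truth.cells.loc[b, "is_doublet"]
    ]
    calls = call_receptors(sim_norm, catalog, sim_thresholds, cells=mature)
    tp = fp = fn = 0
    for bc in mature:
        for fam, col in [
            ("V1R", "called_V1R"),
            ("ABD", "called_ABD"),
            ("C1", "called_C1"),
            ("C2", "called_C2"),
            ("H2Mv", "called_H2Mv"),
        ]:
            planted = truth.receptor_sets[bc][fam]
            called = calls.table.loc[bc, col]
            tp += len(planted & called)
            fp += len(called - planted)
            fn += len(planted - called)
    assert tp / (tp + fp) >= 0.98
    assert tp / (tp + fn) >= 0.98


def test_count_histogram_by_hand():
    calls = calls_of(
        {
            "a": {"C2": {"Vmn2r2", "Vmn2r3"}},
            "b": {"C2": {"Vmn2r2", "Vmn2r3"}},
            "c": {},
        }
    )
    assert count_per_cell(calls, "C").to_dict() == {0: 1, 2: 2}
    assert count_per_cell(calls, "C").sum() == 3


def test_c2_counts_within_planted_range(sim_norm, sim_bundle, sim_labels, sim_thresholds):
    """Planted C2 cells carry 2-6 members; detected k stays in that band."""
    _, catalog, _, truth = sim_bundle
    c2_cells = [
        b
        for b in sim_norm.barcodes
        if sim_labels[b] == "mature_Gnao1"
        and not truth.cells.loc[b, "is_doublet"]
        and truth.receptor_sets[b]["C2"]
    ]
    calls = call_receptors(sim_norm, catalog, sim_thresholds, cells=c2_cells)
    ks = calls.table["called_C2"].map(len)
    assert ks.quantile(0.01) >= 2 - 1  # allow rare single dropout
    assert ks.max() <= 6


def test_pattern_enumeration_by_hand():
    calls = calls_of(
        {
            "a": {"ABD": {"A", "B"}},
            "b": {"ABD": {"A", "B"}},
            "c": {"ABD": {"A", "B"}},
            "d": {"ABD": {"C", "D"}},
        }
    )
    at2 = enumerate_patterns(calls, "ABD", min_cells=2)
    assert len(at2) == 1
    assert at2.iloc[0]["gene_combination"] == ("A", "B")
    assert at2.iloc[0]["n_cells"] == 3
    at1 = enumerate_patterns(calls, "ABD", min_cells=1)
    assert ("C", "D") in set(at1["gene_combination"])


def test_pattern_sum_equals_calling_cells(sim_norm, sim_bundle, sim_labels, sim_thresholds):
    _, catalog, _, _ = sim_bundle
    mature = [b for b in sim_norm.barcodes if str(sim_labels[b]).startswith("mature")]
    calls = call_receptors(sim_norm, catalog, sim_thresholds, cells=mature)
    pat = enumerate_patterns(calls, "V1R", min_cells=1)
    n_with_calls = int((calls.table["called_V1R"].map(len) > 0).sum())
    assert pat["n_cells"].sum() == n_with_calls


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.data())
def test_patterns_match_bruteforce_and_cell_order(data):
    """On <=20 cells the table equals a brute-force enumeration and is
    invariant to cell order."""
    n_cells = data.draw(st.integers(1, 20))
    genes = ["A", "B", "C", "D"]
    sets = [
        frozenset(data.draw(st.sets(st.sampled_from(genes), max_size=4)))
        for _ in range(n_cells)
    ]
    calls = calls_of({f"c{i}": {"ABD": set(s)} for i, s in enumerate(sets)})
    min_cells = data.draw(st.integers(1, 3))
    table = enumerate_patterns(calls, "ABD", min_cells=min_cells)
    brute = Counter(tuple(sorted(s)) for s in sets if s)
    expected = {c: n for c, n in brute.items() if n >= min_cells}
    assert dict(zip(table["gene_combination"], table["n_cells"])) == expected
    # permutation invariance
    perm = np.random.default_rng(0).permutation(n_cells)
    shuffled = calls_of({f"c{i}": {"ABD": set(sets[j])} for i, j in enumerate(perm)})
    table2 = enumerate_patterns(shuffled, "ABD", min_cells=min_cells)
    assert sorted(zip(table["gene_combination"], table["n_cells"])) == sorted(
        zip(table2["gene_combination"], table2["n_cells"])
    )


def test_cross_family_scope_tags_genes():
    calls = calls_of(
        {
            "a": {"ABD": {"Vmn2r20"}, "C1": {"Vmn2r1"}},
            "b": {"ABD": {"Vmn2r20"}, "C1": {"Vmn2r1"}},
        }
    )
    pat = enumerate_patterns(calls, ["ABD", "C", "H2Mv"], min_cells=2)
    assert pat.iloc[0]["gene_combination"] == ("ABD:Vmn2r20", "C:Vmn2r1")
    assert pat.iloc[0]["family_scope"] == "ABDxCxH2Mv"


def test_dosage_by_hand():
    norm = norm_of([[0.0, 1.5, 2.0, 0.0, 0.0, 3.0]])
    calls = calls_of({"c0": {"C2": {"Vmn2r2", "Vmn2r3"}}})
    summary, per_cell = dosage_analysis(norm, calls, V2R_CATALOG, "C", "Vmn1r1")
    assert per_cell.loc["c0", "k"] == 2
    assert per_cell.loc["c0", "family_total"] == pytest.approx(3.5)
    assert per_cell.loc["c0", "control"] == pytest.approx(3.0)
    assert summary.loc[0, "n_cells"] == 1


def test_dosage_missing_control_gene():
    norm = norm_of([[0.0] * 6])
    calls = calls_of({"c0": {}})
    with pytest.raises(ConfigurationError):
        dosage_analysis(norm, calls, V2R_CATALOG, "C", "NotAGene")


def test_dosage_proportionality_on_simulation(
    sim_norm, sim_bundle, sim_labels, sim_thresholds
):
    """Summed family-C expression doubles from k=1 to k=2 while the Gnao1
    control stays flat (planted receptors share one on-distribution)."""
    _, catalog, _, _ = sim_bundle
    gnao1 = [b for b in sim_norm.barcodes if sim_labels[b] == "mature_Gnao1"]
    calls = call_receptors(sim_norm, catalog, sim_thresholds, cells=gnao1)
    summary, _ = dosage_analysis(sim_norm, calls, catalog, "C", "Gnao1")
    m = summary.set_index("k")
    assert 1.6 <= m.loc[2, "total_median"] / m.loc[1, "total_median"] <= 2.4
    assert 0.9 <= m.loc[2, "control_median"] / m.loc[1, "control_median"] <= 1.1


@pytest.mark.parametrize(
    "sets,expected",
    [
        ({"C1": {"Vmn2r1"}}, "C1"),
        ({"C2": {"Vmn2r2", "Vmn2r3"}, "H2Mv": {"H2-M10.1"}}, "C2_H2Mv_pos"),
        ({"C2": {"Vmn2r2"}}, "C2_H2Mv_neg"),
        ({}, "C_none"),
        ({"C1": {"Vmn2r1"}, "C2": {"Vmn2r2"}}, "mixed"),
    ],
)
def test_subtype_rules(sets, expected):
    calls = calls_of({"c0": sets})
    classes, _ = classify_gnao1_subsets(calls)
    assert classes["c0"] == expected


def test_subtype_mixed_rule_folding():
    calls = calls_of({"c0": {"C1": {"Vmn2r1"}, "C2": {"Vmn2r2"}}})
    classes, _ = classify_gnao1_subsets(calls, mixed_rule="C1")
    assert classes["c0"] == "C1"


def test_h2mv_negative_fraction_summary():
    calls = calls_of(
        {
            "a": {"C1": {"Vmn2r1"}},
            "b": {"C2": {"Vmn2r2"}, "H2Mv": {"H2-M10.1"}},
            "c": {"C2": {"Vmn2r2"}},
            "d": {},
        }
    )
    _, summary = classify_gnao1_subsets(calls)
    # among the 3 family-C callers, a and c lack H2-Mv
    assert summary["frac_h2mv_negative"] == pytest.approx(2 / 3)
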