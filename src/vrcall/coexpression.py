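"""Per-cell receptor calling, combinatorial patterns, dosage, and subtypes.

A receptor (V1R, V2R, or H2-Mv gene) is called expressed in a cell only
when its normalized expression strictly exceeds the family threshold.
Distinct per-cell combinations of called genes are then enumerated; the
combinations seen in fewer than ``min_cells`` cells (default 2) are
discarded, because a chimeric droplet containing two cells produces a
given spurious combination more than once only with very low probability.

Family scopes: ``V1R``, ``ABD`` (family-A/B/D/E V2Rs), ``C`` (family-C
V2Rs: C1 = Vmn2r1 plus the C2 group), ``C1``, ``C2``, and ``H2Mv``.
Cross-family scopes are expressed as a list (e.g. ``["ABD", "C",
"H2Mv"]``); genes in cross-family combinations carry a family tag so the
same symbol in two families cannot collide.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from vrcall.errors import ConfigurationError, ValidationError
from vrcall.io_catalog import GeneCatalog, NormMatrix
from vrcall.threshold_detect import ThresholdResult

#: scope name -> (catalog classes, thresholding family)
SCOPES: Mapping[str, tuple[tuple[str, ...], str]] = {
    "V1R": (("V1R",), "V1R"),
    "ABD": (("V2R_ABDE",), "V2R"),
    "C": (("V2R_C1", "V2R_C2"), "V2R"),
    "C1": (("V2R_C1",), "V2R"),
    "C2": (("V2R_C2",), "V2R"),
    "H2Mv": (("H2Mv",), "H2Mv"),
}

CALL_COLUMNS = ("called_V1R", "called_ABD", "called_C1", "called_C2", "called_H2Mv")


@dataclass
class ReceptorCalls:
    """Per-cell called receptor sets, one frozenset column per family scope."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(CALL_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValidationError(f"call table missing columns {sorted(missing)}")

    @property
    def barcodes(self) -> list[str]:
        return list(self.table.index)

    def sets_for_scope(self, scope: str | Sequence[str]) -> pd.Series:
        """Called genes per cell within one scope or a cross-family scope.

        Single-family scopes yield plain gene frozensets; list scopes yield
        frozensets of ``family:gene`` tags.
        """
        if isinstance(scope, str):
            if scope == "C":
                return self.table["called_C1"].combine(
                    self.table["called_C2"], frozenset.union
                )
            col = f"called_{scope}"
            if col not in self.table.columns:
                raise ValidationError(f"unknown family scope {scope!r}")
            return self.table[col]
        tagged = []
        for fam in scope:
            sets = self.sets_for_scope(fam)
            tagged.append(sets.map(lambda s, f=fam: frozenset(f"{f}:{g}" for g in s)))
        out = tagged[0]
        for t in tagged[1:]:
            out = out.combine(t, frozenset.union)
        return out

    def to_flat_frame(self) -> pd.DataFrame:
        """Calls as a writable table with comma-joined gene lists."""
        flat = {
            col: self.table[col].map(lambda s: ",".join(sorted(s)))
            for col in CALL_COLUMNS
        }
        return pd.DataFrame(flat, index=self.table.index)


def call_receptors(
    norm: NormMatrix,
    catalog: GeneCatalog,
    thresholds: Mapping[str, ThresholdResult | float],
    cells: Sequence[str] | None = None,
) -> ReceptorCalls:
    """Call expressed receptors per cell by strict threshold exceedance.

    A gene is called when value > threshold (a value exactly at the
    threshold is not called). Cells with no calls are retained with empty
    sets. Families absent from *thresholds* are left uncalled.
    """
    rows = norm.cell_indices(cells) if cells is not None else np.arange(norm.n_cells)
    barcodes = [norm.barcodes[i] for i in rows]
    cutoffs = {
        fam: (t.threshold if isinstance(t, ThresholdResult) else float(t))
        for fam, t in thresholds.items()
    }

    empty = frozenset()
    data: dict[str, list[frozenset]] = {}
    for scope in ("V1R", "ABD", "C1", "C2", "H2Mv"):
        classes, family = SCOPES[scope]
        genes = [g for g in catalog.genes_of_class(classes) if g in norm.genes]
        col = f"called_{scope}"
        if not genes or family not in cutoffs:
            data[col] = [empty] * len(rows)
            continue
        cut = cutoffs[family]
        sub = norm.values[np.ix_(rows, norm.gene_indices(genes))]
        exceed = sub > cut
        gene_arr = np.array(genes, dtype=object)
        data[col] = [frozenset(gene_arr[exceed[i]]) for i in range(len(rows))]

    return ReceptorCalls(pd.DataFrame(data, index=pd.Index(barcodes, name="barcode")))


def count_per_cell(calls: ReceptorCalls, family_scope: str | Sequence[str]) -> pd.Series:
    """Histogram of k = number of called genes per cell within a scope.

    Includes k = 0 cells; the histogram total equals the number of cells.
    """
    sizes = calls.sets_for_scope(family_scope).map(len)
    hist = sizes.value_counts().sort_index()
    hist.index.name = "k"
    hist.name = "n_cells"
    return hist


def enumerate_patterns(
    calls: ReceptorCalls,
    family_scope: str | Sequence[str],
    min_cells: int = 2,
) -> pd.DataFrame:
    """Count every distinct called-gene combination within a scope.

    Cells with an empty call set in the scope do not form a pattern.
    Combinations observed in fewer than *min_cells* cells are dropped —
    the frequency-based doublet filter. Rows are sorted by descending
    cell count, then lexicographically by combination.
    """
    sets = calls.sets_for_scope(family_scope)
    counter = Counter(tuple(sorted(s)) for s in sets if s)
    scope_name = family_scope if isinstance(family_scope, str) else "x".join(family_scope)
    rows = [
        {"family_scope": scope_name, "gene_combination": combo, "n_cells": n}
        for combo, n in counter.items()
        if n >= min_cells
    ]
    df = pd.DataFrame(rows, columns=["family_scope", "gene_combination", "n_cells"])
    if len(df):
        df = df.sort_values(
            ["n_cells", "gene_combination"], ascending=[False, True]
        ).reset_index(drop=True)
    return df


def dosage_analysis(
    norm: NormMatrix,
    calls: ReceptorCalls,
    catalog: GeneCatalog,
    family_scope: str | Sequence[str],
    control_gene: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summed called-family expression per cell, grouped by the number of
    called members k, with a control gene (e.g. Gnao1) reported per k.

    Returns ``(summary, per_cell)``: the summary has one row per observed
    k with the cell count and median/quartiles of the summed family
    expression and of the control gene; per_cell carries the underlying
    per-cell values.
    """
    if control_gene not in norm.genes:
        raise ConfigurationError(f"control gene {control_gene!r} not in matrix")
    sets = calls.sets_for_scope(family_scope)
    rows = norm.cell_indices(sets.index)
    control = norm.gene_values(control_gene)[rows]

    totals = np.zeros(len(sets))
    for i, (bc, geneset) in enumerate(sets.items()):
        if geneset:
            cols = norm.gene_indices(sorted(geneset))
            totals[i] = norm.values[rows[i], cols].sum()
    per_cell = pd.DataFrame(
        {"k": sets.map(len).to_numpy(), "family_total": totals, "control": control},
        index=sets.index,
    )

    def q(s, p):
        return s.quantile(p)

    summary = (
        per_cell.groupby("k")
        .agg(
            n_cells=("family_total", "size"),
            total_median=("family_total", "median"),
            total_q1=("family_total", lambda s: q(s, 0.25)),
            total_q3=("family_total", lambda s: q(s, 0.75)),
            control_median=("control", "median"),
            control_q1=("control", lambda s: q(s, 0.25)),
            control_q3=("control", lambda s: q(s, 0.75)),
        )
        .reset_index()
    )
    return summary, per_cell


def classify_gnao1_subsets(
    calls: ReceptorCalls,
    cells: Sequence[str] | None = None,
    mixed_rule: str = "mixed",
) -> tuple[pd.Series, dict[str, float]]:
    """Classify mature Gnao1 cells by family-C V2R and H2-Mv usage.

    Classes: ``C1`` (a C1 call and no C2), ``C2_H2Mv_pos`` / ``C2_H2Mv_neg``
    (C2 calls split by H2-Mv presence), ``C_none`` (no family-C call),
    and — for the rare cells calling both C1 and C2 — the class given by
    *mixed_rule*: ``"mixed"`` reports them separately, ``"C1"`` or
    ``"C2"`` folds them into that branch.

    The summary includes ``frac_h2mv_negative``: the fraction of family-C
    callers (C1 or C2) without any H2-Mv call.
    """
    table = calls.table if cells is None else calls.table.loc[list(cells)]
    labels = []
    for _, row in table.iterrows():
        has_c1 = bool(row["called_C1"])
        has_c2 = bool(row["called_C2"])
        has_h2 = bool(row["called_H2Mv"])
        if has_c1 and has_c2:
            if mixed_rule == "mixed":
                labels.append("mixed")
                continue
            has_c1, has_c2 = mixed_rule == "C1", mixed_rule == "C2"
        if has_c1:
            labels.append("C1")
        elif has_c2:
            labels.append("C2_H2Mv_pos" if has_h2 else "C2_H2Mv_neg")
        else:
            labels.append("C_none")
    classes = pd.Series(labels, index=table.index, name="subtype")

    c_callers = table.index[(table["called_C1"].map(bool)) | (table["called_C2"].map(bool))]
    if len(c_callers):
        h2_neg = (~table.loc[c_callers, "called_H2Mv"].map(bool)).mean()
    else:
        h2_neg = float("nan")
    counts = classes.value_counts()
    summary = {f"n_{k}": int(v) for k, v in counts.items()}
    summary["n_cells"] = int(len(classes))
    summary["frac_h2mv_negative"] = float(h2_neg)
    return classes, summary
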