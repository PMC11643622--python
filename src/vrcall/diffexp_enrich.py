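"""Wilcoxon rank-sum differential expression and hypergeometric ORA.

Differential expression between two cell groups uses the two-sided
Wilcoxon rank-sum (Mann-Whitney) test per gene — exact permutation
enumeration for small groups, tie-corrected normal approximation with
continuity correction otherwise — with Bonferroni adjustment over the
tested genes. Fold changes are computed on de-logged normalized means
with a pseudocount of 1:

    log2FC = log2((mean(expm1 x_A) + 1) / (mean(expm1 x_B) + 1))

Gene-set over-representation uses the upper-tail hypergeometric test of
the overlap between a query gene list and each set, inside a stated
universe.
"""

from __future__ import annotations

from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, norm, rankdata

from vrcall.errors import ValidationError
from vrcall.io_catalog import NormMatrix


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p for the rank-sum of group x.

    Enumerates all assignments of the pooled values into groups of the
    observed sizes and counts those whose rank-sum deviates from its
    permutation mean at least as much as observed. Valid with ties.
    """
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n_a, n = len(x), len(pooled)
    w_obs = ranks[:n_a].sum()
    mu = n_a * (n + 1) / 2.0
    d_obs = abs(w_obs - mu)
    count = 0
    total = 0
    for idx in combinations(range(n), n_a):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= d_obs - 1e-9:
            count += 1
    return count / total


def _asymptotic_ranksum_p(
    ranks: np.ndarray, tie_term: np.ndarray, n_a: int, n_b: int
) -> np.ndarray:
    """Vectorized tie-corrected normal approximation, continuity corrected.

    *ranks* is cells x genes with group A in the first ``n_a`` rows;
    *tie_term* is sum(t^3 - t) per gene.
    """
    n = n_a + n_b
    w = ranks[:n_a].sum(axis=0)
    mu = n_a * (n + 1) / 2.0
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    var = np.maximum(var, 0.0)
    d = np.abs(w - mu)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, np.maximum(d - 0.5, 0.0) / np.sqrt(var), 0.0)
    p = 2.0 * norm.sf(z)
    return np.minimum(p, 1.0)


def wilcoxon_de(
    norm_matrix: NormMatrix,
    cells_A: Sequence[str],
    cells_B: Sequence[str],
    pseudocount: float = 1.0,
    min_pct: float = 0.01,
    lfc_cut: float = 1.0,
    alpha: float = 1e-6,
    exact_max_n: int = 10,
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum differential expression of A over B.

    Only genes detected (value > 0) in at least *min_pct* of either group
    are tested; Bonferroni adjustment runs over the tested genes. Groups
    must be disjoint with at least 3 cells each. When both groups have at
    most *exact_max_n* cells, p-values come from exact permutation
    enumeration.
    """
    set_a, set_b = set(cells_A), set(cells_B)
    if set_a & set_b:
        raise ValidationError("groups A and B overlap")
    if len(set_a) < 3 or len(set_b) < 3:
        raise ValidationError("each group needs at least 3 cells")

    rows_a = norm_matrix.cell_indices(cells_A)
    rows_b = norm_matrix.cell_indices(cells_B)
    va = norm_matrix.values[rows_a]
    vb = norm_matrix.values[rows_b]

    pct_a = (va > 0).mean(axis=0)
    pct_b = (vb > 0).mean(axis=0)
    tested = (pct_a >= min_pct) | (pct_b >= min_pct)

    mean_a = np.expm1(va).mean(axis=0)
    mean_b = np.expm1(vb).mean(axis=0)
    log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))

    n_a, n_b = len(rows_a), len(rows_b)
    p = np.full(norm_matrix.values.shape[1], np.nan)
    cols = np.flatnonzero(tested)
    if cols.size:
        if n_a <= exact_max_n and n_b <= exact_max_n:
            for j in cols:
                p[j] = _exact_ranksum_p(va[:, j], vb[:, j])
        else:
            stacked = np.vstack([va[:, cols], vb[:, cols]])
            ranks = rankdata(stacked, axis=0)
            tie_term = np.zeros(cols.size)
            for jj in range(cols.size):
                _, counts = np.unique(stacked[:, jj], return_counts=True)
                tie_term[jj] = np.sum(counts.astype(float) ** 3 - counts)
            p[cols] = _asymptotic_ranksum_p(ranks, tie_term, n_a, n_b)

    n_tested = int(tested.sum())
    p_adj = np.minimum(p * n_tested, 1.0)

    df = pd.DataFrame(
        {
            "log2FC": log2fc,
            "p_value": p,
            "p_adj": p_adj,
            "pct_expressed_A": pct_a,
            "pct_expressed_B": pct_b,
            "tested": tested,
        },
        index=pd.Index(norm_matrix.genes, name="gene"),
    )
    df["significant"] = (
        df["tested"] & (df["log2FC"].abs() > lfc_cut) & (df["p_adj"] < alpha)
    )
    return df


def filter_significant(
    de: pd.DataFrame, lfc_cut: float = 1.0, alpha: float = 1e-6
) -> pd.DataFrame:
    """Rows with |log2FC| > lfc_cut and p_adj < alpha, tagged by direction."""
    keep = (de["log2FC"].abs() > lfc_cut) & (de["p_adj"] < alpha)
    out = de.loc[keep.fillna(False)].copy()
    out["direction"] = np.where(out["log2FC"] > 0, "A_enriched", "B_enriched")
    return out


def read_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    """Read GMT gene sets: one set per line, name<TAB>description<TAB>genes..."""
    sets: dict[str, tuple[str, list[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(f"malformed GMT line: {line[:50]!r}")
        sets[parts[0]] = (parts[1], [g for g in parts[2:] if g])
    return sets


def hypergeom_ora(
    query_genes: Iterable[str],
    gene_sets: Mapping[str, tuple[str, list[str]]] | Mapping[str, list[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of each gene set.

    p = P(overlap >= observed) when drawing |query| genes from the
    universe with |set ∩ universe| marked. Gene sets are intersected with
    the universe before testing; the query must be inside the universe.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("universe is empty")
    query = set(query_genes)
    if not query <= universe:
        raise ValidationError("query genes must be a subset of the universe")

    rows = []
    for name, payload in gene_sets.items():
        genes = payload[1] if isinstance(payload, tuple) else payload
        in_universe = set(genes) & universe
        overlap = len(in_universe & query)
        p = float(hypergeom.sf(overlap - 1, len(universe), len(in_universe), len(query)))
        rows.append(
            {
                "gene_set": name,
                "overlap": overlap,
                "set_size": len(in_universe),
                "query_size": len(query),
                "universe_size": len(universe),
                "p_value": min(p, 1.0),
            }
        )
    return (
        pd.DataFrame(
            rows,
            columns=[
                "gene_set",
                "overlap",
                "set_size",
                "query_size",
                "universe_size",
                "p_value",
            ],
        )
        .sort_values("p_value", kind="stable")
        .reset_index(drop=True)
    )
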