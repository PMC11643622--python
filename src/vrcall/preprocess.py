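"""Quality control, log-normalization, and marker-based cell typing.

The QC contract follows the standard droplet scRNA-seq recipe for this
tissue: keep cells detecting 200-7000 genes (inclusive), drop red-blood
cell contamination (any count in a hemoglobin-class gene), and drop
mitochondria-dominated cells via a per-cell percentage cutoff.
Normalization is the LogNormalize transform: counts scaled to a fixed
per-cell total (default 10,000) and ln(1 + x) transformed.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from vrcall.errors import ConfigurationError, ValidationError
from vrcall.io_catalog import CountMatrix, GeneCatalog, NormMatrix

#: Marker roles required by the rule-based classifier mapped to the default
#: mouse gene symbols. Gnao1/Gnai2 mark the basal/apical neuronal lineages,
#: Gap43 marks immature neurons, Ascl1/Neurod1 mark progenitors.
DEFAULT_ROLE_MAP: Mapping[str, str] = {
    "gnao1": "Gnao1",
    "gnai2": "Gnai2",
    "immature": "Gap43",
    "progenitor_1": "Ascl1",
    "progenitor_2": "Neurod1",
}


def compute_qc(counts: CountMatrix, catalog: GeneCatalog) -> pd.DataFrame:
    """Per-cell QC metrics: n_genes, total_counts, pct_mito, hbb_positive.

    Mito and hemoglobin gene classes come from the catalog and may be
    empty, in which case pct_mito is 0 and hbb_positive is False.
    """
    mat = counts.counts
    n_genes = np.asarray((mat > 0).sum(axis=1)).ravel()
    total = np.asarray(mat.sum(axis=1)).ravel()

    mito = [g for g in catalog.genes_of_class("mito") if g in counts.genes]
    hbb = [g for g in catalog.genes_of_class("hemoglobin") if g in counts.genes]
    gene_pos = {g: i for i, g in enumerate(counts.genes)}

    if mito:
        mito_counts = np.asarray(mat[:, [gene_pos[g] for g in mito]].sum(axis=1)).ravel()
        with np.errstate(divide="ignore", invalid="ignore"):
            pct_mito = np.where(total > 0, 100.0 * mito_counts / total, 0.0)
    else:
        pct_mito = np.zeros(counts.n_cells)

    if hbb:
        hbb_pos = (
            np.asarray(mat[:, [gene_pos[g] for g in hbb]].sum(axis=1)).ravel() > 0
        )
    else:
        hbb_pos = np.zeros(counts.n_cells, dtype=bool)

    return pd.DataFrame(
        {
            "n_genes": n_genes,
            "total_counts": total,
            "pct_mito": pct_mito,
            "hbb_positive": hbb_pos,
        },
        index=pd.Index(counts.barcodes, name="barcode"),
    )


def filter_cells(
    counts: CountMatrix,
    qc: pd.DataFrame,
    min_genes: int = 200,
    max_genes: int = 7000,
    drop_hbb: bool = True,
    max_pct_mito: float = 20.0,
) -> CountMatrix:
    """Drop low/high-complexity cells, hemoglobin-positive cells, and
    mitochondria-dominated cells. Bounds are inclusive; cell order is
    preserved. Returns an empty matrix (with a warning) if nothing passes.
    """
    qc = qc.loc[counts.barcodes]
    keep = (qc["n_genes"] >= min_genes) & (qc["n_genes"] <= max_genes)
    keep &= qc["pct_mito"] <= max_pct_mito
    if drop_hbb:
        keep &= ~qc["hbb_positive"]
    idx = np.flatnonzero(keep.to_numpy())
    if idx.size == 0:
        warnings.warn("all cells removed by QC filters", stacklevel=2)
    return counts.subset_cells(idx)


def lognormalize(counts: CountMatrix, scale: float = 10000.0) -> NormMatrix:
    """LogNormalize: value(c, g) = ln(1 + scale * count(c, g) / total(c)).

    Zero counts map to exactly zero; a zero-total cell is an error.
    """
    total = np.asarray(counts.counts.sum(axis=1)).ravel().astype(float)
    if np.any(total == 0):
        bad = counts.barcodes[int(np.argmin(total))]
        raise ValidationError(f"cell {bad!r} has zero total counts; filter first")
    mat = counts.counts.tocoo()
    values = np.zeros((counts.n_cells, counts.n_genes))
    values[mat.row, mat.col] = np.log1p(scale * mat.data / total[mat.row])
    return NormMatrix(list(counts.barcodes), list(counts.genes), values)


def classify_cells(
    norm: NormMatrix,
    catalog: GeneCatalog,
    labels: pd.Series | None = None,
    marker_cut: float = 1.0,
    role_map: Mapping[str, str] | None = None,
) -> pd.Series:
    """Assign cell-type labels from marker expression, or pass through
    externally supplied labels verbatim.

    Rules (normalized expression vs ``marker_cut``):

    * progenitor: Ascl1 or Neurod1 above cut (and Gap43 at/below cut);
    * immature_Gnao1 / immature_Gnai2: Gap43 above cut, split by the
      dominant G-protein marker;
    * mature_Gnao1: Gnao1 above cut, Gap43 at/below cut (mature_Gnai2
      analogous); both G-protein markers above cut -> ``ambiguous``;
    * anything else -> ``other``.
    """
    if labels is not None:
        return labels

    roles = dict(DEFAULT_ROLE_MAP)
    if role_map:
        roles.update(role_map)
    missing = [g for g in roles.values() if g not in norm.genes]
    if missing:
        raise ConfigurationError(f"marker gene(s) missing from matrix: {missing}")

    gnao1 = norm.gene_values(roles["gnao1"])
    gnai2 = norm.gene_values(roles["gnai2"])
    gap43 = norm.gene_values(roles["immature"])
    prog = np.maximum(
        norm.gene_values(roles["progenitor_1"]), norm.gene_values(roles["progenitor_2"])
    )

    out = np.full(norm.n_cells, "other", dtype=object)
    immature = gap43 > marker_cut
    out[immature & (gnao1 > gnai2)] = "immature_Gnao1"
    out[immature & (gnai2 > gnao1)] = "immature_Gnai2"
    mature = ~immature
    out[mature & (prog > marker_cut)] = "progenitor"
    is_ao = gnao1 > marker_cut
    is_ai = gnai2 > marker_cut
    out[mature & (prog <= marker_cut) & is_ao & ~is_ai] = "mature_Gnao1"
    out[mature & (prog <= marker_cut) & is_ai & ~is_ao] = "mature_Gnai2"
    out[mature & is_ao & is_ai] = "ambiguous"
    return pd.Series(out, index=pd.Index(norm.barcodes, name="barcode"), name="label")
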