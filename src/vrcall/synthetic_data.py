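"""Synthetic datasets with planted ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes in
a vomeronasal single-cell experiment:

* a mixed population of progenitors, immature neurons, mature Gnao1 and
  Gnai2 neurons, and non-neuronal cells, each with its marker genes on;
* receptor expression that is bimodal across cells — every receptor gene
  carries a small ambient (cell-free contamination) negative-binomial
  mean in all cells and a much larger "on" mean in the cells that truly
  express it;
* planted co-expression rules: mature Gnai2 neurons express one V1R with
  rare recurring pairs; mature Gnao1 neurons express one family-ABD V2R
  (with planted recurring multi-gene exceptions), plus either the single
  C1 gene (Vmn2r1) or a 2-6 member subset of the C2 group
  (Vmn2r2-Vmn2r7), with 1-4 H2-Mv genes coupled to the C2 branch;
* endoplasmic-reticulum genes upregulated in mature Gnao1 cells by a
  configurable log2 fold change;
* optional chimeric doublets formed by summing two cells' counts.

Counts are negative binomial with per-cell lognormal library-size
factors. All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from vrcall.axis_profile import AxisProfile
from vrcall.errors import ValidationError
from vrcall.io_catalog import CountMatrix, GeneCatalog

MARKER_GENES = ("Gnao1", "Gnai2", "Gap43", "Omp", "Ascl1", "Neurod1")
MITO_GENES = tuple(f"mt-Gene{i}" for i in range(1, 11))
HBB_GENE = "Hbb-bs"
ER_SEED_NAMES = ("Creld2", "Pdia6", "Dnajc3", "Sdf2l1", "Hspa5")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the count-matrix generator.

    Cell numbers and co-expression rules mirror the structure of the
    mature vomeronasal epithelium at a desk-testable scale; the gene
    panel loosely mirrors the mouse receptor repertoire (150 V1Rs, 70
    family-ABD V2Rs, 1 + 6 family-C V2Rs, 6 H2-Mv genes).
    """

    # cells per type
    n_mature_gnao1: int = 1000
    n_mature_gnai2: int = 2000
    n_immature_gnao1: int = 400
    n_immature_gnai2: int = 400
    n_progenitor: int = 400
    n_other: int = 800
    # gene panel sizes
    n_V1R: int = 150
    n_ABD: int = 70
    n_C2: int = 6  # plus the single C1 gene Vmn2r1
    n_H2Mv: int = 6
    n_background: int = 1000
    n_ER: int = 50
    # expression model
    on_mean: float = 25.0
    ambient_mean: float = 0.05
    marker_mean: float = 20.0
    marker_ambient_mean: float = 0.0
    background_mean: float = 1.0
    er_base_mean: float = 2.0
    dispersion: float = 0.15
    library_size_logmean: float = 0.0
    library_size_logsd: float = 0.3
    # co-expression rules
    p_V1R_pair: float = 0.04
    planted_v1r_pairs: tuple[tuple[tuple[str, ...], float], ...] = (
        (("Vmn1r85", "Vmn1r86"), 0.03),
    )
    planted_abd_patterns: tuple[tuple[tuple[str, ...], float], ...] = (
        (("Vmn2r20", "Vmn2r22"), 0.043),
        (("Vmn2r39", "Vmn2r43", "Vmn2r50"), 0.010),
    )
    C2_members_range: tuple[int, int] = (2, 6)
    H2Mv_range: tuple[int, int] = (1, 4)
    p_H2Mv_given_C2: float = 0.7
    p_C1_vs_C2: float = 0.4
    er_log2fc: float = 2.0
    # contamination knobs
    doublet_rate: float = 0.0
    rbc_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "p_V1R_pair",
            "p_H2Mv_given_C2",
            "p_C1_vs_C2",
            "rbc_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.doublet_rate < 0.5:
            raise ValidationError("doublet_rate must be in [0, 0.5)")
        for name in ("C2_members_range", "H2Mv_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValidationError(f"{name} must be an ordered range")
        if self.C2_members_range[1] > self.n_C2:
            raise ValidationError("C2 range exceeds the C2 panel size")
        if self.H2Mv_range[1] > self.n_H2Mv:
            raise ValidationError("H2-Mv range exceeds the H2-Mv panel size")
        if self.on_mean <= self.ambient_mean:
            raise ValidationError("on_mean must exceed ambient_mean")


@dataclass
class GroundTruth:
    """Planted truth carrier: per-cell types and receptor sets, per-gene DE."""

    cells: pd.DataFrame
    receptor_sets: dict[str, dict[str, frozenset]]
    de_log2fc: pd.Series

    def true_patterns(
        self, scope: str | Sequence[str], min_cells: int = 2, exclude_doublets: bool = True
    ) -> dict[tuple[str, ...], int]:
        """Distinct planted combinations and their cell frequencies."""
        from collections import Counter

        counter: Counter = Counter()
        for bc, sets in self.receptor_sets.items():
            if exclude_doublets and bool(self.cells.loc[bc, "is_doublet"]):
                continue
            if isinstance(scope, str):
                combo = sets.get(scope, frozenset())
            else:
                combo = frozenset(
                    f"{fam}:{g}" for fam in scope for g in sets.get(fam, frozenset())
                )
            if combo:
                counter[tuple(sorted(combo))] += 1
        return {c: n for c, n in counter.items() if n >= min_cells}


def _gene_panel(config: SimConfig) -> tuple[list[str], pd.DataFrame]:
    """Build the gene list and its catalog table."""
    records = []

    def add(gene: str, cls: str, subfamily: str = "") -> None:
        records.append({"gene_id": gene, "class": cls, "subfamily": subfamily})

    for i in range(1, config.n_V1R + 1):
        add(f"Vmn1r{i}", "V1R", "A")
    for i in range(8, 8 + config.n_ABD):
        add(f"Vmn2r{i}", "V2R_ABDE", "A" if i < 40 else "B")
    add("Vmn2r1", "V2R_C1", "C1")
    for i in range(2, 2 + config.n_C2):
        add(f"Vmn2r{i}", "V2R_C2", "C2")
    for i in range(1, config.n_H2Mv + 1):
        add(f"H2-M10.{i}", "H2Mv", "")
    for g in MARKER_GENES:
        add(g, "marker", "")
    for g in MITO_GENES:
        add(g, "mito", "")
    add(HBB_GENE, "hemoglobin", "")
    er_names = list(ER_SEED_NAMES) + [
        f"Ergene{i}" for i in range(len(ER_SEED_NAMES) + 1, config.n_ER + 1)
    ]
    for g in er_names[: config.n_ER]:
        add(g, "ER", "")
    for i in range(1, config.n_background + 1):
        add(f"Bg{i:04d}", "other", "")

    df = pd.DataFrame(records).set_index("gene_id")
    if df.index.duplicated().any():
        raise ValidationError("gene panel sizes produce duplicate gene names")
    return list(df.index), df


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = m + dispersion * m^2 (Poisson if 0)."""
    if dispersion <= 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def _draw_receptor_sets(
    config: SimConfig,
    rng: np.random.Generator,
    cell_types: np.ndarray,
    catalog: GeneCatalog,
) -> list[dict[str, frozenset]]:
    v1r = catalog.genes_of_class("V1R")
    abd = catalog.genes_of_class("V2R_ABDE")
    c1 = catalog.genes_of_class("V2R_C1")
    c2 = catalog.genes_of_class("V2R_C2")
    h2 = catalog.genes_of_class("H2Mv")

    empty: dict[str, frozenset] = {
        k: frozenset() for k in ("V1R", "ABD", "C1", "C2", "H2Mv")
    }
    out = []
    for ct in cell_types:
        sets = dict(empty)
        if ct == "mature_Gnai2":
            u = rng.random()
            acc = 0.0
            chosen = None
            for pair, p in config.planted_v1r_pairs:
                acc += p
                if u < acc:
                    chosen = frozenset(pair)
                    break
            if chosen is None:
                if u < acc + config.p_V1R_pair:
                    chosen = frozenset(rng.choice(v1r, size=2, replace=False))
                else:
                    chosen = frozenset([str(rng.choice(v1r))])
            sets["V1R"] = chosen
        elif ct == "mature_Gnao1":
            u = rng.random()
            acc = 0.0
            chosen = None
            for combo, p in config.planted_abd_patterns:
                acc += p
                if u < acc:
                    chosen = frozenset(combo)
                    break
            if chosen is None:
                chosen = frozenset([str(rng.choice(abd))])
            sets["ABD"] = chosen
            if rng.random() < config.p_C1_vs_C2:
                sets["C1"] = frozenset(c1)
            else:
                k = rng.integers(config.C2_members_range[0], config.C2_members_range[1] + 1)
                sets["C2"] = frozenset(rng.choice(c2, size=k, replace=False))
                if rng.random() < config.p_H2Mv_given_C2:
                    m = rng.integers(config.H2Mv_range[0], config.H2Mv_range[1] + 1)
                    sets["H2Mv"] = frozenset(rng.choice(h2, size=m, replace=False))
        out.append(sets)
    return out


def generate_dataset(
    config: SimConfig | None = None, seed: int | None = None
) -> tuple[CountMatrix, GeneCatalog, pd.Series, GroundTruth]:
    """Generate (counts, catalog, labels, truth) under the planted model.

    *seed* overrides ``config.seed`` when given; the same (config, seed)
    always yields bit-identical output. Doublets are injected afterwards
    when ``config.doublet_rate > 0``.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    genes, catalog_df = _gene_panel(config)
    catalog = GeneCatalog(catalog_df)
    gene_pos = {g: i for i, g in enumerate(genes)}

    type_counts = [
        ("progenitor", config.n_progenitor),
        ("immature_Gnao1", config.n_immature_gnao1),
        ("immature_Gnai2", config.n_immature_gnai2),
        ("mature_Gnao1", config.n_mature_gnao1),
        ("mature_Gnai2", config.n_mature_gnai2),
        ("other", config.n_other),
    ]
    cell_types = np.concatenate(
        [np.full(n, ct, dtype=object) for ct, n in type_counts if n > 0]
    )
    n_cells = cell_types.size
    barcodes = [f"cell_{i:05d}" for i in range(n_cells)]

    planted = [
        g
        for combos in (config.planted_v1r_pairs, config.planted_abd_patterns)
        for combo, _ in combos
        for g in combo
    ]
    missing = [g for g in planted if g not in gene_pos]
    if missing:
        raise ValidationError(
            f"planted pattern gene(s) outside the configured panel: {missing}"
        )

    receptor_sets = _draw_receptor_sets(config, rng, cell_types, catalog)

    # --- mean matrix ------------------------------------------------------
    mean = np.zeros((n_cells, len(genes)))
    receptor_cols = [
        gene_pos[g]
        for g in catalog.genes_of_class(("V1R", "V2R_ABDE", "V2R_C1", "V2R_C2", "H2Mv"))
    ]
    mean[:, receptor_cols] = config.ambient_mean
    for i, sets in enumerate(receptor_sets):
        for fam_genes in sets.values():
            for g in fam_genes:
                mean[i, gene_pos[g]] = config.on_mean

    marker_on = {
        "Gnao1": ("mature_Gnao1", "immature_Gnao1"),
        "Gnai2": ("mature_Gnai2", "immature_Gnai2"),
        "Gap43": ("immature_Gnao1", "immature_Gnai2"),
        "Omp": ("mature_Gnao1", "mature_Gnai2"),
        "Ascl1": ("progenitor",),
        "Neurod1": ("progenitor",),
    }
    for g, active in marker_on.items():
        col = gene_pos[g]
        mean[:, col] = config.marker_ambient_mean
        mean[np.isin(cell_types, active), col] = config.marker_mean

    bg_cols = [gene_pos[g] for g in catalog.genes_of_class("other")]
    bg_means = rng.lognormal(np.log(config.background_mean), 1.0, size=len(bg_cols))
    mean[:, bg_cols] = bg_means[None, :]

    er_cols = [gene_pos[g] for g in catalog.genes_of_class("ER")]
    er_means = rng.lognormal(np.log(config.er_base_mean), 0.5, size=len(er_cols))
    mean[:, er_cols] = er_means[None, :]
    gnao1_rows = cell_types == "mature_Gnao1"
    mean[np.ix_(gnao1_rows, er_cols)] *= 2.0**config.er_log2fc

    mito_cols = [gene_pos[g] for g in MITO_GENES]
    mean[:, mito_cols] = 1.0

    if config.rbc_fraction > 0:
        n_rbc = int(np.floor(config.rbc_fraction * n_cells))
        rbc_rows = rng.choice(n_cells, size=n_rbc, replace=False)
        mean[rbc_rows, gene_pos[HBB_GENE]] = 30.0

    lib = rng.lognormal(config.library_size_logmean, config.library_size_logsd, n_cells)
    mean *= lib[:, None]

    counts_arr = _nb_sample(rng, mean, config.dispersion)
    counts = CountMatrix(barcodes, genes, sp.csr_matrix(counts_arr))

    labels = pd.Series(
        cell_types, index=pd.Index(barcodes, name="barcode"), name="label"
    )
    de = pd.Series(0.0, index=pd.Index(genes, name="gene"), name="true_log2fc")
    de.iloc[er_cols] = config.er_log2fc

    truth = GroundTruth(
        cells=pd.DataFrame(
            {
                "cell_type": cell_types,
                "is_doublet": False,
                "constituents": "",
            },
            index=pd.Index(barcodes, name="barcode"),
        ),
        receptor_sets=dict(zip(barcodes, receptor_sets)),
        de_log2fc=de,
    )

    if config.doublet_rate > 0:
        counts, labels, truth = inject_doublets(
            counts,
            labels,
            config.doublet_rate,
            seed=int(rng.integers(2**31 - 1)),
            truth=truth,
        )
    return counts, catalog, labels, truth


def inject_doublets(
    counts: CountMatrix,
    labels: pd.Series,
    rate: float,
    seed: int = 0,
    truth: GroundTruth | None = None,
) -> tuple[CountMatrix, pd.Series, GroundTruth | None]:
    """Replace floor(rate * n) cells with synthetic doublets.

    Each doublet sums the counts of two distinct cells; the first
    constituent's barcode is replaced by ``doublet_<i>`` and both
    constituents are recorded in the truth table. The doublet's planted
    receptor set is the union of its constituents'.
    """
    if not 0.0 <= rate < 0.5:
        raise ValidationError("doublet rate must be in [0, 0.5)")
    if counts.n_cells == 0:
        raise ValidationError("cannot inject doublets into an empty matrix")
    rng = np.random.default_rng(seed)
    n = counts.n_cells
    m = int(np.floor(rate * n))
    if m == 0:
        return counts, labels, truth

    picked = rng.choice(n, size=2 * m, replace=False)
    targets, partners = picked[:m], picked[m:]
    dense = counts.counts.toarray()
    dense[targets] += dense[partners]
    barcodes = list(counts.barcodes)
    rename: dict[str, str] = {}
    if truth is not None:
        truth = GroundTruth(
            truth.cells.copy(), dict(truth.receptor_sets), truth.de_log2fc
        )

    for i, (t, p) in enumerate(zip(targets, partners)):
        b_t, b_p = counts.barcodes[t], counts.barcodes[p]
        new_bc = f"doublet_{i:04d}"
        barcodes[t] = new_bc
        rename[b_t] = new_bc
        if truth is not None:
            truth.cells.loc[b_t, ["is_doublet", "constituents"]] = [True, f"{b_t}+{b_p}"]
            merged = {
                fam: truth.receptor_sets[b_t][fam] | truth.receptor_sets[b_p][fam]
                for fam in truth.receptor_sets[b_t]
            }
            del truth.receptor_sets[b_t]
            truth.receptor_sets[new_bc] = merged

    labels = labels.rename(index=rename)
    if truth is not None:
        truth.cells = truth.cells.rename(index=rename)
    out = CountMatrix(barcodes, list(counts.genes), sp.csr_matrix(dense))
    return out, labels, truth


def generate_de_dataset(
    n_null: int = 1000,
    n_planted: int = 50,
    log2fc: float = 2.0,
    cells_per_group: int = 200,
    base_mean: float = 4.0,
    dispersion: float = 0.15,
    library_size_logsd: float = 0.2,
    seed: int = 0,
) -> tuple[CountMatrix, pd.Series, list[str]]:
    """Two-group count matrix with planted up-regulated genes.

    Null genes share one negative-binomial mean in both groups; planted
    genes are upregulated in group A by 2**log2fc. Returns (counts,
    group labels, planted gene names).
    """
    rng = np.random.default_rng(seed)
    genes = [f"null_{i:04d}" for i in range(n_null)] + [
        f"planted_{i:03d}" for i in range(n_planted)
    ]
    n_cells = 2 * cells_per_group
    groups = pd.Series(
        ["A"] * cells_per_group + ["B"] * cells_per_group,
        index=pd.Index([f"cell_{i:05d}" for i in range(n_cells)], name="barcode"),
        name="group",
    )
    gene_means = rng.lognormal(np.log(base_mean), 0.5, size=len(genes))
    mean = np.tile(gene_means, (n_cells, 1))
    mean[:cells_per_group, n_null:] *= 2.0**log2fc
    lib = rng.lognormal(0.0, library_size_logsd, n_cells)
    mean *= lib[:, None]
    counts = _nb_sample(rng, mean, dispersion)
    matrix = CountMatrix(list(groups.index), genes, sp.csr_matrix(counts))
    return matrix, groups, genes[n_null:]


def generate_axis_profiles(
    n_sections: int = 24,
    n_points: int = 60,
    noise_sd: float = 0.05,
    trends: dict[str, str] | None = None,
    seed: int = 0,
) -> list[AxisProfile]:
    """Intensity profiles with planted per-channel trends.

    *trends* maps channel name to one of ``sigmoid`` (apical-to-basal
    increase, the ER / Gnao1 pattern), ``flat`` (the Omp pan-neuronal
    pattern), or ``linear``. Raw intensities get a per-section random
    affine distortion (gain and offset) so that min-max normalization is
    actually exercised; Gaussian noise of sd *noise_sd* is added on the
    normalized scale before distortion.
    """
    trends = trends or {"ER": "sigmoid", "Gnao1": "sigmoid", "Omp": "flat"}
    rng = np.random.default_rng(seed)
    profiles = []
    for s in range(n_sections):
        pos = np.linspace(0.0, 1.0, n_points) * rng.uniform(80, 120)
        x01 = (pos - pos.min()) / (pos.max() - pos.min())
        channels = {}
        for name, kind in trends.items():
            if kind == "sigmoid":
                base = 1.0 / (1.0 + np.exp(-10.0 * (x01 - 0.5)))
            elif kind == "flat":
                base = np.full_like(x01, 0.6)
            elif kind == "linear":
                base = x01.copy()
            else:
                raise ValidationError(f"unknown trend kind {kind!r}")
            signal = base + (rng.normal(0.0, noise_sd, n_points) if noise_sd > 0 else 0.0)
            gain = rng.uniform(500, 2000)
            offset = rng.uniform(10, 100)
            channels[name] = offset + gain * signal
        profiles.append(AxisProfile(f"section_{s:03d}", pos, channels))
    return profiles
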