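"""Data-driven receptor-expression thresholds from bimodal value distributions.

Pooled normalized expression of a receptor family across cells is
bimodal: a low peak of ambient (cell-free contaminating) transcripts and
a higher peak of true expression. The calling cutoff is the start of the
second peak, operationalized here as the density minimum (valley)
between the two main modes.

Mode detection uses a Gaussian kernel density estimate with Silverman's
bandwidth. The valley itself is located on the density of a two-component
Gaussian mixture fitted to the pooled values rather than on the KDE: a
global Silverman bandwidth substantially oversmooths mixtures whose
ambient component is much narrower than the expression component, which
drags the KDE valley toward the wide component; the parametric mixture
does not share that bias. If fewer than two sufficiently separated modes
are found, the configured default threshold is returned with
``fallback_used`` set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import gaussian_kde, norm
from sklearn.mixture import GaussianMixture

from vrcall.errors import ValidationError
from vrcall.io_catalog import GeneCatalog, NormMatrix

#: Fixed thresholds on normalized expression used when thresholds are
#: pinned or when automatic detection falls back.
DEFAULT_THRESHOLDS: Mapping[str, float] = {"V1R": 2.5, "V2R": 1.25, "H2Mv": 1.25}


@dataclass
class ThresholdResult:
    """A per-family threshold with its derivation record."""

    threshold: float
    kde_bandwidth: float
    n_values: int
    modes_found: int
    fallback_used: bool
    mode_locations: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValidationError("threshold must be positive")


def pool_family_values(
    norm: NormMatrix,
    catalog: GeneCatalog,
    family: str,
    cells: Sequence[str] | None = None,
) -> np.ndarray:
    """Pool nonzero normalized values of all *family* genes over *cells*.

    One value per (cell, gene) pair with expression > 0. Exact zeros are
    excluded: the zero point mass carries no information about where the
    second peak starts and would dominate any density estimate.
    """
    genes = [g for g in catalog.genes_of_family(family) if g in norm.genes]
    if not genes:
        raise ValidationError(f"no {family} genes present in the matrix")
    rows = (
        norm.cell_indices(cells) if cells is not None else np.arange(norm.n_cells)
    )
    if rows.size == 0:
        raise ValidationError("cell subset is empty")
    sub = norm.values[np.ix_(rows, norm.gene_indices(genes))]
    return sub[sub > 0].ravel()


def _kde_modes(
    values: np.ndarray, grid_size: int
) -> tuple[np.ndarray, np.ndarray, float]:
    kde = gaussian_kde(values, bw_method="silverman")
    grid = np.linspace(values.min(), values.max(), grid_size)
    density = kde(grid)
    bandwidth = float(np.sqrt(kde.covariance[0, 0]))
    interior = (density[1:-1] > density[:-2]) & (density[1:-1] >= density[2:])
    peaks = np.flatnonzero(interior) + 1
    # boundary grid points can carry a mode truncated by the data range
    if density[0] > density[1]:
        peaks = np.concatenate([[0], peaks])
    if density[-1] > density[-2]:
        peaks = np.concatenate([peaks, [grid_size - 1]])
    return grid, density, bandwidth, peaks  # type: ignore[return-value]


def detect_threshold(
    values: Iterable[float],
    default: float,
    min_separation: float = 0.2,
    grid_size: int = 512,
    random_state: int = 0,
) -> ThresholdResult:
    """Locate the valley between the two main modes of *values*.

    Returns the configured *default* with ``fallback_used=True`` (and a
    warning) when no two modes separated by at least *min_separation*
    are found.
    """
    values = np.asarray(list(values) if not isinstance(values, np.ndarray) else values)
    if values.size == 0:
        raise ValidationError("cannot detect a threshold from an empty value list")
    if values.size < 3 or np.ptp(values) == 0:
        warnings.warn("too few distinct values; using default threshold", stacklevel=2)
        return ThresholdResult(default, 0.0, values.size, 0, True)

    grid, density, bandwidth, peaks = _kde_modes(values, grid_size)

    # two highest-density modes separated by >= min_separation; the second
    # mode must carry real mass (not a tail/boundary ripple) and the density
    # must dip between the two (a genuine valley)
    order = peaks[np.argsort(density[peaks])[::-1]]
    lo = hi = None
    if order.size:
        first = order[0]
        for cand in order[1:]:
            if abs(grid[cand] - grid[first]) < min_separation:
                continue
            if density[cand] < 0.05 * density[first]:
                continue
            a, b = sorted((first, cand))
            if density[a : b + 1].min() < 0.9 * min(density[a], density[b]):
                lo, hi = a, b
                break
    if lo is None:
        warnings.warn(
            "no bimodal structure detected; using default threshold", stacklevel=2
        )
        return ThresholdResult(default, bandwidth, values.size, min(peaks.size, 1), True)

    mode_lo, mode_hi = float(grid[lo]), float(grid[hi])

    # valley of a 2-component Gaussian mixture fitted to the values,
    # restricted to the open interval between the detected modes
    gmm = GaussianMixture(n_components=2, random_state=random_state, n_init=2)
    gmm.fit(values.reshape(-1, 1))
    means = gmm.means_.ravel()
    sds = np.sqrt(gmm.covariances_.ravel())
    weights = gmm.weights_
    fine = np.linspace(mode_lo, mode_hi, 4 * grid_size)[1:-1]
    mix_density = np.zeros_like(fine)
    for w, m, s in zip(weights, means, sds):
        mix_density += w * norm.pdf(fine, m, s)
    threshold = float(fine[np.argmin(mix_density)])

    # guard against a degenerate mixture fit (both components on one mode):
    # then fall back to the KDE valley between the modes
    if not (mode_lo < threshold < mode_hi) or min(weights) < 1e-3:
        valley = lo + int(np.argmin(density[lo : hi + 1]))
        threshold = float(grid[valley])

    return ThresholdResult(
        threshold,
        bandwidth,
        values.size,
        int(peaks.size),
        False,
        (mode_lo, mode_hi),
    )


def detect_family_thresholds(
    norm: NormMatrix,
    catalog: GeneCatalog,
    cells: Sequence[str] | None = None,
    families: Sequence[str] = ("V1R", "V2R", "H2Mv"),
    defaults: Mapping[str, float] | None = None,
    mode: str = "auto",
    min_separation: float = 0.2,
) -> dict[str, ThresholdResult]:
    """Derive (or pin) one threshold per receptor family.

    ``mode='auto'`` detects the valley from the pooled distribution;
    ``mode='fixed'`` pins every family to its default. Families with no
    genes in the matrix are silently skipped.
    """
    defaults = dict(DEFAULT_THRESHOLDS) | dict(defaults or {})
    out: dict[str, ThresholdResult] = {}
    for family in families:
        genes = [g for g in catalog.genes_of_family(family) if g in norm.genes]
        if not genes:
            continue
        if mode == "fixed":
            out[family] = ThresholdResult(defaults[family], 0.0, 0, 0, True)
            continue
        values = pool_family_values(norm, catalog, family, cells)
        if values.size == 0:
            out[family] = ThresholdResult(defaults[family], 0.0, 0, 0, True)
            continue
        out[family] = detect_threshold(
            values, defaults[family], min_separation=min_separation
        )
    return out
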