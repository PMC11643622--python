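"""Apical-basal immunofluorescence intensity profiles.

Rectangular regions of interest are drawn along the apical-basal axis of
the neuroepithelium and the per-channel signal intensity is exported as a
(position, intensity) table per section. To compare sections and
antibodies, both the position axis and every channel are min-max
normalized per ROI:

    x' = (x - min(x)) / (max(x) - min(x))

with position 0 = apical and 1 = basal. Trendlines over pooled sections
are fitted with a locally weighted linear smoother (tricube weights,
tunable span) evaluated on a common grid, and co-trending of two channels
is summarized by the Spearman rank correlation of their fitted curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from statsmodels.nonparametric.smoothers_lowess import lowess

from vrcall.errors import FormatError, ValidationError


@dataclass
class AxisProfile:
    """Ordered samples along one ROI axis with per-channel intensities."""

    section_id: str
    positions: np.ndarray
    channels: dict[str, np.ndarray] = field(default_factory=dict)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if np.any(np.diff(self.positions) <= 0):
            raise ValidationError(
                f"profile {self.section_id!r}: positions must be strictly increasing"
            )
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        for name, vals in self.channels.items():
            if vals.shape != self.positions.shape:
                raise FormatError(
                    f"channel {name!r} length does not match positions"
                )

    @property
    def n_samples(self) -> int:
        return self.positions.size


def normalize_profile(profile: AxisProfile) -> AxisProfile:
    """Min-max normalize the position axis and every channel to [0, 1].

    A constant channel has no range; it maps to all zeros with a warning.
    Idempotent: a profile already in [0, 1] end-to-end is unchanged.
    """
    if profile.n_samples < 2:
        raise ValidationError("need at least 2 samples to normalize a profile")

    def minmax(x: np.ndarray, what: str) -> np.ndarray:
        rng = x.max() - x.min()
        if rng == 0:
            warnings.warn(
                f"profile {profile.section_id!r}: constant {what}; set to zeros",
                stacklevel=3,
            )
            return np.zeros_like(x)
        return (x - x.min()) / rng

    if all(np.ptp(v) == 0 for v in profile.channels.values()):
        raise ValidationError("all channels are constant; nothing to normalize")

    return replace(
        profile,
        positions=minmax(profile.positions, "position axis"),
        channels={k: minmax(v, f"channel {k!r}") for k, v in profile.channels.items()},
        normalized=True,
    )


def fit_trendline(
    profiles: Sequence[AxisProfile],
    channel: str,
    span: float = 0.5,
    grid_size: int = 101,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit a smooth trend of *channel* vs position over pooled profiles.

    Points from all profiles are pooled before fitting a locally weighted
    linear regression (tricube weights, fraction *span* of points per
    local fit) evaluated on a uniform grid over [0, 1]. Requires at least
    10 pooled points. Returns (grid, fitted values).
    """
    xs, ys = [], []
    for p in profiles:
        if channel not in p.channels:
            raise ValidationError(f"profile {p.section_id!r} lacks channel {channel!r}")
        xs.append(p.positions)
        ys.append(p.channels[channel])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if x.size < 10:
        raise ValidationError(f"need >= 10 pooled points, got {x.size}")
    grid = np.linspace(0.0, 1.0, grid_size)
    fitted = lowess(y, x, frac=span, it=0, xvals=grid)
    return grid, np.asarray(fitted)


def channel_cotrend(
    profiles: Sequence[AxisProfile],
    channel_a: str,
    channel_b: str,
    span: float = 0.5,
    grid_size: int = 101,
) -> float:
    """Spearman rank correlation between the fitted trends of two channels."""
    _, fa = fit_trendline(profiles, channel_a, span=span, grid_size=grid_size)
    _, fb = fit_trendline(profiles, channel_b, span=span, grid_size=grid_size)
    rho = spearmanr(fa, fb).statistic
    return float(rho)


def load_profiles(path: str | Path) -> list[AxisProfile]:
    """Read profiles from a long TSV: section_id, position, channel, intensity."""
    df = pd.read_csv(path, sep="\t")
    required = {"section_id", "position", "channel", "intensity"}
    if not required.issubset(df.columns):
        raise FormatError(f"profile TSV needs columns {sorted(required)}")
    profiles = []
    for sid, block in df.groupby("section_id", sort=False):
        wide = block.pivot_table(
            index="position", columns="channel", values="intensity", sort=True
        )
        profiles.append(
            AxisProfile(
                str(sid),
                wide.index.to_numpy(),
                {str(c): wide[c].to_numpy() for c in wide.columns},
            )
        )
    return profiles


def write_profiles(profiles: Sequence[AxisProfile], path: str | Path) -> None:
    """Write profiles to the long TSV layout accepted by :func:`load_profiles`."""
    rows = []
    for p in profiles:
        for ch, vals in p.channels.items():
            for pos, v in zip(p.positions, vals):
                rows.append(
                    {
                        "section_id": p.section_id,
                        "position": pos,
                        "channel": ch,
                        "intensity": v,
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
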