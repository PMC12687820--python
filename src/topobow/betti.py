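"""Betti-curve vectorization of persistence diagrams.

A Betti curve samples, at a fixed ladder of intensity thresholds, how many
topological features of one homology dimension are alive: point (b, d) of
the diagram is counted at threshold t when ``b <= t < d`` (half-open, so
a feature is not alive at its own death).  Thresholds are the 100 left
bin edges of the fixed global range [0, 255] — fixed, not per-image, so
curves are comparable across images, which the downstream classifier
requires.  Essential classes (death = inf) count at every t >= birth.

The per-image feature block concatenates the beta_0 and beta_1 curves of
the gray, red, green and blue channel filtrations, in that order, giving
200 values per channel and 800 in total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cubical import PersistenceDiagram, sublevel_diagrams
from .preprocess import CHANNELS, ImageRecord

N_BINS = 100
INTENSITY_RANGE = (0.0, 255.0)
TDA_DIM = 2 * N_BINS * len(CHANNELS)  # 800


def threshold_grid(n_bins: int = N_BINS,
                   intensity_range: tuple[float, float] = INTENSITY_RANGE) -> np.ndarray:
    """Left bin edges: ``n_bins`` evenly spaced thresholds over the range."""
    lo, hi = intensity_range
    if lo >= hi:
        raise ValueError(f"invalid intensity range {intensity_range}")
    return lo + (hi - lo) * np.arange(n_bins) / n_bins


@dataclass(frozen=True)
class BettiCurve:
    """Sampled Betti curve for one (channel, homology-dimension) pair."""

    values: np.ndarray  # length n_bins, nonnegative integers
    dim: int
    channel: str
    thresholds: np.ndarray


def betti_curve(diagram: PersistenceDiagram, dim: int, n_bins: int = N_BINS,
                intensity_range: tuple[float, float] = INTENSITY_RANGE,
                channel: str = "") -> BettiCurve:
    """Count features of ``dim`` alive at each threshold of the fixed grid."""
    ts = threshold_grid(n_bins, intensity_range)
    pts = diagram.in_dim(dim)
    if len(pts) == 0:
        counts = np.zeros(n_bins, dtype=np.int64)
    else:
        births = pts[:, 0][None, :]
        deaths = pts[:, 1][None, :]
        alive = (births <= ts[:, None]) & (ts[:, None] < deaths)
        counts = alive.sum(axis=1).astype(np.int64)
    return BettiCurve(values=counts, dim=dim, channel=channel, thresholds=ts)


@dataclass(frozen=True)
class TdaFeatureBlock:
    """The 800-dim topological block: [gray b0, gray b1, red b0, ..., blue b1].

    Each of the eight sub-blocks is one length-100 Betti curve; block
    boundaries sit at multiples of 100.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (TDA_DIM,):
            raise ValueError(f"TDA block must have length {TDA_DIM}, got {v.shape}")
        object.__setattr__(self, "values", v)

    def sub_block(self, channel: str, dim: int) -> np.ndarray:
        k = CHANNELS.index(channel) * 2 + dim
        return self.values[k * N_BINS:(k + 1) * N_BINS]


def feature_names() -> list[str]:
    """Column names ``tda_<channel>_b<dim>_<bin>`` in block order."""
    return [
        f"tda_{ch}_b{dim}_{i}"
        for ch in CHANNELS
        for dim in (0, 1)
        for i in range(N_BINS)
    ]


def tda_features(record: ImageRecord) -> TdaFeatureBlock:
    """Compute the fused multi-channel Betti-curve block for one image."""
    parts = []
    for ch in CHANNELS:
        diagram = sublevel_diagrams(record.channels[ch])
        for dim in (0, 1):
            parts.append(betti_curve(diagram, dim, channel=ch).values)
    return TdaFeatureBlock(values=np.concatenate(parts).astype(float))
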