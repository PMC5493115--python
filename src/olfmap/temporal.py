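"""Time-resolved population analyses of odor representations.

A population tensor holds trial-averaged firing rates per (time bin, neuron
class, odor). Odor representations are followed through time as
trajectories in a shared PC space (basis fitted once on the pooled
time × odor observations), as the mean pairwise Euclidean distance between
odor representations per time bin (whose peak marks maximal odor
separation, ~150 ms after onset for transient responses), and as full
odor × odor distance matrices evaluated at chosen time frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import odor_space


@dataclass
class PopulationTensor:
    """Rates (time × class × odor, spikes/s) on a uniform time axis.

    ``t0`` is the time of the first bin's left edge relative to stimulus
    onset (onset = 0).
    """

    rates: np.ndarray
    bin_width: float
    t0: float
    class_ids: list
    odor_ids: list

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.ndim != 3:
            raise ValueError("rates must be time × class × odor")
        if not np.all(np.isfinite(self.rates)):
            raise ValueError("rates must be finite")
        t, c, o = self.rates.shape
        if c != len(self.class_ids) or o != len(self.odor_ids):
            raise ValueError("axis lengths must match class/odor id lists")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")

    @property
    def n_bins(self) -> int:
        return self.rates.shape[0]

    @property
    def bin_starts(self) -> np.ndarray:
        return self.t0 + self.bin_width * np.arange(self.n_bins)

    @property
    def bin_centers(self) -> np.ndarray:
        return self.bin_starts + self.bin_width / 2.0

    def bin_of(self, t: float) -> int:
        """Index of the bin containing time ``t`` (half-open bins)."""
        idx = int(np.floor((t - self.t0) / self.bin_width + 1e-12))
        if not 0 <= idx < self.n_bins:
            raise ValueError(f"time {t} outside the tensor span")
        return idx

    def window_mean_matrix(self, window: tuple[float, float]) -> pd.DataFrame:
        """Class × odor mean rate over the bins whose centers fall in window."""
        centers = self.bin_centers
        mask = (centers >= window[0]) & (centers < window[1])
        if not mask.any():
            raise ValueError("window contains no bin centers")
        mean = self.rates[mask].mean(axis=0)
        return pd.DataFrame(mean, index=self.class_ids, columns=self.odor_ids)


def trajectories(tensor: PopulationTensor, n_components: int = 3):
    """Per-odor paths of the population vector in a shared PC space.

    The PCA basis is fitted once on the pooled (time × odor) × class
    observations (mean-centered, unscaled), then each odor's sequence of
    time bins is projected into it. Returns ``(paths, PCAResult)`` with
    ``paths[odor]`` an (n_bins × n_components) array.
    """
    t, c, o = tensor.rates.shape
    if n_components > c:
        raise ValueError("cannot extract more components than neuron classes")
    pooled = tensor.rates.transpose(0, 2, 1).reshape(t * o, c)  # (time·odor) × class
    frame = pd.DataFrame(pooled, columns=tensor.class_ids)
    result = odor_space.pca(frame, items="rows")
    scores = result.scores.to_numpy()[:, :n_components]
    paths = {odor: scores[np.arange(t) * o + j]
             for j, odor in enumerate(tensor.odor_ids)}
    return paths, result


def inter_odor_distance_timecourse(tensor: PopulationTensor):
    """Mean pairwise Euclidean distance between odor representations per bin.

    Returns ``(distances, peak_time)`` where ``distances`` is indexed by bin
    center and the peak is the earliest bin center achieving the maximum.
    Homogeneous of degree 1 in the rates.
    """
    t, c, o = tensor.rates.shape
    if o < 2:
        raise ValueError("need at least two odors")
    x = tensor.rates  # (t, c, o)
    diff = x[:, :, :, None] - x[:, :, None, :]
    dist = np.sqrt((diff**2).sum(axis=1))  # (t, o, o)
    iu = np.triu_indices(o, k=1)
    mean_d = dist[:, iu[0], iu[1]].mean(axis=1)
    series = pd.Series(mean_d, index=tensor.bin_centers, name="mean_pairwise_distance")
    peak_time = float(series.index[int(np.argmax(series.to_numpy()))])
    return series, peak_time


def time_resolved_distance_matrices(tensor: PopulationTensor, times,
                                    metric: str = "cosine"):
    """One odor × odor distance matrix per requested time.

    Each time is mapped to its containing bin; the bin's class × odor rate
    slice is handed to :func:`olfmap.odor_space.odor_distance_matrix`.
    Out-of-span times raise.
    """
    out = []
    for t in times:
        sl = tensor.rates[tensor.bin_of(t)]
        frame = pd.DataFrame(sl, index=tensor.class_ids, columns=tensor.odor_ids)
        out.append(odor_space.odor_distance_matrix(frame, metric=metric))
    return out
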