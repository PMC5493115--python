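"""Tuning curves, lifetime sparseness, and the OSN → PN transformation.

Lifetime sparseness quantifies how selective a neuron class is across a
fixed odor panel:

    S = (1 / (1 − 1/N)) · (1 − (Σ r_j / N)² / (Σ r_j² / N))

with N the panel size and r_j the (rectified) response to odor j. S = 0 for
a perfectly uniform profile and S = 1 for a single-odor responder. Negative
control-subtracted responses are set to zero before the formula is applied.

The transformation of odor coding from sensory neurons (OSNs) to projection
neurons (PNs) of the same glomerulus is summarized two ways: per-glomerulus
Pearson correlation between the OSN and PN odor-response vectors (with a
pairing-shuffle control), and paired sparseness values showing how tuning
breadth changes across the synapse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class TuningCurve:
    """Center-out ordered responses of one class with its sparseness."""

    class_id: str
    ordered_odor_ids: list
    ordered_responses: np.ndarray
    sparseness: float | None

    def __post_init__(self) -> None:
        self.ordered_responses = np.asarray(self.ordered_responses, dtype=float)
        if self.sparseness is not None and not (0 <= self.sparseness <= 1):
            raise ValueError("sparseness must lie in [0, 1]")


def lifetime_sparseness(responses, n_odors: int | None = None) -> float:
    """Lifetime sparseness S ∈ [0, 1] of a response vector.

    Negative values are rectified to zero first. An all-zero rectified
    vector leaves S undefined (0/0) and raises ``ValueError`` rather than
    returning an arbitrary number. Scale-invariant: S(c·r) = S(r), c > 0.
    """
    r = np.clip(np.asarray(responses, dtype=float), 0.0, None)
    n = len(r) if n_odors is None else n_odors
    if n < 2 or len(r) != n:
        raise ValueError("need a response vector of length n_odors ≥ 2")
    sum_sq = float(np.sum(r**2))
    if sum_sq == 0.0:
        raise ValueError("sparseness undefined: all rectified responses are zero")
    mean_sq = (float(np.sum(r)) / n) ** 2
    s = (1.0 / (1.0 - 1.0 / n)) * (1.0 - mean_sq / (sum_sq / n))
    return float(min(max(s, 0.0), 1.0))  # clip fp noise at the exact limits


def order_tuning_curve(responses: pd.Series, class_id: str = "",
                       *, compute_sparseness: bool = True) -> TuningCurve:
    """Center-out ordering of a tuning curve.

    Responses are ranked descending (ties broken by odor id) and interleaved
    so the strongest sits at the center, the second-strongest immediately to
    its right, the third to its left, and so on outward; the weakest
    responses end up at the edges. The output is a permutation of the input.
    """
    items = sorted(responses.items(), key=lambda kv: (-kv[1], str(kv[0])))
    n = len(items)
    center = n // 2
    positions = [center]
    right, left = center + 1, center - 1
    for rank in range(1, n):
        # odd ranks go right, even ranks left, spilling over when one side fills
        if (rank % 2 == 1 and right < n) or left < 0:
            positions.append(right)
            right += 1
        else:
            positions.append(left)
            left -= 1
    ordered = [None] * n
    for rank, (odor, val) in enumerate(items):
        ordered[positions[rank]] = (odor, val)
    odor_ids = [o for o, _ in ordered]
    vals = np.array([v for _, v in ordered], dtype=float)
    s = None
    if compute_sparseness:
        try:
            s = lifetime_sparseness(vals)
        except ValueError:
            s = None
    return TuningCurve(class_id=class_id, ordered_odor_ids=odor_ids,
                       ordered_responses=vals, sparseness=s)


def _glomerulus_rows(matrix) -> pd.DataFrame:
    """Response frame re-indexed by glomerulus (one class per glomerulus)."""
    frame = matrix.frame.copy()
    frame.index = pd.Index(matrix.row_meta["glomerulus"], name="glomerulus")
    if frame.index.has_duplicates:
        raise ValueError("expected one class per glomerulus")
    return frame


def osn_pn_correlation(pn, osn) -> tuple[pd.DataFrame, dict]:
    """Per-glomerulus Pearson r between OSN and PN odor-response vectors.

    Matrices must share their odor columns; glomeruli present in only one
    matrix are skipped and listed in the summary. p-values are two-sided,
    from the t distribution with n_odors − 2 df. The summary holds the mean
    and sd of r over the shared glomeruli. Symmetric in its arguments.
    """
    pn_f, osn_f = _glomerulus_rows(pn), _glomerulus_rows(osn)
    if list(pn_f.columns) != list(osn_f.columns):
        raise ValueError("matrices must have identical odor columns")
    shared = [g for g in pn_f.index if g in set(osn_f.index)]
    skipped = sorted(set(pn_f.index).symmetric_difference(osn_f.index))
    if skipped:
        logger.info("glomeruli present in only one matrix, skipped: %s", skipped)
    rows = []
    for g in shared:
        r, p = stats.pearsonr(pn_f.loc[g].to_numpy(), osn_f.loc[g].to_numpy())
        rows.append({"glomerulus": g, "r": float(r), "p": float(p)})
    table = pd.DataFrame(rows).set_index("glomerulus")
    summary = {"mean_r": float(table["r"].mean()), "sd_r": float(table["r"].std(ddof=1)),
               "n": len(table), "skipped": skipped}
    return table, summary


def shuffled_correlation_control(pn, osn, n_runs: int = 100,
                                 seed: int | None = 0):
    """Glomerulus-pairing shuffle control for :func:`osn_pn_correlation`.

    Per run the pairing between PN and OSN glomeruli is permuted uniformly
    (fixed points allowed: with ~29 glomeruli a random permutation keeps on
    average one true pairing, a negligible bias) and the mean r over
    glomeruli recomputed. Returns ``(mean, sd, per_run_means)`` across runs.
    """
    if n_runs < 2:
        raise ValueError("need at least two shuffle runs")
    pn_f, osn_f = _glomerulus_rows(pn), _glomerulus_rows(osn)
    shared = [g for g in pn_f.index if g in set(osn_f.index)]
    x = pn_f.loc[shared].to_numpy(dtype=float)
    y = osn_f.loc[shared, pn_f.columns].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    n = len(shared)

    def _rowwise_r(a, b):
        a = a - a.mean(axis=1, keepdims=True)
        b = b - b.mean(axis=1, keepdims=True)
        denom = np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, (a * b).sum(axis=1) / denom, np.nan)

    means = []
    for _ in range(n_runs):
        perm = rng.permutation(n)
        means.append(float(np.nanmean(_rowwise_r(x, y[perm]))))
    means = np.asarray(means)
    return float(means.mean()), float(means.std(ddof=1)), means


def sparseness_comparison(pn, osn) -> tuple[pd.DataFrame, list]:
    """Paired lifetime sparseness (S_osn, S_pn) per shared glomerulus.

    Glomeruli whose rectified response vector is all-zero in either matrix
    have undefined sparseness; they are excluded and returned in the second
    element (mirroring the exclusion of silent classes from the paired
    comparison). No direction of change is assumed — the transformation is
    glomerulus-dependent.
    """
    pn_f, osn_f = _glomerulus_rows(pn), _glomerulus_rows(osn)
    shared = [g for g in pn_f.index if g in set(osn_f.index)]
    rows, excluded = [], []
    for g in shared:
        try:
            s_pn = lifetime_sparseness(pn_f.loc[g].to_numpy())
            s_osn = lifetime_sparseness(osn_f.loc[g, pn_f.columns].to_numpy())
        except ValueError:
            excluded.append(g)
            continue
        rows.append({"glomerulus": g, "S_osn": s_osn, "S_pn": s_pn})
    if excluded:
        logger.info("glomeruli with undefined sparseness excluded: %s", excluded)
    return pd.DataFrame(rows).set_index("glomerulus") if rows else pd.DataFrame(), excluded
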