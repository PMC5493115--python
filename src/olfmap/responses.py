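"""From spike trains to odor response intensities.

The response of a neuron to an odor is the number of spikes in a 1-s
counting window that starts 50 ms after stimulus onset (the odor's travel
delay to the antenna), minus the spike count for the solvent-matched control
stimulus in the same window. Responses of neurons recorded from the same
glomerulus (sister neurons / one neuron class) are averaged — by default
using each neuron's first stimulus round — into a class × odor response
matrix, the central object of every downstream analysis. Negative
control-subtracted values are kept; rectification happens only where a
specific statistic requires it (lifetime sparseness, functional maps,
Bray–Curtis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Default counting window, seconds relative to stimulus onset (half-open).
DEFAULT_WINDOW = (0.05, 1.05)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class SpikeTrainSet:
    """Spike times per (neuron, stimulus, trial) with the counting window.

    ``records`` columns: neuron_id, class_id, glomerulus, odor_id, trial
    (1-based), spikes (sorted float array, seconds relative to onset).
    Control stimuli appear as ordinary records whose odor_id is a control
    id; ``control_odor_map`` maps each real odor to its solvent-matched
    control id.
    """

    records: pd.DataFrame
    window: tuple[float, float] = DEFAULT_WINDOW
    span: tuple[float, float] = (-1.0, 3.0)
    control_odor_map: dict = field(default_factory=dict)

    REQUIRED = ("neuron_id", "class_id", "glomerulus", "odor_id", "trial", "spikes")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"records missing columns: {missing}")
        if self.window[0] >= self.window[1]:
            raise ValueError("window must be well-ordered")

    @property
    def odor_ids(self) -> list:
        """Stimulus ids that are odors (controls excluded)."""
        controls = set(self.control_odor_map.values())
        return [o for o in pd.unique(self.records["odor_id"]) if o not in controls]

    @property
    def class_ids(self) -> list:
        return list(pd.unique(self.records["class_id"]))

    def to_csv(self, path) -> None:
        """Long format: one row per spike (plus sentinel rows for empty trains)."""
        rows = []
        for rec in self.records.itertuples(index=False):
            times = np.asarray(rec.spikes, dtype=float)
            if len(times) == 0:
                rows.append((rec.neuron_id, rec.class_id, rec.glomerulus,
                             rec.odor_id, rec.trial, np.nan))
            for t in times:
                rows.append((rec.neuron_id, rec.class_id, rec.glomerulus,
                             rec.odor_id, rec.trial, t))
        pd.DataFrame(rows, columns=["neuron_id", "class_id", "glomerulus",
                                    "odor_id", "trial", "t_spike_s"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, *, window=DEFAULT_WINDOW, span=(-1.0, 3.0),
                 control_odor_map=None) -> "SpikeTrainSet":
        long = pd.read_csv(path)
        keys = ["neuron_id", "class_id", "glomerulus", "odor_id", "trial"]
        recs = []
        for key_vals, grp in long.groupby(keys, sort=False):
            times = np.sort(grp["t_spike_s"].dropna().to_numpy(dtype=float))
            recs.append(dict(zip(keys, key_vals)) | {"spikes": times})
        return cls(records=pd.DataFrame(recs), window=window, span=span,
                   control_odor_map=control_odor_map or {})


@dataclass
class ResponseMatrix:
    """Class × odor mean response intensities (spikes per 1-s window).

    ``frame`` is indexed by class id with odor-id columns; ``row_meta``
    (same index) carries the glomerulus and the neuron type ("PN" or "OSN").
    Values are control-subtracted and may be negative.
    """

    frame: pd.DataFrame
    row_meta: pd.DataFrame
    panel: object | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.frame.to_numpy(dtype=float))):
            raise ValueError("response matrix must be finite")
        if self.frame.index.has_duplicates or self.frame.columns.has_duplicates:
            raise ValueError("class and odor labels must be unique")
        if not self.row_meta.index.equals(self.frame.index):
            raise ValueError("row_meta index must match the matrix rows")
        self.frame.index.name = "class_id"
        self.frame.columns.name = "odor_id"

    @property
    def class_ids(self) -> list:
        return list(self.frame.index)

    @property
    def odor_ids(self) -> list:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def rectified(self) -> pd.DataFrame:
        return self.frame.clip(lower=0.0)

    def to_csv(self, path) -> None:
        out = pd.concat([self.row_meta[["glomerulus", "neuron_type"]], self.frame], axis=1)
        out.to_csv(path, index_label="class_id")

    @classmethod
    def from_csv(cls, path, *, panel=None) -> "ResponseMatrix":
        raw = pd.read_csv(path, index_col="class_id")
        meta = raw[["glomerulus", "neuron_type"]]
        frame = raw.drop(columns=["glomerulus", "neuron_type"]).astype(float)
        return cls(frame=frame, row_meta=meta, panel=panel)

    @classmethod
    def from_spreadsheet(cls, path, *, neuron_type: str = "PN",
                         sheet: int | str = 0, panel=None) -> "ResponseMatrix":
        """Read a supplementary-style table: first column = class/glomerulus
        label, header row = odor names, cells = spikes per 1-s window.

        Accepts .xlsx (via openpyxl) or delimited text. The glomerulus is
        taken to equal the class label, as in the published class tables.
        """
        path = str(path)
        if path.endswith((".xlsx", ".xls")):
            frame = pd.read_excel(path, sheet_name=sheet, index_col=0)
        else:
            frame = pd.read_csv(path, index_col=0)
        frame = frame.astype(float)
        frame.index = frame.index.astype(str)
        meta = pd.DataFrame({"glomerulus": frame.index, "neuron_type": neuron_type},
                            index=frame.index)
        return cls(frame=frame, row_meta=meta, panel=panel)


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def count_response(spikes, window: tuple[float, float] = DEFAULT_WINDOW,
                   control_count: float = 0.0) -> float:
    """Spike count in the half-open window minus the control count.

    Negative results are preserved. Spike times must be sorted.
    """
    t = np.asarray(spikes, dtype=float)
    if window[0] >= window[1]:
        raise ValueError("window must be well-ordered")
    if len(t) > 1 and np.any(np.diff(t) < 0):
        raise ValueError("spike times must be sorted")
    count = int(np.searchsorted(t, window[1], side="left")
                - np.searchsorted(t, window[0], side="left"))
    return count - control_count


def _control_counts(train_set: SpikeTrainSet) -> dict:
    """(neuron_id, control_id, trial) → in-window spike count."""
    controls = set(train_set.control_odor_map.values())
    out = {}
    for rec in train_set.records.itertuples(index=False):
        if rec.odor_id in controls:
            out[(rec.neuron_id, rec.odor_id, rec.trial)] = count_response(
                rec.spikes, train_set.window, 0.0)
    return out


def build_response_matrix(train_set: SpikeTrainSet,
                          aggregation: str = "first_round") -> ResponseMatrix:
    """Aggregate a spike-train set into one value per class × odor.

    Per record the control-subtracted in-window count is computed (control =
    the solvent-matched control stimulus of the same neuron and trial, when
    present). ``first_round`` keeps each neuron's first trial, then averages
    across the neurons of a class; ``mean`` first averages each neuron's
    trials, then averages neurons. Missing (class, odor) cells raise with
    their ids.
    """
    if aggregation not in ("first_round", "mean"):
        raise ValueError("aggregation must be 'first_round' or 'mean'")
    controls = set(train_set.control_odor_map.values())
    ctrl = _control_counts(train_set)

    rows = []
    for rec in train_set.records.itertuples(index=False):
        if rec.odor_id in controls:
            continue
        ctrl_id = train_set.control_odor_map.get(rec.odor_id)
        c = ctrl.get((rec.neuron_id, ctrl_id, rec.trial), 0.0) if ctrl_id else 0.0
        rows.append({
            "neuron_id": rec.neuron_id, "class_id": rec.class_id,
            "glomerulus": rec.glomerulus, "odor_id": rec.odor_id,
            "trial": rec.trial,
            "response": count_response(rec.spikes, train_set.window, c),
        })
    tidy = pd.DataFrame(rows)
    if tidy.empty:
        raise ValueError("no odor records in the spike-train set")

    if aggregation == "first_round":
        first = tidy.groupby(["neuron_id", "odor_id"])["trial"].transform("min")
        tidy = tidy[tidy["trial"] == first]
    per_neuron = tidy.groupby(["class_id", "glomerulus", "neuron_id", "odor_id"],
                              sort=False)["response"].mean().reset_index()
    per_class = per_neuron.groupby(["class_id", "glomerulus", "odor_id"],
                                   sort=False)["response"].mean().reset_index()
    frame = per_class.pivot(index="class_id", columns="odor_id", values="response")

    odor_order = [o for o in train_set.odor_ids if o in frame.columns]
    frame = frame.reindex(columns=odor_order)
    if frame.isna().any().any():
        missing = [(c, o) for c in frame.index for o in frame.columns
                   if pd.isna(frame.loc[c, o])]
        raise ValueError(f"missing (class, odor) cells: {missing}")

    glom = per_class.drop_duplicates("class_id").set_index("class_id")["glomerulus"]
    meta = pd.DataFrame({"glomerulus": glom.reindex(frame.index),
                         "neuron_type": "PN"}, index=frame.index)
    return ResponseMatrix(frame=frame, row_meta=meta)


def per_neuron_response_matrix(train_set: SpikeTrainSet) -> tuple[pd.DataFrame, dict]:
    """Neuron × odor first-round response matrix plus neuron → glomerulus map.

    Used for pairwise neuron-reliability analyses, where sister neurons must
    not be averaged away.
    """
    controls = set(train_set.control_odor_map.values())
    ctrl = _control_counts(train_set)
    rows, glom_of = [], {}
    for rec in train_set.records.itertuples(index=False):
        if rec.odor_id in controls:
            continue
        ctrl_id = train_set.control_odor_map.get(rec.odor_id)
        c = ctrl.get((rec.neuron_id, ctrl_id, rec.trial), 0.0) if ctrl_id else 0.0
        rows.append({"neuron_id": rec.neuron_id, "odor_id": rec.odor_id,
                     "trial": rec.trial,
                     "response": count_response(rec.spikes, train_set.window, c)})
        glom_of[rec.neuron_id] = rec.glomerulus
    tidy = pd.DataFrame(rows)
    first = tidy.groupby(["neuron_id", "odor_id"])["trial"].transform("min")
    tidy = tidy[tidy["trial"] == first]
    mat = tidy.pivot(index="neuron_id", columns="odor_id", values="response")
    return mat, glom_of


# ---------------------------------------------------------------------------
# Reliability and threshold statistics
# ---------------------------------------------------------------------------

def pairwise_neuron_correlation(per_neuron: pd.DataFrame, glomerulus_of_neuron: dict):
    """Pearson r of odor-response vectors for every unordered neuron pair.

    Pairs are partitioned by whether the two neurons innervate the same
    glomerulus; a two-sided Wilcoxon rank-sum (Mann–Whitney) p-value
    compares the partitions (exact for small tie-free samples, tie-corrected
    normal approximation otherwise). Neurons with zero response variance
    have undefined r and are excluded with a logged count.

    Returns ``(same_glomerulus_r, different_glomerulus_r, p)``.
    """
    if per_neuron.shape[0] < 2:
        raise ValueError("need at least two neurons")
    vals = per_neuron.to_numpy(dtype=float)
    neurons = list(per_neuron.index)
    sds = vals.std(axis=1)
    keep = sds > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("excluding %d zero-variance neurons from pairwise correlation",
                       n_dropped)
    vals, neurons = vals[keep], [n for n, k in zip(neurons, keep) if k]
    cmat = np.corrcoef(vals)
    same, diff = [], []
    for i in range(len(neurons)):
        for j in range(i + 1, len(neurons)):
            r = float(cmat[i, j])
            if glomerulus_of_neuron[neurons[i]] == glomerulus_of_neuron[neurons[j]]:
                same.append(r)
            else:
                diff.append(r)
    if same and diff:
        p = float(stats.mannwhitneyu(same, diff, alternative="two-sided").pvalue)
    else:
        p = float("nan")
    return same, diff, p


def threshold_fractions(matrix: ResponseMatrix | pd.DataFrame,
                        thresholds) -> dict:
    """Fraction of class-odor cells with response ≥ threshold.

    Returns ``{threshold: (count, total, fraction)}`` with
    total = n_classes × n_odors. Monotone non-increasing in the threshold.
    """
    frame = getattr(matrix, "frame", matrix)
    vals = frame.to_numpy(dtype=float)
    total = vals.size
    out = {}
    for thr in thresholds:
        count = int((vals >= thr).sum())
        out[thr] = (count, total, count / total)
    return out


def psth(train_set: SpikeTrainSet, bin_width: float = 0.1):
    """Trial-averaged spike rate per (time bin, class, odor), spikes/s.

    The bin width must divide the recording span. Empty bins are 0. The
    result is a :class:`olfmap.temporal.PopulationTensor` whose rate tensor
    satisfies ``sum(bins) · bin_width = mean total spike count``.
    """
    from .temporal import PopulationTensor  # deferred to avoid an import cycle

    t0, t1 = train_set.span
    n_bins = (t1 - t0) / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin_width must divide the recording span")
    n_bins = int(round(n_bins))
    edges = t0 + bin_width * np.arange(n_bins + 1)

    classes = train_set.class_ids
    odors = train_set.odor_ids
    c_idx = {c: i for i, c in enumerate(classes)}
    o_idx = {o: i for i, o in enumerate(odors)}
    rates = np.zeros((n_bins, len(classes), len(odors)))
    counts = np.zeros((len(classes), len(odors)), dtype=int)
    for rec in train_set.records.itertuples(index=False):
        if rec.odor_id not in o_idx:
            continue
        hist, _ = np.histogram(np.asarray(rec.spikes, dtype=float), bins=edges)
        rates[:, c_idx[rec.class_id], o_idx[rec.odor_id]] += hist
        counts[c_idx[rec.class_id], o_idx[rec.odor_id]] += 1
    with np.errstate(invalid="ignore"):
        rates = np.where(counts > 0, rates / np.maximum(counts, 1), 0.0)
    rates /= bin_width
    return PopulationTensor(rates=rates, bin_width=bin_width, t0=t0,
                            class_ids=list(classes), odor_ids=list(odors))
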