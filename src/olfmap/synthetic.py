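"""Synthetic study data with the statistical structure the analyses assume.

The generator emulates the recorded system end to end so every downstream
stage is testable without the original recordings:

* an odor panel of attractive and aversive odors (default 17 = 8 + 9, each
  dissolved in mineral oil or water);
* a ground-truth model in which neuron classes (one per glomerulus) belong
  to planted glomerular groups, odors belong to matching odor groups, and a
  class responds ``within_group_gain`` times more strongly to odors of its
  own group — the cluster structure that odor-space analyses must recover;
* inhomogeneous Poisson spike trains over [-1, 3] s around a 1-s stimulus,
  with an onset transient peaking ~150 ms after onset that decays toward a
  sustained level, shared by the sister neurons of a class up to
  independent multiplicative trial noise, plus solvent-control stimuli;
* a glomerulus atlas whose centroids can be spatially clustered by planted
  group, emulating the tendency of neighboring glomeruli to share response
  properties;
* SWC axonal skeletons whose lateral-horn target loci are structured by
  glomerular group (attractive-group classes dorsal, aversive ventral)
  while calyx targeting is distributed — the planted analog of
  valence-segregated projection patterns.

Every operation is a pure function of its arguments and seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import morphology
from .morphology import NeuronSkeleton, region_box
from .responses import ResponseMatrix, SpikeTrainSet

logger = logging.getLogger(__name__)

#: Control stimulus ids keyed by solvent.
CONTROL_IDS = {"mineral_oil": "ctrl_mineral_oil", "water": "ctrl_water"}

#: Antennal-lobe bounding box for atlas centroids, μm.
AL_BOX = np.array([100.0, 100.0, 60.0])


# ---------------------------------------------------------------------------
# Panel
# ---------------------------------------------------------------------------

@dataclass
class OdorPanel:
    """Odor ids with valence (attractive/aversive), solvent and dilution."""

    frame: pd.DataFrame  # index odor_id; columns name, valence, solvent, dilution

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            raise ValueError("odor ids must be unique")
        bad_val = set(self.frame["valence"]) - {"attractive", "aversive"}
        bad_sol = set(self.frame["solvent"]) - set(CONTROL_IDS)
        if bad_val or bad_sol:
            raise ValueError(f"invalid valence {bad_val} or solvent {bad_sol}")

    @property
    def odor_ids(self) -> list:
        return list(self.frame.index)

    @property
    def n_odors(self) -> int:
        return len(self.frame)

    @property
    def valence(self) -> pd.Series:
        return self.frame["valence"]

    def control_odor_map(self) -> dict:
        return {o: CONTROL_IDS[s] for o, s in self.frame["solvent"].items()}


def generate_panel(n_attractive: int = 8, n_aversive: int = 9,
                   seed: int = 0) -> OdorPanel:
    """Synthetic odor panel; defaults mirror a 17-odor, 8/9 valence split.

    Names are synthetic placeholders. Water is assigned as solvent to every
    eighth odor (standing in for the acids of a real panel), mineral oil to
    the rest. Deterministic under a fixed seed.
    """
    if n_attractive < 0 or n_aversive < 0 or n_attractive + n_aversive < 2:
        raise ValueError("need a total of at least two odors")
    rows = []
    for i in range(n_attractive):
        rows.append({"odor_id": f"attr{i + 1:02d}", "name": f"attractive odor {i + 1}",
                     "valence": "attractive"})
    for i in range(n_aversive):
        rows.append({"odor_id": f"aver{i + 1:02d}", "name": f"aversive odor {i + 1}",
                     "valence": "aversive"})
    frame = pd.DataFrame(rows).set_index("odor_id")
    frame["solvent"] = ["water" if i % 8 == 7 else "mineral_oil"
                       for i in range(len(frame))]
    frame["dilution"] = 1e-3
    return OdorPanel(frame=frame)


# ---------------------------------------------------------------------------
# Ground-truth model
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthModel:
    """Planted tuning structure behind the synthetic population.

    ``mean_rate`` (class × odor, spikes/s) is the stimulus-driven rate above
    baseline; classes map 1:1 onto glomeruli, glomeruli onto planted groups,
    and odors onto the same group ids.
    """

    panel: OdorPanel
    class_ids: list
    glomerulus_of_class: dict
    group_of_glomerulus: dict
    group_of_odor: dict
    mean_rate: pd.DataFrame
    trial_sd: float = 0.2
    onset_peak_time: float = 0.15
    baseline_rate: float = 5.0
    sustained_fraction: float = 0.5

    def __post_init__(self) -> None:
        if (self.mean_rate.to_numpy() < 0).any():
            raise ValueError("mean rates must be non-negative")
        if set(self.mean_rate.index) != set(self.class_ids):
            raise ValueError("mean_rate rows must match class_ids")

    @property
    def group_of_class(self) -> dict:
        return {c: self.group_of_glomerulus[g]
                for c, g in self.glomerulus_of_class.items()}

    def response_matrix(self) -> ResponseMatrix:
        """The noise-free planted class × odor matrix as a ResponseMatrix."""
        meta = pd.DataFrame(
            {"glomerulus": [self.glomerulus_of_class[c] for c in self.mean_rate.index],
             "neuron_type": "PN"}, index=self.mean_rate.index)
        return ResponseMatrix(frame=self.mean_rate.copy(), row_meta=meta,
                              panel=self.panel)


def generate_model(panel: OdorPanel, n_classes: int = 31, n_groups: int = 3,
                   within_group_gain: float = 6.0, seed: int = 0, *,
                   base_rate_mean: float = 8.0, trial_sd: float = 0.2,
                   onset_peak_time: float = 0.15, baseline_rate: float = 5.0,
                   ) -> GroundTruthModel:
    """Planted cluster-structured class × odor mean-rate matrix.

    Baseline tuning is exponential with mean ``base_rate_mean`` spikes/s
    (most responses weak, a few strong); responses of a class to odors of
    its own planted group are multiplied by ``within_group_gain``.
    Attractive odors form group 0; aversive odors are split over the
    remaining groups. ``within_group_gain = 1`` plants no structure.
    """
    if not 1 <= n_groups <= n_classes:
        raise ValueError("need 1 ≤ n_groups ≤ n_classes")
    if within_group_gain <= 0:
        raise ValueError("within_group_gain must be positive")
    rng = np.random.default_rng(seed)
    glomeruli = [f"G{i + 1:02d}" for i in range(n_classes)]
    class_ids = [f"PN-{g}" for g in glomeruli]
    group_of_glom = {g: i % n_groups for i, g in enumerate(glomeruli)}

    group_of_odor = {}
    n_aversive_groups = max(n_groups - 1, 1)
    k = 0
    for odor, val in panel.valence.items():
        if n_groups == 1:
            group_of_odor[odor] = 0
        elif val == "attractive":
            group_of_odor[odor] = 0
        else:
            group_of_odor[odor] = 1 + (k % n_aversive_groups)
            k += 1

    base = rng.exponential(scale=base_rate_mean,
                           size=(n_classes, panel.n_odors))
    gain = np.ones_like(base)
    for j, odor in enumerate(panel.odor_ids):
        for i, g in enumerate(glomeruli):
            if group_of_glom[g] == group_of_odor[odor]:
                gain[i, j] = within_group_gain
    mean_rate = pd.DataFrame(base * gain, index=class_ids, columns=panel.odor_ids)
    return GroundTruthModel(
        panel=panel, class_ids=class_ids,
        glomerulus_of_class=dict(zip(class_ids, glomeruli)),
        group_of_glomerulus=group_of_glom, group_of_odor=group_of_odor,
        mean_rate=mean_rate, trial_sd=trial_sd,
        onset_peak_time=onset_peak_time, baseline_rate=baseline_rate)


def derive_osn_matrix(pn: ResponseMatrix, noise_frac: float = 0.5,
                      seed: int = 0) -> ResponseMatrix:
    """An OSN response matrix correlated glomerulus-by-glomerulus with ``pn``.

    Each OSN class inherits its glomerulus's PN tuning vector up to a
    log-normal per-glomerulus gain and additive Gaussian noise scaled to
    ``noise_frac`` of that vector's standard deviation, then rectified —
    emulating a conserved but noisy periphery-to-output transformation.
    """
    rng = np.random.default_rng(seed)
    vals = pn.frame.to_numpy(dtype=float)
    gains = rng.lognormal(mean=0.0, sigma=0.3, size=(vals.shape[0], 1))
    sds = vals.std(axis=1, keepdims=True)
    noisy = np.clip(vals * gains + rng.normal(0.0, noise_frac * sds, vals.shape),
                    0.0, None)
    gloms = pn.row_meta["glomerulus"]
    index = pd.Index([f"OSN-{g}" for g in gloms], name="class_id")
    frame = pd.DataFrame(noisy, index=index, columns=pn.frame.columns)
    meta = pd.DataFrame({"glomerulus": list(gloms), "neuron_type": "OSN"}, index=index)
    return ResponseMatrix(frame=frame, row_meta=meta, panel=pn.panel)


# ---------------------------------------------------------------------------
# Spike trains
# ---------------------------------------------------------------------------

def _rate_profile_factory(model: GroundTruthModel):
    """rate(t) for one trial: baseline plus a normalized stimulus transient.

    The transient starts at 0.05 s (odor arrival delay), rises as an alpha
    function peaking at ``onset_peak_time``, and decays toward a sustained
    plateau (``sustained_fraction`` of peak shape); it is normalized so that
    its integral over the 1-s counting window [0.05, 1.05) equals 1. A trial
    with amplitude A therefore adds A expected spikes to the window.
    """
    t_on = 0.05
    tau = model.onset_peak_time - t_on
    if tau <= 0:
        raise ValueError("onset_peak_time must exceed the 0.05-s arrival delay")
    s = model.sustained_fraction
    # mean of the alpha function (u/tau) e^(1 - u/tau) over u in [0, 1]
    alpha_mean = math.e * tau * (1.0 - (1.0 + 1.0 / tau) * math.exp(-1.0 / tau))
    norm = s + (1.0 - s) * alpha_mean

    def shape(t: np.ndarray) -> np.ndarray:
        u = np.asarray(t, dtype=float) - t_on
        active = (u >= 0) & (u < 1.0)
        a = np.where(active, (np.maximum(u, 0.0) / tau) * np.exp(1.0 - u / tau), 0.0)
        return np.where(active, (s + (1.0 - s) * a) / norm, 0.0)

    peak_shape = 1.0 / norm  # shape() maximum, used for thinning
    return shape, peak_shape


def _poisson_train(rng, baseline: float, amplitude: float, shape, peak_shape,
                   span: tuple[float, float]) -> np.ndarray:
    """Inhomogeneous Poisson spikes by thinning against the maximum rate."""
    rmax = baseline + amplitude * peak_shape
    if rmax <= 0:
        return np.empty(0)
    n = rng.poisson(rmax * (span[1] - span[0]))
    t = np.sort(rng.uniform(span[0], span[1], size=n))
    rate = baseline + amplitude * shape(t)
    keep = rng.uniform(0.0, rmax, size=n) < rate
    return t[keep]


def simulate_spike_trains(model: GroundTruthModel, n_trials: int = 2,
                          n_sisters_per_class: int = 3, seed: int = 0,
                          span: tuple[float, float] = (-1.0, 3.0)) -> SpikeTrainSet:
    """Poisson spike trains for all sister neurons, odors and trials.

    Sister neurons of a class share the class rate profile; each
    (neuron, odor, trial) gets an independent multiplicative amplitude drawn
    from N(1, trial_sd), clipped at zero (clipping is logged). Control
    stimuli (both solvents) are simulated at baseline rate for every neuron
    and trial.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be ≥ 1")
    if n_sisters_per_class < 1:
        raise ValueError("need at least one sister neuron per class")
    rng = np.random.default_rng(seed)
    shape, peak_shape = _rate_profile_factory(model)
    stimuli = list(model.mean_rate.columns) + sorted(set(CONTROL_IDS.values()))
    n_clipped = 0
    records = []
    for class_id in model.class_ids:
        glom = model.glomerulus_of_class[class_id]
        for sister in range(1, n_sisters_per_class + 1):
            neuron_id = f"{class_id}.n{sister}"
            for stim in stimuli:
                is_control = stim not in model.mean_rate.columns
                mean_amp = 0.0 if is_control else float(model.mean_rate.loc[class_id, stim])
                for trial in range(1, n_trials + 1):
                    gain = rng.normal(1.0, model.trial_sd)
                    if gain < 0:
                        n_clipped += 1
                        gain = 0.0
                    spikes = _poisson_train(rng, model.baseline_rate,
                                            gain * mean_amp, shape, peak_shape, span)
                    records.append({"neuron_id": neuron_id, "class_id": class_id,
                                    "glomerulus": glom, "odor_id": stim,
                                    "trial": trial, "spikes": spikes})
    if n_clipped:
        logger.warning("clipped %d negative trial amplitudes to zero", n_clipped)
    return SpikeTrainSet(records=pd.DataFrame(records), span=span,
                         control_odor_map=model.panel.control_odor_map())


# ---------------------------------------------------------------------------
# Glomerulus atlas
# ---------------------------------------------------------------------------

@dataclass
class GlomerulusAtlas:
    """Glomerulus centroids (μm) with their planted group ids."""

    frame: pd.DataFrame  # index glomerulus_id; columns x, y, z, group

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.frame[["x", "y", "z"]].to_numpy())):
            raise ValueError("centroids must be finite")

    @property
    def centroids(self) -> np.ndarray:
        return self.frame[["x", "y", "z"]].to_numpy(dtype=float)

    def distance_matrix(self):
        """Euclidean distances between centroids as a DistanceMatrix."""
        from . import odor_space
        from scipy.spatial.distance import pdist, squareform
        d = squareform(pdist(self.centroids))
        return odor_space.DistanceMatrix(labels=list(self.frame.index), values=d,
                                         metric="euclidean")


def generate_atlas(model: GroundTruthModel, spatial_clustering: float = 1.0,
                   seed: int = 0, jitter_sd: float = 5.0) -> GlomerulusAtlas:
    """Glomerulus centroids in the antennal-lobe box.

    ``spatial_clustering`` interpolates between uniform placement (0) and
    placement around planted group centers (1), emulating the anatomical
    arrangement where neighboring glomeruli share response properties.
    """
    rng = np.random.default_rng(seed)
    gloms = sorted(model.group_of_glomerulus)
    groups = sorted(set(model.group_of_glomerulus.values()))
    centers = {g: AL_BOX * (0.2 + 0.6 * rng.random(3)) for g in groups}
    lam = float(spatial_clustering)
    rows = []
    for g in gloms:
        uniform = AL_BOX * rng.random(3)
        grouped = centers[model.group_of_glomerulus[g]] + rng.normal(0, jitter_sd, 3)
        p = (1 - lam) * uniform + lam * grouped
        rows.append({"glomerulus_id": g, "x": p[0], "y": p[1], "z": p[2],
                     "group": model.group_of_glomerulus[g]})
    return GlomerulusAtlas(frame=pd.DataFrame(rows).set_index("glomerulus_id"))


# ---------------------------------------------------------------------------
# Axonal skeletons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArborSpec:
    """Target locus and branching statistics for one arbor in one region."""

    region: str                       # "calyx" | "LH"
    target_locus: tuple[float, float, float]
    spread_sd: float = 4.0            # μm; arbor extent around the locus
    n_branch_points: int = 10
    segment_length_mean: float = 2.0  # μm

    def __post_init__(self) -> None:
        if self.spread_sd < 0:
            raise ValueError("spread_sd must be non-negative")
        lo, size = region_box(self.region)
        locus = np.asarray(self.target_locus)
        if np.any(locus < lo) or np.any(locus >= lo + size):
            raise ValueError(f"target locus {self.target_locus} outside the "
                             f"{self.region} bounding box")


def default_arbor_specs(model: GroundTruthModel, seed: int = 0, *,
                        spread_sd: float = 4.0, n_branch_points: int = 10,
                        segment_length_mean: float = 2.0,
                        lh_locus_jitter: float = 3.0) -> dict:
    """Per-class (calyx spec, LH spec) pairs with planted regional structure.

    Lateral-horn target loci are placed by planted group — group 0 (the
    attractive-odor group) dorsally, the remaining groups at distinct
    ventral positions — while calyx loci are drawn uniformly within the
    calyx box, reflecting stereotyped LH versus distributed calyx wiring.
    """
    rng = np.random.default_rng(seed)
    _, lh_size = region_box("LH")
    _, cal_size = region_box("calyx")
    groups = sorted(set(model.group_of_glomerulus.values()))
    n_aversive = max(len(groups) - 1, 1)
    lh_centers = {}
    for g in groups:
        if g == 0:
            frac = np.array([0.5, 0.5, 0.8])     # dorsal
        else:
            # aversive groups converge onto a common ventral zone, offset
            # only slightly from one another
            x = 0.35 + 0.3 * ((g - 1) / max(n_aversive - 1, 1) if n_aversive > 1 else 0.5)
            frac = np.array([x, 0.5, 0.2])       # ventral band
        lh_centers[g] = lh_size * frac
    specs = {}
    for class_id in model.class_ids:
        group = model.group_of_class[class_id]
        lh_locus = np.clip(lh_centers[group] + rng.normal(0, lh_locus_jitter, 3),
                           1.0, lh_size - 1.0)
        cal_locus = cal_size * (0.15 + 0.7 * rng.random(3))
        specs[class_id] = (
            ArborSpec(region="calyx", target_locus=tuple(cal_locus),
                      spread_sd=spread_sd, n_branch_points=n_branch_points,
                      segment_length_mean=segment_length_mean),
            ArborSpec(region="LH", target_locus=tuple(lh_locus),
                      spread_sd=spread_sd, n_branch_points=n_branch_points,
                      segment_length_mean=segment_length_mean),
        )
    return specs


def _walk(rng, start: np.ndarray, target: np.ndarray, step: float,
          wobble: float, box_lo: np.ndarray, box_hi: np.ndarray) -> list:
    """Biased random-walk positions from start toward target (excl. start)."""
    out = []
    pos = start.astype(float).copy()
    for _ in range(2000):
        delta = target - pos
        dist = float(np.linalg.norm(delta))
        if dist <= step:
            if dist > 1e-9:
                out.append(np.clip(target, box_lo, box_hi - 1e-6).copy())
            break
        direction = delta / dist
        if wobble > 0:
            direction = direction + rng.normal(0.0, wobble, 3)
            direction /= np.linalg.norm(direction)
        pos = np.clip(pos + step * direction, box_lo, box_hi - 1e-6)
        out.append(pos.copy())
    return out


def _build_arbor(rng, spec: ArborSpec) -> NeuronSkeleton:
    lo, size = region_box(spec.region)
    hi = lo + size
    locus = np.asarray(spec.target_locus, dtype=float)
    step = spec.segment_length_mean
    wobble = min(spec.spread_sd / 10.0, 0.5)

    root = np.array([lo[0], lo[1] + size[1] / 2.0, lo[2] + size[2] / 2.0])
    xyz = [root]
    parents = [-1]
    # trunk: biased walk from the region entry face to the target locus
    for p in _walk(rng, root, locus, step, wobble, lo, hi):
        xyz.append(p)
        parents.append(len(xyz) - 2 + 1)  # previous node id (1-based below)
    trunk_end = len(xyz)
    attach_candidates = [trunk_end]
    # branches: each walks from an existing node toward its own target drawn
    # around the locus, so the arbor collapses onto the locus as spread_sd → 0
    for _ in range(spec.n_branch_points):
        attach = int(rng.choice(attach_candidates))
        target = np.clip(locus + rng.normal(0.0, spec.spread_sd, 3), lo, hi - 1e-6)
        prev = attach
        for p in _walk(rng, xyz[attach - 1], target, step, wobble, lo, hi):
            xyz.append(p)
            parents.append(prev)
            prev = len(xyz)
        attach_candidates.append(prev)
    n = len(xyz)
    skel = NeuronSkeleton(node_ids=np.arange(1, n + 1), xyz=np.asarray(xyz),
                          radius=np.full(n, 0.5), parent_ids=np.asarray(parents))
    skel.tag_regions({spec.region: (lo, size)})
    return skel


def generate_skeletons(model: GroundTruthModel, arbor_specs: dict,
                       seed: int = 0) -> list:
    """One connected SWC tree per class and region (calyx + lateral horn).

    ``arbor_specs`` maps class_id → (calyx ArborSpec, LH ArborSpec) as built
    by :func:`default_arbor_specs`. Trees are rooted at the region entry
    face; parents always precede children, so the SWC output is valid by
    construction and byte-identical under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    out = []
    for class_id in model.class_ids:
        if class_id not in arbor_specs:
            raise ValueError(f"no arbor specs for class {class_id}")
        for spec in arbor_specs[class_id]:
            skel = _build_arbor(rng, spec)
            skel.class_id = class_id
            out.append(skel)
    return out


def skeletons_by_class(skeletons: list, region: str) -> dict:
    """Group skeletons of one region by class id (majority node tag)."""
    out: dict[str, list] = {}
    for s in skeletons:
        tags = s.region_of_node
        if tags is not None and (tags == region).mean() > 0.5:
            out.setdefault(s.class_id, []).append(s)
    return out
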