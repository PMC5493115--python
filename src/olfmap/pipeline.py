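"""End-to-end orchestration: simulate → responses → tuning → odor space →
density maps → functional maps → temporal dynamics.

A run takes an :class:`AnalysisConfig` (all analysis constants plus the
synthetic-data scale) and produces a run directory with the response
matrices, statistic tables, map projections, figures, a log, the resolved
configuration and a checksum manifest. Runs are idempotent: the same config
and seed produce identical manifests. Each stochastic stage draws a sub-seed
derived from the global seed and the stage name, so stages are reproducible
independently of each other.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import functional_maps as fm
from . import morphology, odor_space, responses, synthetic, temporal, tuning

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """All analysis constants and synthetic-data study conditions.

    Analysis constants follow the reference protocol: a [0.05, 1.05) s
    counting window, cosine distances with an absolute 0.6 linkage cut for
    the antennal-lobe odor space (0.7 of the maximum height for Euclidean),
    correlation distances for map similarity, a 30 spikes/s
    cluster-signature threshold, a 135 × 135 × 105 grid of 1 μm³ voxels with
    a 9-voxel boxcar, 100 shuffle runs and 10,000 ANOSIM permutations.
    """

    seed: int = 0
    # synthetic study conditions
    n_attractive: int = 8
    n_aversive: int = 9
    n_classes: int = 31
    n_groups: int = 3
    within_group_gain: float = 6.0
    trial_sd: float = 0.2
    n_trials: int = 2
    n_sisters: int = 3
    spatial_clustering: float = 1.0
    osn_noise_frac: float = 0.5
    # analysis constants
    window: tuple = (0.05, 1.05)
    metric_al: str = "cosine"
    metric_maps: str = "correlation"
    cut_absolute: float = 0.6
    cut_fraction_of_max: float = 0.7
    signature_threshold: float = 30.0
    shuffle_runs: int = 100
    anosim_permutations: int = 10000
    grid_shape: tuple = (135, 135, 105)
    voxel_size: float = 1.0
    resample_step: float = 0.5
    boxcar_width: int = 9
    bin_width: float = 0.1

    def __post_init__(self) -> None:
        for name in ("n_classes", "n_groups", "n_trials", "n_sisters",
                     "shuffle_runs", "anosim_permutations", "boxcar_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage sub-seed (stage-name hash mixed with seed)."""
        return (zlib.crc32(stage.encode()) ^ (self.seed * 0x9E3779B1)) % (2**31)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["window"] = list(data["window"])
        data["grid_shape"] = list(data["grid_shape"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["window"] = tuple(data["window"])
        data["grid_shape"] = tuple(data["grid_shape"])
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _save_projection(vmap, path: Path) -> None:
    np.savetxt(path, morphology.project2d(vmap, "z"), delimiter=",", fmt="%.6g")


def run(config: AnalysisConfig, out_dir, inputs: dict | None = None, *,
        make_figures: bool = True) -> Path:
    """Execute the pipeline and write a run directory.

    With ``inputs=None`` (default) all inputs are synthesized from the
    config. Alternatively ``inputs`` may supply paths: ``pn_matrix`` (CSV in
    :meth:`ResponseMatrix.to_csv` layout; mandatory in this mode) and
    optionally ``osn_matrix``. Stages whose inputs are unavailable in
    matrices-only mode (spike statistics, maps, temporal dynamics) are
    skipped and recorded in ``summary.json`` under ``skipped_stages``.

    Returns the run directory path. ``summary.json`` holds the headline
    statistics; ``manifest.json`` lists every output file with its SHA-256
    checksum (stable across identical config + seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("olfmap")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    summary: dict = {"skipped_stages": []}
    timings: dict = {}
    try:
        t0 = time.perf_counter()

        # --- simulate (or load) -------------------------------------------
        model = atlas = trains = skeletons = panel = osn = None
        if inputs is None:
            panel = synthetic.generate_panel(config.n_attractive, config.n_aversive,
                                             seed=config.stage_seed("panel"))
            model = synthetic.generate_model(
                panel, n_classes=config.n_classes, n_groups=config.n_groups,
                within_group_gain=config.within_group_gain,
                seed=config.stage_seed("model"), trial_sd=config.trial_sd)
            atlas = synthetic.generate_atlas(model, config.spatial_clustering,
                                             seed=config.stage_seed("atlas"))
            trains = synthetic.simulate_spike_trains(
                model, n_trials=config.n_trials, n_sisters_per_class=config.n_sisters,
                seed=config.stage_seed("spikes"))
            specs = synthetic.default_arbor_specs(model, seed=config.stage_seed("arbors"))
            skeletons = synthetic.generate_skeletons(model, specs,
                                                     seed=config.stage_seed("skeletons"))
            osn = synthetic.derive_osn_matrix(model.response_matrix(),
                                              noise_frac=config.osn_noise_frac,
                                              seed=config.stage_seed("osn"))
            panel.frame.to_csv(out / "panel.csv")
            atlas.frame.to_csv(out / "atlas.csv")
            trains.to_csv(out / "spikes.csv")
            swc_dir = out / "swc"
            swc_dir.mkdir(exist_ok=True)
            for sk in skeletons:
                region = "calyx" if (sk.region_of_node == "calyx").mean() > 0.5 else "LH"
                morphology.write_swc(sk, swc_dir / f"{sk.class_id}_{region}.swc")
        else:
            if "pn_matrix" not in inputs:
                raise ValueError("inputs must provide at least 'pn_matrix'")
        timings["simulate"] = time.perf_counter() - t0

        # --- responses ----------------------------------------------------
        t1 = time.perf_counter()
        if trains is not None:
            trains.window = tuple(config.window)
            matrix = responses.build_response_matrix(trains, aggregation="first_round")
            per_neuron, glom_of = responses.per_neuron_response_matrix(trains)
            same_r, diff_r, rank_p = responses.pairwise_neuron_correlation(
                per_neuron, glom_of)
            summary["sister_correlation"] = {
                "median_same_glomerulus_r": float(np.median(same_r)) if same_r else None,
                "median_different_glomerulus_r": float(np.median(diff_r)) if diff_r else None,
                "ranksum_p": rank_p, "n_same": len(same_r), "n_diff": len(diff_r)}
        else:
            matrix = responses.ResponseMatrix.from_csv(inputs["pn_matrix"])
            logger.info("spike-train stage skipped: response matrix supplied directly")
            summary["skipped_stages"].append("sister_correlation")
            if "osn_matrix" in inputs:
                osn = responses.ResponseMatrix.from_csv(inputs["osn_matrix"])
        matrix.to_csv(out / "pn_matrix.csv")
        fractions = responses.threshold_fractions(matrix, [30.0, 50.0])
        summary["threshold_fractions"] = {
            str(k): {"count": v[0], "total": v[1], "fraction": v[2]}
            for k, v in fractions.items()}
        timings["responses"] = time.perf_counter() - t1

        # --- tuning -------------------------------------------------------
        t1 = time.perf_counter()
        sp_rows = []
        for class_id in matrix.class_ids:
            try:
                s = tuning.lifetime_sparseness(matrix.frame.loc[class_id].to_numpy())
            except ValueError:
                s = np.nan
            sp_rows.append({"class_id": class_id, "sparseness": s})
        pd.DataFrame(sp_rows).to_csv(out / "sparseness.csv", index=False)
        summary["mean_sparseness"] = float(np.nanmean([r["sparseness"] for r in sp_rows]))
        if osn is not None:
            osn.to_csv(out / "osn_matrix.csv")
            corr_table, corr_summary = tuning.osn_pn_correlation(matrix, osn)
            corr_table.to_csv(out / "osn_pn_correlation.csv")
            sh_mean, sh_sd, _ = tuning.shuffled_correlation_control(
                matrix, osn, n_runs=config.shuffle_runs,
                seed=config.stage_seed("shuffle"))
            pairs, _excluded = tuning.sparseness_comparison(matrix, osn)
            pairs.to_csv(out / "sparseness_pairs.csv")
            summary["osn_pn_correlation"] = {
                "mean_r": corr_summary["mean_r"], "sd_r": corr_summary["sd_r"],
                "n": corr_summary["n"],
                "shuffled_mean_r": sh_mean, "shuffled_sd_r": sh_sd}
        else:
            logger.info("OSN comparison skipped: no OSN matrix available")
            summary["skipped_stages"].append("osn_pn_comparison")
        timings["tuning"] = time.perf_counter() - t1

        # --- odor space ---------------------------------------------------
        t1 = time.perf_counter()
        dmat = odor_space.odor_distance_matrix(matrix, metric=config.metric_al)
        dmat.to_frame().to_csv(out / "odor_distances.csv")
        dend = odor_space.hierarchical_cluster(dmat)
        clusters = odor_space.cut_dendrogram(dend, config.cut_absolute)
        clusters.to_csv(out / "odor_clusters.csv")
        signatures = odor_space.cluster_signature_glomeruli(
            matrix, clusters, config.signature_threshold)
        pca_res = odor_space.pca(matrix, items="odors")
        from sklearn.metrics import adjusted_rand_score
        summary["odor_space"] = {
            "n_clusters": int(clusters.nunique()),
            "cluster_sizes": clusters.value_counts().sort_index().tolist(),
            "pc1_variance_pct": float(pca_res.explained_variance_fraction[0] * 100),
            "pc2_variance_pct": float(pca_res.explained_variance_fraction[1] * 100),
            "signature_glomeruli": {str(k): sorted(v) for k, v in signatures.items()}}
        if panel is not None:
            r_stat, p_anosim = odor_space.anosim(
                matrix, {o: v for o, v in panel.valence.items()},
                n_perm=config.anosim_permutations, seed=config.stage_seed("anosim"))
            k_clusters = odor_space.cut_dendrogram_k(dend, config.n_groups)
            planted = [model.group_of_odor[o] for o in k_clusters.index]
            summary["odor_space"].update({
                "ari_vs_planted": float(
                    adjusted_rand_score(planted, k_clusters.to_numpy())),
                "anosim_R": r_stat, "anosim_p": p_anosim})
        else:
            summary["skipped_stages"].append("anosim_valence")
        if atlas is not None:
            r_af, p_af, shuffle_af = odor_space.matrix_correlation(
                atlas.distance_matrix(),
                _per_glomerulus_response_distances(matrix, config.metric_al),
                shuffle=(config.shuffle_runs, config.stage_seed("anat_shuffle")))
            summary["odor_space"].update({
                "anatomy_function_r": r_af, "anatomy_function_p": p_af,
                "anatomy_function_shuffle": list(shuffle_af)})
        else:
            summary["skipped_stages"].append("anatomy_function_correlation")
        timings["odor_space"] = time.perf_counter() - t1

        # --- density + functional maps (per region) ------------------------
        t1 = time.perf_counter()
        if skeletons is not None:
            from sklearn.metrics import adjusted_rand_score as ari
            valence = panel.valence
            summary["maps"] = {}
            for region in ("LH", "calyx"):
                grid = morphology.region_grid(region, grid_shape=tuple(config.grid_shape),
                                              voxel_size=config.voxel_size)
                by_class = synthetic.skeletons_by_class(skeletons, region)
                density = morphology.class_density_maps(
                    by_class, grid, step=config.resample_step,
                    boxcar_width=config.boxcar_width)
                maps = fm.functional_maps_for_panel(density, matrix)
                _, dend_maps, map_clusters = fm.functional_map_clustering(
                    maps, config.cut_absolute)
                map_clusters.to_csv(out / f"map_clusters_{region}.csv")
                val = [valence[o] for o in map_clusters.index]
                two_way = odor_space.cut_dendrogram_k(dend_maps, 2)
                summary["maps"][region] = {
                    "n_clusters": int(map_clusters.nunique()),
                    "ari_vs_valence": float(ari(val, map_clusters.to_numpy())),
                    "ari_vs_valence_two_way": float(ari(val, two_way.to_numpy()))}
                proj_dir = out / f"projections_{region}"
                proj_dir.mkdir(exist_ok=True)
                for odor in list(maps)[:3]:  # a few representative projections
                    _save_projection(maps[odor].voxels, proj_dir / f"{odor}.csv")
                if make_figures and region == "LH":
                    _figure_projection(maps, out / "functional_maps_LH.png")
        else:
            logger.info("map stages skipped: no skeletons available")
            summary["skipped_stages"].append("maps")
        timings["maps"] = time.perf_counter() - t1

        # --- temporal -----------------------------------------------------
        t1 = time.perf_counter()
        if trains is not None:
            tensor = responses.psth(trains, bin_width=config.bin_width)
            series, peak = temporal.inter_odor_distance_timecourse(tensor)
            series.to_csv(out / "distance_timecourse.csv")
            summary["temporal"] = {"separation_peak_time_s": peak}
        else:
            logger.info("temporal stage skipped: no spike trains available")
            summary["skipped_stages"].append("temporal")
        timings["temporal"] = time.perf_counter() - t1

        for stage, dt in timings.items():
            logger.info("stage %s finished in %.2f s", stage, dt)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        config.to_yaml(out / "config.yaml")
        if make_figures:
            _figure_matrix(matrix, out / "pn_matrix.png")

        manifest = {str(p.relative_to(out)): _sha256(p)
                    for p in sorted(out.rglob("*"))
                    if p.is_file() and p.name not in ("manifest.json", "run.log")}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    finally:
        root.removeHandler(handler)
        handler.close()
    return out


def _per_glomerulus_response_distances(matrix, metric: str):
    """Distance matrix between glomerulus tuning vectors (rows), for the
    anatomy–function comparison (items = glomeruli)."""
    frame = matrix.frame.copy()
    frame.index = pd.Index(matrix.row_meta["glomerulus"])
    from scipy.spatial.distance import pdist, squareform
    d = pdist(frame.to_numpy(dtype=float), metric=metric)
    d = np.where(np.isfinite(d), d, 1.0)
    return odor_space.DistanceMatrix(labels=list(frame.index),
                                     values=squareform(d), metric=metric)


def _figure_matrix(matrix, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(7, 8))
    im = ax.imshow(matrix.values, aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(matrix.odor_ids)))
    ax.set_xticklabels(matrix.odor_ids, rotation=90, fontsize=6)
    ax.set_yticks(range(len(matrix.class_ids)))
    ax.set_yticklabels(matrix.class_ids, fontsize=6)
    ax.set_title("PN response intensities (spikes / 1-s window)")
    fig.colorbar(im, ax=ax, shrink=0.6)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _figure_projection(maps: dict, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from .morphology import project2d
    odors = list(maps)[:6]
    fig, axes = plt.subplots(2, 3, figsize=(9, 6))
    for ax, odor in zip(axes.ravel(), odors):
        img = project2d(maps[odor].voxels, "z")
        ax.imshow(img.T, origin="lower", cmap="inferno")
        ax.set_title(odor, fontsize=8)
        ax.axis("off")
    fig.suptitle("Functional maps, LH (z projection, per-image scale)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def report(run_dir) -> str:
    """Render the headline statistics of a completed run as Markdown.

    Missing stages are reported as absent, not as failures. The report is a
    pure function of the run directory contents. Writes ``report.md`` into
    the run directory and returns the text.
    """
    run_dir = Path(run_dir)
    summary_path = run_dir / "summary.json"
    if not summary_path.exists():
        raise FileNotFoundError(f"no summary.json in {run_dir}; not a completed run")
    with open(summary_path) as fh:
        s = json.load(fh)
    lines = ["# Analysis run report", ""]

    tf = s.get("threshold_fractions")
    if tf:
        lines.append("## Response statistics")
        for thr, d in sorted(tf.items(), key=lambda kv: float(kv[0])):
            lines.append(f"- fraction of class-odor pairs ≥ {thr} spikes: "
                         f"{d['count']}/{d['total']} = {100 * d['fraction']:.1f}%")
    sc = s.get("sister_correlation")
    if sc and sc["median_same_glomerulus_r"] is not None:
        lines.append(f"- sister-neuron r (median): same glomerulus "
                     f"{sc['median_same_glomerulus_r']:.3f} (n={sc['n_same']}), "
                     f"different {sc['median_different_glomerulus_r']:.3f} "
                     f"(n={sc['n_diff']}), rank-sum p = {sc['ranksum_p']:.2e}")
    oc = s.get("osn_pn_correlation")
    if oc:
        lines += ["", "## OSN → PN transformation",
                  f"- per-glomerulus Pearson r = {oc['mean_r']:.2f} ± {oc['sd_r']:.2f} "
                  f"(n = {oc['n']})",
                  f"- pairing-shuffle control: r = {oc['shuffled_mean_r']:.2f} ± "
                  f"{oc['shuffled_sd_r']:.3f}"]
    os_ = s.get("odor_space")
    if os_:
        lines += ["", "## Odor space",
                  f"- clusters at the fixed cut: {os_['n_clusters']} "
                  f"(sizes {os_['cluster_sizes']}), ARI vs planted groups = "
                  f"{os_['ari_vs_planted']:.2f}",
                  f"- PC1 {os_['pc1_variance_pct']:.1f}%, PC2 "
                  f"{os_['pc2_variance_pct']:.1f}% of variance",
                  f"- ANOSIM on valence: R = {os_['anosim_R']:.2f}, "
                  f"p = {os_['anosim_p']:.2e}",
                  f"- anatomy–function correlation r = {os_['anatomy_function_r']:.3f} "
                  f"(shuffle {os_['anatomy_function_shuffle'][0]:.3f} ± "
                  f"{os_['anatomy_function_shuffle'][1]:.3f})"]
    maps = s.get("maps")
    if maps:
        lines += ["", "## Functional maps"]
        for region, d in maps.items():
            lines.append(f"- {region}: {d['n_clusters']} map clusters, "
                         f"ARI vs valence = {d['ari_vs_valence']:.2f}")
    else:
        lines += ["", "## Functional maps", "- stage absent"]
    tp = s.get("temporal")
    if tp:
        lines += ["", "## Temporal dynamics",
                  f"- inter-odor separation peaks at "
                  f"{1000 * tp['separation_peak_time_s']:.0f} ms after onset"]
    text = "\n".join(lines) + "\n"
    with open(run_dir / "report.md", "w") as fh:
        fh.write(text)
    return text
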