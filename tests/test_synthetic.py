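"""The synthetic-data generator: determinism, planted structure, realism."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import olfmap as om
from olfmap.morphology import region_box
from olfmap.synthetic import (default_arbor_specs, derive_osn_matrix,
                              generate_atlas, generate_model, generate_panel,
                              generate_skeletons, simulate_spike_trains,
                              skeletons_by_class)


class TestGeneratePanel:
    def test_counts_match_arguments(self):
        panel = generate_panel(8, 9, seed=1)
        assert panel.n_odors == 17
        assert (panel.valence == "attractive").sum() == 8
        assert (panel.valence == "aversive").sum() == 9

    def test_deterministic(self):
        a, b = generate_panel(8, 9, seed=1), generate_panel(8, 9, seed=1)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            generate_panel(0, 0, seed=1)

    def test_both_solvents_present(self):
        panel = generate_panel(8, 9, seed=1)
        assert set(panel.frame["solvent"]) == {"mineral_oil", "water"}


class TestGenerateModel:
    @staticmethod
    def _group_cosine_means(model):
        rows = model.mean_rate.to_numpy()
        sim = 1 - squareform(pdist(rows, "cosine"))
        groups = np.array([model.group_of_class[c] for c in model.mean_rate.index])
        same = sim[np.equal.outer(groups, groups) & ~np.eye(len(groups), dtype=bool)]
        diff = sim[~np.equal.outer(groups, groups)]
        return same.mean(), diff.mean()

    def test_gain_creates_within_group_similarity(self, small_panel):
        model = generate_model(small_panel, n_classes=15, n_groups=3,
                               within_group_gain=10.0, seed=4)
        same, diff = self._group_cosine_means(model)
        assert same > diff

    def test_unit_gain_plants_no_structure(self, small_panel):
        sames, diffs = [], []
        for seed in range(10):
            model = generate_model(small_panel, n_classes=15, n_groups=3,
                                   within_group_gain=1.0, seed=seed)
            s, d = self._group_cosine_means(model)
            sames.append(s)
            diffs.append(d)
        assert np.mean(sames) == pytest.approx(np.mean(diffs), abs=0.05)

    def test_deterministic_and_nonnegative(self, small_panel):
        a = generate_model(small_panel, n_classes=10, seed=2)
        b = generate_model(small_panel, n_classes=10, seed=2)
        pd.testing.assert_frame_equal(a.mean_rate, b.mean_rate)
        assert (a.mean_rate.to_numpy() >= 0).all()

    def test_invalid_group_count_rejected(self, small_panel):
        with pytest.raises(ValueError):
            generate_model(small_panel, n_classes=3, n_groups=5, seed=0)


class TestSimulateSpikeTrains:
    def test_baseline_rate_recovered_without_stimulus(self, small_panel):
        model = generate_model(small_panel, n_classes=1, n_groups=1, seed=0)
        model.mean_rate.iloc[:, :] = 0.0
        trains = simulate_spike_trains(model, n_trials=50,
                                       n_sisters_per_class=1, seed=0)
        counts = [np.sum((r.spikes >= 0.05) & (r.spikes < 1.05))
                  for r in trains.records.itertuples()]
        mean = np.mean(counts)
        se = np.sqrt(model.baseline_rate / len(counts))
        assert abs(mean - model.baseline_rate) < 3 * se

    def test_psth_peaks_near_150ms_for_strong_responses(self, small_panel):
        model = generate_model(small_panel, n_classes=1, n_groups=1, seed=1)
        model.mean_rate.iloc[:, :] = 120.0  # strong transient
        trains = simulate_spike_trains(model, n_trials=60,
                                       n_sisters_per_class=1, seed=1)
        tensor = om.psth(trains, bin_width=0.05)
        mean_over_odors = tensor.rates[:, 0, :].mean(axis=1)
        peak = tensor.bin_centers[int(np.argmax(mean_over_odors))]
        assert 0.10 <= peak <= 0.20

    def test_zero_trials_rejected(self, small_model):
        with pytest.raises(ValueError):
            simulate_spike_trains(small_model, n_trials=0)

    def test_deterministic(self, small_model):
        a = simulate_spike_trains(small_model, n_trials=1,
                                  n_sisters_per_class=1, seed=9)
        b = simulate_spike_trains(small_model, n_trials=1,
                                  n_sisters_per_class=1, seed=9)
        for ra, rb in zip(a.records.spikes, b.records.spikes):
            assert np.array_equal(ra, rb)

    def test_mean_rate_recovered_in_window(self, small_panel):
        model = generate_model(small_panel, n_classes=1, n_groups=1, seed=3)
        model.mean_rate.iloc[:, :] = 40.0
        trains = simulate_spike_trains(model, n_trials=60,
                                       n_sisters_per_class=1, seed=3)
        m = om.build_response_matrix(trains, aggregation="mean")
        expected = 40.0
        # trial noise (sd 0.2) dominates the Monte-Carlo error here
        n_obs = 60
        se = expected * model.trial_sd / np.sqrt(n_obs * small_panel.n_odors)
        assert m.values.mean() == pytest.approx(expected, abs=4 * se + 2.0)


class TestGenerateAtlas:
    @staticmethod
    def _within_between(model, atlas):
        d = squareform(pdist(atlas.centroids))
        groups = atlas.frame["group"].to_numpy()
        same = np.equal.outer(groups, groups) & ~np.eye(len(groups), dtype=bool)
        return d[same].mean(), d[~np.equal.outer(groups, groups)].mean()

    def test_full_clustering_separates_groups(self, small_model):
        atlas = generate_atlas(small_model, spatial_clustering=1.0, seed=2)
        w, b = self._within_between(small_model, atlas)
        assert w < b

    def test_no_clustering_no_structure(self, small_model):
        # permutation test on the within-between gap at clustering = 0
        atlas = generate_atlas(small_model, spatial_clustering=0.0, seed=2)
        w, b = self._within_between(small_model, atlas)
        gap = b - w
        rng = np.random.default_rng(0)
        groups = atlas.frame["group"].to_numpy().copy()
        d = squareform(pdist(atlas.centroids))
        null = []
        for _ in range(500):
            g = rng.permutation(groups)
            same = np.equal.outer(g, g) & ~np.eye(len(g), dtype=bool)
            null.append(d[~np.equal.outer(g, g)].mean() - d[same].mean())
        p = (1 + np.sum(np.asarray(null) >= gap)) / 501
        assert p > 0.05

    def test_deterministic(self, small_model):
        a = generate_atlas(small_model, 0.7, seed=5)
        b = generate_atlas(small_model, 0.7, seed=5)
        pd.testing.assert_frame_equal(a.frame, b.frame)


class TestGenerateSkeletons:
    def test_valid_swc_with_one_root(self, small_model, tmp_path):
        specs = default_arbor_specs(small_model, seed=1)
        skels = generate_skeletons(small_model, specs, seed=1)
        assert len(skels) == 2 * len(small_model.class_ids)
        sk = skels[0]
        path = tmp_path / "s.swc"
        om.write_swc(sk, path)
        back = om.read_swc(path)
        assert (back.parent_ids == -1).sum() == 1

    def test_byte_identical_under_fixed_seed(self, small_model, tmp_path):
        specs = default_arbor_specs(small_model, seed=1)
        for tag in ("a", "b"):
            skels = generate_skeletons(small_model, specs, seed=42)
            om.write_swc(skels[0], tmp_path / f"{tag}.swc")
        assert (tmp_path / "a.swc").read_bytes() == (tmp_path / "b.swc").read_bytes()

    def test_zero_spread_collapses_onto_locus_line(self, small_model):
        from olfmap.synthetic import ArborSpec
        _, size = region_box("LH")
        locus = tuple(size * 0.5)
        spec = ArborSpec(region="LH", target_locus=locus, spread_sd=0.0,
                         n_branch_points=5, segment_length_mean=2.0)
        specs = {c: (ArborSpec(region="calyx",
                               target_locus=tuple(region_box("calyx")[1] * 0.5),
                               spread_sd=0.0), spec)
                 for c in small_model.class_ids}
        skels = generate_skeletons(small_model, specs, seed=0)
        lh = [s for s in skels if (s.region_of_node == "LH").mean() > 0.5][0]
        root = lh.xyz[lh.parent_ids == -1][0]
        line = np.asarray(locus) - root
        line = line / np.linalg.norm(line)
        rel = lh.xyz - root
        perp = np.linalg.norm(rel - np.outer(rel @ line, line), axis=1)
        assert np.all(perp <= 3 * spec.segment_length_mean + 1e-9)

    def test_locus_outside_box_rejected(self):
        from olfmap.synthetic import ArborSpec
        with pytest.raises(ValueError, match="outside"):
            ArborSpec(region="LH", target_locus=(999.0, 0.0, 0.0))

    def test_lh_loci_structured_by_group(self, small_model):
        specs = default_arbor_specs(small_model, seed=3)
        skels = generate_skeletons(small_model, specs, seed=3)
        by_class = skeletons_by_class(skels, "LH")
        group_of = small_model.group_of_class
        cents = {c: s[0].xyz.mean(axis=0) for c, s in by_class.items()}
        classes = list(cents)
        d, same = [], []
        for i, a in enumerate(classes):
            for b in classes[i + 1:]:
                d.append(np.linalg.norm(cents[a] - cents[b]))
                same.append(group_of[a] == group_of[b])
        d, same = np.asarray(d), np.asarray(same)
        assert d[same].mean() < d[~same].mean()


class TestDeriveOsn:
    def test_correlated_with_source(self, small_model):
        pn = small_model.response_matrix()
        osn = derive_osn_matrix(pn, noise_frac=0.5, seed=0)
        table, summary = om.osn_pn_correlation(pn, osn)
        assert summary["mean_r"] > 0.5
        assert (osn.values >= 0).all()
        assert list(osn.row_meta["glomerulus"]) == list(pn.row_meta["glomerulus"])
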