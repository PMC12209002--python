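"""CAP pipeline: normalization, frame selection, clustering, consensus."""

import itertools

import numpy as np
import pytest

from capdyn.caps import (
    FrameSelectionPolicy,
    assign_states,
    consensus_select_k,
    kmeans_caps,
    kmeans_correlation,
    match_maps,
    select_frames,
    zscore_run,
)
from capdyn.io import ParcelTimeSeries, SeedDefinition
from capdyn.synthetic import default_state_model, generate_subject_timeseries, sample_state_sequence


class TestZscore:
    def test_closed_form(self):
        ts = ParcelTimeSeries(values=np.array([[1.0], [2.0], [3.0]]))
        z = zscore_run(ts)
        assert np.allclose(z.values[:, 0], [-1.2247448, 0.0, 1.2247448], atol=1e-6)

    def test_idempotence(self, rng):
        ts = ParcelTimeSeries(values=rng.standard_normal((40, 5)))
        once = zscore_run(ts)
        twice = zscore_run(once)
        assert np.allclose(once.values, twice.values, atol=1e-12)

    def test_censored_frame_excluded_from_stats(self):
        mask = np.array([True, False, True])
        ts = ParcelTimeSeries(values=np.array([[1.0], [9.0], [3.0]]), censor_mask=mask)
        z = zscore_run(ts)
        # stats from {1, 3}: mean 2, population SD 1
        assert np.allclose(z.values[mask, 0], [-1.0, 1.0])
        assert z.values[1, 0] == 9.0  # untouched

    def test_zero_variance_parcel_named(self):
        vals = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        ts = ParcelTimeSeries(values=vals, parcel_ids=["a", "flat"])
        with pytest.raises(ValueError, match="flat"):
            zscore_run(ts)
        with pytest.warns(UserWarning, match="flat"):
            z = zscore_run(ts, drop_constant=True)
        assert z.n_parcels == 1


class TestFrameSelection:
    def _series(self, seedvals, n_other=3):
        t = len(seedvals)
        vals = np.column_stack(
            [np.asarray(seedvals, dtype=float)]
            + [np.linspace(-1, 1, t) * (j + 1) for j in range(n_other)]
        )
        return ParcelTimeSeries(values=vals)

    def test_top_fraction_counts(self, rng):
        ts = ParcelTimeSeries(values=rng.standard_normal((100, 4)))
        z = zscore_run(ts)
        seed = SeedDefinition(name="s", parcel_indices=np.array([0, 1]))
        act, deact, _ = select_frames(z, seed, FrameSelectionPolicy(fraction=0.15))
        assert act.size == 15
        assert deact.size == 0
        assert np.all(np.diff(act) > 0)

    def test_z_threshold_both_polarity(self):
        vals = np.zeros((4, 2))
        vals[:, 0] = [3.0, 0.0, 0.0, -3.0]
        vals[:, 1] = [0.1, -0.1, 0.2, -0.2]
        ts = ParcelTimeSeries(values=vals)
        seed = SeedDefinition(name="s", parcel_indices=np.array([0]))
        # seed column is already symmetric; threshold between 0 and max z
        act, deact, z = select_frames(
            ts, seed, FrameSelectionPolicy(mode="z_threshold", z_cut=1.0, polarity="both")
        )
        assert act.tolist() == [0]
        assert deact.tolist() == [3]

    def test_censored_frames_never_selected(self, rng):
        vals = rng.standard_normal((50, 3))
        mask = np.ones(50, dtype=bool)
        top = np.argmax(vals[:, 0])
        mask[top] = False
        ts = ParcelTimeSeries(values=vals, censor_mask=mask)
        z = zscore_run(ts)
        seed = SeedDefinition(name="s", parcel_indices=np.array([0]))
        act, _, _ = select_frames(z, seed, FrameSelectionPolicy(fraction=0.5))
        assert top not in act

    def test_noiseless_selection_matches_planted_states(self):
        """With no noise, a z-threshold cleanly separates CAP from baseline frames."""
        model = default_state_model(noise_sd=0.0, amplitude_sd=0.0, n_parcels=30,
                                    n_seed_parcels=4)
        seq = sample_state_sequence(model.transition_matrix, 200, rng_seed=2)
        ts = generate_subject_timeseries(model, seq, rng_seed=1)
        # baseline frames are exactly zero -> constant parcels; add tiny jitter
        rng = np.random.default_rng(0)
        ts = ParcelTimeSeries(values=ts.values + 1e-9 * rng.standard_normal(ts.values.shape))
        z = zscore_run(ts)
        seed = SeedDefinition(name="FPN", parcel_indices=model.seed_parcels)
        act, _, _ = select_frames(
            z, seed, FrameSelectionPolicy(mode="z_threshold", z_cut=0.5)
        )
        assert set(act) == set(np.flatnonzero(seq.labels > 0))


def partition_objective(frames, labels):
    """Total 1 - Pearson(frame, its cluster centroid) for a fixed partition."""
    x = frames - frames.mean(axis=1, keepdims=True)
    x = x / np.linalg.norm(x, axis=1, keepdims=True)
    obj = 0.0
    for c in np.unique(labels):
        members = x[labels == c]
        m = members.sum(axis=0)
        norm = np.linalg.norm(m)
        if norm == 0:
            return np.inf
        obj += np.sum(1.0 - members @ (m / norm))
    return obj


class TestKmeans:
    def test_separable_two_cluster_recovery(self, rng):
        a = rng.standard_normal(20)
        b = rng.standard_normal(20)
        frames = np.vstack([a] * 10 + [b] * 10) + 0.0
        caps, labels = kmeans_caps(frames, 2, rng_seed=0)
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[10]
        _, corrs = match_maps(np.vstack([a, b]), caps.maps)
        assert np.allclose(corrs, 1.0)

    def test_k1_grand_mean(self, rng):
        frames = rng.standard_normal((12, 6))
        caps, labels = kmeans_caps(frames, 1, rng_seed=0)
        assert np.allclose(caps.maps[0], frames.mean(axis=0))
        assert set(labels) == {1}

    def test_matches_bruteforce_partition(self, rng):
        """6-frame instances: k-means finds the global optimum over all 2-partitions."""
        for trial in range(10):
            frames = rng.standard_normal((6, 3))
            _, labels = kmeans_caps(frames, 2, rng_seed=trial, n_init=20)
            got = partition_objective(frames, np.asarray(labels))
            best = np.inf
            for assign in itertools.product([0, 1], repeat=6):
                if len(set(assign)) < 2:
                    continue
                best = min(best, partition_objective(frames, np.array(assign)))
            assert got == pytest.approx(best, abs=1e-9)

    def test_caps_ordered_by_member_count(self, rng):
        a, b = rng.standard_normal(10), rng.standard_normal(10)
        frames = np.vstack([a] * 12 + [b] * 5)
        caps, labels = kmeans_caps(frames, 2, rng_seed=0)
        assert caps.member_counts.tolist() == [12, 5]
        assert (labels[:12] == 1).all()

    def test_n_less_than_k_errors(self, rng):
        with pytest.raises(ValueError, match="at least"):
            kmeans_correlation(rng.standard_normal((3, 4)), 4, rng_seed=0)


class TestConsensus:
    def test_four_planted_clusters_selects_four(self, rng):
        centers = rng.standard_normal((4, 20)) * 3
        frames = np.vstack([
            centers[i] + 0.15 * rng.standard_normal((25, 20)) for i in range(4)
        ])
        report = consensus_select_k(frames, list(range(2, 9)), n_resamples=40,
                                    subsample_fraction=0.8, rng_seed=0)
        assert report.selected_k == 4
        assert report.pac[4] <= min(report.pac.values()) + 1e-12

    def test_identical_frames_degenerate_tiebreak(self, rng):
        frames = np.tile(rng.standard_normal(10), (20, 1))
        frames = frames + 1e-12 * rng.standard_normal(frames.shape)
        report = consensus_select_k(frames, [2, 3, 4], n_resamples=10, rng_seed=0)
        assert report.selected_k == 2  # all PAC equal -> smaller k wins

    def test_within_cluster_consensus_exceeds_between(self, rng):
        centers = rng.standard_normal((3, 15)) * 3
        frames = np.vstack([
            centers[i] + 0.2 * rng.standard_normal((20, 15)) for i in range(3)
        ])
        report = consensus_select_k(frames, [3], n_resamples=50, rng_seed=1)
        assert report.pac[3] < 0.05
        assert report.mean_consensus[3] < 1.0  # between-cluster pairs dilute the mean

    def test_invalid_k_range(self, rng):
        with pytest.raises(ValueError, match="k_range"):
            consensus_select_k(rng.standard_normal((10, 4)), [2, 8], n_resamples=5)


class TestAssignment:
    def _planted(self, noise=0.0, t=200, seed=5):
        model = default_state_model(noise_sd=noise, amplitude_sd=0.0, n_parcels=30,
                                    n_seed_parcels=4)
        seq = sample_state_sequence(model.transition_matrix, t, rng_seed=seed)
        ts = generate_subject_timeseries(model, seq, rng_seed=seed + 1)
        rng = np.random.default_rng(0)
        ts = ParcelTimeSeries(values=ts.values + 1e-9 * rng.standard_normal(ts.values.shape))
        return model, seq, zscore_run(ts)

    def test_noiseless_recovery_exact(self):
        from capdyn.caps import CAPSet

        model, seq, z = self._planted()
        seed = SeedDefinition(name="FPN", parcel_indices=model.seed_parcels)
        policy = FrameSelectionPolicy(mode="z_threshold", z_cut=0.5)
        caps = CAPSet(maps=model.maps, k=model.n_states)
        rec = assign_states(z, caps, policy, seed)
        assert np.array_equal(rec.labels, seq.labels)

    def test_frame_equal_to_map_gets_its_label(self):
        from capdyn.caps import CAPSet

        model, _, _ = self._planted()
        caps = CAPSet(maps=model.maps, k=4)
        vals = np.vstack([model.maps[1], np.zeros(30)])
        ts = ParcelTimeSeries(values=vals + 1e-12)
        seed = SeedDefinition(name="FPN", parcel_indices=model.seed_parcels)
        rec = assign_states(
            ts, caps, FrameSelectionPolicy(mode="z_threshold", z_cut=0.5), seed
        )
        assert rec.labels[0] == 2

    def test_tie_goes_to_lower_cap_index(self):
        from capdyn.caps import CAPSet

        # palindromic frame is exactly equally correlated with a map and
        # its mirror (small dyadic values keep float arithmetic exact)
        frame = np.array([1.0, 2.0, 2.0, 1.0])
        m1 = np.array([0.0, 1.0, 2.0, 5.0])
        maps = np.vstack([m1, m1[::-1]])
        caps = CAPSet(maps=maps, k=2)
        vals = np.vstack([frame, [-5.0, -5.0, -5.0, -4.0]])
        ts = ParcelTimeSeries(values=vals)
        seed = SeedDefinition(name="s", parcel_indices=np.arange(4))
        seq = assign_states(
            ts, caps, FrameSelectionPolicy(mode="top_fraction", fraction=0.5), seed
        )
        assert seq.labels[0] == 1  # lower CAP index wins the exact tie

    def test_label_permutation_invariance_of_metrics(self):
        """Relabeling planted states relabels recovered metrics identically."""
        from capdyn.caps import CAPSet
        from capdyn.dynamics import compute_metrics

        model, seq, z = self._planted(t=300)
        seed = SeedDefinition(name="FPN", parcel_indices=model.seed_parcels)
        policy = FrameSelectionPolicy(mode="z_threshold", z_cut=0.5)
        perm = np.array([2, 3, 0, 1])  # new order of the 4 maps
        caps_a = CAPSet(maps=model.maps, k=4)
        caps_b = CAPSet(maps=model.maps[perm], k=4)
        ma = compute_metrics(assign_states(z, caps_a, policy, seed), 2.0).set_index("state")
        mb = compute_metrics(assign_states(z, caps_b, policy, seed), 2.0).set_index("state")
        for new_pos, old_map in enumerate(perm):
            a = ma.loc[old_map + 1, ["occurrence", "resilience", "in_degree"]]
            b = mb.loc[new_pos + 1, ["occurrence", "resilience", "in_degree"]]
            assert np.allclose(a.to_numpy(dtype=float), b.to_numpy(dtype=float))
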