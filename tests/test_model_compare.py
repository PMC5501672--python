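"""Superposition, alignment-guided RMSD, equilibration and clustering."""

import numpy as np
import pytest

from conftest import quaternion_superpose_rmsd, random_proper_rotation
from porexlink.model_compare import (
    CorrespondenceMap,
    RMSDSeries,
    align_and_rmsd,
    cluster_frames,
    detect_equilibration,
    pairwise_rmsd_matrix,
    rmsd_timeseries,
    segment_rmsd,
    superpose,
)
from porexlink.structure_io import FrameEnsemble
from porexlink.synthetic_data import perturb_ensemble


class TestSuperpose:
    def test_self_fit_is_identity(self):
        A = np.random.default_rng(0).normal(size=(12, 3))
        s = superpose(A, A)
        assert s.rmsd <= 1e-8
        np.testing.assert_allclose(s.rotation, np.eye(3), atol=1e-9)

    def test_rigid_motion_recovered(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(10, 3))
        Q = random_proper_rotation(rng)
        B = A @ Q.T + rng.normal(size=3)
        s = superpose(A, B)
        assert s.rmsd <= 1e-8
        assert np.linalg.det(s.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_reflection_forbidden(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(10, 3))
        B = A.copy()
        B[:, 0] *= -1  # mirrored: cannot be reached by a proper rotation
        s = superpose(A, B)
        assert np.linalg.det(s.rotation) == pytest.approx(1.0, abs=1e-9)
        assert s.rmsd > 0.1

    def test_matches_quaternion_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            A = rng.normal(size=(10, 3))
            B = rng.normal(size=(10, 3))
            assert superpose(A, B).rmsd == pytest.approx(
                quaternion_superpose_rmsd(A, B), abs=1e-8
            )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(ValueError, match="collinear"):
            superpose(line, line)

    def test_rmsd_is_a_metric_on_superposed_frames(self):
        rng = np.random.default_rng(4)
        frames = rng.normal(size=(8, 15, 3))
        M = pairwise_rmsd_matrix(frames)
        assert np.allclose(M, M.T, atol=1e-9)
        assert np.all(np.diag(M) == 0)
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    assert M[i, j] <= M[i, k] + M[k, j] + 1e-6


class TestCorrespondence:
    def test_identity_map_self_rmsd_zero(self, open_channel):
        ens, _ = open_channel
        cmap = CorrespondenceMap.identity(ens)
        s = align_and_rmsd(ens, ens, cmap, selection="CA")
        assert s.rmsd <= 1e-8
        assert s.coverage == 1.0

    def test_alignment_handles_numbering_offset(self, open_channel):
        # same structure renumbered by +100: sequence alignment still pairs
        # every residue, so the fit is exact
        import copy

        ens, _ = open_channel
        shifted = copy.deepcopy(ens)
        shifted.atoms = shifted.atoms.assign(resnum=shifted.atoms["resnum"] + 100)
        cmap = CorrespondenceMap.from_structures(ens, shifted)
        assert cmap.coverage == pytest.approx(1.0)
        s = align_and_rmsd(ens, shifted, cmap, selection="CA")
        assert s.rmsd <= 1e-8

    def test_reversed_map_gives_identical_rmsd(self, open_channel, closed_channel):
        ens_a, _ = open_channel
        ens_b, _ = closed_channel
        cmap = CorrespondenceMap.from_structures(ens_a, ens_b)
        fwd = align_and_rmsd(ens_a, ens_b, cmap, selection="CA")
        back = align_and_rmsd(ens_b, ens_a, cmap.reversed(), selection="CA")
        assert fwd.rmsd == pytest.approx(back.rmsd, abs=1e-9)

    def test_one_to_one_enforced(self):
        with pytest.raises(ValueError, match="one-to-one"):
            CorrespondenceMap(pairs=[(("A", 1), ("B", 1)), (("A", 1), ("B", 2))])


class TestSegmentRmsd:
    def test_identical_structures_all_zero(self, open_channel, channel_segments):
        ens, _ = open_channel
        cmap = CorrespondenceMap.identity(ens)
        table = segment_rmsd(ens, ens, cmap, channel_segments, selection="CA").set_index("segment")
        assert (table["rmsd_global"] <= 1e-8).all()
        assert (table["rmsd_local"] <= 1e-8).all()

    def test_displaced_helix_detected_by_global_fit_only(self, open_channel, channel_segments):
        import copy

        ens, _ = open_channel
        moved = copy.deepcopy(ens)
        mask = moved.atoms["chain"].to_numpy() == "C"  # displace helix H3 rigidly
        moved.coords[:, mask] += np.array([5.0, 0.0, 0.0])
        cmap = CorrespondenceMap.identity(ens)
        table = segment_rmsd(ens, moved, cmap, channel_segments, selection="CA").set_index("segment")
        # the global fit absorbs a little of the shift, so ≈5 Å, not exactly 5
        assert table.loc["H3", "rmsd_global"] == pytest.approx(5.0, abs=1.0)
        assert table.loc["H3", "rmsd_local"] <= 1e-6  # internally rigid
        others = table.drop(index=["H3", "membrane"])
        assert (others["rmsd_global"] < 1.0).all()

    def test_local_fit_never_exceeds_global(self, open_channel, closed_channel, channel_segments):
        ens_a, _ = open_channel
        ens_b, _ = closed_channel
        cmap = CorrespondenceMap.identity(ens_a)
        table = segment_rmsd(ens_a, ens_b, cmap, channel_segments, selection="CA")
        assert (table["rmsd_local"] <= table["rmsd_global"] + 1e-9).all()


class TestTimeSeries:
    def test_static_ensemble_all_zero(self, open_channel):
        ens0, _ = open_channel
        ens = perturb_ensemble(ens0, 0.0, 5, seed=0)
        series = rmsd_timeseries(ens, "first-frame")
        assert np.all(series.rmsd <= 1e-8)

    def test_converging_drift_decreases_toward_last_frame(self, open_channel):
        ens0, _ = open_channel
        ens = perturb_ensemble(ens0, 0.0, 10, seed=0)
        drift = np.linspace(3.0, 0.0, 10)
        rng = np.random.default_rng(5)
        direction = rng.normal(size=ens0.coords[0].shape)
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        ens.coords = ens.coords + drift[:, None, None] * direction[None]
        series = rmsd_timeseries(ens, "last-frame")
        assert np.all(np.diff(series.rmsd) < 0)
        assert series.rmsd[-1] <= 1e-8

    def test_single_frame_rejected(self, open_channel):
        ens, _ = open_channel
        with pytest.raises(ValueError):
            rmsd_timeseries(ens, "first-frame")


def _plateau_series(k, n=150, noise=0.05, seed=0):
    rng = np.random.default_rng(seed)
    v = np.where(np.arange(n) < k, np.arange(n) * 3.0 / max(k, 1), 3.0)
    return RMSDSeries(frame_labels=list(range(n)), rmsd=np.abs(v + rng.normal(0, noise, n)))


class TestEquilibration:
    def test_flat_series_detected_at_frame_zero(self):
        series = RMSDSeries(frame_labels=list(range(60)), rmsd=np.full(60, 2.0))
        assert detect_equilibration(series, window=10) == 0

    @pytest.mark.parametrize("k", [20, 50, 80])
    def test_planted_plateau_detected_within_one_window(self, k):
        window = 20
        for seed in range(10):
            onset = detect_equilibration(_plateau_series(k, seed=seed), window=window)
            assert onset is not None
            assert abs(onset - k) <= window

    def test_monotone_ramp_never_equilibrates(self):
        series = RMSDSeries(frame_labels=list(range(100)),
                            rmsd=np.linspace(0, 30, 100))
        assert detect_equilibration(series, window=20) is None

    def test_window_bounds_validated(self):
        series = RMSDSeries(frame_labels=[0, 1], rmsd=[0.0, 0.1])
        with pytest.raises(ValueError):
            detect_equilibration(series, window=10)


def _planted_ensemble(base_ensemble, n_conformers=5, frames_per=20, noise=0.15, seed=0):
    """Frames drawn from well-separated rigid-jitter conformers + small noise."""
    conformers = [
        perturb_ensemble(base_ensemble, 3.0, 1, seed=100 + c, mode="rigid-helix-jitter")
        for c in range(n_conformers)
    ]
    labels = np.repeat(np.arange(n_conformers), frames_per)
    rng = np.random.default_rng(seed)
    coords = np.concatenate(
        [
            perturb_ensemble(conf, noise, frames_per, seed=int(rng.integers(2**31))).coords
            for conf in conformers
        ]
    )
    ens = FrameEnsemble(atoms=base_ensemble.atoms, coords=coords,
                        frame_labels=list(range(len(labels))))
    return ens, labels


class TestClustering:
    def test_identical_frames_one_cluster(self, open_channel):
        ens0, _ = open_channel
        ens = perturb_ensemble(ens0, 0.0, 6, seed=0)
        result = cluster_frames(ens, threshold=2.0)
        assert result.n_clusters == 1
        assert set(result.assignment) == {0}

    def test_threshold_above_max_rmsd_one_cluster(self, open_channel):
        ens0, _ = open_channel
        ens = perturb_ensemble(ens0, 0.5, 6, seed=1)
        result = cluster_frames(ens, threshold=1e6)
        assert result.n_clusters == 1

    def test_centroid_belongs_to_cluster(self, open_channel):
        ens0, _ = open_channel
        ens, _ = _planted_ensemble(ens0, n_conformers=3, frames_per=5)
        result = cluster_frames(ens, threshold=2.0)
        for c, centroid in enumerate(result.centroids):
            assert result.assignment[centroid] == c

    def test_relabelling_frames_permutes_clusters_only(self, open_channel):
        ens0, _ = open_channel
        ens, _ = _planted_ensemble(ens0, n_conformers=3, frames_per=4, seed=3)
        result = cluster_frames(ens, threshold=2.0)
        perm = np.random.default_rng(0).permutation(ens.n_frames)
        shuffled = ens.subset_frames(perm)
        result2 = cluster_frames(shuffled, threshold=2.0)
        # same partition up to cluster-id permutation
        for i in range(ens.n_frames):
            for j in range(ens.n_frames):
                same_a = result.assignment[perm[i]] == result.assignment[perm[j]]
                same_b = result2.assignment[i] == result2.assignment[j]
                assert same_a == same_b

    def test_two_state_mixture_weight_recovered(self, open_channel):
        # 60 frames at weights (0.3, 0.7): the larger cluster's size must fall
        # inside the binomial 95% interval around 42
        ens0, _ = open_channel
        conf_a = perturb_ensemble(ens0, 3.0, 1, seed=500, mode="rigid-helix-jitter")
        conf_b = perturb_ensemble(ens0, 3.0, 1, seed=501, mode="rigid-helix-jitter")
        n, w = 60, 0.7
        rng = np.random.default_rng(0)
        pick = rng.random(n) < w
        frames = np.where(
            pick[:, None, None],
            perturb_ensemble(conf_b, 0.2, n, seed=7).coords,
            perturb_ensemble(conf_a, 0.2, n, seed=8).coords,
        )
        ens = FrameEnsemble(atoms=ens0.atoms, coords=frames, frame_labels=list(range(n)))
        result = cluster_frames(ens, threshold=2.0)
        assert result.n_clusters == 2
        # the partition reproduces the planted membership exactly ...
        sizes = sorted(len(result.members(c)) for c in range(2))
        assert sizes == sorted([int(pick.sum()), n - int(pick.sum())])
        # ... and the big-cluster size estimates w within the binomial 95% CI
        big = max(sizes)
        sd = np.sqrt(n * w * (1 - w))
        assert n * w - 1.96 * sd <= big <= n * w + 1.96 * sd
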