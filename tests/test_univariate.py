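"""Two-gamma HRF, GLM design/fit, contrasts, FDR maps, preference maps."""

import numpy as np
import pytest

from imdec.containers import BOLDDataset, StatMap
from imdec.paradigm import ParadigmSpec, generate_events
from imdec.preprocess import zscore_runs
from imdec.univariate import (
    VoxelGLM,
    build_design,
    fdr_threshold_t,
    preference_map,
    two_gamma_hrf,
)

from conftest import make_informative_dataset


class TestTwoGammaHrf:
    def test_zero_at_onset(self):
        assert two_gamma_hrf(np.array([0.0]))[0] == pytest.approx(0.0)

    def test_peak_near_five_seconds_and_unit_height(self):
        t = np.arange(0.0, 32.0, 0.1)
        h = two_gamma_hrf(t)
        assert t[np.argmax(h)] == pytest.approx(5.0, abs=0.2)
        assert h.max() == pytest.approx(1.0, abs=1e-6)

    def test_late_tail_is_negligible(self):
        assert abs(two_gamma_hrf(np.array([30.0]))[0]) < 0.01

    def test_undershoot_is_negative(self):
        h = two_gamma_hrf(np.array([15.0]))
        assert h[0] < 0


class TestBuildDesign:
    def test_single_trial_column_matches_convolution_oracle(self):
        import pandas as pd

        from imdec.containers import EventTable

        nv = 30
        events = EventTable(
            pd.DataFrame([(1, 8.0, 6.0, 1), (1, 30.0, 6.0, 2),
                          (1, 40.0, 6.0, 3), (1, 50.0, 6.0, 4)],
                         columns=["run", "onset", "duration", "condition"]),
            run_volumes=(nv,),
        )
        design = build_design(events, tr_s=2.0, drift=False)
        hrf = two_gamma_hrf(np.arange(0.0, 34.0, 2.0))
        box = np.zeros(nv)
        box[4:7] = 1.0  # onset 8 s, duration 6 s at TR 2
        expected = np.array(
            [sum(box[s] * (hrf[t - s] if 0 <= t - s < len(hrf) else 0.0)
                 for s in range(nv)) for t in range(nv)]
        )
        got = design.matrix[:, design.condition_column(1)]
        assert np.allclose(got, expected, atol=1e-12)

    def test_missing_condition_makes_design_rank_deficient(self, tiny_spec):
        events = generate_events(tiny_spec)
        frame = events.frame[events.frame["condition"] != 3]
        from imdec.containers import EventTable

        crippled = EventTable(frame, run_volumes=events.run_volumes)
        with pytest.raises(ValueError, match="rank"):
            build_design(crippled, tr_s=2.0)

    def test_full_design_has_expected_columns(self, tiny_spec):
        events = generate_events(tiny_spec)
        design = build_design(events, tr_s=2.0, drift=True)
        # 4 conditions + 2 run intercepts + 2 run drifts
        assert design.matrix.shape[1] == 8
        assert design.rank == 8
        assert design.n_volumes == sum(events.run_volumes)


class TestVoxelGLM:
    @pytest.fixture(scope="class")
    @staticmethod
    def noise_free():
        spec = ParadigmSpec(n_runs=2, blocks_per_run=3, seed=13)
        # lexicographic order so GLM columns align with informative indices
        informative = np.array([[0, 0, 0], [0, 1, 0], [1, 0, 0], [1, 1, 0]])
        events, truth, bold = make_informative_dataset(
            spec, (2, 2, 1), informative, amplitude=2.0, noise_sd=0.0, seed=1
        )
        design = build_design(events, spec.tr_s, drift=False)
        return events, truth, bold, design

    def test_noise_free_betas_recover_ground_truth(self, noise_free):
        events, truth, bold, design = noise_free
        fit = VoxelGLM(bold, design).fit()
        # voxel v responds to condition v+1 with amplitude 2
        for v in range(4):
            expected = np.zeros(4)
            expected[v] = 2.0
            got = fit.beta[:4, v]
            assert np.allclose(got, expected, atol=1e-8)

    def test_betas_are_linear_in_amplitude(self, noise_free):
        events, truth, bold, design = noise_free
        spec = ParadigmSpec(n_runs=2, blocks_per_run=3, seed=13)
        _, _, double = make_informative_dataset(
            spec, (2, 2, 1), truth.informative_voxels, amplitude=4.0,
            noise_sd=0.0, seed=1,
        )
        a = VoxelGLM(bold, design).fit()
        b = VoxelGLM(double, design).fit()
        assert np.allclose(2.0 * a.beta[:4], b.beta[:4], atol=1e-8)

    def test_residuals_orthogonal_to_design(self, noise_free):
        events, truth, bold, design = noise_free
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(design.n_volumes, 5))
        fit = VoxelGLM(Y, design).fit()
        resid = Y - design.matrix @ fit.beta
        assert np.allclose(design.matrix.T @ resid, 0.0, atol=1e-8)

    def test_null_t_statistics_are_centrally_distributed(self, noise_free):
        events, truth, bold, design = noise_free
        rng = np.random.default_rng(42)
        Y = rng.normal(size=(design.n_volumes, 4000))
        fit = VoxelGLM(Y, design).fit()
        t = fit.one_vs_all_t(1)
        # central t with large dof: mean ~ 0, SD ~ 1
        assert abs(t.mean()) < 0.05
        assert t.std() == pytest.approx(1.0, abs=0.05)

    def test_selective_voxel_has_positive_preferred_negative_other_t(self):
        spec = ParadigmSpec(n_runs=2, blocks_per_run=4, seed=17)
        events, truth, bold = make_informative_dataset(
            spec, (2, 1, 1), np.array([[0, 0, 0]]), amplitude=3.0,
            noise_sd=0.5, seed=5,
        )
        design = build_design(events, spec.tr_s)
        fit = VoxelGLM(bold, design).fit()
        t1 = fit.one_vs_all_t(1)[0]
        others = [fit.one_vs_all_t(c)[0] for c in (2, 3, 4)]
        assert t1 > 5.0
        assert all(t < 0 for t in others)

    def test_label_permutation_permutes_t_maps(self):
        """Relabelling conditions in the events permutes the one-vs-all
        t-values identically (contrast symmetry)."""
        from imdec.containers import EventTable

        spec = ParadigmSpec(n_runs=2, blocks_per_run=3, seed=13)
        informative = np.array([[0, 0, 0], [0, 1, 0], [1, 0, 0], [1, 1, 0]])
        events, truth, bold = make_informative_dataset(
            spec, (2, 2, 1), informative, amplitude=2.0, noise_sd=0.5, seed=1
        )
        design = build_design(events, 2.0, drift=False)
        mapping = {1: 2, 2: 1, 3: 4, 4: 3}
        frame = events.frame.copy()
        frame["condition"] = frame["condition"].map(mapping)
        swapped = EventTable(frame, run_volumes=events.run_volumes)
        design_swapped = build_design(swapped, 2.0, drift=False)
        a = VoxelGLM(bold, design).fit()
        b = VoxelGLM(bold, design_swapped).fit()
        for orig, new in mapping.items():
            assert np.allclose(a.one_vs_all_t(orig), b.one_vs_all_t(new), atol=1e-8)


class TestFdrThresholdT:
    def test_all_zero_t_gives_empty_mask(self):
        mask, _ = fdr_threshold_t(np.zeros(50), dof=100)
        assert not mask.any()

    def test_single_extreme_voxel_survives_among_nulls(self):
        rng = np.random.default_rng(0)
        t = rng.standard_t(100, size=200) * 0.5
        t[7] = 20.0
        mask, p_adj = fdr_threshold_t(t, dof=100, q=0.05)
        assert mask[7]
        assert mask.sum() <= 3  # essentially only the planted voxel

    def test_invariant_to_voxel_ordering(self):
        rng = np.random.default_rng(3)
        t = rng.normal(size=100)
        t[[3, 50]] = [8.0, -9.0]
        mask, _ = fdr_threshold_t(t, dof=60)
        perm = rng.permutation(100)
        mask_perm, _ = fdr_threshold_t(t[perm], dof=60)
        assert np.array_equal(mask_perm, mask[perm])

    def test_null_false_positive_fraction_controlled(self):
        """On pure-noise t-values the average FDR-significant fraction
        stays at or below q over seeds."""
        fractions = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            t = rng.standard_t(80, size=500)
            mask, _ = fdr_threshold_t(t, dof=80, q=0.05)
            fractions.append(mask.mean())
        assert np.mean(fractions) <= 0.05


class TestPreferenceMap:
    @staticmethod
    def _tmap(values):
        return StatMap(np.asarray(values, float)[..., None, None], "t")

    def test_argmax_with_tie_to_lowest_label(self):
        tmaps = {
            1: self._tmap([3.0, 1.0]),
            2: self._tmap([1.0, 1.0]),
            3: self._tmap([0.0, 1.0]),
            4: self._tmap([-1.0, 0.5]),
        }
        sig = StatMap(np.ones((2, 1, 1)), "mask")
        pref = preference_map(tmaps, sig)
        assert pref.values[0, 0, 0] == 1.0  # clear argmax
        assert pref.values[1, 0, 0] == 1.0  # three-way tie -> lowest label

    def test_empty_mask_gives_empty_map(self):
        tmaps = {c: self._tmap([1.0, 2.0]) for c in (1, 2, 3, 4)}
        sig = StatMap(np.zeros((2, 1, 1)), "mask")
        pref = preference_map(tmaps, sig)
        assert np.all(np.isnan(pref.values))

    def test_shape_mismatch_rejected(self):
        tmaps = {c: self._tmap([1.0, 2.0]) for c in (1, 2, 3, 4)}
        sig = StatMap(np.ones((3, 1, 1)), "mask")
        with pytest.raises(ValueError, match="grid shape"):
            preference_map(tmaps, sig)

    def test_implanted_cluster_recovers_its_direction(self):
        """A direction-1 cluster should be labelled 1 at >= 90% of its
        FDR-significant voxels."""
        spec = ParadigmSpec(n_runs=2, blocks_per_run=5, seed=23)
        shape = (4, 4, 2)
        cluster = np.array([[i, j, 0] for i in (1, 2) for j in (1, 2)])
        events = generate_events(spec)
        from imdec.synth import GroundTruth, generate_bold

        amp = np.zeros((4, len(cluster)))
        amp[0] = 2.5  # all cluster voxels prefer direction 1
        truth = GroundTruth(informative_voxels=cluster, amplitude_matrix=amp,
                            noise_sd=0.8, seed=9)
        bold = generate_bold(events, truth, shape, spec)
        design = build_design(events, spec.tr_s)
        fit = VoxelGLM(bold, design).fit()
        tmaps = {c: fit.t_map(c) for c in (1, 2, 3, 4)}
        mask1, _ = fdr_threshold_t(fit.one_vs_all_t(1), fit.dof, q=0.05)
        sig = fit._to_map(mask1.astype(float), "mask")
        pref = preference_map(tmaps, sig)
        in_cluster = np.zeros(shape, bool)
        in_cluster[cluster[:, 0], cluster[:, 1], cluster[:, 2]] = True
        labels = pref.values[in_cluster & (sig.values > 0)]
        assert len(labels) >= 3
        assert np.mean(labels == 1.0) >= 0.9
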