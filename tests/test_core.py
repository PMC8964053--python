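"""Core microstate operations against brute-force and exhaustive oracles."""

import itertools

import numpy as np
import pytest

from microstates import core, synth
from microstates.types import (
    UNASSIGNED,
    EpochSet,
    GfpSeries,
    MicrostateSegmentation,
    TemplateSet,
)


def _avg_ref_epochs(rng, n_ep=2, n_ch=16, n=200, sfreq=500.0):
    data = rng.standard_normal((n_ep, n_ch, n))
    data -= data.mean(axis=1, keepdims=True)
    return EpochSet(data, sfreq, [f"E{i}" for i in range(n_ch)])


class TestGfp:
    def test_zero_dispersion_gives_zero_gfp(self):
        data = np.zeros((1, 4, 10))
        eps = EpochSet(data, 500.0, list("abcd"))
        gfp = core.compute_gfp(eps)
        np.testing.assert_array_equal(gfp.values, 0.0)

    def test_two_channel_antisymmetric_sample(self):
        eps = EpochSet(np.array([[[1.0], [-1.0]]]), 500.0, ["a", "b"])
        gfp = core.compute_gfp(eps, normalization="population")
        assert gfp.values[0, 0] == pytest.approx(1.0)

    def test_matches_per_sample_std_loop(self):
        rng = np.random.default_rng(0)
        eps = _avg_ref_epochs(rng, n_ch=64)
        gfp = core.compute_gfp(eps)
        for ep in range(eps.n_epochs):
            for t in range(0, eps.n_samples, 17):
                expected = np.std(eps.data[ep, :, t])  # population std
                assert gfp.values[ep, t] == pytest.approx(expected, rel=1e-12)

    def test_rejects_unreferenced_input(self):
        eps = EpochSet(np.ones((1, 4, 10)) + np.arange(4)[None, :, None],
                       500.0, list("abcd"))
        with pytest.raises(ValueError):
            core.compute_gfp(eps)


class TestDetectPeaks:
    def test_monotone_series_has_no_peaks(self):
        gfp = GfpSeries(np.arange(50, dtype=float)[None, :], 500.0)
        assert core.detect_peaks(gfp)[0].size == 0

    def test_triangular_series_peaks_at_apex(self):
        vals = np.concatenate([np.arange(10.0), np.arange(8.0)[::-1]])
        gfp = GfpSeries(vals[None, :], 500.0)
        np.testing.assert_array_equal(core.detect_peaks(gfp)[0], [9])

    def test_rectified_sinusoid_peak_count(self, templates8):
        spec = synth.DynamicsSpec(n_epochs=3, snr=np.inf)
        eps, _ = synth.simulate_subject(templates8, spec, seed=6)
        gfp = core.compute_gfp(eps)
        for idx in core.detect_peaks(gfp):
            assert abs(len(idx) - 40) <= 1  # 20 rectified lobes/s x 2 s

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(4)
        vals = rng.random(300)
        gfp = GfpSeries(vals[None, :], 500.0)
        found = core.detect_peaks(gfp, min_separation_samples=1)[0]
        brute = [
            t
            for t in range(1, len(vals) - 1)
            if vals[t] > vals[t - 1] and vals[t] > vals[t + 1]
        ]
        np.testing.assert_array_equal(found, brute)

    def test_min_separation_keeps_larger_peak(self):
        vals = np.array([0, 5, 0, 6, 0, 1, 0], dtype=float)
        gfp = GfpSeries(vals[None, :], 500.0)
        idx = core.detect_peaks(gfp, min_separation_samples=3)[0]
        assert 3 in idx and 1 not in idx


class TestSpatialCorrelation:
    def test_identity_and_negation(self):
        rng = np.random.default_rng(1)
        m = rng.standard_normal(32)
        m -= m.mean()
        assert core.spatial_correlation(m, m) == pytest.approx(1.0)
        assert core.spatial_correlation(m, -m) == pytest.approx(-1.0)

    def test_orthogonal_zero_mean_maps(self):
        ts = synth.make_templates(8, 3, "orthogonal", seed=2)
        assert core.spatial_correlation(ts.maps[0], ts.maps[1]) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(2)
        a, b = rng.standard_normal((2, 20))
        expected = np.cov(a, b)[0, 1] / (np.std(a, ddof=1) * np.std(b, ddof=1))
        assert core.spatial_correlation(a, b) == pytest.approx(expected)

    def test_zero_variance_map_rejected(self):
        with pytest.raises(ValueError):
            core.spatial_correlation(np.ones(8), np.arange(8.0))


def _exhaustive_kmeans_oracle(maps, weights, k):
    """Best GEV over every label assignment, applying the same
    principal-eigenvector template update to convergence from each."""
    n = maps.shape[0]
    centered = maps - maps.mean(axis=1, keepdims=True)
    best = -1.0
    for assign in itertools.product(range(k), repeat=n):
        labels = np.array(assign)
        if len(set(assign)) < k:
            continue
        for _ in range(100):
            templates = np.stack(
                [core._principal_map(centered[labels == j]) for j in range(k)]
            )
            corr = core._corr_matrix(maps, templates)
            new = np.argmax(corr**2, axis=1)
            if (new == labels).all():
                break
            if len(set(new.tolist())) < k:
                break  # collapsed: keep previous labeling
            labels = new
        gev = core._gev_from_assignment(maps, weights, templates, labels)
        best = max(best, gev)
    return best


class TestModifiedKmeans:
    def test_noiseless_identifiability(self):
        """Maps that are exactly +/- scaled orthogonal templates are
        recovered with GEV 1."""
        gen = synth.make_templates(16, 3, "orthogonal", seed=8)
        rng = np.random.default_rng(9)
        idx = rng.integers(0, 3, size=60)
        amps = rng.uniform(0.5, 3.0, size=60)
        signs = rng.choice([-1.0, 1.0], size=60)
        maps = (amps * signs)[:, None] * gen.maps[idx]
        res = core.modified_kmeans(maps, k=3, n_restarts=5, seed=1)
        assert res.gev == pytest.approx(1.0, abs=1e-12)
        canon = core.label_canonical(res.templates, gen)
        for i in range(3):
            assert abs(
                core.spatial_correlation(canon.maps[i], gen.maps[i])
            ) == pytest.approx(1.0, abs=1e-10)

    def test_matches_exhaustive_assignment_enumeration(self):
        rng = np.random.default_rng(12)
        maps = rng.standard_normal((12, 6))
        maps -= maps.mean(axis=1, keepdims=True)
        weights = np.sqrt(np.mean(maps**2, axis=1))
        res = core.modified_kmeans(maps, k=2, n_restarts=20, seed=5)
        oracle = _exhaustive_kmeans_oracle(maps, weights, k=2)
        assert res.gev == pytest.approx(oracle, rel=1e-9)

    def test_polarity_flip_invariance(self):
        rng = np.random.default_rng(13)
        maps = rng.standard_normal((80, 16))
        maps -= maps.mean(axis=1, keepdims=True)
        flip = rng.choice([-1.0, 1.0], size=80)
        a = core.modified_kmeans(maps, k=4, n_restarts=6, seed=3)
        b = core.modified_kmeans(flip[:, None] * maps, k=4, n_restarts=6, seed=3)
        assert a.gev == pytest.approx(b.gev, rel=1e-10)
        for i in range(4):
            assert abs(
                core.spatial_correlation(a.templates.maps[i], b.templates.maps[i])
            ) == pytest.approx(1.0, abs=1e-9)

    def test_gev_non_decreasing_in_restarts(self):
        rng = np.random.default_rng(14)
        maps = rng.standard_normal((60, 12))
        maps -= maps.mean(axis=1, keepdims=True)
        gevs = [
            core.modified_kmeans(maps, k=3, n_restarts=m, seed=7).gev
            for m in (1, 3, 6, 12)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(gevs, gevs[1:]))

    def test_objective_monotone_within_restart(self):
        rng = np.random.default_rng(15)
        maps = rng.standard_normal((100, 16))
        maps -= maps.mean(axis=1, keepdims=True)
        res = core.modified_kmeans(maps, k=4, n_restarts=1, seed=2)
        trace = res.gev_trace
        assert all(b >= a - 1e-10 for a, b in zip(trace, trace[1:]))

    def test_default_configuration(self):
        import inspect

        sig = inspect.signature(core.modified_kmeans)
        assert sig.parameters["k"].default == 4
        assert sig.parameters["n_restarts"].default == 20
        # and the peak-map extractor includes all maps by default (no cap)
        sig2 = inspect.signature(core.extract_peak_maps)
        assert sig2.parameters["max_maps"].default is None


class TestGev:
    def test_planted_labels_give_unity(self):
        gen = synth.make_templates(16, 3, "orthogonal", seed=8)
        rng = np.random.default_rng(20)
        idx = rng.integers(0, 3, size=40)
        amps = rng.uniform(0.5, 2.0, size=40)
        maps = amps[:, None] * gen.maps[idx]
        w = np.sqrt(np.mean(maps**2, axis=1))
        assert core.compute_gev(maps, w, gen, idx) == pytest.approx(1.0)

    def test_orthogonal_assignment_gives_zero(self):
        gen = synth.make_templates(16, 3, "orthogonal", seed=8)
        rng = np.random.default_rng(21)
        amps = rng.uniform(0.5, 2.0, size=30)
        maps = amps[:, None] * gen.maps[0]
        w = np.sqrt(np.mean(maps**2, axis=1))
        labels = np.full(30, 1)  # orthogonal template
        assert core.compute_gev(maps, w, gen, labels) == pytest.approx(
            0.0, abs=1e-20
        )

    def test_matches_direct_summation_loop(self):
        gen = synth.make_templates(10, 4, seed=3)
        rng = np.random.default_rng(22)
        maps = rng.standard_normal((25, 10))
        maps -= maps.mean(axis=1, keepdims=True)
        w = rng.uniform(0.5, 2.0, size=25)
        labels = rng.integers(0, 4, size=25)
        num = 0.0
        for t in range(25):
            r = core.spatial_correlation(maps[t], gen.maps[labels[t]])
            num += (w[t] * r) ** 2
        expected = num / np.sum(w**2)
        assert core.compute_gev(maps, w, gen, labels) == pytest.approx(expected)

    def test_all_zero_gfp_rejected(self):
        gen = synth.make_templates(10, 2, seed=3)
        with pytest.raises(ValueError):
            core.compute_gev(
                np.zeros((5, 10)), np.zeros(5), gen, np.zeros(5, int)
            )


def _alignment_oracle(moving, reference):
    """Independent exhaustive search over permutations x signs."""
    k = moving.n_classes
    best = (-np.inf, None, None)
    for perm in itertools.permutations(range(k)):
        for signs in itertools.product([-1.0, 1.0], repeat=k):
            score = np.mean(
                [
                    core.spatial_correlation(
                        signs[j] * moving.maps[perm[j]], reference.maps[j]
                    )
                    for j in range(k)
                ]
            )
            if score > best[0]:
                best = (score, perm, signs)
    return best


class TestAggregation:
    def test_identical_sets_are_fixed_point(self, templates8):
        agg = core.aggregate_templates([templates8, templates8, templates8])
        np.testing.assert_allclose(agg.maps, templates8.maps, atol=1e-12)

    def test_alignment_undoes_permutation_and_signs(self, templates8):
        perm = [2, 0, 3, 1]
        signs = np.array([1.0, -1.0, -1.0, 1.0])
        shuffled = TemplateSet(
            signs[:, None] * templates8.maps[perm], list("WXYZ")
        )
        agg = core.aggregate_templates(
            [templates8, shuffled], reference=templates8
        )
        np.testing.assert_allclose(agg.maps, templates8.maps, atol=1e-10)

    def test_matches_exhaustive_alignment_oracle(self):
        a = synth.make_templates(12, 3, seed=31)
        b = synth.make_templates(12, 3, seed=32)
        perm, signs, score = core.align_templates(b, a)
        best_score, best_perm, best_signs = _alignment_oracle(b, a)
        assert score == pytest.approx(best_score, rel=1e-12)
        assert tuple(perm) == best_perm
        np.testing.assert_array_equal(signs, best_signs)

    def test_inconsistent_k_rejected(self, templates8):
        other = synth.make_templates(8, 3, seed=1)
        with pytest.raises(ValueError):
            core.aggregate_templates([templates8, other])


class TestBackfit:
    def test_single_sample_exact_template(self, templates8):
        data = templates8.maps[1][None, :, None] * 4.2
        eps = EpochSet(data, 500.0, [f"E{i}" for i in range(8)])
        seg = core.backfit(eps, templates8)
        assert seg.labels[0, 0] == 1
        assert seg.correlation[0, 0] == pytest.approx(1.0)

    def test_matches_per_sample_argmax_loop(self, templates8):
        rng = np.random.default_rng(40)
        eps = _avg_ref_epochs(rng, n_ep=1, n_ch=8, n=150)
        seg = core.backfit(eps, templates8)
        for t in range(eps.n_samples):
            corrs = [
                abs(core.spatial_correlation(eps.data[0, :, t], m))
                for m in templates8.maps
            ]
            assert seg.labels[0, t] == int(np.argmax(corrs))
            assert seg.correlation[0, t] == pytest.approx(max(corrs))

    def test_zero_variance_sample_unassigned(self, templates8):
        rng = np.random.default_rng(41)
        eps = _avg_ref_epochs(rng, n_ep=1, n_ch=8, n=50)
        eps.data[0, :, 10] = 0.0
        seg = core.backfit(eps, templates8)
        assert seg.labels[0, 10] == UNASSIGNED
        assert seg.correlation[0, 10] == 0.0

    def test_peak_domain_extends_to_nearest_peak_boundaries(self, templates8):
        spec = synth.DynamicsSpec(n_epochs=2, snr=np.inf)
        eps, gt = synth.simulate_subject(templates8, spec, seed=42)
        seg = core.backfit(eps, templates8, fit_domain="gfp_peaks_interpolated")
        # every labeled sample carries the label of its nearest GFP peak
        gfp = core.compute_gfp(eps)
        peaks = core.detect_peaks(gfp)
        for ep in range(2):
            idx = peaks[ep]
            for t in range(0, eps.n_samples, 7):
                nearest = idx[np.argmin(np.abs(idx - t))]
                assert seg.labels[ep, t] == seg.labels[ep, nearest]


class TestSmoothing:
    def _seg_with_intrusion(self, templates8):
        spec = synth.DynamicsSpec(n_epochs=1, snr=np.inf)
        eps, _ = synth.simulate_subject(templates8, spec, seed=50)
        return core.backfit(eps, templates8)

    def test_zero_min_duration_is_identity(self, templates8):
        seg = self._seg_with_intrusion(templates8)
        out = core.smooth_labels(seg, 0.0)
        np.testing.assert_array_equal(out.labels, seg.labels)

    def test_single_sample_intrusion_absorbed(self, templates8):
        seg = self._seg_with_intrusion(templates8)
        runs = core._runs(seg.labels[0])
        # plant a 1-sample intrusion inside the longest run
        s, e, lab = max(runs, key=lambda r: r[1] - r[0])
        mid = (s + e) // 2
        intruder = (lab + 1) % 4
        seg.labels[0, mid] = intruder
        out = core.smooth_labels(seg, 10.0)
        assert out.labels[0, mid] == lab

    def test_no_short_interior_segment_remains(self, templates8):
        rng = np.random.default_rng(51)
        eps = _avg_ref_epochs(rng, n_ep=2, n_ch=8, n=400)
        seg = core.backfit(eps, templates8)  # noisy: many short runs
        out = core.smooth_labels(seg, 10.0)  # 5 samples at 500 Hz
        for ep in range(out.n_epochs):
            runs = core._runs(out.labels[ep])
            for i, (s, e, lab) in enumerate(runs):
                if 0 < i < len(runs) - 1 and lab != UNASSIGNED:
                    assert e - s >= 5


class TestMetrics:
    def test_single_class_epoch(self):
        labels = np.zeros((1, 1000), dtype=int)
        seg = MicrostateSegmentation(
            labels, np.ones((1, 1000)), list("ABCD"), 500.0
        )
        sm = core.compute_metrics(seg, boundary_policy="include")
        assert sm.contribution[0] == 1.0
        assert sm.duration_ms[0] == pytest.approx(2000.0)
        assert sm.occurrence_per_s[0] == pytest.approx(0.5)

    def test_alternating_runs_arithmetic(self):
        row = np.repeat(np.tile([0, 1], 10), 50)  # 20 runs of 50 samples
        seg = MicrostateSegmentation(
            row[None, :], np.ones((1, 1000)), list("AB"), 500.0
        )
        sm = core.compute_metrics(seg)
        np.testing.assert_allclose(sm.duration_ms, [100.0, 100.0])
        np.testing.assert_allclose(sm.contribution, [0.5, 0.5])
        np.testing.assert_allclose(sm.occurrence_per_s, [5.0, 5.0])

    def test_duration_occurrence_contribution_identity(self, noisy_subject):
        eps, gt, templates = noisy_subject
        seg = core.backfit(eps, templates)
        sm = core.compute_metrics(seg, boundary_policy="include")
        if np.all(seg.labels >= 0):
            prod = sm.duration_ms * sm.occurrence_per_s
            np.testing.assert_allclose(
                prod, sm.contribution * 1000.0, rtol=1e-9
            )

    def test_exclude_truncated_drops_edge_runs_from_duration(self):
        row = np.concatenate(
            [np.full(100, 0), np.full(200, 1), np.full(700, 0)]
        )
        seg = MicrostateSegmentation(
            row[None, :], np.ones((1, 1000)), list("AB"), 500.0
        )
        sm = core.compute_metrics(seg, boundary_policy="exclude_truncated")
        assert np.isnan(sm.duration_ms[0])  # both class-0 runs touch an edge
        assert sm.duration_ms[1] == pytest.approx(400.0)
        assert sm.contribution[0] == pytest.approx(0.8)  # contribution keeps them

    def test_empty_segmentation_rejected(self):
        seg = MicrostateSegmentation(
            np.empty((0, 0), int), np.empty((0, 0)), list("AB"), 500.0
        )
        with pytest.raises(ValueError):
            core.compute_metrics(seg)
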