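"""GFP, segmentation, backfitting, features, TCT and subject screening."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import tepstates as tp
from tepstates.core_io import CONDITIONS, DatasetError
from tepstates.microstates import (
    LabelSequence,
    TemplateSet,
    _assign,
    _gev,
    _unit_maps,
    backfit,
    compute_gfp,
    features,
    kmeans_microstates,
    mahalanobis_outliers,
    match_templates,
    min_duration_filter,
    normalize_by_gfp,
    tct,
)


class TestGfp:
    @pytest.mark.parametrize(
        "map_, expected",
        [
            ([1.0, -1.0, 1.0, -1.0], 1.0),
            ([3.0, 3.0, 3.0, 3.0], 0.0),
            ([3.0, -1.0, -1.0, -1.0], np.sqrt(3.0)),
        ],
    )
    def test_closed_forms(self, map_, expected):
        out = compute_gfp(np.array(map_)[:, None])
        assert out[0] == pytest.approx(expected, abs=1e-12)

    def test_single_channel_rejected(self):
        with pytest.raises(DatasetError):
            compute_gfp(np.ones((1, 5)))


class TestNormalize:
    def _rec(self, scale=1.0, seed=0):
        rng = np.random.default_rng(seed)
        data = scale * rng.standard_normal((8, 100))
        return tp.SubjectEvoked("S1", "monophasic", "PA", data, 1000.0, 0.0)

    def test_scale_invariance(self):
        a = normalize_by_gfp(self._rec(1.0, seed=1))
        b = normalize_by_gfp(self._rec(5.0, seed=1))
        np.testing.assert_allclose(a.data, b.data, atol=1e-12)

    def test_idempotent_and_unit_mean_gfp(self):
        a = normalize_by_gfp(self._rec(3.0))
        assert compute_gfp(a.data).mean() == pytest.approx(1.0, abs=1e-12)
        b = normalize_by_gfp(a)
        np.testing.assert_allclose(a.data, b.data, atol=1e-12)

    def test_zero_record_errors(self):
        rec = tp.SubjectEvoked("S1", "monophasic", "PA",
                               np.zeros((4, 10)), 1000.0, 0.0)
        with pytest.raises(DatasetError, match="zero mean GFP"):
            normalize_by_gfp(rec)


def brute_force_best_gev(maps: np.ndarray) -> float:
    """Exhaustive K=2 oracle: max GEV over all binary labelings.

    Each labeling is scored with its optimal templates (first principal
    component of the class's GFP^2-weighted map scatter), i.e. the same
    update rule the polarity-indifferent segmentation uses.
    """
    n_t = maps.shape[0]
    unit, _ = _unit_maps(maps)
    w = compute_gfp(maps.T) ** 2
    best = 0.0
    for code in range(2**n_t):
        labels = np.array([(code >> i) & 1 for i in range(n_t)])
        if labels.min() == labels.max():
            continue
        r = np.zeros(n_t)
        degenerate = False
        for j in (0, 1):
            sel = labels == j
            scatter = (unit[sel] * w[sel][:, None]).T @ unit[sel]
            _, vecs = np.linalg.eigh(scatter)
            u = vecs[:, -1]
            u = u - u.mean()
            nrm = np.linalg.norm(u)
            if nrm == 0:
                degenerate = True
                break
            r[sel] = unit[sel] @ (u / nrm)
        if not degenerate:
            best = max(best, _gev(w, r))
    return best


class TestKmeans:
    def test_small_instance_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            maps = rng.standard_normal((8, 3))
            got = kmeans_microstates(maps, 2, restarts=64, seed=trial,
                                     max_iter=60, polarity="ignore")[2]
            want = brute_force_best_gev(maps)
            assert got == pytest.approx(want, abs=1e-10)

    def test_k1_reproducible_dominant_pattern(self):
        rng = np.random.default_rng(1)
        maps = rng.standard_normal((20, 5)) + 3 * np.array([1, -1, 0, 1, -1.0])
        t1, l1, g1, _ = kmeans_microstates(maps, 1, restarts=5, seed=2)
        t2, l2, g2, _ = kmeans_microstates(maps, 1, restarts=5, seed=3)
        np.testing.assert_allclose(np.abs(t1 @ t2.T), 1.0, atol=1e-9)
        assert g1 == pytest.approx(g2, abs=1e-12)

    def test_gev_non_decreasing_in_k_small_instance(self):
        rng = np.random.default_rng(4)
        maps = rng.standard_normal((10, 4))
        gevs = [
            kmeans_microstates(maps, k, restarts=200, seed=0, max_iter=60)[2]
            for k in (1, 2, 3)
        ]
        assert gevs[0] <= gevs[1] + 1e-12
        assert gevs[1] <= gevs[2] + 1e-12

    def test_amplitude_rescaling_invariance(self):
        rng = np.random.default_rng(5)
        maps = rng.standard_normal((30, 6))
        _, l1, g1, _ = kmeans_microstates(maps, 3, restarts=20, seed=1)
        _, l2, g2, _ = kmeans_microstates(maps * 7.0, 3, restarts=20, seed=1)
        np.testing.assert_array_equal(l1, l2)
        assert g1 == pytest.approx(g2, abs=1e-12)

    def test_retained_solution_dominates_restarts(self):
        rng = np.random.default_rng(6)
        maps = rng.standard_normal((40, 6))
        _, _, gev, info = kmeans_microstates(maps, 3, restarts=30, seed=2)
        assert gev >= info["restart_gevs"].max() - 1e-12


class TestSegmentRecovery:
    def test_noiseless_exact_recovery(self, noiseless_dataset):
        ds, truth = noiseless_dataset
        tset, seqs = tp.segment(ds, k=6, restarts=40, seed=1)
        assert abs(1.0 - tset.gev) < 1e-9
        _, corrs = match_templates(tset.maps, truth.templates)
        assert np.abs(corrs).min() >= 0.999

    def test_noiseless_backfit_reproduces_plan(self, noiseless_dataset):
        ds, truth = noiseless_dataset
        tset, _ = tp.segment(ds, k=6, restarts=40, seed=1)
        perm, _ = match_templates(tset.maps, truth.templates)
        to_truth = {int(perm[i]) + 1: i + 1 for i in range(6)}
        rec = tp.normalize_by_gfp(ds.get("S02", "monophasic", "AP"), (5, 400))
        seq = backfit(tset, rec, window=(5, 400))
        dt = 1000.0 / seq.srate
        truth_onsets = truth.true_onsets()[("monophasic", "AP")]
        f = features(seq, n_classes=6)
        for _, row in f.iterrows():
            true_cls = to_truth[int(row["class"])]
            assert abs(row["onset_ms"] - truth_onsets[true_cls]) <= dt

    def test_single_template_record_all_one_class(self, montage74):
        maps = tp.make_template_maps(montage74, 3, seed=0)
        data = np.outer(maps[2], np.linspace(1, 2, 50))
        rec = tp.SubjectEvoked("S1", "monophasic", "PA", data, 1000.0, 0.0)
        seq = backfit(maps, rec)
        assert (seq.labels == 3).all()
        assert seq.low_confidence_fraction == 0.0

    def test_orthogonal_record_flagged_low_confidence(self, montage74):
        maps = tp.make_template_maps(montage74, 2, seed=1)
        rng = np.random.default_rng(0)
        # build maps orthogonal to both templates
        raw = rng.standard_normal((74, 30))
        basis = np.vstack([maps, np.ones(74) / np.sqrt(74)])
        proj = basis.T @ np.linalg.solve(basis @ basis.T, basis @ raw)
        data = raw - proj
        rec = tp.SubjectEvoked("S1", "monophasic", "PA", data, 1000.0, 0.0)
        seq = backfit(maps, rec)
        np.testing.assert_allclose(np.abs(seq.corr), 0.0, atol=1e-9)
        assert seq.low_confidence_fraction == 1.0
        # with unassignment enabled these timepoints carry no class
        seq0 = backfit(maps, rec, unassign_low_r=True)
        assert (seq0.labels == 0).all()

    def test_exact_tie_resolves_to_lowest_class(self, montage74):
        maps = tp.make_template_maps(montage74, 1, seed=2)
        twins = np.vstack([maps[0], maps[0]])  # identical templates
        data = np.outer(maps[0], np.ones(20))
        rec = tp.SubjectEvoked("S1", "monophasic", "PA", data, 1000.0, 0.0)
        seq = backfit(twins, rec)
        assert (seq.labels == 1).all()


class TestFeatures:
    def _seq(self, labels, gfp, srate=960.0):
        labels = np.asarray(labels)
        t = 5.0 + np.arange(len(labels)) * (1000.0 / srate)
        return LabelSequence(labels=labels, gfp=np.asarray(gfp, float),
                             times=t, srate=srate)

    def test_uniform_class_arithmetic(self):
        seq = self._seq(np.full(100, 2), np.ones(100))
        f = features(seq, n_classes=2).set_index("class")
        dt = 1000.0 / 960.0
        assert f.loc[2, "duration_ms"] == pytest.approx(100 * dt)
        assert f.loc[2, "auc"] == pytest.approx(100 * dt)
        assert f.loc[2, "onset_ms"] == pytest.approx(5.0)

    def test_absent_class(self):
        seq = self._seq(np.full(10, 1), np.ones(10))
        f = features(seq, n_classes=3).set_index("class")
        assert f.loc[3, "duration_ms"] == 0.0
        assert f.loc[3, "auc"] == 0.0
        assert np.isnan(f.loc[3, "onset_ms"])

    def test_conservation(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(1, 4, size=200)
        gfp = rng.uniform(0.1, 3.0, size=200)
        seq = self._seq(labels, gfp)
        f = features(seq, n_classes=3)
        dt = 1000.0 / 960.0
        assert f["duration_ms"].sum() == pytest.approx(200 * dt, abs=1e-9)
        assert f["auc"].sum() == pytest.approx(gfp.sum() * dt, abs=1e-9)

    def test_min_duration_filter_removes_blips(self):
        labels = np.array([0] * 10 + [1] + [0] * 10 + [1] * 8)
        scores = np.zeros((len(labels), 2))
        scores[np.arange(len(labels)), labels] = 1.0
        out = min_duration_filter(labels, scores, min_samples=3)
        assert (out[:21] == 0).all()
        assert (out[21:] == 1).all()


class TestTct:
    def _shared_map_dataset(self, montage, n_sub=12, noise=0.5, seed=0,
                            gfp_uv=2.0):
        from tepstates.synthetic import (GfpEnvelope, GroundTruth, Segment,
                                         simulate_dataset)

        truth = GroundTruth(
            templates=tp.make_template_maps(montage, 1, seed=seed),
            plans={c: (Segment(1, -200.0, 600.0),) for c in CONDITIONS},
            noise_sd=noise, seed=seed, amp_sigma=0.0, jitter_sd_ms=0.0,
            latency_scale_sd=0.0, spatial_noise=0.0,
        )
        env = GfpEnvelope(((0.0, 1e6, gfp_uv),))
        ds, _ = simulate_dataset(truth, env, n_sub, montage, srate=240.0)
        return ds

    def test_identical_subjects_hit_permutation_floor(self, montage74):
        ds = self._shared_map_dataset(montage74, n_sub=6, noise=0.0)
        res = tct(ds, window=(5, 100), n_perm=200, seed=1)
        r = res[("monophasic", "PA")]
        # observed equals each subject's GFP; p at the add-one floor
        assert (r.p <= 1.5 / 201).all()
        np.testing.assert_allclose(
            r.observed, compute_gfp(ds.records[0].data)[
                np.flatnonzero((ds.times >= 5) & (ds.times < 100))
            ], atol=1e-12)

    def test_shared_topography_significant_everywhere(self, montage74):
        ds = self._shared_map_dataset(montage74, n_sub=12, noise=1.0, seed=2)
        res = tct(ds, window=(5, 400), n_perm=500, seed=3)
        assert res[("biphasic", "LM")].significant_fraction >= 0.95

    def test_null_data_calibrated(self, montage74):
        ds, _ = tp.make_fixture_dataset("nullflat", seed=4, n_subjects=12,
                                        srate=960.0)
        res = tct(ds, window=(5, 400), n_perm=500, seed=5)
        pooled = np.concatenate([r.p for r in res.values()])
        assert 0.02 < np.mean(pooled < 0.05) < 0.08

    def test_deterministic_in_seed(self, montage74):
        ds = self._shared_map_dataset(montage74, n_sub=5, noise=1.0, seed=6)
        a = tct(ds, window=(5, 50), n_perm=100, seed=7)
        b = tct(ds, window=(5, 50), n_perm=100, seed=7)
        for cond in a:
            np.testing.assert_array_equal(a[cond].p, b[cond].p)


class TestMahalanobis:
    def test_scrambled_deviant_ranks_first(self):
        ds, _ = tp.make_fixture_dataset("deviant1", seed=3, n_subjects=12)
        out = mahalanobis_outliers(ds)
        assert out.iloc[0]["subject"] == "S01"

    def test_duplicate_subjects_equal_distances(self, montage74):
        ds, _ = tp.make_fixture_dataset("clean6", seed=9, n_subjects=6)
        # duplicate S02's records into S01
        from dataclasses import replace

        records = []
        for rec in ds.records:
            if rec.subject_id == "S01":
                twin = ds.get("S02", rec.waveform, rec.direction)
                records.append(replace(rec, data=twin.data.copy()))
            else:
                records.append(rec)
        dup = tp.EvokedDataset(ds.montage, records, ds.analysis_window)
        out = mahalanobis_outliers(dup).set_index("subject")
        assert out.loc["S01", "distance2"] == pytest.approx(
            out.loc["S02", "distance2"], rel=1e-9)

    def test_needs_five_subjects(self):
        ds, _ = tp.make_fixture_dataset("clean6", seed=1, n_subjects=4)
        with pytest.raises(DatasetError, match="at least 5"):
            mahalanobis_outliers(ds)
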