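"""Peak detection, fragments, ICA, split proposals and the tree."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

import flywalk as fw
from flywalk.segmentation import (
    FragmentSegmenter,
    SubmodeCatalog,
    assemble_standardize,
    detect_peaks,
    extract_fragments,
    fit_ica,
    propose_split,
    whiten_reduce,
)
from flywalk.trajectory import VelocityTrajectory


def _vel_from_vR(vR, fr=30.0, tid="v"):
    n = len(vR)
    return VelocityTrajectory(
        id=tid, frame_rate=fr, times=np.arange(n) / fr,
        vT=np.full(n, 1.0), vR=np.asarray(vR, float), vS=np.zeros(n),
    )


class TestDetectPeaks:
    def test_sinusoid_extrema_alternate_every_250ms(self):
        fr = 30.0
        t = np.arange(150) / fr
        vel = _vel_from_vR(200 * np.sin(2 * np.pi * t / 0.5), fr)  # 500 ms period
        pk = detect_peaks(vel, window=2)
        gaps = np.diff(pk) / fr
        assert np.all(np.abs(gaps - 0.25) <= 1.5 / fr)
        signs = np.sign(vel.vR[pk])
        assert np.all(signs[1:] * signs[:-1] == -1)

    def test_monotone_has_no_interior_peaks(self):
        assert len(detect_peaks(_vel_from_vR(np.linspace(5, 100, 50)))) == 0
        assert len(detect_peaks(_vel_from_vR(np.linspace(-100, -5, 50)))) == 0

    def test_plateau_tie_broken_to_earliest(self):
        vR = np.zeros(20)
        vR[8:11] = 50.0
        pk = detect_peaks(_vel_from_vR(vR))
        assert list(pk) == [8]

    def test_planted_peaks_recovered(self, templates):
        cfg = fw.GeneratorConfig(
            noise_scale=0.05, interval_shape=16.0, interval_scale_s=0.025,
            min_interval_s=0.2,
        )
        lt = fw.render_velocities([1, 4, 2, 3, 1, 4], templates, cfg, 3)
        pk = detect_peaks(lt.vel)
        for p in lt.peak_frames:
            assert np.min(np.abs(pk - p)) <= 1


class TestFragments:
    def test_sample_counts_match_half_width(self, templates):
        cfg = fw.GeneratorConfig(mean_peaks=8)
        lt = fw.render_velocities(
            fw.sample_state_sequence(fw.TABLE1_RATES, 10, 0),
            templates, cfg, 0,
        )
        f550 = extract_fragments(lt.vel, half_width_s=0.55)
        assert f550.arrays["vR"].shape[1] == 33
        f300 = extract_fragments(lt.vel, half_width_s=0.3)
        assert f300.arrays["vR"].shape[1] == 19
        # reduced 2-component vector (vH, vT) has 38 rows
        fm = assemble_standardize(f300, components=("vH", "vT"))
        assert fm.data.shape[0] == 38

    def test_sign_normalization(self):
        fr = 30.0
        t = np.arange(40) / fr
        vR = -120.0 * np.exp(-0.5 * ((t - t[20]) / 0.05) ** 2)
        vS = 0.3 * np.exp(-0.5 * ((t - t[20]) / 0.08) ** 2)
        vel = VelocityTrajectory("s", fr, t, vT=np.full(40, 1.0), vR=vR, vS=vS)
        frags = extract_fragments(vel, half_width_s=0.3)
        i = np.argmin(np.abs(frags.peak_frames - 20))
        assert frags.c[i] == -1
        mid = len(frags.tprime) // 2
        assert frags.arrays["vR"][i, mid] == pytest.approx(120.0)
        assert frags.arrays["vS"][i, mid] == pytest.approx(-0.3, rel=1e-6)

    def test_sign_normalization_idempotent(self):
        # applying c twice returns the original: c * (c * v) == v
        rng = np.random.default_rng(0)
        vR = rng.normal(size=19)
        c = -1 if vR[9] < 0 else 1
        np.testing.assert_allclose(c * (c * vR), vR)

    def test_peaks_near_edges_dropped(self):
        vR = np.zeros(30)
        vR[3] = 100.0  # full support would need frames -6..12
        frags = extract_fragments(_vel_from_vR(vR), half_width_s=0.3)
        assert 3 not in frags.peak_frames


class TestMatrix:
    def test_standardized_rows(self, templates):
        frags, _ = fw.sample_fragments(templates, 300, 1)
        fm = assemble_standardize(frags, components=("vR", "vT", "vS"))
        np.testing.assert_allclose(fm.data.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(fm.data.std(axis=1), 1, atol=1e-9)

    def test_destandardize_round_trip(self, templates):
        frags, _ = fw.sample_fragments(templates, 200, 2)
        fm = assemble_standardize(frags, components=("vH", "vT"))
        raw = np.vstack([frags.arrays["vH"].T, frags.arrays["vT"].T])
        np.testing.assert_allclose(fm.destandardize(), raw, atol=1e-9)

    def test_zero_variance_row_rejected(self):
        from flywalk.segmentation import FragmentSet

        tprime = np.arange(-2, 3) / 30.0
        arrays = {
            k: np.random.default_rng(0).normal(size=(10, 5))
            for k in ("vR", "vT", "vS", "vH")
        }
        arrays["vT"][:, 2] = 7.0  # constant row
        fs = FragmentSet(tprime, arrays, ["t"] * 10, np.zeros(10),
                         np.zeros(10), np.ones(10), 30.0)
        with pytest.raises(ValueError, match="vT"):
            assemble_standardize(fs, components=("vR", "vT"))

    def test_whitening_contract_and_subspace(self, templates):
        frags, _ = fw.sample_fragments(templates, 500, 3)
        fm = assemble_standardize(frags, components=("vR", "vT", "vS"))
        Xw, basis = whiten_reduce(fm, var_threshold=0.9)
        cov = (Xw @ Xw.T) / Xw.shape[1]
        np.testing.assert_allclose(cov, np.eye(basis.D), atol=1e-6)
        assert basis.explained_variance >= 0.9

    def test_exact_2d_subspace_keeps_2_pcs(self):
        from flywalk.segmentation import FragmentMatrix

        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(2, 500))
        mix = rng.normal(size=(10, 2))
        Z = mix @ np.vstack([a, b])
        Z = (Z - Z.mean(1, keepdims=True)) / Z.std(1, keepdims=True)
        fm = FragmentMatrix(
            data=Z, components=("x",), tprime=np.arange(10),
            row_component=np.array(["x"] * 10), row_tprime=np.arange(10),
            row_mean=np.zeros(10), row_sd=np.ones(10),
        )
        _, basis = whiten_reduce(fm, var_threshold=0.85)
        assert basis.D == 2

    def test_reconstruction_captures_threshold_variance(self, rng):
        from flywalk.segmentation import FragmentMatrix

        Z = rng.normal(size=(12, 800))
        Z = (Z - Z.mean(1, keepdims=True)) / Z.std(1, keepdims=True)
        fm = FragmentMatrix(
            data=Z, components=("x",), tprime=np.arange(12),
            row_component=np.array(["x"] * 12), row_tprime=np.arange(12),
            row_mean=np.zeros(12), row_sd=np.ones(12),
        )
        Xw, basis = whiten_reduce(fm, var_threshold=0.8)
        recon = basis.eigvecs @ (np.sqrt(basis.eigvals)[:, None] * Xw)
        explained = 1 - ((Z - recon) ** 2).sum() / (Z**2).sum()
        assert explained >= 0.8 - 1e-9


class TestICA:
    def test_planted_rotation_recovered(self, rng):
        S = rng.uniform(-np.sqrt(3), np.sqrt(3), size=(2, 4000))
        ang = 0.6
        R = np.array(
            [[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]]
        )
        res = fit_ica(R @ S, rng=1)
        assert res.converged
        corr = np.abs(np.corrcoef(np.vstack([res.S, S]))[:2, 2:])
        # each source matched by one component up to sign/permutation
        assert np.all(corr.max(axis=0) > 0.99)

    def test_three_sources_recovered(self, rng):
        S = np.vstack(
            [
                rng.uniform(-1, 1, 5000),
                rng.laplace(size=5000),
                rng.choice([-1.0, 1.0], 5000) + 0.1 * rng.normal(size=5000),
            ]
        )
        S = (S - S.mean(1, keepdims=True)) / S.std(1, keepdims=True)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        res = fit_ica(q @ S, rng=2)
        assert res.converged
        corr = np.abs(np.corrcoef(np.vstack([res.S, S]))[:3, 3:])
        assert np.all(corr.max(axis=0) > 0.99)

    def test_gaussian_data_is_nonconvergent(self, rng):
        res = fit_ica(rng.normal(size=(3, 4000)), rng=3)
        assert res.status == "no_convergence"

    def test_deterministic_under_seed(self, rng):
        X = rng.uniform(-1, 1, size=(2, 2000))
        a = fit_ica(X, rng=7)
        b = fit_ica(X, rng=7)
        np.testing.assert_array_equal(a.W, b.W)


class TestProposeSplit:
    def test_unimodal_gaussian_returns_none(self, rng):
        S = rng.normal(size=(3, 3000))
        assert propose_split(S, rng=0) is None

    def test_balanced_mixture_split_at_valley(self, rng):
        x = np.concatenate(
            [rng.normal(-3, 1, 2000), rng.normal(3, 1, 2000)]
        )
        S = np.vstack([x, rng.normal(size=4000)])
        rule = propose_split(S, rng=0)
        assert rule is not None and rule.kind == "valley1d"
        assert rule.dims == (0,)
        assert abs(rule.threshold - 0.0) < 0.5  # within 0.5 s.d. of midpoint
        side = rule.assign(S)
        assert 0.45 < side.mean() < 0.55

    def test_lognormal_tail_flagged_as_tail_split(self, rng):
        core = rng.normal(0, 0.5, 4500)
        tail = np.exp(rng.normal(1.8, 0.5, 500))
        S = np.vstack([np.concatenate([core, tail])])
        rule = propose_split(S, rng=0)
        assert rule is not None
        assert rule.tail


@pytest.fixture(scope="module")
def fitted_three_modes(templates):
    frags, labels = fw.sample_fragments(
        {m: templates[m] for m in ("I", "II", "V")}, 2500, 9
    )
    seg = FragmentSegmenter(random_state=4).fit(frags)
    return frags, labels, seg


class TestTree:
    def test_two_planted_templates_recovered(self, templates):
        frags, labels = fw.sample_fragments(
            {m: templates[m] for m in ("I", "V")}, 4000, 7
        )
        seg = FragmentSegmenter(random_state=0).fit(frags)
        assert seg.n_leaves_ == 2
        assert adjusted_rand_score(labels, seg.labels_) > 0.9

    def test_three_planted_templates_recovered(self, fitted_three_modes):
        frags, labels, seg = fitted_three_modes
        assert seg.n_leaves_ == 3
        assert adjusted_rand_score(labels, seg.labels_) > 0.9

    def test_single_template_gives_one_leaf(self, templates):
        frags, _ = fw.sample_fragments({"V": templates["V"]}, 2000, 5)
        seg = FragmentSegmenter(random_state=0).fit(frags)
        assert seg.n_leaves_ == 1

    def test_rerun_same_seed_identical_tree(self, fitted_three_modes):
        frags, _, a = fitted_three_modes
        b = FragmentSegmenter(random_state=4).fit(frags)
        assert a.catalog_.tree_hash() == b.catalog_.tree_hash()

    def test_training_fragments_reclassified_identically(
        self, fitted_three_modes
    ):
        frags, _, seg = fitted_three_modes
        np.testing.assert_array_equal(seg.predict(frags), seg.labels_)

    def test_partition_sums_to_fragment_count(self, fitted_three_modes):
        frags, _, seg = fitted_three_modes

        def check(node):
            if node.children:
                assert (
                    sum(ch.n_fragments for ch in node.children)
                    == node.n_fragments
                )
                for ch in node.children:
                    check(ch)

        check(seg.catalog_.root)
        counts = np.bincount(seg.labels_, minlength=seg.n_leaves_)
        assert counts.sum() == len(frags)

    def test_classification_invariant_to_turn_mirroring(
        self, fitted_three_modes
    ):
        frags, _, seg = fitted_three_modes
        mirrored = frags.mirrored()
        np.testing.assert_array_equal(seg.predict(mirrored), seg.labels_)

    def test_catalog_json_round_trip(self, fitted_three_modes):
        frags, _, seg = fitted_three_modes
        back = SubmodeCatalog.from_json(seg.catalog_.to_json())
        np.testing.assert_array_equal(
            back.classify(frags), seg.catalog_.classify(frags)
        )
        assert back.n_leaves == seg.n_leaves_

    def test_tprime_grid_mismatch_rejected(self, templates):
        frags, _ = fw.sample_fragments({"V": templates["V"]}, 1000, 1)
        seg = FragmentSegmenter(random_state=0).fit(frags)
        short = fw.default_templates(half_width_s=0.2)
        other, _ = fw.sample_fragments({"V": short["V"]}, 100, 1)
        with pytest.raises(ValueError, match="grid"):
            seg.catalog_.classify(other)

    def test_end_to_end_two_distinct_modes(self, templates):
        """Detect, segment and classify rendered trajectories of two
        maximally distinct movement patterns."""
        P = np.array([[0.5, 0.5], [0.5, 0.5]])
        cfg = fw.GeneratorConfig(
            mean_peaks=6, interval_shape=4.0, interval_scale_s=0.15,
            transition_matrix=P, mode_names=("II", "V"), noise_scale=0.7,
        )
        data = fw.simulate_dataset(
            cfg, 300, 11, templates={m: templates[m] for m in ("II", "V")}
        )
        vels = [
            fw.compute_velocities(
                fw.smooth_trajectory(fw.integrate_velocities(lt.vel), 1.0)
            )
            for lt in data
        ]
        frags = extract_fragments(vels, half_width_s=0.2)
        truth = {}
        for lt in data:
            for f, m in zip(lt.peak_frames, lt.modes):
                for off in range(-3, 4):
                    # velocity grid starts one frame into the raw grid
                    truth.setdefault((lt.vel.id, int(f) + off - 1), m)
        gt = np.array(
            [
                truth.get((tid, int(pf)), -1)
                for tid, pf in zip(frags.traj_ids, frags.peak_frames)
            ]
        )
        seg = FragmentSegmenter(random_state=0, half_width_s=0.2).fit(frags)
        matched = gt >= 0
        ari = adjusted_rand_score(gt[matched], seg.labels_[matched])
        assert ari > 0.9


@settings(max_examples=20, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_detect_peaks_are_local_extrema(seed):
    rng = np.random.default_rng(seed)
    vel = _vel_from_vR(rng.normal(0, 100, 60))
    for p in detect_peaks(vel, window=2):
        m = np.abs(vel.vR)
        lo, hi = max(0, p - 2), min(len(m), p + 3)
        assert m[p] >= m[lo:hi].max() - 1e-12
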