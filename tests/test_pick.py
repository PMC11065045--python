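"""Stage-2 scanning: window enumeration, scoring, density threshold."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maepick import (MaskedAutoencoder, Micrograph, PickConfig,
                     density_threshold, enumerate_windows, n_windows,
                     pick_particles, score_windows)


def oracle_density_threshold(scores, k):
    """Independent brute-force evaluation of the density cutoff rule."""
    s = sorted(scores, reverse=True)
    avg = []
    for i, si in enumerate(s):
        dists = sorted(abs(si - sj) for j, sj in enumerate(s) if j != i)
        avg.append(sum(dists[:k]) / k)
    best_i, best_drop = 0, -np.inf
    for i in range(len(s) - 1):
        drop = avg[i] - avg[i + 1]
        if drop > best_drop:
            best_i, best_drop = i, drop
    return s[best_i + 1]


class TestEnumerateWindows:
    def test_counts_match_closed_form(self):
        origins = enumerate_windows(100, 100, 50, 25)
        assert len(origins) == 9 == n_windows(100, 100, 50, 25)

    def test_non_overlapping_tiling(self):
        origins = enumerate_windows(128, 128, 32, 32)
        assert len(origins) == 16
        assert {tuple(o) for o in origins} == {(x, y) for x in range(0, 128, 32)
                                               for y in range(0, 128, 32)}

    def test_single_full_window(self):
        origins = enumerate_windows(64, 64, 64, 28)
        np.testing.assert_array_equal(origins, [[0, 0]])

    def test_oversized_window_rejected(self):
        with pytest.raises(ValueError, match="window_size"):
            enumerate_windows(32, 32, 64, 28)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(40, 200), st.integers(40, 200), st.integers(8, 40),
           st.integers(1, 40))
    def test_count_formula_property(self, h, w, win, stride):
        if win > min(h, w) or stride > win:
            return
        origins = enumerate_windows(h, w, win, stride)
        assert len(origins) == n_windows(h, w, win, stride)
        # all windows fully inside, row-major order
        assert (origins[:, 0] + win <= w).all() and (origins[:, 1] + win <= h).all()


class TestDensityThreshold:
    def test_bimodal_fixture_isolates_top_cluster(self):
        scores = [0.90, 0.89, 0.88, 0.30, 0.29, 0.28, 0.27, 0.26]
        thr = density_threshold(scores, k_neighbors=5)
        assert thr == oracle_density_threshold(scores, 5)
        assert 0.30 <= thr < 0.88
        picked = [s for s in scores if s > thr]
        assert picked == [0.90, 0.89, 0.88]

    def test_separated_clusters_split_exactly(self, rng):
        top = 0.8 + 0.02 * rng.random(20)
        bottom = 0.1 + 0.02 * rng.random(20)
        scores = np.concatenate([top, bottom])
        rng.shuffle(scores)
        thr = density_threshold(scores, k_neighbors=5)
        assert (top > thr).all()
        assert (bottom <= thr).all()

    def test_uniform_spacing_tie_break(self):
        scores = np.linspace(1.0, 0.0, 11)
        thr = density_threshold(scores, k_neighbors=2)
        # all drops tie at zero except the edge effects; the tie-break
        # keeps the highest-score position -> cut right below the top score
        assert thr == oracle_density_threshold(scores, 2)
        assert thr == pytest.approx(0.9)

    def test_matches_oracle_on_random_lists(self, rng):
        for _ in range(25):
            scores = rng.normal(size=rng.integers(10, 60))
            thr = density_threshold(scores, k_neighbors=5)
            assert thr == pytest.approx(oracle_density_threshold(scores, 5))
            assert scores.min() <= thr <= scores.max()

    def test_too_few_scores_falls_back_to_midpoint(self):
        with pytest.warns(UserWarning, match="midpoint"):
            thr = density_threshold([0.1, 0.9], k_neighbors=5)
        assert thr == pytest.approx(0.5)


class TestScoreWindows:
    @pytest.fixture
    def setup(self, tiny_cfg, rng):
        model = MaskedAutoencoder(tiny_cfg, seed=0)
        image = rng.normal(size=(96, 96)).astype(np.float32)
        mic = Micrograph(image, "test")
        return model, mic

    def test_window_identical_to_exemplar_scores_one(self, setup):
        from maepick.train import contrast_scale

        model, mic = setup
        cfg = PickConfig(stride=32, window_size=32)
        # exemplar = the window at origin (32, 32), on the scan's scale
        crop = contrast_scale(mic.image)[32:64, 32:64]
        feats = model.embed(crop[None])
        centers, scores = score_windows(model, mic, feats, cfg)
        idx = np.where((centers == (48.0, 48.0)).all(axis=1))[0][0]
        assert scores[idx] == pytest.approx(1.0, abs=1e-5)

    def test_single_exemplar_max_equals_mean(self, setup):
        model, mic = setup
        feats = model.embed(mic.image[:32, :32][None])
        cfg_max = PickConfig(stride=16, window_size=32, match_mode="max")
        cfg_mean = PickConfig(stride=16, window_size=32, match_mode="mean")
        _, s_max = score_windows(model, mic, feats, cfg_max)
        _, s_mean = score_windows(model, mic, feats, cfg_mean)
        np.testing.assert_allclose(s_max, s_mean)

    def test_max_mode_dominates_mean_mode(self, setup, rng):
        model, mic = setup
        feats = model.embed(rng.normal(size=(4, 32, 32)).astype(np.float32))
        cfg_max = PickConfig(stride=16, window_size=32, match_mode="max")
        cfg_mean = PickConfig(stride=16, window_size=32, match_mode="mean")
        _, s_max = score_windows(model, mic, feats, cfg_max)
        _, s_mean = score_windows(model, mic, feats, cfg_mean)
        assert (s_max >= s_mean - 1e-6).all()

    def test_empty_exemplars_rejected(self, setup):
        model, mic = setup
        with pytest.raises(ValueError, match="nonempty"):
            score_windows(model, mic, np.zeros((0, 16)), PickConfig(window_size=32))

    def test_candidate_count_and_score_range(self, setup, rng):
        model, mic = setup
        feats = model.embed(rng.normal(size=(3, 32, 32)).astype(np.float32))
        cfg = PickConfig(stride=8, window_size=32)
        centers, scores = score_windows(model, mic, feats, cfg)
        assert len(centers) == n_windows(96, 96, 32, 8)
        assert (scores >= -1 - 1e-6).all() and (scores <= 1 + 1e-6).all()


class TestPickParticles:
    def test_pickset_invariants_and_dedupe(self, tiny_cfg, rng):
        model = MaskedAutoencoder(tiny_cfg, seed=0)
        mic = Micrograph(rng.normal(size=(128, 128)).astype(np.float32), "m")
        feats = model.embed(rng.normal(size=(2, 32, 32)).astype(np.float32))
        ps = pick_particles(model, mic, feats, PickConfig(stride=16, window_size=32))
        assert ps.scores.min() <= ps.threshold <= ps.scores.max()
        assert (ps.picked_scores > ps.threshold).all()
        # dedupe keeps at most one pick per radius neighborhood
        ps_d = pick_particles(model, mic, feats,
                              PickConfig(stride=16, window_size=32,
                                         dedupe_radius=40.0))
        c = ps_d.picked_centers
        if len(c) > 1:
            d = np.hypot(c[:, 0, None] - c[None, :, 0], c[:, 1, None] - c[None, :, 1])
            np.fill_diagonal(d, np.inf)
            assert d.min() >= 40.0

    def test_dedupe_default_and_explicit_off(self, tiny_cfg, rng):
        model = MaskedAutoencoder(tiny_cfg, seed=0)
        mic = Micrograph(rng.normal(size=(128, 128)).astype(np.float32), "m")
        feats = model.embed(rng.normal(size=(3, 32, 32)).astype(np.float32))
        cfg_auto = PickConfig(stride=16, window_size=32)
        assert cfg_auto.dedupe_radius == 16.0  # auto = window_size / 2
        cfg_off = PickConfig(stride=16, window_size=32, dedupe_radius=None)
        ps_auto = pick_particles(model, mic, feats, cfg_auto)
        ps_off = pick_particles(model, mic, feats, cfg_off)
        # suppression can only remove picks, never add them
        assert set(map(tuple, ps_auto.picked_centers)) <= \
            set(map(tuple, ps_off.picked_centers))
        np.testing.assert_array_equal(
            ps_off.picked_idx, np.flatnonzero(ps_off.scores > ps_off.threshold))

    def test_config_validation(self):
        with pytest.raises(ValueError, match="stride"):
            PickConfig(stride=0)
        with pytest.raises(ValueError, match="match_mode"):
            PickConfig(match_mode="median")
        with pytest.raises(ValueError, match="k_neighbors"):
            PickConfig(k_neighbors=0)
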