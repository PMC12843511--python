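"""Saliency consensus metrics vs analytic and Monte-Carlo oracles."""

import numpy as np
import pytest
from scipy import stats

from orgfate.saliency import (SaliencyMap, center_of_mass_drift,
                              cross_model_rank_correlation,
                              load_saliency_store, pairwise_method_dice,
                              save_saliency_store, slic_superpixels,
                              superpixel_votes, synthesize_saliency_maps,
                              topq_center_of_mass, topq_entropy,
                              zscore_within_mask)


@pytest.fixture()
def mask64():
    yy, xx = np.mgrid[0:64, 0:64]
    return (yy - 32) ** 2 + (xx - 32) ** 2 <= 28 ** 2


class TestZScore:
    def test_mean_zero_sd_one_inside_mask(self, mask64):
        rng = np.random.default_rng(0)
        z = zscore_within_mask(rng.normal(3, 7, (64, 64)), mask64)
        assert np.nanmean(z[mask64]) == pytest.approx(0.0, abs=1e-12)
        assert np.nanstd(z[mask64]) == pytest.approx(1.0, abs=1e-12)
        assert np.isnan(z[~mask64]).all()

    def test_affine_invariance(self, mask64):
        rng = np.random.default_rng(1)
        m = rng.normal(size=(64, 64))
        a = zscore_within_mask(m, mask64)
        b = zscore_within_mask(2.5 * m - 11.0, mask64)
        assert np.allclose(a[mask64], b[mask64])

    def test_tiny_or_constant_mask_rejected(self):
        one_px = np.zeros((8, 8), bool)
        one_px[3, 3] = True
        with pytest.raises(ValueError, match="at least 2"):
            zscore_within_mask(np.ones((8, 8)), one_px)
        two_px = one_px.copy()
        two_px[3, 4] = True
        with pytest.raises(ValueError, match="constant"):
            zscore_within_mask(np.ones((8, 8)), two_px)


class TestPairwiseDice:
    def test_identical_maps_dice_one(self, mask64):
        rng = np.random.default_rng(2)
        m = rng.normal(size=(64, 64))
        out = pairwise_method_dice({"a": m, "b": m.copy()}, mask64)
        assert out[("a", "b")] == 1.0

    def test_disjoint_top_sets_dice_zero(self, mask64):
        coords = np.argwhere(mask64)
        a = np.zeros((64, 64))
        b = np.zeros((64, 64))
        half = len(coords) // 2
        a[tuple(coords[:half].T)] = 1.0   # hot in the first half
        b[tuple(coords[half:].T)] = 1.0   # hot in the second half
        out = pairwise_method_dice({"a": a, "b": b}, mask64)
        assert out[("a", "b")] == 0.0

    def test_random_maps_match_combinatorial_expectation(self, mask64):
        # top-fraction f of n pixels: E[|A & B|] = f^2 n, so E[Dice] = f
        rng = np.random.default_rng(3)
        vals = []
        for _ in range(300):
            a, b = rng.normal(size=(2, 64, 64))
            vals.append(pairwise_method_dice({"a": a, "b": b}, mask64,
                                             top_fracs=(0.10,))[("a", "b")])
        assert np.mean(vals) == pytest.approx(0.10, abs=0.01)

    def test_symmetry_and_out_of_mask_invariance(self, mask64):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=(2, 64, 64))
        base = pairwise_method_dice({"a": a, "b": b}, mask64)[("a", "b")]
        flipped = pairwise_method_dice({"a": b, "b": a}, mask64)[("a", "b")]
        assert base == flipped
        a2 = a.copy()
        a2[~mask64] = 1e9  # garbage outside the mask
        assert pairwise_method_dice({"a": a2, "b": b},
                                    mask64)[("a", "b")] == base


class TestRankCorrelation:
    def test_monotone_transform_of_magnitudes_gives_one(self, mask64):
        rng = np.random.default_rng(5)
        m = np.abs(rng.normal(size=(64, 64))) + 0.1
        out = cross_model_rank_correlation({"m1": m, "m2": m ** 3}, mask64)
        assert out[("m1", "m2")] == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self, mask64):
        rng = np.random.default_rng(6)
        vals = np.abs(rng.normal(size=int(mask64.sum()))) + 0.1
        a = np.zeros((64, 64))
        b = np.zeros((64, 64))
        order = np.argsort(vals)
        coords = np.argwhere(mask64)
        a[tuple(coords.T)] = vals
        b[tuple(coords[order].T)] = np.sort(vals)[::-1]  # reversed ranks
        out = cross_model_rank_correlation({"m1": a, "m2": b}, mask64)
        assert out[("m1", "m2")] == pytest.approx(-1.0)

    def test_matches_rank_pearson_oracle_with_ties(self):
        rng = np.random.default_rng(7)
        mask = np.zeros((10, 10), bool)
        mask.flat[:50] = True
        a = rng.integers(0, 8, (10, 10)).astype(float)  # plenty of ties
        b = rng.integers(0, 8, (10, 10)).astype(float)
        got = cross_model_rank_correlation({"m1": a, "m2": b},
                                           mask)[("m1", "m2")]
        ra = stats.rankdata(np.abs(a[mask]))
        rb = stats.rankdata(np.abs(b[mask]))
        want = np.corrcoef(ra, rb)[0, 1]
        assert got == pytest.approx(want, abs=1e-9)
        # and identical to scipy's spearman
        assert got == pytest.approx(
            stats.spearmanr(np.abs(a[mask]), np.abs(b[mask])).statistic,
            abs=1e-9)


class TestEntropyAndDrift:
    def test_uniform_top_set_entropy_log_m(self, mask64):
        m = np.where(mask64, 1.0, 0.0)
        n_sel = max(1, int(0.10 * mask64.sum()))
        assert topq_entropy(m, mask64) == pytest.approx(np.log(n_sel))

    def test_point_mass_entropy_near_zero(self, mask64):
        m = np.where(mask64, 1e-9, 0.0)
        m[32, 32] = 1e9
        assert topq_entropy(m, mask64) < 0.01

    def test_entropy_bounds_and_monotone_concentration(self, mask64):
        yy, xx = np.mgrid[0:64, 0:64]
        n_sel = max(1, int(0.10 * mask64.sum()))
        prev = np.inf
        for width in (32.0, 8.0, 2.0, 0.5):
            m = np.exp(-((yy - 32) ** 2 + (xx - 32) ** 2) / (2 * width ** 2))
            ent = topq_entropy(m, mask64)
            assert 0.0 <= ent <= np.log(n_sel) + 1e-12
            assert ent <= prev + 1e-12
            prev = ent

    def test_static_map_zero_drift(self, mask64):
        rng = np.random.default_rng(8)
        m = np.abs(rng.normal(size=(64, 64))) + 0.1
        drift = center_of_mass_drift({0: m, 1: m.copy()},
                                     {0: mask64, 1: mask64})
        assert drift == {0: 0.0}

    def test_translation_gives_pythagorean_drift(self):
        yy, xx = np.mgrid[0:64, 0:64]
        full = np.ones((64, 64), bool)
        a = np.exp(-((yy - 20) ** 2 + (xx - 20) ** 2) / 18.0) + 0.01
        b = np.exp(-((yy - 23) ** 2 + (xx - 24) ** 2) / 18.0) + 0.01
        drift = center_of_mass_drift({0: a, 1: b}, {0: full, 1: full})
        assert drift[0] == pytest.approx(5.0, abs=0.05)

    def test_missing_intermediate_loop_skipped(self, mask64):
        rng = np.random.default_rng(9)
        m = np.abs(rng.normal(size=(64, 64))) + 0.1
        drift = center_of_mass_drift({0: m, 2: m, 3: m},
                                     {0: mask64, 2: mask64, 3: mask64})
        assert set(drift) == {2}

    def test_com_matches_brute_force(self, mask64):
        rng = np.random.default_rng(10)
        m = np.abs(rng.normal(size=(64, 64))) + 0.1
        got = topq_center_of_mass(m, mask64)
        vals = m[mask64]
        n_sel = max(1, int(0.10 * vals.size))
        order = np.argsort(-vals, kind="stable")[:n_sel]
        coords = np.argwhere(mask64)[order]
        weights = vals[order] / vals[order].sum()
        want = (coords * weights[:, None]).sum(axis=0)
        assert np.allclose(got, want, atol=1e-9)


class TestSuperpixelVotes:
    def test_identical_methods_share_every_vote(self, mask64):
        maps = synthesize_saliency_maps(mask64, ["IG", "GC", "DLS", "OCC"],
                                        ["m"], n_loops=1, agreement=1.0, seed=0)
        seg = slic_superpixels(maps[0].map, mask64)
        out = superpixel_votes({m.method_id: m.map for m in maps}, mask64, seg)
        votes = list(out["votes"].values())
        assert all(v == votes[0] for v in votes)
        frac_voted = len(votes[0]) / out["n_regions"]
        assert out["agreement_fractions"][2] == pytest.approx(frac_voted)
        assert out["agreement_fractions"][4] == pytest.approx(frac_voted)

    def test_disjoint_hotspots_no_agreement(self, mask64):
        seg = slic_superpixels(np.zeros((64, 64)), mask64, n_segments=50)
        regions = sorted(set(seg[mask64 & (seg > 0)]))
        rng = np.random.default_rng(11)
        base = rng.normal(0, 0.01, (64, 64))
        a, b = base.copy(), base.copy()
        a[seg == regions[0]] = 10.0   # method A's hotspot
        b[seg == regions[-1]] = 10.0  # method B's, elsewhere
        out = superpixel_votes({"a": a, "b": b}, mask64, seg, q=0.02)
        assert out["agreement_fractions"][2] == 0.0

    def test_random_maps_match_permutation_oracle(self, mask64):
        # two independent methods each vote v regions out of n: the expected
        # >=2-agreement fraction is E[|A & B|]/n = v^2/n^2
        rng = np.random.default_rng(12)
        seg = slic_superpixels(np.zeros((64, 64)), mask64, n_segments=50)
        fracs = []
        for _ in range(150):
            a = rng.normal(size=(64, 64))
            b = rng.normal(size=(64, 64))
            out = superpixel_votes({"a": a, "b": b}, mask64, seg)
            fracs.append(out["agreement_fractions"][2])
        n = out["n_regions"]
        v = max(1, int(np.floor(0.10 * n)))
        expected = v ** 2 / n ** 2
        mc_err = 3 * np.std(fracs) / np.sqrt(len(fracs))
        assert np.mean(fracs) == pytest.approx(expected, abs=max(mc_err, 0.01))


class TestStore:
    def test_hdf5_roundtrip(self, tmp_path, mask64):
        maps = synthesize_saliency_maps(mask64, ["IG_NT", "GC"],
                                        ["densenet", "resnet"], n_loops=2,
                                        agreement=0.5, seed=13)
        path = tmp_path / "maps.h5"
        save_saliency_store(path, maps)
        back = load_saliency_store(path)
        assert len(back) == len(maps)
        key = lambda m: (m.well_id, m.loop, m.model_id, m.method_id)  # noqa: E731
        orig = {key(m): m for m in maps}
        for m in back:
            assert np.allclose(m.map, orig[key(m)].map, atol=1e-6)
            assert np.array_equal(m.mask, orig[key(m)].mask)

    def test_condition_validation(self, mask64):
        with pytest.raises(ValueError, match="condition"):
            SaliencyMap("m", "IG", "W0", 0, np.zeros((4, 4)),
                        np.ones((4, 4), bool), condition="bogus")

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="share shape"):
            SaliencyMap("m", "IG", "W0", 0, np.zeros((4, 4)),
                        np.ones((5, 5), bool))
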