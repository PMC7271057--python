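import numpy as np
import pytest

from conftest import two_valued_instance
from oracles import exhaustive_minimum, naive_smoothness
from renoseg.distributions import (
    IntensityDistribution,
    KernelSpec,
    bhattacharyya,
    kde_estimate,
    make_bins,
)
from renoseg.image_model import DomainPartition, IntensityImage, split_domain
from renoseg.metrics_stats import dice
from renoseg.phantom import PhantomSpec, make_slice
from renoseg.segmentation import (
    DegenerateRegionError,
    EmptySegmentationError,
    EnergyParams,
    LabelMap,
    _EnergyState,
    evaluate_energy,
    extract_kidneys,
    matching_term,
    neighbor_pairs,
    optimize_labeling,
    smoothness_term,
)


def small_partition(h, w, split):
    phi_s = np.zeros((h, w), dtype=bool)
    phi_s[:, :split] = True
    return DomainPartition(
        phi_s=phi_s, phi_s_bar=~phi_s, split_kind="vertical",
        split_index=split, side_choice="right_kidney",
    )


class TestMatchingTerm:
    def test_hand_computed_value(self):
        model = IntensityDistribution(
            bin_centers=np.array([0.0, 1.0]), probabilities=np.array([0.9, 0.1])
        )
        m = matching_term(np.array([0.0, 0.0, 1.0, 1.0]), model, KernelSpec("dirac"))
        assert m == pytest.approx(-(np.sqrt(0.45) + np.sqrt(0.05)), abs=1e-12)

    def test_disjoint_support_gives_zero(self):
        model = IntensityDistribution(
            bin_centers=np.array([0.0, 1.0]), probabilities=np.array([1.0, 0.0])
        )
        assert matching_term(np.array([1.0, 1.0]), model, KernelSpec("dirac")) == 0.0

    def test_sampling_from_model_approaches_minus_one(self, rng):
        bins = make_bins(np.arange(0.0, 8.0), n_bins=8)
        base = rng.integers(0, 8, size=20000).astype(float)
        model = kde_estimate(base, KernelSpec("dirac"), bins)
        sample = rng.choice(base, size=20000)
        assert matching_term(sample, model, KernelSpec("dirac")) < -0.99

    def test_empty_region_rejected(self):
        model = IntensityDistribution(
            bin_centers=np.array([0.0, 1.0]), probabilities=np.array([0.5, 0.5])
        )
        with pytest.raises(DegenerateRegionError):
            matching_term(np.array([]), model, KernelSpec("dirac"))


class TestSmoothnessTerm:
    def test_constant_labelings_have_zero_boundary(self):
        part = small_partition(3, 6, 3)
        for fill in (0, 1):
            lm = LabelMap(partition=part, labels=np.full(9, fill))
            assert smoothness_term(lm, 8) == 0.0

    def test_two_column_split_four_connectivity(self):
        # 2x2 phi_s labeled [[1,0],[1,0]]: two horizontal cut pairs, weight 1
        part = small_partition(2, 4, 2)
        lm = LabelMap(partition=part, labels=np.array([1, 0, 1, 0]))
        assert smoothness_term(lm, 4) == pytest.approx(2.0)

    def test_checkerboard_eight_connectivity(self):
        # [[1,0],[0,1]]: 4 axial disagreements (w=1), diagonals agree
        part = small_partition(2, 4, 2)
        lm = LabelMap(partition=part, labels=np.array([1, 0, 0, 1]))
        assert smoothness_term(lm, 8) == pytest.approx(4.0)

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_enumeration_oracle(self, connectivity, rng):
        part = small_partition(5, 10, 5)
        for _ in range(10):
            lab = rng.integers(0, 2, size=25)
            lm = LabelMap(partition=part, labels=lab)
            assert smoothness_term(lm, connectivity) == pytest.approx(
                naive_smoothness(lab, part.phi_s, connectivity), abs=1e-12
            )

    def test_pairs_crossing_phi_s_ignored(self):
        i, j, w = neighbor_pairs(small_partition(2, 4, 2).phi_s, 8)
        # 2x2 block: 2 horizontal + 2 vertical + 2 diagonal pairs
        assert len(i) == 6
        assert w.sum() == pytest.approx(4 + 2 / np.sqrt(2))


class TestEvaluateEnergy:
    def test_component_wise_recomputation(self, rng):
        """C(L) equals −B + γ·smoothness recomputed with independent calls."""
        for trial in range(5):
            vals = rng.integers(0, 40, size=(4, 8)).astype(float)
            image = IntensityImage(values=vals)
            part = small_partition(4, 8, 4)
            params = EnergyParams(gamma=0.3, kernel=KernelSpec("dirac"), n_bins=64)
            bins = make_bins(vals, 64)
            model = kde_estimate(vals[part.phi_s_bar], params.kernel, bins)
            lab = rng.integers(0, 2, size=16)
            if lab.sum() == 0:
                lab[0] = 1
            lm = LabelMap(partition=part, labels=lab)
            e = evaluate_energy(lm, image, part, params, model)
            p_e = kde_estimate(vals[part.phi_s][lab == 1], params.kernel, bins)
            expect = -bhattacharyya(p_e, model) + 0.3 * naive_smoothness(
                lab, part.phi_s, 8
            )
            assert e == pytest.approx(expect, abs=1e-10)

    def test_constant_labeling_matches_phi_s_distribution(self, rng):
        vals = rng.integers(0, 40, size=(4, 8)).astype(float)
        image = IntensityImage(values=vals)
        part = small_partition(4, 8, 4)
        params = EnergyParams(gamma=5.0, kernel=KernelSpec("dirac"), n_bins=64)
        bins = make_bins(vals, 64)
        model = kde_estimate(vals[part.phi_s_bar], params.kernel, bins)
        lm = LabelMap(partition=part, labels=np.ones(16))
        e = evaluate_energy(lm, image, part, params, model)
        assert e == pytest.approx(
            matching_term(vals[part.phi_s], model, params.kernel), abs=1e-12
        )


class TestBoundContract:
    """The auxiliary objective must upper-bound C on shrink moves and touch it."""

    @pytest.mark.parametrize("kernel", [KernelSpec("dirac"),
                                        KernelSpec("gaussian", sigma=3.0)])
    def test_upper_bound_and_tightness(self, kernel, rng):
        vals = rng.integers(0, 30, size=(3, 6)).astype(float)
        image = IntensityImage(values=vals)
        part = small_partition(3, 6, 3)
        params = EnergyParams(gamma=0.05, kernel=kernel, n_bins=32)
        state = _EnergyState(image, part, params)
        L = (rng.random(9) < 0.7).astype(float)
        L[:2] = 1
        costs = state.removal_costs(L)
        e_idx = np.flatnonzero(L == 1)
        c_l = state.energy(L)
        aux0 = -state.bhatt(L) + params.gamma * state.smooth(L)
        assert aux0 == pytest.approx(c_l, abs=1e-12)  # tight at the current L
        for bits in range(1, 2 ** len(e_idx) - 1):
            u = (bits >> np.arange(len(e_idx))) & 1
            lp = L.copy()
            lp[e_idx[u.astype(bool)]] = 0
            aux = -state.bhatt(L) + float(costs @ u) + params.gamma * state.smooth(lp)
            assert aux >= state.energy(lp) - 1e-10


class TestOptimizer:
    @pytest.mark.parametrize("method", ["bound", "sweep"])
    def test_two_valued_instances_reach_global_minimum(self, method, rng):
        """On separated two-valued 4×4 instances the final energy equals the
        exhaustive minimum over all 2^16 labelings."""
        for _ in range(20):
            image, part, params = two_valued_instance(rng, gamma=0.0)
            res = optimize_labeling(image, part, params, method=method)
            best, _ = exhaustive_minimum(image, part, params)
            assert res.energy == pytest.approx(best, abs=1e-6)

    def test_kidney_mask_is_high_value_pixels(self, rng):
        image, part, params = two_valued_instance(rng, gamma=0.0)
        res = optimize_labeling(image, part, params)
        high = (image.values == 200.0) & part.phi_s
        assert np.array_equal(res.kidney_mask, high)

    def test_nothing_to_segment(self, rng):
        """Φs drawn from the model distribution: empty-or-singleton kidney."""
        # both halves share the same value pool exactly
        half = rng.integers(0, 5, size=(6, 6)).astype(float)
        image = IntensityImage(values=np.hstack([half, rng.permuted(half, axis=1)]))
        part = small_partition(6, 12, 6)
        params = EnergyParams(gamma=0.01, kernel=KernelSpec("dirac"), n_bins=16)
        res = optimize_labeling(image, part, params)
        assert res.kidney_mask.sum() <= 1
        assert res.energy <= res.energy_trace[0] + 1e-12

    def test_trace_monotone_and_shrink_on_phantoms(self):
        for seed in (0, 1, 2):
            spec = PhantomSpec.make("normal", seed=seed)
            image, _ = make_slice(spec)
            part = split_domain(image, "two_kidneys")
            res = optimize_labeling(image, part, EnergyParams())
            diffs = np.diff(res.energy_trace)
            assert np.all(diffs <= 1e-9)
            assert res.shrink_monotone
            assert res.iterations <= 10

    def test_local_optimality_at_convergence(self, rng):
        """No single 1→0 flip strictly decreases C (exhaustive, ≤ 8×8)."""
        for trial in range(5):
            image, part, params = two_valued_instance(
                rng, gamma=0.02, shape=(6, 6)
            )
            res = optimize_labeling(image, part, params)
            state = _EnergyState(image, part, params)
            L = res.final_labels.labels.astype(float)
            c0 = state.energy(L)
            for x in np.flatnonzero(L == 1):
                if L.sum() <= 1:
                    break
                lp = L.copy()
                lp[x] = 0
                assert state.energy(lp) >= c0 - 1e-9

    def test_gamma_never_lengthens_boundary(self):
        spec = PhantomSpec.make("normal", seed=3)
        image, _ = make_slice(spec)
        part = split_domain(image, "two_kidneys")
        i, j, _ = neighbor_pairs(part.phi_s, 8)
        lengths = []
        for gamma in (0.0, 0.1, 1.0, 10.0):
            with pytest.warns(UserWarning) if gamma > 0 else _nullcontext():
                res = optimize_labeling(image, part, EnergyParams(gamma=gamma))
            lab = res.final_labels.labels
            lengths.append(int((lab[i] != lab[j]).sum()))
        assert lengths == sorted(lengths, reverse=True)

    def test_tiny_phi_s_rejected(self, rng):
        image, _, params = two_valued_instance(rng)
        phi_s = np.zeros(image.shape, dtype=bool)
        phi_s[0, 0] = True
        single = DomainPartition(
            phi_s=phi_s, phi_s_bar=~phi_s, split_kind="vertical",
            split_index=1, side_choice="right_kidney",
        )
        with pytest.raises(DegenerateRegionError):
            optimize_labeling(image, single, params)


class _nullcontext:
    def __enter__(self):
        return self

    def __exit__(self, *exc):
        return False


class TestExtractKidneys:
    def _result_with_mask(self, mask):
        h, w = mask.shape
        phi_s = np.zeros((h, 2 * w), dtype=bool)
        phi_s[:, :w] = True
        part = DomainPartition(
            phi_s=phi_s, phi_s_bar=~phi_s, split_kind="vertical",
            split_index=w, side_choice="right_kidney",
        )
        labels = np.where(mask[phi_s[:, :w]], 0, 1)
        full_mask = np.zeros((h, 2 * w), dtype=bool)
        full_mask[:, :w] = mask
        from renoseg.segmentation import SegmentationResult

        return SegmentationResult(
            final_labels=LabelMap(partition=part, labels=labels),
            kidney_mask=full_mask, energy_trace=[0.0], iterations=1,
            matching_term=0.0, smoothness_term=0.0,
        )

    def test_largest_component_kept(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:12, 2:7] = True  # 50-pixel blob
        mask[16, 15:17] = True  # 2-pixel speck
        res = self._result_with_mask(mask)
        out = extract_kidneys(res, "right_kidney")
        assert out["right"].sum() == 50

    def test_two_kidneys_assigned_by_centroid_column(self):
        spec = PhantomSpec.make("normal", seed=5)
        image, masks = make_slice(spec)
        part = split_domain(image, "two_kidneys")
        res = optimize_labeling(image, part, EnergyParams())
        out = extract_kidneys(res, "two_kidneys")
        # patient right appears viewer-left (low columns) by convention
        from scipy import ndimage

        col_r = ndimage.center_of_mass(out["right"])[1]
        col_l = ndimage.center_of_mass(out["left"])[1]
        assert col_r < col_l
        assert dice(out["right"], masks["right"]) > 0.9

    def test_empty_mask_raises(self):
        res = self._result_with_mask(np.zeros((6, 6), dtype=bool))
        with pytest.raises(EmptySegmentationError):
            extract_kidneys(res, "right_kidney")

    def test_single_component_in_two_kidney_mode_warns(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:6, 2:6] = True
        res = self._result_with_mask(mask)
        with pytest.warns(UserWarning):
            out = extract_kidneys(res, "two_kidneys")
        assert "single" in out
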