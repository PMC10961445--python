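"""Designed field, constrained least squares, subset search, normalization."""

import itertools

import numpy as np
import pytest

from tesopt.leadfield import LeadFieldDataset, Montage, MontageSet, enumerate_montages
from tesopt.optimize import (
    DesignField,
    build_design_field,
    electrode_currents,
    normalize_to_level,
    optimize_electrode_subset,
    rmse,
    solve_weights,
)


def make_dataset(matrix: np.ndarray, n_montages: int) -> LeadFieldDataset:
    """Small synthetic dataset wrapper for pure-optimizer tests."""
    n = matrix.shape[0] // 3
    montages = tuple(Montage(0, i + 1) for i in range(n_montages))
    return LeadFieldDataset(
        matrix=matrix,
        mode="volume",
        region="deep",
        elements_mm=np.zeros((n, 3)),
        element_voxels=np.zeros((n, 3), dtype=int),
        montage_set=MontageSet(tuple(range(n_montages + 1)), montages),
    )


def design_from_vector(b: np.ndarray) -> DesignField:
    return DesignField(vector=b, target_elements=np.arange(len(b) // 3), e0=np.array([1.0, 0, 0]))


class TestDesignField:
    def test_direction_normalized(self, toy_surface_dataset, toy_setup):
        design = build_design_field(
            toy_surface_dataset["dataset"], toy_setup["model"].masks["target"], (2.0, 0.0, 0.0)
        )
        assert np.allclose(design.e0, [1.0, 0.0, 0.0])

    def test_sum_of_squares_equals_target_count(self, toy_surface_dataset):
        design = toy_surface_dataset["design"]
        assert np.sum(design.vector**2) == pytest.approx(design.n_target)

    def test_zero_on_complement(self, toy_surface_dataset):
        design = toy_surface_dataset["design"]
        n = len(design.vector) // 3
        comp = np.setdiff1d(np.arange(n), design.target_elements)
        rows = (3 * comp[:, None] + np.arange(3)).ravel()
        assert np.all(design.vector[rows] == 0)

    def test_full_target_tiles_e0(self, toy_surface_dataset, toy_setup):
        ds = toy_surface_dataset["dataset"]
        design = build_design_field(ds, toy_setup["model"].masks["deep"], (0.0, 0.0, 5.0))
        assert np.allclose(design.vector.reshape(-1, 3), [0.0, 0.0, 1.0])

    def test_empty_target_raises(self, toy_surface_dataset, toy_setup):
        with pytest.raises(ValueError):
            build_design_field(
                toy_surface_dataset["dataset"],
                np.zeros_like(toy_setup["model"].masks["target"]),
                (1, 0, 0),
            )

    def test_zero_direction_raises(self, toy_surface_dataset, toy_setup):
        with pytest.raises(ValueError):
            build_design_field(
                toy_surface_dataset["dataset"], toy_setup["model"].masks["target"], (0, 0, 0)
            )


class TestSolveWeights:
    def test_exactly_representable_design(self):
        rng = np.random.default_rng(1)
        col = rng.normal(size=(12, 1))
        ds = make_dataset(col, 1)
        sol = solve_weights(ds, design_from_vector(1.5 * col[:, 0]))
        assert sol.w[0] == pytest.approx(1.5, abs=1e-8)
        assert sol.rmse == pytest.approx(0.0, abs=1e-8)

    def test_bound_clips_active_constraint(self):
        rng = np.random.default_rng(2)
        col = rng.normal(size=(12, 1))
        ds = make_dataset(col, 1)
        sol = solve_weights(ds, design_from_vector(3.0 * col[:, 0]), bound=2.0)
        assert sol.w[0] == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", [42, 7, 19])
    def test_matches_grid_search_oracle(self, seed):
        """m=2 instance vs exhaustive search over w in [-2,2]^2 at 1e-3 step
        (coarse pass then 1e-3 refinement around the coarse optimum)."""
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(12, 2))
        b = rng.normal(size=12) * 2.0
        ds = make_dataset(A, 2)
        sol = solve_weights(ds, design_from_vector(b))

        def objective(w):
            r = A @ w - b
            return r @ r

        g = np.arange(-2.0, 2.0001, 0.01)
        coarse = min(((objective(np.array([w1, w2])), w1, w2) for w1 in g for w2 in g))
        f1 = np.clip(np.arange(coarse[1] - 0.02, coarse[1] + 0.0201, 1e-3), -2, 2)
        f2 = np.clip(np.arange(coarse[2] - 0.02, coarse[2] + 0.0201, 1e-3), -2, 2)
        best = min(objective(np.array([w1, w2])) for w1 in f1 for w2 in f2)
        assert objective(sol.w) <= best + 1e-2

    def test_feasibility_and_kkt(self, toy_surface_dataset):
        ds = toy_surface_dataset["dataset"].subset_columns(range(10))
        sol = solve_weights(ds, toy_surface_dataset["design"])
        assert np.all(np.abs(sol.w) <= 2.0 + 1e-9)
        assert sol.kkt_ok
        assert sol.status == "converged"

    def test_dimension_mismatch_raises(self):
        ds = make_dataset(np.ones((12, 2)), 2)
        with pytest.raises(ValueError):
            solve_weights(ds, design_from_vector(np.ones(9)))


class TestRmse:
    def test_exact_fit_zero(self):
        col = np.arange(1.0, 13.0)[:, None]
        ds = make_dataset(col, 1)
        assert rmse(ds, np.array([1.0]), design_from_vector(col[:, 0])) == 0.0

    def test_zero_weights_give_design_norm(self, toy_surface_dataset):
        ds, design = toy_surface_dataset["dataset"], toy_surface_dataset["design"]
        expected = np.sqrt(design.n_target / (3 * ds.n_elements))
        assert rmse(ds, np.zeros(171), design) == pytest.approx(expected)

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(15, 4))
        b = rng.normal(size=15)
        w = rng.uniform(-2, 2, size=4)
        ds = make_dataset(A, 4)
        total = 0.0
        for i in range(15):
            pred = sum(A[i, j] * w[j] for j in range(4))
            total += (pred - b[i]) ** 2
        assert rmse(ds, w, design_from_vector(b)) == pytest.approx(np.sqrt(total / 15))


class TestElectrodeCurrents:
    def test_signed_sum_example(self):
        mset = MontageSet((0, 1, 2), (Montage(0, 1), Montage(0, 2)))
        cur = electrode_currents(np.array([1.0, 1.0]), mset)
        assert cur.as_dict() == pytest.approx({0: 2e-3, 1: -1e-3, 2: -1e-3})

    def test_zero_weights_zero_currents(self, toy_surface_dataset):
        mset = toy_surface_dataset["dataset"].montage_set
        cur = electrode_currents(np.zeros(len(mset)), mset)
        assert np.all(cur.currents_a == 0)

    def test_negation_and_zero_sum(self):
        rng = np.random.default_rng(4)
        mset = enumerate_montages(range(5))
        w = rng.uniform(-2, 2, size=len(mset))
        pos = electrode_currents(w, mset)
        neg = electrode_currents(-w, mset)
        assert np.allclose(pos.currents_a, -neg.currents_a)
        assert pos.currents_a.sum() == pytest.approx(0.0, abs=1e-15)


class TestNormalization:
    def test_scale_ratio_and_exact_level(self, toy_setup, toy_surface_dataset):
        model = toy_setup["model"]
        bank = toy_setup["bank"]
        result = optimize_electrode_subset(
            bank,
            model,
            k=2,
            mode="surface",
            full_dataset=toy_surface_dataset["dataset"],
            target_rows=toy_surface_dataset["target_rows"],
        )
        assert result.target_mean_v_per_m == pytest.approx(0.4, rel=1e-9)
        # pre-normalization average (scale 1) times scale equals the level
        from tesopt.optimize import _target_average

        idx = [
            i
            for i, m in enumerate(toy_surface_dataset["dataset"].montage_set)
            if (m.anode, m.cathode)
            in {(mm.anode, mm.cathode) for mm in result.montage_set}
        ]
        pre = _target_average(toy_surface_dataset["target_rows"][:, idx], result.weights.w)
        assert result.scale == pytest.approx(0.4 / pre, rel=1e-9)

    def test_idempotent(self, toy_setup, toy_surface_dataset):
        result = optimize_electrode_subset(
            toy_setup["bank"],
            toy_setup["model"],
            k=2,
            mode="surface",
            full_dataset=toy_surface_dataset["dataset"],
            target_rows=toy_surface_dataset["target_rows"],
        )
        idx = [
            i
            for i, m in enumerate(toy_surface_dataset["dataset"].montage_set)
            if (m.anode, m.cathode)
            in {(mm.anode, mm.cathode) for mm in result.montage_set}
        ]
        again = normalize_to_level(result, toy_surface_dataset["target_rows"][:, idx])
        assert again.scale == pytest.approx(result.scale, rel=1e-12)
        assert np.allclose(again.currents.currents_a, result.currents.currents_a)


class TestSubsetSearch:
    def test_k_equal_n_evaluates_single_subset(self, six_electrode_bank, toy_setup):
        result = optimize_electrode_subset(six_electrode_bank, toy_setup["model"], k=6)
        assert result.electrodes == tuple(range(6))

    def test_k_out_of_range(self, six_electrode_bank, toy_setup):
        with pytest.raises(ValueError):
            optimize_electrode_subset(six_electrode_bank, toy_setup["model"], k=1)
        with pytest.raises(ValueError):
            optimize_electrode_subset(six_electrode_bank, toy_setup["model"], k=7)

    def test_exhaustive_replay_oracle(self, six_electrode_bank, toy_setup):
        """Independent re-enumeration of all C(6,3)=20 subsets reproduces the
        winner's RMSE as the minimum."""
        from tesopt.leadfield import build_dataset

        model = toy_setup["model"]
        bank = six_electrode_bank
        result = optimize_electrode_subset(bank, model, k=3, mode="surface", cap_ma=None)

        all_mont = enumerate_montages(range(6))
        full = build_dataset(bank, all_mont, model, "deep", mode="surface")
        design = build_design_field(full, model.masks["target"], (0.0, 1.0, 0.0))
        col = {(m.anode, m.cathode): j for j, m in enumerate(all_mont)}
        rmses = []
        for subset in itertools.combinations(range(6), 3):
            mset = enumerate_montages(subset)
            ds = full.subset_columns([col[(m.anode, m.cathode)] for m in mset])
            rmses.append(solve_weights(ds, design).rmse)
        assert len(rmses) == 20
        assert result.rmse == pytest.approx(min(rmses), rel=1e-9)

    def test_rmse_monotone_in_k_without_cap(self, six_electrode_bank, toy_setup):
        """A k-subset solution embeds in a (k+1)-subset with zero extra
        weights, so the unconstrained best RMSE cannot increase with k."""
        model = toy_setup["model"]
        best = [
            optimize_electrode_subset(
                six_electrode_bank, model, k=k, mode="surface", cap_ma=None
            ).rmse
            for k in (2, 3, 4, 5)
        ]
        for lo, hi in zip(best[1:], best[:-1]):
            assert lo <= hi + 1e-12

    def test_surface_and_volume_modes_agree_on_target_field(self, toy_setup, toy_surface_dataset):
        """Per-unit-scale target field of the two optimization modes within 20%."""
        model, bank = toy_setup["model"], toy_setup["bank"]
        res_s = optimize_electrode_subset(
            bank,
            model,
            k=2,
            mode="surface",
            full_dataset=toy_surface_dataset["dataset"],
            target_rows=toy_surface_dataset["target_rows"],
        )
        res_v = optimize_electrode_subset(
            bank,
            model,
            k=2,
            mode="volume",
            full_dataset=toy_surface_dataset["volume_dataset"],
            target_rows=toy_surface_dataset["target_rows"],
        )
        pre_s = res_s.level / res_s.scale
        pre_v = res_v.level / res_v.scale
        assert pre_s == pytest.approx(pre_v, rel=0.2)

    def test_reported_solution_respects_weight_bound(self, six_electrode_bank, toy_setup):
        result = optimize_electrode_subset(six_electrode_bank, toy_setup["model"], k=4)
        assert np.all(np.abs(result.weights.w) <= 2.0 + 1e-9)

    def test_infeasible_when_cap_tiny(self, six_electrode_bank, toy_setup):
        result = optimize_electrode_subset(
            six_electrode_bank, toy_setup["model"], k=3, cap_ma=1e-9
        )
        assert not result.feasible
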