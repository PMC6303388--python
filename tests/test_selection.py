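"""Selection stage: cell-consistency filter, multi-crystal scaling,
error-model/ISa fitting (with a grid-search oracle), rejection rules."""

import math

import numpy as np
import pandas as pd
import pytest

import ssxmerge as sx
from ssxmerge.datasets import ObservationSet
from ssxmerge.selection import (
    _loo_reference,
    build_observation_table,
    check_cell_consistency,
    fit_error_model,
    fit_error_models,
    run_selection,
    scale_datasets,
)
from ssxmerge.symmetry import UnitCell, space_group


def _obs_from_truth(truth, dataset_id, factor=1.0, b_rel=0.0, sigma=1.0):
    """Noiseless dataset: intensities are an exact scaled copy of truth."""
    d = truth.d
    g = factor * np.exp(-b_rel / (2 * d * d))
    return ObservationSet(
        dataset_id=dataset_id,
        cell=truth.cell,
        hkl=truth.hkl.copy(),
        intensity=g * truth.intensity,
        sigma_raw=np.full(truth.n_unique, sigma),
    )


# ---------------------------------------------------------------------------
# Cell filter
# ---------------------------------------------------------------------------

class TestCellFilter:
    REF = UnitCell(60.8, 68.8, 257.0)

    def _ds(self, cell):
        return ObservationSet("d", cell, np.array([[1, 1, 2]]),
                              np.array([1.0]), np.array([1.0]))

    def test_native_vs_zn_edge_spread_accepted(self):
        # the two crystal forms of the same protein differ by <= ~1.3%
        rep = check_cell_consistency(
            [self._ds(UnitCell(61.41, 69.69, 258.15))], self.REF,
            length_tol=0.02, angle_tol=2.0,
        )
        chk = rep.checks[0]
        assert chk.accepted
        assert chk.max_length_dev == pytest.approx(0.89 / 68.8, rel=1e-3)

    def test_misindexed_axis_rejected_with_named_axis(self):
        rep = check_cell_consistency(
            [self._ds(UnitCell(63.5, 68.8, 257.0))], self.REF)
        chk = rep.checks[0]
        assert not chk.accepted
        assert "axis a" in chk.reason
        assert chk.max_length_dev == pytest.approx(2.7 / 60.8, rel=1e-3)

    def test_identical_cell_has_zero_deviations(self):
        chk = check_cell_consistency([self._ds(self.REF)], self.REF).checks[0]
        assert chk.accepted and chk.max_length_dev == 0 and chk.max_angle_dev == 0

    def test_angle_deviation_rejected(self):
        cell = UnitCell(60.8, 68.8, 257.0, 90, 93.0, 90)
        chk = check_cell_consistency([self._ds(cell)], self.REF).checks[0]
        assert not chk.accepted and "angle beta" in chk.reason

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            check_cell_consistency([], self.REF)


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def mini_truth(c2221):
    return sx.make_ground_truth(UnitCell(30, 34, 44), c2221, 3.0,
                                scale_C=1000.0, wilson_B=20.0, seed=1)


class TestScaling:
    def test_exact_two_dataset_gauge_case(self, mini_truth, c2221):
        d1 = _obs_from_truth(mini_truth, "a")
        d2 = _obs_from_truth(mini_truth, "b", factor=0.5)
        model, _ = scale_datasets([d1, d2], c2221)
        assert model.gauge_id == "a"
        assert model.K("a") == pytest.approx(1.0)
        assert model.B("a") == pytest.approx(0.0)
        assert model.K("b") == pytest.approx(0.5, abs=1e-6)
        assert model.B("b") == pytest.approx(0.0, abs=1e-4)
        assert model.converged

    def test_planted_relative_b_recovered_exactly_without_noise(
        self, mini_truth, c2221
    ):
        d1 = _obs_from_truth(mini_truth, "a")
        d2 = _obs_from_truth(mini_truth, "b", b_rel=20.0)
        model, _ = scale_datasets([d1, d2], c2221)
        assert model.B("b") == pytest.approx(20.0, abs=0.1)

    def test_gauge_invariance_under_global_intensity_rescale(
        self, mini_truth, c2221
    ):
        d1 = _obs_from_truth(mini_truth, "a")
        d2 = _obs_from_truth(mini_truth, "b", factor=0.7, b_rel=5.0)
        m1, _ = scale_datasets([d1, d2], c2221)
        d1s = ObservationSet("a", d1.cell, d1.hkl, d1.intensity * 1000,
                             d1.sigma_raw * 1000)
        d2s = ObservationSet("b", d2.cell, d2.hkl, d2.intensity * 1000,
                             d2.sigma_raw * 1000)
        m2, _ = scale_datasets([d1s, d2s], c2221)
        assert m2.K("b") == pytest.approx(m1.K("b"), rel=1e-6)
        assert m2.B("b") == pytest.approx(m1.B("b"), abs=1e-6)

    def test_noisy_benchmark_recovers_planted_scales(
        self, recovery, recovery_selection
    ):
        specs = {s.dataset_id: s for s in recovery.specs}
        scaling = recovery_selection.rounds[-1].scaling
        rel = [
            abs(sf.K - specs[d].K) / specs[d].K
            for d, sf in scaling.factors.items()
        ]
        assert float(np.median(rel)) < 0.03

    def test_disconnected_graph_raises(self, c2221):
        cell = UnitCell(30, 34, 44)
        d1 = ObservationSet("a", cell, np.array([[1, 1, 2], [2, 0, 2]]),
                            np.array([5.0, 6.0]), np.array([1.0, 1.0]))
        d2 = ObservationSet("b", cell, np.array([[3, 1, 2], [2, 2, 4]]),
                            np.array([5.0, 6.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError, match="disconnected"):
            scale_datasets([d1, d2], c2221)

    def test_round_two_does_not_degrade_scale_recovery(
        self, benchmark, benchmark_selection
    ):
        specs = {s.dataset_id: s for s in benchmark.specs}

        def rms_rel_err(rnd):
            errs = [
                (sf.K - specs[d].K) / specs[d].K
                for d, sf in rnd.scaling.factors.items()
                if d in rnd.retained
            ]
            return float(np.sqrt(np.mean(np.square(errs))))

        r1, r2 = benchmark_selection.rounds[0], benchmark_selection.rounds[-1]
        assert rms_rel_err(r2) <= rms_rel_err(r1) + 1e-9


# ---------------------------------------------------------------------------
# Error model / ISa
# ---------------------------------------------------------------------------

def _single_dataset_table(truth, sg, spec):
    obs = sx.simulate_dataset(truth, spec)
    tab = build_observation_table([obs], sg, truth.cell)
    tab["i_scaled"] = tab["i_obs"]
    tab["sigma_scaled"] = tab["sigma_raw"]
    return tab


class TestErrorModel:
    def test_pure_sigma_inflation_gives_infinite_isa(self, mini_truth, c2221):
        spec = sx.DatasetSpec("ds", err_a=1.0, err_b=0.0, coverage=1.0,
                              multiplicity=3.0, seed=5)
        tab = _single_dataset_table(mini_truth, c2221, spec)
        fits, _ = fit_error_models(tab)
        f = fits["ds"]
        assert f.b <= 1e-6
        assert math.isinf(f.isa)
        assert f.as_dict()["isa"] == "inf"

    def test_planted_isa_recovered_within_fifteen_percent(self, c2221):
        truth = sx.make_ground_truth(UnitCell(52, 60, 108), c2221, 3.0,
                                     scale_C=2000.0, wilson_B=40.0, seed=2)
        a_t, b_t = 1.2, 4e-4
        isa_t = (a_t * b_t) ** -0.5  # ~45.6
        spec = sx.DatasetSpec("ds", err_a=a_t, err_b=b_t, coverage=1.0,
                              multiplicity=3.0, seed=9)
        tab = _single_dataset_table(truth, c2221, spec)
        fits, _ = fit_error_models(tab)
        f = fits["ds"]
        assert f.n_pairs >= 2000
        assert f.isa == pytest.approx(isa_t, rel=0.15)

    def test_fitted_isa_ordering_matches_planted(self, mini_truth, c2221):
        fitted = {}
        for isa in (1.5, 25.0):
            b = 1.0 / (1.2 * isa * isa)
            spec = sx.DatasetSpec("ds", err_a=1.2, err_b=b, coverage=1.0,
                                  multiplicity=3.0, seed=9)
            tab = _single_dataset_table(mini_truth, c2221, spec)
            fits, _ = fit_error_models(tab)
            fitted[isa] = fits["ds"].isa
        assert fitted[1.5] < fitted[25.0]

    def test_isa_decreases_as_planted_error_product_grows(self, mini_truth, c2221):
        isas = []
        for ab in (1e-4, 1e-3, 1e-2):
            spec = sx.DatasetSpec("ds", err_a=1.0, err_b=ab, coverage=1.0,
                                  multiplicity=3.0, seed=9)
            tab = _single_dataset_table(mini_truth, c2221, spec)
            fits, _ = fit_error_models(tab)
            isas.append(fits["ds"].isa)
        assert isas[0] > isas[1] > isas[2]

    def test_too_few_pairs_raises_with_count(self, mini_truth, c2221):
        spec = sx.DatasetSpec("ds", coverage=0.02, multiplicity=2.0, seed=1)
        tab = _single_dataset_table(mini_truth, c2221, spec)
        tab = _loo_reference(tab)
        with pytest.raises(ValueError, match=r"only \d+ multiply-measured"):
            fit_error_model(tab, "ds", min_pairs=10 ** 6)

    def test_matches_grid_search_oracle_on_small_instance(self, c2221):
        """Brute-force (a, b) grid minimising the same binned objective
        must agree with the analytic least-squares solution."""
        truth = sx.make_ground_truth(UnitCell(26, 30, 40), c2221, 3.2,
                                     scale_C=1000.0, wilson_B=10.0, seed=3)
        spec = sx.DatasetSpec("ds", err_a=1.5, err_b=2e-3, coverage=1.0,
                              multiplicity=4.0, seed=3)
        tab = _single_dataset_table(truth, c2221, spec)
        tab = _loo_reference(tab)
        fit = fit_error_model(tab, "ds")

        rows = tab[(tab["n_group"] >= 2)].dropna(subset=["loo_ref"])
        resid = rows["i_scaled"].to_numpy() - rows["loo_ref"].to_numpy()
        s2 = rows["sigma_scaled"].to_numpy() ** 2
        iref = rows["loo_ref"].to_numpy()
        vref = rows["loo_var"].to_numpy()
        nb = max(3, min(5, len(rows) // 20))
        q = np.unique(np.quantile(iref, np.linspace(0, 1, nb + 1)))
        bins = np.clip(np.searchsorted(q, iref, side="right") - 1, 0, len(q) - 2)
        n_j = np.maximum(np.bincount(bins), 1)
        v_j = np.bincount(bins, weights=resid ** 2) / n_j
        v_j = v_j - np.bincount(bins, weights=vref) / n_j
        s_j = np.bincount(bins, weights=s2) / n_j
        m_j = np.bincount(bins, weights=iref ** 2) / n_j

        def objective(a, b):
            return float((n_j * (v_j - a * (s_j + b * m_j)) ** 2).sum())

        a_grid = np.linspace(0.5, 3.0, 120)
        b_grid = np.linspace(0.0, 6e-3, 160)
        vals = np.array([[objective(a, b) for b in b_grid] for a in a_grid])
        ia, ib = np.unravel_index(vals.argmin(), vals.shape)
        # agreement to within the grid resolution...
        assert fit.a == pytest.approx(a_grid[ia], abs=3 * 2.5 / 119)
        assert fit.b == pytest.approx(b_grid[ib], abs=2e-4)
        # ...and the analytic solution is at least as good as the best
        # grid point under the identical objective
        assert objective(fit.a, fit.b) <= vals.min() + 1e-9


# ---------------------------------------------------------------------------
# Two-round selection
# ---------------------------------------------------------------------------

class TestRunSelection:
    def test_strict_cutoff_keeps_dataset_exactly_at_threshold(self):
        # the rejection rule itself: isa < cutoff, not <=
        from ssxmerge.selection import ErrorModelFit
        fits = {
            "A": ErrorModelFit("A", 1, 1e-2, 5.2, 100, True),
            "B": ErrorModelFit("B", 1, 1e-2, 2.9, 100, True),
            "C": ErrorModelFit("C", 1, 1e-2, 3.0, 100, True),
        }
        retained = [d for d, f in fits.items() if not f.isa < 3.0]
        assert retained == ["A", "C"]

    def test_zero_cutoff_disables_isa_rejection(self, small_collection, c2221):
        cell = small_collection.ground_truth.cell
        sel = run_selection(list(small_collection.datasets), cell, c2221,
                            isa_cutoff=0.0)
        cell_ok = set(sel.cell_filter.accepted_ids)
        assert set(sel.final_retained) == cell_ok

    def test_raising_cutoff_never_enlarges_retained_set(
        self, small_collection, c2221
    ):
        cell = small_collection.ground_truth.cell
        prev = None
        for cutoff in (0.0, 3.0, 8.0):
            sel = run_selection(list(small_collection.datasets), cell, c2221,
                                isa_cutoff=cutoff)
            got = set(sel.final_retained)
            if prev is not None:
                assert got <= prev
            prev = got

    def test_misindexed_rejection_reason_names_cell(self, benchmark_selection):
        rejected = benchmark_selection.cell_filter.rejected
        assert len(rejected) == 3
        assert all("axis" in reason for reason in rejected.values())

    def test_round_structure_is_recorded(self, benchmark_selection):
        rounds = benchmark_selection.rounds
        assert len(rounds) == 2
        # round-2 input equals round-1 retained
        r2_members = set(rounds[1].retained) | set(rounds[1].rejected)
        assert r2_members == set(rounds[0].retained)
        assert not rounds[1].rejected

    def test_all_rejected_raises_attrition_summary(self, small_collection, c2221):
        cell = small_collection.ground_truth.cell
        with pytest.raises(ValueError, match="round 1"):
            run_selection(list(small_collection.datasets), cell, c2221,
                          isa_cutoff=1e6)
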