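import numpy as np
import pytest

from rdrbc import (
    CoreModelSpec,
    NestingError,
    build_design,
    build_priors,
    check_nesting,
    core_offset_means,
    default_prior_variance,
)
from rdrbc.design import core_cell_functional
from rdrbc.simulate import generate_trial, make_perforated
from rdrbc.trial_data import TrialData

from conftest import small_config

CORES = ["MAR", "J2R", "CIR", "CR", "LMCF", "RTB"]


class TestCoreOffsetMeans:
    def test_copy_increments_arithmetic(self):
        mu = np.zeros((2, 4))
        mu[0, 3] = 1.0  # mu_0j
        mu[1, 1] = 3.0  # mu_tk
        mu[0, 1] = 2.0  # mu_0k
        assert core_offset_means("CIR", mu, t=1, k=2, j=4) == pytest.approx(2.0)

    def test_j2r_equals_mar_for_reference_arm(self):
        mu = np.random.default_rng(0).normal(size=(2, 4))
        for k in (1, 2, 3):
            for j in range(k + 1, 5):
                assert core_offset_means("J2R", mu, 0, k, j) == core_offset_means(
                    "MAR", mu, 0, k, j
                )

    def test_mar_delta_adds_per_visit_offset(self):
        mu = np.zeros((2, 4))
        core = CoreModelSpec("MAR_DELTA", delta={0: (0.0,), 1: (2.0, 4.0)})
        assert core_offset_means(core, mu, t=1, k=2, j=4) == pytest.approx(4.0)
        assert core_offset_means(core, mu, t=1, k=2, j=3) == pytest.approx(2.0)
        assert core_offset_means(core, mu, t=0, k=2, j=4) == pytest.approx(0.0)

    def test_on_treatment_cell_rejected(self):
        with pytest.raises(ValueError, match="j > k"):
            core_offset_means("J2R", np.zeros((2, 4)), 0, 3, 2)

    @pytest.mark.parametrize("kind", CORES + ["MAR_DELTA"])
    def test_functional_representation_agrees_with_formula(self, kind):
        """The design-row encoding and the direct formula must coincide for
        every off-treatment cell (consistency of the two representations)."""
        J = 4
        rng = np.random.default_rng(5)
        mu = rng.normal(size=(2, J))
        data, _ = generate_trial(small_config(n_visits=3), seed=0)
        core = (
            CoreModelSpec("MAR_DELTA", delta={0: (1.0, 2.0), 1: (2.0, 4.0)})
            if kind == "MAR_DELTA"
            else CoreModelSpec(kind)
        )
        bl = float(np.mean(data.baseline))
        for t in (0, 1):
            for k in range(1, J):
                for j in range(k + 1, J + 1):
                    w, c = core_cell_functional(core, t, k, j, J, data=None)
                    if kind == "RTB":
                        # functional uses placeholder constants without data
                        w, c = core_cell_functional(
                            CoreModelSpec("RTB"), t, k, j, J, data=data
                        )
                        expected = core_offset_means(core, mu, t, k, j, baseline_mean=bl)
                    else:
                        expected = core_offset_means(core, mu, t, k, j)
                    got = w @ mu.reshape(-1) + c
                    assert got == pytest.approx(expected, abs=1e-10)


class TestNesting:
    @pytest.mark.parametrize(
        "core,compliance,ok",
        [
            ("J2R", "current", True),
            ("J2R", "historic", True),
            ("CIR", "current", False),
            ("CIR", "historic", True),
            ("LMCF", "current", False),
            ("LMCF", "historic", True),
            ("MAR", "current", True),
            ("MAR", "historic", True),
            ("RTB", "current", True),
            ("RTB", "historic", True),
            ("CR", "current", True),
        ],
    )
    def test_history_dependence_drives_the_nesting_matrix(self, core, compliance, ok):
        assert bool(check_nesting(core, compliance, J=4)) is ok

    def test_mar_delta_nesting_depends_on_delta_shape(self):
        ramp = CoreModelSpec("MAR_DELTA", delta={0: (0.0,), 1: (2.0, 4.0, 6.0)})
        flat = CoreModelSpec("MAR_DELTA", delta={0: (0.0,), 1: (2.0,)})
        assert not check_nesting(ramp, "current", J=4)
        assert check_nesting(ramp, "historic", J=4)
        assert check_nesting(flat, "current", J=4)

    def test_offending_cells_are_reported(self):
        rep = check_nesting("CIR", "current", J=3)
        assert not rep and rep.offending
        assert all(j > k for (_, k, j) in rep.offending)

    def test_build_design_enforces_nesting(self, covered_small):
        data, _ = covered_small
        with pytest.raises(NestingError):
            build_design(data, "CIR", "current")


class TestBuildDesign:
    def test_deviation_rows_zero_while_on_treatment(self, covered_small):
        data, _ = covered_small
        on = ~data.off_treatment_mask()
        for compliance in ("current", "historic"):
            design = build_design(data, "J2R", compliance)
            dev_block = design.X[:, :, design.is_deviation]
            assert not dev_block[on].any()

    def test_historic_deviation_block_size(self, covered_small):
        data, _ = covered_small
        J = data.n_visits
        design = build_design(data, "J2R", "historic")
        assert int(design.is_deviation.sum()) == 2 * J * (J - 1) // 2

    def test_never_occurring_cells_are_kept_and_reported(self):
        data, _ = generate_trial(small_config(), seed=0)
        covered = build_design(data, "J2R", "historic", check=False)
        holed = build_design(
            make_perforated(data, [(1, 1)]), "J2R", "historic", check=False
        )
        assert holed.n_params == covered.n_params
        assert any(lab[1:3] == (1, 1) for lab in holed.never_observed)
        assert holed.rank_report["rank_observed"] <= holed.n_params

    def test_current_compliance_implied_mean_is_core_plus_alpha(self):
        """Off-treatment row under J2R + current: mu[0, j] weight plus a
        single alpha*[t, j] indicator."""
        y = np.full((2, 3), 1.0)
        data = TrialData(
            ids=["a", "b"], arm=[1, 0], baseline=[1.0, 2.0], y=y,
            dev_visit=[1, 3], last_visit=[3, 3],
        )
        design = build_design(data, "J2R", "current", baseline="none")
        J = 3
        row = design.X[0, 2]  # active patient off treatment at visit 3
        np.testing.assert_allclose(row[: 2 * J], [0, 0, 1, 0, 0, 0])
        dev_cols = np.flatnonzero(design.is_deviation)
        active_dev = [design.labels[c] for c in dev_cols if row[c] != 0]
        assert active_dev == [("alpha*", 1, None, 3)]

    def test_mar_delta_offset_enters_design_offset(self):
        y = np.full((2, 4), 0.0)
        data = TrialData(
            ids=["a", "b"], arm=[1, 0], baseline=[0.0, 1.0], y=y,
            dev_visit=[2, 4], last_visit=[4, 4],
        )
        core = CoreModelSpec("MAR_DELTA", delta={0: (0.0,), 1: (2.0, 4.0)})
        design = build_design(data, core, "historic", baseline="none")
        np.testing.assert_allclose(design.offset[0], [0, 0, 2.0, 4.0])
        np.testing.assert_allclose(design.offset[1], 0)


class TestPriors:
    def test_default_variance_recovers_generating_residual(self, mmrm_big):
        data, truth, fit = mmrm_big
        v = float(fit.sigma[-1, -1])
        assert v == pytest.approx(truth.config.sigma[-1, -1], rel=0.15)
        assert default_prior_variance(data) == pytest.approx(v)

    def test_range_method_and_degenerate_warning(self):
        y = np.full((4, 2), 7.0)
        data = TrialData(
            ids=list("abcd"), arm=[0, 0, 1, 1], baseline=np.zeros(4), y=y,
            dev_visit=[2] * 4, last_visit=[2] * 4,
        )
        with pytest.warns(RuntimeWarning, match="degenerate"):
            assert default_prior_variance(data, method="range") == 0.0
        y2 = y.copy()
        y2[:, 1] = [1.0, 7.0, 4.0, 3.0]
        data2 = TrialData(
            ids=list("abcd"), arm=[0, 0, 1, 1], baseline=np.zeros(4), y=y2,
            dev_visit=[2] * 4, last_visit=[2] * 4,
        )
        assert default_prior_variance(data2, method="range") == pytest.approx(1.0)

    def test_too_few_final_visit_observations_error(self):
        y = np.array([[1.0, np.nan], [1.0, 2.0], [1.0, np.nan], [1.0, np.nan]])
        data = TrialData(
            ids=list("abcd"), arm=[0, 0, 1, 1], baseline=np.zeros(4), y=y,
            dev_visit=[1, 2, 1, 1], last_visit=[1, 2, 1, 1],
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            default_prior_variance(data, method="range")

    def test_prior_structure(self, covered_small):
        data, _ = covered_small
        design = build_design(data, "J2R", "historic")
        v = 4.0
        diag = build_priors(design, v=v, diffuse_variance=1e6)
        dev = np.flatnonzero(design.is_deviation)
        core = np.flatnonzero(~design.is_deviation)
        assert np.allclose(diag.cov[np.ix_(dev, dev)], v * np.eye(len(dev)))
        assert np.allclose(np.diag(diag.cov)[core], 1e6)

        corr = build_priors(design, v=v, diffuse_variance=1e6, adjacent_corr=0.5)
        # adjacent visits within the same (t, k) group share 0.5 * v
        groups = design.deviation_groups
        C = corr.cov[np.ix_(dev, dev)]
        for a in range(len(dev)):
            for b in range(len(dev)):
                ga, ja = groups[a]
                gb, jb = groups[b]
                expected = (
                    v if a == b else 0.5 * v if ga == gb and abs(ja - jb) == 1 else 0.0
                )
                assert C[a, b] == pytest.approx(expected)
        np.linalg.cholesky(corr.cov)  # positive definite

    def test_invalid_prior_parameters_rejected(self, covered_small):
        data, _ = covered_small
        design = build_design(data, "J2R", "historic")
        with pytest.raises(ValueError):
            build_priors(design, v=0.0, diffuse_variance=1e6)
        with pytest.raises(ValueError):
            build_priors(design, v=1.0, diffuse_variance=1e6, adjacent_corr=1.0)
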