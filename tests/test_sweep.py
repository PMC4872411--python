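"""Density sweep, AUC summarisation, group tests and FDR adjustment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fcnet.connectivity import ConnectivityMatrix
from fcnet.nulls import NullEnsembleSpec
from fcnet.sweep import (
    SweepConfig,
    auc,
    default_density_grid,
    fdr_adjust,
    group_test,
    group_tests_with_fdr,
    study_aucs,
    sweep_metrics,
)


def _random_cm(rng, n=30, subject="s1", condition="placebo"):
    z = rng.standard_normal((n, n)) * 0.3
    z = (z + z.T) / 2
    np.fill_diagonal(z, 0)
    return ConnectivityMatrix(
        z=z, region_labels=[f"r{i}" for i in range(n)],
        subject_id=subject, condition=condition,
    )


class TestSweepMetrics:
    def test_default_grid_has_16_levels(self):
        grid = default_density_grid()
        assert len(grid) == 16
        assert grid[0] == 0.05 and grid[-1] == 0.20
        assert np.allclose(np.diff(grid), 0.01)

    def test_one_value_per_density_and_measure(self, rng):
        cm = _random_cm(rng)
        cfg = SweepConfig(null_spec=NullEnsembleSpec(n_nulls=2, seed=0))
        df = sweep_metrics(cm, cfg)
        per_measure = df.groupby("measure")["density"].count()
        assert (per_measure == 16).all()
        # 5 metrics + 8 motif classes + 2 totals
        assert per_measure.size == 15

    def test_global_efficiency_nondecreasing_in_density(self, rng):
        cm = _random_cm(rng)
        cfg = SweepConfig(
            metrics=("E_glob",), motifs=False,
            null_spec=NullEnsembleSpec(n_nulls=1, seed=0),
        )
        df = sweep_metrics(cm, cfg).sort_values("density")
        vals = df[df["measure"] == "E_glob"]["value"].to_numpy()
        assert np.all(np.diff(vals) >= -1e-12)

    def test_identical_inputs_identical_curves(self, rng):
        cm = _random_cm(rng)
        cfg = SweepConfig(null_spec=NullEnsembleSpec(n_nulls=2, seed=3))
        a = sweep_metrics(cm, cfg)
        b = sweep_metrics(cm, cfg)
        pd.testing.assert_frame_equal(a, b)


class TestAuc:
    def test_constant_curve_rectangle(self):
        grid = default_density_grid()
        assert auc(grid, np.ones(16)) == pytest.approx(0.15, abs=1e-12)

    def test_linear_curve_triangle(self):
        grid = default_density_grid()
        vals = np.linspace(0, 1, 16)
        assert auc(grid, vals) == pytest.approx(0.075, abs=1e-12)

    def test_matches_numerical_integration_oracle(self, rng):
        grid = default_density_grid()
        vals = rng.standard_normal(16)
        expected = sum(
            (vals[i] + vals[i + 1]) / 2 * (grid[i + 1] - grid[i])
            for i in range(15)
        )
        assert auc(grid, vals) == pytest.approx(expected, abs=1e-12)

    def test_linearity(self, rng):
        grid = default_density_grid()
        f, g = rng.standard_normal(16), rng.standard_normal(16)
        assert auc(grid, 2.0 * f + 3.0 * g) == pytest.approx(
            2.0 * auc(grid, f) + 3.0 * auc(grid, g), abs=1e-10
        )

    def test_missing_values_rejected_with_densities_named(self):
        grid = default_density_grid()
        vals = np.ones(16)
        vals[2] = np.nan
        with pytest.raises(ValueError, match="0.07"):
            auc(grid, vals)


def _auc_frame(diffs, base=1.0):
    rows = []
    for i, d in enumerate(diffs):
        rows.append({"subject_id": f"s{i}", "condition": "placebo",
                     "group": "", "measure": "C", "auc": base})
        rows.append({"subject_id": f"s{i}", "condition": "drug",
                     "group": "", "measure": "C", "auc": base + d})
    return pd.DataFrame(rows)


class TestGroupTest:
    def test_zero_differences_give_t0_p1(self):
        res = group_test(_auc_frame([0.0] * 5), "paired")
        assert res.loc[0, "t"] == 0.0
        assert res.loc[0, "p_raw"] == 1.0
        assert res.loc[0, "df"] == 4

    def test_constant_nonzero_differences_degenerate(self):
        with pytest.raises(ValueError, match="zero-variance"):
            group_test(_auc_frame([1.0, 1.0, 1.0, 1.0]), "paired")

    def test_paired_matches_scipy(self, rng):
        diffs = rng.standard_normal(10)
        res = group_test(_auc_frame(diffs), "paired")
        t, p = stats.ttest_rel(1.0 + diffs, np.ones(10))
        assert res.loc[0, "t"] == pytest.approx(t, abs=1e-12)
        assert res.loc[0, "p_raw"] == pytest.approx(p, abs=1e-12)

    def test_unpairable_subject_named(self):
        df = _auc_frame([0.1, 0.2, 0.3])
        df = df.drop(df[(df.subject_id == "s1") & (df.condition == "drug")].index)
        with pytest.raises(ValueError, match="s1"):
            group_test(df, "paired")

    def test_two_group_pooled_matches_scipy(self, rng):
        rows = []
        x, y = rng.standard_normal(9), rng.standard_normal(9) + 0.5
        for i, v in enumerate(x):
            rows.append({"subject_id": f"a{i}", "condition": "placebo",
                         "group": "placebo", "measure": "C", "auc": v})
        for i, v in enumerate(y):
            rows.append({"subject_id": f"b{i}", "condition": "drug",
                         "group": "drug", "measure": "C", "auc": v})
        res = group_test(pd.DataFrame(rows), "two_group")
        t, p = stats.ttest_ind(y, x, equal_var=True)
        assert res.loc[0, "t"] == pytest.approx(t, abs=1e-12)
        assert res.loc[0, "df"] == 16
        assert res.loc[0, "p_raw"] == pytest.approx(p, abs=1e-12)

    def test_null_p_values_uniform(self, rng):
        """Calibration: p of the paired test is Uniform(0,1) under the null."""
        pvals = []
        for _ in range(1000):
            res = group_test(_auc_frame(rng.standard_normal(8) * 0.1), "paired")
            pvals.append(res.loc[0, "p_raw"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestFdr:
    def test_bh_step_up_by_hand(self):
        p = [0.01, 0.02, 0.03, 0.04, 0.05]
        assert np.allclose(fdr_adjust(p), [0.05] * 5)

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.123])[0] == pytest.approx(0.123)

    def test_equal_ps_fixed_point(self):
        assert np.allclose(fdr_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            fdr_adjust([0.1, 1.2])

    def test_adjusted_never_below_raw(self, rng):
        p = rng.uniform(size=20)
        assert np.all(fdr_adjust(p) >= p - 1e-15)

    def test_families_adjusted_separately(self, rng):
        df = []
        for i, d in enumerate(rng.standard_normal(6)):
            for measure in ("C", "L", "triangle"):
                df.append({"subject_id": f"s{i}", "condition": "placebo",
                           "group": "", "measure": measure, "auc": 1.0})
                df.append({"subject_id": f"s{i}", "condition": "drug",
                           "group": "", "measure": measure,
                           "auc": 1.0 + d + rng.standard_normal() * 0.1})
        res = group_tests_with_fdr(pd.DataFrame(df), "paired")
        assert set(res["family"]) == {"metrics", "motifs"}
        within = res[res.family == "metrics"]
        # two metrics adjusted as a family of 2: p_fdr = min(2p/rank corrections)
        assert np.all(within["p_fdr"] >= within["p_raw"] - 1e-15)


def test_study_aucs_end_to_end_shape(rng):
    mats = []
    for s in range(2):
        for cond in ("placebo", "drug"):
            mats.append(_random_cm(rng, n=40, subject=f"s{s}", condition=cond))
    # denser grid so sigma's null ensemble cannot be triangle-free
    cfg = SweepConfig(densities=(0.15, 0.20, 0.25, 0.30),
                      null_spec=NullEnsembleSpec(n_nulls=2, seed=1))
    aucs = study_aucs(mats, cfg)
    assert len(aucs) == 4 * 15
    assert set(aucs["condition"]) == {"placebo", "drug"}
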