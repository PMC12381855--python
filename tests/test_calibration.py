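"""Agreement statistics, λ regression, outlier truncation, r0 scanning."""

import numpy as np
import pandas as pd
import pytest

from chdamp.calibration import (
    fit_lambda,
    pearson_r,
    recommend_defaults,
    rmse,
    scan_r0,
    sum_avg_E,
    truncate_outliers,
)
from chdamp.errors import DataError
from chdamp.synthetic import generate_regression_set


def oracle_pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    dx, dy = x - x.mean(), y - y.mean()
    return float(np.sum(dx * dy) / np.sqrt(np.sum(dx**2) * np.sum(dy**2)))


def make_frame(rows):
    return pd.DataFrame(rows, columns=["snapshot", "state", "residue", "distance",
                                       "E_QM", "E_CH@0"])


class TestPearson:
    def test_affine_relations(self, rng):
        x = rng.normal(size=30)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0, abs=1e-12)
        assert pearson_r(x, -x) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_covariance_oracle(self, rng):
        x, y = rng.normal(size=100), rng.normal(size=100)
        assert pearson_r(x, y) == pytest.approx(oracle_pearson(x, y), abs=1e-12)

    def test_affine_invariance(self, rng):
        x, y = rng.normal(size=40), rng.normal(size=40)
        assert pearson_r(3.2 * x + 7, y) == pytest.approx(pearson_r(x, y), abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DataError):
            pearson_r([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])


class TestRmse:
    def test_identical_lists_give_zero(self, rng):
        x = rng.normal(size=10)
        assert rmse(x, x) == 0.0

    def test_arithmetic_example(self):
        assert rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(np.sqrt(12.5))

    def test_matches_definition(self, rng):
        ref, app = rng.normal(size=60), rng.normal(size=60)
        brute = np.sqrt(np.mean([(a - r) ** 2 for r, a in zip(ref, app)]))
        assert rmse(ref, app) == pytest.approx(brute, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])


class TestSumAvgE:
    def test_single_snapshot_sums(self):
        frame = make_frame(
            [("s1", "R", f"r{i}", 3.0, e, e) for i, e in enumerate([-1.0, -2.0, -3.0])]
        )
        assert sum_avg_E(frame, "E_QM", "R") == pytest.approx(-6.0)

    def test_mean_over_snapshots(self):
        rows = [("s1", "R", "r1", 3.0, -10.0, -10.0), ("s2", "R", "r1", 3.0, -20.0, -20.0)]
        assert sum_avg_E(make_frame(rows), "E_QM", "R") == pytest.approx(-15.0)

    def test_matches_group_then_mean_oracle(self, rng):
        rows = []
        sums = {}
        for s in range(5):
            snap = f"s{s}"
            sums[snap] = 0.0
            for i in range(12):
                e = float(rng.normal())
                sums[snap] += e
                rows.append((snap, "TS", f"r{i}", 5.0, e, e))
        frame = make_frame(rows)
        assert sum_avg_E(frame, "E_QM", "TS") == pytest.approx(
            np.mean(list(sums.values())), abs=1e-12
        )

    def test_missing_state_rejected(self):
        frame = make_frame([("s1", "R", "r1", 3.0, -1.0, -1.0)])
        with pytest.raises(DataError):
            sum_avg_E(frame, "E_QM", "TS")


class TestFitLambda:
    def test_exact_proportionality_recovered(self):
        rows = []
        for s in range(4):
            for i in range(5):
                x = float(i + 1 + s)
                rows.append((f"s{s}", "R", f"r{i}", 3.0, 1.3 * x, x))
        fit = fit_lambda(make_frame(rows), "E_CH@0")
        assert fit.lam == pytest.approx(1.3, abs=1e-12)
        assert fit.lam_std == pytest.approx(0.0, abs=1e-12)

    def test_identity_gives_unity(self, rng):
        rows = [("s1", "R", f"r{i}", 3.0, x, x) for i, x in enumerate(rng.normal(size=20))]
        assert fit_lambda(make_frame(rows), "E_CH@0").lam == pytest.approx(1.0, abs=1e-12)

    def test_exact_recovery_independent_of_grouping(self, rng):
        lam = 0.87
        rows = []
        for s in range(7):
            for i in range(9):
                x = float(rng.normal())
                rows.append((f"s{s}", "R", f"r{i}", 3.0, lam * x, x))
        frame = make_frame(rows)
        whole = fit_lambda(frame, "E_CH@0", group_cols=("state",))
        per_snap = fit_lambda(frame, "E_CH@0")
        assert whole.lam == pytest.approx(lam, abs=1e-12)
        assert per_snap.lam == pytest.approx(lam, abs=1e-12)

    def test_noisy_recovery_within_three_standard_errors(self):
        frame = generate_regression_set(1.12, n_per_subset=200, n_subsets=10,
                                        noise_sigma=0.5, seed=11)
        fit = fit_lambda(frame, "E_CH@0")
        se = fit.lam_std / np.sqrt(len(fit.per_subset))
        assert abs(fit.lam - 1.12) <= 3 * se

    def test_matches_no_intercept_least_squares(self, rng):
        """Cross-check the closed form against an independent lstsq solve."""
        x = rng.normal(size=50) * 5
        y = 1.2 * x + rng.normal(size=50)
        rows = [("s1", "R", f"r{i}", 3.0, float(y[i]), float(x[i])) for i in range(50)]
        fit = fit_lambda(make_frame(rows), "E_CH@0")
        lstsq = float(np.linalg.lstsq(x[:, None], y, rcond=None)[0][0])
        assert fit.lam == pytest.approx(lstsq, rel=1e-10)

    def test_degenerate_subset_rejected(self):
        rows = [("s1", "R", f"r{i}", 3.0, 1.0, 0.0) for i in range(3)]
        with pytest.raises(DataError):
            fit_lambda(make_frame(rows), "E_CH@0")


class TestTruncation:
    def _frame(self):
        return make_frame(
            [("s1", "R", "r1", 3.0, -5.0, -5.5), ("s1", "R", "r2", 2.0, -130.0, -160.0)]
        )

    def test_full_mode_is_identity(self):
        frame = self._frame()
        kept, dropped = truncate_outliers(frame, "full")
        assert kept.equals(frame) and dropped.empty

    def test_threshold_drops_large_reference_energies(self):
        kept, dropped = truncate_outliers(self._frame(), "threshold", threshold=50.0)
        assert list(kept["residue"]) == ["r1"]
        assert list(dropped["residue"]) == ["r2"]

    def test_exclude_list_drops_named_residue_everywhere(self):
        rows = [(f"s{s}", "R", r, 3.0, -1.0, -1.0) for s in range(5) for r in ("r1", "rArg")]
        kept, dropped = truncate_outliers(make_frame(rows), "exclude-list",
                                          exclude_residues=["rArg"])
        assert len(dropped) == 5
        assert set(kept["residue"]) == {"r1"}

    def test_survivors_unmodified(self):
        frame = self._frame()
        kept, _ = truncate_outliers(frame, "threshold", threshold=50.0)
        assert kept.iloc[0].equals(frame.iloc[0])

    def test_empty_result_rejected(self):
        with pytest.raises(DataError):
            truncate_outliers(self._frame(), "threshold", threshold=1.0)


class TestScanR0:
    def _constant_grid_frame(self, rng):
        rows = []
        for s in range(2):
            for i in range(10):
                x = float(rng.normal())
                rows.append(
                    {"snapshot": f"s{s}", "state": "R", "residue": f"r{i}",
                     "distance": 4.0, "E_QM": x + 0.1 * rng.normal(),
                     "E_CH@0": x, "E_CH@2": x, "E_CH@3": x}
                )
        return pd.DataFrame(rows)

    def test_r0_independent_energies_tie_break_to_zero(self, rng):
        res = scan_r0(self._constant_grid_frame(rng), "R")
        assert res.optimal.r0 == 0.0
        vals = {(s.pearson_r, s.rmse, s.lam) for s in res.summaries}
        assert len(vals) == 1

    def test_perfect_plain_ch_selects_zero(self, rng):
        rows = []
        for s in range(2):
            for i in range(10):
                x = float(rng.normal())
                rows.append(
                    {"snapshot": f"s{s}", "state": "R", "residue": f"r{i}",
                     "distance": 4.0, "E_QM": x, "E_CH@0": x,
                     "E_CH@2.5": x + 0.3 * float(rng.normal())}
                )
        res = scan_r0(pd.DataFrame(rows), "R")
        assert res.optimal.r0 == 0.0
        assert res.min_rmse_r0 == 0.0
        assert res.summary_at(0.0).rmse == 0.0
        assert res.summary_at(0.0).lam == pytest.approx(1.0, abs=1e-12)

    def test_one_summary_per_grid_point(self, neutral_benchmark):
        res = scan_r0(neutral_benchmark.records, "R")
        assert [s.r0 for s in res.summaries] == sorted(neutral_benchmark.r0_grid)
        assert res.optimal.r0 in neutral_benchmark.r0_grid

    def test_fitted_lambda_improves_total_energy_match(self, neutral_benchmark):
        """λ·Σ_avg E(CH-d@optimum) is closer to Σ_avg E(QM) than unscaled."""
        for state in ("R", "TS"):
            res = scan_r0(neutral_benchmark.records, state)
            s = res.optimal
            gap_raw = abs(s.sum_avg_e_qm - s.sum_avg_e_ch)
            gap_fit = abs(s.sum_avg_e_qm - s.lam * s.sum_avg_e_ch)
            assert gap_fit < gap_raw

    def test_missing_plain_ch_column_rejected(self, rng):
        frame = self._constant_grid_frame(rng).drop(columns=["E_CH@0"])
        with pytest.raises(DataError):
            scan_r0(frame, "R")


class TestRecommendations:
    def test_neutral_kernel_scheme(self):
        rec = recommend_defaults(0)
        assert rec.r0_range == (2.5, 3.0)
        assert rec.lambda_range == (1.1, 1.3)

    @pytest.mark.parametrize("q", [-2, +1, -3])
    def test_charged_kernel_scheme(self, q):
        rec = recommend_defaults(q)
        assert rec.r0_range == (0.0, 2.0)
        assert rec.lambda_range == (1.0, 1.0)
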