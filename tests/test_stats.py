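"""Unit and oracle tests for the cohort statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from ctaperv.records import PatientRecord
from ctaperv.simulate import cohort_spec, generate_cohort, generate_rater_pairs
from ctaperv.stats import (
    DegenerateDataError,
    SchemaError,
    StatsConfig,
    analyze_cohort,
    filter_cohort,
    icc_two_way,
    logistic_fit,
    mann_whitney,
    ols_residuals,
    partial_corr,
    spearman_corr,
)


def make_record(i=0, **kw):
    base = dict(
        id=f"p{i:03d}", cta_index=-0.6, age=75.0, sex="F",
        slice_thickness_mm=0.6, mtici="2b", procedure_time_min=30.0,
        nihss_pre=14, nihss_post=6, mrs90=2,
    )
    base.update(kw)
    return PatientRecord(**base)


# ---------------------------------------------------------------------------
# cohort filter

class TestFilterCohort:
    def test_boundary_thickness_kept(self):
        kept, tally = filter_cohort([make_record(slice_thickness_mm=3.0)])
        assert len(kept) == 1 and sum(tally.values()) == 0

    def test_residual_flow_excluded(self):
        kept, tally = filter_cohort([make_record(residual_flow=True)])
        assert not kept and tally["residual_flow"] == 1

    def test_mixed_roster(self):
        records = [make_record(i) for i in range(7)]
        records.append(make_record(7, occlusion_site="M2-distal"))
        records.append(make_record(8, residual_flow=True))
        records.append(make_record(9, slice_thickness_mm=5.0))
        kept, tally = filter_cohort(records)
        assert len(kept) == 7
        assert tally == {
            "distal_occlusion": 1, "residual_flow": 1, "slice_thickness": 1
        }

    def test_first_criterion_wins(self):
        rec = make_record(occlusion_site="M3", residual_flow=True,
                          slice_thickness_mm=5.0)
        _, tally = filter_cohort([rec])
        assert tally == {
            "distal_occlusion": 1, "residual_flow": 0, "slice_thickness": 0
        }


# ---------------------------------------------------------------------------
# Mann-Whitney

def _permutation_p(a, b):
    """Brute-force two-sided permutation p for the U statistic."""
    pooled = list(a) + list(b)
    n_a = len(a)

    def u_stat(x, y):
        return sum(1 for xi in x for yi in y if xi > yi)

    u_obs = u_stat(a, b)
    n = len(pooled)
    mean_u = n_a * (n - n_a) / 2.0
    dev_obs = abs(u_obs - mean_u)
    count = total = 0
    for idx in itertools.combinations(range(n), n_a):
        x = [pooled[i] for i in idx]
        y = [pooled[i] for i in range(n) if i not in idx]
        total += 1
        if abs(u_stat(x, y) - mean_u) >= dev_obs - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_separated_groups(self):
        u, p, method = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0 and method == "exact"
        assert p == pytest.approx(0.1)

    def test_identical_multisets(self):
        # cross-group ties force the tie-corrected approximation; with a
        # centred U the two-sided p is exactly 1
        _, p, method = mann_whitney([1, 2, 3], [1, 3, 2])
        assert method == "normal-approximation"
        assert p == pytest.approx(1.0)

    def test_exact_matches_enumeration(self, rng):
        for _ in range(20):
            n_a, n_b = rng.integers(2, 6, 2)
            vals = rng.permutation(40)[: n_a + n_b]  # distinct -> no ties
            a, b = vals[:n_a].tolist(), vals[n_a:].tolist()
            _, p, method = mann_whitney(a, b)
            assert method == "exact"
            assert p == pytest.approx(_permutation_p(a, b), abs=1e-12)

    def test_large_uses_normal_approx(self, rng):
        a, b = rng.normal(size=30), rng.normal(size=51)
        _, p, method = mann_whitney(a, b)
        assert method == "normal-approximation"
        assert 0 <= p <= 1

    def test_empty_group_raises(self):
        with pytest.raises(DegenerateDataError):
            mann_whitney([], [1.0])


class TestMannWhitneyTies:
    def test_tied_data_falls_back(self):
        _, p, method = mann_whitney([1, 1, 2], [2, 3, 3])
        assert method == "normal-approximation"
        assert 0 <= p <= 1


# ---------------------------------------------------------------------------
# OLS residuals

class TestOlsResiduals:
    def test_perfect_fit(self, rng):
        x = rng.normal(size=(20, 2))
        y = 1.0 + x @ [2.0, -1.0]
        assert np.allclose(ols_residuals(y, x), 0.0, atol=1e-10)

    def test_intercept_only(self, rng):
        y = rng.normal(size=15)
        assert np.allclose(ols_residuals(y, None), y - y.mean(), atol=1e-12)

    def test_three_point_fixture(self):
        # hand solve of the normal equations for y = a + b x
        resid = ols_residuals([1.0, 2.0, 4.0], np.array([[0.0], [1.0], [2.0]]))
        assert resid == pytest.approx([1 / 6, -1 / 3, 1 / 6], abs=1e-12)

    def test_orthogonality(self, rng):
        x = rng.normal(size=(50, 4))
        y = rng.normal(size=50)
        r = ols_residuals(y, x)
        design = np.column_stack([np.ones(50), x])
        assert np.all(np.abs(design.T @ r) < 1e-8 * 50)

    def test_collinear_named(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        with pytest.raises(DegenerateDataError, match="collinear"):
            ols_residuals([1.0, 2, 3, 4], df)


# ---------------------------------------------------------------------------
# Spearman

class TestSpearman:
    def test_perfect_monotone(self):
        r, _ = spearman_corr([1, 2, 3, 5], [2, 4, 9, 10])
        assert r == pytest.approx(1.0)

    def test_reversed(self):
        r, _ = spearman_corr([1, 2, 3, 5], [10, 9, 4, 2])
        assert r == pytest.approx(-1.0)

    def test_hand_rank_fixture(self):
        r, _ = spearman_corr([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6)

    def test_constant_raises(self):
        with pytest.raises(DegenerateDataError):
            spearman_corr([1, 1, 1], [1, 2, 3])

    def test_exact_small_sample_p(self):
        # n=4, rho=1: only 1 of 24 rank permutations reaches |rho|=1 ... but
        # -1 also qualifies under two-sidedness -> p = 2/24
        _, p = spearman_corr([1, 2, 3, 4], [10, 20, 30, 40])
        assert p == pytest.approx(2 / 24)


# ---------------------------------------------------------------------------
# logistic regression

class TestLogistic:
    def test_two_by_two_log_odds(self):
        # cells: exposed (x=1): 10 events / 5 non-events; unexposed: 5 / 10
        x = np.r_[np.ones(15), np.zeros(15)].reshape(-1, 1)
        y = np.r_[np.ones(10), np.zeros(5), np.ones(5), np.zeros(10)]
        rep = logistic_fit(y, x)
        assert rep.coefficients["x0"] == pytest.approx(math.log(4.0), abs=1e-6)

    def test_zero_variance_predictor(self):
        x = np.ones((20, 1))
        y = np.r_[np.ones(10), np.zeros(10)]
        with pytest.raises(DegenerateDataError, match="collinear"):
            logistic_fit(y, x)

    def test_separation_detected(self):
        x = np.arange(20, dtype=float).reshape(-1, 1)
        y = (x.ravel() > 9.5).astype(float)
        with pytest.raises(DegenerateDataError, match="separation"):
            logistic_fit(y, x)

    def test_one_class_raises(self):
        with pytest.raises(DegenerateDataError):
            logistic_fit(np.ones(10), np.random.default_rng(0).normal(size=(10, 1)))

    def test_pseudo_r2_bounds(self, rng):
        x = rng.normal(size=(100, 2))
        y = (x[:, 0] + rng.normal(size=100) > 0).astype(float)
        rep = logistic_fit(y, x)
        assert 0.0 <= rep.r2_coxsnell <= rep.r2_nagelkerke <= 1.0


# ---------------------------------------------------------------------------
# partial correlation

class TestPartialCorr:
    def test_no_covariates_is_pearson(self, rng):
        from scipy import stats as sps
        x, y = rng.normal(size=50), rng.normal(size=50)
        r, p = partial_corr(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert r == pytest.approx(r_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-8)

    def test_single_covariate_closed_form(self, rng):
        z = rng.normal(size=80)
        x = 0.5 * z + rng.normal(size=80)
        y = -0.3 * z + rng.normal(size=80)
        r, _ = partial_corr(x, y, z.reshape(-1, 1))
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        ryz = np.corrcoef(y, z)[0, 1]
        expected = (rxy - rxz * ryz) / math.sqrt((1 - rxz**2) * (1 - ryz**2))
        assert r == pytest.approx(expected, abs=1e-10)

    def test_fully_explained_covariate(self, rng):
        z = rng.normal(size=30)
        x = rng.normal(size=30)
        with pytest.raises(DegenerateDataError):
            partial_corr(x, z.copy(), z.reshape(-1, 1))

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        df = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("xyzc"))
        r, p = partial_corr(df["x"], df["y"], df[["z", "c"]])
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["z", "c"])
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)


# ---------------------------------------------------------------------------
# ICC

def _icc_anova_oracle(R):
    """Independent variance-components computation from the ANOVA table."""
    R = np.asarray(R, float)
    n, k = R.shape
    grand = R.mean()
    msr = k * ((R.mean(1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((R.mean(0) - grand) ** 2).sum() / (k - 1)
    mse = (
        ((R - R.mean(1, keepdims=True) - R.mean(0, keepdims=True) + grand) ** 2)
        .sum() / ((n - 1) * (k - 1))
    )
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


FIXTURE_6x2 = np.array(
    [[9.0, 10.0], [6.0, 7.0], [8.0, 7.5], [7.0, 5.0], [10.0, 11.0], [6.0, 6.5]]
)


class TestICC:
    def test_perfect_agreement(self):
        r = np.column_stack([FIXTURE_6x2[:, 0], FIXTURE_6x2[:, 0]])
        res = icc_two_way(r)
        assert res.estimate == pytest.approx(1.0)

    def test_fixture_matches_anova_oracle(self):
        res = icc_two_way(FIXTURE_6x2)
        assert res.estimate == pytest.approx(
            _icc_anova_oracle(FIXTURE_6x2), abs=1e-10
        )

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        n = len(FIXTURE_6x2)
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(n), 2),
            "rater": np.tile([0, 1], n),
            "score": FIXTURE_6x2.ravel(),
        })
        ref = pingouin.intraclass_corr(
            df, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
        res = icc_two_way(FIXTURE_6x2)
        assert res.estimate == pytest.approx(
            ref.loc["ICC(A,1)", "ICC"], abs=1e-8
        )
        lo, hi = ref.loc["ICC(A,1)", "CI95"]
        assert res.ci_low == pytest.approx(lo, abs=0.011)  # pingouin rounds
        assert res.ci_high == pytest.approx(hi, abs=0.011)

    def test_zero_between_subject_variance(self):
        r = np.array([[5.0, 6.0]] * 8)
        with pytest.raises(DegenerateDataError):
            icc_two_way(r)

    def test_large_noise_drives_icc_to_zero(self, rng):
        subj = np.zeros(60)
        r = np.column_stack([subj + rng.normal(0, 10, 60),
                             subj + rng.normal(0, 10, 60)])
        res = icc_two_way(r)
        assert abs(res.estimate) < 0.35

    def test_convergence_to_variance_ratio(self):
        # subject-effect + noise: population ICC = 0.8
        rng = np.random.default_rng(42)
        subj = rng.normal(0, 2.0, 500)
        noise = rng.normal(0, 1.0, (500, 2))
        res = icc_two_way(subj[:, None] + noise)
        assert res.estimate == pytest.approx(0.8, abs=0.02)
        assert res.ci_low <= res.estimate <= res.ci_high


# ---------------------------------------------------------------------------
# analyze_cohort

@pytest.fixture(scope="module")
def cohort():
    spec = cohort_spec("validation", seed=11)
    records = generate_cohort(spec)
    raters = generate_rater_pairs(records, spec.rater_noise_sd, seed=12)
    return records, raters


class TestAnalyzeCohort:
    def test_all_analyses_present(self, cohort):
        records, raters = cohort
        rep = analyze_cohort(records, rater_pairs=raters)
        assert rep.wilcoxon and rep.logistic and rep.spearman_residual
        assert rep.partial_corr and rep.icc
        assert (
            rep.group_summaries["favorable"]["mean"]
            > rep.group_summaries["non_favorable"]["mean"]
        )

    def test_missing_outcome_skips_outcome_analyses(self, cohort):
        records, _ = cohort
        from dataclasses import replace
        no_mrs = [replace(r, mrs90=None) for r in records]
        rep = analyze_cohort(no_mrs)
        assert rep.wilcoxon is None and rep.logistic is None
        assert "wilcoxon" in rep.skipped and "logistic" in rep.skipped
        assert rep.spearman_residual is not None
        assert rep.partial_corr is not None

    def test_deterministic(self, cohort):
        import json
        records, raters = cohort
        r1 = analyze_cohort(records, rater_pairs=raters)
        r2 = analyze_cohort(records, rater_pairs=raters)
        assert json.dumps(r1.to_dict()) == json.dumps(r2.to_dict())

    def test_order_invariance(self, cohort, rng):
        records, raters = cohort
        shuffled = [records[i] for i in rng.permutation(len(records))]
        r1 = analyze_cohort(records, rater_pairs=raters)
        r2 = analyze_cohort(shuffled, rater_pairs=raters)
        assert r1.to_dict() == r2.to_dict()

    def test_empty_cohort_raises(self):
        with pytest.raises(SchemaError):
            analyze_cohort([])

    def test_config_echo(self, cohort):
        records, raters = cohort
        rep = analyze_cohort(records, rater_pairs=raters,
                             config=StatsConfig(alpha=0.01))
        assert rep.config["alpha"] == 0.01
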