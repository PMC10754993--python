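import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats

from gpcochlea.anatomy import canonical_mean_profile, eca_btl, predict_v360
from gpcochlea.evaluation import (
    Cohort,
    compare_groups,
    loocv_insertion,
    loocv_volume,
    mann_whitney,
    pearson_r2,
    rsd,
)
from gpcochlea.profile import VolumeProfile
from gpcochlea.synthetic import make_insertion_dataset


def model_exact_cohort(n=8):
    """Cohort generated exactly from the estimation model: canonical shape,
    V(360°) exactly on the BTL regression line."""
    rng = np.random.default_rng(7)
    base = canonical_mean_profile()
    rows, profiles = [], {}
    for i in range(n):
        a, b = rng.uniform(3.5, 4.3), rng.uniform(2.55, 2.95)
        v360 = predict_v360(eca_btl((a, b)))
        sid = f"s{i}"
        profiles[sid] = VolumeProfile(base.angles, base.volumes / base.v360 * v360)
        rows.append({"specimen_id": sid, "group": "g", "A_mm": a, "B_mm": b,
                     "v360_uL": v360})
    return Cohort(pd.DataFrame(rows), profiles)


class TestLoocvVolume:
    def test_zero_error_on_model_generated_data(self):
        """A model validated on data it generated must be exact."""
        res = loocv_volume(model_exact_cohort(), "scaling")
        assert res.deviations["dv_uL"].abs().max() < 1e-9

    def test_log_zero_error_on_log_shaped_data(self):
        rng = np.random.default_rng(8)
        grid = np.arange(0.0, 1080.1, 22.5)
        shape = np.log1p(grid / 120.0)
        rows, profiles = [], {}
        for i in range(6):
            a, b = rng.uniform(3.5, 4.3), rng.uniform(2.55, 2.95)
            v360 = predict_v360(eca_btl((a, b)))
            profiles[f"s{i}"] = VolumeProfile(
                grid, shape / np.log1p(360.0 / 120.0) * v360)
            rows.append({"specimen_id": f"s{i}", "group": "g", "A_mm": a,
                         "B_mm": b, "v360_uL": v360})
        res = loocv_volume(Cohort(pd.DataFrame(rows), profiles), "log")
        assert res.deviations["dv_uL"].abs().max() < 1e-6

    def test_scaling_beats_mean_on_heterogeneous_cohort(self, cohort12):
        """Individualized scaling yields lower errors than one-size-fits-all."""
        res_mean = loocv_volume(cohort12, "mean")
        res_scal = loocv_volume(cohort12, "scaling")
        assert (res_scal.deviations["dv_uL"].abs().median()
                <= res_mean.deviations["dv_uL"].abs().median())

    def test_log_worst_in_basal_region(self, cohort12):
        """The log curve's basal overshoot dominates errors at 90°."""
        at90 = lambda r: r.deviations.query("angle_deg == 90")["dv_uL"].abs().median()
        assert at90(loocv_volume(cohort12, "log")) > at90(loocv_volume(cohort12, "scaling"))

    def test_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            loocv_volume(model_exact_cohort(n=2), "scaling")

    def test_summary_counts(self, cohort12):
        res = loocv_volume(cohort12, "scaling")
        counts = res.deviations.groupby("angle_deg").size()
        assert (counts == len(cohort12)).all()


class TestLoocvInsertion:
    def test_collinear_data_is_exact(self):
        pairs = [(e, 60.0 * e) for e in (1.0, 2.0, 3.0, 4.5)]
        res = loocv_insertion(pairs)
        assert np.max(np.abs(res.deviations)) < 1e-9
        assert res.median_deviation == pytest.approx(0.0, abs=1e-10)

    def test_monte_carlo_deviation_envelope(self):
        """With σ = 10° IA noise at n = 15 the typical |deviation| is ≈ 7°."""
        medians = []
        for seed in range(100):
            df = make_insertion_dataset(n=15, seed=seed, slope=72.0,
                                        intercept=0.0, noise_sd=10.0)
            medians.append(loocv_insertion(df).median_abs_deviation)
        assert 5.0 <= np.median(medians) <= 15.0

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            loocv_insertion([(1.0, 60.0), (2.0, 120.0)])


class TestRsd:
    @pytest.mark.parametrize("mean,sd,expected", [
        (5.3, 0.78, 14.7), (3.8, 0.2, 5.3), (2.8, 0.1, 3.6),
    ])
    def test_published_summaries(self, mean, sd, expected):
        assert round(rsd(mean=mean, sd=sd), 1) == expected

    def test_constant_sample(self):
        assert rsd([4.0, 4.0, 4.0]) == 0.0

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            rsd(mean=0.0, sd=1.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(hnp.arrays(np.float64, st.integers(3, 30),
                      elements=st.floats(1.0, 100.0)))
    def test_sample_path_matches_brute_force(self, x):
        """RSD from raw samples equals the textbook n−1 formula."""
        if x.mean() == 0:
            return
        brute = 100.0 * np.sqrt(np.sum((x - x.mean()) ** 2) / (x.size - 1)) / x.mean()
        assert rsd(x) == pytest.approx(brute, rel=1e-9, abs=1e-12)


class TestPearsonR2:
    def test_collinear(self):
        assert pearson_r2([1, 2, 3, 4], [3, 5, 7, 9]) == pytest.approx(1.0)

    def test_hand_computed_examples(self):
        assert pearson_r2([1, 2, 3], [1, 3, 2]) == pytest.approx(0.25, abs=1e-12)
        assert pearson_r2([1, 2, 3, 4], [1, -1, 1, -1]) == pytest.approx(0.2, abs=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            pearson_r2([1, 1, 1], [1, 2, 3])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_formula(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=20), rng.normal(size=20)
        xc, yc = x - x.mean(), y - y.mean()
        brute = (np.sum(xc * yc) ** 2) / (np.sum(xc ** 2) * np.sum(yc ** 2))
        assert pearson_r2(x, y) == pytest.approx(brute, rel=1e-12)


def enumerate_mww_p(x, y):
    """Independent brute-force two-sided exact Mann–Whitney p-value."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    mu = n1 * len(y) / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    d = abs(u_obs - mu)
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2.0
        total += 1
        hits += abs(u - mu) >= d - 1e-12
    return hits / total


class TestMannWhitney:
    def test_identical_groups_have_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        _, p, _ = mann_whitney(x, x.copy())
        assert p == pytest.approx(1.0)

    def test_fully_separated_groups_exact_p(self):
        x = np.arange(1.0, 7.0)          # n = 6
        y = np.arange(10.0, 22.0)        # n = 12
        _, p, method = mann_whitney(x, y)
        assert method == "exact"
        assert p == pytest.approx(2 / 18564, rel=1e-9)
        assert p == pytest.approx(1.0774e-4, rel=1e-4)

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_matches_enumeration(self, seed):
        """Exact p-values agree with full enumeration up to 7 vs 7."""
        rng = np.random.default_rng(seed)
        x = rng.normal(0.0, 1.0, 6)
        y = rng.normal(0.8, 1.0, 7)
        _, p, method = mann_whitney(x, y)
        assert method == "exact"
        assert p == pytest.approx(enumerate_mww_p(x, y), rel=1e-9)

    def test_tied_small_samples_use_permutation(self):
        x = np.array([1.0, 2.0, 2.0, 3.0])
        y = np.array([2.0, 3.0, 4.0, 5.0])
        _, p, method = mann_whitney(x, y)
        assert method == "exact_permutation"
        assert p == pytest.approx(enumerate_mww_p(x, y), rel=1e-9)

    def test_monotone_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=8), rng.normal(0.5, 1.0, 9)
        _, p1, _ = mann_whitney(x, y)
        _, p2, _ = mann_whitney(np.exp(x), np.exp(y))
        assert p1 == pytest.approx(p2, rel=1e-12)


class TestCompareGroups:
    @staticmethod
    def _cohort_five_groups():
        rng = np.random.default_rng(9)
        rows = []
        shifts = {"g1": 0.0, "g2": 0.0, "g3": 0.0, "g4": 0.0, "g5": 1.0}
        i = 0
        for g, shift in shifts.items():
            for _ in range(6):
                rows.append({"specimen_id": f"s{i}", "group": g,
                             "A_mm": 3.8 + shift + rng.normal(0, 0.05),
                             "B_mm": 2.8 + rng.normal(0, 0.05)})
                i += 1
        return Cohort(pd.DataFrame(rows))

    def test_bonferroni_family_of_ten(self):
        comp, values = compare_groups(self._cohort_five_groups(), "A")
        assert len(comp) == 10
        capped = comp["p_bonferroni"]
        raw = comp["p_uncorrected"]
        assert (capped == np.minimum(1.0, raw * 10)).all()
        # the shifted group separates from every other group
        hits = comp[(comp["group1"] == "g5") | (comp["group2"] == "g5")]
        assert (hits["p_bonferroni"] < 0.05).all()

    def test_outlier_flags_use_iqr_rule(self):
        rows = [{"specimen_id": f"s{i}", "group": "g",
                 "A_mm": v, "B_mm": 2.8}
                for i, v in enumerate([3.7, 3.75, 3.8, 3.85, 3.9, 9.0])]
        rows += [{"specimen_id": f"t{i}", "group": "h", "A_mm": 3.8, "B_mm": 2.8}
                 for i in range(3)]
        _, values = compare_groups(Cohort(pd.DataFrame(rows)), "A")
        flagged = values[values["outlier"]]
        assert list(flagged["specimen_id"]) == ["s5"]

    def test_duplicate_ids_rejected(self):
        df = pd.DataFrame([
            {"specimen_id": "a", "group": "g", "A_mm": 3.8, "B_mm": 2.8},
            {"specimen_id": "a", "group": "g", "A_mm": 3.9, "B_mm": 2.8},
        ])
        with pytest.raises(ValueError, match="duplicate"):
            Cohort(df)

    def test_tiny_group_rejected(self):
        df = pd.DataFrame([
            {"specimen_id": "a", "group": "g", "A_mm": 3.8, "B_mm": 2.8},
            {"specimen_id": "b", "group": "g", "A_mm": 3.9, "B_mm": 2.8},
            {"specimen_id": "c", "group": "h", "A_mm": 3.7, "B_mm": 2.8},
        ])
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_groups(Cohort(df), "A")
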