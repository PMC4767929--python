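"""Mixed-design factorial ANOVA, Mauchly's test and epsilon corrections."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from altsem import (
    epsilon_corrections, mauchly_from_covariance, mauchly_test, mixed_anova,
    partial_eta_squared, simulate_alt, sphericity_from_moments,
    SimulationConfig,
)
from altsem.anova import helmert_contrasts
from altsem.data_model import LongitudinalDataset
from altsem.exceptions import DesignError


def make_dataset(Y, factors=None):
    n, T = Y.shape
    df = pd.DataFrame(Y, columns=[f"day_{t}" for t in range(1, T + 1)])
    names = ()
    if factors:
        for name, vals in factors.items():
            df[name] = vals
        names = tuple(factors)
    df.insert(0, "subject_id", np.arange(n))
    return LongitudinalDataset(df, names, tuple(f"day_{t}"
                                                for t in range(1, T + 1)),
                               check_bounds=False)


def classical_oracle(Y, a, b):
    """Textbook cell-means decomposition for a balanced 2x2 x day design."""
    n, T = Y.shape
    grand = Y.mean()
    subj = Y.mean(axis=1)
    # between-subjects part (on subject means, times T)
    def lvl(mask):
        return subj[mask].mean()
    ss_a = T * sum((subj[a == v].mean() - subj.mean()) ** 2 * (a == v).sum()
                   for v in (0, 1))
    ss_b = T * sum((subj[b == v].mean() - subj.mean()) ** 2 * (b == v).sum()
                   for v in (0, 1))
    ss_ab = 0.0
    for va in (0, 1):
        for vb in (0, 1):
            m = (a == va) & (b == vb)
            dev = (subj[m].mean() - subj[a == va].mean()
                   - subj[b == vb].mean() + subj.mean())
            ss_ab += T * m.sum() * dev ** 2
    ss_err_b = T * sum(
        ((subj[(a == va) & (b == vb)]
          - subj[(a == va) & (b == vb)].mean()) ** 2).sum()
        for va in (0, 1) for vb in (0, 1))
    # within-subjects part
    day_means = Y.mean(axis=0)
    ss_day = n * ((day_means - grand) ** 2).sum()
    def ss_inter(f):
        out = 0.0
        for v in (0, 1):
            m = f == v
            cell = Y[m].mean(axis=0)
            out += m.sum() * ((cell - Y[m].mean() - day_means + grand) ** 2).sum()
        return out
    ss_day_a = ss_inter(a)
    ss_day_b = ss_inter(b)
    ss_day_ab = 0.0
    for va in (0, 1):
        for vb in (0, 1):
            m = (a == va) & (b == vb)
            cell = Y[m].mean(axis=0)
            dev = (cell - Y[m].mean()
                   - (Y[a == va].mean(axis=0) - Y[a == va].mean())
                   - (Y[b == vb].mean(axis=0) - Y[b == vb].mean())
                   + day_means - grand)
            ss_day_ab += m.sum() * (dev ** 2).sum()
    ss_within_total = ((Y - subj[:, None]) ** 2).sum()
    ss_err_w = (ss_within_total - ss_day - ss_day_a - ss_day_b - ss_day_ab)
    return {"a": ss_a, "b": ss_b, "a * b": ss_ab, "err_b": ss_err_b,
            "day": ss_day, "a * day": ss_day_a, "b * day": ss_day_b,
            "a * b * day": ss_day_ab, "err_w": ss_err_w}


class TestMixedAnova:
    def test_no_within_variation_gives_zero_day_ss(self, rng):
        base = rng.normal(30, 5, 12)
        Y = np.tile(base[:, None], (1, 4))
        data = make_dataset(Y, {"g": np.repeat([0, 1], 6)})
        res = mixed_anova(data, ("g",))
        day = res.effect("day", "within")
        assert day["ss"] == pytest.approx(0.0)
        assert day["F"] == pytest.approx(0.0)

    def test_balanced_2x2_matches_cell_means_oracle(self, rng):
        a = np.repeat([0, 0, 1, 1], 2)
        b = np.tile([0, 1], 4)
        Y = rng.normal(20, 4, (8, 3)) + 2 * a[:, None] - 1.5 * b[:, None] \
            + 0.8 * np.arange(3)[None, :] * a[:, None]
        data = make_dataset(Y, {"a": a, "b": b})
        res = mixed_anova(data, ("a", "b"))
        oracle = classical_oracle(Y, a, b)
        assert res.effect("a")["ss"] == pytest.approx(oracle["a"])
        assert res.effect("b")["ss"] == pytest.approx(oracle["b"])
        assert res.effect("a * b")["ss"] == pytest.approx(oracle["a * b"])
        assert res.effect("Error")["ss"] == pytest.approx(oracle["err_b"])
        assert res.effect("day", "within")["ss"] == pytest.approx(oracle["day"])
        assert res.effect("a * day", "within")["ss"] == pytest.approx(
            oracle["a * day"])
        assert res.effect("a * b * day", "within")["ss"] == pytest.approx(
            oracle["a * b * day"])
        assert res.effect("Error (day)", "within")["ss"] == pytest.approx(
            oracle["err_w"])
        # F ratio assembled as MS_effect / MS_error
        f_exp = (oracle["a"] / 1) / (oracle["err_b"] / 4)
        assert res.effect("a")["F"] == pytest.approx(f_exp)

    def test_type3_equals_sequential_on_balanced(self, rng):
        a = np.repeat([0, 1], 8)
        b = np.tile([0, 1], 8)
        Y = rng.normal(10, 2, (16, 4)) + a[:, None] - 0.5 * b[:, None]
        data = make_dataset(Y, {"a": a, "b": b})
        res = mixed_anova(data, ("a", "b"))
        # sequential (Type I) via orthogonal projections on effect codes
        subj = np.sqrt(4) * Y.mean(axis=1)
        for name, code in (("a", 1 - 2 * a), ("b", 1 - 2 * b),
                           ("a * b", (1 - 2 * a) * (1 - 2 * b))):
            c = code - code.mean()
            ss_seq = (c @ subj) ** 2 / (c @ c)
            assert res.effect(name)["ss"] == pytest.approx(ss_seq)

    def test_unbalanced_cells_supported(self, rng):
        a = np.array([0] * 5 + [1] * 9)
        Y = rng.normal(15, 3, (14, 3)) + a[:, None]
        res = mixed_anova(make_dataset(Y, {"a": a}), ("a",))
        assert res.effect("a")["df"] == 1
        assert res.effect("Error")["df"] == 12

    def test_empty_cell_reported(self, rng):
        a = np.repeat([0, 1], 4)
        b = np.zeros(8, dtype=int)
        b[a == 0] = np.array([0, 0, 1, 1])  # cell a=1,b=1 empty
        Y = rng.normal(10, 1, (8, 3))
        with pytest.raises(DesignError, match="a=1, b=1"):
            mixed_anova(make_dataset(Y, {"a": a, "b": b}), ("a", "b"))

    def test_matches_pingouin_one_between_factor(self, small_data):
        pg = pytest.importorskip("pingouin")
        res = mixed_anova(small_data, ("stress",))
        long = small_data.data.melt(
            id_vars=["subject_id", "stress"],
            value_vars=list(small_data.outcome_names),
            var_name="day", value_name="y")
        ref = pg.mixed_anova(long, dv="y", within="day",
                             subject="subject_id", between="stress")
        ref = ref.set_index("Source")
        assert res.effect("stress")["F"] == pytest.approx(
            ref.loc["stress", "F"])
        assert res.effect("day", "within")["F"] == pytest.approx(
            ref.loc["day", "F"])
        assert res.effect("stress * day", "within")["F"] == pytest.approx(
            ref.loc["Interaction", "F"])
        assert res.effect("stress", "between")["partial_eta_sq"] == \
            pytest.approx(ref.loc["stress", "np2"])
        # pingouin pools over the grand-centered (not within-cells)
        # covariance, so its epsilon differs slightly in between-group
        # designs
        assert res.epsilons.gg == pytest.approx(ref.loc["day", "eps"],
                                                abs=0.005)

    def test_hf_corrected_type_one_error_calibrated(self, rng):
        """Null day effect, spherical errors: HF-corrected day test rejects
        at the nominal rate (500 replicates, binomial CI)."""
        rejections = 0
        reps = 500
        for _ in range(reps):
            Y = rng.normal(0, 1, (20, 4)) + rng.normal(0, 1, (20, 1))
            g = np.repeat([0, 1], 10)
            res = mixed_anova(make_dataset(Y, {"g": g}), ("g",))
            rejections += res.effect("day", "within")["p_hf"] < 0.05
        rate = rejections / reps
        half = 1.96 * np.sqrt(0.05 * 0.95 / reps)
        assert 0.05 - half <= rate <= 0.05 + half

    def test_sphericity_violation_inflates_uncorrected_test(self, rng):
        """Strong sphericity violation, null day effect: the uncorrected
        test over-rejects while the HF-corrected test stays near nominal."""
        L = np.linalg.cholesky(np.diag([0.3, 0.5, 3.0, 9.0]) + 0.2)
        raw_rej = hf_rej = 0
        reps = 500
        for _ in range(reps):
            Y = rng.standard_normal((16, 4)) @ L.T
            res = mixed_anova(make_dataset(Y), ())
            raw_rej += res.effect("day", "within")["p"] < 0.05
            hf_rej += res.effect("day", "within")["p_hf"] < 0.05
        half = 1.96 * np.sqrt(0.05 * 0.95 / reps)
        assert raw_rej / reps > 0.05 + half  # inflated
        assert hf_rej / reps <= 0.05 + 2 * half  # controlled


class TestMauchly:
    def test_compound_symmetry_gives_w_one(self):
        S = 0.4 * np.ones((5, 5)) + 0.6 * np.eye(5)
        res = mauchly_from_covariance(S, n_e=40)
        assert res.W == pytest.approx(1.0)
        assert res.chi2 == pytest.approx(0.0, abs=1e-10)

    def test_df_is_35_for_nine_days(self, rng):
        Y = rng.normal(30, 5, (60, 9))
        res = mauchly_test(make_dataset(Y), ())
        assert res.df == 35

    def test_matches_pingouin_one_group(self, rng):
        pg = pytest.importorskip("pingouin")
        Y = rng.normal(10, 2, (40, 5)) + rng.normal(0, 2, (40, 1))
        data = make_dataset(Y)
        res = mauchly_test(data, ())
        long = data.data.melt(id_vars=["subject_id"],
                              value_vars=list(data.outcome_names),
                              var_name="day", value_name="y")
        ref = pg.sphericity(long, dv="y", within="day", subject="subject_id")
        assert res.W == pytest.approx(ref.W, rel=1e-9)
        assert res.chi2 == pytest.approx(ref.chi2, rel=1e-9)
        # pingouin adds a higher-order term to the chi-square p-value
        assert res.p == pytest.approx(ref.pval, abs=0.005)

    def test_table1_day_block_near_printed_sphericity(self, table1):
        mauchly, eps = sphericity_from_moments(
            table1, tuple(f"day_{t}" for t in range(1, 10)),
            ("sex", "age", "stress", "genotype"))
        assert mauchly.approximate and eps.approximate
        assert mauchly.df == 35
        assert abs(mauchly.chi2 - 117.62) <= 15.0
        assert abs(eps.hf - 0.983) <= 0.02


class TestEpsilons:
    def test_spherical_covariance_gives_one(self):
        res = epsilon_corrections(np.eye(8), n_e=100)
        assert res.gg == pytest.approx(1.0)
        assert res.hf == 1.0

    def test_rank_one_contrast_hits_lower_bound(self):
        v = np.arange(1.0, 9.0)
        res = epsilon_corrections(np.outer(v, v), n_e=100)
        assert res.gg == pytest.approx(1.0 / 8)
        assert res.lower_bound == pytest.approx(0.125)

    def test_hf_at_least_gg_before_capping(self, rng):
        for _ in range(10):
            L = rng.standard_normal((6, 6))
            G = L @ L.T
            res = epsilon_corrections(G, n_e=80)
            assert res.hf_uncapped >= res.gg - 1e-12
            assert res.hf <= 1.0

    def test_corrected_p_monotone_in_epsilon(self):
        F, df1, df2 = 2.5, 8, 200
        ps = [stats.f.sf(F, df1 * e, df2 * e) for e in (1.0, 0.9, 0.6, 0.3)]
        assert ps == sorted(ps)

    def test_small_error_df_rejected(self):
        with pytest.raises(DesignError):
            epsilon_corrections(np.eye(8), n_e=4)


class TestPartialEta:
    def test_limits(self):
        assert partial_eta_squared(3.0, 0.0) == 1.0
        assert partial_eta_squared(0.0, 2.0) == 0.0

    def test_both_zero_undefined(self):
        with pytest.raises(DesignError):
            partial_eta_squared(0.0, 0.0)

    def test_f_to_ss_reconstruction(self, rng):
        # reconstruct SS_effect = F * df1 * MS_error and check eta recovers
        a = np.repeat([0, 1], 10)
        Y = rng.normal(8, 2, (20, 3)) + 1.2 * a[:, None]
        res = mixed_anova(make_dataset(Y, {"a": a}), ("a",))
        row = res.effect("a")
        err = res.effect("Error")
        ss_rebuilt = row["F"] * row["df"] * err["ms"]
        assert partial_eta_squared(ss_rebuilt, err["ss"]) == pytest.approx(
            row["partial_eta_sq"])
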