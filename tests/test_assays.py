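"""qPCR standard curves, allelic ratios, NMD contrast, and MFI inference."""

import numpy as np
import pandas as pd
import pytest

from balscan.assays import (
    MfiModel,
    allelic_ratio,
    fit_standard_curve,
    iqr_filter,
    nmd_effect,
)
from balscan.synth import gen_mfi_fixture, gen_qpcr_fixture


def standards_frame(fractions, slope=1.0, intercept=0.0, noise=None, rng=None):
    rows = []
    for f in fractions:
        dct = (np.log2(f / (1 - f)) - intercept) / slope
        for _ in range(3):
            eps = rng.normal(0, noise) if noise else 0.0
            rows.append({"fraction": f, "ct_a": 24 + dct + eps, "ct_b": 24.0})
    return pd.DataFrame(rows)


class TestStandardCurve:
    def test_noiseless_recovery_exact(self):
        df = standards_frame([0.1, 0.3, 0.5, 0.7, 0.9])
        curve = fit_standard_curve(df)
        assert curve.slope == pytest.approx(1.0)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0)

    def test_nonunit_slope_recovered(self):
        df = standards_frame([0.2, 0.4, 0.6, 0.8], slope=0.9, intercept=0.3)
        curve = fit_standard_curve(df)
        assert curve.slope == pytest.approx(0.9)
        assert curve.intercept == pytest.approx(0.3)

    def test_noisy_slope_recovered_within_5pct(self, rng):
        slopes = []
        for _ in range(100):
            df = standards_frame([0.1, 0.3, 0.5, 0.7, 0.9], noise=0.1, rng=rng)
            slopes.append(fit_standard_curve(df).slope)
        assert np.mean(slopes) == pytest.approx(1.0, rel=0.05)

    def test_two_point_design_rejected(self):
        df = standards_frame([0.3, 0.7])
        with pytest.raises(ValueError, match="3 distinct"):
            fit_standard_curve(df)

    def test_leave_one_out_recovers_held_fraction(self):
        """The curve predicts each standard's own mix ratio."""
        fractions = [0.1, 0.25, 0.5, 0.75, 0.9]
        df = standards_frame(fractions)
        for held in fractions:
            curve = fit_standard_curve(df[df["fraction"] != held])
            sub = df[df["fraction"] == held]
            r = allelic_ratio(sub, curve)
            assert r.ratio == pytest.approx(held / (1 - held), rel=1e-9)


class TestAllelicRatio:
    def test_identity_curve_equal_ct(self):
        from balscan.assays import StandardCurve

        curve = StandardCurve(slope=1.0, intercept=0.0, r_squared=1.0, n_points=9)
        df = pd.DataFrame({"ct_a": [24.0] * 3, "ct_b": [24.0] * 3})
        assert allelic_ratio(df, curve).ratio == pytest.approx(1.0)

    def test_missing_replicate_flagged(self):
        from balscan.assays import StandardCurve

        curve = StandardCurve(slope=1.0, intercept=0.0, r_squared=1.0, n_points=9)
        df = pd.DataFrame({"ct_a": [24.0, np.nan, 24.0], "ct_b": [24.0] * 3})
        r = allelic_ratio(df, curve)
        assert r.flagged_missing and r.n_replicates == 2

    def test_synthetic_unknown_recovered(self):
        recovered = []
        for seed in range(60):
            records, truth = gen_qpcr_fixture(true_ratio=0.3, ct_sd=0.1, seed=seed)
            curve = fit_standard_curve(records[records["role"] == "standard"])
            unk = records[records["role"] == "unknown"]
            recovered.append(allelic_ratio(unk, curve).ratio)
        assert np.mean(recovered) == pytest.approx(0.3, rel=0.1)


class TestNmdEffect:
    def _ratio(self, x):
        from balscan.assays import AllelicRatio

        return AllelicRatio(ratio=x, sem=0.02, n_replicates=3)

    def test_nmd_consistent_contrast(self):
        out = nmd_effect({"c1": self._ratio(0.3)}, {"c1": self._ratio(1.0)})
        assert out.iloc[0]["verdict"] == "NMD-consistent"

    def test_no_signal_when_ratios_equal(self):
        out = nmd_effect({"c1": self._ratio(1.0)}, {"c1": self._ratio(1.0)})
        assert out.iloc[0]["verdict"] == "no NMD signal"

    def test_unpaired_arms_error(self):
        with pytest.raises(ValueError, match="unpaired"):
            nmd_effect({"c1": self._ratio(0.3)}, {"c2": self._ratio(1.0)})


class TestIqrFilter:
    def test_fence_removes_extreme(self):
        mask = iqr_filter(np.array([1.0, 2.0, 3.0, 4.0, 100.0]))
        assert mask.tolist() == [True, True, True, True, False]

    def test_all_equal_kept(self):
        assert iqr_filter(np.full(6, 3.0)).all()

    def test_small_groups_pass_through(self):
        mask = iqr_filter(np.array([1.0, 100.0, 2.0]), groups=pd.Series(["a"] * 3))
        assert mask.all()

    def test_idempotent(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0, 100.0, 2.5, 2.6])
        mask = iqr_filter(vals)
        again = iqr_filter(vals[mask])
        assert again.all()

    def test_default_generator_removes_at_most_quarter(self):
        """Sanity bound: on default generator parameters the fence trims at
        most a quarter of the dataset (per-group fractions can be larger in
        a 6-point group, where one removal is already 17%)."""
        for seed in range(40):
            records, _ = gen_mfi_fixture(seed=seed)
            std = (records["hla_mfi"] / records["cd19_mfi"]).to_numpy()
            kept = iqr_filter(std, records[["experiment", "genotype"]])
            assert (~kept).sum() <= 0.25 * len(records)


class TestMfiInference:
    def test_hand_computed_anova_table(self):
        # Balanced 2x2 design, 3 observations per cell; the expected sums of
        # squares and F statistics were computed by hand from the standard
        # additive two-way decomposition before this class was written:
        # SS_genotype = 12, SS_experiment = 27, SS_residual = 8 on 9 df,
        # F_genotype = 13.5, F_experiment = 30.375.
        rows = []
        cells = {
            ("AA", 1): [10, 11, 12],
            ("AA", 2): [13, 14, 15],
            ("BB", 1): [8, 9, 10],
            ("BB", 2): [11, 12, 13],
        }
        for (gt, e), vals in cells.items():
            for i, v in enumerate(vals):
                rows.append(
                    {
                        "sample": f"{gt}{e}{i}",
                        "genotype": gt,
                        "experiment": e,
                        "hla_mfi": float(v),
                        "cd19_mfi": 1.0,
                    }
                )
        res = MfiModel(pd.DataFrame(rows), measure="standardized").fit()
        anova = res.anova
        assert anova.loc["C(genotype)", "sum_sq"] == pytest.approx(12.0)
        assert anova.loc["C(experiment)", "sum_sq"] == pytest.approx(27.0)
        assert anova.loc["Residual", "sum_sq"] == pytest.approx(8.0)
        assert anova.loc["C(genotype)", "F"] == pytest.approx(13.5)
        assert anova.loc["C(experiment)", "F"] == pytest.approx(30.375)

    def test_missing_genotype_in_experiment_errors(self):
        records, _ = gen_mfi_fixture(seed=0)
        broken = records[~((records["experiment"] == 2) & (records["genotype"] == "BB"))]
        with pytest.raises(ValueError, match="lacks genotype"):
            MfiModel(broken).fit()

    def test_experiment_effect_only(self):
        """With no genotype effect the experiment factor dominates."""
        ps_g, ps_e = [], []
        for seed in range(25):
            records, _ = gen_mfi_fixture(
                genotype_effect=0.0, experiment_effect=0.5, seed=seed
            )
            res = MfiModel(records).fit()
            ps_g.append(res.p_genotype)
            ps_e.append(res.p_experiment)
        assert np.mean(np.asarray(ps_e) < 0.05) > 0.9
        assert 0.2 < np.mean(ps_g) < 0.8  # roughly uniform

    def test_null_calibration(self):
        rejections = []
        for seed in range(80):
            records, _ = gen_mfi_fixture(
                genotype_effect=0.0, experiment_effect=0.0, seed=1000 + seed
            )
            rejections.append(MfiModel(records).fit().p_genotype < 0.05)
        assert np.mean(rejections) < 0.15

    def test_power_at_default_effect(self):
        hits = 0
        n = 50
        for seed in range(n):
            records, _ = gen_mfi_fixture(seed=2000 + seed)
            hits += MfiModel(records).fit().p_genotype < 0.05
        assert hits / n >= 0.8

    def test_summary_mentions_both_factors(self):
        records, _ = gen_mfi_fixture(seed=3)
        text = MfiModel(records).fit().summary()
        assert "genotype" in text and "experiment" in text and "Welch" in text
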