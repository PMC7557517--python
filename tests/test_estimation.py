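"""Weighted national estimates, replacement correction, bootstrap, chi2."""

import numpy as np
import pandas as pd
import pytest

from injloc import (EstimationConfig, GeneratorConfig, bootstrap_ci,
                    combine_locations, compare_distributions_chi2,
                    impute_replacement_hospitals, resample_psus,
                    stratified_estimates, weighted_annual_estimates)
from injloc.records import LOCATION_CLASSES, MISSING, RecordSet, UNKNOWN, \
    recode_records
from injloc.synthetic import generate_records, inject_hospital_replacement


def assignment_frame(locations, weights=None, **extra):
    n = len(locations)
    df = pd.DataFrame({
        "record_id": [f"r{i}" for i in range(n)],
        "location": locations,
        "weight": weights if weights is not None else [1.0] * n,
        "hospital_id": "H1",
        "stratum": "large",
        "year": 2000,
    })
    for k, v in extra.items():
        df[k] = v
    return df


def recorded_world(n=600, seed=1, **kwargs):
    rs, truth = generate_records(GeneratorConfig(n_records=n, seed=seed,
                                                 **kwargs))
    return recode_records(rs), truth


class TestCombine:
    def test_no_missing_identity(self):
        rs, _ = recorded_world(50)
        out = combine_locations(rs, pd.DataFrame(columns=["record_id",
                                                          "predicted"]))
        assert (out["location"] == out["location4"]).all()
        assert (out["location_source"] == "observed").all()

    def test_prediction_for_nonmissing_rejected(self):
        rs, _ = recorded_world(20)
        bad = pd.DataFrame({"record_id": [rs.records["record_id"].iloc[0]],
                            "predicted": ["HOME"]})
        with pytest.raises(ValueError, match="nonmissing"):
            combine_locations(rs, bad)

    def test_uncovered_missing_rejected(self):
        rs, _ = recorded_world(50)
        df = rs.records.copy()
        df.loc[0, "location4"] = MISSING
        with pytest.raises(ValueError, match="without prediction"):
            combine_locations(RecordSet(df), pd.DataFrame(
                columns=["record_id", "predicted"]))

    def test_classwise_bookkeeping(self):
        rs, _ = recorded_world(200, seed=3)
        df = rs.records.copy()
        mask_ids = df["record_id"].iloc[:60]
        df.loc[df["record_id"].isin(mask_ids), "location4"] = MISSING
        preds = pd.DataFrame({"record_id": mask_ids,
                              "predicted": np.resize(list(LOCATION_CLASSES),
                                                     60)})
        out = combine_locations(RecordSet(df), preds)
        for c in LOCATION_CLASSES:
            observed = ((df["location4"] == c)
                        & ~df["record_id"].isin(mask_ids)).sum()
            predicted = (preds["predicted"] == c).sum()
            assert (out["location"] == c).sum() == observed + predicted


class TestReplacementCorrection:
    def test_no_events_identity(self):
        df = assignment_frame(["HOME"] * 5)
        out, factors = impute_replacement_hospitals(df, [])
        pd.testing.assert_frame_equal(out, df)
        assert factors == []

    def test_other_hospitals_untouched(self):
        df = pd.concat([
            assignment_frame(["HOME"] * 4).assign(hospital_id="HA",
                                                  year=[1999, 2000, 2000, 2001]),
            assignment_frame(["HOME"] * 2).assign(
                hospital_id="HB",
                record_id=["s0", "s1"], year=[2000, 2001]),
        ], ignore_index=True)
        out, _ = impute_replacement_hospitals(df, [("HA", 2000)])
        hb = out[out["hospital_id"] == "HB"]
        assert (hb["weight"] == 1.0).all()

    def test_rescales_to_prior_year_level(self):
        # HA: 1999 level 10; 2000 level 30 -> factor 1/3 restores 10
        df = assignment_frame(["HOME"] * 4, weights=[10, 10, 10, 10])
        df["hospital_id"] = "HA"
        df["year"] = [1999, 2000, 2000, 2000]
        out, factors = impute_replacement_hospitals(df, [("HA", 2000)])
        post = out[out["year"] == 2000]["weight"].sum()
        assert post == pytest.approx(10.0)
        assert factors[0]["factor"] == pytest.approx(1 / 3)

    def test_recovers_pre_event_level_on_synthetic_truth(self):
        # tripled hospital volume corrected back near its pre-event level
        errs = []
        for seed in range(10):
            cfg = GeneratorConfig(n_records=4000, years=(2000, 2009),
                                  seed=seed)
            rs, truth = generate_records(cfg)
            hid = rs.records.groupby("hospital_id").size().idxmax()
            out, truth2 = inject_hospital_replacement(rs, truth,
                                                      [(hid, 2005, 3.0)],
                                                      seed=seed + 50)
            df = recode_records(out).records
            corrected, _ = impute_replacement_hospitals(
                df, truth2.replacement_log)
            pre = df[(df["hospital_id"] == hid)
                     & (df["year"] == 2004)]["weight"].sum()
            post_ann = corrected[(corrected["hospital_id"] == hid)
                                 & (corrected["year"] >= 2005)
                                 ]["weight"].sum() / 5
            errs.append(post_ann / pre - 1)
        assert abs(np.mean(errs)) < 0.10


class TestWeightedEstimates:
    def test_unit_weight_arithmetic(self):
        locs = (["HOME"] * 2 + ["STREET"] * 3 + ["PUBLIC"] * 4 + ["OTHER"])
        df = assignment_frame(locs)
        cfg = EstimationConfig(years=(2000, 2000))
        est = weighted_annual_estimates(df, cfg, adjusted=True)
        assert list(est["estimate"]) == [2, 3, 4, 1]
        assert list(est["share"]) == [0.2, 0.3, 0.4, 0.1]

    def test_mass_conservation_exact(self):
        rs, _ = recorded_world(400, seed=5)
        df = rs.records.copy()
        df.loc[df.index[:150], "location4"] = MISSING
        preds = pd.DataFrame({
            "record_id": df["record_id"].iloc[:150],
            "predicted": np.resize(list(LOCATION_CLASSES), 150)})
        combined = combine_locations(RecordSet(df), preds)
        cfg = EstimationConfig(years=(1993, 2015))
        adjusted = weighted_annual_estimates(combined, cfg, adjusted=True)
        unadjusted = weighted_annual_estimates(df, cfg, adjusted=False)
        assert adjusted["estimate"].sum() == pytest.approx(
            unadjusted["estimate"].sum(), rel=1e-12)
        assert UNKNOWN not in set(adjusted["location"])
        assert UNKNOWN in set(unadjusted["location"])

    def test_adjusted_mode_rejects_unknown(self):
        df = assignment_frame(["HOME", MISSING])
        with pytest.raises(ValueError, match="UNKNOWN"):
            weighted_annual_estimates(df, EstimationConfig(), adjusted=True)

    def test_shares_sum_to_one(self):
        rs, _ = recorded_world(300, seed=6)
        est = weighted_annual_estimates(rs.records, EstimationConfig(),
                                        adjusted=False)
        assert est["share"].sum() == pytest.approx(1.0, abs=1e-9)


class TestBootstrap:
    def test_resample_preserves_stratum_psu_counts(self):
        rs, _ = recorded_world(2000, seed=7)
        rng = np.random.default_rng(0)
        boot = resample_psus(rs, rng)
        for stratum in rs.records["stratum"].unique():
            orig = rs.records[rs.records["stratum"] == stratum][
                "hospital_id"].nunique()
            new = boot.records[boot.records["stratum"] == stratum][
                "hospital_id"].nunique()
            assert new == orig  # resampled draws keep the PSU count

    def test_constant_closure_zero_width_ci(self):
        rs, _ = recorded_world(300, seed=8)
        const = weighted_annual_estimates(
            assignment_frame(list(LOCATION_CLASSES)),
            EstimationConfig(years=(2000, 2000)), adjusted=True)

        cis = bootstrap_ci(rs, lambda r, s: const,
                           EstimationConfig(n_bootstrap=10, seed=1))
        assert (cis["ci_low"] == cis["ci_high"]).all()

    def test_bootstrap_reproducible(self):
        rs, _ = recorded_world(500, seed=9)
        cfg = EstimationConfig(n_bootstrap=5, seed=42, years=(1993, 2015))

        def closure(rs_b, seed):
            df = rs_b.records.rename(columns={"location4": "location"})
            df = df[df["location"] != MISSING]
            return weighted_annual_estimates(df, cfg, adjusted=True)

        c1 = bootstrap_ci(rs, closure, cfg)
        c2 = bootstrap_ci(rs, closure, cfg)
        pd.testing.assert_frame_equal(c1, c2)

    def test_ci_width_shrinks_with_sample_size(self):
        # quadrupling records should roughly halve the share CI width
        from injloc.studies import world_share_ci
        widths = {}
        for n in (800, 3200):
            ws = []
            for seed in range(3):
                cfg = GeneratorConfig(n_records=n, years=(2000, 2004),
                                      seed=100 + seed)
                t = world_share_ci(cfg, n_bootstrap=60,
                                   seed=seed).set_index("location")
                ws.append(t.loc["STREET", "share_ci_high"]
                          - t.loc["STREET", "share_ci_low"])
            widths[n] = np.mean(ws)
        ratio = widths[800] / widths[3200]
        assert 1.5 < ratio < 3.0


class TestChi2:
    def test_identical_distributions(self):
        d = {c: 0.25 for c in LOCATION_CLASSES}
        stat, p = compare_distributions_chi2(d, d, n_effective=1000)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_textbook_four_category_example(self):
        # hand-checked Pearson statistic on effective-n-scaled counts
        adj = {"HOME": 0.5, "STREET": 0.3, "PUBLIC": 0.1, "OTHER": 0.1}
        unadj = {"HOME": 0.25, "STREET": 0.25, "PUBLIC": 0.25, "OTHER": 0.25}
        stat, _ = compare_distributions_chi2(adj, unadj, n_effective=100)
        expected = sum((o - 25) ** 2 / 25 for o in (50, 30, 10, 10))
        assert stat == pytest.approx(expected, abs=1e-12)

    def test_unknown_mass_dropped_and_renormalized(self):
        adj = {"HOME": 0.3, "STREET": 0.5, "PUBLIC": 0.15, "OTHER": 0.05}
        unadj = {"HOME": 0.15, "STREET": 0.25, "PUBLIC": 0.075,
                 "OTHER": 0.025, UNKNOWN: 0.5}
        stat, p = compare_distributions_chi2(adj, unadj, n_effective=500)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_alpha_significance_rule(self):
        adj = {"HOME": 0.5, "STREET": 0.3, "PUBLIC": 0.15, "OTHER": 0.05}
        unadj = {"HOME": 0.25, "STREET": 0.5, "PUBLIC": 0.2, "OTHER": 0.05}
        stat, p = compare_distributions_chi2(adj, unadj, n_effective=2000)
        assert p < 0.05  # large shift at effective n=2000 is significant


class TestStratified:
    def test_single_level_covariate_share_one(self):
        df = assignment_frame(["HOME"] * 3 + ["STREET"] * 2, sex="male")
        out = stratified_estimates(df, "sex", EstimationConfig(), True)
        assert (out["share_within_location"] == 1.0).all()

    def test_within_location_shares_sum_to_one(self):
        rs, _ = recorded_world(500, seed=10)
        df = rs.records.rename(columns={"location4": "location"})
        out = stratified_estimates(df, "intent", EstimationConfig(), True)
        sums = out.groupby("location")["share_within_location"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_recovers_generator_intent_mix(self):
        rs, truth = recorded_world(8000, seed=11)
        df = rs.records.rename(columns={"location4": "location"})
        out = stratified_estimates(df, "intent", EstimationConfig(), True)
        street_assault = out[(out["location"] == "STREET")
                             & (out["intent"] == "assault")
                             ]["share_within_location"].iloc[0]
        assert abs(street_assault - 0.88) < 0.03

    def test_unsupported_covariate_rejected(self):
        df = assignment_frame(["HOME"])
        with pytest.raises(ValueError):
            stratified_estimates(df, "disposition", EstimationConfig(), True)
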