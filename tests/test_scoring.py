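"""Liability contributions, FGRS aggregation, cohabitation adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import truncated_normal_tail_mean
from pedrisk.pedigree import attach_cohab_years, relative_links
from pedrisk.scoring import (
    GAEA_TRAIT,
    LiabilityModel,
    ScoringConfig,
    cohabitation_adjust,
    compute_fgrs,
    fit_cohab_slope,
    relative_contribution,
)
from pedrisk.simulate import RegistryBundle


def manual_bundle(n_extra_parents=0):
    """One proband (id 2) with parents 0, 1; optionally more 1st-degree kin."""
    ids = [0, 1, 2]
    persons = pd.DataFrame(
        {
            "id": ids,
            "sex": ["M", "F", "M"],
            "yob": [1950, 1950, 1980],
            "county": [0, 0, 0],
            "death_month": np.nan,
            "emig_month": np.nan,
            "ea_z": [0.5, -0.5, 0.0],
            "iq_z": np.nan,
            "res_z": np.nan,
        }
    )
    pedigree = pd.DataFrame(
        {"id": ids, "father_id": [np.nan, np.nan, 0], "mother_id": [np.nan, np.nan, 1]}
    )
    events = pd.DataFrame({"id": [0], "disorder": ["MD"], "age_months": [300.0]})
    cohab = pd.DataFrame({"id_a": [], "id_b": [], "years": []})
    return RegistryBundle(persons=persons, pedigree=pedigree, events=events, cohab=cohab)


class TestLiabilityModel:
    def test_symmetric_case(self):
        m = LiabilityModel(prevalence=0.5)
        assert relative_contribution(m, True) == pytest.approx(0.7978845608, abs=1e-6)

    @given(st.floats(min_value=0.001, max_value=0.999))
    @settings(max_examples=50, deadline=None)
    def test_mean_zero_identity(self, k):
        m = LiabilityModel(prevalence=k)
        assert k * m.z_affected + (1 - k) * m.z_unaffected == pytest.approx(0, abs=1e-10)

    @pytest.mark.parametrize("k", [0.002, 0.005, 0.013, 0.05, 0.2])
    def test_matches_quadrature(self, k):
        m = LiabilityModel(prevalence=k)
        assert relative_contribution(m, True) == pytest.approx(
            truncated_normal_tail_mean(k), abs=1e-6
        )

    def test_threshold_monotone_in_prevalence(self):
        taus = [LiabilityModel(prevalence=k).threshold for k in (0.01, 0.05, 0.2, 0.5)]
        assert all(a > b for a, b in zip(taus, taus[1:]))

    def test_invalid_prevalence(self):
        with pytest.raises(ValueError):
            LiabilityModel(prevalence=1.0)


class TestComputeFgrs:
    def test_single_affected_parent_hand_value(self):
        """One affected parent, K=0.05, lambda=0:
        raw = (w * z_aff) / w * s, s = 1 -> phi(1.6449)/0.05 ~ 2.0627... times
        nothing else; the score equals the affected tail mean."""
        bundle = manual_bundle()
        links = pd.DataFrame(
            {"proband": [2, 2], "relative": [0, 1], "phi": [0.25, 0.25],
             "degree": [1, 1], "cohab_years": [0.0, 0.0]}
        )
        model = LiabilityModel(prevalence=0.05)
        cfg = ScoringConfig(shrinkage_lambda=0.0, cohab_adjust=False)
        # father affected (z_a ~ 2.0627), mother unaffected (z_u ~ -0.1086)
        scores = compute_fgrs(bundle, links, "MD", model=model, config=cfg)
        raw = scores.set_index("id").loc[2, "raw"]
        z_a = truncated_normal_tail_mean(0.05)
        z_u = -0.05 * z_a / 0.95
        assert z_a == pytest.approx(2.0627, abs=2e-4)
        assert raw == pytest.approx((0.5 * z_a + 0.5 * z_u) / 1.0, abs=1e-9)

    def test_only_affected_parent_with_shrinkage_off_equals_tail_mean(self):
        bundle = manual_bundle()
        links = pd.DataFrame(
            {"proband": [2], "relative": [0], "phi": [0.25],
             "degree": [1], "cohab_years": [0.0]}
        )
        cfg = ScoringConfig(shrinkage_lambda=0.0, cohab_adjust=False)
        raw = compute_fgrs(
            bundle, links, "MD", model=LiabilityModel(0.05), config=cfg
        ).set_index("id").loc[2, "raw"]
        assert raw == pytest.approx(truncated_normal_tail_mean(0.05), abs=1e-6)

    def test_no_phenotyped_relatives_scores_zero(self):
        bundle = manual_bundle()
        links = pd.DataFrame(
            {"proband": [2], "relative": [99], "phi": [0.25], "degree": [1],
             "cohab_years": [0.0]}
        )  # relative unknown to persons table
        scores = compute_fgrs(bundle, links, "MD", model=LiabilityModel(0.05),
                              probands=np.array([2]))
        assert scores.set_index("id").loc[2, "raw"] == 0.0
        assert scores.set_index("id").loc[2, "weight_sum"] == 0.0

    def test_monotone_in_affected_first_degree_relative(self, small_sim, small_links):
        """Adding one affected 1st-degree relative never lowers the raw score."""
        cfg, bundle, _ = small_sim
        model = LiabilityModel(prevalence=0.05)
        sc = ScoringConfig(cohab_adjust=False)
        base = compute_fgrs(bundle, small_links, "DUD", model=model, config=sc)
        proband = base["id"].iloc[0]
        # plant a new affected full sib for that proband
        new_id = int(bundle.persons["id"].max()) + 1
        row = bundle.persons.iloc[[0]].copy()
        row["id"] = new_id
        persons = pd.concat([bundle.persons, row], ignore_index=True)
        events = pd.concat(
            [bundle.events, pd.DataFrame({"id": [new_id], "disorder": ["DUD"],
                                          "age_months": [300.0]})],
            ignore_index=True,
        )
        bundle2 = RegistryBundle(persons=persons, pedigree=bundle.pedigree,
                                 events=events, cohab=bundle.cohab)
        links2 = pd.concat(
            [small_links,
             pd.DataFrame({"proband": [proband], "relative": [new_id],
                           "phi": [0.25], "degree": [1], "cohab_years": [0.0]})],
            ignore_index=True,
        )
        after = compute_fgrs(bundle2, links2, "DUD", model=model, config=sc)
        r0 = base.set_index("id").loc[proband, "raw"]
        r1 = after.set_index("id").loc[proband, "raw"]
        assert r1 >= r0 - 1e-12

    def test_standardization_contract(self, small_sim, small_links):
        cfg, bundle, _ = small_sim
        scores = compute_fgrs(bundle, small_links, "MD")
        merged = scores.merge(bundle.persons[["id", "yob", "county"]], on="id")
        for (_, _), grp in merged.groupby(["yob", "county"]):
            if len(grp) < 2 or grp["z"].abs().sum() == 0:
                continue
            assert abs(grp["z"].mean()) < 1e-8
            assert grp["z"].std(ddof=1) == pytest.approx(1.0, abs=1e-8)

    def test_empty_cohort_raises(self):
        bundle = manual_bundle()
        empty = RegistryBundle(
            persons=bundle.persons.iloc[0:0], pedigree=bundle.pedigree.iloc[0:0],
            events=bundle.events.iloc[0:0], cohab=bundle.cohab,
        )
        with pytest.raises(ValueError, match="empty"):
            compute_fgrs(empty, pd.DataFrame(columns=["proband", "relative", "phi", "degree"]),
                         "MD", model=LiabilityModel(0.05))

    def test_recovery_correlates_with_true_genetics(self, small_sim, small_links):
        """FGRS tracks the latent additive-genetic liability, more tightly for
        probands with more phenotyped relatives."""
        cfg, bundle, truth = small_sim
        scores = compute_fgrs(bundle, small_links, "MD").set_index("id")
        t = truth.set_index("id").loc[scores.index]
        r_all = np.corrcoef(scores["z"], t["g_MD"])[0, 1]
        assert r_all > 0.05
        med = scores["weight_sum"].median()
        few = scores["weight_sum"] < med
        r_few = np.corrcoef(scores.loc[few, "z"], t.loc[few, "g_MD"])[0, 1]
        r_many = np.corrcoef(scores.loc[~few, "z"], t.loc[~few, "g_MD"])[0, 1]
        assert r_many > r_few

    def test_negative_score_correlation_for_dud(self, small_sim, small_links):
        cfg, bundle, _ = small_sim
        f = compute_fgrs(bundle, small_links, "DUD").set_index("id")["z"]
        g = compute_fgrs(bundle, small_links, GAEA_TRAIT).set_index("id")["z"]
        assert np.corrcoef(f, g.loc[f.index])[0, 1] < 0


class TestCohabAdjust:
    def test_constant_cohab_is_identity(self):
        df = pd.DataFrame(
            {"z": np.random.default_rng(0).normal(size=50), "degree": 1,
             "cohab_years": 15.0}
        )
        out = cohabitation_adjust(df)
        assert np.allclose(out["z"], df["z"])

    def test_independent_contributions_barely_change(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {"z": rng.normal(size=2000), "degree": 1,
             "cohab_years": rng.uniform(0, 20, 2000)}
        )
        out = cohabitation_adjust(df)
        assert np.mean(np.abs(out["z"] - df["z"])) < 0.05

    def test_planted_slope_recovered(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 20, 1000)
        z = 0.1 * x + rng.normal(scale=0.5, size=1000)
        df = pd.DataFrame({"z": z, "degree": 1, "cohab_years": x})
        assert fit_cohab_slope(df, 1) == pytest.approx(0.1, abs=0.02)
        out = cohabitation_adjust(df)
        # residualized contributions no longer trend with cohab years
        assert abs(fit_cohab_slope(out, 1)) < 1e-10
        assert out["z"].mean() == pytest.approx(df["z"].mean(), abs=1e-10)

    def test_small_class_passes_through(self):
        df = pd.DataFrame(
            {"z": [1.0, 2.0], "degree": 1, "cohab_years": [0.0, 10.0]}
        )
        out = cohabitation_adjust(df, min_n=10)
        assert np.allclose(out["z"], df["z"])
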