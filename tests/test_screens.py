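"""Screen statistics: normalization, Welch tests, client calling rules."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from golgisort.io import QuantTable, ValidationError, _sample_metadata
from golgisort.screens import (
    call_pulldown_hits,
    degradation_ratios,
    EnrichmentResult,
    DegradationResult,
    high_confidence_clients,
    normalize_abundances,
    overlap_with_reference,
    pathway_position_summary,
    welch_enrichment,
)


def make_table(values_by_sample, kind="tmt_abundance", transformed=False):
    """Build a QuantTable from {sample_id: {accession: value}}."""
    rows = [
        {"accession": acc, "sample_id": sid, "value": v}
        for sid, col in values_by_sample.items()
        for acc, v in col.items()
    ]
    return QuantTable(
        data=pd.DataFrame(rows),
        samples=_sample_metadata(values_by_sample.keys()),
        kind=kind,
        transformed=transformed,
    )


def welch_oracle(a, b):
    """Textbook Welch t-test with Welch–Satterthwaite degrees of freedom."""
    from scipy.stats import t as t_dist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2 * t_dist.sf(abs(t), df)


class TestNormalization:
    def test_output_columns_have_median_zero(self):
        rng = np.random.default_rng(0)
        table = make_table({
            f"WT_{i}": {f"P{j}": float(v) for j, v in
                        enumerate(2.0 ** rng.normal(20, 2, 50))}
            for i in (1, 2)
        })
        norm = normalize_abundances(table)
        for sid in norm.samples.index:
            col = norm.data.loc[norm.data["sample_id"] == sid, "value"]
            assert col.median() == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_column_scaled_by_mad_rule(self):
        # log2 values {1,2,3}: median 2, MAD 1, scale 1.4826
        table = make_table({"WT_1": {"P1": 1.0, "P2": 2.0, "P3": 3.0}},
                           transformed=True)
        norm = normalize_abundances(table, already_log2=True)
        c = 1.0 / 1.4826
        got = norm.wide()["WT_1"].sort_values().tolist()
        assert got == pytest.approx([-c, 0.0, c])

    def test_constant_column_becomes_zeros(self):
        table = make_table({"WT_1": {f"P{i}": 8.0 for i in range(5)}},
                           transformed=True)
        norm = normalize_abundances(table, already_log2=True)
        assert (norm.data["value"] == 0).all()

    def test_too_few_values_rejected(self):
        table = make_table({"WT_1": {"P1": 1.0, "P2": 2.0}}, transformed=True)
        with pytest.raises(ValidationError, match="WT_1"):
            normalize_abundances(table, already_log2=True)

    def test_wrong_kind_rejected(self):
        table = make_table({"WT_1": {"P1": 1.0}}, kind="pulldown_intensity")
        with pytest.raises(ValidationError):
            normalize_abundances(table)


class TestWelchEnrichment:
    def two_group_table(self, a, b):
        return make_table(
            {
                **{f"GOLPH3_{i+1}": {"P1": v} for i, v in enumerate(a)},
                **{f"GST_{i+1}": {"P1": v} for i, v in enumerate(b)},
            },
            transformed=True,
        )

    def test_identical_groups_are_null(self):
        table = self.two_group_table([10, 11, 12], [10, 11, 12])
        (r,) = welch_enrichment(table, "GOLPH3", "GST")
        assert r.log2fc == 0.0
        assert r.p_value == pytest.approx(1.0)
        assert not r.enriched

    def test_zero_variance_different_means_convention(self):
        table = self.two_group_table([5, 5, 5], [3, 3, 3])
        (r,) = welch_enrichment(table, "GOLPH3", "GST")
        assert r.p_value == 0.0
        assert r.enriched

    def test_zero_variance_equal_means_convention(self):
        table = self.two_group_table([5, 5, 5], [5, 5, 5])
        (r,) = welch_enrichment(table, "GOLPH3", "GST")
        assert r.p_value == 1.0

    def test_matches_textbook_oracle(self):
        a, b = [5.1, 5.3, 5.0], [3.9, 4.1, 4.0]
        table = self.two_group_table(a, b)
        (r,) = welch_enrichment(table, "GOLPH3", "GST")
        assert r.p_value == pytest.approx(welch_oracle(a, b), abs=1e-10)
        assert r.log2fc == pytest.approx(np.mean(a) - np.mean(b))

    @given(
        a=st.lists(st.floats(-5, 5), min_size=2, max_size=6),
        b=st.lists(st.floats(-5, 5), min_size=2, max_size=6),
    )
    def test_oracle_parity_fuzz(self, a, b):
        if np.var(a) == 0 and np.var(b) == 0:
            return
        table = self.two_group_table(a, b)
        (r,) = welch_enrichment(table, "GOLPH3", "GST")
        assert r.p_value == pytest.approx(welch_oracle(a, b), abs=1e-10)

    def test_insufficient_replicates_reported_untested(self):
        table = make_table(
            {"GOLPH3_1": {"P1": 5.0}, "GOLPH3_2": {"P1": np.nan},
             "GST_1": {"P1": 3.0}, "GST_2": {"P1": 3.1}},
            transformed=True,
        )
        (r,) = welch_enrichment(table, "GOLPH3", "GST")
        assert math.isnan(r.p_value)
        assert not r.enriched
        assert r.reason == "insufficient_replicates"
        assert r.n_valid == (1, 2)


def enr(acc, bait, enriched=True):
    return EnrichmentResult(accession=acc, bait=bait, log2fc=1.0, p_value=0.01,
                            n_valid=(3, 3), enriched=enriched)


class TestPulldownHits:
    def test_disjoint_sets(self):
        info = call_pulldown_hits({"GOLPH3": [enr("A", "GOLPH3")],
                                   "GOLPH3L": [enr("B", "GOLPH3L")]})
        assert info["counts"] == {"union": 2, "common": 0,
                                  "GOLPH3_specific": 1, "GOLPH3L_specific": 1}

    def test_identical_sets_all_common(self):
        results = {b: [enr("A", b), enr("B", b)] for b in ("GOLPH3", "GOLPH3L")}
        info = call_pulldown_hits(results)
        assert info["counts"]["common"] == 2
        assert info["counts"]["GOLPH3_specific"] == 0

    def test_golgi_filter_restricts_hits(self):
        info = call_pulldown_hits(
            {"GOLPH3": [enr("A", "GOLPH3"), enr("B", "GOLPH3")]},
            golgi_filter={"A"},
        )
        assert info["hits"]["GOLPH3"] == {"A"}

    def test_set_algebra_common_plus_specific_equals_union(self, proteome,
                                                           default_config):
        from golgisort.simulate import simulate_pulldown

        table = simulate_pulldown(proteome, default_config).log2()
        results = {b: welch_enrichment(table, b, "GST")
                   for b in ("GOLPH3", "GOLPH3L")}
        c = call_pulldown_hits(results)["counts"]
        assert (c["common"] + c["GOLPH3_specific"] + c["GOLPH3L_specific"]
                == c["union"])


class TestDegradation:
    def table_with_ratio(self, ratio):
        return make_table(
            {"KO_1": {"P1": ratio}, "KO_2": {"P1": ratio},
             "rescue_1": {"P1": 0.0}, "rescue_2": {"P1": 0.0}},
            transformed=True,
        )

    def test_boundary_ratio_is_degraded(self):
        (d,) = degradation_ratios(self.table_with_ratio(-0.1), "KO", "rescue")
        assert d.log2_ratio == pytest.approx(-0.1)
        assert d.degraded

    def test_just_above_boundary_is_not(self):
        (d,) = degradation_ratios(self.table_with_ratio(-0.099), "KO", "rescue")
        assert not d.degraded

    def test_equal_groups_ratio_zero(self):
        (d,) = degradation_ratios(self.table_with_ratio(0.0), "KO", "rescue")
        assert d.log2_ratio == 0.0
        assert not d.degraded


def dres(acc, ratio):
    return DegradationResult(accession=acc, log2_ratio=ratio, degraded=ratio <= -0.1)


class TestHighConfidenceClients:
    LOC = {"A": "Golgi", "B": "Golgi", "C": "other", "D": "other"}

    def toy(self):
        return [dres("A", -1.0), dres("B", -0.3), dres("C", -0.5), dres("D", -0.05)]

    def test_threshold_from_most_depleted_non_golgi(self):
        calls, threshold = high_confidence_clients(self.toy(), {"A", "B"}, self.LOC)
        assert threshold == -0.5
        assert {c.accession for c in calls if c.high_confidence} == {"A"}

    def test_pulldown_membership_required(self):
        calls, _ = high_confidence_clients(self.toy(), {"B"}, self.LOC)
        assert not any(c.high_confidence for c in calls)

    def test_all_golgi_above_threshold_gives_empty_set(self):
        degr = [dres("A", -0.2), dres("C", -0.5)]
        calls, _ = high_confidence_clients(degr, {"A"}, self.LOC)
        assert not any(c.high_confidence for c in calls)

    def test_tie_with_threshold_excluded(self):
        degr = [dres("A", -0.5), dres("C", -0.5)]
        calls, threshold = high_confidence_clients(degr, {"A"}, self.LOC)
        assert threshold == -0.5
        assert not any(c.high_confidence for c in calls)

    def test_no_non_golgi_rejected(self):
        with pytest.raises(ValidationError):
            high_confidence_clients([dres("A", -1.0)], {"A"}, {"A": "Golgi"})

    @given(data=st.data())
    def test_monotone_in_non_golgi_membership(self, data):
        """Removing a non-Golgi protein never shrinks the client set;
        adding one never grows it."""
        n = data.draw(st.integers(2, 8))
        ratios = data.draw(st.lists(st.floats(-2, 0.5), min_size=n, max_size=n))
        golgi = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
        if sum(not g for g in golgi) < 2:
            return
        accs = [f"P{i}" for i in range(n)]
        degr = [dres(a, r) for a, r in zip(accs, ratios)]
        loc = {a: ("Golgi" if g else "other") for a, g in zip(accs, golgi)}
        hits = set(accs)
        calls, _ = high_confidence_clients(degr, hits, loc)
        full = {c.accession for c in calls if c.high_confidence}
        drop = next(a for a, g in zip(accs, golgi) if not g)
        degr2 = [d for d in degr if d.accession != drop]
        calls2, _ = high_confidence_clients(degr2, hits, loc)
        reduced = {c.accession for c in calls2 if c.high_confidence}
        assert reduced >= full


class TestOverlapAndPathways:
    def test_overlap_percentages(self):
        assert overlap_with_reference({"A"}, ["A", "B", "C", "D"]) == (1, 25.0)
        assert overlap_with_reference({"X"}, ["A", "B"]) == (0, 0.0)
        assert overlap_with_reference({"A", "B"}, ["A", "B"]) == (2, 100.0)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValidationError):
            overlap_with_reference({"A"}, [])

    def test_all_early_toy_set(self):
        df = pathway_position_summary({"A": "early", "B": "early"},
                                      {"A": True, "B": True})
        deg = df[df["group"] == "degraded"].set_index("stage")
        assert deg.loc["early", "percent"] == 100.0
        assert deg.loc["intermediate", "count"] == 0

    def test_dual_stage_counted_once_per_stage(self):
        df = pathway_position_summary({"A": "intermediate+late"}, {"A": True})
        deg = df[df["group"] == "degraded"].set_index("stage")
        assert deg.loc["intermediate", "count"] == 1
        assert deg.loc["late", "count"] == 1
        assert deg.loc["intermediate", "n_assignments"] == 2  # one protein, two stages

    def test_mixed_toy_percentages(self):
        stages = {f"P{i}": "early" for i in range(7)}
        stages.update({f"Q{i}": "intermediate" for i in range(3)})
        degraded = {acc: False for acc in stages}
        df = pathway_position_summary(stages, degraded)
        nd = df[df["group"] == "nondegraded"].set_index("stage")
        assert nd.loc["intermediate", "percent"] == pytest.approx(30.0)


class TestNullCalibration:
    def test_null_fpr_matches_welch_small_sample_level(self):
        """Without a planted effect the pipeline's p < 0.05 fraction matches
        the actual small-sample level of Welch's test at 3 vs 3 replicates,
        estimated independently by direct Monte Carlo on Gaussian draws
        (Welch is conservative at this n; the nominal 5% is not the
        reference point)."""
        from scipy.stats import ttest_ind

        from golgisort.simulate import (CompartmentMix, PulldownDesign,
                                        SimulationConfig, simulate_proteome,
                                        simulate_pulldown)

        flags = []
        for seed in range(3):
            cfg = SimulationConfig(
                seed=seed,
                compartments={"Golgi": CompartmentMix(n=1000, tail_mu=5.0,
                                                      include_acidic=False),
                              "ER": CompartmentMix(n=1000, tail_mu=20.0)},
                client_fraction=0.0,
                pulldown=PulldownDesign(effect_log2=0.0, missing_rate=0.0),
            )
            table = simulate_pulldown(simulate_proteome(cfg), cfg).log2()
            for r in welch_enrichment(table, "GOLPH3", "GST"):
                if not math.isnan(r.p_value):
                    flags.append(r.p_value < 0.05)
        rng = np.random.default_rng(99)
        a = rng.normal(size=(100_000, 3))
        b = rng.normal(size=(100_000, 3))
        reference = (ttest_ind(a, b, axis=1, equal_var=False).pvalue < 0.05).mean()
        # binomial tolerance at n = 6000 pooled proteins
        assert np.mean(flags) == pytest.approx(reference, abs=0.01)
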