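"""Generator determinism and self-consistency against its own parameters."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from golgisort.simulate import (
    CompartmentMix,
    FlowDesign,
    PulldownDesign,
    SimulationConfig,
    simulate_flow,
    simulate_proteome,
    simulate_pulldown,
    simulate_tmt,
)


def small_config(seed, **kw):
    base = dict(
        compartments={
            "Golgi": CompartmentMix(n=60, tail_mu=5.0, p_proximal_rk=0.6,
                                    p_distal_rk=0.15, include_acidic=False),
            "ER": CompartmentMix(n=60, tail_mu=20.0, p_proximal_rk=0.08),
            "PM": CompartmentMix(n=60, tail_mu=30.0, p_proximal_rk=0.10),
        },
        flow=FlowDesign(n_events=3000),
    )
    base.update(kw)
    return SimulationConfig(seed=seed, **base)


class TestProteome:
    def test_fixed_seed_reproducibility(self):
        a = simulate_proteome(small_config(3))
        b = simulate_proteome(small_config(3))
        assert a == b

    def test_different_seeds_differ(self):
        a = simulate_proteome(small_config(3))
        b = simulate_proteome(small_config(4))
        assert a != b

    def test_zero_jitter_annotations_equal_truth(self):
        for rec in simulate_proteome(small_config(3, jitter=0)):
            assert rec.tm_start == rec.truth["true_tm_start"]
            assert rec.tm_end == rec.truth["true_tm_end"]

    def test_jitter_bounded(self):
        for rec in simulate_proteome(small_config(3, jitter=3)):
            assert abs(rec.tm_start - rec.truth["true_tm_start"]) <= 3
            assert abs(rec.tm_end - rec.truth["true_tm_end"]) <= 3

    def test_proximal_charge_probabilities_separate_compartments(self):
        """Monte-Carlo check of the generator against its own parameters:
        Golgi proximal R/K probability 0.8 vs ER 0.1 shows up as a strictly
        larger mean proximal count."""
        config = SimulationConfig(
            seed=7,
            compartments={
                "Golgi": CompartmentMix(n=500, tail_mu=8.0, p_proximal_rk=0.8,
                                        include_acidic=False),
                "ER": CompartmentMix(n=500, tail_mu=8.0, p_proximal_rk=0.1),
            },
        )
        from golgisort.tails import count_proximal_positives

        counts = {"Golgi": [], "ER": []}
        for rec in simulate_proteome(config):
            counts[rec.localization].append(count_proximal_positives(rec.tail))
        assert np.mean(counts["Golgi"]) > np.mean(counts["ER"])

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            small_config(1, client_fraction=1.5)


class TestPulldown:
    def test_fixed_seed_reproducibility(self):
        cfg = small_config(5)
        prot = simulate_proteome(cfg)
        a = simulate_pulldown(prot, cfg)
        b = simulate_pulldown(prot, cfg)
        assert a.data.equals(b.data)

    def test_null_effect_clients_exchangeable(self):
        """With a zero enrichment effect, client and background log2
        intensities in the bait groups come from the same distribution
        (KS test over a small seed battery)."""
        passes = 0
        for seed in range(5):
            cfg = small_config(seed, pulldown=PulldownDesign(effect_log2=0.0,
                                                             missing_rate=0.0))
            prot = simulate_proteome(cfg)
            table = simulate_pulldown(prot, cfg).log2()
            wide = table.wide()
            bait_cols = table.sample_ids("GOLPH3") + table.sample_ids("GOLPH3L")
            clients = {r.accession for r in prot if r.truth["is_client"]}
            vals = wide[bait_cols]
            # per-protein baselines dominate; compare bait-minus-control shifts
            shift = vals.mean(axis=1) - wide[table.sample_ids("GST")].mean(axis=1)
            a = shift[shift.index.isin(clients)]
            b = shift[~shift.index.isin(clients)]
            if stats.ks_2samp(a, b).pvalue > 0.01:
                passes += 1
        assert passes >= 4

    def test_planted_effect_recovered(self):
        """Median observed client log2 fold change is within 0.2 of the
        configured +2 effect across seeds."""
        medians = []
        for seed in range(30):
            cfg = small_config(seed, pulldown=PulldownDesign(missing_rate=0.0))
            prot = simulate_proteome(cfg)
            table = simulate_pulldown(prot, cfg).log2()
            wide = table.wide()
            clients = {r.accession for r in prot
                       if r.truth["client_of"] in ("both", "GOLPH3")}
            fc = (wide[table.sample_ids("GOLPH3")].mean(axis=1)
                  - wide[table.sample_ids("GST")].mean(axis=1))
            medians.append(fc[fc.index.isin(clients)].median())
        assert abs(np.median(medians) - 2.0) < 0.2

    def test_requires_truth_labels(self):
        cfg = small_config(1)
        prot = simulate_proteome(cfg)
        prot[0] = dataclasses.replace(prot[0], truth=None)
        with pytest.raises(ValueError):
            simulate_pulldown(prot, cfg)


class TestTmt:
    def test_clients_depleted_in_ko_only(self):
        cfg = small_config(9)
        prot = simulate_proteome(cfg)
        table = simulate_tmt(prot, cfg).log2()
        wide = table.wide()
        clients = [r.accession for r in prot if r.truth["is_client"]]
        ko = wide[table.sample_ids("KO")].mean(axis=1)
        wt = wide[table.sample_ids("WT")].mean(axis=1)
        rescue = wide[table.sample_ids("rescue")].mean(axis=1)
        assert (ko - rescue)[clients].mean() == pytest.approx(-1.0, abs=0.15)
        assert (wt - rescue).mean() == pytest.approx(0.0, abs=0.05)

    def test_fixed_seed_reproducibility(self):
        cfg = small_config(2)
        prot = simulate_proteome(cfg)
        assert simulate_tmt(prot, cfg).data.equals(simulate_tmt(prot, cfg).data)


class TestFlow:
    def test_event_count_honored_exactly(self):
        tables = simulate_flow(small_config(1))
        for df in tables.values():
            assert len(df) == 3000

    def test_zero_surface_fraction_gives_pure_noise(self):
        cfg = small_config(1, flow=FlowDesign(n_events=3000,
                                              genotypes={"WT": 0.0}))
        df = simulate_flow(cfg)["WT"]
        analysis = df[df["label"] == "analysis"]
        # noise is centred at 0 and truncated: median a647 is ~0 vs gfp ~1000
        assert analysis["a647"].median() < 50
        assert analysis["gfp"].median() > 500

    def test_genotype_ordering_by_surface_fraction(self):
        """A 10x difference in planted surface fraction orders the gated
        median ratio in every seeded run."""
        from golgisort.flow import retention_index

        for seed in range(5):
            tables = simulate_flow(small_config(seed))
            med = {g: retention_index(df).median for g, df in tables.items()}
            assert med["dGOLPH3_3L"] > med["WT"]

    def test_truth_labels_partition_events(self):
        df = simulate_flow(small_config(3))["WT"]
        assert set(df["label"]) == {"doublet", "dead", "gfp_negative", "analysis"}
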