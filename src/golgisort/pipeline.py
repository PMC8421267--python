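"""End-to-end reproduction pipeline on a synthetic dataset.

``run_pipeline`` chains every stage — simulate, refine TM spans, tail
features, logo matrices, screen integration, retention assay — on one seeded
synthetic dataset, writes TSV/CSV/JSON outputs into an output directory, and
emits a manifest listing every file with a content hash.  Outputs are
deterministic for a fixed seed; the echoed config suffices to re-run
identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import flow, io, logo, screens, simulate, tails, tm

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    outdir: str = "results/run"
    seed: int = 0
    scale: str = "kyte_doolittle"
    alpha: float = 0.05
    degradation_cutoff: float = screens.DEGRADATION_CUTOFF
    refine_before_logo: bool = True
    simulation: simulate.SimulationConfig | None = None
    gate: flow.GateConfig = field(default_factory=flow.GateConfig)

    def __post_init__(self) -> None:
        tm.get_scale(self.scale)
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.simulation is None:
            self.simulation = simulate.SimulationConfig(seed=self.seed)
        else:
            self.simulation = dataclasses.replace(self.simulation, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        sim = raw.pop("simulation", None)
        if sim is not None:
            comps = {
                name: simulate.CompartmentMix(**c)
                for name, c in sim.pop("compartments", {}).items()
            }
            kwargs = dict(sim)
            if comps:
                kwargs["compartments"] = comps
            for key, klass in (
                ("pulldown", simulate.PulldownDesign),
                ("tmt", simulate.TmtDesign),
                ("flow", simulate.FlowDesign),
            ):
                if key in kwargs:
                    kwargs[key] = klass(**kwargs[key])
            raw["simulation"] = simulate.SimulationConfig(**kwargs)
        if "gate" in raw:
            raw["gate"] = flow.GateConfig(**raw["gate"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on a seeded synthetic dataset; returns the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation

    # --- stage 1: synthetic dataset -------------------------------------
    proteome = simulate.simulate_proteome(sim)
    pulldown = simulate.simulate_pulldown(proteome, sim)
    tmt = simulate.simulate_tmt(proteome, sim)
    flow_tables = simulate.simulate_flow(sim)

    io.write_fasta({r.accession: r.sequence for r in proteome}, out / "proteome.fasta")
    io.write_annotation_table(proteome, out / "annotation.tsv")
    io.write_quant_table(pulldown, out / "pulldown.csv")
    io.write_quant_table(tmt, out / "tmt.csv")
    for genotype, events in flow_tables.items():
        io.write_flow_table(events, out / f"flow_{genotype}.csv")

    # --- stage 2: TM refinement -----------------------------------------
    spans = tm.refine_all(proteome, config.scale)
    tm.spans_to_frame(spans).to_csv(out / "refined_spans.tsv", sep="\t", index=False)
    span_map = {s.accession: s for s in spans}

    # --- stage 3: tail features -----------------------------------------
    features = tails.tail_features_table(proteome, span_map)
    features.to_csv(out / "tail_features.tsv", sep="\t", index=False)
    summary, hists = tails.compartment_tail_stats(features)
    summary.to_csv(out / "tail_summary.tsv", sep="\t", index=False)
    hists.to_csv(out / "tail_histograms.tsv", sep="\t", index=False)

    # --- stage 4: logo matrices (clients vs non-clients) ----------------
    starts = (
        {s.accession: s.refined[0] for s in spans} if config.refine_before_logo else None
    )
    clients = [r for r in proteome if r.truth and r.truth.get("is_client")]
    others = [r for r in proteome if not (r.truth and r.truth.get("is_client"))]
    la, lb, diff = logo.compare_logo_sets(clients, others, starts)
    la.frequencies.to_csv(out / "logo_clients.tsv", sep="\t")
    lb.frequencies.to_csv(out / "logo_background.tsv", sep="\t")
    diff.to_csv(out / "logo_difference.tsv", sep="\t")

    # --- stage 5: screen integration ------------------------------------
    log2_pd = pulldown.log2()
    results_by_bait = {
        bait: screens.welch_enrichment(log2_pd, bait, sim.pulldown.control, config.alpha)
        for bait in sim.pulldown.baits
    }
    enr_rows = [
        dataclasses.asdict(r) for results in results_by_bait.values() for r in results
    ]
    pd.DataFrame(enr_rows).to_csv(out / "enrichment.tsv", sep="\t", index=False)
    hit_info = screens.call_pulldown_hits(results_by_bait)
    norm = screens.normalize_abundances(tmt)
    degr = screens.degradation_ratios(
        norm, sim.tmt.ko_group, sim.tmt.rescue_group, config.degradation_cutoff
    )
    pd.DataFrame([dataclasses.asdict(d) for d in degr]).to_csv(
        out / "degradation.tsv", sep="\t", index=False
    )
    loc_map = {r.accession: r.localization for r in proteome}
    calls, threshold = screens.high_confidence_clients(
        degr, hit_info["union"], loc_map
    )
    pd.DataFrame([dataclasses.asdict(c) for c in calls]).to_csv(
        out / "client_calls.tsv", sep="\t", index=False
    )
    stage_map = {r.accession: r.pathway_position for r in proteome}
    degraded_map = {d.accession: d.degraded for d in degr}
    screens.pathway_position_summary(stage_map, degraded_map).to_csv(
        out / "pathway_positions.tsv", sep="\t", index=False
    )

    truth_clients = {r.accession for r in clients}
    called = {c.accession for c in calls if c.high_confidence}
    overlap = {
        "pulldown_counts": hit_info["counts"],
        "degradation_threshold": threshold,
        "n_high_confidence_clients": len(called),
        "n_true_clients": len(truth_clients),
        "sensitivity": (
            len(called & truth_clients) / len(truth_clients) if truth_clients else None
        ),
        "precision": len(called & truth_clients) / len(called) if called else None,
    }
    (out / "screen_summary.json").write_text(json.dumps(overlap, indent=2))

    # --- stage 6: retention assay ---------------------------------------
    retention = {}
    for genotype, events in flow_tables.items():
        s = flow.retention_index(events, config.gate)
        retention[genotype] = {
            "n_gated": s.n_gated,
            "median_ratio": s.median,
            "stage_counts": s.stage_counts,
        }
        pd.DataFrame(
            {"bin_left": s.hist_edges[:-1], "count": s.hist_counts}
        ).to_csv(out / f"retention_hist_{genotype}.tsv", sep="\t", index=False)
    (out / "retention_summary.json").write_text(json.dumps(retention, indent=2))

    # --- config echo and manifest ---------------------------------------
    (out / "config.yaml").write_text(
        yaml.safe_dump(
            {
                "seed": config.seed,
                "scale": config.scale,
                "alpha": config.alpha,
                "degradation_cutoff": config.degradation_cutoff,
                "refine_before_logo": config.refine_before_logo,
                "simulation": sim.to_dict(),
                "gate": dataclasses.asdict(config.gate),
            },
            sort_keys=True,
        )
    )
    files = sorted(p for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "seed": config.seed,
        "files": {p.name: _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
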