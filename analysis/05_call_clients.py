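#!/usr/bin/env python
"""Integrate the two proteomic screens into high-confidence client calls.

Per bait, Welch-tests log2 pulldown intensities against the GST control
(raw P < 0.05, positive fold change); normalizes the TMT table
(median-centred, MAD-scaled log2); computes log2(KO/rescue) degradation
ratios; and calls high-confidence clients as Golgi residents depleted
strictly below the most depleted non-Golgi protein that are also pulldown
hits.  Reports overlap counts, the degradation threshold, pathway-position
proportions, and recovery against generator truth.
"""

import argparse
import dataclasses
import json
from pathlib import Path

import pandas as pd

from golgisort import io, screens


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--alpha", type=float, default=0.05)
    ap.add_argument("--cutoff", type=float, default=screens.DEGRADATION_CUTOFF)
    args = ap.parse_args()

    sequences = io.read_fasta(args.datadir / "proteome.fasta")
    records = io.read_annotation_table(args.datadir / "annotation.tsv", sequences)
    loc = {r.accession: r.localization for r in records}
    golgi = {r.accession for r in records if r.localization == "Golgi"}

    pulldown = io.read_quant_table(args.datadir / "pulldown.csv",
                                   "pulldown_intensity").log2()
    results = {b: screens.welch_enrichment(pulldown, b, "GST", args.alpha)
               for b in ("GOLPH3", "GOLPH3L")}
    pd.DataFrame([dataclasses.asdict(r) for rs in results.values() for r in rs]
                 ).to_csv(args.outdir / "enrichment.tsv", sep="\t", index=False)
    hits = screens.call_pulldown_hits(results)
    golgi_hits = screens.call_pulldown_hits(results, golgi_filter=golgi)

    tmt = io.read_quant_table(args.datadir / "tmt.csv", "tmt_abundance")
    degr = screens.degradation_ratios(screens.normalize_abundances(tmt),
                                      "KO", "rescue", args.cutoff)
    pd.DataFrame([dataclasses.asdict(d) for d in degr]).to_csv(
        args.outdir / "degradation.tsv", sep="\t", index=False)
    calls, threshold = screens.high_confidence_clients(degr, hits["union"], loc)
    pd.DataFrame([dataclasses.asdict(c) for c in calls]).to_csv(
        args.outdir / "client_calls.tsv", sep="\t", index=False)

    stages = {r.accession: r.pathway_position for r in records}
    degraded = {d.accession: d.degraded for d in degr}
    pathways = screens.pathway_position_summary(stages, degraded)
    pathways.to_csv(args.outdir / "pathway_positions.tsv", sep="\t", index=False)

    truth = {r.accession for r in records
             if r.truth and r.truth.get("is_client")}
    called = {c.accession for c in calls if c.high_confidence}
    summary = {
        "pulldown_counts_all": hits["counts"],
        "pulldown_counts_golgi_resident": golgi_hits["counts"],
        "degradation_threshold": threshold,
        "n_degraded": sum(d.degraded for d in degr),
        "n_high_confidence_clients": len(called),
        "n_true_clients": len(truth),
        "sensitivity": len(called & truth) / len(truth) if truth else None,
        "precision": len(called & truth) / len(called) if called else None,
    }
    (args.outdir / "screen_summary.json").write_text(json.dumps(summary, indent=2))
    print(json.dumps(summary, indent=2))
    print("\npathway positions of degraded vs nondegraded Golgi proteins:")
    print(pathways.to_string(index=False))


if __name__ == "__main__":
    main()
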