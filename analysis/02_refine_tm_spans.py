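#!/usr/bin/env python
"""Refine annotated TM-span edges and score recovery against truth.

Reads the synthetic dataset written by 01_simulate_dataset.py, refines every
span with the hydrophobicity-difference rule (+-5 search window,
Kyte-Doolittle scale, one trim/extend step), and reports how many jittered
N-edges were restored to the true boundary.
"""

import argparse
from collections import Counter
from pathlib import Path

from golgisort import io, tm


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--scale", default="kyte_doolittle")
    args = ap.parse_args()

    sequences = io.read_fasta(args.datadir / "proteome.fasta")
    records = io.read_annotation_table(args.datadir / "annotation.tsv", sequences)
    spans = tm.refine_all(records, args.scale)
    tm.spans_to_frame(spans).to_csv(args.outdir / "refined_spans.tsv",
                                    sep="\t", index=False)

    with_truth = [(s, r) for s, r in zip(spans, records)
                  if r.truth and "true_tm_start" in r.truth]
    exact = sum(s.refined[0] == r.truth["true_tm_start"] for s, r in with_truth)
    jittered = sum(r.tm_start != r.truth["true_tm_start"] for _, r in with_truth)
    prov = Counter(s.start_provenance for s in spans)
    print(f"refined {len(spans)} spans ({dict(prov)} N-edge provenance)")
    print(f"annotation jitter had displaced {jittered}/{len(with_truth)} N-edges; "
          f"refinement recovered {exact}/{len(with_truth)} "
          f"({100 * exact / len(with_truth):.1f}%) exactly")


if __name__ == "__main__":
    main()
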