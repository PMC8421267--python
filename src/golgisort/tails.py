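"""Cytoplasmic-tail features of type II membrane proteins.

Three statistics characterize the Golgi-retention signal carried by the
short N-terminal tail of a type II protein:

* membrane-proximal positive-charge count — arginines and lysines within the
  six tail residues adjacent to the TM span, plus the N-terminal alpha-amino
  group when the tail is at most six residues long (so the N terminus itself
  lies inside the proximal window);
* predicted net charge at cytosolic pH 7.4 — +1 per R/K anywhere in the tail
  and +1 for the alpha-amino group, -1 per D/E, 0 for H/C/Y (side-chain pKa
  outside the cytosolic range), and -2 per supplied phosphosite;
* tail length.

"Membrane-proximal" is counted from the TM-adjacent end of the tail.
Phosphosites must be supplied externally; no prediction is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import AMINO_ACIDS, ProteinRecord, ValidationError
from .tm import RefinedSpan

PROXIMAL_WINDOW = 6
POSITIVE = frozenset("RK")
NEGATIVE = frozenset("DE")
PHOSPHO_CHARGE = -2.0  # phosphoserine/threonine at pH 7.4


@dataclass
class TailFeatures:
    accession: str
    tail_sequence: str
    tail_length: int
    proximal_positive_count: int
    net_charge: float  # NaN for an empty tail (no N terminus in the cytosol)
    phospho_positions: tuple[int, ...] = ()


def extract_tail(
    record: ProteinRecord, span: RefinedSpan | None = None
) -> str:
    """Cytoplasmic tail (positions 1..tm_start-1) of a type II record.

    Uses the refined start when a span is supplied, the annotated start
    otherwise.  Empty when the TM begins at residue 1.
    """
    if record.topology != "type_II":
        raise ValidationError(
            f"{record.accession}: tail extraction requires type_II topology, "
            f"got {record.topology}"
        )
    tm_start = span.refined[0] if span is not None else record.tm_start
    return record.sequence[: tm_start - 1]


def count_proximal_positives(tail_sequence: str) -> int:
    """Count positive charges in the 6 membrane-proximal tail residues.

    R and K side chains within the last ``min(6, len)`` tail positions, plus
    1 for the alpha-amino group when the whole tail is <= 6 residues long
    (and non-empty).
    """
    bad = set(tail_sequence) - set(AMINO_ACIDS)
    if bad:
        raise ValidationError(f"non-standard tail residues {sorted(bad)}")
    window = tail_sequence[-PROXIMAL_WINDOW:]
    count = sum(1 for ch in window if ch in POSITIVE)
    if 0 < len(tail_sequence) <= PROXIMAL_WINDOW:
        count += 1
    return count


def predict_net_charge(
    tail_sequence: str, phospho_positions: Sequence[int] | None = None
) -> float:
    """Predicted total tail charge at cytosolic pH 7.4.

    Includes the +1 of the N-terminal alpha-amino group; histidine counts 0
    (not fully protonated at pH 7.4); each phosphosite contributes -2.
    Raises on an empty tail, whose N terminus is not cytosolic.
    """
    if not tail_sequence:
        raise ValidationError("net charge undefined for an empty tail")
    bad = set(tail_sequence) - set(AMINO_ACIDS)
    if bad:
        raise ValidationError(f"non-standard tail residues {sorted(bad)}")
    charge = 1.0  # alpha-amino group
    charge += sum(1.0 for ch in tail_sequence if ch in POSITIVE)
    charge -= sum(1.0 for ch in tail_sequence if ch in NEGATIVE)
    if phospho_positions:
        for p in phospho_positions:
            if not (1 <= p <= len(tail_sequence)):
                raise ValidationError(f"phosphosite {p} outside tail")
        charge += PHOSPHO_CHARGE * len(phospho_positions)
    return charge


def compute_tail_features(
    record: ProteinRecord,
    span: RefinedSpan | None = None,
    phospho_positions: Sequence[int] | None = None,
) -> TailFeatures:
    tail = extract_tail(record, span)
    return TailFeatures(
        accession=record.accession,
        tail_sequence=tail,
        tail_length=len(tail),
        proximal_positive_count=count_proximal_positives(tail),
        net_charge=(
            predict_net_charge(tail, phospho_positions) if tail else float("nan")
        ),
        phospho_positions=tuple(phospho_positions or ()),
    )


def tail_features_table(
    records: Iterable[ProteinRecord],
    spans: dict[str, RefinedSpan] | None = None,
) -> pd.DataFrame:
    """Per-protein tail feature table for all type II records."""
    rows = []
    for rec in records:
        if rec.topology != "type_II":
            continue
        span = spans.get(rec.accession) if spans else None
        f = compute_tail_features(rec, span)
        rows.append(
            {
                "accession": rec.accession,
                "localization": rec.localization,
                "tail_sequence": f.tail_sequence,
                "tail_length": f.tail_length,
                "proximal_positive_count": f.proximal_positive_count,
                "net_charge": f.net_charge,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "accession",
            "localization",
            "tail_sequence",
            "tail_length",
            "proximal_positive_count",
            "net_charge",
        ],
    )


def compartment_tail_stats(
    features: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-compartment tail summaries and count histograms.

    Returns ``(summary, histograms)``: ``summary`` has one row per
    localization (n, median tail length, median proximal positive count);
    ``histograms`` is long-format counts of both statistics, suitable for a
    bar representation.  Empty compartments yield no rows, not an error.
    """
    summary_rows = []
    hist_rows = []
    for loc, grp in features.groupby("localization", sort=True):
        summary_rows.append(
            {
                "localization": loc,
                "n": len(grp),
                "median_tail_length": float(grp["tail_length"].median()),
                "median_proximal_positive_count": float(
                    grp["proximal_positive_count"].median()
                ),
            }
        )
        for metric in ("tail_length", "proximal_positive_count"):
            for value, count in grp[metric].value_counts().sort_index().items():
                hist_rows.append(
                    {
                        "localization": loc,
                        "metric": metric,
                        "value": int(value),
                        "count": int(count),
                    }
                )
    summary = pd.DataFrame(
        summary_rows,
        columns=[
            "localization",
            "n",
            "median_tail_length",
            "median_proximal_positive_count",
        ],
    )
    hists = pd.DataFrame(
        hist_rows, columns=["localization", "metric", "value", "count"]
    )
    return summary, hists
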