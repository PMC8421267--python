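"""Transmembrane-span edge refinement by a hydrophobicity-difference rule.

Database TM annotations are frequently off by a few residues.  Each edge is
re-placed by a single consistent rule: among candidate boundary positions
within +-5 residues of the annotated edge, pick the one maximizing the
difference between the mean hydrophobicity of the five TM-side residues and
the five flank-side residues; then apply at most one post-adjustment — trim
the terminal TM residue if it is hydrophilic (R, K, D, E, Q, N, H or S), or
extend the span by one if the adjacent flank residue is hydrophobic
(F, M, I, L, V, C, W, A, T or G).  Proline and tyrosine belong to neither
set and trigger no adjustment.  If no candidate has a full 5+5 window inside
the sequence, the annotated edge is kept (provenance ``fallback``).

Ties in the edge score are broken toward the candidate closest to the
annotated edge, then toward the N-terminus — minimal perturbation of the
curated annotation.

The hydrophobicity scale defaults to Kyte–Doolittle and is pluggable for
sensitivity analysis.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io import AMINO_ACIDS, ProteinRecord

log = logging.getLogger(__name__)

#: Kyte & Doolittle residue hydropathy values.
KYTE_DOOLITTLE: Mapping[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

SCALES: Mapping[str, Mapping[str, float]] = {"kyte_doolittle": KYTE_DOOLITTLE}

#: Residues whose presence at the TM end triggers a one-residue trim.
HYDROPHILIC_TRIM = frozenset("RKDEQNHS")
#: Flank residues whose adjacency triggers a one-residue extension.
HYDROPHOBIC_EXTEND = frozenset("FMILVCWATG")

WINDOW = 5          # flank/TM half-window for the edge score
SEARCH_RADIUS = 5   # candidate positions relative to the annotated edge


def get_scale(name_or_mapping: str | Mapping[str, float]) -> Mapping[str, float]:
    """Resolve a hydrophobicity scale by name or accept a full mapping."""
    if isinstance(name_or_mapping, str):
        try:
            scale = SCALES[name_or_mapping]
        except KeyError as exc:
            raise ValueError(f"unknown hydrophobicity scale {name_or_mapping!r}") from exc
        return scale
    missing = set(AMINO_ACIDS) - set(name_or_mapping)
    if missing:
        raise ValueError(f"scale missing residues {sorted(missing)}")
    return name_or_mapping


@dataclass
class RefinedSpan:
    """Refined TM span with per-edge provenance.

    Provenance values: ``shifted`` (window moved the edge), ``trimmed`` /
    ``extended`` (post-adjustment applied), ``unchanged``, ``fallback``
    (no valid candidate window; annotated edge kept).
    """

    accession: str
    original: tuple[int, int]
    refined: tuple[int, int]
    start_provenance: str
    end_provenance: str


def edge_score(
    sequence: str,
    boundary: int,
    side: str,
    scale: Mapping[str, float] | str = "kyte_doolittle",
) -> float | None:
    """Hydrophobicity difference at a candidate TM boundary (1-based).

    For the N edge, ``boundary`` is the first TM residue: the TM side is
    ``boundary..boundary+4`` and the flank (tail) side ``boundary-5..boundary-1``.
    For the C edge, ``boundary`` is the last TM residue, mirrored.  Returns
    ``mean(TM side) - mean(flank side)``, or ``None`` when either 5-residue
    window falls outside the sequence (invalid candidate).
    """
    scale = get_scale(scale)
    n = len(sequence)
    if side == "N_edge":
        tm_lo, tm_hi = boundary, boundary + WINDOW - 1
        fl_lo, fl_hi = boundary - WINDOW, boundary - 1
    elif side == "C_edge":
        tm_lo, tm_hi = boundary - WINDOW + 1, boundary
        fl_lo, fl_hi = boundary + 1, boundary + WINDOW
    else:
        raise ValueError(f"side must be N_edge or C_edge, got {side!r}")
    if tm_lo < 1 or fl_lo < 1 or tm_hi > n or fl_hi > n:
        return None
    tm_mean = sum(scale[sequence[i - 1]] for i in range(tm_lo, tm_hi + 1)) / WINDOW
    fl_mean = sum(scale[sequence[i - 1]] for i in range(fl_lo, fl_hi + 1)) / WINDOW
    return tm_mean - fl_mean


def refine_edge(
    record: ProteinRecord,
    edge: str,
    scale: Mapping[str, float] | str = "kyte_doolittle",
) -> tuple[int, str]:
    """Refine one TM edge of a record; returns (position, provenance)."""
    scale = get_scale(scale)
    seq = record.sequence
    annotated = record.tm_start if edge == "N_edge" else record.tm_end
    candidates: list[tuple[float, int, int]] = []
    for delta in range(-SEARCH_RADIUS, SEARCH_RADIUS + 1):
        pos = annotated + delta
        score = edge_score(seq, pos, edge, scale)
        if score is not None:
            candidates.append((score, abs(delta), pos))
    if not candidates:
        return annotated, "fallback"
    # max score; ties -> closest to annotation, then toward the N-terminus
    best = min(candidates, key=lambda c: (-c[0], c[1], c[2]))[2]
    provenance = "shifted" if best != annotated else "unchanged"
    if edge == "N_edge":
        terminal_tm = seq[best - 1]
        if terminal_tm in HYDROPHILIC_TRIM:
            return best + 1, "trimmed"
        if best > 1 and seq[best - 2] in HYDROPHOBIC_EXTEND:
            return best - 1, "extended"
    else:
        terminal_tm = seq[best - 1]
        if terminal_tm in HYDROPHILIC_TRIM:
            return best - 1, "trimmed"
        if best < len(seq) and seq[best] in HYDROPHOBIC_EXTEND:
            return best + 1, "extended"
    return best, provenance


def refine_span(
    record: ProteinRecord, scale: Mapping[str, float] | str = "kyte_doolittle"
) -> RefinedSpan:
    """Refine both edges of one record, guarding span validity."""
    start, start_prov = refine_edge(record, "N_edge", scale)
    end, end_prov = refine_edge(record, "C_edge", scale)
    if start > end:  # degenerate refinement; keep the curated annotation
        start, end = record.tm_start, record.tm_end
        start_prov = end_prov = "fallback"
    return RefinedSpan(
        accession=record.accession,
        original=(record.tm_start, record.tm_end),
        refined=(start, end),
        start_provenance=start_prov,
        end_provenance=end_prov,
    )


def refine_all(
    records: Iterable[ProteinRecord],
    scale: Mapping[str, float] | str = "kyte_doolittle",
) -> list[RefinedSpan]:
    """Refine every record, preserving order; logs provenance counts."""
    spans = [refine_span(r, scale) for r in records]
    counts = Counter(s.start_provenance for s in spans)
    counts.update(s.end_provenance for s in spans)
    log.info("refined %d spans; edge provenance: %s", len(spans), dict(counts))
    return spans


def spans_to_frame(spans: Sequence[RefinedSpan]):
    """Tabulate refined spans for TSV output."""
    import pandas as pd

    return pd.DataFrame(
        {
            "accession": [s.accession for s in spans],
            "tm_start": [s.original[0] for s in spans],
            "tm_end": [s.original[1] for s in spans],
            "refined_start": [s.refined[0] for s in spans],
            "refined_end": [s.refined[1] for s in spans],
            "start_provenance": [s.start_provenance for s in spans],
            "end_provenance": [s.end_provenance for s in spans],
        }
    )
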