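"""Anchor-aligned positional frequency (logo) matrices.

Sequences are aligned on the cytoplasmic edge of the TM span: offset 0 is the
first TM residue, the window runs from 15 residues before to 35 residues
after it (51 positions).  Offsets before residue 1 or past the end of the
sequence emit the padding symbol X, which is tallied alongside the 20 amino
acids — the prevalence of X just upstream of the anchor directly visualizes
how short the cytoplasmic tails are.

Stored quantities are plain frequencies (each column sums to 1); any
information-content weighting is a rendering choice, not part of the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import AMINO_ACIDS, ProteinRecord

WINDOW_BEFORE = 15
WINDOW_AFTER = 35
OFFSETS = tuple(range(-WINDOW_BEFORE, WINDOW_AFTER + 1))  # 51 positions
PAD = "X"
SYMBOLS = tuple(AMINO_ACIDS) + (PAD,)


@dataclass
class LogoMatrix:
    """51-position x 21-symbol frequency matrix anchored on the TM start."""

    frequencies: pd.DataFrame  # index: offsets -15..+35; columns: symbols
    n_sequences: int

    def __post_init__(self) -> None:
        if list(self.frequencies.index) != list(OFFSETS):
            raise ValueError("logo matrix must cover offsets -15..+35")
        if list(self.frequencies.columns) != list(SYMBOLS):
            raise ValueError("logo matrix must cover the 20 amino acids plus X")


def window_string(
    sequence: str, tm_start: int
) -> str:
    """51-symbol window at offsets -15..+35 from the TM start (X-padded)."""
    n = len(sequence)
    chars = []
    for k in OFFSETS:
        pos = tm_start + k  # 1-based
        chars.append(sequence[pos - 1] if 1 <= pos <= n else PAD)
    return "".join(chars)


def build_alignment_window(
    records: Iterable[ProteinRecord],
    starts: Mapping[str, int] | None = None,
) -> list[str]:
    """One 51-symbol window per record, anchored on the (refined) TM start.

    ``starts`` optionally maps accession to a refined start position; records
    absent from the mapping fall back to their annotated ``tm_start``.
    """
    out = []
    for rec in records:
        if rec.topology != "type_II":
            raise ValueError(
                f"{rec.accession}: logo windows require type_II topology"
            )
        start = starts.get(rec.accession, rec.tm_start) if starts else rec.tm_start
        out.append(window_string(rec.sequence, start))
    return out


def position_frequency_matrix(windows: Iterable[str]) -> LogoMatrix:
    """Per-position symbol frequencies (including X) over aligned windows."""
    windows = list(windows)
    counts = np.zeros((len(OFFSETS), len(SYMBOLS)), dtype=float)
    sym_index = {s: j for j, s in enumerate(SYMBOLS)}
    for w in windows:
        if len(w) != len(OFFSETS):
            raise ValueError(f"window of length {len(w)}, expected {len(OFFSETS)}")
        for i, ch in enumerate(w):
            counts[i, sym_index[ch]] += 1
    if windows:
        counts /= len(windows)
    freq = pd.DataFrame(counts, index=list(OFFSETS), columns=list(SYMBOLS))
    freq.index.name = "offset"
    return LogoMatrix(frequencies=freq, n_sequences=len(windows))


def compare_logo_sets(
    records_a: Iterable[ProteinRecord],
    records_b: Iterable[ProteinRecord],
    starts: Mapping[str, int] | None = None,
) -> tuple[LogoMatrix, LogoMatrix, pd.DataFrame]:
    """Paired logo matrices for two protein sets plus their difference (a - b)."""
    la = position_frequency_matrix(build_alignment_window(records_a, starts))
    lb = position_frequency_matrix(build_alignment_window(records_b, starts))
    return la, lb, la.frequencies - lb.frequencies


def render_heatmap(matrix: LogoMatrix, path, title: str = "") -> None:
    """Render a frequency matrix as a heatmap (presentation only)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(12, 5))
    im = ax.imshow(
        matrix.frequencies.T.to_numpy(), aspect="auto", cmap="viridis",
        extent=(OFFSETS[0] - 0.5, OFFSETS[-1] + 0.5, len(SYMBOLS) - 0.5, -0.5),
    )
    ax.set_yticks(range(len(SYMBOLS)))
    ax.set_yticklabels(SYMBOLS)
    ax.axvline(-0.5, color="w", lw=0.8, ls="--")
    ax.set_xlabel("offset from cytoplasmic TM edge")
    ax.set_title(title or f"positional frequencies (n={matrix.n_sequences})")
    fig.colorbar(im, ax=ax, label="frequency")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
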