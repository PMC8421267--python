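"""Readers, writers, and shared domain types.

All on-disk transmembrane (TM) span coordinates are 1-based inclusive,
following the UniProt convention.  Subcellular localization strings are
normalized through a fixed alias map (``LOCALIZATION_ALIASES``); strings the
map does not know collapse to ``"unknown"``, never silently to ``"other"``.

Quantitation tables are accepted in two CSV dialects:

* wide — first column ``accession``, one column per sample (``GROUP_REP``
  headers, e.g. ``GOLPH3_1``);
* long — columns ``accession, sample_id, value``.

Both parse to the same long-format :class:`QuantTable`.  In pulldown
(spectral-intensity) tables a value of 0 means "not detected" and is treated
as missing by default; TMT abundance tables keep zeros as zeros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
TOPOLOGIES = frozenset({"type_II", "type_I", "multi", "other"})
LOCALIZATIONS = frozenset({"ER", "Golgi", "PM", "other", "unknown"})
PATHWAY_STAGES = frozenset({"early", "intermediate", "late"})

#: Fixed alias map for subcellular localization strings (lower-cased keys).
LOCALIZATION_ALIASES: Mapping[str, str] = {
    "golgi": "Golgi",
    "golgi apparatus": "Golgi",
    "golgi apparatus membrane": "Golgi",
    "golgi membrane": "Golgi",
    "er": "ER",
    "endoplasmic reticulum": "ER",
    "endoplasmic reticulum membrane": "ER",
    "pm": "PM",
    "plasma membrane": "PM",
    "cell membrane": "PM",
    "other": "other",
    "unknown": "unknown",
}


class ParseError(ValueError):
    """Raised for malformed sequence or table files."""


class ValidationError(ValueError):
    """Raised when parsed content violates a domain invariant."""


def normalize_localization(raw: str) -> str:
    """Map a free-text localization string onto the fixed vocabulary."""
    return LOCALIZATION_ALIASES.get(str(raw).strip().lower(), "unknown")


def normalize_topology(raw: str) -> str:
    s = str(raw).strip().replace(" ", "_")
    if s.lower() in {"type_ii", "typeii", "ii"}:
        return "type_II"
    if s.lower() in {"type_i", "typei", "i"}:
        return "type_I"
    if s in TOPOLOGIES:
        return s
    raise ValidationError(f"unknown topology {raw!r}")


@dataclass
class ProteinRecord:
    """One membrane protein with sequence, topology and TM span.

    For ``topology == "type_II"`` the cytoplasmic tail is positions
    ``1..tm_start-1`` (possibly empty).  ``truth`` optionally carries
    simulation labels (``is_client``, ``client_of``, ``true_tm_start``,
    ``true_tm_end``).
    """

    accession: str
    sequence: str
    topology: str
    tm_start: int
    tm_end: int
    gene: str = ""
    localization: str = "unknown"
    pathway_position: str | None = None
    truth: dict | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"{self.accession}: empty sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise ValidationError(
                f"{self.accession}: non-standard residues {sorted(bad)}"
            )
        if self.topology not in TOPOLOGIES:
            raise ValidationError(f"{self.accession}: bad topology {self.topology!r}")
        if self.localization not in LOCALIZATIONS:
            raise ValidationError(
                f"{self.accession}: bad localization {self.localization!r}"
            )
        if not (1 <= self.tm_start <= self.tm_end <= len(self.sequence)):
            raise ValidationError(
                f"{self.accession}: TM span {self.tm_start}..{self.tm_end} outside "
                f"sequence of length {len(self.sequence)}"
            )
        if self.pathway_position not in (None, "none"):
            stages = set(str(self.pathway_position).split("+"))
            if not stages <= PATHWAY_STAGES:
                raise ValidationError(
                    f"{self.accession}: bad pathway position {self.pathway_position!r}"
                )

    @property
    def tail(self) -> str:
        """Cytoplasmic N-terminal tail of a type II protein."""
        if self.topology != "type_II":
            raise ValidationError(
                f"{self.accession}: cytoplasmic tail undefined for {self.topology}"
            )
        return self.sequence[: self.tm_start - 1]


@dataclass
class QuantTable:
    """Long-format protein x sample quantitation matrix with group metadata.

    ``data`` has columns ``accession, sample_id, value`` (missing values NaN);
    ``samples`` is indexed by ``sample_id`` with columns ``group`` and
    ``replicate``.  ``kind`` is ``"pulldown_intensity"`` or ``"tmt_abundance"``.
    Raw intensities/abundances must be non-negative; tables whose values have
    been log2-transformed or centred (``transformed=True``) are exempt.
    """

    data: pd.DataFrame
    samples: pd.DataFrame
    kind: str
    transformed: bool = False

    def __post_init__(self) -> None:
        if self.kind not in {"pulldown_intensity", "tmt_abundance"}:
            raise ValidationError(f"bad quant table kind {self.kind!r}")
        dup = self.data.duplicated(subset=["accession", "sample_id"])
        if dup.any():
            raise ValidationError("duplicate (accession, sample_id) pairs")
        missing_meta = set(self.data["sample_id"]) - set(self.samples.index)
        if missing_meta:
            raise ValidationError(f"samples without group metadata: {sorted(missing_meta)}")
        vals = self.data["value"]
        if not self.transformed and (vals.dropna() < 0).any():
            raise ValidationError("negative quantitation values")
        if np.isinf(vals.to_numpy(dtype=float)).any():
            raise ValidationError("non-finite quantitation values")

    def wide(self) -> pd.DataFrame:
        """Pivot to an accession x sample_id matrix (NaN where missing)."""
        return self.data.pivot(index="accession", columns="sample_id", values="value")

    def sample_ids(self, group: str) -> list[str]:
        ids = list(self.samples.index[self.samples["group"] == group])
        if not ids:
            raise ValidationError(f"no samples in group {group!r}")
        return ids

    def log2(self) -> "QuantTable":
        """Return a copy with values on the log2 scale (0/missing -> NaN)."""
        data = self.data.copy()
        v = data["value"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            data["value"] = np.where(v > 0, np.log2(np.where(v > 0, v, 1.0)), np.nan)
        return QuantTable(
            data=data, samples=self.samples, kind=self.kind, transformed=True
        )


#: Required channel columns of a flow-event table.
FLOW_CHANNELS = ("fsc_h", "fsc_w", "ssc_h", "ssc_w", "viability", "gfp", "a647")


@dataclass
class FlowEvent:
    """One cytometry event: scatter, viability dye, GFP and A647 channels.

    Flow tables are handled as DataFrames with the :data:`FLOW_CHANNELS`
    columns; this dataclass documents and validates the per-row schema.
    """

    fsc_h: float
    fsc_w: float
    ssc_h: float
    ssc_w: float
    viability: float
    gfp: float
    a647: float
    label: str | None = None
    true_surface_fraction: float | None = None

    def __post_init__(self) -> None:
        for name in FLOW_CHANNELS:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"flow channel {name} = {v!r} not finite/non-negative")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ``accession -> uppercase sequence`` mapping.

    Duplicate record ids and empty sequences are rejected.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ParseError(f"duplicate FASTA record id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"empty sequence for FASTA record {rec.id!r}")
        out[rec.id] = seq
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=acc, description="") for acc, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ("accession", "topology", "tm_start", "tm_end", "localization")


def read_annotation_table(
    path: str | Path, sequences: Mapping[str, str]
) -> list[ProteinRecord]:
    """Read a TSV annotation table and join it to sequences by accession.

    Rows whose accession has no sequence are reported (warning) and skipped.
    Rows violating the TM-span invariants raise a single
    :class:`ValidationError` listing every offending accession.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ParseError(f"annotation table missing columns {sorted(missing_cols)}")
    records: list[ProteinRecord] = []
    skipped: list[str] = []
    bad: list[str] = []
    for row in df.itertuples(index=False):
        acc = str(row.accession)
        if acc not in sequences:
            skipped.append(acc)
            continue
        truth = None
        if hasattr(row, "is_client") and not pd.isna(row.is_client):
            truth = {"is_client": str(row.is_client).lower() in {"true", "1", "yes"}}
            if hasattr(row, "true_tm_start") and not pd.isna(row.true_tm_start):
                truth["true_tm_start"] = int(float(row.true_tm_start))
            if hasattr(row, "true_tm_end") and not pd.isna(row.true_tm_end):
                truth["true_tm_end"] = int(float(row.true_tm_end))
        pathway = None
        if hasattr(row, "pathway_position") and not pd.isna(row.pathway_position):
            pathway = str(row.pathway_position)
            if pathway == "none":
                pathway = None
        try:
            records.append(
                ProteinRecord(
                    accession=acc,
                    sequence=sequences[acc],
                    topology=normalize_topology(row.topology),
                    tm_start=int(float(row.tm_start)),
                    tm_end=int(float(row.tm_end)),
                    gene=str(getattr(row, "gene", "")) if hasattr(row, "gene") else "",
                    localization=normalize_localization(row.localization),
                    pathway_position=pathway,
                    truth=truth,
                )
            )
        except ValidationError:
            bad.append(acc)
    if bad:
        raise ValidationError(f"invalid TM annotation for accessions: {bad}")
    if skipped:
        log.warning("skipped %d annotation rows without sequence: %s", len(skipped), skipped)
    return records


def write_annotation_table(records: Iterable[ProteinRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {
            "accession": r.accession,
            "gene": r.gene,
            "topology": r.topology,
            "tm_start": r.tm_start,
            "tm_end": r.tm_end,
            "localization": r.localization,
            "pathway_position": r.pathway_position if r.pathway_position else "none",
        }
        if r.truth:
            row["is_client"] = r.truth.get("is_client", False)
            row["true_tm_start"] = r.truth.get("true_tm_start", "")
            row["true_tm_end"] = r.truth.get("true_tm_end", "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Quantitation tables
# ---------------------------------------------------------------------------

def _sample_metadata(sample_ids: Iterable[str]) -> pd.DataFrame:
    rows = []
    for sid in sample_ids:
        if "_" not in sid:
            raise ValidationError(f"sample {sid!r} has no GROUP_REP group label")
        group, rep = sid.rsplit("_", 1)
        try:
            rep_i = int(rep)
        except ValueError as exc:
            raise ValidationError(f"sample {sid!r} has no replicate index") from exc
        rows.append({"sample_id": sid, "group": group, "replicate": rep_i})
    return pd.DataFrame(rows).set_index("sample_id")


def read_quant_table(
    path: str | Path, kind: str, zero_as_missing: bool | None = None
) -> QuantTable:
    """Read a quantitation CSV (wide or long dialect, autodetected).

    ``zero_as_missing`` defaults to True for ``pulldown_intensity`` (spectral
    counting semantics: 0 means not detected) and False for ``tmt_abundance``.
    """
    if zero_as_missing is None:
        zero_as_missing = kind == "pulldown_intensity"
    df = pd.read_csv(path)
    if {"accession", "sample_id", "value"} <= set(df.columns):
        long = df[["accession", "sample_id", "value"]].copy()
    else:
        if "accession" not in df.columns:
            raise ParseError("quant table needs an 'accession' column")
        long = df.melt(id_vars="accession", var_name="sample_id", value_name="value")
    long["value"] = pd.to_numeric(long["value"], errors="raise").astype(float)
    if zero_as_missing:
        long.loc[long["value"] == 0, "value"] = np.nan
    samples = _sample_metadata(pd.unique(long["sample_id"]))
    return QuantTable(data=long.reset_index(drop=True), samples=samples, kind=kind)


def write_quant_table(table: QuantTable, path: str | Path, wide: bool = False) -> None:
    if wide:
        w = table.wide().fillna(0.0)
        w.reset_index().to_csv(path, index=False)
    else:
        table.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Flow-event tables
# ---------------------------------------------------------------------------

def read_flow_table(path: str | Path) -> pd.DataFrame:
    """Read a per-event flow-cytometry CSV export.

    Requires the :data:`FLOW_CHANNELS` columns; optional ``label`` and
    ``true_surface_fraction`` truth columns are preserved.
    """
    df = pd.read_csv(path)
    missing = set(FLOW_CHANNELS) - set(df.columns)
    if missing:
        raise ParseError(f"flow table missing channels {sorted(missing)}")
    for col in FLOW_CHANNELS:
        v = df[col].to_numpy(dtype=float)
        if not np.isfinite(v).all() or (v < 0).any():
            raise ValidationError(f"flow channel {col} has negative or non-finite values")
    return df


def write_flow_table(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, index=False)
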