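"""Statistics and integration of the two proteomic screens.

The client-calling pipeline combines:

1. pulldown enrichment — per protein, a two-sided Welch t-test of log2
   spectral intensities, bait vs GST control, with the raw-P < alpha and
   positive log2 fold-change rule (no multiple-testing correction by
   default; a Benjamini–Hochberg option exists but is off to match the
   screen's calling rule);
2. knockout-proteome degradation — per-sample median-centred, robustly
   scaled log2 abundances; log2(KO / rescue) at or below the -0.1 cutoff
   classifies a protein as degraded (boundary inclusive);
3. high-confidence clients — Golgi-resident proteins depleted strictly more
   than the most depleted non-Golgi protein AND enriched in the pulldown.

Proteins with too few valid replicates are reported as untested rather than
silently dropped; missing values are never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import QuantTable, ValidationError

DEGRADATION_CUTOFF = -0.1
MAD_SCALE = 1.4826  # consistency factor: MAD -> sigma for a normal


@dataclass
class EnrichmentResult:
    accession: str
    bait: str
    log2fc: float
    p_value: float          # NaN when untested
    n_valid: tuple[int, int]  # (bait, control) replicates with values
    enriched: bool
    reason: str = ""        # why untested, when applicable


@dataclass
class DegradationResult:
    accession: str
    log2_ratio: float
    degraded: bool


@dataclass
class ClientCall:
    accession: str
    in_pulldown: bool
    log2_ratio: float
    localization: str
    high_confidence: bool
    threshold_used: float


def normalize_abundances(
    table: QuantTable, robust: bool = True, already_log2: bool = False
) -> QuantTable:
    """Median-centre and scale each sample column of a TMT table.

    Values are log2-transformed, centred on the per-sample median, and scaled
    by a robust spread estimate (MAD x 1.4826; constant columns fall back to
    a scale of 1).  ``robust=False`` substitutes the plain standard deviation.
    Every output column has median 0.
    """
    if table.kind != "tmt_abundance":
        raise ValidationError("normalization is defined for tmt_abundance tables")
    src = table if already_log2 else table.log2()
    data = src.data.copy()
    for sid in table.samples.index:
        mask = data["sample_id"] == sid
        v = data.loc[mask, "value"].to_numpy(dtype=float)
        finite = np.isfinite(v)
        if finite.sum() < 3:
            raise ValidationError(f"sample {sid!r} has fewer than 3 finite values")
        med = np.median(v[finite])
        if robust:
            scale = MAD_SCALE * np.median(np.abs(v[finite] - med))
        else:
            scale = float(np.std(v[finite], ddof=1))
        if scale <= 0:
            scale = 1.0
        data.loc[mask, "value"] = (v - med) / scale
    return QuantTable(
        data=data, samples=table.samples, kind=table.kind, transformed=True
    )


def welch_enrichment(
    table: QuantTable,
    bait_group: str,
    control_group: str,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> list[EnrichmentResult]:
    """Per-protein two-sided Welch t-test of log2 values, bait vs control.

    ``table`` must hold log2-scale values (see :meth:`QuantTable.log2`).
    Proteins with fewer than 2 valid replicates in either group get an
    undefined p-value and ``enriched=False`` with the reason recorded.
    Degenerate zero-variance-in-both-groups cases use the convention
    p=1 for equal means, p=0 otherwise.
    """
    wide = table.wide()
    A = wide[table.sample_ids(bait_group)].to_numpy(dtype=float)
    B = wide[table.sample_ids(control_group)].to_numpy(dtype=float)
    nA = np.isfinite(A).sum(axis=1)
    nB = np.isfinite(B).sum(axis=1)
    import warnings

    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN / ddof slices
        meanA = np.nanmean(np.where(np.isfinite(A), A, np.nan), axis=1)
        meanB = np.nanmean(np.where(np.isfinite(B), B, np.nan), axis=1)
        varA = np.nanvar(np.where(np.isfinite(A), A, np.nan), axis=1, ddof=1)
        varB = np.nanvar(np.where(np.isfinite(B), B, np.nan), axis=1, ddof=1)
    valid = (nA >= 2) & (nB >= 2)
    degenerate = valid & (varA <= 0) & (varB <= 0)
    regular = valid & ~degenerate
    p = np.full(len(wide), np.nan)
    if regular.any():
        res = stats.ttest_ind(
            A[regular], B[regular], axis=1, equal_var=False, nan_policy="omit"
        )
        p[regular] = np.asarray(res.pvalue, dtype=float)
    p[degenerate] = np.where(meanA[degenerate] == meanB[degenerate], 1.0, 0.0)
    if bh_correct:
        defined = np.isfinite(p)
        p_adj = p.copy()
        p_adj[defined] = stats.false_discovery_control(p[defined], method="bh")
        p_eff = p_adj
    else:
        p_eff = p
    log2fc = meanA - meanB
    results = []
    for i, acc in enumerate(wide.index):
        enriched = bool(valid[i] and np.isfinite(p_eff[i]) and p_eff[i] < alpha
                        and log2fc[i] > 0)
        results.append(
            EnrichmentResult(
                accession=str(acc),
                bait=bait_group,
                log2fc=float(log2fc[i]) if valid[i] else float("nan"),
                p_value=float(p_eff[i]) if valid[i] else float("nan"),
                n_valid=(int(nA[i]), int(nB[i])),
                enriched=enriched,
                reason="" if valid[i] else "insufficient_replicates",
            )
        )
    return results


def call_pulldown_hits(
    results_by_bait: Mapping[str, Sequence[EnrichmentResult]],
    golgi_filter: set[str] | None = None,
) -> dict:
    """Hit sets per bait plus overlap counts (common / bait-specific / union).

    ``golgi_filter`` optionally restricts hits to a set of accessions
    (e.g. Golgi-resident integral membrane proteins).
    """
    baits = list(results_by_bait)
    hits: dict[str, set[str]] = {}
    for bait, results in results_by_bait.items():
        s = {r.accession for r in results if r.enriched}
        if golgi_filter is not None:
            s &= golgi_filter
        hits[bait] = s
    union = set().union(*hits.values()) if hits else set()
    common = set.intersection(*hits.values()) if hits else set()
    out = {"hits": hits, "union": union, "common": common}
    counts = {"union": len(union), "common": len(common)}
    for bait in baits:
        specific = hits[bait] - set().union(
            *(hits[b] for b in baits if b != bait)
        ) if len(baits) > 1 else hits[bait]
        out[f"{bait}_specific"] = specific
        counts[f"{bait}_specific"] = len(specific)
    out["counts"] = counts
    return out


def degradation_ratios(
    normalized: QuantTable,
    ko_group: str,
    rescue_group: str,
    cutoff: float = DEGRADATION_CUTOFF,
) -> list[DegradationResult]:
    """Per-protein log2(KO / rescue) with the inclusive degradation cutoff.

    The ratio is the difference of group means on the (normalized) log2
    scale; a ratio exactly at the cutoff classifies as degraded.
    """
    wide = normalized.wide()
    ko = wide[normalized.sample_ids(ko_group)].to_numpy(dtype=float)
    rs = wide[normalized.sample_ids(rescue_group)].to_numpy(dtype=float)
    import warnings

    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        ratio = np.nanmean(ko, axis=1) - np.nanmean(rs, axis=1)
    return [
        DegradationResult(
            accession=str(acc),
            log2_ratio=float(r),
            degraded=bool(np.isfinite(r) and r <= cutoff),
        )
        for acc, r in zip(wide.index, ratio)
    ]


def high_confidence_clients(
    degradation: Sequence[DegradationResult],
    pulldown_hits: set[str],
    localization: Mapping[str, str],
    golgi_label: str = "Golgi",
) -> tuple[list[ClientCall], float]:
    """Call clients depleted strictly below every non-Golgi protein.

    The threshold is the minimum log2 ratio among non-Golgi proteins; a
    high-confidence client is Golgi-resident, strictly below that threshold
    (ties with the threshold protein excluded), and a pulldown hit.  Raises
    when no non-Golgi protein is present (threshold undefined).
    """
    missing = [d.accession for d in degradation if d.accession not in localization]
    if missing:
        raise ValidationError(f"accessions without localization: {missing[:5]}")
    non_golgi = [
        d.log2_ratio
        for d in degradation
        if localization[d.accession] != golgi_label and np.isfinite(d.log2_ratio)
    ]
    if not non_golgi:
        raise ValidationError("no non-Golgi proteins: degradation threshold undefined")
    threshold = float(min(non_golgi))
    calls = []
    for d in degradation:
        loc = localization[d.accession]
        hc = bool(
            loc == golgi_label
            and np.isfinite(d.log2_ratio)
            and d.log2_ratio < threshold
            and d.accession in pulldown_hits
        )
        calls.append(
            ClientCall(
                accession=d.accession,
                in_pulldown=d.accession in pulldown_hits,
                log2_ratio=d.log2_ratio,
                localization=loc,
                high_confidence=hc,
                threshold_used=threshold,
            )
        )
    return calls, threshold


def overlap_with_reference(
    hits: set[str], reference: Iterable[str]
) -> tuple[int, float]:
    """Intersection count and percentage of a reference list covered by hits."""
    ref = set(reference)
    if not ref:
        raise ValidationError("empty reference list")
    n = len(hits & ref)
    return n, 100.0 * n / len(ref)


def pathway_position_summary(
    stages: Mapping[str, str | None],
    degraded: Mapping[str, bool],
) -> pd.DataFrame:
    """Stage proportions (early/intermediate/late) for degraded vs nondegraded.

    A protein annotated with multiple stages (``"early+late"``) is counted
    once per stage, so group denominators are stage assignments, not
    proteins.  Proteins without a stage are excluded.
    """
    rows = []
    for group_name, want in (("degraded", True), ("nondegraded", False)):
        assignments: list[str] = []
        for acc, flag in degraded.items():
            if flag != want:
                continue
            stage = stages.get(acc)
            if stage in (None, "none"):
                continue
            assignments.extend(str(stage).split("+"))
        total = len(assignments)
        for stage in ("early", "intermediate", "late"):
            count = assignments.count(stage)
            rows.append(
                {
                    "group": group_name,
                    "stage": stage,
                    "count": count,
                    "n_assignments": total,
                    "percent": 100.0 * count / total if total else float("nan"),
                }
            )
    return pd.DataFrame(rows)
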