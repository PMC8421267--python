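"""Seeded generators emulating the study's data shapes with known truth.

Four generators share one :class:`SimulationConfig` and one global seed:

* :func:`simulate_proteome` — annotated type II proteomes for the ER, Golgi
  and plasma membrane, with Golgi tails drawn short and basic, sharp
  polar-tail/hydrophobic-TM boundaries, and integer jitter on the annotated
  TM edges;
* :func:`simulate_pulldown` — GST-bait spectral-intensity tables
  (3 replicates x {GST, GOLPH3, GOLPH3L}) with an additive log2 enrichment
  effect for planted clients;
* :func:`simulate_tmt` — whole-proteome abundance tables (duplicate channels
  x {WT, KO, rescue}) with clients depleted in the knockout channels;
* :func:`simulate_flow` — per-event cytometry tables as a labelled mixture of
  doublets, dead cells, GFP-negative cells and analysable GFP-positive cells
  whose surface signal is ``surface_fraction * gfp * gain`` plus truncated
  Gaussian noise.

Intensity noise is log-normal (Gaussian on the log2 scale) — an assumption
matching the log-ratio analyses downstream, not a measured property.
Per-generator random substreams are derived deterministically from the one
seed so modules can be re-run independently; a fixed seed and config give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .io import ProteinRecord, QuantTable, _sample_metadata

# Substream ids for deriving independent generators from the global seed.
_STREAMS = {"proteome": 1, "pulldown": 2, "tmt": 3, "flow": 4}

# Tail residues are polar/charged and deliberately exclude every residue of
# the refinement module's hydrophobic extend set, so that the generated
# tail|TM boundaries are sharp and the true edge is recoverable.
_TAIL_BACKGROUND = "SNQPH"
_TAIL_ACIDIC = "DE"
_TM_RESIDUES = "LIVFA"
_TM_WEIGHTS = (0.40, 0.20, 0.15, 0.15, 0.10)
_ALL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class CompartmentMix:
    """Per-compartment proteome composition parameters."""

    n: int = 170
    tail_mu: float = 6.0          # mean extra tail length beyond 1 residue
    p_proximal_rk: float = 0.10   # P(R or K) per residue in the 6 TM-proximal slots
    p_distal_rk: float = 0.10     # P(R or K) per residue further from the TM
    include_acidic: bool = True   # allow D/E in the tail background


@dataclass
class PulldownDesign:
    n_replicates: int = 3
    baits: tuple[str, ...] = ("GOLPH3", "GOLPH3L")
    control: str = "GST"
    effect_log2: float = 2.0      # client enrichment, bait vs GST, log2 units
    noise_sd: float = 0.3         # log2 units
    baseline_mean: float = 20.0   # log2 intensity
    baseline_sd: float = 2.0
    missing_rate: float = 0.05    # dropout probability for low-intensity values
    missing_quantile: float = 0.2


@dataclass
class TmtDesign:
    n_replicates: int = 2
    wt_group: str = "WT"
    ko_group: str = "KO"
    rescue_group: str = "rescue"
    depletion_log2: float = -1.0  # client log2(KO / rescue)
    noise_sd: float = 0.2
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0


@dataclass
class FlowDesign:
    n_events: int = 10_000
    genotypes: dict = field(
        default_factory=lambda: {"WT": 0.05, "dGOLPH3_3L": 0.5}
    )  # genotype -> true surface fraction of the reporter
    f_doublet: float = 0.08
    f_dead: float = 0.05
    f_gfp_negative: float = 0.12
    gain: float = 1.0
    a647_noise_sd: float = 30.0   # absolute counts; GFP-positive cells ~1e3
    gfp_log2_mean: float = 10.0
    gfp_log2_sd: float = 1.0


@dataclass
class SimulationConfig:
    """Full design of the synthetic study; defaults are the study conditions."""

    seed: int = 0
    compartments: dict = field(
        default_factory=lambda: {
            "Golgi": CompartmentMix(n=170, tail_mu=5.0, p_proximal_rk=0.6,
                                    p_distal_rk=0.15, include_acidic=False),
            "ER": CompartmentMix(n=165, tail_mu=20.0, p_proximal_rk=0.08,
                                 p_distal_rk=0.10, include_acidic=True),
            "PM": CompartmentMix(n=165, tail_mu=30.0, p_proximal_rk=0.10,
                                 p_distal_rk=0.10, include_acidic=True),
        }
    )
    tm_mu: float = 21.0
    tm_sd: float = 2.0
    lumenal_mu: float = 80.0
    jitter: int = 3               # annotated edge = true edge + U{-j..j}
    client_fraction: float = 0.3  # of Golgi type II proteins
    # split of clients between both baits / GOLPH3 only / GOLPH3L only
    client_bait_probs: tuple[float, float, float] = (0.58, 0.18, 0.24)
    pulldown: PulldownDesign = field(default_factory=PulldownDesign)
    tmt: TmtDesign = field(default_factory=TmtDesign)
    flow: FlowDesign = field(default_factory=FlowDesign)

    def __post_init__(self) -> None:
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")
        probs = [self.client_fraction, *self.client_bait_probs,
                 self.flow.f_doublet, self.flow.f_dead, self.flow.f_gfp_negative]
        for c in self.compartments.values():
            probs += [c.p_proximal_rk, c.p_distal_rk]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.client_bait_probs) - 1.0) > 1e-9:
            raise ValueError("client_bait_probs must sum to 1")

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic per-module substream of the global seed."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        )

    def to_dict(self) -> dict:
        return asdict(self)


def _draw_tail(rng: np.random.Generator, length: int, mix: CompartmentMix) -> str:
    background = _TAIL_BACKGROUND + (_TAIL_ACIDIC if mix.include_acidic else "")
    chars = []
    for pos in range(1, length + 1):
        proximal = (length - pos) < 6  # within the 6 residues next to the TM
        p = mix.p_proximal_rk if proximal else mix.p_distal_rk
        if rng.random() < p:
            chars.append("R" if rng.random() < 0.5 else "K")
        else:
            chars.append(background[rng.integers(len(background))])
    if chars:
        chars[0] = "M"  # initiator methionine
    return "".join(chars)


def simulate_proteome(config: SimulationConfig) -> list[ProteinRecord]:
    """Generate an annotated type II proteome with truth labels.

    Annotated TM edges are the true edges plus independent uniform integer
    jitter in ``[-j, +j]`` (clipped to stay a valid span), emulating imperfect
    database annotation.  Golgi proteins are flagged as clients with
    probability ``client_fraction`` and assigned to one or both baits.
    """
    rng = config.rng("proteome")
    records: list[ProteinRecord] = []
    counter = 0
    bait_labels = ("both", "GOLPH3", "GOLPH3L")
    for comp in sorted(config.compartments):
        mix = config.compartments[comp]
        for _ in range(mix.n):
            counter += 1
            tail_len = 1 + int(rng.poisson(mix.tail_mu))
            tm_len = int(np.clip(round(rng.normal(config.tm_mu, config.tm_sd)), 15, 30))
            lum_len = 30 + int(rng.poisson(config.lumenal_mu))
            tail = _draw_tail(rng, tail_len, mix)
            tm = "".join(
                np.asarray(list(_TM_RESIDUES))[
                    rng.choice(len(_TM_RESIDUES), size=tm_len, p=_TM_WEIGHTS)
                ]
            )
            lumenal = "".join(
                np.asarray(list(_ALL_RESIDUES))[rng.integers(0, 20, size=lum_len)]
            )
            seq = tail + tm + lumenal
            true_start = tail_len + 1
            true_end = tail_len + tm_len
            j = config.jitter
            ann_start = int(np.clip(true_start + rng.integers(-j, j + 1), 1, len(seq)))
            ann_end = int(np.clip(true_end + rng.integers(-j, j + 1), ann_start, len(seq)))
            is_client = comp == "Golgi" and rng.random() < config.client_fraction
            client_of = (
                bait_labels[rng.choice(3, p=config.client_bait_probs)]
                if is_client
                else None
            )
            if comp == "Golgi":
                if is_client:
                    stage_p = (0.80, 0.15, 0.05)
                else:
                    stage_p = (0.45, 0.35, 0.20)
                stages = ["early", "intermediate", "late"]
                stage = stages[rng.choice(3, p=stage_p)]
                if rng.random() < 0.05:  # occasional dual-pathway enzyme
                    other = stages[rng.choice(3)]
                    if other != stage:
                        stage = "+".join(sorted([stage, other],
                                                key=stages.index))
            else:
                stage = None
            records.append(
                ProteinRecord(
                    accession=f"SIM{counter:05d}",
                    gene=f"GENE{counter}",
                    sequence=seq,
                    topology="type_II",
                    tm_start=ann_start,
                    tm_end=ann_end,
                    localization=comp,
                    pathway_position=stage,
                    truth={
                        "is_client": is_client,
                        "client_of": client_of,
                        "true_tm_start": true_start,
                        "true_tm_end": true_end,
                    },
                )
            )
    return records


def _require_truth(proteome: list[ProteinRecord]) -> None:
    if any(r.truth is None for r in proteome):
        raise ValueError("proteome records must carry truth labels")


def simulate_pulldown(
    proteome: list[ProteinRecord], config: SimulationConfig
) -> QuantTable:
    """Simulate GST-pulldown spectral intensities for the whole proteome.

    Intensities are log-normal around a per-protein baseline; clients of a
    bait receive an additive log2 enrichment in that bait's replicates, with
    the GST group as baseline.  A fraction of low-intensity values drops out
    (recorded as missing), emulating spectral-counting detection limits.
    """
    _require_truth(proteome)
    rng = config.rng("pulldown")
    d = config.pulldown
    groups = [d.control, *d.baits]
    sample_ids = [f"{g}_{i + 1}" for g in groups for i in range(d.n_replicates)]
    baselines = rng.normal(d.baseline_mean, d.baseline_sd, size=len(proteome))
    rows = []
    for rec, base in zip(proteome, baselines):
        client_of = rec.truth.get("client_of")
        for g in groups:
            bound = client_of is not None and g != d.control and (
                client_of in ("both", g)
            )
            for i in range(d.n_replicates):
                log2v = base + (d.effect_log2 if bound else 0.0) + rng.normal(0, d.noise_sd)
                rows.append((rec.accession, f"{g}_{i + 1}", 2.0 ** log2v))
    data = pd.DataFrame(rows, columns=["accession", "sample_id", "value"])
    # dropout among the lowest-intensity values
    if d.missing_rate > 0:
        cutoff = data["value"].quantile(d.missing_quantile)
        low = (data["value"] <= cutoff).to_numpy()
        drop = low & (rng.random(len(data)) < d.missing_rate)
        data.loc[drop, "value"] = np.nan
    return QuantTable(
        data=data, samples=_sample_metadata(sample_ids), kind="pulldown_intensity"
    )


def simulate_tmt(
    proteome: list[ProteinRecord], config: SimulationConfig
) -> QuantTable:
    """Simulate TMT whole-proteome abundances for WT / KO / rescue.

    Clients (of either bait) are depleted by ``depletion_log2`` in the KO
    channels; WT and rescue are equal in expectation.
    """
    _require_truth(proteome)
    rng = config.rng("tmt")
    d = config.tmt
    groups = [d.wt_group, d.ko_group, d.rescue_group]
    sample_ids = [f"{g}_{i + 1}" for g in groups for i in range(d.n_replicates)]
    baselines = rng.normal(d.baseline_mean, d.baseline_sd, size=len(proteome))
    rows = []
    for rec, base in zip(proteome, baselines):
        is_client = bool(rec.truth.get("is_client"))
        for g in groups:
            eff = d.depletion_log2 if (is_client and g == d.ko_group) else 0.0
            for i in range(d.n_replicates):
                log2v = base + eff + rng.normal(0, d.noise_sd)
                rows.append((rec.accession, f"{g}_{i + 1}", 2.0 ** log2v))
    data = pd.DataFrame(rows, columns=["accession", "sample_id", "value"])
    return QuantTable(
        data=data, samples=_sample_metadata(sample_ids), kind="tmt_abundance"
    )


def simulate_flow(config: SimulationConfig) -> dict[str, pd.DataFrame]:
    """Simulate per-event flow tables, one DataFrame per genotype.

    Each genotype gets exactly ``n_events`` events drawn from a labelled
    mixture: doublets (inflated width channels), dead cells (high viability
    dye), GFP-negative cells, and analysable GFP-positive cells whose A647
    signal is ``surface_fraction * gfp * gain`` plus Gaussian noise truncated
    at zero (non-negative detector counts).
    """
    rng = config.rng("flow")
    d = config.flow
    f_analysis = 1.0 - d.f_doublet - d.f_dead - d.f_gfp_negative
    if f_analysis <= 0:
        raise ValueError("population fractions exceed 1")
    out: dict[str, pd.DataFrame] = {}
    for genotype in sorted(d.genotypes):
        sf = float(d.genotypes[genotype])
        counts = rng.multinomial(
            d.n_events, [d.f_doublet, d.f_dead, d.f_gfp_negative, f_analysis]
        )
        labels = np.repeat(
            np.array(["doublet", "dead", "gfp_negative", "analysis"]), counts
        )
        n = d.n_events
        fsc_h = np.clip(rng.normal(50_000, 8_000, n), 1_000, None)
        ssc_h = np.clip(rng.normal(30_000, 6_000, n), 1_000, None)
        fsc_w = fsc_h * (1.0 + rng.normal(0, 0.05, n))
        ssc_w = ssc_h * (1.0 + rng.normal(0, 0.05, n))
        dbl = labels == "doublet"
        fsc_w[dbl] *= 2.0
        ssc_w[dbl] *= 2.0
        viability = np.abs(rng.normal(100, 30, n))
        viability[labels == "dead"] = rng.normal(5_000, 500, (labels == "dead").sum())
        gfp = 2.0 ** rng.normal(d.gfp_log2_mean, d.gfp_log2_sd, n)
        neg = labels == "gfp_negative"
        gfp[neg] = np.abs(rng.normal(10, 5, neg.sum()))
        a647 = np.clip(sf * gfp * d.gain + rng.normal(0, d.a647_noise_sd, n), 0.0, None)
        df = pd.DataFrame(
            {
                "fsc_h": fsc_h,
                "fsc_w": np.clip(fsc_w, 0, None),
                "ssc_h": ssc_h,
                "ssc_w": np.clip(ssc_w, 0, None),
                "viability": np.clip(viability, 0, None),
                "gfp": np.clip(gfp, 0, None),
                "a647": a647,
                "label": labels,
                "true_surface_fraction": sf,
            }
        )
        out[genotype] = df.iloc[rng.permutation(n)].reset_index(drop=True)
    return out
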