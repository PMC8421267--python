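# golgisort

Analysis pipeline for the sorting signal that keeps resident enzymes in the
Golgi apparatus. Most Golgi glycosylation enzymes are type II membrane
proteins — a short cytoplasmic N-terminal tail, a single transmembrane
domain (TMD), and a lumenal catalytic domain — and a large fraction of them
are retained by the COPI adaptors GOLPH3 and GOLPH3L, which recognize
membrane-proximal positively charged residues in the tail. This package
reimplements, as a tested and reusable pipeline over synthetic data with
known ground truth, the computational analyses by which such clients are
identified and their recognition signal characterized:

1. **TM-edge refinement** — database TM annotations are re-placed by the
   position maximizing the hydrophobicity difference between the five
   TM-side and five flank-side residues within ±5 of the annotated edge
   (Kyte–Doolittle scale by default), followed by a single trim (terminal
   residue ∈ {R,K,D,E,Q,N,H,S}) or extension (adjacent flank residue ∈
   {F,M,I,L,V,C,W,A,T,G}).
2. **Tail statistics** — for each type II protein, tail length, the count of
   R/K within the six membrane-proximal tail residues (plus the α-amino
   group for tails ≤ 6 residues), and the predicted net tail charge at
   cytosolic pH 7.4 (+1 per R/K and for the N terminus, −1 per D/E, His
   neutral, −2 per supplied phosphosite).
3. **Logo matrices** — 51-position × 21-symbol frequency matrices over the
   window −15..+35 anchored on the cytoplasmic TM edge, with X padding
   beyond sequence ends so that short tails are visible as X enrichment.
4. **Dual-screen client calling** — per-bait Welch *t*-tests of log2
   pulldown intensities vs the GST control (raw *P* < 0.05, positive fold
   change); median-centred, MAD-scaled log2 TMT abundances; degradation =
   log2(ΔΔ/rescue) ≤ −0.1; high-confidence clients are Golgi residents
   depleted strictly more than every non-Golgi protein *and* enriched in
   the pulldown.
5. **Retention index** — hierarchically gated flow events (singlets → live →
   GFP-positive); the median per-event A647:GFP ratio measures surface
   exposure of a GFP-tagged reporter, i.e. failure of Golgi retention.

A seeded synthetic-data module generates annotated proteomes, pulldown and
knockout-proteome quantitation tables, and flow events with planted effects,
so every stage can be scored against known truth.

## Worked example

```sh
python analysis/01_simulate_dataset.py --seed 1
python analysis/02_refine_tm_spans.py
python analysis/05_call_clients.py
```

The first command writes a 500-protein type II proteome (ER/Golgi/PM,
45 planted clients) plus quantitation and flow tables under `results/data/`.
The second prints

```
annotation jitter had displaced 417/500 N-edges; refinement recovered 479/500 (95.8%) exactly
```

— the ±3-residue annotation jitter is undone for ~96% of proteins because
the charged-tail/hydrophobic-TM boundary is where the 5+5 hydrophobicity
difference peaks. The third integrates the two screens and prints

```
"pulldown_counts_all": {"union": 59, "common": 25, "GOLPH3_specific": 15, "GOLPH3L_specific": 19},
"degradation_threshold": -0.205,
"n_high_confidence_clients": 43, "n_true_clients": 45,
"sensitivity": 0.956, "precision": 1.0
```

i.e. 43 of the 45 planted clients are recovered with no false positives:
the degradation threshold (the most depleted non-Golgi protein, here
−0.205) combined with the pulldown requirement is a stringent but sensitive
filter. `03_tail_features.py`, `04_logo_matrices.py` and
`06_retention_assay.py` complete the picture: Golgi median tail length 6 vs
21/31 for ER/PM, a positive proximal R+K logo difference for clients, and a
gated median A647:GFP ratio of 0.050 (WT) vs 0.501 (double knockout) for
planted surface fractions of 0.05/0.5.

The same stages are exposed as a CLI (`golgisort simulate | refine-tm |
tail-stats | logo | call-clients | retention | reproduce`) for running on
external FASTA/TSV/CSV inputs.

## Layout

- `src/golgisort/` — library: `io`, `simulate`, `tm`, `tails`, `logo`,
  `screens`, `flow`, `pipeline`, `cli`
- `analysis/` — numbered narrative drivers writing tables under `results/`
- `tests/` — unit, property (hypothesis) and acceptance suites
- `docs/methods.md` — models, assumptions, parameter choices, limitations
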