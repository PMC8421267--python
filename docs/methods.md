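# Methods

## The biological question and the pipeline's shape

Golgi glycosylation enzymes are predominantly type II membrane proteins
whose short cytoplasmic tails are read by the COPI adaptors GOLPH3 and
GOLPH3L during recycling of residents into intra-Golgi transport vesicles.
The pipeline characterizes that recognition signal along five stages: TM
edge refinement, tail feature statistics, anchor-aligned logo matrices,
dual proteomic-screen integration, and a flow-cytometry retention index.
Because the raw datasets behind such a study (pulldown and TMT
supplementary tables, FCS exports) are not redistributable here, a seeded
synthetic-data module generates inputs with the same shapes and planted
effects with known truth; every stage is then scored as a
parameter-recovery problem.

## TM-span edge refinement

Each edge is refined independently. Candidate boundary positions are the
annotated edge ±5. A candidate is valid when both 5-residue windows (TM
side and flank side) lie inside the sequence; the score is
mean(hydrophobicity of 5 TM-side residues) − mean(5 flank-side residues).
The maximizing candidate wins; ties go to the candidate closest to the
annotation, then toward the N terminus (minimal perturbation of curated
annotation). Exactly one post-adjustment follows: the terminal TM residue
is trimmed if it is in the hydrophilic set {R,K,D,E,Q,N,H,S}; otherwise the
span is extended by one if the adjacent flank residue is in the hydrophobic
set {F,M,I,L,V,C,W,A,T,G}. P and Y are in neither set and trigger nothing.
With no valid candidate the annotated edge is kept (provenance
`fallback`); if the two refined edges cross, both revert to the annotation.
Consequences: a refined edge is never more than 6 residues from the
annotation, and spans never become empty.

The hydrophobicity scale is not dictated by the refinement rule itself;
Kyte–Doolittle is the default and the scale is pluggable (`tm.SCALES`,
`--scale`) for sensitivity analysis. Whether trim/extend may iterate is a
second genuinely open choice; we read the rule as a single conditional and
apply it exactly once per edge.

## Tail features

The cytoplasmic tail of a type II protein is positions 1..tm_start−1
(possibly empty). Membrane-proximal positive charges are R/K within the
last min(6, length) tail positions — counted from the TM-adjacent end,
which is the biologically meaningful direction — plus one for the
N-terminal α-amino group when the whole tail is ≤ 6 residues, i.e. when the
N terminus itself lies inside the proximal window. Predicted net charge at
cytosolic pH 7.4 uses integer charges: +1 per R/K anywhere in the tail, +1
for the α-amino group (always, for any non-empty tail), −1 per D/E, 0 for
H, C and Y (side-chain pKa outside the cytosolic operating point — no
fractional Henderson–Hasselbalch computation is attempted), and −2 per
externally supplied phosphosite. Phosphosite handling is a flag-level
choice: sites are never predicted, and the −2 contribution can simply be
omitted by not supplying sites.

## Logo matrices

Windows cover offsets −15..+35 relative to the cytoplasmic TM edge (offset
0 = first TM residue; 51 positions). Offsets outside the sequence emit the
padding symbol X, tallied like a residue, so short tails appear directly as
X enrichment upstream of the anchor. Stored values are frequencies (each
position sums to 1); information-content weighting would be a rendering
transform and is deliberately not part of the matrix contract. Refinement
runs before logo construction by default (`refine_before_logo`), since edge
noise otherwise blurs the anchor. Rendering is a plain matplotlib heatmap;
letter-stack aesthetics are out of scope.

## Screen statistics

**Pulldown enrichment.** Spectral intensities are log2-transformed; zeros
are treated as missing (spectral counting semantics — a zero is a
non-detection, not an abundance), controlled by a reader flag. Per protein
and bait, a two-sided Welch *t*-test (scipy, Welch–Satterthwaite df)
compares bait vs GST replicates; enrichment requires raw *P* < α (default
0.05) and positive log2 fold change. No multiple-testing correction is
applied by default, reproducing the screen's calling rule; a
Benjamini–Hochberg flag exists but is off. Proteins with fewer than two
valid replicates in either group are reported as untested, never dropped or
imputed. Degenerate zero-variance-in-both-groups cases use p = 1 for equal
means, p = 0 otherwise, and are recorded as such.

A calibration note: at 3 vs 3 replicates the Welch–Satterthwaite
approximation is conservative — the true null rejection rate at nominal
0.05 is ≈ 0.035, not 0.05 (Student's *t* would be exact under equal
variances, but Welch is the screen's prescribed test). The test suite
therefore checks the null false-positive rate against an independent Monte
Carlo estimate of Welch's actual small-sample level rather than against
the nominal α.

**Knockout proteome.** TMT abundances are log2-transformed and each sample
column is centred on its median and scaled by MAD × 1.4826 (robust σ
estimate; constant columns fall back to scale 1; a plain-SD option exists
because "normalized according to the median" admits either reading). The
degradation statistic is the difference of group means, log2(KO/rescue);
the cutoff −0.1 is inclusive (a ratio of exactly −0.1 is degraded).

**High-confidence clients.** The threshold is the minimum log2 ratio among
non-Golgi proteins — an empirical false-positive floor — and a client must
be Golgi-resident, strictly below that threshold (ties excluded), and a
pulldown hit (union over baits). The rule is monotone: removing a non-Golgi
protein can only relax the threshold, never shrink the client set. With no
non-Golgi proteins the threshold is undefined and the call errors rather
than guessing.

**Pathway positions.** Stage proportions (early/intermediate/late) are
computed over stage *assignments*: an enzyme annotated with two stages
(written `early+late`) counts once per stage, so group denominators can
exceed protein counts by design.

## Retention assay

Gating applies, in order, a singlet fence (width/height ≤ 1.3 on both
scatter channels), a live gate (viability dye ≤ 1000), and a GFP-positive
gate (absolute threshold 100 by default, or the 99.5th percentile of a
supplied GFP-negative control). All three stages are threshold
intersections, so gating is idempotent and order-insensitive; per-stage
attrition is reported. The retention index is the median per-event
A647:GFP ratio — the source assays report histograms rather than a scalar,
so the median is this package's own summary convention. Condition
comparisons report the ratio of medians plus mode-normalized histogram
pairs on shared bins. Compensation/spillover and polygon gate geometry are
out of scope.

## Synthetic-data generator

The generator emulates the statistical structure of the study's data, not
its molecular detail.

* **Proteome.** Per compartment (Golgi/ER/PM), tail length is 1 + Poisson
  with mean 5 (Golgi), 20 (ER) or 30 (PM) — Golgi tails short, others long;
  TM length is normal(21, 2) clipped to 15..30; a lumenal domain of
  30 + Poisson(80) uniform residues follows. Tail residues are R/K with
  probability 0.6 (Golgi) vs ≈ 0.1 (ER/PM) in the six TM-proximal slots and
  ≈ 0.1 elsewhere; the non-basic tail background is polar (S,N,Q,P,H, plus
  D/E outside the Golgi), deliberately excluding every residue of the
  hydrophobic extend set so that the generated tail|TM boundaries are
  sharp and the true edge is recoverable — real boundaries are fuzzier,
  so recovery rates here are an upper bound, not a field estimate.
  Annotated edges are the true edges plus independent uniform integer
  jitter in [−3, +3]. 30% of Golgi proteins are clients, split
  both-baits / GOLPH3-only / GOLPH3L-only at 0.58/0.18/0.24.
* **Pulldown.** Log-normal intensities: per-protein baseline log2 ~
  N(20, 2); clients of a bait gain +2 log2 in that bait's three replicates;
  replicate noise sd 0.3 log2 units; 5% dropout among the lowest-intensity
  quintile. The noise magnitudes (0.3 pulldown, 0.2 TMT) are calibration
  choices — the source screens do not state theirs.
* **TMT.** Duplicate channels for WT/KO/rescue; clients depleted −1.0 log2
  in KO only; noise sd 0.2.
* **Flow.** Exactly n events per genotype from a labelled mixture: 8%
  doublets (doubled width channels), 5% dead (viability ≈ 5000 vs ≈ 100),
  12% GFP-negative, remainder analysable with GFP = 2^N(10,1) and A647 =
  surface_fraction × GFP + N(0, 30) truncated at 0.

All generators draw from substreams derived deterministically from one
seed (`SeedSequence` spawn keys), so stages can be re-run independently and
a fixed seed gives byte-identical outputs. Gaussian-on-log2 noise,
symmetric annotation jitter, and truncated-Gaussian detector noise are
modelling assumptions of this package. The generator does not emulate
peptide-level identification, TMT ratio compression, isotopic impurity, or
manual gate geometry — so passing recovery tests demonstrates correctness
of the analysis rules under the stated noise model, not performance on
real screens.

## Problem sizes and numerical choices

Default analyses use 500-protein proteomes (170/165/165 per compartment),
10⁴ flow events per genotype, and seed batteries of 3–50 depending on the
statistic; these sizes put Monte-Carlo error well inside the asserted
tolerances while keeping any run in seconds. Logo frequencies are exact
rationals stored as floats (column sums asserted to 1e−9); Welch p-values
are checked against the closed-form Welch–Satterthwaite formula to 1e−10;
ties in refinement are broken deterministically as described; all
degenerate inputs (empty tails, empty compartments, empty gated sets,
missing non-Golgi anchor) either produce well-defined empty outputs or
raise a named validation error, never a silent guess.

## Known limitations

* The refinement scale and the single-pass trim/extend reading are
  documented choices where the underlying method description is ambiguous.
* The synthetic proteome's sharp boundaries and polar tails overstate edge
  recoverability relative to real sequences (see above).
* Net charge uses integer charges at pH 7.4; His in particular is treated
  as fully neutral.
* The retention index summarizes a histogram by its median; bimodal
  populations (e.g. saturated retention at high expression) are visible
  only in the histograms.
* Client calling depends on the single most depleted non-Golgi protein;
  with few non-Golgi proteins the threshold is noisy, which is why the
  generator plants several hundred.
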