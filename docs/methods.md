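# Methods

## The reporter construct

Every simulated minigene shares one scaffold: a 60-nt first exon, a 43-nt
intron 5′ segment beginning GTAAGT, the 25-nt degenerate region N25A, an
invariant pyrimidine-rich heptamer ending in AG (so SA1's immediate acceptor
context never varies), the 156-nt inter-acceptor segment carrying the 25-nt
N25B slot 10 nt downstream of SA1 and the SA2 context (a canonical ACTAAC
branch point whose adenosine sits 29 bp upstream of SA2, a 12-nt
polypyrimidine tract, AG), a 40-nt second exon, the 20-bp barcode and a 40-nt
3′ tail. Coordinates are 0-based and half-open; an acceptor position is its
first exonic base; only the plus strand exists (reporter construct).

Two design constraints are deliberate. First, the final 18 nt of the intron
segment and the SA2-proximal filler are adenosine-free, so that within the
branch-point search window SA1's candidates come only from N25A and SA2's
only from the planted ACTAAC — SA1 strength varies purely with degenerate
content while SA2 strength is constant. Second, the barcode lies downstream
of SA2, so it appears unchanged in every isoform and read 2 can be taken
directly from the transcript. The packaged `base_minigene()` carries CTAAC at
the start of N25A (branch adenosine 29 bp upstream of SA1) with otherwise
adenosine-free inserts, making it the single-branch-point control construct.

The exact distances of the degenerate regions to SA1 are declared choices
(N25A ends 7 nt upstream, N25B starts 10 nt downstream); the geometry that
matters for the statistics — 25-nt inserts, 156-bp acceptor spacing, 20-bp
barcodes, invariant immediate acceptor context — is fixed by the assay being
emulated.

## U2–branch point duplex model

The U2 snRNA recognition hexamer 5′-GUAGUA-3′ pairs antiparallel with intron
positions −4…−1 and +1 around the bulged branch adenosine (position 0); the
−5 partner of the full biological register falls outside a 9-mer window and
is omitted. Pairing is Watson–Crick plus G·U wobble, except at −1 where only
the canonical adenosine counts as paired: G at −1 is treated as a variant,
not a wobble pair, matching the strict conservation of −1 in the YTAAY
consensus and the assay's TAA→TGA/TCA/TTA variant series.

Energy terms (kcal/mol at 37 °C):

- **Stacks.** The ten unique Watson–Crick nearest-neighbour stacking
  parameters (Turner-style values, packaged in `DuplexParams.stacks`) are
  applied between consecutively paired positions; any step involving a wobble
  pair uses a single flat value (−0.50), strictly weaker than the weakest
  Watson–Crick stack. Keeping the table in one data structure makes the
  energy model swappable.
- **Bulge.** +1.0 for the bulged branch adenosine when both flanking
  positions pair. This is deliberately below the weakest bulge-closing stack
  plus the +1 mismatch penalty: a larger (more physical) bulge cost makes
  *not* pairing +1 optimal, which would break both consensus optimality and
  mismatch monotonicity. The packaged value trades absolute realism for these
  structural guarantees; absolute ΔG values are therefore model-internal and
  only comparisons between windows are meaningful.
- **Mismatches.** Per-position penalties {−4: 0.5, −3: 1.0, −2: 2.0,
  −1: 2.5, +1: 1.0}, graded by the positions' conservation in the consensus.
- **Clamp.** Totals above 0 are reported as 0 — a window that cannot form a
  stabilising duplex does not bind.

With these choices, exhaustively over all 4⁸ contexts with A fixed at the
fifth base: breaking any formed pair never stabilises the duplex (wild-type
mode), and the global minimum (−6.89) is attained exactly by windows with a
YTAAY core.

**Mutant mode.** K700E scales the −1 mismatch penalty by λ ∈ [0, 1] before
the clamp, so the bulk of the mutant stabilisation is realised only where a
duplex actually forms; an additional strict-preference margin
ε(1 − λ) = 0.1(1 − λ) is subtracted for any window whose −1 base is not A.
The margin makes the mutant preference for −1 variants strict for *every*
such window (including those clamped to 0 in both modes) while perturbing
binding-competent windows negligibly. λ = 1 reproduces the wild type
exactly. A pre-clamp-only formulation loses strictness on non-binding
windows; a post-clamp-only relief hands the full stabilisation to windows
with no duplex at all; the combined form keeps both properties. Note the
consequence: global mismatch monotonicity is a wild-type-mode property — in
mutant mode with λ < 1, introducing a −1 variant into a non-binding window
is (by design) slightly stabilising.

Branch-point prediction scans all adenosine-centred 9-mers whose adenosine
lies within a window of offsets upstream of the acceptor (default
[−50, −10]) and returns the minimum-ΔG candidate, ties broken toward the
acceptor-proximal position. This is a declared heuristic stand-in for
deep-learning branch-point predictors, chosen so that the simulator and the
analysis share one transparent energy model.

## Acceptor-competition model

For each candidate acceptor a (SA1, SA2, and every AG dinucleotide inside
N25A/N25B with ≥6 nt of downstream room, treated as a novel acceptor):

log w(a) = β_bp·(−ΔG_bp(a, mode)) + β_ppt·pyr₂₀(a) + baseline(a),

normalised by softmax; transcript counts are multinomial at Poisson(depth)
per minigene. Defaults: β_bp = 1.0, β_ppt = 2.0, baseline 0 for SA1,
sa2_bonus = −1.3 for SA2 (a residual term on top of SA2's strong invariant
context), novel_penalty = −4.0, depth 50. The weight scale was calibrated
once against the assay's observed usage regime: SA2 predominant, a
wild-type SA1 transcript fraction of one to two percent, and roughly 37% of
filtered minigenes using SA1 at least once at depth ~50. The condition
enters *only* through λ: λ = 1 makes WT and K700E identical in
distribution, so any detected condition effect is attributable to the single
encoded mechanism. With λ = 0.4 the simulation yields an SA1 fold change of
~1.15, mutant-exclusive SA1 minigenes outnumbering wild-type-exclusive ones,
and a Δlog₂ enhancer set with a −1-variant share more than twice the 17.2%
census background.

What the simulator does not model: PCR duplicates and amplification bias,
indels, NMD (single-intron reporter), intramolecular RNA structure, and any
positional preference of branch points beyond the energy model. Passing
tests therefore certify the pipeline's statistics and bookkeeping on data
matching these assumptions, not performance on real sequencing artefacts.

## Demultiplexing and junction calling

Read 2's first 20 nt are matched against the barcode index: exact match
first, then the unique entry within Hamming distance ≤ max_mismatch
(default 1); ties stay unassigned. Read 1 is matched against minigene-local
isoform references (exon 1 joined to each candidate acceptor's downstream
sequence) allowing at most one substitution; a call needs a unique best
isoform with the junction covered by ≥15 nt on each side, and ambiguity at
equal mismatch count stays uncalled. A "transcript" is a read pair — no UMI
collapsing. The representation filter keeps a minigene only with ≥5 summed
reads in every condition, and is idempotent and monotone in the threshold.

## Odds-ratio statistics

The presence unit is the minigene: a 6-mer is present or absent in one
25-nt region, and a minigene "utilizes SA1" if it has ≥1 SA1 read after
filtering (the threshold is exposed as a parameter). The Haldane–Anscombe
pseudocount of 0.5 keeps log₂OR finite for rare 6-mers at desk scale. For
mutant-preferred enhancer ranking, survivors must exceed OR 1.5 in the
K700E condition *and* have Δlog₂ > 0, then rank by Δlog₂; the upstream
region 25A is the default for branch-point inference, 25B is supported and
labelled. No multiple-testing correction is applied — the outputs are
rankings and class shares, not per-6-mer significance claims.

Two statistical notes from the null calibration (β_bp = β_ppt = 0).
First, with a pseudocount and small per-6-mer carrier counts the log₂OR
distribution is only approximately centred (median ≈ +0.05 at 2000
minigenes); this bias is condition-independent and cancels in Δlog₂.
Second, Δlog₂ values are strongly correlated across 6-mers that share core
trinucleotides (they co-occur in the same minigenes), so per-6-mer rank
tests of class enrichment are anti-conservative. Enrichment is therefore
tested at the replicate level: one enrichment statistic per seed (mean
Δlog₂ of −1-variant minus no-core 6-mers), compared to zero across 10
independent seeds by a Wilcoxon signed-rank test — exactly calibrated under
the null and sensitive to the λ < 1 alternative.

## Energy comparison between minigene sets

Predicted SA1 branch points of shared versus K700E-exclusive SA1 minigenes
are scored with a single wild-type (λ = 1) energy model — the comparison
asks which branch points each genotype ends up using, not what the mutant
thinks of them — and compared by a two-sided Wilcoxon rank-sum test
(`scipy.stats.mannwhitneyu`; verified against exact permutation on small
sets).

## Problem sizes and determinism

The packaged study sizes are desk-scale choices: 20,000 minigenes at mean
depth 50 for the condition contrast (carrier counts per 6-mer of ~100 give
workable odds-ratio precision), 1000 minigenes at depth 30 for the
demultiplexer round trip, 2000 minigenes at depth 10 per null-calibration
seed (with the SA2 baseline set to +3.0 there so the sequence-independent
acceptor split is non-degenerate). Every random stage draws its seed from
one run seed via `numpy.random.SeedSequence`; a fixed configuration
reproduces byte-identical artifacts, and the run manifest records content
hashes per artifact.

## Known limitations

- The energy model is a five-position register with packaged parameters;
  it captures relative stability and the −1 mechanism, not thermodynamic
  absolutes (no dangling ends, no suboptimal structures, no −5 pair).
- Novel-acceptor competition uses a flat class baseline; real cryptic-site
  strength would vary with its own splice-site context.
- Barcode collisions are excluded at generation time; the demultiplexer
  assumes a collision-free index and fails loudly otherwise.
- The mutant mechanism is a single scalar (λ); real SF3B1 K700E likely
  perturbs additional steps (branch-point-to-3′SS distance preferences,
  co-transcriptional timing) that are outside this model.
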