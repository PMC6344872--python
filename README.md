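# bpmpra — branch-point selection in a massively parallel 3′ splice-site assay

`bpmpra` simulates and analyses a barcoded minigene library that measures how
spliceosomes choose between competing 3′ splice sites, and how the recurrent
cancer mutation SF3B1 K700E shifts that choice toward non-canonical branch
points. It is aimed at computational biologists studying splicing-factor
mutations (MDS, CLL, uveal melanoma) who want a reusable, fully ground-truthed
pipeline for reporter-library splicing readouts.

## The assay and the model

The reporter is a single-intron minigene with two splice acceptors, SA1 and
SA2, 156 bp apart. SA1 is framed by two 25-nt degenerate regions (N25A
upstream, N25B downstream) whose random content determines how well SA1
competes against the constitutively strong SA2; a unique 20-bp barcode in the
3′ end identifies each minigene in read 2 of a paired-end readout, while
read 1 spans the splice junction.

Three pieces of quantitative machinery:

- **Per-6-mer odds ratios.** For each of the 4⁶ = 4096 6-mers, a 2×2 table
  over minigenes (uses SA1 × contains the 6-mer in N25A or N25B) gives

  OR = ((a+p)(d+p)) / ((b+p)(c+p)),  p = ½ (Haldane–Anscombe),

  per condition; Δlog₂ = log₂OR(K700E) − log₂OR(WT) ranks 6-mers that
  enhance splicing specifically in the mutant. Enhancer 6-mers are classified
  against the canonical branch-point core TAA (positions −2, −1, 0 relative
  to the branch adenosine): TAA → canonical; T[CGT]A → −1 variant;
  [ACG]AA → −2 variant; other XYA → both; else none.

- **U2–branch point duplex energetics.** A branch-point candidate is a 9-mer
  with the nucleophilic adenosine at the fifth base, pairing antiparallel with
  the U2 snRNA recognition sequence 5′-GUAGUA-3′ with the branch A bulged.
  ΔG sums nearest-neighbour stacks over consecutively paired positions, a
  bulge penalty and per-position mismatch penalties, clamped at 0. Mutant
  (K700E) mode scales the −1 mismatch penalty by λ ∈ [0, 1]: the single
  mechanistic knob by which the mutant tolerates −1-variant branch points.

- **A generative simulator.** Acceptor choice per minigene is a softmax over
  log-weights β_bp·(−ΔG of the best branch point) + β_ppt·(pyrimidine
  fraction of the 20 nt upstream) + a class baseline, sampled to transcript
  counts and optionally to paired FASTQ with sequencing errors, with a truth
  sidecar for every read.

## Worked example

```bash
bpmpra demo --outdir demo --seed 3 --n-minigenes 2000
```

simulates 2000 minigenes at mean depth 50 under both conditions
(λ_K700E = 0.4), applies the five-read representation filter, and writes
`demo/report.md`, which for this seed prints:

| condition | SA1 | SA2 | NOVEL | minigene SA1 ratio |
|---|---|---|---|---|
| WT | 0.01538 | 0.9841 | 0.0005499 | 0.2215 |
| K700E | 0.01798 | 0.9814 | 0.0006289 | 0.2775 |

- SA2 is the predominant acceptor in both conditions; SA1 usage rises
  1.17-fold in K700E (two-sided test of the condition effect:
  p = 6.0 × 10⁻⁶).
- Of 769 SA1-utilizing minigenes, 42.4% are K700E-exclusive against 27.8%
  WT-exclusive: the mutant unlocks SA1 on minigenes the wild type skips.
- The census table (4096 6-mers: 255 canonical TAA, 705 −1 variants, …) is
  the random background against which mutant-preferred enhancers are judged.

At the full demo scale (20,000 minigenes, the default) the Δlog₂-ranked
enhancer set is dominated by −1-variant 6-mers at more than twice their
census background share, and predicted branch points behind K700E-exclusive
SA1 minigenes are markedly less stable than behind shared ones — the
simulator's encoded mechanism, recovered by the analysis.

The same stages are available individually (`bpmpra simulate`, `demux`,
`usage`, `kmer`, `energy`, `run`, `report`) and as library functions.

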