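# Methods

## The problem

Transgenic RNAi in *Drosophila melanogaster* expresses ~300 bp hairpins
that are diced into ~19-nt siRNAs.  The accepted specificity control is a
rescue with an ortholog from a related species whose sequence has diverged
enough to escape the knock-down.  The rule of thumb in the field is that a
contiguous identity of **19 nt or more** between an siRNA and a transcript
suffices for silencing; an ortholog whose longest identity stretch with
the hairpin-targeted region is *shorter* than 19 nt is called
**refractory** and is a good rescue donor.

This package implements that analysis as a reusable pipeline:

1. **Projection.**  Pairwise whole-genome alignments (AXT or MAF, one
   fixed reference species) are projected through each gene's
   representative transcript (longest isoform; ties broken by transcript
   id) into transcript space.  The result per gene is a reference-anchored
   stack: the ungapped transcript as the reference row and one row per
   donor species over `A/C/G/T/N`, `-` (aligned gap = deletion in the
   donor) and `.` (no alignment block covers the position).  Donor
   insertions do not lengthen the row; they are kept as break points
   between adjacent reference positions.  This is deliberately *not* a
   multiple alignment — it is a set of pairwise alignments sharing one
   coordinate row, which is exactly the comparison the analysis needs.
2. **Hairpin mapping.**  Each gene's hairpin must match the reference row
   exactly over its full length (either strand) to enter the statistics;
   near-misses are classified `partial`, everything else `unmapped`, and
   both are counted but excluded.
3. **Conservation statistics.**  Per (hairpin, species): percent identity
   (per reference position; `-`, `.` and N count as mismatches, and N
   never matches anything including N) and the longest identity stretch.
4. **Refractory classification and aggregation.**  `refractory ⇔
   longest_stretch < 19`; per-species summary fractions; gene-level
   any-species aggregation and attribution of rescue potential to a
   species subset.
5. **siRNA efficiency and cross-silencing risk.**  Every sliding 19-mer
   is scored (below); a ≥19-nt stretch is only a real cross-silencing
   threat when an *efficient* 19-mer fits wholly inside it.
6. **Clone selection.**  Genomic clones must contain the donor gene plus
   ≥10 kb upstream and ≥5 kb downstream regulatory flank; covering clones
   are joined to screen hits through a one-to-one ortholog table.

## Key modelling decisions

**Insertions break stretches but not identity.**  Percent identity is
defined per reference position, so a donor insertion cannot change it.  A
19-mer siRNA, however, needs contiguous perfectly complementary target
sequence, so an insertion interrupts an identity stretch.  Both statistics
are therefore computed from the same alignment slice but treat insertions
differently; stretch-breaking can be disabled
(`insertions_break_stretch: false`) to reproduce the naive reading.

**Hairpin mapping thresholds.**  "Partial" versus "unmapped" is decided by
the best infix (semi-global) edit distance of the hairpin against the
reference row, computed with edlib on both strands: distance 0 and full
length is `mapped_full`; distance ≤ 25 % of hairpin length is `partial`;
worse is `unmapped`.  The 25 % bound is this package's choice — the
distinction only affects bookkeeping, since both classes are excluded from
statistics.

**siRNA score surrogate.**  Published siRNA design servers score each
19-mer on GC content, GC balance along the window and homopolymer runs,
with a cutoff of 5 below which a window counts as RNAi-efficient; the
exact weighting is not public.  The surrogate used here is

    gc_penalty      = 10 · |GC − 0.5|
    balance_penalty =  5 · |GC(bases 1–9) − GC(bases 11–19)|
    poly_penalty    =  1 · max(0, longest homopolymer − 3)
    total           = sum;   efficient ⇔ total < 5

Weights live in `ScoreWeights` and are recorded in every run manifest.
The defaults make the canonical pathological windows fail (all-G and
all-A score 21) and a balanced mixed window pass (≈0.8).  On random
near-balanced synthetic sequence most windows pass, so the surrogate is
more permissive than production design tools on real, biased sequence;
conclusions drawn from it are qualitative (which stretches contain *any*
efficient window), not calibrated efficiency predictions.

**Clone flanks are strand-aware by default.**  The 10 kb flank exists to
capture promoter/enhancer context, which is strand-dependent, so the
10 kb side follows gene orientation; `strand_aware_flanks: false` gives
plain left-10 kb/right-5 kb arithmetic.

**Refractory attribution is reported under both readings.**  "How much of
the rescue potential comes from species subset S" can mean the share of
refractory (gene, species) calls contributed by S, or the share of
rescuable genes whose refractory options involve (or lie only within) S.
The aggregate reports all of these rather than asserting one.

## The synthetic data generator

The generator is first-class code: it is the ground truth every pipeline
stage is tested against.  It emulates

- a random-sequence chromosome carrying `n_genes` three-exon genes
  (1200-nt fully coding transcripts, random introns, random strand, a
  fraction with a shorter second isoform to exercise representative
  selection), spaced 12 kb apart so fosmid-sized clones can or cannot
  reach the neighbour genes;
- per-species divergence with **codon-phase-specific substitution
  probabilities** (`p0, p1, p2` with `p2 ≫ p0, p1`), transition bias 2:1,
  and geometric-length indels initiating at `p_indel` per site, split
  evenly between insertions and deletions.  Intronic sites use the
  third-position rate (both are largely unconstrained);
- 300-bp hairpins cut from transcript sense strands (a fraction
  reverse-complemented; a decoy fraction given injected mismatches or
  scrambled sequence to exercise the partial/unmapped paths; one
  duplicate record to exercise one-hairpin-per-gene deduplication);
- clone intervals drawn to hit a configured coverage fraction, an
  ortholog table with configurable non-one-to-one defects, and a random
  hit list.

The default species panel is a five-species divergence ladder shaped like
the sequenced *Drosophila* genomes relative to *D. melanogaster* — one
near-identical sister species (`dsim`, p = 0.015/0.015/0.10), one
intermediate (`dana`, 0.06/0.06/0.35), a nearly indistinguishable close
pair (`dpse`/`dper`, 0.08/0.08/0.42) and a distant outgroup (`dvir`,
0.11/0.11/0.55).  These values were fixed once to reproduce the
qualitative ordering (sister species almost never refractory; the distant
outgroup mostly refractory; the close pair intermediate) and the period-3
structure of stretch lengths; they are presets, not fits.

What the generator does **not** emulate: codon models or selection,
phylogenetic correlation between species (each diverges independently
from the reference, mirroring the pairwise design), repeats and
paralogy (hairpin mapping is therefore unambiguous by construction), and
assembly/alignment artefacts.  Passing tests on synthetic data therefore
demonstrate correctness of the computation, not robustness to the messier
failure modes of real genome alignments.

Every dataset flows from a single seeded NumPy generator; the seed and all
parameters are recorded in `manifest.txt`, and identical arguments give
byte-identical files.

## The exact run-length oracle

`prob_longest_run_at_least(n, p, k)` computes the exact probability that
`n` i.i.d. Bernoulli(`p`) positions contain ≥ `k` consecutive successes,
by a dynamic program over current-run-length states with an absorbing
state at `k` (O(n·k)).  It anchors the statistical acceptance checks: the
fraction of simulated hairpins with a ≥19-nt stretch at uniform match
probability `q` must agree with the DP within binomial sampling error.
Under codon-structured divergence the i.i.d. law does not apply — which
is the point of the phase-specific generator.

## Numerical and bookkeeping choices

- All internal coordinates are 0-based half-open; AXT and GFF3 are
  converted at the I/O boundary only.
- Ambiguity codes other than N are normalised to N with a warning; N is
  always a mismatch.
- Representative-transcript ties break to the lexicographically smallest
  transcript id; all outputs are sorted on stable keys, so every run is
  deterministic and reruns are byte-identical.
- Percent identities are written with 4 decimals; all fractions are
  percentages in [0, 100].
- Zero-length slices, invalid probabilities, overlapping exons,
  double-covered reference bases and duplicate clone ids are hard errors;
  a missing species alignment file, an uncovered gene and a clone on the
  wrong chromosome are expected data conditions that are flagged and
  counted instead.

## Problem sizes

The shipped analysis and acceptance runs use 150 genes × 5 species
(~659 conservation records), 10,000 random slice pairs for the
stretch-oracle check and 3×3,000–5,000 simulated hairpins for the
run-length law — sizes chosen so the whole analysis reruns from scratch
in well under a minute while keeping binomial standard errors small
enough for 3-SE acceptance bands to be meaningful.

## Known limitations

- The siRNA score is a documented surrogate, not a clone of any published
  server's internals.
- Attribution percentages depend on which reading (calls vs genes) is
  used; both are reported, neither is privileged.
- `spans_adjacent_genes` treats a missing neighbour annotation as
  vacuously satisfied (flagged), which over-reports at chromosome ends.
- The pipeline keys strictly by gene id; overlapping transcripts from
  neighbouring genes are not disambiguated.
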