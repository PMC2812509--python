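"""Synthetic five-species datasets with built-in ground truth.

The generator emulates the statistical structure the analysis assumes:
reference transcripts with CDS structure on a synthetic chromosome,
per-species sequence divergence with codon-position-specific substitution
probabilities (third position >> first/second, which is what produces the
period-3 peaks in stretch-length histograms), occasional indels, 300-bp
hairpins cut from the transcripts (a configurable fraction of decoys with
injected mismatches or scrambled sequence to exercise the partial/unmapped
paths), fosmid-sized clone intervals around donor genes, an ortholog
table and a screen-hit list.  Every emitted file is accompanied by truth
tables that are consistent with the files by construction, plus an exact
dynamic-programming oracle for the distribution of the longest run of
i.i.d. matches.

It does not attempt realistic molecular evolution: no codon model, no
selection, and each species diverges independently from the reference,
mirroring the pairwise design of the analysis itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    AlignmentBlock,
    GeneModel,
    write_axt,
    write_bed12,
    write_genome_fasta,
    write_tsv,
    reverse_complement,
)

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass(frozen=True)
class DivergenceModel:
    """Per-site divergence of one donor species from the reference.

    Substitution probabilities are per codon phase (0, 1, 2); intronic and
    other unphased sites use ``p_intron`` (default: the third-position
    rate, since both are largely unconstrained).  Codon-realistic presets
    have p2 >= p0, p1.
    """

    name: str
    p_sub_by_phase: tuple[float, float, float]
    p_indel: float = 0.0
    indel_length_geometric_p: float = 0.5
    transition_bias: float = 2.0
    p_intron: float | None = None

    def __post_init__(self) -> None:
        probs = (*self.p_sub_by_phase, self.p_indel)
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError(f"{self.name}: probabilities must lie in [0,1]")
        if not (0.0 < self.indel_length_geometric_p <= 1.0):
            raise ValueError(f"{self.name}: geometric parameter must be in (0,1]")
        if self.transition_bias < 0:
            raise ValueError(f"{self.name}: negative transition bias")

    def rate_for_phase(self, phase: int | None) -> float:
        if phase is None:
            return self.p_intron if self.p_intron is not None else self.p_sub_by_phase[2]
        return self.p_sub_by_phase[phase]


#: Default species panel: a divergence ladder shaped like the sequenced
#: Drosophila genomes relative to D. melanogaster — one near-identical
#: sister species, one intermediate, a close species pair, and one distant
#: outgroup.  Third-position rates dominate throughout.
SPECIES_PRESETS: dict[str, DivergenceModel] = {
    "dsim": DivergenceModel("dsim", (0.015, 0.015, 0.10), p_indel=0.001),
    "dana": DivergenceModel("dana", (0.06, 0.06, 0.35), p_indel=0.003),
    "dpse": DivergenceModel("dpse", (0.08, 0.08, 0.42), p_indel=0.004),
    "dper": DivergenceModel("dper", (0.08, 0.08, 0.42), p_indel=0.004),
    "dvir": DivergenceModel("dvir", (0.11, 0.11, 0.55), p_indel=0.005),
}


# ---------------------------------------------------------------------------
# Exact run-length oracle
# ---------------------------------------------------------------------------


def prob_longest_run_at_least(n: int, match_prob: float, k: int) -> float:
    """Exact P(longest success run >= k) for n i.i.d. Bernoulli(match_prob).

    Dynamic program over current-run-length states with an absorbing state
    at k.  k > n returns 0.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 1:
        raise ValueError("k must be >= 1")
    if not (0.0 <= match_prob <= 1.0):
        raise ValueError("match_prob must lie in [0,1]")
    if k > n:
        return 0.0
    p, q = match_prob, 1.0 - match_prob
    state = np.zeros(k)  # state[j] = P(current run == j, not yet absorbed)
    state[0] = 1.0
    absorbed = 0.0
    for _ in range(n):
        new = np.zeros(k)
        new[0] = state.sum() * q
        new[1:] = state[:-1] * p
        absorbed += state[-1] * p
        state = new
    return float(absorbed)


# ---------------------------------------------------------------------------
# Pairwise divergence simulation
# ---------------------------------------------------------------------------


@dataclass
class PairTruth:
    """Truth table for one simulated aligned pair, in reference offsets."""

    state: list[str]  # per reference position: "match" | "sub" | "del"
    insertion_after: set[int]  # reference offsets followed by an insertion


def _substitute(base: str, model: DivergenceModel, rng: np.random.Generator) -> str:
    others = [b for b in _BASES if b != base]
    weights = np.array(
        [model.transition_bias if b == _TRANSITION[base] else 1.0 for b in others]
    )
    return rng.choice(others, p=weights / weights.sum())


def simulate_divergent_pair(
    reference_seq: str,
    model: DivergenceModel,
    rng: np.random.Generator,
    phases: list[int | None] | None = None,
) -> tuple[str, str, PairTruth]:
    """Diverge a reference sequence under the model.

    Returns (reference_aligned, donor_aligned, truth).  Substituted bases
    always differ from the original (drawn with transition bias); indels
    initiate at ``p_indel`` per site, split evenly between insertions and
    deletions, with geometric lengths.
    """
    n = len(reference_seq)
    if phases is not None and len(phases) != n:
        raise ValueError("phases must match reference length")
    ref_cols: list[str] = []
    donor_cols: list[str] = []
    truth = PairTruth(state=[], insertion_after=set())
    del_remaining = 0
    for i, base in enumerate(reference_seq):
        if del_remaining == 0 and model.p_indel and rng.random() < model.p_indel / 2:
            del_remaining = int(rng.geometric(model.indel_length_geometric_p))
        ref_cols.append(base)
        if del_remaining > 0:
            donor_cols.append("-")
            truth.state.append("del")
            del_remaining -= 1
        else:
            rate = model.rate_for_phase(phases[i] if phases is not None else None)
            if rate and rng.random() < rate:
                donor_cols.append(_substitute(base, model, rng))
                truth.state.append("sub")
            else:
                donor_cols.append(base)
                truth.state.append("match")
        if model.p_indel and rng.random() < model.p_indel / 2:
            ins_len = int(rng.geometric(model.indel_length_geometric_p))
            ref_cols.append("-" * ins_len)
            donor_cols.append("".join(rng.choice(list(_BASES), size=ins_len)))
            truth.insertion_after.add(i)
    return "".join(ref_cols), "".join(donor_cols), truth


# ---------------------------------------------------------------------------
# Whole-dataset simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CloneGeometry:
    """Geometry of synthetic clone end-mappings around donor genes."""

    coverage_fraction: float = 0.6  # fraction of genes given a fully covering clone
    up: int = 10_000
    down: int = 5_000
    margin_min: int = 2_000  # extra clone sequence beyond the required flanks
    margin_max: int = 8_000


@dataclass
class SyntheticDataset:
    outdir: Path
    genes: list[GeneModel]
    genome: dict[str, str]
    species: list[str]
    hairpin_truth: pd.DataFrame
    conservation_truth: pd.DataFrame
    clone_truth: pd.DataFrame
    paths: dict[str, Path] = field(default_factory=dict)


def _make_gene(
    gene_idx: int, offset: int, rng: np.random.Generator
) -> GeneModel:
    exon_sizes = [450, 450, 300]  # 1200 nt transcript, CDS = whole transcript
    introns = [int(rng.integers(60, 100)) for _ in range(len(exon_sizes) - 1)]
    exons = []
    pos = offset
    for i, size in enumerate(exon_sizes):
        exons.append((pos, pos + size))
        pos += size + (introns[i] if i < len(introns) else 0)
    strand = "+" if rng.random() < 0.5 else "-"
    gene_id = f"FBgn{gene_idx:07d}"
    return GeneModel(
        gene_id=gene_id,
        transcript_id=f"{gene_id}.t1",
        chrom="chr2R",
        strand=strand,
        exons=exons,
        cds_start=exons[0][0],
        cds_end=exons[-1][1],
    )


def _transcript_truth(
    model: GeneModel, span_start: int, covered: tuple[int, int] | None, truth: PairTruth | None
) -> tuple[list[str], set[int]]:
    """Map genomic-offset pair truth into transcript space (strand-aware)."""
    genomic = model.genomic_positions()
    states: list[str] = []
    for g in genomic:
        if truth is None or covered is None or not (covered[0] <= g < covered[1]):
            states.append("uncovered")
        else:
            states.append(truth.state[g - span_start])
    breaks: set[int] = set()
    if truth is not None:
        ins = {span_start + off for off in truth.insertion_after}
        for i in range(len(genomic) - 1):
            g, g_next = genomic[i], genomic[i + 1]
            if model.strand == "+" and g_next == g + 1 and g in ins:
                breaks.add(i)
            elif model.strand == "-" and g_next == g - 1 and g_next in ins:
                breaks.add(i)
    return states, breaks


def _truth_stretch(states: list[str], breaks: set[int], start: int, end: int) -> int:
    best = run = 0
    for i in range(start, end):
        if states[i] == "match":
            run += 1
            best = max(best, run)
            if i in breaks:
                run = 0
        else:
            run = 0
    return best


def simulate_dataset(
    outdir: str | Path,
    n_genes: int = 40,
    species: dict[str, DivergenceModel] | None = None,
    hairpin_length: int = 300,
    decoy_fraction: float = 0.1,
    revcomp_fraction: float = 0.2,
    isoform_fraction: float = 0.2,
    missing_block_fraction: float = 0.02,
    partial_coverage_fraction: float = 0.05,
    n_duplicate_hairpins: int = 1,
    clone_geometry: CloneGeometry = CloneGeometry(),
    hit_fraction: float = 0.3,
    n_genes_without_ortholog: int = 1,
    n_genes_multi_ortholog: int = 1,
    seed: int = 0,
) -> SyntheticDataset:
    """Write a complete synthetic input set plus truth tables and manifest.

    All randomness flows from one seeded generator, so identical arguments
    give byte-identical files.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    outdir = Path(outdir)
    (outdir / "alignments").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    species = dict(SPECIES_PRESETS) if species is None else species
    sp_names = sorted(species)

    spacing = 12_000
    chrom_len = 20_000 + n_genes * spacing + 20_000
    chrom_seq = "".join(rng.choice(list(_BASES), size=chrom_len))
    genome = {"chr2R": chrom_seq}

    genes: list[GeneModel] = []
    all_models: list[GeneModel] = []
    for i in range(n_genes):
        g = _make_gene(i, 20_000 + i * spacing, rng)
        genes.append(g)
        all_models.append(g)
        if rng.random() < isoform_fraction:
            short = GeneModel(
                gene_id=g.gene_id,
                transcript_id=f"{g.gene_id}.t2",
                chrom=g.chrom,
                strand=g.strand,
                exons=g.exons[:-1],
                cds_start=g.exons[0][0],
                cds_end=g.exons[-2][1],
            )
            all_models.append(short)

    # --- per-species alignments ---------------------------------------
    blocks_by_species: dict[str, list[AlignmentBlock]] = {sp: [] for sp in sp_names}
    # (gene, species) -> (covered genomic interval or None, PairTruth or None)
    pair_info: dict[tuple[str, str], tuple[tuple[int, int] | None, PairTruth | None]] = {}
    for g in genes:
        span_start, span_end = g.span
        phase_by_genomic = dict(zip(g.genomic_positions(), g.phase_row()))
        for sp in sp_names:
            if rng.random() < missing_block_fraction:
                pair_info[(g.gene_id, sp)] = (None, None)
                continue
            if rng.random() < partial_coverage_fraction:
                cov_end = span_start + int(0.6 * (span_end - span_start))
            else:
                cov_end = span_end
            region = chrom_seq[span_start:cov_end]
            phases = [phase_by_genomic.get(p) for p in range(span_start, cov_end)]
            ref_aln, donor_aln, truth = simulate_divergent_pair(
                region, species[sp], rng, phases
            )
            blocks_by_species[sp].append(
                AlignmentBlock(
                    reference_chrom=g.chrom,
                    reference_start=span_start,
                    reference_aligned=ref_aln,
                    donor_species=sp,
                    donor_chrom="scaffold_1",
                    donor_start=span_start,
                    donor_strand="+",
                    donor_aligned=donor_aln,
                )
            )
            pair_info[(g.gene_id, sp)] = ((span_start, cov_end), truth)

    # --- hairpins ------------------------------------------------------
    n_decoys = int(round(decoy_fraction * n_genes))
    decoy_ids = set(rng.choice(n_genes, size=n_decoys, replace=False).tolist()) if n_decoys else set()
    decoy_partial = set(list(sorted(decoy_ids))[: n_decoys // 2 + n_decoys % 2])

    hp_rows = []
    fasta_records: list[tuple[str, str]] = []
    gene_map_rows = []
    cons_rows = []
    for idx, g in enumerate(genes):
        tseq = g.transcript_sequence(genome)
        tlen = len(tseq)
        off = int(rng.integers(0, tlen - hairpin_length + 1))
        seq = tseq[off : off + hairpin_length]
        orientation = "sense"
        status = "mapped_full"
        if idx in decoy_ids:
            if idx in decoy_partial:
                s = list(seq)
                for p in (50, 150, 250):
                    s[p] = _substitute(s[p], species[sp_names[0]], rng)
                seq = "".join(s)
                status = "partial"
            else:
                seq = "".join(rng.choice(list(_BASES), size=hairpin_length))
                status = "unmapped"
        elif rng.random() < revcomp_fraction:
            seq = reverse_complement(seq)
            orientation = "antisense"
        hp_id = f"hp{idx:05d}"
        fasta_records.append((hp_id, seq))
        gene_map_rows.append({"hairpin_id": hp_id, "gene_id": g.gene_id})
        hp_rows.append(
            {
                "hairpin_id": hp_id,
                "gene_id": g.gene_id,
                "true_status": status,
                "offset": off if status == "mapped_full" else -1,
                "orientation": orientation if status == "mapped_full" else "",
            }
        )
        if status != "mapped_full":
            continue
        span_start = g.span[0]
        for sp in sp_names:
            covered, truth = pair_info[(g.gene_id, sp)]
            states, breaks = _transcript_truth(g, span_start, covered, truth)
            window = states[off : off + hairpin_length]
            if all(s == "uncovered" for s in window):
                continue
            n_match = sum(1 for s in window if s == "match")
            cons_rows.append(
                {
                    "hairpin_id": hp_id,
                    "gene_id": g.gene_id,
                    "species": sp,
                    "true_percent_identity": 100.0 * n_match / hairpin_length,
                    "true_longest_stretch": _truth_stretch(
                        states, breaks, off, off + hairpin_length
                    ),
                }
            )

    # extra records for already-seen genes exercise the dedup path
    for d in range(min(n_duplicate_hairpins, n_genes)):
        g = genes[d]
        tseq = g.transcript_sequence(genome)
        fasta_records.append((f"hp_dup{d:03d}", tseq[:hairpin_length]))
        gene_map_rows.append({"hairpin_id": f"hp_dup{d:03d}", "gene_id": g.gene_id})

    # --- orthologs, donor annotation, clones, hits ---------------------
    no_orth = set(range(n_genes - n_genes_without_ortholog, n_genes))
    multi_orth = set(range(n_genes_multi_ortholog))
    orth_rows = []
    donor_rows = []
    clone_rows = []
    clone_truth_rows = []
    geom = clone_geometry
    for i, g in enumerate(genes):
        donor_id = f"GA{i:05d}"
        gs, ge = g.span
        donor_rows.append(
            {
                "donor_gene_id": donor_id,
                "chrom": "scaffold_1",
                "start": gs,
                "end": ge,
                "strand": g.strand,
            }
        )
        if i not in no_orth:
            orth_rows.append({"reference_gene_id": g.gene_id, "donor_gene_id": donor_id})
            if i in multi_orth:
                orth_rows.append(
                    {"reference_gene_id": g.gene_id, "donor_gene_id": f"GA{i:05d}b"}
                )
        up, down = (geom.up, geom.down) if g.strand == "+" else (geom.down, geom.up)
        covered = bool(rng.random() < geom.coverage_fraction)
        if covered:
            m1 = int(rng.integers(geom.margin_min, geom.margin_max))
            m2 = int(rng.integers(geom.margin_min, geom.margin_max))
            clone_rows.append(
                {
                    "clone_id": f"FF{i:05d}",
                    "chrom": "scaffold_1",
                    "start": max(0, gs - up - m1),
                    "end": ge + down + m2,
                }
            )
        elif rng.random() < 0.5:
            # deficient clone: upstream flank too short
            clone_rows.append(
                {
                    "clone_id": f"FF{i:05d}",
                    "chrom": "scaffold_1",
                    "start": max(0, gs - min(up, 3000)),
                    "end": ge + down + 2000,
                }
            )
        clone_truth_rows.append(
            {"gene_id": g.gene_id, "donor_gene_id": donor_id, "true_covered": covered}
        )

    hit_rows = [
        {"gene_id": g.gene_id} for g in genes if rng.random() < hit_fraction
    ]

    # --- write everything ----------------------------------------------
    paths: dict[str, Path] = {}

    paths["genome"] = outdir / "genome.fa"
    write_genome_fasta(genome, paths["genome"])
    paths["annotation"] = outdir / "annotation.bed"
    write_bed12(all_models, paths["annotation"])
    for sp in sp_names:
        p = outdir / "alignments" / f"{sp}.axt"
        write_axt(blocks_by_species[sp], p)
        paths[f"alignment_{sp}"] = p
    paths["hairpins"] = outdir / "hairpins.fa"
    with open(paths["hairpins"], "w") as fh:
        for hp_id, seq in fasta_records:
            fh.write(f">{hp_id}\n{seq}\n")
    paths["hairpin_gene_map"] = outdir / "hairpin_gene_map.tsv"
    write_tsv(pd.DataFrame(gene_map_rows), paths["hairpin_gene_map"])
    paths["orthologs"] = outdir / "orthologs.tsv"
    write_tsv(pd.DataFrame(orth_rows), paths["orthologs"])
    paths["donor_annotation"] = outdir / "donor_genes.tsv"
    write_tsv(pd.DataFrame(donor_rows), paths["donor_annotation"])
    paths["clones"] = outdir / "clones.tsv"
    write_tsv(pd.DataFrame(clone_rows), paths["clones"])
    paths["hits"] = outdir / "hits.tsv"
    write_tsv(pd.DataFrame(hit_rows, columns=["gene_id"]), paths["hits"])

    hairpin_truth = pd.DataFrame(hp_rows)
    conservation_truth = pd.DataFrame(cons_rows)
    clone_truth = pd.DataFrame(clone_truth_rows)
    write_tsv(hairpin_truth, outdir / "truth_hairpins.tsv")
    write_tsv(conservation_truth, outdir / "truth_conservation.tsv")
    write_tsv(clone_truth, outdir / "truth_clones.tsv")

    with open(outdir / "manifest.txt", "w") as fh:
        fh.write(f"seed\t{seed}\n")
        fh.write(f"n_genes\t{n_genes}\n")
        fh.write(f"species\t{','.join(sp_names)}\n")
        fh.write(f"hairpin_length\t{hairpin_length}\n")
        fh.write(f"decoy_fraction\t{decoy_fraction}\n")
        fh.write(f"clone_coverage_fraction\t{geom.coverage_fraction}\n")
        for sp in sp_names:
            m = species[sp]
            fh.write(
                f"model_{sp}\tp_phase={m.p_sub_by_phase} p_indel={m.p_indel} "
                f"ts_bias={m.transition_bias}\n"
            )

    config = {
        "reference_genome": str(paths["genome"]),
        "annotation": str(paths["annotation"]),
        "annotation_format": "bed12",
        "alignment_format": "axt",
        "alignments": {sp: str(paths[f"alignment_{sp}"]) for sp in sp_names},
        "hairpins": str(paths["hairpins"]),
        "hairpin_gene_map": str(paths["hairpin_gene_map"]),
        "orthologs": str(paths["orthologs"]),
        "donor_annotation": str(paths["donor_annotation"]),
        "clones": str(paths["clones"]),
        "hits": str(paths["hits"]),
        "clone_species": "dpse",
        "seed": seed,
    }
    paths["config"] = outdir / "pipeline_config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)

    return SyntheticDataset(
        outdir=outdir,
        genes=all_models,
        genome=genome,
        species=sp_names,
        hairpin_truth=hairpin_truth,
        conservation_truth=conservation_truth,
        clone_truth=clone_truth,
        paths=paths,
    )
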