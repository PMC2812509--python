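"""Project pairwise genome alignments into transcript space, per gene.

Each gene is represented by its longest transcript.  For every donor
species the pairwise alignment blocks covering the transcript's exons are
projected onto transcript coordinates, producing one donor row per species
over the alphabet A/C/G/T/N plus ``-`` (donor aligns a gap, i.e. deletion)
and ``.`` (no alignment block covers the position).  Donor insertions do
not lengthen the row; they are recorded as break points between adjacent
reference positions.  Stacking the per-species rows under the reference
transcript gives a reference-anchored alignment stack — pairwise alignments
sharing one coordinate row, not a true multiple alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import AlignmentBlock, GeneModel, IntegrityError

_COMP = str.maketrans("ACGTN", "TGCAN")

UNCOVERED = "."
GAP = "-"


class ProjectionError(ValueError):
    """Raised when alignment blocks cannot be projected unambiguously."""


def select_representative_transcript(models: list[GeneModel]) -> GeneModel:
    """Longest transcript represents the gene; ties break to the
    lexicographically smallest transcript id (deterministic)."""
    if not models:
        raise ValueError("no transcripts supplied")
    return min(models, key=lambda m: (-m.transcript_length, m.transcript_id))


def project_transcript(
    blocks: list[AlignmentBlock], transcript: GeneModel
) -> tuple[str, frozenset[int]]:
    """Project one species' blocks onto a transcript.

    Returns the donor row (length = transcript length, 5'->3' in transcript
    orientation) and the set of transcript positions after which the donor
    carries an insertion.  Net-style single coverage is enforced: two blocks
    claiming the same reference base is an error.
    """
    t_start, t_end = transcript.span
    per_base: dict[int, str] = {}  # ref genomic position -> donor symbol
    ins_after: set[int] = set()  # insertion after this ref genomic position

    relevant = [
        b
        for b in blocks
        if b.reference_chrom == transcript.chrom
        and b.reference_start < t_end
        and b.reference_end > t_start
    ]
    for b in relevant:
        ref_pos = b.reference_start
        prev_ref = ref_pos - 1
        for rc, dc in zip(b.reference_aligned, b.donor_aligned):
            if rc == GAP:
                # donor insertion relative to the reference
                ins_after.add(prev_ref)
            else:
                if ref_pos in per_base:
                    raise ProjectionError(
                        f"{transcript.transcript_id}: reference base "
                        f"{transcript.chrom}:{ref_pos} covered by more than one "
                        "block (net alignments must be single-coverage)"
                    )
                per_base[ref_pos] = dc
                prev_ref = ref_pos
                ref_pos += 1

    genomic = transcript.genomic_positions()
    if transcript.strand == "+":
        row = "".join(per_base.get(g, UNCOVERED) for g in genomic)
    else:
        row = "".join(
            per_base.get(g, UNCOVERED).translate(_COMP) if per_base.get(g, UNCOVERED) not in (UNCOVERED, GAP)
            else per_base.get(g, UNCOVERED)
            for g in genomic
        )

    breaks: set[int] = set()
    for i in range(len(genomic) - 1):
        g, g_next = genomic[i], genomic[i + 1]
        if transcript.strand == "+":
            if g_next == g + 1 and g in ins_after:
                breaks.add(i)
        else:
            if g_next == g - 1 and g_next in ins_after:
                breaks.add(i)
    return row, frozenset(breaks)


@dataclass
class GeneAlignment:
    """Reference-anchored per-gene alignment stack."""

    gene_id: str
    reference_row: str  # ungapped transcript sequence
    species_rows: dict[str, str]
    insertion_breaks: dict[str, frozenset[int]]
    phase_row: list[int | None] | None = None
    missing_species: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.reference_row)
        for sp, row in self.species_rows.items():
            if len(row) != n:
                raise IntegrityError(
                    f"{self.gene_id}/{sp}: row length {len(row)} != reference {n}"
                )
        for sp, brk in self.insertion_breaks.items():
            if any(p < 0 or p >= n for p in brk):
                raise IntegrityError(f"{self.gene_id}/{sp}: insertion break out of range")

    @property
    def n_species(self) -> int:
        return len(self.species_rows)

    def species_covered(self, species: str) -> bool:
        row = self.species_rows[species]
        return any(c != UNCOVERED for c in row)


def build_gene_alignment(
    transcript: GeneModel,
    reference_row: str,
    projections: dict[str, tuple[str, frozenset[int]]],
    species: list[str] | None = None,
) -> GeneAlignment:
    """Stack per-species projections; species absent from ``projections``
    get an all-'.' row and are flagged as missing their alignment file."""
    species = species if species is not None else sorted(projections)
    rows: dict[str, str] = {}
    breaks: dict[str, frozenset[int]] = {}
    missing: list[str] = []
    blank = UNCOVERED * len(reference_row)
    for sp in species:
        if sp in projections:
            rows[sp], breaks[sp] = projections[sp]
        else:
            rows[sp], breaks[sp] = blank, frozenset()
            missing.append(sp)
    return GeneAlignment(
        gene_id=transcript.gene_id,
        reference_row=reference_row,
        species_rows=rows,
        insertion_breaks=breaks,
        phase_row=transcript.phase_row(),
        missing_species=missing,
    )


def dump_stack(ga: GeneAlignment) -> str:
    """MAF-like multi-row text rendering of a gene stack, for debugging."""
    lines = [f"# gene {ga.gene_id}", f"ref\t{ga.reference_row}"]
    for sp in sorted(ga.species_rows):
        lines.append(f"{sp}\t{ga.species_rows[sp]}")
    return "\n".join(lines) + "\n"
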