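"""Locate hairpins on their gene's reference row and score conservation.

A hairpin enters the statistics only when it matches the reference
transcript exactly over its whole length (on either strand).  For each
mapped hairpin and each donor species we compute the percent of hairpin
positions at which the donor base equals the reference base, and the
longest identity stretch: the maximal run of consecutive identical
positions uninterrupted by mismatch, gap, uncovered position or donor
insertion.  The stretch statistic is the one that matters for RNAi: a
19-mer siRNA needs contiguous perfectly complementary target sequence, so
donor insertions break stretches even though they do not change per-position
identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from .gene_alignment import GAP, UNCOVERED, GeneAlignment
from .io_formats import HairpinRecord, reverse_complement

#: best infix edit distance at or below this fraction of hairpin length
#: distinguishes a partial hit from no hit at all
PARTIAL_MAX_DIVERGENCE = 0.25


@dataclass
class HairpinMapping:
    hairpin_id: str
    gene_id: str
    start: int  # 0-based transcript offset; -1 when not mapped_full
    end: int
    orientation: str  # "sense" | "antisense"
    status: str  # "mapped_full" | "partial" | "unmapped"


@dataclass
class ConservationRecord:
    hairpin_id: str
    gene_id: str
    species: str
    n_positions: int
    percent_identity: float
    longest_stretch: int


def map_hairpin(hairpin: HairpinRecord, gene_alignment: GeneAlignment) -> HairpinMapping:
    """Exact substring search of the hairpin (both strands) on the
    reference row.

    Full-length exact match -> mapped_full with the transcript offset.
    A near-miss (best infix edit distance within PARTIAL_MAX_DIVERGENCE of
    the hairpin length, on either strand) -> partial.  Otherwise unmapped.
    Partial and unmapped hairpins carry no coordinates and are excluded
    from conservation statistics.
    """
    ref = gene_alignment.reference_row
    seq = hairpin.sequence
    if len(seq) <= len(ref):
        pos = ref.find(seq)
        if pos >= 0:
            return HairpinMapping(
                hairpin.hairpin_id, gene_alignment.gene_id, pos, pos + len(seq),
                "sense", "mapped_full",
            )
        rc = reverse_complement(seq)
        pos = ref.find(rc)
        if pos >= 0:
            return HairpinMapping(
                hairpin.hairpin_id, gene_alignment.gene_id, pos, pos + len(seq),
                "antisense", "mapped_full",
            )
    best = min(
        edlib.align(seq, ref, mode="HW")["editDistance"],
        edlib.align(reverse_complement(seq), ref, mode="HW")["editDistance"],
    )
    status = "partial" if 0 <= best <= PARTIAL_MAX_DIVERGENCE * len(seq) else "unmapped"
    return HairpinMapping(hairpin.hairpin_id, gene_alignment.gene_id, -1, -1, "sense", status)


def _is_identity(ref_char: str, donor_char: str) -> bool:
    # N never matches anything, including N (conservative for off-target risk)
    return ref_char == donor_char and ref_char in "ACGT"


def percent_identity(reference_slice: str, species_slice: str) -> float:
    """Percent of positions where the donor symbol equals the reference
    nucleotide; '-', '.' and N all count as non-identical."""
    if len(reference_slice) != len(species_slice):
        raise ValueError("slices differ in length")
    if not reference_slice:
        raise ValueError("zero-length slice")
    if GAP in reference_slice or UNCOVERED in reference_slice:
        raise ValueError("reference slice must be gap-free")
    r = reference_slice.upper()
    s = species_slice.upper()
    n_id = sum(1 for a, b in zip(r, s) if _is_identity(a, b))
    return 100.0 * n_id / len(r)


def identity_stretch_intervals(
    reference_slice: str,
    species_slice: str,
    insertion_breaks: frozenset[int] | set[int] = frozenset(),
) -> list[tuple[int, int]]:
    """Maximal runs [start, end) of identical positions with no donor
    insertion between adjacent run members.  ``insertion_breaks`` holds
    slice positions after which the donor carries an insertion."""
    if len(reference_slice) != len(species_slice):
        raise ValueError("slices differ in length")
    if not reference_slice:
        raise ValueError("zero-length slice")
    r = reference_slice.upper()
    s = species_slice.upper()
    runs: list[tuple[int, int]] = []
    start: int | None = None
    for i in range(len(r)):
        if _is_identity(r[i], s[i]):
            if start is None:
                start = i
            if i in insertion_breaks:  # run cannot continue past an insertion
                runs.append((start, i + 1))
                start = None
        else:
            if start is not None:
                runs.append((start, i))
                start = None
    if start is not None:
        runs.append((start, len(r)))
    return runs


def longest_identity_stretch(
    reference_slice: str,
    species_slice: str,
    insertion_breaks: frozenset[int] | set[int] = frozenset(),
) -> int:
    """Length of the longest identity stretch; 0 if no position matches."""
    runs = identity_stretch_intervals(reference_slice, species_slice, insertion_breaks)
    return max((e - s for s, e in runs), default=0)


def conserve_all(
    mappings: list[HairpinMapping],
    gene_alignments: dict[str, GeneAlignment],
    *,
    insertions_break_stretch: bool = True,
) -> tuple[list[ConservationRecord], int]:
    """One ConservationRecord per (mapped_full hairpin, covered species).

    Species whose row is entirely uncovered for a gene are omitted and
    counted (second return value).  Output order is deterministic:
    (gene_id, species).
    """
    records: list[ConservationRecord] = []
    n_uncovered = 0
    for m in sorted(mappings, key=lambda m: m.gene_id):
        if m.status != "mapped_full":
            continue
        ga = gene_alignments[m.gene_id]
        ref_slice = ga.reference_row[m.start : m.end]
        for sp in sorted(ga.species_rows):
            row = ga.species_rows[sp]
            sp_slice = row[m.start : m.end]
            if set(sp_slice) <= {UNCOVERED}:
                n_uncovered += 1
                continue
            if insertions_break_stretch:
                brk = frozenset(
                    p - m.start
                    for p in ga.insertion_breaks.get(sp, frozenset())
                    if m.start <= p < m.end - 1
                )
            else:
                brk = frozenset()
            records.append(
                ConservationRecord(
                    hairpin_id=m.hairpin_id,
                    gene_id=m.gene_id,
                    species=sp,
                    n_positions=len(ref_slice),
                    percent_identity=percent_identity(ref_slice, sp_slice),
                    longest_stretch=longest_identity_stretch(ref_slice, sp_slice, brk),
                )
            )
    return records, n_uncovered
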