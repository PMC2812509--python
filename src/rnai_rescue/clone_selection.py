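"""Select genomic rescue clones covering donor-species orthologs.

A fosmid-sized genomic clone can rescue a knock-down only if it carries
the whole donor gene plus enough regulatory context: by default at least
10 kb on the promoter side and 5 kb downstream of the gene model, with
flank sides assigned by gene strand (a strand-blind mode replicates naive
interval arithmetic).  A stricter, reported-but-not-required property is
whether the clone spans at least into the nearest annotated neighbour
gene on each side.  Candidates are the intersection of screen hits,
one-to-one orthologs and covering clones, annotated with the refractory
call and cross-silencing risk of the donor ortholog.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

DEFAULT_UP = 10_000
DEFAULT_DOWN = 5_000


@dataclass
class CloneRecord:
    clone_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.clone_id}: empty interval [{self.start},{self.end})")


@dataclass
class GeneSpan:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class RescueCandidate:
    reference_gene_id: str
    donor_gene_id: str
    clone_id: str
    covered_with_flanks: bool
    spans_adjacent_genes: bool
    refractory: bool
    risk: str


def covers_gene_with_flanks(
    clone: CloneRecord,
    gene: GeneSpan,
    up: int = DEFAULT_UP,
    down: int = DEFAULT_DOWN,
    strand_aware: bool = True,
) -> bool:
    """True iff the clone contains the gene plus the required flanks.

    Strand-aware (default): the ``up`` flank sits on the promoter side.
    A clone on a different chromosome simply does not cover (end-mapping
    noise is tolerated, not raised).
    """
    if clone.chrom != gene.chrom:
        return False
    left, right = (up, down) if (gene.strand == "+" or not strand_aware) else (down, up)
    return clone.start <= gene.start - left and clone.end >= gene.end + right


def spans_adjacent_genes(
    clone: CloneRecord, gene: GeneSpan, neighbors: Sequence[GeneSpan]
) -> tuple[bool, bool]:
    """Does the clone overlap the nearest annotated gene on each side?

    Returns (spans_both, vacuous_flag); a missing neighbour on one side is
    vacuously satisfied but flagged.
    """
    same_chrom = sorted(
        (g for g in neighbors if g.chrom == gene.chrom and g.gene_id != gene.gene_id),
        key=lambda g: g.start,
    )
    left = [g for g in same_chrom if g.end <= gene.start]
    right = [g for g in same_chrom if g.start >= gene.end]
    vacuous = not left or not right
    ok = True
    if left:
        nb = left[-1]
        ok &= clone.start < nb.end and clone.end > nb.start
    if right:
        nb = right[0]
        ok &= clone.start < nb.end and clone.end > nb.start
    return ok, vacuous


@dataclass
class SelectionSummary:
    n_hits: int = 0
    n_hits_without_one_to_one_ortholog: int = 0
    n_hits_covered: int = 0
    n_hits_uncovered: int = 0


def select_rescue_candidates(
    hit_genes: Sequence[str],
    ortholog_table: pd.DataFrame,  # columns: reference_gene_id, donor_gene_id
    clones: Sequence[CloneRecord],
    donor_annotation: Mapping[str, GeneSpan],
    refractory_calls: Mapping[str, bool],
    risk_calls: Mapping[str, str],
    up: int = DEFAULT_UP,
    down: int = DEFAULT_DOWN,
    strand_aware: bool = True,
) -> tuple[list[RescueCandidate], SelectionSummary]:
    """Join screen hits to orthologs and covering clones.

    Hit genes with zero or more than one donor ortholog are excluded and
    counted.  Duplicate clone ids are an error.  Output is sorted by
    (reference_gene_id, clone_id).
    """
    ids = [c.clone_id for c in clones]
    if len(ids) != len(set(ids)):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate clone ids: {dups}")

    counts = ortholog_table["reference_gene_id"].value_counts()
    one_to_one = {
        row.reference_gene_id: row.donor_gene_id
        for row in ortholog_table.itertuples()
        if counts[row.reference_gene_id] == 1
    }
    donor_counts = ortholog_table["donor_gene_id"].value_counts()
    one_to_one = {
        r: d for r, d in one_to_one.items() if donor_counts[d] == 1 and d in donor_annotation
    }

    all_spans = list(donor_annotation.values())
    summary = SelectionSummary(n_hits=len(hit_genes))
    candidates: list[RescueCandidate] = []
    for ref_gene in sorted(hit_genes):
        donor_gene = one_to_one.get(ref_gene)
        if donor_gene is None:
            summary.n_hits_without_one_to_one_ortholog += 1
            continue
        gene = donor_annotation[donor_gene]
        covering = []
        for clone in clones:
            if covers_gene_with_flanks(clone, gene, up, down, strand_aware):
                spans, _ = spans_adjacent_genes(clone, gene, all_spans)
                covering.append(
                    RescueCandidate(
                        reference_gene_id=ref_gene,
                        donor_gene_id=donor_gene,
                        clone_id=clone.clone_id,
                        covered_with_flanks=True,
                        spans_adjacent_genes=spans,
                        refractory=bool(refractory_calls.get(ref_gene, False)),
                        risk=risk_calls.get(ref_gene, "none"),
                    )
                )
        if covering:
            summary.n_hits_covered += 1
            candidates.extend(covering)
        else:
            summary.n_hits_uncovered += 1
    candidates.sort(key=lambda c: (c.reference_gene_id, c.clone_id))
    return candidates, summary


def candidates_to_frame(candidates: Sequence[RescueCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "reference_gene_id": c.reference_gene_id,
                "donor_gene_id": c.donor_gene_id,
                "clone_id": c.clone_id,
                "covered_with_flanks": c.covered_with_flanks,
                "spans_adjacent_genes": c.spans_adjacent_genes,
                "refractory": c.refractory,
                "risk": c.risk,
            }
            for c in candidates
        ],
        columns=[
            "reference_gene_id",
            "donor_gene_id",
            "clone_id",
            "covered_with_flanks",
            "spans_adjacent_genes",
            "refractory",
            "risk",
        ],
    )


def clones_to_bed(clones: Sequence[CloneRecord], path) -> None:
    with open(path, "w") as fh:
        for c in sorted(clones, key=lambda c: (c.chrom, c.start)):
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.clone_id}\n")
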