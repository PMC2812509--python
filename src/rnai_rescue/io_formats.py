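"""Readers and writers for every external format the pipeline touches.

All internal coordinates are 0-based half-open.  Conversions from 1-based
conventions (AXT block headers, GFF3 features) happen in this module and
nowhere else.  After normalisation the sequence alphabet is A/C/G/T/N plus
``-`` inside alignment rows; other IUPAC ambiguity codes are mapped to N
with a warning, because downstream identity logic treats N as a mismatch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import AlignIO, SeqIO

log = logging.getLogger(__name__)

VALID_ALIGNED = frozenset("ACGTN-")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """A record could not be parsed; the message names the offending line."""


class IntegrityError(ValueError):
    """A parsed record violates a structural invariant (e.g. row lengths)."""


class ValidationError(ValueError):
    """A record parsed but fails a semantic check (e.g. overlapping exons)."""


def normalize_seq(seq: str, *, allow_gap: bool = False) -> str:
    """Uppercase and map ambiguity codes other than N to N.

    Gap characters (``-``) are only legal inside alignment rows
    (``allow_gap=True``).
    """
    s = seq.upper()
    valid = VALID_ALIGNED if allow_gap else frozenset("ACGTN")
    if set(s) <= valid:
        return s
    out = []
    n_mapped = 0
    for c in s:
        if c in valid:
            out.append(c)
        else:
            out.append("N")
            n_mapped += 1
    log.warning("mapped %d non-ACGTN symbols to N", n_mapped)
    return "".join(out)


def reverse_complement(seq: str) -> str:
    """Reverse complement over A/C/G/T/N (gaps and '.' preserved in place)."""
    tr = str.maketrans("ACGTNacgtn", "TGCANtgcan")
    return seq.translate(tr)[::-1]


# ---------------------------------------------------------------------------
# Pairwise alignments (AXT / MAF)
# ---------------------------------------------------------------------------


@dataclass
class AlignmentBlock:
    """One block of a pairwise genome alignment, reference-anchored.

    ``donor_aligned`` is stored exactly as it aligns to the reference row:
    minus-strand donors were already reverse-complemented by the aligner
    (UCSC AXT/MAF semantics) and are kept that way, with the strand flag
    retained.
    """

    reference_chrom: str
    reference_start: int  # 0-based
    reference_aligned: str
    donor_species: str
    donor_chrom: str
    donor_start: int  # 0-based, on the strand given by donor_strand
    donor_strand: str
    donor_aligned: str

    def __post_init__(self) -> None:
        self.reference_aligned = normalize_seq(self.reference_aligned, allow_gap=True)
        self.donor_aligned = normalize_seq(self.donor_aligned, allow_gap=True)
        if len(self.reference_aligned) != len(self.donor_aligned):
            raise IntegrityError(
                f"block at {self.reference_chrom}:{self.reference_start}: "
                f"gapped row lengths differ "
                f"({len(self.reference_aligned)} vs {len(self.donor_aligned)})"
            )
        if self.donor_strand not in "+-":
            raise IntegrityError(f"bad strand {self.donor_strand!r}")

    @property
    def reference_span(self) -> int:
        return len(self.reference_aligned) - self.reference_aligned.count("-")

    @property
    def reference_end(self) -> int:
        return self.reference_start + self.reference_span


def read_pairwise_alignment(
    path: str | Path, format_tag: str, donor_species: str | None = None
) -> list[AlignmentBlock]:
    """Read AXT or MAF into sorted AlignmentBlocks.

    AXT carries no species name, so ``donor_species`` defaults to the file
    stem.  Blocks are returned sorted by (reference_chrom, reference_start).
    """
    path = Path(path)
    if format_tag == "axt":
        blocks = _read_axt(path, donor_species or path.stem)
    elif format_tag == "maf":
        blocks = _read_maf(path)
    else:
        raise ValueError(f"unknown alignment format {format_tag!r}")
    blocks.sort(key=lambda b: (b.reference_chrom, b.reference_start))
    return blocks


def _read_axt(path: Path, donor_species: str) -> list[AlignmentBlock]:
    blocks: list[AlignmentBlock] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line or line.startswith("#"):
            i += 1
            continue
        fields = line.split()
        if len(fields) != 9:
            raise FormatError(f"{path}:{i + 1}: expected 9-field AXT header, got {line!r}")
        try:
            ref_start = int(fields[2])
            ref_end = int(fields[3])
            donor_start = int(fields[5])
        except ValueError as exc:
            raise FormatError(f"{path}:{i + 1}: non-numeric coordinate") from exc
        if i + 2 >= len(lines):
            raise FormatError(f"{path}:{i + 1}: truncated AXT block")
        ref_row = lines[i + 1].strip()
        donor_row = lines[i + 2].strip()
        block = AlignmentBlock(
            reference_chrom=fields[1],
            reference_start=ref_start - 1,  # AXT is 1-based inclusive
            reference_aligned=ref_row,
            donor_species=donor_species,
            donor_chrom=fields[4],
            donor_start=donor_start - 1,
            donor_strand=fields[7],
            donor_aligned=donor_row,
        )
        if block.reference_span != ref_end - (ref_start - 1):
            raise IntegrityError(
                f"{path}:{i + 1}: ungapped reference length {block.reference_span} "
                f"does not match header span {ref_end - ref_start + 1}"
            )
        blocks.append(block)
        i += 3
    return blocks


def _read_maf(path: Path) -> list[AlignmentBlock]:
    blocks: list[AlignmentBlock] = []
    try:
        alignments = list(AlignIO.parse(str(path), "maf"))
    except ValueError as exc:
        raise IntegrityError(f"{path}: {exc}") from exc
    for aln in alignments:
        if len(aln) < 2:
            continue
        ref, donor = aln[0], aln[1]
        ref_src = ref.id
        donor_src = donor.id
        donor_species = donor_src.split(".", 1)[0]
        donor_chrom = donor_src.split(".", 1)[1] if "." in donor_src else donor_src
        ref_chrom = ref_src.split(".", 1)[1] if "." in ref_src else ref_src
        strand = "+" if donor.annotations["strand"] == 1 else "-"
        blocks.append(
            AlignmentBlock(
                reference_chrom=ref_chrom,
                reference_start=ref.annotations["start"],
                reference_aligned=str(ref.seq),
                donor_species=donor_species,
                donor_chrom=donor_chrom,
                donor_start=donor.annotations["start"],
                donor_strand=strand,
                donor_aligned=str(donor.seq),
            )
        )
    return blocks


def write_axt(blocks: Sequence[AlignmentBlock], path: str | Path) -> None:
    """Write blocks in AXT (1-based inclusive header coordinates)."""
    with open(path, "w") as fh:
        for idx, b in enumerate(blocks):
            donor_span = len(b.donor_aligned) - b.donor_aligned.count("-")
            fh.write(
                f"{idx} {b.reference_chrom} {b.reference_start + 1} "
                f"{b.reference_end} {b.donor_chrom} {b.donor_start + 1} "
                f"{b.donor_start + donor_span} {b.donor_strand} 0\n"
            )
            fh.write(b.reference_aligned + "\n")
            fh.write(b.donor_aligned + "\n\n")


# ---------------------------------------------------------------------------
# Gene models (BED12 / GFF3)
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """One transcript: sorted non-overlapping exons, optional CDS interval."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        prev_end = -1
        for s, e in self.exons:
            if s >= e:
                raise ValidationError(f"{self.transcript_id}: empty exon [{s},{e})")
            if s < prev_end:
                raise ValidationError(f"{self.transcript_id}: overlapping exons")
            prev_end = e

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def genomic_positions(self) -> list[int]:
        """Genomic position of each transcript position, 5'->3'."""
        pos = [p for s, e in self.exons for p in range(s, e)]
        return pos[::-1] if self.strand == "-" else pos

    def transcript_sequence(self, genome: Mapping[str, str]) -> str:
        chrom_seq = genome[self.chrom]
        seq = "".join(chrom_seq[s:e] for s, e in self.exons)
        seq = normalize_seq(seq)
        return reverse_complement(seq) if self.strand == "-" else seq

    def phase_row(self) -> list[int | None]:
        """Codon phase (0/1/2) per transcript position; None outside the CDS.

        Phase 0 marks the first base of a codon, counted from the CDS start
        in transcript orientation.
        """
        if self.cds_start is None or self.cds_end is None:
            return [None] * self.transcript_length
        phases: list[int | None] = []
        k = 0
        for g in self.genomic_positions():
            if self.cds_start <= g < self.cds_end:
                phases.append(k % 3)
                k += 1
            else:
                phases.append(None)
        return phases


def read_gene_models(
    path: str | Path,
    format_tag: str,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[GeneModel]:
    """Read BED12 or GFF3 into GeneModels (one per transcript).

    BED12 is 0-based half-open natively; GFF3 features (1-based closed) are
    converted here.  BED names of the form ``gene:transcript`` carry the
    gene assignment; a bare name is both gene and transcript id.
    """
    path = Path(path)
    if format_tag == "bed12":
        models = _read_bed12(path)
    elif format_tag == "gff3":
        models = _read_gff3(path)
    else:
        raise ValueError(f"unknown annotation format {format_tag!r}")
    if chrom_sizes is not None:
        for m in models:
            size = chrom_sizes.get(m.chrom)
            if size is not None and (m.span[0] < 0 or m.span[1] > size):
                raise ValidationError(
                    f"{m.transcript_id}: exon outside chromosome bounds "
                    f"({m.span} vs {m.chrom} size {size})"
                )
    return models


def _read_bed12(path: Path) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}:{lineno}: BED12 needs 12 columns, got {len(f)}")
            chrom, chrom_start = f[0], int(f[1])
            name, strand = f[3], f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise FormatError(f"{path}:{lineno}: blockCount disagrees with block lists")
            exons = [(chrom_start + st, chrom_start + st + sz) for st, sz in zip(starts, sizes)]
            gene_id, _, transcript_id = name.partition(":")
            models.append(
                GeneModel(
                    gene_id=gene_id,
                    transcript_id=transcript_id or name,
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    cds_start=thick_start if thick_start != thick_end else None,
                    cds_end=thick_end if thick_start != thick_end else None,
                )
            )
    return models


def _read_gff3(path: Path) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for tr in db.features_of_type(("mRNA", "transcript")):
        parents = tr.attributes.get("Parent", [tr.id])
        exons = sorted((e.start - 1, e.end) for e in db.children(tr, featuretype="exon"))
        cds = [(c.start - 1, c.end) for c in db.children(tr, featuretype="CDS")]
        models.append(
            GeneModel(
                gene_id=parents[0],
                transcript_id=tr.id,
                chrom=tr.seqid,
                strand=tr.strand,
                exons=exons,
                cds_start=min(s for s, _ in cds) if cds else None,
                cds_end=max(e for _, e in cds) if cds else None,
            )
        )
    return models


def write_bed12(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            start, end = m.span
            sizes = ",".join(str(e - s) for s, e in m.exons)
            starts = ",".join(str(s - start) for s, _ in m.exons)
            thick_s = m.cds_start if m.cds_start is not None else start
            thick_e = m.cds_end if m.cds_end is not None else start
            fh.write(
                f"{m.chrom}\t{start}\t{end}\t{m.gene_id}:{m.transcript_id}\t0\t"
                f"{m.strand}\t{thick_s}\t{thick_e}\t0\t{len(m.exons)}\t"
                f"{sizes}\t{starts}\n"
            )


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        by_gene: dict[str, list[GeneModel]] = {}
        for m in models:
            by_gene.setdefault(m.gene_id, []).append(m)
        for gene_id, trs in by_gene.items():
            g_start = min(t.span[0] for t in trs)
            g_end = max(t.span[1] for t in trs)
            chrom, strand = trs[0].chrom, trs[0].strand
            fh.write(
                f"{chrom}\t.\tgene\t{g_start + 1}\t{g_end}\t.\t{strand}\t.\tID={gene_id}\n"
            )
            for t in trs:
                s, e = t.span
                fh.write(
                    f"{chrom}\t.\tmRNA\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                    f"ID={t.transcript_id};Parent={gene_id}\n"
                )
                for i, (es, ee) in enumerate(t.exons):
                    fh.write(
                        f"{chrom}\t.\texon\t{es + 1}\t{ee}\t.\t{strand}\t.\t"
                        f"ID={t.transcript_id}.e{i};Parent={t.transcript_id}\n"
                    )
                if t.cds_start is not None:
                    for i, (es, ee) in enumerate(t.exons):
                        cs, ce = max(es, t.cds_start), min(ee, t.cds_end)
                        if cs < ce:
                            fh.write(
                                f"{chrom}\t.\tCDS\t{cs + 1}\t{ce}\t.\t{strand}\t0\t"
                                f"ID={t.transcript_id}.c{i};Parent={t.transcript_id}\n"
                            )


# ---------------------------------------------------------------------------
# Hairpins (FASTA) and tabular inputs (TSV)
# ---------------------------------------------------------------------------


@dataclass
class HairpinRecord:
    hairpin_id: str
    target_gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = normalize_seq(self.sequence)
        if not self.sequence:
            raise ValidationError(f"{self.hairpin_id}: empty hairpin sequence")


@dataclass
class HairpinReadSummary:
    n_records: int = 0
    n_kept: int = 0
    n_dropped_duplicates: int = 0
    n_unresolved: int = 0


def read_hairpin_fasta(
    path: str | Path, gene_map: Mapping[str, str] | None = None
) -> tuple[list[HairpinRecord], HairpinReadSummary]:
    """Read the hairpin library; keep the first hairpin per target gene.

    ``gene_map`` resolves FASTA record ids to gene ids; without it the
    record id is taken as the gene id.  Records whose gene cannot be
    resolved are skipped and counted; extra hairpins for an already-seen
    gene are dropped and counted (one hairpin per gene enters the analysis).
    """
    summary = HairpinReadSummary()
    seen: set[str] = set()
    records: list[HairpinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        summary.n_records += 1
        if gene_map is not None:
            gene_id = gene_map.get(rec.id)
            if gene_id is None:
                log.warning("hairpin %s: no gene mapping, skipped", rec.id)
                summary.n_unresolved += 1
                continue
        else:
            gene_id = rec.id
        if gene_id in seen:
            log.info("hairpin %s: duplicate for gene %s, dropped", rec.id, gene_id)
            summary.n_dropped_duplicates += 1
            continue
        seen.add(gene_id)
        records.append(HairpinRecord(rec.id, gene_id, str(rec.seq)))
        summary.n_kept += 1
    return records, summary


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: normalize_seq(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def write_genome_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_tsv(path: str | Path, required: Sequence[str] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(required) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
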