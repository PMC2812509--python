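"""Classify orthologs as RNAi-refractory and summarise across species.

The silencing rule of thumb: a contiguous identity of 19 or more
nucleotides between hairpin and target can cross-silence.  An ortholog
whose longest identity stretch with the hairpin footprint is *below* the
threshold is called refractory — a transgene carrying it should escape the
knock-down.  This module applies the rule per (gene, species), builds
per-species summary fractions, stretch-length histograms (which show a
period-3 structure driven by third-codon-position divergence), and the
cross-species aggregate: the fraction of genes with at least one refractory
ortholog anywhere in the species panel, and how that rescue potential
distributes over species.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .hairpin_conservation import ConservationRecord

DEFAULT_THRESHOLD = 19


@dataclass
class RefractoryCall:
    gene_id: str
    species: str
    longest_stretch: int
    refractory: bool
    threshold: int = DEFAULT_THRESHOLD


@dataclass
class SpeciesSummary:
    species: str
    n_hairpins: int
    fraction_refractory: float
    fraction_identity_gt_90: float
    fraction_identity_gt_75: float
    fraction_stretch_gt_18: float


def classify_refractory(
    record: ConservationRecord, threshold: int = DEFAULT_THRESHOLD
) -> RefractoryCall:
    """Refractory iff the longest identity stretch is shorter than the
    threshold (default 19 nt)."""
    if threshold < 1:
        raise ValueError(f"threshold must be >= 1, got {threshold}")
    if record.longest_stretch < 0:
        raise ValueError("negative stretch length")
    return RefractoryCall(
        gene_id=record.gene_id,
        species=record.species,
        longest_stretch=record.longest_stretch,
        refractory=record.longest_stretch < threshold,
        threshold=threshold,
    )


def species_summary(
    records: Sequence[ConservationRecord], threshold: int = DEFAULT_THRESHOLD
) -> SpeciesSummary:
    """Summary fractions (percent) over one species' mapped hairpins."""
    if not records:
        raise ValueError("no records for species summary")
    species = {r.species for r in records}
    if len(species) != 1:
        raise ValueError(f"records span multiple species: {sorted(species)}")
    n = len(records)
    n_refr = sum(1 for r in records if r.longest_stretch < threshold)
    return SpeciesSummary(
        species=species.pop(),
        n_hairpins=n,
        fraction_refractory=100.0 * n_refr / n,
        fraction_identity_gt_90=100.0 * sum(r.percent_identity > 90 for r in records) / n,
        fraction_identity_gt_75=100.0 * sum(r.percent_identity > 75 for r in records) / n,
        fraction_stretch_gt_18=100.0 * sum(r.longest_stretch > threshold - 1 for r in records) / n,
    )


@dataclass
class CrossSpeciesAggregate:
    gene_table: pd.DataFrame  # gene_id, any_refractory, refractory_species
    fraction_genes_any_refractory: float  # percent
    call_share_by_species: dict[str, float]  # percent of refractory calls
    subset: tuple[str, ...] | None = None
    subset_call_share: float | None = None  # percent of refractory calls in subset
    subset_gene_share: float | None = None  # percent of rescuable genes with a subset option
    subset_only_gene_share: float | None = None  # percent rescuable ONLY via subset


def aggregate_across_species(
    calls: Iterable[RefractoryCall], subset: Sequence[str] | None = None
) -> CrossSpeciesAggregate:
    """Gene-level aggregation of per-species refractory calls.

    A gene is rescuable if at least one species' ortholog is refractory.
    Attribution to a species subset is reported under both readings: the
    share of refractory (gene, species) calls the subset contributes, and
    the share of rescuable genes whose refractory options include / lie
    only within the subset.
    """
    by_gene: dict[str, set[str]] = {}
    all_genes: set[str] = set()
    n_refr_calls = 0
    refr_calls_by_sp: Counter[str] = Counter()
    for c in calls:
        all_genes.add(c.gene_id)
        if c.refractory:
            by_gene.setdefault(c.gene_id, set()).add(c.species)
            refr_calls_by_sp[c.species] += 1
            n_refr_calls += 1

    rows = [
        {
            "gene_id": g,
            "any_refractory": g in by_gene,
            "refractory_species": ",".join(sorted(by_gene.get(g, ()))),
        }
        for g in sorted(all_genes)
    ]
    gene_table = pd.DataFrame(rows, columns=["gene_id", "any_refractory", "refractory_species"])
    n_genes = len(all_genes)
    n_any = len(by_gene)
    agg = CrossSpeciesAggregate(
        gene_table=gene_table,
        fraction_genes_any_refractory=100.0 * n_any / n_genes if n_genes else 0.0,
        call_share_by_species={
            sp: 100.0 * k / n_refr_calls for sp, k in sorted(refr_calls_by_sp.items())
        }
        if n_refr_calls
        else {},
    )
    if subset is not None:
        sub = set(subset)
        agg.subset = tuple(sorted(sub))
        in_sub = sum(k for sp, k in refr_calls_by_sp.items() if sp in sub)
        agg.subset_call_share = 100.0 * in_sub / n_refr_calls if n_refr_calls else 0.0
        with_sub = sum(1 for sps in by_gene.values() if sps & sub)
        only_sub = sum(1 for sps in by_gene.values() if sps and sps <= sub)
        agg.subset_gene_share = 100.0 * with_sub / n_any if n_any else 0.0
        agg.subset_only_gene_share = 100.0 * only_sub / n_any if n_any else 0.0
    return agg


@dataclass
class StretchHistogram:
    bin_size: int
    max_tracked: int | None
    zero_count: int
    counts: dict[tuple[int, int], int]  # inclusive (lo, hi) nucleotide bins
    overflow: int

    @property
    def total(self) -> int:
        return self.zero_count + sum(self.counts.values()) + self.overflow


def stretch_histogram(
    stretches: Iterable[int], bin_size: int = 3, max_tracked: int | None = None
) -> StretchHistogram:
    """Histogram of longest-stretch lengths.

    Bins are [1..b], [b+1..2b], ...; zeros go to a dedicated zero bin and,
    when ``max_tracked`` is set, values above it go to an overflow bin.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    zero = 0
    overflow = 0
    counts: Counter[tuple[int, int]] = Counter()
    for v in stretches:
        if v < 0:
            raise ValueError(f"negative stretch length {v}")
        if v == 0:
            zero += 1
        elif max_tracked is not None and v > max_tracked:
            overflow += 1
        else:
            b = (v - 1) // bin_size
            counts[(b * bin_size + 1, (b + 1) * bin_size)] += 1
    top = max_tracked if max_tracked is not None else max((hi for _, hi in counts), default=0)
    full: dict[tuple[int, int], int] = {}
    lo = 1
    while lo <= top:
        key = (lo, lo + bin_size - 1)
        full[key] = counts.get(key, 0)
        lo += bin_size
    return StretchHistogram(bin_size, max_tracked, zero, full, overflow)


def mismatch_phase_spectrum(phases: Iterable[int]) -> np.ndarray:
    """Distribution of mismatch positions over codon phases {0,1,2}."""
    counts = np.zeros(3)
    for p in phases:
        if p not in (0, 1, 2):
            raise ValueError(f"invalid codon phase {p}")
        counts[p] += 1
    if counts.sum() == 0:
        raise ValueError("no mismatch phases supplied")
    return counts / counts.sum()


def collect_mismatch_phases(gene_alignment) -> list[int]:
    """Phases of positions where a donor symbol differs from the reference.

    Requires the gene alignment to carry a phase row; raises naming the
    gene otherwise.  Uncovered ('.') positions are not mismatches in the
    divergence sense and are skipped.
    """
    if gene_alignment.phase_row is None or all(p is None for p in gene_alignment.phase_row):
        raise ValueError(f"gene {gene_alignment.gene_id}: no codon phase information")
    phases: list[int] = []
    ref = gene_alignment.reference_row
    for row in gene_alignment.species_rows.values():
        for i, (a, b) in enumerate(zip(ref, row)):
            ph = gene_alignment.phase_row[i]
            if ph is None or b == ".":
                continue
            if a != b:
                phases.append(ph)
    return phases


def stretch_mod3_spectrum(stretches: Sequence[int]) -> np.ndarray:
    """Distribution of stretch lengths modulo 3 — codon-structured
    divergence concentrates interior stretch lengths at residue 2."""
    if len(stretches) == 0:
        raise ValueError("no stretches supplied")
    counts = np.zeros(3)
    for v in stretches:
        if v < 0:
            raise ValueError(f"negative stretch length {v}")
        counts[v % 3] += 1
    return counts / counts.sum()


def summaries_to_frame(summaries: Sequence[SpeciesSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": s.species,
                "n_hairpins": s.n_hairpins,
                "fraction_refractory": s.fraction_refractory,
                "fraction_identity_gt_90": s.fraction_identity_gt_90,
                "fraction_identity_gt_75": s.fraction_identity_gt_75,
                "fraction_stretch_gt_18": s.fraction_stretch_gt_18,
            }
            for s in summaries
        ],
        columns=[
            "species",
            "n_hairpins",
            "fraction_refractory",
            "fraction_identity_gt_90",
            "fraction_identity_gt_75",
            "fraction_stretch_gt_18",
        ],
    )


def histogram_to_frame(h: StretchHistogram) -> pd.DataFrame:
    rows = [{"bin": "0", "count": h.zero_count}]
    rows += [{"bin": f"{lo}-{hi}", "count": c} for (lo, hi), c in h.counts.items()]
    if h.max_tracked is not None:
        rows.append({"bin": f">{h.max_tracked}", "count": h.overflow})
    return pd.DataFrame(rows)
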