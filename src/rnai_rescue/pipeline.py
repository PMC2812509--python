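"""End-to-end orchestration: inputs -> conservation -> summaries -> clones.

Every stage writes TSV outputs into the configured output directory; a
run manifest records the seed, every threshold in force, and the count of
records surviving each filter (total hairpins, deduplicated, mapped_full,
partial, unmapped, genes without any alignment), so that
``deduplicated = mapped_full + partial + unmapped`` can always be audited.
Given identical config and inputs the run is fully deterministic and the
output files are byte-identical across reruns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import clone_selection as cs
from . import io_formats as io
from .gene_alignment import (
    build_gene_alignment,
    project_transcript,
    select_representative_transcript,
)
from .hairpin_conservation import (
    ConservationRecord,
    conserve_all,
    identity_stretch_intervals,
    map_hairpin,
)
from .refractory_summary import (
    aggregate_across_species,
    classify_refractory,
    histogram_to_frame,
    species_summary,
    stretch_histogram,
    stretch_mod3_spectrum,
    summaries_to_frame,
)
from .sirna_scoring import ScoreWeights, cross_silencing_risk, score_track

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class PipelineConfig:
    reference_genome: str
    annotation: str
    hairpins: str
    alignments: dict[str, str]  # species -> path
    outdir: str = "results"
    annotation_format: str = "bed12"
    alignment_format: str = "axt"
    hairpin_gene_map: str | None = None
    orthologs: str | None = None
    donor_annotation: str | None = None
    clones: str | None = None
    hits: str | None = None
    clone_species: str | None = None  # species whose clones are being selected
    refractory_threshold: int = 19
    sirna_cutoff: float = 5.0
    sirna_weights: dict = field(default_factory=dict)
    flank_up: int = 10_000
    flank_down: int = 5_000
    strand_aware_flanks: bool = True
    insertions_break_stretch: bool = True
    histogram_bin_size: int = 3
    histogram_max_tracked: int = 50
    attribution_subset: list[str] = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        return cls(**raw)

    def score_weights(self) -> ScoreWeights:
        return ScoreWeights(cutoff=self.sirna_cutoff, **self.sirna_weights)


@dataclass
class PipelineResult:
    conservation: pd.DataFrame
    species_summaries: pd.DataFrame
    gene_aggregate: pd.DataFrame
    candidates: pd.DataFrame | None
    manifest: dict


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name}: {exc}") from exc

        return wrapper

    return deco


@_stage("load_inputs")
def _load_inputs(config: PipelineConfig):
    genome = io.read_genome_fasta(config.reference_genome)
    models = io.read_gene_models(config.annotation, config.annotation_format)
    gene_map = None
    if config.hairpin_gene_map:
        df = io.read_tsv(config.hairpin_gene_map, required=("hairpin_id", "gene_id"))
        gene_map = dict(zip(df["hairpin_id"], df["gene_id"]))
    hairpins, hp_summary = io.read_hairpin_fasta(config.hairpins, gene_map)
    blocks = {}
    missing_species = []
    for sp, path in sorted(config.alignments.items()):
        if not Path(path).exists():
            log.warning("species %s: alignment file %s missing", sp, path)
            missing_species.append(sp)
            continue
        blocks[sp] = io.read_pairwise_alignment(path, config.alignment_format, donor_species=sp)
    return genome, models, hairpins, hp_summary, blocks, missing_species


@_stage("build_alignments")
def _build_alignments(config, genome, models, blocks):
    by_gene: dict[str, list] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    species = sorted(config.alignments)
    gene_alignments = {}
    n_without_alignment = 0
    for gene_id in sorted(by_gene):
        tr = select_representative_transcript(by_gene[gene_id])
        ref_row = tr.transcript_sequence(genome)
        projections = {}
        for sp in species:
            if sp not in blocks:
                continue
            row, brk = project_transcript(blocks[sp], tr)
            projections[sp] = (row, brk)
        ga = build_gene_alignment(tr, ref_row, projections, species=species)
        if all(not ga.species_covered(sp) for sp in species):
            n_without_alignment += 1
        gene_alignments[gene_id] = ga
    return gene_alignments, n_without_alignment


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    weights = config.score_weights()

    genome, models, hairpins, hp_summary, blocks, missing_species = _load_inputs(config)
    gene_alignments, n_without_alignment = _build_alignments(config, genome, models, blocks)

    # --- hairpin mapping & conservation --------------------------------
    mappings = []
    status_counts = {"mapped_full": 0, "partial": 0, "unmapped": 0}
    for hp in hairpins:
        ga = gene_alignments.get(hp.target_gene_id)
        if ga is None:
            status_counts["unmapped"] += 1
            continue
        m = map_hairpin(hp, ga)
        status_counts[m.status] += 1
        mappings.append(m)
    records, n_uncovered = conserve_all(
        mappings, gene_alignments, insertions_break_stretch=config.insertions_break_stretch
    )
    cons_df = pd.DataFrame(
        [
            {
                "hairpin_id": r.hairpin_id,
                "gene_id": r.gene_id,
                "species": r.species,
                "n_positions": r.n_positions,
                "percent_identity": round(r.percent_identity, 4),
                "longest_stretch": r.longest_stretch,
                "status": "mapped_full",
            }
            for r in records
        ],
        columns=[
            "hairpin_id", "gene_id", "species", "n_positions",
            "percent_identity", "longest_stretch", "status",
        ],
    )
    io.write_tsv(cons_df, outdir / "conservation.tsv")

    # --- refractory classification & summaries -------------------------
    calls = [classify_refractory(r, config.refractory_threshold) for r in records]
    by_species: dict[str, list[ConservationRecord]] = {}
    for r in records:
        by_species.setdefault(r.species, []).append(r)
    summaries = [
        species_summary(by_species[sp], config.refractory_threshold)
        for sp in sorted(by_species)
    ]
    summ_df = summaries_to_frame(summaries)
    io.write_tsv(summ_df, outdir / "species_summary.tsv")

    subset = config.attribution_subset or None
    agg = aggregate_across_species(calls, subset=subset)
    io.write_tsv(agg.gene_table, outdir / "gene_aggregate.tsv")

    stretches = [r.longest_stretch for r in records]
    hist3 = stretch_histogram(stretches, bin_size=config.histogram_bin_size)
    hist1 = stretch_histogram(stretches, bin_size=1, max_tracked=config.histogram_max_tracked)
    io.write_tsv(histogram_to_frame(hist3), outdir / "stretch_histogram_bin3.tsv")
    io.write_tsv(histogram_to_frame(hist1), outdir / "stretch_histogram_bin1.tsv")
    mod3 = stretch_mod3_spectrum(stretches) if stretches else None

    # --- siRNA scoring & cross-silencing risk --------------------------
    track_rows = []
    risk_rows = []
    risk_by_gene_species: dict[tuple[str, str], str] = {}
    hp_by_gene = {hp.target_gene_id: hp for hp in hairpins}
    for m in mappings:
        if m.status != "mapped_full":
            continue
        ga = gene_alignments[m.gene_id]
        hp = hp_by_gene[m.gene_id]
        footprint = ga.reference_row[m.start : m.end]
        track = score_track(m.hairpin_id, footprint, weights)
        for s in track.scores:
            track_rows.append(
                {
                    "hairpin_id": m.hairpin_id,
                    "position": s.position,
                    "gc_penalty": round(s.gc_penalty, 4),
                    "balance_penalty": round(s.balance_penalty, 4),
                    "poly_penalty": round(s.poly_penalty, 4),
                    "total": round(s.total, 4),
                    "efficient": s.efficient,
                }
            )
        for sp in sorted(ga.species_rows):
            sp_slice = ga.species_rows[sp][m.start : m.end]
            if set(sp_slice) <= {"."}:
                continue
            brk = frozenset(
                p - m.start
                for p in ga.insertion_breaks.get(sp, frozenset())
                if m.start <= p < m.end - 1
            )
            intervals = identity_stretch_intervals(footprint, sp_slice, brk)
            call = cross_silencing_risk(
                m.gene_id, sp, intervals, track,
                threshold=config.refractory_threshold,
                hairpin_length=len(footprint),
            )
            risk_by_gene_species[(m.gene_id, sp)] = call.risk
            risk_rows.append(
                {
                    "gene_id": m.gene_id,
                    "species": sp,
                    "risk": call.risk,
                    "n_long_stretches": len(call.evidence),
                    "n_efficient_19mers_in_stretches": sum(n for _, n in call.evidence),
                }
            )
    io.write_tsv(
        pd.DataFrame(
            track_rows,
            columns=[
                "hairpin_id", "position", "gc_penalty", "balance_penalty",
                "poly_penalty", "total", "efficient",
            ],
        ),
        outdir / "sirna_tracks.tsv",
    )
    io.write_tsv(
        pd.DataFrame(
            risk_rows,
            columns=[
                "gene_id", "species", "risk", "n_long_stretches",
                "n_efficient_19mers_in_stretches",
            ],
        ),
        outdir / "cross_silencing_risk.tsv",
    )

    # --- clone selection -------------------------------------------------
    cand_df = None
    selection_summary = None
    if config.clones and config.orthologs and config.hits and config.donor_annotation:
        clones_df = io.read_tsv(config.clones, required=("clone_id", "chrom", "start", "end"))
        clones = [
            cs.CloneRecord(r.clone_id, r.chrom, int(r.start), int(r.end))
            for r in clones_df.itertuples()
        ]
        orth = io.read_tsv(config.orthologs, required=("reference_gene_id", "donor_gene_id"))
        donor_df = io.read_tsv(
            config.donor_annotation, required=("donor_gene_id", "chrom", "start", "end", "strand")
        )
        donor_ann = {
            r.donor_gene_id: cs.GeneSpan(
                r.donor_gene_id, r.chrom, int(r.start), int(r.end), r.strand
            )
            for r in donor_df.itertuples()
        }
        hits = io.read_tsv(config.hits, required=("gene_id",))["gene_id"].tolist()
        sp = config.clone_species
        refractory = {
            c.gene_id: c.refractory for c in calls if sp is None or c.species == sp
        }
        risks = {
            g: r for (g, s), r in risk_by_gene_species.items() if sp is None or s == sp
        }
        try:
            candidates, selection_summary = cs.select_rescue_candidates(
                hits, orth, clones, donor_ann, refractory, risks,
                up=config.flank_up, down=config.flank_down,
                strand_aware=config.strand_aware_flanks,
            )
        except ValueError as exc:
            raise PipelineError(f"stage select_clones: {exc}") from exc
        cand_df = cs.candidates_to_frame(candidates)
        io.write_tsv(cand_df, outdir / "rescue_candidates.tsv")
        cs.clones_to_bed(clones, outdir / "clones.bed")

    # --- manifest --------------------------------------------------------
    manifest = {
        "seed": config.seed,
        "refractory_threshold": config.refractory_threshold,
        "sirna_cutoff": weights.cutoff,
        "sirna_weights": {
            "gc": weights.gc, "balance": weights.balance,
            "poly": weights.poly, "poly_free_run": weights.poly_free_run,
        },
        "flank_up": config.flank_up,
        "flank_down": config.flank_down,
        "strand_aware_flanks": config.strand_aware_flanks,
        "insertions_break_stretch": config.insertions_break_stretch,
        "counts": {
            "hairpins_total": hp_summary.n_records,
            "hairpins_deduplicated": hp_summary.n_kept,
            "hairpins_dropped_duplicates": hp_summary.n_dropped_duplicates,
            "hairpins_unresolved": hp_summary.n_unresolved,
            "mapped_full": status_counts["mapped_full"],
            "partial": status_counts["partial"],
            "unmapped": status_counts["unmapped"],
            "genes_without_alignment": n_without_alignment,
            "species_missing_alignment_file": sorted(missing_species),
            "uncovered_gene_species_pairs": n_uncovered,
            "conservation_records": len(records),
        },
        "fraction_genes_any_refractory": round(agg.fraction_genes_any_refractory, 4),
        "call_share_by_species": {
            k: round(v, 4) for k, v in agg.call_share_by_species.items()
        },
        "stretch_mod3_spectrum": [round(float(x), 4) for x in mod3] if mod3 is not None else None,
    }
    if subset:
        manifest["attribution_subset"] = list(agg.subset or ())
        manifest["subset_call_share"] = round(agg.subset_call_share, 4)
        manifest["subset_gene_share"] = round(agg.subset_gene_share, 4)
        manifest["subset_only_gene_share"] = round(agg.subset_only_gene_share, 4)
    if selection_summary is not None:
        manifest["clone_selection"] = asdict(selection_summary)
    with open(outdir / "run_manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)

    return PipelineResult(
        conservation=cons_df,
        species_summaries=summ_df,
        gene_aggregate=agg.gene_table,
        candidates=cand_df,
        manifest=manifest,
    )
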