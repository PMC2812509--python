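#!/usr/bin/env python
"""Per-species refractory fractions, histograms and the cross-species view.

Reads the conservation table written by 02 and reports which species make
the best RNAi-rescue donors: high divergence means many orthologs with no
19-nt identity stretch.  Optionally draws the hairpin-rank conservation
curve and the stretch-length histograms (requires matplotlib).
"""

import argparse
from pathlib import Path

import pandas as pd

from rnai_rescue.hairpin_conservation import ConservationRecord
from rnai_rescue.refractory_summary import (
    aggregate_across_species,
    classify_refractory,
    species_summary,
    stretch_histogram,
    stretch_mod3_spectrum,
)

ROOT = Path(__file__).resolve().parents[1]


def load_records(path: Path) -> list[ConservationRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        ConservationRecord(r.hairpin_id, r.gene_id, r.species, int(r.n_positions),
                           float(r.percent_identity), int(r.longest_stretch))
        for r in df.itertuples()
    ]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--conservation", type=Path,
                    default=ROOT / "results" / "analysis" / "conservation.tsv")
    ap.add_argument("--plot", action="store_true", help="write figures (needs matplotlib)")
    args = ap.parse_args()

    records = load_records(args.conservation)
    by_species: dict[str, list[ConservationRecord]] = {}
    for r in records:
        by_species.setdefault(r.species, []).append(r)

    print(f"{'species':8} {'n':>5} {'refractory%':>12} {'id>90%':>8} {'id>75%':>8}")
    for sp in sorted(by_species):
        s = species_summary(by_species[sp])
        print(f"{sp:8} {s.n_hairpins:5d} {s.fraction_refractory:12.2f} "
              f"{s.fraction_identity_gt_90:8.2f} {s.fraction_identity_gt_75:8.2f}")

    calls = [classify_refractory(r) for r in records]
    agg = aggregate_across_species(calls, subset=["dpse", "dvir"])
    print(f"\ngenes with a refractory ortholog in >=1 species: "
          f"{agg.fraction_genes_any_refractory:.2f}%")
    print(f"share of refractory calls from dpse+dvir: {agg.subset_call_share:.2f}%")
    print(f"rescuable genes whose only options are dpse/dvir: "
          f"{agg.subset_only_gene_share:.2f}%")

    stretches = [r.longest_stretch for r in records]
    spec = stretch_mod3_spectrum(stretches)
    print(f"stretch length mod 3 spectrum: {spec.round(3).tolist()} "
          "(codon structure -> mass at residue 2)")

    if args.plot:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        figdir = ROOT / "results" / "figures"
        figdir.mkdir(parents=True, exist_ok=True)
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
        for sp in sorted(by_species):
            ids = sorted(r.percent_identity for r in by_species[sp])
            ax1.plot(range(len(ids)), ids, label=sp)
        ax1.set_xlabel("hairpins ordered by conservation")
        ax1.set_ylabel("% identity")
        ax1.legend(fontsize=7)
        h = stretch_histogram(stretches, bin_size=1, max_tracked=50)
        ax2.bar([lo for lo, _ in h.counts], list(h.counts.values()), width=1)
        ax2.axvline(19, color="green", ls="--", label="19 nt threshold")
        ax2.set_xlabel("longest identity stretch (nt)")
        ax2.set_ylabel("hairpins")
        ax2.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(figdir / "conservation_overview.png", dpi=120)
        print(f"wrote {figdir / 'conservation_overview.png'}")


if __name__ == "__main__":
    main()
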