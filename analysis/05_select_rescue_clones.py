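#!/usr/bin/env python
"""Nominate rescue clones for screen hits.

Reads the rescue-candidate table written by 02 and summarises the final
join: screen hits x one-to-one orthologs x clones covering the gene with
the required regulatory flanks, annotated with refractory status and
cross-silencing risk.  The genes a practitioner would order clones for
are the covered, refractory, low/none-risk ones.
"""

import argparse
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--analysis-dir", type=Path, default=ROOT / "results" / "analysis")
    args = ap.parse_args()

    cands = pd.read_csv(args.analysis_dir / "rescue_candidates.tsv", sep="\t")
    print(f"{len(cands)} (hit gene, clone) candidate pairs over "
          f"{cands['reference_gene_id'].nunique()} covered hit genes")
    print(f"  clones also spanning both neighbour genes: "
          f"{cands['spans_adjacent_genes'].sum()}")
    best = cands[cands["refractory"] & cands["risk"].isin(["none", "low"])]
    print(f"  refractory ortholog with no/low cross-silencing risk: "
          f"{best['reference_gene_id'].nunique()} genes "
          f"({len(best)} clone options) — the set to take into transgenesis")


if __name__ == "__main__":
    main()
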