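#!/usr/bin/env python
"""Cross-silencing risk: do efficient siRNAs fall inside long stretches?

Reads the siRNA score tracks and risk calls written by 02 and summarises
how often a >=19-nt identity stretch actually contains an efficient
19-mer (high risk) versus only inefficient ones (low risk) — the
distinction that decides whether a rescue transgene is likely silenced.
"""

import argparse
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--analysis-dir", type=Path, default=ROOT / "results" / "analysis")
    args = ap.parse_args()

    tracks = pd.read_csv(args.analysis_dir / "sirna_tracks.tsv", sep="\t")
    risk = pd.read_csv(args.analysis_dir / "cross_silencing_risk.tsv", sep="\t")

    eff = tracks["efficient"].mean()
    print(f"{len(tracks)} 19-mer windows scored over "
          f"{tracks['hairpin_id'].nunique()} hairpins; "
          f"{100 * eff:.1f}% predicted RNAi-efficient (score < cutoff)")
    print("\ncross-silencing risk per (gene, species):")
    print(risk.groupby(["species", "risk"]).size().unstack(fill_value=0).to_string())
    n_long = (risk["risk"] != "none").sum()
    n_high = (risk["risk"] == "high").sum()
    if n_long:
        print(f"\nof {n_long} pairs with a >=19-nt stretch, "
              f"{n_high} ({100 * n_high / n_long:.1f}%) contain an efficient siRNA window")


if __name__ == "__main__":
    main()
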