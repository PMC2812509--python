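"""Per-19-mer siRNA efficiency scoring and cross-silencing risk.

A ~300 bp hairpin is diced into 19-nt siRNAs; not all of them silence
equally well.  Each sliding 19-mer is scored on three sequence criteria —
GC content, GC balance between the two window halves, and homopolymer
runs — into a penalty score where lower means better predicted RNAi
performance; windows below the cutoff (default 5) are called efficient.
The exact weighting used by published design servers is not public, so
this is a parameterised surrogate with the same three criteria, defaults
chosen so that the canonical pathological windows (all-G, all-A) fail the
cutoff and a balanced mixed-composition window passes.  The weight set in
force is recorded with every output.

Combining the score track with identity stretches gives the
cross-silencing risk for a rescue transgene: a long (>= threshold)
identity stretch is only dangerous if an efficient siRNA window fits
wholly inside it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

log = logging.getLogger(__name__)

WINDOW = 19
DEFAULT_CUTOFF = 5.0


@dataclass(frozen=True)
class ScoreWeights:
    """Weights of the three penalty terms; defaults give the canonical
    behaviour (all-G: 5 + 16 = 21, all-A: 5 + 16 = 21, balanced mixed
    window: < 1)."""

    gc: float = 10.0  # times |GC fraction - 0.5|
    balance: float = 5.0  # times |GC(first half) - GC(second half)|
    poly: float = 1.0  # times max(0, longest homopolymer - poly_free_run)
    poly_free_run: int = 3
    cutoff: float = DEFAULT_CUTOFF


@dataclass
class SiRNAScore:
    position: int
    gc_penalty: float
    balance_penalty: float
    poly_penalty: float
    total: float
    efficient: bool
    flagged_n: bool = False


@dataclass
class SiRNAScoreTrack:
    hairpin_id: str
    cutoff: float
    scores: list[SiRNAScore]
    weights: ScoreWeights = field(default_factory=ScoreWeights)

    def efficient_positions(self) -> list[int]:
        return [s.position for s in self.scores if s.efficient]


def _gc_fraction(seq: str) -> float:
    return sum(1 for c in seq if c in "GC") / len(seq)


def _longest_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def score_19mer(seq: str, weights: ScoreWeights = ScoreWeights(), position: int = 0) -> SiRNAScore:
    """Score one 19-mer.

    Windows containing N are unscorable and get every penalty at its
    maximum (flagged), so they can never be called efficient.
    """
    seq = seq.upper()
    if len(seq) != WINDOW:
        raise ValueError(f"need exactly {WINDOW} nt, got {len(seq)}")
    if set(seq) - set("ACGT"):
        gc = weights.gc * 0.5
        bal = weights.balance * 1.0
        poly = weights.poly * (WINDOW - weights.poly_free_run)
        return SiRNAScore(position, gc, bal, poly, gc + bal + poly, False, flagged_n=True)
    gc_frac = _gc_fraction(seq)
    gc_pen = weights.gc * abs(gc_frac - 0.5)
    # halves: positions 1-9 and 11-19 (1-based), centre base excluded
    bal_pen = weights.balance * abs(_gc_fraction(seq[:9]) - _gc_fraction(seq[10:]))
    poly_pen = weights.poly * max(0, _longest_homopolymer(seq) - weights.poly_free_run)
    total = gc_pen + bal_pen + poly_pen
    return SiRNAScore(position, gc_pen, bal_pen, poly_pen, total, total < weights.cutoff)


def score_track(
    hairpin_id: str, sequence: str, weights: ScoreWeights = ScoreWeights()
) -> SiRNAScoreTrack:
    """Score every sliding 19-mer left-to-right; a hairpin shorter than
    19 nt yields an empty track with a warning."""
    sequence = sequence.upper()
    if len(sequence) < WINDOW:
        log.warning("%s: hairpin shorter than %d nt, empty score track", hairpin_id, WINDOW)
        return SiRNAScoreTrack(hairpin_id, weights.cutoff, [], weights)
    scores = [
        score_19mer(sequence[i : i + WINDOW], weights, position=i)
        for i in range(len(sequence) - WINDOW + 1)
    ]
    return SiRNAScoreTrack(hairpin_id, weights.cutoff, scores, weights)


@dataclass
class CrossSilencingCall:
    gene_id: str
    species: str
    risk: str  # "none" | "low" | "high"
    evidence: list[tuple[tuple[int, int], int]]  # (stretch interval, n efficient 19-mers inside)


def cross_silencing_risk(
    gene_id: str,
    species: str,
    stretch_intervals: list[tuple[int, int]],
    track: SiRNAScoreTrack,
    threshold: int = 19,
    hairpin_length: int | None = None,
) -> CrossSilencingCall:
    """Risk of the hairpin silencing the rescue ortholog.

    none: no identity stretch reaches the threshold.
    high: some efficient 19-mer lies wholly inside a >= threshold stretch.
    low:  long stretches exist but every interior 19-mer is inefficient.
    """
    n = hairpin_length if hairpin_length is not None else (
        len(track.scores) + WINDOW - 1 if track.scores else 0
    )
    for s, e in stretch_intervals:
        if s < 0 or e > n or s >= e:
            raise ValueError(f"stretch interval [{s},{e}) outside hairpin of length {n}")
    long_intervals = [(s, e) for s, e in stretch_intervals if e - s >= threshold]
    if not long_intervals:
        return CrossSilencingCall(gene_id, species, "none", [])
    eff = set(track.efficient_positions())
    evidence = []
    any_hit = False
    for s, e in long_intervals:
        inside = [p for p in range(s, e - WINDOW + 1) if p in eff]
        evidence.append(((s, e), len(inside)))
        if inside:
            any_hit = True
    return CrossSilencingCall(gene_id, species, "high" if any_hit else "low", evidence)
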