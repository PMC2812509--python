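import numpy as np
import pandas as pd
import pytest

from rnai_rescue.clone_selection import (
    CloneRecord,
    GeneSpan,
    covers_gene_with_flanks,
    select_rescue_candidates,
    spans_adjacent_genes,
)


def clone(start, end, cid="c1", chrom="scaf"):
    return CloneRecord(cid, chrom, start, end)


def gene(start, end, strand="+", gid="g1", chrom="scaf"):
    return GeneSpan(gid, chrom, start, end, strand)


class TestFlankCoverage:
    @pytest.mark.parametrize(
        "clone_iv,strand,expected",
        [
            ((9500, 30500), "+", True),  # required [10000, 30000)
            ((10500, 30500), "+", False),  # upstream short
            ((14000, 36000), "-", True),  # required [15000, 35000)
            ((14000, 29000), "-", False),  # downstream (left, 5 kb) ok, upstream short
        ],
    )
    def test_interval_arithmetic(self, clone_iv, strand, expected):
        g = gene(20000, 25000, strand)
        assert covers_gene_with_flanks(clone(*clone_iv), g) is expected

    def test_strand_blind_mode_ignores_orientation(self):
        g = gene(20000, 25000, "-")
        c = clone(9500, 30500)
        assert covers_gene_with_flanks(c, g, strand_aware=False)
        assert not covers_gene_with_flanks(c, g, strand_aware=True)

    def test_different_chromosome_is_not_covering(self):
        g = gene(20000, 25000, chrom="scaf2")
        assert covers_gene_with_flanks(clone(0, 100000), g) is False

    def test_invariant_under_translation(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            s = int(rng.integers(20000, 50000))
            e = s + int(rng.integers(1000, 5000))
            cs = s - int(rng.integers(0, 20000))
            ce = e + int(rng.integers(0, 20000))
            shift = int(rng.integers(0, 100000))
            before = covers_gene_with_flanks(clone(cs, ce), gene(s, e))
            after = covers_gene_with_flanks(
                clone(cs + shift, ce + shift), gene(s + shift, e + shift)
            )
            assert before == after

    def test_enlarging_clone_never_loses_coverage(self):
        g = gene(20000, 25000)
        for cs, ce in [(9500, 30500), (10500, 30000)]:
            before = covers_gene_with_flanks(clone(cs, ce), g)
            after = covers_gene_with_flanks(clone(cs - 500, ce + 500), g)
            assert after >= before


class TestNeighbourSpanning:
    NEIGHBOURS = [gene(5000, 8000, gid="left"), gene(31000, 33000, gid="right")]

    def test_spans_both_neighbours(self):
        ok, vacuous = spans_adjacent_genes(
            clone(4000, 34000), gene(20000, 25000), self.NEIGHBOURS
        )
        assert ok and not vacuous

    def test_missing_left_overlap(self):
        ok, _ = spans_adjacent_genes(clone(9000, 30000), gene(20000, 25000), self.NEIGHBOURS)
        assert not ok

    def test_no_right_neighbour_is_vacuously_true_but_flagged(self):
        ok, vacuous = spans_adjacent_genes(
            clone(4000, 34000), gene(20000, 25000), [gene(5000, 8000, gid="left")]
        )
        assert ok and vacuous


def brute_force_candidates(hits, orth_df, clones, ann, up=10000, down=5000):
    """Exhaustive interval-join oracle: plain nested loops and arithmetic."""
    counts = orth_df["reference_gene_id"].value_counts()
    pairs = set()
    for ref_gene in hits:
        rows = orth_df[orth_df["reference_gene_id"] == ref_gene]
        if counts.get(ref_gene, 0) != 1:
            continue
        donor = rows.iloc[0]["donor_gene_id"]
        if donor not in ann:
            continue
        g = ann[donor]
        left, right = (up, down) if g.strand == "+" else (down, up)
        for c in clones:
            if (
                c.chrom == g.chrom
                and c.start <= g.start - left
                and c.end >= g.end + right
            ):
                pairs.add((ref_gene, c.clone_id))
    return pairs


class TestSelection:
    def _fixture(self, seed=0, n=10):
        rng = np.random.default_rng(seed)
        ann = {}
        orth_rows = []
        hits = []
        clones = []
        for i in range(n):
            s = 30000 * (i + 1)
            e = s + int(rng.integers(2000, 6000))
            donor = f"GA{i}"
            ann[donor] = GeneSpan(donor, "scaf", s, e, "+" if rng.random() < 0.5 else "-")
            orth_rows.append({"reference_gene_id": f"FB{i}", "donor_gene_id": donor})
            if rng.random() < 0.7:
                hits.append(f"FB{i}")
            if rng.random() < 0.7:
                clones.append(
                    CloneRecord(
                        f"c{i}",
                        "scaf",
                        s - int(rng.integers(5000, 20000)),
                        e + int(rng.integers(2000, 15000)),
                    )
                )
        return hits, pd.DataFrame(orth_rows), clones, ann

    def test_matches_brute_force_join(self):
        for seed in range(5):
            hits, orth, clones, ann = self._fixture(seed)
            cands, _ = select_rescue_candidates(hits, orth, clones, ann, {}, {})
            got = {(c.reference_gene_id, c.clone_id) for c in cands}
            assert got == brute_force_candidates(hits, orth, clones, ann)

    def test_covered_and_uncovered_hits_counted(self):
        hits, orth, clones, ann = self._fixture(3)
        cands, summary = select_rescue_candidates(hits, orth, clones, ann, {}, {})
        assert summary.n_hits == len(hits)
        assert summary.n_hits_covered + summary.n_hits_uncovered + \
            summary.n_hits_without_one_to_one_ortholog == summary.n_hits
        assert summary.n_hits_covered == len({c.reference_gene_id for c in cands})

    def test_multi_ortholog_gene_excluded_and_counted(self):
        hits, orth, clones, ann = self._fixture(1)
        extra = pd.DataFrame(
            [{"reference_gene_id": hits[0], "donor_gene_id": "GA_other"}]
        )
        orth2 = pd.concat([orth, extra], ignore_index=True)
        cands, summary = select_rescue_candidates(hits, orth2, clones, ann, {}, {})
        assert summary.n_hits_without_one_to_one_ortholog >= 1
        assert all(c.reference_gene_id != hits[0] for c in cands)

    def test_duplicate_clone_ids_rejected(self):
        hits, orth, clones, ann = self._fixture(2)
        clones = clones + [CloneRecord(clones[0].clone_id, "scaf", 1, 2)]
        with pytest.raises(ValueError):
            select_rescue_candidates(hits, orth, clones, ann, {}, {})

    def test_output_sorted(self):
        hits, orth, clones, ann = self._fixture(4)
        cands, _ = select_rescue_candidates(hits, orth, clones, ann, {}, {})
        keys = [(c.reference_gene_id, c.clone_id) for c in cands]
        assert keys == sorted(keys)

    def test_candidates_carry_refractory_and_risk(self):
        hits, orth, clones, ann = self._fixture(0)
        refr = {h: True for h in hits}
        risk = {h: "low" for h in hits}
        cands, _ = select_rescue_candidates(hits, orth, clones, ann, refr, risk)
        assert all(c.refractory and c.risk == "low" for c in cands)
        assert all(c.covered_with_flanks for c in cands)
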