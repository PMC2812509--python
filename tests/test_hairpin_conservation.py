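import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rnai_rescue.gene_alignment import GeneAlignment
from rnai_rescue.hairpin_conservation import (
    conserve_all,
    identity_stretch_intervals,
    longest_identity_stretch,
    map_hairpin,
    percent_identity,
)
from rnai_rescue.io_formats import HairpinRecord, reverse_complement

from conftest import brute_force_longest_stretch, random_slice_pair


def make_ga(gene_id, ref, rows=None, breaks=None):
    rows = rows or {}
    return GeneAlignment(
        gene_id=gene_id,
        reference_row=ref,
        species_rows=rows,
        insertion_breaks=breaks or {sp: frozenset() for sp in rows},
    )


RNG = np.random.default_rng(42)
REF_ROW = "".join(RNG.choice(list("ACGT"), size=600))


class TestMapHairpin:
    def test_exact_substring_maps_full(self):
        hp = HairpinRecord("h", "g", REF_ROW[40:340])
        m = map_hairpin(hp, make_ga("g", REF_ROW))
        assert (m.status, m.start, m.end, m.orientation) == ("mapped_full", 40, 340, "sense")

    def test_reverse_complement_maps_antisense(self):
        hp = HairpinRecord("h", "g", reverse_complement(REF_ROW[40:340]))
        m = map_hairpin(hp, make_ga("g", REF_ROW))
        assert (m.status, m.start, m.orientation) == ("mapped_full", 40, "antisense")

    def test_single_mismatch_is_partial(self):
        seq = list(REF_ROW[40:340])
        seq[150] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[150]]
        m = map_hairpin(HairpinRecord("h", "g", "".join(seq)), make_ga("g", REF_ROW))
        assert m.status == "partial"
        assert m.start == -1  # excluded from statistics

    def test_unrelated_sequence_is_unmapped(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        m = map_hairpin(HairpinRecord("h", "g", seq), make_ga("g", REF_ROW))
        assert m.status == "unmapped"

    def test_hairpin_longer_than_row_is_unmapped(self):
        m = map_hairpin(HairpinRecord("h", "g", "ACGT" * 200), make_ga("g", REF_ROW[:100]))
        assert m.status == "unmapped"


class TestPercentIdentity:
    def test_identical_slices(self):
        s = REF_ROW[:300]
        assert percent_identity(s, s) == 100.0

    def test_counted_fraction(self):
        ref, donor = random_slice_pair(np.random.default_rng(3), 300, 0.8)
        n_id = sum(1 for a, b in zip(ref, donor) if a == b)
        assert percent_identity(ref, donor) == pytest.approx(100 * n_id / 300)
        # a concrete anchored case: 240 of 300 identical -> 80%
        donor2 = ref[:240] + "".join("A" if c != "A" else "C" for c in ref[240:])
        assert percent_identity(ref, donor2) == 80.0

    def test_all_uncovered_scores_zero(self):
        assert percent_identity("ACGT" * 5, "." * 20) == 0.0

    def test_gaps_and_n_never_match(self):
        assert percent_identity("ACGTN", "AC-TN") == 60.0  # N-N does not count

    def test_zero_length_is_an_error(self):
        with pytest.raises(ValueError):
            percent_identity("", "")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_joint_reverse_complement(self, seed):
        ref, donor = random_slice_pair(np.random.default_rng(seed), 120, 0.7)
        assert percent_identity(ref, donor) == pytest.approx(
            percent_identity(reverse_complement(ref), reverse_complement(donor))
        )


class TestLongestStretch:
    def test_identical_no_insertions(self):
        s = REF_ROW[:21]
        assert longest_identity_stretch(s, s) == 21

    def test_single_mismatch_example(self):
        assert longest_identity_stretch("ACGTACGTT", "ACGAACGTT") == 5

    def test_insertion_break_splits_run(self):
        s = REF_ROW[:30]
        # break after position 9 -> runs of 10 and 20
        assert longest_identity_stretch(s, s, frozenset({9})) == 20

    def test_no_match_returns_zero(self):
        assert longest_identity_stretch("AAAA", "CCCC") == 0

    def test_zero_length_is_an_error(self):
        with pytest.raises(ValueError):
            longest_identity_stretch("", "")

    @given(st.integers(0, 2**31 - 1), st.integers(1, 500), st.floats(0.3, 0.98))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_with_breaks(self, seed, n, p):
        rng = np.random.default_rng(seed)
        ref, donor = random_slice_pair(rng, n, p)
        breaks = frozenset(int(i) for i in rng.integers(0, n, size=max(1, n // 50)))
        assert longest_identity_stretch(ref, donor, breaks) == brute_force_longest_stretch(
            ref, donor, breaks
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_stretch_never_exceeds_identical_count(self, seed):
        ref, donor = random_slice_pair(np.random.default_rng(seed), 200, 0.8)
        n_id = sum(1 for a, b in zip(ref, donor) if a == b)
        assert longest_identity_stretch(ref, donor) <= n_id

    def test_intervals_partition_matches(self):
        ref, donor = random_slice_pair(np.random.default_rng(9), 200, 0.8)
        runs = identity_stretch_intervals(ref, donor)
        covered = sum(e - s for s, e in runs)
        assert covered == sum(1 for a, b in zip(ref, donor) if a == b)


class TestConserveAll:
    def _setup(self):
        rng = np.random.default_rng(17)
        alignments = {}
        mappings = []
        from rnai_rescue.hairpin_conservation import HairpinMapping

        for g in ("geneA", "geneB"):
            ref = "".join(rng.choice(list("ACGT"), size=400))
            rows = {}
            for i in range(5):
                _, donor = random_slice_pair(rng, 400, 0.85)
                rows[f"sp{i}"] = donor
            alignments[g] = make_ga(g, ref, rows)
            mappings.append(HairpinMapping(f"hp_{g}", g, 50, 350, "sense", "mapped_full"))
        return mappings, alignments

    def test_two_genes_five_species_gives_ten_records(self):
        mappings, alignments = self._setup()
        records, n_uncovered = conserve_all(mappings, alignments)
        assert len(records) == 10
        assert n_uncovered == 0

    def test_all_dot_species_omitted_and_counted(self):
        mappings, alignments = self._setup()
        ga = alignments["geneA"]
        ga.species_rows["sp0"] = "." * 400
        records, n_uncovered = conserve_all(mappings, alignments)
        assert len(records) == 9
        assert n_uncovered == 1

    def test_order_independent_of_input_order(self):
        mappings, alignments = self._setup()
        fwd, _ = conserve_all(mappings, alignments)
        rev, _ = conserve_all(mappings[::-1], alignments)
        assert fwd == rev

    def test_partial_mappings_excluded(self):
        mappings, alignments = self._setup()
        mappings[0].status = "partial"
        records, _ = conserve_all(mappings, alignments)
        assert len(records) == 5
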