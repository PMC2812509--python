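import itertools

import numpy as np
import pytest

from rnai_rescue.hairpin_conservation import ConservationRecord
from rnai_rescue.refractory_summary import (
    RefractoryCall,
    aggregate_across_species,
    classify_refractory,
    mismatch_phase_spectrum,
    species_summary,
    stretch_histogram,
    stretch_mod3_spectrum,
)


def rec(gene, species, stretch, pid=50.0, n=300):
    return ConservationRecord(f"hp_{gene}", gene, species, n, pid, stretch)


class TestClassification:
    @pytest.mark.parametrize(
        "stretch,expected",
        [(18, True), (19, False), (104, False), (0, True)],
    )
    def test_threshold_rule(self, stretch, expected):
        assert classify_refractory(rec("g", "sp", stretch)).refractory is expected

    def test_exhaustive_boundary_scan(self):
        for s in range(0, 41):
            call = classify_refractory(rec("g", "sp", s))
            assert call.refractory == (s < 19)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            classify_refractory(rec("g", "sp", 10), threshold=0)


class TestSpeciesSummary:
    def test_refractory_fraction_count_oracle(self):
        records = [rec("g%d" % i, "sp", s) for i, s in enumerate([10, 18, 19, 25])]
        assert species_summary(records).fraction_refractory == 50.0

    def test_identity_fractions(self):
        records = [
            rec("g%d" % i, "sp", 10, pid=p) for i, p in enumerate([95, 91, 80, 60])
        ]
        s = species_summary(records)
        assert s.fraction_identity_gt_90 == 50.0
        assert s.fraction_identity_gt_75 == 75.0

    def test_single_record(self):
        assert species_summary([rec("g", "sp", 5)]).fraction_refractory == 100.0

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            species_summary([])

    def test_refractory_and_long_stretch_fractions_are_complementary(self):
        rng = np.random.default_rng(0)
        records = [
            rec(f"g{i}", "sp", int(s)) for i, s in enumerate(rng.integers(0, 60, size=200))
        ]
        s = species_summary(records)
        assert s.fraction_refractory + s.fraction_stretch_gt_18 == 100.0


class TestAggregation:
    def test_single_species_attribution(self):
        calls = [
            RefractoryCall("g1", "spV", 10, True),
            RefractoryCall("g1", "spW", 30, False),
        ]
        agg = aggregate_across_species(calls, subset=["spV"])
        row = agg.gene_table.iloc[0]
        assert bool(row.any_refractory) and row.refractory_species == "spV"
        assert agg.subset_only_gene_share == 100.0

    def test_gene_refractory_nowhere(self):
        calls = [RefractoryCall("g1", "spV", 30, False)]
        agg = aggregate_across_species(calls)
        assert not agg.gene_table.iloc[0].any_refractory
        assert agg.fraction_genes_any_refractory == 0.0

    def test_matches_exhaustive_enumeration(self):
        """Global any-refractory fraction equals a brute-force count over
        every per-species flag combination of a 3-gene panel."""
        species = ["a", "b", "c"]
        for flags in itertools.product([True, False], repeat=9):
            calls = [
                RefractoryCall(f"g{i}", sp, 5 if flag else 30, flag)
                for i, gene_flags in enumerate(zip(*[iter(flags)] * 3))
                for sp, flag in zip(species, gene_flags)
            ]
            agg = aggregate_across_species(calls)
            expected = sum(
                any(flags[i * 3 : i * 3 + 3]) for i in range(3)
            ) / 3 * 100
            assert agg.fraction_genes_any_refractory == pytest.approx(expected)

    def test_call_shares_sum_to_100(self):
        rng = np.random.default_rng(2)
        calls = [
            RefractoryCall(f"g{i}", f"sp{j}", int(s), s < 19)
            for i in range(20)
            for j, s in enumerate(rng.integers(0, 40, size=4))
        ]
        agg = aggregate_across_species(calls, subset=["sp0", "sp1"])
        assert sum(agg.call_share_by_species.values()) == pytest.approx(100.0)
        assert 0 <= agg.subset_only_gene_share <= agg.subset_gene_share <= 100


class TestHistogram:
    def test_hand_counted_bins(self):
        h = stretch_histogram([1, 2, 3, 4], bin_size=3)
        assert h.counts == {(1, 3): 3, (4, 6): 1}
        assert h.zero_count == 0 and h.overflow == 0

    def test_overflow_in_bin1_mode(self):
        h = stretch_histogram([51], bin_size=1, max_tracked=50)
        assert h.overflow == 1
        assert sum(h.counts.values()) == 0

    def test_empty_input(self):
        h = stretch_histogram([], bin_size=3)
        assert h.total == 0

    def test_zeros_get_dedicated_bin(self):
        h = stretch_histogram([0, 0, 5], bin_size=3)
        assert h.zero_count == 2

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            stretch_histogram([-1])

    def test_permutation_invariance_and_total(self):
        rng = np.random.default_rng(4)
        values = rng.integers(0, 80, size=500).tolist()
        h1 = stretch_histogram(values, bin_size=1, max_tracked=50)
        h2 = stretch_histogram(values[::-1], bin_size=1, max_tracked=50)
        assert (h1.counts, h1.zero_count, h1.overflow) == (h2.counts, h2.zero_count, h2.overflow)
        assert h1.total == 500


class TestPhaseSpectra:
    def test_third_position_only_divergence(self):
        spec = mismatch_phase_spectrum([2] * 50)
        assert spec.tolist() == [0.0, 0.0, 1.0]

    def test_uniform_divergence_is_flat_within_ci(self):
        rng = np.random.default_rng(8)
        phases = rng.integers(0, 3, size=3000).tolist()
        spec = mismatch_phase_spectrum(phases)
        se = np.sqrt((1 / 3) * (2 / 3) / 3000)
        assert np.all(np.abs(spec - 1 / 3) < 3 * se)

    def test_mod3_spectrum_concentrates(self):
        spec = stretch_mod3_spectrum([2, 5, 8])
        assert spec[2] == 1.0

    def test_empty_phase_input_rejected(self):
        with pytest.raises(ValueError):
            mismatch_phase_spectrum([])
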