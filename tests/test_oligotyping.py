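import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_matrix
from oligodecomp.oligotyping import (
    EntropyProfile,
    OligotypeConfig,
    column_counts,
    decompose,
    entropy_profile,
    filter_noise,
    nearest_reference,
    oligotype_table,
    refine,
    select_components,
    shannon_entropy,
)
from oligodecomp.seqio import SampleMap
from oligodecomp.taxonomy import Reference


class TestColumnCounts:
    def test_monomorphic(self):
        counts, n = column_counts(make_matrix(["A"] * 10), 0)
        assert counts == {"A": 10} and n == 0

    def test_biallelic(self):
        counts, _ = column_counts(make_matrix(["A"] * 6 + ["C"] * 4), 0)
        assert counts == {"A": 6, "C": 4}

    def test_n_tallied_separately(self):
        counts, n = column_counts(make_matrix(["A"] * 9 + ["N"]), 0)
        assert counts == {"A": 9} and n == 1

    def test_out_of_range_raises(self):
        with pytest.raises(IndexError):
            column_counts(make_matrix(["ACGT"]), 4)


class TestShannonEntropy:
    def test_monomorphic_is_zero(self):
        assert shannon_entropy({"A": 10}) == 0.0

    def test_balanced_biallelic_is_one_bit(self):
        assert shannon_entropy({"A": 5, "C": 5}) == pytest.approx(1.0)

    def test_97_1_1_1_composition(self):
        # direct formula evaluation: -0.97 lg 0.97 - 3 * 0.01 lg 0.01
        assert shannon_entropy({"A": 97, "C": 1, "G": 1, "T": 1}) == pytest.approx(
            0.2419, abs=1e-4
        )

    def test_uniform_four_way_is_two_bits(self):
        assert shannon_entropy({"A": 1, "C": 1, "G": 1, "T": 1}) == pytest.approx(2.0)

    def test_all_n_column_defined_as_zero(self):
        assert shannon_entropy({}) == 0.0

    @given(
        st.lists(st.integers(min_value=0, max_value=1000), min_size=1, max_size=4).filter(
            lambda c: sum(c) > 0
        )
    )
    @settings(derandomize=True, max_examples=80)
    def test_bounds_and_monomorphic_iff_zero(self, counts):
        composition = {base: c for base, c in zip("ACGT", counts)}
        h = shannon_entropy(composition)
        assert -1e-12 <= h <= 2 + 1e-12
        n_polymorphic = sum(1 for c in composition.values() if c > 0)
        assert (h < 1e-12) == (n_polymorphic <= 1)


class TestEntropyProfile:
    def test_identical_reads_all_zero(self):
        profile = entropy_profile(make_matrix(["ACGT"] * 20))
        assert np.all(profile.values == 0.0)

    def test_two_haplotypes_spike_at_variant_position(self):
        a = "A" * 50 + "A" + "A" * 49  # length 100
        b = "A" * 50 + "C" + "A" * 49
        profile = entropy_profile(make_matrix([a] * 10 + [b] * 10))
        assert profile.values[50] == pytest.approx(1.0)
        others = np.delete(profile.values, 50)
        assert np.all(others == 0.0)

    def test_noise_stays_under_threshold_with_true_variant_above(self):
        """At 1 % i.i.d. substitution error and depth 10 000, exactly the
        true 50/50 variant column exceeds 0.2 bits."""
        rng = np.random.default_rng(5)
        depth, length, variant_pos = 10_000, 60, 30
        codes = np.zeros((depth, length), dtype=np.uint8)
        codes[: depth // 2, variant_pos] = 1
        mask = rng.random(codes.shape) < 0.01
        codes[mask] = (codes[mask] + rng.integers(1, 4, size=int(mask.sum()))) % 4
        from oligodecomp.preprocess import PositionalMatrix, decode_residues

        matrix = PositionalMatrix(
            codes, [f"r{i}" for i in range(depth)], ["s1"] * depth
        )
        profile = entropy_profile(matrix)
        above = np.flatnonzero(profile.values > 0.2)
        assert list(above) == [variant_pos]

    def test_empty_matrix_raises(self):
        from oligodecomp.preprocess import PositionalMatrix

        empty = PositionalMatrix(np.empty((0, 5), dtype=np.uint8), [], [])
        with pytest.raises(ValueError):
            entropy_profile(empty)


class TestSelectComponents:
    def test_entropy_ordered_above_threshold(self):
        profile = EntropyProfile(np.array([0.0, 0.95, 0.1, 0.3]))
        assert select_components(profile, OligotypeConfig()) == [1, 3]

    def test_all_zero_profile_selects_nothing(self):
        profile = EntropyProfile(np.zeros(10))
        assert select_components(profile, OligotypeConfig()) == []

    def test_zero_threshold_selects_all_positive_entropy_ordered(self):
        profile = EntropyProfile(np.array([0.2, 0.9, 0.5]))
        config = OligotypeConfig(entropy_threshold=0.0)
        assert select_components(profile, config) == [1, 2, 0]

    def test_position_order_option(self):
        profile = EntropyProfile(np.array([0.3, 0.9, 0.5]))
        config = OligotypeConfig(entropy_threshold=0.2, component_order="position_asc")
        assert select_components(profile, config) == [0, 1, 2]

    def test_max_components_truncates(self):
        profile = EntropyProfile(np.array([0.3, 0.9, 0.5]))
        config = OligotypeConfig(max_components=1)
        assert select_components(profile, config) == [1]

    def test_ties_broken_by_ascending_position(self):
        profile = EntropyProfile(np.array([0.5, 0.9, 0.5]))
        assert select_components(profile, OligotypeConfig()) == [1, 0, 2]

    def test_matches_brute_force_on_random_profiles(self):
        rng = np.random.default_rng(31)
        config = OligotypeConfig(entropy_threshold=0.2)
        for _ in range(30):
            values = rng.uniform(0, 1.2, size=20).round(3)
            expected = [
                p
                for p, h in sorted(
                    enumerate(values), key=lambda t: (-t[1], t[0])
                )
                if h > 0.2
            ]
            got = select_components(EntropyProfile(values), config)
            assert got == expected


class TestDecompose:
    def test_single_position_partition(self):
        seqs = ["AAA"] * 60 + ["ACA"] * 40
        groups, n_bucket = decompose(make_matrix(seqs), [1])
        assert [(g.label, g.total_count) for g in groups] == [("A", 60), ("C", 40)]
        assert n_bucket == []

    def test_label_built_in_component_order(self):
        seq = "CCCCCACCCG"
        groups, _ = decompose(make_matrix([seq]), [5, 9])
        assert groups[0].label == "AG"

    def test_read_with_n_goes_to_bucket(self):
        groups, n_bucket = decompose(make_matrix(["AAA", "ANA"]), [1])
        assert [(g.label, g.total_count) for g in groups] == [("A", 1)]
        assert len(n_bucket) == 1

    def test_empty_components_raise(self):
        with pytest.raises(ValueError, match="select_components"):
            decompose(make_matrix(["AAA"]), [])

    def test_groups_partition_all_reads(self):
        rng = np.random.default_rng(41)
        seqs = ["".join(rng.choice(list("ACGTN"), p=[0.24] * 4 + [0.04], size=8)) for _ in range(50)]
        matrix = make_matrix(seqs)
        groups, n_bucket = decompose(matrix, [2, 5])
        ids = [rid for g in groups for rid in g.read_ids] + list(n_bucket)
        assert sorted(ids) == sorted(matrix.read_ids)

    def test_matches_brute_force_partition(self):
        rng = np.random.default_rng(43)
        for _ in range(10):
            n = int(rng.integers(2, 21))
            length = int(rng.integers(5, 31))
            seqs = ["".join(rng.choice(list("ACGT"), size=length)) for _ in range(n)]
            components = sorted(
                rng.choice(length, size=int(rng.integers(1, 4)), replace=False).tolist()
            )
            expected: dict[str, int] = {}
            for s in seqs:
                label = "".join(s[c] for c in components)
                expected[label] = expected.get(label, 0) + 1
            groups, n_bucket = decompose(make_matrix(seqs), components)
            assert {g.label: g.total_count for g in groups} == expected
            assert n_bucket == []


class TestFilterNoise:
    config = OligotypeConfig(min_oligotype_count=10, min_oligotype_fraction=0.001)

    def groups_of(self, counts):
        seqs = []
        for i, c in enumerate(counts):
            seqs.extend(["ACGT"[i] + "AAA"] * c)
        groups, _ = decompose(make_matrix(seqs), [0])
        return groups

    def test_threshold_arithmetic(self):
        groups = self.groups_of([990, 7, 3])
        kept, noise = filter_noise(groups, self.config, 1000)
        assert [g.total_count for g in kept] == [990]
        assert sorted(g.total_count for g in noise) == [3, 7]

    def test_single_group_always_kept(self):
        # a lone group holds every read of the taxon; it is kept even when
        # its count sits below the abundance floor
        groups = self.groups_of([5])
        kept, noise = filter_noise(groups, self.config, 5)
        assert len(kept) == 1 and not noise

    def test_exactly_at_floor_kept(self):
        groups = self.groups_of([10, 990])
        kept, _ = filter_noise(groups, self.config, 1000)
        assert {g.total_count for g in kept} == {10, 990}

    def test_fraction_floor_dominates_at_scale(self):
        config = OligotypeConfig(min_oligotype_count=10, min_oligotype_fraction=0.01)
        groups = self.groups_of([50, 950])
        kept, noise = filter_noise(groups, config, 10_000)  # floor = 100
        assert [g.total_count for g in kept] == [950]
        assert [g.total_count for g in noise] == [50]

    def test_counts_conserved(self):
        groups = self.groups_of([500, 30, 7])
        kept, noise = filter_noise(groups, self.config, 537)
        assert sum(g.total_count for g in kept) + sum(g.total_count for g in noise) == 537

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(47)
        for _ in range(20):
            counts = rng.integers(1, 200, size=int(rng.integers(2, 5))).tolist()
            groups = self.groups_of(counts)
            total = sum(g.total_count for g in groups)
            floor = max(10, 0.001 * total)
            kept, noise = filter_noise(groups, self.config, total)
            assert {g.label for g in kept} == {
                g.label for g in groups if g.total_count >= floor
            }


class TestRefine:
    def test_noiseless_two_haplotypes_converges_first_pass(self):
        a = "AAAAAAAAAA"
        b = "AAAAACAAAA"
        matrix = make_matrix([a] * 60 + [b] * 40)
        result = refine(matrix, OligotypeConfig())
        assert result.components == (5,)
        assert [(g.label, g.total_count) for g in result.kept] == [("A", 60), ("C", 40)]
        assert result.iterations <= 2  # second pass only verifies stability

    def test_monomorphic_matrix_yields_trivial_group(self):
        matrix = make_matrix(["ACGT"] * 50)
        result = refine(matrix, OligotypeConfig())
        assert result.components == ()
        assert len(result.kept) == 1
        assert result.kept[0].total_count == 50
        assert result.iterations == 1

    def test_nested_variation_needs_two_iterations(self):
        """Three haplotypes with nested variants: position 1 splits A/C, and
        only within the 'A' branch does position 7 segregate G/T. The
        second variant is invisible in the whole-matrix profile (minor
        fraction 2.5 %, entropy 0.17 bits) and is only found by re-profiling
        the 'A' group; hand-enumerated final partition has 3 groups."""
        hap_ag = "TATTTTTGTT"
        hap_at = "TATTTTTTTT"
        hap_cg = "TCTTTTTGTT"
        matrix = make_matrix([hap_ag] * 50 + [hap_at] * 50 + [hap_cg] * 1900)
        config = OligotypeConfig(min_oligotype_count=10)
        whole = entropy_profile(matrix)
        assert whole.values[7] < 0.2 < whole.values[1]  # setup sanity
        result = refine(matrix, config)
        assert set(result.components) == {1, 7}
        # components are label-ordered by descending entropy, so the promoted
        # within-group position (1 bit) precedes the original one (0.29 bits)
        assert result.components == (7, 1)
        assert {(g.label, g.total_count) for g in result.kept} == {
            ("GA", 50), ("TA", 50), ("GC", 1900),
        }
        assert result.iterations == 2

    def test_refinement_skips_splits_below_abundance_floor(self):
        """A handful of coincident errors inside a kept group can push a
        column over 0.2 bits, but a split that cannot reach the abundance
        floor does not improve resolution and must not be promoted."""
        clean = "GGGGGGGGGG"
        errored = "GGGGGGGGAG"  # 5 reads sharing an error column
        other = "GCGGGGGGGG"
        matrix = make_matrix([clean] * 95 + [errored] * 5 + [other] * 100)
        config = OligotypeConfig(min_oligotype_count=10)
        result = refine(matrix, config)
        assert result.components == (1,)
        assert {g.label for g in result.kept} == {"G", "C"}

    def test_determinism(self):
        rng = np.random.default_rng(53)
        seqs = ["".join(rng.choice(list("ACGT"), size=12)) for _ in range(40)] * 3
        a = refine(make_matrix(seqs), OligotypeConfig(min_oligotype_count=2))
        b = refine(make_matrix(seqs), OligotypeConfig(min_oligotype_count=2))
        assert a == b


class TestOligotypeTable:
    smap = SampleMap.from_records(
        [("s1", "dirty_ice", "site_1"), ("s2", "clean_ice", "site_2")]
    )

    def test_single_group_all_ones(self):
        matrix = make_matrix(["AAA"] * 4, samples=["s1", "s1", "s2", "s2"])
        groups, _ = decompose(matrix, [0])
        table = oligotype_table(groups, self.smap)
        assert (table["A"] == 1.0).all()

    def test_rows_sum_to_one(self):
        matrix = make_matrix(
            ["AAA"] * 3 + ["CAA"] * 1, samples=["s1", "s1", "s2", "s2"]
        )
        groups, _ = decompose(matrix, [0])
        table = oligotype_table(groups, self.smap)
        assert table.sum(axis=1).tolist() == pytest.approx([1.0, 1.0])
        assert table.loc["s2", "A"] == pytest.approx(0.5)

    def test_empty_sample_row_is_zero(self):
        matrix = make_matrix(["AAA"] * 3, samples=["s1"] * 3)
        groups, _ = decompose(matrix, [0])
        table = oligotype_table(groups, self.smap)
        assert table.loc["s2"].sum() == 0.0

    def test_unknown_sample_raises(self):
        matrix = make_matrix(["AAA"], samples=["mystery"])
        groups, _ = decompose(matrix, [0])
        with pytest.raises(KeyError):
            oligotype_table(groups, self.smap)


class TestNearestReference:
    BASE = "ACGT" * 80

    def mutate(self, positions):
        swap = {"A": "C", "C": "G", "G": "T", "T": "A"}
        out = list(self.BASE)
        for p in positions:
            out[p] = swap[out[p]]
        return "".join(out)

    refs = property(
        lambda self: [
            Reference("R1", "taxon one", self.BASE),
            Reference("R2", "taxon two", self.mutate(list(range(0, 64, 4)))),
        ]
    )

    def test_exact_hit_100_percent(self):
        ref_id, identity = nearest_reference(self.BASE, self.refs)
        assert ref_id == "R1" and identity == 1.0

    def test_one_mismatch_99_7(self):
        _, identity = nearest_reference(self.mutate([7]), self.refs)
        assert round(identity * 100, 1) == 99.7

    def test_two_mismatches_99_4(self):
        _, identity = nearest_reference(self.mutate([7, 100]), self.refs)
        assert round(identity * 100, 1) == 99.4

    def test_empty_references_raise(self):
        with pytest.raises(ValueError):
            nearest_reference(self.BASE, [])
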