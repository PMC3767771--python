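import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import sicore as sc
from oracles import dp_edit_distance

seed_strings = st.text(alphabet="ACGU", min_size=0, max_size=12)


class TestExtractSeed:
    def test_positions_two_to_seven(self):
        assert sc.extract_seed("UGAGGUAGUAGGUU") == "GAGGUA"

    @given(st.text(alphabet="ACGU", min_size=7, max_size=25))
    def test_output_length_is_six(self, seq):
        assert len(sc.extract_seed(seq)) == 6

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sc.extract_seed("ACGU")

    def test_invalid_character_rejected(self):
        with pytest.raises(ValueError):
            sc.extract_seed("ACGUXAC")

    def test_dna_converted_with_warning(self):
        with pytest.warns(UserWarning, match="DNA"):
            assert sc.extract_seed("TGAGGTAGTAGGTT") == "GAGGUA"


class TestEditDistance:
    @pytest.mark.parametrize("s1,s2,expected", [
        ("GAGGUA", "GAGGUA", 0),
        ("AAAAAA", "AAAAAC", 1),
        ("GAGGUA", "AGGUAG", 2),
        ("", "ACG", 3),
    ])
    def test_known_distances(self, s1, s2, expected):
        assert sc.edit_distance(s1, s2) == expected

    @given(seed_strings, seed_strings)
    def test_matches_dynamic_programming_oracle(self, s1, s2):
        assert sc.edit_distance(s1, s2) == dp_edit_distance(s1, s2)

    @given(seed_strings, seed_strings, seed_strings)
    def test_is_a_metric(self, a, b, c):
        assert sc.edit_distance(a, b) == sc.edit_distance(b, a)
        assert (sc.edit_distance(a, b) == 0) == (a == b)
        assert sc.edit_distance(a, c) <= \
            sc.edit_distance(a, b) + sc.edit_distance(b, c)


class TestGroupSimilarity:
    def test_identical_seeds(self):
        assert sc.group_similarity(["GAGGUA", "GAGGUA", "GAGGUA"]) == 0.0

    def test_single_pair(self):
        assert sc.group_similarity(["AAAAAA", "AAACCC"]) == 3.0

    def test_mean_over_pairs(self):
        # pairwise distances 1, 2, 3
        seeds = ["AAAAAA", "AAAAAC", "AAACCC"]
        d = [sc.edit_distance(a, b) for a, b in itertools.combinations(seeds, 2)]
        assert sc.group_similarity(seeds) == pytest.approx(sum(d) / 3)

    def test_singleton_rejected(self):
        with pytest.raises(ValueError):
            sc.group_similarity(["GAGGUA"])


def record(i, seed6):
    # prepend a base so that positions 2-7 of the mature sequence are seed6
    return sc.SeedRecord(f"mir-{i}", "U" + seed6)


class TestPermutationTest:
    def test_uniform_universe_gives_p_one(self):
        universe = [record(i, "GAGGUA") for i in range(5)]
        df = sc.permutation_test_similarity(
            {"g": ["mir-0", "mir-1"]}, universe, n_perm=200, seed=0)
        assert df["p_value"].iloc[0] == 1.0

    def test_group_equal_to_universe_gives_p_one(self):
        seqs = ["GAGGUA", "CCCUGA", "AGCAGC", "GGCAGU"]
        universe = [record(i, s) for i, s in enumerate(seqs)]
        df = sc.permutation_test_similarity(
            {"g": [r.mirna_id for r in universe]}, universe,
            n_perm=100, seed=1)
        assert df["p_value"].iloc[0] == 1.0

    def test_matches_exhaustive_subset_enumeration(self):
        seqs = ["AAAAAA", "AAAAAC", "CCGGUU", "GGUUCC", "UUUGGG"]
        universe = [record(i, s) for i, s in enumerate(seqs)]
        observed = sc.edit_distance("AAAAAA", "AAAAAC")  # the minimal pair
        exact = np.mean([
            float(sc.group_similarity([seqs[i], seqs[j]]) <= observed)
            for i, j in itertools.combinations(range(5), 2)])
        n_perm = 4000
        df = sc.permutation_test_similarity(
            {"g": ["mir-0", "mir-1"]}, universe, n_perm=n_perm, seed=2)
        p = df["p_value"].iloc[0]
        se = math.sqrt(exact * (1 - exact) / n_perm)
        # add-one smoothing shifts the estimate by at most 1/(n_perm+1)
        assert abs(p - exact) <= 3 * se + 1 / (n_perm + 1)

    def test_smaller_similarity_gives_no_larger_p(self):
        rng_seqs = ["AACCGG", "AACCGU", "GGUUAA", "CCAAUU", "UUGGCC",
                    "AGAGAG", "UCUCUC"]
        universe = [record(i, s) for i, s in enumerate(rng_seqs)]
        df = sc.permutation_test_similarity(
            {"tight": ["mir-0", "mir-1"],      # distance 1
             "loose": ["mir-2", "mir-5"]},     # larger distance
            universe, n_perm=2000, seed=3)
        tight = df.set_index("group").loc["tight"]
        loose = df.set_index("group").loc["loose"]
        assert tight["observed_similarity"] < loose["observed_similarity"]
        assert tight["p_value"] <= loose["p_value"]

    def test_group_outside_universe_rejected(self):
        universe = [record(0, "GAGGUA")]
        with pytest.raises(ValueError):
            sc.permutation_test_similarity({"g": ["mir-0", "ghost"]},
                                           universe, n_perm=10, seed=0)


class TestHypergeometric:
    def test_zero_overlap_gives_p_one(self):
        assert sc.hypergeom_upper_tail(0, 10, 3, 4) == 1.0

    def test_combinatorial_example(self):
        # [C(3,2)C(7,2) + C(3,3)C(7,1)] / C(10,4) = 70/210 = 1/3
        assert sc.hypergeom_upper_tail(2, 10, 3, 4) == pytest.approx(1 / 3,
                                                                     abs=1e-12)

    def test_group_equal_to_population_gives_p_one(self):
        pop = [f"m{i}" for i in range(6)]
        fam = pop[:2]
        assert sc.family_enrichment(pop, fam, pop) == pytest.approx(1.0)

    def test_pmf_sums_to_one_over_support(self):
        N, K, n = 12, 5, 6
        lo, hi = max(0, n + K - N), min(n, K)
        total = sum(
            math.comb(K, k) * math.comb(N - K, n - k) / math.comb(N, n)
            for k in range(lo, hi + 1))
        assert total == pytest.approx(1.0)
        assert sc.hypergeom_upper_tail(lo, N, K, n) == pytest.approx(1.0)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            sc.hypergeom_upper_tail(5, 10, 3, 4)
        with pytest.raises(ValueError):
            sc.hypergeom_upper_tail(1, 5, 6, 2)

    def test_enrich_groups_table(self):
        families = {"m1": "let-7", "m2": "let-7", "m3": "mir-99", "m4": "let-7"}
        pop = ["m1", "m2", "m3", "m4", "m5", "m6"]
        df = sc.enrich_groups({"g1": ["m1", "m2", "m5"]}, families, pop)
        row = df.set_index(["group", "family"]).loc[("g1", "let-7")]
        assert row["family_in_group"] == 2
        assert row["p_value"] == pytest.approx(
            sc.hypergeom_upper_tail(2, 6, 3, 3))


def test_read_seed_records_tsv_and_fasta(tmp_path):
    tsv = tmp_path / "seeds.tsv"
    tsv.write_text("id\tsequence\nmir-a\tUGAGGUAGUA\nmir-b\tUCCCUGAGAC\n")
    fasta = tmp_path / "seeds.fasta"
    fasta.write_text(">mir-a\nUGAGGUAGUA\n>mir-b\nUCCCUGAGAC\n")
    from_tsv = sc.read_seed_records(tsv)
    from_fasta = sc.read_seed_records(fasta)
    assert [(r.mirna_id, r.seed) for r in from_tsv] == \
        [(r.mirna_id, r.seed) for r in from_fasta]
    assert from_tsv[0].seed == "GAGGUA"
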