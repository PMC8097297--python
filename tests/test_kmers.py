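"""Unit and property tests for 8-mer indexing and E/Z statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pbmspec import (DesignSpec, IntensityTable, KmerClass, ProbeSet,
                     compute_escore, compute_kmer_table, enriched_kmers,
                     generate_probe_set, index_kmers, revcomp)
from pbmspec._dna import canonical_kmer_strings, canonicalize

from conftest import brute_force_escore, random_intensities


class TestKmerClasses:
    def test_canonical_class_enumeration_by_independent_count(self):
        """Collapsing all 4^8 8-mers by reverse complement leaves
        (65536 - 256)/2 + 256 classes; check against direct enumeration."""
        seen = set()
        n_palindromes = 0
        for kmer in itertools.product("ACGT", repeat=8):
            kmer = "".join(kmer)
            rc = revcomp(kmer)
            if kmer == rc:
                n_palindromes += 1
            seen.add(min(kmer, rc))
        assert n_palindromes == 256
        assert len(seen) == 32896
        assert seen == set(canonical_kmer_strings(8))

    def test_palindromic_kmer_is_single_self_class(self):
        k = KmerClass("ACGTACGT")
        assert k.is_palindrome
        assert KmerClass(revcomp("ACGTACGT")).canonical == k.canonical

    def test_canonicalize_picks_lexicographic_minimum(self):
        assert canonicalize("TTTTTTTT") == "AAAAAAAA"
        assert KmerClass("TTTTTTTT").canonical == "AAAAAAAA"


class TestIndexKmers:
    def test_membership_counts_either_strand_once(self):
        probes = ProbeSet("T", ["p1", "p2", "p3"],
                          ["ACGGCGGA" + "T" * 27,
                           revcomp("ACGGCGGA" + "T" * 27),
                           "G" * 35])
        idx = index_kmers(probes)
        cls = canonicalize("ACGGCGGA")
        assert idx[cls] == {"p1", "p2"}

    def test_multiple_occurrences_count_once(self):
        probes = ProbeSet("T", ["p1"], ["ACGTACGTCC" + "ACGTACGT" + "G" * 17])
        idx = index_kmers(probes)
        assert idx[canonicalize("ACGTACGT")] == {"p1"}

    def test_k_larger_than_probe_errors(self, small_probe_set):
        with pytest.raises(ValueError):
            index_kmers(small_probe_set, k=36)

    def test_index_invariant_under_reverse_complement(self, small_probe_set):
        rc_probes = ProbeSet(small_probe_set.design_id, small_probe_set.ids,
                             [revcomp(s) for s in small_probe_set.sequences])
        assert index_kmers(small_probe_set) == index_kmers(rc_probes)


class TestComputeEscore:
    def test_complete_separation_is_maximal(self):
        vals = {f"p{i}": 100.0 - i for i in range(10)}
        fg = {f"p{i}" for i in range(4)}
        assert compute_escore(vals, fg, set(vals) - fg) == pytest.approx(0.5)

    def test_interleaved_example_scores_zero(self):
        """fg at ranks {1,4,6,8} of 8: fg'={1,4}, bg'={2,3}, U=2/4 -> E=0.
        Frozen from the brute-force oracle."""
        vals = dict(zip("abcdefgh", [8.0, 7.0, 6.0, 5.0, 4.0, 3.0, 2.0, 1.0]))
        fg, bg = set("adfh"), set("bceg")
        assert brute_force_escore(vals, fg, bg) == 0.0
        assert compute_escore(vals, fg, bg) == 0.0

    def test_empty_side_gives_missing(self):
        assert math.isnan(compute_escore({"a": 1.0}, {"a"}, set()))

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError):
            compute_escore({"a": 1.0, "b": 2.0}, {"a"}, {"a", "b"})

    @given(st.data())
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_brute_force_on_random_configs(self, data):
        n = data.draw(st.integers(2, 12))
        values = {f"p{i:02d}": data.draw(st.integers(0, 6)) * 1.0
                  for i in range(n)}
        k = data.draw(st.integers(1, n - 1))
        fg = {f"p{i:02d}" for i in data.draw(
            st.sets(st.integers(0, n - 1), min_size=k, max_size=k))}
        bg = set(values) - fg
        got = compute_escore(values, fg, bg)
        assert got == pytest.approx(brute_force_escore(values, fg, bg), abs=1e-12)
        assert -0.5 <= got <= 0.5

    def test_invariant_under_monotone_transform(self, rng):
        vals = {f"p{i}": float(v) for i, v in enumerate(rng.lognormal(0, 1, 30))}
        fg = set(list(vals)[:11])
        bg = set(vals) - fg
        base = compute_escore(vals, fg, bg)
        for f in (np.exp, lambda x: x**3, lambda x: 5 * x + 2):
            transformed = {k: float(f(v)) for k, v in vals.items()}
            assert compute_escore(transformed, fg, bg) == pytest.approx(base)


class TestComputeKmerTable:
    @pytest.fixture(scope="class")
    def table_and_inputs(self, small_probe_set):
        rng = np.random.default_rng(5)
        intens = random_intensities(small_probe_set, rng)
        table = compute_kmer_table(small_probe_set, intens, min_fg=1)
        return small_probe_set, intens, table

    def test_fast_path_matches_definitional_escore(self, table_and_inputs):
        probes, intens, table = table_and_inputs
        idx = index_kmers(probes)
        all_ids = set(probes.ids)
        picked = sorted(idx)[::211]
        for kmer in picked:
            expected = compute_escore(intens.values, idx[kmer], all_ids - idx[kmer])
            assert table.df.loc[kmer, "E"] == pytest.approx(expected, abs=1e-12)

    def test_tied_intensities_fall_back_to_exact_path(self, small_probe_set):
        rng = np.random.default_rng(6)
        vals = rng.integers(1, 15, size=len(small_probe_set)).astype(float)
        intens = IntensityTable("tied", "SM",
                                pd.Series(vals, index=small_probe_set.ids))
        table = compute_kmer_table(small_probe_set, intens, min_fg=1)
        idx = index_kmers(small_probe_set)
        all_ids = set(small_probe_set.ids)
        for kmer in sorted(idx)[::997]:
            expected = brute_force_escore(intens.values, idx[kmer],
                                          all_ids - idx[kmer])
            assert table.df.loc[kmer, "E"] == pytest.approx(expected, abs=1e-12)

    def test_strand_symmetry_of_full_table(self, small_probe_set):
        rng = np.random.default_rng(7)
        intens = random_intensities(small_probe_set, rng)
        rc_probes = ProbeSet(small_probe_set.design_id, small_probe_set.ids,
                             [revcomp(s) for s in small_probe_set.sequences])
        t1 = compute_kmer_table(small_probe_set, intens, min_fg=1)
        t2 = compute_kmer_table(rc_probes, intens, min_fg=1)
        pd.testing.assert_frame_equal(t1.df, t2.df)

    def test_low_support_classes_flagged_missing_not_zero(self, small_probe_set):
        rng = np.random.default_rng(8)
        intens = random_intensities(small_probe_set, rng)
        table = compute_kmer_table(small_probe_set, intens, min_fg=3)
        df = table.df
        low = df["n_fg_probes"] < 3
        assert low.any()
        assert df.loc[low, "E"].isna().all()
        assert (df.index.size == 32896)

    def test_max_median_class_has_max_z(self, table_and_inputs):
        _, _, table = table_and_inputs
        df = table.df.dropna(subset=["Z"])
        assert df["Z"].idxmax() == df["median_intensity"].idxmax()


class TestEnrichedKmers:
    def make_table(self, e_by_kmer):
        strings = canonical_kmer_strings(8)
        df = pd.DataFrame({"E": np.nan, "Z": np.nan,
                           "median_intensity": 1.0, "n_fg_probes": 20},
                          index=pd.Index(strings, name="canonical_8mer"))
        for k, e in e_by_kmer.items():
            df.loc[k, "E"] = e
        from pbmspec import KmerStatTable
        return KmerStatTable("t", "d", df)

    def test_threshold_is_inclusive_and_missing_excluded(self):
        t = self.make_table({"AAAAAAAA": 0.45, "AAAAAAAC": 0.449,
                             "AAAAAAAG": 0.5})
        assert enriched_kmers(t) == {"AAAAAAAA", "AAAAAAAG"}

    def test_lower_bound_threshold_returns_all_non_missing(self):
        t = self.make_table({"AAAAAAAA": -0.2, "AAAAAAAC": 0.0})
        assert enriched_kmers(t, threshold=-0.5) == {"AAAAAAAA", "AAAAAAAC"}

    def test_all_zero_table_yields_empty_set(self):
        t = self.make_table({"AAAAAAAA": 0.0, "AAAAAAAC": 0.0})
        assert enriched_kmers(t) == set()
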