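"""Cleavage-site recognition and partial pepsin digestion enumeration."""

import math
import re
from itertools import combinations

import numpy as np
import pytest

from milkamp.digestion import (
    CleavageSiteSet,
    RuleConfigError,
    digest_protein,
    enumerate_fragments,
    expected_fragment_count,
    filter_length,
    find_sites,
    load_rules,
    pepsin_boundaries,
)

from conftest import RESIDUES, random_sequence

# Curated short peptides with hand-derived cleavage calls (bond i = bond
# after residue i). Covers the trypsin KP veto and Keil veto contexts, the
# WKP/MRP overrides, enterokinase's acidic-run rule, both thrombin contexts,
# pepsin P1/P1' cases and the chymotrypsin variants.
HAND_DERIVED_CALLS = [
    ("AKA", "T", [2]),
    ("AKPA", "T", []),           # K before P: vetoed
    ("AWKPA", "T", [3]),         # WKP override
    ("AMRPA", "T", [3]),         # MRP override
    ("ACKDA", "T", []),          # CKD veto
    ("ADKDA", "T", []),          # DKD veto
    ("ACKHA", "T", []),          # CKH veto
    ("ACKYA", "T", []),          # CKY veto
    ("ACRKA", "T", [4]),         # CRK veto on bond 3; K4 still cleaved
    ("ARRHA", "T", [2]),         # RRH veto on bond 3 only
    ("ARRRA", "T", [2, 4]),      # RRR veto silences the middle bond only
    ("AKXA", "T", []),           # ambiguity letter at P1' blocks the call
    ("AAADDDDKGGG", "E", [8]),   # ...DDDK| with acidic P2-P4
    ("ADDEKA", "E", [5]),
    ("ADDKA", "E", []),          # only two acidic residues before K
    ("AGRGA", "Th", [3]),        # G-R|G context
    ("AARGA", "Th", []),
    ("AAPRAA", "Th", [4]),       # P4-P3-P-R| context, non-acidic P1'/P2'
    ("AAPRDA", "Th", []),        # acidic P1' blocks
    ("GVPRGS", "Th", [4]),       # classical thrombin site
    ("AALAA", "Pa", [2, 3]),     # cleavage on both sides of L
    ("AFAA", "Pa", [1, 2]),
    ("LAAA", "Pa", [1]),
    ("AAAL", "Pa", [3]),
    ("AWAA", "Pa", []),          # W is a pH>2 residue only
    ("AWAA", "Pb", [1, 2]),
    ("AFAA", "CT", [2]),
    ("AFPA", "CT", []),          # P veto
    ("AWMA", "CT", [3]),         # W before M vetoed; M3 cleaved (low spec)
    ("AWAA", "CT", [2]),
    ("ALAA", "CT", [2]),         # low-specificity default cleaves after L
    ("AHAA", "CT", [2]),         # ... and after H
    ("AMYA", "CT", [3]),         # M before Y vetoed; Y3 cleaved
]


class TestFindSites:
    @pytest.mark.parametrize("seq,enzyme,expected", HAND_DERIVED_CALLS)
    def test_hand_derived_calls(self, rules, seq, enzyme, expected):
        assert list(find_sites(seq, rules[enzyme]).positions) == expected

    def test_high_specificity_chymotrypsin_variant(self, rules_ct_high):
        assert list(find_sites("ALAA", rules_ct_high["CT"]).positions) == []
        assert list(find_sites("AFAA", rules_ct_high["CT"]).positions) == [2]
        assert list(find_sites("AWMA", rules_ct_high["CT"]).positions) == []

    def test_unknown_chymotrypsin_variant_rejected(self):
        with pytest.raises(RuleConfigError):
            load_rules(chymotrypsin="medium")

    def test_position_locality(self, rules, rng):
        # inserting residues >= 5 positions away never changes a bond's call
        for _ in range(30):
            seq = random_sequence(rng, 30)
            bond = 15
            for enzyme in ("Pa", "Pb", "T", "CT", "E", "Th"):
                before = rules[enzyme].bond_cleaved(seq, bond)
                mutated = seq[:25] + random_sequence(rng, 5) + seq[30:]
                assert rules[enzyme].bond_cleaved(mutated, bond) == before

    def test_determinism(self, rules, rng):
        seq = random_sequence(rng, 100)
        for enzyme, rule in rules.items():
            assert find_sites(seq, rule) == find_sites(seq, rule)


class TestExpasyRegexCrossCheck:
    """Independent oracle: pyteomics' ExPASy regexes, where dialects coincide."""

    @staticmethod
    def _regex_sites(seq, pattern):
        return {m.end() for m in re.finditer(pattern, seq) if m.end() < len(seq)}

    @pytest.mark.parametrize(
        "enzyme,key",
        [("CT", "chymotrypsin low specificity"), ("E", "enterokinase")],
    )
    def test_enzymes_match_expasy_regex(self, rules, enzyme, key, rng):
        from pyteomics.parser import expasy_rules

        for _ in range(200):
            seq = random_sequence(rng, 40)
            got = set(find_sites(seq, rules[enzyme]).positions)
            assert got == self._regex_sites(seq, expasy_rules[key])

    def test_chymotrypsin_high_matches_expasy_regex(self, rules_ct_high, rng):
        from pyteomics.parser import expasy_rules

        for _ in range(200):
            seq = random_sequence(rng, 40)
            got = set(find_sites(seq, rules_ct_high["CT"]).positions)
            assert got == self._regex_sites(
                seq, expasy_rules["chymotrypsin high specificity"]
            )

    def test_trypsin_matches_expasy_regex_minus_exceptions(self, rules, rng):
        from pyteomics.parser import expasy_rules

        for _ in range(200):
            seq = random_sequence(rng, 40)
            expected = self._regex_sites(
                seq, expasy_rules["trypsin"]
            ) - self._regex_sites(seq, expasy_rules["trypsin_exception"])
            assert set(find_sites(seq, rules["T"]).positions) == expected

    def test_thrombin_matches_expasy_regex_with_full_context(self, rules, rng):
        from pyteomics.parser import expasy_rules

        for _ in range(200):
            seq = random_sequence(rng, 40)
            limit = len(seq) - 2  # regex requires P2' to exist
            got = {
                b for b in find_sites(seq, rules["Th"]).positions if b <= limit
            }
            expected = {
                b
                for b in self._regex_sites(seq, expasy_rules["thrombin"])
                if b <= limit
            }
            assert got == expected


class TestBoundariesAndFragments:
    def test_boundaries_basic(self):
        sites = CleavageSiteSet("p", "Pa", (2,))
        assert pepsin_boundaries("ACDE", sites) == [0, 2, 4]

    def test_boundaries_no_sites(self):
        assert pepsin_boundaries("A" * 9, CleavageSiteSet("p", "Pa", ())) == [0, 9]

    def test_boundaries_every_bond(self):
        L = 6
        sites = CleavageSiteSet("p", "Pa", tuple(range(1, L)))
        assert len(pepsin_boundaries("A" * L, sites)) == L + 1

    def test_single_site_two_fragments(self):
        frags = enumerate_fragments("MKCD", [0, 2, 4])
        assert {(f.start, f.end, f.sequence) for f in frags} == {
            (1, 2, "MK"),
            (3, 4, "CD"),
        }
        assert expected_fragment_count(1) == 2

    def test_no_sites_no_fragments(self):
        assert enumerate_fragments("MKCD", [0, 4]) == []
        assert expected_fragment_count(0) == 0

    def test_closed_form_for_all_site_counts(self):
        # C(N+2, 2) - 1 against actual enumeration for N = 0..50
        for n in range(0, 51):
            L = n + 10
            bounds = [0, *range(1, n + 1), L]
            frags = enumerate_fragments("A" * L, bounds)
            assert len(frags) == expected_fragment_count(n) == math.comb(n + 2, 2) - 1

    def test_subset_oracle_equivalence(self, rng):
        # fragments = union over all hydrolysed-site subsets of the contiguous
        # fragments each subset yields, minus the intact protein
        for _ in range(20):
            L = int(rng.integers(8, 30))
            n = int(rng.integers(0, min(8, L - 1)))
            sites = sorted(rng.choice(range(1, L), size=n, replace=False).tolist())
            seq = random_sequence(rng, L)
            got = {(f.start, f.end) for f in enumerate_fragments(seq, [0, *sites, L])}
            expected = set()
            for r in range(len(sites) + 1):
                for sub in combinations(sites, r):
                    bounds = [0, *sub, L]
                    for a, b in zip(bounds, bounds[1:]):
                        expected.add((a + 1, b))
            expected.discard((1, L))
            assert got == expected

    def test_adjacent_fragments_tile_parent(self, rng):
        seq = random_sequence(rng, 40)
        sites = [5, 17, 30]
        bounds = [0, *sites, 40]
        frags = enumerate_fragments(seq, bounds)
        adjacent = [
            f for f in frags if (f.start - 1, f.end) in zip(bounds, bounds[1:])
        ]
        assert "".join(f.sequence for f in sorted(adjacent, key=lambda f: f.start)) == seq

    def test_fragment_sequences_are_parent_substrings(self, rules, rng):
        seq = random_sequence(rng, 60)
        for f in digest_protein(seq, rules["Pa"], min_len=1, max_len=60):
            assert f.sequence == seq[f.start - 1 : f.end]
            assert not (f.start == 1 and f.end == len(seq))


class TestFilterLength:
    def test_inclusive_bracket(self):
        def frag(n):
            from milkamp.digestion import DigestPeptide
            return DigestPeptide("p", 1, n, "A" * n)
        lengths = [5, 12, 30, 47, 48, 50]
        kept = filter_length([frag(n) for n in lengths])
        assert [len(f) for f in kept] == [12, 30, 47]

    def test_bad_bounds_rejected(self):
        with pytest.raises(RuleConfigError):
            filter_length([], min_len=20, max_len=10)
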