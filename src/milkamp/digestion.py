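"""Protease cleavage-site recognition and partial pepsin digestion.

Cleavage rules are data, not code: the shipped table transcribes
PeptideCutter/SpirPep-style context conditions over the Schechter–Berger
positions P4…P4′ around each candidate peptide bond. A bond matches an enzyme
iff at least one of its pattern rows passes and none of its exception rows
does. Bond *i* is the peptide bond following residue *i* (1-based), so valid
bonds run 1 … L−1.

Enzymes:

========  ==============================================================
``Pa``    pepsin at pH < 1.8 (gastric) — cleaves N- or C-terminal to F/L
``Pb``    pepsin at pH > 2 — F/L/W/Y on either side of the bond
``T``     trypsin — after K/R, not before P, with the classical veto
          contexts (e.g. CKD, RRH) and the WKP/MRP overrides
``CT``    chymotrypsin — low- (default) or high-specificity variant
``E``     enterokinase — K preceded by three acidic residues
``Th``    thrombin — G-R↓G and the A/F/G/I/L/T/V/M-x-P-R↓ context
========  ==============================================================

Partial gastric digestion is modelled exhaustively: with ``N`` pepsin (pH<1.8)
sites plus the two termini there are C(N+2, 2) boundary pairs; every pair
except (start, end) yields one fragment, i.e. C(N+2, 2) − 1 peptides — every
fragment obtainable under *any* subset of hydrolysed sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

from .io import AMBIGUITY_RESIDUES

# offsets of P4..P1, P1'..P4' relative to bond index i (1-based residue pos)
_POSITIONS = ("p4", "p3", "p2", "p1", "p1p", "p2p", "p3p", "p4p")
_OFFSETS = {"p4": -3, "p3": -2, "p2": -1, "p1": 0, "p1p": 1, "p2p": 2, "p3p": 3, "p4p": 4}

CANONICAL_ENZYMES = ("Pa", "Pb", "T", "CT", "E", "Th")
INTESTINAL_ENZYMES = ("Pb", "CT", "E", "T", "Th")


class RuleConfigError(ValueError):
    """Unknown enzyme or malformed rule table."""


@dataclass(frozen=True)
class _Condition:
    offset: int
    residues: frozenset[str]
    negated: bool

    def ok(self, residue: str | None) -> bool:
        if self.negated:
            # a "must not be" condition is satisfied by a missing residue
            return residue is None or residue not in self.residues
        return residue is not None and residue in self.residues


@dataclass(frozen=True)
class CleavageRule:
    """One enzyme's pattern and exception context rows."""

    enzyme: str
    patterns: tuple[tuple[_Condition, ...], ...]
    exceptions: tuple[tuple[_Condition, ...], ...] = ()

    def bond_cleaved(self, sequence: str, bond: int) -> bool:
        """Is the bond after residue ``bond`` (1-based) cleaved?"""

        def ctx(offset: int) -> str | None:
            pos = bond + offset  # 1-based residue position
            if 1 <= pos <= len(sequence):
                return sequence[pos - 1]
            return None

        p1, p1p = ctx(0), ctx(1)
        if p1 in AMBIGUITY_RESIDUES or p1p in AMBIGUITY_RESIDUES:
            return False  # rules undefined: never call such a bond cleaved
        if not any(all(c.ok(ctx(c.offset)) for c in pat) for pat in self.patterns):
            return False
        return not any(all(c.ok(ctx(c.offset)) for c in exc) for exc in self.exceptions)


@dataclass(frozen=True)
class CleavageSiteSet:
    """Sorted cleavage bond indices for one enzyme on one parent sequence."""

    parent_id: str
    enzyme: str
    positions: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class DigestPeptide:
    """A digestion fragment; 1-based inclusive coordinates on the parent."""

    parent_id: str
    start: int
    end: int
    sequence: str

    def __len__(self) -> int:
        return self.end - self.start + 1


def _parse_cell(pos: str, cell: str) -> _Condition | None:
    cell = cell.strip()
    if cell == "*":
        return None
    negated = cell.startswith("^")
    residues = frozenset(cell[1:] if negated else cell)
    return _Condition(offset=_OFFSETS[pos], residues=residues, negated=negated)


def load_rules(
    path: str | Path | None = None, chymotrypsin: str = "low"
) -> dict[str, CleavageRule]:
    """Load the rule table, returning rules keyed by canonical enzyme name.

    ``chymotrypsin`` selects which table variant (``low`` or ``high``
    specificity) backs the canonical ``CT`` enzyme.
    """
    if chymotrypsin not in ("low", "high"):
        raise RuleConfigError(f"unknown chymotrypsin variant {chymotrypsin!r}")
    if path is None:
        from . import RESOURCES

        path = str(RESOURCES / "cleavage_rules.tsv")
    rows: dict[str, dict[str, list]] = {}
    with open(path) as fh:
        header = fh.readline().split()
        idx = {name: k for k, name in enumerate(header)}
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.rstrip("\n").split("\t")
            enzyme, kind = cells[idx["enzyme"]], cells[idx["kind"]]
            conds = tuple(
                c
                for p in _POSITIONS
                if (c := _parse_cell(p, cells[idx[p]])) is not None
            )
            bucket = rows.setdefault(enzyme, {"pattern": [], "exception": []})
            if kind not in bucket:
                raise RuleConfigError(f"unknown rule kind {kind!r} for {enzyme!r}")
            bucket[kind].append(conds)
    ct_variant = f"CT_{chymotrypsin}"
    rules: dict[str, CleavageRule] = {}
    for name in CANONICAL_ENZYMES:
        table_name = ct_variant if name == "CT" else name
        if table_name not in rows:
            raise RuleConfigError(f"enzyme {table_name!r} not in rule table {path}")
        rules[name] = CleavageRule(
            enzyme=name,
            patterns=tuple(rows[table_name]["pattern"]),
            exceptions=tuple(rows[table_name]["exception"]),
        )
    return rules


def find_sites(
    sequence: str, rule: CleavageRule, parent_id: str = ""
) -> CleavageSiteSet:
    """Evaluate every bond of ``sequence`` against one enzyme's rule.

    Bonds are evaluated independently (overlapping contexts allowed); context
    positions beyond the termini hold no residue and satisfy only conditions
    that do not require one.
    """
    positions = tuple(
        b for b in range(1, len(sequence)) if rule.bond_cleaved(sequence, b)
    )
    return CleavageSiteSet(parent_id=parent_id, enzyme=rule.enzyme, positions=positions)


def pepsin_boundaries(sequence: str, pa_sites: CleavageSiteSet) -> list[int]:
    """Fragment boundaries: {0} ∪ gastric pepsin sites ∪ {L} (0-based gaps)."""
    return sorted({0, len(sequence), *pa_sites.positions})


def expected_fragment_count(n_sites: int) -> int:
    """Closed form for the partial-digestion fragment count: C(N+2, 2) − 1."""
    return math.comb(n_sites + 2, 2) - 1


def enumerate_fragments(
    sequence: str, boundaries: list[int], parent_id: str = ""
) -> list[DigestPeptide]:
    """All fragments over unordered boundary pairs, excluding the full protein.

    One fragment per pair (b1 < b2) covering residues [b1+1, b2]; the pair
    (0, L) — the intact protein — is excluded, so the count is exactly
    C(N+2, 2) − 1. This covers complete and every partial digestion outcome.
    """
    L = len(sequence)
    frags: list[DigestPeptide] = []
    for i, b1 in enumerate(boundaries):
        for b2 in boundaries[i + 1 :]:
            if b1 == 0 and b2 == L:
                continue
            frags.append(
                DigestPeptide(
                    parent_id=parent_id,
                    start=b1 + 1,
                    end=b2,
                    sequence=sequence[b1:b2],
                )
            )
    return frags


def filter_length(
    fragments: list[DigestPeptide], min_len: int = 12, max_len: int = 47
) -> list[DigestPeptide]:
    """Keep fragments with min_len ≤ length ≤ max_len (inclusive bracket)."""
    if min_len > max_len:
        raise RuleConfigError(f"min_len {min_len} > max_len {max_len}")
    return [f for f in fragments if min_len <= len(f) <= max_len]


def digest_protein(
    sequence: str,
    pa_rule: CleavageRule,
    parent_id: str = "",
    min_len: int = 12,
    max_len: int = 47,
) -> list[DigestPeptide]:
    """Convenience: gastric sites → boundaries → fragments → length filter."""
    sites = find_sites(sequence, pa_rule, parent_id)
    bounds = pepsin_boundaries(sequence, sites)
    return filter_length(
        enumerate_fragments(sequence, bounds, parent_id), min_len, max_len
    )
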