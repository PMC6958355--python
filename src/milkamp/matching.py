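"""Match pepsin-digest fragments to propensity stretches.

A fragment matches a stretch when both lie on the same parent protein, the
fragment fully contains the stretch, and the fragment extends at most
``max_overhang`` (default 2) residues beyond the stretch at either terminus.
Because matching is coordinate-based within one parent, the overlapping
sequence is identical by construction. A match with both overhangs zero is an
*exact* match — the pepsin cleavage positions coincide with the stretch
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .digestion import DigestPeptide
from .propensity import AmpStretch


@dataclass(frozen=True)
class MatchedAmp:
    fragment: DigestPeptide
    stretch: AmpStretch
    n_overhang: int
    c_overhang: int
    exact: bool

    @property
    def peptide(self) -> str:
        return self.fragment.sequence


def match(
    fragments: list[DigestPeptide],
    stretches: list[AmpStretch],
    max_overhang: int = 2,
) -> list[MatchedAmp]:
    """All (fragment, stretch) containment pairs with overhangs ≤ max_overhang.

    A fragment may match several stretches and vice versa; every qualifying
    pair yields one record.
    """
    by_parent: dict[str, list[AmpStretch]] = {}
    for st in stretches:
        by_parent.setdefault(st.parent_id, []).append(st)
    out: list[MatchedAmp] = []
    for frag in fragments:
        for st in by_parent.get(frag.parent_id, ()):
            n_over = st.start - frag.start
            c_over = frag.end - st.end
            if 0 <= n_over <= max_overhang and 0 <= c_over <= max_overhang:
                out.append(
                    MatchedAmp(
                        fragment=frag,
                        stretch=st,
                        n_overhang=n_over,
                        c_overhang=c_over,
                        exact=(n_over == 0 and c_over == 0),
                    )
                )
    return out


@dataclass
class PeptideTrace:
    """One unique peptide sequence with its cross-proteome provenance."""

    peptide: str
    proteomes: set[str] = field(default_factory=set)
    witnesses: list[tuple[str, str, int, int]] = field(default_factory=list)
    #: lowest stretch propensity among witnesses (best antimicrobial call)
    pv: float = float("inf")
    #: any witness with zero overhang on both termini
    exact: bool = False


def dedupe_and_trace(
    matches_per_set: dict[str, list[MatchedAmp]],
) -> dict[str, PeptideTrace]:
    """Deduplicate matches by fragment sequence and back-trace memberships.

    The key is the peptide (fragment) sequence; each trace records every
    (proteome, parent, start, end) witness, the set of proteome names, the
    minimum stretch propensity among its witnesses, and whether any witness
    is an exact match.
    """
    traces: dict[str, PeptideTrace] = {}
    for set_name, matches in matches_per_set.items():
        for m in matches:
            tr = traces.setdefault(m.peptide, PeptideTrace(peptide=m.peptide))
            tr.proteomes.add(set_name)
            tr.witnesses.append(
                (set_name, m.fragment.parent_id, m.fragment.start, m.fragment.end)
            )
            tr.pv = min(tr.pv, m.stretch.pv)
            tr.exact = tr.exact or m.exact
    return traces


def membership_counts(
    traces: dict[str, PeptideTrace], proteomes: list[str]
) -> pd.DataFrame:
    """Per-proteome total/unique peptide counts and pairwise common counts."""
    rows = []
    for p in proteomes:
        total = sum(1 for t in traces.values() if p in t.proteomes)
        unique = sum(1 for t in traces.values() if t.proteomes == {p})
        rows.append({"proteome": p, "n_peptides": total, "n_unique": unique})
    return pd.DataFrame(rows)


def matches_table(matches_per_set: dict[str, list[MatchedAmp]]) -> pd.DataFrame:
    rows = []
    for set_name, matches in matches_per_set.items():
        for m in matches:
            rows.append(
                {
                    "peptide": m.peptide,
                    "proteome": set_name,
                    "parent_id": m.fragment.parent_id,
                    "start": m.fragment.start,
                    "end": m.fragment.end,
                    "stretch_start": m.stretch.start,
                    "stretch_end": m.stretch.end,
                    "pv": m.stretch.pv,
                    "n_overhang": m.n_overhang,
                    "c_overhang": m.c_overhang,
                    "exact": m.exact,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "peptide",
            "proteome",
            "parent_id",
            "start",
            "end",
            "stretch_start",
            "stretch_end",
            "pv",
            "n_overhang",
            "c_overhang",
            "exact",
        ],
    )
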