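"""Peptide stability: intestinal cleavage-site counts, CSS and decay rate.

Once released by gastric pepsin, a peptide faces the intestinal proteases
(pepsin at pH>2, chymotrypsin, enterokinase, trypsin, thrombin). The cleavage
stability score summarises its susceptibility:

    CSS = 100 / (1 + Σ_i N_i),   i ∈ {Pb, CT, E, T, Th}

where N_i counts enzyme-i cleavage bonds found in the peptide *in isolation*
(its termini are true termini — it is a free peptide after gastric release).
CSS is 100 for a peptide with no sites and decreases towards 0.

Half-lives come from a pluggable provider — a lookup table exported from an
external half-life predictor, or a clearly-flagged constant stub — and are
converted to first-order decay rates by d = ln 2 / τ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .digestion import CleavageRule, INTESTINAL_ENZYMES, find_sites

STUB_TAU_SECONDS = 1.0


class HalfLifeLookupError(KeyError):
    """Raised when requested peptides are missing from a half-life table."""

    def __init__(self, missing: list[str]):
        self.missing = missing
        super().__init__(
            f"{len(missing)} peptide(s) missing from half-life table: "
            + ", ".join(missing[:10])
            + ("…" if len(missing) > 10 else "")
        )


@dataclass(frozen=True)
class StabilityRecord:
    peptide: str
    site_counts: Mapping[str, int]
    css: float
    half_life: float  # seconds
    decay: float  # s^-1
    tau_source: str = "table"


def count_intestinal_sites(
    peptide: str, rules: Mapping[str, CleavageRule]
) -> dict[str, int]:
    """Per-enzyme cleavage-bond counts on the free peptide."""
    return {
        enz: len(find_sites(peptide, rules[enz]).positions)
        for enz in INTESTINAL_ENZYMES
    }


def css(site_counts: Mapping[str, int]) -> float:
    """Cleavage stability score 100/(1+ΣN); 100 iff no sites."""
    if any(n < 0 for n in site_counts.values()):
        raise ValueError(f"negative site count in {dict(site_counts)}")
    return 100.0 / (1.0 + sum(site_counts.values()))


def decay_rate(half_life: float) -> float:
    """First-order decay rate d = ln2/τ (τ in seconds, d in s⁻¹)."""
    if half_life <= 0:
        raise ValueError(f"half-life must be positive, got {half_life}")
    return math.log(2) / half_life


def load_half_life_table(path: str | Path) -> dict[str, float]:
    """Read a TSV (sequence, tau_seconds) half-life table with a header row."""
    taus: dict[str, float] = {}
    with open(path) as fh:
        next(fh)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            seq, tau = line.split()[:2]
            tau = float(tau)
            if tau <= 0:
                raise ValueError(
                    f"{path}: row {lineno}: non-positive half-life {tau} for {seq!r}"
                )
            taus[seq] = tau
    return taus


def half_life_provider(
    peptides: Iterable[str],
    source: str | Path | Mapping[str, float] | None = None,
    allow_stub_fallback: bool = False,
    stub_tau: float = STUB_TAU_SECONDS,
) -> dict[str, tuple[float, str]]:
    """Resolve a half-life (τ, source-label) for every requested peptide.

    ``source=None`` selects the stub provider: every peptide receives the
    documented constant ``stub_tau`` (default 1 s) labelled ``"stub"``. With a
    table (path or mapping), misses abort with the full missing list unless
    ``allow_stub_fallback`` is set, in which case they fall back to the stub
    value and are labelled ``"stub"``.
    """
    peptides = list(peptides)
    if source is None:
        return {p: (stub_tau, "stub") for p in peptides}
    table = (
        dict(source)
        if isinstance(source, Mapping)
        else load_half_life_table(source)
    )
    missing = [p for p in peptides if p not in table]
    if missing and not allow_stub_fallback:
        raise HalfLifeLookupError(missing)
    out: dict[str, tuple[float, str]] = {}
    for p in peptides:
        if p in table:
            out[p] = (table[p], "table")
        else:
            out[p] = (stub_tau, "stub")
    return out


def score_stability(
    peptides: Iterable[str],
    rules: Mapping[str, CleavageRule],
    half_life_source: str | Path | Mapping[str, float] | None = None,
    allow_stub_fallback: bool = False,
) -> list[StabilityRecord]:
    """Full stability assessment for a set of free peptides."""
    peptides = list(peptides)
    taus = half_life_provider(peptides, half_life_source, allow_stub_fallback)
    records = []
    for p in peptides:
        counts = count_intestinal_sites(p, rules)
        tau, label = taus[p]
        records.append(
            StabilityRecord(
                peptide=p,
                site_counts=counts,
                css=css(counts),
                half_life=tau,
                decay=decay_rate(tau),
                tau_source=label,
            )
        )
    return records
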