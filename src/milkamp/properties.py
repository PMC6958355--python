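"""Physicochemical descriptors of candidate antimicrobial peptides.

Standard calculators for the descriptors typically reported alongside AMP
sets: length, Henderson–Hasselbalch net charge at a given pH, isoelectric
point, mean hydrophobicity (Eisenberg consensus scale by default),
amphipathicity as the normalised hydrophobic moment at the α-helical angle
of 100° per residue, and molecular weight.

The pK set and hydrophobicity scale ship as editable resource tables so the
calculators can be aligned with any external reference tool; the bundled
defaults are the EMBOSS pK values and the Eisenberg consensus scale.
"""

from __future__ import annotations

import cmath
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

from Bio.SeqUtils import molecular_weight as _bio_mw
from scipy.optimize import brentq

from . import RESOURCES

HELIX_ANGLE_DEG = 100.0


def _load_pk(path: str | Path) -> tuple[dict[str, float], dict[str, float]]:
    positive, negative = {}, {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            group, pk, sign = line.split()[:3]
            (positive if sign == "+" else negative)[group] = float(pk)
    return positive, negative


def _load_scale(path: str | Path) -> dict[str, float]:
    values = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            res, val = line.split()[:2]
            values[res] = float(val)
    return values


DEFAULT_PK_POSITIVE, DEFAULT_PK_NEGATIVE = _load_pk(str(RESOURCES / "pk_emboss.tsv"))
EISENBERG = _load_scale(str(RESOURCES / "eisenberg_hydrophobicity.tsv"))


@dataclass(frozen=True)
class PropertyProfile:
    length: int
    net_charge: float
    pI: float
    hydrophobicity: float
    amphipathicity: float
    mw: float


def net_charge(
    peptide: str,
    pH: float = 7.0,
    pk_positive: dict[str, float] | None = None,
    pk_negative: dict[str, float] | None = None,
) -> float:
    """Henderson–Hasselbalch net charge at ``pH``.

    Positive groups (free N-terminus, K, R, H) contribute
    1/(1+10^(pH−pK)); negative groups (free C-terminus, D, E, C, Y)
    contribute −1/(1+10^(pK−pH)).
    """
    pos = pk_positive if pk_positive is not None else DEFAULT_PK_POSITIVE
    neg = pk_negative if pk_negative is not None else DEFAULT_PK_NEGATIVE
    charge = 0.0
    groups_pos = [("Nterm", 1)] + [(r, peptide.count(r)) for r in ("K", "R", "H")]
    groups_neg = [("Cterm", 1)] + [(r, peptide.count(r)) for r in ("D", "E", "C", "Y")]
    for g, n in groups_pos:
        if n and g in pos:
            charge += n / (1.0 + 10.0 ** (pH - pos[g]))
    for g, n in groups_neg:
        if n and g in neg:
            charge -= n / (1.0 + 10.0 ** (neg[g] - pH))
    return charge


def isoelectric_point(
    peptide: str,
    pk_positive: dict[str, float] | None = None,
    pk_negative: dict[str, float] | None = None,
    tol: float = 1e-4,
) -> float:
    """pH at which the net charge vanishes, by root bracketing on [0, 14]."""
    f = lambda ph: net_charge(peptide, ph, pk_positive, pk_negative)
    lo, hi = f(0.0), f(14.0)
    if lo == 0:
        return 0.0
    if hi == 0:
        return 14.0
    if lo * hi > 0:
        boundary = 0.0 if abs(lo) < abs(hi) else 14.0
        warnings.warn(
            f"net charge does not change sign on [0, 14] for {peptide!r}; "
            f"returning boundary pH {boundary}"
        )
        return boundary
    return float(brentq(f, 0.0, 14.0, xtol=tol))


def mean_hydrophobicity(peptide: str, scale: dict[str, float] | None = None) -> float:
    """Arithmetic-mean hydrophobicity over the peptide's residues."""
    sc = scale if scale is not None else EISENBERG
    missing = set(peptide) - set(sc)
    if missing:
        raise KeyError(f"residues missing from hydrophobicity scale: {sorted(missing)}")
    return sum(sc[c] for c in peptide) / len(peptide)


def hydrophobic_moment(
    peptide: str,
    scale: dict[str, float] | None = None,
    angle_deg: float = HELIX_ANGLE_DEG,
) -> float:
    """Normalised hydrophobic moment μH = |Σ h_j · e^(i·δ·j)| / N, δ = angle.

    With the default 100° per residue this is the classical helical-wheel
    amphipathicity measure: hydrophobicity arranged periodically at the
    α-helical repeat gives a large moment, uniform sequences give ≈ 0.
    """
    sc = scale if scale is not None else EISENBERG
    missing = set(peptide) - set(sc)
    if missing:
        raise KeyError(f"residues missing from hydrophobicity scale: {sorted(missing)}")
    delta = math.radians(angle_deg)
    total = sum(sc[c] * cmath.exp(1j * delta * j) for j, c in enumerate(peptide))
    return abs(total) / len(peptide)


def molecular_weight(peptide: str, monoisotopic: bool = False) -> float:
    """Peptide molecular weight in Daltons (average by default)."""
    return float(_bio_mw(peptide, seq_type="protein", monoisotopic=monoisotopic))


def property_profile(peptide: str, pH: float = 7.0) -> PropertyProfile:
    """All descriptors with the bundled default resource tables."""
    return PropertyProfile(
        length=len(peptide),
        net_charge=net_charge(peptide, pH),
        pI=isoelectric_point(peptide),
        hydrophobicity=mean_hydrophobicity(peptide),
        amphipathicity=hydrophobic_moment(peptide),
        mw=molecular_weight(peptide),
    )
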