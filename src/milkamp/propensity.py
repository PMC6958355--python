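"""Sliding-window antimicrobial propensity scan.

A propensity scale assigns every standard residue a strictly positive value
(lower = more antimicrobial, IC50-like). A window of ``window`` consecutive
residues qualifies when its arithmetic-mean propensity is strictly below the
threshold; a *stretch* is the residue span covered by a maximal run of
consecutive qualifying window starts, kept only if it is at least
``min_stretch`` residues long. Windows that contain an ambiguity letter are
omitted from the profile (the scale does not define them) and therefore break
runs.

The stretch's reported propensity value ``pv`` is the mean residue propensity
over the whole span — the quantity later fed (max-normalised) into the
combined antimicrobial score.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import ProteomeSet, STANDARD_RESIDUES

DEFAULT_WINDOW = 7
DEFAULT_THRESHOLD = 0.225
DEFAULT_MIN_STRETCH = 12


@dataclass(frozen=True)
class PropensityScale:
    """Per-residue antimicrobial propensity values plus scan parameters."""

    values: dict[str, float]
    name: str = "custom"
    window: int = DEFAULT_WINDOW
    threshold: float = DEFAULT_THRESHOLD
    min_stretch: int = DEFAULT_MIN_STRETCH

    def __post_init__(self) -> None:
        missing = STANDARD_RESIDUES - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues {sorted(missing)}")
        nonpos = {r: v for r, v in self.values.items() if v <= 0}
        if nonpos:
            raise ValueError(f"scale {self.name!r} has non-positive values {nonpos}")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.min_stretch < self.window:
            raise ValueError("min_stretch must be >= window")


@dataclass(frozen=True)
class AmpStretch:
    """A candidate antimicrobial stretch on a parent protein (1-based, inclusive)."""

    parent_id: str
    start: int
    end: int
    sequence: str
    pv: float

    def __len__(self) -> int:
        return self.end - self.start + 1


def load_scale(
    path: str | Path,
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_THRESHOLD,
    min_stretch: int = DEFAULT_MIN_STRETCH,
) -> PropensityScale:
    """Load a two-column (residue, value) scale file with a header row."""
    path = Path(path)
    values: dict[str, float] = {}
    with open(path) as fh:
        next(fh)  # header
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            res, val = line.split()[:2]
            values[res] = float(val)
    return PropensityScale(
        values=values,
        name=path.stem,
        window=window,
        threshold=threshold,
        min_stretch=min_stretch,
    )


def default_scale(**kwargs) -> PropensityScale:
    """The bundled default scale (a synthetic stand-in; see resource file)."""
    from . import RESOURCES

    return load_scale(str(RESOURCES / "synthetic_propensity_scale.tsv"), **kwargs)


def window_profile(
    sequence: str, scale: PropensityScale
) -> list[tuple[int, float]]:
    """Mean propensity per window start (1-based); undefined windows omitted.

    Returns one ``(start, mean)`` entry per window start 1 … L−W+1 whose W
    residues are all defined in the scale. Sequences shorter than the window
    yield an empty profile.
    """
    w = scale.window
    n = len(sequence)
    if n < w:
        return []
    vals = np.array([scale.values.get(c, np.nan) for c in sequence], dtype=float)
    kernel = np.ones(w) / w
    means = np.convolve(vals, kernel, mode="valid")
    defined = ~np.isnan(means)
    return [(int(i) + 1, float(means[i])) for i in np.nonzero(defined)[0]]


def call_stretches(sequence: str, scale: PropensityScale) -> list[AmpStretch]:
    """Call antimicrobial stretches from maximal runs of qualifying windows.

    A run of consecutive qualifying window starts w1…wk spans residues
    [w1, wk+W−1]; spans shorter than ``min_stretch`` are discarded. The
    comparison against the threshold is strict (<).
    """
    w = scale.window
    qualifying = [s for s, m in window_profile(sequence, scale) if m < scale.threshold]
    stretches: list[AmpStretch] = []
    i = 0
    while i < len(qualifying):
        j = i
        while j + 1 < len(qualifying) and qualifying[j + 1] == qualifying[j] + 1:
            j += 1
        start, end = qualifying[i], qualifying[j] + w - 1
        if end - start + 1 >= scale.min_stretch:
            sub = sequence[start - 1 : end]
            pv = float(np.mean([scale.values[c] for c in sub]))
            stretches.append(
                AmpStretch(parent_id="", start=start, end=end, sequence=sub, pv=pv)
            )
        i = j + 1
    return stretches


def scan_proteome(proteome: ProteomeSet, scale: PropensityScale) -> list[AmpStretch]:
    """Run :func:`call_stretches` over every record, tagging parent ids."""
    out: list[AmpStretch] = []
    for rec in proteome:
        for st in call_stretches(rec.sequence, scale):
            out.append(
                AmpStretch(
                    parent_id=rec.id,
                    start=st.start,
                    end=st.end,
                    sequence=st.sequence,
                    pv=st.pv,
                )
            )
    return out
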