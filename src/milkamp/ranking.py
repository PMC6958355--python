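"""Combined antimicrobial score (CAS) ranking and cross-proteome summaries.

Each selected peptide carries three strictly positive quantities: its
cleavage stability score (CSS, higher = more stable), its antimicrobial
propensity (PV, lower = more antimicrobial) and its decay rate (d, lower =
longer-lived). Each is divided by its maximum over the whole selected set
(pooled across proteomes), and

    CAS = CSS̄ / (PV̄ · d̄)

so CAS rewards stability and penalises both poor propensity and fast decay.
Multiplying all values of any one variable by a positive constant leaves CAS
unchanged — the normalisation absorbs units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ScoredAmp:
    peptide: str
    css: float
    pv: float
    decay: float
    css_bar: float
    pv_bar: float
    d_bar: float
    cas: float
    rank: int
    proteomes: frozenset[str]


def normalize(values: Sequence[float]) -> list[float]:
    """Divide by the maximum; all inputs must be strictly positive."""
    if len(values) == 0:
        raise ValueError("cannot normalize an empty list")
    arr = np.asarray(values, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("all values must be strictly positive for normalization")
    return list(arr / arr.max())


def score_and_rank(
    records: Iterable[Mapping],
) -> list[ScoredAmp]:
    """Compute CAS on max-normalised variables and rank descending.

    Each record needs keys peptide, css, pv, decay (all > 0) and optionally
    proteomes. Ties are broken deterministically: higher CSS first, then
    lexicographic peptide.
    """
    recs = list(records)
    if not recs:
        return []
    offenders = [
        r.get("peptide", "?")
        for r in recs
        if any(k not in r or r[k] is None for k in ("css", "pv", "decay"))
    ]
    if offenders:
        raise ValueError(f"missing css/pv/decay for peptides: {offenders[:10]}")
    css_bar = normalize([r["css"] for r in recs])
    pv_bar = normalize([r["pv"] for r in recs])
    d_bar = normalize([r["decay"] for r in recs])
    scored = []
    for r, cb, pb, db in zip(recs, css_bar, pv_bar, d_bar):
        scored.append(
            dict(
                peptide=r["peptide"],
                css=r["css"],
                pv=r["pv"],
                decay=r["decay"],
                css_bar=cb,
                pv_bar=pb,
                d_bar=db,
                cas=cb / (pb * db),
                proteomes=frozenset(r.get("proteomes", ())),
            )
        )
    scored.sort(key=lambda s: (-s["cas"], -s["css"], s["peptide"]))
    return [ScoredAmp(rank=i + 1, **s) for i, s in enumerate(scored)]


def top_n(scored: list[ScoredAmp], n: int = 100) -> list[ScoredAmp]:
    """The n best-ranked peptides (all if fewer)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return scored[:n]


def cutoff_cas(scored: list[ScoredAmp], n: int = 100) -> float:
    """The CAS value of the last peptide admitted to the top-n set."""
    subset = top_n(scored, n)
    return subset[-1].cas if subset else float("nan")


def proteome_summary(
    scored: list[ScoredAmp],
    proteome_sizes: Mapping[str, int],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-proteome population metrics and the pairwise common-peptide matrix.

    Returns ``(summary, pairwise)``: one summary row per proteome (peptide
    count, ratio to proteome size, mean PV / decay / CSS / CAS, unique
    count) and a symmetric proteome × proteome common-count matrix whose
    diagonal is each proteome's total.
    """
    names = list(proteome_sizes)
    rows = []
    for p in names:
        sub = [s for s in scored if p in s.proteomes]
        uniq = sum(1 for s in scored if s.proteomes == {p})
        n = len(sub)
        rows.append(
            {
                "proteome": p,
                "proteins": proteome_sizes[p],
                "n_amps": n,
                "ratio_to_proteome": n / proteome_sizes[p] if proteome_sizes[p] else np.nan,
                "mean_pv": np.mean([s.pv for s in sub]) if n else np.nan,
                "mean_decay": np.mean([s.decay for s in sub]) if n else np.nan,
                "mean_css": np.mean([s.css for s in sub]) if n else np.nan,
                "mean_cas": np.mean([s.cas for s in sub]) if n else np.nan,
                "n_unique": uniq,
            }
        )
    pairwise = pd.DataFrame(
        0, index=pd.Index(names, name="proteome"), columns=names, dtype=int
    )
    for s in scored:
        present = [p for p in names if p in s.proteomes]
        for a in present:
            for b in present:
                pairwise.loc[a, b] += 1
    return pd.DataFrame(rows), pairwise


def scored_table(scored: list[ScoredAmp]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "peptide": s.peptide,
                "rank": s.rank,
                "cas": s.cas,
                "css": s.css,
                "pv": s.pv,
                "decay": s.decay,
                "css_bar": s.css_bar,
                "pv_bar": s.pv_bar,
                "d_bar": s.d_bar,
                "proteomes": ",".join(sorted(s.proteomes)),
            }
            for s in scored
        ]
    )
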