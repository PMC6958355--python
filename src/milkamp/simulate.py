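"""Synthetic proteome generator with planted, ground-truthed AMP stretches.

Real milk-whey proteome sets are not redistributable, so the generator builds
proteome sets in which every antimicrobial stretch is *planted* and recorded
in a ground-truth table, and nothing else in the sequence can be called:

* Plants are composed from a dedicated cationic/hydrophobic *plant alphabet*
  (K, R, W, I, V, C); background residues come from the remaining letters
  minus F and L. Under the generator's two-valued scan scale (plant residues
  0.1, everything else 1.2, threshold 0.225, window 7) a window qualifies iff
  all seven residues lie inside one plant — zero false-positive stretches and
  exact stretch boundaries, by construction rather than by rejection
  sampling.
* Neither alphabet contains F or L, so gastric pepsin (pH < 1.8) sites exist
  only at deliberately inserted L flank residues. Placing the flanking L at
  ``start − n − 1`` and ``end + c + 1`` forces the nearest released fragment
  to overhang the plant by exactly (n, c) residues: ``exact`` mode uses
  n = c = 0, ``jitter`` draws each overhang from {0, 1, 2}, and ``reject``
  forces n = c = 3 so no fragment survives the ≤2-overhang matching rule.
* Cross-proteome sharing copies whole proteins (with their plants) between
  sets, mimicking the shared milk proteins that drive cross-breed overlaps.

The generator emits its scan scale alongside the sequences; pipeline runs on
synthetic data must use that scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ProteomeSet, ProteinRecord, write_fasta, write_table
from .propensity import PropensityScale

PLANT_ALPHABET = "KRWIVC"
#: residues never used in plants; F/L excluded so pepsin sites are engineered
BACKGROUND_ALPHABET = "ADEGHMNPQSTY"
PLANT_VALUE = 0.1
BACKGROUND_VALUE = 1.2

#: cationic residues are favoured, echoing typical AMP composition
PLANT_WEIGHTS = {"K": 0.30, "R": 0.30, "W": 0.10, "I": 0.12, "V": 0.10, "C": 0.08}

OVERHANG_MODES = ("exact", "jitter", "reject")


@dataclass
class SynthesisConfig:
    """Study-condition defaults: a handful of few-hundred-protein proteomes.

    ``plant_rate`` is the expected number of planted stretches per protein
    (Poisson); protein lengths are log-normal (median ≈ 270 residues).
    """

    n_proteomes: int = 5
    proteins_per_proteome: int = 500
    length_log_mean: float = 5.6
    length_log_sigma: float = 0.45
    plant_rate: float = 2.0
    plant_length_range: tuple[int, int] = (12, 43)
    overhang_mode: str = "exact"
    share_prob: float = 0.2
    seed: int = 0
    proteome_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        lo, hi = self.plant_length_range
        if not (12 <= lo <= hi <= 43):
            raise ValueError(
                f"plant_length_range must lie within [12, 43], got {self.plant_length_range}"
            )
        if self.overhang_mode not in OVERHANG_MODES:
            raise ValueError(f"overhang_mode must be one of {OVERHANG_MODES}")
        if not 0.0 <= self.share_prob <= 1.0:
            raise ValueError("share_prob must be in [0, 1]")
        if self.plant_rate < 0:
            raise ValueError("plant_rate must be >= 0")
        if not self.proteome_names:
            self.proteome_names = [f"SP{i+1}" for i in range(self.n_proteomes)]
        if len(self.proteome_names) != self.n_proteomes:
            raise ValueError("proteome_names length must equal n_proteomes")


def scan_scale() -> PropensityScale:
    """The generator's two-valued scan scale (plant 0.1, background 1.2)."""
    values = {c: (PLANT_VALUE if c in PLANT_ALPHABET else BACKGROUND_VALUE)
              for c in "ACDEFGHIKLMNPQRSTVWY"}
    return PropensityScale(values=values, name="synthetic-scan")


def _background(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BACKGROUND_ALPHABET), size=n)) if n else ""


def _plant(rng: np.random.Generator, length: int) -> str:
    letters = list(PLANT_WEIGHTS)
    probs = np.array([PLANT_WEIGHTS[c] for c in letters])
    return "".join(rng.choice(letters, size=length, p=probs / probs.sum()))


def _overhangs(rng: np.random.Generator, mode: str) -> tuple[int, int]:
    if mode == "exact":
        return 0, 0
    if mode == "jitter":
        return int(rng.integers(0, 3)), int(rng.integers(0, 3))
    return 3, 3  # reject: nearest pepsin boundary 3 residues out on each side


def _build_protein(
    rng: np.random.Generator, cfg: SynthesisConfig, protein_id: str
) -> tuple[ProteinRecord, list[dict]]:
    n_plants = int(rng.poisson(cfg.plant_rate))
    lo, hi = cfg.plant_length_range
    parts: list[str] = [_background(rng, int(rng.integers(6, 16)))]
    pos = len(parts[0])
    truth: list[dict] = []
    for k in range(n_plants):
        n_over, c_over = _overhangs(rng, cfg.overhang_mode)
        plant = _plant(rng, int(rng.integers(lo, hi + 1)))
        block = "L" + _background(rng, n_over) + plant + _background(rng, c_over) + "L"
        start = pos + 1 + n_over + 1  # after the flanking L and N-side spacer
        truth.append(
            {
                "parent_id": protein_id,
                "start": start,
                "end": start + len(plant) - 1,
                "sequence": plant,
                "n_overhang": n_over,
                "c_overhang": c_over,
            }
        )
        parts.append(block)
        pos += len(block)
        pad = _background(rng, int(rng.integers(8, 20)))
        parts.append(pad)
        pos += len(pad)
    target = int(round(rng.lognormal(cfg.length_log_mean, cfg.length_log_sigma)))
    if pos < target:
        parts.append(_background(rng, target - pos))
    seq = "".join(parts)
    return ProteinRecord(id=protein_id, description=protein_id, sequence=seq), truth


def generate(
    cfg: SynthesisConfig,
) -> tuple[list[ProteomeSet], pd.DataFrame, PropensityScale]:
    """Generate proteome sets, the ground-truth plant table, and the scale.

    Deterministic for a given config (including its seed): identical calls
    produce identical sequences and tables.
    """
    rng = np.random.default_rng(cfg.seed)
    proteomes: list[ProteomeSet] = []
    truth_rows: list[dict] = []
    per_set_records: list[list[ProteinRecord]] = []
    per_set_truth: list[dict[str, list[dict]]] = []
    native_ids: list[set[str]] = []
    for si, name in enumerate(cfg.proteome_names):
        records: list[ProteinRecord] = []
        truth_by_protein: dict[str, list[dict]] = {}
        for pi in range(cfg.proteins_per_proteome):
            pid = f"{name}_P{pi+1:04d}"
            rec, truth = _build_protein(rng, cfg, pid)
            records.append(rec)
            truth_by_protein[pid] = truth
        per_set_records.append(records)
        per_set_truth.append(truth_by_protein)
        native_ids.append({r.id for r in records})
    # cross-proteome sharing: copy whole proteins (and their plants) between sets
    for i in range(cfg.n_proteomes):
        for j in range(cfg.n_proteomes):
            if i == j:
                continue
            present = {r.id for r in per_set_records[j]}
            for rec in list(per_set_records[i]):
                if rec.id in native_ids[i] and rng.random() < cfg.share_prob:
                    if rec.id in present:
                        continue
                    per_set_records[j].append(rec)
                    per_set_truth[j][rec.id] = per_set_truth[i][rec.id]
                    present.add(rec.id)
    for name, records, truth_by_protein in zip(
        cfg.proteome_names, per_set_records, per_set_truth
    ):
        proteomes.append(ProteomeSet(name=name, records=records))
        for pid, truths in truth_by_protein.items():
            for t in truths:
                truth_rows.append({"proteome": name, **t})
    columns = ["proteome", "parent_id", "start", "end", "sequence",
               "n_overhang", "c_overhang"]
    truth = pd.DataFrame(truth_rows, columns=columns)
    return proteomes, truth, scan_scale()


def assign_half_lives(
    peptides: list[str] | pd.Series,
    log_median: float = float(np.log(0.6)),
    log_sigma: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a log-normal half-life (seconds) per unique peptide sequence.

    The defaults put the median τ at 0.6 s so mean decay rates land near the
    ~1 s⁻¹ regime typical of short peptides in intestinal extracts, with the
    heavy right tail of a log-normal. Deterministic given the seed.
    """
    if log_sigma < 0:
        raise ValueError("log_sigma must be >= 0")
    uniq = list(dict.fromkeys(peptides))
    rng = np.random.default_rng(seed)
    taus = np.exp(rng.normal(log_median, log_sigma, size=len(uniq)))
    return pd.DataFrame({"sequence": uniq, "tau_seconds": taus})


def write_simulation(
    outdir: str | Path,
    proteomes: list[ProteomeSet],
    truth: pd.DataFrame,
    scale: PropensityScale,
) -> dict[str, Path]:
    """Write per-proteome FASTA, the ground-truth TSV and the scan scale."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for ps in proteomes:
        p = outdir / f"{ps.name}.fasta"
        write_fasta(ps, p)
        paths[ps.name] = p
    truth_path = outdir / "ground_truth.tsv"
    write_table(truth, truth_path, float_format="%g")
    paths["ground_truth"] = truth_path
    scale_path = outdir / "scan_scale.tsv"
    with open(scale_path, "w") as fh:
        fh.write("residue\tvalue\n")
        for res in sorted(scale.values):
            fh.write(f"{res}\t{scale.values[res]}\n")
    paths["scan_scale"] = scale_path
    return paths
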