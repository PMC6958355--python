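# milkamp

In silico mining of **gastrointestinal-digestion-survivable antimicrobial
peptides (AMPs)** in milk and dairy proteomes.

Food proteins release bioactive peptides during digestion, but a candidate
AMP is only interesting if gastric pepsin can actually excise it and it then
survives the intestinal proteases long enough to act on the gut microbiota.
`milkamp` implements that whole screen as a tested pipeline:

1. **Propensity scan** — an AMPA-style sliding-window scan (window 7,
   threshold 0.225) calls sequence *stretches* ≥ 12 residues whose window-mean
   antimicrobial propensity is below threshold (lower propensity = more
   antimicrobial). Each stretch carries its mean residue propensity *PV*.
2. **Gastric digestion** — pepsin (pH < 1.8) cleavage sites are found with
   data-driven PeptideCutter/SpirPep-style context rules; complete *and*
   partial digestion are enumerated exhaustively. With *N* sites plus the two
   termini, the fragment count is the closed form C(N+2, 2) − 1. Fragments
   are kept in the 12–47-residue bracket.
3. **Matching** — a fragment is retained when it contains a stretch on the
   same parent with at most 2 residual residues beyond either terminus
   (overlap identity is 100% by construction); zero overhang on both ends is
   an *exact* match. Unique peptide sequences are back-traced across all
   proteome sets.
4. **Stability** — per-peptide cleavage sites are counted for the intestinal
   enzymes (pepsin pH > 2, trypsin, chymotrypsin, enterokinase, thrombin) and
   summarised as the cleavage stability score
   **CSS = 100 / (1 + Σᵢ Nᵢ)**; a half-life provider (lookup table of an
   external predictor's output, or a flagged stub) supplies τ, converted to a
   decay rate **d = ln 2 / τ**.
5. **Ranking** — each variable is divided by its maximum over the selected
   set and combined into the combined antimicrobial score
   **CAS = C̄SS / (P̄V · d̄)**; peptides are ranked, a top-N subset is cut,
   and per-proteome population metrics plus pairwise overlap counts are
   reported.

Because real proteome retrievals and trained external predictors are outside
the package, a first-class **synthetic generator** builds proteome sets with
*planted*, ground-truthed AMP stretches and engineered pepsin flanks, so every
stage — including 100% exact-match recall — is verifiable end to end.

## Worked example

Generate three synthetic proteomes (~50 proteins each plus shared copies)
with planted stretches and half-lives, then run the full pipeline:

```bash
milkamp simulate --out demo/sim --seed 42 --n-proteomes 3 --proteins 50 \
    --overhang-mode jitter
milkamp run-all \
    --fasta CP=demo/sim/SP1.fasta --fasta S=demo/sim/SP2.fasta \
    --fasta F=demo/sim/SP3.fasta \
    --scale demo/sim/scan_scale.tsv \
    --half-life-table demo/sim/half_lives.tsv \
    --out demo/out
```

which prints

```
wrote 3 proteomes, 425 plants, 824 half-lives to demo/sim
pipeline complete: {'proteins': 199, 'stretches': 425, 'fragments': 4318,
 'matches': 1151, 'selected': 824, 'exact': 27, 'ranked': 824, 'top_n': 100}
 -> demo/out
```

Read: 199 proteins yielded 425 called stretches; partial pepsin digestion
produced 4318 length-filtered fragments, of which 1151 matched a stretch
within the ±2-residue margin; deduplication left 824 unique peptides (27 with
an exact pepsin match), all ranked by CAS. `demo/out/ranked.tsv` begins

```
peptide         rank  cas    css    pv   decay   proteomes
KCVKKKKKVKVKVR  1     52.28  11.11  0.1  0.2105  CP,F
LSVIRRKRKKVRIRA 2     36.71  9.091  0.1  0.2453  F
```

— the top peptide combines few intestinal cleavage sites (CSS 11.1), the best
propensity and a slow decay, and is shared by two proteomes. Per-proteome
population metrics (counts, ratios, mean PV/decay/CSS/CAS, unique counts) are
in `summary.tsv`, pairwise overlaps in `pairwise_common.tsv`, and every stage
table plus a parameter/checksum manifest sits alongside them.

As a single-peptide illustration of the stability score, the cationic 13-mer
`FHKFICKMMKIYL` carries 14 intestinal cleavage sites under the shipped rule
tables (5 pepsin pH>2, 6 chymotrypsin, 3 trypsin), so CSS = 100/15 = **6.67**
— a peptide with excellent propensity can still be flagged as proteolytically
fragile.

## Notes

* The bundled propensity scale is a clearly-labelled synthetic stand-in
  (`resources/synthetic_propensity_scale.tsv`); swap in a published scale via
  `--scale` for production use. Cleavage rules, pK values and the
  hydrophobicity scale are editable resource tables too.
* The external half-life predictor's SVM is intentionally not reimplemented;
  feed its batch output as a TSV (`sequence`, `tau_seconds`) or use the
  flagged stub.
* See `docs/methods.md` for the model, parameter defaults, numerical choices
  and limitations.
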