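# Methods

## Model and assumptions

`milkamp` treats the gastrointestinal tract as two sequential compartments.
In the stomach, pepsin at pH < 1.8 is the only active protease; any subset of
its cleavage sites may be hydrolysed (partial digestion), so the set of
peptides that can reach the intestine is the set of all contiguous intervals
between pepsin boundaries. In the intestine, the released peptide is a free
molecule exposed to pepsin (pH > 2), trypsin, chymotrypsin, enterokinase and
thrombin; its survival is summarised by a count-based stability score and an
externally supplied half-life. Microbial proteases and cleavage kinetics are
deliberately out of scope: the pipeline ranks *relative* candidate quality,
it does not predict concentrations or time courses.

An antimicrobial candidate must satisfy three independent filters: it must be
called by the propensity scan, it must be excisable by gastric pepsin with at
most two residual residues at either terminus, and it must fall in the
12–47-residue bracket (the scan's minimum stretch length, plus the observed
43-residue maximum stretch length with the 2+2 overhang margin).

## Propensity scan

A scale maps each standard residue to a strictly positive propensity (lower =
more antimicrobial). With window W (default 7) and threshold t (default
0.225), window start w qualifies when the mean scale value over residues
[w, w+W−1] is strictly below t. A maximal run of consecutive qualifying
starts w1…wk yields the stretch [w1, wk+W−1]; stretches shorter than
`min_stretch` (default 12) are dropped. The reported per-stretch PV is the
mean residue propensity over the whole span (a windowed-mean alternative
would differ only at stretch edges; the residue mean is the single
unambiguous choice and is what enters CAS).

Two consequences of the run construction are documented rather than hidden:
(i) two runs separated by a gap of fewer than W−1 non-qualifying windows
produce spans that overlap on up to W−2 residues — spans are reported in
position order and are *usually* disjoint but not guaranteed to be; (ii)
windows containing an ambiguity letter (B, J, O, U, X, Z) are omitted and
therefore break runs. Both choices favour predictability over smoothing.

The bundled default scale is a **synthetic stand-in** (the established
propensity index is not redistributable here): it preserves the qualitative
ordering — cationic lowest, then aromatic/cysteine, aliphatic, polar, acidic
highest — but not reference numerics. Every quantitative test uses an
explicit scale, so pipeline correctness is scale-independent; production
analyses should supply a published scale file.

## Cleavage rules

Rules are data (`resources/cleavage_rules.tsv`): one row per pattern or
exception, with an allowed-residue set per Schechter–Berger position P4…P4′
(`*` = unconstrained, `^XYZ` = must not be one of XYZ). A bond is cleaved iff
some pattern row passes and no exception row does. A negated condition is
satisfied by a position beyond the terminus; a positive condition requires a
residue. Bonds whose P1 or P1′ is an ambiguity letter are never called.

The shipped dialect was **calibrated against a known worked example**: the
13-mer FHKFICKMMKIYL must carry 14 intestinal sites (CSS = 6.67). This fixes
two choices the rule literature leaves open:

* **Pepsin** follows the simplified bidirectional P1/P1′ reading — cleavage
  on either side of F/L at pH < 1.8, F/L/W/Y at pH > 2 — rather than the
  longer H/K/R- and P-context regex variant. (The contextual variant yields
  only 2–4 pepsin sites on the calibration peptide and cannot reproduce the
  known score under any chymotrypsin variant.)
* **Chymotrypsin** defaults to the low-specificity variant
  (F/L/Y not before P; W not before M/P; M not before P/Y; H not before
  D/M/P/W). The high-specificity variant (F/Y/W only) ships in the same
  table and is selected with `--chymotrypsin-variant high`.

Trypsin implements the full veto table (no cleavage at CKD, DKD, CKH, CKY,
CRK, RRH, RRR contexts; WKP and MRP override the no-P1′-proline rule),
enterokinase requires three acidic residues before K, and thrombin implements
both classical contexts. Tests cross-check every enzyme whose dialect
coincides with the ExPASy regex transcriptions in `pyteomics` and pin the
rest with hand-derived fixtures.

## Digestion combinatorics

Boundaries are {0} ∪ sites ∪ {L} (0-based gap indices; reported peptide
coordinates are 1-based inclusive). Every unordered boundary pair except
(0, L) is a fragment, giving exactly C(N+2, 2) − 1 fragments — the union of
fragment sets over all 2^N hydrolysis subsets. The intact protein is never a
fragment. Identical sequences at different coordinates remain distinct
records until reporting, so every peptide can be back-traced to its parents.

## Matching and deduplication

Matching is coordinate containment within one parent: fragment ⊇ stretch with
N-/C-overhangs each in [0, 2]. This makes the 100%-identity requirement hold
by construction and matches the rejection rule "a pepsin site strictly more
than 2 residues outside the stretch terminus". Deduplication happens *before*
stability scoring (one score per reportable sequence); when a sequence has
several stretch witnesses the lowest PV is kept — the most favourable
antimicrobial call.

## Stability and ranking

CSS = 100/(1 + ΣN) over the five intestinal enzymes, computed on the peptide
in isolation (its termini are real termini after gastric release — bonds
whose full context extends into the former parent are judged on the truncated
context). Decay d = ln 2/τ with τ in seconds. Half-lives come from a lookup
table (e.g. an external predictor's batch export); missing entries abort with
the full list unless stub fallback is enabled. The stub provider assigns a
constant τ = 1 s and is flagged `stub` in every output row.

CAS = C̄SS/(P̄V·d̄) with each variable divided by its maximum over the pooled
selected set (no per-proteome stratification, matching a single pooled
ranking). All three inputs must be strictly positive — violations abort
rather than clamp, since CAS divides by two of them. Ties (possible with
discrete site counts) break deterministically by higher CSS then lexicographic
peptide. The top-N cutoff defaults to 100 and carries no physical meaning;
the CAS value at the cutoff is reported so users can choose a threshold
instead.

## Synthetic data

The generator's defaults emulate the study conditions the pipeline targets:
five proteome sets of a few hundred proteins (default 500 before sharing),
log-normal protein lengths (median ≈ 270 residues), an expected two planted
stretches per protein (Poisson), plant lengths uniform on [12, 43], and a
0.2 per-pair probability of copying a protein (with its plants) into another
set — whole-protein sharing mimics the conserved milk proteins that drive
cross-breed overlaps.

Plants are drawn from a plant alphabet (K/R/W/I/V/C, cationic-weighted);
background residues come from the remaining letters minus F and L. Under the
generator's two-valued scan scale (plant 0.1, background 1.2, threshold
0.225, window 7) a window qualifies iff it lies wholly inside one plant,
because one background residue already lifts the mean to
(6·0.1 + 1.2)/7 = 0.257 ≥ 0.225. Hence: zero false-positive stretches, and
called boundaries equal planted boundaries exactly — recall assertions are
exact, not statistical. Since neither alphabet contains F or L, gastric
pepsin sites exist only at deliberately placed flanking L residues:
positioned at start−n−1 and end+c+1 they force a released fragment with
overhangs exactly (n, c). `exact` mode sets n = c = 0, `jitter` draws each
from {0, 1, 2}, and `reject` forces n = c = 3, in which case no fragment can
satisfy the ≤2-overhang rule. Synthetic half-lives are log-normal with
median 0.6 s and σ_log = 0.8, putting mean decay near the ~1 s⁻¹ regime
reported for short peptides in intestinal extracts, with a heavy right tail.

What the generator does **not** emulate: real residue composition and
homology families (caseins, lactoglobulins), propensity scales with twenty
distinct values, pepsin sites arising inside antimicrobial stretches'
flanking regions, and sequence-level convergence of unrelated proteins.
Passing the recovery tests therefore demonstrates correctness of the
machinery — scan, combinatorial digestion, matching, scoring — not predictive
accuracy on real milk proteomes, which additionally depends on the quality of
the supplied scale and half-life source.

## Numerical choices

* Window means via a length-W moving average; NaN propagation removes
  windows containing ambiguity letters.
* Threshold comparison is strict (<); "length over 12" is implemented as
  ≥ 12, consistent with a reported 12–47 bracket.
* pI by Brent root-finding of the Henderson–Hasselbalch charge on [0, 14]
  (tolerance 1e-4); if the charge does not change sign the nearer boundary is
  returned with a warning. EMBOSS pK defaults.
* Hydrophobic moment μH = |Σ h_j e^(i·δ·j)|/N at δ = 100°; the
  "amphipathicity index" column is this normalised moment — an approximation,
  since external tools do not publish their index formula. Eisenberg
  consensus scale; average (not monoisotopic) masses by default.
* Molecular weights via Biopython's standard residue mass tables.
* TSV floats are written at 4 significant digits; internal computation is
  double precision throughout.

## Known limitations

* Fragment enumeration is O(N²) in the number of gastric sites per protein;
  for F/L-rich real proteins the per-protein fragment list can reach a few
  thousand entries. The pipeline filters by length inline but does not
  stream.
* CSS counts recognition patterns; it ignores cleavage efficiency, pH
  dynamics, and competition between substrates.
* The pipeline's headline numbers on any real proteome depend on the supplied
  propensity scale and half-life table; with the bundled synthetic scale the
  results are structurally valid but not biologically calibrated.
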