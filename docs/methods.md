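# Methods

## Motif model

The two family motifs are compiled from a PROSITE-like dialect: exact
residues, `[..]` choice sets, `{..}` exclusion sets, and `xN` for exactly
N wildcards (no variable-length repeats, no terminal anchors). Matching
is ungapped, case-insensitive, and reported for every offset, overlaps
included. The cofactor-binding motif spans 29 residues, the active-site
motif 15.

Two policies matter in practice:

* **Ambiguity.** `X` in a subject sequence fails exact/choice/negation
  sites and satisfies wildcards under the default lenient policy
  (`x_in_wildcard=False` makes it fail everywhere). Conservative
  handling avoids false candidates from low-quality translations.
* **Mismatch budget.** A per-scan budget (default 0, at most 2) lets
  bracketed sites — choice or negation — deviate; exact and wildcard
  sites never do. The budget exists because some panel members carry
  residues at bracketed motif positions that the literal pattern would
  reject; at budget 0 the scanner is strict.

## Reference numbering

Key residues are always reported in the coordinate system of the
*S. kanamyceticus* reference IRED. Mapping uses optimal global pairwise
alignment: BLOSUM62, gap open 10, gap extend 0.5 (first gapped residue
costs 10, each further residue 0.5). Pairwise alignment replaces a
multiple alignment because it is deterministic, dependency-free and
adequate for within-family mapping at the panel's 30–70% identity.
Among co-optimal alignments the aligner's first enumerated alignment is
taken, making outputs byte-reproducible. Pairwise identity is made
symmetric by canonicalising the argument order before aligning.

The packaged reference sequence is **synthetic** (the real UniProt entry
is not redistributed): a 293-residue protein carrying the cofactor motif
at positions 26–54 — placing its invariant Arg at 50 and terminal [KR]
at 54 — and the active-site motif at 178–192, a register under which
positions 187 and 191 fall on wildcard sites. That register was a
genuine design choice: it keeps all four residue-187 classes (D/Y/E/N)
motif-conformant at mismatch budget 0 and lets Asn191 "near-miss"
sequences carry both motifs while still being excluded by the residue
rule, which is how the family discrimination actually operates.

## Calling and classification rules

A candidate IRED must (i) match both motifs at least once, and then
(ii) not carry Asn at reference 191 and (iii) carry Arg at reference 50
(toggleable; enabling it can only shrink the candidate set). The residue
rules are applied only to motif-confirmed sequences: motif confirmation
comes first in the mining procedure, and alignment-mapped residues of a
motif-free random protein are not meaningful evidence. When a motif hits
more than once, the hit whose alignment-mapped position is nearest the
reference motif locus is primary; others are kept as secondary evidence.
An optional identity prefilter (disabled by default) stands in for the
original similarity search against the reference genome.

Classification is a pure function of the key-residue profile: subgroup
label `<r187>187-<r196>196` (unassigned when either position is
gapped; pairs outside the eight characterised subgroups are flagged
novel); stereoselectivity R iff Asp187, S iff Tyr187; NADH-capable iff
Glu/Asn187. Predictions carry `provenance="heuristic"` and a caveat
flag when Pro139 is present or residue 194 is not Met/Phe — the residues
known to modulate stereoselectivity and responsible for at least one
documented inversion (a Asp187 enzyme with Pro139 and Cys194 giving the
(S)-product).

## Phylogenetics

Distance is `1 − identity` over aligned columns of the global alignment.
These distances are symmetric with zero diagonal but are **not**
guaranteed metric (the triangle inequality can fail for identity
distances) nor additive. Neighbor joining is implemented directly:
Q-criterion agglomeration with deterministic tie-breaking by index
order, canonical branch-length formulas, terminal trifurcation for the
last three nodes, and negative branch lengths clamped to zero with the
deficit logged. On additive matrices the implementation recovers the
generating tree exactly (topology and lengths), which is the main
correctness property the tests assert, alongside agreement with
scikit-bio's independent NJ.

## Kinetics

`rate [µmol/mL·min ≡ mM/min] = −slope/(ε·l)·1000` with
ε = 6220 M⁻¹cm⁻¹ and path length l defaulting to 1.0 cm (the microplate
optical path is configurable and reported with every rate). The initial
slope is fitted by least squares over the steepest window with
R² ≥ 0.95 among all contiguous windows of ≥ 5 points within the first
30% of the time span, falling back to the first 5 points; the early-
window restriction keeps the fit off the plateau that follows cofactor
exhaustion. Replicates are fitted individually and averaged afterwards.
Net activity subtracts the mean of matched controls (empty-plasmid and
lysate-free, same substrate/cofactor/pH); negative nets floor at zero
with a below-background flag and the raw value retained. Rates are per
reaction volume; a lysate-dilution multiplier can be applied externally
if per-lysate rates are wanted. The heat map is a dense enzyme ×
(substrate, cofactor, pH) matrix in which absent conditions stay NaN —
explicitly missing, never zero.

## Biotransformation arithmetic

Calibration lines are fitted with an intercept (not forced through the
origin) on ≥ 3 external standards. Yields: product mode
`100·product/initial`; consumption mode `100·(1 − final/initial)`, used
when the product is too unstable to quantify. Yields may overshoot 100%
by at most 5 points (calibration noise) before raising. ee is
`100·|major − minor|/(major + minor)`, displayed as ">99" at ≥ 99.05 to
mirror the usual table formatting while keeping the numeric value.
Peak-to-compound assignment uses the published retention-time windows
(3.3–5.6 min) with a ±0.2 min tolerance.

Fold improvement is coupled/uncoupled yield, reported to one decimal.
Over the seven published enzyme–substrate pairs the minimum is 1.2; the
maximum computes to **4.3** (91/21 = 4.33) from the printed, rounded
yields, whereas the source text states 4.4 — presumably computed from
unrounded data. The package reports the recomputable 4.3 and does not
silently match the printed bound.

## Synthetic-data generators

All generators are deterministic under a single integer seed.

* **Sequences.** Background composition is uniform over the 20 letters.
  Evolution is i.i.d. per-site substitution with no indels, so planted
  residue coordinates stay exact. Constrained motif sites
  (exact/choice/negation), short conserved blocks flanking the non-motif
  key residues (52–58, 104–112, 135–143, 193–200), and the nine key
  positions are held fixed; motif wildcard sites drift freely. The
  conserved blocks emulate the clustered conservation of real family
  alignments and are what keeps the alignment register readable at
  30–40% identity.
* **Panels.** Members evolve on a planted two-sided clade tree
  (Asp+Glu vs Tyr+Asn at residue 187). Default edge divergences
  (side 0.50, group 0.42, within 0.23 substitutions/site) were
  calibrated once so a 29-member panel's pairwise-identity range lands
  near 30–70%, the within-family spread of the characterised panel. At
  that depth, cross-clade signal is close to saturation for an i.i.d.
  substitution model — clade-recovery properties are therefore tested
  at milder divergence, where the planted topology is identifiable.
  The `gen_table1_panel` convenience plants the characterised panel's
  exact 187/196 composition, with Lys54 on the NADH-preferring Glu/Asn
  subgroups plus a fixed set of Asp187 members (13 Lys54 / 16 Arg54 in
  total, the published split). These are planted compositions: recovering
  them exercises the profiling pipeline, it does not re-derive the
  published statistics from real sequences.
* **Traces.** `a340(t) = max(a0 − ε·l·rate·t/1000, floor) + N(0, σ)`
  with `floor = a0 − ε·l·[cofactor]/1000`; defaults a0 = 1.35 AU,
  0.2 mM cofactor, 30 min at 0.5-min steps, σ = 0.002 AU.
* **Peak tables.** Linear area response per compound with multiplicative
  log-normal noise; retention times drawn within ±0.1 min of the
  compound's window.

What the generators do **not** emulate: insertions/deletions (optional
nowhere by default), rate heterogeneity across sites, empirical
substitution matrices, compositional bias, instrument drift or
saturation, and chromatographic peak-shape effects. Passing tests
therefore demonstrate correctness of the analysis arithmetic and the
discrimination logic under the stated noise models — not robustness to
every artefact of real proteomes or instruments.

## Numerical choices and degenerate inputs

* A perfectly constant trace fits with slope 0 and R² defined as 1.
* Quantified concentrations below zero floor at 0 with a flag; the same
  convention applies to net rates.
* Fold improvement with zero uncoupled yield is reported as
  not-computable rather than infinite.
* Neighbor joining requires ≥ 3 taxa; distance matrices require ≥ 2
  distinct labels.
* Empty sequences scan to empty hit lists; empty panels summarise to
  zero counts.

## Problem sizes

The test suite and the acceptance script use a 100-protein proteome
(5 planted IREDs, 95 decoys), a 29-member panel (406 alignments),
100 noisy traces per recovery estimate, 50 random 6–10-taxon trees for
the NJ oracle, and length-≤12 pairs for the exhaustive alignment oracle
— sizes at which every oracle is exact and the full run completes in
seconds.
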