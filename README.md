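# iredmine

Genome mining and activity analysis for **imine reductases (IREDs)** —
NADPH-dependent oxidoreductases that reduce cyclic imines to chiral
amines and, as reductive aminases, aminate prochiral ketones. The package
re-implements a complete discovery-to-characterisation workflow as a
tested pipeline:

1. **Motif mining** — scan proteomes with the two IRED-specific
   PROSITE-style motifs, the NADPH cofactor-binding motif
   `GLGxMGx5[ATS]x4Gx4[VIL]WNR[TS]x2[KR]` (which contains the Rossmann
   GxGxxG consensus and the invariant VWNR block) and the active-site
   motif `Gx[DE]x[GDA]x[APS]x3{K}x[ASL]x[LMVIAG]`.
2. **Reference numbering** — map every candidate onto the
   *S. kanamyceticus* IRED coordinate system by global alignment
   (BLOSUM62, affine gaps) and read out the nine key residues
   50, 54, 108, 139, 187, 191, 194, 195, 196.
3. **Calling and classification** — a candidate must carry both motifs,
   must not carry Asn191 (the discriminator against β-hydroxyacid
   dehydrogenases) and, by default, must carry the conserved Arg50.
   The residue-187/196 pair assigns the subgroup; Asp187/Tyr187 predict
   (R)/(S) stereoselectivity and Glu187/Asn187 predict NADH capability —
   heuristics that carry an explicit caveat flag when Pro139 or an
   unusual residue 194 is present.
4. **Phylogenetics** — all-pairs global-alignment percent identity,
   distance `d = 1 − identity`, and a deterministic neighbor-joining
   tree with Newick output.
5. **Screening kinetics** — initial rates from plate-reader A340 time
   courses, `rate [µmol/mL·min] = −slope/(ε·l)` with
   ε(NAD(P)H, 340 nm) = 6220 M⁻¹cm⁻¹, control subtraction, and an
   enzyme × condition heat-map matrix.
6. **Biotransformation analysis** — external-standard HPLC calibration,
   THIQ yields (product-formation or substrate-consumption mode),
   enantiomeric excess `ee = 100·|R−S|/(R+S)`, and the fold-improvement
   obtained by coupling the reaction to glucose-6-phosphate dehydrogenase
   (G6PDH) for NADPH recycling.
7. **Synthetic data** — seeded generators for proteomes, panels, plates
   and peak tables with truth labels, so every stage is testable offline.

## Worked example

Mine a labelled synthetic proteome (5 planted IREDs among 95 decoys,
three of them Asn191 near-misses) and tabulate the calls:

```bash
iredmine simulate proteome --seed 1 --out sim/
iredmine mine --fasta sim/proteome.fa --out calls.tsv
```

prints the mining summary

```json
{
  "n_records": 100,
  "n_candidates": 5,
  "exclusions": {
    "missing_cofactor_motif": 85,
    "missing_active_site_motif": 86,
    "N191": 5
  }
}
```

— all five planted IREDs are recovered, every decoy is excluded with its
reason (here the default decoy mix plants five Asn191 near-misses: both
motifs present, rejected by the residue rule alone).

Compute the published-yield arithmetic from the bundled biotransformation
table:

```python
>>> from iredmine.tables import load_table2
>>> from iredmine.biotrans import panel_fold_range
>>> panel_fold_range(load_table2())
(1.2, 4.3)
```

The G6PDH coupling improves THIQ yields between 1.2-fold and 4.3-fold
across the seven enzyme–substrate pairs (the upper bound computed from
the printed, rounded yields).

Build a tree over a synthetic 29-member panel planted with the
characterised subgroup composition:

```bash
iredmine simulate panel --seed 1 --out panel/
iredmine tree --fasta panel/panel.fa --out tree.nwk --matrix dist.tsv
# similarity range 33-70% ; tree -> tree.nwk
```

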