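# orthosav

Orthogonal in-silico ensemble prioritization of single amino-acid variants
(SAVs) in a protein, with apolipoprotein E (APOE) — a central gene in
Alzheimer's disease risk — as the packaged worked case.

Most variant-effect predictors probe one facet of protein biology: a protein
language model scores sequence plausibility, a structure predictor's output
can be compared to the wild-type fold, stability tools estimate the folding
free-energy change, and structural-damage classifiers flag specific defects.
These tools correlate only weakly with each other, which makes each of them
unreliable alone but *orthogonal* in combination. `orthosav` implements the
ensemble strategy built on that observation: harmonize the tools' scores,
threshold each one into a binary damaging / non-damaging call, and classify a
variant as a **candidate disruptor** when two or more tools agree.

## The method

For a protein of length *L* and a variant *ref → alt* at position *p*:

- **Language-model score (LLR).** Given per-position amino-acid
  probabilities *P* from any masked-language-model backend,
  `score = −ln(P[p, alt] / P[p, ref])`; higher = more damaging. The full
  *L* × 20 in-silico mutagenesis table covers all 19·L substitutions
  (6,023 for the 317-residue APOE precursor).
- **Structure score (RMSD).** Cα RMSD in Å between the predicted wild-type
  and mutant models after optimal proper superposition (Kabsch algorithm,
  reflections excluded); larger deviation = more structural disruption.
- **Stability score (ΔΔG).** Signed DynaMut2-style ΔΔG in kcal/mol
  (negative = destabilizing, cutoff −0.5); FoldX/DDGun/Maestro-style columns
  are absolute-valued at ingestion.
- **Structural-damage flag.** Missense3D-style binary call (1 = damaging).
- **Majority vote.** Each tool's call comes from an inclusive cutoff —
  fixed, or a top-percentile of the analyzed score distribution. With
  evidence count = number of damaging calls: `candidate` if ≥ 2,
  `benign_candidate` if all four tools are present and non-damaging,
  `indeterminate` otherwise.

Evaluation utilities implement confusion counts, trapezoidal auROC (exactly
the Mann–Whitney statistic, ties half-credited), step-wise average
precision, and Pearson/Spearman correlations with p-values — used e.g. to
test the purifying-selection signature (scores rising with −log10 allele
frequency).

A synthetic-data module generates every input with known ground truth —
probability matrices with planted conserved positions, structure pairs with
exactly planted RMSD, score tables with planted damaging variants,
ClinVar-like variant files, and allele frequencies depressed for deleterious
variants — so the full pipeline runs and is tested without any downloads.

## Worked example

The package ships the published per-tool scores for the six printed APOE
variants. Applying the published cutoffs (LLR ≥ 7.97, ΔΔG ≤ −0.5,
flag = 1, RMSD ≥ 6.42) with a 2-of-4 vote:

```sh
orthosav ensemble --scores src/orthosav/data/apoe_published_scores.tsv --out demo/
cat demo/classification.tsv
```

```text
variant  call_ESM      call_DynaMut  call_Missense3D  call_AlphaFold  evidence_count  classification
C130R    non_damaging  damaging      damaging         damaging        3               candidate
R132C    damaging      damaging      damaging         non_damaging    3               candidate
R163C    damaging      damaging      non_damaging     damaging        3               candidate
R163P    damaging      non_damaging  non_damaging     damaging        2               candidate
R160C    damaging      non_damaging  non_damaging     damaging        2               candidate
L46P     non_damaging  non_damaging  non_damaging     non_damaging    0               benign_candidate
```

Five candidates reach the 2-of-4 majority; C130R — the variant that defines
the APOE4 isoform (C112R in mature-protein numbering; the 18-residue signal
peptide shifts coordinates by 18) — is called damaging by three of the four
tools despite a language-model score of 0, which is exactly the situation
the orthogonal vote is designed to rescue. L46P, reported with conflicting
clinical interpretations, is non-damaging by all four tools and is flagged
as the benign candidate.

The other subcommands: `orthosav score` (LLR table from a probability
matrix or the mock backend, RMSD table from PDB pairs), `orthosav evaluate`
(auROC / average precision / correlation report) and `orthosav simulate`
(synthetic fixture bundle with `truth.json`).

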