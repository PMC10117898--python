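# Methods

## Scope and model

`orthosav` prioritizes single amino-acid variants (SAVs) by combining four
orthogonal in-silico signals into a percentile-cutoff majority vote. The
package deliberately does **not** run any heavyweight predictor: language
models, structure predictors and stability web services are treated as
*backends* whose outputs (probability matrices, PDB models, score tables)
are ingested, harmonized and voted on. What the package authors itself is
everything downstream of those outputs: the log-likelihood-ratio scoring,
the superposition RMSD, the score harmonization rules, the vote, and the
evaluation statistics.

## Coordinate systems

Secreted proteins carry a signal peptide that is cleaved from the mature
protein, so the same substitution has two coordinates in the literature.
All internal computation uses **precursor** numbering (1-based, first
residue of the signal peptide = 1); mature numbering exists only at I/O
boundaries, converted by adding/subtracting the signal-peptide length (18
for APOE, so C112R mature = C130R precursor). A signal-peptide variant has
no mature coordinate and conversion raises an error rather than clamping.
The packaged APOE precursor (reference isoform E3) has L = 317 = 18 + 299
residues; its full substitution space is 19 × 317 = 6,023 SAVs. The
precursor length is not usually quoted directly; it is fixed by that
mutagenesis-space identity and verified against the reference residues of
all worked-example variants.

## Language-model scoring

Backends return an L × 20 row-stochastic matrix (columns in fixed
alphabetical one-letter order, documented in `lm_scoring.ALPHABET`). The
variant score is −ln(P[pos, alt] / P[pos, ref]).

Numerical choices:

- **Natural log.** Likelihood ratios are conventionally natural-log; every
  downstream use (percentile cutoffs, ranks, correlations) is invariant to
  the base, so the choice affects only the printed scale.
- **Probability floor 1e-12** at ingestion: a degenerate backend cannot
  produce infinite scores, and the clamp preserves score ordering.
- Identity substitutions score exactly 0 and are excluded from mutagenesis
  tables. Exact-zero scores for *non*-identity variants are legal input
  (they occur in real predictor exports) and are counted in logs, since
  they can also indicate a missing-value placeholder upstream.
- Matrix files round-trip bit-identically: values are written with
  shortest-round-trip `repr` and parsed with round-trip float precision.

## Structure comparison

The structural-disruption surrogate is the Cα RMSD between the predicted
wild-type and mutant models after least-squares optimal superposition
(Kabsch/SVD). Design choices, made where the convention is genuinely open:

- **Superposition before RMSD.** Predicted models live in arbitrary frames;
  un-superposed RMSD would measure the frame, not the structure.
- **Cα only.** Robust to side-chain naming and the common convention for
  fold-level comparison; no per-region weighting — one global value per
  variant.
- **Reflections excluded.** The sign of the smallest singular vector is
  corrected so the rotation determinant is +1; mirrored structures are not
  physical.
- **First MODEL only** in multi-model PDB files (rank-1 convention).

Per-residue confidence (pLDDT ∈ [0, 100]) is read from the PDB B-factor
column; values outside the range are clamped with a warning. The
high-confidence mask uses strict `pLDDT > 70`.

## Predictor harmonization

Each score column carries directionality (`higher_is_damaging`,
`lower_is_damaging`, `flag`) and an ingestion transform. The asymmetry is
deliberate and mirrors how the tools are used in practice: DynaMut2-style
signed ΔΔG is kept **signed** (its damaging cutoff −0.5 kcal/mol lives on
the destabilizing side), while FoldX/DDGun/Maestro-style ΔΔG columns are
**absolute-valued**, because for those tools both stabilizing and
destabilizing shifts are treated as potentially disruptive. Missing cells
(`NA`/`.`/empty) stay missing; nothing is imputed.

The ClinVar-style filter keeps records that match the gene, are
single-nucleotide variants, and are missense; insertions and deletions never
pass. Protein-level duplicates collapse to the first occurrence (stable,
order-preserving — the collapsing rule for database exports is not
standardized, so the package documents its own). The tab-delimited fixture
dialect is the primary tested path; a VCF subset (INFO keys `GENEINFO`,
`CLNVC`, `MC`, plus a `PCHANGE` protein-change key, since standard clinical
VCFs do not carry protein changes in a dedicated field) is also read.

## Ensemble vote

Per-tool rules: `ge` / `le` / `flag_eq_1`, with **inclusive** comparisons
(a score equal to the cutoff is damaging — this choice reproduces the
worked example's call pattern). "Top p percent" cutoffs are the
linear-interpolation quantile at (100 − p)/100 of the non-missing analyzed
scores, mirrored for `le` tools; the convention is documented and
configurable because published cutoff values rarely state their quantile
rule. Defaults are the worked example's: vote threshold 2 of 4, LLR ≥ 7.97,
ΔΔG ≤ −0.5, flag = 1, RMSD ≥ 6.42 (the two percentile-derived values enter
as fixed ingested numbers; recomputing them requires the full 38-variant
supplementary score set, which is an external input).

Missing scores never count as evidence, but a `benign_candidate` call
requires *unanimous* non-damaging calls from all configured tools with
nothing missing. Candidates are ordered by evidence count, ties broken by
the variant's maximum within-tool percentile rank in the damaging
direction, then lexicographically for determinism.

## Evaluation statistics

Positives are pathogenic-labeled variants. auROC is computed from integer
cumulative TP/FP counts at distinct thresholds with a single final
division, which makes it bit-for-bit the Mann–Whitney pairwise statistic
(ties half-credited). Average precision is the step-wise, non-interpolated
sum Σ(R_k − R_{k−1})·P_k. Pearson p-values use the t-transform with n − 2
df; Spearman is Pearson on mid-ranks; an exact permutation p-value is
available for n ≤ 10. Zero allele frequencies are excluded from
−log10(AF) correlations (no pseudo-count) with a log entry. One-class label
sets make classification metrics undefined; the report records NaN and
warns instead of raising.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *rank structure* the real pipeline consumes,
with exact ground truth:

- **Probability matrices**: conserved positions put mass ≥ 0.9 on the
  wild-type residue (default 0.95, giving the closed-form LLR ln 361 ≈ 5.89
  for every substitution there); background rows are symmetric Dirichlet
  draws (concentration 5), so background LLRs center on zero.
- **Structure pairs**: wild-type is an ideal α-helix (rise 1.5 Å, 100°
  turn, radius 2.3 Å). The mutant adds a random displacement field from
  which the translation- and rotation-absorbable components are projected
  out (zero mean and zero cross-covariance with the centered wild-type
  coordinates). That projection makes the identity transform the exact
  Kabsch optimum, so the planted post-superposition RMSD is analytic and
  exact — a naive "shift every atom by d" construction would be undone by
  superposition and plant nothing. A random rigid motion then hides the
  frame. Displacements can be confined to a residue window (≥ 5 residues).
- **Score tables**: default scale mirrors the worked case — 38 variants, 5
  planted damaging. Planted variants clear each tool's cutoff by at least a
  margin (defaults: 2.0 LLR units, 0.3 kcal/mol, 2.0 Å) on 3 or 4 of the 4
  tools; background variants sit on the non-damaging side by the same
  margin; injected missing cells never land on planted variants. With those
  margins the 2-of-4 vote recovers the planted set exactly.
- **Allele frequencies**: background AF = 10^−U(1,5); planted damaging
  variants are divided by a penalty factor (default 100), emulating
  purifying selection; a factor of 1 removes the signal. Labels: planted →
  pathogenic, half of background → benign, rest unlabeled. Conservation is
  Gaussian noise (σ 1.5) elevated by 4 units at planted positions. For the
  purifying-selection property check the package uses n = 500 variants with
  50 planted — the same planted fraction as the 5-of-38 default.

A single bundle seed fans out to fixed per-generator substreams (CRC32 of
the generator name), so adding a generator never perturbs existing
fixtures; one seed yields byte-identical bundles.

What the generators do **not** emulate: real energetics, MSA structure,
tool-specific error modes, or score distributions beyond rank structure.
Passing recovery tests therefore demonstrates that the pipeline's
bookkeeping, thresholds and vote logic are correct under controlled signal
— not that any particular backend is accurate on real proteins.

## Problem sizes and determinism

Tests and the acceptance script run at the worked example's own scale
(317-residue sequence, 38-variant tables; 100-seed property sweeps; 500
variants for the purifying-selection check), which the package treats as
its reference configuration. All randomness flows through explicit seeds;
the CLI exposes `--seed`, writes a run manifest (config snapshot, input
SHA-256 digests, seed, version, timestamp) next to every output, and
re-runs on identical inputs and seed produce identical result files (the
manifest's timestamp is the one intentionally non-reproducible field).

## Known limitations

- Raw backend scores (language-model LLRs from a real model, AlphaFold-pair
  RMSDs, web-service ΔΔG/flags) are inputs; the package cannot validate
  their accuracy, only their format and harmonization.
- The percentile over which published cutoffs were derived (analyzed
  variant subset vs full mutagenesis space) is configurable but cannot be
  inferred from the cutoff values alone.
- Nucleotide-level reasoning (codon reachability of an amino-acid change)
  is out of scope; the ClinVar filter trusts the variant-type and
  consequence annotations.
- No isoform alignment beyond a fixed signal-peptide offset, and no
  meta-learning on top of the vote (the ensemble is intentionally a
  transparent counting rule).
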