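"""Synthetic fixtures with known ground truth for every pipeline stage.

Real inputs to this pipeline come from heavyweight sources (language-model
inference, structure prediction, web services, population databases).  The
generators here emulate the *rank structure* those sources produce —
conserved positions with probability mass concentrated on the wild-type
residue, mutant structures displaced from the wild-type model by a known
RMSD, score tables with planted damaging variants, ClinVar-like records of
mixed consequence classes, and allele frequencies depressed for deleterious
variants (purifying selection) — without simulating any actual energetics.

Every generator is deterministic for a fixed seed and returns its ground
truth alongside the data; downstream recovery tests consume only the data
until assertion time.  A single bundle seed fans out to fixed per-generator
substreams, so adding a generator never perturbs existing fixtures.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._errors import ConfigError, ValidationError
from .ensemble import (
    FLAG_EQ_1,
    GE,
    LE,
    EnsembleConfig,
    default_config,
)
from .lm_scoring import AA_INDEX, ALPHABET, SubstitutionProbabilityMatrix
from .predictor_io import (
    DEFAULT_META,
    BENIGN,
    PATHOGENIC,
    UNLABELED,
    LabeledVariantSet,
    PredictorScoreTable,
)
from .seqvar import AMINO_ACIDS, SAV, ProteinSequence, apoe_precursor
from .structure_compare import StructureModel

#: Default scale mirrors the worked APOE analysis: a 317-residue precursor
#: and a 38-variant score table with 5 planted damaging variants.
DEFAULT_N_VARIANTS = 38
DEFAULT_N_DAMAGING = 5

DEFAULT_MARGINS = {"ESM": 2.0, "DynaMut": 0.3, "AlphaFold": 2.0}

# Ideal alpha-helix geometry for synthetic C-alpha traces.
HELIX_RISE = 1.5       # Angstrom per residue
HELIX_TURN = 100.0     # degrees per residue
HELIX_RADIUS = 2.3     # Angstrom


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, stable random substream for one generator."""
    return np.random.default_rng([int(seed), zlib.crc32(name.encode())])


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside synthetic data."""

    seed: int
    planted_damaging_variants: List[str] = field(default_factory=list)
    planted_conserved_positions: List[int] = field(default_factory=list)
    planted_rmsd: Dict[str, float] = field(default_factory=dict)
    af_model: Dict[str, float] = field(default_factory=dict)
    all_variants: List[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Probability matrices with planted conservation
# ---------------------------------------------------------------------------

def gen_probability_matrix(
    seq: ProteinSequence,
    conserved_positions: Sequence[int] = (),
    wt_mass: float = 0.95,
    background_concentration: float = 5.0,
    seed: int = 0,
) -> SubstitutionProbabilityMatrix:
    """Row-stochastic L x 20 matrix with conservation planted at given positions.

    Conserved rows put ``wt_mass`` (>= 0.9) on the wild-type residue with the
    remainder spread uniformly, giving every substitution there the
    closed-form LLR -ln(((1 - wt_mass)/19) / wt_mass).  Background rows are
    symmetric Dirichlet draws, so background LLRs are centered on zero.
    """
    if wt_mass < 0.9 or wt_mass >= 1.0:
        raise ConfigError("wt_mass must be in [0.9, 1.0) for a conserved position")
    conserved = set(int(p) for p in conserved_positions)
    bad = [p for p in conserved if not 1 <= p <= len(seq)]
    if bad:
        raise ConfigError(f"conserved positions outside sequence: {bad}")
    rng = substream(seed, "probability_matrix")
    probs = rng.dirichlet(
        np.full(20, background_concentration), size=len(seq)
    )
    for pos in conserved:
        row = np.full(20, (1.0 - wt_mass) / 19.0)
        row[AA_INDEX[seq.residues[pos - 1]]] = wt_mass
        probs[pos - 1] = row
    return SubstitutionProbabilityMatrix(
        sequence_id=seq.id, residues=seq.residues, probs=probs
    )


# ---------------------------------------------------------------------------
# Structure pairs with exactly planted RMSD
# ---------------------------------------------------------------------------

def ideal_helix(n_residues: int) -> np.ndarray:
    """C-alpha coordinates of an ideal alpha-helix (rise 1.5 A, 100 deg/res,
    radius 2.3 A)."""
    i = np.arange(n_residues)
    theta = np.deg2rad(HELIX_TURN) * i
    return np.column_stack([
        HELIX_RADIUS * np.cos(theta),
        HELIX_RADIUS * np.sin(theta),
        HELIX_RISE * i,
    ])


def plddt_track(n_residues: int, high_region: Optional[Tuple[int, int]] = None,
                high: float = 90.0, low: float = 50.0) -> np.ndarray:
    """Constant confidence track, optionally high only on a 1-based inclusive
    residue range (emulating a confident core flanked by flexible termini)."""
    if high_region is None:
        return np.full(n_residues, high)
    a, b = high_region
    track = np.full(n_residues, low)
    track[a - 1 : b] = high
    return track


def _project_out_rigid(base_centered: np.ndarray, disp: np.ndarray,
                       support: np.ndarray) -> np.ndarray:
    """Remove the components of a displacement field that a rigid-body
    superposition would absorb, modifying only residues in ``support``.

    After projection the field has zero mean and zero cross-covariance with
    the centered base coordinates, which makes the identity transform the
    exact Kabsch optimum for (base, base + field): the post-superposition
    RMSD is then analytically sqrt(mean |field|^2).
    """
    m = int(support.sum())
    C = base_centered[support]                      # (m, 3)
    A = np.zeros((12, 3 * m))
    for k in range(3):                              # translation null space
        A[k, k::3] = 1.0
    for j in range(3):                              # rotation coupling
        for k in range(3):
            A[3 + 3 * j + k, k::3] = C[:, j]
    d = disp[support].reshape(-1)
    lam = np.linalg.lstsq(A @ A.T, A @ d, rcond=None)[0]
    out = disp.copy()
    out[support] = (d - A.T @ lam).reshape(m, 3)
    return out


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def gen_structure_pair(
    n_residues: int,
    target_rmsd: float,
    region: Optional[Tuple[int, int]] = None,
    plddt: Optional[np.ndarray] = None,
    seed: int = 0,
) -> Tuple[StructureModel, StructureModel, float]:
    """Wild-type/mutant C-alpha model pair with an exactly planted RMSD.

    The wild-type is an ideal helix.  The mutant adds a random displacement
    field — confined to a 1-based inclusive ``region`` if given — from which
    the components removable by rigid superposition are projected out, scaled
    so the post-superposition RMSD over all residues equals ``target_rmsd``
    exactly, then hidden behind a random rigid motion.  Returns
    (wt, mutant, planted_rmsd).
    """
    if n_residues < 3:
        raise ConfigError("need at least 3 residues")
    if target_rmsd < 0:
        raise ConfigError("target_rmsd must be non-negative")
    rng = substream(seed, "structure_pair")
    base = ideal_helix(n_residues)
    track = plddt_track(n_residues) if plddt is None else np.asarray(plddt, float)
    support = np.zeros(n_residues, dtype=bool)
    if region is None:
        support[:] = True
    else:
        a, b = region
        if not (1 <= a <= b <= n_residues):
            raise ConfigError(f"region {region} outside 1..{n_residues}")
        support[a - 1 : b] = True
    if support.sum() < 5 and target_rmsd > 0:
        raise ConfigError("displacement region must span at least 5 residues")
    if target_rmsd == 0:
        disp = np.zeros((n_residues, 3))
    else:
        disp = np.zeros((n_residues, 3))
        disp[support] = rng.normal(size=(int(support.sum()), 3))
        centered = base - base.mean(axis=0)
        disp = _project_out_rigid(centered, disp, support)
        norm = np.sqrt(np.mean(np.sum(disp**2, axis=1)))
        if norm == 0:
            raise ConfigError("degenerate displacement field; change the seed")
        disp *= target_rmsd / norm
    R = _random_rotation(rng)
    t = rng.uniform(-50.0, 50.0, size=3)
    mut_coords = (base + disp) @ R.T + t
    idx = np.arange(1, n_residues + 1)
    wt = StructureModel("wt", idx, base, track)
    mut = StructureModel("mut", idx.copy(), mut_coords, track.copy())
    return wt, mut, float(target_rmsd)


# ---------------------------------------------------------------------------
# Score tables with planted damaging variants
# ---------------------------------------------------------------------------

def _sample_distinct_savs(seq: ProteinSequence, n: int, rng: np.random.Generator) -> List[SAV]:
    if n > 19 * len(seq):
        raise ConfigError(f"cannot draw {n} distinct variants from a length-{len(seq)} sequence")
    out: List[SAV] = []
    seen = set()
    while len(out) < n:
        pos = int(rng.integers(1, len(seq) + 1))
        ref = seq.residues[pos - 1]
        alt = AMINO_ACIDS[int(rng.integers(0, 20))]
        if alt == ref or (pos, alt) in seen:
            continue
        seen.add((pos, alt))
        out.append(SAV(ref_aa=ref, position=pos, alt_aa=alt))
    return out


def gen_score_table(
    n_variants: int = DEFAULT_N_VARIANTS,
    n_damaging: int = DEFAULT_N_DAMAGING,
    effect_margins: Optional[Dict[str, float]] = None,
    missing_rate: float = 0.0,
    seed: int = 0,
    seq: Optional[ProteinSequence] = None,
    cfg: Optional[EnsembleConfig] = None,
) -> Tuple[PredictorScoreTable, SyntheticTruth]:
    """Score table with ``n_damaging`` planted damaging variants.

    Planted variants land on the damaging side of each tool's cutoff by at
    least the stated margin on 3 or 4 of the 4 tools (never fewer, so a
    2-of-4 vote always recovers them); background variants land on the
    non-damaging side by the same margin on every tool.  Missing cells are
    injected at ``missing_rate`` on background variants only.
    """
    if n_damaging > n_variants:
        raise ConfigError("n_damaging cannot exceed n_variants")
    if not 0 <= missing_rate <= 1:
        raise ConfigError("missing_rate must be in [0, 1]")
    cfg = cfg or default_config()
    margins = dict(DEFAULT_MARGINS if effect_margins is None else effect_margins)
    for name, m in margins.items():
        if m < 0:
            raise ConfigError(f"negative margin for {name}")
        rule = cfg.rules.get(name)
        if rule is not None and rule.direction == GE and rule.cutoff is not None:
            if rule.cutoff - m <= 0:
                raise ConfigError(
                    f"margin {m} for {name} leaves no background range below "
                    f"cutoff {rule.cutoff}"
                )
    seq = seq or apoe_precursor()
    rng = substream(seed, "score_table")
    variants = _sample_distinct_savs(seq, n_variants, rng)
    planted_idx = set(rng.choice(n_variants, size=n_damaging, replace=False).tolist())

    tools = list(cfg.rules)
    scores = pd.DataFrame(
        index=[str(v) for v in variants], columns=tools, dtype=float
    )
    scores.index.name = "variant"
    for i, v in enumerate(variants):
        planted = i in planted_idx
        if planted:
            damaging_tools = set(tools)
            if len(tools) > 3 and rng.random() < 0.5:
                damaging_tools.discard(tools[int(rng.integers(len(tools)))])
        else:
            damaging_tools = set()
        for name in tools:
            rule = cfg.rules[name]
            m = margins.get(name, 0.0)
            dam = name in damaging_tools
            if rule.direction == FLAG_EQ_1:
                val = 1.0 if dam else 0.0
            elif rule.direction == GE:
                if dam:
                    val = rule.cutoff + m + rng.exponential(1.0)
                else:
                    val = rng.uniform(0.0, rule.cutoff - m)
            elif rule.direction == LE:
                if dam:
                    val = rule.cutoff - m - rng.exponential(0.5)
                else:
                    val = rng.uniform(rule.cutoff + m, rule.cutoff + m + 0.7)
            else:  # pragma: no cover
                raise ConfigError(f"unsupported direction {rule.direction}")
            if not planted and missing_rate and rng.random() < missing_rate:
                val = np.nan
            scores.at[str(v), name] = val

    meta = {name: DEFAULT_META.get(name) for name in tools}
    if any(m is None for m in meta.values()):
        missing = [n for n, m in meta.items() if m is None]
        raise ConfigError(f"no default metadata for tools {missing}")
    table = PredictorScoreTable(variants=variants, scores=scores, meta=meta)
    planted_variants = sorted(str(variants[i]) for i in planted_idx)
    truth = SyntheticTruth(
        seed=seed,
        planted_damaging_variants=planted_variants,
        planted_conserved_positions=sorted(
            {variants[i].position for i in planted_idx}
        ),
        all_variants=[str(v) for v in variants],
    )
    return table, truth


# ---------------------------------------------------------------------------
# ClinVar-like files
# ---------------------------------------------------------------------------

_COMPOSITION_CLASSES = ("in_gene_missense_snv", "in_gene_synonymous",
                        "in_gene_indel", "off_gene")


def _largest_remainder(n: int, fractions: Sequence[float]) -> List[int]:
    raw = [f * n for f in fractions]
    counts = [int(np.floor(x)) for x in raw]
    rem = n - sum(counts)
    order = np.argsort([c - x for c, x in zip(counts, raw)])
    for i in range(rem):
        counts[order[i]] += 1
    return counts


def gen_clinvar_like_file(
    path: str | Path,
    n_records: int = 10,
    composition: Sequence[float] = (0.4, 0.1, 0.1, 0.4),
    seed: int = 0,
    gene: str = "APOE",
    seq: Optional[ProteinSequence] = None,
) -> int:
    """Write a ClinVar-like fixture file; returns the exact number of records
    that must survive the missense filter.

    ``composition`` gives the fractions of (in-gene missense SNV, in-gene
    synonymous SNV, in-gene indel, off-gene) records; they must sum to 1.
    The file dialect follows the extension: ``.vcf`` writes a VCF subset,
    anything else the tab-delimited fixture dialect.
    """
    if len(composition) != 4 or abs(sum(composition) - 1.0) > 1e-9:
        raise ConfigError("composition must be 4 fractions summing to 1")
    rng = substream(seed, "clinvar")
    seq = seq or apoe_precursor()
    counts = _largest_remainder(n_records, composition)
    savs = _sample_distinct_savs(seq, counts[0], rng)
    rows = []
    for sav in savs:
        rows.append((gene, "single_nucleotide_variant", "missense_variant", str(sav)))
    for _ in range(counts[1]):
        rows.append((gene, "single_nucleotide_variant", "synonymous_variant", "."))
    for _ in range(counts[2]):
        kind = "Deletion" if rng.random() < 0.5 else "Insertion"
        rows.append((gene, kind, "frameshift_variant", "."))
    for _ in range(counts[3]):
        rows.append((f"GENE{int(rng.integers(1, 99))}", "single_nucleotide_variant",
                     "missense_variant", "."))
    order = rng.permutation(len(rows))
    rows = [rows[i] for i in order]
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        _write_clinvar_vcf(path, rows)
    else:
        lines = ["gene\tvariant_type\tconsequence\tprotein_change"]
        lines += ["\t".join(r) for r in rows]
        path.write_text("\n".join(lines) + "\n")
    return counts[0]


def _write_clinvar_vcf(path: Path, rows) -> None:
    header = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=GENEINFO,Number=1,Type=String,Description="Gene:ID">',
        '##INFO=<ID=CLNVC,Number=1,Type=String,Description="Variant type">',
        '##INFO=<ID=MC,Number=.,Type=String,Description="Molecular consequence">',
        '##INFO=<ID=PCHANGE,Number=1,Type=String,Description="Protein change">',
        "##contig=<ID=19>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    body = []
    for i, (gene, vtype, cons, pchange) in enumerate(rows, start=1):
        ref, alt = ("A", "G") if "nucleotide" in vtype else ("AT", "A")
        info = f"GENEINFO={gene}:1;CLNVC={vtype};MC=SO:000|{cons}"
        if pchange != ".":
            info += f";PCHANGE={pchange}"
        body.append(f"19\t{44900000 + i}\t{i}\t{ref}\t{alt}\t.\t.\t{info}")
    path.write_text("\n".join(header + body) + "\n")


# ---------------------------------------------------------------------------
# Allele frequencies and conservation with purifying-selection structure
# ---------------------------------------------------------------------------

def gen_af_conservation(
    truth: SyntheticTruth,
    seed: int = 0,
    penalty_factor: float = 100.0,
    benign_fraction: float = 0.5,
    base_exponent_range: Tuple[float, float] = (1.0, 5.0),
) -> LabeledVariantSet:
    """Allele frequencies and conservation for the variants of a truth set.

    Background variants draw AF = 10^-U(a, b); planted damaging variants draw
    from the same law divided by ``penalty_factor`` (purifying selection;
    a factor of 1 removes the signal).  Planted variants are labeled
    pathogenic, a random ``benign_fraction`` of background variants benign,
    the rest unlabeled.  Conservation is a noisy track elevated by 4 units at
    planted conserved positions.
    """
    if penalty_factor < 1:
        raise ConfigError("penalty_factor must be >= 1")
    if not truth.all_variants:
        raise ConfigError("truth has no variant list; generate a score table first")
    rng = substream(seed, "af_conservation")
    planted = set(truth.planted_damaging_variants)
    conserved = set(truth.planted_conserved_positions)
    a, b = base_exponent_range
    records = []
    for name in truth.all_variants:
        af = float(10.0 ** (-rng.uniform(a, b)))
        is_planted = name in planted
        if is_planted:
            af /= penalty_factor
        if is_planted:
            label = PATHOGENIC
        elif rng.random() < benign_fraction:
            label = BENIGN
        else:
            label = UNLABELED
        pos = int("".join(c for c in name if c.isdigit()))
        cons = float(rng.normal(0.0, 1.5) + (4.0 if pos in conserved else 0.0))
        records.append((name, label, af, cons))
    frame = pd.DataFrame(
        records, columns=["variant", "label", "allele_frequency", "conservation"]
    ).set_index("variant")
    truth.af_model = {
        "penalty_factor": float(penalty_factor),
        "benign_fraction": float(benign_fraction),
        "base_exponent_low": float(a),
        "base_exponent_high": float(b),
    }
    return LabeledVariantSet(frame=frame)


def write_annotations(ann: LabeledVariantSet, path: str | Path) -> None:
    out = ann.frame.copy()
    out["label"] = out["label"].replace({UNLABELED: "."})
    out.insert(0, "variant", out.index)
    out.to_csv(path, sep="\t", index=False, na_rep=".")


# ---------------------------------------------------------------------------
# Full fixture bundle
# ---------------------------------------------------------------------------

def gen_bundle(
    out_dir: str | Path,
    seed: int = 0,
    n_variants: int = DEFAULT_N_VARIANTS,
    n_damaging: int = DEFAULT_N_DAMAGING,
    missing_rate: float = 0.0,
    n_clinvar_records: int = 20,
    target_rmsd: float = 2.0,
    structure_length: int = 100,
) -> SyntheticTruth:
    """Write every fixture the pipeline reads, plus a ``truth.json`` sidecar.

    Outputs (all deterministic for a fixed seed): ``sequence.fasta``,
    ``prob_matrix.tsv``, ``scores.tsv``, ``annotations.tsv``,
    ``clinvar.tsv``, ``wt.pdb``/``mut.pdb``, ``truth.json``.
    """
    from .lm_scoring import write_matrix
    from .predictor_io import write_score_table
    from .seqvar import write_protein_fasta
    from .structure_compare import write_structure

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seq = apoe_precursor()
    table, truth = gen_score_table(
        n_variants=n_variants, n_damaging=n_damaging,
        missing_rate=missing_rate, seed=seed, seq=seq,
    )
    matrix = gen_probability_matrix(
        seq, conserved_positions=truth.planted_conserved_positions, seed=seed
    )
    ann = gen_af_conservation(truth, seed=seed)
    wt, mut, planted = gen_structure_pair(structure_length, target_rmsd, seed=seed)
    truth.planted_rmsd = {"mut": planted}
    write_protein_fasta(seq, out / "sequence.fasta")
    write_matrix(matrix, out / "prob_matrix.tsv")
    write_score_table(table, out / "scores.tsv")
    write_annotations(ann, out / "annotations.tsv")
    gen_clinvar_like_file(out / "clinvar.tsv", n_records=n_clinvar_records, seed=seed)
    write_structure(wt, out / "wt.pdb")
    write_structure(mut, out / "mut.pdb")
    truth.to_json(out / "truth.json")
    return truth
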