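"""Backend-agnostic in-silico mutagenesis scoring.

A masked protein language model (or any stand-in) supplies, for every
position of a sequence, a probability distribution over the 20 amino acids.
The variant-effect score used throughout this package is the negated
log-likelihood ratio

    score(ref -> alt at pos) = -ln( P[pos, alt] / P[pos, ref] )

so that a variant the model finds less plausible than the wild-type residue
receives a *higher* (more damaging) score.  The natural logarithm is used;
the percentile-based cutoffs applied downstream depend only on score ranks,
which are invariant to the base.

The model itself is deliberately out of scope: any provider that returns a
row-stochastic L x 20 matrix satisfies the backend contract, including the
:class:`MockBackend` used in tests and the :class:`FileBackend` that reads a
previously exported matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Protocol

import numpy as np
import pandas as pd

from ._errors import BackendError, DimensionError, FormatError, ValidationError
from .seqvar import AMINO_ACIDS, SAV, ProteinSequence, parse_variant_notation

logger = logging.getLogger(__name__)

#: Column order of probability matrices (alphabetical one-letter codes).
ALPHABET = AMINO_ACIDS
AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

#: Probabilities below this are clamped at ingestion so degenerate backends
#: cannot produce infinite scores; the ordering of scores is preserved.
PROB_FLOOR = 1e-12

ROW_SUM_TOL = 1e-6


@dataclass
class SubstitutionProbabilityMatrix:
    """Per-position amino-acid probabilities for a wild-type sequence.

    ``probs[i, j]`` is the model probability of amino acid ``ALPHABET[j]`` at
    precursor position ``i + 1``.  Rows are probability distributions: every
    entry in (0, 1] and each row sums to 1 within ``ROW_SUM_TOL``.
    """

    sequence_id: str
    residues: str
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        L = len(self.residues)
        if self.probs.shape != (L, 20):
            raise DimensionError(
                f"probability matrix shape {self.probs.shape} does not match "
                f"sequence length {L} x 20"
            )
        self.probs = np.clip(self.probs, PROB_FLOOR, None)
        if np.any(self.probs > 1.0):
            raise ValidationError("probabilities must lie in (0, 1]")
        sums = self.probs.sum(axis=1)
        bad = np.flatnonzero(np.abs(sums - 1.0) > ROW_SUM_TOL)
        if bad.size:
            raise ValidationError(
                f"rows {bad[:5].tolist()} of the probability matrix do not sum "
                f"to 1 (tolerance {ROW_SUM_TOL})"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class LLRScoreSet:
    """Negated log-likelihood-ratio scores for a set of variants."""

    sequence_id: str
    scores: Dict[SAV, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"variant": str(v), "position": v.position, "ref": v.ref_aa,
             "alt": v.alt_aa, "score": s}
            for v, s in self.scores.items()
        ]
        return pd.DataFrame(rows, columns=["variant", "position", "ref", "alt", "score"])

    def write(self, path: str | Path) -> None:
        self.to_frame()[["variant", "score"]].to_csv(path, sep="\t", index=False)


def score_variant(m: SubstitutionProbabilityMatrix, v: SAV) -> float:
    """Score one substitution as ``-ln(P[pos, alt] / P[pos, ref])``.

    Requires precursor numbering and a reference residue consistent with the
    matrix's wild-type sequence.
    """
    if v.numbering != "precursor":
        raise ValidationError("score_variant requires precursor numbering")
    if not 1 <= v.position <= len(m):
        raise DimensionError(
            f"position {v.position} outside matrix of length {len(m)}"
        )
    wt = m.residues[v.position - 1]
    if wt != v.ref_aa:
        raise ValidationError(
            f"variant {v}: matrix wild-type residue at {v.position} is {wt}"
        )
    row = m.probs[v.position - 1]
    p_alt = row[AA_INDEX[v.alt_aa]]
    p_ref = row[AA_INDEX[v.ref_aa]]
    if p_alt <= 0 or p_ref <= 0:
        raise BackendError(
            "zero probability encountered; clamp probabilities (>= PROB_FLOOR) "
            "at the backend level"
        )
    return float(-np.log(p_alt / p_ref))


def mutagenesis_table(m: SubstitutionProbabilityMatrix) -> LLRScoreSet:
    """Scores for all 19*L non-identity substitutions of the wild-type.

    The result is consistent with :func:`score_variant` entry by entry and is
    the tidy-table equivalent of the full in-silico mutagenesis heatmap.
    """
    log_probs = np.log(m.probs)
    out = LLRScoreSet(sequence_id=m.sequence_id)
    for pos, ref in enumerate(m.residues, start=1):
        ref_lp = log_probs[pos - 1, AA_INDEX[ref]]
        for alt in ALPHABET:
            if alt == ref:
                continue
            v = SAV(ref_aa=ref, position=pos, alt_aa=alt)
            out.scores[v] = float(-(log_probs[pos - 1, AA_INDEX[alt]] - ref_lp))
    n_zero = sum(1 for s in out.scores.values() if s == 0.0)
    if n_zero:
        logger.info("mutagenesis table contains %d exact-zero scores", n_zero)
    return out


# ---------------------------------------------------------------------------
# Matrix file format: tab-delimited, header "pos ref A C D ... Y"
# ---------------------------------------------------------------------------

def write_matrix(m: SubstitutionProbabilityMatrix, path: str | Path) -> None:
    df = pd.DataFrame(m.probs, columns=list(ALPHABET))
    df.insert(0, "ref", list(m.residues))
    df.insert(0, "pos", np.arange(1, len(m) + 1))
    # shortest round-trip repr keeps write -> read -> write bit-identical
    df.to_csv(path, sep="\t", index=False, float_format=lambda v: repr(float(v)))


def read_matrix(path: str | Path, sequence_id: str | None = None) -> SubstitutionProbabilityMatrix:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    expected = ["pos", "ref"] + list(ALPHABET)
    if list(df.columns) != expected:
        raise FormatError(
            f"matrix file {path} must have columns {' '.join(expected)}"
        )
    if not np.array_equal(df["pos"].to_numpy(), np.arange(1, len(df) + 1)):
        raise FormatError(f"matrix file {path}: pos column must be 1..L contiguous")
    residues = "".join(df["ref"].astype(str))
    return SubstitutionProbabilityMatrix(
        sequence_id=sequence_id or Path(path).stem,
        residues=residues,
        probs=df[list(ALPHABET)].to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# Backends
# ---------------------------------------------------------------------------

class ProbabilityBackend(Protocol):
    """Contract for probability providers: sequence in, L x 20 matrix out.

    Implementations must be deterministic for a fixed configuration/seed and
    must return a matrix satisfying the
    :class:`SubstitutionProbabilityMatrix` invariants.
    """

    def __call__(self, seq: ProteinSequence) -> SubstitutionProbabilityMatrix: ...


class MockBackend:
    """Deterministic random backend for tests and dry runs.

    Samples each row from a Dirichlet distribution mildly biased toward the
    wild-type residue; carries no biological signal beyond that bias.
    """

    def __init__(self, seed: int = 0, wt_concentration: float = 8.0,
                 background_concentration: float = 2.0) -> None:
        self.seed = seed
        self.wt_concentration = wt_concentration
        self.background_concentration = background_concentration

    def __call__(self, seq: ProteinSequence) -> SubstitutionProbabilityMatrix:
        rng = np.random.default_rng(self.seed)
        alpha = np.full(20, self.background_concentration)
        rows = np.empty((len(seq), 20))
        for i, ref in enumerate(seq.residues):
            a = alpha.copy()
            a[AA_INDEX[ref]] = self.wt_concentration
            rows[i] = rng.dirichlet(a)
        return SubstitutionProbabilityMatrix(
            sequence_id=seq.id, residues=seq.residues, probs=rows
        )


class FileBackend:
    """Backend that serves a matrix previously exported with :func:`write_matrix`."""

    def __init__(self, path: str | Path) -> None:
        self.path = Path(path)

    def __call__(self, seq: ProteinSequence) -> SubstitutionProbabilityMatrix:
        try:
            m = read_matrix(self.path, sequence_id=seq.id)
        except OSError as exc:
            raise BackendError(f"cannot read matrix {self.path}: {exc}") from exc
        if m.residues != seq.residues:
            raise BackendError(
                f"matrix {self.path} was computed for a different sequence"
            )
        return m
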