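"""Structural disruption surrogate: superposition RMSD between predicted models.

Predicted structures arrive in arbitrary coordinate frames, so a raw
coordinate difference is meaningless.  The comparison here is the standard
one: least-squares optimal rigid superposition of the mutant model onto the
wild-type model (Kabsch algorithm over C-alpha atoms, reflections excluded)
followed by the root-mean-square deviation of the superposed pairs.  A
variant whose predicted structure deviates more from the wild-type model is
taken to be more structurally disruptive, and the RMSD in Angstroms is the
structure column of the predictor score table.

Per-residue model confidence (pLDDT, in [0, 100]) is read from the B-factor
column of PDB files, following the AlphaFold convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

from ._errors import DimensionError, FormatError, ValidationError

logger = logging.getLogger(__name__)

PLDDT_DEFAULT_THRESHOLD = 70.0


@dataclass
class StructureModel:
    """C-alpha trace of one predicted model with per-residue confidence."""

    model_id: str
    residue_index: np.ndarray  # 1-based, strictly increasing
    ca_coords: np.ndarray      # (N, 3) in Angstroms
    plddt: np.ndarray          # (N,) in [0, 100]

    def __post_init__(self) -> None:
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        self.plddt = np.asarray(self.plddt, dtype=float)
        n = self.residue_index.shape[0]
        if self.ca_coords.shape != (n, 3) or self.plddt.shape != (n,):
            raise DimensionError("residue_index, ca_coords and plddt lengths differ")
        if not np.all(np.isfinite(self.ca_coords)):
            raise ValidationError("coordinates must be finite")
        if np.any(self.plddt < 0) or np.any(self.plddt > 100):
            raise ValidationError("pLDDT values must lie in [0, 100]")
        if n > 1 and not np.all(np.diff(self.residue_index) > 0):
            raise ValidationError("residue_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.residue_index)


@dataclass
class SuperpositionResult:
    """Optimal proper rigid motion of one model onto another.

    Applying ``x -> rotation @ x + translation`` to the second (mobile) model
    superposes it onto the first; ``rmsd`` is the residual in Angstroms.
    """

    rotation: np.ndarray     # (3, 3), proper orthonormal
    translation: np.ndarray  # (3,)
    rmsd: float


def read_structure(path: str | Path) -> StructureModel:
    """Read a C-alpha model from a PDB file.

    Uses the first MODEL only (the rank-1 convention of predicted ensembles).
    pLDDT is taken from the B-factor column; values outside [0, 100] are
    clamped with a warning.  Residues that have atoms but no CA raise a
    :class:`FormatError` naming them.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"no models in PDB file {path}")
    model = st[0]
    idx, coords, plddt, missing = [], [], [], []
    for chain in model:
        for res in chain:
            ca = res.find_atom("CA", "*")
            if ca is None:
                missing.append(res.seqid.num)
                continue
            idx.append(res.seqid.num)
            coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
            plddt.append(ca.b_iso)
    if missing:
        raise FormatError(
            f"{path}: residues without CA atoms: {missing}"
        )
    if not idx:
        raise FormatError(f"no ATOM records with CA atoms in {path}")
    plddt_arr = np.asarray(plddt, dtype=float)
    n_out = int(np.sum((plddt_arr < 0) | (plddt_arr > 100)))
    if n_out:
        logger.warning(
            "%s: %d B-factor values outside [0, 100]; clamping (not pLDDT-like?)",
            path, n_out,
        )
        plddt_arr = np.clip(plddt_arr, 0.0, 100.0)
    return StructureModel(
        model_id=Path(path).stem,
        residue_index=np.asarray(idx),
        ca_coords=np.asarray(coords),
        plddt=plddt_arr,
    )


def write_structure(s: StructureModel, path: str | Path) -> None:
    """Write a C-alpha-only PDB file (poly-ALA, pLDDT in the B-factor column)."""
    st = gemmi.Structure()
    st.name = s.model_id
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i, num in enumerate(s.residue_index):
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(int(num), " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*s.ca_coords[i])
        atom.occ = 1.0
        atom.b_iso = float(s.plddt[i])
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def _check_pair(a: StructureModel, b: StructureModel) -> None:
    if len(a) != len(b):
        raise DimensionError(
            f"residue counts differ: {len(a)} vs {len(b)}"
        )
    if not np.array_equal(a.residue_index, b.residue_index):
        raise DimensionError("residue indices of the two models do not match")
    if len(a) < 3:
        raise ValidationError("superposition requires at least 3 residues")


def kabsch_superpose(a: StructureModel, b: StructureModel) -> SuperpositionResult:
    """Least-squares optimal proper superposition of ``b`` onto ``a``.

    Classic SVD solution: center both coordinate sets, take the SVD of the
    cross-covariance, and correct the sign of the smallest singular vector if
    the optimum would be a reflection (physical structures cannot be
    mirrored).  The returned rotation has determinant +1 within 1e-8.
    """
    _check_pair(a, b)
    pa, pb = a.ca_coords, b.ca_coords
    ca, cb = pa.mean(axis=0), pb.mean(axis=0)
    A, B = pa - ca, pb - cb
    H = B.T @ A  # cross-covariance, mobile x target
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    resid = B @ R.T - A
    rmsd = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    t = ca - R @ cb
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def variant_rmsd_score(wt: StructureModel, mut: StructureModel) -> float:
    """Structural disruption score for a variant: CA RMSD in Angstroms after
    optimal superposition of the mutant model onto the wild-type model."""
    return kabsch_superpose(wt, mut).rmsd


def plddt_profile(s: StructureModel, threshold: float = PLDDT_DEFAULT_THRESHOLD) -> np.ndarray:
    """Boolean per-residue mask of high-confidence regions (pLDDT strictly
    greater than ``threshold``; the conventional confidence floor is 70)."""
    return s.plddt > threshold
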