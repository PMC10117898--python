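"""Ingestion and harmonization of external predictor outputs and annotations.

Stability predictors disagree on conventions: DynaMut2-style tools report a
signed ddG where *negative* means destabilizing (and the downstream cutoff,
-0.5 kcal/mol, is signed), while FoldX/DDGun/Maestro-style ddG columns are
absolute-valued here because both stabilizing and destabilizing shifts can
disrupt function.  Each predictor column therefore carries explicit
directionality and transform metadata, applied once at load time.

Also included: a ClinVar-style missense filter (gene match, single-nucleotide
variants only, insertions/deletions excluded), and allele-frequency /
conservation annotation tables used by the evaluation stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from ._errors import (
    ConfigError,
    FormatError,
    IntegrityError,
    ValidationError,
)
from .seqvar import SAV, parse_variant_notation

logger = logging.getLogger(__name__)

HIGHER_IS_DAMAGING = "higher_is_damaging"
LOWER_IS_DAMAGING = "lower_is_damaging"
FLAG = "flag"

IDENTITY = "identity"
ABSOLUTE_VALUE = "absolute_value"

MISSING_TOKENS = {"", ".", "NA", "NaN", "nan", "na"}


@dataclass(frozen=True)
class PredictorMeta:
    """Directionality and ingestion transform for one predictor column."""

    directionality: str
    transform: str = IDENTITY

    def __post_init__(self) -> None:
        if self.directionality not in (HIGHER_IS_DAMAGING, LOWER_IS_DAMAGING, FLAG):
            raise ConfigError(f"unknown directionality {self.directionality!r}")
        if self.transform not in (IDENTITY, ABSOLUTE_VALUE):
            raise ConfigError(f"unknown transform {self.transform!r}")


#: Default harmonization for the predictors used in the worked APOE analysis.
#: The four core ensemble tools plus three optional stability columns.
DEFAULT_META: Dict[str, PredictorMeta] = {
    "ESM": PredictorMeta(HIGHER_IS_DAMAGING),
    "DynaMut": PredictorMeta(LOWER_IS_DAMAGING),      # signed ddG, kept signed
    "Missense3D": PredictorMeta(FLAG),
    "AlphaFold": PredictorMeta(HIGHER_IS_DAMAGING),   # superposition RMSD, A
    "FoldX": PredictorMeta(HIGHER_IS_DAMAGING, ABSOLUTE_VALUE),
    "DDGun": PredictorMeta(HIGHER_IS_DAMAGING, ABSOLUTE_VALUE),
    "Maestro": PredictorMeta(HIGHER_IS_DAMAGING, ABSOLUTE_VALUE),
}


@dataclass
class PredictorScoreTable:
    """Variants x predictors score matrix with per-predictor metadata.

    ``scores`` is indexed by variant notation (precursor numbering); missing
    cells are NaN and are never silently imputed.
    """

    variants: List[SAV]
    scores: pd.DataFrame
    meta: Dict[str, PredictorMeta]

    def __post_init__(self) -> None:
        for name in self.scores.columns:
            if name not in self.meta:
                raise ConfigError(f"no metadata for predictor column {name!r}")
            if self.meta[name].directionality == FLAG:
                col = self.scores[name].dropna()
                if not col.isin([0.0, 1.0]).all():
                    raise ValidationError(
                        f"flag predictor {name!r} contains values other than 0/1"
                    )

    @property
    def predictors(self) -> List[str]:
        return list(self.scores.columns)

    def __len__(self) -> int:
        return len(self.variants)


def load_score_table(
    path: str | Path,
    meta: Optional[Dict[str, PredictorMeta]] = None,
) -> PredictorScoreTable:
    """Load a tab-delimited score table (header ``variant <predictor...>``).

    Per-predictor transforms are applied here (e.g. absolute value for
    FoldX-style ddG columns); ``NA``/``.``/empty cells become missing.
    Duplicate variant rows raise :class:`IntegrityError`.
    """
    meta = dict(DEFAULT_META if meta is None else meta)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0].lower() != "variant":
        raise FormatError(f"{path}: first column must be 'variant'")
    dup = df.iloc[:, 0][df.iloc[:, 0].duplicated()]
    if not dup.empty:
        raise IntegrityError(
            f"{path}: duplicate variant rows: {sorted(set(dup))}"
        )
    unknown = [c for c in df.columns[1:] if c not in meta]
    if unknown:
        raise ConfigError(f"{path}: no metadata for predictors {unknown}")
    variants = [parse_variant_notation(s) for s in df.iloc[:, 0]]
    scores = pd.DataFrame(index=df.iloc[:, 0].tolist())
    scores.index.name = "variant"
    for name in df.columns[1:]:
        raw = df[name].str.strip()
        vals = pd.to_numeric(raw.mask(raw.isin(MISSING_TOKENS)), errors="raise")
        if meta[name].transform == ABSOLUTE_VALUE:
            vals = vals.abs()
        scores[name] = vals.to_numpy()
        n_zero = int((scores[name] == 0.0).sum()) if meta[name].directionality != FLAG else 0
        if n_zero:
            logger.info(
                "%s: predictor %s has %d exact-zero scores", path, name, n_zero
            )
    return PredictorScoreTable(variants=variants, scores=scores, meta=meta)


def write_score_table(table: PredictorScoreTable, path: str | Path) -> None:
    """Write the (already transformed) table; missing cells become ``.``."""
    out = table.scores.copy()
    out.insert(0, "variant", out.index)
    out.to_csv(path, sep="\t", index=False, na_rep=".")


# ---------------------------------------------------------------------------
# ClinVar-style missense filtering
# ---------------------------------------------------------------------------

_THREE_TO_ONE = {
    "Ala": "A", "Cys": "C", "Asp": "D", "Glu": "E", "Phe": "F", "Gly": "G",
    "His": "H", "Ile": "I", "Lys": "K", "Leu": "L", "Met": "M", "Asn": "N",
    "Pro": "P", "Gln": "Q", "Arg": "R", "Ser": "S", "Thr": "T", "Val": "V",
    "Trp": "W", "Tyr": "Y",
}

SNV_TYPES = {"snv", "single_nucleotide_variant", "single nucleotide variant"}
MISSENSE_TERMS = {"missense", "missense_variant", "non-synonymous", "nonsynonymous"}


def _parse_protein_change(s: str) -> SAV:
    s = s.strip()
    if s.startswith("p."):
        s = s[2:]
    if len(s) >= 7 and s[:3] in _THREE_TO_ONE:  # p.Cys130Arg style
        ref3, alt3 = s[:3], s[-3:]
        if ref3 in _THREE_TO_ONE and alt3 in _THREE_TO_ONE:
            s = _THREE_TO_ONE[ref3] + s[3:-3] + _THREE_TO_ONE[alt3]
    return parse_variant_notation(s)


def filter_clinvar_missense(path: str | Path, gene: str) -> List[SAV]:
    """Extract missense SAVs for one gene from a ClinVar-style file.

    Keeps records that (1) match ``gene``, (2) are single-nucleotide
    variants, and (3) are missense; all insertions and deletions are
    excluded.  Records are deduplicated at the protein level, first
    occurrence kept, order preserved.  Passing records without a parseable
    protein change are excluded with a warning.

    Both a simplified tab-delimited dialect (columns ``gene``,
    ``variant_type``, ``consequence``, ``protein_change``) and a VCF subset
    (INFO keys ``GENEINFO``, ``CLNVC``, ``MC``, ``PCHANGE``) are supported.
    """
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        rows = _read_clinvar_vcf(path)
    else:
        rows = _read_clinvar_tsv(path)
    out: List[SAV] = []
    seen = set()
    n_dropped = n_collapsed = 0
    for rec in rows:
        if rec["gene"] != gene:
            continue
        if rec["variant_type"].strip().lower() not in SNV_TYPES:
            continue
        cons = rec["consequence"].strip().lower()
        if not any(term in cons for term in MISSENSE_TERMS):
            continue
        pchange = rec.get("protein_change", "").strip()
        if not pchange or pchange in MISSING_TOKENS:
            n_dropped += 1
            continue
        try:
            sav = _parse_protein_change(pchange)
        except (FormatError, ValidationError):
            n_dropped += 1
            continue
        key = str(sav)
        if key in seen:
            n_collapsed += 1
            continue
        seen.add(key)
        out.append(sav)
    if n_dropped:
        logger.warning(
            "%s: %d passing records lacked a usable protein change", path, n_dropped
        )
    if n_collapsed:
        logger.info(
            "%s: collapsed %d duplicate protein-level records", path, n_collapsed
        )
    return out


def _read_clinvar_tsv(path: Path) -> List[dict]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene", "variant_type", "consequence"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: expected columns {sorted(required)} (plus protein_change)"
        )
    return df.to_dict("records")


def _read_clinvar_vcf(path: Path) -> List[dict]:
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            geneinfo = str(info.get("GENEINFO", "") or "")
            gene = geneinfo.split(":")[0] if geneinfo else ""
            mc = info.get("MC", ())
            if isinstance(mc, str):
                mc = (mc,)
            rows.append({
                "gene": gene,
                "variant_type": str(info.get("CLNVC", "") or ""),
                "consequence": ";".join(str(x) for x in mc),
                "protein_change": str(info.get("PCHANGE", "") or ""),
            })
    return rows


# ---------------------------------------------------------------------------
# Annotations: clinical labels, allele frequencies, conservation
# ---------------------------------------------------------------------------

PATHOGENIC = "pathogenic"
BENIGN = "benign"
UNLABELED = "unlabeled"

_LABEL_MAP = {
    "pathogenic": PATHOGENIC,
    "likely_pathogenic": PATHOGENIC,
    "likely pathogenic": PATHOGENIC,
    "benign": BENIGN,
    "likely_benign": BENIGN,
    "likely benign": BENIGN,
}


@dataclass
class LabeledVariantSet:
    """Per-variant clinical label, maximum population allele frequency and
    conservation score (GERP++-style units); any field but the variant may
    be missing."""

    frame: pd.DataFrame  # index: variant notation; columns: label, allele_frequency, conservation

    def __post_init__(self) -> None:
        af = self.frame["allele_frequency"]
        bad = af.dropna()[(af.dropna() < 0) | (af.dropna() > 1)]
        if not bad.empty:
            raise ValidationError(
                f"allele frequencies outside [0, 1]: {bad.to_dict()}"
            )

    @property
    def variants(self) -> List[SAV]:
        return [parse_variant_notation(s) for s in self.frame.index]

    def labels(self) -> pd.Series:
        return self.frame["label"]


def load_annotations(path: str | Path) -> LabeledVariantSet:
    """Load a tab-delimited annotation table (``variant`` plus any subset of
    ``label``, ``allele_frequency``, ``conservation``).

    Labels are normalized to pathogenic / benign / unlabeled; conflicting or
    uncertain interpretations map to unlabeled.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "variant" not in df.columns:
        raise FormatError(f"{path}: missing 'variant' column")
    idx = df["variant"].tolist()
    for v in idx:
        parse_variant_notation(v)
    out = pd.DataFrame(index=idx)
    out.index.name = "variant"
    if "label" in df.columns:
        raw = df["label"].str.strip().str.lower()
        out["label"] = [
            _LABEL_MAP.get(s, UNLABELED) if s not in MISSING_TOKENS else UNLABELED
            for s in raw
        ]
    else:
        out["label"] = UNLABELED
    for col in ("allele_frequency", "conservation"):
        if col in df.columns:
            raw = df[col].str.strip()
            out[col] = pd.to_numeric(
                raw.mask(raw.isin(MISSING_TOKENS)), errors="raise"
            ).to_numpy()
        else:
            out[col] = np.nan
    return LabeledVariantSet(frame=out)


def neglog10_af(af: float) -> float:
    """-log10 of an allele frequency in (0, 1].

    Zero or missing frequencies have no finite value on this scale and must
    be excluded upstream (no pseudo-count is applied).
    """
    if not 0 < af <= 1:
        raise ValidationError(f"allele frequency must be in (0, 1], got {af}")
    return float(-np.log10(af))
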