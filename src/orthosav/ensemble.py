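"""Majority-vote ensemble over orthogonal variant-effect predictors.

Each tool gets a binary damaging/non-damaging call from a per-tool rule:
either a fixed cutoff (e.g. signed ddG <= -0.5 kcal/mol for a
DynaMut2-style stability predictor, flag == 1 for a structural-damage
classifier) or a percentile cutoff derived from the analyzed score
distribution (e.g. "top 25 percent" of language-model or RMSD scores).
Cutoff comparisons are inclusive.  A variant whose damaging calls reach the
vote threshold (default 2 of 4) is a *candidate*; a variant called
non-damaging by every tool, with no missing score, is a *benign candidate*;
everything else is indeterminate.  Missing scores never count as evidence
but block the unanimous benign call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from ._errors import ConfigError, OrthosavError, ValidationError
from .predictor_io import FLAG, LOWER_IS_DAMAGING, PredictorScoreTable
from .seqvar import SAV

logger = logging.getLogger(__name__)

DAMAGING = "damaging"
NON_DAMAGING = "non_damaging"
MISSING = "missing"

CANDIDATE = "candidate"
BENIGN_CANDIDATE = "benign_candidate"
INDETERMINATE = "indeterminate"

GE = "ge"
LE = "le"
FLAG_EQ_1 = "flag_eq_1"

FIXED = "fixed"
UPPER_PERCENTILE = "upper_percentile"


@dataclass(frozen=True)
class ToolRule:
    """Thresholding rule for one predictor.

    ``direction``: ``ge`` (damaging iff score >= cutoff), ``le`` (damaging
    iff score <= cutoff) or ``flag_eq_1``.  ``cutoff_mode``: ``fixed`` uses
    ``cutoff`` as-is; ``upper_percentile`` derives the cutoff so that the top
    ``percentile`` percent of the tool's non-missing scores (in the damaging
    direction) are called damaging.
    """

    direction: str
    cutoff: Optional[float] = None
    cutoff_mode: str = FIXED
    percentile: Optional[float] = None

    def __post_init__(self) -> None:
        if self.direction not in (GE, LE, FLAG_EQ_1):
            raise ConfigError(f"unknown direction {self.direction!r}")
        if self.cutoff_mode not in (FIXED, UPPER_PERCENTILE):
            raise ConfigError(f"unknown cutoff_mode {self.cutoff_mode!r}")
        if self.direction == FLAG_EQ_1:
            return
        if self.cutoff_mode == FIXED and self.cutoff is None:
            raise ConfigError("fixed cutoff_mode requires a cutoff value")
        if self.cutoff_mode == UPPER_PERCENTILE:
            if self.percentile is None or not 0 < self.percentile < 100:
                raise ConfigError("upper_percentile mode requires percentile in (0, 100)")


@dataclass
class EnsembleConfig:
    """Per-tool rules plus the majority-vote threshold (default 2)."""

    rules: Dict[str, ToolRule]
    vote_threshold: int = 2
    benign_threshold: int = 0

    def __post_init__(self) -> None:
        if self.vote_threshold < 1:
            raise ConfigError("vote_threshold must be >= 1")
        if self.benign_threshold != 0:
            raise ConfigError("benign classification requires zero damaging calls")
        if not self.rules:
            raise ConfigError("at least one tool rule is required")


def default_config() -> EnsembleConfig:
    """The worked-example configuration: four orthogonal tools with the
    published cutoffs (language-model LLR >= 7.97, signed ddG <= -0.5,
    structural flag == 1, superposition RMSD >= 6.42) and a 2-of-4 vote."""
    from importlib import resources

    ref = resources.files("orthosav.data").joinpath("default_ensemble.yaml")
    with resources.as_file(ref) as p:
        return load_config(p)


def load_config(path: str | Path) -> EnsembleConfig:
    """Load an ensemble configuration from YAML."""
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(raw, dict) or "predictors" not in raw:
        raise ConfigError(f"{path}: config must contain a 'predictors' mapping")
    rules = {}
    for name, spec in raw["predictors"].items():
        if not isinstance(spec, dict) or "direction" not in spec:
            raise ConfigError(f"{path}: predictor {name!r} needs a 'direction'")
        rules[name] = ToolRule(
            direction=spec["direction"],
            cutoff=spec.get("cutoff"),
            cutoff_mode=spec.get("cutoff_mode", FIXED),
            percentile=spec.get("percentile"),
        )
    return EnsembleConfig(
        rules=rules,
        vote_threshold=int(raw.get("vote_threshold", 2)),
        benign_threshold=int(raw.get("benign_threshold", 0)),
    )


def percentile_cutoff(scores, p: float) -> float:
    """Cutoff c such that scores >= c form the top ``p`` percent.

    Computed as the linear-interpolation quantile at (100 - p)/100 of the
    non-missing scores; with ``p`` = 25 this is the 75th percentile.
    """
    arr = np.asarray(pd.Series(scores).dropna(), dtype=float)
    if arr.size == 0:
        raise ConfigError("percentile cutoff over an empty (all-missing) score list")
    if not 0 < p < 100:
        raise ConfigError(f"percentile must be in (0, 100), got {p}")
    return float(np.quantile(arr, (100.0 - p) / 100.0))


def resolve_cutoffs(cfg: EnsembleConfig, table: PredictorScoreTable) -> Dict[str, float]:
    """Concrete per-tool cutoffs for a score table.

    Percentile-mode cutoffs are taken over the analyzed variant set; for
    ``le`` tools the top percentile is in the low tail, so the quantile is
    mirrored.
    """
    out: Dict[str, float] = {}
    for name, rule in cfg.rules.items():
        if rule.direction == FLAG_EQ_1:
            out[name] = 1.0
        elif rule.cutoff_mode == FIXED:
            out[name] = float(rule.cutoff)
        else:
            if name not in table.scores.columns:
                raise ConfigError(
                    f"percentile cutoff for {name!r} needs a score column"
                )
            col = table.scores[name]
            if rule.direction == GE:
                out[name] = percentile_cutoff(col, rule.percentile)
            else:
                out[name] = -percentile_cutoff(-col, rule.percentile)
    return out


def call_tool(score: float, rule: ToolRule, cutoff: Optional[float] = None) -> str:
    """Binary call for one tool on one variant; missing scores propagate."""
    if score is None or (isinstance(score, float) and np.isnan(score)):
        return MISSING
    if rule.direction == FLAG_EQ_1:
        return DAMAGING if score == 1 else NON_DAMAGING
    c = rule.cutoff if cutoff is None else cutoff
    if c is None:
        raise ConfigError("no cutoff available for fixed-mode call")
    if rule.direction == GE:
        return DAMAGING if score >= c else NON_DAMAGING
    return DAMAGING if score <= c else NON_DAMAGING


def evidence_count(v: SAV | str, table: PredictorScoreTable, cfg: EnsembleConfig) -> int:
    """Number of tools calling ``v`` damaging under ``cfg``."""
    key = str(v)
    if key not in table.scores.index:
        raise OrthosavError(f"variant {key} not present in score table")
    cutoffs = resolve_cutoffs(cfg, table)
    n = 0
    for name, rule in cfg.rules.items():
        if name not in table.scores.columns:
            continue
        score = table.scores.at[key, name]
        if call_tool(score, rule, cutoffs[name]) == DAMAGING:
            n += 1
    return n


def _damaging_percentile_ranks(table: PredictorScoreTable, cfg: EnsembleConfig) -> pd.DataFrame:
    """Percentile rank of each score in the damaging direction, per tool."""
    ranks = pd.DataFrame(index=table.scores.index)
    for name, rule in cfg.rules.items():
        if name not in table.scores.columns:
            continue
        col = table.scores[name]
        oriented = -col if rule.direction == LE else col
        ranks[name] = oriented.rank(pct=True, method="average")
    return ranks


def classify_variants(table: PredictorScoreTable, cfg: Optional[EnsembleConfig] = None) -> pd.DataFrame:
    """Classify every variant in the table by majority vote.

    Returns a DataFrame indexed by variant with one ``call_<tool>`` column
    per configured tool, ``evidence_count`` and ``classification``
    (candidate / benign_candidate / indeterminate).  Rows are sorted by
    evidence count descending, ties broken by the maximum within-tool
    percentile rank in the damaging direction, then by variant notation for
    determinism.  Score columns not named in the configuration are ignored.
    """
    if cfg is None:
        cfg = default_config()
    if len(table) == 0:
        raise ValidationError("cannot classify an empty score table")
    cutoffs = resolve_cutoffs(cfg, table)
    tools = [n for n in cfg.rules if n in table.scores.columns]
    if not tools:
        raise ConfigError("no configured tool has a score column in the table")
    result = pd.DataFrame(index=table.scores.index)
    result.index.name = "variant"
    calls = {}
    for name in tools:
        rule = cfg.rules[name]
        calls[name] = table.scores[name].map(
            lambda s, rule=rule, c=cutoffs[name]: call_tool(s, rule, c)
        )
        result[f"call_{name}"] = calls[name]
    call_frame = pd.DataFrame(calls)
    result["evidence_count"] = (call_frame == DAMAGING).sum(axis=1)
    n_missing = (call_frame == MISSING).sum(axis=1)
    all_missing = n_missing == len(tools)
    if all_missing.any():
        logger.warning(
            "%d variants have no scores from any configured tool; indeterminate",
            int(all_missing.sum()),
        )
    classification = np.where(
        result["evidence_count"] >= cfg.vote_threshold,
        CANDIDATE,
        np.where(
            (result["evidence_count"] == 0) & (n_missing == 0),
            BENIGN_CANDIDATE,
            INDETERMINATE,
        ),
    )
    result["classification"] = classification
    tie_break = _damaging_percentile_ranks(table, cfg).max(axis=1)
    result["_tie"] = tie_break
    result = result.sort_values(
        by=["evidence_count", "_tie", "variant"],
        ascending=[False, False, True],
        kind="mergesort",
    ).drop(columns="_tie")
    return result


def candidates(result: pd.DataFrame) -> List[str]:
    """Candidate variant notations from a :func:`classify_variants` result."""
    return result.index[result["classification"] == CANDIDATE].tolist()


def write_classification(result: pd.DataFrame, path: str | Path) -> None:
    out = result.copy()
    out.insert(0, "variant", out.index)
    out.to_csv(path, sep="\t", index=False)
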