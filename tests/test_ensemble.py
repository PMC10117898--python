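import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orthosav import (
    EnsembleConfig,
    ToolRule,
    call_tool,
    classify_variants,
    default_config,
    evidence_count,
    percentile_cutoff,
)
from orthosav.ensemble import (
    BENIGN_CANDIDATE,
    CANDIDATE,
    DAMAGING,
    INDETERMINATE,
    MISSING,
    NON_DAMAGING,
    candidates,
    load_config,
)
from orthosav._errors import ConfigError
from orthosav.predictor_io import DEFAULT_META, PredictorScoreTable
from orthosav.seqvar import parse_variant_notation
from orthosav.synthetic_data import gen_score_table


def make_table(rows: dict) -> PredictorScoreTable:
    scores = pd.DataFrame.from_dict(rows, orient="index",
                                    columns=["ESM", "DynaMut", "Missense3D", "AlphaFold"])
    scores.index.name = "variant"
    return PredictorScoreTable(
        variants=[parse_variant_notation(v) for v in rows],
        scores=scores.astype(float),
        meta={k: DEFAULT_META[k] for k in scores.columns},
    )


class TestPercentileCutoff:
    def test_constant_list(self):
        assert percentile_cutoff([5, 5, 5, 5], 25) == 5

    def test_linear_interpolation_quantile(self):
        # 75th percentile of [1,2,3,4] by linear interpolation
        assert percentile_cutoff([1, 2, 3, 4], 25) == pytest.approx(3.25)

    def test_independent_order_statistics_check(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=37)
        # manual linear-interpolation quantile at 0.75
        s = np.sort(x)
        h = 0.75 * (len(s) - 1)
        lo, frac = int(np.floor(h)), h - np.floor(h)
        expected = s[lo] + frac * (s[lo + 1] - s[lo])
        assert percentile_cutoff(x, 25) == pytest.approx(expected, abs=1e-12)

    def test_missing_dropped_and_empty_rejected(self):
        assert percentile_cutoff([np.nan, 1.0, np.nan, 3.0], 50) == pytest.approx(2.0)
        with pytest.raises(ConfigError):
            percentile_cutoff([np.nan, np.nan], 25)


class TestCallTool:
    le_rule = ToolRule(direction="le", cutoff=-0.5)
    ge_rule = ToolRule(direction="ge", cutoff=7.97)
    flag_rule = ToolRule(direction="flag_eq_1")

    @pytest.mark.parametrize("score,rule,expected", [
        (-1.07, le_rule, DAMAGING),        # destabilizing ddG
        (-0.48, le_rule, NON_DAMAGING),    # above the signed cutoff
        (-0.5, le_rule, DAMAGING),         # inclusive comparison
        (0.0, ge_rule, NON_DAMAGING),      # zero LLR below cutoff
        (7.97, ge_rule, DAMAGING),         # inclusive comparison
        (1.0, flag_rule, DAMAGING),
        (0.0, flag_rule, NON_DAMAGING),
        (np.nan, ge_rule, MISSING),
    ])
    def test_calls(self, score, rule, expected):
        assert call_tool(score, rule) == expected


class TestEvidenceCount:
    def test_published_counts(self, published_scores):
        cfg = default_config()
        expected = {"C130R": 3, "R163C": 3, "R132C": 3,
                    "R163P": 2, "R160C": 2, "L46P": 0}
        for variant, count in expected.items():
            assert evidence_count(variant, published_scores, cfg) == count

    def test_all_four_damaging(self):
        t = make_table({"C130R": [10.0, -1.0, 1.0, 20.0]})
        assert evidence_count("C130R", t, default_config()) == 4

    def test_absent_variant_is_error(self, published_scores):
        from orthosav import OrthosavError
        with pytest.raises(OrthosavError):
            evidence_count("A19C", published_scores, default_config())


class TestClassifyVariants:
    def test_published_candidate_set(self, published_scores):
        res = classify_variants(published_scores)
        assert set(candidates(res)) == {"C130R", "R163C", "R132C", "R163P", "R160C"}
        assert res.at["L46P", "classification"] == BENIGN_CANDIDATE
        # the unanimously non-damaging variant has no damaging call at all
        calls = res.loc["L46P", [c for c in res.columns if c.startswith("call_")]]
        assert (calls == NON_DAMAGING).all()

    def test_vote_threshold_three(self, published_scores):
        cfg = default_config()
        cfg.vote_threshold = 3
        res = classify_variants(published_scores, cfg)
        assert set(candidates(res)) == {"C130R", "R163C", "R132C"}

    def test_nesting_over_vote_thresholds(self, published_scores):
        sets = []
        for k in (1, 2, 3):
            cfg = default_config()
            cfg.vote_threshold = k
            sets.append(set(candidates(classify_variants(published_scores, cfg))))
        assert sets[0] >= sets[1] >= sets[2]

    def test_permutation_invariance(self, published_scores):
        rng = np.random.default_rng(0)
        base = set(candidates(classify_variants(published_scores)))
        shuffled = published_scores.scores.sample(frac=1.0, random_state=1)
        t = PredictorScoreTable(
            variants=[parse_variant_notation(v) for v in shuffled.index],
            scores=shuffled, meta=published_scores.meta,
        )
        assert set(candidates(classify_variants(t))) == base

    def test_all_missing_variant_indeterminate(self, caplog):
        t = make_table({
            "C130R": [np.nan, np.nan, np.nan, np.nan],
            "L46P": [1.0, 0.0, 0.0, 1.0],
        })
        with caplog.at_level("WARNING"):
            res = classify_variants(t)
        assert res.at["C130R", "classification"] == INDETERMINATE
        assert res.at["C130R", "evidence_count"] == 0

    def test_missing_blocks_benign_call(self):
        t = make_table({"L46P": [1.0, 0.0, np.nan, 1.0]})
        res = classify_variants(t)
        assert res.at["L46P", "classification"] == INDETERMINATE

    def test_monotonicity_raising_a_score_never_lowers_evidence(self, published_scores):
        cfg = default_config()
        base = {v: evidence_count(v, published_scores, cfg)
                for v in published_scores.scores.index}
        bumped = published_scores.scores.copy()
        bumped["ESM"] = bumped["ESM"] + 5.0  # higher-is-damaging column
        t = PredictorScoreTable(variants=published_scores.variants,
                                scores=bumped, meta=published_scores.meta)
        for v, old in base.items():
            assert evidence_count(v, t, cfg) >= old

    @pytest.mark.parametrize("seed", range(20))
    def test_planted_variant_recovery(self, seed):
        table, truth = gen_score_table(n_variants=38, n_damaging=5, seed=seed)
        res = classify_variants(table)
        assert set(candidates(res)) == set(truth.planted_damaging_variants)

    def test_background_missing_rate_one(self):
        table, truth = gen_score_table(n_variants=20, n_damaging=3,
                                       missing_rate=1.0, seed=1)
        res = classify_variants(table)
        planted = set(truth.planted_damaging_variants)
        for v in table.scores.index:
            expected = CANDIDATE if v in planted else INDETERMINATE
            assert res.at[v, "classification"] == expected


class TestConfig:
    def test_percentile_mode_resolution(self):
        from orthosav.ensemble import resolve_cutoffs
        t = make_table({
            "C130R": [1.0, -1.0, 1.0, 1.0],
            "L46P": [2.0, -1.0, 0.0, 2.0],
            "R132C": [3.0, -1.0, 0.0, 3.0],
            "R160C": [4.0, -1.0, 0.0, 4.0],
        })
        cfg = EnsembleConfig(rules={
            "ESM": ToolRule(direction="ge", cutoff_mode="upper_percentile", percentile=25),
        })
        cutoffs = resolve_cutoffs(cfg, t)
        assert cutoffs["ESM"] == pytest.approx(3.25)

    def test_yaml_roundtrip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text(
            "vote_threshold: 2\n"
            "predictors:\n"
            "  ESM: {direction: ge, cutoff: 7.97}\n"
            "  DynaMut: {direction: le, cutoff: -0.5}\n"
        )
        cfg = load_config(p)
        assert cfg.vote_threshold == 2
        assert cfg.rules["DynaMut"].cutoff == -0.5

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            ToolRule(direction="ge")  # fixed mode without a cutoff
        with pytest.raises(ConfigError):
            ToolRule(direction="ge", cutoff_mode="upper_percentile", percentile=150)
        with pytest.raises(ConfigError):
            EnsembleConfig(rules={}, vote_threshold=2)
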