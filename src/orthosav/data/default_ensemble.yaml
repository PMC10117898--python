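# Default majority-vote configuration for the four orthogonal predictors.
# Cutoffs are the published worked-example values: the two continuous
# predictors (language-model LLR, superposition RMSD) use fixed cutoffs that
# were originally derived as top-25-percentile values over the analyzed
# variant set; the stability ddG cutoff is signed (destabilizing <= -0.5);
# the structural-damage predictor is a binary flag.
vote_threshold: 2
benign_threshold: 0
predictors:
  ESM:
    direction: ge
    cutoff: 7.97
  DynaMut:
    direction: le
    cutoff: -0.5
  Missense3D:
    direction: flag_eq_1
  AlphaFold:
    direction: ge
    cutoff: 6.42
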