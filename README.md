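# flowcpm

Behavioral and connectome-based dissociation of the two faces of creative
idea generation: **novelty** and **appropriateness**.

Creativity research scores an idea on two axes — how original it is and
how sensible it is — and asks which cognitive systems support each.
`flowcpm` implements the full analysis pipeline for that question as a
reusable Python library, exercised end-to-end on synthetic cohorts with
planted ground truth:

1. **Behavioral scoring.** Associative ability from free-association
   word streams via the *forward flow* statistic; executive function
   from a three-task battery (2-back, stop-signal with
   integration-method SSRT, number–letter switching) aggregated into
   standardized RT and accuracy composites; novelty/appropriateness from
   multi-rater alternative-uses-task (AUT) ratings.
2. **Dissociation GLMs.** OLS models testing whether novelty loads on
   associative ability while appropriateness loads on executive speed.
3. **Connectome-based predictive modeling (CPM).** Edge-wise feature
   selection (p < 0.01 Pearson or partial correlation) feeding a
   relevance vector regression (sparse Bayesian, linear kernel) under
   repeated 10-fold cross-validation, with permutation-test inference
   and >80%-retention consensus edge masks.
4. **Network decomposition.** Mask edges mapped onto the 28 within-/
   between-network pairs of the Yeo–Krienen 7-network cortical scheme,
   with cross-variant similarity summaries.
5. **External validation.** Transfer to an independent resting-state
   cohort (partial correlation, one-tailed) and to block-wise task
   connectivity (per-participant Spearman ρ vs. a shuffled-assignment
   null, group-level Wilcoxon signed-rank).
6. **Mediation.** Percentile-bootstrap mediation linking cognition →
   brain pattern → creativity rating.

## The statistics at the core

**Forward flow** of a thought stream with `n` thoughts and pairwise
semantic distances `D[i, j] = 1 − cos(vᵢ, vⱼ)` over word-embedding
vectors:

```
FF = ( Σ_{i=2..n}  Σ_{j=1..i-1} D[i, j] / (i − 1) ) / (n − 1)
```

i.e. the mean, over positions, of each thought's average distance from
all preceding thoughts.

**Integration-method SSRT** at stop-signal delay `s` with observed
respond-given-signal probability `p`: `SSRT(s) = Q_p(go RT) − s`, the
p-quantile of the go distribution minus the delay, averaged over delays.

**CPM with RVR**: within each training fold, every connectome edge is
correlated with the behavioral score; suprathreshold positive and
negative edges jointly enter a relevance vector regression
`y = Σ_m w_m k(x, x_m) + b` whose per-basis prior precisions αₘ are set
by evidence maximization, pruning all but a few "relevance vectors".
Significance is the permutation p-value
`p_pt = (1 + #{r_null ≥ r_obs}) / (1 + n_perm)`.

**Mediation**: paths `a` (X→M), `b` (M→Y|X), `c` (total), `c′` (direct);
the indirect effect is `a·b` with percentile bootstrap intervals, and
`c = c′ + a·b` exactly for OLS on one sample.

## Worked example

```bash
python examples/03_cpm_prediction.py
```

prints (seeded, so exactly reproducible):

```
cross-validated prediction r = 0.851
permutation p_pt = 0.010  (observed vs 99 shuffled cohorts)
consensus mask: 11 positive, 10 negative edges (of 435)
planted edges recovered: 20/20
```

A 200-participant synthetic cohort carries 20 planted edges whose
Fisher-z weight couples to behavior at r = ±0.4. The cross-validated
prediction correlates with the observed score at r = 0.85, beats all 99
permutations (the smallest p the add-one convention can report), and the
consensus mask recovers every planted edge while admitting only one
noise edge. The other scripts in `examples/` walk through forward-flow
scoring, the behavioral GLMs, network decomposition, mediation and the
full pipeline (`run_all`), each printing what its numbers mean.

## Layout

```
src/flowcpm/
  semantic.py     forward flow, cosine distances, associative ability
  behavior.py     AUT aggregation, EF task scoring, outlier rule, GLMs
  connectome.py   Fisher-z FC matrices, canonical edge ordering, atlas
  rvr.py          relevance vector regression (sequential evidence max.)
  cpm.py          selection, cross-validation, permutation, masks,
                  external validation, specificity profiles
  networks.py     28-pair network decomposition and variant similarity
  mediation.py    bootstrap mediation
  synthetic.py    generators for every input, with planted ground truth
  studies.py      calibration/recovery simulation studies
  pipeline.py     run_all: the one-seed end-to-end replica
  io.py           word2vec-text, CSV/TSV and matrix readers/writers
```

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.
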