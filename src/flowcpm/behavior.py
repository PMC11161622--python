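"""Behavioral battery scoring and the dissociation GLMs.

The battery comprises:

* the alternative-uses task (AUT), rated 1-5 for novelty and
  appropriateness by multiple raters over two items (brick, can);
* three executive-function tasks — 2-back (working memory), stop-signal
  (inhibitory control, scored by the integration-method SSRT) and
  number-letter category switching (flexibility, scored by the switch
  cost);
* the forward-flow association task (scored in :mod:`flowcpm.semantic`).

Reaction times of the three EF tasks are each z-scored across the cohort
and averaged into a single RT composite (lower = better executive
function); accuracies likewise into an ACC composite, entered into the
GLMs as a speed-accuracy control.

The dissociation GLMs regress novelty or appropriateness on associative
ability and the EF composites (model "1"), optionally with their
interaction ("1x") or demographic covariates ("2").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._utils import CollinearityError, DegenerateDataError

logger = logging.getLogger(__name__)

__all__ = [
    "aggregate_aut",
    "cronbach_alpha",
    "score_nback",
    "ssrt_integration",
    "score_switch",
    "executive_composites",
    "exclude_outliers",
    "dissociation_glm",
    "GlmResult",
]

#: standardized columns checked by the outlier rule
Z_COLUMNS = ["novelty_z", "appropriateness_z", "assoc_z", "ef_rt_z", "ef_acc_z"]


def _cohort_z(s: pd.Series, ddof: int = 1) -> pd.Series:
    sd = s.std(ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateDataError(f"zero variance in column {s.name!r}")
    return (s - s.mean()) / sd


def aggregate_aut(
    ratings: pd.DataFrame, ddof: int = 1, on_missing_item: str = "exclude"
) -> pd.DataFrame:
    """Aggregate AUT ratings into per-participant novelty/appropriateness z.

    ``ratings`` columns: participant_id, item_id, response_index, rater,
    novelty, appropriateness (1-5 scales; ragged response counts allowed).

    Aggregation order: mean over responses within (participant, item,
    rater) -> mean over raters -> z-score across the cohort within each
    item -> mean over items.  Participants missing an item are excluded
    with a log message (``on_missing_item='error'`` raises instead).
    """
    required = {"participant_id", "item_id", "rater", "novelty", "appropriateness"}
    missing = required - set(ratings.columns)
    if missing:
        raise ValueError(f"ratings table missing columns: {sorted(missing)}")
    for dim in ("novelty", "appropriateness"):
        vals = ratings[dim]
        if vals.min() < 1 or vals.max() > 5:
            raise ValueError(f"{dim} ratings must lie in [1, 5]")

    per_rater = (
        ratings.groupby(["participant_id", "item_id", "rater"])[
            ["novelty", "appropriateness"]
        ].mean()
    )
    per_item = per_rater.groupby(["participant_id", "item_id"]).mean()

    n_items = ratings["item_id"].nunique()
    counts = per_item.groupby("participant_id").size()
    incomplete = counts[counts < n_items].index
    if len(incomplete):
        if on_missing_item == "error":
            raise ValueError(f"participants missing an item: {list(incomplete)}")
        logger.warning(
            "excluding %d participant(s) missing an AUT item: %s",
            len(incomplete), list(incomplete),
        )
        per_item = per_item.drop(index=incomplete, level="participant_id")

    z_parts = []
    for item, grp in per_item.groupby(level="item_id"):
        z_parts.append(grp.apply(lambda c: _cohort_z(c, ddof)))
    z = pd.concat(z_parts).sort_index()
    out = z.groupby("participant_id").mean()
    out.columns = ["novelty_z", "appropriateness_z"]
    return out


def cronbach_alpha(scores: np.ndarray | pd.DataFrame) -> float:
    """Cronbach's alpha of a participants x raters score matrix.

    alpha = k/(k-1) * (1 - sum of per-rater variances / variance of the
    rater sum), with sample (ddof=1) variances.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2 or x.shape[0] < 3:
        raise ValueError("need a 2-D matrix with >=3 participants and >=2 raters")
    k = x.shape[1]
    item_vars = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise DegenerateDataError("zero variance of rater sums")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def score_nback(trials: pd.DataFrame) -> tuple[float, float]:
    """(mean RT, accuracy) for the 2-back task.

    ``trials`` columns: rt (ms), correct (bool), responded (bool).  RT is
    averaged over correct responded trials only; accuracy is the correct
    fraction among responded trials (no-response trials excluded).
    Returns ``(nan, nan)`` when no trial is usable.
    """
    responded = trials[trials["responded"].astype(bool)]
    correct = responded[responded["correct"].astype(bool)]
    if len(correct) == 0 or len(responded) == 0:
        return (math.nan, math.nan)
    return (
        float(correct["rt"].mean()),
        float(responded["correct"].mean()),
    )


def _nearest_rank_quantile(sorted_rts: np.ndarray, p: float) -> float:
    """Nearest-rank quantile: the ceil(p*n)-th smallest value."""
    n = len(sorted_rts)
    idx = max(int(math.ceil(p * n)) - 1, 0)
    return float(sorted_rts[min(idx, n - 1)])


def ssrt_integration(
    go_rts, stop_by_ssd: dict[float, tuple[int, int]]
) -> float:
    """Integration-method stop-signal reaction time.

    For each stop-signal delay (SSD) with observed respond-given-signal
    probability p, the stopping latency is the p-quantile of the go-RT
    distribution minus the SSD; the overall SSRT averages these per-SSD
    estimates.  ``stop_by_ssd`` maps SSD (ms) -> (n stop trials,
    n responded).  SSDs with p = 0 are skipped with a warning; if all are
    skipped the score is NaN (missing-score marker).

    The quantile is nearest-rank on the sorted go-RT list.
    """
    go = np.sort(np.asarray(list(go_rts), dtype=float))
    if go.size == 0:
        raise ValueError("empty go-RT distribution")
    per_ssd = []
    for ssd, (n_stop, n_resp) in stop_by_ssd.items():
        if n_stop <= 0 or n_resp < 0 or n_resp > n_stop:
            raise ValueError(f"invalid stop counts at SSD {ssd}: ({n_stop}, {n_resp})")
        p = n_resp / n_stop
        if p == 0:
            logger.warning("SSD %s skipped: no signal-respond trials", ssd)
            continue
        per_ssd.append(_nearest_rank_quantile(go, p) - float(ssd))
    if not per_ssd:
        return math.nan
    return float(np.mean(per_ssd))


def score_switch(
    trials: pd.DataFrame, correct_only: bool = True
) -> tuple[float, float]:
    """(switch cost, accuracy) for the number-letter switching task.

    ``trials`` columns: trial_type ('switch'|'repeat'), rt (ms), correct
    (bool), responded (bool).  Switch cost = mean RT on switch trials minus
    mean RT on repeat trials, over correct responded trials by default
    (``correct_only=False`` uses all responded trials).  Accuracy is the
    unweighted mean of the per-type correct fractions, no-response counting
    as incorrect.  Returns ``(nan, nan)`` if either trial type has no
    usable RT trial.
    """
    rts, accs = {}, {}
    for ttype in ("switch", "repeat"):
        sub = trials[trials["trial_type"] == ttype]
        if len(sub) == 0:
            return (math.nan, math.nan)
        accs[ttype] = float(sub["correct"].astype(bool).mean())
        pool = sub[sub["responded"].astype(bool)]
        if correct_only:
            pool = pool[pool["correct"].astype(bool)]
        if len(pool) == 0:
            return (math.nan, math.nan)
        rts[ttype] = float(pool["rt"].mean())
    cost = rts["switch"] - rts["repeat"]
    acc = (accs["switch"] + accs["repeat"]) / 2.0
    return (cost, acc)


def executive_composites(
    task_scores: pd.DataFrame, ddof: int = 1
) -> pd.DataFrame:
    """EF composites: mean of cohort-z RT scores and of cohort-z accuracies.

    ``task_scores`` is indexed by participant with columns nback_rt, ssrt,
    switch_cost_rt, nback_acc, stop_acc, switch_acc.  Participants with any
    missing score are excluded (listwise) with a log message.  Returns a
    frame with ef_rt_z and ef_acc_z (lower ef_rt_z = better executive
    function).
    """
    rt_cols = ["nback_rt", "ssrt", "switch_cost_rt"]
    acc_cols = ["nback_acc", "stop_acc", "switch_acc"]
    missing = set(rt_cols + acc_cols) - set(task_scores.columns)
    if missing:
        raise ValueError(f"task score table missing columns: {sorted(missing)}")
    complete = task_scores.dropna(subset=rt_cols + acc_cols)
    dropped = len(task_scores) - len(complete)
    if dropped:
        logger.warning("excluding %d participant(s) with missing EF scores", dropped)
    if len(complete) < 2:
        raise ValueError("need >=2 complete participants for standardization")
    out = pd.DataFrame(index=complete.index)
    out["ef_rt_z"] = complete[rt_cols].apply(lambda c: _cohort_z(c, ddof)).mean(axis=1)
    out["ef_acc_z"] = complete[acc_cols].apply(lambda c: _cohort_z(c, ddof)).mean(axis=1)
    return out


def exclude_outliers(
    table: pd.DataFrame, limit: float = 3.0, columns: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop participants with any standardized score beyond ``limit`` in
    magnitude.

    Returns (filtered table, exclusion log with participant index and the
    offending column/value pairs).
    """
    cols = columns if columns is not None else [c for c in Z_COLUMNS if c in table]
    if not cols:
        raise ValueError("no standardized columns found to screen")
    bad = table[cols].abs() > limit
    offenders = bad.any(axis=1)
    records = []
    for idx in table.index[offenders]:
        for col in cols:
            if bad.at[idx, col]:
                records.append(
                    {"participant": idx, "column": col, "value": table.at[idx, col]}
                )
    log = pd.DataFrame(records, columns=["participant", "column", "value"])
    if len(log):
        logger.info("excluded %d outlier participant(s)", offenders.sum())
    return table[~offenders].copy(), log


@dataclass
class GlmResult:
    """Coefficient table of one dissociation GLM plus fit metadata."""

    outcome: str
    model: str
    table: pd.DataFrame  # index: term; columns: beta, se, t, df, p_raw, p_bonferroni
    n: int
    family_size: int

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]


_MODEL_TERMS = {
    "1": ["assoc_z", "ef_rt_z", "ef_acc_z"],
    "1x": ["assoc_z", "ef_rt_z", "ef_acc_z", "assoc_z:ef_rt_z"],
    "2": ["assoc_z", "ef_rt_z", "ef_acc_z", "gender", "age", "handedness"],
}
#: terms whose tests define the Bonferroni family (focal predictors)
_FOCAL_TERMS = {
    "1": ["assoc_z", "ef_rt_z"],
    "1x": ["assoc_z", "ef_rt_z", "assoc_z:ef_rt_z"],
    "2": ["assoc_z", "ef_rt_z"],
}


def dissociation_glm(
    table: pd.DataFrame,
    outcome: str,
    model: str = "1",
    family_size: int | None = None,
) -> GlmResult:
    """OLS dissociation model for novelty or appropriateness.

    ``outcome`` is 'novelty' or 'appropriateness' (column ``<outcome>_z``).
    ``model`` selects the predictor set: '1' = associative ability + EF-RT
    composite + EF-ACC control; '1x' adds the association x EF-RT
    interaction; '2' adds gender, age, handedness.  Bonferroni correction
    multiplies raw p values by ``family_size`` (default: the number of
    focal predictor tests in the model).
    """
    if model not in _MODEL_TERMS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(_MODEL_TERMS)}")
    ycol = f"{outcome}_z"
    if ycol not in table:
        raise ValueError(f"outcome column {ycol!r} not in table")
    terms = _MODEL_TERMS[model]

    X = pd.DataFrame(index=table.index)
    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            X[term] = table[a] * table[b]
        else:
            X[term] = table[term]
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > {p + 1} observations, got {n}")

    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # identify columns whose removal restores full rank
        culprits = []
        arr = design.to_numpy()
        for j, col in enumerate(design.columns):
            sub = np.delete(arr, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                culprits.append(col)
        raise CollinearityError(
            f"rank-deficient design (rank {rank} < {design.shape[1]}); "
            f"offending columns: {culprits}",
            columns=culprits,
        )

    fit = sm.OLS(table[ycol], design).fit()
    m = family_size if family_size is not None else len(_FOCAL_TERMS[model])
    rows = pd.DataFrame(
        {
            "beta": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "df": float(fit.df_resid),
            "p_raw": fit.pvalues,
            "p_bonferroni": np.minimum(1.0, fit.pvalues * m),
        }
    ).drop(index="const")
    return GlmResult(outcome=outcome, model=model, table=rows, n=n, family_size=m)
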