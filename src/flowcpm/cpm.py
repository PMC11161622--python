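"""Connectome-based predictive modeling (CPM) with relevance vector
regression.

The pipeline, per cross-validation fold: correlate every edge with the
behavioral score in the training set, keep edges whose (optionally
partial) Pearson correlation is suprathreshold (p below the selection
threshold), split them by sign, feed the selected edges jointly into a
relevance vector regression, and predict the held-out participants.  The
fold loop is repeated over fresh random 10-fold splits and the per-
participant predictions averaged; significance of the predicted-vs-
observed correlation comes from a permutation null in which the
participant-to-connectome assignment is shuffled and the whole pipeline
re-run.  Edges selected in more than a retention fraction (80%) of all
folds form the consensus mask — the model's network signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from ._utils import DegenerateDataError, IntegrityError, rng_from, spawn_seeds
from .rvr import RVR

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionConfig",
    "EdgeMask",
    "CPMResult",
    "select_edges",
    "cpm_cross_validate",
    "permutation_null",
    "consensus_mask",
    "external_validate_rest",
    "external_validate_task",
    "specificity_profile",
    "partial_correlation",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Edge-selection settings.

    threshold_p : two-tailed p threshold for retaining an edge (the study
        default is 0.01, with 0.05 and 0.005 as robustness alternates).
    correlation_kind : 'plain' Pearson or 'partial' Pearson controlling
        for ``partial_covariates`` (e.g. mean framewise displacement,
        age, gender, handedness).
    """

    threshold_p: float = 0.01
    correlation_kind: str = "plain"
    partial_covariates: tuple[str, ...] = ()

    def __post_init__(self):
        if not 0 < self.threshold_p <= 1:
            raise ValueError("threshold_p must lie in (0, 1]")
        if self.correlation_kind not in ("plain", "partial"):
            raise ValueError("correlation_kind must be 'plain' or 'partial'")
        if self.correlation_kind == "partial" and not self.partial_covariates:
            raise ValueError("partial selection needs partial_covariates")


@dataclass
class EdgeMask:
    """Consensus edge sets (ids into the canonical edge order) with the
    retention fraction of every edge."""

    positive_edges: np.ndarray
    negative_edges: np.ndarray
    retention_pos: np.ndarray
    retention_neg: np.ndarray
    n_edges: int
    retention_threshold: float

    def __post_init__(self):
        if np.intersect1d(self.positive_edges, self.negative_edges).size:
            raise IntegrityError("positive and negative edge sets overlap")

    @property
    def all_edges(self) -> np.ndarray:
        return np.union1d(self.positive_edges, self.negative_edges)


@dataclass
class CPMResult:
    """Cross-validated CPM outcome for one behavioral target."""

    predicted: np.ndarray  # mean prediction per participant over repetitions
    observed: np.ndarray
    prediction_r: float
    config: SelectionConfig
    k: int
    repetitions: int
    seed: int
    pos_counts: np.ndarray  # per-edge positive-selection counts over folds
    neg_counts: np.ndarray
    n_folds_total: int
    null_r: np.ndarray | None = None
    p_pt: float | None = None
    mask: EdgeMask | None = None


def _residualize(v: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Residuals of columns of v after OLS on [1, cov]."""
    design = np.column_stack([np.ones(len(cov)), cov])
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ coef


def _corr_columns(X: np.ndarray, y: np.ndarray, dof_drop: int = 0):
    """Pearson r of each column of X with y, plus two-tailed p values.

    ``dof_drop`` lowers the t-test degrees of freedom (n - 2 - dof_drop),
    as required after partialling out covariates.  Zero-variance columns
    get r = 0, p = 1.
    """
    n = len(y)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    if sy == 0:
        raise DegenerateDataError("behavioral score is constant")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    r = np.where(sx > 0, r, 0.0)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2 - dof_drop
    if df <= 0:
        raise ValueError("not enough observations for the correlation test")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return r, p


def partial_correlation(x, y, covariates) -> tuple[float, float, float]:
    """Partial Pearson correlation of x and y given covariate columns.

    Returns (r, two-tailed p, one-tailed p for r > 0).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    xr = _residualize(x[:, None], cov)[:, 0]
    yr = _residualize(y[:, None], cov)[:, 0]
    k = cov.shape[1]
    r, p_two = _corr_columns(xr[:, None], yr, dof_drop=k)
    r = float(r[0])
    df = len(x) - 2 - k
    t = r * np.sqrt(df / max(1.0 - r**2, 1e-300))
    p_one = float(stats.t.sf(t, df))
    return r, float(p_two[0]), p_one


def select_edges(
    X: np.ndarray,
    y: np.ndarray,
    config: SelectionConfig,
    covariate_table: pd.DataFrame | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Suprathreshold edge selection.

    Correlates every edge (column of ``X``) with ``y``; edges with
    two-tailed p below ``config.threshold_p`` are returned as
    (positive ids, negative ids) by correlation sign.  With
    ``correlation_kind='partial'`` both the edges and the score are
    residualized on the covariates first.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y disagree on the number of participants")
    if X.shape[0] < 10:
        raise ValueError("edge selection needs at least 10 participants")
    if np.std(y) == 0:
        raise DegenerateDataError("behavioral score is constant")

    dof_drop = 0
    if config.correlation_kind == "partial":
        if covariate_table is None:
            raise ValueError("partial selection requires a covariate table")
        missing = set(config.partial_covariates) - set(covariate_table.columns)
        if missing:
            raise ValueError(f"covariate table missing columns: {sorted(missing)}")
        cov = covariate_table[list(config.partial_covariates)].to_numpy(dtype=float)
        rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(cov)), cov]))
        if rank < cov.shape[1] + 1:
            from ._utils import CollinearityError

            raise CollinearityError("collinear covariates in partial selection")
        X = _residualize(X, cov)
        y = _residualize(y[:, None], cov)[:, 0]
        dof_drop = cov.shape[1]

    r, p = _corr_columns(X, y, dof_drop=dof_drop)
    hit = p < config.threshold_p
    pos = np.flatnonzero(hit & (r > 0))
    neg = np.flatnonzero(hit & (r < 0))
    return pos, neg


def _fit_fold(X_train, y_train, sel, rvr_kwargs) -> tuple[RVR | None, float]:
    """Fit the fold model; returns (model or None, training mean)."""
    if sel.size == 0:
        return None, float(np.mean(y_train))
    model = RVR(**rvr_kwargs).fit(X_train[:, sel], y_train)
    return model, float(np.mean(y_train))


def cpm_cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    config: SelectionConfig = SelectionConfig(),
    k: int = 10,
    repetitions: int = 150,
    seed: int = 0,
    covariate_table: pd.DataFrame | None = None,
    rvr_kwargs: dict | None = None,
) -> CPMResult:
    """Repeated k-fold cross-validated CPM.

    Per repetition a fresh random fold split is drawn; per fold, edge
    selection and the RVR fit use the training participants only, so the
    held-out fold never influences its own predictions.  Folds whose
    selection is empty predict the training mean (logged).  The final
    prediction per participant is the mean over repetitions, and
    ``prediction_r`` the Pearson correlation of those means with the
    observed scores.  Per-fold selected edge sets are accumulated for
    :func:`consensus_mask`.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, n_edges = X.shape
    if n != y.size:
        raise ValueError("X and y disagree on the number of participants")
    if n < 2 * k:
        raise ValueError(f"need at least {2 * k} participants for {k}-fold CV")
    rvr_kwargs = rvr_kwargs or {}

    fold_seeds = spawn_seeds(seed, repetitions)
    preds = np.zeros((repetitions, n))
    pos_counts = np.zeros(n_edges, dtype=np.int64)
    neg_counts = np.zeros(n_edges, dtype=np.int64)
    n_folds_total = 0
    n_empty = 0

    for rep in range(repetitions):
        kf = KFold(n_splits=k, shuffle=True, random_state=int(fold_seeds[rep]))
        for train_idx, test_idx in kf.split(X):
            pos, neg = select_edges(
                X[train_idx], y[train_idx], config,
                None if covariate_table is None
                else covariate_table.iloc[train_idx],
            )
            pos_counts[pos] += 1
            neg_counts[neg] += 1
            n_folds_total += 1
            sel = np.concatenate([pos, neg])
            model, train_mean = _fit_fold(X[train_idx], y[train_idx], sel, rvr_kwargs)
            if model is None:
                n_empty += 1
                preds[rep, test_idx] = train_mean
            else:
                preds[rep, test_idx] = model.predict(X[test_idx][:, sel])

    if n_empty:
        logger.warning(
            "%d of %d folds had empty edge selection; those folds predicted "
            "the training mean", n_empty, n_folds_total,
        )
    mean_pred = preds.mean(axis=0)
    prediction_r = float(stats.pearsonr(mean_pred, y).statistic)
    return CPMResult(
        predicted=mean_pred,
        observed=y.copy(),
        prediction_r=prediction_r,
        config=config,
        k=k,
        repetitions=repetitions,
        seed=int(seed),
        pos_counts=pos_counts,
        neg_counts=neg_counts,
        n_folds_total=n_folds_total,
    )


def permutation_null(
    X: np.ndarray,
    y: np.ndarray,
    config: SelectionConfig = SelectionConfig(),
    n_perm: int = 1000,
    seed: int = 0,
    observed_r: float | None = None,
    k: int = 10,
    repetitions: int = 10,
    covariate_table: pd.DataFrame | None = None,
    rvr_kwargs: dict | None = None,
) -> tuple[np.ndarray, float]:
    """Permutation null distribution for the CPM prediction correlation.

    Each iteration shuffles the participant-to-connectome assignment
    (a permutation of the rows of ``X``) and re-runs the full
    cross-validated pipeline, typically with fewer repetitions than the
    observed analysis (default 10) for tractability.  Returns the null r
    distribution and, when ``observed_r`` is given, the add-one
    permutation p value p_pt = (1 + #{null >= observed}) / (1 + n_perm) —
    beating all 1000 nulls thus reports p_pt < 0.001.
    """
    y = np.asarray(y, dtype=float).ravel()
    if np.std(y) == 0:
        raise DegenerateDataError("behavioral score is constant under shuffling")
    rng = rng_from(seed)
    perm_seeds = spawn_seeds(rng.integers(2**31 - 1), n_perm)
    null_r = np.empty(n_perm)
    for b in range(n_perm):
        order = rng.permutation(len(y))
        res = cpm_cross_validate(
            X[order], y, config, k=k, repetitions=repetitions,
            seed=int(perm_seeds[b]), covariate_table=covariate_table,
            rvr_kwargs=rvr_kwargs,
        )
        null_r[b] = res.prediction_r
    if observed_r is None:
        return null_r, float("nan")
    p_pt = (1.0 + np.sum(null_r >= observed_r)) / (1.0 + n_perm)
    return null_r, float(p_pt)


def consensus_mask(result: CPMResult, retention: float = 0.8) -> EdgeMask:
    """Edges selected (per sign) in strictly more than ``retention`` of
    all folds pooled across repetitions."""
    if result.n_folds_total < 1:
        raise ValueError("no completed folds logged")
    frac_pos = result.pos_counts / result.n_folds_total
    frac_neg = result.neg_counts / result.n_folds_total
    mask = EdgeMask(
        positive_edges=np.flatnonzero(frac_pos > retention),
        negative_edges=np.flatnonzero(frac_neg > retention),
        retention_pos=frac_pos,
        retention_neg=frac_neg,
        n_edges=len(frac_pos),
        retention_threshold=retention,
    )
    result.mask = mask
    return mask


def fit_full_model(
    train_X: np.ndarray,
    train_y: np.ndarray,
    config: SelectionConfig = SelectionConfig(),
    covariate_table: pd.DataFrame | None = None,
    mask: EdgeMask | None = None,
    rvr_kwargs: dict | None = None,
) -> tuple[RVR, np.ndarray]:
    """One RVR fitted on the whole training cohort.

    Features are either re-selected on the full cohort at the configured
    threshold (default) or taken from a given consensus ``mask``.
    Returns (model, selected edge ids).
    """
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y, dtype=float).ravel()
    if mask is None:
        pos, neg = select_edges(train_X, train_y, config, covariate_table)
        sel = np.concatenate([pos, neg])
    else:
        if mask.n_edges != train_X.shape[1]:
            raise IntegrityError(
                f"mask indexes {mask.n_edges} edges but data has "
                f"{train_X.shape[1]}"
            )
        sel = mask.all_edges
    if sel.size == 0:
        raise DegenerateDataError("no edges selected for the full-cohort model")
    model = RVR(**(rvr_kwargs or {})).fit(train_X[:, sel], train_y)
    return model, sel


def external_validate_rest(
    train_X: np.ndarray,
    train_y: np.ndarray,
    config: SelectionConfig,
    new_X: np.ndarray,
    new_y: np.ndarray,
    covariates: pd.DataFrame,
    mask: EdgeMask | None = None,
    rvr_kwargs: dict | None = None,
) -> tuple[float, float]:
    """Generalization test on an independent resting-state cohort.

    Fits a single full-cohort model on the training data, predicts the
    new participants, and reports the partial Pearson correlation of
    predicted vs observed scores given the covariates (mean framewise
    displacement, age, gender), with a one-tailed p for a positive
    association.
    """
    new_X = np.asarray(new_X, dtype=float)
    if new_X.shape[1] != np.asarray(train_X).shape[1]:
        raise IntegrityError(
            "training and validation data disagree on the edge count "
            "(atlas mismatch)"
        )
    model, sel = fit_full_model(
        train_X, train_y, config, mask=mask, rvr_kwargs=rvr_kwargs
    )
    pred = model.predict(new_X[:, sel])
    r, _p_two, p_one = partial_correlation(pred, new_y, covariates.to_numpy(dtype=float))
    return r, p_one


def external_validate_task(
    model: RVR,
    selected_edges: np.ndarray,
    block_X: np.ndarray,
    block_scores: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Generalization test on block-wise task connectivity.

    ``block_X`` is participants x blocks x edges; ``block_scores`` is
    participants x blocks.  Per participant, the model (trained on
    resting data) predicts a score per block, and the Spearman rank
    correlation against the observed block scores is computed.  The null
    shuffles the block-to-connectome assignment within participant and
    recomputes the correlation; a one-tailed Wilcoxon signed-rank test
    compares observed correlations against the within-participant null
    means.  Returns (rho per participant, null mean per participant,
    group p).
    """
    block_X = np.asarray(block_X, dtype=float)
    block_scores = np.asarray(block_scores, dtype=float)
    if block_X.ndim != 3 or block_scores.shape != block_X.shape[:2]:
        raise ValueError("block_X must be participants x blocks x edges")
    n_sub, n_blocks, _ = block_X.shape
    if n_blocks < 3:
        raise ValueError("need at least 3 blocks per participant")
    rng = rng_from(seed)

    rhos = np.empty(n_sub)
    null_means = np.empty(n_sub)
    for s in range(n_sub):
        pred = model.predict(block_X[s][:, selected_edges])
        rhos[s] = stats.spearmanr(pred, block_scores[s]).statistic
        null = np.empty(n_perm)
        for b in range(n_perm):
            null[b] = stats.spearmanr(
                pred[rng.permutation(n_blocks)], block_scores[s]
            ).statistic
        null_means[s] = null.mean()
    diffs = rhos - null_means
    group_p = float(stats.wilcoxon(diffs, alternative="greater").pvalue)
    return rhos, null_means, group_p


def specificity_profile(
    predictions: pd.Series,
    outcome_battery: pd.DataFrame,
    target_name: str,
) -> pd.DataFrame:
    """Correlation of model predictions with a battery of outcomes.

    Pearson r per outcome with pairwise deletion of missing values,
    ranked by |r|; eta squared is the squared correlation (the
    proportion-of-variance effect size, insensitive to the per-outcome
    sample size).  The frame carries ``attrs['target_ranks_first']``.
    Outcomes with fewer than 3 complete pairs are excluded with a warning.
    """
    if target_name not in outcome_battery.columns:
        raise ValueError(f"target {target_name!r} not in battery")
    if outcome_battery.shape[1] < 2:
        raise ValueError("battery needs at least 2 outcomes")
    rows = []
    for col in outcome_battery.columns:
        pair = pd.concat([predictions, outcome_battery[col]], axis=1).dropna()
        if len(pair) < 3:
            logger.warning("outcome %r excluded: <3 complete pairs", col)
            continue
        r = float(stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1]).statistic)
        rows.append({"outcome": col, "r": r, "eta_sq": r**2, "n": len(pair)})
    table = pd.DataFrame(rows).set_index("outcome")
    table = table.reindex(table["r"].abs().sort_values(ascending=False).index)
    table.attrs["target_ranks_first"] = bool(
        len(table) and table.index[0] == target_name
    )
    return table
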