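"""Three-variable mediation with a percentile bootstrap.

The causal chain X -> M -> Y is quantified by three OLS fits:

    M = a X           (path a)
    Y = c' X + b M    (paths c' and b)
    Y = c X           (path c, the total effect)

The indirect effect is the product a*b, and for OLS on one sample the
decomposition c = c' + a*b holds exactly.  Significance of the indirect
effect comes from a case-resampling bootstrap: participants are resampled
with replacement, a*b recomputed each time, and the percentile interval
at the requested coverage reported; the effect is called significant when
the interval excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._utils import check_1d_equal, rng_from, zscore

__all__ = ["MediationResult", "mediate"]


@dataclass
class MediationResult:
    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    p_a: float
    p_b: float
    p_c: float
    p_c_prime: float
    ci: dict[float, tuple[float, float]]  # coverage -> (lower, upper)
    n_boot: int
    seed: int
    boot_indirect: np.ndarray

    def significant(self, coverage: float = 0.95) -> bool:
        lo, hi = self.ci[coverage]
        return lo > 0 or hi < 0


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients and two-tailed p values for y ~ [1, X]."""
    n = len(y)
    design = np.column_stack([np.ones(n), X])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    df = n - design.shape[1]
    s2 = float(resid @ resid) / df
    cov = s2 * np.linalg.inv(design.T @ design)
    se = np.sqrt(np.diag(cov))
    t = coef / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return coef[1:], p[1:]


def _paths(x: np.ndarray, m: np.ndarray, y: np.ndarray):
    """(a, b, c, c') from the three regressions on one sample."""
    a = float(np.cov(x, m, ddof=1)[0, 1] / np.var(x, ddof=1))
    # two-predictor OLS for Y ~ X + M, closed form
    X2 = np.column_stack([x, m])
    coef, _, _, _ = np.linalg.lstsq(np.column_stack([np.ones(len(y)), X2]), y, rcond=None)
    c_prime, b = float(coef[1]), float(coef[2])
    c = float(np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1))
    return a, b, c, c_prime


def mediate(
    x,
    m,
    y,
    n_boot: int = 1000,
    coverage: tuple[float, ...] = (0.95, 0.90),
    seed: int = 0,
    standardize: bool = True,
) -> MediationResult:
    """Mediation of the x -> y relation through m.

    Variables are z-normalized by default (sample SD), so the paths are
    standardized regression coefficients.  The bootstrap resamples cases
    (participants) with replacement, ``n_boot`` times, and the interval
    at each requested coverage is the percentile interval of the
    bootstrapped a*b products.
    """
    x, m, y = check_1d_equal(x, m, y, min_len=10)
    for name, v in (("x", x), ("m", m), ("y", y)):
        if np.std(v) == 0:
            raise ValueError(f"constant input vector {name!r}")
    if standardize:
        x, m, y = zscore(x), zscore(m), zscore(y)

    a, b, c, c_prime = _paths(x, m, y)
    (_a,), (p_a,) = _ols(m, x[:, None])
    (_cp, _b), (p_cp, p_b) = _ols(y, np.column_stack([x, m]))
    (_c,), (p_c,) = _ols(y, x[:, None])

    rng = rng_from(seed)
    n = len(x)
    idx = rng.integers(0, n, size=(n_boot, n))
    xb, mb, yb = x[idx], m[idx], y[idx]
    # vectorized per-sample paths: a_boot from cov/var, b_boot from the
    # 2-predictor normal equations, all computed row-wise
    xc = xb - xb.mean(axis=1, keepdims=True)
    mc = mb - mb.mean(axis=1, keepdims=True)
    yc = yb - yb.mean(axis=1, keepdims=True)
    sxx = np.einsum("ij,ij->i", xc, xc)
    sxm = np.einsum("ij,ij->i", xc, mc)
    smm = np.einsum("ij,ij->i", mc, mc)
    sxy = np.einsum("ij,ij->i", xc, yc)
    smy = np.einsum("ij,ij->i", mc, yc)
    a_boot = sxm / sxx
    det = sxx * smm - sxm**2
    b_boot = (sxx * smy - sxm * sxy) / det
    boot = a_boot * b_boot

    ci = {}
    for cov_level in coverage:
        alpha = 1.0 - cov_level
        lo, hi = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        ci[cov_level] = (float(lo), float(hi))

    return MediationResult(
        a=a, b=b, c=c, c_prime=c_prime, indirect=a * b,
        p_a=float(p_a), p_b=float(p_b), p_c=float(p_c), p_c_prime=float(p_cp),
        ci=ci, n_boot=n_boot, seed=int(seed), boot_indirect=boot,
    )
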