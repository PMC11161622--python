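"""Shared helpers: standardization, validation, exceptions."""

from __future__ import annotations

import numpy as np


class DegenerateDataError(ValueError):
    """Raised when an operation requires variation that the data lack
    (zero-variance column, constant outcome, empty response stream)."""


class CollinearityError(ValueError):
    """Raised when a design matrix is rank deficient; carries the names of
    the offending columns when they can be identified."""

    def __init__(self, message: str, columns: list[str] | None = None):
        super().__init__(message)
        self.columns = columns or []


class IntegrityError(ValueError):
    """Raised when two artifacts that must refer to the same structure
    (atlas, edge index, feature columns) do not."""


def zscore(x, ddof: int = 1) -> np.ndarray:
    """Standardize a 1-D array to mean 0, SD 1.

    Uses the sample SD (``ddof=1``) by default; pass ``ddof=0`` for the
    population convention. Raises :class:`DegenerateDataError` on zero
    variance.
    """
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateDataError("cannot standardize a zero-variance vector")
    return (x - x.mean()) / sd


def check_1d_equal(*arrays, min_len: int = 1):
    """Coerce arguments to equal-length finite 1-D float arrays."""
    out = [np.asarray(a, dtype=float).ravel() for a in arrays]
    n = len(out[0])
    if any(len(a) != n for a in out):
        raise ValueError("input vectors must have equal length")
    if n < min_len:
        raise ValueError(f"need at least {min_len} observations, got {n}")
    for a in out:
        if not np.all(np.isfinite(a)):
            raise ValueError("inputs must be finite")
    return out


def rng_from(seed) -> np.random.Generator:
    """A fresh Generator; accepts an int seed or an existing Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_seeds(seed: int, n: int) -> np.ndarray:
    """Derive ``n`` independent child seeds (< 2**31) from one parent seed."""
    return rng_from(seed).integers(0, 2**31 - 1, size=n)
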