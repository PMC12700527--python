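"""Shared helpers: RNG handling, validation, count-matrix access."""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

MAX_SEED = 2**31 - 1


def as_rng(seed) -> np.random.Generator:
    """Accept an int seed, a Generator, or None and return a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def split_seed(seed: int, *keys: str) -> int:
    """Derive a child seed (< 2**31) deterministically from a parent seed and keys.

    Used to give every stage / puck / permutation stream its own independent
    stream while keeping the whole analysis reproducible from one integer.
    """
    ss = np.random.SeedSequence([int(seed) % MAX_SEED] + [abs(hash(k)) % MAX_SEED for k in keys])
    return int(ss.generate_state(1)[0] % MAX_SEED)


def dense_counts(adata) -> np.ndarray:
    """Return the count matrix of an AnnData as a dense float array."""
    X = adata.X
    if sp.issparse(X):
        return np.asarray(X.todense(), dtype=float)
    return np.asarray(X, dtype=float)


def check_nonnegative(X: np.ndarray, name: str = "matrix") -> None:
    if np.min(X) < 0:
        raise ValueError(f"{name} must be non-negative")


def row_normalize(X: np.ndarray, axis: int = 1) -> np.ndarray:
    """Normalize rows (or columns) to sum to 1; all-zero rows stay zero."""
    s = X.sum(axis=axis, keepdims=True)
    out = np.divide(X, s, out=np.zeros_like(X, dtype=float), where=s > 0)
    return out
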