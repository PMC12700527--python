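"""Integrative NMF expression programs with batch-specific loadings.

The model decomposes per-batch expression matrices X_d (cells × genes) as

    X_d ≈ H_d (W + V_d)

with all factors non-negative: W holds k shared "program" loadings, V_d
batch-specific distortions of those programs, and H_d per-cell program
usages.  The fit minimizes

    Σ_d ‖X_d − H_d (W + V_d)‖²_F + λ Σ_d ‖H_d V_d‖²_F

by block-coordinate HALS (exact non-negative coordinate minimization per
factor row/column), which makes the objective non-increasing by
construction.  λ trades batch-specific flexibility against shared
structure: as λ grows, ‖V_d‖ shrinks toward 0.

Input is expected on a count-like scale (library-size normalized counts,
no log transform), matching the interpretation of programs as additive
expression profiles.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import as_rng, row_normalize, split_seed

logger = logging.getLogger(__name__)
_EPS = 1e-12


class INMFModel:
    """Integrative NMF over one or more batches.

    Parameters
    ----------
    data : mapping batch name -> (cells × genes) array / DataFrame, or a
        single array for one batch.  Shared gene vocabulary required.
    k : number of programs (default 20).
    lam : batch-penalty weight λ (default 5).
    """

    def __init__(self, data, k: int = 20, lam: float = 5.0):
        if isinstance(data, (np.ndarray, pd.DataFrame)):
            data = {"batch0": data}
        self.batches = sorted(data)
        self.genes = None
        self.X: dict[str, np.ndarray] = {}
        self.obs_names: dict[str, list] = {}
        for b in self.batches:
            Xb = data[b]
            if isinstance(Xb, pd.DataFrame):
                if self.genes is None:
                    self.genes = list(Xb.columns)
                elif list(Xb.columns) != self.genes:
                    raise ValueError("batches must share the gene vocabulary")
                self.obs_names[b] = list(Xb.index)
                Xb = Xb.to_numpy(dtype=float)
            else:
                Xb = np.asarray(Xb, dtype=float)
                self.obs_names[b] = list(range(Xb.shape[0]))
            if Xb.min() < 0:
                raise ValueError("expression must be non-negative")
            self.X[b] = Xb
        n_genes = next(iter(self.X.values())).shape[1]
        if self.genes is None:
            self.genes = [f"g{i}" for i in range(n_genes)]
        total_cells = sum(X.shape[0] for X in self.X.values())
        if k > min(n_genes, total_cells):
            raise ValueError("k must not exceed min(genes, total cells)")
        self.k = k
        self.lam = float(lam)

    # -- objective ---------------------------------------------------------
    def _objective(self, W, V, H) -> float:
        obj = 0.0
        for b in self.batches:
            R = self.X[b] - H[b] @ (W + V[b])
            obj += float((R * R).sum()) + self.lam * float(((H[b] @ V[b]) ** 2).sum())
        return obj

    # -- HALS blocks -------------------------------------------------------
    @staticmethod
    def _hals_H(X, W, V, H, lam):
        Y = W + V
        A = Y @ Y.T + lam * (V @ V.T)          # k × k
        B = X @ Y.T                            # n × k
        for j in range(H.shape[1]):
            denom = A[j, j]
            if denom <= _EPS:
                continue
            h = H[:, j] + (B[:, j] - H @ A[:, j]) / denom
            H[:, j] = np.maximum(h, 0.0)
        return H

    @staticmethod
    def _hals_V(X, W, V, H, lam):
        G = H.T @ H                            # k × k
        T = H.T @ (X - H @ W)                  # k × g
        c = 1.0 + lam
        for j in range(V.shape[0]):
            denom = c * G[j, j]
            if denom <= _EPS:
                continue
            v = V[j] + (T[j] - c * (G @ V)[j]) / denom
            V[j] = np.maximum(v, 0.0)
        return V

    def _hals_W(self, W, V, H):
        G = np.zeros((self.k, self.k))
        T = np.zeros_like(W)
        for b in self.batches:
            Gb = H[b].T @ H[b]
            G += Gb
            T += H[b].T @ self.X[b] - Gb @ V[b]
        for j in range(self.k):
            denom = G[j, j]
            if denom <= _EPS:
                continue
            w = W[j] + (T[j] - (G @ W)[j]) / denom
            W[j] = np.maximum(w, 0.0)
        return W

    # -- fitting -----------------------------------------------------------
    def fit(self, max_iter: int = 200, tol: float = 1e-5, seed: int = 0,
            n_restarts: int = 1) -> "INMFResult":
        """Fit by alternating HALS; with ``n_restarts`` > 1, keep the best
        objective over seeded restarts."""
        best = None
        for r in range(n_restarts):
            res = self._fit_once(max_iter, tol, split_seed(seed, f"restart{r}"))
            if best is None or res.objective < best.objective:
                best = res
        return best

    def _fit_once(self, max_iter, tol, seed):
        rng = as_rng(seed)
        n_genes = len(self.genes)
        scale = np.sqrt(np.mean([X.mean() for X in self.X.values()]) / self.k + _EPS)
        W = rng.random((self.k, n_genes)) * scale
        V = {b: rng.random((self.k, n_genes)) * scale * 0.1 for b in self.batches}
        H = {b: rng.random((self.X[b].shape[0], self.k)) * scale for b in self.batches}
        trace = [self._objective(W, V, H)]
        for it in range(max_iter):
            for b in self.batches:
                H[b] = self._hals_H(self.X[b], W, V[b], H[b], self.lam)
            for b in self.batches:
                V[b] = self._hals_V(self.X[b], W, V[b], H[b], self.lam)
            W = self._hals_W(W, V, H)
            obj = self._objective(W, V, H)
            trace.append(obj)
            if trace[-2] - obj <= tol * max(trace[-2], _EPS):
                break
        else:
            warnings.warn(f"iNMF did not converge in {max_iter} iterations "
                          f"(last relative change "
                          f"{(trace[-2] - trace[-1]) / max(trace[-2], _EPS):.2e})")
        return INMFResult(self, W, V, H, np.asarray(trace))


class INMFResult:
    """Fitted program set: shared loadings W, batch loadings V_d, usages H_d."""

    def __init__(self, model: INMFModel, W, V, H, trace):
        self.model = model
        self.W = W
        self.V = V
        self.H = H
        self.trace = trace
        self.objective = float(trace[-1])

    @property
    def program_names(self) -> list[str]:
        return [f"program{j}" for j in range(self.model.k)]

    def programs(self, normalized: bool = True) -> pd.DataFrame:
        """Shared program-by-gene loadings; rows sum to 1 if normalized."""
        W = row_normalize(self.W) if normalized else self.W
        return pd.DataFrame(W, index=self.program_names, columns=self.model.genes)

    def usages(self, normalized: bool = True) -> pd.DataFrame:
        """Observation-by-program usages stacked over batches."""
        blocks, idx = [], []
        for b in self.model.batches:
            blocks.append(self.H[b])
            idx += [str(i) for i in self.model.obs_names[b]]
        H = np.vstack(blocks)
        if normalized:
            H = row_normalize(H)
        return pd.DataFrame(H, index=idx, columns=self.program_names)

    def corrected_counts(self) -> pd.DataFrame:
        """Count-like batch-corrected matrix H_d · W (batch term dropped)."""
        blocks, idx = [], []
        for b in self.model.batches:
            blocks.append(self.H[b] @ self.W)
            idx += [str(i) for i in self.model.obs_names[b]]
        return pd.DataFrame(np.vstack(blocks), index=idx, columns=self.model.genes)

    def top_genes(self, n: int = 20) -> dict[str, list[str]]:
        """Per program, the n genes with largest shared loading.

        Ties broken lexicographically by gene name."""
        if n > len(self.model.genes):
            warnings.warn("n exceeds the gene vocabulary; truncating")
            n = len(self.model.genes)
        genes = np.asarray(self.model.genes)
        out = {}
        for j, name in enumerate(self.program_names):
            order = sorted(range(len(genes)), key=lambda i: (-self.W[j, i], genes[i]))
            out[name] = [genes[i] for i in order[:n]]
        return out

    def relative_error(self) -> float:
        """Relative Frobenius reconstruction error over all batches."""
        num = den = 0.0
        for b in self.model.batches:
            R = self.model.X[b] - self.H[b] @ (self.W + self.V[b])
            num += float((R * R).sum())
            den += float((self.model.X[b] ** 2).sum())
        return np.sqrt(num / max(den, _EPS))

    def summary(self) -> pd.DataFrame:
        rows = []
        for b in self.model.batches:
            rows.append({
                "batch": b, "n_obs": self.model.X[b].shape[0],
                "V_norm": float(np.linalg.norm(self.V[b])),
            })
        df = pd.DataFrame(rows)
        df.attrs["k"] = self.model.k
        df.attrs["lambda"] = self.model.lam
        df.attrs["objective"] = self.objective
        df.attrs["n_iter"] = len(self.trace) - 1
        df.attrs["relative_error"] = self.relative_error()
        return df


def fit_inmf(data, k: int = 20, lam: float = 5.0, max_iter: int = 200,
             tol: float = 1e-5, seed: int = 0, n_restarts: int = 1) -> INMFResult:
    """Functional wrapper: build an :class:`INMFModel` and fit it."""
    return INMFModel(data, k=k, lam=lam).fit(max_iter=max_iter, tol=tol,
                                             seed=seed, n_restarts=n_restarts)


def correct_counts(data, k_large: int = 50, seed: int = 0, **kw) -> pd.DataFrame:
    """High-rank iNMF batch correction returning the count-like H·W matrix."""
    return fit_inmf(data, k=k_large, seed=seed, **kw).corrected_counts()
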