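"""Marker-panel selection for targeted in situ assays.

Candidate genes are grouped into redundancy sets (genes expected to carry
overlapping information); the panel takes a fixed quota from each set.
Selection quality is a cross-validated objective on reference single-cell
data thinned to the sparsity of the targeted assay: the unweighted mean of
grouped 4-fold CV accuracies of a multinomial logistic classifier (one per
classification task) and CV R² of ridge regressions of program weights
(one per regression task).  The optimizer sweeps the redundancy sets in
fixed order, exhaustively evaluating every within-set choice with the rest
held fixed and accepting the best (ties keep the incumbent), until a full
sweep changes nothing.  Each accepted move can only increase the
objective, so termination is guaranteed.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from itertools import combinations
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.model_selection import GroupKFold, cross_val_score

from ._utils import as_rng, dense_counts

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ClassificationTask:
    """Discriminate the labels of ``labels`` restricted to cells where the
    label is not null."""
    name: str
    labels: pd.Series


@dataclasses.dataclass
class RegressionTask:
    """Predict continuous targets (e.g. program usages) from panel counts."""
    name: str
    targets: pd.DataFrame


class PanelProblem:
    """A panel-selection instance.

    Parameters
    ----------
    reference : labelled single-cell AnnData restricted to candidate genes.
    redundancy_sets : mapping set name -> list of member genes; every
        candidate belongs to exactly one set (singletons allowed).
    quotas : mapping set name -> how many genes to pick from that set
        (default 1 per set); the panel size is the sum of quotas.
    tasks : list of Classification/RegressionTask.
    depth : target mean total count per cell over the candidate panel after
        binomial thinning (the expected sparsity of the in situ assay).
    groups : per-cell sample ids for GroupKFold (default obs['sample']).
    """

    def __init__(self, reference: ad.AnnData,
                 redundancy_sets: Mapping[str, Sequence[str]],
                 tasks: Sequence, depth: float = 20.0,
                 quotas: Mapping[str, int] | None = None,
                 groups: pd.Series | None = None,
                 cv_folds: int = 4, seed: int = 0):
        self.sets = {k: list(v) for k, v in redundancy_sets.items()}
        members = [g for v in self.sets.values() for g in v]
        if len(set(members)) != len(members):
            raise ValueError("each gene must belong to exactly one set")
        missing = set(members) - set(reference.var_names)
        if missing:
            raise ValueError(f"candidate genes missing from reference: {sorted(missing)[:5]}")
        if not tasks:
            raise ValueError("tasks must be non-empty")
        self.quotas = dict(quotas) if quotas else {k: 1 for k in self.sets}
        for k, q in self.quotas.items():
            if not (0 <= q <= len(self.sets[k])):
                raise ValueError(f"infeasible quota for set {k!r}")
        self.panel_size = sum(self.quotas.values())
        self.tasks = list(tasks)
        self.cv_folds = cv_folds
        self.seed = seed
        self.candidates = members
        if groups is None:
            groups = reference.obs.get("sample")
        self.groups = (groups.reindex(reference.obs_names)
                       if groups is not None else
                       pd.Series(np.arange(reference.n_obs) % cv_folds,
                                 index=reference.obs_names))
        # thin the candidate matrix once (seeded) to the target sparsity so
        # the objective is a deterministic function of the selection
        X = dense_counts(reference[:, members])
        mean_total = X.sum(axis=1).mean()
        p = min(1.0, depth / mean_total) if mean_total > 0 else 1.0
        rng = as_rng(seed)
        self.X = rng.binomial(X.astype(np.int64), p).astype(float)
        self.obs_names = reference.obs_names
        self.gene_pos = {g: i for i, g in enumerate(members)}

    # -- objective ---------------------------------------------------------
    def objective(self, selection: Sequence[str]) -> float:
        """Mean CV score of all tasks on the thinned counts restricted to
        ``selection``; empty selection scores 0."""
        sel = list(selection)
        if not sel:
            return 0.0
        cols = [self.gene_pos[g] for g in sel]
        Xs = self.X[:, cols]
        scores = []
        for task in self.tasks:
            if isinstance(task, ClassificationTask):
                y = task.labels.reindex(self.obs_names)
                m = y.notna().to_numpy()
                if y[m].nunique() < 2:
                    logger.warning("task %s has one class; skipped", task.name)
                    continue
                est = LogisticRegression(max_iter=500, C=1.0)
                cv = GroupKFold(n_splits=self.cv_folds)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    s = cross_val_score(est, Xs[m], y[m].astype(str),
                                        groups=self.groups[m], cv=cv)
            else:
                Y = task.targets.reindex(self.obs_names)
                m = Y.notna().all(axis=1).to_numpy()
                est = Ridge(alpha=1.0)
                cv = GroupKFold(n_splits=self.cv_folds)
                s = cross_val_score(est, Xs[m], Y[m].to_numpy(),
                                    groups=self.groups[m], cv=cv, scoring="r2")
            scores.append(float(np.mean(s)))
        return float(np.mean(scores)) if scores else 0.0

    def initial_selection(self) -> list:
        """Feasible start: the first ``quota`` genes of each set."""
        out = []
        for k in sorted(self.sets):
            out += self.sets[k][: self.quotas[k]]
        return out


class PanelOptimizer:
    """Redundancy-set coordinate descent over panel selections."""

    def __init__(self, problem: PanelProblem):
        self.problem = problem

    def fit(self, initial: Sequence[str] | None = None,
            max_sweeps: int = 20) -> "PanelResult":
        prob = self.problem
        sel = list(initial) if initial is not None else prob.initial_selection()
        chosen = {k: [g for g in sel if g in prob.sets[k]] for k in prob.sets}
        for k in prob.sets:
            if len(chosen[k]) != prob.quotas[k]:
                raise ValueError(f"initial selection infeasible for set {k!r}")
        current = prob.objective([g for v in chosen.values() for g in v])
        trace = [{"sweep": 0, "set": None, "choice": None, "objective": current}]
        for sweep in range(1, max_sweeps + 1):
            changed = False
            for k in sorted(prob.sets):
                if prob.quotas[k] == len(prob.sets[k]):
                    continue            # no freedom in this set
                incumbent = tuple(chosen[k])
                best_choice, best_obj = incumbent, current
                for cand in combinations(prob.sets[k], prob.quotas[k]):
                    if cand == incumbent:
                        continue
                    chosen[k] = list(cand)
                    obj = prob.objective([g for v in chosen.values() for g in v])
                    if obj > best_obj:          # ties keep the incumbent
                        best_choice, best_obj = cand, obj
                chosen[k] = list(best_choice)
                if best_choice != incumbent:
                    changed = True
                    current = best_obj
                    trace.append({"sweep": sweep, "set": k,
                                  "choice": "+".join(best_choice),
                                  "objective": current})
            if not changed:
                break
        selection = sorted(g for v in chosen.values() for g in v)
        return PanelResult(self.problem, selection, current,
                           pd.DataFrame(trace))


class PanelResult:
    def __init__(self, problem, selection, objective, trace):
        self.problem = problem
        self.selection = selection
        self.objective = objective
        self.trace = trace

    def summary(self) -> pd.DataFrame:
        rows = [{"set": k, "chosen": "+".join(g for g in self.selection
                                              if g in self.problem.sets[k])}
                for k in sorted(self.problem.sets)]
        out = pd.DataFrame(rows).set_index("set")
        out.attrs["objective"] = self.objective
        out.attrs["panel_size"] = len(self.selection)
        return out


def optimize_panel(problem: PanelProblem, initial=None) -> PanelResult:
    """Functional wrapper around :class:`PanelOptimizer`."""
    return PanelOptimizer(problem).fit(initial)
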