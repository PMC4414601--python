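"""Transductive positive-unlabeled (PU) classification of candidate peaks.

The learner sees only positive examples (peaks of known TF targets) and
unlabeled examples (all other candidate peaks) and must label the unlabeled
set itself — the transductive setting. A positive-fraction parameter ``p``
controls how many unlabeled examples end up labeled positive: exactly

    k = max(1, round(p * U))

of the U unlabeled examples, enforced by calibrating the decision threshold
to the k-th largest score. The classifier is a class-weighted linear
soft-margin SVM (biased-SVM heuristic: positives weighted heavily so the
margin respects them) refined by label switching: fit, re-score the
unlabeled pool, relabel the top-k, repeat to a fixed point or an iteration
cap. Sweeping p over a grid and intersecting the per-p positive sets yields
the *robust positives* — examples predicted positive at every p — used as
the final high-confidence prediction.

Model/results API
-----------------
:class:`TransductivePU` is the model (data + hyperparameters);
``fit(p)`` returns a :class:`PUResults` carrying labels, decision scores,
the linear model, and a ``summary()``; ``sweep(grid)`` fits the whole grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

#: p from 0.05 to 0.95 in steps of 0.05 (19 values).
DEFAULT_P_GRID: tuple[float, ...] = tuple(round(0.05 * i, 2) for i in range(1, 20))
DEFAULT_HOLDOUT_FRACTIONS: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def positive_count(p: float, n_unlabeled: int) -> int:
    """Number of unlabeled examples labeled positive at fraction ``p``."""
    return max(1, _round_half_up(p * n_unlabeled))


@dataclass
class PUDataset:
    """Positive and unlabeled feature rows, indexed by identifier."""

    positives: pd.DataFrame
    unlabeled: pd.DataFrame

    def __post_init__(self) -> None:
        overlap = set(self.positives.index) & set(self.unlabeled.index)
        if overlap:
            raise ValueError(f"identifiers in both sets: {sorted(overlap)[:5]}")
        if list(self.positives.columns) != list(self.unlabeled.columns):
            raise ValueError("positive and unlabeled sets have different columns")
        if self.positives.index.duplicated().any() or self.unlabeled.index.duplicated().any():
            raise ValueError("duplicate identifiers within a set")

    @classmethod
    def from_arrays(
        cls,
        X_pos: np.ndarray,
        pos_ids: Sequence[str],
        X_unl: np.ndarray,
        unl_ids: Sequence[str],
        columns: Optional[Sequence[str]] = None,
    ) -> "PUDataset":
        X_pos = np.atleast_2d(np.asarray(X_pos, dtype=float))
        X_unl = np.atleast_2d(np.asarray(X_unl, dtype=float))
        if columns is None:
            columns = [f"f{i}" for i in range(X_pos.shape[1])]
        return cls(
            pd.DataFrame(X_pos, index=list(pos_ids), columns=list(columns)),
            pd.DataFrame(X_unl, index=list(unl_ids), columns=list(columns)),
        )

    @property
    def n_positives(self) -> int:
        return len(self.positives)

    @property
    def n_unlabeled(self) -> int:
        return len(self.unlabeled)


@dataclass
class PUConfig:
    """Learner hyperparameters.

    C : SVM regularization strength.
    class_weight_ratio : weight of positive training examples relative to
        unit weight (biased-SVM heuristic; default 10).
    unlabeled_weight : per-example weight of unlabeled examples (default
        1.0). Values below 1 dampen the influence of pseudo-labels on the
        margin — as transductive SVMs do by costing unlabeled errors less
        — at the price of weaker separation of the unlabeled bulk.
    max_refine_iters : cap on label-switching refinement rounds.
    """

    C: float = 1.0
    class_weight_ratio: float = 10.0
    unlabeled_weight: float = 1.0
    max_refine_iters: int = 50


class PUResults:
    """Fitted transductive labeling at one value of p.

    Attributes
    ----------
    labels : pd.Series mapping unlabeled identifier -> "positive"/"negative".
    scores : pd.Series of decision values over the unlabeled set.
    coef_, intercept_ : the final linear model.
    n_iter : refinement rounds used.
    """

    def __init__(
        self,
        model: "TransductivePU",
        p: float,
        labels: pd.Series,
        scores: pd.Series,
        coef: np.ndarray,
        intercept: float,
        n_iter: int,
    ):
        self.model = model
        self.p = p
        self.labels = labels
        self.scores = scores
        self.coef_ = coef
        self.intercept_ = intercept
        self.n_iter = n_iter

    @property
    def positive_ids(self) -> set[str]:
        return set(self.labels.index[self.labels == "positive"])

    @property
    def negative_ids(self) -> set[str]:
        return set(self.labels.index[self.labels == "negative"])

    @property
    def k(self) -> int:
        return int((self.labels == "positive").sum())

    def summary(self) -> str:
        lines = [
            "Transductive PU classification results",
            "=" * 42,
            f"positive fraction p     {self.p:.2f}",
            f"unlabeled examples      {len(self.labels)}",
            f"labeled positive (k)    {self.k}",
            f"training positives      {self.model.data.n_positives}",
            f"refinement iterations   {self.n_iter}",
            f"C / class-weight ratio  {self.model.config.C:g} / "
            f"{self.model.config.class_weight_ratio:g}",
            "-" * 42,
            "feature weights:",
        ]
        for name, w in zip(self.model.data.positives.columns, self.coef_):
            lines.append(f"  {name:<20s} {w:+.4f}")
        lines.append(f"  {'intercept':<20s} {self.intercept_:+.4f}")
        return "\n".join(lines)


class TransductivePU:
    """Transductive PU model over a :class:`PUDataset`.

    Parameters
    ----------
    data : the positive/unlabeled dataset.
    config : learner hyperparameters.
    seed : controls any stochastic choices; the fit itself is deterministic
        for fixed data order, and identifier ties are broken
        lexicographically, so results are reproducible.
    """

    def __init__(
        self,
        data: PUDataset,
        config: Optional[PUConfig] = None,
        seed: int = 0,
    ):
        self.data = data
        self.config = config or PUConfig()
        self.seed = int(seed)
        if data.n_positives < 2:
            raise ValueError("need at least 2 positive examples")
        if data.n_unlabeled < 1:
            raise ValueError("need at least 1 unlabeled example")

    @classmethod
    def from_dataframes(
        cls, positives: pd.DataFrame, unlabeled: pd.DataFrame, **kwargs
    ) -> "TransductivePU":
        return cls(PUDataset(positives, unlabeled), **kwargs)

    # -- fitting ---------------------------------------------------------

    def _top_k(self, scores: np.ndarray, ids: Sequence[str], k: int) -> np.ndarray:
        """Boolean mask of the k highest-scoring examples, identifier ties
        broken lexicographically."""
        order = sorted(range(len(ids)), key=lambda i: (-scores[i], ids[i]))
        mask = np.zeros(len(ids), dtype=bool)
        mask[order[:k]] = True
        return mask

    def fit(self, p: float) -> PUResults:
        """Fit the transductive labeling at positive fraction ``p``."""
        if not (0.0 < p < 1.0):
            raise ValueError("p must be in (0, 1)")
        U = self.data.n_unlabeled
        k = positive_count(p, U)
        if k >= U:
            raise ValueError(
                f"p={p} demands k={k} positives from only {U} unlabeled examples"
            )
        X_pos = self.data.positives.to_numpy(dtype=float)
        X_unl = self.data.unlabeled.to_numpy(dtype=float)
        unl_ids = list(self.data.unlabeled.index)
        X = np.vstack([X_pos, X_unl])
        w_pos = self.config.class_weight_ratio

        if np.allclose(X, X[0]):
            warnings.warn(
                "all feature rows identical; labels assigned by identifier order"
            )
            scores = np.zeros(U)
            mask = self._top_k(scores, unl_ids, k)
            labels = pd.Series(
                np.where(mask, "positive", "negative"), index=unl_ids
            )
            return PUResults(
                self, p, labels, pd.Series(scores, index=unl_ids),
                np.zeros(X.shape[1]), 0.0, 0,
            )

        sample_weight = np.concatenate(
            [np.full(len(X_pos), w_pos), np.full(U, self.config.unlabeled_weight)]
        )
        y = np.concatenate([np.ones(len(X_pos)), -np.ones(U)])
        mask = None
        n_iter = 0
        svm = None
        for n_iter in range(1, self.config.max_refine_iters + 1):
            svm = SVC(kernel="linear", C=self.config.C, random_state=self.seed)
            svm.fit(X, y, sample_weight=sample_weight)
            scores = svm.decision_function(X_unl)
            new_mask = self._top_k(scores, unl_ids, k)
            if mask is not None and np.array_equal(new_mask, mask):
                break
            mask = new_mask
            y = np.concatenate([np.ones(len(X_pos)), np.where(mask, 1.0, -1.0)])

        labels = pd.Series(np.where(mask, "positive", "negative"), index=unl_ids)
        coef = np.asarray(svm.coef_).ravel()
        return PUResults(
            self, p, labels, pd.Series(scores, index=unl_ids),
            coef, float(svm.intercept_[0]), n_iter,
        )

    def sweep(self, grid: Sequence[float] = DEFAULT_P_GRID) -> list[PUResults]:
        """Fit the full p grid; grid must be strictly increasing in (0, 1).

        A p value whose fit fails is skipped with a warning naming it;
        an error is raised only if every p fails.
        """
        grid = list(grid)
        if any(not (0 < g < 1) for g in grid) or any(
            b <= a for a, b in zip(grid, grid[1:])
        ):
            raise ValueError("grid must be strictly increasing within (0, 1)")
        results, failures = [], []
        for p in grid:
            try:
                results.append(self.fit(p))
            except ValueError as exc:
                failures.append((p, str(exc)))
                logger.warning("fit failed at p=%.2f: %s", p, exc)
        if not results:
            raise RuntimeError(f"every p in the sweep failed: {failures}")
        return results


# -- aggregation and evaluation ------------------------------------------


def positives_at(scores: pd.Series, p: float) -> set[str]:
    """Top-k positive set implied by a fixed score vector at fraction ``p``.

    Useful for studying how the positive set grows with p when the decision
    scores are held fixed (the sets are then nested in p by construction).
    """
    U = len(scores)
    k = positive_count(p, U)
    if k >= U:
        raise ValueError(f"p={p} demands k={k} of {U} unlabeled examples")
    order = sorted(scores.index, key=lambda i: (-scores[i], i))
    return set(order[:k])


def robust_positives(results: Sequence[PUResults]) -> set[str]:
    """Identifiers predicted positive at every p (across-sweep intersection)."""
    if not results:
        raise ValueError("need at least one labeling")
    out = set(results[0].positive_ids)
    for r in results[1:]:
        out &= r.positive_ids
    return out


@dataclass
class PUEvaluation:
    recall: float
    removal_rate: float
    p: float
    holdout_fraction: Optional[float] = None


def evaluate(
    result: PUResults,
    known_positive_ids: Iterable[str],
    unlabeled_ids: Iterable[str],
    holdout_fraction: Optional[float] = None,
) -> PUEvaluation:
    """Recall over known positives and removal rate over the unlabeled pool.

    recall = |predicted positive ∩ known positives| / |known positives|;
    removal rate = |predicted negative ∩ unlabeled| / |unlabeled|.
    """
    known = set(known_positive_ids)
    if not known:
        raise ValueError("recall undefined: no known positives")
    unl = set(unlabeled_ids)
    pos = result.positive_ids
    neg = result.negative_ids
    return PUEvaluation(
        recall=len(pos & known) / len(known),
        removal_rate=len(neg & unl) / len(unl) if unl else 0.0,
        p=result.p,
        holdout_fraction=holdout_fraction,
    )


def holdout_experiment(
    positives: pd.DataFrame,
    unlabeled: pd.DataFrame,
    fractions: Sequence[float] = DEFAULT_HOLDOUT_FRACTIONS,
    grid: Sequence[float] = DEFAULT_P_GRID,
    config: Optional[PUConfig] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Move random fractions of the positives into the unlabeled pool and
    measure recall on the moved-out positives across the p grid.

    For each fraction f, floor(f * P) positives are selected (seeded) and
    joined to the unlabeled pool; the model is refit over the grid; recall
    is computed on the moved-out identifiers and the removal rate on the
    augmented pool. Fractions leaving fewer than 2 training positives, or
    moving out none, are skipped with a warning.

    Returns a table with columns (holdout_fraction, p, recall, removal_rate).
    """
    rng = np.random.default_rng(seed)
    rows = []
    P = len(positives)
    for f in fractions:
        n_move = int(np.floor(f * P))
        if n_move == 0:
            warnings.warn(f"fraction {f} moves no positives; skipped")
            continue
        if P - n_move < 2:
            warnings.warn(f"fraction {f} leaves <2 training positives; skipped")
            continue
        moved_idx = rng.choice(P, size=n_move, replace=False)
        moved = positives.iloc[sorted(moved_idx)]
        kept = positives.drop(index=moved.index)
        pool = pd.concat([unlabeled, moved])
        model = TransductivePU(PUDataset(kept, pool), config=config, seed=seed)
        for result in model.sweep(grid):
            ev = evaluate(result, moved.index, pool.index, holdout_fraction=f)
            rows.append(
                {
                    "holdout_fraction": f,
                    "p": result.p,
                    "recall": ev.recall,
                    "removal_rate": ev.removal_rate,
                }
            )
    return pd.DataFrame(rows, columns=["holdout_fraction", "p", "recall", "removal_rate"])


def cross_validate(
    positives: pd.DataFrame,
    unlabeled: pd.DataFrame,
    folds: int = 5,
    grid: Sequence[float] = DEFAULT_P_GRID,
    config: Optional[PUConfig] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """k-fold cross-validation of the PU classifier.

    Positives are partitioned into ``folds`` seeded folds; each fold in turn
    is moved into the unlabeled pool, the model refit over the grid, recall
    measured on the held-out fold and removal rate on the augmented pool.
    Metrics are averaged over folds per p.
    """
    P = len(positives)
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if folds > P:
        raise ValueError(f"{folds} folds exceed {P} positives")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(P)
    assignments = np.array_split(perm, folds)
    rows = []
    for fold_no, held_idx in enumerate(assignments):
        held = positives.iloc[sorted(held_idx)]
        kept = positives.drop(index=held.index)
        if len(kept) < 2:
            warnings.warn(f"fold {fold_no} leaves <2 training positives; skipped")
            continue
        pool = pd.concat([unlabeled, held])
        model = TransductivePU(PUDataset(kept, pool), config=config, seed=seed)
        for result in model.sweep(grid):
            ev = evaluate(result, held.index, pool.index)
            rows.append(
                {
                    "fold": fold_no,
                    "p": result.p,
                    "recall": ev.recall,
                    "removal_rate": ev.removal_rate,
                }
            )
    table = pd.DataFrame(rows)
    return (
        table.groupby("p", as_index=False)[["recall", "removal_rate"]]
        .mean()
        .sort_values("p")
        .reset_index(drop=True)
    )
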