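"""Mean-reciprocal-rank peak selection and miRNA ranking.

Within a comparison group, every candidate is ranked per feature
(competition ranking: ties share the minimal rank) and summarized by

    MRR = (1/N) * sum_i 1 / rank_i

over the N features. Per miRNA, the candidate with the highest MRR is the
chosen peak, with exact ties broken by proximity to the precursor and then
by peak identifier. The miRNAs themselves are then ranked by recomputing
MRR across the pool of chosen peaks (one per miRNA): within-group MRRs are
not comparable across groups of different sizes, so the ranks are re-pooled.

Ranks depend only on feature order, so the ranking is identical on raw and
min-max-normalized features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .features import FEATURE_COLUMNS, FeatureMatrix

#: Default rank direction per feature. Significance-like features rank
#: higher-is-better; the summit-to-precursor distance ranks lower-is-better
#: (proximal binding is the stronger evidence).
DEFAULT_ORIENTATION: dict[str, str] = {
    "tags": "higher_better",
    "neg_log10_p": "higher_better",
    "fold_enrichment": "higher_better",
    "distance_bp": "lower_better",
    "dnase_flag": "higher_better",
    "motif_score": "higher_better",
    "conservation_flag": "higher_better",
}


@dataclass
class RankProfile:
    """Per-feature competition ranks of one candidate and their MRR."""

    candidate_id: str
    ranks: dict[str, int]
    mrr: float


def _check_orientation(orientation: Mapping[str, str], columns: Sequence[str]) -> None:
    if set(orientation) != set(columns):
        raise ValueError(
            f"orientation must cover exactly the feature columns {list(columns)}"
        )
    bad = {v for v in orientation.values()} - {"higher_better", "lower_better"}
    if bad:
        raise ValueError(f"unknown rank directions {bad}")


def rank_within_group(values: Sequence[float], direction: str) -> np.ndarray:
    """Competition ranks ("1, 2, 2, 4") of a list of feature values.

    The best value (largest for ``higher_better``, smallest for
    ``lower_better``) gets rank 1; tied values share the minimal rank.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot rank an empty group")
    if np.any(np.isnan(arr)):
        bad = int(np.flatnonzero(np.isnan(arr))[0])
        raise ValueError(f"NaN feature value at group position {bad}")
    if direction == "higher_better":
        arr = -arr
    elif direction != "lower_better":
        raise ValueError(f"unknown direction {direction!r}")
    return rankdata(arr, method="min").astype(int)


def mrr_score(ranks: Sequence[int]) -> float:
    """Mean reciprocal rank of a vector of per-feature ranks."""
    arr = np.asarray(ranks, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one rank")
    if np.any(arr < 1):
        raise ValueError("ranks must be >= 1")
    return float(np.mean(1.0 / arr))


def _rank_table(
    group: pd.DataFrame, orientation: Mapping[str, str]
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-feature rank table and MRR vector for a group of candidates."""
    ranks = pd.DataFrame(index=group.index)
    for col in FEATURE_COLUMNS:
        ranks[col] = rank_within_group(group[col].to_numpy(), orientation[col])
    mrrs = (1.0 / ranks.to_numpy(dtype=float)).mean(axis=1)
    return ranks, mrrs


def select_best_peak(
    group: pd.DataFrame,
    orientation: Mapping[str, str] = DEFAULT_ORIENTATION,
) -> RankProfile:
    """Choose one peak among a miRNA's candidates by maximal MRR.

    ``group`` is the slice of a feature matrix belonging to one miRNA
    (index = candidate ids; must include ``distance_bp`` and ``peak_id``).
    Exact MRR ties go to the candidate nearer the precursor, residual ties
    to the lexicographically smallest peak_id.
    """
    _check_orientation(orientation, FEATURE_COLUMNS)
    if len(group) == 0:
        raise ValueError("empty candidate group")
    ranks, mrrs = _rank_table(group, orientation)
    order = sorted(
        range(len(group)),
        key=lambda i: (-mrrs[i], group["distance_bp"].iloc[i], str(group["peak_id"].iloc[i])),
    )
    best = order[0]
    return RankProfile(
        candidate_id=str(group.index[best]),
        ranks={c: int(ranks[c].iloc[best]) for c in FEATURE_COLUMNS},
        mrr=float(mrrs[best]),
    )


def select_best_peaks(
    matrix: FeatureMatrix,
    orientation: Mapping[str, str] = DEFAULT_ORIENTATION,
) -> pd.DataFrame:
    """One chosen peak per miRNA: the per-group MRR winners.

    Returns the chosen rows of the matrix (index = candidate id) with an
    added ``group_mrr`` column.
    """
    chosen_ids, chosen_mrr = [], []
    for _, group in matrix.frame.groupby("mirna_id", sort=True):
        profile = select_best_peak(group, orientation)
        chosen_ids.append(profile.candidate_id)
        chosen_mrr.append(profile.mrr)
    out = matrix.frame.loc[chosen_ids].copy()
    out["group_mrr"] = chosen_mrr
    return out


def rank_mirnas(
    chosen: pd.DataFrame,
    orientation: Mapping[str, str] = DEFAULT_ORIENTATION,
) -> pd.DataFrame:
    """Rank miRNAs by the MRR of their chosen peaks, re-pooled globally.

    ``chosen`` holds one row per miRNA (as from :func:`select_best_peaks`).
    Per-feature ranks are recomputed across this pool; the result is sorted
    by descending MRR, ties by ascending distance then mirna_id. Returns a
    frame (mirna_id, peak_id, mrr, rank) in final order.
    """
    _check_orientation(orientation, FEATURE_COLUMNS)
    if chosen["mirna_id"].duplicated().any():
        dup = chosen["mirna_id"][chosen["mirna_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate mirna_id {dup!r} in chosen-peak set")
    _, mrrs = _rank_table(chosen, orientation)
    out = pd.DataFrame(
        {
            "mirna_id": chosen["mirna_id"].to_numpy(),
            "peak_id": chosen["peak_id"].to_numpy(),
            "mrr": mrrs,
            "distance_bp": chosen["distance_bp"].to_numpy(),
        },
        index=chosen.index,
    )
    out = out.sort_values(
        by=["mrr", "distance_bp", "mirna_id"], ascending=[False, True, True]
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out.drop(columns=["distance_bp"])
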