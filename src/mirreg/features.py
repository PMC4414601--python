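"""Motif scoring, conservation, and the seven-feature candidate matrix.

Each candidate peak is described by seven features: three peak-caller
statistics (tag count, -log10 p-value, fold enrichment), the summit-to-
precursor distance, an open-chromatin flag, a PWM log-odds motif score over
a 200-bp summit-centered window, and a cross-species conservation flag. The
matrix is min-max normalized per column to [0, 1]:

    x' = (x - x_min) / (x_max - x_min)

A constant column maps to all zeros (it is uninformative either way).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from .annotations import RegulatoryRegion
from .intervals import GenomicInterval
from .peaks import CandidatePeak

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = (
    "tags",
    "neg_log10_p",
    "fold_enrichment",
    "distance_bp",
    "dnase_flag",
    "motif_score",
    "conservation_flag",
)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_BACKGROUND = (0.25, 0.25, 0.25, 0.25)
DEFAULT_PSEUDOCOUNT = 0.8
PROB_FLOOR = 1e-4  # keeps log-odds finite for zero counts


@dataclass
class PWM:
    """Log-odds position weight matrix (rows A, C, G, T)."""

    matrix: np.ndarray  # shape (4, L)
    motif_id: str
    background: np.ndarray  # shape (4,)
    pseudocount: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4 or self.length < 1:
            raise ValueError("PWM matrix must be 4 x L with L >= 1")
        if np.any(self.background <= 0):
            raise ValueError("background probabilities must be positive")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def consensus(self) -> str:
        return "".join("ACGT"[b] for b in np.argmax(self.matrix, axis=0))


def pwm_from_counts(
    counts: np.ndarray,
    background: Sequence[float] = DEFAULT_BACKGROUND,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    motif_id: str = "motif",
    prob_floor: float = PROB_FLOOR,
) -> PWM:
    """Build a base-2 log-odds PWM from a 4 x L count matrix.

    The pseudocount is distributed by background (the JASPAR convention):

        p[b, j] = (counts[b, j] + pc * bg[b]) / (sum_b counts[b, j] + pc)
        score[b, j] = log2(max(p[b, j], prob_floor) / bg[b])
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 4:
        raise ValueError("counts must be a 4 x L matrix (rows A, C, G, T)")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    bg = np.asarray(background, dtype=float)
    colsums = counts.sum(axis=0) + pseudocount
    if np.any(colsums <= 0):
        raise ValueError("zero-sum count column with zero pseudocount")
    probs = (counts + pseudocount * bg[:, None]) / colsums[None, :]
    probs = np.maximum(probs, prob_floor)
    matrix = np.log2(probs / bg[:, None])
    return PWM(matrix=matrix, motif_id=motif_id, background=bg, pseudocount=pseudocount)


def read_jaspar_pfm(
    path: str | Path,
    background: Sequence[float] = DEFAULT_BACKGROUND,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> PWM:
    """Read a JASPAR-format PFM file and convert it to a log-odds PWM."""
    with open(path) as fh:
        motif = bio_motifs.read(fh, "jaspar")
    counts = np.array([motif.counts[b] for b in "ACGT"], dtype=float)
    return pwm_from_counts(
        counts, background=background, pseudocount=pseudocount,
        motif_id=motif.matrix_id or motif.name or "motif",
    )


def write_jaspar_pfm(counts: np.ndarray, motif_id: str, name: str, path: str | Path) -> None:
    counts = np.asarray(counts)
    with open(path, "w") as fh:
        fh.write(f">{motif_id} {name}\n")
        for b, row in zip("ACGT", counts):
            fh.write(f"{b} [ " + " ".join(f"{int(v):6d}" for v in row) + " ]\n")


@dataclass
class SummitWindow:
    """Sequence under a summit-centered window, with clipping bookkeeping."""

    seq: str
    start: int
    end: int
    clipped: bool


def extract_summit_window(
    genome, candidate: CandidatePeak, width: int = 200
) -> SummitWindow:
    """Extract the ``width``-bp sequence centered on the candidate's summit.

    ``genome`` is a pyfaidx.Fasta (or any mapping of chrom -> sliceable
    sequence). The window [summit - width/2, summit + width/2) is clipped at
    chromosome ends; the returned object records the realized bounds.
    """
    if width < 2 or width % 2 != 0:
        raise ValueError("width must be even and >= 2")
    chrom = candidate.peak.interval.chrom
    try:
        record = genome[chrom]
    except KeyError as exc:
        raise KeyError(f"chromosome {chrom!r} not in genome") from exc
    chrom_len = len(record)
    summit = candidate.peak.summit
    start = summit - width // 2
    end = summit + width // 2
    if end <= 0 or start >= chrom_len:
        raise ValueError(
            f"peak {candidate.peak.peak_id}: window entirely outside {chrom}"
        )
    clipped = start < 0 or end > chrom_len
    start, end = max(0, start), min(chrom_len, end)
    seq = str(record[start:end]).upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(
            f"peak {candidate.peak.peak_id}: non-nucleotide characters {sorted(bad)}"
        )
    return SummitWindow(seq=seq, start=start, end=end, clipped=clipped)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _scan_scores(idx: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Per-offset windowed log-odds sums; N positions (idx -1) contribute 0."""
    L = matrix.shape[1]
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    cols = np.arange(L)
    vals = np.where(windows >= 0, matrix[np.clip(windows, 0, 3), cols], 0.0)
    return vals.sum(axis=1)


def motif_score(sequence: str, pwm: PWM, scan_both_strands: bool = True) -> float:
    """Maximum windowed log-odds score of ``pwm`` over the sequence.

    Scans every offset on the forward strand and, by default, the reverse
    complement too; the maximum over all windows is the motif score.
    Positions holding N contribute 0 (the background expectation).
    """
    seq = sequence.upper()
    if len(seq) < pwm.length:
        raise ValueError(
            f"sequence length {len(seq)} shorter than motif length {pwm.length}"
        )
    idx = np.array([_BASE_INDEX[c] for c in seq], dtype=np.int64)
    best = _scan_scores(idx, pwm.matrix).max()
    if scan_both_strands:
        rc = np.array([_BASE_INDEX[c] for c in reverse_complement(seq)], dtype=np.int64)
        best = max(best, _scan_scores(rc, pwm.matrix).max())
    return float(best)


@dataclass
class HomologyMap:
    """Mouse-human miRNA homology plus a cross-species coordinate map.

    ``pairs`` holds (mouse_mirna_id, human_mirna_id) homolog pairs.
    ``liftover`` maps source intervals (matched exactly by chrom/start/end)
    to their mapped counterparts, emulating a liftOver output table.
    """

    pairs: set[tuple[str, str]] = field(default_factory=set)
    liftover: dict[tuple[str, int, int], GenomicInterval] = field(default_factory=dict)

    def lift(self, interval: GenomicInterval) -> Optional[GenomicInterval]:
        return self.liftover.get((interval.chrom, interval.start, interval.end))

    @classmethod
    def from_files(cls, homology_tsv: str | Path, liftover_tsv: str | Path) -> "HomologyMap":
        """Load homolog pairs (2-column TSV) and a 6-column liftover table
        (src_chrom, src_start, src_end, dst_chrom, dst_start, dst_end)."""
        pairs: set[tuple[str, str]] = set()
        with open(homology_tsv) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                a, b = line.split("\t")[:2]
                pairs.add((a.strip(), b.strip()))
        lift: dict[tuple[str, int, int], GenomicInterval] = {}
        with open(liftover_tsv) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                sc, ss, se, dc, ds, de = line.split("\t")[:6]
                lift[(sc, int(ss), int(se))] = GenomicInterval(dc, int(ds), int(de))
        return cls(pairs=pairs, liftover=lift)


def conservation_flag(
    candidate: CandidatePeak,
    homology: HomologyMap,
    human_regions: Sequence[RegulatoryRegion],
) -> bool:
    """Whether the candidate peak is conserved in a homologous human miRNA's
    regulatory region.

    The peak interval is lifted to human coordinates; the lifted interval's
    midpoint must fall inside the regulatory region of a human miRNA that is
    a recorded homolog of the candidate's miRNA. Unmapped peaks are not
    conserved.
    """
    lifted = homology.lift(candidate.peak.interval)
    if lifted is None:
        return False
    mid = (lifted.start + lifted.end) // 2
    homologs = {h for (m, h) in homology.pairs if m == candidate.mirna_id}
    for region in human_regions:
        if region.mirna_id in homologs and region.interval.contains(lifted.chrom, mid):
            return True
    return False


class FeatureMatrix:
    """Seven named features per candidate peak, optionally normalized.

    Thin wrapper over a DataFrame indexed by candidate identifier
    (``mirna_id|peak_id``) with the fixed column order of
    :data:`FEATURE_COLUMNS` plus the bookkeeping columns ``mirna_id``,
    ``peak_id``.
    """

    def __init__(self, frame: pd.DataFrame, normalized: bool = False):
        missing = [c for c in FEATURE_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"feature matrix missing columns {missing}")
        self.frame = frame
        self.normalized = normalized
        if normalized:
            vals = frame[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
            if vals.size and (vals.min() < -1e-12 or vals.max() > 1 + 1e-12):
                raise ValueError("normalized matrix has values outside [0, 1]")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def values(self) -> np.ndarray:
        return self.frame[list(FEATURE_COLUMNS)].to_numpy(dtype=float)

    @property
    def identifiers(self) -> list[str]:
        return list(self.frame.index)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="candidate_id")

    @classmethod
    def from_tsv(cls, path: str | Path, normalized: bool = False) -> "FeatureMatrix":
        frame = pd.read_csv(path, sep="\t", index_col="candidate_id")
        return cls(frame, normalized=normalized)


def candidate_identifier(candidate: CandidatePeak) -> str:
    return f"{candidate.mirna_id}|{candidate.peak.peak_id}"


def build_feature_matrix(
    candidates: Sequence[CandidatePeak],
    dnase_flags: Sequence[bool],
    motif_scores: Sequence[Optional[float]],
    conservation_flags: Sequence[bool],
) -> FeatureMatrix:
    """Assemble the raw (unnormalized) feature matrix.

    A candidate whose motif score is missing (summit window clipped shorter
    than the motif) is dropped with a warning.
    """
    n = len(candidates)
    if not (len(dnase_flags) == len(motif_scores) == len(conservation_flags) == n):
        raise ValueError("feature inputs have mismatched lengths")
    rows, index = [], []
    for cand, dnase, score, cons in zip(
        candidates, dnase_flags, motif_scores, conservation_flags
    ):
        if score is None or (isinstance(score, float) and np.isnan(score)):
            logger.warning(
                "dropping %s: no motif score (window shorter than motif)",
                candidate_identifier(cand),
            )
            continue
        rows.append(
            {
                "mirna_id": cand.mirna_id,
                "peak_id": cand.peak.peak_id,
                "tags": float(cand.peak.tags),
                "neg_log10_p": float(cand.peak.neg_log10_p),
                "fold_enrichment": float(cand.peak.fold_enrichment),
                "distance_bp": float(cand.distance_bp),
                "dnase_flag": float(bool(dnase)),
                "motif_score": float(score),
                "conservation_flag": float(bool(cons)),
            }
        )
        index.append(candidate_identifier(cand))
    frame = pd.DataFrame(
        rows, index=index, columns=["mirna_id", "peak_id", *FEATURE_COLUMNS]
    )
    return FeatureMatrix(frame, normalized=False)


def normalize_minmax(matrix: FeatureMatrix) -> FeatureMatrix:
    """Min-max normalize every feature column to [0, 1].

    Constant columns become all zeros (warned): the feature carries no
    information and zero keeps the output deterministic. Binary flags whose
    observed min is 0 and max is 1 pass through unchanged, as the formula
    is the identity for them.
    """
    if matrix.normalized:
        raise ValueError("matrix is already normalized")
    if len(matrix) == 0:
        raise ValueError("cannot normalize an empty feature matrix")
    frame = matrix.frame.copy()
    for col in FEATURE_COLUMNS:
        x = frame[col].to_numpy(dtype=float)
        lo, hi = x.min(), x.max()
        if hi == lo:
            warnings.warn(f"feature {col!r} is constant; normalized to 0")
            frame[col] = 0.0
        else:
            frame[col] = (x - lo) / (hi - lo)
    return FeatureMatrix(frame, normalized=True)
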