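"""ChIP-Seq peak parsing, candidate assignment, and DNase overlap.

Two peak dialects are read: ENCODE narrowPeak (BED6+4, 0-based) and the
MACS 1.x tabular "xls" (1-based, converted on read). A peak becomes a
*candidate* for a miRNA when its summit falls inside that miRNA's regulatory
region; a peak whose summit lies in two overlapping regions yields one
candidate per region. DNase open-chromatin status is a >=1 bp overlap of the
whole peak interval with a concordant open region.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .annotations import MiRNAGene, RegulatoryRegion
from .intervals import GenomicInterval, IntervalIndex

logger = logging.getLogger(__name__)


@dataclass
class Peak:
    """A called ChIP-Seq peak with its summit and peak-caller statistics."""

    interval: GenomicInterval
    summit: int
    tags: int
    neg_log10_p: float
    fold_enrichment: float
    peak_id: str

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"peak {self.peak_id}: summit {self.summit} outside "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )
        if self.tags < 0 or self.fold_enrichment < 0 or self.neg_log10_p < 0:
            raise ValueError(f"peak {self.peak_id}: negative statistic")


@dataclass
class CandidatePeak:
    """A peak assigned to one miRNA's regulatory region."""

    peak: Peak
    mirna_id: str
    distance_bp: int


class PeakParseError(ValueError):
    pass


def _detect_dialect(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            if line.startswith("#") or line.lower().startswith("chr\t"):
                return "macs_xls"
            return "narrowPeak" if len(line.split("\t")) >= 10 else "macs_xls"
    raise PeakParseError(f"{path}: empty peak file")


def parse_peaks(
    path: str | Path,
    dialect: Optional[str] = None,
    default_tags: int = 1,
) -> list[Peak]:
    """Parse a peak file into :class:`Peak` records.

    narrowPeak: ``signalValue`` -> fold_enrichment, ``pValue`` (already
    -log10) -> neg_log10_p, summit = start + offset column; an offset of -1
    puts the summit at the interval midpoint with a warning. narrowPeak
    carries no tag count: an optional 11th column supplies it, otherwise
    ``default_tags`` is used and the tags feature is uninformative (warned).

    macs_xls: 1-based start and absolute 1-based summit converted to 0-based;
    the ``-10*log10(pvalue)`` column is divided by 10.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = _detect_dialect(path)
    if dialect not in ("narrowPeak", "macs_xls"):
        raise PeakParseError(f"unknown peak dialect {dialect!r}")

    peaks: list[Peak] = []
    warned_tags = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if dialect == "macs_xls" and fields[0].lower() == "chr":
                continue  # header row
            try:
                if dialect == "narrowPeak":
                    (chrom, start, end, name, _score, _strand,
                     signal, pval, _qval, offset) = fields[:10]
                    start, end, offset = int(start), int(end), int(offset)
                    if offset == -1:
                        summit = start + (end - start) // 2
                        logger.warning(
                            "%s line %d: summit offset -1, using midpoint",
                            path, lineno,
                        )
                    else:
                        summit = start + offset
                    if len(fields) > 10:
                        tags = int(fields[10])
                    else:
                        tags = default_tags
                        if not warned_tags:
                            logger.warning(
                                "%s: narrowPeak has no tag counts; using "
                                "default %d (tags feature uninformative)",
                                path, default_tags,
                            )
                            warned_tags = True
                    peak = Peak(
                        interval=GenomicInterval(chrom, start, end),
                        summit=summit,
                        tags=tags,
                        neg_log10_p=float(pval),
                        fold_enrichment=float(signal),
                        peak_id=name,
                    )
                else:  # macs_xls: chr start end length summit tags -10log10p fold
                    chrom, start1, end, _length, summit1, tags, m10lp, fold = fields[:8]
                    peak = Peak(
                        interval=GenomicInterval(chrom, int(start1) - 1, int(end)),
                        summit=int(summit1) - 1,
                        tags=int(tags),
                        neg_log10_p=float(m10lp) / 10.0,
                        fold_enrichment=float(fold),
                        peak_id=f"{path.stem}_peak_{lineno}",
                    )
            except (ValueError, IndexError) as exc:
                raise PeakParseError(f"{path}, line {lineno}: {exc}") from exc
            peaks.append(peak)
    return peaks


def write_narrowpeak(peaks: Sequence[Peak], path: str | Path) -> None:
    """Write peaks as narrowPeak with the tag count as an 11th column."""
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.peak_id}\t0\t.\t"
                f"{p.fold_enrichment:g}\t{p.neg_log10_p:g}\t-1\t"
                f"{p.summit - iv.start}\t{p.tags}\n"
            )


def assign_candidates(
    peaks: Iterable[Peak],
    regions: Sequence[RegulatoryRegion],
    mirnas: Sequence[MiRNAGene],
) -> list[CandidatePeak]:
    """Assign peaks to regulatory regions by summit membership.

    Emits one candidate per (peak, region) pair with summit in the region;
    distance_bp = |summit - precursor 5' end|.
    """
    five_prime = {m.mirna_id: m.five_prime for m in mirnas}
    for r in regions:
        if r.mirna_id not in five_prime:
            raise ValueError(f"region references unknown mirna_id {r.mirna_id!r}")
    out: list[CandidatePeak] = []
    for peak in peaks:
        for region in regions:
            if region.interval.contains(peak.interval.chrom, peak.summit):
                out.append(
                    CandidatePeak(
                        peak=peak,
                        mirna_id=region.mirna_id,
                        distance_bp=abs(peak.summit - five_prime[region.mirna_id]),
                    )
                )
    return out


def concordant_dnase(
    rep1: Sequence[Peak] | Sequence[GenomicInterval],
    rep2: Sequence[Peak] | Sequence[GenomicInterval],
) -> list[GenomicInterval]:
    """Replicate-concordant open-chromatin intervals.

    Returns every rep1 interval having >= 1 bp overlap with some rep2
    interval. This deterministic rule replaces M-A renormalization of the
    replicates; only the intersection step matters downstream.
    """

    def _ivs(xs):
        return [x.interval if isinstance(x, Peak) else x for x in xs]

    iv1, iv2 = _ivs(rep1), _ivs(rep2)
    if not iv1 or not iv2:
        warnings.warn("empty DNase replicate; no concordant open regions")
        return []
    index = IntervalIndex(iv2)
    return [iv for iv in iv1 if index.any_overlap(iv)]


def dnase_overlap_flag(
    candidate: CandidatePeak, open_regions: Sequence[GenomicInterval] | IntervalIndex
) -> bool:
    """True iff the candidate's whole peak interval shares >= 1 bp with an
    open-chromatin region."""
    index = (
        open_regions
        if isinstance(open_regions, IntervalIndex)
        else IntervalIndex(open_regions)
    )
    return index.any_overlap(candidate.peak.interval)


def load_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read plain BED (>=3 columns) into intervals."""
    out = []
    with open(Path(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
            except (ValueError, IndexError) as exc:
                raise PeakParseError(f"{path}, line {lineno}: {exc}") from exc
    return out


def candidates_to_frame(
    candidates: Sequence[CandidatePeak], dnase_flags: Optional[Sequence[bool]] = None
) -> pd.DataFrame:
    """Tabular view of candidates (the candidates TSV layout)."""
    rows = []
    for i, c in enumerate(candidates):
        rows.append(
            {
                "peak_id": c.peak.peak_id,
                "mirna_id": c.mirna_id,
                "chrom": c.peak.interval.chrom,
                "start": c.peak.interval.start,
                "end": c.peak.interval.end,
                "summit": c.peak.summit,
                "tags": c.peak.tags,
                "neg_log10_p": c.peak.neg_log10_p,
                "fold_enrichment": c.peak.fold_enrichment,
                "distance_bp": c.distance_bp,
                "dnase_flag": int(dnase_flags[i]) if dnase_flags is not None else 0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "peak_id", "mirna_id", "chrom", "start", "end", "summit",
            "tags", "neg_log10_p", "fold_enrichment", "distance_bp", "dnase_flag",
        ],
    )
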