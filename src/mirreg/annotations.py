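"""miRNA and gene annotations, and regulatory-region construction.

The regulatory region of an intergenic miRNA is a fixed-length window
upstream of the precursor's 5' end (strand-aware): 700 kb for mouse, 1000 kb
for human by default. If a protein-coding gene intrudes into the window, the
region is truncated at the nearest intervening gene boundary so that the
emitted region never overlaps a gene. Windows are clipped at position 0 and,
when a chromosome length is known, at the chromosome end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .intervals import GenomicInterval, IntervalIndex

logger = logging.getLogger(__name__)

WINDOW_BP_MOUSE = 700_000
WINDOW_BP_HUMAN = 1_000_000
DEFAULT_GFF_FEATURE_TYPE = "miRNA_primary_transcript"


@dataclass
class MiRNAGene:
    """An annotated miRNA precursor."""

    mirna_id: str
    interval: GenomicInterval
    expressed: bool = True
    intergenic: Optional[bool] = None  # None until classified

    @property
    def five_prime(self) -> int:
        """Strand-aware 5' end of the precursor (a single coordinate).

        For a + strand precursor this is ``start``; for - strand it is
        ``end`` (the half-open right edge, i.e. the first upstream base sits
        at this coordinate).
        """
        return self.interval.start if self.interval.strand == "+" else self.interval.end


@dataclass
class RegulatoryRegion:
    """The upstream window assigned to one miRNA, after truncation."""

    mirna_id: str
    interval: GenomicInterval
    window_bp: int
    truncated: bool = False


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


def _parse_gff3_attributes(field: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in field.strip().split(";"):
        if not item:
            continue
        if "=" not in item:
            continue
        k, v = item.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def _iter_annotation_records(path: Path, gff_feature_type: str):
    """Yield (lineno, chrom, start0, end, strand, name) from GFF3 or BED6.

    Dialect is decided per file: ``.gff``/``.gff3`` suffix or a ``##gff``
    header means GFF3 (1-based inclusive, converted here); anything else is
    treated as BED6 (already 0-based half-open).
    """
    text = path.read_text()
    lines = text.splitlines()
    is_gff = path.suffix.lower() in (".gff", ".gff3") or text.startswith("##gff")
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        try:
            if is_gff:
                if len(fields) < 9:
                    raise ValueError("GFF3 record has fewer than 9 columns")
                chrom, _src, ftype, start1, end, _score, strand, _phase, attrs = fields[:9]
                if ftype != gff_feature_type:
                    continue
                attributes = _parse_gff3_attributes(attrs)
                name = attributes.get("ID") or attributes.get("Name")
                if name is None:
                    raise ValueError("GFF3 record lacks ID/Name attribute")
                start0 = int(start1) - 1
                end = int(end)
            else:
                if len(fields) < 6:
                    raise ValueError("BED6 record has fewer than 6 columns")
                chrom, start0, end, name, _score, strand = fields[:6]
                start0 = int(start0)
                end = int(end)
        except ValueError as exc:
            raise AnnotationError(f"{path}, line {lineno}: {exc}") from exc
        yield lineno, chrom, start0, int(end), strand, name


def load_mirna_annotations(
    path: str | Path,
    expressed_ids: Optional[Iterable[str]] = None,
    gff_feature_type: str = DEFAULT_GFF_FEATURE_TYPE,
) -> list[MiRNAGene]:
    """Load miRNA precursor annotations from GFF3 or BED6.

    Parameters
    ----------
    path : path to a GFF3 or BED6 file.
    expressed_ids : optional collection of miRNA identifiers.
        ``expressed`` is set true iff the id is in this set; when None
        (absent) every precursor is marked expressed.
    gff_feature_type : GFF3 feature type to keep (default
        ``miRNA_primary_transcript``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    expressed_set = None if expressed_ids is None else set(expressed_ids)
    out: list[MiRNAGene] = []
    seen: set[str] = set()
    for lineno, chrom, start0, end, strand, name in _iter_annotation_records(
        path, gff_feature_type
    ):
        if strand not in ("+", "-"):
            raise AnnotationError(
                f"{path}, line {lineno}: miRNA record {name!r} lacks a strand"
            )
        if name in seen:
            raise AnnotationError(f"{path}, line {lineno}: duplicate mirna_id {name!r}")
        seen.add(name)
        try:
            interval = GenomicInterval(chrom, start0, end, strand)
        except ValueError as exc:
            raise AnnotationError(f"{path}, line {lineno}: {exc}") from exc
        expressed = True if expressed_set is None else name in expressed_set
        out.append(MiRNAGene(mirna_id=name, interval=interval, expressed=expressed))
    return out


def load_gene_intervals(
    path: str | Path, gff_feature_type: str = "gene"
) -> list[GenomicInterval]:
    """Load protein-coding gene intervals from BED6 or GFF3."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out = []
    for lineno, chrom, start0, end, strand, _name in _iter_annotation_records(
        path, gff_feature_type
    ):
        if strand not in ("+", "-", "."):
            raise AnnotationError(f"{path}, line {lineno}: invalid strand {strand!r}")
        try:
            out.append(GenomicInterval(chrom, start0, end, strand))
        except ValueError as exc:
            raise AnnotationError(f"{path}, line {lineno}: {exc}") from exc
    return out


def classify_intergenic(
    mirnas: Sequence[MiRNAGene], genes: Iterable[GenomicInterval]
) -> list[MiRNAGene]:
    """Set ``intergenic`` on each miRNA: false iff it overlaps any gene.

    Overlap is >= 1 bp and strand-ignorant. Returns the same objects,
    mutated in place (and the list, for chaining).
    """
    index = IntervalIndex(genes)
    for m in mirnas:
        m.intergenic = not index.any_overlap(m.interval)
    return list(mirnas)


class EmptyRegionError(ValueError):
    """The upstream window collapsed to length zero (a gene abuts the 5' end)."""


def compute_regulatory_region(
    mirna: MiRNAGene,
    genes: Iterable[GenomicInterval],
    window_bp: int = WINDOW_BP_MOUSE,
    chrom_length: Optional[int] = None,
) -> RegulatoryRegion:
    """Build the truncated upstream regulatory window for one intergenic miRNA.

    The window of length ``window_bp`` ends at the precursor's strand-aware 5'
    end and extends upstream (leftward on +, rightward on -). Any
    protein-coding gene intersecting the window truncates it at that gene's
    nearest boundary (gene end for + strand miRNAs, gene start for -),
    regardless of the gene's own strand. Clipped at 0 and, if ``chrom_length``
    is given, at the chromosome end.

    Raises
    ------
    ValueError : if the miRNA is not classified intergenic.
    EmptyRegionError : if the window collapses to zero length.
    """
    if mirna.intergenic is not True:
        raise ValueError(
            f"{mirna.mirna_id}: regulatory regions are defined only for "
            "intergenic miRNAs (classify_intergenic first)"
        )
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    chrom = mirna.interval.chrom
    anchor = mirna.five_prime
    if mirna.interval.strand == "+":
        start = max(0, anchor - window_bp)
        end = anchor
    else:
        start = anchor
        end = anchor + window_bp
        if chrom_length is not None:
            end = min(end, chrom_length)
    truncated = False
    if start < end:
        window = GenomicInterval(chrom, start, end)
        nearest = None
        for g in IntervalIndex(genes).overlapping(window):
            if mirna.interval.strand == "+":
                # gene truncates from the left; region starts at its end
                boundary = g.end
                if nearest is None or boundary > nearest:
                    nearest = boundary
            else:
                boundary = g.start
                if nearest is None or boundary < nearest:
                    nearest = boundary
        if nearest is not None:
            truncated = True
            if mirna.interval.strand == "+":
                start = max(start, nearest)
            else:
                end = min(end, nearest)
    if start >= end:
        raise EmptyRegionError(
            f"{mirna.mirna_id}: upstream window is empty (gene abuts the 5' end)"
        )
    return RegulatoryRegion(
        mirna_id=mirna.mirna_id,
        interval=GenomicInterval(chrom, start, end),
        window_bp=window_bp,
        truncated=truncated,
    )


def build_regulatory_regions(
    mirnas: Sequence[MiRNAGene],
    genes: Sequence[GenomicInterval],
    window_bp: int = WINDOW_BP_MOUSE,
    chrom_lengths: Optional[Mapping[str, int]] = None,
    expressed_only: bool = True,
) -> list[RegulatoryRegion]:
    """Regions for every (expressed) intergenic miRNA; empty windows are
    dropped with a logged warning rather than raised."""
    regions = []
    for m in mirnas:
        if m.intergenic is not True:
            continue
        if expressed_only and not m.expressed:
            continue
        clen = None if chrom_lengths is None else chrom_lengths.get(m.interval.chrom)
        try:
            regions.append(
                compute_regulatory_region(m, genes, window_bp, chrom_length=clen)
            )
        except EmptyRegionError as exc:
            logger.warning("dropping %s: %s", m.mirna_id, exc)
    return regions


def write_regions_bed(
    regions: Sequence[RegulatoryRegion], bed_path: str | Path, tsv_path: str | Path
) -> None:
    """Write regions as BED6 (name = mirna_id) plus a TSV sidecar."""
    with open(bed_path, "w") as bed:
        for r in regions:
            bed.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}"
                f"\t{r.mirna_id}\t0\t.\n"
            )
    with open(tsv_path, "w") as tsv:
        tsv.write("mirna_id\ttruncated\twindow_bp\n")
        for r in regions:
            tsv.write(f"{r.mirna_id}\t{int(r.truncated)}\t{r.window_bp}\n")
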