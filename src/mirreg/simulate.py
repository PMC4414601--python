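"""Synthetic input bundles with planted TF-binding ground truth.

Writes a complete, mutually consistent set of pipeline inputs — genome
FASTA, miRNA GFF3, gene BED, narrowPeak ChIP peaks, two DNase BED
replicates, a JASPAR PFM, a liftover table, a homology table, an
expressed-miRNA list and a known-positives TSV — in which a chosen subset
of miRNAs is truly bound: their regions carry one extra peak whose
statistics are shifted upward (in pooled-sd units), whose summit carries a
planted motif consensus, which tends to sit in open chromatin, to be
conserved in the homologous human region, and to lie near the precursor.
Decoy peaks are background draws. The generator is fully deterministic
given the seed.

Geometry: each miRNA lives in its own slot along the chromosome with a
protein-coding "insulator" gene placed just upstream, so every regulatory
window is gene-truncated to the slot and windows of neighboring miRNAs do
not overlap. This keeps the planted edge set well-posed: a true peak can
only ever be a candidate for its own miRNA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
import numpy as np

from .features import motif_score, pwm_from_counts, write_jaspar_pfm

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Parameters of the stated synthetic world.

    Effect sizes for the three peak statistics are in pooled standard
    deviations of the decoy distribution; probabilities give the chance a
    true (resp. decoy) peak receives the open-chromatin / conservation /
    planted-motif property.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length_bp: int = 5_000_000
    n_mirnas: int = 20
    n_intragenic: int = 2
    n_unexpressed: int = 2
    n_true_bound_mirnas: int = 8
    peaks_per_region_mean: float = 8.0
    # effect sizes (pooled-sd units) for tags / fold enrichment / -log10 p
    shift_tags: float = 2.0
    shift_fold: float = 2.0
    shift_neg_log10_p: float = 2.0
    motif_plant_prob: float = 0.9
    dnase_prob_true: float = 0.9
    dnase_prob_decoy: float = 0.2
    cons_prob_true: float = 0.8
    cons_prob_decoy: float = 0.1
    true_distance_scale_bp: float = 20_000.0
    # decoy feature distributions
    tags_mean: float = 30.0
    tags_dispersion: float = 10.0  # NB size parameter r
    fold_logmean: float = math.log(5.0)
    fold_logsd: float = 0.5
    nlp_base: float = 5.0
    nlp_scale: float = 3.0
    motif_len: int = 8
    known_positive_fraction: float = 0.5
    n_extra_positives: int = 0
    tf_name: str = "TF"

    def __post_init__(self) -> None:
        probs = (
            self.motif_plant_prob, self.dnase_prob_true, self.dnase_prob_decoy,
            self.cons_prob_true, self.cons_prob_decoy, self.known_positive_fraction,
        )
        if any(not (0 <= q <= 1) for q in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.chromosome_length_bp <= 0 or self.n_mirnas <= 0:
            raise ValueError("lengths and counts must be positive")


@dataclass
class GroundTruth:
    """What was planted: the targets the pipeline should recover."""

    true_edges: set[tuple[str, str]]
    true_peak_ids: set[str]
    known_positive_mirnas: set[str]
    motif_positions: list[tuple[str, int]]
    intergenic_expressed_mirnas: set[str] = field(default_factory=set)

    @property
    def true_mirnas(self) -> set[str]:
        return {m for (_tf, m) in self.true_edges}

    @property
    def novel_true_mirnas(self) -> set[str]:
        """True targets not already given to the learner as positives."""
        return self.true_mirnas - self.known_positive_mirnas


_SLOT_MARGIN = 20_000
_GENE_LEN = 50_000
_PRE_LEN = 80
_REGION_MIN, _REGION_MAX = 150_000, 250_000
_HUMAN_OFFSET = 1_000_000


def _write_fasta(path: Path, chroms: dict[str, bytearray]) -> None:
    with open(path, "w") as fh:
        for name, seq in chroms.items():
            fh.write(f">{name}\n")
            data = bytes(seq).decode("ascii")
            for i in range(0, len(data), 80):
                fh.write(data[i : i + 80] + "\n")


def simulate_bundle(
    config: SimulationConfig, outdir: str | Path
) -> tuple[dict[str, Path], GroundTruth]:
    """Write the full input bundle under ``outdir``; return paths and truth.

    Raises ValueError when the geometry is infeasible (slots too narrow for
    a truncated region plus its insulator gene).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    n_per_chrom = math.ceil(cfg.n_mirnas / cfg.n_chromosomes)
    slot = cfg.chromosome_length_bp // n_per_chrom
    if slot < _SLOT_MARGIN + _REGION_MAX + _GENE_LEN + _PRE_LEN:
        raise ValueError(
            f"infeasible geometry: slot width {slot} bp cannot hold a "
            f"{_REGION_MAX} bp region plus a {_GENE_LEN} bp insulator gene"
        )

    # -- genome -----------------------------------------------------------
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    genome = {
        name: bytearray(
            _BASES[rng.integers(0, 4, cfg.chromosome_length_bp, dtype=np.int64)]
            .tobytes()
        )
        for name in chrom_names
    }

    # -- motif ------------------------------------------------------------
    consensus_idx = rng.integers(0, 4, cfg.motif_len)
    consensus = "".join("ACGT"[i] for i in consensus_idx)
    counts = np.full((4, cfg.motif_len), 5, dtype=int)
    counts[consensus_idx, np.arange(cfg.motif_len)] = 85
    pwm = pwm_from_counts(counts, motif_id="SIM0001")

    # -- miRNA / gene layout ---------------------------------------------
    mirnas = []  # dicts: id, chrom, start, end, strand, kind, region(start,end)
    genes = []  # (chrom, start, end)
    idx = 0
    for chrom in chrom_names:
        for s in range(n_per_chrom):
            if idx >= cfg.n_mirnas:
                break
            s0, s1 = s * slot, (s + 1) * slot
            strand = "+" if idx % 2 == 0 else "-"
            mid = f"mmu-mir-{idx + 1}"
            if idx < cfg.n_intragenic:
                # precursor buried inside a protein-coding gene
                pre_start = s0 + slot // 2
                mirnas.append(
                    dict(id=mid, chrom=chrom, start=pre_start,
                         end=pre_start + _PRE_LEN, strand=strand,
                         kind="intragenic", region=None)
                )
                genes.append((chrom, pre_start - 5_000, pre_start + _PRE_LEN + 5_000))
            else:
                region_len = int(rng.uniform(_REGION_MIN, _REGION_MAX))
                if strand == "+":
                    five = s1 - _SLOT_MARGIN
                    pre = (five, five + _PRE_LEN)
                    region = (five - region_len, five)
                    genes.append((chrom, region[0] - _GENE_LEN, region[0]))
                else:
                    anchor = s0 + _SLOT_MARGIN
                    pre = (anchor - _PRE_LEN, anchor)
                    region = (anchor, anchor + region_len)
                    genes.append((chrom, region[1], region[1] + _GENE_LEN))
                mirnas.append(
                    dict(id=mid, chrom=chrom, start=pre[0], end=pre[1],
                         strand=strand, kind="intergenic", region=region)
                )
            idx += 1

    intergenic = [m for m in mirnas if m["kind"] == "intergenic"]
    unexpressed_ids = {m["id"] for m in intergenic[-cfg.n_unexpressed:]} if cfg.n_unexpressed else set()
    expressed_ids = [m["id"] for m in mirnas if m["id"] not in unexpressed_ids]
    usable = [m for m in intergenic if m["id"] not in unexpressed_ids]

    n_true = min(cfg.n_true_bound_mirnas, len(usable))
    true_idx = rng.choice(len(usable), size=n_true, replace=False)
    true_mirnas = {usable[i]["id"] for i in true_idx}

    # -- peaks -------------------------------------------------------------
    tags_r = cfg.tags_dispersion
    tags_sd = math.sqrt(cfg.tags_mean + cfg.tags_mean**2 / tags_r)
    fold_var = (math.exp(cfg.fold_logsd**2) - 1) * math.exp(
        2 * cfg.fold_logmean + cfg.fold_logsd**2
    )
    fold_sd = math.sqrt(fold_var)

    def nb_draw(mean: float) -> int:
        pr = tags_r / (tags_r + mean)
        return int(rng.negative_binomial(tags_r, pr))

    peak_rows = []  # (chrom, start, end, name, fold, nlp, offset, tags)
    dnase_true = []  # intervals to place in both replicates
    lift_rows = []
    truth_edges: set[tuple[str, str]] = set()
    truth_peaks: set[str] = set()
    motif_positions: list[tuple[str, int]] = []
    peak_counter = 0

    def add_peak(m, summit: int, is_true: bool) -> None:
        nonlocal peak_counter
        peak_counter += 1
        name = f"peak_{peak_counter:04d}"
        chrom = m["chrom"]
        half = int(rng.integers(120, 220))
        start = max(0, summit - half)
        end = min(cfg.chromosome_length_bp, summit + half)
        if is_true:
            tags = nb_draw(cfg.tags_mean + cfg.shift_tags * tags_sd)
            fold = rng.lognormal(cfg.fold_logmean, cfg.fold_logsd) + cfg.shift_fold * fold_sd
            nlp = cfg.nlp_base + rng.exponential(cfg.nlp_scale) + cfg.shift_neg_log10_p * cfg.nlp_scale
            if rng.random() < cfg.motif_plant_prob:
                half_m = cfg.motif_len // 2
                genome[chrom][summit - half_m : summit - half_m + cfg.motif_len] = \
                    consensus.encode("ascii")
                motif_positions.append((chrom, summit - half_m))
            dnase_p, cons_p = cfg.dnase_prob_true, cfg.cons_prob_true
            truth_edges.add((cfg.tf_name, m["id"]))
            truth_peaks.add(name)
        else:
            tags = nb_draw(cfg.tags_mean)
            fold = rng.lognormal(cfg.fold_logmean, cfg.fold_logsd)
            nlp = cfg.nlp_base + rng.exponential(cfg.nlp_scale)
            dnase_p, cons_p = cfg.dnase_prob_decoy, cfg.cons_prob_decoy
        if rng.random() < dnase_p:
            dnase_true.append((chrom, summit - 160, summit + 160))
        if rng.random() < cons_p:
            lift_rows.append(
                (chrom, start, end, "h" + chrom,
                 start + _HUMAN_OFFSET, end + _HUMAN_OFFSET)
            )
        elif rng.random() < 0.5:
            # mapped, but nowhere near any human regulatory region
            far = int(rng.integers(0, cfg.chromosome_length_bp))
            lift_rows.append((chrom, start, end, "hchr_un", far, far + (end - start)))
        peak_rows.append((chrom, start, end, name, fold, nlp, summit - start, tags))

    for m in usable:
        r0, r1 = m["region"]
        five = m["start"] if m["strand"] == "+" else m["end"]
        for _ in range(int(rng.poisson(cfg.peaks_per_region_mean))):
            add_peak(m, int(rng.integers(r0 + 5, r1 - 5)), is_true=False)
        if m["id"] in true_mirnas:
            if math.isfinite(cfg.true_distance_scale_bp):
                d = int(min(rng.exponential(cfg.true_distance_scale_bp),
                            (r1 - r0) - 10.0))
                summit = five - 1 - d if m["strand"] == "+" else five + 1 + d
                summit = int(np.clip(summit, r0 + 1, r1 - 2))
            else:  # null world: proximity carries no signal
                summit = int(rng.integers(r0 + 5, r1 - 5))
            add_peak(m, summit, is_true=True)

    # -- DNase replicates --------------------------------------------------
    rep1, rep2 = [], []
    for chrom, a, b in dnase_true:
        rep1.append((chrom, max(0, a - 10), b))
        rep2.append((chrom, max(0, a), b + 10))
    for chrom in chrom_names:
        for _ in range(20):  # discordant background opens
            pos = int(rng.integers(0, cfg.chromosome_length_bp - 400))
            rep1.append((chrom, pos, pos + 300))
            pos = int(rng.integers(0, cfg.chromosome_length_bp - 400))
            rep2.append((chrom, pos, pos + 300))

    # -- write files -------------------------------------------------------
    paths = {
        "genome_fasta": outdir / "genome.fa",
        "mirna_annotations": outdir / "mirnas.gff3",
        "gene_annotations": outdir / "genes.bed",
        "peaks": outdir / "peaks.narrowPeak",
        "dnase_rep1": outdir / "dnase_rep1.bed",
        "dnase_rep2": outdir / "dnase_rep2.bed",
        "pwm_jaspar": outdir / "motif.jaspar",
        "liftover": outdir / "liftover.tsv",
        "homology": outdir / "homology.tsv",
        "expressed_ids": outdir / "expressed.txt",
        "positives": outdir / "positives.tsv",
        "human_mirna_annotations": outdir / "human_mirnas.bed",
        "ground_truth": outdir / "ground_truth.tsv",
    }

    _write_fasta(paths["genome_fasta"], genome)
    write_jaspar_pfm(counts, "SIM0001", cfg.tf_name, paths["pwm_jaspar"])

    with open(paths["mirna_annotations"], "w") as fh:
        fh.write("##gff-version 3\n")
        for m in mirnas:
            fh.write(
                f"{m['chrom']}\tsim\tmiRNA_primary_transcript\t{m['start'] + 1}\t"
                f"{m['end']}\t.\t{m['strand']}\t.\tID={m['id']};Name={m['id']}\n"
            )
    with open(paths["gene_annotations"], "w") as fh:
        for i, (chrom, a, b) in enumerate(sorted(genes)):
            fh.write(f"{chrom}\t{a}\t{b}\tgene_{i + 1}\t0\t+\n")
    with open(paths["peaks"], "w") as fh:
        for chrom, a, b, name, fold, nlp, off, tags in sorted(peak_rows):
            fh.write(
                f"{chrom}\t{a}\t{b}\t{name}\t0\t.\t{fold:.4f}\t{nlp:.4f}\t-1\t"
                f"{off}\t{tags}\n"
            )
    for key, rows in (("dnase_rep1", rep1), ("dnase_rep2", rep2)):
        with open(paths[key], "w") as fh:
            for chrom, a, b in sorted(rows):
                fh.write(f"{chrom}\t{max(0, a)}\t{b}\n")
    with open(paths["liftover"], "w") as fh:
        fh.write("#src_chrom\tsrc_start\tsrc_end\tdst_chrom\tdst_start\tdst_end\n")
        for row in sorted(lift_rows):
            fh.write("\t".join(str(x) for x in row) + "\n")
    with open(paths["homology"], "w") as fh:
        for m in usable:
            fh.write(f"{m['id']}\t{m['id'].replace('mmu', 'hsa')}\n")
    with open(paths["human_mirna_annotations"], "w") as fh:
        for m in usable:
            fh.write(
                f"h{m['chrom']}\t{m['start'] + _HUMAN_OFFSET}\t"
                f"{m['end'] + _HUMAN_OFFSET}\t{m['id'].replace('mmu', 'hsa')}\t0\t"
                f"{m['strand']}\n"
            )
    with open(paths["expressed_ids"], "w") as fh:
        for mid in expressed_ids:
            fh.write(mid + "\n")

    n_known = max(2, int(round(cfg.known_positive_fraction * len(true_mirnas))))
    n_known = min(n_known, len(true_mirnas))
    known = set(
        rng.choice(sorted(true_mirnas), size=n_known, replace=False)
    ) if true_mirnas else set()
    with open(paths["positives"], "w") as fh:
        fh.write("identifier\tprovenance\n")
        for mid in sorted(known):
            fh.write(f"{mid}\tmirna-derived\n")

    if cfg.n_extra_positives > 0:
        paths["extra_positive_features"] = outdir / "extra_positives.tsv"
        consensus_max = float(np.max(pwm.matrix, axis=0).sum())
        with open(paths["extra_positive_features"], "w") as fh:
            fh.write(
                "candidate_id\ttags\tneg_log10_p\tfold_enrichment\tdistance_bp\t"
                "dnase_flag\tmotif_score\tconservation_flag\n"
            )
            for i in range(cfg.n_extra_positives):
                tags = nb_draw(cfg.tags_mean + cfg.shift_tags * tags_sd)
                nlp = cfg.nlp_base + rng.exponential(cfg.nlp_scale) + \
                    cfg.shift_neg_log10_p * cfg.nlp_scale
                fold = rng.lognormal(cfg.fold_logmean, cfg.fold_logsd) + \
                    cfg.shift_fold * fold_sd
                dist = rng.exponential(cfg.true_distance_scale_bp)
                dn = float(rng.random() < cfg.dnase_prob_true)
                cons = float(rng.random() < cfg.cons_prob_true)
                score = consensus_max - rng.exponential(0.5)
                fh.write(
                    f"pc_{i + 1}\t{tags}\t{nlp:.4f}\t{fold:.4f}\t{dist:.1f}\t"
                    f"{dn:.0f}\t{score:.4f}\t{cons:.0f}\n"
                )

    truth = GroundTruth(
        true_edges=truth_edges,
        true_peak_ids=truth_peaks,
        known_positive_mirnas=known,
        motif_positions=motif_positions,
        intergenic_expressed_mirnas={m["id"] for m in usable},
    )
    with open(paths["ground_truth"], "w") as fh:
        fh.write("tf\tmirna_id\tknown_positive\n")
        for _tf, mid in sorted(truth.true_edges):
            fh.write(f"{cfg.tf_name}\t{mid}\t{int(mid in known)}\n")

    _check_planted_motifs(genome, pwm, motif_positions, cfg, rng)
    return paths, truth


def _check_planted_motifs(genome, pwm, motif_positions, cfg, rng) -> None:
    """Planted instances must outscore the 95th percentile of background
    windows; with a full consensus planted this is a consistency check that
    nothing overwrote the instance."""
    if not motif_positions:
        return
    chrom0 = next(iter(genome))
    n_bg, width = 200, 200
    bg_scores = []
    for _ in range(n_bg):
        pos = int(rng.integers(0, len(genome[chrom0]) - width))
        seq = bytes(genome[chrom0][pos : pos + width]).decode("ascii")
        bg_scores.append(motif_score(seq, pwm))
    threshold = float(np.percentile(bg_scores, 95))
    for chrom, pos in motif_positions:
        seq = bytes(genome[chrom][pos : pos + cfg.motif_len]).decode("ascii")
        if motif_score(seq, pwm) < threshold:
            raise AssertionError(
                f"planted motif at {chrom}:{pos} scores below the background "
                "95th percentile"
            )


def null_config(config: SimulationConfig) -> SimulationConfig:
    """The matched null world: every true-vs-decoy difference removed."""
    return replace(
        config,
        shift_tags=0.0,
        shift_fold=0.0,
        shift_neg_log10_p=0.0,
        motif_plant_prob=0.0,
        dnase_prob_true=config.dnase_prob_decoy,
        cons_prob_true=config.cons_prob_decoy,
        true_distance_scale_bp=float("inf"),
    )


def null_bundle(
    config: SimulationConfig, outdir: str | Path
) -> tuple[dict[str, Path], GroundTruth]:
    """Bundle in which planted 'true' labels exist but carry no signal:
    all effect sizes zero, all property probabilities equalized, summit
    positions uniform. Used to verify the pipeline manufactures nothing."""
    cfg = null_config(config)
    return simulate_bundle(cfg, outdir)


def bundle_config(paths: dict[str, Path], **overrides) -> dict:
    """Pipeline configuration dict pointing at a simulated bundle."""
    cfg = {k: str(v) for k, v in paths.items() if k != "ground_truth"}
    cfg["peak_dialect"] = "narrowPeak"
    cfg.update(overrides)
    return cfg
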