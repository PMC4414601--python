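"""End-to-end orchestration: annotations -> candidates -> features -> MRR ->
PU sweep -> merge.

The final prediction merges the two routes: the across-p intersection of
PU-positive miRNAs (the robust positives, P of them) is intersected with the
top-P miRNAs of the MRR ranking. Every stage writes its table under the
output directory, and a manifest (input hashes, config, seed) makes reruns
verifiable: identical inputs and seed give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import pandas as pd
import yaml
from pyfaidx import Fasta

from . import annotations as ann
from . import features as feat
from . import mrr as mrr_mod
from . import peaks as peaks_mod
from . import pu as pu_mod
from .features import FEATURE_COLUMNS, FeatureMatrix
from .intervals import GenomicInterval, IntervalIndex

logger = logging.getLogger(__name__)

DEFAULT_PARAMS: dict[str, Any] = {
    "tf_name": "TF",
    "window_bp_mouse": ann.WINDOW_BP_MOUSE,
    "window_bp_human": ann.WINDOW_BP_HUMAN,
    "motif_window": 200,
    "p_grid": list(pu_mod.DEFAULT_P_GRID),
    "holdout_fractions": list(pu_mod.DEFAULT_HOLDOUT_FRACTIONS),
    "folds": 5,
    "C": 1.0,
    "class_weight_ratio": 10.0,
    "unlabeled_weight": 1.0,
    "max_refine_iters": 50,
    "seed": 0,
    "gff_feature_type": ann.DEFAULT_GFF_FEATURE_TYPE,
    "default_tags": 1,
}

INPUT_KEYS = (
    "mirna_annotations", "gene_annotations", "peaks", "dnase_rep1", "dnase_rep2",
    "genome_fasta", "pwm_jaspar", "liftover", "homology", "expressed_ids",
    "positives", "human_mirna_annotations", "extra_positive_features",
)


def load_config(path: str | Path) -> dict[str, Any]:
    """Read a YAML config and fill in parameter defaults."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    merged = dict(DEFAULT_PARAMS)
    merged.update(cfg)
    return merged


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class PipelineResult:
    """Artifacts of a full pipeline run."""

    edges: pd.DataFrame
    ranking: pd.DataFrame
    chosen: pd.DataFrame
    robust_mirnas: set[str]
    outdir: Path
    manifest: dict[str, Any] = field(default_factory=dict)


def _load_expressed(path: Optional[str]) -> Optional[set[str]]:
    if path is None:
        return None
    return {
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    }


def stage_regions(cfg: Mapping[str, Any], outdir: Path):
    """Build mouse regulatory regions (and human ones for conservation)."""
    expressed = _load_expressed(cfg.get("expressed_ids"))
    mirnas = ann.load_mirna_annotations(
        cfg["mirna_annotations"], expressed, cfg["gff_feature_type"]
    )
    genes = ann.load_gene_intervals(cfg["gene_annotations"])
    ann.classify_intergenic(mirnas, genes)
    regions = ann.build_regulatory_regions(
        mirnas, genes, window_bp=int(cfg["window_bp_mouse"])
    )
    ann.write_regions_bed(regions, outdir / "regions.bed", outdir / "regions.tsv")

    human_regions: list[ann.RegulatoryRegion] = []
    if cfg.get("human_mirna_annotations"):
        h_mirnas = ann.load_mirna_annotations(
            cfg["human_mirna_annotations"], None, cfg["gff_feature_type"]
        )
        ann.classify_intergenic(h_mirnas, [])
        human_regions = ann.build_regulatory_regions(
            h_mirnas, [], window_bp=int(cfg["window_bp_human"])
        )
    return mirnas, regions, human_regions


def stage_candidates(cfg: Mapping[str, Any], outdir: Path, mirnas, regions):
    """Parse peaks, assign candidates, and flag open chromatin."""
    peaks = peaks_mod.parse_peaks(
        cfg["peaks"], cfg.get("peak_dialect"), default_tags=int(cfg["default_tags"])
    )
    candidates = peaks_mod.assign_candidates(peaks, regions, mirnas)
    open_regions: list[GenomicInterval] = []
    if cfg.get("dnase_rep1") and cfg.get("dnase_rep2"):
        rep1 = peaks_mod.load_bed_intervals(cfg["dnase_rep1"])
        rep2 = peaks_mod.load_bed_intervals(cfg["dnase_rep2"])
        open_regions = peaks_mod.concordant_dnase(rep1, rep2)
    index = IntervalIndex(open_regions)
    dnase_flags = [peaks_mod.dnase_overlap_flag(c, index) for c in candidates]
    frame = peaks_mod.candidates_to_frame(candidates, dnase_flags)
    frame.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    return candidates, dnase_flags


def stage_features(cfg: Mapping[str, Any], outdir: Path, candidates, dnase_flags,
                   human_regions) -> Optional[FeatureMatrix]:
    """Motif + conservation features; raw and normalized matrices."""
    if not candidates:
        logger.warning("no candidate peaks in any regulatory region")
        return None
    genome = Fasta(cfg["genome_fasta"])
    pwm = feat.read_jaspar_pfm(cfg["pwm_jaspar"])
    width = int(cfg["motif_window"])
    motif_scores: list[Optional[float]] = []
    for cand in candidates:
        window = feat.extract_summit_window(genome, cand, width)
        if len(window.seq) < pwm.length:
            motif_scores.append(None)
        else:
            motif_scores.append(feat.motif_score(window.seq, pwm))
    if cfg.get("homology") and cfg.get("liftover") and human_regions:
        homology = feat.HomologyMap.from_files(cfg["homology"], cfg["liftover"])
        cons = [feat.conservation_flag(c, homology, human_regions) for c in candidates]
    else:
        cons = [False] * len(candidates)
    raw = feat.build_feature_matrix(candidates, dnase_flags, motif_scores, cons)
    raw.to_tsv(outdir / "features_raw.tsv")
    norm = feat.normalize_minmax(raw)
    norm.to_tsv(outdir / "features_norm.tsv")
    # raw per-column bounds, needed to place external positive rows on the
    # same scale
    bounds = raw.frame[list(FEATURE_COLUMNS)].agg(["min", "max"])
    bounds.to_csv(outdir / "feature_bounds.tsv", sep="\t")
    return norm


def stage_mrr(cfg: Mapping[str, Any], outdir: Path, norm: FeatureMatrix):
    """Per-miRNA best-peak selection and global miRNA ranking."""
    chosen = mrr_mod.select_best_peaks(norm)
    ranking = mrr_mod.rank_mirnas(chosen)
    chosen.to_csv(outdir / "chosen_peaks.tsv", sep="\t", index_label="candidate_id")
    ranking.to_csv(outdir / "mirna_ranking.tsv", sep="\t", index_label="candidate_id")
    return chosen, ranking


def _load_positives_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", comment="#")
    if "identifier" not in table.columns:
        table.columns = ["identifier", "provenance"][: len(table.columns)]
    if "provenance" not in table.columns:
        table["provenance"] = "mirna-derived"
    return table


def stage_pu(cfg: Mapping[str, Any], outdir: Path, norm: FeatureMatrix,
             chosen: pd.DataFrame):
    """PU sweep over all candidate peaks.

    Positive training examples are the MRR-chosen peaks of the known-positive
    miRNAs (each known target miRNA is represented by its best peak); every
    other candidate peak is unlabeled. A miRNA is a robust positive when at
    least one of its peaks is predicted positive at every p.
    """
    positives_tbl = _load_positives_table(cfg["positives"])
    mirna_pos = set(
        positives_tbl.loc[
            positives_tbl["provenance"] == "mirna-derived", "identifier"
        ]
    )
    pos_ids = chosen.index[chosen["mirna_id"].isin(mirna_pos)]
    feats = norm.frame[list(FEATURE_COLUMNS)]
    pos_frame = feats.loc[pos_ids]
    unl_frame = feats.drop(index=pos_ids)

    if cfg.get("extra_positive_features"):
        extra = pd.read_csv(
            cfg["extra_positive_features"], sep="\t", index_col="candidate_id"
        )
        bounds = pd.read_csv(outdir / "feature_bounds.tsv", sep="\t", index_col=0)
        scaled = {}
        for col in FEATURE_COLUMNS:
            lo, hi = bounds.loc["min", col], bounds.loc["max", col]
            x = extra[col].to_numpy(dtype=float)
            scaled[col] = ((x - lo) / (hi - lo)).clip(0, 1) if hi > lo else 0.0
        pos_frame = pd.concat([pos_frame, pd.DataFrame(scaled, index=extra.index)])

    if len(pos_frame) < 2 or len(unl_frame) < 1:
        logger.warning(
            "PU skipped: %d positives / %d unlabeled", len(pos_frame), len(unl_frame)
        )
        return set(), pd.DataFrame(), mirna_pos

    config = pu_mod.PUConfig(
        C=float(cfg["C"]),
        class_weight_ratio=float(cfg["class_weight_ratio"]),
        unlabeled_weight=float(cfg.get("unlabeled_weight", 1.0)),
        max_refine_iters=int(cfg["max_refine_iters"]),
    )
    model = pu_mod.TransductivePU(
        pu_mod.PUDataset(pos_frame, unl_frame), config=config, seed=int(cfg["seed"])
    )
    results = model.sweep([float(p) for p in cfg["p_grid"]])
    labels = pd.DataFrame(
        {f"p_{r.p:.2f}": r.labels for r in results}
    ).sort_index()
    labels.to_csv(outdir / "pu_labels.tsv", sep="\t", index_label="candidate_id")
    robust_cands = pu_mod.robust_positives(results)
    # predictions concern the unlabeled pool only: a known-positive miRNA
    # re-surfacing through one of its decoy peaks is an input, not a finding
    robust_mirnas = set(norm.frame.loc[sorted(robust_cands), "mirna_id"]) - mirna_pos
    with open(outdir / "robust_positives.tsv", "w") as fh:
        fh.write("mirna_id\n")
        for m in sorted(robust_mirnas):
            fh.write(m + "\n")
    return robust_mirnas, labels, mirna_pos


def merge(robust_positive_ids: set[str], mrr_ranked: pd.DataFrame,
          tf_name: str = "TF") -> pd.DataFrame:
    """Intersect the robust PU positives with the top-P MRR miRNAs.

    P = |robust_positive_ids|. ``mrr_ranked`` is the output of
    :func:`mirreg.mrr.rank_mirnas` (mirna_id, peak_id, mrr, rank in final
    order). Edges are returned in MRR order.
    """
    P = len(robust_positive_ids)
    if P == 0:
        logger.warning("no robust positives; empty edge set")
    unknown = robust_positive_ids - set(mrr_ranked["mirna_id"])
    if unknown:
        raise ValueError(f"robust positives not in the MRR ranking: {sorted(unknown)}")
    top = mrr_ranked.head(P)
    hits = top[top["mirna_id"].isin(robust_positive_ids)]
    return pd.DataFrame(
        {
            "tf": tf_name,
            "mirna_id": hits["mirna_id"].to_numpy(),
            "peak_id": hits["peak_id"].to_numpy(),
            "mrr": hits["mrr"].to_numpy(),
            "robust": True,
        },
        columns=["tf", "mirna_id", "peak_id", "mrr", "robust"],
    )


def _empty_edges() -> pd.DataFrame:
    return pd.DataFrame(columns=["tf", "mirna_id", "peak_id", "mrr", "robust"])


def write_edges(edges: pd.DataFrame, outdir: Path) -> None:
    edges.to_csv(outdir / "edges.tsv", sep="\t", index=False)
    with open(outdir / "edges.dot", "w") as fh:
        fh.write("digraph tf_mirna {\n")
        for _, row in edges.iterrows():
            fh.write(f'  "{row.tf}" -> "{row.mirna_id}" [label="{row.mrr:.3f}"];\n')
        fh.write("}\n")


def run_pipeline(
    config: str | Path | Mapping[str, Any],
    outdir: str | Path,
    seed: Optional[int] = None,
) -> PipelineResult:
    """Run every stage end to end and write all artifacts plus a manifest."""
    cfg = dict(load_config(config)) if isinstance(config, (str, Path)) else {
        **DEFAULT_PARAMS, **dict(config)
    }
    if seed is not None:
        cfg["seed"] = int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    mirnas, regions, human_regions = stage_regions(cfg, outdir)
    candidates, dnase_flags = stage_candidates(cfg, outdir, mirnas, regions)
    norm = stage_features(cfg, outdir, candidates, dnase_flags, human_regions)
    if norm is None or len(norm) == 0:
        edges = _empty_edges()
        write_edges(edges, outdir)
        result = PipelineResult(
            edges=edges, ranking=pd.DataFrame(), chosen=pd.DataFrame(),
            robust_mirnas=set(), outdir=outdir,
        )
    else:
        chosen, ranking = stage_mrr(cfg, outdir, norm)
        robust_mirnas, _labels, known = stage_pu(cfg, outdir, norm, chosen)
        # merge predictions against predictions: the known-positive training
        # miRNAs sit at the top of the MRR list but are inputs, so they are
        # removed from the ranked list before taking the top P
        eligible = ranking[~ranking["mirna_id"].isin(known)]
        edges = merge(robust_mirnas, eligible, tf_name=str(cfg["tf_name"]))
        write_edges(edges, outdir)
        result = PipelineResult(
            edges=edges, ranking=ranking, chosen=chosen,
            robust_mirnas=robust_mirnas, outdir=outdir,
        )

    manifest = {
        "seed": int(cfg["seed"]),
        "params": {
            k: cfg[k]
            for k in DEFAULT_PARAMS
            if k in cfg and not isinstance(cfg[k], Path)
        },
        "inputs": {
            k: _sha256(Path(cfg[k])) for k in INPUT_KEYS if cfg.get(k)
        },
        "n_edges": int(len(edges)),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    result.manifest = manifest
    return result
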