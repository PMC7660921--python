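"""Applying the trained-model interpretation workflow to peak-derived
enhancer data.

Stages mirror the simulation-side analysis but start from genomic
intervals: enhancers are H3K27ac regions with H3K4me1 subtracted at
base-pair level, the genome is tiled into 200-bp bins labeled per tissue by
majority overlap, bins are expanded with 250-bp flanks to 700-bp training
sequences, the classifier is trained against 8-mer-shuffled negatives, and
the top-scoring sequences per tissue are scanned for motifs, attributed,
filtered, clustered, and tested for per-cluster motif enrichment with
Fisher's exact test.

A synthetic planted-grammar study generator stands in for real peak data:
it writes a random genome in which one tissue's enhancers carry a planted
heterotypic trio of TFs, so the full pipeline can be exercised and its
ability to co-cluster the trio verified end to end.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta
from scipy.stats import fisher_exact

from .attribution import AttributionConfig, profile_matrix
from .grammar_sim import AnnotatedSequence, TFBSAnnotation, kmer_shuffle
from .grammar_recover import (
    filter_top_fraction,
    kmeans_cluster,
    normalize_profile_rows,
    select_k_silhouette,
)
from .motifs import ALPHABET, MotifSet, sample_site, scan_sequence, synthetic_motif_set
from .resnet_model import ModelConfig, TrainConfig, build_model, encode_sequences, train
from . import nnet


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int
    tissue: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")


@dataclass
class BinLabelMatrix:
    bins: list[Interval]
    tissues: list[str]
    matrix: np.ndarray  # bins x tissues, binary

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.bins), len(self.tissues)):
            raise ValueError("matrix shape inconsistent with bins/tissues")
        if len(self.bins) and not (self.matrix.sum(axis=1) >= 1).all():
            raise ValueError("every retained bin must be positive in >= 1 tissue")


def read_bed(path, tissue: str | None = None) -> list[Interval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            out.append(Interval(f[0], int(f[1]), int(f[2]), tissue))
    return out


def write_bed(intervals: Sequence[Interval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def _merge(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def define_enhancers(h3k27ac: Sequence[Interval], h3k4me1: Sequence[Interval]) -> list[Interval]:
    """Base-pair-level subtraction: H3K27ac regions minus H3K4me1 cover.

    Remainder fragments are returned per chromosome in sorted order; empty
    remainders are dropped.
    """
    by_chrom_b: dict[str, list[tuple[int, int]]] = {}
    for iv in h3k4me1:
        by_chrom_b.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged_b = {c: _merge(v) for c, v in by_chrom_b.items()}
    out: list[Interval] = []
    for iv in sorted(h3k27ac, key=lambda i: (i.chrom, i.start, i.end)):
        cuts = merged_b.get(iv.chrom, [])
        cur = iv.start
        for bs, be in cuts:
            if be <= iv.start or bs >= iv.end:
                continue
            if bs > cur:
                out.append(Interval(iv.chrom, cur, min(bs, iv.end), iv.tissue))
            cur = max(cur, be)
        if cur < iv.end:
            out.append(Interval(iv.chrom, cur, iv.end, iv.tissue))
    return out


def bin_and_label(
    enhancers_per_tissue: dict[str, Sequence[Interval]],
    chrom_sizes: dict[str, int],
    bin_size: int = 200,
    min_overlap_frac: float = 0.5,
) -> BinLabelMatrix:
    """Tile chromosomes into bins; a bin is positive for a tissue iff its
    overlap with that tissue's enhancers is strictly greater than
    ``min_overlap_frac`` of the bin.  Bins positive nowhere are dropped."""
    tissues = list(enhancers_per_tissue)
    cover: dict[str, dict[str, np.ndarray]] = {}
    for t, ivs in enhancers_per_tissue.items():
        for iv in ivs:
            if iv.chrom not in chrom_sizes:
                raise ValueError(f"interval on unknown chromosome {iv.chrom}")
            arr = cover.setdefault(t, {}).setdefault(
                iv.chrom, np.zeros(chrom_sizes[iv.chrom], dtype=bool)
            )
            arr[iv.start : iv.end] = True
    bins: list[Interval] = []
    rows: list[np.ndarray] = []
    thresh = min_overlap_frac * bin_size
    for chrom, size in chrom_sizes.items():
        for s in range(0, size - bin_size + 1, bin_size):
            row = np.zeros(len(tissues), dtype=np.int8)
            for j, t in enumerate(tissues):
                arr = cover.get(t, {}).get(chrom)
                if arr is not None and arr[s : s + bin_size].sum() > thresh:
                    row[j] = 1
            if row.any():
                bins.append(Interval(chrom, s, s + bin_size))
                rows.append(row)
    matrix = np.stack(rows) if rows else np.zeros((0, len(tissues)), dtype=np.int8)
    return BinLabelMatrix(bins, tissues, matrix)


def expand_and_extract(
    bins: Sequence[Interval],
    genome_fasta,
    flank: int = 250,
) -> tuple[list[str], list[str], np.ndarray]:
    """Expand bins by ``flank`` on each side and extract uppercase sequences.

    Returns (names, sequences, clipped_mask); regions truncated by a
    chromosome edge are flagged and excluded from training by default.
    """
    fa = Fasta(str(genome_fasta))
    names, seqs = [], []
    clipped = np.zeros(len(bins), dtype=bool)
    for i, b in enumerate(bins):
        if b.chrom not in fa:
            raise KeyError(f"chromosome {b.chrom} missing from genome")
        clen = len(fa[b.chrom])
        s, e = b.start - flank, b.end + flank
        if s < 0 or e > clen:
            clipped[i] = True
            s, e = max(0, s), min(clen, e)
        names.append(f"{b.chrom}:{s}-{e}")
        seqs.append(str(fa[b.chrom][s:e]).upper())
    return names, seqs, clipped


def enrichment_fisher(cluster_ids: np.ndarray, motif_ids: np.ndarray) -> pd.DataFrame:
    """Two-sided Fisher's exact test per (motif, cluster) 2x2 table.

    Table: [[in cluster & motif, in cluster & other], [out & motif,
    out & other]].  Zero-margin tables get p = 1 and are flagged.
    """
    cluster_ids = np.asarray(cluster_ids)
    motif_ids = np.asarray(motif_ids)
    if len(np.unique(cluster_ids)) < 2 or len(np.unique(motif_ids)) < 2:
        raise ValueError("need >= 2 clusters and >= 2 motifs")
    rows = []
    n = len(cluster_ids)
    for c in np.unique(cluster_ids):
        in_c = cluster_ids == c
        for m in np.unique(motif_ids):
            is_m = motif_ids == m
            a = int((in_c & is_m).sum())
            b = int((in_c & ~is_m).sum())
            cc = int((~in_c & is_m).sum())
            d = n - a - b - cc
            degenerate = (a + b == 0) or (cc + d == 0) or (a + cc == 0) or (b + d == 0)
            if degenerate:
                odds, p = np.nan, 1.0
            else:
                odds, p = fisher_exact([[a, b], [cc, d]], alternative="two-sided")
            rows.append(
                {"cluster": c, "motif_id": m, "in_cluster": a, "out_cluster": cc,
                 "odds_ratio": odds, "pvalue": float(p), "degenerate": degenerate}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# synthetic planted-grammar study


@dataclass
class PlantedStudy:
    genome_fasta: str
    peaks: dict[str, dict[str, str]]  # tissue -> {"h3k27ac": path, "h3k4me1": path}
    motifs: MotifSet
    trio: list[str]
    chrom_sizes: dict[str, int]


def make_planted_study(
    out_dir,
    seed: int = 0,
    genome_length: int = 1_000_000,
    n_regions_per_tissue: int = 50,
    region_length: int = 600,
    n_motifs: int = 10,
) -> PlantedStudy:
    """Write a synthetic genome + peak files with a planted 3-TF heterotypic
    grammar in tissue A enhancers.

    Tissue A regions each carry two 120-bp windows in which one site of each
    trio TF is placed at random non-overlapping offsets, plus scattered
    decoy sites of the remaining motifs (so cluster enrichment has a
    background to contrast against); tissue B regions carry scattered
    single sites of the remaining motifs only.  H3K4me1 peaks
    overlap the edges of some H3K27ac peaks so interval subtraction is
    exercised.  The files are a synthetic stand-in for histone-mark peak
    data; nothing in them derives from a real genome.
    """
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    motifs = synthetic_motif_set(n_motifs, (8, 12), info_bits=1.8, seed=rng)
    trio = motifs.ids[:3]
    others = motifs.ids[3:]
    genome = rng.integers(0, 4, size=genome_length, dtype=np.int8)

    spacing = genome_length // (2 * n_regions_per_tissue + 2)
    regions: dict[str, list[Interval]] = {"tissueA": [], "tissueB": []}
    pos = spacing
    from .motifs import seq_to_indices

    for i in range(2 * n_regions_per_tissue):
        tissue = "tissueA" if i % 2 == 0 else "tissueB"
        start = pos
        end = start + region_length
        regions[tissue].append(Interval("chr1", start, end, tissue))
        if tissue == "tissueA":
            # two planted trio windows per region
            for w in range(2):
                wstart = start + 40 + w * (region_length // 2)
                offs: list[tuple[int, int]] = []
                for mid in trio:
                    site = sample_site(motifs[mid], rng)
                    for _try in range(100):
                        o = int(rng.integers(0, 120 - len(site) + 1))
                        if all(o + len(site) <= a or o >= b for a, b in offs):
                            offs.append((o, o + len(site)))
                            genome[wstart + o : wstart + o + len(site)] = seq_to_indices(site)
                            break
            # decoy singles between the windows, from the non-trio motifs
            for _ in range(5):
                mid = others[int(rng.integers(0, len(others)))]
                site = sample_site(motifs[mid], rng)
                o = start + 170 + int(rng.integers(0, region_length // 2 - 190))
                genome[o : o + len(site)] = seq_to_indices(site)
        else:
            for _ in range(4):
                mid = others[int(rng.integers(0, len(others)))]
                site = sample_site(motifs[mid], rng)
                o = start + int(rng.integers(0, region_length - len(site)))
                genome[o : o + len(site)] = seq_to_indices(site)
        pos += spacing

    fasta_path = os.path.join(out_dir, "genome.fa")
    with open(fasta_path, "w") as fh:
        fh.write(">chr1\n")
        s = "".join(ALPHABET[c] for c in genome)
        for i in range(0, len(s), 80):
            fh.write(s[i : i + 80] + "\n")

    peaks: dict[str, dict[str, str]] = {}
    for tissue, ivs in regions.items():
        k27 = os.path.join(out_dir, f"{tissue}_h3k27ac.bed")
        k4 = os.path.join(out_dir, f"{tissue}_h3k4me1.bed")
        write_bed(ivs, k27)
        # trim-only K4me1 peaks hanging off the first few K27ac regions
        k4_ivs = [Interval(iv.chrom, iv.start - 60, iv.start + 20) for iv in ivs[:3]]
        write_bed(k4_ivs, k4)
        peaks[tissue] = {"h3k27ac": k27, "h3k4me1": k4}
    return PlantedStudy(fasta_path, peaks, motifs, trio, {"chr1": genome_length})


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class PipelineConfig:
    genome_fasta: str
    peaks: dict[str, dict[str, str]]
    motifs: MotifSet
    chrom_sizes: dict[str, int]
    bin_size: int = 200
    flank: int = 250
    min_overlap_frac: float = 0.5
    top_n_sequences: int = 100
    filter_top: float = 0.30
    k_range: tuple[int, int] = (2, 12)
    scan_p_threshold: float = 1e-4
    negatives_k: int = 8
    n_references: int = 10
    model: ModelConfig | None = None
    train: TrainConfig | None = None
    seed: int = 0
    exclude_clipped: bool = True


def apply_pipeline(cfg: PipelineConfig, out_dir=None, model: nnet.ResNet1D | None = None) -> dict:
    """Run the peak-data workflow end to end.

    Stages: enhancer definition -> binning -> flank extraction -> training
    against k-mer-shuffled negatives (skipped when a trained ``model`` is
    passed) -> per-tissue top-N scoring sequences -> attribution with
    k-mer-shuffled references -> motif scan -> saliency profile -> top-
    fraction filter -> silhouette k selection -> k-means -> Fisher
    enrichment.  Returns a report dict with per-stage artifacts.
    """
    rng = np.random.default_rng(cfg.seed)
    report: dict = {"stages": {}}
    stage = "define_enhancers"
    try:
        enhancers: dict[str, list[Interval]] = {}
        for tissue, files in cfg.peaks.items():
            k27 = read_bed(files["h3k27ac"], tissue)
            k4 = read_bed(files["h3k4me1"], tissue)
            enhancers[tissue] = define_enhancers(k27, k4)
        report["stages"][stage] = {t: len(v) for t, v in enhancers.items()}

        stage = "bin_and_label"
        blm = bin_and_label(enhancers, cfg.chrom_sizes, cfg.bin_size, cfg.min_overlap_frac)
        report["stages"][stage] = {"bins": len(blm.bins)}

        stage = "expand_and_extract"
        names, seqs, clipped = expand_and_extract(blm.bins, cfg.genome_fasta, cfg.flank)
        keep = ~clipped if cfg.exclude_clipped else np.ones(len(seqs), dtype=bool)
        names = [n for n, k in zip(names, keep) if k]
        seqs = [s for s, k in zip(seqs, keep) if k]
        labels = blm.matrix[keep].astype(np.float32)
        report["stages"][stage] = {"sequences": len(seqs), "clipped_excluded": int(clipped.sum())}

        stage = "train"
        neg_seqs = [kmer_shuffle(s, cfg.negatives_k, rng) for s in seqs]
        x = encode_sequences(seqs + neg_seqs)
        y = np.concatenate([labels, np.zeros_like(labels)])
        if model is None:
            mcfg = cfg.model or ModelConfig(
                n_outputs=len(blm.tissues), n_residual_blocks=3, filters_per_block=(8, 8, 8)
            )
            tcfg = cfg.train or TrainConfig(epochs=12, patience=12, batch_size=8, seed=cfg.seed)
            model = build_model(mcfg, input_length=len(seqs[0]), seed=cfg.seed)
            history = train(model, x, y, tcfg)
            report["stages"][stage] = {"epochs_run": len(history["train_loss"])}
        else:
            report["stages"][stage] = {"reused": True}

        stage = "score_and_select"
        probs = model.predict_proba(encode_sequences(seqs))
        top: dict[str, list[int]] = {}
        for j, tissue in enumerate(blm.tissues):
            pos_idx = np.nonzero(labels[:, j] > 0)[0]
            ranked = pos_idx[np.argsort(-probs[pos_idx, j], kind="stable")]
            top[tissue] = ranked[: cfg.top_n_sequences].tolist()
        report["stages"][stage] = {t: len(v) for t, v in top.items()}

        # downstream interpretation on the first tissue's top sequences
        focus_tissue = blm.tissues[0]
        focus_idx = top[focus_tissue]

        stage = "motif_scan"
        annseqs: list[AnnotatedSequence] = []
        n_hits = 0
        for i in focus_idx:
            anns = []
            for motif in cfg.motifs:
                for m in scan_sequence(seqs[i], motif, p_threshold=cfg.scan_p_threshold):
                    anns.append(TFBSAnnotation(m.start, m.end, m.motif_id, None, None, m.strand))
            anns.sort(key=lambda a: a.start)
            n_hits += len(anns)
            annseqs.append(AnnotatedSequence(names[i], seqs[i], anns))
        report["stages"][stage] = {"hits": n_hits}
        if n_hits == 0:
            raise RuntimeError("no motif hits in the selected sequences")

        stage = "attribution"
        acfg = AttributionConfig(
            method="grad_input",
            layer="penultimate",
            n_references=cfg.n_references,
            reference_mode="kmer",
            reference_k=cfg.negatives_k,
            seed=cfg.seed,
        )
        profile = profile_matrix(model, [s for s in annseqs if s.annotations], cfg=acfg)
        report["stages"][stage] = {"tfbs_rows": len(profile)}

        stage = "filter_top_fraction"
        filtered, _mask = filter_top_fraction(profile, cfg.filter_top)
        report["stages"][stage] = {"kept": len(filtered)}

        stage = "cluster"
        kmax = min(cfg.k_range[1], len(filtered) - 1)
        Xn = normalize_profile_rows(filtered.values)
        best_k, sil = select_k_silhouette(Xn, range(cfg.k_range[0], kmax + 1), seed=cfg.seed)
        assignments = kmeans_cluster(Xn, best_k, seed=cfg.seed)
        report["stages"][stage] = {"k": best_k, "silhouettes": sil}

        stage = "enrichment"
        enr = enrichment_fisher(assignments, filtered.meta["motif_id"].to_numpy())
        report["enrichment"] = enr
        report["assignments"] = assignments
        report["profile_meta"] = filtered.meta
        report["tissue"] = focus_tissue
        report["model"] = model
        report["stages"][stage] = {"tests": len(enr)}
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        report["enrichment"].to_csv(os.path.join(out_dir, "enrichment.tsv"), sep="\t", index=False)
        meta = report["profile_meta"].copy()
        meta["cluster"] = report["assignments"]
        meta.to_csv(os.path.join(out_dir, "clusters.tsv"), sep="\t", index=False)
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(
                {"stages": report["stages"], "tissue": report["tissue"]},
                fh, indent=1, default=str,
            )
    return report
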