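"""Interval algebra, binning, extraction, and Fisher enrichment."""

import numpy as np
import pytest
from scipy.stats import hypergeom

from grammarscope import genome_pipeline as gp


def iv(chrom, s, e, t=None):
    return gp.Interval(chrom, s, e, t)


class TestDefineEnhancers:
    def test_internal_cut_splits_region(self):
        out = gp.define_enhancers([iv("c", 0, 100)], [iv("c", 40, 60)])
        assert [(i.start, i.end) for i in out] == [(0, 40), (60, 100)]

    def test_disjoint_marks_leave_region_unchanged(self):
        out = gp.define_enhancers([iv("c", 0, 100)], [iv("c", 200, 300)])
        assert [(i.start, i.end) for i in out] == [(0, 100)]

    def test_full_cover_drops_region(self):
        assert gp.define_enhancers([iv("c", 10, 20)], [iv("c", 0, 50)]) == []

    def test_matches_bitmask_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            G = 1000
            a = [iv("c", int(s), int(s) + int(l))
                 for s, l in zip(rng.integers(0, 900, 8), rng.integers(10, 100, 8))]
            b = [iv("c", int(s), int(s) + int(l))
                 for s, l in zip(rng.integers(0, 900, 5), rng.integers(10, 100, 5))]
            out = gp.define_enhancers(a, b)
            mask_a = np.zeros(G + 100, dtype=bool)
            mask_b = np.zeros(G + 100, dtype=bool)
            for x in a:
                mask_a[x.start : x.end] = True
            for x in b:
                mask_b[x.start : x.end] = True
            mask_out = np.zeros(G + 100, dtype=bool)
            for x in out:
                assert x.end <= G + 100
                mask_out[x.start : x.end] = True
            assert np.array_equal(mask_out, mask_a & ~mask_b)

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            iv("c", 10, 10)


class TestBinAndLabel:
    def test_strictly_greater_than_half(self):
        sizes = {"c": 1000}
        pos = gp.bin_and_label({"t": [iv("c", 0, 101)]}, sizes)
        assert [(b.start, b.end) for b in pos.bins] == [(0, 200)]
        # exactly 100 bp of overlap is NOT enough
        neg = gp.bin_and_label({"t": [iv("c", 0, 100)]}, sizes)
        assert len(neg.bins) == 0

    def test_matches_bitmask_oracle(self):
        rng = np.random.default_rng(1)
        sizes = {"c": 10_000}
        enh = {
            "t1": [iv("c", int(s), int(s) + int(l))
                   for s, l in zip(rng.integers(0, 9000, 10), rng.integers(50, 500, 10))],
            "t2": [iv("c", int(s), int(s) + int(l))
                   for s, l in zip(rng.integers(0, 9000, 6), rng.integers(50, 500, 6))],
        }
        blm = gp.bin_and_label(enh, sizes, bin_size=200)
        masks = {}
        for t, ivs in enh.items():
            m = np.zeros(10_500, dtype=bool)
            for x in ivs:
                m[x.start : x.end] = True
            masks[t] = m
        expected = []
        for s in range(0, 10_000 - 200 + 1, 200):
            row = [int(masks[t][s : s + 200].sum() > 100) for t in enh]
            if any(row):
                expected.append((s, row))
        assert [(b.start, list(r)) for b, r in zip(blm.bins, blm.matrix)] == expected

    def test_every_retained_bin_positive_somewhere(self):
        blm = gp.bin_and_label({"t": [iv("c", 0, 500)]}, {"c": 2000})
        assert (blm.matrix.sum(axis=1) >= 1).all()


class TestExpandAndExtract:
    @pytest.fixture()
    def genome(self, tmp_path):
        rng = np.random.default_rng(2)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=3000))
        p = tmp_path / "g.fa"
        p.write_text(">chr1\n" + "\n".join(seq[i : i + 70] for i in range(0, 3000, 70)) + "\n")
        return p, seq

    def test_flank_arithmetic(self, genome):
        p, seq = genome
        names, seqs, clipped = gp.expand_and_extract([iv("chr1", 1000, 1200)], p)
        assert names == ["chr1:750-1450"]
        assert len(seqs[0]) == 700
        assert not clipped[0]
        assert seqs[0] == seq[750:1450]

    def test_chromosome_start_clipping_flagged(self, genome):
        p, seq = genome
        names, seqs, clipped = gp.expand_and_extract([iv("chr1", 0, 200)], p)
        assert clipped[0]
        assert seqs[0] == seq[0:450]

    def test_missing_chromosome(self, genome):
        p, _ = genome
        with pytest.raises(KeyError):
            gp.expand_and_extract([iv("chr9", 500, 700)], p)


def _fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by enumerating all tables with fixed margins."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    obs = hypergeom.pmf(a, n, col1, row1)
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    p = 0.0
    for x in range(lo, hi + 1):
        px = hypergeom.pmf(x, n, col1, row1)
        if px <= obs * (1 + 1e-9):
            p += px
    return min(p, 1.0)


class TestFisher:
    def test_perfect_segregation(self):
        clusters = np.array([0] * 5 + [1] * 5)
        motifs = np.array(["A"] * 5 + ["B"] * 5)
        df = gp.enrichment_fisher(clusters, motifs)
        row = df[(df.cluster == 0) & (df.motif_id == "A")].iloc[0]
        assert row.pvalue == pytest.approx(2 / 252, rel=1e-9)

    def test_uniform_motif_not_enriched(self):
        clusters = np.array([0, 0, 0, 1, 1, 1])
        motifs = np.array(["A", "B", "A", "A", "B", "A"])
        df = gp.enrichment_fisher(clusters, motifs)
        assert (df.pvalue > 0.9).all()

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 16, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            from scipy.stats import fisher_exact

            _, p = fisher_exact([[a, b], [c, d]])
            assert p == pytest.approx(_fisher_oracle(a, b, c, d), abs=1e-12)

    def test_needs_two_clusters_and_motifs(self):
        with pytest.raises(ValueError):
            gp.enrichment_fisher(np.zeros(4), np.array(["A", "B", "A", "B"]))


class TestPipelineSmoke:
    @pytest.fixture(scope="class")
    def study(self, tmp_path_factory):
        return gp.make_planted_study(
            tmp_path_factory.mktemp("study"), seed=0,
            genome_length=120_000, n_regions_per_tissue=24, n_motifs=8,
        )

    def test_planted_files_exist_and_parse(self, study):
        assert len(study.trio) == 3
        k27 = gp.read_bed(study.peaks["tissueA"]["h3k27ac"])
        assert len(k27) == 24

    def test_pipeline_stages_consistent(self, study, tmp_path):
        from grammarscope.resnet_model import ModelConfig, TrainConfig

        cfg = gp.PipelineConfig(
            genome_fasta=study.genome_fasta, peaks=study.peaks, motifs=study.motifs,
            chrom_sizes=study.chrom_sizes, top_n_sequences=20, k_range=(2, 6),
            n_references=4, seed=0,
            model=ModelConfig(n_outputs=2, n_residual_blocks=2, filters_per_block=(8, 8)),
            train=TrainConfig(epochs=6, patience=6, seed=0),
        )
        report = gp.apply_pipeline(cfg, out_dir=tmp_path / "out")
        st = report["stages"]
        # monotone filtering: scan hits >= profile rows >= filtered rows
        assert st["motif_scan"]["hits"] >= st["attribution"]["tfbs_rows"]
        assert st["attribution"]["tfbs_rows"] >= st["filter_top_fraction"]["kept"]
        # selected k maximizes the reported silhouettes
        sil = st["cluster"]["silhouettes"]
        assert st["cluster"]["k"] == min(k for k, v in sil.items() if v == max(sil.values()))
        assert (tmp_path / "out" / "enrichment.tsv").exists()
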