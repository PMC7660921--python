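"""Grammar definitions, sequence simulation, and negative sets."""

from collections import Counter
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

from grammarscope import grammar_sim as gs
from grammarscope import motifs as mo


class TestDefaultGrammars:
    def test_kind_counts(self, grammars):
        kinds = Counter(g.kind for g in grammars)
        assert kinds == {"homotypic": 5, "heterotypic": 5, "enhanceosome": 2}

    def test_homotypic_copy_range(self, grammars):
        for g in grammars:
            if g.kind == "homotypic":
                assert g.copies == (3, 5)
                assert len(g.members) == 1

    def test_four_members_in_multi_tf_grammars(self, grammars):
        for g in grammars:
            if g.kind in ("heterotypic", "enhanceosome"):
                assert len(g.members) == 4
                assert len(set(g.members)) == 4

    def test_some_motifs_shared_between_grammars(self, grammars):
        all_members = [m for g in grammars for m in g.members]
        assert len(all_members) > len(set(all_members))

    def test_too_few_motifs_rejected(self):
        small = mo.synthetic_motif_set(10, seed=0)
        with pytest.raises(ValueError, match="26"):
            gs.default_grammars(small, seed=0)


def test_class_chaining_covers_each_grammar_twice(classes):
    counts = Counter(g for c in classes for g in c.grammars)
    assert all(v == 2 for v in counts.values())
    assert classes[0].grammars == ["hom1", "het1"]
    assert classes[1].grammars == ["het1", "hom2"]
    assert classes[5].grammars == ["hom3", "het3"]


class TestRenderInstance:
    def test_homotypic_copy_counts(self, grammars, motif_set, rng):
        spec = grammars[0]
        counts = set()
        for _ in range(300):
            _, anns = gs.render_grammar_instance(spec, motif_set, rng)
            counts.add(len(anns))
        assert counts == {3, 4, 5}

    def test_enhanceosome_order_and_spacing_fixed(self, grammars, motif_set, rng):
        spec = next(g for g in grammars if g.kind == "enhanceosome")
        orders, gaps = set(), set()
        for _ in range(200):
            _, anns = gs.render_grammar_instance(spec, motif_set, rng)
            anns = sorted(anns, key=lambda a: a.start)
            orders.add(tuple(a.motif_id for a in anns))
            gaps.add(tuple(b.start - a.end for a, b in zip(anns, anns[1:])))
        assert orders == {tuple(spec.members)}
        assert gaps == {(5, 5, 5)}

    def test_heterotypic_orders_vary(self, grammars, motif_set, rng):
        """Member order should cover many permutations, not a fixed one."""
        spec = next(g for g in grammars if g.kind == "heterotypic")
        orders = set()
        for _ in range(300):
            _, anns = gs.render_grammar_instance(spec, motif_set, rng)
            orders.add(tuple(a.motif_id for a in sorted(anns, key=lambda a: a.start)))
        assert len(orders) >= 2
        assert orders <= set(permutations(spec.members))

    def test_window_annotations_nonoverlapping(self, grammars, motif_set, rng):
        for spec in grammars:
            win, anns = gs.render_grammar_instance(spec, motif_set, rng)
            assert len(win) == spec.window_bp
            anns = sorted(anns, key=lambda a: a.start)
            for a, b in zip(anns, anns[1:]):
                assert a.end <= b.start


class TestSimulateSequence:
    def test_instance_counts_in_range(self, classes, grammar_dict, motif_set, rng):
        for _ in range(20):
            s = gs.simulate_sequence(classes[0], grammar_dict, motif_set, length=1500, rng=rng)
            per_grammar = Counter(
                (a.grammar_id, a.grammar_instance) for a in s.annotations
            )
            n_instances = Counter(g for g, _ in per_grammar)
            for g in classes[0].grammars:
                assert 2 <= n_instances[g] <= 4

    def test_annotations_in_bounds_nonoverlapping(self, small_dataset):
        for s in small_dataset.sequences:
            anns = sorted(s.annotations, key=lambda a: a.start)
            assert anns[0].start >= 0 and anns[-1].end <= len(s.seq)
            for a, b in zip(anns, anns[1:]):
                assert a.end <= b.start

    def test_background_composition_uniform(self, classes, grammar_dict, motif_set, rng):
        counts = np.zeros(4)
        for _ in range(60):
            s = gs.simulate_sequence(classes[0], grammar_dict, motif_set, length=1500, rng=rng)
            mask = np.ones(len(s.seq), dtype=bool)
            for a in s.annotations:
                mask[a.start : a.end] = False
            idx = mo.seq_to_indices(s.seq)[mask]
            counts += np.bincount(idx, minlength=4)[:4]
        freqs = counts / counts.sum()
        assert np.abs(freqs - 0.25).max() < 0.02


class TestSimulateDataset:
    def test_counts_and_one_hot_labels(self, small_dataset):
        assert len(small_dataset.sequences) == 10
        y = small_dataset.label_matrix()
        assert y.shape == (10, 2)
        assert (y.sum(axis=1) == 1).all()

    def test_heterogeneous_labels(self, classes, grammars, motif_set):
        het = gs.default_heterogeneous()
        ds = gs.simulate_dataset(
            classes[:1], grammars, motif_set, n_per_class=2, length=1500, seed=0, het_specs=het
        )
        # class 1 belongs to heterogeneous categories 1 ({1,3,5}) and 5 ({1,6,12})
        for s in ds.sequences:
            assert list(s.label_vector) == [1, 0, 0, 0, 1]

    def test_every_class_in_at_least_one_heterogeneous_category(self):
        het = gs.default_heterogeneous()
        covered = {c for h in het for c in h.member_classes}
        assert covered == set(range(1, 13))

    def test_disjoint_preset_grammar_pairs_disjoint_across_categories(self):
        classes, het = gs.disjoint_grammar_specs()
        by_cat = {
            h.id: {g for cid in h.member_classes for g in classes[cid - 1].grammars}
            for h in het
        }
        cats = list(by_cat.values())
        for i in range(len(cats)):
            for j in range(i + 1, len(cats)):
                assert not (cats[i] & cats[j])


class TestNonGrammarSites:
    def test_target_fraction_exact_ratio(self, grammars, motif_set, classes):
        ds = gs.simulate_dataset(classes[:1], grammars, motif_set, 2, length=3000, seed=3)
        out = gs.add_nongrammar_tfbs(ds, motif_set, 0.8, seed=4)
        for s in out.sequences:
            g = sum(a.grammar_id is not None for a in s.annotations)
            non = sum(a.grammar_id is None for a in s.annotations)
            assert non == round(g * 0.8 / 0.2)

    def test_fraction_zero_is_identity(self, small_dataset, motif_set):
        out = gs.add_nongrammar_tfbs(small_dataset, motif_set, 0.0, seed=1)
        assert out is small_dataset

    def test_added_sites_have_no_grammar(self, grammars, motif_set, classes):
        ds = gs.simulate_dataset(classes[:1], grammars, motif_set, 1, length=3000, seed=5)
        before = len(ds.sequences[0].annotations)
        out = gs.add_nongrammar_tfbs(ds, motif_set, 0.5, seed=6)
        added = [a for a in out.sequences[0].annotations if a.grammar_id is None]
        assert len(added) == len(out.sequences[0].annotations) - before


def _kmer_multiset(seq, k):
    return Counter(seq[i : i + k] for i in range(len(seq) - k + 1))


class TestKmerShuffle:
    def test_single_arrangement(self, rng):
        assert gs.kmer_shuffle("AAAA", 2, rng) == "AAAA"

    def test_k1_preserves_letter_counts(self, rng):
        seq = "ACGTACGGGTTA"
        out = gs.kmer_shuffle(seq, 1, rng)
        assert Counter(out) == Counter(seq)

    @pytest.mark.parametrize("k", [1, 2, 4, 8, 12])
    def test_kmer_multiset_preserved(self, rng, k):
        seq = "".join(
            mo.ALPHABET[i] for i in np.random.default_rng(17).integers(0, 4, size=400)
        )
        out = gs.kmer_shuffle(seq, k, rng)
        assert _kmer_multiset(out, k) == _kmer_multiset(seq, k)
        assert len(out) == len(seq)

    def test_all_outputs_are_valid_eulerian_arrangements(self, rng):
        """Every shuffle of a short string appears in the brute-force set of
        sequences with the same 2-mer multiset, and coverage is broad."""
        from itertools import permutations as perms

        seq = "ACGTACGGAC"
        target = _kmer_multiset(seq, 2)
        valid = {
            "".join(p)
            for p in set(perms(seq))
            if _kmer_multiset("".join(p), 2) == target
        }
        seen = set()
        for _ in range(400):
            out = gs.kmer_shuffle(seq, 2, rng)
            assert out in valid
            seen.add(out)
        # the shuffler should reach a substantial part of the valid space
        assert len(seen) > len(valid) / 2

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        seq=st.text(alphabet="ACGT", min_size=2, max_size=60),
        k=st.integers(min_value=1, max_value=12),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_shuffle_preserves_kmer_multiset_for_any_input(self, seq, k, seed):
        if k > len(seq):
            return
        out = gs.kmer_shuffle(seq, k, np.random.default_rng(seed))
        assert len(out) == len(seq)
        assert _kmer_multiset(out, k) == _kmer_multiset(seq, k)

    def test_k_bounds(self, rng):
        with pytest.raises(ValueError):
            gs.kmer_shuffle("ACGT", 0, rng)
        with pytest.raises(ValueError):
            gs.kmer_shuffle("ACGT", 5, rng)
        assert gs.kmer_shuffle("ACGT", 4, rng) == "ACGT"


class TestTfShuffle:
    def test_site_multiset_conserved(self, small_dataset, rng):
        s = small_dataset.sequences[0]
        out = gs.tf_shuffle(s, rng)
        before = sorted((a.motif_id, s.seq[a.start : a.end]) for a in s.annotations)
        after = sorted((a.motif_id, out.seq[a.start : a.end]) for a in out.annotations)
        assert before == after

    def test_labels_zeroed_and_grammar_dropped(self, small_dataset, rng):
        out = gs.tf_shuffle(small_dataset.sequences[0], rng)
        assert not out.label_vector.any()
        assert out.class_id is None
        assert all(a.grammar_id is None for a in out.annotations)

    def test_site_starts_approximately_uniform(self, small_dataset):
        """KS test of re-placed start positions against uniform."""
        s = small_dataset.sequences[0]
        rng = np.random.default_rng(0)
        L = len(s.seq)
        site_len = s.annotations[0].end - s.annotations[0].start
        starts = []
        for _ in range(1000):
            out = gs.tf_shuffle(s, rng)
            starts.extend(
                a.start for a in out.annotations if a.end - a.start == site_len
            )
        _, p = kstest(np.array(starts) / (L - site_len), "uniform")
        assert p > 0.01


class TestPersistence:
    def test_round_trip_exact(self, small_dataset, tmp_path):
        gs.write_dataset(small_dataset, tmp_path / "d")
        back = gs.read_dataset(tmp_path / "d")
        assert back.label_names == small_dataset.label_names
        assert len(back.sequences) == len(small_dataset.sequences)
        for a, b in zip(small_dataset.sequences, back.sequences):
            assert a.name == b.name and a.seq == b.seq
            assert a.class_id == b.class_id
            assert np.array_equal(a.label_vector, b.label_vector)
            assert a.annotations == b.annotations

    def test_bed_is_zero_based_half_open(self, small_dataset, tmp_path):
        gs.write_dataset(small_dataset, tmp_path / "d")
        s = small_dataset.sequences[0]
        first = s.annotations[0]
        lines = (tmp_path / "d" / "annotations.bed").read_text().splitlines()
        chrom, start, end = lines[0].split("\t")[:3]
        assert (chrom, int(start), int(end)) == (s.name, first.start, first.end)

    def test_fasta_and_label_rows_consistent(self, small_dataset, tmp_path):
        gs.write_dataset(small_dataset, tmp_path / "d")
        fasta = (tmp_path / "d" / "sequences.fasta").read_text().count(">")
        rows = len((tmp_path / "d" / "labels.tsv").read_text().splitlines()) - 1
        assert fasta == rows == len(small_dataset.sequences)


def test_dataset_regeneration_is_bit_identical(classes, grammars, motif_set):
    a = gs.simulate_dataset(classes[:2], grammars, motif_set, 3, length=1500, seed=42)
    b = gs.simulate_dataset(classes[:2], grammars, motif_set, 3, length=1500, seed=42)
    for x, y in zip(a.sequences, b.sequences):
        assert x.seq == y.seq and x.annotations == y.annotations
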