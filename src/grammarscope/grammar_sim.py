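"""Simulation of regulatory grammars, annotated enhancer sequences, and
matched negative sets.

Three grammar kinds are modeled:

* **homotypic cluster** — 3-5 non-overlapping sites of one TF scattered in a
  small window;
* **heterotypic cluster** — one site each for four distinct TFs, random
  order and positions within the window;
* **enhanceosome** — four TFs in fixed order with fixed inter-site spacing.

Positive sequences are uniform-random background DNA with several grammar
instances inserted at random non-overlapping locations.  Two families of
negatives are provided: k-mer-preserving shuffles of positives (Euler-path
shuffle on the (k-1)-mer de Bruijn multigraph) and TF-shuffled sequences in
which the exact binding-site strings are kept but re-placed at random
positions, destroying grammar geometry.
"""

from __future__ import annotations

import json
import os
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motifs import ALPHABET, MotifSet, sample_site

DEFAULT_WINDOW_BP = 120
DEFAULT_SEQ_LENGTH = 3000


class SimulationError(RuntimeError):
    """Raised when site/window placement cannot be satisfied."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class GrammarSpec:
    """Arrangement rule for motif sites within a window."""

    id: str
    kind: str  # homotypic | heterotypic | enhanceosome
    members: list[str]
    copies: tuple[int, int] = (3, 5)
    window_bp: int = DEFAULT_WINDOW_BP
    spacing_bp: list[int] = field(default_factory=list)
    fixed_order: bool = False

    def __post_init__(self) -> None:
        if self.kind == "homotypic":
            if len(self.members) != 1:
                raise ValueError(f"{self.id}: homotypic grammar needs exactly 1 member")
        elif self.kind in ("heterotypic", "enhanceosome"):
            if len(self.members) != 4:
                raise ValueError(f"{self.id}: {self.kind} grammar needs exactly 4 members")
        else:
            raise ValueError(f"{self.id}: unknown grammar kind {self.kind!r}")
        if self.kind == "enhanceosome" and not self.fixed_order:
            raise ValueError(f"{self.id}: enhanceosome requires fixed_order")


@dataclass
class ClassSpec:
    """A regulatory sequence class: which grammars it carries, how often."""

    id: int
    grammars: list[str]
    instances_per_grammar: tuple[int, int] = (2, 4)


@dataclass
class HeterogeneousSpec:
    """A heterogeneous output category pooling several sequence classes."""

    id: str
    member_classes: list[int]


@dataclass
class TFBSAnnotation:
    """Ground-truth binding site: 0-based half-open coordinates."""

    start: int
    end: int
    motif_id: str
    grammar_id: str | None = None
    grammar_instance: int | None = None
    strand: str = "+"


@dataclass
class AnnotatedSequence:
    name: str
    seq: str
    annotations: list[TFBSAnnotation] = field(default_factory=list)
    class_id: int | None = None
    label_vector: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.label_vector = np.asarray(self.label_vector, dtype=np.int8)


@dataclass
class Dataset:
    sequences: list[AnnotatedSequence]
    label_names: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        widths = {len(s.label_vector) for s in self.sequences}
        if widths and widths != {len(self.label_names)}:
            raise ValueError("label_vector widths inconsistent with label_names")

    def label_matrix(self) -> np.ndarray:
        return np.stack([s.label_vector for s in self.sequences])


# ---------------------------------------------------------------------------
# placement helpers


def _random_background(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)


def _feasible_start(
    L: int, span: int, placed: list[tuple[int, int]], rng: np.random.Generator
) -> int | None:
    """Uniform draw from all starts where an item of length L fits."""
    # forbidden starts for each placed (a, b): [a - L + 1, b)
    segments: list[tuple[int, int]] = []  # allowed start ranges, half-open
    cur = 0
    hi = span - L + 1
    if hi <= 0:
        raise SimulationError(f"item of length {L} cannot fit in span {span}")
    for a, b in sorted(placed):
        fa, fb = max(0, a - L + 1), min(hi, b)
        if fa > cur:
            segments.append((cur, fa))
        cur = max(cur, fb)
    if cur < hi:
        segments.append((cur, hi))
    total = sum(b - a for a, b in segments)
    if total == 0:
        return None
    u = int(rng.integers(0, total))
    for a, b in segments:
        if u < b - a:
            return a + u
        u -= b - a
    raise AssertionError("unreachable")


def _place_nonoverlapping(
    lengths: Sequence[int],
    span: int,
    rng: np.random.Generator,
    occupied: list[tuple[int, int]] | None = None,
    max_restarts: int = 50,
) -> list[int]:
    """Place items at random non-overlapping starts within [0, span).

    Items are placed sequentially in random order, each drawing a uniform
    start from the exact set of positions where it still fits (avoiding
    pre-``occupied`` intervals).  A rare sequential dead end triggers a
    bounded restart; exhaustion raises :class:`SimulationError`.
    """
    base = list(occupied or [])
    n = len(lengths)
    for _ in range(max_restarts):
        order = rng.permutation(n)
        placed = list(base)
        starts: list[int | None] = [None] * n
        ok = True
        for i in order:
            s = _feasible_start(lengths[i], span, placed, rng)
            if s is None:
                ok = False
                break
            placed.append((s, s + lengths[i]))
            starts[i] = s
        if ok:
            return starts  # type: ignore[return-value]
    raise SimulationError(
        f"could not place {len(lengths)} items (total {sum(lengths)} bp) in span {span}"
    )


# ---------------------------------------------------------------------------
# default grammar / class presets


def default_grammars(motifs: MotifSet, seed: int | np.random.Generator = 0) -> list[GrammarSpec]:
    """Build the default 12-grammar preset: 5 homotypic clusters, 5
    heterotypic clusters, and 2 enhanceosomes.

    Member TFs are drawn from a shuffled order of the motif set; because 12
    grammars require 33 member slots, some TFs occur in more than one
    grammar.  Enhanceosomes use fixed 5-bp gaps between consecutive sites.
    """
    if len(motifs) < 26:
        raise ValueError(f"need >= 26 motifs, got {len(motifs)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = [motifs.ids[i] for i in rng.permutation(len(motifs))]
    pool = order * 3  # cycled supply of ids
    pos = 0

    def _take(n: int) -> list[str]:
        nonlocal pos
        out: list[str] = []
        p = pos
        while len(out) < n:
            cand = pool[p]
            p += 1
            if cand not in out:  # members within one grammar must be distinct
                out.append(cand)
        pos = p
        return out

    specs: list[GrammarSpec] = []
    for i in range(5):
        specs.append(GrammarSpec(f"hom{i + 1}", "homotypic", _take(1), copies=(3, 5)))
    for i in range(5):
        specs.append(GrammarSpec(f"het{i + 1}", "heterotypic", _take(4)))
    for i in range(2):
        specs.append(
            GrammarSpec(
                f"enh{i + 1}",
                "enhanceosome",
                _take(4),
                spacing_bp=[5, 5, 5],
                fixed_order=True,
            )
        )
    return specs


#: grammar ordering used to chain grammars across the 12 default classes
_DEFAULT_CHAIN = [
    "hom1", "het1", "hom2", "het2", "enh1", "hom3",
    "het3", "hom4", "het4", "enh2", "hom5", "het5",
]


def default_classes() -> list[ClassSpec]:
    """Twelve classes, each carrying two grammars, chained so that every
    grammar occurs in exactly two classes (class 1 = hom1+het1, class 2 =
    het1+hom2, ..., class 6 = hom3+het3, ...)."""
    return [
        ClassSpec(i + 1, [_DEFAULT_CHAIN[i], _DEFAULT_CHAIN[(i + 1) % 12]])
        for i in range(12)
    ]


def default_heterogeneous() -> list[HeterogeneousSpec]:
    """Five heterogeneous categories pooling the 12 classes, with overlap."""
    groups = [(1, 3, 5), (2, 4, 6), (7, 9, 11), (5, 8, 10), (1, 6, 12)]
    return [HeterogeneousSpec(f"het_class_{i + 1}", list(g)) for i, g in enumerate(groups)]


def disjoint_grammar_specs() -> tuple[list[ClassSpec], list[HeterogeneousSpec]]:
    """The failure-mode preset: three heterogeneous categories, each the
    union of two sequence types, with grammar pairs disjoint across
    categories.  Because several grammars can separate one category from
    another, the network need not learn them all."""
    classes = [
        ClassSpec(1, ["hom1", "hom2"]),
        ClassSpec(2, ["hom4", "het4"]),
        ClassSpec(3, ["het1", "het2"]),
        ClassSpec(4, ["hom5", "enh1"]),
        ClassSpec(5, ["hom3", "het3"]),
        ClassSpec(6, ["het5", "enh2"]),
    ]
    het = [
        HeterogeneousSpec("mix_1", [1, 2]),
        HeterogeneousSpec("mix_2", [3, 4]),
        HeterogeneousSpec("mix_3", [5, 6]),
    ]
    return classes, het


# ---------------------------------------------------------------------------
# rendering and simulation


def render_grammar_instance(
    spec: GrammarSpec,
    motifs: MotifSet,
    rng: np.random.Generator,
    consensus: bool = False,
) -> tuple[str, list[TFBSAnnotation]]:
    """Render one grammar instance as a window string plus local annotations."""
    window = _random_background(spec.window_bp, rng)
    anns: list[TFBSAnnotation] = []

    if spec.kind == "homotypic":
        k = int(rng.integers(spec.copies[0], spec.copies[1] + 1))
        member_ids = [spec.members[0]] * k
    elif spec.kind == "heterotypic":
        member_ids = [spec.members[i] for i in rng.permutation(4)]
    else:  # enhanceosome
        member_ids = list(spec.members)

    sites = [sample_site(motifs[mid], rng, consensus=consensus) for mid in member_ids]
    lengths = [len(s) for s in sites]

    if spec.kind == "enhanceosome":
        gaps = spec.spacing_bp or [0] * (len(sites) - 1)
        span = sum(lengths) + sum(gaps)
        if span > spec.window_bp:
            raise SimulationError(f"{spec.id}: enhanceosome span {span} > window {spec.window_bp}")
        offset = int(rng.integers(0, spec.window_bp - span + 1))
        starts = []
        s = offset
        for i, L in enumerate(lengths):
            starts.append(s)
            s += L + (gaps[i] if i < len(gaps) else 0)
    else:
        starts = _place_nonoverlapping(lengths, spec.window_bp, rng)

    from .motifs import seq_to_indices

    for mid, site, s in zip(member_ids, sites, starts):
        window[s : s + len(site)] = seq_to_indices(site)
        anns.append(TFBSAnnotation(s, s + len(site), mid, grammar_id=spec.id))
    anns.sort(key=lambda a: a.start)
    return _codes_to_str(window), anns


def simulate_sequence(
    class_spec: ClassSpec,
    grammars: dict[str, GrammarSpec],
    motifs: MotifSet,
    length: int = DEFAULT_SEQ_LENGTH,
    rng: np.random.Generator | None = None,
    name: str = "seq",
    consensus: bool = False,
) -> AnnotatedSequence:
    """Simulate one positive sequence for a class.

    For each grammar of the class a uniform random number of instances
    (``instances_per_grammar``) is rendered; instance windows are inserted
    at uniform random non-overlapping offsets into a uniform-background
    sequence of the requested length.
    """
    rng = rng if rng is not None else np.random.default_rng()
    codes = _random_background(length, rng)
    renders: list[tuple[str, list[TFBSAnnotation], int]] = []
    lo, hi = class_spec.instances_per_grammar
    for gid in class_spec.grammars:
        spec = grammars[gid]
        m = int(rng.integers(lo, hi + 1))
        for inst in range(1, m + 1):
            win, anns = render_grammar_instance(spec, motifs, rng, consensus=consensus)
            renders.append((win, anns, inst))
    lengths = [len(w) for w, _, _ in renders]
    if sum(lengths) > length:
        raise SimulationError("total grammar window length exceeds sequence length")
    starts = _place_nonoverlapping(lengths, length, rng)

    from .motifs import seq_to_indices

    all_anns: list[TFBSAnnotation] = []
    for (win, anns, inst), s in zip(renders, starts):
        codes[s : s + len(win)] = seq_to_indices(win)
        for a in anns:
            all_anns.append(
                TFBSAnnotation(a.start + s, a.end + s, a.motif_id, a.grammar_id, inst, a.strand)
            )
    all_anns.sort(key=lambda a: a.start)
    return AnnotatedSequence(name, _codes_to_str(codes), all_anns, class_id=class_spec.id)


def _labels_for_class(
    class_id: int,
    classes: list[ClassSpec],
    het_specs: list[HeterogeneousSpec] | None,
) -> np.ndarray:
    if het_specs is None:
        vec = np.zeros(len(classes), dtype=np.int8)
        vec[[c.id for c in classes].index(class_id)] = 1
    else:
        vec = np.zeros(len(het_specs), dtype=np.int8)
        for j, h in enumerate(het_specs):
            if class_id in h.member_classes:
                vec[j] = 1
    return vec


def simulate_dataset(
    classes: list[ClassSpec],
    grammars: list[GrammarSpec] | dict[str, GrammarSpec],
    motifs: MotifSet,
    n_per_class: int = 2500,
    length: int = DEFAULT_SEQ_LENGTH,
    seed: int | np.random.Generator = 0,
    het_specs: list[HeterogeneousSpec] | None = None,
    consensus: bool = False,
) -> Dataset:
    """Simulate ``len(classes) * n_per_class`` positive sequences.

    Labels are one-hot over classes, or multi-hot over heterogeneous
    categories when ``het_specs`` is given (a sequence gets a 1 for every
    heterogeneous category containing its class).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gdict = grammars if isinstance(grammars, dict) else {g.id: g for g in grammars}
    label_names = (
        [f"class_{c.id}" for c in classes]
        if het_specs is None
        else [h.id for h in het_specs]
    )
    seqs: list[AnnotatedSequence] = []
    for c in classes:
        for i in range(n_per_class):
            s = simulate_sequence(
                c, gdict, motifs, length=length, rng=rng,
                name=f"class{c.id}_seq{i + 1}", consensus=consensus,
            )
            s.label_vector = _labels_for_class(c.id, classes, het_specs)
            seqs.append(s)
    prov = {
        "n_per_class": n_per_class,
        "length": length,
        "n_classes": len(classes),
        "heterogeneous": het_specs is not None,
        "seed": int(seed) if not isinstance(seed, np.random.Generator) else None,
    }
    return Dataset(seqs, label_names, prov)


def add_nongrammar_tfbs(
    dataset: Dataset,
    motifs: MotifSet,
    nongrammar_fraction: float = 0.8,
    seed: int | np.random.Generator = 0,
) -> Dataset:
    """Scatter single (non-grammar) TF sites into every sequence until they
    make up ``nongrammar_fraction`` of all TFBS annotations (up to rounding).

    Motifs are drawn uniformly from the set; added annotations carry
    ``grammar_id = None``.  Returns a new Dataset; the input is unchanged.
    """
    if not (0 <= nongrammar_fraction < 1):
        raise ValueError("nongrammar_fraction must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if nongrammar_fraction == 0:
        return dataset

    from .motifs import seq_to_indices

    new_seqs: list[AnnotatedSequence] = []
    for s in dataset.sequences:
        g = len(s.annotations)
        n_add = int(round(g * nongrammar_fraction / (1.0 - nongrammar_fraction)))
        codes = seq_to_indices(s.seq)
        occupied = [(a.start, a.end) for a in s.annotations]
        site_ids = [motifs.ids[i] for i in rng.integers(0, len(motifs), size=n_add)]
        sites = [sample_site(motifs[mid], rng) for mid in site_ids]
        starts = _place_nonoverlapping([len(x) for x in sites], len(s.seq), rng, occupied=occupied)
        anns = list(s.annotations)
        for mid, site, st in zip(site_ids, sites, starts):
            codes[st : st + len(site)] = seq_to_indices(site)
            anns.append(TFBSAnnotation(st, st + len(site), mid, grammar_id=None))
        anns.sort(key=lambda a: a.start)
        new_seqs.append(
            AnnotatedSequence(s.name, _codes_to_str(codes), anns, s.class_id, s.label_vector.copy())
        )
    prov = dict(dataset.provenance)
    prov["nongrammar_fraction"] = nongrammar_fraction
    return Dataset(new_seqs, list(dataset.label_names), prov)


# ---------------------------------------------------------------------------
# negatives


def kmer_shuffle(seq: str, k: int, rng: np.random.Generator) -> str:
    """Shuffle a sequence while preserving its multiset of overlapping k-mers.

    Implements the Euler-path shuffle: the sequence is viewed as an Eulerian
    walk on the de Bruijn multigraph of (k-1)-mers; a uniform random
    spanning arborescence toward the terminal vertex (Wilson's loop-erased
    random walk) fixes the last exit edge of every vertex, the remaining
    out-edges are permuted uniformly, and the walk is replayed.  By the BEST
    theorem this draws uniformly from all sequences with the same k-mer
    multiset.  ``k = 1`` degenerates to a plain letter permutation.
    """
    n = len(seq)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError("k must not exceed the sequence length")
    if k == 1:
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        return bytes(arr[rng.permutation(n)]).decode()
    if n == k:
        return seq

    m = k - 1
    start, end = seq[:m], seq[n - m :]
    out_edges: dict[str, list[str]] = defaultdict(list)
    for i in range(n - m):
        out_edges[seq[i : i + m]].append(seq[i + 1 : i + 1 + m])

    # Wilson's algorithm: loop-erased random walks build a uniform random
    # arborescence rooted at the end vertex; edge choice is proportional to
    # multiplicity because successors are drawn from the out-edge multiset.
    in_tree: dict[str, str | None] = {end: None}
    for v in list(out_edges):
        if v in in_tree:
            continue
        path_next: dict[str, str] = {}
        u = v
        while u not in in_tree:
            succ = out_edges[u]
            u_next = succ[int(rng.integers(0, len(succ)))]
            path_next[u] = u_next
            u = u_next
        u = v
        while u not in in_tree:
            in_tree[u] = path_next[u]
            u = path_next[u]

    # permute out-edges; move one copy of the arborescence edge to the end
    ordered: dict[str, list[str]] = {}
    for v, targets in out_edges.items():
        t = [targets[i] for i in rng.permutation(len(targets))]
        last = in_tree.get(v)
        if v != end and last is not None:
            t.remove(last)
            t.append(last)
        ordered[v] = t

    # replay the Eulerian walk
    pos: dict[str, int] = defaultdict(int)
    out = [start]
    u = start
    total_edges = n - m
    for _ in range(total_edges):
        nxt = ordered[u][pos[u]]
        pos[u] += 1
        out.append(nxt[-1])
        u = nxt
    return "".join(out)


def tf_shuffle(
    annseq: AnnotatedSequence,
    rng: np.random.Generator,
    name_suffix: str = "|tfshuf",
) -> AnnotatedSequence:
    """Randomize binding-site positions while keeping the sites themselves.

    The exact site strings of all annotations are re-placed at uniform
    random non-overlapping positions on a freshly drawn uniform background
    of the same length.  Annotations keep their motif ids but lose grammar
    membership; the label vector is zeroed (negative by construction).
    """
    if not annseq.annotations:
        raise ValueError("tf_shuffle requires an annotated sequence")
    from .motifs import seq_to_indices

    sites = [(a.motif_id, annseq.seq[a.start : a.end], a.strand) for a in annseq.annotations]
    codes = _random_background(len(annseq.seq), rng)
    starts = _place_nonoverlapping([len(s) for _, s, _ in sites], len(annseq.seq), rng)
    anns: list[TFBSAnnotation] = []
    for (mid, site, strand), st in zip(sites, starts):
        codes[st : st + len(site)] = seq_to_indices(site)
        anns.append(TFBSAnnotation(st, st + len(site), mid, None, None, strand))
    anns.sort(key=lambda a: a.start)
    return AnnotatedSequence(
        annseq.name + name_suffix,
        _codes_to_str(codes),
        anns,
        class_id=None,
        label_vector=np.zeros_like(annseq.label_vector),
    )


def make_negatives(
    dataset: Dataset,
    mode: str,
    seed: int | np.random.Generator = 0,
    k: int | None = None,
) -> Dataset:
    """Negative counterpart of a positive dataset.

    ``mode`` is ``"tfshuffle"`` or ``"kmer"`` (requires ``k``).  One
    negative is produced per positive; all label vectors are zero.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    negs: list[AnnotatedSequence] = []
    for s in dataset.sequences:
        if mode == "tfshuffle":
            negs.append(tf_shuffle(s, rng))
        elif mode == "kmer":
            if k is None:
                raise ValueError("kmer mode requires k")
            negs.append(
                AnnotatedSequence(
                    f"{s.name}|k{k}shuf",
                    kmer_shuffle(s.seq, k, rng),
                    [],
                    None,
                    np.zeros_like(s.label_vector),
                )
            )
        else:
            raise ValueError(f"unknown negative mode {mode!r}")
    prov = dict(dataset.provenance)
    prov["negatives"] = {"mode": mode, "k": k}
    return Dataset(negs, list(dataset.label_names), prov)


# ---------------------------------------------------------------------------
# persistence


def write_dataset(dataset: Dataset, out_dir) -> None:
    """Write FASTA + BED6 + label TSV + provenance JSON."""
    os.makedirs(out_dir, exist_ok=True)
    records = [SeqRecord(Seq(s.seq), id=s.name, description="") for s in dataset.sequences]
    SeqIO.write(records, os.path.join(out_dir, "sequences.fasta"), "fasta")
    with open(os.path.join(out_dir, "annotations.bed"), "w") as fh:
        for s in dataset.sequences:
            for a in s.annotations:
                name = f"{a.motif_id}|{a.grammar_id or '.'}|{a.grammar_instance or '.'}"
                fh.write(f"{s.name}\t{a.start}\t{a.end}\t{name}\t0\t{a.strand}\n")
    with open(os.path.join(out_dir, "labels.tsv"), "w") as fh:
        fh.write("name\tclass_id\t" + "\t".join(dataset.label_names) + "\n")
        for s in dataset.sequences:
            cid = "" if s.class_id is None else str(s.class_id)
            fh.write(f"{s.name}\t{cid}\t" + "\t".join(str(int(v)) for v in s.label_vector) + "\n")
    with open(os.path.join(out_dir, "provenance.json"), "w") as fh:
        json.dump({"label_names": dataset.label_names, "provenance": dataset.provenance}, fh, indent=1)


def read_dataset(in_dir) -> Dataset:
    """Inverse of :func:`write_dataset`; validates file consistency."""
    with open(os.path.join(in_dir, "provenance.json")) as fh:
        meta = json.load(fh)
    label_names = meta["label_names"]
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(os.path.join(in_dir, "sequences.fasta"), "fasta"):
        seqs[rec.id] = str(rec.seq)
    anns: dict[str, list[TFBSAnnotation]] = defaultdict(list)
    with open(os.path.join(in_dir, "annotations.bed")) as fh:
        for line in fh:
            chrom, start, end, name, _score, strand = line.rstrip("\n").split("\t")
            mid, gid, inst = name.split("|")
            anns[chrom].append(
                TFBSAnnotation(
                    int(start), int(end), mid,
                    None if gid == "." else gid,
                    None if inst == "." else int(inst),
                    strand,
                )
            )
    sequences: list[AnnotatedSequence] = []
    with open(os.path.join(in_dir, "labels.tsv")) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[2:] != label_names:
            raise ValueError("labels.tsv columns do not match provenance label names")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            name, cid = fields[0], fields[1]
            if name not in seqs:
                raise ValueError(f"label row {name} missing from FASTA")
            vec = np.array([int(v) for v in fields[2:]], dtype=np.int8)
            sequences.append(
                AnnotatedSequence(
                    name, seqs[name], anns.get(name, []),
                    None if cid == "" else int(cid), vec,
                )
            )
    if len(sequences) != len(seqs):
        raise ValueError("FASTA record count does not match label-table row count")
    return Dataset(sequences, label_names, meta["provenance"])
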