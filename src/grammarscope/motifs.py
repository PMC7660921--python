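"""Position weight matrices: reading, sampling, scanning, and synthesis.

A :class:`Motif` stores a position probability matrix (PPM) over the DNA
alphabet with columns ordered A, C, G, T.  Scanning uses log-odds scores in
bits against a background distribution, with exact p-values computed from
the null score distribution by dynamic programming over motif positions
(scores discretized to a fixed granularity, in the style of FIMO).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: pseudocount added to PPM entries before taking log-odds
LOGODDS_PSEUDOCOUNT = 1e-3
#: bin width (bits) used when discretizing scores for the exact null DP
SCORE_GRANULARITY = 1e-3


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class MotifError(ValueError):
    """Raised for malformed motif files or invalid matrices."""


@dataclass
class Motif:
    """A TF binding motif as a position probability matrix.

    Parameters
    ----------
    id : str
        Short unique identifier.
    name : str
        Human-readable name (may equal ``id``).
    ppm : ndarray of shape (L, 4)
        Per-position base probabilities, columns A, C, G, T.
    source : str
        Free-text provenance (file name, generator, ...).
    """

    id: str
    name: str
    ppm: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        if self.ppm.ndim != 2 or self.ppm.shape[1] != 4:
            raise MotifError(f"motif {self.id}: ppm must be L x 4")
        L = self.ppm.shape[0]
        if not (4 <= L <= 30):
            raise MotifError(f"motif {self.id}: length {L} outside [4, 30]")
        if (self.ppm < 0).any():
            raise MotifError(f"motif {self.id}: negative probabilities")
        rowsums = self.ppm.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-9):
            raise MotifError(
                f"motif {self.id}: rows do not sum to 1 (max dev "
                f"{np.abs(rowsums - 1).max():.3g})"
            )

    def __len__(self) -> int:
        return self.ppm.shape[0]

    @property
    def consensus(self) -> str:
        """Highest-probability base at each position."""
        return "".join(ALPHABET[i] for i in self.ppm.argmax(axis=1))

    def information_content(self) -> np.ndarray:
        """Per-column information content in bits (2 - entropy)."""
        p = np.clip(self.ppm, 1e-12, 1.0)
        return 2.0 + (p * np.log2(p)).sum(axis=1)


@dataclass
class MotifSet:
    """Ordered collection of motifs with unique ids."""

    motifs: list[Motif] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [m.id for m in self.motifs]
        if len(set(ids)) != len(ids):
            raise MotifError("duplicate motif ids in MotifSet")
        self._by_id = {m.id: m for m in self.motifs}

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self) -> Iterator[Motif]:
        return iter(self.motifs)

    def __getitem__(self, key: int | str) -> Motif:
        if isinstance(key, str):
            return self._by_id[key]
        return self.motifs[key]

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.motifs]


@dataclass
class MotifMatch:
    """A scan hit: 0-based half-open coordinates on the forward strand.

    ``score`` is the log-odds score in bits; ``pvalue`` is the exact
    probability of a score at least this large for a random background
    window.
    """

    motif_id: str
    start: int
    end: int
    strand: str
    score: float
    pvalue: float


# ---------------------------------------------------------------------------
# reading


def read_motifs(path, format: str = "meme_minimal", pseudocount: float = 1.0) -> MotifSet:
    """Read a motif file.

    ``meme_minimal`` parses MEME minimal motif format (letter-probability
    matrices).  ``count_matrix`` parses plain-text count matrices in the
    HOCOMOCO PCM style: a ``>id`` header line followed by one line of four
    whitespace-separated counts (A C G T) per motif position; counts are
    converted to probabilities with an additive ``pseudocount``.
    """
    if format == "meme_minimal":
        return _read_meme(path)
    if format == "count_matrix":
        return _read_counts(path, pseudocount)
    raise ValueError(f"unknown motif format: {format!r}")


def _read_meme(path) -> MotifSet:
    motifs: list[Motif] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise MotifError(f"line {i + 1}: MOTIF line without identifier")
            mid = parts[1]
            name = parts[2] if len(parts) > 2 else mid
            # advance to the letter-probability header
            j = i + 1
            while j < n and not lines[j].strip().startswith("letter-probability matrix"):
                if lines[j].strip().startswith("MOTIF"):
                    raise MotifError(f"line {j + 1}: motif {mid} has no probability matrix")
                j += 1
            if j >= n:
                raise MotifError(f"line {i + 1}: motif {mid} has no probability matrix")
            header = lines[j].strip()
            w = None
            toks = header.replace("=", " = ").split()
            for t_idx, tok in enumerate(toks):
                if tok == "w" and t_idx + 2 < len(toks):
                    w = int(toks[t_idx + 2])
            rows = []
            j += 1
            while j < n:
                s = lines[j].strip()
                if not s or s.startswith(("MOTIF", "URL")):
                    break
                vals = s.split()
                if len(vals) != 4:
                    raise MotifError(f"line {j + 1}: expected 4 probabilities, got {len(vals)}")
                try:
                    rows.append([float(v) for v in vals])
                except ValueError as e:
                    raise MotifError(f"line {j + 1}: {e}") from None
                j += 1
                if w is not None and len(rows) == w:
                    break
            if w is not None and len(rows) != w:
                raise MotifError(f"motif {mid}: expected {w} rows, found {len(rows)}")
            motifs.append(Motif(mid, name, np.array(rows), source=str(path)))
            i = j
        else:
            i += 1
    if not motifs:
        raise MotifError(f"{path}: no MOTIF records found")
    return MotifSet(motifs)


def _read_counts(path, pseudocount: float) -> MotifSet:
    motifs: list[Motif] = []
    cur_id: str | None = None
    cur_name = ""
    rows: list[list[float]] = []

    def _flush(lineno: int) -> None:
        nonlocal rows, cur_id
        if cur_id is None:
            return
        if not rows:
            raise MotifError(f"line {lineno}: motif {cur_id} has no count rows")
        counts = np.array(rows, dtype=float)
        probs = (counts + pseudocount) / (
            counts.sum(axis=1, keepdims=True) + 4.0 * pseudocount
        )
        motifs.append(Motif(cur_id, cur_name or cur_id, probs, source=str(path)))
        rows = []
        cur_id = None

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush(lineno)
                fields = line[1:].split(None, 1)
                if not fields:
                    raise MotifError(f"line {lineno}: empty header")
                cur_id = fields[0]
                cur_name = fields[1] if len(fields) > 1 else ""
            else:
                if cur_id is None:
                    raise MotifError(f"line {lineno}: counts before any '>' header")
                vals = line.split()
                if len(vals) != 4:
                    raise MotifError(f"line {lineno}: expected 4 counts, got {len(vals)}")
                try:
                    rows.append([float(v) for v in vals])
                except ValueError as e:
                    raise MotifError(f"line {lineno}: {e}") from None
        _flush(lineno=-1)
    if not motifs:
        raise MotifError(f"{path}: no motif records found")
    return MotifSet(motifs)


# ---------------------------------------------------------------------------
# sampling


def sample_site(motif: Motif, rng: np.random.Generator, consensus: bool = False) -> str:
    """Draw one binding-site string from the motif.

    Each position is sampled independently from the corresponding PPM row;
    with ``consensus=True`` the highest-probability base is used instead,
    giving identical site strings on every call.
    """
    if consensus:
        return motif.consensus
    L = len(motif)
    u = rng.random(L)
    cum = np.cumsum(motif.ppm, axis=1)
    idx = (u[:, None] > cum).sum(axis=1)
    return "".join(ALPHABET[i] for i in idx)


# ---------------------------------------------------------------------------
# scanning


def seq_to_indices(seq: str) -> np.ndarray:
    """Map a DNA string to integer codes A=0 C=1 G=2 T=3, N=4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, i in _BASE_INDEX.items():
        out[arr == ord(base)] = i
    bad = (out == 4) & (arr != ord("N"))
    if bad.any():
        pos = int(np.nonzero(bad)[0][0])
        raise ValueError(f"invalid character {seq[pos]!r} at position {pos}")
    return out


def _logodds(motif: Motif, background: np.ndarray) -> np.ndarray:
    p = (motif.ppm + LOGODDS_PSEUDOCOUNT) / (1.0 + 4.0 * LOGODDS_PSEUDOCOUNT)
    return np.log2(p / background[None, :])


def null_score_distribution(
    motif: Motif,
    background: Sequence[float],
    granularity: float = SCORE_GRANULARITY,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact null distribution of the discretized log-odds score.

    Returns ``(int_scores, offsets, sf)`` where ``int_scores`` is the
    integer-binned score matrix (L x 4), ``offsets`` the minimum integer
    score per DP stage, and ``sf`` the survival function over total integer
    scores: ``sf[s]`` = P(score_int >= s + total_offset) under i.i.d.
    background bases.
    """
    bg = np.asarray(background, dtype=float)
    lod = _logodds(motif, bg)
    iscores = np.round(lod / granularity).astype(np.int64)
    L = len(motif)
    # DP: distribution of the running sum, stored as a dense pmf array
    pmf = np.array([1.0])
    offset = 0
    for i in range(L):
        lo, hi = iscores[i].min(), iscores[i].max()
        new = np.zeros(len(pmf) + (hi - lo), dtype=float)
        for b in range(4):
            shift = iscores[i, b] - lo
            new[shift : shift + len(pmf)] += bg[b] * pmf
        pmf = new
        offset += lo
    sf = np.cumsum(pmf[::-1])[::-1]
    return iscores, np.array([offset]), sf


def scan_sequence(
    seq: str,
    motif: Motif,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    p_threshold: float = 1e-4,
    both_strands: bool = True,
    granularity: float = SCORE_GRANULARITY,
) -> list[MotifMatch]:
    """Scan a sequence for motif matches with exact p-values.

    Scores every window on the forward strand (and, if ``both_strands``,
    the reverse complement) and returns matches with p <= ``p_threshold``
    sorted by start position.  Windows containing N never match.
    """
    bg = np.asarray(background, dtype=float)
    if not math.isclose(bg.sum(), 1.0, rel_tol=0, abs_tol=1e-6):
        raise ValueError("background must sum to 1")
    L = len(motif)
    n = len(seq)
    if n < L or n == 0:
        return []
    iscores, offset, sf = null_score_distribution(motif, bg, granularity)
    total_offset = int(offset[0])

    idx = seq_to_indices(seq)
    matches: list[MotifMatch] = []
    lod = _logodds(motif, bg)

    def _scan_strand(codes: np.ndarray, strand: str) -> None:
        nwin = len(codes) - L + 1
        if nwin <= 0:
            return
        windows = np.lib.stride_tricks.sliding_window_view(codes, L)
        valid = ~(windows == 4).any(axis=1)
        safe = np.where(windows == 4, 0, windows)
        pos_idx = np.arange(L)
        int_tot = iscores[pos_idx, safe].sum(axis=1)
        real_tot = lod[pos_idx, safe].sum(axis=1)
        rel = int_tot - total_offset
        rel = np.clip(rel, 0, len(sf) - 1)
        pvals = sf[rel]
        hit = valid & (pvals <= p_threshold)
        for w in np.nonzero(hit)[0]:
            if strand == "+":
                start = int(w)
            else:
                start = len(codes) - int(w) - L
            matches.append(
                MotifMatch(motif.id, start, start + L, strand, float(real_tot[w]), float(pvals[w]))
            )

    _scan_strand(idx, "+")
    if both_strands:
        _scan_strand(seq_to_indices(revcomp(seq)), "-")
    matches.sort(key=lambda m: (m.start, m.strand))
    return matches


def scan_hits_to_tsv(hits: Iterable[tuple[str, MotifMatch]], path) -> None:
    """Write scan hits as a FIMO-style TSV.

    ``hits`` yields (sequence_name, match) pairs.  Coordinates in the TSV
    are 1-based inclusive; internal coordinates are 0-based half-open.
    """
    with open(path, "w") as fh:
        fh.write("motif_id\tsequence_name\tstart\tstop\tstrand\tscore\tp-value\n")
        for name, m in hits:
            fh.write(
                f"{m.motif_id}\t{name}\t{m.start + 1}\t{m.end}\t{m.strand}"
                f"\t{m.score:.4f}\t{m.pvalue:.3g}\n"
            )


# ---------------------------------------------------------------------------
# synthetic motif sets


def _ic_to_p(target: float) -> float:
    # invert IC(p) = 2 + p log2 p + (1-p) log2((1-p)/3) for p in [0.25, 1)
    lo, hi = 0.25, 1.0 - 1e-12
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        q = (1.0 - mid) / 3.0
        ic = 2.0 + mid * math.log2(mid) + 3.0 * q * (math.log2(q) if q > 0 else 0.0)
        if ic < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def synthetic_motif_set(
    n: int,
    length_range: tuple[int, int] = (8, 15),
    info_bits: float = 1.5,
    seed: int | np.random.Generator = 0,
    max_retries: int = 200,
) -> MotifSet:
    """Generate ``n`` synthetic motifs with pairwise-distinct consensus strings.

    Column distributions put probability ``p`` on a random consensus base
    and the remainder equally on the other three, with ``p`` chosen so the
    column information content is a jittered version of ``info_bits``
    (mean within 0.2 bits of target).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 < info_bits <= 2):
        raise ValueError("info_bits must be in (0, 2]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = length_range
    motifs: list[Motif] = []
    seen: set[str] = set()
    attempts = 0
    while len(motifs) < n:
        attempts += 1
        if attempts > n + max_retries:
            raise RuntimeError("could not generate distinct consensus strings")
        L = int(rng.integers(lo, hi + 1))
        # jitter shrinks near the information-content bounds so extreme
        # targets (e.g. 2 bits) yield near-deterministic motifs
        sd = min(0.12, 0.8 * (2.0 - info_bits), 0.8 * max(info_bits - 0.05, 0.0))
        ic_cols = np.clip(rng.normal(info_bits, sd, size=L), 0.05, 1.9995)
        # recentre the jitter so the realized mean stays on target
        ic_cols += np.clip(info_bits - ic_cols.mean(), -0.1, 0.1)
        ic_cols = np.clip(ic_cols, 0.05, 1.9995)
        ppm = np.empty((L, 4))
        cons = rng.integers(0, 4, size=L)
        for i in range(L):
            p = _ic_to_p(float(ic_cols[i]))
            row = np.full(4, (1.0 - p) / 3.0)
            row[cons[i]] = p
            ppm[i] = row
        m = Motif(f"TF{len(motifs) + 1:02d}", f"synTF{len(motifs) + 1:02d}", ppm, source="synthetic")
        if m.consensus in seen:
            continue
        seen.add(m.consensus)
        motifs.append(m)
    return MotifSet(motifs)
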