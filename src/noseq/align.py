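"""Deamination-aware seed-and-extend alignment against a single amplicon.

Partial nitrous-acid deamination degenerates the read signal: a reference A
may legitimately read as G (A->I, inosine pairs like G), a reference C as T
(C->U), and a reference G occasionally as A (xanthosine read-through).  A
conventional mapper would count these as mismatches, so alignment is scored
with an *asymmetric* substitution matrix: chemistry-compatible (read, ref)
pairings reward +1, everything else penalises -1.  Note the direction
matters -- read T over reference C is compatible, read C over reference T
is not (no reaction produces C from U).

Two retention filters follow the scoring:

* perfect-score filter -- a read is kept only if its total gapless score
  equals its length (every pairing compatible); any -1 pairing or gap is
  fatal, so extension is implemented ungapped;
* anchor filter -- the alignment must start at the first nucleotide of the
  reference, which keeps the reading frame and makes coverage homogeneous.

Reads must additionally cover the configured evaluation window (default:
the entire reference), so per-position denominators downstream are constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import ReferenceAmplicon, StructuredRead

__all__ = [
    "BASES",
    "SubstitutionMatrix",
    "KmerIndex",
    "AlignedRead",
    "Rejection",
    "AlignedReadSet",
    "build_index",
    "seed_matches",
    "extend_and_score",
    "align_all",
    "decisions_table",
    "write_sam",
]

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}

# byte -> 0..3 code, 255 for anything else (N etc.)
_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _i in _CODE.items():
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i

_ASCII = np.frombuffer(BASES.encode(), dtype=np.uint8)


def encode(sequence: str) -> np.ndarray:
    """Map a base string to uint8 codes (A=0 C=1 G=2 T=3, other=255)."""
    return _LUT[np.frombuffer(sequence.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _ASCII[codes].tobytes().decode()


# Chemistry-compatible (read base, reference base) pairings.  (G,A): A->I
# read as G; (T,C): C->U read as T; (A,G): minor xanthosine-as-A signal.
_COMPATIBLE = (
    ("A", "A"), ("C", "C"), ("G", "G"), ("T", "T"),
    ("G", "A"), ("A", "G"), ("T", "C"),
)


@dataclass(frozen=True)
class SubstitutionMatrix:
    """4x4 asymmetric score table over (read base, reference base).

    Entries are +1 (compatible) or -1; rows index the read base, columns the
    reference base, both in A,C,G,T order.
    """

    scores: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.scores, dtype=np.int8)
        if arr.shape != (4, 4):
            raise ValidationError("substitution matrix must be 4x4")
        if not np.isin(arr, (-1, 1)).all():
            raise ValidationError("substitution matrix entries must be +1 or -1")
        object.__setattr__(self, "scores", arr)

    @classmethod
    def default(cls) -> "SubstitutionMatrix":
        """The deamination matrix: +1 exactly on the compatible pairings."""
        arr = np.full((4, 4), -1, dtype=np.int8)
        for read_base, ref_base in _COMPATIBLE:
            arr[_CODE[read_base], _CODE[ref_base]] = 1
        return cls(arr)

    @classmethod
    def from_table(cls, path: str | Path) -> "SubstitutionMatrix":
        """Load a 4x4 table (TSV with A C G T header row and index column)."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        df = df.loc[list(BASES), list(BASES)]
        return cls(df.to_numpy())

    def to_table(self, path: str | Path) -> None:
        pd.DataFrame(self.scores, index=list(BASES), columns=list(BASES)).to_csv(
            path, sep="\t", index_label="read_base"
        )

    def score(self, read_base: str, ref_base: str) -> int:
        return int(self.scores[_CODE[read_base], _CODE[ref_base]])

    @property
    def compatible(self) -> np.ndarray:
        """Boolean (4,4) array of +1 pairings."""
        return self.scores > 0


@dataclass(frozen=True)
class KmerIndex:
    """Alphabetically ordered k-mer index of the reference.

    Every reference offset 1..L-k+1 appears exactly once across the position
    lists; lookup by exact k-mer string is O(1) via the backing dict.
    """

    k: int
    entries: tuple[tuple[str, tuple[int, ...]], ...]
    reference: ReferenceAmplicon

    @property
    def lookup(self) -> dict[str, tuple[int, ...]]:
        return dict(self.entries)


def build_index(reference: ReferenceAmplicon, k: int = 11) -> KmerIndex:
    """Index the reference by its overlapping k-mers (1-based start positions)."""
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if k > len(reference):
        raise ValidationError(
            f"k={k} exceeds reference length {len(reference)}"
        )
    seq = reference.sequence
    positions: dict[str, list[int]] = {}
    for start in range(len(seq) - k + 1):
        positions.setdefault(seq[start : start + k], []).append(start + 1)
    entries = tuple(
        (kmer, tuple(starts)) for kmer, starts in sorted(positions.items())
    )
    return KmerIndex(k=k, entries=entries, reference=reference)


def _compat_grid(
    read_codes: np.ndarray, ref_codes: np.ndarray, matrix: SubstitutionMatrix
) -> np.ndarray:
    """Boolean (len(read), len(ref)) grid of +1 pairings; non-ACGT never match."""
    comp = np.zeros((256, 256), dtype=bool)
    comp[:4, :4] = matrix.compatible
    return comp[read_codes[:, None], ref_codes[None, :]]


def seed_matches(
    read: str, index: KmerIndex, matrix: SubstitutionMatrix | None = None
) -> list[tuple[int, int]]:
    """All (read k-mer start, reference k-mer start) seed pairs, 1-based.

    A seed is a k-length window pairing that scores +k under the matrix,
    i.e. every position is a compatible pairing.  This deamination-
    compatible seeding (rather than literal string equality) is what lets
    heavily converted reads, which may contain no exact k-mer of the
    reference, still be found.  Pairs are returned in lexicographic
    (read_offset, reference_offset) order.
    """
    matrix = matrix or SubstitutionMatrix.default()
    k = index.k
    if len(read) < k:
        return []
    grid = _compat_grid(encode(read), encode(index.reference.sequence), matrix)
    n_read, n_ref = grid.shape
    out: list[tuple[int, int]] = []
    for i in range(n_read - k + 1):
        # window of rows i..i+k-1; a seed at (i, j) needs the k-diagonal true
        window = grid[i : i + k]
        diag = np.ones(n_ref - k + 1, dtype=bool)
        for t in range(k):
            diag &= window[t, t : t + n_ref - k + 1]
        for j in np.nonzero(diag)[0]:
            out.append((i + 1, int(j) + 1))
    return out


@dataclass
class AlignedRead:
    """A read that survived the perfect-score and anchor filters."""

    read_id: str
    umi: str | None
    reference_start: int  # 1-based; == 1 after the anchor filter
    aligned_bases: str  # read bases in reference coordinates
    score: int


@dataclass
class Rejection:
    """Why a read was discarded: 'score', 'anchor', 'coverage', 'no_seed' or 'N'."""

    read_id: str
    reason: str
    umi: str | None = None


@dataclass
class AlignedReadSet:
    """Accepted reads plus the filter funnel accounting.

    ``stats`` counts: input >= seeded >= score_ok >= accepted, plus the
    rejection reasons; accepted + rejections sum back to the input count.
    """

    reference: ReferenceAmplicon
    reads: list[AlignedRead]
    rejections: list[Rejection] = field(default_factory=list)
    stats: dict[str, int] = field(default_factory=dict)

    @property
    def n_reads(self) -> int:
        return len(self.reads)


def _evaluate_read(
    read: StructuredRead,
    ref_codes: np.ndarray,
    index: KmerIndex,
    matrix: SubstitutionMatrix,
    window_end: int,
) -> AlignedRead | Rejection:
    """Full seed-and-extend decision for one read (general path)."""
    if "N" in read.insert:
        return Rejection(read.read_id, "N", read.umi)
    seeds = seed_matches(read.insert, index, matrix)
    if not seeds:
        return Rejection(read.read_id, "no_seed", read.umi)
    length = len(read.insert)
    n_ref = len(ref_codes)
    read_codes = encode(read.insert)
    saw_anchor_fail = False
    saw_coverage_fail = False
    seen_diagonals: set[int] = set()
    for read_off, ref_off in seeds:
        start = ref_off - read_off + 1  # implied 1-based reference start
        if start in seen_diagonals:
            continue
        seen_diagonals.add(start)
        if start < 1 or start + length - 1 > n_ref:
            saw_coverage_fail = True  # extension runs off the reference
            continue
        segment = ref_codes[start - 1 : start - 1 + length]
        n_compatible = int(
            (matrix.compatible[read_codes, segment]).sum()
        )
        score = 2 * n_compatible - length
        if score != length:
            continue  # a -1 pairing somewhere: perfect-score filter fails
        if start != 1:
            saw_anchor_fail = True
            continue
        if length < window_end:
            saw_coverage_fail = True  # does not span the evaluation window
            continue
        return AlignedRead(
            read_id=read.read_id,
            umi=read.umi,
            reference_start=1,
            aligned_bases=read.insert,
            score=score,
        )
    if saw_coverage_fail and not saw_anchor_fail:
        return Rejection(read.read_id, "coverage", read.umi)
    if saw_anchor_fail:
        return Rejection(read.read_id, "anchor", read.umi)
    return Rejection(read.read_id, "score", read.umi)


def extend_and_score(
    read: StructuredRead,
    seed: tuple[int, int],
    reference: ReferenceAmplicon,
    matrix: SubstitutionMatrix | None = None,
    window_end: int | None = None,
) -> AlignedRead | Rejection:
    """Gapless extension of a single seed to the whole read.

    Accepts only if the total score equals the read length, the implied
    reference start is 1, and the read spans the evaluation window
    (default: the full reference); otherwise returns a :class:`Rejection`
    whose reason names the first failed filter.
    """
    matrix = matrix or SubstitutionMatrix.default()
    window_end = window_end or len(reference)
    read_off, ref_off = seed
    start = ref_off - read_off + 1
    length = len(read.insert)
    ref_codes = encode(reference.sequence)
    if start < 1 or start + length - 1 > len(reference):
        return Rejection(read.read_id, "coverage", read.umi)
    segment = ref_codes[start - 1 : start - 1 + length]
    read_codes = encode(read.insert)
    score = int(
        np.where(
            (read_codes < 4),
            np.where(matrix.compatible[np.minimum(read_codes, 3), segment], 1, -1),
            -1,
        ).sum()
    )
    if score != length:
        return Rejection(read.read_id, "score", read.umi)
    if start != 1:
        return Rejection(read.read_id, "anchor", read.umi)
    if length < window_end:
        return Rejection(read.read_id, "coverage", read.umi)
    return AlignedRead(read.read_id, read.umi, 1, read.insert, score)


def align_all(
    reads: Iterable[StructuredRead],
    reference: ReferenceAmplicon,
    k: int = 11,
    matrix: SubstitutionMatrix | None = None,
    window_end: int | None = None,
) -> AlignedReadSet:
    """Seed-and-extend every read and apply the retention filters.

    Deterministic given input order; each read contributes at most one
    alignment (first accepted seed in lexicographic order -- with the anchor
    filter at most one placement can survive anyway).

    Reads whose length equals the evaluation window take a vectorised
    short-cut (a full-length read is accepted iff its diagonal-0 pairing is
    compatible everywhere, which is exactly the seed+extend outcome for
    k <= read length); the remainder go through the per-read general path
    so rejection reasons are precise.
    """
    matrix = matrix or SubstitutionMatrix.default()
    window_end = window_end or len(reference)
    index = build_index(reference, k=k)
    ref_codes = encode(reference.sequence)
    reads = list(reads)

    accepted: dict[int, AlignedRead] = {}
    rejections: dict[int, Rejection] = {}

    full = [
        i
        for i, r in enumerate(reads)
        if len(r.insert) == window_end == len(reference) and "N" not in r.insert
    ]
    if full:
        block = np.empty((len(full), len(reference)), dtype=np.uint8)
        for row, i in enumerate(full):
            block[row] = encode(reads[i].insert)
        ok = matrix.compatible[block, ref_codes[None, :]].all(axis=1)
        for row, i in enumerate(full):
            if ok[row]:
                r = reads[i]
                accepted[i] = AlignedRead(r.read_id, r.umi, 1, r.insert, len(r.insert))

    for i, read in enumerate(reads):
        if i in accepted:
            continue
        result = _evaluate_read(read, ref_codes, index, matrix, window_end)
        if isinstance(result, AlignedRead):
            accepted[i] = result
        else:
            rejections[i] = result

    reasons = [rejections[i].reason for i in rejections]
    n_input = len(reads)
    n_unseeded = reasons.count("no_seed") + reasons.count("N")
    n_score_fail = reasons.count("score")
    n_anchor_fail = reasons.count("anchor")
    n_coverage_fail = reasons.count("coverage")
    stats = {
        "input": n_input,
        "seeded": n_input - n_unseeded,
        "score_ok": n_input - n_unseeded - n_score_fail,
        "accepted": len(accepted),
        "rejected_score": n_score_fail,
        "rejected_anchor": n_anchor_fail,
        "rejected_coverage": n_coverage_fail,
        "rejected_no_seed": n_unseeded,
    }
    return AlignedReadSet(
        reference=reference,
        reads=[accepted[i] for i in sorted(accepted)],
        rejections=[rejections[i] for i in sorted(rejections)],
        stats=stats,
    )


def decisions_table(aligned: AlignedReadSet) -> pd.DataFrame:
    """Per-read decision table (read_id, umi, start, score, reason)."""
    rows = []
    for r in aligned.reads:
        rows.append((r.read_id, r.umi, r.reference_start, r.score, "accepted"))
    for rej in aligned.rejections:
        rows.append((rej.read_id, rej.umi, None, None, rej.reason))
    return pd.DataFrame(
        rows, columns=["read_id", "umi", "start", "score", "reason"]
    )


def write_sam(aligned: AlignedReadSet, path: str | Path) -> None:
    """Render accepted reads as ungapped SAM records for standard viewers."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": aligned.reference.name, "LN": len(aligned.reference)}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read in aligned.reads:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = read.read_id
            rec.query_sequence = read.aligned_bases
            rec.reference_id = 0
            rec.reference_start = read.reference_start - 1
            rec.cigarstring = f"{len(read.aligned_bases)}M"
            rec.mapping_quality = 60
            rec.flag = 0
            if read.umi:
                rec.set_tag("RX", read.umi)
            rec.set_tag("AS", read.score)
            out.write(rec)
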