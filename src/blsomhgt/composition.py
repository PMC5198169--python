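"""Degenerate k-mer composition of genome windows.

A genome signature here is the frequency vector of *degenerate sets* of
k-mers: every k-mer is pooled with its reverse complement (e.g. ATGC with
GCAT), so the signature is independent of which strand was sequenced.  For
k = 4 this collapses the 256 tetranucleotides onto 136 dimensions (16 of the
tetranucleotides are their own reverse complement and form singleton sets).

Sequences are cut either into sliding windows (for querying a trained map)
or into non-overlapping fragments (for training).  Windows whose undetermined
base (N) content exceeds 10% of the window size are omitted; otherwise k-mer
counts are taken over the N-free k-mer positions only and normalised so the
vector sums to one.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger("blsomhgt")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: IUPAC ambiguity codes other than N; converted to N on sanitisation.
_IUPAC_AMBIGUOUS = set("RYSWKMBDHV")

# base encoding used throughout: A=0 C=1 G=2 T=3, N (or any ambiguity)=4
_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGTN"):
    _BASE_CODE[ord(_b)] = _i


class SourceClass(str, Enum):
    """Origin of a training sequence: the genome under scrutiny or a reference."""

    HOST = "host"
    REFERENCE = "reference"


class OmitReason(str, Enum):
    TOO_MANY_N = "too_many_n"          # N count exceeds the allowed fraction
    NO_VALID_KMERS = "no_valid_kmers"  # N fraction fine but no N-free k-mer window


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def sanitize_sequence(seq: str, record_id: str = "?") -> str:
    """Upper-case a raw sequence and map IUPAC ambiguity codes to N.

    Soft-masked (lower-case) stretches are kept; characters outside the IUPAC
    nucleotide alphabet raise ``ValueError``.
    """
    s = seq.upper()
    bad = set(s) - set("ACGTN")
    ambiguous = bad & _IUPAC_AMBIGUOUS
    if bad - _IUPAC_AMBIGUOUS:
        raise ValueError(
            f"record {record_id!r}: invalid sequence characters "
            f"{sorted(bad - _IUPAC_AMBIGUOUS)}"
        )
    if ambiguous:
        logger.warning(
            "record %r: %d ambiguity-code bases (%s) converted to N",
            record_id,
            sum(s.count(c) for c in ambiguous),
            "".join(sorted(ambiguous)),
        )
        s = s.translate(str.maketrans({c: "N" for c in ambiguous}))
    return s


@dataclass
class SequenceRecord:
    """A named DNA sequence with its role in the analysis.

    Reference records must carry a phylum; the genus may be absent when the
    source taxonomy resolves only to a coarser rank.
    """

    id: str
    sequence: str
    source_class: SourceClass = SourceClass.HOST
    phylum: Optional[str] = None
    genus: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.source_class == SourceClass.REFERENCE and not self.phylum:
            raise ValueError(f"reference record {self.id!r} lacks a phylum")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DegenerateKmerIndex:
    """Mapping from the 4^k k-mers onto reverse-complement-collapsed dimensions.

    Dimension order is the lexicographic order of the canonical (lexicographically
    smaller) member of each reverse-complement pair.  ``code_to_dim`` is the same
    map keyed by the base-4 integer encoding of a k-mer (A=0, C=1, G=2, T=3),
    used for vectorised counting.
    """

    k: int
    dim: int
    kmer_to_dim: dict[str, int]
    class_labels: tuple[str, ...]
    code_to_dim: np.ndarray = field(repr=False, compare=False)


def build_index(k: int) -> DegenerateKmerIndex:
    """Enumerate all 4^k k-mers and collapse reverse-complement pairs.

    The resulting dimensionality is (4^k + 4^(k/2))/2 for even k (rc-palindromes
    exist only at even k) and 4^k/2 for odd k; k=4 gives the 136-dimensional
    degenerate tetranucleotide set.
    """
    if not isinstance(k, int) or not 1 <= k <= 8:
        raise ValueError(f"k must be an integer in [1, 8], got {k!r}")
    canonicals = sorted(
        {min(m, revcomp(m)) for m in ("".join(p) for p in itertools.product("ACGT", repeat=k))}
    )
    dim_of = {m: d for d, m in enumerate(canonicals)}
    kmer_to_dim = {}
    for m in ("".join(p) for p in itertools.product("ACGT", repeat=k)):
        kmer_to_dim[m] = dim_of[min(m, revcomp(m))]
    code_to_dim = np.empty(4 ** k, dtype=np.int64)
    powers = [4 ** (k - 1 - t) for t in range(k)]
    base = {"A": 0, "C": 1, "G": 2, "T": 3}
    for m, d in kmer_to_dim.items():
        code_to_dim[sum(base[c] * p for c, p in zip(m, powers))] = d
    return DegenerateKmerIndex(
        k=k,
        dim=len(canonicals),
        kmer_to_dim=kmer_to_dim,
        class_labels=tuple(canonicals),
        code_to_dim=code_to_dim,
    )


@dataclass
class Segment:
    """A windowed slice of a contig with its composition vector.

    Coordinates are 0-based half-open.  ``composition`` is None when the
    segment is omitted (N policy) and a unit-sum frequency vector otherwise.
    """

    contig_id: str
    start: int
    end: int
    n_count: int
    composition: Optional[np.ndarray]
    omitted: bool
    omit_reason: Optional[OmitReason] = None


def _encode(seq: str) -> np.ndarray:
    arr = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        raise ValueError("sequence contains characters outside {A,C,G,T,N}")
    return arr


def _kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 code of every k-mer position and a validity mask (no N in window)."""
    if len(arr) < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(arr, k)
    valid = (win < 4).all(axis=1)
    codes = np.zeros(len(win), dtype=np.int64)
    for t in range(k):
        codes = codes * 4 + np.where(valid, win[:, t], 0)
    return codes, valid


def _counts_from_codes(
    codes: np.ndarray, valid: np.ndarray, index: DegenerateKmerIndex
) -> tuple[np.ndarray, int]:
    v = codes[valid]
    counts = np.bincount(index.code_to_dim[v], minlength=index.dim).astype(np.float64)
    return counts, int(valid.sum())


def composition_vector(
    seq: str,
    index: DegenerateKmerIndex,
    window: int,
    n_fraction_max: float = 0.10,
) -> tuple[Optional[np.ndarray], int, bool, Optional[OmitReason]]:
    """Degenerate k-mer frequencies of one window.

    Returns ``(vector, n_count, omitted, reason)``.  Any k-mer position
    containing an N contributes nothing; the count vector is normalised by the
    number of N-free k-mer positions ("length without Ns"), so non-omitted
    vectors sum to one.  A window whose N count exceeds ``n_fraction_max`` of
    its length is omitted, as is the degenerate case of no valid k-mer
    position at all.
    """
    if len(seq) != window:
        raise ValueError(f"expected a sequence of length {window}, got {len(seq)}")
    arr = _encode(seq)
    n_count = int((arr == 4).sum())
    if n_count > n_fraction_max * window:
        return None, n_count, True, OmitReason.TOO_MANY_N
    codes, valid = _kmer_codes(arr, index.k)
    counts, n_valid = _counts_from_codes(codes, valid, index)
    if n_valid == 0:
        return None, n_count, True, OmitReason.NO_VALID_KMERS
    return counts / n_valid, n_count, False, None


def _segments_from_starts(
    record: SequenceRecord,
    starts: Sequence[int],
    window: int,
    index: DegenerateKmerIndex,
    n_fraction_max: float,
) -> list[Segment]:
    arr = _encode(record.sequence)
    codes, valid = _kmer_codes(arr, index.k)
    is_n = arr == 4
    ncum = np.concatenate([[0], np.cumsum(is_n)])
    out: list[Segment] = []
    for s in starts:
        e = s + window
        n_count = int(ncum[e] - ncum[s])
        if n_count > n_fraction_max * window:
            out.append(Segment(record.id, s, e, n_count, None, True, OmitReason.TOO_MANY_N))
            continue
        sl = slice(s, e - index.k + 1)
        counts, n_valid = _counts_from_codes(codes[sl], valid[sl], index)
        if n_valid == 0:
            out.append(Segment(record.id, s, e, n_count, None, True, OmitReason.NO_VALID_KMERS))
        else:
            out.append(Segment(record.id, s, e, n_count, counts / n_valid, False))
    return out


def segment_sliding(
    record: SequenceRecord,
    index: DegenerateKmerIndex,
    window: int = 5000,
    step: int = 1000,
    n_fraction_max: float = 0.10,
) -> list[Segment]:
    """Sliding windows over a contig: starts 0, step, 2·step, …

    The trailing residue shorter than ``window`` is dropped; a contig shorter
    than one window yields no segments.  Segment count is
    floor((L − window)/step) + 1 for L ≥ window.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    L = len(record)
    if L < window:
        return []
    starts = range(0, step * ((L - window) // step) + 1, step)
    return _segments_from_starts(record, starts, window, index, n_fraction_max)


def fragment_training(
    record: SequenceRecord,
    index: DegenerateKmerIndex,
    fragment: int = 5000,
    min_total: int = 0,
    n_fraction_max: float = 0.10,
) -> list[Segment]:
    """Non-overlapping training fragments of exactly ``fragment`` bp.

    Records whose total length is below ``min_total`` (e.g. the 10 kb minimum
    applied to reference genomes) are excluded entirely.  Training fragments
    do not overlap so no part of a genome is double-weighted during map
    construction.
    """
    if fragment <= 0:
        raise ValueError("fragment size must be positive")
    if len(record) < max(min_total, fragment):
        return []
    starts = range(0, (len(record) // fragment) * fragment, fragment)
    return _segments_from_starts(record, starts, fragment, index, n_fraction_max)


def composition_matrix(segments: Sequence[Segment]) -> np.ndarray:
    """Stack the composition vectors of non-omitted segments into one matrix."""
    rows = [s.composition for s in segments if not s.omitted]
    if not rows:
        return np.empty((0, 0))
    return np.vstack(rows)
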