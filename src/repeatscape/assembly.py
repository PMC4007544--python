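"""Greedy overlap-layout-consensus assembly and the split-assemble-merge strategy.

The assembler repeatedly merges the highest-scoring pair of overlapping
sequences (exact k-mer seeded, ungapped verification with mismatches allowed)
until no pair satisfies the overlap-length and identity cutoffs; the
consensus is a per-column majority over all constituent reads. It is a
deliberately simple stand-in for production assemblers — the property of
interest downstream is the effect of splitting a read set into subpackages
before assembly, which lowers per-package coverage of single-copy DNA (those
reads stay short singletons and are dropped) while repeat-derived reads still
assemble, so the retained contigs are enriched for redundant sequence.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .simulate import ReadSet

_KMER = 12
_MAX_KMER_OCC = 40  # partners per seed k-mer considered (repeat-seed damping)
_MAX_PARTNERS = 60  # partner contigs evaluated per newly created contig


@dataclass
class Contig:
    id: str
    sequence: str
    n_reads: int

    def __len__(self) -> int:
        return len(self.sequence)


class _Work:
    """A live assembly node: per-column base counts over constituent reads."""

    __slots__ = ("uid", "counts", "n_reads", "codes")

    def __init__(self, uid: int, counts: np.ndarray, n_reads: int):
        self.uid = uid
        self.counts = counts
        self.n_reads = n_reads
        # majority consensus; np.argmax tie-breaks to the first (A<C<G<T)
        self.codes = counts.argmax(axis=1).astype(np.uint8)

    def __len__(self) -> int:
        return len(self.codes)


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.zeros(arr.shape, dtype=np.uint8)
    for code, base in enumerate(b"ACGT"):
        out[arr == base] = code
    return out


def _decode(codes: np.ndarray) -> str:
    return np.frombuffer(b"ACGT", dtype=np.uint8)[codes].tobytes().decode()


def _rc_counts(counts: np.ndarray) -> np.ndarray:
    return counts[::-1, ::-1]


def _best_overlap(a: np.ndarray, b: np.ndarray, min_overlap: int, min_identity: float):
    """Best ungapped overlap between code arrays a and b (b in both strands).

    Returns (score=matches, diag, rc_flag) or None. ``diag`` is the start of b
    on a's coordinates (may be negative; containment allowed).
    """
    best = None
    for rc_flag, bb in ((0, b), (1, (3 - b)[::-1])):
        diags = set()
        k = min(_KMER, min_overlap)
        pos_a: dict[bytes, int] = {}
        ab = a.tobytes()
        bbb = bb.tobytes()
        for i in range(0, len(a) - k + 1):
            pos_a.setdefault(ab[i : i + k], i)
        for j in range(0, len(bb) - k + 1):
            i = pos_a.get(bbb[j : j + k])
            if i is not None:
                diags.add(i - j)
        for diag in diags:
            start = max(0, diag)
            end = min(len(a), diag + len(bb))
            ov = end - start
            if ov < min_overlap:
                continue
            matches = int(np.count_nonzero(a[start:end] == bb[start - diag : end - diag]))
            if matches / ov < min_identity:
                continue
            if best is None or matches > best[0]:
                best = (matches, diag, rc_flag)
    return best


def _onehot(codes: np.ndarray) -> np.ndarray:
    counts = np.zeros((len(codes), 4), dtype=np.int32)
    counts[np.arange(len(codes)), codes] = 1
    return counts


def _merge(a: _Work, b: _Work, diag: int, rc_flag: int, uid: int) -> _Work:
    counts_b = _rc_counts(b.counts) if rc_flag else b.counts
    shift = -min(0, diag)
    new_len = max(len(a), diag + len(b.codes)) + shift
    counts = np.zeros((new_len, 4), dtype=np.int32)
    counts[shift : shift + len(a)] += a.counts
    counts[shift + diag : shift + diag + len(b.codes)] += counts_b
    if rc_flag and len(b) > len(a):
        counts = _rc_counts(counts)  # adopt the longer partner's orientation
    return _Work(uid, counts, a.n_reads + b.n_reads)


def _input_works(reads) -> list[_Work]:
    if isinstance(reads, ReadSet):
        seqs = reads.sequences
        counts = [1] * len(seqs)
    else:
        seqs, counts = [], []
        for item in reads:
            if isinstance(item, Contig):
                seqs.append(item.sequence)
                counts.append(item.n_reads)
            else:
                seqs.append(str(item))
                counts.append(1)
    return [_Work(i, _onehot(_encode(s)), n) for i, (s, n) in enumerate(zip(seqs, counts))]


def greedy_assemble(reads, min_overlap: int = 40, min_identity: float = 0.9) -> list[Contig]:
    """Greedy OLC assembly; unmerged inputs come back as singleton contigs.

    Iteratively merges the highest-scoring overlapping pair (score = matching
    columns in the ungapped overlap); ties break on the smallest contig-id
    pair, which keeps runs reproducible. Total constituent reads are conserved
    across the output.
    """
    works = _input_works(reads)
    if not works:
        return []
    alive: dict[int, _Work] = {w.uid: w for w in works}
    next_uid = len(works)
    k = min(_KMER, min_overlap)

    index: dict[bytes, list[int]] = {}
    heap: list[tuple[int, int, int, int, int]] = []  # (-score, idA, idB, diag, rc)

    def push_candidates(w: _Work) -> None:
        partners: list[int] = []
        seen = set()
        buf = w.codes.tobytes()
        rc_buf = (3 - w.codes)[::-1].tobytes()
        for buffer in (buf, rc_buf):
            for i in range(0, len(buffer) - k + 1):
                for uid in index.get(buffer[i : i + k], ()):
                    if uid not in seen and uid in alive and uid != w.uid:
                        seen.add(uid)
                        partners.append(uid)
                        if len(partners) >= _MAX_PARTNERS:
                            break
                if len(partners) >= _MAX_PARTNERS:
                    break
            if len(partners) >= _MAX_PARTNERS:
                break
        for uid in partners:
            other = alive[uid]
            hit = _best_overlap(other.codes, w.codes, min_overlap, min_identity)
            if hit is not None:
                score, diag, rc_flag = hit
                lo, hi = min(uid, w.uid), max(uid, w.uid)
                # store relative to the pair (other=a, w=b) regardless of order
                heapq.heappush(heap, (-score, lo, hi, diag, rc_flag, uid, w.uid))

    def add_to_index(w: _Work) -> None:
        buf = w.codes.tobytes()
        seen_here = set()
        for i in range(0, len(buf) - k + 1):
            kmer = buf[i : i + k]
            if kmer in seen_here:
                continue
            seen_here.add(kmer)
            occ = index.setdefault(kmer, [])
            if len(occ) < _MAX_KMER_OCC:
                occ.append(w.uid)

    for w in works:
        push_candidates(w)
        add_to_index(w)

    while heap:
        neg_score, _lo, _hi, diag, rc_flag, uid_a, uid_b = heapq.heappop(heap)
        if uid_a not in alive or uid_b not in alive:
            continue
        a, b = alive.pop(uid_a), alive.pop(uid_b)
        merged = _merge(a, b, diag, rc_flag, next_uid)
        next_uid += 1
        alive[merged.uid] = merged
        push_candidates(merged)
        add_to_index(merged)

    return [
        Contig(id=f"contig_{i:06d}", sequence=_decode(w.codes), n_reads=w.n_reads)
        for i, w in enumerate(alive.values())
    ]


def split_assemble_merge(
    reads: ReadSet,
    n_splits: int = 1,
    min_overlap: int = 40,
    min_identity: float = 0.9,
    merge_min_identity: float = 0.8,
    singleton_min_length: int = 1000,
    seed: int = 0,
) -> list[Contig]:
    """Split reads into subpackages, assemble each, merge across packages.

    Reads are partitioned uniformly at random into ``n_splits`` subpackages,
    each assembled at ``min_identity``. Only the assembled contigs of each
    package (plus singletons of at least ``singleton_min_length`` nt) enter
    the cross-package merge, a second greedy pass at the laxer
    ``merge_min_identity``: reads a subpackage could not assemble are
    dropped, which is what enriches high-split assemblies for redundant
    sequence — subpackage coverage of single-copy DNA is too thin to
    overlap, while repeat-derived reads still pile up. Set the threshold to
    0 to keep every singleton (full read conservation).
    """
    n = len(reads.sequences)
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    if n_splits > n:
        raise ValueError(f"n_splits={n_splits} exceeds the number of reads ({n})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    packages = np.array_split(order, n_splits)

    pooled: list[Contig] = []
    for pkg in packages:
        sub = [reads.sequences[i] for i in pkg]
        pooled.extend(
            c
            for c in greedy_assemble(sub, min_overlap, min_identity)
            if c.n_reads > 1 or len(c.sequence) >= singleton_min_length
        )

    merged = greedy_assemble(pooled, min_overlap, merge_min_identity)
    kept = [
        c
        for c in merged
        if c.n_reads > 1 or len(c.sequence) >= singleton_min_length
    ]
    return [
        Contig(id=f"contig_{i:06d}", sequence=c.sequence, n_reads=c.n_reads)
        for i, c in enumerate(kept)
    ]
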