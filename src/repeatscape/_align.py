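"""Low-level alignment helpers shared by the mapper, the assembler and the annotators.

All pairwise alignment is edit-distance based (edlib); callers rescore the
resulting operation counts with their own cost schemes where needed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib
import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

BASES = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}


def revcomp(seq: str) -> str:
    """Reverse complement (A<->T, C<->G; N self)."""
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode A,C,G,T as 0..3 (anything else 4) in a uint8 array."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.uint8)
    for base, code in _BASE_TO_CODE.items():
        out[arr == ord(base)] = code
    return out


def codes_to_seq(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Parse an extended CIGAR string ('=', 'X', 'I', 'D') into (count, op) runs.

    'I' consumes query, 'D' consumes target (SAM read-vs-reference convention).
    """
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


@dataclass
class InfixHit:
    """Best placement of a query inside a target, with clipping bookkeeping.

    Terminal insertion runs (query bases hanging off the aligned block, e.g. a
    read overhanging a contig end) are trimmed off and counted as clipped.
    """

    target_start: int  # 0-based, half-open on the target, after trimming
    target_end: int
    matches: int
    mismatches: int
    insertions: int  # query-only bases inside the aligned block
    deletions: int  # target-only bases inside the aligned block
    clipped: int  # query bases trimmed at either end
    edit_distance: int
    #: all equally good raw placements (half-open target spans); the trimmed
    #: stats above describe the first one
    locations: tuple[tuple[int, int], ...] = ()

    @property
    def alignment_columns(self) -> int:
        return self.matches + self.mismatches + self.insertions + self.deletions

    @property
    def identity(self) -> float:
        cols = self.alignment_columns
        return self.matches / cols if cols else 0.0

    @property
    def aligned_query_bases(self) -> int:
        return self.matches + self.mismatches + self.insertions

    @property
    def aligned_target_bases(self) -> int:
        return self.matches + self.mismatches + self.deletions


def infix_align(query: str, target: str, max_edits: int = -1) -> InfixHit | None:
    """Best infix (query-inside-target) alignment, or None beyond ``max_edits``.

    The whole query participates; leading/trailing query-insertion runs are
    trimmed and reported as ``clipped`` so callers can apply a
    length-fraction acceptance rule.
    """
    res = edlib.align(query, target, mode="HW", task="path", k=max_edits)
    if res["editDistance"] < 0:
        return None
    runs = parse_cigar(res["cigar"])
    tstart, tend = res["locations"][0]
    tend += 1  # edlib reports inclusive end

    lead_clip = trail_clip = 0
    # trim leading/trailing I runs (query overhang)
    while runs and runs[0][1] == "I":
        lead_clip += runs[0][0]
        runs.pop(0)
    while runs and runs[-1][1] == "I":
        trail_clip += runs[-1][0]
        runs.pop()
    counts = {"=": 0, "X": 0, "I": 0, "D": 0}
    for n, op in runs:
        counts[op] += n
    # a terminal edit can be emitted as an insertion even when target bases
    # are available next to the aligned block (1I and 1X cost the same);
    # extend gaplessly into the target so such bases count as columns, and
    # only true overhang beyond the target boundary remains clipped
    ext = min(lead_clip, tstart)
    if ext:
        for q, t in zip(query[lead_clip - ext : lead_clip], target[tstart - ext : tstart]):
            counts["=" if q == t else "X"] += 1
        tstart -= ext
        lead_clip -= ext
    ext = min(trail_clip, len(target) - tend)
    if ext:
        qoff = len(query) - trail_clip
        for q, t in zip(query[qoff : qoff + ext], target[tend : tend + ext]):
            counts["=" if q == t else "X"] += 1
        tend += ext
        trail_clip -= ext
    clipped = lead_clip + trail_clip
    return InfixHit(
        target_start=tstart,
        target_end=tend,
        matches=counts["="],
        mismatches=counts["X"],
        insertions=counts["I"],
        deletions=counts["D"],
        clipped=clipped,
        edit_distance=res["editDistance"],
        locations=tuple((s, e + 1) for s, e in res["locations"]),
    )


def global_identity(a: str, b: str) -> float:
    """Identity of the global (NW) alignment of two sequences."""
    res = edlib.align(a, b, mode="NW", task="distance")
    d = res["editDistance"]
    cols = max(len(a), len(b))  # lower bound on columns; exact for subs-only
    return 1.0 - d / cols if cols else 1.0


def hamming(a: str, b: str) -> int:
    """Hamming distance of two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming() requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))
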