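"""LTR-retrotransposon structure and the LTR : inter-LTR coverage ratio.

An intact element is LTR-internal-LTR. Because the genome holds two LTR
copies per intact insertion, the LTR sequence of a family should be covered
twice as deeply as its internal (inter-LTR) region: the expected
LTR:inter-LTR average-coverage ratio of a fully intact family is 2. Unequal
recombination leaves solo-LTRs behind, and S solo copies alongside N intact
elements raise the expectation to (2N+S)/N = 2 + S/N, so the ratio doubles
as an estimator of solo-LTR abundance; ratios below 2 instead point to
distinct families sharing (part of) the internal region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._align import revcomp

#: Families whose ratio sits within this band around 2 are called intact-dominated.
INTACT_RATIO_TOLERANCE = 0.25


# --------------------------------------------------------------------------
# Terminal direct-repeat (LTR) detection
# --------------------------------------------------------------------------


def _self_match_profile(seq: str, diag: int) -> np.ndarray:
    s = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    return s[:-diag] == s[diag:]


def find_ltrs(
    sequence: str,
    min_ltr_len: int = 100,
    min_identity: float = 0.85,
    terminal_slack: int = 50,
    kmer: int = 12,
) -> tuple[tuple[int, int], tuple[int, int]] | None:
    """Locate the two terminal direct repeats of a putative intact element.

    Works like scanning the off-diagonals of a self dot plot: exact k-mers
    shared between the two halves of the sequence vote for a lag; the best
    lag's matching run is extended outwards while overall identity stays
    above ``min_identity``. The repeat must be at least ``min_ltr_len`` long,
    non-overlapping, and anchored within ``terminal_slack`` of both termini.
    Returns ((ltr5_start, ltr5_end), (ltr3_start, ltr3_end)) half-open, or
    None (e.g. for a solo LTR, which has no second terminal copy).
    """
    seq = sequence.upper()
    L = len(seq)
    if L < 2 * min_ltr_len:
        raise ValueError("sequence shorter than two minimal LTRs")
    half = L // 2
    positions: dict[str, list[int]] = {}
    for i in range(0, half - kmer + 1):
        positions.setdefault(seq[i : i + kmer], []).append(i)
    votes: dict[int, int] = {}
    for j in range(half, L - kmer + 1):
        for i in positions.get(seq[j : j + kmer], ()):
            votes[j - i] = votes.get(j - i, 0) + 1

    best = None
    for diag in sorted(votes, key=lambda d: (-votes[d], d)):
        if diag < min_ltr_len:
            continue
        # positions i (0 <= i < L - diag) where seq[i] == seq[i + diag]; the
        # 5' LTR is a run of mostly-ones that starts near 0 and whose mate
        # (shifted by diag) ends near L
        window = _self_match_profile(seq, diag)
        if window.size < min_ltr_len:
            continue
        csum = np.concatenate(([0], np.cumsum(window)))

        def identity(a: int, b: int) -> float:
            return (csum[b] - csum[a]) / (b - a) if b > a else 0.0

        start, end = 0, window.size
        # trim mismatching edges, then shrink the worse edge until the
        # overall identity clears the cutoff
        while end - start > min_ltr_len and not window[start]:
            start += 1
        while end - start > min_ltr_len and not window[end - 1]:
            end -= 1
        while end - start > min_ltr_len and identity(start, end) < min_identity:
            if identity(start + 1, end) >= identity(start, end - 1):
                start += 1
            else:
                end -= 1
        length = end - start
        if length < min_ltr_len or identity(start, end) < min_identity:
            continue
        if start > terminal_slack:
            continue
        if start + diag + length < L - terminal_slack:
            continue
        if length > diag:  # the two repeats would overlap
            continue
        score = csum[end] - csum[start]
        if best is None or score > best[0]:
            best = (score, start, start + length, start + diag, start + diag + length)
    if best is None:
        return None
    _, s1, e1, s2, e2 = best
    return (int(s1), int(e1)), (int(s2), int(e2))


# --------------------------------------------------------------------------
# Coverage ratio
# --------------------------------------------------------------------------


@dataclass
class LTRElementModel:
    """An annotated element with its measured coverages and ratio statistic."""

    element_id: str
    superfamily: str = "unknown"
    ltr5: tuple[int, int] | None = None
    ltr3: tuple[int, int] | None = None
    inter: tuple[int, int] | None = None
    cov_ltr: float = float("nan")
    cov_inter: float = float("nan")
    ratio: float = float("nan")
    single_ltr_only: bool = False

    @classmethod
    def from_sequence(cls, element_id: str, sequence: str, superfamily: str = "unknown",
                      **find_kwargs) -> "LTRElementModel":
        hit = find_ltrs(sequence, **find_kwargs)
        if hit is None:
            return cls(element_id=element_id, superfamily=superfamily)
        (s1, e1), (s2, e2) = hit
        return cls(
            element_id=element_id,
            superfamily=superfamily,
            ltr5=(s1, e1),
            ltr3=(s2, e2),
            inter=(e1, s2),
        )


def ltr_inter_ltr_ratio(
    depth: np.ndarray,
    ltr5: tuple[int, int] | None,
    inter: tuple[int, int],
    ltr3: tuple[int, int] | None = None,
) -> tuple[float, float, float]:
    """LTR and inter-LTR average coverage and their ratio from per-base depth.

    Mapped bases falling in the LTR intervals are pooled and divided by the
    length of ONE LTR (the mean of the annotated LTR interval lengths): the
    two LTRs of an element are copies of a single genomic sequence family, so
    an intact-only family yields cov_ltr = 2 x cov_inter and ratio 2. Reads
    straddling an interval boundary contribute proportionally, by their
    overlapping bases. A zero inter-LTR coverage flags the ratio as infinite
    rather than raising.
    """
    intervals = [iv for iv in (ltr5, ltr3) if iv is not None]
    if not intervals:
        raise ValueError("at least one LTR interval is required")
    ltr_bases = float(sum(depth[s:e].sum() for s, e in intervals))
    one_ltr_len = float(np.mean([e - s for s, e in intervals]))
    if one_ltr_len <= 0:
        raise ValueError("empty LTR interval")
    s, e = inter
    if e <= s:
        raise ValueError("empty inter-LTR interval")
    cov_ltr = ltr_bases / one_ltr_len
    cov_inter = float(depth[s:e].sum()) / (e - s)
    ratio = cov_ltr / cov_inter if cov_inter > 0 else math.inf
    return cov_ltr, cov_inter, ratio


def measure_element(model: LTRElementModel, mapping, contig_id: str) -> LTRElementModel:
    """Fill an element model's coverages from a mapping onto its sequence."""
    if model.inter is None:
        raise ValueError(f"{model.element_id}: no annotated LTR/inter-LTR structure")
    depth = mapping.depth(contig_id)
    cov_ltr, cov_inter, ratio = ltr_inter_ltr_ratio(depth, model.ltr5, model.inter, model.ltr3)
    model.cov_ltr, model.cov_inter, model.ratio = cov_ltr, cov_inter, ratio
    model.single_ltr_only = (model.ltr5 is None) != (model.ltr3 is None)
    return model


# --------------------------------------------------------------------------
# Solo-LTR inference
# --------------------------------------------------------------------------

_CAVEAT = (
    "ratio-based inference assumes one shared internal region per family; "
    "families sharing LTRs but carrying different internal regions cannot be "
    "ruled out"
)


@dataclass
class SoloLTRInference:
    label: str  # solo-LTR excess | intact-dominated | shared internal region
    solo_per_intact: float  # estimated S/N (0 when not in excess)
    ratio: float
    caveat: str = _CAVEAT


def infer_solo_ltr(ratio: float, tolerance: float = INTACT_RATIO_TOLERANCE) -> SoloLTRInference:
    """Interpret an LTR:inter-LTR coverage ratio.

    Within ``tolerance`` of 2 the family looks intact-dominated (S/N = 0);
    above, the excess estimates S/N = ratio - 2 solo copies per intact
    element; below, the internal region is over-represented, pointing at
    families sharing inter-LTR sequence.
    """
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    if math.isinf(ratio):
        return SoloLTRInference("solo-LTR excess", math.inf, ratio)
    if abs(ratio - 2.0) <= tolerance:
        return SoloLTRInference("intact-dominated", 0.0, ratio)
    if ratio > 2.0:
        return SoloLTRInference("solo-LTR excess", ratio - 2.0, ratio)
    return SoloLTRInference("shared internal region", 0.0, ratio)


# --------------------------------------------------------------------------
# Reporting
# --------------------------------------------------------------------------


def superfamily_ratio_table(records) -> pd.DataFrame:
    """Per-cluster LTR:inter-LTR ratios with per-superfamily mean rows.

    ``records`` is an iterable of (superfamily, cluster_id, cov_ltr,
    cov_inter). Ratios are computed unrounded and the superfamily mean is the
    mean of those unrounded ratios; the returned frame carries both raw and
    3-decimal columns.
    """
    rows = []
    for superfamily, cluster, cov_ltr, cov_inter in records:
        ratio = cov_ltr / cov_inter if cov_inter > 0 else math.inf
        rows.append(
            {
                "superfamily": superfamily,
                "cluster": cluster,
                "cov_ltr": cov_ltr,
                "cov_inter": cov_inter,
                "ratio": ratio,
            }
        )
    df = pd.DataFrame(rows)
    out = []
    for superfamily, grp in df.groupby("superfamily", sort=False):
        out.append(grp)
        out.append(
            pd.DataFrame(
                [
                    {
                        "superfamily": superfamily,
                        "cluster": "mean",
                        "cov_ltr": float("nan"),
                        "cov_inter": float("nan"),
                        "ratio": grp["ratio"].mean(),
                    }
                ]
            )
        )
    table = pd.concat(out, ignore_index=True)
    table["ratio_3dp"] = table["ratio"].round(3)
    return table


def strand_flipped_intervals(hit, length: int):
    """Map ((s1,e1),(s2,e2)) through reverse complementation of the element."""
    (s1, e1), (s2, e2) = hit
    return (length - e2, length - s2), (length - e1, length - s1)


__all__ = [
    "find_ltrs",
    "ltr_inter_ltr_ratio",
    "measure_element",
    "infer_solo_ltr",
    "superfamily_ratio_table",
    "LTRElementModel",
    "SoloLTRInference",
    "strand_flipped_intervals",
    "revcomp",
    "INTACT_RATIO_TOLERANCE",
]
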