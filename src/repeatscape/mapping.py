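"""Seed-and-extend read mapping with random multiread assignment.

Reads are placed on contigs CLC-style: every contig sharing an exact seed
k-mer with the read (either strand) is evaluated by banded edit-distance
alignment; hits must cover at least ``length_fraction`` of the read at
``similarity`` identity or better; surviving hits are rescored with the
configured mismatch/indel costs and one of the minimum-cost hits is chosen
uniformly at random with a dedicated seeded generator, so that a read mapping
equally well to several repeat copies is distributed among them. Average
coverage of a contig is mapped bases over contig length — the redundancy
proxy used downstream.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._align import infix_align, revcomp
from .simulate import ReadSet


@dataclass(frozen=True)
class MappingParams:
    """CLC-style mapping stringency knobs.

    A read is accepted on a contig only if an alignment covers at least
    ``length_fraction`` of the read at identity >= ``similarity``. Costs are
    linear (per-event) and used to rank candidate hits.
    """

    mismatch_cost: int = 2
    deletion_cost: int = 3
    insertion_cost: int = 3
    length_fraction: float = 0.8
    similarity: float = 0.8
    kmer_size: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.length_fraction <= 1:
            raise ValueError("length_fraction must be in (0, 1]")
        if not 0 < self.similarity <= 1:
            raise ValueError("similarity must be in (0, 1]")
        if self.kmer_size < 4:
            raise ValueError("kmer_size too small")


#: Default parameter grid mirroring the calibration axes used against
#: sequences of known copy number.
DEFAULT_CALIBRATION_GRID = [
    MappingParams(
        mismatch_cost=mc,
        deletion_cost=ic,
        insertion_cost=ic,
        length_fraction=lf,
        similarity=sim,
    )
    for mc, ic, lf, sim in itertools.product(
        (2, 3), (2, 3), (0.5, 0.8, 1.0), (0.8, 0.9, 0.95)
    )
]


@dataclass
class MappingResult:
    """Per-contig and per-read outcome of one mapping run.

    Each read is assigned to at most one contig; ``intervals`` carries the
    target span of each placement so per-base depth can be reconstructed.
    """

    contig_ids: list[str]
    contig_lengths: dict[str, int]
    n_mapped_reads: dict[str, int]
    mapped_bases: dict[str, int]
    assignments: list[str | None]
    intervals: list[tuple[int, int] | None]
    params: MappingParams
    read_ids: list[str] = field(default_factory=list)

    @property
    def n_matched(self) -> int:
        return sum(1 for a in self.assignments if a is not None)

    @property
    def n_unmatched(self) -> int:
        return len(self.assignments) - self.n_matched

    def average_coverage(self, contig_id: str) -> float:
        if contig_id not in self.contig_lengths:
            raise KeyError(f"unknown contig id: {contig_id}")
        return self.mapped_bases.get(contig_id, 0) / self.contig_lengths[contig_id]

    def depth(self, contig_id: str) -> np.ndarray:
        """Per-base depth on one contig from the recorded placements."""
        if contig_id not in self.contig_lengths:
            raise KeyError(f"unknown contig id: {contig_id}")
        d = np.zeros(self.contig_lengths[contig_id] + 1, dtype=np.int64)
        for cid, iv in zip(self.assignments, self.intervals):
            if cid == contig_id and iv is not None:
                d[iv[0]] += 1
                d[iv[1]] -= 1
        return np.cumsum(d[:-1])

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "contig": cid,
                "length": self.contig_lengths[cid],
                "n_reads": self.n_mapped_reads.get(cid, 0),
                "mapped_bases": self.mapped_bases.get(cid, 0),
                "avg_coverage": self.average_coverage(cid),
            }
            for cid in self.contig_ids
        ]
        return pd.DataFrame(rows)


def _as_contig_dict(contigs) -> dict[str, str]:
    if isinstance(contigs, dict):
        return {str(k): v.upper() for k, v in contigs.items()}
    out = {}
    for item in contigs:
        if hasattr(item, "id") and hasattr(item, "sequence"):
            out[str(item.id)] = item.sequence.upper()
        else:
            cid, seq = item
            out[str(cid)] = seq.upper()
    return out


def _read_sequences(reads) -> list[str]:
    if isinstance(reads, ReadSet):
        return reads.sequences
    return list(reads)


def _edge_placements(read: str, target: str, params: MappingParams):
    """Clipped (ungapped) placements of a read hanging off a contig end.

    Edit-distance alignment cannot represent soft clipping, so reads
    straddling a contig terminus are handled explicitly: every suffix of the
    read against the contig start and every prefix against the contig end,
    accepting overlaps that satisfy the length-fraction and similarity rules.
    Yields (cost, tstart, tend) like the interior path.
    """
    L, T = len(read), len(target)
    min_l = max(1, int(np.ceil(params.length_fraction * L)))
    out = []
    for l in range(min_l, min(L, T)):
        # read suffix at contig start
        m = sum(a == b for a, b in zip(read[L - l :], target[:l]))
        if m / l >= params.similarity:
            out.append((params.mismatch_cost * (l - m), 0, l))
        # read prefix at contig end
        m = sum(a == b for a, b in zip(read[:l], target[T - l :]))
        if m / l >= params.similarity:
            out.append((params.mismatch_cost * (l - m), T - l, T))
    return out


def build_seed_index(contigs: dict[str, str], k: int) -> dict[str, list[int]]:
    """Exact k-mer -> list of contig indices (deduplicated, in input order)."""
    index: dict[str, list[int]] = {}
    for ci, seq in enumerate(contigs.values()):
        seen_here = set()
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if kmer in seen_here:
                continue
            seen_here.add(kmer)
            index.setdefault(kmer, []).append(ci)
    return index


def map_reads(reads, contigs, params: MappingParams | None = None) -> MappingResult:
    """Map a read set onto contigs; multireads are assigned randomly.

    For each read, candidate contigs are those sharing a seed k-mer with the
    read or its reverse complement; each candidate is aligned (infix,
    edit-distance band from the stringency settings), filtered on
    similarity/length-fraction, rescored with the mismatch/indel costs, and
    one minimum-cost hit is drawn with the mapping RNG.
    """
    params = params or MappingParams()
    contig_dict = _as_contig_dict(contigs)
    cids = list(contig_dict)
    seqs = list(contig_dict.values())
    sequences = _read_sequences(reads)
    rng = np.random.default_rng(params.seed)

    n_mapped = {cid: 0 for cid in cids}
    mapped_bases = {cid: 0 for cid in cids}
    assignments: list[str | None] = []
    intervals: list[tuple[int, int] | None] = []

    if not cids:
        n = len(sequences)
        return MappingResult(
            contig_ids=[], contig_lengths={}, n_mapped_reads={}, mapped_bases={},
            assignments=[None] * n, intervals=[None] * n, params=params,
        )

    k = params.kmer_size
    index = build_seed_index(contig_dict, k)

    for seq in sequences:
        L = len(seq)
        if L < k:
            assignments.append(None)
            intervals.append(None)
            continue
        rc = revcomp(seq)
        max_edits = (
            int(np.ceil(L * (1 - params.similarity)))
            + int(np.ceil(L * (1 - params.length_fraction)))
            + 1
        )
        # sample non-overlapping seed offsets across the read; remember which
        # orientation seeded each candidate so only that one is aligned
        offsets = range(0, L - k + 1, max(1, k))
        candidates: dict[int, set[str]] = {}
        for off in offsets:
            for oriented, tag in ((seq, "+"), (rc, "-")):
                for ci in index.get(oriented[off : off + k], ()):
                    candidates.setdefault(ci, set()).add(tag)

        best_cost = None
        best_hits: list[tuple[int, int, int]] = []  # (contig idx, tstart, tend)
        for ci, orients in candidates.items():
            target = seqs[ci]
            for oriented, tag in ((seq, "+"), (rc, "-")):
                if tag not in orients:
                    continue
                hit = infix_align(oriented, target, max_edits=max_edits)
                passed = (
                    hit is not None
                    and hit.identity >= params.similarity
                    and hit.aligned_query_bases >= params.length_fraction * L
                )
                cost = None
                placements: list[tuple[int, int, int]] = []
                if passed:
                    cost = (
                        params.mismatch_cost * hit.mismatches
                        + params.insertion_cost * hit.insertions
                        + params.deletion_cost * hit.deletions
                    )
                    placements = [(ci, s, e) for s, e in hit.locations] or [
                        (ci, hit.target_start, hit.target_end)
                    ]
                # a read straddling a contig terminus has a clipped placement
                # that edit-distance alignment cannot represent; a costly
                # interior hit may also just be a terminus read whose overhang
                # got absorbed as gapped noise, so compare against edge
                # placements whenever the interior hit is poor or absent
                if cost is None or cost > 2 * params.mismatch_cost:
                    edge = _edge_placements(oriented, target, params)
                    if edge:
                        edge_cost = min(c for c, _, _ in edge)
                        if cost is None or edge_cost < cost:
                            cost = edge_cost
                            placements = [(ci, s, e) for c, s, e in edge if c == edge_cost]
                        elif edge_cost == cost:
                            placements.extend(
                                (ci, s, e) for c, s, e in edge if c == edge_cost
                            )
                if cost is None:
                    continue
                if best_cost is None or cost < best_cost:
                    best_cost = cost
                    best_hits = placements
                elif cost == best_cost:
                    best_hits.extend(placements)
        if not best_hits:
            assignments.append(None)
            intervals.append(None)
            continue
        # a read matching both strands of the same contig equally well still
        # counts once per placement; draw uniformly among best placements
        choice = best_hits[rng.integers(len(best_hits))] if len(best_hits) > 1 else best_hits[0]
        ci, tstart, tend = choice
        cid = cids[ci]
        n_mapped[cid] += 1
        mapped_bases[cid] += tend - tstart
        assignments.append(cid)
        intervals.append((tstart, tend))

    read_ids = reads.read_ids() if isinstance(reads, ReadSet) else []
    return MappingResult(
        contig_ids=cids,
        contig_lengths={cid: len(s) for cid, s in contig_dict.items()},
        n_mapped_reads=n_mapped,
        mapped_bases=mapped_bases,
        assignments=assignments,
        intervals=intervals,
        params=params,
        read_ids=read_ids,
    )


def average_coverage(result: MappingResult, contig_id: str) -> float:
    """Mapped bases over contig length (per-base mean depth)."""
    return result.average_coverage(contig_id)


@dataclass
class CalibrationResult:
    """Outcome of a stringency sweep against known-copy-number references."""

    best_params: MappingParams
    table: pd.DataFrame  # one row per grid point with r and p-value
    stable: bool  # False when the best correlation is not significant


def calibrate_mapping(
    reads,
    references,
    known_copy_number: dict[str, float],
    params_grid: list[MappingParams] | None = None,
    alpha: float = 0.05,
) -> CalibrationResult:
    """Choose mapping stringency by correlating coverage with known copy number.

    For each grid point the reads are mapped to the reference sequences and
    the Pearson correlation between known copy number and average coverage is
    computed; the grid point with the largest r wins, ties going to the most
    stringent setting (highest similarity, then highest length fraction).
    """
    refs = _as_contig_dict(references)
    if len(refs) < 3:
        raise ValueError("calibration needs at least 3 reference sequences")
    missing = [r for r in refs if r not in known_copy_number]
    if missing:
        raise ValueError(f"no known copy number for: {', '.join(missing)}")
    copies = np.array([known_copy_number[r] for r in refs], dtype=float)
    if np.allclose(copies, copies[0]):
        raise ValueError("copy numbers have zero variance; correlation undefined")

    grid = params_grid or DEFAULT_CALIBRATION_GRID
    rows = []
    for params in grid:
        result = map_reads(reads, refs, params)
        cov = np.array([result.average_coverage(r) for r in refs])
        if np.allclose(cov, cov[0]):
            r, p = 0.0, 1.0
        else:
            r, p = stats.pearsonr(copies, cov)
        rows.append(
            {
                "mismatch_cost": params.mismatch_cost,
                "deletion_cost": params.deletion_cost,
                "insertion_cost": params.insertion_cost,
                "length_fraction": params.length_fraction,
                "similarity": params.similarity,
                "pearson_r": r,
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows)
    order = table.sort_values(
        ["pearson_r", "similarity", "length_fraction"], ascending=[False, False, False]
    )
    best_row = order.iloc[0]
    best = replace(
        grid[0],
        mismatch_cost=int(best_row.mismatch_cost),
        deletion_cost=int(best_row.deletion_cost),
        insertion_cost=int(best_row.insertion_cost),
        length_fraction=float(best_row.length_fraction),
        similarity=float(best_row.similarity),
    )
    return CalibrationResult(
        best_params=best, table=table, stable=bool(best_row.p_value < alpha)
    )
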