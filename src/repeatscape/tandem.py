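"""Satellite (tandem repeat) analysis: periodicity, consensus, monomer
extraction, GC content, nucleotide diversity and a neighbor-joining tree.

The workflow mirrors how satellite families are characterised from shotgun
reads: detect the repeat period, build a family consensus, pull one monomer
per read (the best-matching repeat copy, so every monomer represents a
distinct genomic locus), align the monomers to the consensus, and summarise
within-family variability as nucleotide diversity pi — the average number of
pairwise nucleotide differences per site — with its sampling standard
deviation. Families are compared with a distance (p-distance) NJ tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import edlib
import numpy as np
from scipy.optimize import brentq
from skbio import DistanceMatrix
from skbio.tree import TreeNode
from skbio.tree import nj as _skbio_nj

from ._align import infix_align, parse_cigar, revcomp
from .simulate import ReadSet

GAP = 4  # gap code in alignment matrices (bases are 0..3)


# --------------------------------------------------------------------------
# Elementary statistics
# --------------------------------------------------------------------------


def gc_content(sequence: str) -> float:
    """(G+C) / (A+C+G+T); non-ACGT symbols excluded from both counts."""
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        raise ValueError("sequence has no unambiguous bases")
    return gc / (gc + at)


def detect_period(
    sequence: str,
    min_period: int = 2,
    max_period: int = 500,
    match_threshold: float = 0.8,
) -> int | None:
    """Smallest lag at which the sequence matches itself above a threshold.

    The self-match fraction at lag p (fraction of positions i with
    base(i) == base(i+p)) is the 1-D analogue of the diagonals of a dot plot;
    a true tandem unit produces a peak at its length and at every multiple,
    so the smallest qualifying lag is the unit length. Lags are limited to
    half the sequence so at least two full units support the call. Returns
    None when no lag qualifies (e.g. non-repetitive sequence, where the
    expected fraction is ~0.25).
    """
    s = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
    if len(s) < 2 * min_period:
        raise ValueError("sequence shorter than two minimal periods")
    hi = min(max_period, len(s) // 2)
    for p in range(min_period, hi + 1):
        frac = float(np.mean(s[:-p] == s[p:]))
        if frac >= match_threshold:
            return p
    return None


# --------------------------------------------------------------------------
# Consensus and monomer extraction
# --------------------------------------------------------------------------


def _project_onto_reference(unit: str, ref: str) -> np.ndarray:
    """Codes of ``unit`` in the coordinates of ``ref`` via global alignment.

    Deletions relative to the reference become gap codes; insertions (extra
    unit bases) are dropped, i.e. the star alignment keeps the reference's
    column space.
    """
    res = edlib.align(unit, ref, mode="NW", task="path")
    out = np.full(len(ref), GAP, dtype=np.uint8)
    codes = {"A": 0, "C": 1, "G": 2, "T": 3}
    qi = ti = 0
    useq = unit.upper()
    for n, op in parse_cigar(res["cigar"]):
        if op in ("=", "X", "M"):
            for _ in range(n):
                out[ti] = codes.get(useq[qi], GAP)
                qi += 1
                ti += 1
        elif op == "I":
            qi += n
        elif op == "D":
            ti += n
    return out


def star_align(units: list[str], reference: str | None = None) -> np.ndarray:
    """Star multiple alignment of monomers against a reference (default: the
    first unit); returns an (n, len(reference)) code matrix with gaps = 4."""
    if not units:
        raise ValueError("no units to align")
    ref = (reference or units[0]).upper()
    return np.vstack([_project_onto_reference(u, ref) for u in units])


def build_consensus(units: list[str], reference: str | None = None) -> str:
    """Per-column majority consensus of a star alignment of the units.

    Units are star-aligned to ``reference`` (default: the first unit). Ties
    break alphabetically (A<C<G<T); columns where the gap state wins
    outright are dropped.
    """
    if len(units) < 2:
        raise ValueError("consensus needs at least 2 units")
    msa = star_align(units, reference)
    counts = np.stack([(msa == c).sum(axis=0) for c in range(5)], axis=1)
    best_base = counts[:, :4].argmax(axis=1)
    keep = counts[np.arange(len(best_base)), best_base] >= counts[:, 4]
    return "".join("ACGT"[b] for b, k in zip(best_base, keep) if k)


# Karlin-Altschul lambda for match +1 / mismatch -2 at uniform base
# composition: solves (1/4) e^lam + (3/4) e^(-2 lam) = 1.
_KA_LAMBDA = brentq(lambda lam: 0.25 * math.exp(lam) + 0.75 * math.exp(-2 * lam) - 1, 0.1, 3.0)
_KA_K = 0.62


def _evalue(score: float, query_len: int, db_len: float) -> float:
    return _KA_K * query_len * db_len * math.exp(-_KA_LAMBDA * score)


def extract_units(
    reads,
    consensus: str,
    evalue_cutoff: float = 1e-10,
    n: int = 100,
) -> list[tuple[str, str]]:
    """Select the ``n`` monomers most similar to the consensus, one per read.

    Every read (both strands) is scanned for its best local match to the
    consensus; when a read contains several repeat copies only the most
    similar one is taken, so each returned unit represents a different locus.
    Hits are scored +1/-2 and filtered on a Karlin-Altschul e-value against
    the whole read set, then ranked by identity (score breaking ties).
    Returns (read id, unit sequence) pairs.
    """
    if isinstance(reads, ReadSet):
        ids = reads.read_ids()
        seqs = reads.sequences
    else:
        ids, seqs = zip(*reads) if reads else ((), ())
    db_len = float(sum(len(s) for s in seqs)) or 1.0
    cons = consensus.upper()
    scored = []
    for rid, seq in zip(ids, seqs):
        best = None
        for oriented in (seq.upper(), revcomp(seq.upper())):
            if len(oriented) < 8:
                continue
            hit = infix_align(cons, oriented)
            if hit is None:
                continue
            score = hit.matches - 2 * (hit.mismatches + hit.insertions + hit.deletions)
            if _evalue(score, len(cons), db_len) > evalue_cutoff:
                continue
            key = (hit.identity, score)
            if best is None or key > best[0]:
                # the aligned read segment is the monomer; note the query here
                # is the consensus, so the segment is the target span
                unit = oriented[hit.target_start : hit.target_end]
                best = (key, unit)
        if best is not None:
            scored.append((best[0], rid, best[1]))
    scored.sort(key=lambda t: (-t[0][0], -t[0][1], t[1]))
    return [(rid, unit) for _, rid, unit in scored[:n]]


# --------------------------------------------------------------------------
# Nucleotide diversity
# --------------------------------------------------------------------------


def nucleotide_diversity(alignment) -> tuple[float, float]:
    """Nucleotide diversity pi and its sampling standard deviation.

    ``alignment`` is a list of equal-length gapped sequences or a code matrix
    from :func:`star_align`. Pairwise deletion: sites gapped in either member
    of a pair are skipped for that pair. pi = 2/(n(n-1)) * sum_{i<j} d_ij with
    d_ij = differences / compared sites. The SD is the square root of the
    no-recombination sampling variance of pi for n sequences of L sites,
    Var = (n+1)/(3(n-1)L) * pi + 2(n^2+n+3)/(9n(n-1)) * pi^2.
    """
    if isinstance(alignment, np.ndarray):
        msa = alignment
    else:
        codes = {"A": 0, "C": 1, "G": 2, "T": 3}
        L = {len(s) for s in alignment}
        if len(L) != 1:
            raise ValueError("aligned sequences must have equal length")
        msa = np.array(
            [[codes.get(ch, GAP) for ch in s.upper()] for s in alignment], dtype=np.uint8
        )
    n = msa.shape[0]
    if n < 2:
        raise ValueError("pi needs at least 2 sequences")
    valid = msa < 4
    total = 0.0
    lengths = []
    for i in range(n - 1):
        both = valid[i] & valid[i + 1 :]
        sites = both.sum(axis=1)
        if np.any(sites == 0):
            raise ValueError("a sequence pair shares no ungapped sites")
        diffs = ((msa[i] != msa[i + 1 :]) & both).sum(axis=1)
        total += float((diffs / sites).sum())
        lengths.extend(sites.tolist())
    pi = 2.0 * total / (n * (n - 1))
    L_eff = float(np.mean(lengths))
    var = (n + 1) / (3 * (n - 1) * L_eff) * pi + 2 * (n * n + n + 3) / (9 * n * (n - 1)) * pi * pi
    return pi, math.sqrt(var)


def pairwise_pdistance(msa: np.ndarray, ids: list[str]) -> DistanceMatrix:
    """Pairwise-deletion p-distance matrix over a code matrix."""
    n = msa.shape[0]
    valid = msa < 4
    d = np.zeros((n, n))
    for i in range(n - 1):
        both = valid[i] & valid[i + 1 :]
        sites = both.sum(axis=1).astype(float)
        sites[sites == 0] = np.nan
        diffs = ((msa[i] != msa[i + 1 :]) & both).sum(axis=1)
        d[i, i + 1 :] = d[i + 1 :, i] = diffs / sites
    return DistanceMatrix(d, ids)


# --------------------------------------------------------------------------
# Neighbor joining
# --------------------------------------------------------------------------


def nj_tree(
    distances,
    ids: list[str] | None = None,
    alignment: np.ndarray | None = None,
    bootstrap: int = 0,
    seed: int = 0,
) -> TreeNode:
    """Neighbor-joining tree from a distance matrix (optionally bootstrapped).

    ``distances`` is a skbio DistanceMatrix or a square symmetric array with
    ``ids``. When ``alignment`` (the code matrix the distances came from) and
    ``bootstrap`` > 0 are given, alignment columns are resampled with a seeded
    generator and internal nodes receive support values in [0, 1].
    """
    if not isinstance(distances, DistanceMatrix):
        distances = DistanceMatrix(np.asarray(distances, dtype=float), ids)
    if len(distances.ids) < 3:
        raise ValueError("NJ needs at least 3 taxa")
    tree = _skbio_nj(distances)
    if bootstrap and alignment is not None:
        rng = np.random.default_rng(seed)
        leaf_ids = list(distances.ids)
        observed = {}
        for node in tree.non_tips():
            clade = frozenset(t.name for t in node.tips())
            observed[id(node)] = (node, clade)
        support: dict[int, int] = {k: 0 for k in observed}
        n_cols = alignment.shape[1]
        for _ in range(bootstrap):
            cols = rng.integers(0, n_cols, size=n_cols)
            rep_dm = pairwise_pdistance(alignment[:, cols], leaf_ids)
            rep = _skbio_nj(rep_dm)
            rep_clades = set()
            all_ids = frozenset(leaf_ids)
            for node in rep.non_tips():
                clade = frozenset(t.name for t in node.tips())
                rep_clades.add(clade)
                rep_clades.add(all_ids - clade)
            for key, (_, clade) in observed.items():
                if clade in rep_clades:
                    support[key] += 1
        for key, (node, _) in observed.items():
            node.name = f"{support[key] / bootstrap:.2f}"
    return tree


# --------------------------------------------------------------------------
# Family-level wrapper
# --------------------------------------------------------------------------


@dataclass
class TandemFamily:
    """One satellite family's summary: consensus, monomers, GC, diversity."""

    name: str
    consensus: str
    unit_length: int
    gc: float
    units: list[tuple[str, str]]
    pi: float
    pi_sd: float
    n_truncated: int = 0
    alignment: np.ndarray | None = field(default=None, repr=False)


def analyze_family(
    name: str,
    reads,
    preliminary_consensus: str,
    n_units: int = 100,
    evalue_cutoff: float = 1e-10,
    truncated_fraction_of_consensus: float = 0.5,
) -> TandemFamily:
    """Extract monomers for one family and summarise its variability.

    Units shorter than half the consensus are counted as truncated and left
    out of the alignment and pi (they would otherwise contribute mostly
    missing data), but are reported.
    """
    units = extract_units(reads, preliminary_consensus, evalue_cutoff, n_units)
    min_len = truncated_fraction_of_consensus * len(preliminary_consensus)
    full = [(rid, u) for rid, u in units if len(u) >= min_len]
    n_trunc = len(units) - len(full)
    if len(full) >= 2:
        consensus = build_consensus([u for _, u in full], preliminary_consensus)
        msa = star_align([u for _, u in full], consensus)
        pi, pi_sd = nucleotide_diversity(msa)
    else:
        consensus = preliminary_consensus
        msa = None
        pi, pi_sd = float("nan"), float("nan")
    return TandemFamily(
        name=name,
        consensus=consensus,
        unit_length=len(consensus),
        gc=gc_content(consensus),
        units=full,
        pi=pi,
        pi_sd=pi_sd,
        n_truncated=n_trunc,
        alignment=msa,
    )
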