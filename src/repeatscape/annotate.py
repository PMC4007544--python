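"""Library-based repeat classification, organellar filtering, unknown-repeat
detection and assembly quality control.

Contigs are masked against a labelled repeat library (headers carry the
category after a '#', RepeatMasker style); the per-category masked fraction
drives a single final label per contig, with contigs mixing tandem-repeat and
transposon signal removed as ambiguous. Contigs carrying even a small
fraction of organellar sequence are excluded before any composition is
computed. Unclassified sequences that overlap each other are grouped into
unknown-repeat families, and independently determined (e.g. Sanger) sequences
provide mismatch/indel statistics on the assembly.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from ._align import infix_align, revcomp

#: Minimum +1/-2 score of a window placement; rejects chance-level hits of
#: short windows while keeping genuine fragments at the identity cutoff.
_MIN_WINDOW_SCORE = 12

#: Transposon categories for the ambiguity (tandem + transposon) removal rule.
TRANSPOSON_PREFIXES = (
    "LTR/", "LINE", "SINE", "TIR/", "Helitron", "Crypton", "DNA/", "retrovirus",
)

#: Priority when masked fractions tie exactly.
CATEGORY_PRIORITY = [
    "tandem", "rDNA", "LTR/Gypsy", "LTR/Copia", "LTR/unknown", "LINE", "SINE",
    "TIR/hAT", "TIR/Mutator", "TIR/CACTA", "TIR/Tc1-Mariner", "TIR/PIF-Harbinger",
    "Helitron", "Crypton", "unknown",
]


def is_transposon_category(category: str) -> bool:
    return any(category.startswith(p) for p in TRANSPOSON_PREFIXES)


def parse_library(records: dict[str, str]) -> list[tuple[str, str, str]]:
    """Split 'name#category' FASTA ids into (name, category, sequence)."""
    out = []
    for rid, seq in records.items():
        if "#" not in rid:
            raise ValueError(f"library entry without a #category label: {rid}")
        name, category = rid.split("#", 1)
        out.append((name, category, seq.upper()))
    return out


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _window_hits(query: str, contig: str, min_identity: float,
                 window: int = 30, step: int = 15) -> list[tuple[int, int]]:
    """All placements of ``query`` fragments on ``contig`` at the identity cutoff.

    The query is tiled into windows (the final window flushed to the query
    end so no tail is skipped), each window is placed by banded infix
    alignment, and — because only best-scoring placements are reported per
    call — already-found spans are masked out and the search repeated, so
    every repeat copy on the contig is recovered. Fragments shorter than the
    window are only found when they line up with a window, so the window is
    sized to the minimum hit length of interest.
    """
    hits: list[tuple[int, int]] = []
    if len(query) <= window:
        windows = [query]
    else:
        starts = list(range(0, len(query) - window + 1, step))
        if starts[-1] != len(query) - window:
            starts.append(len(query) - window)
        windows = [query[i : i + window] for i in starts]
    for w in windows:
        if len(w) < 10:
            continue
        max_edits = int(len(w) * (1 - min_identity)) + 1
        for oriented in (w, revcomp(w)):
            working = contig
            for _ in range(200):  # bounded number of copies per window
                hit = infix_align(oriented, working, max_edits=max_edits)
                if hit is None or hit.identity < min_identity:
                    break
                # short windows at the identity cutoff are indistinguishable
                # from chance; require a +1/-2 alignment score high enough to
                # rule out the best random placement
                score = hit.matches - 2 * (hit.mismatches + hit.insertions + hit.deletions)
                if score < _MIN_WINDOW_SCORE:
                    break
                span = (hit.target_start, hit.target_end)
                new_spans = list(hit.locations) or [span]
                hits.extend(new_spans)
                masked = list(working)
                for s, e in new_spans:
                    masked[s:e] = "N" * (e - s)
                working = "".join(masked)
    return hits


def mask_with_library(
    contigs: dict[str, str],
    library,
    min_identity: float = 0.8,
    min_hit_len: int = 30,
) -> dict[str, dict[str, list[tuple[int, int]]]]:
    """Mask contigs with a labelled library; returns merged intervals per
    contig per category. ``library`` is a dict of 'name#category' -> sequence
    or a list of (name, category, sequence)."""
    if isinstance(library, dict):
        entries = parse_library(library)
    else:
        entries = [(n, c, s.upper()) for n, c, s in library]
    if not entries:
        raise ValueError("empty repeat library")
    window = max(20, min_hit_len)
    step = max(5, window // 2)
    out: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for cid, contig in contigs.items():
        per_cat: dict[str, list[tuple[int, int]]] = {}
        for _name, category, seq in entries:
            hits = _window_hits(seq, contig.upper(), min_identity, window, step)
            if hits:
                per_cat.setdefault(category, []).extend(hits)
        merged = {
            cat: [iv for iv in _merge_intervals(ivs) if iv[1] - iv[0] >= min_hit_len]
            for cat, ivs in per_cat.items()
        }
        out[cid] = {cat: ivs for cat, ivs in merged.items() if ivs}
    return out


def masked_fractions(
    masks: dict[str, list[tuple[int, int]]], contig_length: int
) -> dict[str, float]:
    return {
        cat: sum(e - s for s, e in ivs) / contig_length for cat, ivs in masks.items()
    }


def filter_organellar(
    contigs: dict[str, str],
    organellar_library: dict[str, str] | list[str],
    threshold: float = 0.01,
    min_identity: float = 0.8,
    interpretation: str = "masked_fraction",
) -> tuple[dict[str, str], dict[str, str]]:
    """Split contigs into (kept, discarded) by organellar contamination.

    Default reading of the conservative 1% rule: discard a contig when at
    least ``threshold`` of its length is masked by organellar sequence. The
    alternative ``interpretation='any_hit'`` discards on any organellar hit
    whatsoever, regardless of length.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if isinstance(organellar_library, dict):
        lib = [(k, "organellar", v) for k, v in organellar_library.items()]
    else:
        lib = [(f"org_{i}", "organellar", s) for i, s in enumerate(organellar_library)]
    masks = mask_with_library(contigs, lib, min_identity=min_identity, min_hit_len=10)
    kept, discarded = {}, {}
    for cid, seq in contigs.items():
        fracs = masked_fractions(masks.get(cid, {}), len(seq))
        frac = fracs.get("organellar", 0.0)
        if interpretation == "any_hit":
            contaminated = frac > 0
        else:
            contaminated = frac >= threshold
        (discarded if contaminated else kept)[cid] = seq
    return kept, discarded


def classify_contig(
    fractions: dict[str, float],
    gene_hit: bool = False,
    floor: float = 0.2,
) -> str:
    """One final label from per-category masked fractions.

    The winning category must mask at least ``floor`` of the contig; a contig
    with both tandem-repeat and transposon fractions above the floor is
    'removed' (ambiguous); with no qualifying repeat category, a significant
    gene similarity yields 'gene-like', otherwise 'no hit'.
    """
    above = {c: f for c, f in fractions.items() if f >= floor}
    has_tandem = "tandem" in above
    has_te = any(is_transposon_category(c) for c in above)
    if has_tandem and has_te:
        return "removed"
    if above:
        best = max(above.values())
        winners = [c for c, f in above.items() if f == best]
        if len(winners) > 1:
            prio = {c: i for i, c in enumerate(CATEGORY_PRIORITY)}
            winners.sort(key=lambda c: prio.get(c, len(CATEGORY_PRIORITY)))
        return winners[0]
    if gene_hit:
        return "gene-like"
    return "no hit"


def detect_unknown_repeats(
    sequences: dict[str, str],
    min_identity: float = 0.9,
    min_overlap: int = 40,
) -> list[set[str]]:
    """Group unclassified sequences that overlap each other.

    Two sequences are linked when they share a block of at least
    ``min_overlap`` nt at ``min_identity``; connected components with two or
    more members are reported as putative unknown-repeat families.
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    ids = list(sequences)
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i, a in enumerate(ids):
        sa = sequences[a].upper()
        for b in ids[i + 1 :]:
            sb = sequences[b].upper()
            if _share_block(sa, sb, min_identity, min_overlap):
                g.add_edge(a, b)
    return [comp for comp in nx.connected_components(g) if len(comp) >= 2]


def _share_block(a: str, b: str, min_identity: float, min_overlap: int) -> bool:
    """Seeded ungapped check for a shared block anywhere in the two sequences."""
    k = min(12, min_overlap)
    pos: dict[str, int] = {}
    for i in range(len(a) - k + 1):
        pos.setdefault(a[i : i + k], i)
    for bb in (b, revcomp(b)):
        diags = set()
        for j in range(len(bb) - k + 1):
            i = pos.get(bb[j : j + k])
            if i is not None:
                diags.add(i - j)
        for diag in diags:
            start = max(0, diag)
            end = min(len(a), diag + len(bb))
            if end - start < min_overlap:
                continue
            seg_a = a[start:end]
            seg_b = bb[start - diag : end - diag]
            matches = sum(x == y for x, y in zip(seg_a, seg_b))
            # the shared block may be a sub-run of the overlap; accept if the
            # best min_overlap-length sub-window clears the identity bar
            if matches / len(seg_a) >= min_identity:
                return True
            window = min_overlap
            m = [x == y for x, y in zip(seg_a, seg_b)]
            run = sum(m[:window])
            best = run
            for t in range(window, len(m)):
                run += m[t] - m[t - window]
                best = max(best, run)
            if best / window >= min_identity:
                return True
    return False


@dataclass
class QCReport:
    """Assembly quality against independently determined (trusted) sequences."""

    aligned_nt: int
    mismatches: int
    indels: int

    @property
    def mismatch_percent(self) -> float:
        return 100.0 * self.mismatches / self.aligned_nt if self.aligned_nt else 0.0

    @property
    def indel_percent(self) -> float:
        return 100.0 * self.indels / self.aligned_nt if self.aligned_nt else 0.0


def assembly_qc(trusted: dict[str, str], contigs: dict[str, str]) -> QCReport:
    """Align each trusted sequence to its best contig; pool the edit statistics.

    The shorter partner is used as the query of a banded infix alignment;
    terminal overhangs are clipped. Totals are pooled over all trusted
    sequences with at least one alignable contig; percentages are counts over
    aligned nt.
    """
    if not trusted:
        raise ValueError("need at least one trusted sequence")
    aligned = mism = ind = 0
    for _tid, tseq in trusted.items():
        best = None
        for _cid, cseq in contigs.items():
            q, t = (tseq, cseq) if len(tseq) <= len(cseq) else (cseq, tseq)
            for oriented in (q.upper(), revcomp(q.upper())):
                hit = infix_align(oriented, t.upper())
                if hit is None:
                    continue
                if best is None or hit.identity > best.identity:
                    best = hit
        if best is None or best.identity < 0.5:
            continue
        aligned += best.alignment_columns
        mism += best.mismatches
        ind += best.insertions + best.deletions
    return QCReport(aligned_nt=aligned, mismatches=mism, indels=ind)
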