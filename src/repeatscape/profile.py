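"""Coverage-based redundancy classes and read-fraction genome composition.

Contigs are classified against the expected single-copy coverage E (genome
equivalents of the mapped read set): nonredundant below 2E, highly redundant
above 200E, medium redundant in between (both bounds inclusive in MR). With
the canonical E = 8.1 the class bounds are 16.2 and 1,620. Genome composition
is then expressed as the fraction of all genomic reads mapping to the contigs
of each class or annotation category — the read-fraction logic that turns a
mapping into genome percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

RC_MULTIPLIER_DEFAULT = 2.0
HR_MULTIPLIER_DEFAULT = 200.0


def expected_single_copy_coverage(total_read_bases: float, genome_size: float) -> float:
    """Genome equivalents of a read set: total read bases / genome size."""
    if genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    return total_read_bases / genome_size


def classify_by_coverage(
    coverages,
    E: float,
    rc_multiplier: float = RC_MULTIPLIER_DEFAULT,
    hr_multiplier: float = HR_MULTIPLIER_DEFAULT,
):
    """Assign HR / MR / NRC per contig from average coverage.

    NRC: cov < rc_multiplier*E; HR: cov > hr_multiplier*E; MR otherwise
    (both boundary values inclusive in MR, 'comprised between' the bounds).
    Accepts a mapping id -> coverage (returns a dict) or a plain iterable
    (returns a list).
    """
    if E <= 0:
        raise ValueError("expected single-copy coverage E must be > 0")
    lo = rc_multiplier * E
    hi = hr_multiplier * E

    def one(cov: float) -> str:
        if cov < 0:
            raise ValueError("negative coverage")
        if cov < lo:
            return "NRC"
        if cov > hi:
            return "HR"
        return "MR"

    if isinstance(coverages, dict):
        return {cid: one(c) for cid, c in coverages.items()}
    return [one(c) for c in coverages]


@dataclass
class RedundancyProfile:
    """Class thresholds plus the per-contig class labels."""

    E: float
    rc_multiplier: float = RC_MULTIPLIER_DEFAULT
    hr_multiplier: float = HR_MULTIPLIER_DEFAULT
    classes: dict[str, str] = field(default_factory=dict)

    @property
    def rc_threshold(self) -> float:
        """Coverage separating nonredundant from redundant contigs."""
        return self.rc_multiplier * self.E

    @property
    def hr_threshold(self) -> float:
        return self.hr_multiplier * self.E

    @classmethod
    def from_mapping(cls, mapping, E: float, rc_multiplier: float = RC_MULTIPLIER_DEFAULT,
                     hr_multiplier: float = HR_MULTIPLIER_DEFAULT) -> "RedundancyProfile":
        cov = {cid: mapping.average_coverage(cid) for cid in mapping.contig_ids}
        return cls(E, rc_multiplier, hr_multiplier,
                   classify_by_coverage(cov, E, rc_multiplier, hr_multiplier))


@dataclass
class CompositionTable:
    """Read-fraction composition: one row per group plus unmatched and total.

    Percentages are exact fractions of ``total_reads``; formatting (2 decimals
    for class tables, 3 for category tables) happens only on output, with
    round-half-even.
    """

    counts: dict[str, int]
    total_reads: int
    group_order: list[str] | None = None

    @property
    def n_matched(self) -> int:
        return sum(self.counts.values())

    @property
    def n_unmatched(self) -> int:
        return self.total_reads - self.n_matched

    def percent(self, group: str) -> float:
        if group == "unmatched":
            return 100.0 * self.n_unmatched / self.total_reads
        return 100.0 * self.counts.get(group, 0) / self.total_reads

    def to_dataframe(self) -> pd.DataFrame:
        order = self.group_order or sorted(self.counts)
        rows = [
            {"group": g, "n_reads": self.counts.get(g, 0), "percent": self.percent(g)}
            for g in order
        ]
        rows.append(
            {"group": "unmatched", "n_reads": self.n_unmatched, "percent": self.percent("unmatched")}
        )
        rows.append({"group": "total", "n_reads": self.total_reads, "percent": 100.0})
        return pd.DataFrame(rows)

    def to_tsv(self, path, decimals: int = 2) -> None:
        df = self.to_dataframe()
        df["percent"] = df["percent"].map(lambda x: f"{x:.{decimals}f}")
        df.to_csv(path, sep="\t", index=False)


def genome_composition(mapping_or_counts, labels: dict[str, str], total_genomic_reads: int,
                       group_order: list[str] | None = None) -> CompositionTable:
    """Aggregate mapped-read counts per group and express them as percentages.

    ``mapping_or_counts`` is either a MappingResult or a plain dict
    contig -> mapped-read count; ``labels`` assigns each contig a group (a
    redundancy class or an annotation category). The percentage of a group is
    100 x its mapped reads / total genomic reads, with organellar reads
    assumed to have been removed from the total beforehand.
    """
    if total_genomic_reads <= 0:
        raise ValueError("total_genomic_reads must be > 0")
    if hasattr(mapping_or_counts, "n_mapped_reads"):
        per_contig = mapping_or_counts.n_mapped_reads
    else:
        per_contig = dict(mapping_or_counts)
    unlabeled = [c for c in per_contig if c not in labels]
    if unlabeled:
        raise ValueError(f"contigs without a label: {', '.join(map(str, unlabeled[:5]))}")
    n_matched = sum(per_contig.values())
    if n_matched > total_genomic_reads:
        raise ValueError("matched reads exceed total genomic reads")
    counts: dict[str, int] = {}
    for cid, n in per_contig.items():
        counts[labels[cid]] = counts.get(labels[cid], 0) + n
    return CompositionTable(counts=counts, total_reads=total_genomic_reads,
                            group_order=group_order)
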