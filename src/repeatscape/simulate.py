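"""Synthetic repeat-rich genomes with ground truth, and shotgun read simulation.

The simulator emulates, at kb-to-Mb scale, the composition of a satellite-rich
~1.4 Gb plant genome: six tandem-repeat (satellite) families with realistic
unit lengths and GC contents, Gypsy/Copia LTR-retrotransposon families with
optional solo-LTRs, optional organellar decoy sequences and a single-copy
background. Every placed repeat copy is recorded in a ground-truth annotation
so downstream coverage, composition and diversity estimates can be checked
against known values.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import olive_reference as olive
from ._align import codes_to_seq, revcomp, seq_to_codes

GC_TOLERANCE = 0.02


# --------------------------------------------------------------------------
# Specs
# --------------------------------------------------------------------------


@dataclass
class TandemFamilySpec:
    """One satellite family: ``copy_number`` units of ``unit_length`` nt
    arranged head-to-tail in ``n_arrays`` arrays.

    ``per_copy_substitution_rate`` is the per-site probability that a placed
    copy differs from the family unit; ``truncation_fraction`` is the fraction
    of copies shortened to a random partial unit (as seen for the Oe179-like
    families whose truncated units keep amplifying inside arrays).
    """

    name: str
    copy_number: int
    unit_sequence: str | None = None
    unit_length: int | None = None
    gc: float | None = None
    per_copy_substitution_rate: float = 0.02
    truncation_fraction: float = 0.0
    n_arrays: int = 4

    def __post_init__(self) -> None:
        if self.unit_sequence is not None:
            self.unit_sequence = self.unit_sequence.upper()
            self.unit_length = len(self.unit_sequence)
        if self.unit_length is None or self.unit_length < 2:
            raise ValueError(f"{self.name}: unit_length must be >= 2")
        if self.copy_number < 1:
            raise ValueError(f"{self.name}: copy_number must be >= 1")
        if not 0.0 <= self.per_copy_substitution_rate <= 1.0:
            raise ValueError(f"{self.name}: substitution rate outside [0,1]")
        if not 0.0 <= self.truncation_fraction <= 1.0:
            raise ValueError(f"{self.name}: truncation_fraction outside [0,1]")
        if self.n_arrays < 1:
            raise ValueError(f"{self.name}: n_arrays must be >= 1")
        if self.unit_sequence is None and self.gc is None:
            raise ValueError(f"{self.name}: need unit_sequence or a target gc")

    @property
    def nominal_length(self) -> int:
        return self.copy_number * self.unit_length


@dataclass
class LTRFamilySpec:
    """An LTR-retrotransposon family.

    Intact elements are LTR-internal-LTR; solo-LTR copies are a single LTR
    left behind by unequal recombination. Each placed copy is mutated at
    ``per_copy_substitution_rate`` per site relative to the family consensus.
    """

    name: str
    superfamily: str  # "Gypsy" or "Copia"
    ltr_length: int
    internal_length: int
    n_intact: int
    n_solo_ltr: int = 0
    per_copy_substitution_rate: float = 0.02
    gc: float = 0.40

    def __post_init__(self) -> None:
        if self.superfamily not in ("Gypsy", "Copia"):
            raise ValueError(f"{self.name}: superfamily must be Gypsy or Copia")
        if self.ltr_length < 2 or self.internal_length < 1:
            raise ValueError(f"{self.name}: bad element geometry")
        if self.n_intact < 0 or self.n_solo_ltr < 0:
            raise ValueError(f"{self.name}: negative copy counts")

    @property
    def element_length(self) -> int:
        return 2 * self.ltr_length + self.internal_length

    @property
    def nominal_length(self) -> int:
        return self.n_intact * self.element_length + self.n_solo_ltr * self.ltr_length


@dataclass
class GenomeSpec:
    """Declarative description of a synthetic genome.

    Total genome length = background_length + sum of family lengths
    (+ organellar decoys). Output is byte-identical for a fixed seed.
    """

    tandem_families: list[TandemFamilySpec] = field(default_factory=list)
    ltr_families: list[LTRFamilySpec] = field(default_factory=list)
    background_length: int = 100_000
    background_gc: float = olive.GENOME_GC
    organellar_decoys: list[str] | None = None
    seed: int = 0

    @property
    def nominal_genome_length(self) -> int:
        total = self.background_length
        total += sum(f.nominal_length for f in self.tandem_families)
        total += sum(f.nominal_length for f in self.ltr_families)
        if self.organellar_decoys:
            total += sum(len(s) for s in self.organellar_decoys)
        return total

    def to_yaml(self, path) -> None:
        doc = {
            "tandem_families": [dataclasses.asdict(f) for f in self.tandem_families],
            "ltr_families": [dataclasses.asdict(f) for f in self.ltr_families],
            "background_length": self.background_length,
            "background_gc": self.background_gc,
            "organellar_decoys": self.organellar_decoys,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GenomeSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            tandem_families=[TandemFamilySpec(**f) for f in doc.get("tandem_families", [])],
            ltr_families=[LTRFamilySpec(**f) for f in doc.get("ltr_families", [])],
            background_length=doc.get("background_length", 100_000),
            background_gc=doc.get("background_gc", olive.GENOME_GC),
            organellar_decoys=doc.get("organellar_decoys"),
            seed=doc.get("seed", 0),
        )


# --------------------------------------------------------------------------
# Ground truth
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TruthInterval:
    chrom: str
    start: int
    end: int
    category: str  # tandem | ltr | internal | solo_ltr | organellar
    family: str
    copy_index: int
    strand: str = "+"


@dataclass
class GroundTruth:
    """Exact placement and identity of every repeat copy in a built genome."""

    intervals: list[TruthInterval]
    true_copy_number: dict[str, int]
    genome_length: int
    family_sequences: dict[str, str]  # family -> unmutated unit/element
    family_category: dict[str, str]  # family -> tandem | ltr
    family_unit_length: dict[str, int]

    def family_fraction(self) -> dict[str, float]:
        """Fraction of the genome occupied by each family (from intervals)."""
        out: dict[str, float] = {}
        for iv in self.intervals:
            out[iv.family] = out.get(iv.family, 0.0) + (iv.end - iv.start)
        return {k: v / self.genome_length for k, v in out.items()}

    def category_fraction(self) -> dict[str, float]:
        """Fraction of the genome per category; LTR intervals (ltr, internal,
        solo_ltr) are pooled under 'ltr'; remainder is 'background'."""
        pool = {"ltr": "ltr", "internal": "ltr", "solo_ltr": "ltr"}
        out: dict[str, float] = {}
        for iv in self.intervals:
            cat = pool.get(iv.category, iv.category)
            out[cat] = out.get(cat, 0.0) + (iv.end - iv.start)
        frac = {k: v / self.genome_length for k, v in out.items()}
        frac["background"] = 1.0 - sum(frac.values())
        return frac

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for iv in self.intervals:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.family}\t"
                    f"{iv.copy_index}\t{iv.strand}\t{iv.category}\n"
                )


@dataclass
class ReadSet:
    """Simulated single-end shotgun reads with known origins."""

    sequences: list[str]
    read_length: int
    coverage: float
    seed: int
    paired: bool = False
    origins: np.ndarray | None = None  # (n, 2): start, strand(0/1); sim metadata
    ids: list[str] | None = None

    def __len__(self) -> int:
        return len(self.sequences)

    def read_ids(self) -> list[str]:
        if self.ids is None:
            self.ids = [f"read_{i:07d}" for i in range(len(self.sequences))]
        return self.ids

    @property
    def total_bases(self) -> int:
        return sum(len(s) for s in self.sequences)


# --------------------------------------------------------------------------
# Generation
# --------------------------------------------------------------------------


def random_unit(length: int, gc: float, rng: np.random.Generator, max_tries: int = 200) -> str:
    """Random DNA with base probabilities P(G)=P(C)=gc/2, rejection-sampled
    until the realised GC is within ±0.02 of the target."""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    for _ in range(max_tries):
        codes = rng.choice(4, size=length, p=p).astype(np.uint8)
        realised = np.isin(codes, (1, 2)).mean()
        if abs(realised - gc) <= GC_TOLERANCE:
            return codes_to_seq(codes)
    raise RuntimeError(f"could not hit GC {gc} within ±{GC_TOLERANCE} for length {length}")


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each site independently with probability ``rate``; the new
    base is drawn uniformly from the three alternatives."""
    if rate <= 0:
        return seq
    codes = seq_to_codes(seq).copy()
    hit = rng.random(len(codes)) < rate
    n = int(hit.sum())
    if n:
        shift = rng.integers(1, 4, size=n).astype(np.uint8)
        codes[hit] = (codes[hit] + shift) % 4
    return codes_to_seq(codes)


def default_olive_spec(genome_size: int = 2_000_000, seed: int = 0) -> GenomeSpec:
    """Default genome spec emulating the olive repeat landscape.

    Six tandem families (unit lengths 80/178/86/179/218/51 nt with their
    published GC contents) scaled so the tandem fraction is ~31% of the
    genome, plus Gypsy (~20.8%) and Copia (~17.8%) LTR-retrotransposon
    families; the remainder is single-copy background at the genome mean GC.
    Copy numbers derive from fraction x genome_size / unit_length, since
    per-family copy numbers are not published.
    """
    table = olive.TANDEM_FAMILY_TABLE
    raw_total = sum(pct for _, _, pct in table.values())
    scale = olive.TANDEM_TOTAL_PERCENT / raw_total
    sub_rates = {
        "Oe80": 0.030,
        "Oe178": 0.040,
        "Oe86": 0.012,
        "Oe179": 0.015,
        "Oe218": 0.050,
        "Oe51": 0.010,
    }
    tandem = []
    for name, (unit_len, gc, pct) in table.items():
        frac = pct * scale / 100.0
        copies = max(1, int(round(frac * genome_size / unit_len)))
        tandem.append(
            TandemFamilySpec(
                name=name,
                copy_number=copies,
                unit_length=unit_len,
                gc=gc,
                per_copy_substitution_rate=sub_rates[name],
                truncation_fraction=0.15 if name == "Oe179" else 0.0,
            )
        )
    ltr = []
    geometry = {"Gypsy": (500, 4000), "Copia": (350, 3600)}
    for superfamily, pct in olive.LTR_SUPERFAMILY_PERCENT.items():
        ltr_len, internal = geometry[superfamily]
        element = 2 * ltr_len + internal
        n = max(1, int(round(pct / 100.0 * genome_size / element)))
        ltr.append(
            LTRFamilySpec(
                name=f"Ole{superfamily}1",
                superfamily=superfamily,
                ltr_length=ltr_len,
                internal_length=internal,
                n_intact=n,
                per_copy_substitution_rate=0.02,
            )
        )
    repeat_total = sum(f.nominal_length for f in tandem) + sum(f.nominal_length for f in ltr)
    background = genome_size - repeat_total
    if background <= 0:
        raise ValueError(f"genome_size {genome_size} too small for the default families")
    return GenomeSpec(
        tandem_families=tandem,
        ltr_families=ltr,
        background_length=background,
        background_gc=olive.GENOME_GC,
        seed=seed,
    )


def _truncation_length(unit_len: int, rng: np.random.Generator) -> int:
    lo = max(2, int(0.3 * unit_len))
    hi = max(lo + 1, unit_len - 1)
    return int(rng.integers(lo, hi))


def build_genome(spec: GenomeSpec, chrom: str = "chr1") -> tuple[str, GroundTruth]:
    """Materialise a genome from a spec; every placed copy goes into the truth.

    Repeat segments (tandem arrays, LTR elements, solo-LTRs, decoys) are
    shuffled and separated by chunks of single-copy background; truth interval
    lengths plus background chunks sum exactly to the genome length.
    """
    rng = np.random.default_rng(spec.seed)
    family_sequences: dict[str, str] = {}
    family_category: dict[str, str] = {}
    family_unit_length: dict[str, int] = {}
    true_copy_number: dict[str, int] = {}

    # each segment: (sequence, [(offset, length, category, family, copy_idx, strand)])
    segments: list[tuple[str, list[tuple[int, int, str, str, int, str]]]] = []

    for fam in spec.tandem_families:
        unit = fam.unit_sequence or random_unit(fam.unit_length, fam.gc, rng)
        family_sequences[fam.name] = unit
        family_category[fam.name] = "tandem"
        family_unit_length[fam.name] = fam.unit_length
        true_copy_number[fam.name] = fam.copy_number
        per_array = np.full(fam.n_arrays, fam.copy_number // fam.n_arrays, dtype=int)
        per_array[: fam.copy_number % fam.n_arrays] += 1
        copy_idx = 0
        for n_copies in per_array:
            if n_copies == 0:
                continue
            parts: list[str] = []
            annos: list[tuple[int, int, str, str, int, str]] = []
            offset = 0
            for _ in range(n_copies):
                copy = mutate(unit, fam.per_copy_substitution_rate, rng)
                if fam.truncation_fraction and rng.random() < fam.truncation_fraction:
                    copy = copy[: _truncation_length(fam.unit_length, rng)]
                parts.append(copy)
                annos.append((offset, len(copy), "tandem", fam.name, copy_idx, "+"))
                offset += len(copy)
                copy_idx += 1
            segments.append(("".join(parts), annos))

    for fam in spec.ltr_families:
        ltr_unit = random_unit(fam.ltr_length, fam.gc, rng)
        internal_unit = random_unit(fam.internal_length, fam.gc, rng)
        family_sequences[fam.name] = ltr_unit + internal_unit + ltr_unit
        family_category[fam.name] = "ltr"
        family_unit_length[fam.name] = fam.element_length
        true_copy_number[fam.name] = fam.n_intact
        if fam.n_solo_ltr:
            true_copy_number[fam.name + "_solo"] = fam.n_solo_ltr
        L, I = fam.ltr_length, fam.internal_length
        for i in range(fam.n_intact):
            element = mutate(ltr_unit + internal_unit + ltr_unit, fam.per_copy_substitution_rate, rng)
            annos = [
                (0, L, "ltr", fam.name, i, "+"),
                (L, I, "internal", fam.name, i, "+"),
                (L + I, L, "ltr", fam.name, i, "+"),
            ]
            if rng.random() < 0.5:  # insert on the minus strand
                element = revcomp(element)
                annos = [
                    (0, L, "ltr", fam.name, i, "-"),
                    (L, I, "internal", fam.name, i, "-"),
                    (L + I, L, "ltr", fam.name, i, "-"),
                ]
            segments.append((element, annos))
        for i in range(fam.n_solo_ltr):
            solo = mutate(ltr_unit, fam.per_copy_substitution_rate, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                solo = revcomp(solo)
            segments.append((solo, [(0, len(solo), "solo_ltr", fam.name, i, strand)]))

    for i, decoy in enumerate(spec.organellar_decoys or []):
        segments.append(
            (decoy.upper(), [(0, len(decoy), "organellar", f"organellar_{i}", i, "+")])
        )

    order = rng.permutation(len(segments))
    segments = [segments[i] for i in order]

    n_gaps = len(segments) + 1
    if spec.background_length < n_gaps:
        raise ValueError(
            f"background_length {spec.background_length} cannot separate "
            f"{len(segments)} repeat segments"
        )
    cuts = np.sort(rng.choice(spec.background_length, size=n_gaps - 1, replace=False))
    gap_lengths = np.diff(np.concatenate(([0], cuts, [spec.background_length])))
    background = random_unit_background(spec.background_length, spec.background_gc, rng)

    pieces: list[str] = []
    intervals: list[TruthInterval] = []
    pos = 0
    bg_used = 0
    for gap_len, (seg_seq, annos) in zip(gap_lengths, segments):
        pieces.append(background[bg_used : bg_used + gap_len])
        bg_used += gap_len
        pos += int(gap_len)
        for off, length, cat, famname, idx, strand in annos:
            intervals.append(
                TruthInterval(chrom, pos + off, pos + off + length, cat, famname, idx, strand)
            )
        pieces.append(seg_seq)
        pos += len(seg_seq)
    pieces.append(background[bg_used:])
    genome = "".join(pieces)

    truth = GroundTruth(
        intervals=intervals,
        true_copy_number=true_copy_number,
        genome_length=len(genome),
        family_sequences=family_sequences,
        family_category=family_category,
        family_unit_length=family_unit_length,
    )
    return genome, truth


def random_unit_background(length: int, gc: float, rng: np.random.Generator) -> str:
    """I.i.d. background sequence at the target GC (no rejection step; at
    background lengths the realised GC is within tolerance anyway)."""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=length, p=p).astype(np.uint8)
    return codes_to_seq(codes)


# --------------------------------------------------------------------------
# Read simulation
# --------------------------------------------------------------------------


def simulate_reads(
    genome: str,
    coverage: float,
    read_length: int = 75,
    substitution_error_rate: float = 0.0,
    seed: int = 0,
) -> ReadSet:
    """Uniform single-end shotgun reads from both strands.

    Read count = round(coverage x genome_length / read_length); per-base
    substitution errors at the given rate. Origins (start, strand) are kept as
    simulation metadata.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    G = len(genome)
    if read_length > G:
        raise ValueError("read_length exceeds genome length")
    rng = np.random.default_rng(seed)
    n_reads = int(round(coverage * G / read_length))
    starts = rng.integers(0, G - read_length + 1, size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)

    g = seq_to_codes(genome)
    idx = starts[:, None] + np.arange(read_length)[None, :]
    mat = g[idx]
    minus = strands == 1
    # reverse complement minus-strand rows (codes: A0 C1 G2 T3 -> 3-c);
    # simulated genomes contain no ambiguity codes
    mat[minus] = 3 - mat[minus, ::-1]
    if substitution_error_rate > 0:
        err = rng.random(mat.shape) < substitution_error_rate
        shift = rng.integers(1, 4, size=int(err.sum())).astype(np.uint8)
        mat[err] = (mat[err] + shift) % 4
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    byte_rows = lut[np.minimum(mat, 4)]
    sequences = [row.tobytes().decode("ascii") for row in byte_rows]
    origins = np.column_stack([starts, strands])
    return ReadSet(
        sequences=sequences,
        read_length=read_length,
        coverage=coverage,
        seed=seed,
        origins=origins,
    )


def reads_from_category(reads: ReadSet, truth: GroundTruth, min_overlap_fraction: float = 0.5):
    """Map each simulated read to the truth category providing most of its
    bases (simulation metadata; used to score recovery on synthetic data).

    Returns a list of category strings ('tandem', 'ltr', 'background', ...),
    and a parallel list of family names ('' for background).
    """
    if reads.origins is None:
        raise ValueError("read set carries no origin metadata")
    L = reads.read_length
    pool = {"ltr": "ltr", "internal": "ltr", "solo_ltr": "ltr"}
    bounds = np.array([(iv.start, iv.end) for iv in truth.intervals])
    cats: list[str] = []
    fams: list[str] = []
    if len(bounds) == 0:
        return ["background"] * len(reads), [""] * len(reads)
    starts_sorted = np.argsort(bounds[:, 0])
    iv_starts = bounds[starts_sorted, 0]
    for start, _ in reads.origins:
        lo, hi = int(start), int(start) + L
        best_cat, best_fam, best_ov = "background", "", 0
        j = int(np.searchsorted(iv_starts, hi))
        for k in range(j - 1, -1, -1):
            iv = truth.intervals[starts_sorted[k]]
            if iv.end <= lo:
                # intervals are non-overlapping and sorted; once an interval
                # ends before the read starts, only a bounded lookback is
                # needed (adjacent tandem units), so stop after a margin
                if iv.start < lo - 10_000:
                    break
                continue
            ov = min(hi, iv.end) - max(lo, iv.start)
            if ov > best_ov:
                best_ov = ov
                best_cat = pool.get(iv.category, iv.category)
                best_fam = iv.family
        if best_ov < min_overlap_fraction * L:
            best_cat, best_fam = "background", ""
        cats.append(best_cat)
        fams.append(best_fam)
    return cats, fams
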