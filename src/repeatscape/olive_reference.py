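"""Published summary values for the olive (Olea europaea) repeat landscape.

These constants are the worked-example inputs the package's reports are shaped
after: Illumina read counts per redundancy class, read counts per repeat
category, per-cluster LTR vs inter-LTR coverages, the six major tandem-repeat
families, and the Sanger-vs-assembly quality-control counts. They let the
composition, ratio and QC arithmetic be exercised against real printed numbers
without access to the (undeposited) 1.4 Gb read sets.
"""

from __future__ import annotations

# --- Mapping statistics of 8.1 genome equivalents of 75-nt Illumina reads ---

#: Total nuclear (non-organellar) reads used as the composition denominator.
TOTAL_GENOMIC_READS = 138_741_954

#: Organellar reads, excluded before the total above is formed.
ORGANELLAR_READS = 13_203_073

#: Matched reads per redundancy class (HR > 200x expected single-copy
#: coverage, MR between 2x and 200x, NRC below 2x).
READ_CLASS_COUNTS = {
    "HR": 53_587_657,
    "MR": 47_388_283,
    "NRC": 23_469_403,
}

#: Matched reads for the headline annotation categories.
CATEGORY_READ_COUNTS = {
    "Tandem repeats": 43_233_770,
    "LTR/Gypsy": 28_884_342,
    "LTR/Copia": 24_725_640,
    "rDNA": 1_932_081,
    "No hits found": 14_584_090,
}

#: Expected average coverage of a single-copy contig (genome equivalents of
#: the mapped read set): 11,395,877,025 read nt over a ~1.41 Gb genome.
EXPECTED_SINGLE_COPY_COVERAGE = 8.1
TOTAL_MAPPED_READ_BASES = 11_395_877_025

# --- The six major tandem repeat families -----------------------------------

#: name -> (unit length nt, GC fraction, percent of the genome)
TANDEM_FAMILY_TABLE = {
    "Oe80": (80, 0.454, 10.33),
    "Oe178": (178, 0.432, 9.69),
    "Oe86": (86, 0.360, 4.91),
    "Oe179": (179, 0.360, 4.39),
    "Oe218": (218, 0.418, 4.29),
    "Oe51": (51, 0.335, 0.78),
}

#: Tandem repeats as a whole amount to this percent of the genome by read
#: fraction; the per-family table percentages sum slightly higher because they
#: were estimated per matching read independently.
TANDEM_TOTAL_PERCENT = 31.161

#: Genome percent by read fraction for the two LTR-retrotransposon
#: superfamilies.
LTR_SUPERFAMILY_PERCENT = {"Gypsy": 20.819, "Copia": 17.821}

# --- LTR vs inter-LTR average coverages per retrotransposon cluster ---------

#: (superfamily, cluster id, average coverage on the LTR, on the inter-LTR).
#: The LTR:inter-LTR ratio is 2 for a family of intact elements and rises by
#: S/N when S solo-LTRs accompany N intact copies.
LTR_CLUSTER_COVERAGES = [
    ("Copia", 24, 1320.5, 3816.5),
    ("Copia", 39, 7107.8, 5380.4),
    ("Copia", 48, 3161.2, 3119.2),
    ("Copia", 63, 1451.9, 1668.7),
    ("Copia", 66, 2874.1, 2186.8),
    ("Copia", 72, 3068.2, 1570.2),
    ("Copia", 86, 1557.3, 2444.8),
    ("Copia", 90, 418.3, 1475.4),
    ("Copia", 102, 1422.8, 1348.1),
    ("Copia", 108, 507.1, 1101.8),
    ("Copia", 112, 1414.5, 917.7),
    ("Copia", 114, 1306.8, 1211.7),
    ("Copia", 142, 1098.0, 1096.2),
    ("Copia", 165, 744.8, 797.5),
    ("Copia", 172, 409.1, 561.3),
    ("Copia", 178, 1148.4, 652.8),
    ("Copia", 212, 983.4, 520.4),
    ("Copia", 213, 674.7, 450.8),
    ("Copia", 239, 509.9, 497.6),
    ("Copia", 262, 343.4, 418.3),
    ("Gypsy", 45, 5434.3, 3318.0),
    ("Gypsy", 69, 3669.1, 1455.0),
    ("Gypsy", 146, 10393.6, 914.3),
    ("Gypsy", 149, 1338.2, 2626.0),
    ("Gypsy", 157, 38338.0, 869.2),
    ("Gypsy", 180, 1208.5, 658.0),
]

# --- Sanger-clone vs assembled-contig quality control ------------------------

#: Aligned nucleotides, mismatches and indels between independently Sanger
#: sequenced clones and the whole-genome set of assembled sequences.
QC_ALIGNED_NT = 14_807
QC_MISMATCHES = 312
QC_INDELS = 148

#: Mean whole-genome GC content estimated from Illumina reads.
GENOME_GC = 0.38
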