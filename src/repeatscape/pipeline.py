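"""End-to-end desk-scale pipeline: simulate -> assemble -> filter -> map ->
profile -> annotate -> tandem -> LTR, writing the standard report tables.

Every random decision traces to a named seed in the config and every stage
logs its input/output counts, so re-running a config reproduces each report
byte for byte.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as ann
from . import io as rio
from . import ltr as ltrmod
from . import tandem as tdm
from .assembly import split_assemble_merge
from .mapping import MappingParams, calibrate_mapping, map_reads
from .profile import RedundancyProfile, expected_single_copy_coverage, genome_composition
from .simulate import build_genome, default_olive_spec, simulate_reads

logger = logging.getLogger("repeatscape")


@dataclass
class PipelineConfig:
    """Flat, fully serialisable run configuration (defaults = study cutoffs)."""

    genome_size: int = 50_000
    coverage: float = 8.1
    read_length: int = 75
    assembly_coverage: float = 2.03
    assembly_read_length: int = 100
    long_read_coverage: float = 1.0
    long_read_length: int = 400
    read_error_rate: float = 0.005
    n_splits: int = 4
    min_overlap: int = 40
    assembly_identity: float = 0.9
    merge_identity: float = 0.8
    singleton_min_length: int = 1000
    trim_75: bool = True
    similarity: float = 0.8
    length_fraction: float = 0.8
    mismatch_cost: int = 2
    deletion_cost: int = 3
    insertion_cost: int = 3
    kmer_size: int = 15
    rc_multiplier: float = 2.0
    hr_multiplier: float = 200.0
    mask_identity: float = 0.8
    organellar_threshold: float = 0.01
    evalue_tandem: float = 1e-10
    n_units: int = 50
    nj_units_per_family: int = 12
    bootstrap: int = 0
    calibrate: bool = False
    simulation_seed: int = 1
    read_seed: int = 2
    mapping_seed: int = 3
    split_seed: int = 4
    bootstrap_seed: int = 5

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        known = {f.name: f.type for f in dataclasses.fields(cls)}
        casts = {f.name: type(getattr(cls(), f.name)) for f in dataclasses.fields(cls)}
        kwargs = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#")[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, value = (t.strip() for t in line.split("=", 1))
                if key not in known:
                    raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
                caster = casts[key]
                kwargs[key] = value.lower() == "true" if caster is bool else caster(value)
        return cls(**kwargs)

    def mapping_params(self) -> MappingParams:
        return MappingParams(
            mismatch_cost=self.mismatch_cost,
            deletion_cost=self.deletion_cost,
            insertion_cost=self.insertion_cost,
            length_fraction=self.length_fraction,
            similarity=self.similarity,
            kmer_size=self.kmer_size,
            seed=self.mapping_seed,
        )


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute all stages on a default-composition synthetic genome.

    Writes genome/truth/reads, contigs, per-contig coverage, the class and
    category composition tables, the tandem family report (+ NJ tree) and the
    LTR ratio report into ``outdir``; returns the directory path.
    """
    if config.coverage <= 0:
        raise ValueError("coverage must be > 0")
    if config.genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    config.to_file(out / "config.resolved.txt")
    stage = "simulate"
    try:
        spec = default_olive_spec(config.genome_size, seed=config.simulation_seed)
        genome, truth = build_genome(spec)
        reads = simulate_reads(
            genome, config.coverage, config.read_length,
            config.read_error_rate, seed=config.read_seed,
        )
        asm_reads = simulate_reads(
            genome, config.assembly_coverage, config.assembly_read_length,
            config.read_error_rate, seed=config.read_seed + 1,
        )
        logger.info(
            "simulated genome of %d nt; %d mapping reads, %d assembly reads",
            len(genome), len(reads), len(asm_reads),
        )
        rio.write_fasta({"chr1": genome}, out / "genome.fasta")
        truth.to_bed(out / "truth.bed")
        rio.write_fastq(reads, out / "reads.fastq")
        fam_rows = [
            {
                "family": fam,
                "category": truth.family_category[fam],
                "unit_length": truth.family_unit_length[fam],
                "true_copies": truth.true_copy_number[fam],
            }
            for fam in truth.family_sequences
        ]
        pd.DataFrame(fam_rows).to_csv(out / "families.tsv", sep="\t", index=False)

        stage = "assemble"
        contigs = split_assemble_merge(
            asm_reads,
            n_splits=config.n_splits,
            min_overlap=config.min_overlap,
            min_identity=config.assembly_identity,
            merge_min_identity=config.merge_identity,
            singleton_min_length=config.singleton_min_length,
            seed=config.split_seed,
        )
        logger.info("assembled %d contigs from %d reads", len(contigs), len(reads))
        rio.write_contigs_fasta(contigs, out / "contigs.fasta")
        contig_seqs = {c.id: c.sequence for c in contigs}

        stage = "organellar_filter"
        if spec.organellar_decoys:
            contig_seqs, dropped = ann.filter_organellar(
                contig_seqs, list(spec.organellar_decoys),
                threshold=config.organellar_threshold,
            )
            logger.info("organellar filter dropped %d contigs", len(dropped))

        stage = "calibrate"
        params = config.mapping_params()
        if config.calibrate:
            refs = {f: s for f, s in truth.family_sequences.items()}
            copies = {f: float(truth.true_copy_number[f]) for f in refs}
            grid = [
                dataclasses.replace(params, similarity=s) for s in (0.8, 0.9)
            ]
            calib = calibrate_mapping(reads, refs, copies, grid)
            params = dataclasses.replace(calib.best_params, seed=config.mapping_seed)
            calib.table.to_csv(out / "calibration.tsv", sep="\t", index=False)
            logger.info("calibration selected similarity %.2f", params.similarity)

        stage = "map"
        mapping = map_reads(reads, contig_seqs, params)
        logger.info("mapped %d/%d reads", mapping.n_matched, len(reads))
        mapping.to_dataframe().to_csv(out / "coverage.tsv", sep="\t", index=False)

        stage = "profile"
        E = expected_single_copy_coverage(reads.total_bases, len(genome))
        profile = RedundancyProfile.from_mapping(
            mapping, E, config.rc_multiplier, config.hr_multiplier
        )
        class_table = genome_composition(
            mapping, profile.classes, len(reads), group_order=["HR", "MR", "NRC"]
        )
        class_table.to_tsv(out / "composition_by_class.tsv", decimals=2)
        logger.info("E=%.2f; thresholds %.1f / %.1f", E, profile.rc_threshold, profile.hr_threshold)

        stage = "annotate"
        library = {}
        for fam, seq in truth.family_sequences.items():
            if truth.family_category[fam] == "tandem":
                library[f"{fam}#tandem"] = seq
            else:
                sf = "Gypsy" if "Gypsy" in fam else "Copia"
                library[f"{fam}#LTR/{sf}"] = seq
        masks = ann.mask_with_library(contig_seqs, library, min_identity=config.mask_identity)
        labels = {}
        for cid, seq in contig_seqs.items():
            fracs = ann.masked_fractions(masks.get(cid, {}), len(seq))
            labels[cid] = ann.classify_contig(fracs)
        category_table = genome_composition(mapping, labels, len(reads))
        category_table.to_tsv(out / "composition_by_category.tsv", decimals=3)

        stage = "tandem"
        # monomers are pulled from a long-read (454-like) set: a full unit of
        # the longer satellite families never fits inside a 75 nt read
        long_reads = simulate_reads(
            genome, config.long_read_coverage, config.long_read_length,
            config.read_error_rate, seed=config.read_seed + 2,
        )
        fam_reports = []
        alignments = {}
        for fam, seq in truth.family_sequences.items():
            if truth.family_category[fam] != "tandem":
                continue
            report = tdm.analyze_family(
                fam, long_reads, seq, n_units=config.n_units,
                evalue_cutoff=config.evalue_tandem,
            )
            fam_reports.append(report)
            if report.alignment is not None:
                alignments[fam] = report
        tandem_df = pd.DataFrame(
            [
                {
                    "family": r.name,
                    "unit_length": r.unit_length,
                    "gc_percent": round(100 * r.gc, 1),
                    "n_units": len(r.units),
                    "n_truncated": r.n_truncated,
                    "pi": round(r.pi, 4),
                    "pi_sd": round(r.pi_sd, 4),
                }
                for r in fam_reports
            ]
        )
        tandem_df.to_csv(out / "tandem_families.tsv", sep="\t", index=False)
        if len(alignments) >= 2:
            ids, seqs_for_tree = [], []
            for fam, rep in alignments.items():
                take = rep.units[: config.nj_units_per_family]
                ids.extend(f"{fam}|{rid}" for rid, _ in take)
                seqs_for_tree.extend(u for _, u in take)
            msa = tdm.star_align(seqs_for_tree, seqs_for_tree[0])
            dm = tdm.pairwise_pdistance(msa, ids)
            tree = tdm.nj_tree(dm, alignment=msa, bootstrap=config.bootstrap,
                               seed=config.bootstrap_seed)
            tree.write(str(out / "tandem_tree.nwk"))

        stage = "ltr"
        ltr_rows = []
        for fam, seq in truth.family_sequences.items():
            if truth.family_category[fam] != "ltr":
                continue
            sf = "Gypsy" if "Gypsy" in fam else "Copia"
            model = ltrmod.LTRElementModel.from_sequence(fam, seq, superfamily=sf)
            if model.inter is None:
                continue
            element_mapping = map_reads(reads, {fam: seq}, params)
            ltrmod.measure_element(model, element_mapping, fam)
            inference = ltrmod.infer_solo_ltr(model.ratio)
            ltr_rows.append(
                {
                    "superfamily": sf,
                    "element": fam,
                    "cov_ltr": round(model.cov_ltr, 1),
                    "cov_inter": round(model.cov_inter, 1),
                    "ratio": round(model.ratio, 3),
                    "call": inference.label,
                    "solo_per_intact": round(inference.solo_per_intact, 3),
                    "caveat": inference.caveat,
                }
            )
        pd.DataFrame(ltr_rows).to_csv(out / "ltr_ratios.tsv", sep="\t", index=False)
        logger.info("pipeline complete: %s", out)
    except Exception as exc:
        logger.exception("pipeline failed at stage %s (partial outputs kept)", stage)
        raise RuntimeError(f"pipeline failed at stage {stage!r}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out
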