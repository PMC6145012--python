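"""End-to-end run orchestration: FASTQ files in, genotype tables out.

Each sample-sheet row is an analysis unit (a sample, or a
sample-replicate). Singleplex units feed all reads to their one expected
locus; multiplexed units are first split by forward primer and each
locus's reads processed separately. Stage 1 annotates and artifact-flags
unique sequences, stage 2 calls genotypes, stage 3 assembles the run-level
tables and per-locus outputs.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .allele_calling import LocusGenotype, call_locus
from .config_io import (
    KnownAlleleSet,
    LocusDefinition,
    PipelineConfig,
    SampleEntry,
)
from .read_processing import (
    SampleSequenceTable,
    annotate_unique_sequences,
    assign_locus,
    dereplicate_fastq,
    flag_artifacts,
)
from .reporting import (
    AlleleNameRegistry,
    build_contamination_matrix,
    build_flag_tables,
    build_genotype_table,
    build_length_histogram,
    build_locus_outputs,
    name_alleles,
)

__all__ = ["UnitResult", "PipelineResult", "process_unit", "run_pipeline", "write_outputs"]


@dataclass
class UnitResult:
    """Stage-1/2 results for one analysis unit (sample or sample-replicate)."""

    unit_id: str
    sample_id: str
    replicate_id: str
    raw_derep: Counter
    tables: dict[str, SampleSequenceTable]
    genotypes: dict[str, LocusGenotype]


@dataclass
class PipelineResult:
    config: PipelineConfig
    loci: Mapping[str, LocusDefinition]
    units: list[UnitResult]
    registry: AlleleNameRegistry
    genotype_table: pd.DataFrame
    flag_tables: dict[str, pd.DataFrame]
    contamination: pd.DataFrame

    def all_genotypes(self) -> list[LocusGenotype]:
        return [g for unit in self.units for g in unit.genotypes.values()]


def process_unit(
    entry: SampleEntry,
    loci: Mapping[str, LocusDefinition],
    config: Optional[PipelineConfig] = None,
) -> UnitResult:
    """Run stages 1 and 2 on one sample-sheet row."""
    config = config or PipelineConfig()
    derep = dereplicate_fastq(entry.fastq_path)
    unit_id = entry.unit_id
    tables: dict[str, SampleSequenceTable] = {}
    if entry.is_multiplexed:
        expected = {name: loci[name] for name in entry.loci_expected}
        split: dict[str, Counter] = {name: Counter() for name in entry.loci_expected}
        for seq, count in derep.items():
            hit = assign_locus(seq, expected, config.primer_max_mismatch)
            if hit is not None:
                split[hit][seq] += count
        for name in entry.loci_expected:
            tables[name] = annotate_unique_sequences(split[name], loci[name], config, unit_id)
    else:
        name = entry.loci_expected[0]
        tables[name] = annotate_unique_sequences(derep, loci[name], config, unit_id)
    genotypes: dict[str, LocusGenotype] = {}
    for name, table in tables.items():
        flag_artifacts(table, loci[name], config)
        genotypes[name] = call_locus(table, config)
    return UnitResult(
        unit_id=unit_id,
        sample_id=entry.sample_id,
        replicate_id=entry.replicate_id,
        raw_derep=derep,
        tables=tables,
        genotypes=genotypes,
    )


def run_pipeline(
    samples: list[SampleEntry],
    loci: Mapping[str, LocusDefinition],
    config: Optional[PipelineConfig] = None,
    known_alleles: Optional[KnownAlleleSet] = None,
    out_dir=None,
) -> PipelineResult:
    """Run the full pipeline over a sample sheet.

    With ``out_dir`` set, all run outputs (sequence detail CSVs, genotype
    summary, flag tables, contamination matrix, per-locus FASTA and
    alignments, length histograms, run report JSON) are written there.
    """
    config = config or PipelineConfig()
    units = [process_unit(entry, loci, config) for entry in samples]
    registry = AlleleNameRegistry(known_alleles)
    all_genotypes = [g for unit in units for g in unit.genotypes.values()]
    name_alleles(all_genotypes, registry)
    genotype_table = build_genotype_table(all_genotypes, registry, locus_order=list(loci))
    flag_tables = build_flag_tables(all_genotypes)
    contamination = build_contamination_matrix(
        {unit.unit_id: unit.raw_derep for unit in units}, loci, config.primer_max_mismatch
    )
    result = PipelineResult(
        config=config,
        loci=loci,
        units=units,
        registry=registry,
        genotype_table=genotype_table,
        flag_tables=flag_tables,
        contamination=contamination,
    )
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def write_outputs(result: PipelineResult, out_dir) -> None:
    out_dir = Path(out_dir)
    (out_dir / "sequences").mkdir(parents=True, exist_ok=True)
    (out_dir / "flags").mkdir(exist_ok=True)
    (out_dir / "histograms").mkdir(exist_ok=True)

    result.genotype_table.to_csv(out_dir / "genotype_summary.csv")
    for flag, table in result.flag_tables.items():
        table.to_csv(out_dir / "flags" / f"{flag}.csv", index=False)
    result.contamination.to_csv(out_dir / "contamination_matrix.csv")

    for unit in result.units:
        for locus_name, table in unit.tables.items():
            table.to_frame().to_csv(
                out_dir / "sequences" / f"{unit.unit_id}_{locus_name}.csv", index=False
            )
            histogram = build_length_histogram(table, unit.genotypes.get(locus_name))
            histogram.to_csv(
                out_dir / "histograms" / f"{unit.unit_id}_{locus_name}.csv", index=False
            )

    build_locus_outputs(result.registry, result.all_genotypes(), out_dir / "loci")

    report = {
        "n_units": len(result.units),
        "n_loci": len(result.loci),
        "n_genotyped": sum(
            1 for g in result.all_genotypes() if g.zygosity != "no_call"
        ),
        "thresholds": {
            "artifact_ratio": result.config.artifact_ratio,
            "min_allele_fraction": result.config.min_allele_fraction,
            "min_locus_reads": result.config.min_locus_reads,
            "primer_max_mismatch": result.config.primer_max_mismatch,
        },
        "rng_seed": result.config.rng_seed,
    }
    (out_dir / "run_report.json").write_text(json.dumps(report, indent=2) + "\n")
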