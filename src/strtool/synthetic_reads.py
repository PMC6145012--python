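"""Synthetic amplicon-read simulator with known ground truth.

Generates, per locus, a pool of tetranucleotide-repeat alleles (including
same-length sequence variants that fragment sizing could not resolve),
draws diploid genotypes for a population (optionally with parent-offspring
pedigrees), and emits reads carrying the error processes the genotyping
filters are built for: polymerase stutter (one repeat unit shorter than
the template), per-base substitution errors, rare single indels,
off-target reads from other loci, negative-binomial coverage variation,
and per-allele dropout.

Stutter semantics: ``stutter_rate`` is the expected ratio of stuttered to
correct reads per allele — the very quantity the one-third artifact filter
tests — implemented by drawing ``Binomial(coverage, stutter_rate)``
stuttered copies *in addition to* the correct reads. Substitutions and
indels then apply to stuttered and correct reads alike.

Everything is driven by a single :class:`numpy.random.Generator`, so a
fixed seed reproduces the dataset byte for byte.
"""

from __future__ import annotations

import gzip
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .allele_calling import call_locus
from .config_io import LocusDefinition, PipelineConfig, write_locus_definitions
from .read_processing import annotate_unique_sequences, flag_artifacts, stutter_products
from .reporting import AlleleNameRegistry

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "example_loci",
    "simulate_allele_pool",
    "simulate_population_genotypes",
    "simulate_locus_read_counts",
    "simulate_locus_reads",
    "write_fixture_dataset",
    "pipeline_calls",
    "evaluate_recovery",
    "audit_stutter_calls",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a simulated dataset.

    Defaults emulate a pooled-replicate amplicon sequencing run of a
    noninvasively sampled population typed at eight tetranucleotide loci:
    ~2000 reads per allele, stutter at 15% of the allele's reads,
    0.3% per-base substitution error, occasional single indels and
    off-target reads, and no dropout.
    """

    loci: Mapping[str, LocusDefinition]
    alleles_per_locus: int = 8
    same_length_variant_prob: float = 0.25
    n_individuals: int = 20
    coverage_mean: float = 2000.0
    coverage_dispersion: float = 20.0  # negative-binomial shape; larger = tighter
    stutter_rate: float = 0.15  # expected stuttered:correct read ratio
    substitution_rate: float = 0.003  # per base
    indel_rate: float = 0.002  # per read
    off_target_rate: float = 0.02  # per read
    dropout_prob: float = 0.0  # per allele per sample
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "same_length_variant_prob",
            "stutter_rate",
            "substitution_rate",
            "indel_rate",
            "off_target_rate",
            "dropout_prob",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        if self.coverage_dispersion <= 0:
            raise ValueError("coverage_dispersion must be positive")
        if self.alleles_per_locus < 1:
            raise ValueError("alleles_per_locus must be >= 1")


@dataclass
class SimulatedDataset:
    """Ground truth plus on-disk artifacts of one simulated run."""

    root: Path
    pool: dict[str, list[str]]
    genotypes: dict[str, dict[str, tuple[str, str]]]
    locus_table: Path
    sample_sheet: Path
    known_alleles: Path
    truth_genotypes: Path
    fastq_paths: dict[tuple[str, str], Path]
    event_log: pd.DataFrame


def example_loci() -> dict[str, LocusDefinition]:
    """A panel of eight synthetic tetranucleotide loci (150-360 bp amplicons)."""
    rows = [
        ("A", "GTTCCAGGCTAACAGTTAGC", "CATCGTTAAGGCTTCAGGAC", 150, 220, "AGAT"),
        ("B", "ACCTGATTGCACGTAGGTCA", "TGGACCTAATCGCTTACAGG", 180, 260, "TAGA"),
        ("C", "CGATTACCTGAAGTGGTCCA", "AGGTCAACGGATTCCATGTT", 150, 240, "TCTA"),
        ("D", "TTGGCACGATCATACCAGGT", "CCTAGGTTCAATGACGGACA", 220, 320, "GATA"),
        ("1", "AGGCTTACGTCAGATCCTGA", "GTCCATTGGAACGCTAGTCA", 200, 300, "CTTT"),
        ("2", "CCATGGTCAGTTACGAGTCA", "TTCAGGACCATGGTTCAAGC", 240, 340, "TATC"),
        ("3", "GACTCAGGATTACGGTACCT", "AACGGTCCTTGATCAGGTCA", 200, 300, "ATCT"),
        ("4", "TCCGATAACGGTTCACTGGA", "GGTTCACCATTGACGTAGCA", 240, 356, "TTTA"),
    ]
    return {
        name: LocusDefinition(name, fwd, rev, lo, hi, motif)
        for name, fwd, rev, lo, hi, motif in rows
    }


# ---------------------------------------------------------------------------
# Allele pools and genotypes
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _render(locus: LocusDefinition, left: str, repeats: int, right: str) -> str:
    return locus.forward_primer + left + locus.motif * repeats + right + locus.reverse_primer


def _flank_variant(
    left: str, right: str, rng: np.random.Generator
) -> tuple[str, str]:
    """Mutate the flanks, preserving total length and edit distance >= 2.

    Either 2-3 substitutions, or a compensated single-base deletion in one
    flank plus insertion in the other — the homoplasy classes that
    fragment-sizing methods merge into one allele.
    """
    if rng.random() < 0.7:
        combined = list(left + right)
        n_sub = int(rng.integers(2, 4))
        positions = rng.choice(len(combined), size=min(n_sub, len(combined)), replace=False)
        for pos in positions:
            old = combined[pos]
            combined[pos] = rng.choice([b for b in _BASES if b != old])
        new = "".join(combined)
        return new[: len(left)], new[len(left) :]
    # compensated indel: drop one base from the left flank, add one to the right
    lchars = list(left)
    del lchars[int(rng.integers(0, len(lchars)))]
    rchars = list(right)
    rchars.insert(int(rng.integers(0, len(rchars) + 1)), _BASES[int(rng.integers(0, 4))])
    return "".join(lchars), "".join(rchars)


def simulate_allele_pool(
    locus: LocusDefinition,
    alleles_per_locus: int,
    same_length_variant_prob: float,
    rng: np.random.Generator,
    min_repeats: int = 4,
) -> list[str]:
    """Draw a pool of distinct alleles for one locus.

    Alleles share a locus-specific flank template and differ in repeat
    count; with probability ``same_length_variant_prob`` a new allele is
    instead a same-length sequence variant (substitutions or a compensated
    indel) of an existing one.
    """
    m = len(locus.motif)
    left = _random_dna(rng, 12)
    right = _random_dna(rng, 14)
    # avoid extending the repeat run into the flanks
    while left.endswith(locus.motif):
        left = _random_dna(rng, 12)
    while right.startswith(locus.motif):
        right = _random_dna(rng, 14)
    fixed = len(locus.forward_primer) + len(locus.reverse_primer) + len(left) + len(right)
    k_min = max(min_repeats, math.ceil((locus.length_min - fixed) / m))
    k_max = (locus.length_max - fixed) // m
    if k_max < k_min:
        raise ValueError(
            f"locus {locus.name}: length range too narrow for {min_repeats}+ repeats"
        )
    available = list(range(k_min, k_max + 1))
    rng.shuffle(available)

    segments: list[tuple[str, int, str]] = []
    sequences: list[str] = []
    while len(segments) < alleles_per_locus:
        make_variant = segments and (rng.random() < same_length_variant_prob or not available)
        if make_variant:
            for _attempt in range(20):
                bl, bk, br = segments[int(rng.integers(0, len(segments)))]
                vl, vr = _flank_variant(bl, br, rng)
                candidate = _render(locus, vl, bk, vr)
                if candidate not in sequences and locus.motif * min_repeats in candidate:
                    segments.append((vl, bk, vr))
                    sequences.append(candidate)
                    break
            else:
                if not available:
                    raise RuntimeError(f"locus {locus.name}: could not grow allele pool")
                make_variant = False
        if not make_variant:
            k = available.pop()
            segments.append((left, k, right))
            sequences.append(_render(locus, left, k, right))
    for seq in sequences:
        assert locus.length_min <= len(seq) <= locus.length_max
    return sequences


def simulate_population_genotypes(
    pool: Mapping[str, list[str]],
    n_individuals: int,
    rng: np.random.Generator,
    pedigree: Optional[Sequence[tuple[str, str, str]]] = None,
) -> dict[str, dict[str, tuple[str, str]]]:
    """Draw diploid genotypes: founders uniformly, pedigreed children Mendelian.

    ``pedigree`` is a sequence of ``(child_id, mother_id, father_id)``
    tuples; each child draws one allele uniformly from each parent's pair
    at every locus, so children are Mendelian-consistent by construction.
    """
    genotypes: dict[str, dict[str, tuple[str, str]]] = {}
    for i in range(n_individuals):
        individual = f"ind{i + 1:03d}"
        entry: dict[str, tuple[str, str]] = {}
        for locus_name, alleles in pool.items():
            picks = rng.integers(0, len(alleles), size=2)
            pair = (alleles[picks[0]], alleles[picks[1]])
            entry[locus_name] = tuple(sorted(pair))
        genotypes[individual] = entry
    for child, mother, father in pedigree or []:
        for parent in (mother, father):
            if parent not in genotypes:
                raise ValueError(f"pedigree parent {parent!r} has no genotype")
        entry = {}
        for locus_name in pool:
            maternal = genotypes[mother][locus_name][int(rng.integers(0, 2))]
            paternal = genotypes[father][locus_name][int(rng.integers(0, 2))]
            entry[locus_name] = tuple(sorted((maternal, paternal)))
        genotypes[child] = entry
    return genotypes


# ---------------------------------------------------------------------------
# Read generation
# ---------------------------------------------------------------------------

def _one_stutter(sequence: str, motif: str, rng: np.random.Generator) -> str:
    """Delete one motif copy from a repeat run, at a random valid position."""
    m = len(motif)
    positions = [
        i
        for i in range(len(sequence) - m + 1)
        if sequence[i : i + m] == motif
        and (sequence[i + m : i + 2 * m] == motif or (i >= m and sequence[i - m : i] == motif))
    ]
    if not positions:
        raise ValueError("sequence has no repeat run to stutter")
    i = positions[int(rng.integers(0, len(positions)))]
    return sequence[:i] + sequence[i + m :]


def _mutate(seq: str, rng: np.random.Generator, n_subs: int, indel: bool) -> str:
    chars = list(seq)
    if indel:
        if rng.random() < 0.5 and len(chars) > 1:
            del chars[int(rng.integers(0, len(chars)))]
        else:
            chars.insert(int(rng.integers(0, len(chars) + 1)), _BASES[int(rng.integers(0, 4))])
    if n_subs:
        positions = rng.choice(len(chars), size=min(n_subs, len(chars)), replace=False)
        for pos in positions:
            old = chars[pos]
            chars[pos] = rng.choice([b for b in _BASES if b != old])
    return "".join(chars)


def _emit_with_errors(
    template: str,
    n_reads: int,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    counts: Counter,
    log: Counter,
    allow_indel: bool = True,
) -> None:
    """Add ``n_reads`` copies of ``template`` with per-read sequencing errors."""
    if n_reads <= 0:
        return
    length = len(template)
    n_indel = rng.binomial(n_reads, cfg.indel_rate) if (allow_indel and cfg.indel_rate) else 0
    if cfg.substitution_rate:
        sub_counts = rng.binomial(length, cfg.substitution_rate, size=n_reads)
    else:
        sub_counts = np.zeros(n_reads, dtype=int)
    clean = int(np.sum(sub_counts[n_indel:] == 0))
    if clean:
        counts[template] += clean
    for i in range(n_reads):
        has_indel = i < n_indel
        n_subs = int(sub_counts[i])
        if not has_indel and n_subs == 0:
            continue
        counts[_mutate(template, rng, n_subs, has_indel)] += 1
        if has_indel:
            log["indel_reads"] += 1
        if n_subs:
            log["substituted_reads"] += 1


def simulate_locus_read_counts(
    genotype_pair: tuple[str, str],
    locus: LocusDefinition,
    pool: Mapping[str, list[str]],
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[Counter, Counter]:
    """Simulate one sample x locus reaction as dereplicated counts.

    Returns the sequence -> read count map and an event log with the
    number of stutter, substituted, indel, off-target, and dropped-out
    draws actually realized.
    """
    for allele in genotype_pair:
        if allele not in pool.get(locus.name, []):
            raise ValueError(f"genotype allele absent from locus {locus.name} pool")
    counts: Counter = Counter()
    log: Counter = Counter()
    others = [
        seq for name, alleles in pool.items() if name != locus.name for seq in alleles
    ]
    p_nb = cfg.coverage_dispersion / (cfg.coverage_dispersion + cfg.coverage_mean)
    for allele in genotype_pair:
        if cfg.dropout_prob and rng.random() < cfg.dropout_prob:
            log["dropouts"] += 1
            continue
        coverage = max(1, int(rng.negative_binomial(cfg.coverage_dispersion, p_nb)))
        log["coverage"] += coverage
        n_off = rng.binomial(coverage, cfg.off_target_rate) if (cfg.off_target_rate and others) else 0
        n_core = coverage - n_off
        _emit_with_errors(allele, n_core, cfg, rng, counts, log)
        if cfg.stutter_rate:
            n_stutter = rng.binomial(n_core, cfg.stutter_rate)
            if n_stutter:
                log["stutter_reads"] += int(n_stutter)
                stuttered = _one_stutter(allele, locus.motif, rng)
                _emit_with_errors(stuttered, int(n_stutter), cfg, rng, counts, log)
        for _ in range(n_off):
            log["off_target_reads"] += 1
            template = others[int(rng.integers(0, len(others)))]
            _emit_with_errors(template, 1, cfg, rng, counts, log, allow_indel=False)
    return counts, log


def simulate_locus_reads(
    genotype_pair: tuple[str, str],
    locus: LocusDefinition,
    pool: Mapping[str, list[str]],
    cfg: SimulationConfig,
    rng: np.random.Generator,
    read_prefix: str = "read",
) -> tuple[list[tuple[str, str, str]], Counter]:
    """As :func:`simulate_locus_read_counts`, expanded to FASTQ records.

    Records are ``(title, sequence, quality)`` tuples with a constant
    quality string (the pipeline ignores base qualities), emitted in
    deterministic order (descending count, then sequence).
    """
    counts, log = simulate_locus_read_counts(genotype_pair, locus, pool, cfg, rng)
    records = []
    index = 0
    for seq, count in sorted(counts.items(), key=lambda item: (-item[1], item[0])):
        for _ in range(count):
            index += 1
            records.append((f"{read_prefix}_{index}", seq, "I" * len(seq)))
    return records, log


# ---------------------------------------------------------------------------
# On-disk fixtures
# ---------------------------------------------------------------------------

def _write_fastq(path: Path, records: Iterable[tuple[str, str, str]]) -> None:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as handle:
        for title, seq, qual in records:
            handle.write(f"@{title}\n{seq}\n+\n{qual}\n")


def write_fixture_dataset(
    cfg: SimulationConfig,
    out_dir,
    multiplex: bool = False,
    replicates: int = 1,
    gzip_fastq: bool = False,
    pedigree: Optional[Sequence[tuple[str, str, str]]] = None,
) -> SimulatedDataset:
    """Write a complete, ready-to-run dataset: FASTQ + truth tables + sheets.

    Singleplex mode writes one FASTQ per individual x locus (x replicate);
    multiplex mode pools all loci of an individual into one file. The
    dataset is fully determined by ``cfg.rng_seed``.
    """
    out_dir = Path(out_dir)
    (out_dir / "fastq").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.rng_seed)
    pool = {
        name: simulate_allele_pool(
            locus, cfg.alleles_per_locus, cfg.same_length_variant_prob, rng
        )
        for name, locus in cfg.loci.items()
    }
    genotypes = simulate_population_genotypes(pool, cfg.n_individuals, rng, pedigree)

    registry = AlleleNameRegistry()
    allele_rows = []
    for name, alleles in pool.items():
        for seq in alleles:
            allele_rows.append({"Locus": name, "Name": registry.name(name, seq), "Sequence": seq})
    known_alleles = out_dir / "truth_alleles.csv"
    pd.DataFrame(allele_rows).to_csv(known_alleles, index=False)

    genotype_rows = []
    for individual, genotype in genotypes.items():
        for locus_name, (a1, a2) in genotype.items():
            genotype_rows.append(
                {
                    "Individual": individual,
                    "Locus": locus_name,
                    "Allele1": registry.name(locus_name, a1),
                    "Allele2": registry.name(locus_name, a2),
                }
            )
    truth_genotypes = out_dir / "truth_genotypes.csv"
    pd.DataFrame(genotype_rows).to_csv(truth_genotypes, index=False)

    locus_table = out_dir / "loci.csv"
    write_locus_definitions(cfg.loci, locus_table)

    suffix = ".fastq.gz" if gzip_fastq else ".fastq"
    sheet_rows = []
    fastq_paths: dict[tuple[str, str], Path] = {}
    log_rows = []
    for individual in genotypes:
        for replicate in range(1, replicates + 1):
            rep_id = str(replicate) if replicates > 1 else ""
            tag = f"{individual}_r{replicate}" if replicates > 1 else individual
            if multiplex:
                pooled: list[tuple[str, str, str]] = []
                for locus_name, locus in cfg.loci.items():
                    records, log = simulate_locus_reads(
                        genotypes[individual][locus_name],
                        locus,
                        pool,
                        cfg,
                        rng,
                        read_prefix=f"{tag}_{locus_name}",
                    )
                    pooled.extend(records)
                    log_rows.append({"Sample": tag, "Locus": locus_name, **log})
                path = out_dir / "fastq" / f"{tag}{suffix}"
                _write_fastq(path, pooled)
                fastq_paths[(tag, "*")] = path
                sheet_rows.append(
                    {
                        "SampleID": individual,
                        "Replicate": rep_id,
                        "Loci": ";".join(cfg.loci),
                        "FastqPath": str(path.relative_to(out_dir)),
                    }
                )
            else:
                for locus_name, locus in cfg.loci.items():
                    records, log = simulate_locus_reads(
                        genotypes[individual][locus_name],
                        locus,
                        pool,
                        cfg,
                        rng,
                        read_prefix=f"{tag}_{locus_name}",
                    )
                    path = out_dir / "fastq" / f"{tag}_{locus_name}{suffix}"
                    _write_fastq(path, records)
                    fastq_paths[(tag, locus_name)] = path
                    log_rows.append({"Sample": tag, "Locus": locus_name, **log})
                    sheet_rows.append(
                        {
                            "SampleID": individual,
                            "Replicate": rep_id,
                            "Locus": locus_name,
                            "FastqPath": str(path.relative_to(out_dir)),
                        }
                    )
    sample_sheet = out_dir / "samples.csv"
    pd.DataFrame(sheet_rows).to_csv(sample_sheet, index=False)
    event_log = pd.DataFrame(log_rows).fillna(0)
    event_log.to_csv(out_dir / "event_log.csv", index=False)

    return SimulatedDataset(
        root=out_dir,
        pool=pool,
        genotypes=genotypes,
        locus_table=locus_table,
        sample_sheet=sample_sheet,
        known_alleles=known_alleles,
        truth_genotypes=truth_genotypes,
        fastq_paths=fastq_paths,
        event_log=event_log,
    )


# ---------------------------------------------------------------------------
# In-memory round trips (simulation -> stages 1+2), used for evaluation
# ---------------------------------------------------------------------------

def pipeline_calls(
    sim_cfg: SimulationConfig,
    pipeline_cfg: Optional[PipelineConfig] = None,
):
    """Simulate a population and yield per-locus calls next to the truth.

    Yields ``(individual, locus_name, truth_pair, genotype)`` where
    ``genotype`` is the stage-1+2 call on the simulated reads. Runs fully
    in memory; :func:`write_fixture_dataset` covers the on-disk path.
    """
    pipeline_cfg = pipeline_cfg or PipelineConfig()
    rng = np.random.default_rng(sim_cfg.rng_seed)
    pool = {
        name: simulate_allele_pool(
            locus, sim_cfg.alleles_per_locus, sim_cfg.same_length_variant_prob, rng
        )
        for name, locus in sim_cfg.loci.items()
    }
    genotypes = simulate_population_genotypes(pool, sim_cfg.n_individuals, rng)
    for individual, genotype in genotypes.items():
        for locus_name, pair in genotype.items():
            locus = sim_cfg.loci[locus_name]
            counts, _log = simulate_locus_read_counts(pair, locus, pool, sim_cfg, rng)
            table = annotate_unique_sequences(counts, locus, pipeline_cfg, sample_id=individual)
            flag_artifacts(table, locus, pipeline_cfg)
            yield individual, locus_name, pair, call_locus(table, pipeline_cfg)


def evaluate_recovery(
    sim_cfg: SimulationConfig,
    pipeline_cfg: Optional[PipelineConfig] = None,
) -> tuple[int, int, list]:
    """Fraction of truth genotypes recovered exactly by the pipeline.

    Returns ``(n_exact, n_total, miscalls)`` where each miscall records
    ``(individual, locus, truth_pair, called_pair)``.
    """
    n_exact = 0
    n_total = 0
    miscalls = []
    for individual, locus_name, truth, genotype in pipeline_calls(sim_cfg, pipeline_cfg):
        called = genotype.allele_pair
        called_sorted = tuple(sorted(called)) if called is not None else None
        if called_sorted == tuple(sorted(truth)):
            n_exact += 1
        else:
            miscalls.append((individual, locus_name, truth, called_sorted))
        n_total += 1
    return n_exact, n_total, miscalls


def audit_stutter_calls(
    sim_cfg: SimulationConfig,
    pipeline_cfg: Optional[PipelineConfig] = None,
) -> dict:
    """Count called alleles that are stutter products rather than truth.

    A called allele counts as a *stutter call* when it is not one of the
    individual's true alleles but equals a one-motif-unit deletion product
    of one of them. Used to verify that the artifact filter removes all
    stutter below the one-third ratio, and (with stutter overloads) that
    it correctly stops doing so above it.
    """
    n_loci = 0
    n_called_alleles = 0
    n_stutter_calls = 0
    n_exact = 0
    for _individual, locus_name, truth, genotype in pipeline_calls(sim_cfg, pipeline_cfg):
        motif = sim_cfg.loci[locus_name].motif
        n_loci += 1
        truth_set = set(truth)
        called = genotype.allele_pair
        if called is not None and set(called) == truth_set:
            n_exact += 1
        for allele in {a.sequence for a in genotype.alleles}:
            n_called_alleles += 1
            if allele not in truth_set and any(
                allele in stutter_products(t, motif) for t in truth_set
            ):
                n_stutter_calls += 1
    return {
        "n_loci": n_loci,
        "n_exact": n_exact,
        "n_called_alleles": n_called_alleles,
        "n_stutter_calls": n_stutter_calls,
    }
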