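"""Synthetic read simulator: pools, genotypes, error processes, fixtures."""

import gzip
import math
from collections import Counter

import numpy as np
import pytest

from strtool import (
    PipelineConfig,
    SimulationConfig,
    annotate_unique_sequences,
    call_locus,
    dereplicate_fastq,
    example_loci,
    flag_artifacts,
    genotyping_error_rate,
    mendelian_consistency,
    simulate_allele_pool,
    simulate_locus_read_counts,
    simulate_locus_reads,
    simulate_population_genotypes,
    stutter_products,
    write_fixture_dataset,
)
from strtool.config_io import KnownGenotype
from strtool.synthetic_reads import pipeline_calls

import oracle


@pytest.fixture(scope="module")
def loci():
    return example_loci()


def _sim(loci, **overrides):
    return SimulationConfig(loci=loci, **overrides)


# ---------------------------------------------------------------------------
# Allele pools
# ---------------------------------------------------------------------------

def test_pool_without_variants_differs_by_whole_repeat_units(loci, rng):
    locus = loci["B"]
    pool = simulate_allele_pool(locus, 6, same_length_variant_prob=0.0, rng=rng)
    assert len(set(pool)) == 6
    lengths = sorted(len(seq) for seq in pool)
    for a, b in zip(lengths, lengths[1:]):
        assert (b - a) % len(locus.motif) == 0
    for seq in pool:
        assert locus.length_min <= len(seq) <= locus.length_max
        assert seq.startswith(locus.forward_primer)
        assert locus.motif * 3 in seq


def test_pool_with_forced_variants_creates_same_length_homoplasy(loci, rng):
    locus = loci["C"]
    pool = simulate_allele_pool(locus, 2, same_length_variant_prob=1.0, rng=rng)
    assert len(pool) == 2
    assert len(pool[0]) == len(pool[1])
    assert pool[0] != pool[1]
    assert oracle.levenshtein(pool[0], pool[1]) >= 2


def test_pool_is_seed_deterministic(loci):
    first = simulate_allele_pool(loci["A"], 8, 0.25, np.random.default_rng(42))
    second = simulate_allele_pool(loci["A"], 8, 0.25, np.random.default_rng(42))
    assert first == second


# ---------------------------------------------------------------------------
# Population genotypes
# ---------------------------------------------------------------------------

def test_pedigree_children_draw_one_allele_per_parent(loci, rng):
    pool = {"A": ["w", "x", "y", "z"]}
    genotypes = simulate_population_genotypes(pool, 2, rng)
    genotypes_with_child = simulate_population_genotypes(
        pool, 2, np.random.default_rng(0), pedigree=[("kid", "ind001", "ind002")]
    )
    kid = genotypes_with_child["kid"]["A"]
    mother = genotypes_with_child["ind001"]["A"]
    father = genotypes_with_child["ind002"]["A"]
    _, consistent = mendelian_consistency({"A": kid}, {"A": mother}, {"A": father})
    assert consistent
    assert simulate_population_genotypes(pool, 0, rng) == {}
    a, b = genotypes["ind001"]["A"]
    assert a in pool["A"] and b in pool["A"]


def test_simulated_trios_are_always_mendelian_consistent(loci, rng):
    pool = {name: simulate_allele_pool(locus, 6, 0.2, rng) for name, locus in loci.items()}
    pedigree = [(f"child{i}", "ind001", "ind002") for i in range(20)]
    genotypes = simulate_population_genotypes(pool, 5, rng, pedigree=pedigree)
    for child, mother, father in pedigree:
        _, consistent = mendelian_consistency(
            genotypes[child], genotypes[mother], genotypes[father]
        )
        assert consistent


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def test_noise_free_reads_equal_truth_alleles(loci, rng):
    locus = loci["A"]
    pool = {"A": simulate_allele_pool(locus, 4, 0.0, rng)}
    pair = (pool["A"][0], pool["A"][1])
    cfg = _sim(
        loci,
        stutter_rate=0.0,
        substitution_rate=0.0,
        indel_rate=0.0,
        off_target_rate=0.0,
        coverage_mean=200.0,
    )
    counts, log = simulate_locus_read_counts(pair, locus, pool, cfg, rng)
    assert set(counts) == set(pair)
    assert sum(counts.values()) == log["coverage"]


def test_total_dropout_yields_no_reads(loci, rng):
    locus = loci["A"]
    pool = {"A": simulate_allele_pool(locus, 4, 0.0, rng)}
    cfg = _sim(loci, dropout_prob=1.0)
    counts, log = simulate_locus_read_counts(
        (pool["A"][0], pool["A"][1]), locus, pool, cfg, rng
    )
    assert counts == Counter()
    assert log["dropouts"] == 2


def test_stutter_fraction_matches_configured_rate(loci, rng):
    locus = loci["A"]
    pool = {"A": simulate_allele_pool(locus, 4, 0.0, rng)}
    pair = (pool["A"][0], pool["A"][0])
    cfg = _sim(
        loci,
        stutter_rate=0.15,
        substitution_rate=0.0,
        indel_rate=0.0,
        off_target_rate=0.0,
        coverage_mean=2000.0,
    )
    counts, log = simulate_locus_read_counts(pair, locus, pool, cfg, rng)
    n = log["coverage"]
    observed = log["stutter_reads"] / n
    sigma = math.sqrt(0.15 * 0.85 / n)
    assert abs(observed - 0.15) < 3 * sigma
    # stuttered reads really are one motif unit short of the allele
    stuttered = [seq for seq in counts if seq != pair[0]]
    assert all(seq in stutter_products(pair[0], locus.motif) for seq in stuttered)


def test_unknown_genotype_allele_is_rejected(loci, rng):
    locus = loci["A"]
    pool = {"A": simulate_allele_pool(locus, 2, 0.0, rng)}
    cfg = _sim(loci)
    with pytest.raises(ValueError, match="absent from locus"):
        simulate_locus_read_counts(("ACGT", "ACGT"), locus, pool, cfg, rng)


def test_read_records_expand_counts(loci, rng):
    locus = loci["A"]
    pool = {"A": simulate_allele_pool(locus, 2, 0.0, rng)}
    cfg = _sim(loci, coverage_mean=50.0, stutter_rate=0.0, substitution_rate=0.0,
               indel_rate=0.0, off_target_rate=0.0)
    records, log = simulate_locus_reads(
        (pool["A"][0], pool["A"][0]), locus, pool, cfg, rng, read_prefix="x"
    )
    assert len(records) == log["coverage"]
    title, seq, qual = records[0]
    assert title.startswith("x_") and len(seq) == len(qual)


# ---------------------------------------------------------------------------
# Fixture datasets on disk
# ---------------------------------------------------------------------------

def _tiny_cfg(loci):
    two = {name: loci[name] for name in ("A", "B")}
    return SimulationConfig(
        loci=two, n_individuals=3, coverage_mean=60.0, alleles_per_locus=4, rng_seed=11
    )


def test_fixture_dataset_is_byte_identical_across_runs(loci, tmp_path):
    cfg = _tiny_cfg(loci)
    first = write_fixture_dataset(cfg, tmp_path / "one")
    second = write_fixture_dataset(cfg, tmp_path / "two")
    assert first.genotypes == second.genotypes
    for key, path in first.fastq_paths.items():
        assert path.read_bytes() == second.fastq_paths[key].read_bytes()


def test_fixture_dataset_file_layout(loci, tmp_path):
    cfg = _tiny_cfg(loci)
    dataset = write_fixture_dataset(cfg, tmp_path)
    assert len(dataset.fastq_paths) == 3 * 2  # singleplex: individuals x loci
    truth = dataset.truth_genotypes.read_text().strip().splitlines()
    assert len(truth) - 1 == 3 * 2  # header + one row per individual x locus
    multiplexed = write_fixture_dataset(cfg, tmp_path / "mx", multiplex=True)
    assert len(multiplexed.fastq_paths) == 3  # one pooled file per individual


def test_fixture_dataset_gzip_round_trip(loci, tmp_path):
    cfg = _tiny_cfg(loci)
    dataset = write_fixture_dataset(cfg, tmp_path, gzip_fastq=True)
    path = next(iter(dataset.fastq_paths.values()))
    assert path.suffix == ".gz"
    counts = dereplicate_fastq(path)
    assert sum(counts.values()) > 0


# ---------------------------------------------------------------------------
# Error-process realism
# ---------------------------------------------------------------------------

def test_dropout_only_runs_produce_no_false_alleles(loci):
    cfg = SimulationConfig(
        loci=loci,
        n_individuals=6,
        dropout_prob=0.25,
        substitution_rate=0.0,
        indel_rate=0.0,
        off_target_rate=0.0,
        coverage_mean=1500.0,
        rng_seed=5,
    )
    observed = {}
    reference = {}
    for individual, locus_name, truth, genotype in pipeline_calls(cfg):
        observed.setdefault(individual, {})[locus_name] = genotype.allele_pair
        reference.setdefault(individual, {})[locus_name] = truth
    tally = genotyping_error_rate(
        observed,
        {ind: KnownGenotype(ind, genos) for ind, genos in reference.items()},
        loci,
    )
    assert tally.false_allele == 0
    assert tally.allelic_dropout + tally.missing_locus > 0  # dropout did occur


def test_pooling_replicates_reduces_error_tally(loci):
    """Merging reads of three replicate reactions never increases errors."""
    rng = np.random.default_rng(17)
    cfg = SimulationConfig(
        loci=loci,
        n_individuals=4,
        dropout_prob=0.3,
        coverage_mean=1200.0,
        substitution_rate=0.0,
        indel_rate=0.0,
        off_target_rate=0.0,
        rng_seed=17,
    )
    pcfg = PipelineConfig()
    pool = {
        name: simulate_allele_pool(locus, 6, 0.2, rng) for name, locus in loci.items()
    }
    genotypes = simulate_population_genotypes(pool, cfg.n_individuals, rng)

    def tally_for(observed, reference):
        return genotyping_error_rate(
            observed, {ind: KnownGenotype(ind, g) for ind, g in reference.items()}, loci
        )

    replicate_obs = [dict() for _ in range(3)]
    pooled_obs = {}
    reference = {}
    for individual, genotype in genotypes.items():
        reference[individual] = dict(genotype)
        for locus_name, pair in genotype.items():
            locus = loci[locus_name]
            merged = Counter()
            for r in range(3):
                counts, _ = simulate_locus_read_counts(pair, locus, pool, cfg, rng)
                merged.update(counts)
                table = flag_artifacts(
                    annotate_unique_sequences(counts, locus, pcfg), locus, pcfg
                )
                replicate_obs[r].setdefault(individual, {})[locus_name] = call_locus(
                    table, pcfg
                ).allele_pair
            table = flag_artifacts(
                annotate_unique_sequences(merged, locus, pcfg), locus, pcfg
            )
            pooled_obs.setdefault(individual, {})[locus_name] = call_locus(
                table, pcfg
            ).allele_pair

    pooled_errors = tally_for(pooled_obs, reference).erroneous_alleles
    for r in range(3):
        assert pooled_errors <= tally_for(replicate_obs[r], reference).erroneous_alleles
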