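"""Distance scores, identification, Mendelian checks, and diversity statistics."""

import pytest

from strtool import (
    AlleleFrequencyTable,
    KnownGenotype,
    allele_frequencies,
    allelic_diversity,
    expected_heterozygosity,
    genotype_distance,
    genotyping_error_rate,
    identify_individual,
    mean_expected_heterozygosity,
    mendelian_consistency,
)
from strtool.synthetic_reads import example_loci


def _known(individual, **loci):
    return KnownGenotype(individual_id=individual, alleles=dict(loci))


EIGHT = {f"L{i}": (f"a{i}", f"b{i}") for i in range(8)}


# ---------------------------------------------------------------------------
# Distance
# ---------------------------------------------------------------------------

def test_distance_zero_iff_identical():
    reference = _known("x", **EIGHT)
    assert genotype_distance(dict(EIGHT), reference).score == 0
    changed = dict(EIGHT)
    changed["L0"] = ("a0", "zz")
    assert genotype_distance(changed, reference).score == 1


def test_distance_two_allele_difference_scores_two():
    reference = _known("x", **EIGHT)
    query = dict(EIGHT)
    query["L0"] = ("zz", "zz")  # both alleles differ at one locus
    assert genotype_distance(query, reference).score == 2
    query = dict(EIGHT)
    query["L0"] = ("a0", "q")
    query["L1"] = ("a1", "q")  # one allele at each of two loci
    assert genotype_distance(query, reference).score == 2


def test_missing_locus_contributes_two():
    reference = _known("x", **EIGHT)
    query = dict(EIGHT)
    query["L3"] = None
    assert genotype_distance(query, reference).score == 2


def test_distance_is_symmetric_on_complete_genotypes():
    g1 = {f"L{i}": (f"a{i}", f"b{i}") for i in range(4)}
    g2 = {f"L{i}": (f"a{i}", f"c{i}") for i in range(4)}
    assert genotype_distance(g1, g2).score == genotype_distance(g2, g1).score == 4


def test_distance_errors_on_disjoint_panels():
    with pytest.raises(ValueError, match="no loci"):
        genotype_distance({"L0": ("a", "b")}, _known("x", L5=("a", "b")))


def test_homozygote_vs_heterozygote_counts_one_mismatch():
    assert genotype_distance({"L": ("a", "a")}, _known("x", L=("a", "b"))).score == 1


# ---------------------------------------------------------------------------
# Identification
# ---------------------------------------------------------------------------

def test_identification_assigns_perfect_and_dropout_matches():
    knowns = [
        _known("alpha", **EIGHT),
        _known(
            "beta", **{locus: (pair[0], pair[0]) for locus, pair in EIGHT.items()}
        ),
    ]
    scores, assignment = identify_individual(dict(EIGHT), knowns)
    assert assignment == "alpha" and scores[0].score == 0
    dropout = dict(EIGHT)
    dropout["L0"] = ("a0", "a0")  # one allelic dropout -> distance 1
    _, assignment = identify_individual(dropout, knowns)
    assert assignment == "alpha"


def test_identification_rejects_distant_best_match():
    knowns = [_known("alpha", **EIGHT)]
    query = dict(EIGHT)
    for locus in ("L0", "L1", "L2"):
        query[locus] = ("q", "q")  # 6 mismatches
    scores, assignment = identify_individual(query, knowns)
    assert scores[0].score == 6 and assignment is None


def test_identification_is_invariant_to_known_order_and_breaks_ties_by_id():
    twin_a = _known("ina", **EIGHT)
    twin_b = _known("inb", **EIGHT)
    _, first = identify_individual(dict(EIGHT), [twin_b, twin_a])
    _, second = identify_individual(dict(EIGHT), [twin_a, twin_b])
    assert first == second == "ina"


# ---------------------------------------------------------------------------
# Mendelian consistency
# ---------------------------------------------------------------------------

def test_paternity_exclusion_by_homozygous_offspring():
    # offspring homozygous for one allele; a candidate father carrying only
    # a different same-length variant is excluded
    offspring = {"L3": ("238-a", "238-a")}
    mother = {"L3": ("238-a", "240-a")}
    father = {"L3": ("238-b", "242-a")}
    verdicts, consistent = mendelian_consistency(offspring, mother, father)
    assert verdicts == {"L3": False} and not consistent


def test_consistent_and_inconsistent_trios():
    assert mendelian_consistency(
        {"L": ("a", "b")}, {"L": ("a", "a")}, {"L": ("b", "c")}
    )[1]
    # maternal allele absent: a/b offspring cannot come from c/c mother
    assert not mendelian_consistency(
        {"L": ("a", "b")}, {"L": ("c", "c")}, {"L": ("a", "b")}
    )[1]


def test_parent_labels_are_symmetric():
    offspring = {"L": ("a", "b"), "M": ("c", "c")}
    p1 = {"L": ("a", "a"), "M": ("c", "d")}
    p2 = {"L": ("b", "c"), "M": ("c", "e")}
    assert mendelian_consistency(offspring, p1, p2) == mendelian_consistency(offspring, p2, p1)


def test_missing_loci_are_skipped():
    verdicts, consistent = mendelian_consistency(
        {"L": ("a", "b"), "M": None}, {"L": ("a", "a"), "M": ("x", "x")}, {"L": ("b", "b")}
    )
    assert verdicts == {"L": True} and consistent


# ---------------------------------------------------------------------------
# Frequencies, heterozygosity, diversity
# ---------------------------------------------------------------------------

def test_allele_frequencies_count_homozygotes_twice():
    tables = allele_frequencies([{"L": ("a", "a")}, {"L": ("a", "b")}])
    table = tables["L"]
    assert table.frequencies == {"a": 0.75, "b": 0.25}
    assert table.n == 2
    monomorphic = allele_frequencies([{"L": ("a", "a")}, {"L": ("a", "a")}])["L"]
    assert monomorphic.frequencies == {"a": 1.0}


def test_allele_frequencies_exclude_missing_loci_locus_wise():
    tables = allele_frequencies([{"L": ("a", "b"), "M": None}, {"L": ("a", "a"), "M": ("x", "y")}])
    assert tables["L"].n == 2 and tables["M"].n == 1
    complete = allele_frequencies(
        [{"L": ("a", "b"), "M": None}, {"L": ("a", "a"), "M": ("x", "y")}],
        complete_only=True,
    )
    assert complete["L"].n == 1


def test_allele_frequencies_empty_population_errors():
    with pytest.raises(ValueError, match="empty"):
        allele_frequencies([])


def test_heterozygosity_closed_forms():
    single = AlleleFrequencyTable("L", {"a": 1.0}, n=10)
    assert expected_heterozygosity(single, unbiased=False) == 0.0
    assert expected_heterozygosity(single, unbiased=True) == 0.0
    four = AlleleFrequencyTable("L", {k: 0.25 for k in "abcd"}, n=10)
    assert expected_heterozygosity(four, unbiased=False) == pytest.approx(0.75)
    two_n2 = AlleleFrequencyTable("L", {"a": 0.5, "b": 0.5}, n=2)
    assert expected_heterozygosity(two_n2, unbiased=True) == pytest.approx(4 / 3 * 0.5)


def test_unbiased_form_needs_two_individuals():
    table = AlleleFrequencyTable("L", {"a": 0.5, "b": 0.5}, n=1)
    with pytest.raises(ValueError, match="n >= 2"):
        expected_heterozygosity(table, unbiased=True)


def test_heterozygosity_bounds_and_mean(rng):
    for _ in range(30):
        k = int(rng.integers(1, 7))
        raw = rng.random(k) + 0.05
        freqs = {f"a{i}": value / raw.sum() for i, value in enumerate(raw)}
        table = AlleleFrequencyTable("L", freqs, n=int(rng.integers(2, 50)))
        plain = expected_heterozygosity(table, unbiased=False)
        unbiased = expected_heterozygosity(table, unbiased=True)
        assert 0.0 <= plain <= 1.0 - 1.0 / k + 1e-12
        assert unbiased >= plain
    tables = {
        "L1": AlleleFrequencyTable("L1", {"a": 1.0}, n=5),
        "L2": AlleleFrequencyTable("L2", {"a": 0.5, "b": 0.5}, n=5),
    }
    assert mean_expected_heterozygosity(tables, unbiased=False) == pytest.approx(0.25)


def test_allelic_diversity_counts_distinct_called_alleles():
    population = [
        {"L": ("a", "b"), "M": ("x", "x")},
        {"L": ("c", "c"), "M": ("y", "z")},
        {"L": None, "M": ("w", "x")},
    ]
    per_locus, total = allelic_diversity(population)
    assert per_locus == {"L": 3, "M": 4}
    assert total == 7


# ---------------------------------------------------------------------------
# Error tallies
# ---------------------------------------------------------------------------

def test_error_tally_identical_genotypes():
    observed = {"s1": dict(EIGHT)}
    reference = {"s1": _known("s1", **EIGHT)}
    tally = genotyping_error_rate(observed, reference)
    assert tally.erroneous_alleles == 0
    assert tally.compared_loci == 8
    assert tally.error_rate == 0.0


def test_error_tally_single_dropout_rate():
    observed = {"s1": dict(EIGHT)}
    observed["s1"]["L0"] = ("a0", "a0")  # reference heterozygote seen homozygous
    reference = {"s1": _known("s1", **EIGHT)}
    tally = genotyping_error_rate(observed, reference)
    assert tally.allelic_dropout == 1
    assert tally.error_rate == pytest.approx(1 / 16)


def test_error_tally_missing_locus_counts_two_alleles():
    observed = {"s1": {**EIGHT, "L0": None}}
    reference = {"s1": _known("s1", **EIGHT)}
    tally = genotyping_error_rate(observed, reference)
    assert tally.missing_locus == 1
    assert tally.erroneous_alleles == 2
    assert tally.error_rate == pytest.approx(2 / 16)


def test_error_tally_stutter_subcategory():
    loci = example_loci()
    locus = loci["A"]
    allele = locus.forward_primer + "GG" + locus.motif * 10 + "CC" + locus.reverse_primer
    stutter = locus.forward_primer + "GG" + locus.motif * 9 + "CC" + locus.reverse_primer
    observed = {"s1": {"A": (allele, stutter)}}
    reference = {"s1": _known("s1", A=(allele, allele))}
    tally = genotyping_error_rate(observed, reference, loci)
    assert tally.false_allele == 1
    assert tally.pcr_stutter == 1


def test_error_tally_requires_reference_mapping():
    with pytest.raises(ValueError, match="no reference"):
        genotyping_error_rate({"s1": dict(EIGHT)}, {})
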