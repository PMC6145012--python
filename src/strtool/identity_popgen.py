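"""Genotype distance, individual identification, pedigree checks, and
population-genetic summaries.

A multi-locus genotype is a mapping from locus name to an allele pair
(homozygotes doubled) or ``None`` for a no-call. Alleles may be full
sequences or labels, as long as the two genotypes being compared use the
same vocabulary.

The distance score between two genotypes is the number of allelic
mismatches: per locus each genotype is a multiset of two alleles and the
mismatch is ``2 - |multiset intersection|``; a locus missing from the
query contributes 2. Identification assigns a sample to the closest known
individual if its score is within ``id_max_distance`` (default 3, which
tolerates e.g. one dropped-out locus plus one allelic dropout).

Expected heterozygosity (gene diversity) is ``H = 1 - sum(p_i^2)``;
the default, sample-size-corrected estimator multiplies by
``2n / (2n - 1)`` where ``n`` is the number of genotyped individuals at
the locus. Allelic diversity is the count of distinct alleles observed in
called genotypes, summed over loci.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

from .allele_calling import HETEROZYGOUS, HOMOZYGOUS, LocusGenotype
from .config_io import KnownGenotype, LocusDefinition
from .read_processing import stutter_products

__all__ = [
    "DistanceScore",
    "AlleleFrequencyTable",
    "ErrorTally",
    "genotype_from_calls",
    "genotype_distance",
    "identify_individual",
    "mendelian_consistency",
    "allele_frequencies",
    "expected_heterozygosity",
    "mean_expected_heterozygosity",
    "allelic_diversity",
    "genotyping_error_rate",
]

Genotype = Mapping[str, Optional[tuple[str, str]]]


@dataclass(frozen=True)
class DistanceScore:
    sample_id: str
    individual_id: str
    score: int


@dataclass(frozen=True)
class AlleleFrequencyTable:
    """Allele frequencies at one locus over ``n`` genotyped individuals."""

    locus_name: str
    frequencies: Mapping[str, float]
    n: int

    def __post_init__(self) -> None:
        total = sum(self.frequencies.values())
        if self.frequencies and abs(total - 1.0) > 1e-9:
            raise ValueError(f"locus {self.locus_name}: frequencies sum to {total}, not 1")


@dataclass
class ErrorTally:
    """Counts of genotyping errors against reference genotypes.

    ``allelic_dropout`` and ``false_allele`` count erroneous alleles
    (one each); ``missing_locus`` counts loci (two erroneous alleles
    each); ``pcr_stutter`` is the subset of false alleles one motif unit
    shorter than a reference allele. The rate is erroneous alleles over
    total compared alleles (two per compared locus).
    """

    allelic_dropout: int = 0
    missing_locus: int = 0
    false_allele: int = 0
    pcr_stutter: int = 0
    compared_loci: int = 0

    @property
    def compared_alleles(self) -> int:
        return 2 * self.compared_loci

    @property
    def erroneous_alleles(self) -> int:
        return self.allelic_dropout + 2 * self.missing_locus + self.false_allele

    @property
    def error_rate(self) -> float:
        if self.compared_alleles == 0:
            return 0.0
        return self.erroneous_alleles / self.compared_alleles


def _as_mapping(genotype: Union[Genotype, KnownGenotype]) -> Genotype:
    if isinstance(genotype, KnownGenotype):
        return genotype.alleles
    return genotype


def genotype_from_calls(calls: Iterable[LocusGenotype], by: str = "sequence") -> Genotype:
    """Collect per-locus calls of one sample into a genotype mapping.

    ``by`` selects the allele vocabulary: ``"sequence"`` or ``"name"``
    (names must have been assigned by the reporting stage).
    """
    genotype: dict[str, Optional[tuple[str, str]]] = {}
    for call in calls:
        if call.zygosity in (HOMOZYGOUS, HETEROZYGOUS):
            if by == "sequence":
                genotype[call.locus_name] = call.allele_pair
            elif by == "name":
                names = [a.name for a in call.alleles]
                if any(n is None for n in names):
                    raise ValueError(f"allele names not assigned for locus {call.locus_name}")
                pair = (names[0], names[0]) if len(names) == 1 else (names[0], names[1])
                genotype[call.locus_name] = pair
            else:
                raise ValueError("by must be 'sequence' or 'name'")
        else:
            genotype[call.locus_name] = None
    return genotype


def genotype_distance(
    query: Union[Genotype, KnownGenotype],
    reference: Union[Genotype, KnownGenotype],
    sample_id: str = "",
    individual_id: str = "",
) -> DistanceScore:
    """Number of allelic mismatches of ``query`` against ``reference``.

    Summed over the reference's locus panel; a locus uncalled or absent in
    the query contributes 2 mismatches (both alleles unmatched).
    """
    g1, g2 = _as_mapping(query), _as_mapping(reference)
    panel = [locus for locus, pair in g2.items() if pair is not None]
    if not panel:
        raise ValueError("reference genotype has no typed loci")
    if not any(locus in g1 for locus in panel):
        raise ValueError("query and reference genotypes share no loci")
    score = 0
    for locus in panel:
        pair1 = g1.get(locus)
        if pair1 is None:
            score += 2
            continue
        shared = Counter(pair1) & Counter(g2[locus])
        score += 2 - sum(shared.values())
    if isinstance(reference, KnownGenotype) and not individual_id:
        individual_id = reference.individual_id
    return DistanceScore(sample_id=sample_id, individual_id=individual_id, score=score)


def identify_individual(
    query: Genotype,
    knowns: Iterable[KnownGenotype],
    id_max_distance: int = 3,
    sample_id: str = "",
) -> tuple[list[DistanceScore], Optional[str]]:
    """Score a sample against every known genotype and assign the best match.

    Returns the scores sorted ascending (ties broken by individual id) and
    the assigned individual, or ``None`` when the best score exceeds
    ``id_max_distance``.
    """
    knowns = list(knowns)
    if not knowns:
        raise ValueError("no known genotypes to compare against")
    scores = [
        genotype_distance(query, known, sample_id=sample_id, individual_id=known.individual_id)
        for known in knowns
    ]
    scores.sort(key=lambda s: (s.score, s.individual_id))
    best = scores[0]
    assignment = best.individual_id if best.score <= id_max_distance else None
    return scores, assignment


def mendelian_consistency(
    offspring: Union[Genotype, KnownGenotype],
    mother: Union[Genotype, KnownGenotype],
    father: Union[Genotype, KnownGenotype],
) -> tuple[dict[str, bool], bool]:
    """Check whether the offspring could inherit one allele from each parent.

    A locus is consistent iff the offspring's allele pair can be split into
    one allele present in the mother's pair and one in the father's pair.
    Loci missing in any of the three genotypes are skipped. Returns the
    per-locus verdicts and the overall conjunction.
    """
    o, m, f = (_as_mapping(g) for g in (offspring, mother, father))
    verdicts: dict[str, bool] = {}
    for locus, pair in o.items():
        if pair is None or m.get(locus) is None or f.get(locus) is None:
            continue
        a, b = pair
        mom, dad = m[locus], f[locus]
        verdicts[locus] = (a in mom and b in dad) or (b in mom and a in dad)
    return verdicts, all(verdicts.values())


def allele_frequencies(
    genotypes: Iterable[Union[Genotype, KnownGenotype]],
    complete_only: bool = False,
) -> dict[str, AlleleFrequencyTable]:
    """Per-locus allele frequencies over a population.

    Each called genotype contributes two allele observations (a homozygote
    two of one allele); individuals are excluded locus-wise at their
    uncalled loci. With ``complete_only=True`` individuals missing any
    locus of the panel are excluded wholesale.
    """
    mapped = [_as_mapping(g) for g in genotypes]
    if not mapped:
        raise ValueError("empty population")
    panel: list[str] = []
    for genotype in mapped:
        for locus in genotype:
            if locus not in panel:
                panel.append(locus)
    if complete_only:
        mapped = [g for g in mapped if all(g.get(locus) is not None for locus in panel)]
        if not mapped:
            raise ValueError("no individual has a complete genotype")
    tables: dict[str, AlleleFrequencyTable] = {}
    for locus in panel:
        counts: Counter = Counter()
        n = 0
        for genotype in mapped:
            pair = genotype.get(locus)
            if pair is None:
                continue
            counts.update(pair)
            n += 1
        if n == 0:
            continue
        total = sum(counts.values())
        tables[locus] = AlleleFrequencyTable(
            locus_name=locus,
            frequencies={allele: count / total for allele, count in sorted(counts.items())},
            n=n,
        )
    return tables


def expected_heterozygosity(freqs: AlleleFrequencyTable, unbiased: bool = True) -> float:
    """Gene diversity at one locus: ``1 - sum(p_i^2)``.

    With ``unbiased=True`` (default) the small-sample correction
    ``2n / (2n - 1)`` is applied, which requires at least two genotyped
    individuals.
    """
    plain = 1.0 - sum(p * p for p in freqs.frequencies.values())
    if not unbiased:
        return plain
    if freqs.n < 2:
        raise ValueError(
            f"locus {freqs.locus_name}: unbiased estimator needs n >= 2, got n={freqs.n}"
        )
    two_n = 2 * freqs.n
    return two_n / (two_n - 1) * plain


def mean_expected_heterozygosity(
    tables: Mapping[str, AlleleFrequencyTable], unbiased: bool = True
) -> float:
    """Population value: heterozygosity averaged across loci."""
    if not tables:
        raise ValueError("no loci")
    values = [expected_heterozygosity(t, unbiased=unbiased) for t in tables.values()]
    return sum(values) / len(values)


def allelic_diversity(
    genotypes: Iterable[Union[Genotype, KnownGenotype]],
) -> tuple[dict[str, int], int]:
    """Distinct alleles appearing in called genotypes, per locus and total."""
    per_locus: dict[str, set] = {}
    for genotype in genotypes:
        for locus, pair in _as_mapping(genotype).items():
            if pair is None:
                continue
            per_locus.setdefault(locus, set()).update(pair)
    counts = {locus: len(alleles) for locus, alleles in per_locus.items()}
    return counts, sum(counts.values())


def _is_stutter_of_any(allele: str, references: Sequence[str], motif: str) -> bool:
    return any(allele in stutter_products(ref, motif) for ref in set(references))


def genotyping_error_rate(
    observed: Mapping[str, Union[Genotype, KnownGenotype]],
    reference: Mapping[str, Union[Genotype, KnownGenotype]],
    loci: Optional[Mapping[str, LocusDefinition]] = None,
) -> ErrorTally:
    """Tally allelic mismatches of observed genotypes against references.

    ``observed`` and ``reference`` are keyed by sample; every observed
    sample must have a reference. Per reference locus: an uncalled
    observed locus is a missing locus (two erroneous alleles); an observed
    homozygote for one allele of a reference heterozygote is an allelic
    dropout (one); any observed allele absent from the reference pair is a
    false allele (one each), subcategorized as PCR stutter when it is one
    motif unit shorter than a reference allele (requires ``loci`` for the
    motif). The stutter check only works on sequence-vocabulary genotypes.
    """
    tally = ErrorTally()
    for sample in observed:
        if sample not in reference:
            raise ValueError(f"observed sample {sample!r} has no reference genotype")
        obs = _as_mapping(observed[sample])
        ref = _as_mapping(reference[sample])
        for locus, ref_pair in ref.items():
            if ref_pair is None:
                continue
            tally.compared_loci += 1
            obs_pair = obs.get(locus)
            if obs_pair is None:
                tally.missing_locus += 1
                continue
            if Counter(obs_pair) == Counter(ref_pair):
                continue
            obs_alleles = set(obs_pair)
            ref_alleles = set(ref_pair)
            if len(obs_alleles) == 1 and len(ref_alleles) == 2 and obs_pair[0] in ref_alleles:
                tally.allelic_dropout += 1
                continue
            motif = loci[locus].motif if loci is not None and locus in loci else None
            for allele in sorted(obs_alleles - ref_alleles):
                tally.false_allele += 1
                if motif is not None and _is_stutter_of_any(allele, ref_pair, motif):
                    tally.pcr_stutter += 1
    return tally
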