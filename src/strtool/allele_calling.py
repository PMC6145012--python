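"""Stage 2: locus filters and zygosity-resolved genotype calls.

Candidate alleles are the unique sequences that match every locus
attribute (forward primer, repeat motif, length range) and carry no
artifact flag. The *filtered read count* of the locus is the sum of
candidate counts; candidates must additionally hold at least
``min_allele_fraction`` (default 5%) of it. A locus is genotyped only
when the filtered read count is strictly above ``min_locus_reads``
(default 500): one surviving candidate is reported homozygous, two or
more report the two most abundant as a heterozygote.

Threshold semantics, fixed here and relied on by the tests:
* filtered reads must be strictly greater than ``min_locus_reads``
  (a total of exactly 500 is a no-call, 501 is genotyped);
* the allele fraction test is inclusive (exactly 5.0% is retained);
* the upstream artifact ratio test is strict (exactly one-third of a
  more abundant sequence's count is *not* an artifact).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .config_io import PipelineConfig
from .read_processing import SampleSequenceTable

__all__ = [
    "HOMOZYGOUS",
    "HETEROZYGOUS",
    "NO_CALL",
    "AlleleCall",
    "LocusGenotype",
    "filter_candidates",
    "call_genotype",
    "call_locus",
]

HOMOZYGOUS = "homozygous"
HETEROZYGOUS = "heterozygous"
NO_CALL = "no_call"

# QC flag names
STUTTER_FILTER_INVOKED = "stutter_filter_invoked"
MORE_THAN_TWO_CANDIDATES = "more_than_two_candidates"
HIGH_UNASSIGNED_FRACTION = "high_unassigned_fraction"
DROPOUT_RISK = "dropout_risk"

QC_FLAGS = (
    STUTTER_FILTER_INVOKED,
    MORE_THAN_TWO_CANDIDATES,
    HIGH_UNASSIGNED_FRACTION,
    DROPOUT_RISK,
)


@dataclass
class AlleleCall:
    """A sequence retained by all locus filters."""

    sequence: str
    length: int
    count: int
    fraction_of_filtered: float
    name: Optional[str] = None


@dataclass
class LocusGenotype:
    """The 0-2 allele call for one sample x locus, with QC flags."""

    sample_id: str
    locus_name: str
    alleles: tuple[AlleleCall, ...]
    zygosity: str
    total_filtered_reads: int
    qc_flags: frozenset = frozenset()

    @property
    def allele_pair(self) -> Optional[tuple[str, str]]:
        """The genotype as a sequence pair (homozygote doubled), or None."""
        if self.zygosity == HOMOZYGOUS:
            return (self.alleles[0].sequence, self.alleles[0].sequence)
        if self.zygosity == HETEROZYGOUS:
            return (self.alleles[0].sequence, self.alleles[1].sequence)
        return None


def filter_candidates(
    table: SampleSequenceTable,
    config: Optional[PipelineConfig] = None,
) -> tuple[list[AlleleCall], int]:
    """Apply the locus filters and return (candidates, filtered read count).

    The fraction filter is computed over attribute-passing, artifact-free
    reads only — not over the raw read total — so off-target and artifact
    reads cannot dilute true alleles below the cutoff.
    """
    config = config or PipelineConfig()
    passing = [u for u in table.sequences if u.passes_attributes and u.artifact_category is None]
    total = sum(u.count for u in passing)
    candidates: list[AlleleCall] = []
    if total == 0:
        return candidates, 0
    for u in passing:
        fraction = u.count / total
        if fraction >= config.min_allele_fraction:
            candidates.append(
                AlleleCall(sequence=u.sequence, length=u.length, count=u.count, fraction_of_filtered=fraction)
            )
    return candidates, total


def call_genotype(
    candidates: list[AlleleCall],
    total_filtered_reads: int,
    config: Optional[PipelineConfig] = None,
    sample_id: str = "",
    locus_name: str = "",
    stutter_filter_invoked: bool = False,
) -> LocusGenotype:
    """Resolve zygosity from the ordered candidate list.

    ``candidates`` must be ordered by descending count (lexicographic
    tie-break), as produced by :func:`filter_candidates` from an annotated
    table.
    """
    config = config or PipelineConfig()
    flags = set()
    if stutter_filter_invoked:
        flags.add(STUTTER_FILTER_INVOKED)

    if total_filtered_reads <= config.min_locus_reads or not candidates:
        return LocusGenotype(
            sample_id=sample_id,
            locus_name=locus_name,
            alleles=(),
            zygosity=NO_CALL,
            total_filtered_reads=total_filtered_reads,
            qc_flags=frozenset(flags),
        )

    if len(candidates) == 1:
        alleles = (candidates[0],)
        zygosity = HOMOZYGOUS
        if total_filtered_reads < config.dropout_flag_multiplier * config.min_locus_reads:
            flags.add(DROPOUT_RISK)
    else:
        alleles = (candidates[0], candidates[1])
        zygosity = HETEROZYGOUS
        if len(candidates) > 2:
            flags.add(MORE_THAN_TWO_CANDIDATES)

    called_reads = sum(a.count for a in alleles)
    unassigned = (total_filtered_reads - called_reads) / total_filtered_reads
    if unassigned > config.unassigned_flag_fraction:
        flags.add(HIGH_UNASSIGNED_FRACTION)

    return LocusGenotype(
        sample_id=sample_id,
        locus_name=locus_name,
        alleles=alleles,
        zygosity=zygosity,
        total_filtered_reads=total_filtered_reads,
        qc_flags=frozenset(flags),
    )


def call_locus(
    table: SampleSequenceTable,
    config: Optional[PipelineConfig] = None,
) -> LocusGenotype:
    """Filter an annotated, artifact-flagged table and call its genotype."""
    config = config or PipelineConfig()
    candidates, total = filter_candidates(table, config)
    stutter_invoked = any(u.artifact_category == "stutter" for u in table.sequences)
    return call_genotype(
        candidates,
        total,
        config,
        sample_id=table.sample_id,
        locus_name=table.locus_name,
        stutter_filter_invoked=stutter_invoked,
    )
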