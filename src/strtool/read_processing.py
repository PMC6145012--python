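"""Stage 1: dereplication, attribute annotation, and PCR-artifact flagging.

Forward amplicon reads for one sample x locus are collapsed into unique
sequences with counts, each annotated with whether it matches the locus's
forward primer, contains the repeat motif, and falls inside the expected
amplicon length range. Unique sequences are then screened against every
more abundant sequence in the same table for three artifact signatures:

``stutter``
    the sequence equals a more abundant one with a single contiguous
    motif-length block deleted from a repeat run (polymerase slippage is
    typically one repeat unit shorter than the true allele), and
``substitution`` / ``indel``
    the sequence is at edit distance 1 from a more abundant one.

In every case the artifact call additionally requires the candidate's
read count to be *strictly less than* ``artifact_ratio`` (default 1/3) of
the more abundant sequence's count; a true second allele of a heterozygote
carries more than that and survives. The most abundant qualifying
sequence is recorded as the artifact's source. Ordering is always by
descending count with lexicographic sequence tie-breaks, so results are
independent of read input order.
"""

from __future__ import annotations

import gzip
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import edlib
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .config_io import LocusDefinition, PipelineConfig

__all__ = [
    "FastqInputError",
    "UniqueSequence",
    "SampleSequenceTable",
    "dereplicate_reads",
    "dereplicate_fastq",
    "primer_matches",
    "assign_locus",
    "annotate_unique_sequences",
    "stutter_products",
    "flag_artifacts",
]


class FastqInputError(ValueError):
    """Raised for malformed FASTQ input, with the failing record index."""


@dataclass
class UniqueSequence:
    """One dereplicated read variant with its locus-attribute annotations."""

    sequence: str
    count: int
    length: int
    matches_primer: bool
    matches_motif: bool
    in_length_range: bool
    fraction_of_total: float
    artifact_category: Optional[str] = None  # 'stutter' | 'substitution' | 'indel'
    artifact_of: Optional[str] = None  # sequence of the attributed source

    @property
    def passes_attributes(self) -> bool:
        return self.matches_primer and self.matches_motif and self.in_length_range


@dataclass
class SampleSequenceTable:
    """All unique sequences of one sample x locus, ordered by descending count."""

    sample_id: str
    locus_name: str
    sequences: list[UniqueSequence]
    total_reads: int

    def to_frame(self) -> pd.DataFrame:
        """Tabular form matching the on-disk sequence-detail CSV."""
        return pd.DataFrame(
            {
                "Sequence": [u.sequence for u in self.sequences],
                "Count": [u.count for u in self.sequences],
                "Length": [u.length for u in self.sequences],
                "Fraction": [u.fraction_of_total for u in self.sequences],
                "MatchesPrimer": [u.matches_primer for u in self.sequences],
                "MatchesMotif": [u.matches_motif for u in self.sequences],
                "InLengthRange": [u.in_length_range for u in self.sequences],
                "ArtifactCategory": [u.artifact_category or "" for u in self.sequences],
                "ArtifactOfSequence": [u.artifact_of or "" for u in self.sequences],
            }
        )


# ---------------------------------------------------------------------------
# Dereplication
# ---------------------------------------------------------------------------

def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def dereplicate_reads(reads: Iterable) -> Counter:
    """Collapse an iterable of reads into exact-sequence counts.

    Accepts plain strings, ``(title, seq, qual)`` tuples, or objects with a
    ``seq`` attribute (e.g. Bio.SeqRecord). Base qualities are ignored.
    """
    counts: Counter = Counter()
    for read in reads:
        if isinstance(read, str):
            seq = read
        elif isinstance(read, tuple):
            seq = read[1]
        else:
            seq = str(read.seq)
        counts[seq.upper()] += 1
    return counts


def dereplicate_fastq(path) -> Counter:
    """Dereplicate a (plain or gzipped) FASTQ file of forward reads."""
    counts: Counter = Counter()
    n = 0
    with _open_maybe_gzip(path) as handle:
        try:
            for _title, seq, _qual in FastqGeneralIterator(handle):
                counts[seq.upper()] += 1
                n += 1
        except ValueError as exc:
            raise FastqInputError(f"{path}: malformed FASTQ at record {n + 1}: {exc}") from exc
    return counts


# ---------------------------------------------------------------------------
# Locus assignment and attribute annotation
# ---------------------------------------------------------------------------

def primer_matches(sequence: str, primer: str, max_mismatch: int = 0) -> bool:
    """True if ``primer`` matches the prefix of ``sequence``.

    Comparison is positional (no indels) with at most ``max_mismatch``
    substitutions; adapter-trimmed amplicon reads begin at the primer.
    """
    if len(sequence) < len(primer):
        return False
    mismatches = 0
    for a, b in zip(sequence, primer):
        if a != b:
            mismatches += 1
            if mismatches > max_mismatch:
                return False
    return True


def assign_locus(
    sequence: str,
    loci: Mapping[str, LocusDefinition],
    primer_max_mismatch: int = 0,
) -> Optional[str]:
    """Assign a read to the unique locus whose forward primer it starts with.

    Returns ``None`` when no primer matches, or when more than one does
    (ambiguous assignments are dropped with a warning).
    """
    hits = [
        name
        for name, locus in loci.items()
        if primer_matches(sequence, locus.forward_primer, primer_max_mismatch)
    ]
    if len(hits) == 1:
        return hits[0]
    if len(hits) > 1:
        warnings.warn(
            f"read matches forward primers of multiple loci {hits}; left unassigned",
            stacklevel=2,
        )
    return None


def annotate_unique_sequences(
    derep: Mapping[str, int],
    locus: LocusDefinition,
    config: Optional[PipelineConfig] = None,
    sample_id: str = "",
) -> SampleSequenceTable:
    """Build the annotated unique-sequence table for one sample x locus.

    The motif test requires at least ``config.motif_min_repeats``
    consecutive copies of the repeat unit anywhere in the read.
    """
    config = config or PipelineConfig()
    motif_run = locus.motif * config.motif_min_repeats
    total = sum(derep.values())
    rows = []
    for seq, count in sorted(derep.items(), key=lambda item: (-item[1], item[0])):
        if count < 1:
            raise ValueError(f"non-positive read count {count} for sequence {seq[:30]}...")
        rows.append(
            UniqueSequence(
                sequence=seq,
                count=int(count),
                length=len(seq),
                matches_primer=primer_matches(seq, locus.forward_primer, config.primer_max_mismatch),
                matches_motif=motif_run in seq,
                in_length_range=locus.length_min <= len(seq) <= locus.length_max,
                fraction_of_total=count / total if total else 0.0,
            )
        )
    return SampleSequenceTable(
        sample_id=sample_id, locus_name=locus.name, sequences=rows, total_reads=int(total)
    )


# ---------------------------------------------------------------------------
# Artifact flagging
# ---------------------------------------------------------------------------

def stutter_products(sequence: str, motif: str) -> frozenset:
    """All sequences derivable by deleting one motif copy from a repeat run.

    Only deletions inside a run of at least two consecutive motif copies
    qualify: stutter arises from slippage within the repeat, and deleting a
    lone motif occurrence elsewhere is not a slippage product.
    """
    m = len(motif)
    products = set()
    for i in range(len(sequence) - m + 1):
        if sequence[i : i + m] != motif:
            continue
        if sequence[i + m : i + 2 * m] == motif or (i >= m and sequence[i - m : i] == motif):
            products.add(sequence[:i] + sequence[i + m :])
    return frozenset(products)


def _edit_distance_is_one(a: str, b: str) -> bool:
    if abs(len(a) - len(b)) > 1:
        return False
    return edlib.align(a, b, task="distance", k=1)["editDistance"] == 1


def flag_artifacts(
    table: SampleSequenceTable,
    locus: LocusDefinition,
    config: Optional[PipelineConfig] = None,
) -> SampleSequenceTable:
    """Annotate probable PCR/sequencing artifacts in place and return the table.

    For each sequence ``s`` and each strictly more abundant sequence ``a``
    with ``count(s) < artifact_ratio * count(a)``, ``s`` is flagged as
    stutter of ``a`` (one motif unit deleted from a repeat run) or as a
    single-edit substitution/indel of ``a``. The most abundant qualifying
    ``a`` is attributed; the top-count sequence is never flagged.
    """
    config = config or PipelineConfig()
    ratio = config.artifact_ratio
    m = len(locus.motif)
    ordered = table.sequences  # descending count, lexicographic tie-break
    stutter_cache: dict[str, frozenset] = {}
    for i, s in enumerate(ordered):
        if i == 0:
            continue
        s.artifact_category = None
        s.artifact_of = None
        for a in ordered:
            if not s.count < ratio * a.count:
                # counts are non-increasing: no later sequence can qualify
                break
            category = None
            if s.length == a.length - m:
                products = stutter_cache.get(a.sequence)
                if products is None:
                    products = stutter_products(a.sequence, locus.motif)
                    stutter_cache[a.sequence] = products
                if s.sequence in products:
                    category = "stutter"
            if category is None and _edit_distance_is_one(s.sequence, a.sequence):
                category = "substitution" if s.length == a.length else "indel"
            if category is not None:
                s.artifact_category = category
                s.artifact_of = a.sequence
                break
    return table
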