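"""Stage 3: run-level tables, allele naming, and per-locus outputs.

Allele names come from the known-allele table when an exact sequence match
exists; otherwise a run-stable short name ``<length>-<digest>`` is derived
from the amplicon length and the first four hex digits of a SHA-1 content
hash. Within a locus and run the label <-> sequence mapping is a
bijection: a digest collision between distinct sequences (vanishingly
rare) gets a letter suffix.

The genotype summary table has one row per sample, one column per locus,
allele labels joined by ``/`` (homozygotes shown once, no-calls empty).
Flag tables, a cross-locus contamination matrix (raw read counts matching
each locus's forward primer), per-locus FASTA/alignments, and length
histograms round out the run outputs.
"""

from __future__ import annotations

import hashlib
import io
import shutil
import string
import subprocess
import tempfile
from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
from Bio import SeqIO

from . import allele_calling as ac
from .allele_calling import LocusGenotype
from .config_io import KnownAlleleSet, LocusDefinition
from .read_processing import SampleSequenceTable, assign_locus

__all__ = [
    "AlleleNameRegistry",
    "build_genotype_table",
    "parse_genotype_table",
    "build_flag_tables",
    "build_contamination_matrix",
    "align_sequences",
    "build_length_histogram",
    "build_locus_outputs",
]


class AlleleNameRegistry:
    """Run-local allele naming: known labels first, stable auto-names otherwise."""

    def __init__(self, known: Optional[KnownAlleleSet] = None):
        self._known = known
        self._labels: dict[tuple[str, str], str] = {}  # (locus, sequence) -> label
        self._sequences: dict[tuple[str, str], str] = {}  # (locus, label) -> sequence

    @staticmethod
    def auto_label(sequence: str) -> str:
        digest = hashlib.sha1(sequence.encode("ascii")).hexdigest()[:4]
        return f"{len(sequence)}-{digest}"

    def name(self, locus_name: str, sequence: str) -> str:
        key = (locus_name, sequence)
        if key in self._labels:
            return self._labels[key]
        label = None
        if self._known is not None:
            label = self._known.name_for(locus_name, sequence)
        if label is None:
            label = self.auto_label(sequence)
        candidate = label
        for suffix in ("", *string.ascii_lowercase):
            candidate = label + suffix
            held = self._sequences.get((locus_name, candidate))
            if held is None or held == sequence:
                break
        else:  # pragma: no cover - would need 27 colliding digests
            raise RuntimeError(f"could not derive a unique label for {sequence[:30]}...")
        self._labels[key] = candidate
        self._sequences[(locus_name, candidate)] = sequence
        return candidate

    def sequence_for(self, locus_name: str, label: str) -> Optional[str]:
        return self._sequences.get((locus_name, label))

    def catalog(self, locus_name: str) -> dict[str, str]:
        """label -> sequence for every allele named at this locus."""
        return {
            label: seq for (locus, label), seq in self._sequences.items() if locus == locus_name
        }


def name_alleles(genotypes: Iterable[LocusGenotype], registry: AlleleNameRegistry) -> None:
    """Assign labels to every called allele, in place."""
    for genotype in genotypes:
        for allele in genotype.alleles:
            allele.name = registry.name(genotype.locus_name, allele.sequence)


def build_genotype_table(
    genotypes: Iterable[LocusGenotype],
    registry: AlleleNameRegistry,
    locus_order: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Assemble the summary genotype table (samples x loci, label cells)."""
    cells: dict[tuple[str, str], str] = {}
    samples: list[str] = []
    loci: list[str] = list(locus_order) if locus_order is not None else []
    for genotype in genotypes:
        key = (genotype.sample_id, genotype.locus_name)
        if key in cells:
            raise ValueError(f"duplicate genotype for sample {key[0]!r}, locus {key[1]!r}")
        labels = [
            allele.name or registry.name(genotype.locus_name, allele.sequence)
            for allele in genotype.alleles
        ]
        cells[key] = "/".join(labels)
        if genotype.sample_id not in samples:
            samples.append(genotype.sample_id)
        if genotype.locus_name not in loci:
            loci.append(genotype.locus_name)
    table = pd.DataFrame(
        [[cells.get((sample, locus), "") for locus in loci] for sample in samples],
        index=pd.Index(samples, name="Sample"),
        columns=loci,
    )
    return table


def parse_genotype_table(path) -> dict[str, dict[str, Optional[tuple[str, str]]]]:
    """Read a summary genotype CSV back into per-sample label genotypes.

    Single-label cells are expanded to homozygous pairs; empty cells map
    to ``None`` (no call).
    """
    frame = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    genotypes: dict[str, dict[str, Optional[tuple[str, str]]]] = {}
    for sample, row in frame.iterrows():
        entry: dict[str, Optional[tuple[str, str]]] = {}
        for locus, cell in row.items():
            cell = str(cell).strip()
            if not cell:
                entry[locus] = None
            else:
                labels = cell.split("/")
                if len(labels) == 1:
                    labels = [labels[0], labels[0]]
                entry[locus] = (labels[0], labels[1])
        genotypes[str(sample)] = entry
    return genotypes


def build_flag_tables(genotypes: Iterable[LocusGenotype]) -> dict[str, pd.DataFrame]:
    """One table per QC flag kind listing the affected sample x locus calls."""
    rows: dict[str, list[dict]] = {flag: [] for flag in ac.QC_FLAGS}
    for genotype in genotypes:
        for flag in genotype.qc_flags:
            rows[flag].append(
                {
                    "Sample": genotype.sample_id,
                    "Locus": genotype.locus_name,
                    "Zygosity": genotype.zygosity,
                    "TotalFilteredReads": genotype.total_filtered_reads,
                    "AlleleCounts": ";".join(str(a.count) for a in genotype.alleles),
                }
            )
    columns = ["Sample", "Locus", "Zygosity", "TotalFilteredReads", "AlleleCounts"]
    return {flag: pd.DataFrame(data, columns=columns) for flag, data in rows.items()}


def build_contamination_matrix(
    derep_by_sample: Mapping[str, Mapping[str, int]],
    loci: Mapping[str, LocusDefinition],
    primer_max_mismatch: int = 0,
) -> pd.DataFrame:
    """Read counts matching each locus's forward primer, per sample.

    Computed on raw (pre-filter) unique sequences: for singleplex samples
    any off-column signal is potential cross-locus contamination, for
    multiplexed samples this is the read distribution across loci.
    """
    locus_names = list(loci)
    data = []
    for sample, derep in derep_by_sample.items():
        counts = Counter()
        for seq, count in derep.items():
            hit = assign_locus(seq, loci, primer_max_mismatch)
            if hit is not None:
                counts[hit] += count
        data.append([counts.get(name, 0) for name in locus_names])
    return pd.DataFrame(
        data, index=pd.Index(list(derep_by_sample), name="Sample"), columns=locus_names
    )


def align_sequences(sequences: list[str]) -> list[str]:
    """Multiple alignment of allele sequences (progressive, via MAFFT).

    Returns the aligned rows (gaps as ``-``) in input order; a singleton
    input is returned unchanged.
    """
    if not sequences:
        return []
    if len(sequences) == 1:
        return [sequences[0]]
    mafft = shutil.which("mafft")
    if mafft is None:  # pragma: no cover - present in the supported environment
        raise RuntimeError("mafft executable not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "alleles.fasta"
        with open(fasta, "w") as handle:
            for i, seq in enumerate(sequences):
                handle.write(f">s{i}\n{seq}\n")
        result = subprocess.run(
            [mafft, "--quiet", "--auto", str(fasta)],
            capture_output=True,
            text=True,
            check=True,
        )
    aligned = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(io.StringIO(result.stdout), "fasta")
    }
    return [aligned[f"s{i}"] for i in range(len(sequences))]


def build_length_histogram(
    table: SampleSequenceTable,
    genotype: Optional[LocusGenotype] = None,
) -> pd.DataFrame:
    """Length-frequency distribution of one sample x locus with filter status.

    Status per unique sequence: ``called`` (a reported allele),
    ``artifact`` (flagged stutter/substitution/indel), ``off_attribute``
    (fails primer/motif/length), or ``minor`` (locus-like but below the
    allele fraction cutoff / beyond the top two).
    """
    called = set()
    if genotype is not None:
        called = {allele.sequence for allele in genotype.alleles}
    rows = Counter()
    for u in table.sequences:
        if u.sequence in called:
            status = "called"
        elif u.artifact_category is not None:
            status = "artifact"
        elif not u.passes_attributes:
            status = "off_attribute"
        else:
            status = "minor"
        rows[(u.length, status)] += u.count
    frame = pd.DataFrame(
        [
            {"Length": length, "Status": status, "Count": count}
            for (length, status), count in sorted(rows.items())
        ],
        columns=["Length", "Status", "Count"],
    )
    return frame


def build_locus_outputs(
    registry: AlleleNameRegistry,
    genotypes: Iterable[LocusGenotype],
    out_dir,
) -> dict[str, list[str]]:
    """Write per-locus allele FASTA and aligned FASTA files.

    Returns the aligned rows per locus (label order = descending carrier
    count, then label).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    carriers: dict[str, Counter] = {}
    for genotype in genotypes:
        for allele in genotype.alleles:
            label = allele.name or registry.name(genotype.locus_name, allele.sequence)
            carriers.setdefault(genotype.locus_name, Counter())[label] += 1
    alignments: dict[str, list[str]] = {}
    for locus_name, counts in carriers.items():
        labels = sorted(counts, key=lambda lab: (-counts[lab], lab))
        seqs = [registry.sequence_for(locus_name, label) for label in labels]
        with open(out_dir / f"{locus_name}_alleles.fasta", "w") as handle:
            for label, seq in zip(labels, seqs):
                handle.write(f">{label}\n{seq}\n")
        aligned = align_sequences(seqs)
        with open(out_dir / f"{locus_name}_alleles_aligned.fasta", "w") as handle:
            for label, seq in zip(labels, aligned):
                handle.write(f">{label}\n{seq}\n")
        alignments[locus_name] = aligned
    return alignments
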