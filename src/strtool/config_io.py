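"""Configuration and reference-table input.

Everything the genotyping pipeline is driven by comes in through this
module: the per-locus attribute table (primers, repeat motif, amplicon
length range), the pipeline thresholds, the sample sheet, and the optional
known-allele / known-genotype reference tables.

Conventions
-----------
* Amplicon lengths (``length_min``/``length_max`` and reported allele
  lengths) count the **full amplicon including both primers**, so that
  sequencing-derived lengths are directly comparable with fragment-sizing
  results obtained on whole amplicons.
* DNA is parsed case-insensitively and stored uppercase; only A/C/G/T are
  accepted (these are PCR amplicons, so U is rejected).
* A known-genotype row listing a single allele for a locus is read as a
  homozygote (the allele doubled); an explicitly empty locus is "missing".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml

__all__ = [
    "ConfigurationError",
    "LocusDefinition",
    "PipelineConfig",
    "SampleEntry",
    "KnownAllele",
    "KnownAlleleSet",
    "KnownGenotype",
    "load_locus_definitions",
    "write_locus_definitions",
    "load_known_alleles",
    "load_known_genotypes",
    "load_sample_sheet",
    "load_pipeline_config",
    "dump_pipeline_config",
]

_DNA_RE = re.compile(r"^[ACGT]+$")


class ConfigurationError(ValueError):
    """Raised for any invalid configuration or reference input."""


def _dna(value: str, what: str) -> str:
    """Validate and normalize a DNA string (uppercase, A/C/G/T only)."""
    if not isinstance(value, str):
        raise ConfigurationError(f"{what}: expected a DNA string, got {value!r}")
    seq = value.strip().upper()
    if not _DNA_RE.match(seq):
        raise ConfigurationError(f"{what}: invalid DNA string {value!r}")
    return seq


@dataclass(frozen=True)
class LocusDefinition:
    """Attributes of one microsatellite locus.

    ``length_min``/``length_max`` bound the full amplicon length in bp,
    primers included. ``motif`` is the 1-6 bp tandem repeat unit.
    """

    name: str
    forward_primer: str
    reverse_primer: str
    length_min: int
    length_max: int
    motif: str

    def __post_init__(self) -> None:
        if not self.name or not str(self.name).strip():
            raise ConfigurationError("locus name must be nonempty")
        object.__setattr__(self, "name", str(self.name).strip())
        object.__setattr__(self, "forward_primer", _dna(self.forward_primer, f"locus {self.name} forward primer"))
        object.__setattr__(self, "reverse_primer", _dna(self.reverse_primer, f"locus {self.name} reverse primer"))
        object.__setattr__(self, "motif", _dna(self.motif, f"locus {self.name} motif"))
        if not 1 <= len(self.motif) <= 6:
            raise ConfigurationError(f"locus {self.name}: motif must be 1-6 bp, got {len(self.motif)}")
        lo, hi = int(self.length_min), int(self.length_max)
        object.__setattr__(self, "length_min", lo)
        object.__setattr__(self, "length_max", hi)
        if not 0 < lo <= hi:
            raise ConfigurationError(
                f"locus {self.name}: need 0 < length_min <= length_max, got {lo}..{hi}"
            )


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable filter thresholds of the genotyping pipeline.

    Defaults follow the published defaults of the method: artifacts are
    sequences carrying less than one-third of the read count of a more
    abundant sequence; called alleles must carry at least 5% of the
    filtered reads; a locus is genotyped only when its filtered read count
    exceeds 500.
    """

    artifact_ratio: float = 1.0 / 3.0
    min_allele_fraction: float = 0.05
    min_locus_reads: int = 500
    max_alleles: int = 2
    id_max_distance: int = 3
    motif_min_repeats: int = 3
    primer_max_mismatch: int = 0
    require_reverse_primer: bool = False
    dropout_flag_multiplier: float = 3.0
    unassigned_flag_fraction: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.artifact_ratio < 1:
            raise ConfigurationError(f"artifact_ratio must be in (0, 1), got {self.artifact_ratio}")
        if not 0 < self.min_allele_fraction < 1:
            raise ConfigurationError(
                f"min_allele_fraction must be in (0, 1), got {self.min_allele_fraction}"
            )
        if self.min_locus_reads < 0:
            raise ConfigurationError("min_locus_reads must be >= 0")
        if self.id_max_distance < 0:
            raise ConfigurationError("id_max_distance must be >= 0")
        if self.max_alleles != 2:
            raise ConfigurationError("only diploid calling (max_alleles = 2) is supported")
        if self.motif_min_repeats < 1:
            raise ConfigurationError("motif_min_repeats must be >= 1")
        if self.primer_max_mismatch < 0:
            raise ConfigurationError("primer_max_mismatch must be >= 0")
        if self.dropout_flag_multiplier <= 0:
            raise ConfigurationError("dropout_flag_multiplier must be positive")
        if not 0 <= self.unassigned_flag_fraction <= 1:
            raise ConfigurationError("unassigned_flag_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SampleEntry:
    """One row of the sample sheet: a FASTQ file and the loci it contains.

    A single expected locus means a singleplex reaction; several mean a
    multiplexed pool whose reads are split by forward primer downstream.
    """

    sample_id: str
    replicate_id: str
    fastq_path: Path
    loci_expected: tuple[str, ...]

    @property
    def unit_id(self) -> str:
        """Identifier of this analysis unit (sample, or sample-replicate)."""
        return f"{self.sample_id}-{self.replicate_id}" if self.replicate_id else self.sample_id

    @property
    def is_multiplexed(self) -> bool:
        return len(self.loci_expected) > 1


@dataclass(frozen=True)
class KnownAllele:
    locus_name: str
    allele_name: str
    sequence: str


class KnownAlleleSet:
    """Bidirectional (locus, sequence) <-> (locus, name) allele lookup."""

    def __init__(self, alleles: Optional[list[KnownAllele]] = None):
        self._by_seq: dict[tuple[str, str], str] = {}
        self._by_name: dict[tuple[str, str], str] = {}
        self._alleles: list[KnownAllele] = []
        for allele in alleles or []:
            self.add(allele)

    def add(self, allele: KnownAllele) -> None:
        seq_key = (allele.locus_name, allele.sequence)
        name_key = (allele.locus_name, allele.allele_name)
        if seq_key in self._by_seq and self._by_seq[seq_key] != allele.allele_name:
            raise ConfigurationError(
                f"locus {allele.locus_name}: sequence mapped to both "
                f"{self._by_seq[seq_key]!r} and {allele.allele_name!r}"
            )
        if name_key in self._by_name and self._by_name[name_key] != allele.sequence:
            raise ConfigurationError(
                f"locus {allele.locus_name}: allele name {allele.allele_name!r} "
                "mapped to two different sequences"
            )
        if seq_key not in self._by_seq:
            self._alleles.append(allele)
        self._by_seq[seq_key] = allele.allele_name
        self._by_name[name_key] = allele.sequence

    def name_for(self, locus_name: str, sequence: str) -> Optional[str]:
        return self._by_seq.get((locus_name, sequence))

    def sequence_for(self, locus_name: str, allele_name: str) -> Optional[str]:
        return self._by_name.get((locus_name, allele_name))

    def __len__(self) -> int:
        return len(self._alleles)

    def __iter__(self):
        return iter(self._alleles)


@dataclass(frozen=True)
class KnownGenotype:
    """A reference multi-locus genotype for one individual.

    ``alleles`` maps locus name to a pair of full amplicon sequences;
    homozygotes are stored as a doubled allele. Loci without data are
    simply absent from the mapping.
    """

    individual_id: str
    alleles: Mapping[str, tuple[str, str]]

    def loci(self) -> tuple[str, ...]:
        return tuple(self.alleles)


# ---------------------------------------------------------------------------
# Loaders
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    """Read a CSV or TSV table with a header row (delimiter sniffed)."""
    try:
        return pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    except Exception as exc:  # pandas raises several parser error types
        raise ConfigurationError(f"{path}: could not parse table: {exc}") from exc


def _require_columns(frame: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing required column(s) {missing}")


def load_locus_definitions(path) -> dict[str, LocusDefinition]:
    """Load the locus attribute table.

    Expects header columns ``Locus,LengthMin,LengthMax,Primer,
    ReversePrimer,Motif`` (comma- or tab-separated). Returns an
    insertion-ordered mapping of locus name to definition.
    """
    frame = _read_table(path)
    _require_columns(frame, ["Locus", "LengthMin", "LengthMax", "Primer", "ReversePrimer", "Motif"], path)
    loci: dict[str, LocusDefinition] = {}
    for _, row in frame.iterrows():
        try:
            locus = LocusDefinition(
                name=row["Locus"],
                forward_primer=row["Primer"],
                reverse_primer=row["ReversePrimer"],
                length_min=int(row["LengthMin"]),
                length_max=int(row["LengthMax"]),
                motif=row["Motif"],
            )
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(f"{path}: invalid locus row {dict(row)}: {exc}") from exc
        if locus.name in loci:
            raise ConfigurationError(f"{path}: duplicate locus name {locus.name!r}")
        loci[locus.name] = locus
    return loci


def write_locus_definitions(loci: Mapping[str, LocusDefinition], path) -> None:
    frame = pd.DataFrame(
        {
            "Locus": [l.name for l in loci.values()],
            "LengthMin": [l.length_min for l in loci.values()],
            "LengthMax": [l.length_max for l in loci.values()],
            "Primer": [l.forward_primer for l in loci.values()],
            "ReversePrimer": [l.reverse_primer for l in loci.values()],
            "Motif": [l.motif for l in loci.values()],
        }
    )
    frame.to_csv(path, index=False)


def load_known_alleles(path) -> KnownAlleleSet:
    """Load the known-allele table (columns ``Locus,Name,Sequence``)."""
    frame = _read_table(path)
    _require_columns(frame, ["Locus", "Name", "Sequence"], path)
    known = KnownAlleleSet()
    for _, row in frame.iterrows():
        known.add(
            KnownAllele(
                locus_name=str(row["Locus"]).strip(),
                allele_name=str(row["Name"]).strip(),
                sequence=_dna(row["Sequence"], f"{path} allele {row['Name']}"),
            )
        )
    return known


def _resolve_allele(value: str, locus: str, known: Optional[KnownAlleleSet], context: str) -> str:
    """Resolve an allele reference (name or raw sequence) to a sequence."""
    token = str(value).strip()
    if known is not None:
        seq = known.sequence_for(locus, token)
        if seq is not None:
            return seq
    upper = token.upper()
    if _DNA_RE.match(upper):
        return upper
    raise ConfigurationError(f"{context}: cannot resolve allele {token!r} at locus {locus!r}")


def load_known_genotypes(
    path,
    alleles: Optional[KnownAlleleSet] = None,
    loci: Optional[Mapping[str, LocusDefinition]] = None,
    vocabulary: str = "sequence",
) -> dict[str, KnownGenotype]:
    """Load reference genotypes (columns ``Individual,Locus,Allele1,Allele2``).

    With ``vocabulary="sequence"`` (default) allele cells may contain a
    known allele name (resolved against ``alleles``) or a raw DNA
    sequence. With ``vocabulary="label"`` cells are kept verbatim as
    allele labels, for comparisons against label-valued genotype tables.
    A row with a single allele is read as homozygous; a row with both
    cells empty marks the locus missing for that individual and is
    skipped.
    """
    if vocabulary not in ("sequence", "label"):
        raise ValueError("vocabulary must be 'sequence' or 'label'")
    frame = _read_table(path)
    _require_columns(frame, ["Individual", "Locus", "Allele1", "Allele2"], path)
    per_individual: dict[str, dict[str, tuple[str, str]]] = {}
    for _, row in frame.iterrows():
        individual = str(row["Individual"]).strip()
        locus = str(row["Locus"]).strip()
        if loci is not None and locus not in loci:
            raise ConfigurationError(
                f"{path}: individual {individual!r} references undefined locus {locus!r}"
            )
        a1, a2 = str(row["Allele1"]).strip(), str(row["Allele2"]).strip()
        if not a1 and not a2:
            continue  # explicitly missing locus
        context = f"{path} individual {individual}"
        if not a1:
            a1 = a2
        if vocabulary == "label":
            s1, s2 = a1, (a2 or a1)
        else:
            s1 = _resolve_allele(a1, locus, alleles, context)
            s2 = _resolve_allele(a2, locus, alleles, context) if a2 else s1
        entry = per_individual.setdefault(individual, {})
        if locus in entry:
            raise ConfigurationError(f"{path}: duplicate locus {locus!r} for individual {individual!r}")
        entry[locus] = (s1, s2)
    return {
        individual: KnownGenotype(individual_id=individual, alleles=genotype)
        for individual, genotype in per_individual.items()
    }


def load_sample_sheet(
    path,
    loci: Optional[Mapping[str, LocusDefinition]] = None,
    check_files: bool = True,
) -> list[SampleEntry]:
    """Load the sample sheet mapping FASTQ files to samples and loci.

    Columns: ``SampleID, Replicate, Locus`` (or ``Loci``, semicolon
    separated for multiplexed pools), ``FastqPath``. Relative FASTQ paths
    are resolved against the sheet's own directory.
    """
    frame = _read_table(path)
    _require_columns(frame, ["SampleID", "FastqPath"], path)
    locus_col = "Locus" if "Locus" in frame.columns else "Loci" if "Loci" in frame.columns else None
    if locus_col is None:
        raise ConfigurationError(f"{path}: need a 'Locus' or 'Loci' column")
    base = Path(path).parent if isinstance(path, (str, Path)) else Path(".")
    entries: list[SampleEntry] = []
    for _, row in frame.iterrows():
        names = tuple(t.strip() for t in str(row[locus_col]).split(";") if t.strip())
        if not names:
            raise ConfigurationError(f"{path}: sample {row['SampleID']!r} lists no loci")
        if loci is not None:
            unknown = [n for n in names if n not in loci]
            if unknown:
                raise ConfigurationError(
                    f"{path}: sample {row['SampleID']!r} references undefined loci {unknown}"
                )
        fastq = Path(str(row["FastqPath"]).strip())
        if not fastq.is_absolute():
            fastq = base / fastq
        if check_files and not fastq.exists():
            raise ConfigurationError(f"{path}: FASTQ file not found: {fastq}")
        entries.append(
            SampleEntry(
                sample_id=str(row["SampleID"]).strip(),
                replicate_id=str(row.get("Replicate", "")).strip(),
                fastq_path=fastq,
                loci_expected=names,
            )
        )
    return entries


def load_pipeline_config(path=None) -> PipelineConfig:
    """Load pipeline thresholds from a flat ``key: value`` text file.

    Every key is optional; unset keys take the documented defaults.
    Unknown keys and out-of-range values raise :class:`ConfigurationError`.
    """
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text() if isinstance(path, (str, Path)) else path.read()
    try:
        data = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"{path}: could not parse options file: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: options file must contain 'key: value' lines")
    valid = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigurationError(f"{path}: unknown option(s) {sorted(unknown)}")
    return PipelineConfig(**data)


def dump_pipeline_config(config: PipelineConfig, path=None) -> str:
    """Serialize a :class:`PipelineConfig` back to ``key: value`` text."""
    data = {f.name: getattr(config, f.name) for f in fields(PipelineConfig)}
    text = yaml.safe_dump(data, sort_keys=False, default_flow_style=False)
    if path is not None:
        Path(path).write_text(text)
    return text
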