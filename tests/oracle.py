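"""Independent brute-force reference implementations of the filter rules.

Deliberately naive: plain Python, all-pairs scans, a textbook dynamic
programming edit distance (no edlib), direct string equality for stutter
deletions. Used to cross-check stages 1+2 on small unique-sequence
tables, and to generate random tables with realistic structure.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from strtool import LocusDefinition, PipelineConfig

_BASES = "ACGT"


def levenshtein(a: str, b: str) -> int:
    """O(len(a)*len(b)) DP edit distance."""
    if len(a) < len(b):
        a, b = b, a
    previous = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        current = [i]
        for j, cb in enumerate(b, start=1):
            current.append(
                min(previous[j] + 1, current[j - 1] + 1, previous[j - 1] + (ca != cb))
            )
        previous = current
    return previous[-1]


def is_stutter_of(s: str, a: str, motif: str) -> bool:
    """True if s equals a with one motif-length block deleted from a repeat run."""
    m = len(motif)
    if len(s) != len(a) - m:
        return False
    for i in range(len(a) - m + 1):
        if a[i : i + m] != motif:
            continue
        in_run = a[i + m : i + 2 * m] == motif or (i >= m and a[i - m : i] == motif)
        if in_run and a[:i] + a[i + m :] == s:
            return True
    return False


def oracle_annotate(derep: dict, locus: LocusDefinition, cfg: PipelineConfig) -> list[dict]:
    total = sum(derep.values())
    rows = []
    for seq in sorted(derep, key=lambda s: (-derep[s], s)):
        primer = locus.forward_primer
        mismatches = (
            sum(x != y for x, y in zip(seq, primer)) if len(seq) >= len(primer) else None
        )
        rows.append(
            {
                "sequence": seq,
                "count": derep[seq],
                "matches_primer": mismatches is not None and mismatches <= cfg.primer_max_mismatch,
                "matches_motif": locus.motif * cfg.motif_min_repeats in seq,
                "in_length_range": locus.length_min <= len(seq) <= locus.length_max,
                "fraction_of_total": derep[seq] / total if total else 0.0,
                "artifact_category": None,
                "artifact_of": None,
            }
        )
    return rows


def oracle_flag(rows: list[dict], locus: LocusDefinition, cfg: PipelineConfig) -> list[dict]:
    """All-pairs artifact check; attribute to the most abundant qualifying source."""
    for s in rows:
        qualifying = []
        for a in rows:
            if a["sequence"] == s["sequence"]:
                continue
            if not s["count"] < cfg.artifact_ratio * a["count"]:
                continue
            if is_stutter_of(s["sequence"], a["sequence"], locus.motif):
                qualifying.append((a, "stutter"))
            elif levenshtein(s["sequence"], a["sequence"]) == 1:
                category = (
                    "substitution" if len(s["sequence"]) == len(a["sequence"]) else "indel"
                )
                qualifying.append((a, category))
        if qualifying:
            best, category = min(qualifying, key=lambda q: (-q[0]["count"], q[0]["sequence"]))
            s["artifact_category"] = category
            s["artifact_of"] = best["sequence"]
    return rows


def oracle_call(
    derep: dict, locus: LocusDefinition, cfg: PipelineConfig
) -> tuple[str, Optional[tuple], int]:
    """Full stage-1+2 enumeration: returns (zygosity, called pair, filtered total)."""
    rows = oracle_flag(oracle_annotate(derep, locus, cfg), locus, cfg)
    passing = [
        r
        for r in rows
        if r["matches_primer"]
        and r["matches_motif"]
        and r["in_length_range"]
        and r["artifact_category"] is None
    ]
    total = sum(r["count"] for r in passing)
    candidates = [r for r in passing if total and r["count"] / total >= cfg.min_allele_fraction]
    if total <= cfg.min_locus_reads or not candidates:
        return "no_call", None, total
    if len(candidates) == 1:
        seq = candidates[0]["sequence"]
        return "homozygous", (seq, seq), total
    ordered = sorted(candidates, key=lambda r: (-r["count"], r["sequence"]))
    return "heterozygous", (ordered[0]["sequence"], ordered[1]["sequence"]), total


def random_table(
    locus: LocusDefinition, rng: np.random.Generator, max_sequences: int = 10
) -> dict:
    """A random small dereplicated table with locus-like structure.

    Mixes true-allele-like sequences with their stutter products,
    single-substitution/indel neighbors, off-primer reads, out-of-range
    and motif-free sequences, at counts spanning the filter thresholds.
    """

    def random_dna(n: int) -> str:
        return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))

    m = len(locus.motif)
    fixed = len(locus.forward_primer) + len(locus.reverse_primer) + 16
    k_lo = max(3, -(-(locus.length_min - fixed) // m))
    k_hi = max(k_lo, (locus.length_max - fixed) // m)
    left, right = random_dna(8), random_dna(8)

    def allele(k: int) -> str:
        return locus.forward_primer + left + locus.motif * k + right + locus.reverse_primer

    base = allele(int(rng.integers(k_lo, k_hi + 1)))
    derep: dict[str, int] = {}

    def add(seq: str, count: int) -> None:
        if seq and seq not in derep:
            derep[seq] = count

    def rand_count() -> int:
        return int(rng.choice([1, 2, 5, 20, 90, 150, 300, 500, 800, 2000]))

    add(base, rand_count())
    n_target = int(rng.integers(1, max_sequences + 1))
    while len(derep) < n_target:
        kind = rng.integers(0, 7)
        if kind == 0:  # second allele, different repeat count
            add(allele(int(rng.integers(k_lo, k_hi + 1))), rand_count())
        elif kind == 1:  # stutter product of an existing sequence
            src = list(derep)[int(rng.integers(0, len(derep)))]
            idx = src.find(locus.motif + locus.motif)
            if idx >= 0:
                add(src[:idx] + src[idx + m :], rand_count())
        elif kind == 2:  # single substitution neighbor
            src = list(list(derep)[int(rng.integers(0, len(derep)))])
            pos = int(rng.integers(0, len(src)))
            src[pos] = rng.choice([b for b in _BASES if b != src[pos]])
            add("".join(src), rand_count())
        elif kind == 3:  # single indel neighbor
            src = list(list(derep)[int(rng.integers(0, len(derep)))])
            if rng.random() < 0.5 and len(src) > 1:
                del src[int(rng.integers(0, len(src)))]
            else:
                src.insert(int(rng.integers(0, len(src) + 1)), _BASES[int(rng.integers(0, 4))])
            add("".join(src), rand_count())
        elif kind == 4:  # off-primer read
            add(random_dna(len(base)), rand_count())
        elif kind == 5:  # out-of-length-range but primer-matching
            add(locus.forward_primer + locus.motif * 3 + random_dna(4), rand_count())
        else:  # primer match but no motif run
            add(
                locus.forward_primer + random_dna(len(base) - len(locus.forward_primer)),
                rand_count(),
            )
    return derep
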