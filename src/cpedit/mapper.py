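"""Strand-specific, substitution-only short-read alignment.

The aligner reports every placement of a read on the *forward* strand of a
reference with Hamming distance <= max_mm (0 for the exact stages, 2 for
the editing-informative stage).  No reverse-complement matching, no gaps —
an edited transcript fragment differs from its genomic template only by
substitutions, so allowing indels would blur the editing signal.

The <=2-mismatch search uses pigeonhole seeding: a read split into
``max_mm + 1`` contiguous segments must, in any alignment with at most
``max_mm`` substitutions, contain at least one segment that matches the
reference exactly.  Candidate loci found by exact segment lookup are then
verified by a full Hamming comparison.

``hierarchical_partition`` implements the four-stage read triage:

1. exact match against the chloroplast targets (genome + CDS + tRNA) → cp_m0
2. survivors, exact match against nuclear then mitochondrial → discarded
3. survivors, <=2 mismatches against the chloroplast targets → cp_m2
4. the rest are unaligned

Stage 1 preceding stage 2 is deliberate: plastid DNA insertions in the
nuclear genome would otherwise absorb unedited chloroplast reads and bias
quantification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .refio import ConfigError, ReadRecord, ReferenceSequence, ReferenceSet

__all__ = [
    "AlignmentRecord",
    "PartitionResult",
    "PARTITION_CLASSES",
    "pigeonhole_seeds",
    "map_read",
    "hierarchical_partition",
    "partition_summary_frame",
    "write_alignments_tsv",
    "read_alignments_tsv",
]

PARTITION_CLASSES = ("cp_m0", "nuclear", "mito", "cp_m2", "unaligned")


@dataclass(frozen=True)
class AlignmentRecord:
    """Placement of a read on the forward strand of one reference.

    ``start`` is 1-based; ``mismatches`` holds (offset_in_alignment,
    ref_base, read_base) with a 0-based offset; ``n_best_loci`` counts the
    equal-best placements of the same read across the reference set (>1 for
    reads from duplicated regions such as the plastid inverted repeat).
    """

    read_id: str
    ref_id: str
    start: int
    length: int
    mismatches: tuple[tuple[int, str, str], ...]
    n_best_loci: int = 1

    @property
    def nm(self) -> int:
        return len(self.mismatches)

    @property
    def end(self) -> int:
        """1-based inclusive end on the reference."""
        return self.start + self.length - 1


@dataclass
class PartitionResult:
    """Outcome of the hierarchical triage: one class per read."""

    counts: dict[str, int]
    read_class: dict[str, str]
    discarded_n: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def pigeonhole_seeds(read: str, max_mm: int) -> list[tuple[int, str]]:
    """Split a read into ``max_mm + 1`` near-equal contiguous segments.

    Returns (offset, segment) pairs.  Any alignment of the read with at
    most ``max_mm`` substitutions contains at least one segment matching
    the reference exactly at the corresponding offset.
    """
    if max_mm < 0:
        raise ConfigError("max_mm must be >= 0")
    n = max_mm + 1
    length = len(read)
    base, rem = divmod(length, n)
    seeds = []
    off = 0
    for i in range(n):
        size = base + (1 if i < rem else 0)
        if size == 0:
            continue
        seeds.append((off, read[off : off + size]))
        off += size
    return seeds


def _occurrences(haystack: str, needle: str) -> Iterable[int]:
    """All 0-based occurrences of needle in haystack (may overlap)."""
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


def _hamming_within(a: str, b: str, limit: int) -> int:
    """Hamming distance of equal-length strings, or limit+1 on early abort."""
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return d
    return d


def map_read(
    read: ReadRecord,
    refs: Sequence[ReferenceSequence],
    max_mm: int,
) -> list[AlignmentRecord]:
    """All equal-best forward-strand placements of a read, nm-minimal.

    Returns the complete minimal-mismatch stratum across ``refs`` (every
    locus whose Hamming distance equals the best distance <= max_mm), each
    record carrying ``n_best_loci``.  A read longer than every reference
    yields an empty list.
    """
    seq = read.sequence
    L = len(seq)
    seeds = pigeonhole_seeds(seq, max_mm)
    hits: list[tuple[str, int, tuple[tuple[int, str, str], ...]]] = []
    best = max_mm
    for ref in refs:
        rs = ref.sequence
        if L > len(rs):
            continue
        seen: set[int] = set()
        for off, seg in seeds:
            for pos in _occurrences(rs, seg):
                start = pos - off
                if start < 0 or start + L > len(rs) or start in seen:
                    continue
                seen.add(start)
                window = rs[start : start + L]
                d = _hamming_within(seq, window, best)
                if d <= best:
                    mism = tuple(
                        (i, window[i], seq[i]) for i in range(L) if window[i] != seq[i]
                    )
                    hits.append((ref.id, start, mism))
    if not hits:
        return []
    best_nm = min(len(m) for _, _, m in hits)
    stratum = [(r, s, m) for r, s, m in hits if len(m) == best_nm]
    n_best = len(stratum)
    return [
        AlignmentRecord(
            read_id=read.id,
            ref_id=ref_id,
            start=start + 1,
            length=L,
            mismatches=mism,
            n_best_loci=n_best,
        )
        for ref_id, start, mism in stratum
    ]


def hierarchical_partition(
    reads: Iterable[ReadRecord],
    refset: ReferenceSet,
    max_mm_stage3: int = 2,
) -> tuple[PartitionResult, list[AlignmentRecord]]:
    """Four-stage triage of a read library; returns partition + retained hits.

    Retained alignments are the union of the exact chloroplast hits (m0)
    and the <=2-mismatch chloroplast hits of reads surviving the
    nuclear/mitochondrial subtraction (m2).  Reads containing N are
    classified ``unaligned`` and tallied separately in ``discarded_n``.
    """
    cp_targets = refset.chloroplast_targets()
    if not cp_targets:
        raise ConfigError("reference set has no chloroplast targets")
    nuclear = refset.by_category("nuclear")
    mito = refset.by_category("mitochondrial")
    if not nuclear or not mito:
        raise ConfigError("reference set must include nuclear and mitochondrial genomes")

    counts = {c: 0 for c in PARTITION_CLASSES}
    read_class: dict[str, str] = {}
    retained: list[AlignmentRecord] = []
    discarded_n = 0

    for read in reads:
        if "N" in read.sequence:
            discarded_n += 1
            counts["unaligned"] += 1
            read_class[read.id] = "unaligned"
            continue
        hits = map_read(read, cp_targets, 0)
        if hits:
            counts["cp_m0"] += 1
            read_class[read.id] = "cp_m0"
            retained.extend(hits)
            continue
        if map_read(read, nuclear, 0):
            counts["nuclear"] += 1
            read_class[read.id] = "nuclear"
            continue
        if map_read(read, mito, 0):
            counts["mito"] += 1
            read_class[read.id] = "mito"
            continue
        hits = map_read(read, cp_targets, max_mm_stage3)
        if hits:
            counts["cp_m2"] += 1
            read_class[read.id] = "cp_m2"
            retained.extend(hits)
            continue
        counts["unaligned"] += 1
        read_class[read.id] = "unaligned"

    return PartitionResult(counts, read_class, discarded_n), retained


def partition_summary_frame(result: PartitionResult) -> pd.DataFrame:
    """Partition counts and percentages, shaped like the per-genome
    distribution table (total / nuclear / mtDNA / cp m0 / cp m2 / cp total
    / not aligned)."""
    total = result.total
    cp_total = result.counts["cp_m0"] + result.counts["cp_m2"]
    rows = [
        ("total", total),
        ("nuclear", result.counts["nuclear"]),
        ("mtDNA", result.counts["mito"]),
        ("cpDNA_m0", result.counts["cp_m0"]),
        ("cpDNA_m2", result.counts["cp_m2"]),
        ("cpDNA_total", cp_total),
        ("not_aligned", result.counts["unaligned"]),
    ]
    return pd.DataFrame(
        {
            "class": [r[0] for r in rows],
            "count": [r[1] for r in rows],
            "percent": [
                round(100.0 * r[1] / total, 2) if total else 0.0 for r in rows
            ],
        }
    )


_ALN_COLUMNS = ["read_id", "ref_id", "start_1based", "length", "nm", "mismatches", "n_best_loci"]


def write_alignments_tsv(alignments: Iterable[AlignmentRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_ALN_COLUMNS) + "\n")
        for a in alignments:
            mm = ";".join(f"{o}:{rb}>{qb}" for o, rb, qb in a.mismatches) or "."
            fh.write(
                f"{a.read_id}\t{a.ref_id}\t{a.start}\t{a.length}\t{a.nm}\t{mm}\t{a.n_best_loci}\n"
            )


def read_alignments_tsv(path) -> list[AlignmentRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _ALN_COLUMNS:
            raise ConfigError(f"{path}: unexpected alignment TSV header")
        for line in fh:
            read_id, ref_id, start, length, nm, mm, n_best = line.rstrip("\n").split("\t")
            mismatches: list[tuple[int, str, str]] = []
            if mm != ".":
                for part in mm.split(";"):
                    off, _, change = part.partition(":")
                    rb, _, qb = change.partition(">")
                    mismatches.append((int(off), rb, qb))
            records.append(
                AlignmentRecord(
                    read_id=read_id,
                    ref_id=ref_id,
                    start=int(start),
                    length=int(length),
                    mismatches=tuple(mismatches),
                    n_best_loci=int(n_best),
                )
            )
    return records
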