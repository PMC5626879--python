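"""Reference, annotation and read I/O.

This module owns every external format the pipeline touches — FASTA
references, FASTQ/FASTA small-RNA reads, CDS/tRNA annotation (GFF3 or a
six-column TSV) and the predicted-editing-site table — and exposes a
validated in-memory reference model (:class:`ReferenceSet`).

Coordinate conventions
----------------------
All external interfaces (annotation, reports) use 1-based inclusive
positions; internal arithmetic is 0-based half-open.  Feature segments are
stored in transcript (5'→3') orientation: for a minus-strand feature the
first segment is the one with the highest genome coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ParseError",
    "ConfigError",
    "CoordinateError",
    "DataError",
    "ReferenceSequence",
    "Feature",
    "ReadRecord",
    "PredictedSite",
    "ReferenceSet",
    "revcomp",
    "read_fasta",
    "write_fasta",
    "read_reads",
    "write_fastq",
    "filter_by_length",
    "drop_n_reads",
    "extract_feature_sequence",
    "read_annotation",
    "write_annotation_tsv",
    "write_annotation_gff3",
    "read_predicted_sites",
    "write_predicted_sites",
]

CATEGORIES = ("chloroplast", "nuclear", "mitochondrial", "cds", "trna")
FEATURE_TYPES = ("CDS", "tRNA")
_DNA = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class ParseError(ValueError):
    """Malformed input file."""


class ConfigError(ValueError):
    """Invalid parameter combination."""


class CoordinateError(ValueError):
    """Out-of-bounds or inconsistent coordinates."""


class DataError(ValueError):
    """Inputs that parse but are mutually inconsistent."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceSequence:
    """A named reference sequence with its role in the pipeline.

    ``category`` distinguishes mapping targets: the three genomes
    (chloroplast / nuclear / mitochondrial) and the extracted per-gene
    ``cds`` / ``trna`` sense sequences.
    """

    id: str
    sequence: str
    category: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("reference sequence with empty id")
        if len(self.sequence) < 1:
            raise ParseError(f"reference {self.id!r}: empty sequence")
        if self.category not in CATEGORIES:
            raise ConfigError(f"unknown reference category {self.category!r}")
        bad = set(self.sequence) - _DNA
        if bad:
            raise ParseError(
                f"reference {self.id!r}: invalid characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Feature:
    """A CDS or tRNA on a genome, possibly spliced.

    ``segments`` are (start, end) pairs, 1-based inclusive on the genome,
    ordered 5'→3' in transcript orientation.
    """

    gene: str
    ftype: str
    genome_ref: str
    segments: tuple[tuple[int, int], ...]
    strand: str
    anticodon: Optional[str] = None
    _g2c: Optional[dict[int, int]] = field(default=None, repr=False, compare=False)
    _positions: Optional[list[int]] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise ConfigError(f"feature {self.gene!r}: bad type {self.ftype!r}")
        if self.strand not in "+-":
            raise ConfigError(f"feature {self.gene!r}: bad strand {self.strand!r}")
        self.segments = tuple((int(a), int(b)) for a, b in self.segments)
        for a, b in self.segments:
            if a < 1 or b < a:
                raise CoordinateError(
                    f"feature {self.gene!r}: bad segment ({a},{b})"
                )
        # non-overlap check in genome space
        ivs = sorted(self.segments)
        for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
            if a2 <= b1:
                raise CoordinateError(
                    f"feature {self.gene!r}: overlapping segments"
                )

    @property
    def spliced_length(self) -> int:
        return sum(b - a + 1 for a, b in self.segments)

    def genome_positions(self) -> list[int]:
        """1-based genome coordinates in transcript order."""
        if self._positions is None:
            pos: list[int] = []
            for a, b in self.segments:
                if self.strand == "+":
                    pos.extend(range(a, b + 1))
                else:
                    pos.extend(range(b, a - 1, -1))
            self._positions = pos
        return self._positions

    def cds_to_genome(self, cds_pos: int) -> int:
        """Map a 1-based transcript position to its genome coordinate."""
        pos = self.genome_positions()
        if not 1 <= cds_pos <= len(pos):
            raise CoordinateError(
                f"{self.gene}: position {cds_pos} outside 1..{len(pos)}"
            )
        return pos[cds_pos - 1]

    def genome_to_cds(self) -> dict[int, int]:
        """Genome coordinate → 1-based transcript position."""
        if self._g2c is None:
            self._g2c = {g: i + 1 for i, g in enumerate(self.genome_positions())}
        return self._g2c


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read; qualities present iff the source was FASTQ."""

    id: str
    sequence: str
    qualities: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ParseError(f"read {self.id!r}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ParseError(
                f"read {self.id!r}: quality length {len(self.qualities)} != "
                f"sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PredictedSite:
    """One row of a PREP-style predicted-editing-site table."""

    gene: str
    cds_pos: int
    ref_codon: str
    edit_codon: str
    aa_change: str
    score: float

    def __post_init__(self) -> None:
        if self.cds_pos < 1:
            raise ParseError(f"{self.gene}: cds_pos must be >= 1")
        if not 0.0 <= self.score <= 1.0:
            raise ParseError(f"{self.gene}:{self.cds_pos}: score outside [0,1]")


@dataclass
class ReferenceSet:
    """All mapping targets plus feature annotation, with cross-validation."""

    sequences: dict[str, ReferenceSequence]
    features: list[Feature]

    @classmethod
    def build(
        cls,
        sequences: Iterable[ReferenceSequence],
        features: Iterable[Feature],
    ) -> "ReferenceSet":
        seqs: dict[str, ReferenceSequence] = {}
        for s in sequences:
            if s.id in seqs:
                raise DataError(f"duplicate reference id {s.id!r}")
            seqs[s.id] = s
        rs = cls(sequences=seqs, features=list(features))
        rs.validate()
        return rs

    def validate(self) -> None:
        for f in self.features:
            genome = self.sequences.get(f.genome_ref)
            if genome is None:
                raise DataError(f"feature {f.gene!r}: unknown genome {f.genome_ref!r}")
            for a, b in f.segments:
                if b > len(genome):
                    raise CoordinateError(
                        f"feature {f.gene!r}: segment ({a},{b}) outside "
                        f"{f.genome_ref} (length {len(genome)})"
                    )
            if f.ftype == "CDS" and f.spliced_length % 3 != 0:
                raise DataError(
                    f"CDS {f.gene!r}: spliced length {f.spliced_length} "
                    "not divisible by 3"
                )
            # the stored cds/trna copy, when present, must equal the extraction
            stored = self.sequences.get(f.gene)
            if stored is not None and stored.category in ("cds", "trna"):
                extracted = extract_feature_sequence(genome, f)
                if extracted.sequence != stored.sequence:
                    raise DataError(
                        f"feature {f.gene!r}: stored sequence does not match "
                        "extraction from genome"
                    )

    def by_category(self, category: str) -> list[ReferenceSequence]:
        return [s for s in self.sequences.values() if s.category == category]

    def genome(self, category: str) -> ReferenceSequence:
        seqs = self.by_category(category)
        if len(seqs) != 1:
            raise ConfigError(
                f"expected exactly one {category} reference, found {len(seqs)}"
            )
        return seqs[0]

    def chloroplast_targets(self) -> list[ReferenceSequence]:
        """Stage-1/3 mapping targets: cp genome + extracted CDS + tRNA."""
        return (
            self.by_category("chloroplast")
            + self.by_category("cds")
            + self.by_category("trna")
        )

    def feature(self, gene: str) -> Optional[Feature]:
        for f in self.features:
            if f.gene == gene:
                return f
        return None

    def features_by_gene(self, gene: str) -> list[Feature]:
        return [f for f in self.features if f.gene == gene]


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta(path: str | Path, category: str = "chloroplast") -> list[ReferenceSequence]:
    """Read a FASTA file into :class:`ReferenceSequence` records.

    Sequences are uppercased and U is converted to T so RNA-space FASTA is
    accepted.  Malformed records raise :class:`ParseError` naming the line.
    """
    path = Path(path)
    records: list[ReferenceSequence] = []
    seen_header = False
    with open(path) as fh:
        # quick structural pre-scan for line-numbered errors
        header_line = 0
        has_seq = False
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if seen_header and not has_seq:
                    raise ParseError(
                        f"{path}: empty sequence for header at line {header_line}"
                    )
                if line == ">":
                    raise ParseError(f"{path}: empty FASTA header at line {lineno}")
                seen_header = True
                header_line = lineno
                has_seq = False
            else:
                if not seen_header:
                    raise ParseError(
                        f"{path}: sequence before any header at line {lineno}"
                    )
                has_seq = True
        if seen_header and not has_seq:
            raise ParseError(f"{path}: empty sequence for header at line {header_line}")
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ReferenceSequence(rec.id, _normalize(str(rec.seq)), category)
        )
    return records


def write_fasta(records: Iterable[ReferenceSequence], path: str | Path, width: int = 70) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        for rec in seqs:
            fh.write(f">{rec.id}\n")
            s = str(rec.seq)
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_reads(path: str | Path, fmt: str = "fastq") -> Iterator[ReadRecord]:
    """Stream reads from FASTQ or FASTA, order-preserving."""
    fmt = fmt.lower()
    if fmt not in ("fastq", "fasta"):
        raise ConfigError(f"fmt must be 'fastq' or 'fasta', got {fmt!r}")
    try:
        for rec in SeqIO.parse(str(path), fmt):
            quals = None
            if fmt == "fastq":
                quals = tuple(rec.letter_annotations["phred_quality"])
            yield ReadRecord(rec.id, _normalize(str(rec.seq)), quals)
    except ValueError as exc:  # biopython signals length mismatches etc.
        raise ParseError(f"{path}: {exc}") from exc


def write_fastq(reads: Iterable[ReadRecord], path: str | Path, default_qual: int = 40) -> None:
    with open(path, "w") as fh:
        for r in reads:
            quals = r.qualities or (default_qual,) * len(r)
            qs = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qs}\n")


def filter_by_length(
    reads: Iterable[ReadRecord],
    min_len: int = 18,
    max_len: int = 24,
) -> Iterator[ReadRecord]:
    """Keep reads with min_len <= length <= max_len (sRNA: 18–24 nt).

    mRNA mode is expressed by passing ``min_len=1`` and a large ``max_len``.
    """
    if min_len > max_len:
        raise ConfigError(f"min_len {min_len} > max_len {max_len}")
    for r in reads:
        if min_len <= len(r) <= max_len:
            yield r


def drop_n_reads(reads: Iterable[ReadRecord]) -> tuple[list[ReadRecord], int]:
    """Remove reads containing N; mismatch semantics are undefined for N.

    Returns (kept reads, number discarded).
    """
    kept: list[ReadRecord] = []
    discarded = 0
    for r in reads:
        if "N" in r.sequence:
            discarded += 1
        else:
            kept.append(r)
    return kept, discarded


def extract_feature_sequence(genome: ReferenceSequence, f: Feature) -> ReferenceSequence:
    """Spliced, strand-corrected sense sequence of a feature."""
    parts: list[str] = []
    for a, b in f.segments:
        if b > len(genome) or a < 1:
            raise CoordinateError(
                f"feature {f.gene!r}: segment ({a},{b}) outside {genome.id}"
            )
        chunk = genome.sequence[a - 1 : b]
        parts.append(chunk if f.strand == "+" else revcomp(chunk))
    category = "cds" if f.ftype == "CDS" else "trna"
    return ReferenceSequence(f.gene, "".join(parts), category)


# ---------------------------------------------------------------------------
# Annotation (GFF3 or 6-column TSV)

_ANN_COLUMNS = ["gene", "type", "ref", "segments", "strand", "anticodon"]


def read_annotation(path: str | Path) -> list[Feature]:
    """Read CDS/tRNA features from GFF3 (.gff/.gff3) or the documented TSV."""
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_annotation_gff3(path)
    return _read_annotation_tsv(path)


def _parse_segments(text: str) -> tuple[tuple[int, int], ...]:
    segs = []
    for part in text.split(","):
        a, _, b = part.partition("-")
        try:
            segs.append((int(a), int(b)))
        except ValueError as exc:
            raise ParseError(f"bad segment spec {part!r}") from exc
    return tuple(segs)


def _read_annotation_tsv(path: Path) -> list[Feature]:
    feats: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene\t"):
                continue
            cols = line.split("\t")
            if len(cols) < 5:
                raise ParseError(f"{path}:{lineno}: expected >=5 tab columns")
            gene, ftype, ref, segments, strand = cols[:5]
            anticodon = cols[5] if len(cols) > 5 and cols[5] not in ("", ".") else None
            feats.append(
                Feature(gene, ftype, ref, _parse_segments(segments), strand, anticodon)
            )
    return feats


def _read_annotation_gff3(path: Path) -> list[Feature]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    grouped: dict[tuple[str, str, str, str], list[tuple[int, int]]] = {}
    anticodons: dict[str, Optional[str]] = {}
    for ftype in FEATURE_TYPES:
        for feat in db.features_of_type(ftype, order_by="start"):
            gene = (
                feat.attributes.get("gene", [None])[0]
                or feat.attributes.get("ID", [feat.id])[0]
            )
            key = (gene, ftype, feat.seqid, feat.strand)
            grouped.setdefault(key, []).append((feat.start, feat.end))
            ac = feat.attributes.get("anticodon", [None])[0]
            if ac:
                anticodons[gene] = ac
    feats = []
    for (gene, ftype, seqid, strand), segs in grouped.items():
        segs = sorted(segs)
        if strand == "-":
            segs = segs[::-1]  # transcript order for minus strand
        feats.append(
            Feature(gene, ftype, seqid, tuple(segs), strand, anticodons.get(gene))
        )
    return feats


def write_annotation_tsv(features: Iterable[Feature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_ANN_COLUMNS) + "\n")
        for f in features:
            segs = ",".join(f"{a}-{b}" for a, b in f.segments)
            fh.write(
                "\t".join(
                    [f.gene, f.ftype, f.genome_ref, segs, f.strand, f.anticodon or "."]
                )
                + "\n"
            )


def write_annotation_gff3(features: Iterable[Feature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.gene};gene={f.gene}"
            if f.anticodon:
                attrs += f";anticodon={f.anticodon}"
            for a, b in sorted(f.segments):
                fh.write(
                    "\t".join(
                        [
                            f.genome_ref,
                            "cpedit",
                            f.ftype,
                            str(a),
                            str(b),
                            ".",
                            f.strand,
                            "0" if f.ftype == "CDS" else ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Predicted-site table


def read_predicted_sites(path: str | Path) -> list[PredictedSite]:
    """Read the predicted-site TSV.

    Columns: gene, cds_pos, codon_change ("TCA-TTA"), aa_change ("S-L"),
    score.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"gene", "cds_pos", "codon_change", "aa_change", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    sites = []
    for row in df.itertuples(index=False):
        codons = str(row.codon_change).replace("–", "-").split("-")
        if len(codons) != 2:
            raise ParseError(
                f"{path}: bad codon_change {row.codon_change!r} for {row.gene}"
            )
        sites.append(
            PredictedSite(
                gene=str(row.gene),
                cds_pos=int(row.cds_pos),
                ref_codon=codons[0].upper(),
                edit_codon=codons[1].upper(),
                aa_change=str(row.aa_change),
                score=float(row.score),
            )
        )
    return sites


def write_predicted_sites(sites: Iterable[PredictedSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tcds_pos\tcodon_change\taa_change\tscore\n")
        for s in sites:
            fh.write(
                f"{s.gene}\t{s.cds_pos}\t{s.ref_codon}-{s.edit_codon}\t"
                f"{s.aa_change}\t{s.score:g}\n"
            )
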