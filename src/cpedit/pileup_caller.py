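"""Per-position pileups over chloroplast features and editing-site calling.

Retained alignments (m0 + m2) are tallied into per-feature columns in
spliced transcript coordinates.  Genome-mapped alignments are projected
into overlapping features strand-awarely (observed bases complemented for
minus-strand features); a read observed through both its genome placement
and its extracted-CDS placement contributes once.

Calling: a C→T column on a CDS (or A→G on a tRNA) is reported when total
coverage >= min_coverage, at least one edited observation survives the
terminal-end filter, and the variant p-value passes.  The variant test is
a one-sided binomial tail P[X >= edited | X ~ Bin(total, err_rate)]
against a flat per-base sequencing error rate, evaluated in log10 domain
so that extremely deep, fully edited columns (tails far below 1e-300)
remain finite.

Terminal-end filter: mismatch observations within ``terminal_window``
bases of either read end are artifact-prone and are removed from the
column (tallied per column in ``terminal_excluded``); matching bases at
terminal read positions still count toward depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .refio import (
    ConfigError,
    DataError,
    Feature,
    ReferenceSet,
    extract_feature_sequence,
)
from .mapper import AlignmentRecord

__all__ = [
    "NoCoverageError",
    "PileupColumn",
    "FeaturePileup",
    "PileupSet",
    "EditingCall",
    "build_pileup",
    "variant_test",
    "call_sites",
    "editing_percentage",
    "calls_frame",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

CHANGE_TYPES = {"C2T": ("C", "T", "CDS"), "A2G": ("A", "G", "tRNA")}


class NoCoverageError(ValueError):
    """Raised when a quantity is undefined at zero coverage."""


@dataclass(frozen=True)
class PileupColumn:
    """Base tallies at one spliced-feature position (1-based, sense)."""

    feature: str
    ftype: str
    cds_pos: int
    ref_base: str
    counts: dict[str, float]
    terminal_excluded: float

    @property
    def depth(self) -> float:
        return sum(self.counts.values())


@dataclass
class FeaturePileup:
    """Dense per-position tallies for one feature."""

    feature: Feature
    ref_seq: str
    counts: np.ndarray  # (4, L) float
    terminal_excluded: np.ndarray  # (L,) float

    def column(self, cds_pos: int) -> PileupColumn:
        i = cds_pos - 1
        return PileupColumn(
            feature=self.feature.gene,
            ftype=self.feature.ftype,
            cds_pos=cds_pos,
            ref_base=self.ref_seq[i],
            counts={b: float(self.counts[_BASE_INDEX[b], i]) for b in _BASES},
            terminal_excluded=float(self.terminal_excluded[i]),
        )


@dataclass
class PileupSet:
    """Pileups for every feature plus genome-space depth."""

    features: dict[str, FeaturePileup]
    genome_depth: dict[str, np.ndarray]
    terminal_window: int
    multiread: str

    def column(self, gene: str, cds_pos: int) -> Optional[PileupColumn]:
        fp = self.features.get(gene)
        if fp is None or not 1 <= cds_pos <= len(fp.ref_seq):
            return None
        return fp.column(cds_pos)

    def iter_columns(self, ftype: Optional[str] = None) -> Iterator[PileupColumn]:
        for fp in self.features.values():
            if ftype is not None and fp.feature.ftype != ftype:
                continue
            covered = np.nonzero(fp.counts.sum(axis=0) + fp.terminal_excluded)[0]
            for i in covered:
                yield fp.column(int(i) + 1)


def build_pileup(
    alignments: Iterable[AlignmentRecord],
    refset: ReferenceSet,
    terminal_window: int = 1,
    multiread: str = "count",
) -> PileupSet:
    """Tally retained alignments into per-feature pileup columns.

    ``multiread='count'`` counts every equal-best placement once;
    ``'fractional'`` weights each by 1/n_best_loci.
    """
    if terminal_window < 0:
        raise ConfigError("terminal_window must be >= 0")
    if multiread not in ("count", "fractional"):
        raise ConfigError(f"unknown multiread policy {multiread!r}")

    feature_ids = set()
    fps: dict[str, FeaturePileup] = {}
    genome_ids = {s.id for s in refset.by_category("chloroplast")}
    for f in refset.features:
        genome = refset.sequences[f.genome_ref]
        seq = extract_feature_sequence(genome, f).sequence
        L = len(seq)
        fps[f.gene] = FeaturePileup(
            feature=f,
            ref_seq=seq,
            counts=np.zeros((4, L)),
            terminal_excluded=np.zeros(L),
        )
        feature_ids.add(f.gene)

    # genome position -> [(gene, cds_pos, strand)] for projection
    proj: dict[str, dict[int, list[tuple[str, int, str]]]] = {g: {} for g in genome_ids}
    for f in refset.features:
        if f.genome_ref not in proj:
            continue
        table = proj[f.genome_ref]
        for cds_pos, gpos in enumerate(f.genome_positions(), start=1):
            table.setdefault(gpos, []).append((f.gene, cds_pos, f.strand))

    genome_depth = {
        g: np.zeros(len(refset.sequences[g].sequence)) for g in genome_ids
    }

    by_read: dict[str, list[AlignmentRecord]] = {}
    for a in alignments:
        by_read.setdefault(a.read_id, []).append(a)

    for read_id, alns in by_read.items():
        n_best = alns[0].n_best_loci
        weight = 1.0 / n_best if multiread == "fractional" else 1.0
        direct = {a.ref_id for a in alns if a.ref_id in feature_ids}
        gseen: set[tuple[str, int]] = set()  # per-read genome positions
        for a in alns:
            L = a.length
            mism = {o: (rb, qb) for o, rb, qb in a.mismatches}
            if a.ref_id in feature_ids:
                fp = fps[a.ref_id]
                start0 = a.start - 1
                for off in range(L):
                    cds_i = start0 + off
                    terminal = off < terminal_window or off >= L - terminal_window
                    if off in mism:
                        if terminal:
                            fp.terminal_excluded[cds_i] += weight
                            continue
                        base = mism[off][1]
                    else:
                        base = fp.ref_seq[cds_i]
                    fp.counts[_BASE_INDEX[base], cds_i] += weight
                # genome-space depth through the feature placement
                f = fp.feature
                gdep = genome_depth.get(f.genome_ref)
                if gdep is not None:
                    positions = f.genome_positions()
                    for off in range(L):
                        g = positions[start0 + off]
                        key = (f.genome_ref, g)
                        if key not in gseen:
                            gseen.add(key)
                            gdep[g - 1] += weight
            elif a.ref_id in genome_ids:
                table = proj[a.ref_id]
                gdep = genome_depth[a.ref_id]
                rs = refset.sequences[a.ref_id].sequence
                start0 = a.start - 1
                for off in range(L):
                    g = start0 + off + 1
                    key = (a.ref_id, g)
                    if key not in gseen:
                        gseen.add(key)
                        gdep[g - 1] += weight
                    hits = table.get(g)
                    if not hits:
                        continue
                    terminal = off < terminal_window or off >= L - terminal_window
                    if off in mism:
                        obs = mism[off][1]
                        is_mismatch = True
                    else:
                        obs = rs[start0 + off]
                        is_mismatch = False
                    for gene, cds_pos, strand in hits:
                        if gene in direct:
                            continue  # already counted through the feature copy
                        fp = fps[gene]
                        base = obs if strand == "+" else _COMP[obs]
                        if is_mismatch and terminal:
                            fp.terminal_excluded[cds_pos - 1] += weight
                        else:
                            fp.counts[_BASE_INDEX[base], cds_pos - 1] += weight
            else:
                raise DataError(f"alignment to unknown reference {a.ref_id!r}")

    return PileupSet(fps, genome_depth, terminal_window, multiread)


def variant_test(edited_cov: float, total_cov: float, err_rate: float) -> float:
    """log10 of the one-sided binomial tail P[X >= edited | Bin(total, err)].

    Evaluated entirely in log space (gammaln + logsumexp): deep, heavily
    edited columns whose tails underflow double precision still return a
    finite log10 p-value.
    """
    if not 0 < err_rate < 1:
        raise ConfigError(f"err_rate must be in (0,1), got {err_rate}")
    if total_cov <= 0:
        raise NoCoverageError("variant test undefined at zero coverage")
    if edited_cov < 0 or edited_cov > total_cov:
        raise DataError(f"edited {edited_cov} outside [0, {total_cov}]")
    if edited_cov == 0:
        return 0.0
    n = float(total_cov)
    # integer support from ceil(edited) .. n; fractional multiread weights
    # are conservatively rounded down to the nearest achievable count
    k0 = int(math.ceil(edited_cov - 1e-9))
    ks = np.arange(k0, int(math.floor(n + 1e-9)) + 1, dtype=float)
    logp = (
        gammaln(n + 1)
        - gammaln(ks + 1)
        - gammaln(n - ks + 1)
        + ks * math.log(err_rate)
        + (n - ks) * math.log1p(-err_rate)
    )
    return float(logsumexp(logp) / math.log(10))


def editing_percentage(
    edited_cov: float, total_cov: float, decimals: Optional[int] = 1
) -> float:
    """Percent of edited observations: 100 * edited / total.

    Reported values are rounded half-up to ``decimals`` places (matching
    printed report style, e.g. 5/12 → 41.7); pass ``decimals=None`` for
    full precision.
    """
    if total_cov <= 0:
        raise NoCoverageError("editing percentage undefined at zero coverage")
    if decimals is None:
        return 100.0 * edited_cov / total_cov
    q = Decimal(1).scaleb(-decimals)
    value = (Decimal(str(edited_cov)) * 100 / Decimal(str(total_cov))).quantize(
        q, rounding=ROUND_HALF_UP
    )
    return float(value)


@dataclass(frozen=True)
class EditingCall:
    """A called editing site: one row of the per-site report."""

    feature: str
    cds_pos: int
    genome_pos: int
    change: str  # C2T or A2G
    total_cov: float
    edited_cov: float
    percent: float  # full precision
    log10_p: float
    codon_change: Optional[str] = None
    aa_change: Optional[str] = None
    aa_pos: Optional[int] = None
    wobble: bool = False

    @property
    def percent_display(self) -> float:
        return editing_percentage(self.edited_cov, self.total_cov, decimals=1)


def call_sites(
    pileups: PileupSet,
    change_type: str,
    refset: ReferenceSet,
    min_coverage: int = 5,
    max_p: float = 1e-2,
    err_rate: float = 1e-3,
) -> list[EditingCall]:
    """Emit editing calls of one change type from built pileups.

    ``change_type`` is ``'C2T'`` (CDS, C-to-U editing read as C→T) or
    ``'A2G'`` (tRNA, A-to-I editing read as G).  A call requires the
    reference base to match, total coverage >= min_coverage, at least one
    surviving edited observation, and binomial tail p <= max_p.
    """
    if change_type not in CHANGE_TYPES:
        raise ConfigError(f"unknown change type {change_type!r}")
    ref_base, alt_base, ftype = CHANGE_TYPES[change_type]
    log10_max_p = math.log10(max_p)
    calls: list[EditingCall] = []
    from .sites import translate_effect  # late import to avoid a cycle

    for fp in pileups.features.values():
        if fp.feature.ftype != ftype:
            continue
        depth = fp.counts.sum(axis=0)
        alt_counts = fp.counts[_BASE_INDEX[alt_base]]
        for i in np.nonzero(alt_counts)[0]:
            i = int(i)
            if fp.ref_seq[i] != ref_base:
                continue
            total = float(depth[i])
            edited = float(alt_counts[i])
            if total < min_coverage or edited <= 0:
                continue
            log10_p = variant_test(edited, total, err_rate)
            if log10_p > log10_max_p:
                continue
            cds_pos = i + 1
            codon_change = aa_change = None
            aa_pos = None
            if ftype == "CDS":
                eff = translate_effect(fp.ref_seq, cds_pos, alt_base)
                codon_change = f"{eff.ref_codon}-{eff.alt_codon}"
                aa_change = f"{eff.ref_aa}-{eff.alt_aa}"
                aa_pos = eff.codon_index
            calls.append(
                EditingCall(
                    feature=fp.feature.gene,
                    cds_pos=cds_pos,
                    genome_pos=fp.feature.cds_to_genome(cds_pos),
                    change=change_type,
                    total_cov=total,
                    edited_cov=edited,
                    percent=100.0 * edited / total,
                    log10_p=log10_p,
                    codon_change=codon_change,
                    aa_change=aa_change,
                    aa_pos=aa_pos,
                    wobble=(ftype == "tRNA" and cds_pos in (34, 35)),
                )
            )
    calls.sort(key=lambda c: (c.feature, c.cds_pos))
    return calls


def calls_frame(calls: Iterable[EditingCall]) -> pd.DataFrame:
    """Per-site report table (gene / codon change / position / coverage /
    percent / log10 p)."""
    rows = []
    for c in calls:
        rows.append(
            {
                "gene": c.feature,
                "codon_change": c.codon_change or ".",
                "cds_pos": c.cds_pos,
                "genome_pos": c.genome_pos,
                "aa_change": c.aa_change or ".",
                "aa_pos": c.aa_pos if c.aa_pos is not None else ".",
                "total_cov": c.total_cov,
                "edited_cov": c.edited_cov,
                "percent": c.percent_display,
                "log10_p": round(c.log10_p, 3),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "codon_change",
            "cds_pos",
            "genome_pos",
            "aa_change",
            "aa_pos",
            "total_cov",
            "edited_cov",
            "percent",
            "log10_p",
        ],
    )
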