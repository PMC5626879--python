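"""Confirmation of predicted editing sites and site-level reporting.

A predicted C-to-U site is checked against the pileup evidence and
classified:

* ``confirmed``     — edited (C→T) reads support the site
* ``covered_not_edited`` — reads cover the position but none are edited
* ``no_coverage``   — no reads at the position
* ``genomic_T``     — the genome already encodes T, so no editing can occur

``genomic_T`` depends only on the reference sequence, never on reads.
Confirmation has two modes mirroring the two-track usage of site tables:
``lenient`` (>=1 edited read surviving the terminal filter, no p-value
threshold — manual-inspection style confirmation) and ``strict`` (the
caller's coverage and p-value thresholds, as used for novel-site
discovery).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .refio import (
    ConfigError,
    CoordinateError,
    Feature,
    PredictedSite,
    ReferenceSet,
)
from .pileup_caller import EditingCall, PileupSet

__all__ = [
    "EffectAnnotation",
    "ConfirmationRecord",
    "STATUS_GLYPHS",
    "translate_effect",
    "confirm_predicted",
    "compare_predictions_vs_snp",
    "scan_trna_editing",
    "coverage_summary",
    "cds_to_genome",
    "confirmation_frame",
]

STATUS_GLYPHS = {
    "confirmed": "*",
    "covered_not_edited": "-",
    "no_coverage": "0",
    "genomic_T": "T",
}


@dataclass(frozen=True)
class EffectAnnotation:
    """Codon-level consequence of a single-base change in a CDS."""

    codon_index: int  # 1-based amino-acid position
    position_in_codon: int  # 1, 2 or 3
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    synonymous: bool


@dataclass(frozen=True)
class ConfirmationRecord:
    """A predicted site joined with its observed pileup evidence."""

    predicted: PredictedSite
    status: str
    total_cov: float
    edited_cov: float
    call: Optional[EditingCall] = None

    @property
    def glyph(self) -> str:
        return STATUS_GLYPHS[self.status]


def translate_effect(
    cds_sequence: str,
    cds_pos: int,
    alt_base: str,
    table: str | int = "Standard",
) -> EffectAnnotation:
    """Annotate the codon and amino-acid consequence of a base change.

    The default genetic code is the standard table; pass ``table=11`` for
    the bacterial/plastid code (identical for all sense codons, differs
    only in initiation rules).
    """
    if not 1 <= cds_pos <= len(cds_sequence):
        raise CoordinateError(f"cds_pos {cds_pos} outside 1..{len(cds_sequence)}")
    if len(cds_sequence) % 3 != 0:
        warnings.warn(
            "CDS length not divisible by 3; effect computed on available frame",
            stacklevel=2,
        )
    ref_base = cds_sequence[cds_pos - 1]
    if ref_base == alt_base:
        raise ConfigError(f"alt base {alt_base!r} equals reference base at {cds_pos}")
    codon_index = (cds_pos - 1) // 3 + 1
    pos_in_codon = (cds_pos - 1) % 3 + 1
    start = (codon_index - 1) * 3
    ref_codon = cds_sequence[start : start + 3]
    if len(ref_codon) < 3:
        ref_codon = ref_codon.ljust(3, "N")
    alt_codon = (
        ref_codon[: pos_in_codon - 1] + alt_base + ref_codon[pos_in_codon:]
    )
    ref_aa = str(Seq(ref_codon).translate(table=table))
    alt_aa = str(Seq(alt_codon).translate(table=table))
    return EffectAnnotation(
        codon_index=codon_index,
        position_in_codon=pos_in_codon,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        synonymous=(ref_aa == alt_aa),
    )


def confirm_predicted(
    predicted: Sequence[PredictedSite],
    calls: Sequence[EditingCall],
    pileups: PileupSet,
    refset: ReferenceSet,
    score_cutoff: float = 0.5,
    mode: str = "lenient",
) -> tuple[list[ConfirmationRecord], list[PredictedSite]]:
    """Classify predicted sites against the observed evidence.

    Sites below ``score_cutoff`` are dropped first.  Duplicate predictions
    for the same (gene, cds_pos) — e.g. genes present in both inverted
    repeat copies — collapse to one record.  Predictions naming genes
    absent from the annotation are returned separately as unmatchable and
    excluded from all denominators.

    Returns (records, unmatchable).
    """
    if mode not in ("lenient", "strict"):
        raise ConfigError(f"mode must be lenient or strict, got {mode!r}")
    call_index = {(c.feature, c.cds_pos): c for c in calls if c.change == "C2T"}
    records: list[ConfirmationRecord] = []
    unmatchable: list[PredictedSite] = []
    seen: set[tuple[str, int]] = set()
    for site in predicted:
        if site.score < score_cutoff:
            continue
        key = (site.gene, site.cds_pos)
        if key in seen:
            continue
        seen.add(key)
        fp = pileups.features.get(site.gene)
        if fp is None or refset.feature(site.gene) is None:
            unmatchable.append(site)
            continue
        if not 1 <= site.cds_pos <= len(fp.ref_seq):
            unmatchable.append(site)
            continue
        ref_base = fp.ref_seq[site.cds_pos - 1]
        col = fp.column(site.cds_pos)
        total = col.depth
        edited = col.counts.get("T", 0.0)
        call = call_index.get(key)
        if ref_base == "T":
            status = "genomic_T"
        elif total <= 0:
            status = "no_coverage"
        elif mode == "lenient":
            status = "confirmed" if edited > 0 else "covered_not_edited"
        else:
            status = "confirmed" if call is not None else "covered_not_edited"
        records.append(
            ConfirmationRecord(
                predicted=site,
                status=status,
                total_cov=total,
                edited_cov=edited,
                call=call,
            )
        )
    return records, unmatchable


def compare_predictions_vs_snp(
    predicted_keys: Iterable[tuple[str, int]],
    snp_calls: Iterable[EditingCall] | Iterable[tuple[str, int]],
) -> dict[str, set[tuple[str, int]]]:
    """Three-way overlap between predicted sites and SNP-derived calls.

    Returns disjoint sets ``both``, ``prep_only`` and ``snp_only`` keyed by
    (gene, cds_pos).
    """
    pred = set(predicted_keys)
    snp: set[tuple[str, int]] = set()
    for c in snp_calls:
        if isinstance(c, EditingCall):
            snp.add((c.feature, c.cds_pos))
        else:
            snp.add(tuple(c))  # type: ignore[arg-type]
    return {
        "both": pred & snp,
        "prep_only": pred - snp,
        "snp_only": snp - pred,
    }


def scan_trna_editing(
    pileups: PileupSet,
    refset: ReferenceSet,
    min_coverage: int = 5,
    max_p: float = 1e-2,
    err_rate: float = 1e-3,
) -> list[EditingCall]:
    """A→G calls over tRNA pileups (inosine is read as G by sequencers).

    Positions are 1-based from the annotated tRNA 5' end; calls at
    position 34 or 35 carry ``wobble=True`` since either convention may
    denote the anticodon wobble base.
    """
    from .pileup_caller import call_sites

    return call_sites(
        pileups,
        "A2G",
        refset,
        min_coverage=min_coverage,
        max_p=max_p,
        err_rate=err_rate,
    )


def coverage_summary(pileups: PileupSet, genome_id: str) -> dict[str, float]:
    """Genome-space coverage statistics: mean, max, zero-coverage count and
    zero-coverage fraction (percent, 2 decimals)."""
    depth = pileups.genome_depth.get(genome_id)
    if depth is None:
        raise ConfigError(f"no genome depth tracked for {genome_id!r}")
    zero = int(np.sum(depth == 0))
    return {
        "mean_coverage": float(depth.mean()),
        "max_coverage": float(depth.max()) if len(depth) else 0.0,
        "zero_coverage_positions": zero,
        "zero_coverage_percent": round(100.0 * zero / len(depth), 2),
    }


def cds_to_genome(feature: Feature, cds_pos: int) -> int:
    """Strand- and splice-aware 1-based genome coordinate of a transcript
    position (inverse of feature extraction)."""
    return feature.cds_to_genome(cds_pos)


def confirmation_frame(
    records: Sequence[ConfirmationRecord],
) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "gene": r.predicted.gene,
                "cds_pos": r.predicted.cds_pos,
                "codon_change": f"{r.predicted.ref_codon}-{r.predicted.edit_codon}",
                "aa_change": r.predicted.aa_change,
                "score": r.predicted.score,
                "status": r.status,
                "glyph": r.glyph,
                "total_cov": r.total_cov,
                "edited_cov": r.edited_cov,
                "percent": (
                    round(100.0 * r.edited_cov / r.total_cov, 1)
                    if r.total_cov > 0
                    else float("nan")
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "cds_pos",
            "codon_change",
            "aa_change",
            "score",
            "status",
            "glyph",
            "total_cov",
            "edited_cov",
            "percent",
        ],
    )
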