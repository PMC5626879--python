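"""Allele-specific qPCR quantification of editing rates.

Two primer sets per site amplify the edited (T) and unedited (C) template
variants; the editing percentage is derived from the difference of their
mean cycle thresholds d = meanCt(T) − meanCt(C) through the logistic form

    % editing = 100 · 2^d / (2^d + 1)

with amplification efficiency fixed at 2.  The formula is implemented
exactly in this orientation; note that under standard qPCR logic a lower
Ct means *more* template, so users who read d the other way can pass
``flip_sign=True`` to compute with −d.  The output is strictly increasing
in d, symmetric (rate(d) + rate(−d) = 100) and confined to (0, 100) for
finite d.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import math

import pandas as pd

from .refio import DataError

__all__ = [
    "QpcrMeasurement",
    "editing_rate_from_ct",
    "summarize_tissues",
    "read_qpcr_tsv",
]


@dataclass(frozen=True)
class QpcrMeasurement:
    """Ct replicates for both variants of one site in one sample."""

    sample: str
    gene: str
    cds_pos: int
    ct_t: tuple[float, ...]
    ct_c: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.ct_t or not self.ct_c:
            raise DataError(
                f"{self.sample}/{self.gene}:{self.cds_pos}: empty Ct replicate list"
            )
        for ct in (*self.ct_t, *self.ct_c):
            if not math.isfinite(ct) or ct <= 0:
                raise DataError(
                    f"{self.sample}/{self.gene}:{self.cds_pos}: bad Ct value {ct}"
                )


def editing_rate_from_ct(m: QpcrMeasurement, flip_sign: bool = False) -> float:
    """Editing percentage from the Ct difference of the two variants."""
    d = sum(m.ct_t) / len(m.ct_t) - sum(m.ct_c) / len(m.ct_c)
    if flip_sign:
        d = -d
    # 100 * 2^d / (2^d + 1), overflow-safe for large |d|
    if d >= 0:
        return 100.0 / (1.0 + 2.0 ** (-d))
    return 100.0 * 2.0**d / (2.0**d + 1.0)


def summarize_tissues(
    measurements: Iterable[QpcrMeasurement], flip_sign: bool = False
) -> pd.DataFrame:
    """Per-tissue (sample) summary across biological replicates.

    Replicate measurements of the same (sample, gene, cds_pos) are each
    converted to a percentage; the summary reports median, min (lower
    whisker) and max (upper whisker), boxplot-style.
    """
    rows = [
        {
            "sample": m.sample,
            "gene": m.gene,
            "cds_pos": m.cds_pos,
            "percent": editing_rate_from_ct(m, flip_sign=flip_sign),
        }
        for m in measurements
    ]
    df = pd.DataFrame(rows, columns=["sample", "gene", "cds_pos", "percent"])
    if df.empty:
        return pd.DataFrame(
            columns=["sample", "gene", "cds_pos", "median", "min", "max", "n"]
        )
    out = (
        df.groupby(["sample", "gene", "cds_pos"], sort=True)["percent"]
        .agg(median="median", min="min", max="max", n="count")
        .reset_index()
    )
    return out


def read_qpcr_tsv(path) -> list[QpcrMeasurement]:
    """Read a long-format Ct table: sample, gene, cds_pos, replicate,
    variant (T/C), ct.  Rows sharing (sample, gene, cds_pos, replicate)
    form one measurement."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample", "gene", "cds_pos", "variant", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    if "replicate" not in df.columns:
        df["replicate"] = 1
    out: list[QpcrMeasurement] = []
    for (sample, gene, cds_pos, rep), grp in df.groupby(
        ["sample", "gene", "cds_pos", "replicate"], sort=True
    ):
        ct_t = tuple(grp.loc[grp["variant"].str.upper() == "T", "ct"].astype(float))
        ct_c = tuple(grp.loc[grp["variant"].str.upper() == "C", "ct"].astype(float))
        out.append(
            QpcrMeasurement(
                sample=str(sample),
                gene=str(gene),
                cds_pos=int(cds_pos),
                ct_t=ct_t,
                ct_c=ct_c,
            )
        )
    return out
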