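"""Cohort-level statistics over per-genome ZCC results.

Aggregates per-genome results into per-phylum summaries (mean/SD of the ZCC
index, sign counts and percentages), classifies each phylum as P-ZCC or
N-ZCC by the majority sign of its genomes, flags extreme genomes with Tukey
fences (Q1 − 1.5·IQR, Q3 + 1.5·IQR), and cross-tabulates the DE/PC
polymerase grouping (PC = PolC present alongside DnaE; DE = DnaE only)
against phylum, with and without the Tukey outliers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenomeMetadata, ResultRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PhylumSummary",
    "OutlierFences",
    "PolymeraseCrosstab",
    "summarize_phylum",
    "classify_group",
    "tukey_outliers",
    "polymerase_crosstab",
    "sgd_by_sign",
]


@dataclass
class PhylumSummary:
    phylum: str
    n_total: int
    n_negative: int
    n_positive: int
    n_zero: int
    n_degenerate: int
    pct_negative: float  # one decimal, over sign-carrying genomes
    pct_positive: float
    mean_zcc: float
    sd_zcc: float
    group: str  # "P-ZCC" | "N-ZCC" | "unclassified"
    mean_gc_content: float | None = None
    mean_sgd_pos: float | None = None
    mean_sgd_neg: float | None = None


@dataclass
class OutlierFences:
    """Tukey fences and the values flagged strictly outside them."""

    q1: float
    q3: float
    outlier_ids: list = field(default_factory=list)

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def lower(self) -> float:
        return self.q1 - 1.5 * self.iqr

    @property
    def upper(self) -> float:
        return self.q3 + 1.5 * self.iqr


@dataclass
class PolymeraseCrosstab:
    """DE/PC x phylum counts, with and without Tukey-fence outliers."""

    all_genomes: pd.DataFrame
    outliers_removed: pd.DataFrame
    n_matched: int
    n_unmatched: int


def classify_group(n_positive: int, n_negative: int) -> str:
    """Majority-sign group label: P-ZCC, N-ZCC, or unclassified on a tie."""
    if n_positive + n_negative == 0:
        raise ValueError("no sign-carrying genomes to classify")
    if n_positive > n_negative:
        return "P-ZCC"
    if n_negative > n_positive:
        return "N-ZCC"
    warnings.warn("exact positive/negative tie; phylum left unclassified", stacklevel=2)
    return "unclassified"


def summarize_phylum(
    records: list[ResultRecord], min_n: int = 15, ddof: int = 1
) -> list[PhylumSummary]:
    """Per-phylum summaries, restricted to phyla with more than ``min_n`` genomes.

    Mean and SD are over non-degenerate ZCC values (sample SD, ``ddof=1``);
    an exactly-zero ZCC — possible on toy inputs — carries no sign and is
    counted separately.  Percentages are over sign-carrying genomes, rounded
    to one decimal.
    """
    by_phylum: dict[str, list[ResultRecord]] = {}
    for r in records:
        if r.phylum is None:
            logger.warning("record %s has no phylum; skipped from summaries", r.genome_id)
            continue
        by_phylum.setdefault(r.phylum, []).append(r)

    summaries = []
    for phylum in sorted(by_phylum):
        recs = by_phylum[phylum]
        if len(recs) <= min_n:
            continue
        values = [r.zcc for r in recs if not r.zcc_degenerate and r.zcc is not None]
        n_degenerate = len(recs) - len(values)
        n_pos = sum(v > 0 for v in values)
        n_neg = sum(v < 0 for v in values)
        n_zero = sum(v == 0 for v in values)
        if n_zero:
            logger.warning("%s: %d genome(s) with ZCC exactly 0, counted as neither sign", phylum, n_zero)
        signed = n_pos + n_neg
        group = classify_group(n_pos, n_neg) if signed else "unclassified"
        gcs = [r.gc_content for r in recs if r.gc_content is not None]
        sgd_pos = [r.sgd_fraction for r in recs
                   if r.sgd_fraction is not None and r.zcc is not None and r.zcc > 0]
        sgd_neg = [r.sgd_fraction for r in recs
                   if r.sgd_fraction is not None and r.zcc is not None and r.zcc < 0]
        summaries.append(
            PhylumSummary(
                phylum=phylum,
                n_total=len(recs),
                n_negative=n_neg,
                n_positive=n_pos,
                n_zero=n_zero,
                n_degenerate=n_degenerate,
                pct_negative=round(100.0 * n_neg / signed, 1) if signed else float("nan"),
                pct_positive=round(100.0 * n_pos / signed, 1) if signed else float("nan"),
                mean_zcc=float(np.mean(values)) if values else float("nan"),
                sd_zcc=float(np.std(values, ddof=ddof)) if len(values) > ddof else float("nan"),
                group=group,
                mean_gc_content=float(np.mean(gcs)) if gcs else None,
                mean_sgd_pos=float(np.mean(sgd_pos)) if sgd_pos else None,
                mean_sgd_neg=float(np.mean(sgd_neg)) if sgd_neg else None,
            )
        )
    return summaries


def tukey_outliers(values, ids=None, method: str = "linear") -> OutlierFences:
    """Tukey-fence outliers: values strictly outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR].

    Quartiles use interpolated order statistics (numpy's ``linear`` rule, the
    common statistics-environment default); pass another numpy quantile
    ``method`` to change the convention.  Requires at least 4 values.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size < 4:
        raise ValueError("need at least 4 values for Tukey fences")
    if ids is None:
        ids = list(range(values.size))
    if len(ids) != values.size:
        raise ValueError("ids and values must have equal length")
    q1, q3 = np.percentile(values, [25, 75], method=method)
    fences = OutlierFences(q1=float(q1), q3=float(q3))
    fences.outlier_ids = [
        i for i, v in zip(ids, values) if v < fences.lower or v > fences.upper
    ]
    return fences


def polymerase_crosstab(
    records: list[ResultRecord],
    metadata: list[GenomeMetadata],
    outlier_ids=(),
) -> PolymeraseCrosstab:
    """Cross-tabulate DE/PC polymerase groups against phylum.

    Genomes with PolC go to PC regardless of which DnaE types they carry;
    all others go to DE.  Genomes without metadata or with unknown PolC
    status are excluded (with counts reported).  The second variant drops
    the genomes in ``outlier_ids`` (typically the Tukey-fence outliers).
    """
    meta = {m.genome_id: m for m in metadata}
    outlier_ids = set(outlier_ids)
    rows = []
    n_unmatched = 0
    for r in records:
        m = meta.get(r.genome_id)
        if m is None or m.has_polc is None:
            if m is None:
                logger.warning("no polymerase metadata for %s; excluded from cross-tab", r.genome_id)
            n_unmatched += 1
            continue
        rows.append(
            {
                "genome_id": r.genome_id,
                "phylum": m.phylum,
                "pol_group": "PC" if m.has_polc else "DE",
                "is_outlier": r.genome_id in outlier_ids,
            }
        )
    df = pd.DataFrame(rows, columns=["genome_id", "phylum", "pol_group", "is_outlier"])

    def _tab(frame: pd.DataFrame) -> pd.DataFrame:
        tab = pd.crosstab(frame["pol_group"], frame["phylum"]) if len(frame) else pd.DataFrame()
        return tab.reindex(index=["DE", "PC"], columns=sorted(df["phylum"].unique()), fill_value=0)

    return PolymeraseCrosstab(
        all_genomes=_tab(df),
        outliers_removed=_tab(df[~df["is_outlier"]]),
        n_matched=len(df),
        n_unmatched=n_unmatched,
    )


def sgd_by_sign(records: list[ResultRecord]) -> pd.DataFrame:
    """Per-phylum mean leading-strand gene fraction, split by ZCC sign.

    Returns a DataFrame indexed by phylum with columns ``mean_sgd_positive``
    and ``mean_sgd_negative``; a cell is NaN when the phylum has no genome
    of that sign (as the survey found for some entirely-negative phyla).
    """
    rows = []
    for r in records:
        if r.phylum is None or r.sgd_fraction is None or r.zcc is None or r.zcc_degenerate:
            continue
        if r.zcc == 0:
            continue
        rows.append({"phylum": r.phylum, "sign": "positive" if r.zcc > 0 else "negative",
                     "sgd": r.sgd_fraction})
    if not rows:
        return pd.DataFrame(columns=["mean_sgd_positive", "mean_sgd_negative"])
    df = pd.DataFrame(rows)
    pivot = df.pivot_table(index="phylum", columns="sign", values="sgd", aggfunc="mean")
    pivot = pivot.reindex(columns=["positive", "negative"])
    pivot.columns = [f"mean_sgd_{c}" for c in pivot.columns]
    return pivot
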