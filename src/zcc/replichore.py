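"""Replichore partitioning, ori/ter inference and strand-biased gene statistics.

A circular bacterial chromosome is replicated bidirectionally from a single
origin (oriC) to a terminus roughly opposite it, splitting the circle into
two replichores.  On the arc ori→ter (increasing deposited coordinates,
wrapping), the deposited forward strand is the leading strand; on the arc
ter→ori it is the lagging strand.

Because the leading strand is almost universally G-enriched, the cumulative
G−C disparity rises along each leading arc: plotted from the origin it forms
an inverted-V peaking at the terminus.  After removing the linear trend (the
chord from the first to the last point — which makes the extrema invariant
to where the deposited sequence happens to start on the circle), the curve's
minimum sits at the origin and its maximum at the terminus.  That detrended
extremum pair is the estimator used here.

Internal coordinates are 0-based half-open on the circle; gene records
arrive 1-based inclusive and are converted exactly once here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import GeneRecord, GenomeSequence, OriCRecord
from .zcurve import DisparityCurves

logger = logging.getLogger(__name__)

__all__ = [
    "ReplichoreModel",
    "SGDResult",
    "estimate_ori_ter",
    "build_replichores",
    "assign_strand",
    "sgd_fraction",
    "rotate_to_ori",
    "rotate_genes",
]

MIN_RECOMMENDED_N = 1000


@dataclass
class ReplichoreModel:
    """Ori and ter positions (0-based, deposited forward strand) on a circle.

    The arcs [ori, ter) and [ter, ori), taken with increasing coordinate and
    wrap-around, partition the circle.  ``confidence`` is the detrended
    disparity amplitude per base, clipped to [0, 1]; values near 0 mean no
    usable skew signal.
    """

    genome_id: str
    ori: int
    ter: int
    N: int
    source: str  # "extrema" | "table"
    confidence: float

    def __post_init__(self) -> None:
        if not (0 <= self.ori < self.N and 0 <= self.ter < self.N):
            raise ValueError(f"ori/ter must lie in [0, {self.N}), got {self.ori}, {self.ter}")
        if self.ori == self.ter:
            raise ValueError("ori and ter coincide; cannot partition the circle")


@dataclass
class SGDResult:
    """Leading/lagging gene counts and the leading-strand fraction (SGD)."""

    genome_id: str
    n_leading: int
    n_lagging: int

    @property
    def fraction_leading(self) -> float:
        return self.n_leading / (self.n_leading + self.n_lagging)


def _detrended(track: np.ndarray) -> np.ndarray:
    # subtract the chord from (0, track[0]) to (N, track[N])
    n = track.shape[0] - 1
    return track - (track[0] + (track[-1] - track[0]) * np.arange(n + 1) / n)


def estimate_ori_ter(
    curves: DisparityCurves, topology: str = "circular", track: str = "gc"
) -> ReplichoreModel:
    """Estimate ori and ter from the extrema of a detrended disparity curve.

    Uses the GC disparity by default: ori is taken at the detrended minimum
    and ter at the detrended maximum (G-enrichment of the leading strand
    makes G−C rise ori→ter).  Circular topology detrends first so estimates
    are rotation-equivariant; a flat curve raises a no-signal error.
    """
    if track not in ("gc", "at"):
        raise ValueError(f"track must be 'gc' or 'at', got {track!r}")
    y = curves.gc if track == "gc" else curves.at
    n = curves.length
    if n < 2:
        raise ValueError("sequence too short to estimate replichores")
    if n < MIN_RECOMMENDED_N:
        warnings.warn(
            f"{curves.genome_id}: N={n} is below {MIN_RECOMMENDED_N}; "
            "skew extrema are unreliable on short sequences",
            stacklevel=2,
        )
    d = _detrended(y.astype(np.float64)) if topology == "circular" else y.astype(np.float64)
    lo, hi = float(d.min()), float(d.max())
    if lo == hi:
        raise ValueError(f"{curves.genome_id}: disparity curve is flat, no replication signal")
    ori = int(np.argmin(d)) % n
    ter = int(np.argmax(d)) % n
    if ori == ter:  # pathological near-flat input
        raise ValueError(f"{curves.genome_id}: ori and ter estimates coincide")
    confidence = min(1.0, (hi - lo) / n)
    return ReplichoreModel(
        genome_id=curves.genome_id, ori=ori, ter=ter, N=n, source="extrema", confidence=confidence
    )


def _oric_midpoint(oric: OriCRecord, n: int) -> int:
    # 1-based inclusive interval -> 0-based midpoint, ties broken downward;
    # intervals wrapping the deposited origin have start > end.
    start0 = oric.oric_start - 1
    end0 = oric.oric_end - 1
    span = (end0 - start0) % n
    return (start0 + span // 2) % n


def build_replichores(
    oric: OriCRecord | int,
    ter: int | None = None,
    curves: DisparityCurves | None = None,
    N: int | None = None,
    genome_id: str = "",
) -> ReplichoreModel:
    """Build a replichore model from a known origin.

    ``oric`` is either a 0-based position or an :class:`OriCRecord`, in
    which case ori is the interval midpoint.  ``ter`` is used when given;
    otherwise it is estimated as the detrended-curve extremum farther from
    ori (requires ``curves``).
    """
    if isinstance(oric, OriCRecord):
        if N is None:
            N = curves.length if curves is not None else None
        if N is None:
            raise ValueError("need genome length N to resolve an oriC interval")
        ori = _oric_midpoint(oric, N)
        genome_id = genome_id or oric.genome_id
    else:
        ori = int(oric)
        if N is None:
            if curves is None:
                raise ValueError("need N or curves")
            N = curves.length
        if not genome_id and curves is not None:
            genome_id = curves.genome_id
    confidence = 1.0
    if ter is None:
        if curves is None:
            raise ValueError("ter not given and no curves to estimate it from")
        est = estimate_ori_ter(curves)
        # pick the extremum farther from ori on the circle
        candidates = (est.ter, est.ori)
        dist = lambda p: min((p - ori) % N, (ori - p) % N)
        ter = max(candidates, key=dist)
        confidence = est.confidence
    ter = int(ter)
    if ter == ori:
        raise ValueError("terminus collides with origin")
    return ReplichoreModel(
        genome_id=genome_id, ori=ori, ter=ter, N=N, source="table", confidence=confidence
    )


def _gene_midpoint(gene: GeneRecord, n: int) -> int:
    start0 = gene.start - 1
    span = ((gene.end - gene.start) % n) + 1 if gene.wraps else gene.end - gene.start + 1
    return (start0 + (span - 1) // 2) % n


def assign_strand(gene: GeneRecord, model: ReplichoreModel) -> str:
    """Assign a gene to the leading or lagging strand.

    A gene whose midpoint lies on the half-open arc [ori, ter) is leading
    iff it is on the forward strand; on [ter, ori) iff on the reverse
    strand.  The half-open convention decides midpoints exactly at ori/ter.
    """
    if gene.genome_id != model.genome_id:
        raise ValueError(
            f"gene {gene.label!r} on {gene.genome_id!r} does not match model {model.genome_id!r}"
        )
    mid = _gene_midpoint(gene, model.N)
    if mid == model.ori or mid == model.ter:
        logger.info("gene %r midpoint at an arc boundary; half-open convention applies", gene.label)
    on_first_arc = (mid - model.ori) % model.N < (model.ter - model.ori) % model.N
    if on_first_arc:
        return "leading" if gene.strand == "+" else "lagging"
    return "leading" if gene.strand == "-" else "lagging"


def sgd_fraction(genes: list[GeneRecord], model: ReplichoreModel) -> SGDResult:
    """Count leading/lagging genes and the leading-strand fraction (SGD).

    Genes on other replicons are skipped with a warning; zero assignable
    genes is an error (the fraction is undefined).
    """
    n_leading = n_lagging = 0
    for gene in genes:
        if gene.genome_id != model.genome_id:
            logger.warning(
                "skipping gene %r: replicon %r does not match %r",
                gene.label, gene.genome_id, model.genome_id,
            )
            continue
        if assign_strand(gene, model) == "leading":
            n_leading += 1
        else:
            n_lagging += 1
    if n_leading + n_lagging == 0:
        raise ValueError(f"no assignable genes for {model.genome_id!r}; SGD undefined")
    return SGDResult(genome_id=model.genome_id, n_leading=n_leading, n_lagging=n_lagging)


def rotate_to_ori(seq: GenomeSequence, model: ReplichoreModel) -> GenomeSequence:
    """Rotate a circular sequence so the origin becomes index 0."""
    if seq.topology != "circular":
        raise ValueError("rotate_to_ori requires a circular sequence")
    k = model.ori % seq.length if seq.length else 0
    return GenomeSequence(
        genome_id=seq.genome_id,
        residues=seq.residues[k:] + seq.residues[:k],
        topology="circular",
    )


def rotate_genes(genes: list[GeneRecord], model: ReplichoreModel) -> list[GeneRecord]:
    """Rotate gene coordinates by the same offset as :func:`rotate_to_ori`."""
    n = model.N
    k = model.ori % n
    out = []
    for g in genes:
        start0 = (g.start - 1 - k) % n
        end0 = (g.end - 1 - k) % n
        out.append(
            GeneRecord(
                genome_id=g.genome_id,
                start=start0 + 1,
                end=end0 + 1,
                strand=g.strand,
                label=g.label,
                wraps=end0 < start0,
            )
        )
    return out
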