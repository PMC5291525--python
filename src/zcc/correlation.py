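"""The ZCC index: Pearson correlation between disparity tracks.

The ZCC (Z-curve Correlation Coefficient) index of a genome is the Pearson
correlation ``r`` between its AT disparity track ``a_n = A_n - T_n`` and its
GC disparity track ``b_n = G_n - C_n``, taken over positions ``n = 1 .. N``
of the whole sequence (the ``n = 0`` origin point, identically zero on both
tracks, is excluded; for genome-scale ``N`` its inclusion would change ``r``
negligibly).  A positive ZCC means the A-vs-T and G-vs-C excesses rise and
fall together along the chromosome — the purine-asymmetry regime typical of
Firmicutes — while a negative ZCC is the common G+T-rich leading-strand
regime.

The analogous RY-MK index correlates the raw Z-curve components ``x``
(purine minus pyrimidine) and ``y`` (amino minus keto) instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import GenomeSequence
from .zcurve import ZCurve, compute_zcurve, disparity_curves

__all__ = ["ZCCResult", "pearson", "zcc_index", "rymk_index"]


@dataclass
class ZCCResult:
    """A correlation value with degeneracy flag and sequence metadata.

    ``degenerate`` is True when either track has zero variance (e.g. a
    homopolymer): ``value`` is then NaN, never silently 0.
    """

    genome_id: str
    value: float
    n_points: int
    degenerate: bool
    track_pair: str  # "atgc" | "rymk"


def pearson(a, b, strict: bool = False) -> float:
    """Pearson correlation coefficient of two equal-length sequences.

        r = sum((a_i - mean(a)) (b_i - mean(b)))
            / sqrt(sum((a_i - mean(a))^2) * sum((b_i - mean(b))^2))

    Computed with centred float64 accumulation (values are first shifted by
    their means, so the cross and square sums do not suffer the cancellation
    of the raw-moment formula).  Zero variance in either sequence returns
    NaN, or raises if ``strict``.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("pearson requires two 1-d sequences of equal length")
    if a.size < 2:
        raise ValueError("pearson requires at least 2 points")
    da = a - a.mean()
    db = b - b.mean()
    saa = float(da @ da)
    sbb = float(db @ db)
    if saa == 0.0 or sbb == 0.0:
        if strict:
            raise ValueError("degenerate input: a track has zero variance")
        return float("nan")
    r = float(da @ db) / np.sqrt(saa * sbb)
    # guard against |r| drifting past 1 by rounding
    return float(np.clip(r, -1.0, 1.0))


def _index(seq: GenomeSequence, track_pair: str, mk_sign: int, strict: bool) -> ZCCResult:
    if seq.length < 2:
        raise ValueError(f"{seq.genome_id!r}: need N >= 2, got {seq.length}")
    zc = compute_zcurve(seq)
    if track_pair == "atgc":
        d = disparity_curves(zc)
        a, b = d.at[1:], d.gc[1:]
    else:
        a, b = zc.x[1:], mk_sign * zc.y[1:]
    r = pearson(a, b, strict=strict)
    return ZCCResult(
        genome_id=seq.genome_id,
        value=r,
        n_points=seq.length,
        degenerate=bool(np.isnan(r)),
        track_pair=track_pair,
    )


def zcc_index(seq: GenomeSequence, strict: bool = False) -> ZCCResult:
    """ZCC index: Pearson r between the AT and GC disparity curves."""
    return _index(seq, "atgc", 1, strict)


def rymk_index(seq: GenomeSequence, mk_sign: int = 1, strict: bool = False) -> ZCCResult:
    """RY-MK index: Pearson r between the x (RY) and y (MK) components.

    ``y`` as defined measures amino minus keto excess; pass ``mk_sign=-1``
    to correlate against the keto-over-amino convention instead (this only
    flips the sign of r).
    """
    if mk_sign not in (1, -1):
        raise ValueError("mk_sign must be +1 or -1")
    return _index(seq, "rymk", mk_sign, strict)
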