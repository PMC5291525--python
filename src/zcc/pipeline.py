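"""Per-genome analysis pipeline: sequence in, results-table row out."""

from __future__ import annotations

import logging

from .correlation import rymk_index, zcc_index
from .io_formats import GeneRecord, GenomeSequence, OriCRecord, ResultRecord
from .replichore import ReplichoreModel, build_replichores, estimate_ori_ter, sgd_fraction
from .zcurve import compute_zcurve, disparity_curves, gc_content

logger = logging.getLogger(__name__)

__all__ = ["analyze_genome"]


def analyze_genome(
    seq: GenomeSequence,
    genes: list[GeneRecord] | None = None,
    oric: OriCRecord | None = None,
    ori_source: str = "extrema",
    phylum: str | None = None,
    mk_sign: int = 1,
) -> ResultRecord:
    """Compute the full per-genome row: ZCC, RY-MK, GC content, ori/ter, SGD.

    ``ori_source`` selects how replichores are found: ``table`` (use the
    supplied oriC interval, terminus from the disparity extrema), ``extrema``
    (both from the detrended GC disparity curve) or ``none`` (skip replichore
    and SGD analysis).  Failures of the optional stages degrade to blank
    columns with a warning rather than aborting the whole run.
    """
    zc = compute_zcurve(seq)
    curves = disparity_curves(zc)
    zcc = zcc_index(seq)
    rymk = rymk_index(seq, mk_sign=mk_sign)
    rec = ResultRecord(
        genome_id=seq.genome_id,
        length=seq.length,
        gc_content=gc_content(zc),
        zcc=None if zcc.degenerate else zcc.value,
        zcc_degenerate=zcc.degenerate,
        rymk=None if rymk.degenerate else rymk.value,
        rymk_degenerate=rymk.degenerate,
        phylum=phylum,
    )
    if zcc.degenerate:
        logger.warning("%s: degenerate ZCC (zero-variance disparity track)", seq.genome_id)

    model: ReplichoreModel | None = None
    if ori_source == "table":
        if oric is None:
            raise ValueError(f"{seq.genome_id}: ori_source=table but no oriC record supplied")
        try:
            model = build_replichores(oric, curves=curves, N=seq.length)
        except ValueError as exc:
            logger.warning("%s: replichore model failed (%s)", seq.genome_id, exc)
    elif ori_source == "extrema":
        try:
            model = estimate_ori_ter(curves)
        except ValueError as exc:
            logger.warning("%s: ori/ter estimation failed (%s)", seq.genome_id, exc)
    elif ori_source != "none":
        raise ValueError(f"unknown ori_source {ori_source!r}")

    if model is not None:
        rec.ori = model.ori
        rec.ter = model.ter
        rec.ori_source = model.source
        if genes:
            own = [g for g in genes if g.genome_id == seq.genome_id]
            if own:
                try:
                    rec.sgd_fraction = sgd_fraction(own, model).fraction_leading
                except ValueError as exc:
                    logger.warning("%s: SGD failed (%s)", seq.genome_id, exc)
    return rec
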