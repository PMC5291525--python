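"""Cumulative Z-curve decomposition and AT/GC disparity curves.

The Z-curve represents a DNA sequence as three cumulative integer tracks:

* ``x_n = (A_n + G_n) - (C_n + T_n)`` — purine over pyrimidine excess,
* ``y_n = (A_n + C_n) - (G_n + T_n)`` — amino over keto excess,
* ``z_n = (A_n + T_n) - (C_n + G_n)`` — weak over strong hydrogen bonds,

where ``A_n, C_n, G_n, T_n`` are occurrence counts of each base accumulated
from the start of the sequence to position ``n`` (``n = 0 .. N``; all counts
are zero at ``n = 0``).  Two derived tracks, the AT disparity
``a_n = (x_n + y_n)/2 = A_n - T_n`` and the GC disparity
``b_n = (x_n - y_n)/2 = G_n - C_n``, measure the running excess of A over T
and of G over C and are the inputs of the ZCC index.

All tracks are exact integer arrays: each unambiguous base moves each of
x, y, z by exactly +/-1 and the halving in the disparity definitions always
divides evenly.  IUPAC ambiguity codes advance the position counter ``n``
(preserving coordinate alignment with annotations) but touch none of the
four base counters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import GenomeSequence

__all__ = ["ZCurve", "DisparityCurves", "compute_zcurve", "disparity_curves", "gc_content"]

# Row indices into the 4 x (N+1) cumulative count matrix.
_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class ZCurve:
    """Cumulative base counts and the three Z-curve components for one sequence.

    Arrays have length ``N + 1``; index ``n`` holds the totals over the first
    ``n`` residues, so index 0 is all zeros.
    """

    genome_id: str
    counts: np.ndarray  # shape (4, N+1), rows A, C, G, T; dtype int64
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    n_ambiguous: int = 0

    @property
    def length(self) -> int:
        return self.x.shape[0] - 1

    def base_totals(self) -> dict[str, int]:
        """Final cumulative count of each unambiguous base."""
        return {b: int(self.counts[i, -1]) for b, i in _BASE_INDEX.items()}


@dataclass
class DisparityCurves:
    """AT disparity ``a_n = A_n - T_n`` and GC disparity ``b_n = G_n - C_n``."""

    genome_id: str
    at: np.ndarray  # integer, length N+1
    gc: np.ndarray

    @property
    def length(self) -> int:
        return self.at.shape[0] - 1


def compute_zcurve(seq: GenomeSequence) -> ZCurve:
    """Compute cumulative base counts and Z-curve components in one pass.

    Ambiguous residues (any IUPAC code outside A/C/G/T) increment ``n``
    without incrementing any base counter, so every component stays flat
    across them.
    """
    n = seq.length
    counts = np.zeros((4, n + 1), dtype=np.int64)
    if n:
        codes = np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8)
        for base, row in _BASE_INDEX.items():
            counts[row, 1:] = np.cumsum(codes == ord(base))
    a, c, g, t = counts
    x = (a + g) - (c + t)
    y = (a + c) - (g + t)
    z = (a + t) - (c + g)
    n_ambiguous = n - int(counts[:, -1].sum())
    return ZCurve(genome_id=seq.genome_id, counts=counts, x=x, y=y, z=z, n_ambiguous=n_ambiguous)


def disparity_curves(zc: ZCurve) -> DisparityCurves:
    """Derive the AT and GC disparity tracks from a Z-curve.

    ``(x + y) // 2`` and ``(x - y) // 2`` are exact: ``x_n + y_n`` is always
    ``2(A_n - T_n)`` and ``x_n - y_n`` is always ``2(G_n - C_n)``.
    """
    at = (zc.x + zc.y) // 2
    gc = (zc.x - zc.y) // 2
    return DisparityCurves(genome_id=zc.genome_id, at=at, gc=gc)


def gc_content(zc: ZCurve) -> float:
    """Fraction (G + C) / (A + C + G + T), ambiguous residues excluded.

    Raises ``ValueError`` on an empty or all-ambiguous sequence, for which
    the fraction is undefined.
    """
    totals = zc.counts[:, -1]
    denom = int(totals.sum())
    if denom == 0:
        raise ValueError(
            f"GC content undefined for {zc.genome_id!r}: no unambiguous residues"
        )
    g = int(totals[_BASE_INDEX["G"]])
    c = int(totals[_BASE_INDEX["C"]])
    return (g + c) / denom
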