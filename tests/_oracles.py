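"""Independent brute-force reference implementations used only by tests.

These deliberately avoid numpy and the package's own code paths: counts are
accumulated with pure-Python loops and Pearson's r is the textbook two-pass
formula, so agreement with the streaming implementation is a real check.
"""

from __future__ import annotations

import math

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def naive_tracks(residues: str) -> dict[str, list[int]]:
    """Single-pass pure-Python accumulation of all six cumulative tracks."""
    a = c = g = t = 0
    out = {k: [0] for k in ("A", "C", "G", "T", "x", "y", "z", "at", "gc")}
    for ch in residues:
        if ch == "A":
            a += 1
        elif ch == "C":
            c += 1
        elif ch == "G":
            g += 1
        elif ch == "T":
            t += 1
        out["A"].append(a)
        out["C"].append(c)
        out["G"].append(g)
        out["T"].append(t)
        out["x"].append((a + g) - (c + t))
        out["y"].append((a + c) - (g + t))
        out["z"].append((a + t) - (c + g))
        out["at"].append(a - t)
        out["gc"].append(g - c)
    return out


def recount_at_position(residues: str, n: int) -> tuple[int, int, int, int]:
    """O(n) from-scratch recount of the four bases over the first n residues."""
    prefix = residues[:n]
    return (prefix.count("A"), prefix.count("C"), prefix.count("G"), prefix.count("T"))


def naive_pearson(a, b) -> float:
    """Textbook two-pass Pearson r; returns NaN on zero variance."""
    n = len(a)
    mean_a = sum(a) / n
    mean_b = sum(b) / n
    cross = sum((ai - mean_a) * (bi - mean_b) for ai, bi in zip(a, b))
    va = sum((ai - mean_a) ** 2 for ai in a)
    vb = sum((bi - mean_b) ** 2 for bi in b)
    if va == 0 or vb == 0:
        return float("nan")
    return cross / math.sqrt(va * vb)


def naive_zcc(residues: str) -> float:
    """ZCC from scratch: recounted disparity tracks + textbook Pearson."""
    tracks = naive_tracks(residues)
    return naive_pearson(tracks["at"][1:], tracks["gc"][1:])


def naive_rymk(residues: str) -> float:
    tracks = naive_tracks(residues)
    return naive_pearson(tracks["x"][1:], tracks["y"][1:])


def in_arc(pos: int, start: int, end: int, n: int) -> bool:
    """Brute-force membership of pos in the half-open wrapping arc [start, end)."""
    p = start
    while p != end:
        if p == pos:
            return True
        p = (p + 1) % n
    return False
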