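"""Synthetic circular genomes with controlled replication-strand bias.

The generator is the inverse of the disparity analysis: it lays down a
circular chromosome with two replichores around chosen ori/ter positions
and samples each base independently.  On the arc where the deposited
forward strand is the leading strand (ori→ter) base ``b`` is drawn with the
leading-strand probability ``p_b``; on the other arc the forward strand is
the lagging strand, so ``b`` is drawn with ``p_complement(b)`` (there the
reverse-complement strand is leading and sees the same composition).

Two regimes matter:

* A+G-enriched leading strand (purine asymmetry, Firmicutes-like): AT and
  GC disparities rise and fall together, giving strongly positive ZCC.
* G+T-enriched leading strand (the common pattern): the disparities move
  oppositely, giving strongly negative ZCC.

Gene annotations are placed as non-overlapping intervals with a
configurable probability of landing on the leading strand, so the
strand-biased gene distribution (SGD) statistic has known truth.  Sampling
is independent per site — the ZCC statistic only depends on cumulative
single-base counts, so first-order composition suffices; no codon or
dinucleotide structure is emulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io_formats import (
    GeneRecord,
    GenomeSequence,
    write_fasta,
    write_genes_tsv,
)

__all__ = [
    "SkewSpec",
    "SyntheticTruth",
    "leading_probs_for_regime",
    "generate_genome",
    "generate_genes",
    "generate_cohort",
]

_BASES = np.array(list("ACGT"))
# complement permutation of (A, C, G, T) -> (T, G, C, A)
_COMPLEMENT_ORDER = [3, 2, 1, 0]

DEFAULT_DELTA = 0.05


def leading_probs_for_regime(regime: str, delta: float = DEFAULT_DELTA) -> tuple[float, ...]:
    """Leading-strand base probabilities (p_A, p_C, p_G, p_T) for a regime.

    ``positive``: A and G enriched by ``delta`` over 0.25 (purine asymmetry);
    ``negative``: G and T enriched; ``uniform``: no skew.
    """
    if not 0 <= delta < 0.25:
        raise ValueError("delta must be in [0, 0.25)")
    if regime == "positive":
        return (0.25 + delta, 0.25 - delta, 0.25 + delta, 0.25 - delta)
    if regime == "negative":
        return (0.25 - delta, 0.25 - delta, 0.25 + delta, 0.25 + delta)
    if regime == "uniform":
        return (0.25, 0.25, 0.25, 0.25)
    raise ValueError(f"unknown regime {regime!r}")


@dataclass
class SkewSpec:
    """Parameters of one synthetic genome."""

    N: int
    ori: int = 0
    ter: int | None = None  # default: opposite ori
    leading_probs: tuple[float, ...] = (0.30, 0.20, 0.30, 0.20)  # (p_A, p_C, p_G, p_T)
    n_genes: int = 0
    p_leading: float = 0.78
    mean_gene_len: int = 900
    seed: int = 0
    genome_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.ter is None:
            self.ter = (self.ori + self.N // 2) % self.N
        probs = np.asarray(self.leading_probs, dtype=float)
        if probs.shape != (4,) or np.any(probs <= 0) or np.any(probs >= 1):
            raise ValueError("leading_probs must be four probabilities in (0, 1)")
        if abs(float(probs.sum()) - 1.0) > 1e-12:
            raise ValueError("leading_probs must sum to 1")
        if not (0 <= self.ori < self.N and 0 <= self.ter < self.N):
            raise ValueError("ori and ter must lie in [0, N)")
        if self.ori == self.ter:
            raise ValueError("ori and ter must differ")
        if not 0.0 <= self.p_leading <= 1.0:
            raise ValueError("p_leading must be in [0, 1]")

    @property
    def expected_zcc_sign(self) -> int:
        """Designed ZCC sign: sign of (p_A − p_T)(p_G − p_C), 0 when skewless."""
        p_a, p_c, p_g, p_t = self.leading_probs
        return int(np.sign((p_a - p_t) * (p_g - p_c)))


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a generated genome."""

    genome_id: str
    true_ori: int
    true_ter: int
    N: int
    expected_zcc_sign: int
    leading_probs: tuple[float, ...]
    p_leading: float
    seed: int
    gene_classes: dict[str, str] = field(default_factory=dict)  # label -> leading|lagging


def _arc_length(start: int, end: int, n: int) -> int:
    return (end - start) % n


def generate_genome(spec: SkewSpec, rng: np.random.Generator | None = None) -> tuple[GenomeSequence, SyntheticTruth]:
    """Sample a circular genome under the two-replichore composition model."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n = spec.N
    leading = np.asarray(spec.leading_probs, dtype=float)
    lagging = leading[_COMPLEMENT_ORDER]  # forward strand on the ter->ori arc
    len1 = _arc_length(spec.ori, spec.ter, n)

    codes = np.empty(n, dtype=np.int64)
    arc1 = rng.choice(4, size=len1, p=leading)
    arc2 = rng.choice(4, size=n - len1, p=lagging)
    idx1 = (spec.ori + np.arange(len1)) % n
    idx2 = (spec.ter + np.arange(n - len1)) % n
    codes[idx1] = arc1
    codes[idx2] = arc2

    seq = GenomeSequence(
        genome_id=spec.genome_id,
        residues="".join(_BASES[codes]),
        topology="circular",
    )
    truth = SyntheticTruth(
        genome_id=spec.genome_id,
        true_ori=spec.ori,
        true_ter=spec.ter,
        N=n,
        expected_zcc_sign=spec.expected_zcc_sign,
        leading_probs=tuple(spec.leading_probs),
        p_leading=spec.p_leading,
        seed=spec.seed,
    )
    return seq, truth


def generate_genes(
    spec: SkewSpec, truth: SyntheticTruth, rng: np.random.Generator | None = None
) -> list[GeneRecord]:
    """Place non-overlapping gene intervals with a known leading-strand bias.

    The circle is cut into ``n_genes`` equal slots; each gene occupies a
    random sub-interval of its slot (so genes never overlap), and its strand
    is chosen so the gene is leading with probability ``p_leading`` given
    which replichore its midpoint falls on.  Intended classes are recorded
    in ``truth.gene_classes``.
    """
    if spec.n_genes <= 0:
        return []
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    n = spec.N
    slot = n // spec.n_genes
    if slot < 2 or spec.mean_gene_len >= slot:
        raise ValueError(
            f"genome too short for {spec.n_genes} genes of ~{spec.mean_gene_len} bp"
        )
    len1 = _arc_length(spec.ori, spec.ter, n)
    genes: list[GeneRecord] = []
    for i in range(spec.n_genes):
        length = int(rng.integers(max(1, spec.mean_gene_len // 2), spec.mean_gene_len + 1))
        length = min(length, slot - 1)
        offset = int(rng.integers(0, slot - length))
        start0 = i * slot + offset
        end0 = start0 + length - 1
        mid = start0 + (length - 1) // 2
        on_first_arc = (mid - spec.ori) % n < len1
        is_leading = bool(rng.random() < spec.p_leading)
        if on_first_arc:
            strand = "+" if is_leading else "-"
        else:
            strand = "-" if is_leading else "+"
        label = f"{spec.genome_id}_g{i + 1:05d}"
        wraps = end0 >= n  # cannot happen with slot placement, kept for clarity
        genes.append(
            GeneRecord(
                genome_id=spec.genome_id,
                start=start0 + 1,
                end=(end0 % n) + 1,
                strand=strand,
                label=label,
                wraps=wraps,
            )
        )
        truth.gene_classes[label] = "leading" if is_leading else "lagging"
    return genes


def generate_cohort(
    outdir: str | Path,
    regime_mix: dict[str, dict],
    n_genomes: int = 20,
    genome_length: int = 50_000,
    n_genes: int = 40,
    mean_gene_len: int = 600,
    seed: int = 0,
) -> dict:
    """Generate a multi-phylum cohort: FASTA + gene TSV + metadata TSV + truth JSON.

    ``regime_mix`` maps each synthetic phylum name to a dict with keys
    ``regime`` ("positive" | "negative" | "uniform"), optional ``delta``,
    optional ``has_polc`` (bool) and optional ``p_leading``.  Each phylum
    gets ``n_genomes`` genomes with ori placed at a random position.
    Returns the written paths and the per-genome truths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s) % (2**31) for s in ss.generate_state(len(regime_mix) * n_genomes * 2)]
    seq_list, gene_list, truths = [], [], []
    meta_rows = []
    i = 0
    for phylum in sorted(regime_mix):
        cfg = regime_mix[phylum]
        probs = leading_probs_for_regime(cfg["regime"], cfg.get("delta", DEFAULT_DELTA))
        for j in range(n_genomes):
            gid = f"{phylum}_{j + 1:03d}"
            rng = np.random.default_rng(child_seeds[i])
            ori = int(rng.integers(0, genome_length))
            spec = SkewSpec(
                N=genome_length,
                ori=ori,
                leading_probs=probs,
                n_genes=n_genes,
                p_leading=cfg.get("p_leading", 0.78),
                mean_gene_len=mean_gene_len,
                seed=child_seeds[i + 1],
                genome_id=gid,
            )
            seq, truth = generate_genome(spec)
            genes = generate_genes(spec, truth)
            seq_list.append(seq)
            gene_list.extend(genes)
            truths.append(truth)
            meta_rows.append(
                {
                    "genome_id": gid,
                    "phylum": phylum,
                    "has_polc": str(cfg.get("has_polc", False)).lower(),
                    "dnae_types": "DnaE1" if not cfg.get("has_polc", False) else "DnaE3",
                }
            )
            i += 2

    fasta_path = outdir / "cohort.fasta"
    genes_path = outdir / "cohort_genes.tsv"
    meta_path = outdir / "cohort_metadata.tsv"
    truth_path = outdir / "cohort_truth.json"
    write_fasta(seq_list, fasta_path)
    write_genes_tsv(gene_list, genes_path)
    with open(meta_path, "w") as fh:
        fh.write("genome_id\tphylum\thas_polc\tdnae_types\n")
        for row in meta_rows:
            fh.write("\t".join(row[c] for c in ("genome_id", "phylum", "has_polc", "dnae_types")) + "\n")
    with open(truth_path, "w") as fh:
        json.dump([asdict(t) for t in truths], fh, indent=1)
        fh.write("\n")
    return {
        "fasta": fasta_path,
        "genes": genes_path,
        "metadata": meta_path,
        "truth": truth_path,
        "truths": truths,
    }
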