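"""Replichore partitioning, ori/ter estimation and SGD statistics."""

from __future__ import annotations

import numpy as np
import pytest

from zcc.io_formats import GeneRecord, GenomeSequence, OriCRecord
from zcc.replichore import (
    ReplichoreModel,
    assign_strand,
    build_replichores,
    estimate_ori_ter,
    rotate_genes,
    rotate_to_ori,
    sgd_fraction,
)
from zcc.simulate import SkewSpec, generate_genome, leading_probs_for_regime
from zcc.zcurve import DisparityCurves, compute_zcurve, disparity_curves

from _oracles import in_arc


def gene(mid: int, strand: str, genome_id: str = "g", n: int = 100) -> GeneRecord:
    # single-base gene: midpoint == position
    return GeneRecord(genome_id=genome_id, start=mid + 1, end=mid + 1, strand=strand, label=f"m{mid}")


def model(ori: int, ter: int, n: int = 100, genome_id: str = "g") -> ReplichoreModel:
    return ReplichoreModel(genome_id=genome_id, ori=ori, ter=ter, N=n, source="table", confidence=1.0)


class TestAssignStrand:
    @pytest.mark.parametrize(
        "ori, ter, mid, strand, expected",
        [
            (0, 50, 10, "+", "leading"),
            (0, 50, 10, "-", "lagging"),
            (0, 50, 60, "+", "lagging"),
            (0, 50, 60, "-", "leading"),
            (80, 30, 10, "+", "leading"),  # arc wraps through 0
        ],
    )
    def test_conventions(self, ori, ter, mid, strand, expected):
        assert assign_strand(gene(mid, strand), model(ori, ter)) == expected

    def test_strand_flip_antisymmetry_exhaustive(self):
        m = model(80, 30)
        for mid in range(100):
            a = assign_strand(gene(mid, "+"), m)
            b = assign_strand(gene(mid, "-"), m)
            assert {a, b} == {"leading", "lagging"}

    def test_arcs_partition_circle(self):
        """Every midpoint falls in exactly one half-open arc (brute-force walk)."""
        for ori, ter in [(0, 50), (80, 30), (99, 1), (3, 97)]:
            for mid in range(100):
                first = in_arc(mid, ori, ter, 100)
                second = in_arc(mid, ter, ori, 100)
                assert first != second
                expected = "leading" if first else "lagging"
                assert assign_strand(gene(mid, "+"), model(ori, ter)) == expected

    def test_mismatched_replicon_is_error(self):
        with pytest.raises(ValueError, match="does not match"):
            assign_strand(gene(5, "+", genome_id="other"), model(0, 50))

    def test_wrapping_gene_midpoint(self):
        # gene 95..4 on N=100 wraps; span 10, midpoint 99
        g = GeneRecord(genome_id="g", start=96, end=5, strand="+", wraps=True)
        assert assign_strand(g, model(90, 40)) == "leading"


class TestBuildReplichores:
    def test_oric_interval_midpoint(self):
        m = build_replichores(OriCRecord("g", 1, 300), ter=600, N=1000)
        assert m.ori == 149  # midpoint 150 in 1-based, ties broken downward
        assert m.source == "table"

    def test_explicit_positions(self):
        m = build_replichores(0, ter=500, N=1000, genome_id="g")
        assert (m.ori, m.ter) == (0, 500)

    def test_ter_collision_is_error(self):
        with pytest.raises(ValueError, match="collides"):
            build_replichores(5, ter=5, N=100, genome_id="g")

    def test_ter_estimated_from_curves(self):
        spec = SkewSpec(N=100_000, ori=20_000, seed=11)
        seq, truth = generate_genome(spec)
        curves = disparity_curves(compute_zcurve(seq))
        m = build_replichores(truth.true_ori, curves=curves)
        assert abs(m.ter - truth.true_ter) <= 0.01 * spec.N


class TestEstimateOriTer:
    def test_recovers_truth_on_synthetic_genome(self):
        spec = SkewSpec(N=100_000, ori=0, seed=5)
        seq, truth = generate_genome(spec)
        m = estimate_ori_ter(disparity_curves(compute_zcurve(seq)))
        n = spec.N

        def circ_err(a, b):
            return min((a - b) % n, (b - a) % n)

        assert circ_err(m.ori, truth.true_ori) <= 0.01 * n
        assert circ_err(m.ter, truth.true_ter) <= 0.01 * n
        assert m.source == "extrema" and m.confidence > 0.01

    def test_rotation_equivariance(self):
        spec = SkewSpec(N=100_000, ori=0, seed=6)
        seq, _ = generate_genome(spec)
        k = 31_337
        rotated = GenomeSequence(genome_id="rot", residues=seq.residues[k:] + seq.residues[:k])
        m0 = estimate_ori_ter(disparity_curves(compute_zcurve(seq)))
        m1 = estimate_ori_ter(disparity_curves(compute_zcurve(rotated)))
        n = spec.N
        shift = (m0.ori - m1.ori) % n
        assert min((shift - k) % n, (k - shift) % n) <= 0.01 * n

    def test_flat_curve_is_no_signal(self):
        flat = DisparityCurves(genome_id="f", at=np.zeros(5001, dtype=int), gc=np.zeros(5001, dtype=int))
        with pytest.raises(ValueError, match="flat"):
            estimate_ori_ter(flat)

    def test_short_sequence_warns(self):
        spec = SkewSpec(N=500, ori=0, leading_probs=(0.4, 0.1, 0.4, 0.1), seed=7)
        seq, _ = generate_genome(spec)
        with pytest.warns(UserWarning, match="below"):
            estimate_ori_ter(disparity_curves(compute_zcurve(seq)))


class TestSGD:
    def test_toy_half_fraction(self):
        m = model(0, 50)
        genes = [gene(10, "+"), gene(10, "-"), gene(60, "+"), gene(60, "-")]
        res = sgd_fraction(genes, m)
        assert (res.n_leading, res.n_lagging) == (2, 2)
        assert res.fraction_leading == 0.5

    def test_all_leading_by_construction(self):
        m = model(0, 50)
        genes = [gene(p, "+") for p in range(5, 45, 10)]
        assert sgd_fraction(genes, m).fraction_leading == 1.0

    def test_other_replicon_skipped_zero_is_error(self):
        m = model(0, 50)
        with pytest.raises(ValueError, match="SGD undefined"):
            sgd_fraction([gene(5, "+", genome_id="plasmid")], m)


class TestRotate:
    def test_rotate_sequence(self):
        seq = GenomeSequence(genome_id="g", residues="ACGT")
        assert rotate_to_ori(seq, model(2, 3, n=4)).residues == "GTAC"

    def test_rotate_by_n_is_identity(self):
        seq = GenomeSequence(genome_id="g", residues="ACGTACGT")
        assert rotate_to_ori(seq, model(0, 4, n=8)).residues == seq.residues

    def test_rotate_genes_modular(self):
        g = GeneRecord(genome_id="g", start=3, end=4, strand="+")
        (rot,) = rotate_genes([g], model(2, 3, n=4))
        assert (rot.start, rot.end) == (1, 2)

    def test_linear_topology_rejected(self):
        seq = GenomeSequence(genome_id="g", residues="ACGT", topology="linear")
        with pytest.raises(ValueError, match="circular"):
            rotate_to_ori(seq, model(1, 2, n=4))
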