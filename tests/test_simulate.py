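"""Synthetic genome generator: determinism, composition model, gene placement."""

from __future__ import annotations

import filecmp

import numpy as np
import pytest
import scipy.stats

from zcc.correlation import zcc_index
from zcc.replichore import build_replichores, sgd_fraction
from zcc.simulate import (
    SkewSpec,
    generate_cohort,
    generate_genes,
    generate_genome,
    leading_probs_for_regime,
)


class TestSkewSpec:
    def test_default_ter_opposite_ori(self):
        spec = SkewSpec(N=1000, ori=100)
        assert spec.ter == 600

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"leading_probs": (0.5, 0.5, 0.2, -0.2)},
            {"leading_probs": (0.3, 0.3, 0.3, 0.3)},
            {"ori": 5, "ter": 5},
            {"p_leading": 1.5},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SkewSpec(N=1000, **kwargs)

    @pytest.mark.parametrize(
        "regime, sign", [("positive", 1), ("negative", -1), ("uniform", 0)]
    )
    def test_expected_sign_matches_regime(self, regime, sign):
        spec = SkewSpec(N=1000, leading_probs=leading_probs_for_regime(regime))
        assert spec.expected_zcc_sign == sign


class TestGenerateGenome:
    def test_deterministic_given_seed(self):
        spec = SkewSpec(N=5000, seed=42)
        s1, _ = generate_genome(spec)
        s2, _ = generate_genome(spec)
        assert s1.residues == s2.residues

    def test_expected_disparity_slopes(self):
        """Per-base slopes of both tracks on the leading arc match p differences."""
        n = 100_000
        p = (0.32, 0.18, 0.28, 0.22)
        spec = SkewSpec(N=n, ori=0, ter=n // 2, leading_probs=p, seed=9)
        seq, _ = generate_genome(spec)
        from zcc.zcurve import compute_zcurve, disparity_curves

        d = disparity_curves(compute_zcurve(seq))
        half = n // 2
        p_a, p_c, p_g, p_t = p
        for track, drift, var in [
            (d.at, p_a - p_t, p_a + p_t - (p_a - p_t) ** 2),
            (d.gc, p_g - p_c, p_g + p_c - (p_g - p_c) ** 2),
        ]:
            slope = (track[half] - track[0]) / half
            se = np.sqrt(var / half)
            assert abs(slope - drift) < 3 * se

    @pytest.mark.parametrize("regime, check", [
        ("positive", lambda z: z > 0.9),
        ("negative", lambda z: z < -0.9),
    ])
    def test_regime_sign_at_study_scale(self, regime, check):
        spec = SkewSpec(N=200_000, leading_probs=leading_probs_for_regime(regime), seed=1)
        seq, truth = generate_genome(spec)
        z = zcc_index(seq).value
        assert check(z)
        assert np.sign(z) == truth.expected_zcc_sign

    def test_uniform_regime_is_weak(self):
        spec = SkewSpec(N=200_000, leading_probs=leading_probs_for_regime("uniform"), seed=2)
        seq, _ = generate_genome(spec)
        from zcc.zcurve import compute_zcurve, disparity_curves
        from zcc.replichore import estimate_ori_ter

        m = estimate_ori_ter(disparity_curves(compute_zcurve(seq)))
        # no designed skew: amplitude-per-base confidence collapses
        assert m.confidence < 0.01

    def test_complement_arc_swap_indistinguishable(self):
        """Complementing the forward strand and swapping arc roles preserves
        the base-composition model (chi-square on base counts per arc)."""
        from _oracles import COMPLEMENT

        pvals = []
        for seed in range(5):
            spec = SkewSpec(N=40_000, ori=0, ter=20_000, seed=seed)
            swapped_spec = SkewSpec(N=40_000, ori=20_000, ter=0, seed=seed + 100,
                                    leading_probs=spec.leading_probs)
            seq, _ = generate_genome(spec)
            swapped, _ = generate_genome(swapped_spec)
            comp = seq.residues.translate(COMPLEMENT)
            for lo, hi in [(0, 20_000), (20_000, 40_000)]:
                counts = [
                    [s[lo:hi].count(b) for b in "ACGT"] for s in (comp, swapped.residues)
                ]
                pvals.append(scipy.stats.chi2_contingency(counts).pvalue)
        assert min(pvals) > 0.01 / len(pvals)  # Bonferroni at alpha = 0.01


class TestGenerateGenes:
    def test_non_overlapping_and_sorted(self):
        spec = SkewSpec(N=50_000, n_genes=50, mean_gene_len=400, seed=3)
        _, truth = generate_genome(spec)
        genes = generate_genes(spec, truth)
        assert len(genes) == 50
        for g1, g2 in zip(genes, genes[1:]):
            assert g1.end < g2.start

    def test_p_leading_one_gives_fraction_one(self):
        spec = SkewSpec(N=50_000, n_genes=100, mean_gene_len=200, p_leading=1.0, seed=4)
        _, truth = generate_genome(spec)
        genes = generate_genes(spec, truth)
        model = build_replichores(spec.ori, ter=spec.ter, N=spec.N, genome_id=spec.genome_id)
        assert sgd_fraction(genes, model).fraction_leading == 1.0
        assert set(truth.gene_classes.values()) == {"leading"}

    def test_truth_classes_match_assignment(self):
        spec = SkewSpec(N=50_000, n_genes=100, mean_gene_len=200, p_leading=0.7, seed=5)
        _, truth = generate_genome(spec)
        genes = generate_genes(spec, truth)
        from zcc.replichore import assign_strand

        model = build_replichores(spec.ori, ter=spec.ter, N=spec.N, genome_id=spec.genome_id)
        for g in genes:
            assert assign_strand(g, model) == truth.gene_classes[g.label]

    def test_genome_too_short_for_genes(self):
        spec = SkewSpec(N=1000, n_genes=10, mean_gene_len=200, seed=6)
        _, truth = generate_genome(spec)
        with pytest.raises(ValueError, match="too short"):
            generate_genes(spec, truth)


class TestGenerateCohort:
    MIX = {
        "PhyPos": {"regime": "positive", "has_polc": True},
        "PhyNeg": {"regime": "negative", "has_polc": False},
    }

    def test_byte_identical_across_runs(self, tmp_path):
        d1, d2 = tmp_path / "run1", tmp_path / "run2"
        p1 = generate_cohort(d1, self.MIX, n_genomes=2, genome_length=5000, n_genes=5,
                             mean_gene_len=100, seed=7)
        p2 = generate_cohort(d2, self.MIX, n_genomes=2, genome_length=5000, n_genes=5,
                             mean_gene_len=100, seed=7)
        for key in ("fasta", "genes", "metadata", "truth"):
            assert filecmp.cmp(p1[key], p2[key], shallow=False)

    def test_files_round_trip_and_truth_join(self, tmp_path):
        from zcc.io_formats import read_fasta, read_genes, read_metadata_table

        paths = generate_cohort(tmp_path / "c", self.MIX, n_genomes=3, genome_length=5000,
                                n_genes=4, mean_gene_len=100, seed=8)
        seqs = read_fasta(paths["fasta"])
        genes = read_genes(paths["genes"], format="tsv")
        meta = read_metadata_table(paths["metadata"])
        assert len(seqs) == 6 and len(meta) == 6
        ids = {s.genome_id for s in seqs}
        assert ids == {t.genome_id for t in paths["truths"]}
        assert ids == {m.genome_id for m in meta}
        assert {g.genome_id for g in genes} == ids
        polc = {m.genome_id: m.has_polc for m in meta}
        assert all(polc[gid] for gid in ids if gid.startswith("PhyPos"))
        assert not any(polc[gid] for gid in ids if gid.startswith("PhyNeg"))
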