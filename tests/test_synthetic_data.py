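"""Synthetic cohort generator: determinism, composition, planted structure."""

import json
import math

import numpy as np
import pytest
from scipy import stats

from codonbias.codon_core import composition, count_codons, pool_counts
from codonbias.synthetic_data import (
    GeneratorConfig,
    generate_cohort,
    generate_strain,
    write_cohort,
)
from codonbias.usage_indices import compute_enc, compute_gc3s_x3s, compute_rscu


class TestDeterminism:
    def test_same_seed_identical_fasta_bytes(self, tmp_path):
        for d in ("a", "b"):
            cohort = generate_cohort(GeneratorConfig(n_strains=2, seed=42))
            write_cohort(cohort, tmp_path / d)
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_gene_streams_independent_of_order(self):
        # gradient off: sharpness is a function of gene index by design
        cfg = GeneratorConfig(n_strains=1, expression_gradient=0.0, seed=7)
        recs1, _ = generate_strain(cfg, "s1")
        cfg2 = GeneratorConfig(n_strains=1, genes_per_strain=3,
                               expression_gradient=0.0, seed=7)
        recs2, _ = generate_strain(cfg2, "s1")
        by_name1 = {r.gene_name: r.sequence for r in recs1}
        for r in recs2:
            assert r.sequence == by_name1[r.gene_name]

    def test_different_seeds_differ(self):
        a, _ = generate_strain(GeneratorConfig(n_strains=1, seed=0), "s1")
        b, _ = generate_strain(GeneratorConfig(n_strains=1, seed=1), "s1")
        assert any(x.sequence != y.sequence for x, y in zip(a, b))


class TestCohortShape:
    def test_default_cohort_dimensions_and_frames(self, code):
        cohort = generate_cohort(GeneratorConfig(seed=3))
        assert len(cohort.strains) == 13
        lo, hi = cohort.config.length_range_bp
        for recs in cohort.strains.values():
            assert len(recs) == 12
            for r in recs:
                assert r.length_bp % 3 == 0
                # stop codon appended beyond the configured body length
                assert lo <= r.length_bp - 3 <= hi
                t = count_codons(r.sequence, code)
                assert t.terminal_stop == "UAA"
                assert t.internal_stops == 0

    def test_infeasible_planted_codon_rejected(self):
        cfg = GeneratorConfig(planted_optimal={"F": "GCA"})  # GCA is Ala
        with pytest.raises(ValueError, match="absent from family"):
            generate_cohort(cfg)

    def test_written_artifacts(self, tmp_path):
        cohort = generate_cohort(GeneratorConfig(n_strains=2, seed=5))
        paths = write_cohort(cohort, tmp_path)
        truth = json.loads(paths["ground_truth"].read_text())
        assert set(truth) == {"strain01", "strain02"}
        manifest = paths["manifest"].read_text().splitlines()
        assert len(manifest) == 1 + 2 * 12


class TestPlantedStructure:
    def test_uniform_preferences_drive_rscu_to_one(self, code):
        cfg = GeneratorConfig(n_strains=1, genes_per_strain=12, regime="neutral",
                              expression_gradient=0.0,
                              length_range_bp=(30000, 30000), seed=10)
        recs, _ = generate_strain(cfg, "s1")
        pooled = pool_counts([count_codons(r.sequence, code) for r in recs])
        rscu = compute_rscu(pooled).defined()
        assert max(abs(v - 1.0) for v in rscu.values()) < 0.1

    def test_extreme_sharpness_recovers_family_size_rscu(self, code):
        planted = {aa: fam[0] for aa, fam in code.families.items() if len(fam) > 1}
        cfg = GeneratorConfig(n_strains=1, genes_per_strain=2,
                              expression_gradient=50.0, planted_optimal=planted,
                              length_range_bp=(30000, 30000), seed=9)
        recs, truth = generate_strain(cfg, "s1")
        t = count_codons(recs[0].sequence, code)  # sharpest gene
        rscu = compute_rscu(t).rscu
        for aa, codon in planted.items():
            k = code.degeneracy_class[aa]
            assert rscu[codon] == pytest.approx(k, rel=0.08)

    def test_empirical_frequencies_match_ground_truth_probs(self, code):
        """Chi-square goodness of fit against the recorded codon
        probabilities is not rejected at alpha = 0.01."""
        rejections = 0
        n_seeds = 8
        for seed in range(n_seeds):
            cfg = GeneratorConfig(n_strains=1, genes_per_strain=1,
                                  expression_gradient=0.0,
                                  length_range_bp=(30000, 30000), seed=seed)
            recs, truth = generate_strain(cfg, "s1")
            gene = recs[0].gene_name
            probs = truth.gene_codon_probs[gene]
            t = count_codons(recs[0].sequence, code)
            sense = t.sense_counts()
            n = sum(sense.values())
            codons = [c for c, p in probs.items() if p * n >= 5]
            obs = np.array([sense.get(c, 0) for c in codons], dtype=float)
            exp = np.array([probs[c] * n for c in codons])
            exp *= obs.sum() / exp.sum()
            p = stats.chisquare(obs, exp).pvalue
            rejections += p < 0.01
        assert rejections <= 1

    def test_ground_truth_gc3s_is_analytic(self, code):
        """Pipeline GC3s estimate within 3 s.e. of the value implied by the
        ground-truth codon probabilities."""
        cfg = GeneratorConfig(n_strains=1, genes_per_strain=1,
                              expression_gradient=0.0,
                              length_range_bp=(9000, 9000), seed=12)
        recs, truth = generate_strain(cfg, "s1")
        probs = truth.gene_codon_probs[recs[0].gene_name]
        deg = set(code.degenerate_codons)
        p_syn = sum(p for c, p in probs.items() if c in deg)
        p_gc3s = sum(p for c, p in probs.items() if c in deg and c[2] in "GC") / p_syn
        t = count_codons(recs[0].sequence, code)
        got = compute_gc3s_x3s(t).gc3s
        n_syn = sum(t.degenerate_counts().values())
        se = math.sqrt(p_gc3s * (1 - p_gc3s) / n_syn)
        assert abs(got - p_gc3s) < 3 * se + 1e-9

    def test_expression_gradient_orders_enc(self, code):
        """Sharper planted preference => lower ENC (negative rank
        correlation between sharpness and ENC in every seed)."""
        for seed in range(8):
            cfg = GeneratorConfig(n_strains=1, expression_gradient=2.0, seed=seed)
            recs, truth = generate_strain(cfg, "s1")
            enc = [compute_enc(count_codons(r.sequence, code)) for r in recs]
            sharp = [truth.gene_sharpness[r.gene_name] for r in recs]
            rho = stats.spearmanr(sharp, enc).statistic
            assert rho < 0


class TestRegimes:
    def test_mutation_regime_couples_positions(self, code):
        cfg = GeneratorConfig(n_strains=1, regime="mutation",
                              expression_gradient=0.0,
                              length_range_bp=(9000, 9000), seed=13)
        recs, truth = generate_strain(cfg, "s1")
        for r in recs:
            p = composition(r.sequence, code)
            g = truth.gene_gc_target[r.gene_name]
            assert p.gc12 == pytest.approx(g, abs=0.05)
            assert p.gc3 == pytest.approx(g, abs=0.05)

    def test_selection_regime_fixes_positions_one_two(self, code):
        cfg = GeneratorConfig(n_strains=1, regime="selection",
                              expression_gradient=0.0,
                              length_range_bp=(9000, 9000), seed=14)
        recs, _ = generate_strain(cfg, "s1")
        gc12 = [composition(r.sequence, code).gc12 for r in recs]
        gc3 = [composition(r.sequence, code).gc3 for r in recs]
        assert np.std(gc12) < np.std(gc3)
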