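"""Codon-usage index battery: RSCU, GC3s/X3s, ENC, CAI, CBI, FOP,
GRAVY, AROMO and the summary table."""

import math

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st

from codonbias.codon_core import count_codons, load_genetic_code
from codonbias.sequence_io import CodingSequence, StrainGeneSet
from codonbias.usage_indices import (
    compute_aromo,
    compute_cai,
    compute_cbi,
    compute_enc,
    compute_fop,
    compute_gc3s_x3s,
    compute_gravy,
    compute_rscu,
    relative_adaptiveness,
    summarize_indices,
)
from tests.conftest import table_from_counts


class TestRSCU:
    def test_uniform_family_is_one(self, make_table):
        t = make_table({"GCA": 2, "GCC": 2, "GCG": 2, "GCU": 2})
        rscu = compute_rscu(t).rscu
        assert all(rscu[c] == pytest.approx(1.0) for c in ("GCA", "GCC", "GCG", "GCU"))

    def test_phe_three_to_one(self, make_table):
        rscu = compute_rscu(make_table({"UUU": 3, "UUC": 1})).rscu
        assert rscu["UUU"] == pytest.approx(1.5)
        assert rscu["UUC"] == pytest.approx(0.5)

    def test_unobserved_family_is_nan_not_zero(self, make_table):
        rscu = compute_rscu(make_table({"UUU": 3, "UUC": 1})).rscu
        assert math.isnan(rscu["GCA"])

    @settings(max_examples=40, derandomize=True)
    @given(counts=st.dictionaries(
        st.sampled_from(["GCA", "GCC", "GCG", "GCU", "UUU", "UUC", "AUA", "AUC", "AUU"]),
        st.integers(min_value=0, max_value=50), min_size=1))
    def test_family_sums_equal_family_size(self, code, counts):
        rscu = compute_rscu(table_from_counts(counts, code)).rscu
        for aa in ("A", "F", "I"):
            fam = code.families[aa]
            vals = [rscu[c] for c in fam]
            if sum(counts.get(c, 0) for c in fam) > 0:
                assert sum(vals) == pytest.approx(code.degeneracy_class[aa], abs=1e-12)
            else:
                assert all(math.isnan(v) for v in vals)


class TestThirdPositionStats:
    def test_all_at_ending_gives_zero_gc3s(self, make_table):
        t = make_table({"GCA": 5, "GCU": 3, "UUA": 2})
        assert compute_gc3s_x3s(t).gc3s == 0.0

    def test_phe_only_gene(self, make_table):
        stats = compute_gc3s_x3s(make_table({"UUU": 1, "UUC": 1}))
        assert stats.gc3s == pytest.approx(0.5)
        # Phe offers no A-ending codon, so the A3s denominator is empty
        assert math.isnan(stats.a3s)
        assert stats.t3s == pytest.approx(0.5)
        assert stats.c3s == pytest.approx(0.5)

    def test_x3s_denominators_count_only_offering_families(self, make_table):
        # Lys (AAA/AAG) offers A and G; Phe (UUU/UUC) offers U and C
        t = make_table({"AAA": 3, "AAG": 1, "UUU": 2, "UUC": 2})
        stats = compute_gc3s_x3s(t)
        assert stats.a3s == pytest.approx(3 / 4)   # A-ending / Lys codons only
        assert stats.g3s == pytest.approx(1 / 4)
        assert stats.t3s == pytest.approx(2 / 4)
        assert stats.c3s == pytest.approx(2 / 4)
        assert stats.gc3s == pytest.approx(3 / 8)  # (1 G + 2 C) / 8 synonymous


class TestENC:
    def test_single_codon_per_family_is_twenty(self, code):
        counts = {fam[0]: 10 for aa, fam in code.families.items()
                  if code.degeneracy_class[aa] >= 2}
        enc = compute_enc(table_from_counts(counts, code))
        assert enc == pytest.approx(20.0, abs=1e-12)

    def test_uniform_usage_capped_at_61(self, code):
        counts = {}
        for aa, fam in code.families.items():
            k = code.degeneracy_class[aa]
            if k >= 2:
                for c in fam:
                    counts[c] = 600 // k
        enc = compute_enc(table_from_counts(counts, code))
        assert enc == 61.0

    def test_uniform_usage_raw_value_against_closed_form(self, code):
        # hand oracle: per family n=600, p=1/k -> F = (600/k - 1) / 599
        def f(k):
            return (600 / k - 1) / 599

        raw = 2 + 9 / f(2) + 1 / f(3) + 5 / f(4) + 3 / f(6)
        assert raw == pytest.approx(61.29, abs=0.01)

    def test_matches_brute_force_oracle_on_random_tables(self, code):
        rng = np.random.default_rng(0)
        deg = list(code.degenerate_codons)
        for _ in range(20):
            counts = {c: int(n) for c, n in
                      zip(deg, rng.integers(0, 30, size=len(deg))) if n > 0}
            t = table_from_counts(counts, code)
            expected = _enc_oracle(counts, code)
            got = compute_enc(t)
            if math.isnan(expected):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-8)

    def test_converges_to_analytic_value_at_large_counts(self, code):
        # fixed proportions, scaled: ENC -> 2 + 9/f2 + 1/f3 + 5/f4 + 3/f6 on sum(p^2)
        rng = np.random.default_rng(1)
        props = {}
        for aa, fam in code.families.items():
            if code.degeneracy_class[aa] < 2:
                continue
            p = rng.dirichlet(np.ones(len(fam)) * 2)
            for c, pc in zip(fam, p):
                props[c] = pc
        analytic_f = {}
        for k in (2, 3, 4, 6):
            fs = []
            for aa, fam in code.families.items():
                if code.degeneracy_class[aa] == k:
                    fs.append(sum(props[c] ** 2 for c in fam))
            analytic_f[k] = np.mean(fs)
        analytic = 2 + 9 / analytic_f[2] + 1 / analytic_f[3] + 5 / analytic_f[4] + 3 / analytic_f[6]
        scale = 200000
        counts = {c: max(1, round(p * scale)) for c, p in props.items()}
        got = compute_enc(table_from_counts(counts, code))
        assert got == pytest.approx(min(analytic, 61.0), abs=0.05)


def _enc_oracle(counts, code):
    """Independent Wright estimator: explicit per-class bookkeeping."""
    by_class = {2: [], 3: [], 4: [], 6: []}
    for aa, fam in code.families.items():
        k = code.degeneracy_class[aa]
        if k < 2:
            continue
        ns = [counts.get(c, 0) for c in fam]
        n = sum(ns)
        if n < 2:
            continue
        f = (n * sum((x / n) ** 2 for x in ns) - 1) / (n - 1)
        if f > 0:
            by_class[k].append(f)
    fbar = {k: sum(v) / len(v) for k, v in by_class.items() if v}
    if 3 not in fbar and 2 in fbar and 4 in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2
    if any(k not in fbar for k in (2, 3, 4, 6)):
        return float("nan")
    return min(2 + 9 / fbar[2] + 1 / fbar[3] + 5 / fbar[4] + 3 / fbar[6], 61.0)


class TestReferenceWeights:
    def test_relative_adaptiveness(self, make_table):
        w = relative_adaptiveness(make_table({"UUU": 9, "UUC": 1})).w
        assert w["UUU"] == 1.0
        assert w["UUC"] == pytest.approx(1 / 9)

    def test_zero_count_replaced_by_half(self, make_table):
        w = relative_adaptiveness(make_table({"UUU": 4})).w
        assert w["UUC"] == pytest.approx(0.125)

    def test_uniform_reference_ties_break_alphabetically(self, make_table):
        counts = {"GCA": 2, "GCC": 2, "GCG": 2, "GCU": 2}
        ref = relative_adaptiveness(make_table(counts))
        assert "GCA" in ref.optimal_set
        assert len(ref.optimal_set & {"GCA", "GCC", "GCG", "GCU"}) == 1

    def test_empty_reference_rejected(self, make_table):
        with pytest.raises(ValueError, match="empty reference"):
            relative_adaptiveness(make_table({"AUG": 5}))


class TestCaiCbiFop:
    def test_all_preferred_codons_give_cai_one(self, make_table):
        ref = relative_adaptiveness(make_table({"UUU": 9, "UUC": 1, "AAA": 8, "AAG": 2}))
        gene = make_table({"UUU": 5, "AAA": 5})
        assert compute_cai(gene, ref) == pytest.approx(1.0)

    def test_cai_geometric_mean_toy(self, make_table):
        ref = relative_adaptiveness(make_table({"UUU": 9, "UUC": 1}))
        gene = make_table({"UUU": 1, "UUC": 1})
        assert compute_cai(gene, ref) == pytest.approx(1 / 3)

    def test_cbi_extremes_and_toy(self, make_table):
        ref = relative_adaptiveness(make_table({"UUU": 9, "UUC": 1}))
        assert compute_cbi(make_table({"UUU": 10}), ref) == pytest.approx(1.0)
        assert compute_cbi(make_table({"UUU": 5, "UUC": 5}), ref) == pytest.approx(0.0)
        assert compute_cbi(make_table({"UUU": 3, "UUC": 7}), ref) == pytest.approx(-0.4)

    def test_fop(self, make_table):
        ref = relative_adaptiveness(make_table({"UUU": 9, "UUC": 1}))
        assert compute_fop(make_table({"UUU": 10}), ref) == pytest.approx(1.0)
        assert compute_fop(make_table({"UUU": 3, "UUC": 7}), ref) == pytest.approx(0.3)


class TestGravyAromo:
    def test_poly_leu(self, make_table):
        assert compute_gravy(make_table({"CUA": 7})) == pytest.approx(3.8)

    def test_leu_lys_mean(self, make_table):
        t = make_table({"CUA": 5, "AAA": 5})
        assert compute_gravy(t) == pytest.approx(-0.05)

    def test_aromo(self, make_table):
        assert compute_aromo(make_table({"UUU": 4})) == pytest.approx(1.0)
        t = make_table({"UUU": 1, "GCA": 3})
        assert compute_aromo(t) == pytest.approx(0.25)

    def test_agrees_with_translated_peptide_oracle(self, code):
        from Bio.SeqUtils.ProtParamData import kd

        rng = np.random.default_rng(3)
        sense = list(code.sense_codons)
        codons = [sense[i] for i in rng.integers(0, len(sense), size=300)]
        seq = "".join(codons)
        peptide = str(Seq(seq.replace("U", "T")).translate(table=1))
        t = count_codons(seq, code)
        assert compute_gravy(t) == pytest.approx(
            np.mean([kd[a] for a in peptide]), abs=1e-12)
        assert compute_aromo(t) == pytest.approx(
            np.mean([a in "FYW" for a in peptide]), abs=1e-12)


class TestSummary:
    def _strain(self, n_genes, seed):
        from codonbias.synthetic_data import GeneratorConfig, generate_strain

        cfg = GeneratorConfig(n_strains=1, genes_per_strain=n_genes, seed=seed)
        recs, _ = generate_strain(cfg, "s1")
        return StrainGeneSet(strain_id="s1", genes={r.gene_name: r for r in recs})

    def test_single_gene_aggregates_equal_record(self):
        sgs = self._strain(2, seed=5)
        only = dict(list(sgs.genes.items())[:1])
        sgs.genes = only
        df, _ = summarize_indices([sgs])
        gene_row = df[df["level"] == "gene"].iloc[0]
        strain_row = df[df["level"] == "strain_mean"].iloc[0]
        assert gene_row["enc"] == pytest.approx(strain_row["enc"])
        assert gene_row["gc3s"] == pytest.approx(strain_row["gc3s"])

    def test_strain_mean_is_hand_average_of_gene_encs(self):
        sgs = self._strain(12, seed=6)
        df, _ = summarize_indices([sgs])
        genes = df[df["level"] == "gene"]
        strain = df[df["level"] == "strain_mean"].iloc[0]
        assert strain["enc"] == pytest.approx(genes["enc"].mean())
        assert strain["gravy"] == pytest.approx(genes["gravy"].mean())

    def test_sharper_preference_lowers_enc_and_raises_max_rscu(self, code):
        """Dirichlet concentration down => stronger synonymous bias."""
        from codonbias.codon_core import pool_counts
        from codonbias.synthetic_data import GeneratorConfig, generate_strain

        wins_enc = wins_rscu = 0
        n_seeds = 6
        for seed in range(n_seeds):
            encs, rscus = [], []
            for kappa in (50.0, 0.3):
                cfg = GeneratorConfig(n_strains=1, genes_per_strain=6,
                                      regime="neutral", kappa=kappa,
                                      expression_gradient=0.0, seed=seed)
                recs, _ = generate_strain(cfg, "s1")
                tables = [count_codons(r.sequence, code) for r in recs]
                encs.append(np.nanmean([compute_enc(t) for t in tables]))
                pooled = compute_rscu(pool_counts(tables)).rscu
                rscus.append(np.nanmax(list(pooled.values())))
            wins_enc += encs[1] < encs[0]
            wins_rscu += rscus[1] > rscus[0]
        assert wins_enc == n_seeds
        assert wins_rscu == n_seeds
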