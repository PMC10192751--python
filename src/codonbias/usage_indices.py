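"""Per-gene and per-strain codon-usage indicators.

Implements the classical index battery: RSCU, GC3s and the per-base X3s
values, Wright's effective number of codons (ENC), the codon adaptation
index (CAI), codon bias index (CBI), frequency of optimal codons (FOP),
mean Kyte-Doolittle hydropathy (GRAVY) and aromaticity (AROMO).

Reference-set policy for CAI/CBI/FOP: unless the caller supplies explicit
:class:`ReferenceWeights`, relative adaptiveness is derived from a
dataset-internal proxy for highly expressed genes -- the pooled counts of
the lowest-ENC decile of genes within each strain (strong bias standing in
for high expression, the usual move when no expression data exist).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .codon_core import (
    CodonCountTable,
    CompositionProfile,
    GeneticCode,
    composition,
    count_codons,
    load_genetic_code,
    pool_counts,
)
from .sequence_io import StrainGeneSet

logger = logging.getLogger(__name__)

AROMATIC_AA = frozenset("FYW")
NAN = float("nan")


# ---------------------------------------------------------------------------
# RSCU
# ---------------------------------------------------------------------------

@dataclass
class RSCUTable:
    """Relative synonymous codon usage for one source.

    Values are defined only for codons in degenerate families (k >= 2);
    codons of families with zero observations carry NaN (undefined), never
    a silent zero.
    """

    rscu: Dict[str, float]
    source: str
    n_codons_used: int
    code: GeneticCode

    def defined(self) -> Dict[str, float]:
        return {c: v for c, v in self.rscu.items() if not math.isnan(v)}


def compute_rscu(counts: CodonCountTable) -> RSCUTable:
    """RSCU_c = observed count x family size / family total.

    Equivalently the observed count divided by the mean count of the
    synonymous family, so RSCU = 1 means no bias and the values within an
    observed family always sum to the family size k.
    """
    code = counts.code
    rscu: Dict[str, float] = {}
    used = 0
    for aa, fam in code.families.items():
        k = code.degeneracy_class[aa]
        if k < 2:
            continue
        fam_counts = {c: counts.counts.get(c, 0) for c in fam}
        tot = sum(fam_counts.values())
        for c in fam:
            rscu[c] = (fam_counts[c] * k / tot) if tot > 0 else NAN
        used += tot
    return RSCUTable(rscu=rscu, source=counts.source, n_codons_used=used, code=code)


# ---------------------------------------------------------------------------
# GC3s and X3s
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThirdPositionStats:
    gc3s: float
    a3s: float
    t3s: float
    g3s: float
    c3s: float


def compute_gc3s_x3s(counts: CodonCountTable) -> ThirdPositionStats:
    """GC3s and per-base synonymous third-position frequencies.

    GC3s is the fraction of synonymous codons (degenerate families only,
    i.e. Met, Trp and stops excluded under the standard code) ending in G
    or C. X3s for base X divides the count of synonymous codons ending in X
    by the count of synonymous codons whose family offers an X-ending
    alternative -- the convention under which A3s + T3s + G3s + C3s can
    exceed 1.
    """
    code = counts.code
    ends: Dict[str, int] = {b: 0 for b in "AUGC"}
    denom: Dict[str, int] = {b: 0 for b in "AUGC"}
    n_syn = 0
    for aa, fam in code.families.items():
        if code.degeneracy_class[aa] < 2:
            continue
        fam_counts = {c: counts.counts.get(c, 0) for c in fam}
        tot = sum(fam_counts.values())
        if tot == 0:
            continue
        n_syn += tot
        offered = {c[2] for c in fam}
        for b in offered:
            denom[b] += tot
        for c, n in fam_counts.items():
            ends[c[2]] += n
    if n_syn == 0:
        return ThirdPositionStats(NAN, NAN, NAN, NAN, NAN)
    gc3s = (ends["G"] + ends["C"]) / n_syn

    def x3s(b: str) -> float:
        return ends[b] / denom[b] if denom[b] > 0 else NAN

    return ThirdPositionStats(gc3s=gc3s, a3s=x3s("A"), t3s=x3s("U"),
                              g3s=x3s("G"), c3s=x3s("C"))


# ---------------------------------------------------------------------------
# ENC (Wright's effective number of codons)
# ---------------------------------------------------------------------------

def compute_enc(counts: CodonCountTable) -> float:
    """Wright's effective number of codons.

    For each amino acid with family size k >= 2 and n >= 2 observations,
    the codon homozygosity is F = (n * sum(p^2) - 1) / (n - 1) with p the
    within-family codon frequencies. F values are averaged within each
    degeneracy class k (amino acids with F = 0 or n < 2 are excluded from
    the average), and

        ENC = n_singletons + sum_k  N_k / F_k_bar

    where N_k is the number of families in class k (standard code:
    2 + 9/F2 + 1/F3 + 5/F4 + 3/F6). A missing class-3 average is imputed
    as the mean of the class-2 and class-4 averages; any other missing
    class makes ENC undefined (NaN). The result is capped at the number of
    sense codons (61 under the standard code).
    """
    code = counts.code
    class_F: Dict[int, List[float]] = {}
    for aa, fam in code.families.items():
        k = code.degeneracy_class[aa]
        if k < 2:
            continue
        fam_counts = [counts.counts.get(c, 0) for c in fam]
        n = sum(fam_counts)
        if n < 2:
            continue
        sum_p2 = sum((x / n) ** 2 for x in fam_counts)
        f = (n * sum_p2 - 1.0) / (n - 1.0)
        if f > 0:
            class_F.setdefault(k, []).append(f)
    class_sizes: Dict[int, int] = {}
    for aa, k in code.degeneracy_class.items():
        if k >= 2:
            class_sizes[k] = class_sizes.get(k, 0) + 1
    f_bar: Dict[int, float] = {k: float(np.mean(v)) for k, v in class_F.items()}
    if 3 in class_sizes and 3 not in f_bar:
        if 2 in f_bar and 4 in f_bar:
            f_bar[3] = (f_bar[2] + f_bar[4]) / 2.0
    missing = [k for k in class_sizes if k not in f_bar]
    if missing:
        return NAN
    enc = len(code.singleton_amino_acids) + sum(
        class_sizes[k] / f_bar[k] for k in class_sizes
    )
    return min(enc, float(len(code.sense_codons)))


# ---------------------------------------------------------------------------
# Relative adaptiveness, CAI, CBI, FOP
# ---------------------------------------------------------------------------

@dataclass
class ReferenceWeights:
    """Relative adaptiveness w per codon, derived from a reference gene set.

    Within each degenerate family max(w) = 1; ``optimal_set`` holds the
    most-used codon of each family (ties broken alphabetically and logged).
    """

    w: Dict[str, float]
    optimal_set: frozenset
    provenance: str
    code: GeneticCode


def relative_adaptiveness(reference: CodonCountTable, provenance: str = "") -> ReferenceWeights:
    """w_c = count_c / max family count; zero counts are replaced by 0.5
    before normalization so log(w) stays finite."""
    code = reference.code
    if sum(reference.degenerate_counts().values()) == 0:
        raise ValueError("empty reference: no synonymous codons observed")
    w: Dict[str, float] = {}
    optimal: List[str] = []
    for aa, fam in code.families.items():
        if code.degeneracy_class[aa] < 2:
            continue
        adj = {c: (reference.counts.get(c, 0) or 0.5) for c in fam}
        top = max(adj.values())
        for c in fam:
            w[c] = adj[c] / top
        best = sorted(c for c in fam if adj[c] == top)
        if len(best) > 1:
            logger.info("reference %s: tie for optimal codon of %s among %s; "
                        "keeping %s", provenance or reference.source, aa, best, best[0])
        optimal.append(best[0])
    return ReferenceWeights(w=w, optimal_set=frozenset(optimal),
                            provenance=provenance or reference.source, code=code)


def compute_cai(counts: CodonCountTable, weights: ReferenceWeights) -> float:
    """Codon adaptation index: geometric mean of w over the gene's
    synonymous codons (singleton families and stops excluded)."""
    deg = counts.degenerate_counts()
    n = sum(deg.values())
    if n == 0:
        return NAN
    log_sum = sum(cnt * math.log(weights.w[c]) for c, cnt in deg.items())
    return math.exp(log_sum / n)


def compute_cbi(counts: CodonCountTable, weights: ReferenceWeights) -> float:
    """Codon bias index: (N_opt - N_rand) / (N_tot - N_rand), where N_rand
    is the optimal-codon count expected under uniform synonymous usage
    (one optimal codon per family)."""
    code = counts.code
    n_tot = 0
    n_opt = 0
    n_rand = 0.0
    for aa, fam in code.families.items():
        k = code.degeneracy_class[aa]
        if k < 2:
            continue
        fam_n = sum(counts.counts.get(c, 0) for c in fam)
        n_tot += fam_n
        n_rand += fam_n / k
        n_opt += sum(counts.counts.get(c, 0) for c in fam if c in weights.optimal_set)
    if n_tot == 0 or math.isclose(n_tot, n_rand):
        return NAN
    return (n_opt - n_rand) / (n_tot - n_rand)


def compute_fop(counts: CodonCountTable, weights: ReferenceWeights) -> float:
    """Frequency of optimal codons among the gene's synonymous codons."""
    deg = counts.degenerate_counts()
    n = sum(deg.values())
    if n == 0:
        return NAN
    n_opt = sum(cnt for c, cnt in deg.items() if c in weights.optimal_set)
    return n_opt / n


# ---------------------------------------------------------------------------
# GRAVY / AROMO
# ---------------------------------------------------------------------------

def compute_gravy(counts: CodonCountTable) -> float:
    """Mean Kyte-Doolittle hydropathy of the encoded residues
    (positive = hydrophobic)."""
    sense = counts.sense_counts()
    n = sum(sense.values())
    if n == 0:
        return NAN
    total = sum(cnt * KYTE_DOOLITTLE[counts.code.codon_to_aa[c]] for c, cnt in sense.items())
    return total / n


def compute_aromo(counts: CodonCountTable) -> float:
    """Fraction of encoded residues that are aromatic (Phe, Tyr, Trp)."""
    sense = counts.sense_counts()
    n = sum(sense.values())
    if n == 0:
        return NAN
    n_arom = sum(cnt for c, cnt in sense.items()
                 if counts.code.codon_to_aa[c] in AROMATIC_AA)
    return n_arom / n


# ---------------------------------------------------------------------------
# Summary table
# ---------------------------------------------------------------------------

#: columns of the per-gene indicator record, in reporting order
INDEX_COLUMNS = [
    "length_bp", "frac_a", "frac_t", "frac_g", "frac_c",
    "gc1", "gc2", "gc3", "gc12", "gc_total",
    "gc3s", "a3s", "t3s", "g3s", "c3s",
    "enc", "cai", "cbi", "fop", "gravy", "aromo",
]


@dataclass
class GeneIndexRecord:
    """The full indicator vector for one source (gene within strain)."""

    source: str
    values: Dict[str, float]


def lowest_enc_genes(gene_enc: Mapping[str, float], fraction: float = 0.10) -> List[str]:
    """Names of the ``max(1, round(fraction * N))`` genes with the lowest
    (defined) ENC; ties broken by gene name."""
    defined = [(g, e) for g, e in gene_enc.items() if not math.isnan(e)]
    if not defined:
        raise ValueError("no genes with a defined ENC")
    m = max(1, round(fraction * len(defined)))
    defined.sort(key=lambda ge: (ge[1], ge[0]))
    return [g for g, _ in defined[:m]]


def internal_reference_weights(
    gene_counts: Mapping[str, CodonCountTable],
    fraction: float = 0.10,
) -> ReferenceWeights:
    """Dataset-internal CAI/CBI/FOP reference: pooled counts of the
    lowest-ENC decile of genes (strong bias as expression proxy)."""
    enc = {g: compute_enc(t) for g, t in gene_counts.items()}
    chosen = lowest_enc_genes(enc, fraction)
    pooled = pool_counts([gene_counts[g] for g in chosen], source="+".join(chosen))
    return relative_adaptiveness(pooled, provenance=f"internal:lowest-ENC({','.join(chosen)})")


def gene_index_record(
    counts: CodonCountTable,
    profile: CompositionProfile,
    weights: ReferenceWeights,
    length_bp: int,
) -> GeneIndexRecord:
    """Assemble the indicator vector for one gene."""
    third = compute_gc3s_x3s(counts)
    values = {
        "length_bp": float(length_bp),
        "frac_a": profile.frac_a, "frac_t": profile.frac_t,
        "frac_g": profile.frac_g, "frac_c": profile.frac_c,
        "gc1": profile.gc1, "gc2": profile.gc2, "gc3": profile.gc3,
        "gc12": profile.gc12, "gc_total": profile.gc_total,
        "gc3s": third.gc3s, "a3s": third.a3s, "t3s": third.t3s,
        "g3s": third.g3s, "c3s": third.c3s,
        "enc": compute_enc(counts),
        "cai": compute_cai(counts, weights),
        "cbi": compute_cbi(counts, weights),
        "fop": compute_fop(counts, weights),
        "gravy": compute_gravy(counts),
        "aromo": compute_aromo(counts),
    }
    return GeneIndexRecord(source=counts.source, values=values)


def summarize_indices(
    gene_sets: Sequence[StrainGeneSet],
    code: Optional[GeneticCode] = None,
    reference: Optional[ReferenceWeights] = None,
    reference_fraction: float = 0.10,
) -> Tuple[pd.DataFrame, dict]:
    """One indicator row per gene per strain plus aggregate rows.

    Aggregates (``level`` column): ``gene`` rows are the raw records;
    ``strain_mean`` rows average over the genes of a strain; ``gene_mean``
    rows average one gene over all strains. Undefined indicators propagate
    as NaN and are excluded from the means. Returns the tidy table and a
    metadata dict recording the genetic code, reference policy and
    aggregation convention.
    """
    code = code or load_genetic_code(1)
    rows: List[dict] = []
    ref_note = reference.provenance if reference else "internal:lowest-ENC-decile-per-strain"
    for sgs in gene_sets:
        gene_counts = {
            g: count_codons(cds.sequence, code, source=f"{sgs.strain_id}|{g}")
            for g, cds in sorted(sgs.genes.items())
        }
        if not gene_counts:
            continue
        weights = reference or internal_reference_weights(gene_counts, reference_fraction)
        for g, counts in gene_counts.items():
            cds = sgs.genes[g]
            profile = composition(cds.sequence, code)
            rec = gene_index_record(counts, profile, weights, cds.length_bp)
            rows.append({"strain": sgs.strain_id, "gene": g, "level": "gene",
                         **rec.values})
    df = pd.DataFrame(rows)
    if df.empty:
        return df, {"genetic_code": code.table_id}
    strain_means = (
        df.groupby("strain", as_index=False)[INDEX_COLUMNS].mean()
        .assign(gene="__all__", level="strain_mean")
    )
    gene_means = (
        df.groupby("gene", as_index=False)[INDEX_COLUMNS].mean()
        .assign(strain="__all__", level="gene_mean")
    )
    out = pd.concat([df, strain_means, gene_means], ignore_index=True)
    out = out[["strain", "gene", "level"] + INDEX_COLUMNS]
    metadata = {
        "genetic_code": code.table_id,
        "reference_policy": ref_note,
        "aggregation": "unweighted mean over genes (strain_mean) / strains (gene_mean)",
    }
    return out, metadata
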