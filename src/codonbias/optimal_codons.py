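"""Optimal-codon determination from ENC-extreme gene sets.

Genes are ranked by ENC; the low-ENC tail (strong bias, standing in for
high expression) and the high-ENC head (weak bias, low expression) each
take 10% of the genes (at least one). Delta-RSCU is the pooled RSCU of the
high-expression proxy set minus that of the low set. A codon is

* **highly expressed** when delta-RSCU > 0.08,
* **high frequency** when its RSCU on the strain-wide pooled counts > 1,
* **optimal** when both hold (strict inequalities at both thresholds).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .codon_core import CodonCountTable, GeneticCode, count_codons, load_genetic_code, pool_counts
from .sequence_io import StrainGeneSet
from .usage_indices import compute_enc, compute_rscu

logger = logging.getLogger(__name__)

NAN = float("nan")

#: (delta-RSCU, RSCU) thresholds for the optimal-codon call
DEFAULT_THRESHOLDS: Tuple[float, float] = (0.08, 1.0)


def split_by_enc(
    gene_enc: Sequence[Tuple[str, float]],
    fraction: float = 0.10,
) -> Tuple[List[str], List[str]]:
    """Split genes into ENC-extreme sets.

    Returns ``(high_expression_genes, low_expression_genes)``: the
    ``max(1, round(fraction * N))`` genes with the lowest ENC (strong bias,
    expression proxy "high") and the same number with the highest ENC.
    Ties are broken by gene name so the split is deterministic.
    """
    if not 0.0 < fraction <= 0.5:
        raise ValueError(f"fraction must be in (0, 0.5], got {fraction}")
    defined = [(g, e) for g, e in gene_enc if not math.isnan(e)]
    if len(defined) < 2:
        raise ValueError("need at least 2 genes with a defined ENC")
    m = max(1, round(fraction * len(defined)))
    asc = sorted(defined, key=lambda ge: (ge[1], ge[0]))
    desc = sorted(defined, key=lambda ge: (-ge[1], ge[0]))
    high_expression = sorted(g for g, _ in asc[:m])
    low_expression = sorted(g for g, _ in desc[:m])
    return high_expression, low_expression


def delta_rscu(
    high_counts: CodonCountTable,
    low_counts: CodonCountTable,
) -> Dict[str, float]:
    """Per-codon RSCU(high-expression set) - RSCU(low-expression set);
    NaN where either family is unobserved."""
    hi = compute_rscu(high_counts).rscu
    lo = compute_rscu(low_counts).rscu
    return {c: hi[c] - lo[c] for c in hi}


@dataclass
class OptimalCodonReport:
    """Per-strain optimal-codon call with the supporting sets and values."""

    strain_id: str
    high_set_genes: List[str]
    low_set_genes: List[str]
    delta_rscu: Dict[str, float]
    pooled_rscu: Dict[str, float]
    high_frequency: frozenset
    highly_expressed: frozenset
    optimal: frozenset
    thresholds: Tuple[float, float] = DEFAULT_THRESHOLDS


def call_optimal_codons(
    strain: StrainGeneSet,
    code: Optional[GeneticCode] = None,
    thresholds: Tuple[float, float] = DEFAULT_THRESHOLDS,
    fraction: float = 0.10,
) -> OptimalCodonReport:
    """Full optimal-codon determination for one strain.

    High-frequency status is evaluated on the strain-wide pooled counts;
    delta-RSCU on the pooled counts of the two ENC-extreme gene sets.
    """
    code = code or load_genetic_code(1)
    d_thr, r_thr = thresholds
    gene_counts = {
        g: count_codons(cds.sequence, code, source=f"{strain.strain_id}|{g}")
        for g, cds in sorted(strain.genes.items())
    }
    if len(gene_counts) < 2:
        raise ValueError(f"{strain.strain_id}: need at least 2 genes")
    enc = [(g, compute_enc(t)) for g, t in gene_counts.items()]
    high_genes, low_genes = split_by_enc(enc, fraction)
    high_pool = pool_counts([gene_counts[g] for g in high_genes], source="high")
    low_pool = pool_counts([gene_counts[g] for g in low_genes], source="low")
    strain_pool = pool_counts(list(gene_counts.values()), source=strain.strain_id)
    d = delta_rscu(high_pool, low_pool)
    pooled = compute_rscu(strain_pool).rscu
    high_freq = frozenset(c for c, v in pooled.items()
                          if not math.isnan(v) and v > r_thr)
    highly_expr = frozenset(c for c, v in d.items()
                            if not math.isnan(v) and v > d_thr)
    return OptimalCodonReport(
        strain_id=strain.strain_id,
        high_set_genes=high_genes,
        low_set_genes=low_genes,
        delta_rscu=d,
        pooled_rscu=pooled,
        high_frequency=high_freq,
        highly_expressed=highly_expr,
        optimal=high_freq & highly_expr,
        thresholds=thresholds,
    )


def cross_strain_optimal_summary(reports: Sequence[OptimalCodonReport]) -> pd.Series:
    """Per-codon count of strains where the codon is optimal, sorted by
    count (descending) then codon (alphabetical)."""
    if not reports:
        raise ValueError("no reports given")
    codons = sorted(reports[0].delta_rscu)
    counts = {c: sum(1 for r in reports if c in r.optimal) for c in codons}
    s = pd.Series(counts, name="n_strains_optimal")
    return s.sort_index().sort_values(ascending=False, kind="stable")


def optimal_codon_table(
    reports: Sequence[OptimalCodonReport],
    code: Optional[GeneticCode] = None,
) -> pd.DataFrame:
    """Tidy per-strain table: codon, amino acid, pooled RSCU, delta-RSCU
    and the three status flags."""
    code = code or load_genetic_code(1)
    rows = []
    for r in reports:
        for c in sorted(r.delta_rscu):
            rows.append({
                "strain": r.strain_id,
                "codon": c,
                "aa": code.codon_to_aa[c],
                "rscu_pooled": r.pooled_rscu.get(c, NAN),
                "delta_rscu": r.delta_rscu[c],
                "high_frequency": c in r.high_frequency,
                "highly_expressed": c in r.highly_expressed,
                "optimal": c in r.optimal,
            })
    return pd.DataFrame(rows)
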