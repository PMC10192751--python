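"""Mutation-vs-selection diagnostics for codon usage.

Four classical analyses:

* **Neutrality plot** -- ordinary least squares of GC12 on GC3 across the
  genes of a strain; a slope near 1 indicates shared mutational pressure on
  all codon positions, a slope near 0 indicates selection holding the first
  two positions while the third drifts.
* **ENC-GC3s plot** -- observed ENC against the null curve expected when
  composition alone drives bias, ``ENC_exp = 2 + s + 29 / (s^2 + (1-s)^2)``,
  with the relative deviation ``ENC_ratio = (exp - obs) / exp``.
* **PR2-bias plot** -- third-position parity, A3/(A3+T3) against
  G3/(G3+C3) at degenerate sites; (0.5, 0.5) means no strand/selection
  asymmetry.
* **Correspondence analysis** of the gene x codon RSCU matrix (59 sense
  codons under the standard code), plus the pairwise Pearson correlation
  matrix of the usage indicators.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .codon_core import CodonCountTable, CompositionProfile
from .usage_indices import RSCUTable

logger = logging.getLogger(__name__)

NAN = float("nan")


# ---------------------------------------------------------------------------
# Neutrality plot
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeutralityFit:
    strain_id: str
    slope: float
    intercept: float
    r2: float
    pearson_r: float
    p_value: float
    n_points: int

    @property
    def defined(self) -> bool:
        return self.n_points >= 3 and not math.isnan(self.slope)


def neutrality_fit(profiles: Sequence[CompositionProfile], strain_id: str = "") -> NeutralityFit:
    """OLS regression of GC12 on GC3 over the genes of one strain.

    The p-value is the two-sided Pearson test (t with n-2 df). Fewer than
    3 points, or zero variance in GC3, yields an explicitly undefined fit.
    """
    pts = [(p.gc3, p.gc12) for p in profiles
           if not (math.isnan(p.gc3) or math.isnan(p.gc12))]
    n = len(pts)
    if n < 3:
        return NeutralityFit(strain_id, NAN, NAN, NAN, NAN, NAN, n)
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.allclose(x, x[0]):
        return NeutralityFit(strain_id, NAN, NAN, NAN, NAN, NAN, n)
    if np.allclose(y, y[0]):
        # constant response: slope 0, no explained variance
        return NeutralityFit(strain_id, 0.0, float(y[0]), 0.0, 0.0, 1.0, n)
    res = stats.linregress(x, y)
    return NeutralityFit(
        strain_id=strain_id,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        n_points=n,
    )


# ---------------------------------------------------------------------------
# ENC-GC3s plot
# ---------------------------------------------------------------------------

def enc_expected(gc3s: float) -> float:
    """ENC expected under pure compositional (mutational) bias at
    synonymous third-position GC content ``s``:
    ``2 + s + 29 / (s^2 + (1 - s)^2)``."""
    s = float(gc3s)
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"GC3s must be within [0, 1], got {s}")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


def enc_ratio(enc_exp: float, enc_obs: float) -> float:
    """Signed relative deviation (exp - obs) / exp; positive when the
    observed ENC falls below the mutational expectation."""
    if enc_exp <= 0:
        raise ValueError(f"expected ENC must be positive, got {enc_exp}")
    return (enc_exp - enc_obs) / enc_exp


@dataclass(frozen=True)
class EncPlotPoint:
    source: str
    gc3s: float
    enc_obs: float
    enc_exp: float
    enc_ratio: float


def enc_plot_point(source: str, gc3s: float, enc_obs: float) -> EncPlotPoint:
    if math.isnan(gc3s) or math.isnan(enc_obs):
        return EncPlotPoint(source, gc3s, enc_obs, NAN, NAN)
    exp = enc_expected(gc3s)
    return EncPlotPoint(source, gc3s, enc_obs, exp, enc_ratio(exp, enc_obs))


# ---------------------------------------------------------------------------
# PR2-bias plot
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PR2Point:
    source: str
    x: float          # G3 / (G3 + C3)
    y: float          # A3 / (A3 + T3)
    n_sites: int
    mode: str


def pr2_point(counts: CodonCountTable, mode: str = "fourfold") -> PR2Point:
    """Third-position parity coordinates.

    ``fourfold`` (default, Sueoka's construction) restricts the tally to
    fourfold-degenerate families, where the third base is free of amino-acid
    constraint; ``all3rd`` uses every degenerate family.
    """
    if mode not in ("fourfold", "all3rd"):
        raise ValueError(f"unknown PR2 mode {mode!r}")
    code = counts.code
    min_k = 4 if mode == "fourfold" else 2
    max_k = 4 if mode == "fourfold" else 6
    tallies = {b: 0 for b in "AUGC"}
    for aa, fam in code.families.items():
        if not min_k <= code.degeneracy_class[aa] <= max_k:
            continue
        for c in fam:
            tallies[c[2]] += counts.counts.get(c, 0)
    n_sites = sum(tallies.values())
    at = tallies["A"] + tallies["U"]
    gc = tallies["G"] + tallies["C"]
    y = tallies["A"] / at if at > 0 else NAN
    x = tallies["G"] / gc if gc > 0 else NAN
    if at == 0 or gc == 0:
        logger.warning("%s: PR2 coordinate undefined (zero denominator)", counts.source)
    return PR2Point(source=counts.source, x=x, y=y, n_sites=n_sites, mode=mode)


# ---------------------------------------------------------------------------
# Correspondence analysis
# ---------------------------------------------------------------------------

@dataclass
class COAResult:
    row_coords: pd.DataFrame       # genes x axes, principal coordinates
    col_coords: pd.DataFrame       # codons x axes
    inertia: np.ndarray            # principal inertias (squared singular values)
    contribution_pct: np.ndarray   # 100 * inertia / total inertia
    n_axes: int
    degenerate: bool = False       # all rows identical -> zero inertia


def correspondence_analysis(
    matrix: pd.DataFrame,
    n_axes: Optional[int] = None,
) -> COAResult:
    """Classical correspondence analysis of a non-negative matrix.

    Rows are genes, columns codons (typically the 59-codon RSCU matrix).
    The matrix is scaled to proportions P, standardized residuals
    ``S = Dr^-1/2 (P - r c^T) Dc^-1/2`` are decomposed by SVD, principal
    inertias are the squared singular values and the axis contribution is
    each inertia's share of the total. NaN cells are imputed as 0 with a
    logged count; all-zero columns are dropped from the decomposition.
    """
    X = matrix.to_numpy(dtype=float)
    n_nan = int(np.isnan(X).sum())
    if n_nan:
        logger.info("COA: imputed %d undefined cell(s) as 0", n_nan)
        X = np.nan_to_num(X, nan=0.0)
    if X.shape[0] < 2:
        raise ValueError("correspondence analysis needs at least 2 rows")
    if (X < 0).any():
        raise ValueError("correspondence analysis requires non-negative input")
    col_keep = X.sum(axis=0) > 0
    if not col_keep.all():
        logger.info("COA: dropped %d all-zero column(s)", int((~col_keep).sum()))
    X = X[:, col_keep]
    cols = matrix.columns[col_keep]
    total = X.sum()
    if total <= 0:
        raise ValueError("correspondence analysis requires a positive matrix total")
    P = X / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if (r <= 0).any():
        raise ValueError("all-zero row in correspondence analysis input")
    Dr = 1.0 / np.sqrt(r)
    Dc = 1.0 / np.sqrt(c)
    S = Dr[:, None] * (P - np.outer(r, c)) * Dc[None, :]
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    max_axes = min(X.shape[0], X.shape[1]) - 1
    sv = sv[:max_axes]
    U = U[:, :max_axes]
    Vt = Vt[:max_axes]
    inertia = sv**2
    total_inertia = inertia.sum()
    if n_axes is not None:
        sv, U, Vt, inertia = sv[:n_axes], U[:, :n_axes], Vt[:n_axes], inertia[:n_axes]
    degenerate = total_inertia < 1e-12
    if degenerate:
        logger.warning("COA: zero total inertia (all row profiles identical)")
        contribution = np.full(len(inertia), NAN)
    else:
        contribution = 100.0 * inertia / total_inertia
    row_coords = Dr[:, None] * U * sv[None, :]
    col_coords = Dc[:, None] * Vt.T * sv[None, :]
    axes = [f"axis{i+1}" for i in range(len(sv))]
    return COAResult(
        row_coords=pd.DataFrame(row_coords, index=matrix.index, columns=axes),
        col_coords=pd.DataFrame(col_coords, index=cols, columns=axes),
        inertia=inertia,
        contribution_pct=contribution,
        n_axes=len(sv),
        degenerate=degenerate,
    )


def rscu_gene_matrix(tables: Sequence[RSCUTable]) -> pd.DataFrame:
    """Stack per-gene RSCU tables into a genes x 59-codon matrix
    (fixed column order; undefined families as NaN for the caller to
    impute)."""
    if not tables:
        raise ValueError("no RSCU tables given")
    code = tables[0].code
    cols = list(code.degenerate_codons)
    rows = {t.source: [t.rscu.get(c, NAN) for c in cols] for t in tables}
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


# ---------------------------------------------------------------------------
# Indicator correlations
# ---------------------------------------------------------------------------

def indicator_correlations(
    table: pd.DataFrame,
    indicators: Optional[Sequence[str]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-sided p over gene-level indicator rows.

    Missing values are pairwise-deleted; pairs with fewer than 3 complete
    observations or a zero-variance member get NaN.
    """
    if indicators is None:
        indicators = [c for c in table.columns
                      if table[c].dtype.kind in "fi" and c != "length_bp"]
    k = len(indicators)
    r = pd.DataFrame(np.full((k, k), NAN), index=indicators, columns=indicators)
    p = r.copy()
    for i, a in enumerate(indicators):
        for j, b in enumerate(indicators):
            if j < i:
                continue
            if i == j:
                xa = table[a].dropna().to_numpy()
                if len(xa) >= 3 and not np.allclose(xa, xa[0]):
                    r.loc[a, a] = 1.0
                    p.loc[a, a] = 0.0
                continue
            sub = table[[a, b]].dropna()
            if len(sub) < 3:
                continue
            xa, xb = sub[a].to_numpy(), sub[b].to_numpy()
            if np.allclose(xa, xa[0]) or np.allclose(xb, xb[0]):
                continue
            rr, pp = stats.pearsonr(xa, xb)
            r.loc[a, b] = r.loc[b, a] = float(rr)
            p.loc[a, b] = p.loc[b, a] = float(pp)
    return r, p
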