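"""Synthetic CDS cohorts with planted codon-usage structure.

The generator emulates the statistical shape of fungal mitochondrial core
protein-coding genes -- AT-rich composition (T around 40%, A around 33% of
the CDS), strong A/T preference at synonymous third positions, 12 core
genes per strain with lengths between roughly 360 and 1990 bp -- while
planting known structure that every pipeline stage can be tested against:

* ``mutation`` regime: a per-gene GC pressure drives all three codon
  positions jointly, so GC12 tracks GC3 across genes (expected neutrality
  slope 1).
* ``selection`` regime: amino-acid usage (hence positions 1-2) is fixed
  while each gene draws its own third-position GC target, so GC12 is flat
  against GC3 (expected slope 0).
* ``neutral`` regime: uniform synonymous usage, optionally perturbed by a
  per-gene Dirichlet draw with concentration ``kappa`` (smaller kappa =
  sharper random preference = lower ENC).

An ``expression_gradient`` sharpens within-family preference toward a
planted optimal codon as the gene index decreases, so low-index genes have
low ENC -- the ground truth for optimal-codon recovery tests.

Codons are sampled i.i.d. within a gene (no phylogenetic autocorrelation);
every statistic under test is compositional, so independence is the
correct minimal model. Each gene ends with a UAA stop codon.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .codon_core import GeneticCode, load_genetic_code
from .sequence_io import CORE_GENES, CodingSequence, write_fasta_cds

#: base model for codon positions 1-2 (sets amino-acid usage; GC ~ 0.32,
#: T-rich so the whole CDS lands near T 40% / A 33%)
DEFAULT_BASE_MODEL: Dict[str, float] = {"A": 0.26, "U": 0.42, "G": 0.17, "C": 0.15}
#: third-position base preference at synonymous sites (A > U >> G > C)
DEFAULT_THIRD_BASE_WEIGHTS: Dict[str, float] = {"A": 0.52, "U": 0.34, "G": 0.08, "C": 0.06}


@dataclass
class GeneratorConfig:
    """Tunable study design for a synthetic cohort.

    Defaults mirror the mitochondrial dataset the pipeline targets:
    13 strains x 12 core genes, 360-1990 bp, extreme AT richness with a
    selection-driven third-position preference and a moderate expression
    gradient.
    """

    n_strains: int = 13
    genes_per_strain: int = 12
    gene_names: Tuple[str, ...] = CORE_GENES
    length_range_bp: Tuple[int, int] = (360, 1990)
    regime: str = "selection"                 # mutation | selection | neutral
    gc_pressure: float = 0.27                 # mutation regime: mean GC
    gc_spread: float = 0.12                   # mutation regime: per-gene half-range
    gc3_range: Tuple[float, float] = (0.06, 0.22)  # selection regime: per-gene GC3 target
    base_model: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASE_MODEL))
    third_base_weights: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_THIRD_BASE_WEIGHTS))
    aa_frequency: Optional[Dict[str, float]] = None   # default: derived from base_model
    kappa: Optional[float] = None             # Dirichlet concentration on family prefs
    planted_optimal: Optional[Dict[str, str]] = None  # amino acid -> codon
    expression_gradient: float = 0.8          # sharpening toward planted codons
    strain_effect: float = 0.04               # per-strain third-base jitter
    table_id: int = 1
    seed: int = 0

    def validate(self, code: GeneticCode) -> None:
        lo, hi = self.length_range_bp
        # generated lengths are whole codons within [lo, hi]
        if lo <= 0 or hi < lo or hi // 3 < 1:
            raise ValueError(f"invalid length range {self.length_range_bp}")
        if self.regime not in ("mutation", "selection", "neutral"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if not 0.0 < self.gc_pressure < 1.0:
            raise ValueError("gc_pressure must be in (0, 1)")
        if self.expression_gradient < 0:
            raise ValueError("expression_gradient must be >= 0")
        if self.planted_optimal:
            for aa, codon in self.planted_optimal.items():
                fam = code.families.get(aa, ())
                if codon not in fam:
                    raise ValueError(f"planted codon {codon} absent from family of {aa}")


@dataclass
class GroundTruth:
    """Everything needed to compute expected values of pipeline statistics."""

    strain_id: str
    regime: str
    expected_neutrality_slope: float
    planted_optimal: Dict[str, str]
    gene_codon_probs: Dict[str, Dict[str, float]]
    gene_sharpness: Dict[str, float]
    gene_gc_target: Dict[str, float]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stream_seed(seed: int, *parts: str) -> int:
    """Stable per-(strain, gene) seed: insertion order never changes output."""
    key = "|".join([str(seed), *parts]).encode()
    return int.from_bytes(hashlib.blake2b(key, digest_size=8).digest(), "big") % (2**63)


def _rng(seed: int, *parts: str) -> np.random.Generator:
    return np.random.default_rng(_stream_seed(seed, *parts))


def _derive_aa_frequency(code: GeneticCode, base_model: Mapping[str, float]) -> Dict[str, float]:
    """Amino-acid frequencies implied by an i.i.d. base model (stops
    excluded, renormalized)."""
    probs: Dict[str, float] = {}
    for codon, aa in code.codon_to_aa.items():
        if codon in code.stop_codons:
            continue
        p = base_model[codon[0]] * base_model[codon[1]] * base_model[codon[2]]
        probs[aa] = probs.get(aa, 0.0) + p
    total = sum(probs.values())
    return {aa: p / total for aa, p in sorted(probs.items())}


def _auto_planted(code: GeneticCode, third_weights: Mapping[str, float]) -> Dict[str, str]:
    """Default planted optimum per degenerate family: the codon whose third
    base carries the highest weight (tie -> alphabetical)."""
    planted = {}
    for aa, fam in code.families.items():
        if code.degeneracy_class[aa] < 2:
            continue
        planted[aa] = max(sorted(fam), key=lambda c: third_weights[c[2]])
    return planted


def _family_pref_from_third(fam: Sequence[str], weights: Mapping[str, float]) -> np.ndarray:
    w = np.array([weights[c[2]] for c in fam], dtype=float)
    if w.sum() <= 0:
        w = np.ones(len(fam))
    return w / w.sum()


def _sample_mutation_gene(rng: np.random.Generator, n_codons: int, g: float,
                          code: GeneticCode) -> Tuple[str, Dict[str, float]]:
    """All three positions share one GC level g (AT split slightly T-rich)."""
    base_p = {"G": 0.52 * g, "C": 0.48 * g, "U": 0.55 * (1 - g), "A": 0.45 * (1 - g)}
    bases = np.array(list("ACGU"))
    p = np.array([base_p[b] for b in bases])
    codons = []
    need = n_codons
    while need > 0:
        draw = rng.choice(bases, size=(need, 3), p=p)
        for row in draw:
            c = "".join(row)
            if c not in code.stop_codons:
                codons.append(c)
        need = n_codons - len(codons)
    # analytic codon probabilities under the stop-rejected i.i.d. model
    probs = {}
    for codon in sorted(code.codon_to_aa):
        if codon in code.stop_codons:
            continue
        probs[codon] = base_p[codon[0]] * base_p[codon[1]] * base_p[codon[2]]
    tot = sum(probs.values())
    probs = {c: v / tot for c, v in probs.items()}
    return "".join(codons[:n_codons]), probs


def _sample_family_gene(
    rng: np.random.Generator,
    n_codons: int,
    aa_names: Sequence[str],
    aa_p: np.ndarray,
    family_prefs: Mapping[str, np.ndarray],
    code: GeneticCode,
) -> Tuple[str, Dict[str, float]]:
    """Amino acid from aa frequencies, codon from the family preference."""
    aa_seq = rng.choice(np.array(aa_names), size=n_codons, p=aa_p)
    codon_seq = np.empty(n_codons, dtype=object)
    for aa in sorted(set(aa_seq)):
        fam = list(code.families[aa])
        idx = np.flatnonzero(aa_seq == aa)
        pref = family_prefs[aa]
        if len(fam) == 1:
            codon_seq[idx] = fam[0]
        else:
            codon_seq[idx] = rng.choice(np.array(fam), size=len(idx), p=pref)
    probs = {}
    for aa, p_aa in zip(aa_names, aa_p):
        fam = list(code.families[aa])
        for c, p_c in zip(fam, family_prefs[aa]):
            probs[c] = float(p_aa * p_c)
    return "".join(codon_seq), probs


def generate_strain(
    config: GeneratorConfig,
    strain_id: str,
) -> Tuple[List[CodingSequence], GroundTruth]:
    """Generate one strain's gene set plus its ground truth.

    Per-gene random streams are keyed by (seed, strain, gene), so output is
    byte-identical for a given config regardless of call order.
    """
    code = load_genetic_code(config.table_id)
    config.validate(code)
    gene_names = list(config.gene_names[: config.genes_per_strain])
    while len(gene_names) < config.genes_per_strain:
        gene_names.append(f"g{len(gene_names) + 1:02d}")
    aa_freq = config.aa_frequency or _derive_aa_frequency(code, config.base_model)
    aa_names = sorted(aa_freq)
    aa_p = np.array([aa_freq[a] for a in aa_names])
    aa_p = aa_p / aa_p.sum()
    planted = config.planted_optimal or (
        _auto_planted(code, config.third_base_weights)
        if config.expression_gradient > 0 else {}
    )

    # per-strain jitter on the third-base preference (log-scale)
    third_w = dict(config.third_base_weights)
    if config.strain_effect > 0:
        srng = _rng(config.seed, strain_id, "strain_effect")
        jitter = srng.normal(0.0, config.strain_effect, size=4)
        for b, j in zip("ACGU", jitter):
            third_w[b] = third_w[b] * float(np.exp(j))
        tot = sum(third_w.values())
        third_w = {b: w / tot for b, w in third_w.items()}

    records: List[CodingSequence] = []
    gene_probs: Dict[str, Dict[str, float]] = {}
    gene_sharp: Dict[str, float] = {}
    gene_gc: Dict[str, float] = {}
    n_genes = len(gene_names)
    lo, hi = config.length_range_bp
    for i, gene in enumerate(gene_names):
        rng = _rng(config.seed, strain_id, gene)
        n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
        frac = 1.0 - (i / (n_genes - 1) if n_genes > 1 else 0.0)
        sharp = min(0.97, config.expression_gradient * frac)
        if config.regime == "mutation":
            g = float(np.clip(config.gc_pressure + rng.uniform(-config.gc_spread,
                                                               config.gc_spread),
                              0.02, 0.98))
            seq, probs = _sample_mutation_gene(rng, n_codons, g, code)
            gene_gc[gene] = g
        else:
            if config.regime == "selection":
                gc3 = float(rng.uniform(*config.gc3_range))
                w = {"G": 0.6 * gc3, "C": 0.4 * gc3,
                     "A": 0.56 * (1 - gc3), "U": 0.44 * (1 - gc3)}
                gene_gc[gene] = gc3
            else:  # neutral
                w = {b: 1.0 for b in "ACGU"}
                gene_gc[gene] = float("nan")
            prefs: Dict[str, np.ndarray] = {}
            for aa in aa_names:
                fam = list(code.families[aa])
                if config.regime == "neutral":
                    pref = np.full(len(fam), 1.0 / len(fam))
                else:
                    pref = _family_pref_from_third(fam, w)
                if config.kappa is not None and len(fam) > 1:
                    pref = rng.dirichlet(config.kappa * len(fam) * pref)
                if sharp > 0 and aa in planted:
                    onehot = np.array([1.0 if c == planted[aa] else 0.0 for c in fam])
                    pref = (1.0 - sharp) * pref + sharp * onehot
                prefs[aa] = pref / pref.sum()
            seq, probs = _sample_family_gene(rng, n_codons, aa_names, aa_p, prefs, code)
        gene_probs[gene] = probs
        gene_sharp[gene] = sharp
        records.append(CodingSequence(strain_id=strain_id, gene_name=gene,
                                      sequence=seq + "UAA"))
    truth = GroundTruth(
        strain_id=strain_id,
        regime=config.regime,
        expected_neutrality_slope=1.0 if config.regime == "mutation" else 0.0,
        planted_optimal=dict(planted),
        gene_codon_probs=gene_probs,
        gene_sharpness=gene_sharp,
        gene_gc_target=gene_gc,
    )
    return records, truth


@dataclass
class Cohort:
    """A generated multi-strain fixture."""

    config: GeneratorConfig
    strains: Dict[str, List[CodingSequence]]
    truths: Dict[str, GroundTruth]

    @property
    def records(self) -> List[CodingSequence]:
        return [r for sid in sorted(self.strains) for r in self.strains[sid]]

    def manifest(self) -> pd.DataFrame:
        rows = [{"strain": r.strain_id, "gene": r.gene_name, "length_bp": r.length_bp}
                for r in self.records]
        return pd.DataFrame(rows)


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate the full cohort (default: 13 strains x 12 core genes)."""
    strains: Dict[str, List[CodingSequence]] = {}
    truths: Dict[str, GroundTruth] = {}
    for s in range(config.n_strains):
        sid = f"strain{s + 1:02d}"
        recs, truth = generate_strain(config, sid)
        strains[sid] = recs
        truths[sid] = truth
    return Cohort(config=config, strains=strains, truths=truths)


def write_cohort(cohort: Cohort, outdir) -> Dict[str, Path]:
    """Write per-strain FASTA files, ground_truth.json and manifest.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    for sid in sorted(cohort.strains):
        p = outdir / f"{sid}.fasta"
        write_fasta_cds(cohort.strains[sid], p)
        paths[sid] = p
    gt = {sid: t.to_dict() for sid, t in sorted(cohort.truths.items())}
    gt_path = outdir / "ground_truth.json"
    gt_path.write_text(json.dumps(gt, indent=1, sort_keys=True))
    paths["ground_truth"] = gt_path
    man_path = outdir / "manifest.tsv"
    cohort.manifest().to_csv(man_path, sep="\t", index=False)
    paths["manifest"] = man_path
    return paths
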