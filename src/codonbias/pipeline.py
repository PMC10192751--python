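"""End-to-end orchestration: extract -> indices -> diagnostics -> optimal
codons -> clustering, with machine-readable outputs.

Every artifact is a plain-text table (TSV), JSON, or Newick; rerunning with
identical inputs and config produces byte-identical files. All headline
numbers in ``summary.json`` are re-derivable from the stage TSVs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import bias_diagnostics as diag
from . import optimal_codons as oc
from . import rscu_clustering as rc
from .codon_core import composition, count_codons, load_genetic_code, pool_counts
from .sequence_io import (
    CORE_GENES,
    CodingSequence,
    StrainGeneSet,
    read_fasta_cds,
    read_genbank_cds,
    select_core_genes,
)
from .usage_indices import compute_rscu, summarize_indices

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


@dataclass
class RunConfig:
    """Fully serializable run configuration; the resolved config is written
    verbatim into the output directory."""

    fasta: Optional[str] = None           # single FASTA, ">strain|gene" headers
    genbank_dir: Optional[str] = None     # directory of GenBank flat files
    out_dir: str = "cub_out"
    table_id: int = 1
    min_len: int = 300
    genes: Tuple[str, ...] = CORE_GENES
    reference_fraction: float = 0.10      # lowest-ENC decile for CAI/CBI/FOP
    enc_split_fraction: float = 0.10
    delta_rscu_threshold: float = 0.08
    rscu_threshold: float = 1.0
    pr2_mode: str = "fourfold"
    cluster_distance: str = "squared_euclidean"
    cluster_linkage: str = "average"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "genes" in data:
            data["genes"] = tuple(data["genes"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["genes"] = list(d["genes"])
        return d


@dataclass
class RunReport:
    """Paths to all artifacts plus the parsed summary."""

    out_dir: Path
    artifacts: Dict[str, Path]
    summary: dict


def _load_records(config: RunConfig) -> List[CodingSequence]:
    if (config.fasta is None) == (config.genbank_dir is None):
        raise ValueError("exactly one of fasta / genbank_dir must be set")
    if config.fasta:
        return read_fasta_cds(config.fasta)
    records: List[CodingSequence] = []
    gb_dir = Path(config.genbank_dir)
    files = sorted(gb_dir.glob("*.gb")) + sorted(gb_dir.glob("*.gbk")) \
        + sorted(gb_dir.glob("*.genbank"))
    if not files:
        raise ValueError(f"no GenBank files found under {gb_dir}")
    for f in files:
        records.extend(read_genbank_cds(f))
    return records


def validate_inputs(config: RunConfig) -> List[str]:
    """Pre-flight diagnostics: missing genes, frame violations, internal
    stops, duplicates and length exclusions. Pure report, never raises on
    data problems."""
    notes: List[str] = []
    records = _load_records(config)
    code = load_genetic_code(config.table_id)
    seen: Dict[Tuple[str, str], int] = {}
    for r in records:
        key = (r.strain_id, r.gene_name)
        seen[key] = seen.get(key, 0) + 1
        if seen[key] == 2:
            notes.append(f"{r.strain_id}/{r.gene_name}: duplicate annotation")
        if not r.frame_valid:
            notes.append(f"{r.strain_id}/{r.gene_name}: length {r.length_bp} "
                         "not divisible by 3")
            continue
        if r.gene_name in config.genes and r.length_bp < config.min_len:
            notes.append(f"{r.strain_id}/{r.gene_name}: length<{config.min_len}")
        table = count_codons(r.sequence, code, source=f"{r.strain_id}|{r.gene_name}")
        if table.internal_stops:
            notes.append(f"{r.strain_id}/{r.gene_name}: {table.internal_stops} "
                         "internal stop codon(s)")
    strains = {r.strain_id for r in records}
    for s in sorted(strains):
        present = {r.gene_name for r in records if r.strain_id == s}
        missing = [g for g in config.genes if g not in present]
        if missing:
            notes.append(f"{s}: missing core genes {','.join(missing)}")
    return notes


def run_pipeline(config: RunConfig) -> RunReport:
    """Run the full analysis and write all artifacts under ``out_dir``."""
    logging.basicConfig(level=config.log_level)
    code = load_genetic_code(config.table_id)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: Dict[str, Path] = {}

    def write_tsv(name: str, df: pd.DataFrame, index: bool = False) -> None:
        p = out / name
        df.to_csv(p, sep="\t", index=index, float_format=FLOAT_FORMAT)
        artifacts[name] = p

    # -- stage 1: extraction and filtering
    records = _load_records(config)
    gene_sets = select_core_genes(records, min_len=config.min_len,
                                  core_genes=config.genes)
    gene_sets = [s for s in gene_sets if s.genes]
    if not gene_sets:
        raise RuntimeError("extract: no strain retained any core genes")
    logger.info("extract: %d strains, %d genes retained", len(gene_sets),
                sum(len(s.genes) for s in gene_sets))

    # -- stage 2: usage indices
    indices, meta = summarize_indices(gene_sets, code,
                                      reference_fraction=config.reference_fraction)
    write_tsv("indices.tsv", indices)
    gene_rows = indices[indices["level"] == "gene"]

    # -- stage 3: diagnostics
    neut_rows, enc_rows, pr2_rows = [], [], []
    coa_inertia_rows, coa_coord_rows, corr_rows = [], [], []
    for sgs in gene_sets:
        sid = sgs.strain_id
        gene_counts = {g: count_codons(cds.sequence, code, source=f"{sid}|{g}")
                       for g, cds in sorted(sgs.genes.items())}
        profiles = [composition(cds.sequence, code)
                    for _, cds in sorted(sgs.genes.items())]
        fit = diag.neutrality_fit(profiles, strain_id=sid)
        neut_rows.append(dataclasses.asdict(fit))
        sub = gene_rows[gene_rows["strain"] == sid]
        for _, row in sub.iterrows():
            pt = diag.enc_plot_point(f"{sid}|{row['gene']}", row["gc3s"], row["enc"])
            enc_rows.append(dataclasses.asdict(pt))
        for g, t in gene_counts.items():
            pr2 = diag.pr2_point(t, mode=config.pr2_mode)
            pr2_rows.append(dataclasses.asdict(pr2))
        rscu_tables = [compute_rscu(t) for t in gene_counts.values()]
        coa = diag.correspondence_analysis(diag.rscu_gene_matrix(rscu_tables))
        for i in range(coa.n_axes):
            coa_inertia_rows.append({
                "strain": sid, "axis": i + 1,
                "inertia": float(coa.inertia[i]),
                "contribution_pct": float(coa.contribution_pct[i]),
            })
        rcoords = coa.row_coords.reset_index(names="gene").assign(strain=sid)
        coa_coord_rows.append(rcoords)
        r, p = diag.indicator_correlations(sub)
        stacked = r.stack().rename("pearson_r").to_frame()
        stacked["p_value"] = p.stack()
        stacked = stacked.reset_index(names=["indicator_a", "indicator_b"])
        stacked.insert(0, "strain", sid)
        corr_rows.append(stacked)
    write_tsv("neutrality_fits.tsv", pd.DataFrame(neut_rows))
    write_tsv("enc_plot.tsv", pd.DataFrame(enc_rows))
    write_tsv("pr2_points.tsv", pd.DataFrame(pr2_rows))
    coa_inertia = pd.DataFrame(coa_inertia_rows)
    write_tsv("coa_inertia.tsv", coa_inertia)
    write_tsv("coa_coords.tsv", pd.concat(coa_coord_rows, ignore_index=True))
    write_tsv("correlations.tsv", pd.concat(corr_rows, ignore_index=True))

    # -- stage 4: optimal codons
    reports = [
        oc.call_optimal_codons(
            sgs, code,
            thresholds=(config.delta_rscu_threshold, config.rscu_threshold),
            fraction=config.enc_split_fraction,
        )
        for sgs in gene_sets
    ]
    write_tsv("optimal_codons.tsv", oc.optimal_codon_table(reports, code))
    cross = oc.cross_strain_optimal_summary(reports)
    write_tsv("optimal_codons_cross_strain.tsv",
              cross.rename_axis("codon").reset_index())

    # -- stage 5: RSCU clustering (needs >= 2 strains)
    strain_rscu = []
    for sgs in gene_sets:
        pooled = pool_counts(
            [count_codons(cds.sequence, code, source=g)
             for g, cds in sorted(sgs.genes.items())],
            source=sgs.strain_id,
        )
        strain_rscu.append(compute_rscu(pooled))
    feature_matrix = rc.rscu_feature_matrix(strain_rscu)
    write_tsv("rscu_matrix.tsv", feature_matrix, index=True)
    newick = None
    if len(gene_sets) >= 2:
        tree = rc.hierarchical_cluster(feature_matrix,
                                       distance=config.cluster_distance,
                                       linkage=config.cluster_linkage)
        tree_path = out / "rscu_tree.nwk"
        tree_path.write_text(tree.newick + "\n")
        artifacts["rscu_tree.nwk"] = tree_path
        newick = tree.newick

    # -- summary (every number re-derivable from the stage TSVs)
    shared_high_freq = _shared_high_frequency(strain_rscu, config.rscu_threshold)
    axis1 = coa_inertia[coa_inertia["axis"] == 1]["contribution_pct"]
    enc_df = pd.DataFrame(enc_rows)
    summary = {
        "n_strains": len(gene_sets),
        "n_genes_retained": int(sum(len(s.genes) for s in gene_sets)),
        "mean_enc": _round(gene_rows["enc"].mean()),
        "mean_gc3s_pct": _round(100 * gene_rows["gc3s"].mean()),
        "mean_gc3_pct": _round(100 * gene_rows["gc3"].mean()),
        "mean_t_content_pct": _round(100 * gene_rows["frac_t"].mean()),
        "mean_a_content_pct": _round(100 * gene_rows["frac_a"].mean()),
        "mean_a3s_pct": _round(100 * gene_rows["a3s"].mean()),
        "strain_gravy_mean": _round(
            gene_rows.groupby("strain")["gravy"].mean().mean(), 4),
        "enc_ratio_max_pct": _round(100 * enc_df["enc_ratio"].max()),
        "coa_axis1_mean_contribution_pct": _round(axis1.mean()),
        "n_shared_high_frequency_codons": shared_high_freq,
        "optimal_codon_counts": {r.strain_id: len(r.optimal) for r in reports},
        "newick": newick,
        "reference_policy": meta.get("reference_policy"),
        "aggregation": meta.get("aggregation"),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    artifacts["summary.json"] = out / "summary.json"
    (out / "run_config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    artifacts["run_config.yaml"] = out / "run_config.yaml"
    return RunReport(out_dir=out, artifacts=artifacts, summary=summary)


def _shared_high_frequency(strain_rscu, threshold: float) -> int:
    """Number of codons with pooled RSCU above threshold in every strain."""
    sets = []
    for t in strain_rscu:
        sets.append({c for c, v in t.rscu.items()
                     if not math.isnan(v) and v > threshold})
    shared = set.intersection(*sets) if sets else set()
    return len(shared)


def _round(x, ndigits: int = 2):
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return None
    return round(float(x), ndigits)
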