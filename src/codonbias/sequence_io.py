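"""Reading CDS inputs: GenBank flat files and FASTA, core-gene selection.

Fungal mitochondrial genomes carry 15 conserved protein-coding genes; after
the length filter (< 300 bp excluded, which removes atp8, atp9 and nad4l in
Ganoderma) twelve remain per strain: atp6, cob, cox1, cox2, cox3, nad1,
nad2, nad3, nad4, nad5, nad6 and rps3.

FASTA convention: one record per gene, header ``>strain|gene``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: the 12 core genes retained after length filtering
CORE_GENES: Tuple[str, ...] = (
    "atp6", "cob", "cox1", "cox2", "cox3", "nad1",
    "nad2", "nad3", "nad4", "nad5", "nad6", "rps3",
)
#: the full conserved mitochondrial PCG set (before length filtering)
ALL_CORE_GENES: Tuple[str, ...] = CORE_GENES + ("atp8", "atp9", "nad4l")

#: editable synonym map for inconsistent GenBank annotations
GENE_SYNONYMS: Dict[str, str] = {
    "cytb": "cob",
    "cob1": "cob",
    "cb": "cob",
    "nadh1": "nad1", "nadh2": "nad2", "nadh3": "nad3",
    "nadh4": "nad4", "nadh5": "nad5", "nadh6": "nad6",
    "nadh4l": "nad4l",
    "nd1": "nad1", "nd2": "nad2", "nd3": "nad3",
    "nd4": "nad4", "nd5": "nad5", "nd6": "nad6", "nd4l": "nad4l",
    "atpase6": "atp6", "atpase8": "atp8", "atpase9": "atp9",
    "coi": "cox1", "coii": "cox2", "coiii": "cox3",
    "co1": "cox1", "co2": "cox2", "co3": "cox3",
    "coxi": "cox1", "coxii": "cox2", "coxiii": "cox3",
}


def normalize_gene_name(name: str) -> str:
    """Lower-case, apply synonyms, and strip allele suffixes (``_1``, ``-2``)."""
    n = name.strip().lower().replace(" ", "")
    n = GENE_SYNONYMS.get(n, n)
    if n in ALL_CORE_GENES:
        return n
    for sep in ("_", "-"):
        head, sep_found, tail = n.rpartition(sep)
        if sep_found and tail.isdigit():
            cand = GENE_SYNONYMS.get(head, head)
            if cand in ALL_CORE_GENES:
                return cand
    return n


@dataclass
class CodingSequence:
    """One CDS with strain and gene labels."""

    strain_id: str
    gene_name: str
    sequence: str
    source_accession: Optional[str] = None

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    @property
    def frame_valid(self) -> bool:
        return self.length_bp % 3 == 0


@dataclass
class StrainGeneSet:
    """Retained core genes of one strain plus the exclusion log."""

    strain_id: str
    genes: Dict[str, CodingSequence] = field(default_factory=dict)
    excluded: List[Tuple[str, str]] = field(default_factory=list)


def read_genbank_cds(path, strain_id: Optional[str] = None) -> List[CodingSequence]:
    """Extract all CDS features from a GenBank flat file.

    Multi-exon (``join``) and minus-strand (``complement``) locations are
    assembled by the feature extractor, so the returned sequence is always
    the coding strand 5'->3'. Gene names are normalized through
    :data:`GENE_SYNONYMS`. A CDS whose assembled length is not a multiple
    of three is returned but logged, never silently dropped.
    """
    out: List[CodingSequence] = []
    for record in SeqIO.parse(str(path), "genbank"):
        sid = strain_id or record.id
        for feat in record.features:
            if feat.type != "CDS":
                continue
            quals = feat.qualifiers
            raw = (quals.get("gene") or quals.get("product") or ["unknown"])[0]
            gene = normalize_gene_name(raw)
            seq = str(feat.extract(record.seq))
            cds = CodingSequence(
                strain_id=sid,
                gene_name=gene,
                sequence=seq,
                source_accession=record.id,
            )
            if not cds.frame_valid:
                logger.warning(
                    "%s/%s: assembled CDS length %d not divisible by 3",
                    sid, gene, cds.length_bp,
                )
            out.append(cds)
    return out


def read_fasta_cds(path) -> List[CodingSequence]:
    """Read ``>strain|gene`` FASTA records, preserving file order."""
    out: List[CodingSequence] = []
    seen = set()
    for i, record in enumerate(SeqIO.parse(str(path), "fasta")):
        header = record.id
        if "|" not in header:
            raise ValueError(f"record {i}: malformed header {header!r} (expected 'strain|gene')")
        strain, _, gene = header.partition("|")
        if not strain or not gene:
            raise ValueError(f"record {i}: malformed header {header!r} (expected 'strain|gene')")
        key = (strain, gene)
        if key in seen:
            raise ValueError(f"record {i}: duplicate strain|gene pair {header!r}")
        seen.add(key)
        out.append(CodingSequence(strain_id=strain, gene_name=normalize_gene_name(gene),
                                  sequence=str(record.seq)))
    return out


def write_fasta_cds(records: Iterable[CodingSequence], path) -> None:
    """Write CDS records as ``>strain|gene`` FASTA."""
    seqs = [
        SeqRecord(Seq(r.sequence), id=f"{r.strain_id}|{r.gene_name}", description="")
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def select_core_genes(
    records: Sequence[CodingSequence],
    min_len: int = 300,
    core_genes: Sequence[str] = ALL_CORE_GENES,
) -> List[StrainGeneSet]:
    """Group records by strain and apply the core-gene and length filters.

    Genes shorter than ``min_len`` bp are excluded (a gene of exactly
    ``min_len`` is retained). Duplicate annotations of one gene keep the
    longest copy. Exclusions are recorded as ``(gene, reason)`` pairs.
    """
    core = set(core_genes)
    by_strain: Dict[str, StrainGeneSet] = {}
    for rec in records:
        sgs = by_strain.setdefault(rec.strain_id, StrainGeneSet(strain_id=rec.strain_id))
        gene = rec.gene_name
        if gene not in core:
            sgs.excluded.append((gene, "not_core"))
            continue
        if rec.length_bp < min_len:
            sgs.excluded.append((gene, f"length<{min_len}"))
            continue
        prev = sgs.genes.get(gene)
        if prev is not None:
            keep, drop = (rec, prev) if rec.length_bp > prev.length_bp else (prev, rec)
            logger.warning("%s: duplicate annotation for %s, keeping the longer copy",
                           rec.strain_id, gene)
            sgs.excluded.append((gene, "duplicate_shorter"))
            sgs.genes[gene] = keep
        else:
            sgs.genes[gene] = rec
    for sgs in by_strain.values():
        if not sgs.genes:
            logger.warning("%s: no core genes retained", sgs.strain_id)
    return [by_strain[s] for s in sorted(by_strain)]
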