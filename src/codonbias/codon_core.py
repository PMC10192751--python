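"""Genetic-code tables, codon counting and nucleotide composition.

Everything downstream (RSCU, ENC, CAI, diagnostics) is computed from the
primitives defined here: a :class:`GeneticCode` describing synonymous-codon
families, a :class:`CodonCountTable` holding in-frame codon counts for a
gene (or a pool of genes), and a :class:`CompositionProfile` with base
fractions and positional GC content.

Conventions
-----------
* Codons are keyed in the RNA alphabet (``AUG`` not ``ATG``); DNA input is
  transcribed on the fly, so ``T`` and ``U`` are interchangeable.
* The terminal stop codon of a CDS is counted and flagged but excluded from
  composition and from every usage index.
* Internal stop codons are reported as a warning diagnostic, never a hard
  error: mitochondrial annotations are frequently imperfect.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from math import isnan
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

RNA_BASES = "ACGU"
#: translation tables supported out of the box: 1 = standard (universal),
#: 4 = mold/protozoan mitochondrial (UGA -> Trp)
SUPPORTED_TABLES = (1, 4)


class FrameError(ValueError):
    """CDS length is not a multiple of three."""


class AlphabetError(ValueError):
    """CDS contains a symbol outside ACGT/ACGU (strict mode only)."""


def normalize_cds(seq: str) -> str:
    """Upper-case a nucleotide string and respell it in the RNA alphabet."""
    return str(seq).strip().upper().replace("T", "U")


@dataclass(frozen=True)
class GeneticCode:
    """A translation table with synonymous-family structure.

    ``families`` maps each amino acid (one-letter symbol) to its ordered
    codon tuple; ``degeneracy_class`` maps it to the family size
    k in {1, 2, 3, 4, 6}. Stop codons are kept separately and belong to no
    family.
    """

    table_id: int
    codon_to_aa: Mapping[str, str]
    families: Mapping[str, Tuple[str, ...]]
    degeneracy_class: Mapping[str, int]
    stop_codons: frozenset

    @property
    def sense_codons(self) -> Tuple[str, ...]:
        return tuple(c for c in sorted(self.codon_to_aa) if c not in self.stop_codons)

    @property
    def degenerate_codons(self) -> Tuple[str, ...]:
        """Sense codons of families with k >= 2 (59 under table 1), ordered
        alphabetically by amino acid then by codon."""
        out = []
        for aa in sorted(self.families):
            if self.degeneracy_class[aa] >= 2:
                out.extend(sorted(self.families[aa]))
        return tuple(out)

    @property
    def singleton_amino_acids(self) -> Tuple[str, ...]:
        return tuple(aa for aa in sorted(self.families) if self.degeneracy_class[aa] == 1)

    def family_of(self, codon: str) -> Tuple[str, ...]:
        return self.families[self.codon_to_aa[codon]]


@lru_cache(maxsize=None)
def load_genetic_code(table_id: int = 1) -> GeneticCode:
    """Load an NCBI translation table as a :class:`GeneticCode`.

    Raises ``ValueError`` for a table outside :data:`SUPPORTED_TABLES`.
    """
    if table_id not in SUPPORTED_TABLES:
        raise ValueError(
            f"unsupported code: translation table {table_id!r} "
            f"(supported: {SUPPORTED_TABLES})"
        )
    tbl = CodonTable.unambiguous_rna_by_id[table_id]
    codon_to_aa: Dict[str, str] = dict(tbl.forward_table)
    stops = frozenset(tbl.stop_codons)
    for stop in stops:
        codon_to_aa[stop] = "*"
    if len(codon_to_aa) != 64:
        raise AssertionError("translation table does not cover 64 codons")
    families: Dict[str, Tuple[str, ...]] = {}
    for aa in sorted(set(tbl.forward_table.values())):
        fam = tuple(sorted(c for c, a in tbl.forward_table.items() if a == aa))
        families[aa] = fam
    degeneracy = {aa: len(fam) for aa, fam in families.items()}
    return GeneticCode(
        table_id=table_id,
        codon_to_aa=codon_to_aa,
        families=families,
        degeneracy_class=degeneracy,
        stop_codons=stops,
    )


@dataclass
class CodonCountTable:
    """In-frame codon counts for one source (a gene, strain, or pooled set).

    ``counts`` includes the terminal stop codon (flagged via
    ``terminal_stop``); use :meth:`sense_counts` / :meth:`degenerate_counts`
    for index computations, which exclude stops.
    """

    counts: Dict[str, int]
    total_codons: int
    source: str
    code: GeneticCode
    terminal_stop: Optional[str] = None
    internal_stops: int = 0
    dropped_ambiguous: int = 0
    pooled_from: Tuple[str, ...] = ()

    def sense_counts(self) -> Dict[str, int]:
        """Counts over non-stop codons."""
        return {c: n for c, n in self.counts.items() if c not in self.code.stop_codons}

    def degenerate_counts(self) -> Dict[str, int]:
        """Counts over codons in synonymous families (k >= 2)."""
        deg = set(self.code.degenerate_codons)
        return {c: n for c, n in self.counts.items() if c in deg}

    def family_counts(self, aa: str) -> Dict[str, int]:
        return {c: self.counts.get(c, 0) for c in self.code.families[aa]}


def count_codons(
    cds: str,
    code: Optional[GeneticCode] = None,
    source: str = "",
    ambiguity: str = "drop",
) -> CodonCountTable:
    """Count in-frame codons of a CDS.

    Parameters
    ----------
    ambiguity : {"drop", "strict"}
        ``drop`` discards triplets containing non-ACGTU symbols (IUPAC
        ambiguity codes) and logs how many; ``strict`` raises
        :class:`AlphabetError`.
    """
    code = code or load_genetic_code(1)
    seq = normalize_cds(cds)
    if len(seq) % 3 != 0:
        raise FrameError(f"{source or 'CDS'}: length {len(seq)} not divisible by 3")
    counts: Counter = Counter()
    dropped = 0
    n_triplets = len(seq) // 3
    last_codon = None
    for i in range(n_triplets):
        codon = seq[3 * i : 3 * i + 3]
        if any(b not in RNA_BASES for b in codon):
            if ambiguity == "strict":
                raise AlphabetError(f"{source or 'CDS'}: non-ACGTU codon {codon!r} at triplet {i}")
            dropped += 1
            continue
        counts[codon] += 1
        if i == n_triplets - 1:
            last_codon = codon
    if dropped:
        logger.info("%s: dropped %d ambiguous codon(s)", source or "CDS", dropped)
    terminal_stop = last_codon if (last_codon in code.stop_codons) else None
    n_stops = sum(counts.get(s, 0) for s in code.stop_codons)
    internal = n_stops - (1 if terminal_stop else 0)
    if internal > 0:
        logger.warning("%s: %d internal stop codon(s) found", source or "CDS", internal)
    return CodonCountTable(
        counts=dict(counts),
        total_codons=sum(counts.values()),
        source=source,
        code=code,
        terminal_stop=terminal_stop,
        internal_stops=internal,
        dropped_ambiguous=dropped,
    )


@dataclass(frozen=True)
class CompositionProfile:
    """Whole-CDS base fractions and positional GC content.

    ``frac_t`` is the combined T/U fraction. All values are fractions in
    [0, 1]; the reporting layer converts to percentages. The terminal stop
    codon is excluded before anything is tallied.
    """

    frac_a: float
    frac_t: float
    frac_g: float
    frac_c: float
    gc1: float
    gc2: float
    gc3: float
    gc12: float
    gc_total: float


def composition(cds: str, code: Optional[GeneticCode] = None) -> CompositionProfile:
    """Base fractions and per-codon-position GC of a frame-valid CDS."""
    code = code or load_genetic_code(1)
    seq = normalize_cds(cds)
    if len(seq) % 3 != 0:
        raise FrameError(f"length {len(seq)} not divisible by 3")
    if seq[-3:] in code.stop_codons:
        seq = seq[:-3]
    if not seq:
        raise ValueError("CDS is empty after removing the terminal stop codon")
    bad = set(seq) - set(RNA_BASES)
    if bad:
        # positional GC on ambiguity codes is ill-defined; drop whole codons
        kept = [seq[i : i + 3] for i in range(0, len(seq), 3)
                if not set(seq[i : i + 3]) - set(RNA_BASES)]
        logger.info("composition: dropped %d ambiguous codon(s)", len(seq) // 3 - len(kept))
        seq = "".join(kept)
        if not seq:
            raise ValueError("no unambiguous codons left")
    n = len(seq)
    frac = {b: seq.count(b) / n for b in RNA_BASES}
    pos = [seq[k::3] for k in range(3)]
    gc = [sum(1 for b in p if b in "GC") / len(p) for p in pos]
    gc12 = (gc[0] + gc[1]) / 2.0
    return CompositionProfile(
        frac_a=frac["A"],
        frac_t=frac["U"],
        frac_g=frac["G"],
        frac_c=frac["C"],
        gc1=gc[0],
        gc2=gc[1],
        gc3=gc[2],
        gc12=gc12,
        gc_total=(gc[0] + gc[1] + gc[2]) / 3.0,
    )


def pool_counts(tables: Sequence[CodonCountTable], source: Optional[str] = None) -> CodonCountTable:
    """Cell-wise sum of codon count tables sharing one genetic code."""
    tables = list(tables)
    if not tables:
        raise ValueError("cannot pool an empty list of count tables")
    table_ids = {t.code.table_id for t in tables}
    if len(table_ids) != 1:
        raise ValueError(f"cannot pool tables with mixed genetic codes: {sorted(table_ids)}")
    total: Counter = Counter()
    for t in tables:
        total.update(t.counts)
    members = tuple(t.source for t in tables)
    return CodonCountTable(
        counts=dict(total),
        total_codons=sum(total.values()),
        source=source if source is not None else "+".join(members),
        code=tables[0].code,
        terminal_stop=None,
        internal_stops=sum(t.internal_stops for t in tables),
        dropped_ambiguous=sum(t.dropped_ambiguous for t in tables),
        pooled_from=members,
    )
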