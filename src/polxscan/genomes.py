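"""Per-genome gene tables and PolX / NHEJ status classification.

Gene records arrive with precomputed domain-role labels (the conserved-domain
matching that produces them is an upstream concern); this module validates
the table, classifies each genome's PolX repertoire and NHEJ capability, and
aggregates one summary row per genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import TableValidationError

logger = logging.getLogger(__name__)

ROLE_VOCABULARY = frozenset(
    {"POLX_CANONICAL", "POLX_ALTERED", "KU", "LIG", "POL_DOM", "PE"}
)

POLX_NONE = "none"
POLX_CANONICAL = "canonical"
POLX_ALTERED = "altered"
POLX_BOTH = "both"
POLX_STATUSES = (POLX_NONE, POLX_CANONICAL, POLX_ALTERED, POLX_BOTH)

NHEJ_NONE = "none"
NHEJ_NUC = "nhej_nuc"
NHEJ_NO_NUC = "nhej_no_nuc"
NHEJ_STATUSES = (NHEJ_NONE, NHEJ_NUC, NHEJ_NO_NUC)

GENE_TABLE_COLUMNS = [
    "genome_id",
    "replicon_id",
    "start",
    "end",
    "strand",
    "protein_id",
    "roles",
    "pfam_families",
    "taxon_class",
    "taxon_phylum",
]


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene; coordinates 1-based inclusive, GenBank style."""

    genome_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    protein_id: str
    roles: frozenset[str] = frozenset()
    pfam_families: frozenset[str] = frozenset()
    taxon_class: str | None = None
    taxon_phylum: str | None = None
    gene_index: int = 0

    def __post_init__(self):
        if self.start < 1:
            raise TableValidationError(
                f"gene {self.protein_id!r}: start {self.start} < 1"
            )
        if self.start > self.end:
            raise TableValidationError(
                f"gene {self.protein_id!r}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise TableValidationError(
                f"gene {self.protein_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        unknown = self.roles - ROLE_VOCABULARY
        if unknown:
            raise TableValidationError(
                f"gene {self.protein_id!r}: unknown role token(s) {sorted(unknown)}"
            )

    @property
    def is_polx(self) -> bool:
        return bool(self.roles & {"POLX_CANONICAL", "POLX_ALTERED"})


@dataclass(frozen=True)
class GenomeSummary:
    genome_id: str
    polx_status: str
    nhej_status: str
    n_polx_genes: int
    taxon_class: str | None = None
    taxon_phylum: str | None = None
    genome_length: int | None = None


def _parse_set(value) -> frozenset[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return frozenset()
    return frozenset(tok.strip() for tok in str(value).split(",") if tok.strip())


def _reindex(records: list[GeneRecord]) -> list[GeneRecord]:
    """Recompute gene_index from (start, end) order within each replicon and
    return the records sorted by (genome, replicon, coordinate)."""
    records = sorted(records, key=lambda g: (g.genome_id, g.replicon_id, g.start, g.end))
    out = []
    prev_key = None
    idx = 0
    for g in records:
        key = (g.genome_id, g.replicon_id)
        idx = idx + 1 if key == prev_key else 0
        prev_key = key
        out.append(replace(g, gene_index=idx))
    return out


def load_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read a gene-table TSV into validated :class:`GeneRecord` rows.

    The TSV must carry the exact header ``genome_id, replicon_id, start,
    end, strand, protein_id, roles, pfam_families, taxon_class,
    taxon_phylum``; roles and pfam_families are comma-separated (empty
    allowed).  gene_index is recomputed from coordinates.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise TableValidationError(f"gene table {path} lacks column(s) {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(
                GeneRecord(
                    genome_id=row.genome_id,
                    replicon_id=row.replicon_id,
                    start=int(row.start),
                    end=int(row.end),
                    strand=row.strand,
                    protein_id=row.protein_id,
                    roles=_parse_set(row.roles),
                    pfam_families=_parse_set(row.pfam_families),
                    taxon_class=row.taxon_class or None,
                    taxon_phylum=row.taxon_phylum or None,
                )
            )
        except (TableValidationError, ValueError) as exc:
            raise TableValidationError(f"row {i + 2} of {path}: {exc}") from exc
    return _reindex(records)


def write_gene_table(records: Iterable[GeneRecord], path: str | Path) -> None:
    rows = [
        {
            "genome_id": g.genome_id,
            "replicon_id": g.replicon_id,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
            "protein_id": g.protein_id,
            "roles": ",".join(sorted(g.roles)),
            "pfam_families": ",".join(sorted(g.pfam_families)),
            "taxon_class": g.taxon_class or "",
            "taxon_phylum": g.taxon_phylum or "",
        }
        for g in records
    ]
    pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def classify_nhej(genes: list[GeneRecord]) -> str:
    """NHEJ status of one genome from its gene roles.

    A nuclease-bearing ligase is a single protein carrying {LIG, POL_DOM,
    PE}; a nuclease-less one carries {LIG, POL_DOM} without PE.  The genome
    is nhej_nuc if it encodes Ku and a nuclease-bearing ligase, nhej_no_nuc
    if Ku plus only the nuclease-less variant, otherwise none.  Split
    ligase/polymerase domains on separate proteins never qualify.
    """
    genome_ids = {g.genome_id for g in genes}
    if len(genome_ids) > 1:
        raise ValueError(f"genes span multiple genomes: {sorted(genome_ids)}")
    ligd_nuc = ligd_no_nuc = ku = False
    for g in genes:
        if {"LIG", "POL_DOM", "PE"} <= g.roles:
            ligd_nuc = True
        elif {"LIG", "POL_DOM"} <= g.roles:
            ligd_no_nuc = True
        if "KU" in g.roles:
            ku = True
            if {"LIG", "POL_DOM"} <= g.roles:
                logger.warning(
                    "protein %s carries KU together with ligase domains",
                    g.protein_id,
                )
    if ku and ligd_nuc:
        return NHEJ_NUC
    if ku and ligd_no_nuc:
        return NHEJ_NO_NUC
    return NHEJ_NONE


def classify_polx_status(genes: list[GeneRecord]) -> str:
    """PolX repertoire of one genome: none / canonical / altered / both."""
    genome_ids = {g.genome_id for g in genes}
    if len(genome_ids) > 1:
        raise ValueError(f"genes span multiple genomes: {sorted(genome_ids)}")
    has_canonical = any("POLX_CANONICAL" in g.roles for g in genes)
    has_altered = any("POLX_ALTERED" in g.roles for g in genes)
    if has_canonical and has_altered:
        return POLX_BOTH
    if has_canonical:
        return POLX_CANONICAL
    if has_altered:
        return POLX_ALTERED
    return POLX_NONE


def summarize_genomes(
    genes: list[GeneRecord],
    genome_lengths: dict[str, int] | None = None,
) -> list[GenomeSummary]:
    """One :class:`GenomeSummary` per distinct genome_id, sorted by id."""
    by_genome: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_genome.setdefault(g.genome_id, []).append(g)
    genome_lengths = genome_lengths or {}
    summaries = []
    for genome_id in sorted(by_genome):
        gg = by_genome[genome_id]
        taxon_class = next((g.taxon_class for g in gg if g.taxon_class), None)
        taxon_phylum = next((g.taxon_phylum for g in gg if g.taxon_phylum), None)
        summaries.append(
            GenomeSummary(
                genome_id=genome_id,
                polx_status=classify_polx_status(gg),
                nhej_status=classify_nhej(gg),
                n_polx_genes=sum(1 for g in gg if g.is_polx),
                taxon_class=taxon_class,
                taxon_phylum=taxon_phylum,
                genome_length=genome_lengths.get(genome_id),
            )
        )
    return summaries


def write_genome_summaries(summaries: Iterable[GenomeSummary], path: str | Path) -> None:
    rows = [
        {
            "genome_id": s.genome_id,
            "polx_status": s.polx_status,
            "nhej_status": s.nhej_status,
            "n_polx_genes": s.n_polx_genes,
            "taxon_class": s.taxon_class or "",
            "taxon_phylum": s.taxon_phylum or "",
            "genome_length": "" if s.genome_length is None else s.genome_length,
        }
        for s in summaries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_genome_summaries(path: str | Path) -> list[GenomeSummary]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        length = getattr(row, "genome_length", "")
        out.append(
            GenomeSummary(
                genome_id=row.genome_id,
                polx_status=row.polx_status,
                nhej_status=row.nhej_status,
                n_polx_genes=int(row.n_polx_genes),
                taxon_class=row.taxon_class or None,
                taxon_phylum=row.taxon_phylum or None,
                genome_length=int(length) if length else None,
            )
        )
    return out
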