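"""Operon-style neighborhood extraction around PolX genes.

From each PolX gene the walk proceeds outward along the replicon, up to a
fixed number of genes on each side, accepting only genes on the focal
strand whose spacing to the previously accepted gene stays within a bp
cutoff.  Accepted neighborhoods feed a per-taxon-class Pfam-family
frequency table with minimum-class-size and minimum-frequency filters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .errors import ContractError
from .genomes import GeneRecord


@dataclass(frozen=True)
class NeighborhoodSpec:
    max_genes_each_side: int = 5
    max_intergenic_bp: int = 300
    require_codirectional: bool = True
    chain_rule: str = "chain"  # or "independent"

    def __post_init__(self):
        if self.max_genes_each_side < 0 or self.max_intergenic_bp < 0:
            raise ValueError("spec parameters must be non-negative")
        if self.chain_rule not in {"chain", "independent"}:
            raise ValueError("chain_rule must be 'chain' or 'independent'")


@dataclass(frozen=True)
class NeighborhoodResult:
    focal_protein_id: str
    focal_polx_class: str
    members: tuple[GeneRecord, ...]
    genome_id: str
    taxon_class: str | None


def intergenic_distance(a: GeneRecord, b: GeneRecord) -> int:
    """bp between two genes: start of the right gene minus end of the left
    gene minus one, floored at 0 for overlaps."""
    left, right = (a, b) if a.start <= b.start else (b, a)
    return max(0, right.start - left.end - 1)


def _polx_class(gene: GeneRecord) -> str:
    if "POLX_CANONICAL" in gene.roles and "POLX_ALTERED" in gene.roles:
        return "both"
    if "POLX_CANONICAL" in gene.roles:
        return "canonical"
    if "POLX_ALTERED" in gene.roles:
        return "altered"
    raise ContractError(f"focal gene {gene.protein_id!r} carries no PolX role")


def _accepts(candidate: GeneRecord, previous: GeneRecord, focal: GeneRecord, spec: NeighborhoodSpec) -> bool:
    if spec.require_codirectional and candidate.strand != focal.strand:
        return False
    return intergenic_distance(previous, candidate) <= spec.max_intergenic_bp


def extract_neighborhood(
    genes: list[GeneRecord], focal_index: int, spec: NeighborhoodSpec | None = None
) -> NeighborhoodResult:
    """Walk outward from ``genes[focal_index]`` and collect accepted genes.

    ``genes`` must be one replicon sorted by start coordinate.  In each
    direction at most ``max_genes_each_side`` positions are considered; a
    candidate is accepted iff it lies on the focal strand and its intergenic
    distance to the previously accepted gene (the focal gene for the first
    step) is within ``max_intergenic_bp``.  Under the default chain rule the
    walk stops at the first rejection; under 'independent' it continues
    through rejections.
    """
    spec = spec or NeighborhoodSpec()
    focal = genes[focal_index]
    focal_class = _polx_class(focal)
    replicons = {g.replicon_id for g in genes}
    if len(replicons) > 1:
        raise ContractError(f"genes span multiple replicons: {sorted(replicons)}")

    members: list[GeneRecord] = []
    for step in (+1, -1):
        previous = focal
        for offset in range(1, spec.max_genes_each_side + 1):
            i = focal_index + step * offset
            if i < 0 or i >= len(genes):
                break
            candidate = genes[i]
            if _accepts(candidate, previous, focal, spec):
                members.append(candidate)
                previous = candidate
            elif spec.chain_rule == "chain":
                break
    members.sort(key=lambda g: (g.start, g.end))
    return NeighborhoodResult(
        focal_protein_id=focal.protein_id,
        focal_polx_class=focal_class,
        members=tuple(members),
        genome_id=focal.genome_id,
        taxon_class=focal.taxon_class,
    )


def brute_force_neighborhood(
    genes: list[GeneRecord], focal_index: int, spec: NeighborhoodSpec | None = None
) -> NeighborhoodResult:
    """Independent oracle for :func:`extract_neighborhood`.

    Enumerates every subset-free acceptance decision over the positional
    window one gene at a time, tracking the last accepted gene per side
    explicitly; written without sharing code with the walk above.
    """
    spec = spec or NeighborhoodSpec()
    focal = genes[focal_index]
    focal_class = _polx_class(focal)

    accepted: list[GeneRecord] = []
    # downstream side (higher coordinates)
    for side_positions in (
        list(range(focal_index + 1, min(len(genes), focal_index + 1 + spec.max_genes_each_side))),
        list(range(focal_index - 1, max(-1, focal_index - 1 - spec.max_genes_each_side), -1)),
    ):
        anchor = focal
        stopped = False
        for i in side_positions:
            g = genes[i]
            ok_strand = (not spec.require_codirectional) or g.strand == focal.strand
            if g.start <= anchor.start:
                left, right = g, anchor
            else:
                left, right = anchor, g
            gap = right.start - left.end - 1
            if gap < 0:
                gap = 0
            ok_gap = gap <= spec.max_intergenic_bp
            if ok_strand and ok_gap and not stopped:
                accepted.append(g)
                anchor = g
            else:
                if spec.chain_rule == "chain":
                    stopped = True
    accepted.sort(key=lambda g: (g.start, g.end))
    return NeighborhoodResult(
        focal_protein_id=focal.protein_id,
        focal_polx_class=focal_class,
        members=tuple(accepted),
        genome_id=focal.genome_id,
        taxon_class=focal.taxon_class,
    )


def extract_all_neighborhoods(
    genes: list[GeneRecord], spec: NeighborhoodSpec | None = None
) -> list[NeighborhoodResult]:
    """Neighborhoods for every PolX gene in a multi-genome gene table."""
    spec = spec or NeighborhoodSpec()
    results = []
    by_replicon: dict[tuple[str, str], list[GeneRecord]] = {}
    for g in genes:
        by_replicon.setdefault((g.genome_id, g.replicon_id), []).append(g)
    for key in sorted(by_replicon):
        replicon = sorted(by_replicon[key], key=lambda g: (g.start, g.end))
        for i, g in enumerate(replicon):
            if g.is_polx:
                results.append(extract_neighborhood(replicon, i, spec))
    return results


@dataclass(frozen=True)
class FamilyFrequencyRow:
    taxon_class: str
    focal_polx_class: str
    pfam_family: str
    n_genomes_with_family: int
    n_genomes_in_class: int

    @property
    def frequency(self) -> float:
        return self.n_genomes_with_family / self.n_genomes_in_class


def family_frequency(
    results: Iterable[NeighborhoodResult],
    min_genomes_per_class: int = 4,
    min_frequency: float = 0.10,
) -> list[FamilyFrequencyRow]:
    """Pfam-family frequencies per (taxon_class, focal PolX class) cell.

    A genome counts once per family regardless of how many neighborhood
    genes carry it.  Cells with fewer than ``min_genomes_per_class``
    genomes are dropped entirely; families below ``min_frequency`` within a
    cell are dropped row-wise.  Rows are sorted by cell, then descending
    frequency, then family name.
    """
    genomes_in_cell: dict[tuple[str, str], set[str]] = {}
    genomes_with_family: dict[tuple[str, str, str], set[str]] = {}
    for res in results:
        if res.taxon_class is None:
            continue
        cell = (res.taxon_class, res.focal_polx_class)
        genomes_in_cell.setdefault(cell, set()).add(res.genome_id)
        for gene in res.members:
            for fam in gene.pfam_families:
                genomes_with_family.setdefault(cell + (fam,), set()).add(res.genome_id)

    rows = []
    for (taxon_class, polx_class), genomes in genomes_in_cell.items():
        n_class = len(genomes)
        if n_class < min_genomes_per_class:
            continue
        for (tc, pc, fam), fam_genomes in genomes_with_family.items():
            if (tc, pc) != (taxon_class, polx_class):
                continue
            n_fam = len(fam_genomes)
            if n_fam / n_class < min_frequency:
                continue
            rows.append(
                FamilyFrequencyRow(
                    taxon_class=taxon_class,
                    focal_polx_class=polx_class,
                    pfam_family=fam,
                    n_genomes_with_family=n_fam,
                    n_genomes_in_class=n_class,
                )
            )
    rows.sort(
        key=lambda r: (r.taxon_class, r.focal_polx_class, -r.frequency, r.pfam_family)
    )
    return rows
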