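import pytest

from polxscan.genomes import GeneRecord


def make_gene(
    genome_id="G1",
    replicon_id="G1_r1",
    start=1,
    end=100,
    strand="+",
    protein_id="p1",
    roles=(),
    pfam_families=(),
    taxon_class=None,
    taxon_phylum=None,
):
    return GeneRecord(
        genome_id=genome_id,
        replicon_id=replicon_id,
        start=start,
        end=end,
        strand=strand,
        protein_id=protein_id,
        roles=frozenset(roles),
        pfam_families=frozenset(pfam_families),
        taxon_class=taxon_class,
        taxon_phylum=taxon_phylum,
    )


@pytest.fixture
def gene_factory():
    return make_gene


def make_replicon(specs, genome_id="G1", gene_length=100):
    """Build a coordinate-ordered replicon from (gap_before, strand, roles[, fams])
    tuples; gap_before is the intergenic bp to the previous gene."""
    genes = []
    pos = 0
    for i, spec in enumerate(specs):
        gap, strand, roles = spec[0], spec[1], spec[2]
        fams = spec[3] if len(spec) > 3 else ()
        start = pos + gap + 1
        end = start + gene_length - 1
        pos = end
        genes.append(
            make_gene(
                genome_id=genome_id,
                replicon_id=f"{genome_id}_r1",
                start=start,
                end=end,
                strand=strand,
                protein_id=f"{genome_id}_p{i:03d}",
                roles=roles,
                pfam_families=fams,
            )
        )
    return genes


@pytest.fixture
def replicon_factory():
    return make_replicon
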