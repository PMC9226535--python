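# polxscan

Alignment-anchored analysis of prokaryotic X-family DNA polymerases (PolXs)
and their genomic association with the bacterial non-homologous end joining
(NHEJ) pathway.

Given a protein multiple sequence alignment containing a reference row
(e.g. human Polβ), the package

* maps reference residue numbers onto alignment columns and classifies each
  sequence's catalytic triad as **canonical** (three acidic residues),
  **altered**, or **indeterminate** (gap/ambiguous at a triad column);
* measures palm/fingers domain-window lengths with strict truncation
  thresholds (palm < 77, fingers < 55 by default) and flags
  double-truncated sequences;
* profiles active-site residue states (dNTP-binding N/basic positions,
  steric gate, GS motif, nine-residue PHP nuclease consensus) and reports
  per-class conservation.

Given per-genome gene tables with precomputed domain-role labels, it

* classifies each genome's PolX status (none/canonical/altered/both) and
  NHEJ status (none / NHEJ+Nuc / NHEJ−Nuc, requiring Ku plus a single
  protein carrying both ligase and polymerase domains);
* builds PolX × NHEJ contingency tables and runs the Pearson chi-square
  test of independence (with a seeded permutation oracle), enrichment
  reports, and genome-length comparisons;
* extracts co-directional gene neighborhoods around PolX genes (±5 genes,
  ≤300 bp spacing) and tabulates Pfam-family frequencies per taxonomic
  class with minimum-class-size and minimum-frequency filters.

A synthetic-data module (`polxscan.simulate`) generates alignments and gene
tables with planted, exactly recoverable ground truth so that every stage is
verifiable without external downloads.

## Command line

All functionality is exposed through the `polx-scan` entry point:

```bash
# triad classification + altered-variant census
polx-scan classify --msa aln.fasta --ref-id POLB_HUMAN --out-prefix run1

# domain-window lengths / truncation flags, motif states, conservation
polx-scan domains --msa aln.fasta --ref-id POLB_HUMAN --out domains.tsv
polx-scan motifs  --msa aln.fasta --ref-id POLB_HUMAN --out motifs.tsv
polx-scan conservation --msa aln.fasta --ref-id POLB_HUMAN

# per-genome PolX/NHEJ classification from a gene table
polx-scan nhej --genes genes.tsv --out summaries.tsv

# contingency table + chi-square (optionally with a permutation check)
polx-scan cooccur --summaries summaries.tsv --both-policy exclude \
    --permutations 20000 --seed 1

# operon neighborhoods and Pfam family frequencies
polx-scan neighbors --genes genes.tsv --max-gap 300 --window 5 \
    --chain-rule chain

# synthetic data with planted truth
polx-scan simulate-msa --n-seqs 200 --f-altered 0.3 --seed 7
polx-scan simulate-genomes --n-genomes 500 --partner-probability 0.5 --seed 7
```

Reference windows, triad residue numbers and site positions default to human
Polβ numbering (triad 190/192/256; palm 178–279; fingers 272–314) and can be
overridden with a TOML config:

```toml
[triad]
residues = [190, 192, 256]

[windows]
palm = [178, 279]
fingers = [272, 314]
palm_truncation_threshold = 77
fingers_truncation_threshold = 55

[sites]
dntp_N = [279]
gs_motif = [274, 275]
```

The gene-table TSV contract (exact header):
`genome_id, replicon_id, start, end, strand, protein_id, roles,
pfam_families, taxon_class, taxon_phylum` — coordinates 1-based inclusive;
`roles` is a comma-separated subset of
`POLX_CANONICAL, POLX_ALTERED, KU, LIG, POL_DOM, PE`.

The tool never aligns: the reference row must already be present in the
input alignment (profile-align it in externally if needed).

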