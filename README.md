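# aspcr

Design and validate allele-specific PCR (ARMS) assays that authenticate a
target species from a DNA-barcode alignment.

Given a species-labelled multiple sequence alignment (e.g. COI fragments),
the toolkit:

1. **finds diagnostic SNPs** — alignment columns where the target species is
   fixed for a base that occurs in no other species (`aspcr.diagnostics`);
2. **builds an allele-specific primer pair** — the reverse primer anchors its
   3′-terminal base on the diagnostic allele and carries one engineered
   destabilizing mismatch at the antepenultimate position, paired with a
   conventional forward primer chosen under product-size/length/Tm/GC
   constraints (`aspcr.primer_design`, `aspcr.thermo`);
3. **screens specificity in silico** — a binding model with 3′-mismatch
   extension blocking predicts which templates amplify, summarized as a
   specificity matrix and an ASCII "virtual gel" (`aspcr.insilico_pcr`);
4. **confirms species monophyly** — p/JC/K2P distances, neighbor joining and
   column-resampling bootstrap, written from scratch, with Newick output
   (`aspcr.phylo`);
5. **generates synthetic test data** — species-structured alignments with
   planted diagnostic sites and exact ground truth (`aspcr.synthetic_data`).

All user-facing coordinates are 1-based inclusive.

## CLI

One entry point, `aspcr`, with five subcommands (exit codes: 0 success,
2 usage/validation error, 3 ran-but-found-nothing; every run writes a JSON
manifest with parameters and input checksums):

```sh
# synthesize a 24-record, 8-species, 574 bp fixture with two planted sites
aspcr synth --seed 11 --out work/synth

# report columns diagnostic for the target species
aspcr diagnose work/synth/alignment.fasta \
    --species-map work/synth/species_map.tsv \
    --target "Cervus nippon" --json --out work/diag

# design the allele-specific pair (reverse primer anchored on the first site)
aspcr design work/synth/alignment.fasta \
    --species-map work/synth/species_map.tsv \
    --target "Cervus nippon" --out work/design

# predict which templates amplify; writes specificity.tsv + virtual_gel.txt
aspcr screen work/design/design.json work/synth/alignment.fasta \
    --species-map work/synth/species_map.tsv --out work/screen

# NJ tree with bootstrap supports and a per-species monophyly report
aspcr tree work/synth/alignment.fasta \
    --species-map work/synth/species_map.tsv \
    --model k2p --replicates 1000 --seed 42 --out work/tree
```

Input alignments are plain multi-FASTA; the species label is either the
header field after the **last** `|` (`>id|Genus species`) or comes from a
two-column `id<TAB>species` TSV that overrides headers.

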