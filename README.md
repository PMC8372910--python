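# plastome-hotspots

Comparative analysis of annotated plastomes: extract shared genes and
intergenic spacers, quantify per-region variability (sliding-window
nucleotide diversity, variable/parsimony-informative site proportions),
compute Kimura 2-parameter distance matrices, build or ingest per-region
trees, and rank candidate barcode regions with a six-point monophyly-based
utility test against a reference topology. Structural analyses map gene
loss/pseudogenization events onto a tree by parsimony and locate inverted
repeat (IR) boundaries and junction genes. A deterministic simulator
generates plastome sets with known truth so every stage is testable offline.

## Layout

| module | contents |
| --- | --- |
| `seqio` | sequence/alignment/feature containers; FASTA + GenBank I/O |
| `regions` | gene/IGS extraction, shared-region sets, concatenation |
| `diversity` | per-window and global pi, site classes, region stats |
| `distances` | K2P and p-distance matrices, two-triangle combined table |
| `trees` | Newick I/O, neighbor joining, rooting, monophyly, backbone match |
| `utility` | six-point utility scoring and region ranking |
| `genecontent` | 3-state parsimony event mapping, IR detection, junction genes |
| `synthetic_data` | two-parameter-model sequence simulator and benchmark fixture |
| `cli` | `plastome-hotspots` entry point, one subcommand per stage |

## CLI

Every stage reads and writes plain-text artifacts (FASTA, GenBank, Newick,
TSV, JSON) so externally produced alignments or ML trees can be substituted
at any point. A manifest with parameters is written next to each result and
identical inputs reproduce outputs byte-for-byte.

```sh
# synthetic 32-taxon fixture with truth files
plastome-hotspots simulate --seed 1 --out fixture/

# shared-region extraction from annotated genomes
plastome-hotspots extract --genbank fixture/genomes \
    --specs specs.json --out regions_out/

# sliding-window nucleotide diversity (window 500 bp, step 100 bp)
plastome-hotspots diversity --alignment fixture/regions/rpl14-rps3.fasta \
    --out div/

# K2P matrix (optionally a combined two-triangle table via --upper)
plastome-hotspots distances --alignment fixture/regions/accD.fasta --out dist/

# neighbor-joining tree, then utility scoring against the reference
plastome-hotspots tree --alignment fixture/regions/rpl14-rps3.fasta --out t.nwk
plastome-hotspots score --tree rpl14-rps3 t.nwk \
    --reference fixture/reference.nwk --clades fixture/clades.json \
    --alignments fixture/regions --out scores/

# parsimony gene-loss mapping and IR boundary detection
plastome-hotspots events --tree fixture/reference.nwk \
    --matrix fixture/presence.tsv --outgroup OUT1 --out ev/
plastome-hotspots ir --fasta fixture/genomes/T01.fasta \
    --genbank fixture/genomes/T01.gb --min-len 400 --out ir/
```

Region specs are JSON/TSV (`name`, `mode` in `gene|igs|concat`, `parts`);
clade definitions are JSON (`clades` mapping names to taxon lists, plus
`outgroup` and `excluded` lists). The utility score grants one point per
monophyletic named clade plus one point for matching the reference backbone
after collapsing clades, so the canonical five-set definition tops out at 6.

## Notes

- Coordinates are 0-based half-open internally; GenBank's 1-based inclusive
  convention is converted only at the I/O boundary.
- Gaps and IUPAC ambiguity codes are treated as missing data; pairwise vs
  complete deletion is switchable for both pi and distances.
- Saturated K2P pairs are flagged undefined (never clamped); neighbor
  joining refuses matrices containing undefined entries.
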