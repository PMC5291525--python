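# zcc — Z-curve Correlation Coefficient toolkit

`zcc` quantifies how the AT and GC compositional biases of a bacterial
chromosome move together. Replication introduces strand asymmetry: most
genomes accumulate G and T on the leading strand, but Firmicutes-like
genomes instead accumulate A and G (purine asymmetry). The toolkit is for
comparative genomicists who want a single windowless number per genome
that separates these regimes, plus the downstream machinery — replichore
inference, leading/lagging gene assignment, and phylum-level cohort
statistics — to study what correlates with it.

## The statistic

For a sequence of length *N*, let *A<sub>n</sub>, C<sub>n</sub>,
G<sub>n</sub>, T<sub>n</sub>* be the occurrence counts of each base over
the first *n* residues. The Z-curve components are

- *x<sub>n</sub>* = (*A<sub>n</sub>* + *G<sub>n</sub>*) − (*C<sub>n</sub>* + *T<sub>n</sub>*)  (purine − pyrimidine)
- *y<sub>n</sub>* = (*A<sub>n</sub>* + *C<sub>n</sub>*) − (*G<sub>n</sub>* + *T<sub>n</sub>*)  (amino − keto)
- *z<sub>n</sub>* = (*A<sub>n</sub>* + *T<sub>n</sub>*) − (*C<sub>n</sub>* + *G<sub>n</sub>*)  (weak − strong H-bonds)

The AT disparity *a<sub>n</sub>* = (*x<sub>n</sub>* + *y<sub>n</sub>*)/2 =
*A<sub>n</sub>* − *T<sub>n</sub>* and GC disparity *b<sub>n</sub>* =
(*x<sub>n</sub>* − *y<sub>n</sub>*)/2 = *G<sub>n</sub>* − *C<sub>n</sub>*
track the running base excesses. The **ZCC index** is the Pearson
correlation *r*(*a*, *b*) over *n* = 1…*N*: near +1 when both excesses
switch polarity together at the replication origin and terminus (purine
asymmetry), near −1 in the common G+T-rich-leading-strand regime. The
analogous **RY–MK index** is *r*(*x*, *y*).

Because the GC disparity curve rises along each leading arc, its detrended
minimum and maximum approximate the replication origin and terminus; genes
are then assigned to the leading or lagging strand by which replichore arc
their midpoint falls on, giving the strand-biased gene distribution (SGD)
fraction.

## Worked example

```sh
zcc simulate --outdir demo --seed 5 \
    --phylum PhyPos:positive:polc --phylum PhyNeg:negative --n-genomes 3
zcc compute demo/cohort.fasta --genes demo/cohort_genes.tsv -o demo/results.tsv
zcc cohort --results demo/results.tsv --metadata demo/cohort_metadata.tsv \
    --min-phylum-n 1 --summary-out demo/summary.tsv --crosstab-out demo/crosstab.tsv
```

`demo/results.tsv` then holds one row per genome, e.g. (columns abridged):

```
genome_id   length  gc_content  zcc       ori    ter    sgd_fraction
PhyPos_001  50000   0.50038     0.99706   43575  18546  0.825
PhyNeg_001  50000   0.5039     -0.99686   48084  23017  0.775
```

A `zcc` of +0.997 with SGD 0.825 is the purine-asymmetry regime (AT and GC
excesses co-vary, strong leading-strand gene preference); −0.997 is the
common anti-correlated regime. `demo/summary.tsv` labels the two synthetic
phyla `P-ZCC` and `N-ZCC` by the majority sign of their genomes, and
`demo/crosstab.tsv` cross-tabulates the PolC-bearing (PC) versus
DnaE-only (DE) genomes per phylum, before and after removing Tukey-fence
outliers (cells `X/Y`). The same computations are available as library
functions (`zcc.zcc_index`, `zcc.estimate_ori_ter`, `zcc.sgd_fraction`,
`zcc.cohort.summarize_phylum`, …); `zcc plot` draws disparity curves and
the cohort boxplot/sign-percentage figures.

Real inputs work the same way: a genome FASTA, annotations as GFF3
(`--genes-format gff3`) or the 4-column TSV, and optionally a DoriC-style
oriC CSV with `--ori-source table`. Survey-scale reproduction of published
phylum tables additionally needs the snapshot-dependent DoriC and NCBI
downloads plus polymerase metadata, and is deliberately outside this
repository's test scope.

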