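# dicodex

Codon- and dicodon-based expression indexes for coding sequences.

Synonymous codons are not used interchangeably: highly expressed genes favor
"optimal" codons, and the codon adaptation index (CAI) exploits this to
predict a gene's expressivity from its coding sequence alone. There is also
a bias at the level of adjacent codon *pairs* (dicodons): some pairs are
specifically avoided, several are experimentally linked to strong
translational inhibition, and this pair-level signal is not reducible to
single-codon frequencies. `dicodex` implements a family of geometric-mean
expression indexes that generalize CAI in two directions — contributions
estimated from dicodons instead of codons, and contributions weighted by
each reference gene's expression level — together with the evaluation
procedures needed to compare the schemes and to screen for candidate
inhibitory dicodons. It is aimed at researchers studying codon usage bias
and translation efficiency, and at applications such as heterologous
expression optimization and codon-pair deoptimization.

## The measures

For a coding sequence with retained tokens (codons or overlapping dicodons)
`t(1) … t(L)`, the expression index is the geometric mean of the token
contributions:

    index = ( Π_i C(t(i)) )^(1/L)

Contributions come from a reference set `S_p` — the genes with expression
above the p-th percentile (S_0 = all genes):

* unweighted (relative adaptiveness): `a_t = o_t / max{o_t'}`, where `o_t`
  is the token's count over `S_p` and the max runs over the token's
  synonymy class (codons encoding the same amino acid; dicodons encoding
  the same ordered dipeptide). Codon-based `a_c` with these conventions is
  the classic CAI.
* expression-weighted: `b_t = Σ_i o_t(s_i) · w(s_i)` over reference genes,
  with `w = exp(E)` for log-normalized expression values and `w = E` for
  linear TPM; then `f_t = b_t / max{b_t'}` per class.
* squared variant: every contribution is squared before the geometric mean,
  which polarizes mid-range contributions (a monotone transform of the
  plain index, so rank-based statistics are unchanged).

QC and tokenization conventions: only sequences longer than 50 codons are
kept; the first codon and first dicodon of each sequence are discarded;
stop codons and stop-containing dicodons are never counted; dicodons are
the overlapping pairs of adjacent codons, written as 6-mers.

## Worked example

`examples/` contains one narrative script per capability. The first builds
a 500-gene synthetic genome whose codon usage is coupled to expression,
estimates codon and dicodon contribution tables from the top-decile
reference set, and scores every gene:

```
$ python examples/01_score_sequences.py
reference set S_90: 50 of 500 genes

gene        E (log)   codon index   dicodon index
g194     -2.07        0.0325          0.0337
g322      1.04        0.0648          0.0517
g383      2.00        0.1978          0.1400
g008      2.87        0.6292          0.5231

Pearson r with expression level: codon 0.497, dicodon 0.527
```

Indexes lie in (0, 1]; a gene scores 1 only if every token is the optimal
member of its synonymy class. The correlations are computed against linear
expression levels (exponentiated log values). The other examples compare
the four schemes across reference percentiles and replicates
(`02_scheme_comparison.py`), recover planted inhibitory dicodons through
the observed-vs-expected ratio and the low-contribution screen
(`03_inhibitory_screen.py`), and examine length bias and contribution
distributions (`04_length_strata_and_distributions.py`).

The same pipeline is available as a CLI for shell use:

```
dicodex simulate --outdir fixture --n-genes 500 --seed 1
dicodex contrib --cds fixture/synthetic_cds.fa --expr fixture/synthetic_expression.tsv \
    --arity 2 --weighted --percentile 97 --out fd.tsv
dicodex index --cds fixture/synthetic_cds.fa --contrib fd.tsv --out index.tsv
dicodex evaluate --index index.tsv --expr fixture/synthetic_expression.tsv \
    --cds fixture/synthetic_cds.fa --out report.tsv
dicodex screen --contrib fd.tsv --threshold 1e-6 --out screen.tsv
```

Real data plug in the same way: point `--cds` at an Ensembl-style
`*.cds.all.fa` dump and `--expr` at a gene-by-sample table (tagged
`log_normalized` for microarray values or `linear` for TPM).

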