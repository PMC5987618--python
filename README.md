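# utr3evo

Comparative analysis of 3'UTR length evolution across teleost genomes.

3'UTRs — the spliced mRNA segment between the stop codon and the
poly(A) site — carry miRNA target sites and RNA-binding-protein motifs,
and their length sets the regulatory real estate of a gene. In rapidly
diversifying clades such as the East African cichlids, longer or
faster-evolving 3'UTRs are a candidate substrate for regulatory
divergence. `utr3evo` is a toolkit for asking that question with nine
teleost genomes (five cichlids as a focal clade, four model teleosts as
background):

1. **Extraction** — parse genome FASTA + GFF3, pick each gene's
   canonical transcript (stop-codon-bearing isoform with the longest
   CDS), extract 5'UTR/CDS/3'UTR sequences and length summaries.
2. **Orthology** — chain BLASTP HSPs into per-pair similarity scores,
   cluster genes into families by average-linkage agglomeration, and
   keep strict 1:1 orthologs across all species.
3. **Repeat content** — fraction of repeat-masked bases in 3'UTRs,
   5'UTRs, CDS and the whole genome, compared per species with the
   exact Wilcoxon signed-rank test.
4. **miRNA targets** — strict-seed scanning (perfect Watson-Crick
   complementarity to miRNA positions 2–8) with a nearest-neighbor
   duplex free-energy cutoff of −20 kcal/mol.
5. **Rate divergence** — per-gene two-regime Brownian motion on a
   time-calibrated painted tree. With T_r the shared root-path time in
   regime r, tip lengths are modelled as N(μ·1, σ²_f·T_f + σ²_b·T_b);
   (σ̂²_f, σ̂²_b) are estimated by REML with the root profiled by GLS,
   and the per-gene statistic log10(σ̂²_f/σ̂²_b) is tested against 0
   with a one-sample t-test, as is the clade mean-length ratio
   log10(L̄_focal/L̄_background).
6. **Enrichment** — top-5% outlier gene sets tested for GO/KEGG term
   over-representation with the one-sided Fisher's exact test
   (hypergeometric upper tail) and Benjamini-Hochberg correction.

A synthetic-data module generates genomes, annotations, repeat tracks,
miRNAs, similarity tables and term maps with planted ground truth, so
the entire pipeline runs and is tested without any downloads. See
`docs/methods.md` for models, assumptions, and measured estimator
behavior.

## Worked example

Run the full pipeline on a synthetic dataset with a twofold focal rate:

```python
from utr3evo import pipeline, synthetic_data as sd

cfg = sd.SimulationConfig(seed=11, n_genes=60,
                          sigma2_focal=2.0, sigma2_background=1.0)
pipeline.run_all(cfg, "run1")
print(open("run1/report.txt").read())
```

```
repeat fractions: genome vs 3'UTR signed-rank p = 0.003906
rate ratios: mean log10 = 0.2787, t = 3.89, p = 0.00026 (60 genes)
length ratios: mean log10 = 0.0002, t = 0.15, p = 0.879
enrichment (length top 5%): 0 significant terms
enrichment (rate top 5%): 0 significant terms
```

Reading the report: all nine species were planted with fewer repeats
in 3'UTRs than genome-wide, so the paired signed-rank test returns its
exact floor for nine same-sign pairs, 2/2⁹ ≈ 0.0039. The planted 2×
focal rate is recovered as a mean log10 rate ratio near log10 2 ≈ 0.30
and is significant already at 60 genes, while the length ratios —
simulated with no focal inflation — stay at 0. Enrichment finds
nothing because a top-5% set of 60 genes holds only 3 genes.

The same stages are available from the shell (`utr3evo extract`,
`orthologs`, `repeats`, `mirna`, `rates`, `enrich`, `simulate`,
`all`); every stage reads and writes ordinary FASTA/GFF3/BED/TSV, so
each is runnable standalone on real data. `utr3evo all --config
cfg.yaml --out dir` writes a `manifest.json` with a checksum for every
output, and reruns with the same config and seed are byte-identical.

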