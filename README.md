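# mirddr

Genome-wide analysis of microRNA expression changes during the DNA damage
response (DDR), from raw small-RNA sequencing reads to the identification of
candidate direct p53 target miRNAs.

When human cells suffer DNA double-strand breaks (e.g. after ionizing
radiation), transcription factors such as p53 reshape gene expression over
the following 4–24 h, and a substantial fraction of known miRNAs change
expression in strongly cell-type-dependent patterns. `mirddr` implements,
as a tested and reusable library plus a thin CLI, the full analysis chain
used to characterize such changes:

1. **Quantification** (`mirddr.ingest`) — adapter trimming, length (18–30 nt)
   and low-complexity filtering, and exact-identity matching of reads to a
   mature-miRNA reference; small-RNA class fractions (miRNA, tRNA, snoRNA, …).
2. **Differential expression** (`mirddr.diffexpr`) — pseudocount,
   aggregate-count filter (< 100 over all samples), library-size scaling,
   technical-replicate merging; per-miRNA M = log2 fold change and
   A = log2 mean abundance; a two-sided exact count test (Fisher on the
   2×2 table of counts vs library sizes, or its binomial approximation),
   Bonferroni corrected. Significance = |M| ≥ 0.75 ∧ A ≥ 5 ∧ p_corr < 0.05.
3. **DDR selection** (`mirddr.selection`) — the robustness filter
   (consistent trend at 4 h and 24 h, corrected significance, support in
   ≥ 2 cell lines and/or ≥ 2 technical replicates), redundancy resolution
   (star arms by read coverage; identical mature sequences), kinetic
   clusters A–D (induced/repressed × early/late peak), Venn comparisons,
   and p53-dependence calls from a TP53⁻/⁻ contrast.
4. **Genomic context** (`mirddr.context`) — intragenic (same-strand host
   transcript) vs intergenic, clustered (< 10 kb spacing, single linkage)
   vs single, and Fisher tests of DDR enrichment per category.
5. **p53 motif ranking** (`mirddr.motifs`) — promoter windows
   ([−5 kb, +500 bp] intergenic; [−4 kb, +2 kb] host TSS;
   [−3.5 kb, −500 bp] intragenic), log2-odds PWM scanning, homotypic CRM
   scoring (best sum of non-overlapping hits in a 500 bp window, floored at
   0), per-species ranking, and cross-species rank aggregation by uniform
   order statistics with a null-calibrated final score −ln(q).
6. **Preranked GSEA** (`mirddr.gsea`) — weighted running enrichment score,
   ES, leading edge ("core enrichment"), permutation NES ("mean div") and
   pooled FDR q.
7. **Synthetic studies** (`mirddr.simulate`) — a fully seeded generator of
   counts (negative-binomial with technical replicates as binomial
   thinnings), reads, genome annotations and multi-species promoters with
   planted p53-like motif clusters, with complete ground-truth bookkeeping.
8. **Orchestration** (`mirddr.pipeline`) — one configuration drives every
   stage end-to-end and writes a reproducible report bundle.

## Worked example

The package ships a published worked example (`mirddr.examples`): the 20
consolidated DDR-induced miRNAs placed on a genome-wide p53-motif ranking of
1531 miRNA features. Re-scoring it reproduces the published running
enrichment profile and core-enrichment calls:

```python
import numpy as np
from mirddr.examples import P53_GSEA_EXAMPLE, P53_GSEA_EXAMPLE_N
from mirddr.gsea import RankedList, running_es

n = P53_GSEA_EXAMPLE_N                      # 1531
ids = [f"filler-{i}" for i in range(n)]
scores = np.full(n, np.nan)
for name, rank, score, _run, _core in P53_GSEA_EXAMPLE:
    ids[rank], scores[rank] = name, score
last = 0.0                                   # non-increasing fill
for i in range(n - 1, -1, -1):
    if np.isnan(scores[i]): scores[i] = last
    else: last = scores[i]

res = running_es(RankedList(ids, scores), {m for m, *_ in P53_GSEA_EXAMPLE})
print(f"ES = {res.ES:.8f} at rank {res.peak}")
print("leading edge:", res.leading_edge)
```

prints

```
ES = 0.67305356 at rank 101
leading edge: ['mir-34a', 'mir-34c', 'mir-486', 'mir-139', 'let-7a-2', 'mir-125b-1']
```

i.e. the enrichment score peaks at the sixth gene-set hit, and exactly those
six miRNAs — the miR-34a/c pair, miR-486, miR-139, let-7a-2 and miR-125b-1 —
are called core enrichment: the candidate direct p53 targets.

The count test behaves as expected at sequencing depth: a miRNA going from
64 to 256 reads in libraries of 150,000 gives

```python
from mirddr.diffexpr import count_test
count_test(256, 150_000, 64, 150_000)   # 2.27e-28: overwhelming evidence
```

A complete synthetic study runs end-to-end from the shell:

```bash
mirddr run --seed 4 --out runout/
```

which logs, per stage, lines such as

```
[selection] 20 induced candidates -> 16 after redundancy; ...
[gsea] ddr_induced: ES=0.940 NES=1.80 p=0.0000 q=0.0000 leading edge 13/16
[p53] 20 p53-dependent calls of 299 assessed
```

— the 20 spiked induced miRNAs are all recovered, consolidate to 16 after
the redundancy rules (two star arms and two identical-sequence twins are
planted in the reference), and the induced set is strongly enriched at the
top of the planted p53-motif ranking.

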