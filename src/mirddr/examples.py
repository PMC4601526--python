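"""Published worked-example inputs for validation.

Two small curated tables from the study this pipeline re-implements, used as
fixed inputs by the test-suite and the reproduction script:

* ``P53_GSEA_EXAMPLE`` — the 20 robustly DDR-induced miRNAs placed on a
  genome-wide p53-motif ranking of ``N = 1531`` features: for each member its
  0-based rank in the list, its rank-metric score (the -log aggregated motif
  q-score), the published running enrichment score at its position, and the
  published core-enrichment flag. The list length 1531 is the unique value
  reconciling every published running-score value with the printed ranks and
  scores under the weighted (p = 1) scheme.

* ``DDR_INDUCED_TABLE`` — the 20 consolidated DDR-induced miRNAs with their
  log2 fold changes (M) at 4 h and 24 h in the two wild-type cell lines and
  the per-cell-line differential-expression flags (1 = satisfied the
  M > 0.75, A > 5, corrected p < 0.05 criteria in that cell line).

* ``REDUNDANT_CANDIDATES`` — the three pre-consolidation candidates removed
  by the redundancy rules: the star arms miR-139-3p and miR-486-3p (lower
  coverage than their 5p siblings) and miR-365b-3p (mature sequence
  identical to miR-365a-3p).
"""

from __future__ import annotations

#: (name, rank0, rank_metric_score, running_es, core_enrichment)
P53_GSEA_EXAMPLE_N = 1531
P53_GSEA_EXAMPLE = [
    ("mir-34a",     0,    34.82690048, 0.19905818,  "Yes"),
    ("mir-34c",     1,    34.6026001,  0.3968343,   "Yes"),
    ("mir-486",     19,   18.5720005,  0.49173445,  "Yes"),
    ("mir-139",     32,   16.42160034, 0.5776527,   "Yes"),
    ("let-7a-2",    76,   12.94890022, 0.623206,    "Yes"),
    ("mir-125b-1",  101,  11.50020027, 0.67305356,  "Yes"),
    ("mir-365a",    323,  6.691860199, 0.5650411,   "No"),
    ("mir-215",     389,  6.109330177, 0.556942,    "No"),
    ("mir-96",      524,  5.189610004, 0.497921,    "No"),
    ("let-7a-1",    651,  4.54610014,  0.44051638,  "No"),
    ("mir-423",     759,  3.868499994, 0.39181334,  "No"),
    ("mir-1247",    789,  3.651760101, 0.3934929,   "No"),
    ("mir-192",     872,  3.154949903, 0.35725677,  "No"),
    ("mir-191",     877,  3.117209911, 0.3724264,   "No"),
    ("mir-3184",    901,  3.018699884, 0.3744585,   "No"),
    ("mir-152",     1051, 2.350739956, 0.2892843,   "No"),
    ("mir-1-2",     1084, 2.201610088, 0.2806899,   "No"),
    ("mir-148b",    1111, 2.113770008, 0.27556428,  "No"),
    ("mir-125b-2",  1520, 0.065534301, 0.005919015, "No"),
    ("let-7a-3",    1529, 0.00653213,  6.62e-04,    "No"),
]

#: name -> (M_mcf_4h, M_mcf_24h, M_hct_4h, M_hct_24h, flag_mcf, flag_hct);
#: None marks a value not measured in that cell line.
DDR_INDUCED_TABLE = {
    "miR-34c-5p":   (2.37, 3.98, 0.59, 3.54, 1, 1),
    "1947411_x4":   (0.37, 0.95, 0.59, 2.65, 1, 1),
    "miR-486-5p":   (None, None, 0.58, 1.95, 1, 1),  # infinite M in MCF10A
    "miR-148a-3p":  (1.10, 1.77, 0.71, 1.26, 1, 1),
    "miR-152":      (0.33, 0.85, 0.23, 1.76, 1, 1),
    "miR-1247-3p":  (None, None, 0.53, 1.69, 0, 1),
    "miR-1":        (1.23, 0.98, 0.77, 1.58, 1, 1),
    "let-7a-3p":    (1.55, 0.49, 0.89, 0.50, 1, 1),
    "miR-365a-3p":  (0.91, 0.16, 0.47, 1.43, 1, 1),
    "miR-3184-3p":  (1.10, 0.30, 0.21, 1.39, 1, 1),
    "miR-423-5p":   (1.10, 0.30, 0.21, 1.39, 1, 1),
    "miR-139-5p":   (1.00, -1.00, 0.40, 1.23, 0, 1),
    "miR-125b-5p":  (-0.54, 0.89, 1.02, 0.87, 0, 1),
    "miR-191-5p":   (0.04, 0.29, 0.17, 0.97, 0, 1),
    "miR-34a-5p":   (0.47, 0.77, 0.32, 0.97, 1, 1),
    "miR-96-5p":    (0.96, 0.93, 0.51, 0.40, 1, 0),
    "miR-192-5p":   (0.18, 0.44, 0.40, 0.93, 0, 1),
    "miR-215":      (0.19, 0.46, 0.40, 0.93, 0, 1),
    "miR-148b-3p":  (0.28, 0.26, 0.43, 0.84, 0, 1),
    "miR-146a-5p":  (-0.64, -0.60, 0.16, 0.84, 0, 1),
}

#: Candidates removed during consolidation, with the rule that removes them.
REDUNDANT_CANDIDATES = {
    "miR-139-3p": "star_arm",
    "miR-486-3p": "star_arm",
    "miR-365b-3p": "identical_sequence",
}
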