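"""Count normalization and per-miRNA differential expression.

The model is the classic digital-gene-expression one: for each miRNA and each
(cell line, time) vs the 0 h control, treat the pair of counts against the
pair of library sizes as a 2x2 contingency table and compute a two-sided
exact test (or its binomial approximation), then Bonferroni-correct over the
number of miRNAs tested. Effect sizes are summarised as an MA pair,

    M = log2(n_treat / n_ctrl),    A = log2((n_treat + n_ctrl) / 2),

computed on normalized counts, so that with library sizes scaled to the mean
raw library size the abundance threshold A >= 5 corresponds to a normalized
count of about 32.

Exact tests run on merged raw integer counts with raw library sizes; the
normalized values feed only M and A.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import CountTable, InputError

__all__ = [
    "NormalizationConfig", "SignificanceThresholds", "ExpressionRecord",
    "normalize", "merge_replicates", "compute_ma", "count_test",
    "correct_and_call", "differential_expression", "records_to_frame",
]


@dataclass(frozen=True)
class NormalizationConfig:
    """Pseudocount, aggregate filter and scale target for normalization.

    ``aggregate_min`` drops miRNAs whose raw counts summed over every sample
    fall strictly below the threshold (100 by default). ``scale_target``:
    ``mean_library`` rescales each column total to the mean raw library size;
    ``fixed_per_million`` to 1e6 (counts per million).
    """

    pseudocount: float = 1.0
    aggregate_min: int = 100
    scale_target: Literal["mean_library", "fixed_per_million"] = "mean_library"

    def __post_init__(self) -> None:
        if self.pseudocount < 0 or self.aggregate_min < 0:
            raise InputError("pseudocount and aggregate_min must be >= 0")


@dataclass(frozen=True)
class SignificanceThresholds:
    """Joint M/A/alpha significance thresholds.

    Defaults are the known-miRNA settings (|M| >= 0.75, i.e. a >= 1.68-fold
    change; A >= 5, i.e. a normalized count >= 32; corrected p < 0.05).
    ``new_mirna_variant()`` returns the laxer preset used for predicted
    miRNAs (0.5, 4, 0.001).
    """

    m_thresh: float = 0.75
    a_thresh: float = 5.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if min(self.m_thresh, self.a_thresh, self.alpha) <= 0:
            raise InputError("thresholds must be strictly positive")

    @staticmethod
    def new_mirna_variant() -> "SignificanceThresholds":
        return SignificanceThresholds(m_thresh=0.5, a_thresh=4.0, alpha=0.001)


@dataclass
class ExpressionRecord:
    """Per-miRNA result for one condition-vs-control comparison."""

    mirna_id: str
    comparison: tuple  # (cell_line, genotype, time_h) vs 0 h
    M: float
    A: float
    p: float
    p_corr: float = np.nan
    significant: bool = False


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize(
    raw: CountTable, cfg: NormalizationConfig = NormalizationConfig()
) -> tuple[CountTable, list[str]]:
    """Pseudocount, aggregate-filter and library-size-scale a raw table.

    Steps, in order: (1) zero cells are replaced by the pseudocount; (2)
    miRNAs whose aggregate *raw* count over all samples is strictly below
    ``aggregate_min`` are dropped; (3) each column is scaled so its total
    equals the scale target. Returns the normalized table and the dropped ids.
    """
    counts = raw.counts.astype(float)
    if (counts.sum(axis=0) == 0).any():
        raise InputError("degenerate library: all-zero sample column")

    aggregate = raw.counts.sum(axis=1)
    dropped = list(aggregate.index[aggregate < cfg.aggregate_min])

    counts = counts.mask(counts == 0, cfg.pseudocount)
    counts = counts.drop(index=dropped)

    lib = raw.library_sizes[counts.columns].astype(float)
    if cfg.scale_target == "mean_library":
        target = float(lib.mean())
    else:
        target = 1e6
    scaled = counts * (target / counts.sum(axis=0))

    out = CountTable(
        counts=scaled,
        sample_meta=raw.sample_meta.copy(),
        library_sizes=lib,
        normalized=True,
    )
    return out, dropped


def merge_replicates(t: CountTable) -> CountTable:
    """Sum technical replicates into one column per (cell line, genotype, time).

    Counts and library sizes are added; merged sample ids are
    ``cellline_genotype_t{time}h``.
    """
    required = {"cell_line", "genotype", "time_h", "replicate"}
    if not required <= set(t.sample_meta.columns):
        raise InputError(
            f"replicate metadata incomplete: need {sorted(required)}"
        )
    keys = ["cell_line", "genotype", "time_h"]
    groups = t.sample_meta.groupby(keys, sort=True).groups
    cols, meta_rows, libs = {}, [], {}
    for (cell, geno, time), samples in groups.items():
        name = f"{cell}_{geno}_t{time}h"
        cols[name] = t.counts[list(samples)].sum(axis=1)
        libs[name] = float(t.library_sizes[list(samples)].sum())
        meta_rows.append(
            {"sample": name, "cell_line": cell, "genotype": geno,
             "time_h": time, "replicate": 0}
        )
    meta = pd.DataFrame(meta_rows).set_index("sample")
    return CountTable(
        counts=pd.DataFrame(cols),
        sample_meta=meta,
        library_sizes=pd.Series(libs),
        normalized=t.normalized,
    )


# ---------------------------------------------------------------------------
# MA statistics and count tests
# ---------------------------------------------------------------------------

def compute_ma(normalized: CountTable, treat: str, ctrl: str) -> pd.DataFrame:
    """Per-miRNA (M, A) between two columns of a normalized table."""
    for col in (treat, ctrl):
        if col not in normalized.counts.columns:
            raise InputError(f"unknown sample {col!r}")
    nt = normalized.counts[treat].to_numpy(dtype=float)
    nc = normalized.counts[ctrl].to_numpy(dtype=float)
    if (nt <= 0).any() or (nc <= 0).any():
        raise InputError("compute_ma requires strictly positive (post-pseudocount) values")
    return pd.DataFrame(
        {"M": np.log2(nt / nc), "A": np.log2((nt + nc) / 2.0)},
        index=normalized.counts.index,
    )


def count_test(
    x_treat: int, lib_treat: int, x_ctrl: int, lib_ctrl: int,
    method: Literal["exact_fisher", "binomial_approx"] = "exact_fisher",
) -> float:
    """Two-sided test of differential abundance for one miRNA.

    ``exact_fisher``: Fisher's exact test on the 2x2 table
    ``[[x_treat, lib_treat - x_treat], [x_ctrl, lib_ctrl - x_ctrl]]`` (sum of
    hypergeometric point probabilities <= that of the observed table).
    ``binomial_approx``: two-sided binomial test of
    x_treat ~ Bin(x_treat + x_ctrl, lib_treat / (lib_treat + lib_ctrl)).
    """
    if lib_treat <= 0 or lib_ctrl <= 0:
        raise InputError("library sizes must be positive")
    for x, lib in ((x_treat, lib_treat), (x_ctrl, lib_ctrl)):
        if not 0 <= x <= lib:
            raise InputError("count outside [0, library size]")
    if method == "exact_fisher":
        table = [[x_treat, lib_treat - x_treat], [x_ctrl, lib_ctrl - x_ctrl]]
        return float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    if method == "binomial_approx":
        n = x_treat + x_ctrl
        if n == 0:
            return 1.0
        p = lib_treat / (lib_treat + lib_ctrl)
        return float(stats.binomtest(x_treat, n, p, alternative="two-sided").pvalue)
    raise InputError(f"unknown method {method!r}")


def correct_and_call(
    records: Sequence[ExpressionRecord],
    th: SignificanceThresholds = SignificanceThresholds(),
    m_tests: int | None = None,
) -> list[ExpressionRecord]:
    """Bonferroni-correct p-values and set significance flags in place.

    ``p_corr = min(1, m_tests * p)`` with ``m_tests`` defaulting to the number
    of records. Significant iff |M| >= m_thresh and A >= a_thresh (inclusive)
    and p_corr < alpha (strict).
    """
    m = m_tests if m_tests is not None else len(records)
    if m < 1:
        raise InputError("m_tests must be >= 1")
    for rec in records:
        rec.p_corr = min(1.0, m * rec.p)
        rec.significant = (
            abs(rec.M) >= th.m_thresh
            and rec.A >= th.a_thresh
            and rec.p_corr < th.alpha
        )
    return list(records)


# ---------------------------------------------------------------------------
# Full per-comparison analysis
# ---------------------------------------------------------------------------

def differential_expression(
    raw: CountTable,
    cfg: NormalizationConfig = NormalizationConfig(),
    th: SignificanceThresholds = SignificanceThresholds(),
    control_time: int = 0,
    method: Literal["exact_fisher", "binomial_approx"] = "exact_fisher",
    merge: bool = True,
) -> pd.DataFrame:
    """Run the full DE analysis of every condition against its 0 h control.

    Normalizes, merges technical replicates (``merge=True``) or keeps them
    separate (``merge=False``; each replicate is then compared to its own
    control), and for each (cell line, genotype[, replicate]) compares each
    non-control time point to the control: exact (or binomial-approximate)
    count tests on raw integer counts and library sizes, M/A on normalized
    counts, Bonferroni correction per comparison over the miRNAs tested.

    Returns a tidy DataFrame with columns (mirna, cell_line, genotype,
    replicate, time_h, M, A, p, p_corr, significant, method); replicate is 0
    for merged tables.
    """
    norm, dropped = normalize(raw, cfg)
    raw_m = merge_replicates(raw) if merge else raw.copy()
    norm_m = merge_replicates(norm) if merge else norm
    raw_m.counts = raw_m.counts.drop(index=dropped)
    raw_m.normalized = True  # column sums no longer equal library sizes

    meta = norm_m.sample_meta
    keys = ["cell_line", "genotype"] + ([] if merge else ["replicate"])
    rows = []
    for group, grp in meta.groupby(keys, sort=True):
        cell, geno = group[0], group[1]
        rep = 0 if merge else group[2]
        times = sorted(grp["time_h"].unique())
        if control_time not in times:
            raise InputError(f"{cell}/{geno}: no {control_time} h control column")
        ctrl = grp.index[grp["time_h"] == control_time][0]
        lib_c = int(round(raw_m.library_sizes[ctrl]))
        for t in times:
            if t == control_time:
                continue
            treat = grp.index[grp["time_h"] == t][0]
            lib_t = int(round(raw_m.library_sizes[treat]))
            ma = compute_ma(norm_m, treat, ctrl)
            xs_t = raw_m.counts[treat]
            xs_c = raw_m.counts[ctrl]
            records = [
                ExpressionRecord(
                    mirna_id=mid, comparison=(cell, geno, t),
                    M=float(ma.at[mid, "M"]), A=float(ma.at[mid, "A"]),
                    p=count_test(int(xs_t[mid]), lib_t, int(xs_c[mid]), lib_c,
                                 method=method),
                )
                for mid in norm_m.counts.index
            ]
            correct_and_call(records, th, m_tests=len(records))
            for rec in records:
                rows.append(
                    {"mirna": rec.mirna_id, "cell_line": cell, "genotype": geno,
                     "replicate": rep, "time_h": t, "M": rec.M, "A": rec.A,
                     "p": rec.p, "p_corr": rec.p_corr,
                     "significant": rec.significant, "method": method}
                )
    return pd.DataFrame(rows)


def records_to_frame(records: Iterable[ExpressionRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        cell, geno, t = r.comparison
        rows.append({"mirna": r.mirna_id, "cell_line": cell, "genotype": geno,
                     "time_h": t, "M": r.M, "A": r.A, "p": r.p,
                     "p_corr": r.p_corr, "significant": r.significant})
    return pd.DataFrame(rows)


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
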