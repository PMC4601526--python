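"""Robust DDR-miRNA selection, redundancy resolution and kinetic clustering.

From the per-comparison differential-expression table this module applies the
three-part robustness filter (consistent trend at 4 h and 24 h, corrected
significance at either time, support from a second cell line and/or a second
technical replicate), collapses redundant mature species (star arms and
identical mature sequences), assigns each DDR miRNA to a kinetic cluster
(induced/repressed x early/late peak, labelled A-D under a configurable
convention), compares DDR sets between cell lines, and calls p53 dependence
by contrasting wild-type against TP53-null records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import InputError, MatureMiRNA

__all__ = [
    "DDRCallSet", "CLUSTER_PRESETS", "robust_filter", "resolve_redundancy",
    "assign_clusters", "compare_sets", "timing_chisq", "p53_dependence",
    "dependence_fractions",
]

Direction = Literal["induced", "repressed"]

#: Cluster-label conventions. Keys are (direction, peak_time) -> label.
#: ``mcf10a``: A = early induced, B = late induced.
#: ``hct116``: A = late induced, B = early induced (the dominant late response
#: carries the first label). C/D are early/late repressed in both.
CLUSTER_PRESETS: dict[str, dict[tuple[str, int], str]] = {
    "mcf10a": {("induced", 4): "A", ("induced", 24): "B",
               ("repressed", 4): "C", ("repressed", 24): "D"},
    "hct116": {("induced", 24): "A", ("induced", 4): "B",
               ("repressed", 4): "C", ("repressed", 24): "D"},
}


@dataclass
class DDRCallSet:
    """Result of the robustness filter for one direction."""

    direction: Direction
    members: set[str]
    flags: pd.DataFrame          # miRNA x cell line, 0/1 per-cell-line call
    provenance: dict[str, dict]  # per-miRNA filter trace

    def __post_init__(self) -> None:
        for mid in self.members:
            if mid not in self.provenance:
                raise InputError(f"member {mid!r} lacks a filter trace")


def _sign(x: float) -> int:
    return 0 if x == 0 else (1 if x > 0 else -1)


def robust_filter(
    records: pd.DataFrame,
    direction: Direction = "induced",
    per_replicate: pd.DataFrame | None = None,
) -> DDRCallSet:
    """Apply the three-criterion robustness filter for one direction.

    ``records`` is a merged-replicate DE table (columns mirna, cell_line,
    time_h, M, significant) restricted to the comparisons of interest;
    ``per_replicate`` optionally carries the same columns plus ``replicate``
    for the two-replicate support route.

    A miRNA is retained iff, in at least one cell line, (1) its M at 4 h and
    24 h have the same sign, matching the direction (zero fails), and (2) it
    is significant in the right direction at 4 h or 24 h — and additionally
    (3) such support exists in >= 2 cell lines, or >= 2 technical replicates
    agree (significant, right direction, at either time) within a supporting
    cell line. miRNAs missing a time point in a cell line are skipped there
    with a trace note.
    """
    want = 1 if direction == "induced" else -1
    trace: dict[str, dict] = {}
    support: dict[str, list[str]] = {}
    flags_rows: dict[str, dict[str, int]] = {}

    for (mid, cell), grp in records.groupby(["mirna", "cell_line"], sort=True):
        t = trace.setdefault(mid, {})
        by_time = {int(r.time_h): r for r in grp.itertuples()}
        entry: dict = {}
        flags_rows.setdefault(mid, {})[cell] = int(
            any(r.significant and _sign(r.M) == want for r in grp.itertuples())
        )
        if 4 not in by_time or 24 not in by_time:
            entry["skipped"] = "missing time point"
            t[cell] = entry
            continue
        m4, m24 = by_time[4].M, by_time[24].M
        entry["trend"] = _sign(m4) == want and _sign(m24) == want
        sig_times = [
            tt for tt in (4, 24)
            if by_time[tt].significant and _sign(by_time[tt].M) == want
        ]
        entry["significant_at"] = sig_times
        entry["passes"] = entry["trend"] and bool(sig_times)
        t[cell] = entry
        if entry["passes"]:
            support.setdefault(mid, []).append(cell)

    rep_support: dict[tuple[str, str], int] = {}
    if per_replicate is not None:
        sig = per_replicate[
            per_replicate["significant"]
            & (np.sign(per_replicate["M"]) == want)
        ]
        rep_support = (
            sig.groupby(["mirna", "cell_line"])["replicate"].nunique().to_dict()
        )

    members: set[str] = set()
    for mid, cells in support.items():
        two_cells = len(cells) >= 2
        two_reps = any(rep_support.get((mid, c), 0) >= 2 for c in cells)
        trace[mid]["criterion3"] = {
            "supporting_cell_lines": cells,
            "replicate_support": {c: rep_support.get((mid, c), 0) for c in cells},
            "passes": two_cells or two_reps,
        }
        if two_cells or two_reps:
            members.add(mid)

    all_cells = sorted(records["cell_line"].unique())
    flags = pd.DataFrame(
        [[flags_rows.get(m, {}).get(c, 0) for c in all_cells]
         for m in sorted(flags_rows)],
        index=sorted(flags_rows), columns=all_cells,
    )
    return DDRCallSet(direction, members, flags,
                      {m: trace[m] for m in trace})


def resolve_redundancy(
    candidates: set[str],
    reference: Sequence[MatureMiRNA],
    coverage: Mapping[str, float],
) -> tuple[set[str], list[tuple[str, str]]]:
    """Collapse redundant mature species in a candidate set.

    Rule 1: when both arms of the same stem-loop are present, keep the arm
    with the larger read coverage (the presumptive functional species; the
    other is the star sequence). Rule 2: when mature sequences are identical,
    keep a single representative, the lexicographically smallest id.

    Returns the consolidated set and ``[(removed_id, rule)]`` with rule in
    {"star_arm", "identical_sequence"}.
    """
    by_id = {m.id: m for m in reference}
    missing = candidates - set(by_id)
    if missing:
        raise InputError(f"candidates not in reference: {sorted(missing)}")
    for mid in candidates:
        if mid not in coverage:
            raise InputError(f"no coverage for candidate {mid!r}")

    kept = set(candidates)
    removed: list[tuple[str, str]] = []

    by_stemloop: dict[str, list[str]] = {}
    for mid in sorted(kept):
        by_stemloop.setdefault(by_id[mid].stemloop_id, []).append(mid)
    for stemloop, ids in by_stemloop.items():
        if len(ids) < 2:
            continue
        best = max(ids, key=lambda i: (coverage[i], i))
        for mid in ids:
            if mid != best:
                kept.discard(mid)
                removed.append((mid, "star_arm"))

    by_seq: dict[str, list[str]] = {}
    for mid in sorted(kept):
        by_seq.setdefault(by_id[mid].sequence, []).append(mid)
    for seq, ids in by_seq.items():
        if len(ids) < 2:
            continue
        keep = min(ids)
        for mid in ids:
            if mid != keep:
                kept.discard(mid)
                removed.append((mid, "identical_sequence"))
    return kept, removed


def assign_clusters(
    records: pd.DataFrame,
    preset: str | Mapping[tuple[str, int], str] = "mcf10a",
) -> pd.DataFrame:
    """Assign each miRNA to a kinetic cluster from its M at 4 h and 24 h.

    The direction is the sign of M at the time of maximal |M|; ties on |M|
    go to the later time point (noted in the output). The
    (direction, peak) -> label mapping comes from ``preset`` (name or
    explicit mapping; see :data:`CLUSTER_PRESETS`).

    ``records`` needs columns (mirna, time_h, M) for one cell line, with both
    time points per miRNA. Returns a frame indexed by miRNA with columns
    (direction, peak_time, label, tie).
    """
    mapping = CLUSTER_PRESETS[preset] if isinstance(preset, str) else dict(preset)
    rows = {}
    for mid, grp in records.groupby("mirna", sort=True):
        by_time = {int(r.time_h): r.M for r in grp.itertuples()}
        if 4 not in by_time or 24 not in by_time:
            raise InputError(f"{mid!r}: need M at both 4 h and 24 h")
        m4, m24 = by_time[4], by_time[24]
        tie = abs(m4) == abs(m24)
        peak = 24 if (abs(m24) >= abs(m4)) else 4
        m_peak = by_time[peak]
        direction = "induced" if m_peak > 0 else "repressed"
        rows[mid] = {
            "direction": direction, "peak_time": peak,
            "label": mapping[(direction, peak)], "tie": tie,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def compare_sets(set_by_cell_line: Mapping[str, set[str]]) -> dict:
    """Venn counts over per-cell-line DDR sets.

    Returns ``{"sizes": {cell: n}, "union": N, "intersections":
    {(a, b): n}, "shared": sorted list of the all-way intersection}``.
    """
    if len(set_by_cell_line) < 2:
        raise InputError("need >= 2 cell lines to compare")
    cells = sorted(set_by_cell_line)
    union: set[str] = set().union(*set_by_cell_line.values())
    inter = set(set_by_cell_line[cells[0]])
    for c in cells[1:]:
        inter &= set_by_cell_line[c]
    return {
        "sizes": {c: len(set_by_cell_line[c]) for c in cells},
        "union": len(union),
        "intersections": {
            (a, b): len(set_by_cell_line[a] & set_by_cell_line[b])
            for i, a in enumerate(cells) for b in cells[i + 1:]
        },
        "shared": sorted(inter),
    }


def timing_chisq(
    table: Sequence[Sequence[float]], correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square (df=1) on a 2x2 cell-line x peak-time table.

    Continuity correction off by default; a zero row/column margin is an
    error.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise InputError("need a non-negative 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise InputError("zero margin in contingency table")
    res = stats.chi2_contingency(arr, correction=correction)
    return float(res.statistic), float(res.pvalue)


def p53_dependence(
    wt_records: pd.DataFrame,
    ko_records: pd.DataFrame,
    m_thresh: float = 0.75,
) -> pd.Series:
    """Call p53 dependence per miRNA from WT vs TP53-null records.

    A miRNA (already DDR-called in the WT background) is ``p53_dependent``
    when it is significant in WT while the knockout shows neither
    significance nor a residual effect (max |M_KO| over time points <
    m_thresh / 2). It is ``p53_independent`` when the knockout remains
    significant with the same sign of effect. Everything else — missing KO
    data, WT not significant, or partial attenuation — is ``indeterminate``.
    """
    calls = {}
    ko_by_mirna = dict(tuple(ko_records.groupby("mirna"))) if len(ko_records) else {}
    for mid, wt in wt_records.groupby("mirna", sort=True):
        wt_sig = wt[wt["significant"]]
        if wt_sig.empty:
            calls[mid] = "indeterminate"
            continue
        wt_dir = _sign(wt_sig.loc[wt_sig["M"].abs().idxmax(), "M"])
        ko = ko_by_mirna.get(mid)
        if ko is None or ko.empty:
            calls[mid] = "indeterminate"
            continue
        ko_sig = ko[ko["significant"] & (np.sign(ko["M"]) == wt_dir)]
        if not ko_sig.empty:
            calls[mid] = "p53_independent"
        elif ko["M"].abs().max() < m_thresh / 2 and not ko["significant"].any():
            calls[mid] = "p53_dependent"
        else:
            calls[mid] = "indeterminate"
    return pd.Series(calls, name="p53_call", dtype=object)


def dependence_fractions(
    calls: pd.Series, clusters: pd.DataFrame
) -> pd.DataFrame:
    """Fraction of p53-dependent members per kinetic cluster label."""
    joined = clusters.join(calls, how="left")
    rows = []
    for label, grp in joined.groupby("label", sort=True):
        n = len(grp)
        dep = int((grp["p53_call"] == "p53_dependent").sum())
        rows.append({"label": label, "n": n, "p53_dependent": dep,
                     "fraction_dependent": dep / n if n else np.nan})
    return pd.DataFrame(rows).set_index("label")
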