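"""Preranked gene-set enrichment analysis over the motif ranking.

Implements the weighted Kolmogorov-Smirnov-like running statistic: walking
down a ranked list, each gene-set hit at rank i increases the running score
by |s_i|^p / sum_set |s|^p and each miss decreases it by 1 / (N - N_hits).
The enrichment score (ES) is the running value furthest from zero; the
leading edge ("core enrichment") contains the set members at or before the
peak (for a positive ES). Significance comes from a gene-set permutation
null: ES of random same-size sets, normalized by the mean same-sign null ES
("mean div"), with the standard pooled positive/negative FDR procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ingest import InputError

__all__ = [
    "RankedList", "EnrichmentResult", "running_es", "nes_and_fdr",
    "core_enrichment_flags", "read_gmt", "write_gmt",
]


@dataclass
class RankedList:
    """A ranked list of feature ids (best first) with rank-metric scores."""

    ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.ids) != len(self.scores):
            raise InputError("ids and scores differ in length")
        if np.any(np.diff(self.scores) > 1e-12):
            raise InputError("scores must be sorted non-increasing")
        if len(set(self.ids)) != len(self.ids):
            raise InputError("duplicate ids in ranked list")

    def __len__(self) -> int:
        return len(self.ids)

    @staticmethod
    def from_frame(frame: pd.DataFrame, score_col: str = "final_score") -> "RankedList":
        """Build from a ranking frame indexed by feature id (sorted best first)."""
        return RankedList(list(frame.index), frame[score_col].to_numpy())


@dataclass
class EnrichmentResult:
    """Preranked GSEA output for one gene set."""

    set_id: str
    hits: list[int]                # sorted 0-based ranks of set members
    running: np.ndarray            # running score after each position
    ES: float
    peak: int                      # 0-based position of the ES
    leading_edge: list[str]
    NES: float = np.nan
    p_nominal: float = np.nan
    fdr_q: float = np.nan
    n_perm: int = 0
    seed: int | None = None


def _running_profile(
    scores: np.ndarray, hit_mask: np.ndarray, p: float
) -> np.ndarray:
    """Running enrichment score after every position of the list."""
    n = len(scores)
    n_hits = int(hit_mask.sum())
    weights = np.abs(scores) ** p
    hit_total = weights[hit_mask].sum()
    if hit_total == 0:
        raise InputError("all set members have zero rank-metric weight")
    steps = np.where(hit_mask, weights / hit_total, -1.0 / (n - n_hits))
    return np.cumsum(steps)


def running_es(
    ranked: RankedList, gene_set: set[str], p: float = 1.0
) -> EnrichmentResult:
    """Running enrichment score, ES, peak and leading edge for one set.

    The ES is the running value furthest from zero (earliest position on
    magnitude ties). For a positive ES the leading edge is every set member
    at or before the peak; for a negative ES, every member at or after it.
    """
    n = len(ranked)
    members = set(gene_set)
    unknown = members - set(ranked.ids)
    if unknown:
        raise InputError(f"set members missing from ranked list: {sorted(unknown)}")
    if not 0 < len(members) < n:
        raise InputError("gene set must be a non-empty proper subset of the list")

    id_arr = np.array(ranked.ids)
    hit_mask = np.isin(id_arr, sorted(members))
    running = _running_profile(ranked.scores, hit_mask, p)
    peak = int(np.argmax(np.abs(running)))
    es = float(running[peak])
    hits = [int(i) for i in np.nonzero(hit_mask)[0]]
    if es >= 0:
        leading = [ranked.ids[i] for i in hits if i <= peak]
    else:
        leading = [ranked.ids[i] for i in hits if i >= peak]
    return EnrichmentResult(
        set_id="", hits=hits, running=running, ES=es, peak=peak,
        leading_edge=leading,
    )


def _null_es(
    ranked: RankedList, set_size: int, n_perm: int, rng: np.random.Generator,
    p: float,
) -> np.ndarray:
    n = len(ranked)
    weights = np.abs(ranked.scores) ** p
    out = np.empty(n_perm)
    miss_step = None
    for b in range(n_perm):
        idx = rng.choice(n, size=set_size, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        hit_total = weights[mask].sum()
        if hit_total == 0:
            out[b] = 0.0
            continue
        steps = np.where(mask, weights / hit_total, -1.0 / (n - set_size))
        running = np.cumsum(steps)
        out[b] = running[np.argmax(np.abs(running))]
    return out


def nes_and_fdr(
    ranked: RankedList,
    gene_sets: Mapping[str, set[str]],
    n_perm: int = 1000,
    seed: int = 0,
    p: float = 1.0,
) -> dict[str, EnrichmentResult]:
    """Permutation NES, nominal p and FDR q for a collection of gene sets.

    The null for each set is the ES of ``n_perm`` random same-size sets
    drawn without replacement from the ranked ids (seeded, so runs are
    reproducible bit-for-bit). NES divides the ES by the mean same-sign null
    ES; nominal p is the same-sign null tail fraction at the observed |ES|.
    FDR q follows the standard pooled procedure: observed and null NES are
    pooled by sign, and q = (tail fraction of pooled null NES) / (tail
    fraction of observed NES), clipped to [0, 1].
    """
    if n_perm < 100:
        raise InputError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    results: dict[str, EnrichmentResult] = {}
    null_nes_pool: list[np.ndarray] = []

    for set_id in sorted(gene_sets):
        res = running_es(ranked, gene_sets[set_id], p=p)
        res.set_id = set_id
        res.n_perm = n_perm
        res.seed = seed
        null = _null_es(ranked, len(res.hits), n_perm, rng, p)
        if np.all(null == 0):
            raise InputError(f"{set_id!r}: degenerate permutation null")
        pos_mean = null[null >= 0].mean() if np.any(null >= 0) else np.nan
        neg_mean = null[null < 0].mean() if np.any(null < 0) else np.nan
        if res.ES >= 0:
            same = null[null >= 0]
            res.NES = res.ES / pos_mean
            res.p_nominal = float(np.mean(same >= res.ES)) if len(same) else np.nan
        else:
            same = null[null < 0]
            res.NES = res.ES / abs(neg_mean)
            res.p_nominal = float(np.mean(same <= res.ES)) if len(same) else np.nan
        with np.errstate(divide="ignore", invalid="ignore"):
            nn = np.where(null >= 0, null / pos_mean, null / abs(neg_mean))
        null_nes_pool.append(nn[np.isfinite(nn)])
        results[set_id] = res

    pool = np.concatenate(null_nes_pool)
    obs = np.array([results[s].NES for s in results])
    for set_id, res in results.items():
        if res.NES >= 0:
            null_tail = np.mean(pool[pool >= 0] >= res.NES) if np.any(pool >= 0) else 0.0
            obs_tail = np.mean(obs[obs >= 0] >= res.NES)
        else:
            null_tail = np.mean(pool[pool < 0] <= res.NES) if np.any(pool < 0) else 0.0
            obs_tail = np.mean(obs[obs < 0] <= res.NES)
        res.fdr_q = float(min(1.0, null_tail / obs_tail)) if obs_tail > 0 else 1.0
    return results


def core_enrichment_flags(
    result: EnrichmentResult, ranked: RankedList
) -> dict[str, str]:
    """Per-member "Yes"/"No" core-enrichment flags (Yes iff in leading edge)."""
    leading = set(result.leading_edge)
    return {
        ranked.ids[i]: ("Yes" if ranked.ids[i] in leading else "No")
        for i in result.hits
    }


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets from GMT (set_id <tab> description <tab> members...)."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError("GMT lines need id, description and members")
            out[fields[0]] = set(fields[2:])
    return out


def write_gmt(sets: Mapping[str, set[str]], path: str | Path,
              description: str = "") -> None:
    with open(path, "w") as fh:
        for set_id in sorted(sets):
            members = "\t".join(sorted(sets[set_id]))
            fh.write(f"{set_id}\t{description}\t{members}\n")


def results_to_frame(results: Mapping[str, EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {"set_id": r.set_id, "size": len(r.hits), "ES": r.ES, "NES": r.NES,
         "p_nominal": r.p_nominal, "fdr_q": r.fdr_q, "peak": r.peak,
         "leading_edge_size": len(r.leading_edge), "n_perm": r.n_perm}
        for r in results.values()
    ]
    return pd.DataFrame(rows).set_index("set_id")
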