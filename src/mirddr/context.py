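"""Genomic context of miRNA loci: intragenic/intergenic, single/clustered.

A miRNA locus is *intragenic* when its stem-loop interval lies fully inside
an annotated transcript on the same strand (the smallest containing
transcript is the host gene); otherwise it is *intergenic* — opposite-strand
containment does not count. Loci are *clustered* when they chain to another
miRNA locus on the same chromosome with an inter-locus gap strictly below
10 kb (single linkage, strand-agnostic), mirroring the miRBase "<10 kb"
cluster convention.

Category enrichment of a DDR set against the background uses a two-sided
exact test on the per-category 2x2 table. All coordinates are 0-based
half-open; GFF3 input (1-based closed) is converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .diffexpr import count_test
from .ingest import InputError

__all__ = [
    "MiRNALocus", "ContextLabel", "classify_location", "classify_grouping",
    "label_loci", "category_enrichment", "read_loci_gff3", "read_loci_bed6",
    "CATEGORIES",
]

CATEGORIES = (
    "intragenic_single", "intragenic_clustered",
    "intergenic_single", "intergenic_clustered",
)


@dataclass(frozen=True)
class MiRNALocus:
    """A miRNA genomic interval (0-based half-open)."""

    mirna_id: str
    chrom: str
    start: int
    end: int
    strand: str
    feature_kind: str = "stemloop"  # {stemloop, mature}

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise InputError(f"{self.mirna_id!r}: start >= end")
        if self.strand not in "+-":
            raise InputError(f"{self.mirna_id!r}: strand {self.strand!r}")


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    chrom: str
    start: int
    end: int
    strand: str

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ContextLabel:
    location: str                 # {intragenic, intergenic}
    grouping: str                 # {single, clustered}
    host_gene: str | None = None  # present iff intragenic
    cluster_id: str | None = None  # present iff clustered

    def __post_init__(self) -> None:
        if (self.location == "intragenic") != (self.host_gene is not None):
            raise InputError("host_gene present iff intragenic")
        if (self.grouping == "clustered") != (self.cluster_id is not None):
            raise InputError("cluster_id present iff clustered")

    @property
    def category(self) -> str:
        return f"{self.location}_{self.grouping}"


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_location(
    locus: MiRNALocus, transcripts: Sequence[Transcript]
) -> tuple[str, str | None]:
    """Classify one locus as ("intragenic", host) or ("intergenic", None).

    Intragenic requires full containment in a same-strand transcript; among
    several containing transcripts the smallest span wins (id breaks ties).
    The locus chromosome must appear in the annotation.
    """
    chroms = {t.chrom for t in transcripts}
    if locus.chrom not in chroms:
        raise InputError(f"unknown chromosome {locus.chrom!r}")
    containing = [
        t for t in transcripts
        if t.chrom == locus.chrom and t.strand == locus.strand
        and t.start <= locus.start and locus.end <= t.end
    ]
    if not containing:
        return "intergenic", None
    host = min(containing, key=lambda t: (t.span, t.transcript_id))
    return "intragenic", host.transcript_id


def classify_grouping(
    loci: Sequence[MiRNALocus], max_gap: int = 10_000
) -> dict[str, str | None]:
    """Chain loci into clusters by single linkage on inter-locus gaps.

    Two loci on the same chromosome are linked iff the gap between their
    intervals (0 for overlapping loci) is strictly below ``max_gap``.
    Connected components of size >= 2 become clusters named
    ``"{chrom}:cl{k}"`` in coordinate order; singletons map to ``None``.
    """
    out: dict[str, str | None] = {}
    by_chrom: dict[str, list[MiRNALocus]] = {}
    for loc in loci:
        by_chrom.setdefault(loc.chrom, []).append(loc)
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom], key=lambda l: (l.start, l.end, l.mirna_id))
        k = 0
        component: list[MiRNALocus] = []
        max_end = None
        for loc in group + [None]:  # sentinel flushes the last component
            if loc is not None and (max_end is None or loc.start - max_end < max_gap):
                component.append(loc)
                max_end = loc.end if max_end is None else max(max_end, loc.end)
                continue
            if len(component) > 1:
                k += 1
                for member in component:
                    out[member.mirna_id] = f"{chrom}:cl{k}"
            elif component:
                out[component[0].mirna_id] = None
            if loc is not None:
                component, max_end = [loc], loc.end
    return out


def label_loci(
    loci: Sequence[MiRNALocus],
    transcripts: Sequence[Transcript],
    max_gap: int = 10_000,
) -> dict[str, ContextLabel]:
    """Full location x grouping labels for a set of loci."""
    clusters = classify_grouping(loci, max_gap)
    labels = {}
    for loc in loci:
        location, host = classify_location(loc, transcripts)
        cid = clusters[loc.mirna_id]
        labels[loc.mirna_id] = ContextLabel(
            location=location,
            grouping="clustered" if cid is not None else "single",
            host_gene=host,
            cluster_id=cid,
        )
    return labels


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def category_enrichment(
    ddr: set[str],
    all_mirnas: set[str],
    labels: Mapping[str, ContextLabel],
) -> pd.DataFrame:
    """Per-category 2x2 tables and two-sided exact p for DDR enrichment.

    miRNAs without a label (unannotated loci) are excluded from every table
    and reported in the ``unassigned`` attribute of the result. For category
    c the table is [[DDR in c, DDR not in c], [non-DDR in c, non-DDR not
    in c]].
    """
    if not ddr:
        raise InputError("empty DDR set")
    if not ddr <= all_mirnas:
        raise InputError("ddr must be a subset of all_mirnas")
    assigned = {m for m in all_mirnas if m in labels}
    ddr_a = ddr & assigned
    non_a = assigned - ddr
    rows = []
    for cat in CATEGORIES:
        in_cat = {m for m in assigned if labels[m].category == cat}
        a = len(ddr_a & in_cat)
        b = len(ddr_a) - a
        c = len(non_a & in_cat)
        d = len(non_a) - c
        p = count_test(a, a + b, c, c + d, method="exact_fisher")
        rows.append({"category": cat, "ddr_in": a, "ddr_out": b,
                     "nonddr_in": c, "nonddr_out": d,
                     "ddr_fraction": a / (a + b) if a + b else np.nan,
                     "nonddr_fraction": c / (c + d) if c + d else np.nan,
                     "p": p})
    result = pd.DataFrame(rows).set_index("category")
    result.attrs["unassigned"] = sorted(all_mirnas - assigned)
    return result


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_loci_gff3(
    path: str | Path,
    feature_types: Sequence[str] = ("miRNA_primary_transcript", "miRNA"),
    id_attr: str = "Name",
) -> list[MiRNALocus]:
    """Read miRNA loci from GFF3 (1-based closed -> 0-based half-open)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique",
        keep_order=True,
    )
    out = []
    for ftype in feature_types:
        for feat in db.features_of_type(ftype):
            name = feat.attributes.get(id_attr, [feat.id])[0]
            kind = "stemloop" if ftype == "miRNA_primary_transcript" else "mature"
            out.append(MiRNALocus(name, feat.seqid, feat.start - 1, feat.end,
                                  feat.strand, kind))
    return out


def read_transcripts_gff3(
    path: str | Path,
    feature_types: Sequence[str] = ("transcript", "mRNA", "gene"),
    id_attr: str = "ID",
) -> list[Transcript]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique",
        keep_order=True,
    )
    out = []
    for ftype in feature_types:
        for feat in db.features_of_type(ftype):
            name = feat.attributes.get(id_attr, [feat.id])[0]
            out.append(Transcript(name, feat.seqid, feat.start - 1, feat.end,
                                  feat.strand))
    return out


def read_loci_bed6(path: str | Path) -> list[MiRNALocus]:
    """Read miRNA loci from BED6 (already 0-based half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise InputError(f"BED6 needs 6 columns, got {len(fields)}")
            chrom, start, end, name, _score, strand = fields[:6]
            out.append(MiRNALocus(name, chrom, int(start), int(end), strand))
    return out


def write_labels(labels: Mapping[str, ContextLabel], path: str | Path) -> None:
    rows = [
        {"mirna": mid, "location": lab.location, "grouping": lab.grouping,
         "host_gene": lab.host_gene or "", "cluster_id": lab.cluster_id or ""}
        for mid, lab in sorted(labels.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")
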