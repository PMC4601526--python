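"""Small-RNA read processing and miRNA quantification.

Turns raw small-RNA sequencing reads into a per-sample count table over a
mature-miRNA reference: adapter trimming, length/low-complexity filtering,
exact-identity matching against the mature reference, and classification of
reads into small non-coding RNA classes (miRNA, tRNA, snoRNA, ...).

Matching is deliberately exact: a read counts toward a mature miRNA only if
its sequence is identical to the reference sequence (an optional end
tolerance allows sub/super-strings differing only at the termini). Reads
containing N never match. isomiR variants are out of scope.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("mirddr")

VALID_BASES = frozenset("ACGTN")

#: Small non-coding RNA classes recognised by :func:`classify_rna_classes`.
RNA_CLASS_NAMES = (
    "miRNA", "rRNA", "scRNA", "snRNA", "snoRNA", "tRNA", "misc_RNA", "predicted",
)


class InputError(ValueError):
    """Raised for malformed sequences or inconsistent inputs."""


class ConfigurationError(ValueError):
    """Raised for unusable configuration (e.g. an empty reference)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SmallRNARead:
    """A single small-RNA read (quality values are ignored throughout)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise InputError(f"read {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise InputError(
                f"read {self.id!r}: invalid characters {sorted(bad)!r} "
                "(alphabet is A/C/G/T/N)"
            )


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA reference entry (one arm of a stem-loop precursor)."""

    id: str
    sequence: str
    stemloop_id: str = ""
    arm: str = "unknown"  # {5p, 3p, unknown}

    def __post_init__(self) -> None:
        if not 16 <= len(self.sequence) <= 30:
            raise InputError(
                f"mature miRNA {self.id!r}: length {len(self.sequence)} outside [16, 30]"
            )
        if self.arm not in ("5p", "3p", "unknown"):
            raise InputError(f"mature miRNA {self.id!r}: arm {self.arm!r}")


@dataclass
class AnnotationClass:
    """A named class of small non-coding RNAs with its member sequences."""

    class_name: str
    sequences: set[str]

    def __post_init__(self) -> None:
        if self.class_name not in RNA_CLASS_NAMES:
            raise InputError(f"unknown RNA class {self.class_name!r}")


@dataclass
class CountTable:
    """miRNA x sample count matrix with per-sample metadata.

    ``counts`` is a DataFrame indexed by miRNA id with one column per sample.
    ``sample_meta`` is indexed by sample id with columns
    ``cell_line`` / ``genotype`` / ``time_h`` / ``replicate``.
    ``library_sizes`` holds, per sample, the number of reads mapped to known
    miRNAs; for a raw table this equals the column sum.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    library_sizes: pd.Series
    normalized: bool = False

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise InputError("negative counts")
        missing = set(self.counts.columns) - set(self.sample_meta.index)
        if missing:
            raise InputError(f"samples without metadata: {sorted(missing)}")
        if (self.library_sizes.reindex(self.counts.columns) <= 0).any():
            raise InputError("non-positive library size")
        if not self.normalized:
            colsums = self.counts.sum(axis=0)
            if not np.allclose(colsums, self.library_sizes[self.counts.columns]):
                raise InputError("raw table: library sizes must equal column sums")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def copy(self) -> "CountTable":
        return CountTable(
            self.counts.copy(), self.sample_meta.copy(),
            self.library_sizes.copy(), self.normalized,
        )


# ---------------------------------------------------------------------------
# Adapter trimming
# ---------------------------------------------------------------------------

def trim_adapter(
    read: SmallRNARead, adapter: str, min_overlap: int = 6
) -> SmallRNARead | None:
    """Trim the 3' adapter from a read.

    The insert is the read prefix preceding the left-most full occurrence of
    the adapter; failing that, a read suffix matching an adapter prefix of
    length >= ``min_overlap`` counts as adapter evidence. Reads with no
    evidence are returned unchanged. Returns ``None`` (rejection) when the
    insert is empty, i.e. the read is adapter from position 0.
    """
    if not adapter:
        raise InputError("empty adapter")
    if min_overlap < 1:
        raise InputError("min_overlap must be >= 1")
    bad = set(adapter) - VALID_BASES
    if bad:
        raise InputError(f"adapter: invalid characters {sorted(bad)!r}")

    seq = read.sequence
    pos = seq.find(adapter)
    if pos == -1:
        # terminal overlap: longest read-suffix == adapter-prefix, >= min_overlap
        max_ov = min(len(seq), len(adapter) - 1)
        pos = -1
        for ov in range(max_ov, min_overlap - 1, -1):
            if seq.endswith(adapter[:ov]):
                pos = len(seq) - ov
                break
        if pos == -1:
            return read
    if pos == 0:
        return None
    return SmallRNARead(read.id, seq[:pos])


# ---------------------------------------------------------------------------
# Read filtering
# ---------------------------------------------------------------------------

def _low_complexity(seq: str, max_mono_frac: float, max_homopolymer: int) -> bool:
    counts = Counter(seq)
    if max(counts.values()) / len(seq) > max_mono_frac:
        return True
    run = best = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best >= max_homopolymer


def filter_reads(
    reads: Sequence[SmallRNARead],
    min_len: int = 18,
    max_len: int = 30,
    max_mono_frac: float = 0.8,
    max_homopolymer: int = 15,
) -> tuple[list[SmallRNARead], dict[str, int]]:
    """Drop short/long and low-complexity (polyN) reads.

    A read is low-complexity when its most frequent base exceeds
    ``max_mono_frac`` of its length or it contains a homopolymer run of
    ``max_homopolymer`` nt or more. Rejections are counted by the first
    failing rule, length before complexity.

    Returns ``(retained, {"length": n, "complexity": m})``.
    """
    if min_len > max_len:
        raise InputError("min_len > max_len")
    kept: list[SmallRNARead] = []
    rejected = {"length": 0, "complexity": 0}
    for read in reads:
        n = len(read.sequence)
        if n < min_len or n > max_len:
            rejected["length"] += 1
        elif _low_complexity(read.sequence, max_mono_frac, max_homopolymer):
            rejected["complexity"] += 1
        else:
            kept.append(read)
    return kept, rejected


# ---------------------------------------------------------------------------
# Exact quantification
# ---------------------------------------------------------------------------

def _match_ids(
    seq: str, by_seq: dict[str, list[str]], end_tolerance: int
) -> list[str]:
    """Reference ids matched by ``seq`` under exact or end-tolerant identity."""
    if "N" in seq:
        return []  # N never matches
    hits = by_seq.get(seq)
    if hits is not None:
        return hits
    if end_tolerance <= 0:
        return []
    out: list[str] = []
    for ref_seq, ids in by_seq.items():
        d = len(seq) - len(ref_seq)
        if d > 0 and d <= end_tolerance:
            # read is a super-string: reference inside, overhang only at ends
            for off in range(d + 1):
                if seq[off:off + len(ref_seq)] == ref_seq:
                    out.extend(ids)
                    break
        elif d < 0 and -d <= end_tolerance:
            for off in range(-d + 1):
                if ref_seq[off:off + len(seq)] == seq:
                    out.extend(ids)
                    break
    return out


def quantify_exact(
    reads: Sequence[SmallRNARead],
    reference: Sequence[MatureMiRNA],
    sample_id: str,
    end_tolerance: int = 0,
) -> tuple[pd.Series, int, list[str]]:
    """Count reads against the mature reference at 100% identity.

    A read increments a reference entry iff its sequence is identical to the
    mature sequence (or, with ``end_tolerance`` > 0, a sub/super-string whose
    overhang at either end totals at most that many nucleotides). A read whose
    sequence equals k > 1 reference entries (identical matures, e.g.
    miR-365a/b-3p) increments all k and is logged as ambiguous.

    Returns ``(counts, n_unmatched, ambiguous_read_ids)`` where ``counts`` is
    indexed by reference id and the column library size — the number of
    matched reads — is ``counts.sum() - duplicated ambiguous increments``,
    i.e. simply the number of reads that matched at least one entry.
    """
    if not reference:
        raise ConfigurationError("empty mature-miRNA reference")
    ids = [m.id for m in reference]
    if len(set(ids)) != len(ids):
        raise ConfigurationError("duplicate ids in mature reference")
    by_seq: dict[str, list[str]] = {}
    for m in reference:
        by_seq.setdefault(m.sequence, []).append(m.id)

    counts = pd.Series(0, index=ids, name=sample_id, dtype=np.int64)
    unmatched = 0
    ambiguous: list[str] = []
    for read in reads:
        hits = _match_ids(read.sequence, by_seq, end_tolerance)
        if not hits:
            unmatched += 1
            continue
        if len(hits) > 1:
            ambiguous.append(read.id)
        counts[hits] += 1
    if ambiguous:
        logger.info(
            "%s: %d ambiguous reads incremented multiple identical matures",
            sample_id, len(ambiguous),
        )
    return counts, unmatched, ambiguous


def classify_rna_classes(
    reads: Sequence[SmallRNARead],
    classes: Sequence[AnnotationClass],
) -> dict[str, float]:
    """Fraction of reads per small-RNA class (exact sequence membership).

    Classes are tried in the given order (priority on overlap); reads matching
    none fall into ``"unannotated"``. Fractions sum to 1 over all reads; an
    empty read list yields an empty dict.
    """
    if not reads:
        return {}
    fractions = {c.class_name: 0 for c in classes}
    fractions["unannotated"] = 0
    for read in reads:
        for c in classes:
            if read.sequence in c.sequences:
                fractions[c.class_name] += 1
                break
        else:
            fractions["unannotated"] += 1
    n = len(reads)
    return {k: v / n for k, v in fractions.items()}


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_reads(path: str | Path) -> list[SmallRNARead]:
    """Read small-RNA reads from FASTQ or FASTA (by extension; Phred ignored)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    return [
        SmallRNARead(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), fmt)
    ]


def read_mature_reference(path: str | Path) -> list[MatureMiRNA]:
    """Read a mature-miRNA reference FASTA.

    Header convention: ``>id [stemloop_id]``; the arm is inferred from a
    ``-5p``/``-3p`` suffix on the id when present. U is converted to T so
    miRBase-style RNA sequences are accepted.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        parts = rec.description.split()
        stemloop = parts[1] if len(parts) > 1 else _infer_stemloop(rec.id)
        arm = "5p" if rec.id.endswith("-5p") else "3p" if rec.id.endswith("-3p") else "unknown"
        out.append(MatureMiRNA(rec.id, seq, stemloop, arm))
    return out


def _infer_stemloop(mature_id: str) -> str:
    for suffix in ("-5p", "-3p"):
        if mature_id.endswith(suffix):
            return mature_id[: -len(suffix)]
    return mature_id


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a TSV sample sheet (sample, cell_line, genotype, time_h, replicate)."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample": str})
    required = {"sample", "cell_line", "genotype", "time_h", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise InputError(f"sample sheet missing columns: {sorted(missing)}")
    return meta.set_index("sample")


def quantify_samples(
    reads_by_sample: dict[str, Sequence[SmallRNARead]],
    reference: Sequence[MatureMiRNA],
    sample_meta: pd.DataFrame,
    end_tolerance: int = 0,
) -> CountTable:
    """Build a raw CountTable by quantifying each sample's filtered reads."""
    cols = {}
    for sample_id, reads in reads_by_sample.items():
        counts, unmatched, _ = quantify_exact(
            reads, reference, sample_id, end_tolerance
        )
        logger.info("%s: %d matched, %d unmatched", sample_id,
                    len(reads) - unmatched, unmatched)
        cols[sample_id] = counts
    counts = pd.DataFrame(cols)
    return CountTable(
        counts=counts,
        sample_meta=sample_meta.loc[list(cols)],
        library_sizes=counts.sum(axis=0).astype(float),
    )


def write_count_table(table: CountTable, path: str | Path) -> None:
    """Write the count matrix as TSV (rows = miRNA ids, columns = samples)."""
    table.counts.to_csv(path, sep="\t", index_label="mirna", lineterminator="\n")


def read_count_table(
    counts_path: str | Path, sample_sheet_path: str | Path, normalized: bool = False
) -> CountTable:
    counts = pd.read_csv(counts_path, sep="\t", index_col="mirna")
    meta = read_sample_sheet(sample_sheet_path)
    return CountTable(
        counts=counts,
        sample_meta=meta.loc[list(counts.columns)],
        library_sizes=counts.sum(axis=0).astype(float),
        normalized=normalized,
    )
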