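"""Synthetic study generator: counts, reads, annotations and promoters.

Emulates the study design end-to-end so every pipeline stage can be tested
against known ground truth: 3 cell lines (one of them TP53-null) x three
time points (0/4/24 h after damage) x 2 technical replicates of miRNA
counts; a mature-miRNA reference containing deliberate redundancies (both
arms of a stem-loop, identical mature sequences under different ids); miRNA
loci laid out as intragenic/intergenic singles and <10 kb clusters inside a
pseudo-genome; and per-species promoter sequences with planted p53-like
motif clusters across a panel of pseudo-species.

Statistical structure of the counts: baseline abundances are log-normal;
each (cell line, time) condition gets one negative-binomial biological draw
per miRNA (gamma-Poisson; dispersion 0 degenerates to Poisson), and the two
technical replicates are binomial thinnings of that draw — replicates share
the biological noise, as repeated library preparations from one RNA sample
do. Spiked miRNAs follow the four kinetic archetypes (induced or repressed,
peaking early at 4 h or late at 24 h); effects flagged p53-dependent are
zeroed in the TP53-null line. All randomness flows from a single seed, so a
fixed configuration is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .context import ContextLabel, MiRNALocus, Transcript
from .ingest import CountTable, InputError, MatureMiRNA, SmallRNARead
from .motifs import PWM

__all__ = [
    "SimulationConfig", "SpikeConfig", "GeometryConfig", "MotifPlantConfig",
    "GroundTruth", "functional_representatives", "simulate_reference",
    "simulate_counts", "simulate_reads",
    "simulate_annotation", "simulate_promoters", "demo_pwms", "write_fastq",
    "write_gff3",
]

#: Kinetic archetypes: fraction of the peak effect applied at (4 h, 24 h).
ARCHETYPE_SHAPES = {
    "A": (1.0, 0.4),    # induced, early peak
    "B": (0.4, 1.0),    # induced, late peak
    "C": (-1.0, -0.4),  # repressed, early peak
    "D": (-0.4, -1.0),  # repressed, late peak
}


@dataclass(frozen=True)
class SpikeConfig:
    """How many miRNAs to spike per kinetic archetype and how strongly."""

    n_per_cluster: int = 10
    effect: float = 2.0  # log2 units at the peak time (4-fold)
    p53_dependent_fraction_induced: float = 0.75
    p53_dependent_fraction_repressed: float = 0.25


@dataclass(frozen=True)
class GeometryConfig:
    """Counts of loci per genomic category; must sum to n_mirnas."""

    intragenic_single: int = 140
    intragenic_clusters: int = 15
    intragenic_cluster_size: int = 4
    intergenic_single: int = 70
    intergenic_clusters: int = 10
    intergenic_cluster_size: int = 3

    @property
    def total(self) -> int:
        return (self.intragenic_single
                + self.intragenic_clusters * self.intragenic_cluster_size
                + self.intergenic_single
                + self.intergenic_clusters * self.intergenic_cluster_size)

    @staticmethod
    def singles(n: int) -> "GeometryConfig":
        """All-intergenic-singles geometry for count-only simulations."""
        return GeometryConfig(intragenic_single=0, intragenic_clusters=0,
                              intergenic_single=n, intergenic_clusters=0)


@dataclass(frozen=True)
class MotifPlantConfig:
    """Planted p53 motif clusters in the synthetic promoters."""

    n_planted: int = 20
    sites_per_feature: int = 3
    species_coverage: int = 6   # of n_species species carry the plant
    promoter_length: int = 1000
    gc: float = 0.41
    temperature: float = 0.5    # < 1 sharpens consensus sampling


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_mirnas: int = 300
    n_species: int = 10
    library_size_mean: int = 150_000
    library_size_cv: float = 0.1
    dispersion: float = 0.005   # NB: var = m + dispersion * m^2; 0 = Poisson
    times: tuple[int, ...] = (0, 4, 24)
    n_replicates: int = 2
    cell_lines: tuple[tuple[str, str], ...] = (
        ("MCF10A", "WT"), ("HCT116", "WT"), ("HCT116", "TP53KO"),
    )
    spikes: SpikeConfig = SpikeConfig()
    geometry: GeometryConfig = GeometryConfig()
    motif_plant: MotifPlantConfig = MotifPlantConfig()
    n_arm_pairs: int = 2        # stem-loops contributing both a 5p and a 3p arm
    n_identical_pairs: int = 2  # id pairs sharing one mature sequence

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise InputError("dispersion must be >= 0")
        if self.geometry.total != self.n_mirnas:
            raise InputError(
                f"infeasible geometry: category counts total {self.geometry.total}"
                f" != n_mirnas {self.n_mirnas}"
            )


@dataclass
class GroundTruth:
    """Complete bookkeeping for every simulated entity."""

    mirnas: pd.DataFrame               # archetype, effects, p53_dependent, ...
    reference: list[MatureMiRNA] = field(default_factory=list)
    expected_merged: pd.DataFrame | None = None  # expected merged counts
    context: dict[str, ContextLabel] = field(default_factory=dict)
    loci: list[MiRNALocus] = field(default_factory=list)
    transcripts: list[Transcript] = field(default_factory=list)
    planted_motifs: dict[str, dict[str, list[tuple[int, str]]]] = field(
        default_factory=dict
    )

    def spiked(self, archetypes: Sequence[str] = ("A", "B", "C", "D")) -> list[str]:
        m = self.mirnas
        return sorted(m.index[m["archetype"].isin(archetypes)])


# ---------------------------------------------------------------------------
# Reference
# ---------------------------------------------------------------------------

def functional_representatives(
    ids: Sequence[str], reference: Sequence[MatureMiRNA]
) -> list[str]:
    """Collapse a set of mature ids to one functional species per group.

    Mirrors the redundancy rules deterministically: when both arms of a
    stem-loop are present keep the 5p arm (the dominant one in this
    generator), and keep the lexicographically smallest id among identical
    mature sequences.
    """
    by_id = {m.id: m for m in reference}
    keep = set(ids)
    by_stem: dict[str, list[str]] = {}
    for mid in sorted(keep):
        by_stem.setdefault(by_id[mid].stemloop_id, []).append(mid)
    for members in by_stem.values():
        if len(members) > 1:
            five = [m for m in members if by_id[m].arm == "5p"]
            best = five[0] if five else min(members)
            keep -= {m for m in members if m != best}
    by_seq: dict[str, list[str]] = {}
    for mid in sorted(keep):
        by_seq.setdefault(by_id[mid].sequence, []).append(mid)
    for members in by_seq.values():
        keep -= set(members[1:])
    return sorted(keep)


def _random_mature_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def simulate_reference(cfg: SimulationConfig,
                       rng: np.random.Generator) -> list[MatureMiRNA]:
    """A mature reference with arm-pair and identical-sequence redundancies.

    The first ``n_arm_pairs`` stem-loops contribute both arms (ids ``-5p``
    and ``-3p``); the next ``n_identical_pairs`` id pairs (suffix ``a``/``b``)
    share one mature sequence, like miR-365a/b-3p. All other entries are
    independent 5p matures. Sequences are unique unless shared on purpose.
    """
    seen: set[str] = set()

    def fresh(length: int) -> str:
        while True:
            s = _random_mature_seq(rng, length)
            if s not in seen:
                seen.add(s)
                return s

    out: list[MatureMiRNA] = []
    k = 0
    for i in range(cfg.n_arm_pairs):
        stem = f"sim-mir-{k:04d}"
        length = int(rng.integers(20, 24))
        out.append(MatureMiRNA(f"{stem}-5p", fresh(length), stem, "5p"))
        out.append(MatureMiRNA(f"{stem}-3p", fresh(length), stem, "3p"))
        k += 1
    for i in range(cfg.n_identical_pairs):
        seq = fresh(int(rng.integers(20, 24)))
        for tag in "ab":
            stem = f"sim-mir-{k:04d}{tag}"
            out.append(MatureMiRNA(f"{stem}-3p", seq, stem, "3p"))
        k += 1
    while len(out) < cfg.n_mirnas:
        stem = f"sim-mir-{k:04d}"
        out.append(MatureMiRNA(f"{stem}-5p", fresh(int(rng.integers(20, 24))),
                               stem, "5p"))
        k += 1
    return out[: cfg.n_mirnas]


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """Negative-binomial via gamma-Poisson; dispersion 0 gives Poisson."""
    if dispersion == 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def simulate_counts(
    cfg: SimulationConfig = SimulationConfig(),
) -> tuple[CountTable, GroundTruth]:
    """Simulate the full raw count table plus its ground truth.

    Spiked miRNAs carry 2^effect expected fold change at their peak time;
    redundant reference entries (arm pairs, identical-sequence pairs) are
    spiked into the early-induced archetype so the downstream redundancy
    rules have work to do. Spike baselines are drawn from the upper part of
    the abundance distribution (at or above the 40th percentile), as the
    strongly regulated species of interest are well-expressed ones.
    """
    rng = np.random.default_rng(cfg.seed)
    reference = simulate_reference(cfg, rng)
    ids = [m.id for m in reference]
    n = len(ids)

    weights = rng.lognormal(mean=math.log(50.0), sigma=1.3, size=n)

    # --- spike assignment ----------------------------------------------
    # the redundant entries (arm pairs + identical pairs) sit first in the
    # reference by construction
    special = ids[: 2 * (cfg.n_arm_pairs + cfg.n_identical_pairs)]
    archetype = pd.Series("null", index=ids, dtype=object)
    pool = [i for i in ids if i not in special]
    order = list(rng.permutation(len(pool)))
    cursor = 0
    for label in "ABCD":
        want = cfg.spikes.n_per_cluster
        take: list[str] = []
        if label == "A":
            take.extend(special)  # redundant entries ride the early-induced set
        while len(take) < want and cursor < len(order):
            take.append(pool[order[cursor]])
            cursor += 1
        archetype[take] = label

    floor = np.quantile(weights, 0.4)
    spiked_mask = (archetype != "null").to_numpy()
    weights = np.where(spiked_mask, np.maximum(weights, floor), weights)
    # star (3p) arms express well below their 5p siblings, as in real
    # libraries, so the best-coverage redundancy rule resolves to the 5p arm
    for i in range(cfg.n_arm_pairs):
        weights[2 * i + 1] = 0.2 * weights[2 * i]

    eff = pd.DataFrame(0.0, index=ids, columns=[4, 24])
    for label, (f4, f24) in ARCHETYPE_SHAPES.items():
        sel = archetype == label
        eff.loc[sel, 4] = f4 * cfg.spikes.effect
        eff.loc[sel, 24] = f24 * cfg.spikes.effect

    p53_dep = pd.Series(False, index=ids)
    for labels, frac in ((("A", "B"), cfg.spikes.p53_dependent_fraction_induced),
                         (("C", "D"), cfg.spikes.p53_dependent_fraction_repressed)):
        for label in labels:
            members = sorted(archetype.index[archetype == label])
            k = int(round(frac * len(members)))
            p53_dep[members[:k]] = True

    # --- draws -----------------------------------------------------------
    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    expected_cols: dict[str, np.ndarray] = {}
    w = weights
    for cell, geno in cfg.cell_lines:
        for t in cfg.times:
            e = eff[t].to_numpy() if t in eff.columns else np.zeros(n)
            if geno == "TP53KO":
                e = np.where(p53_dep.to_numpy(), 0.0, e)
            mu = w * np.exp2(e)
            p = mu / mu.sum()
            lib = rng.normal(cfg.library_size_mean,
                             cfg.library_size_cv * cfg.library_size_mean,
                             size=cfg.n_replicates)
            lib = np.maximum(lib, 0.1 * cfg.library_size_mean).round()
            total = float(lib.sum())
            y = _nb_draw(rng, p * total, cfg.dispersion)
            expected_cols[f"{cell}_{geno}_t{t}h"] = p * total
            remaining = y.copy()
            for r in range(cfg.n_replicates):
                if r == cfg.n_replicates - 1:
                    x = remaining
                else:
                    q = lib[r] / lib[r:].sum()
                    x = rng.binomial(remaining, q)
                remaining = remaining - x
                name = f"{cell}_{geno}_t{t}h_r{r + 1}"
                cols[name] = x.astype(np.int64)
                meta_rows.append({"sample": name, "cell_line": cell,
                                  "genotype": geno, "time_h": t,
                                  "replicate": r + 1})

    counts = pd.DataFrame(cols, index=ids)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    table = CountTable(counts=counts, sample_meta=meta,
                       library_sizes=counts.sum(axis=0).astype(float))

    truth_frame = pd.DataFrame({
        "archetype": archetype,
        "effect_4h": eff[4],
        "effect_24h": eff[24],
        "p53_dependent": p53_dep,
        "baseline_weight": w,
    })
    truth = GroundTruth(
        mirnas=truth_frame,
        reference=reference,
        expected_merged=pd.DataFrame(expected_cols, index=ids),
    )
    return table, truth


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def simulate_reads(
    table: CountTable,
    reference: Sequence[MatureMiRNA],
    adapter: str,
    seed: int = 0,
    contaminant_polyn_fraction: float = 0.0,
    contaminant_short_fraction: float = 0.0,
) -> dict[str, list[SmallRNARead]]:
    """Emit reads (mature sequence + adapter) realizing an integer count table.

    With zero contaminant fractions, trimming + filtering + exact
    quantification reproduces the table exactly. ``contaminant_polyn``
    reads are 22-mer poly(A) inserts; ``contaminant_short`` reads are
    10-mer random inserts — both removed by the standard filters.
    """
    rng = np.random.default_rng(seed)
    if not np.allclose(table.counts, table.counts.round()):
        raise InputError("read simulation needs integer counts")
    seq_of = {m.id: m.sequence for m in reference}
    out: dict[str, list[SmallRNARead]] = {}
    for sample in table.sample_ids:
        reads: list[SmallRNARead] = []
        k = 0
        for mid, c in table.counts[sample].items():
            for _ in range(int(c)):
                reads.append(SmallRNARead(f"{sample}:{k}", seq_of[mid] + adapter))
                k += 1
        n_real = len(reads)
        for _ in range(int(round(contaminant_polyn_fraction * n_real))):
            reads.append(SmallRNARead(f"{sample}:{k}", "A" * 22 + adapter))
            k += 1
        for _ in range(int(round(contaminant_short_fraction * n_real))):
            insert = _random_mature_seq(rng, 10)
            reads.append(SmallRNARead(f"{sample}:{k}", insert + adapter))
            k += 1
        out[sample] = reads
    return out


def write_fastq(reads: Sequence[SmallRNARead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def simulate_annotation(
    cfg: SimulationConfig = SimulationConfig(),
    seed: int | None = None,
) -> tuple[list[MiRNALocus], list[Transcript], dict[str, ContextLabel]]:
    """Place miRNA loci and host transcripts on a pseudo-chromosome.

    Intra-cluster gaps are drawn below 10 kb, inter-unit gaps at or above
    12 kb; intragenic units sit strictly inside a same-strand transcript.
    Every third intergenic single additionally gets an opposite-strand
    covering transcript, which must still classify as intergenic. Returns
    (loci, transcripts, ground-truth labels).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    geo = cfg.geometry
    # regenerate the reference ids deterministically (same first draws as
    # simulate_counts makes from a fresh generator at cfg.seed)
    ids = [m.id for m in simulate_reference(cfg, np.random.default_rng(cfg.seed))]

    units: list[tuple[str, int]] = (  # (category, unit size)
        [("intragenic", 1)] * geo.intragenic_single
        + [("intragenic", geo.intragenic_cluster_size)] * geo.intragenic_clusters
        + [("intergenic", 1)] * geo.intergenic_single
        + [("intergenic", geo.intergenic_cluster_size)] * geo.intergenic_clusters
    )
    loci: list[MiRNALocus] = []
    transcripts: list[Transcript] = []
    labels: dict[str, ContextLabel] = {}
    chrom = "chr1"
    pos = 10_000
    idx = 0
    host_k = 0
    decoy_k = 0
    cluster_k = 0
    intergenic_single_k = 0
    for category, size in units:
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        unit: list[MiRNALocus] = []
        for j in range(size):
            length = int(rng.integers(60, 120))
            loc = MiRNALocus(ids[idx], chrom, pos, pos + length, strand)
            unit.append(loc)
            loci.append(loc)
            idx += 1
            if j < size - 1:
                pos = loc.end + int(rng.integers(200, 9_000))
            else:
                pos = loc.end
        cluster_id = None
        if size > 1:
            cluster_k += 1
            cluster_id = f"{chrom}:cl{cluster_k}"
        if category == "intragenic":
            host_k += 1
            pad_l = int(rng.integers(1_000, 3_000))
            pad_r = int(rng.integers(1_000, 3_000))
            host = Transcript(f"host{host_k:04d}", chrom,
                              unit[0].start - pad_l, unit[-1].end + pad_r, strand)
            transcripts.append(host)
            for loc in unit:
                labels[loc.mirna_id] = ContextLabel(
                    "intragenic", "clustered" if cluster_id else "single",
                    host_gene=host.transcript_id, cluster_id=cluster_id)
        else:
            if size == 1:
                intergenic_single_k += 1
                if intergenic_single_k % 3 == 0:
                    decoy_k += 1
                    anti = "-" if strand == "+" else "+"
                    transcripts.append(Transcript(
                        f"decoy{decoy_k:04d}", chrom,
                        unit[0].start - 500, unit[-1].end + 500, anti))
            for loc in unit:
                labels[loc.mirna_id] = ContextLabel(
                    "intergenic", "clustered" if cluster_id else "single",
                    host_gene=None, cluster_id=cluster_id)
        pos += int(rng.integers(12_000, 30_000))
    return loci, transcripts, labels


def write_gff3(
    loci: Sequence[MiRNALocus] | None,
    transcripts: Sequence[Transcript] | None,
    path: str | Path,
) -> None:
    """Write loci and/or transcripts as GFF3 (1-based closed on output)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in transcripts or []:
            fh.write(
                f"{t.chrom}\tmirddr_sim\ttranscript\t{t.start + 1}\t{t.end}\t."
                f"\t{t.strand}\t.\tID={t.transcript_id};Name={t.transcript_id}\n"
            )
        for l in loci or []:
            fh.write(
                f"{l.chrom}\tmirddr_sim\tmiRNA_primary_transcript\t{l.start + 1}"
                f"\t{l.end}\t.\t{l.strand}\t.\tID={l.mirna_id};Name={l.mirna_id}\n"
            )


# ---------------------------------------------------------------------------
# Promoters
# ---------------------------------------------------------------------------

def demo_pwms(seed: int = 7, n: int = 3, length: int = 12,
              sharpness: float = 0.7) -> list[PWM]:
    """Synthetic p53-like PWMs for simulations and tests.

    These are stand-ins constructed here (the real curated p53 matrices are
    licensed config entries, not shipped data): each has a random consensus
    with ``sharpness`` probability on the consensus base and the remainder
    spread over the other bases.
    """
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n):
        cons = rng.integers(0, 4, size=length)
        m = np.full((4, length), (1 - sharpness) / 3)
        m[cons, np.arange(length)] = sharpness
        out.append(PWM(f"synthP53-{k + 1}", m))
    return out


def _sample_site(pwm: PWM, rng: np.random.Generator, temperature: float) -> str:
    p = pwm.matrix ** (1.0 / temperature)
    p = p / p.sum(axis=0, keepdims=True)
    return "".join(
        "ACGT"[rng.choice(4, p=p[:, j])] for j in range(pwm.length)
    )


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def simulate_promoters(
    cfg: SimulationConfig,
    pwms: Sequence[PWM],
    features: Sequence[str] | None = None,
    planted_features: Sequence[str] | None = None,
    seed: int | None = None,
) -> tuple[dict[str, dict[str, str]], dict[str, dict[str, list[tuple[int, str]]]]]:
    """Per-species promoter FASTA contents with planted motif clusters.

    Backgrounds are i.i.d. with the configured GC content. Each planted
    feature receives ``sites_per_feature`` consensus-sampled, non-overlapping
    sites (random PWM and strand) in ``species_coverage`` randomly chosen
    species. Returns ``(regions, planted)`` with
    ``regions[species][feature] = sequence`` and
    ``planted[feature][species] = [(position, motif_id), ...]``.
    """
    mp = cfg.motif_plant
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    if any(p.length > mp.promoter_length for p in pwms):
        raise InputError("motif site longer than the promoter region")
    if features is None:
        features = [f"feat{i:04d}" for i in range(cfg.n_mirnas)]
    features = list(features)
    if planted_features is None:
        k = min(mp.n_planted, len(features))
        planted_features = [features[i] for i in
                            rng.choice(len(features), size=k, replace=False)]
    species = [f"species{s + 1:02d}" for s in range(cfg.n_species)]
    gc = mp.gc
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    regions: dict[str, dict[str, str]] = {sp: {} for sp in species}
    planted: dict[str, dict[str, list[tuple[int, str]]]] = {}
    for sp in species:
        for fid in features:
            codes = rng.choice(4, size=mp.promoter_length, p=base_p)
            regions[sp][fid] = "".join("ACGT"[c] for c in codes)
    for fid in planted_features:
        cov = min(mp.species_coverage, cfg.n_species)
        chosen = [species[i] for i in
                  rng.choice(cfg.n_species, size=cov, replace=False)]
        planted[fid] = {}
        for sp in chosen:
            seq = list(regions[sp][fid])
            occupied: list[tuple[int, int]] = []
            sites: list[tuple[int, str]] = []
            for _ in range(mp.sites_per_feature):
                pwm = pwms[int(rng.integers(0, len(pwms)))]
                site = _sample_site(pwm, rng, mp.temperature)
                if rng.integers(0, 2):
                    site = site.translate(_COMPLEMENT)[::-1]
                for _attempt in range(1000):
                    pos = int(rng.integers(0, mp.promoter_length - len(site) + 1))
                    if all(pos + len(site) <= s or pos >= e
                           for s, e in occupied):
                        break
                else:  # pragma: no cover - only for absurdly dense plants
                    raise InputError("could not place non-overlapping sites")
                occupied.append((pos, pos + len(site)))
                seq[pos:pos + len(site)] = site
                sites.append((pos, pwm.motif_id))
            regions[sp][fid] = "".join(seq)
            planted[fid][sp] = sorted(sites)
    return regions, planted


def write_region_fastas(
    regions: Mapping[str, Mapping[str, str]], directory: str | Path
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for species, feats in regions.items():
        with open(directory / f"{species}.fa", "w") as fh:
            for fid in sorted(feats):
                fh.write(f">{fid}\n{feats[fid]}\n")
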