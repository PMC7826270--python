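"""Synthetic genomes, phased SNPs, deletion spiking, meioses and paired-end reads.

This module is the stand-in for the wet side of a recombinant-progeny
whole-genome-sequencing experiment in *Drosophila*: two isogenized parental
haplotypes that differ at phased SNP markers, female meioses in which
double-strand breaks (DSBs) resolve as crossovers (CO), noncrossover gene
conversions (NCO-GC) or non-homologous end joining (NHEJ), transmission of
one of the four chromatids to each offspring, a male haplotype contribution
(autosomes plus Y, no X), and an Illumina-style paired-end read simulator.

Coordinates are 0-based half-open throughout; sequences live as uint8 code
arrays (see :mod:`meioscan._encode`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._encode import decode, encode

__all__ = [
    "DEFAULT_CHROM_SPEC",
    "ReferenceGenome",
    "SnpTable",
    "MaleGenome",
    "ParentalGenomes",
    "MeiosisParams",
    "NHEJ_PRESETS",
    "MeiosisTruth",
    "MeiosisResult",
    "ReadSimParams",
    "ReadSet",
    "SpikeResult",
    "Haplotype",
    "build_reference",
    "place_snps",
    "spike_deletions",
    "make_male_genome",
    "simulate_meiosis",
    "simulate_reads",
]

#: Desk-scale stand-ins for the chromosome arms carrying markers in the cross.
DEFAULT_CHROM_SPEC = [
    ("X", 100_000, "X"),
    ("2", 120_000, "A"),
    ("3", 120_000, "A"),
    ("Y", 40_000, "Y"),
]


# ---------------------------------------------------------------------------
# reference genome


@dataclass
class ReferenceGenome:
    """An ordered set of chromosomes with sex flags ('A', 'X' or 'Y')."""

    names: list[str]
    seqs: dict[str, np.ndarray]
    sex: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate chromosome names")
        for name in self.names:
            seq = self.seqs[name]
            if seq.size == 0:
                raise ValueError(f"zero-length chromosome {name!r}")
            if seq.max(initial=0) > 3:
                raise ValueError(f"non-ACGT codes in chromosome {name!r}")
            if self.sex[name] not in ("A", "X", "Y"):
                raise ValueError(f"bad sex flag for {name!r}")

    def length(self, name: str) -> int:
        return int(self.seqs[name].size)

    def total_length(self, names=None) -> int:
        names = self.names if names is None else names
        return sum(self.length(n) for n in names)

    def female_chroms(self) -> list[str]:
        """Chromosomes of the female genome (everything but the Y)."""
        return [n for n in self.names if self.sex[n] != "Y"]

    def autosomes(self) -> list[str]:
        return [n for n in self.names if self.sex[n] == "A"]

    def x_name(self) -> str | None:
        return next((n for n in self.names if self.sex[n] == "X"), None)

    def y_name(self) -> str | None:
        return next((n for n in self.names if self.sex[n] == "Y"), None)

    def sequence(self, name: str) -> str:
        return decode(self.seqs[name])


def build_reference(chrom_spec, seed: int) -> ReferenceGenome:
    """Generate a reference genome with uniform base composition.

    Parameters
    ----------
    chrom_spec : list of (name, length, sex_flag)
        ``sex_flag`` is 'A' (autosome), 'X' or 'Y'.
    seed : int
        Seed; the same seed yields bit-identical sequences.
    """
    rng = np.random.default_rng(seed)
    names, seqs, sex = [], {}, {}
    for name, length, flag in chrom_spec:
        length = int(length)
        if length <= 0:
            raise ValueError(f"zero length for chromosome {name!r}")
        if name in seqs:
            raise ValueError(f"duplicate chromosome name {name!r}")
        names.append(name)
        seqs[name] = rng.integers(0, 4, size=length, dtype=np.uint8)
        sex[name] = flag
    return ReferenceGenome(names, seqs, sex)


# ---------------------------------------------------------------------------
# SNPs


@dataclass
class SnpTable:
    """Phased biallelic markers distinguishing two parental haplotypes.

    ``df`` columns: chrom, pos (0-based), allele_a, allele_b (single bases);
    allele_a is the reference base. Positions are strictly increasing within
    each chromosome.
    """

    df: pd.DataFrame
    mean_spacing: float

    def __post_init__(self) -> None:
        self._cache: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if (self.df["allele_a"] == self.df["allele_b"]).any():
            raise ValueError("allele_a must differ from allele_b")

    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def _arrays(self, chrom: str):
        if chrom not in self._cache:
            sub = self.df[self.df["chrom"] == chrom]
            pos = sub["pos"].to_numpy(dtype=np.int64)
            a = encode("".join(sub["allele_a"]))
            b = encode("".join(sub["allele_b"]))
            self._cache[chrom] = (pos, a, b)
        return self._cache[chrom]

    def positions(self, chrom: str) -> np.ndarray:
        return self._arrays(chrom)[0]

    def codes_a(self, chrom: str) -> np.ndarray:
        return self._arrays(chrom)[1]

    def codes_b(self, chrom: str) -> np.ndarray:
        return self._arrays(chrom)[2]

    def __len__(self) -> int:
        return len(self.df)


def place_snps(
    ref: ReferenceGenome,
    mean_spacing: float = 500.0,
    seed: int = 0,
    chroms=None,
    exclude: SnpTable | None = None,
) -> SnpTable:
    """Place SNPs with geometric (memoryless) inter-marker spacing.

    The alternate allele differs from the reference base at each site.
    ``exclude`` masks positions already used by another marker set (marker
    sites are chosen to be informative between the two parents of a cross).
    """
    if mean_spacing < 2:
        raise ValueError("mean_spacing must be >= 2")
    rng = np.random.default_rng(seed)
    chroms = ref.names if chroms is None else list(chroms)
    rows = []
    for chrom in chroms:
        length = ref.length(chrom)
        banned = set()
        if exclude is not None and chrom in exclude.chroms():
            banned = set(exclude.positions(chrom).tolist())
        positions: list[int] = []
        pos = -1
        while True:
            draw = rng.geometric(1.0 / mean_spacing, size=max(16, int(length / mean_spacing)))
            for gap in draw:
                pos += int(gap)
                if pos >= length:
                    break
                if pos not in banned:
                    positions.append(pos)
            if pos >= length:
                break
        if not positions:
            continue
        parr = np.asarray(positions, dtype=np.int64)
        refb = ref.seqs[chrom][parr]
        altb = (refb + rng.integers(1, 4, size=parr.size, dtype=np.uint8)) % 4
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": parr,
                    "allele_a": list(decode(refb)),
                    "allele_b": list(decode(altb)),
                }
            )
        )
    df = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["chrom", "pos", "allele_a", "allele_b"])
    )
    return SnpTable(df, float(mean_spacing))


def parental_haplotype(ref: ReferenceGenome, snps: SnpTable, which: str, chroms=None):
    """Reference-frame genome dict for parent 'a' (reference alleles) or 'b'."""
    chroms = ref.female_chroms() if chroms is None else chroms
    out = {}
    for chrom in chroms:
        seq = ref.seqs[chrom].copy()
        if chrom in snps.chroms():
            pos = snps.positions(chrom)
            seq[pos] = snps.codes_b(chrom) if which == "b" else snps.codes_a(chrom)
        out[chrom] = seq
    return out


# ---------------------------------------------------------------------------
# deletion spiking


@dataclass
class Haplotype:
    """Reference-frame sequence (with SNP alleles applied) plus deletions."""

    base: dict[str, np.ndarray]
    deletions: list[tuple[str, int, int]] = field(default_factory=list)

    def materialize(self) -> dict[str, np.ndarray]:
        """Sequences with deletions excised (haplotype coordinates)."""
        out = {}
        for chrom, seq in self.base.items():
            dels = sorted((s, e) for c, s, e in self.deletions if c == chrom)
            if not dels:
                out[chrom] = seq
                continue
            pieces, cur = [], 0
            for s, e in dels:
                pieces.append(seq[cur:s])
                cur = e
            pieces.append(seq[cur:])
            out[chrom] = np.concatenate(pieces)
        return out


@dataclass
class SpikeResult:
    haplotypes: list[Haplotype]
    truth: pd.DataFrame  # chrom, start, end, size, haplotype
    offspring: int

    def offspring_truth(self) -> pd.DataFrame:
        """Truth deletions carried by the sampled offspring haplotype."""
        return self.truth[self.truth["haplotype"] == self.offspring].reset_index(drop=True)


def spike_deletions(
    ref: ReferenceGenome,
    n_range=(5, 25),
    size_range=(1, 20),
    seed: int = 0,
    snps: SnpTable | None = None,
    max_retries: int = 100,
) -> SpikeResult:
    """Spike heterozygous deletions into the four meiotic haplotypes.

    The four haplotypes are two copies each of the two parental sequences
    (parent A = reference alleles, parent B = alternate alleles at the SNP
    sites, when ``snps`` is given). Each deletion gets a uniform size on
    ``size_range``, a uniform position on a non-Y chromosome (length
    weighted), and a uniform haplotype; deletions on the same haplotype may
    not overlap (bounded resampling). One haplotype is designated the
    sampled offspring.
    """
    if size_range[0] < 1:
        raise ValueError("minimum deletion size is 1 bp")
    if not (0 <= n_range[0] <= n_range[1] <= 1000):
        raise ValueError("n_range out of bounds")
    rng = np.random.default_rng(seed)
    chroms = ref.female_chroms()
    if snps is not None:
        hap_a = parental_haplotype(ref, snps, "a", chroms)
        hap_b = parental_haplotype(ref, snps, "b", chroms)
    else:
        hap_a = {c: ref.seqs[c] for c in chroms}
        hap_b = hap_a
    haplotypes = [Haplotype(hap_a), Haplotype(hap_a), Haplotype(hap_b), Haplotype(hap_b)]

    lengths = np.array([ref.length(c) for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    n = int(rng.integers(n_range[0], n_range[1] + 1))
    records = []
    for _ in range(n):
        for attempt in range(max_retries):
            size = int(rng.integers(size_range[0], size_range[1] + 1))
            ci = int(rng.choice(len(chroms), p=weights))
            chrom = chroms[ci]
            limit = ref.length(chrom) - size
            if limit < 0:
                continue
            start = int(rng.integers(0, limit + 1))
            hap = int(rng.integers(0, 4))
            end = start + size
            clash = any(
                c == chrom and s < end and start < e
                for c, s, e in haplotypes[hap].deletions
            )
            if not clash:
                haplotypes[hap].deletions.append((chrom, start, end))
                records.append((chrom, start, end, size, hap))
                break
        else:
            raise RuntimeError("could not place deletion without overlap")
    truth = pd.DataFrame(records, columns=["chrom", "start", "end", "size", "haplotype"])
    truth = truth.sort_values(["chrom", "start"]).reset_index(drop=True)
    offspring = int(rng.integers(0, 4))
    return SpikeResult(haplotypes, truth, offspring)


# ---------------------------------------------------------------------------
# male genome


@dataclass
class MaleGenome:
    genome: dict[str, np.ndarray]
    snps: SnpTable


def make_male_genome(
    ref: ReferenceGenome,
    seed: int = 0,
    mean_spacing: float = 500.0,
    exclude: SnpTable | None = None,
) -> MaleGenome:
    """Male haplotype contribution: autosomes plus Y, no X, with its own SNPs.

    Male SNP sites avoid the positions in ``exclude`` (the maternal marker
    set), mirroring the selection of cross-informative markers from
    sequenced isogenized stocks.
    """
    if ref.x_name() is None or ref.y_name() is None:
        raise ValueError("reference must declare an X and a Y chromosome")
    chroms = ref.autosomes() + [ref.y_name()]
    snps = place_snps(ref, mean_spacing, seed, chroms=chroms, exclude=exclude)
    genome = {}
    for chrom in chroms:
        seq = ref.seqs[chrom].copy()
        if chrom in snps.chroms():
            seq[snps.positions(chrom)] = snps.codes_b(chrom)
        genome[chrom] = seq
    return MaleGenome(genome, snps)


# ---------------------------------------------------------------------------
# meiosis


#: Named NHEJ scar models (deletion size ranges, bp). "scarless" is the
#: headline model; the others are power-analysis presets for the scenarios in
#: which 2-nt overhang clipping, Spo11-oligo removal, or post-resection
#: clipping would leave 2-10 bp, ~50-100 bp, or >500 bp deletions.
NHEJ_PRESETS: dict[str, tuple[int, int]] = {
    "scarless": (0, 0),
    "clip-2bp": (2, 10),
    "clip-oligo": (50, 100),
    "clip-resected": (500, 1500),
}


@dataclass
class MeiosisParams:
    """Tunable parameters of one simulated female meiosis.

    dsb_count_range : inclusive range of DSBs per meiosis (uniform draw).
    co_fraction : probability an HR-repaired DSB resolves as a crossover.
    gc_tract_mean : mean gene-conversion tract length (bp), geometric.
    hr_fail_prob : probability a DSB has no homologous template
        (heterosynapsis) and is handed to NHEJ; ~0.8 emulates the mutant.
    nhej_deletion_range : inclusive bp range of the NHEJ scar; (0, 0) is
        scarless repair. May be given as a preset name from NHEJ_PRESETS.
    """

    dsb_count_range: tuple[int, int] = (11, 24)
    co_fraction: float = 0.25
    gc_tract_mean: float = 400.0
    gc_tract_dist: str = "geometric"
    hr_fail_prob: float = 0.0
    nhej_deletion_range: tuple[int, int] | str = (0, 0)

    def __post_init__(self) -> None:
        if isinstance(self.nhej_deletion_range, str):
            self.nhej_deletion_range = NHEJ_PRESETS[self.nhej_deletion_range]
        lo, hi = self.dsb_count_range
        if not (0 <= lo <= hi <= 10_000):
            raise ValueError("dsb_count_range out of bounds")
        for p in (self.co_fraction, self.hr_fail_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.gc_tract_mean < 1:
            raise ValueError("gc_tract_mean must be >= 1")
        if self.gc_tract_dist not in ("geometric", "fixed"):
            raise ValueError("gc_tract_dist must be 'geometric' or 'fixed'")


@dataclass
class ParentalGenomes:
    """The two parental female haplotypes of a cross, as reference + SNPs."""

    ref: ReferenceGenome
    snps: SnpTable
    chroms: list[str]

    @classmethod
    def from_reference(cls, ref: ReferenceGenome, snps: SnpTable) -> "ParentalGenomes":
        return cls(ref, snps, ref.female_chroms())


@dataclass
class MeiosisTruth:
    """Ground-truth events of one meiosis (BED-compatible coordinates)."""

    co: list[tuple[str, int, tuple[int, int]]]  # chrom, breakpoint, chromatid pair
    nco: list[tuple[str, int, int, int]]  # chrom, tract start, tract end, chromatid
    nhej: list[tuple[str, int, int, int]]  # chrom, start, size, chromatid
    offspring_chromatid: int

    def co_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c, p, i, j) for c, p, (i, j) in self.co],
            columns=["chrom", "pos", "chromatid_1", "chromatid_2"],
        )

    def nco_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.nco, columns=["chrom", "start", "end", "chromatid"])

    def nhej_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.nhej, columns=["chrom", "pos", "size", "chromatid"])

    def co_on_offspring(self) -> int:
        k = self.offspring_chromatid
        return sum(1 for _, _, pair in self.co if k in pair)

    def nco_on_offspring(self) -> int:
        k = self.offspring_chromatid
        return sum(1 for _, _, _, c in self.nco if c == k)


@dataclass
class MeiosisResult:
    """Four chromatids (as SNP paintings + deletion lists) plus truth.

    Chromatids 0 and 1 are sisters from parent A, 2 and 3 from parent B.
    ``paintings[chrom]`` is a (4, n_snps) int8 array of parental origin
    (0 = A, 1 = B) at each marker; sequences are materialized on demand.
    """

    parents: ParentalGenomes
    params: MeiosisParams
    paintings: dict[str, np.ndarray]
    deletions: list[list[tuple[str, int, int]]]
    truth: MeiosisTruth

    def chromatid_genome(self, k: int) -> dict[str, np.ndarray]:
        ref, snps = self.parents.ref, self.parents.snps
        base = {}
        for chrom in self.parents.chroms:
            seq = ref.seqs[chrom].copy()
            if chrom in snps.chroms():
                pos = snps.positions(chrom)
                paint = self.paintings[chrom][k]
                seq[pos[paint == 0]] = snps.codes_a(chrom)[paint == 0]
                seq[pos[paint == 1]] = snps.codes_b(chrom)[paint == 1]
            base[chrom] = seq
        return Haplotype(base, list(self.deletions[k])).materialize()

    def offspring_genome(self) -> dict[str, np.ndarray]:
        return self.chromatid_genome(self.truth.offspring_chromatid)

    def offspring_painting(self, chrom: str) -> np.ndarray:
        return self.paintings[chrom][self.truth.offspring_chromatid]


def _draw_tract(rng: np.random.Generator, params: MeiosisParams) -> int:
    if params.gc_tract_dist == "fixed":
        return max(1, int(round(params.gc_tract_mean)))
    return int(rng.geometric(1.0 / params.gc_tract_mean))


def simulate_meiosis(
    parents: ParentalGenomes, params: MeiosisParams | None = None, seed: int = 0
) -> MeiosisResult:
    """Simulate one meiosis: DSBs resolved as CO, NCO-GC or NHEJ.

    Each parent is replicated into two identical sister chromatids (no
    inter-sister events). DSB positions are uniform over the female genome.
    A DSB with no homologous template (probability ``hr_fail_prob``) becomes
    an NHEJ event on one chromatid, deleting a scar drawn from
    ``nhej_deletion_range`` (0 bp = scarless). Otherwise it resolves as a
    crossover with probability ``co_fraction`` (reciprocal exchange of
    everything distal to the breakpoint between one chromatid of each
    parent) or as a gene conversion (a tract of geometric length, placed
    symmetrically around the DSB and clamped to the chromosome, copied from
    a homolog chromatid onto the recipient). One chromatid is sampled as
    the offspring.
    """
    params = MeiosisParams() if params is None else params
    rng = np.random.default_rng(seed)
    ref, snps, chroms = parents.ref, parents.snps, parents.chroms

    paintings = {}
    snp_pos = {}
    for chrom in chroms:
        pos = snps.positions(chrom) if chrom in snps.chroms() else np.empty(0, np.int64)
        snp_pos[chrom] = pos
        paint = np.zeros((4, pos.size), dtype=np.int8)
        paint[2:] = 1
        paintings[chrom] = paint
    deletions: list[list[tuple[str, int, int]]] = [[], [], [], []]

    lengths = np.array([ref.length(c) for c in chroms], dtype=np.int64)
    total = int(lengths.sum())
    offsets = np.concatenate([[0], np.cumsum(lengths)])

    lo, hi = params.dsb_count_range
    n_dsb = int(rng.integers(lo, hi + 1))
    co_events, nco_events, nhej_events = [], [], []
    for _ in range(n_dsb):
        g = int(rng.integers(0, total))
        ci = int(np.searchsorted(offsets, g, side="right") - 1)
        chrom = chroms[ci]
        pos = g - int(offsets[ci])
        length = int(lengths[ci])
        if rng.random() < params.hr_fail_prob:
            k = int(rng.integers(0, 4))
            dlo, dhi = params.nhej_deletion_range
            size = int(rng.integers(dlo, dhi + 1)) if dhi > 0 else 0
            if size > 0:
                start, end = pos, min(pos + size, length)
                # truncate against existing scars on this chromatid so the
                # truth matches the materialized sequence
                for c2, s2, e2 in deletions[k]:
                    if c2 == chrom and s2 < end and start < e2:
                        if pos < s2:
                            end = min(end, s2)
                        else:
                            start = max(start, e2)
                if end > start:
                    deletions[k].append((chrom, start, end))
                    nhej_events.append((chrom, start, end - start, k))
            else:
                nhej_events.append((chrom, pos, 0, k))
        elif rng.random() < params.co_fraction:
            i = int(rng.integers(0, 2))
            j = int(rng.integers(2, 4))
            idx = snp_pos[chrom] > pos
            paint = paintings[chrom]
            tmp = paint[i, idx].copy()
            paint[i, idx] = paint[j, idx]
            paint[j, idx] = tmp
            moved_i = [d for d in deletions[i] if d[0] == chrom and d[1] > pos]
            moved_j = [d for d in deletions[j] if d[0] == chrom and d[1] > pos]
            deletions[i] = [d for d in deletions[i] if d not in moved_i] + moved_j
            deletions[j] = [d for d in deletions[j] if d not in moved_j] + moved_i
            co_events.append((chrom, pos, (i, j)))
        else:
            k = int(rng.integers(0, 4))
            donor = int(rng.integers(2, 4) if k < 2 else rng.integers(0, 2))
            tract = _draw_tract(rng, params)
            start = max(0, pos - tract // 2)
            end = min(length, start + tract)
            pos_arr = snp_pos[chrom]
            idx = (pos_arr >= start) & (pos_arr < end)
            paintings[chrom][k, idx] = paintings[chrom][donor, idx]
            nco_events.append((chrom, start, end, k))

    offspring = int(rng.integers(0, 4))
    truth = MeiosisTruth(co_events, nco_events, nhej_events, offspring)
    return MeiosisResult(parents, params, paintings, deletions, truth)


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class ReadSimParams:
    """Paired-end read simulator settings.

    ``coverage`` is the fold-coverage of each supplied haplotype sequence
    (the convention of per-sequence read simulators): the pair count is
    ``ceil(coverage * total_len / (2 * read_len))`` with ``total_len`` the
    summed length of all supplied sequences, so a diploid locus is read to
    twice the nominal coverage in total.
    """

    read_len: int = 100
    insert_mean: float = 400.0
    insert_sd: float = 40.0
    coverage: float = 10.0
    error_rate: float = 0.001
    base_qual: int = 30

    def __post_init__(self) -> None:
        if self.read_len > self.insert_mean:
            raise ValueError("read_len must be <= insert_mean")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")


@dataclass
class ReadSet:
    """Paired reads as (N, read_len) uint8 code matrices.

    Mate 2 is the reverse complement of the 3' end of the fragment. Truth
    arrays (source haplotype/segment/start/insert) are carried for
    simulator-level tests and are not consulted by any caller.
    """

    r1: np.ndarray
    r2: np.ndarray
    params: ReadSimParams
    hap: np.ndarray | None = None
    chrom: list[str] | None = None
    start: np.ndarray | None = None
    insert: np.ndarray | None = None

    def __len__(self) -> int:
        return int(self.r1.shape[0])

    def read_id(self, i: int) -> str:
        if self.chrom is None:
            return f"read{i}"
        return f"sim:{i}:h{int(self.hap[i])}:{self.chrom[i]}:{int(self.start[i])}"


def simulate_reads(
    haplotypes, params: ReadSimParams | None = None, seed: int = 0
) -> ReadSet:
    """Simulate paired-end reads from one or more haplotype genomes.

    ``haplotypes`` is a genome dict (chrom -> codes) or a list of them;
    fragments are sampled uniformly over the total supplied sequence and
    never cross a chromosome boundary. Substitution errors are applied per
    base at ``error_rate``; qualities are a constant Phred score.
    """
    params = ReadSimParams() if params is None else params
    if isinstance(haplotypes, dict):
        haplotypes = [haplotypes]
    segs = [(hi, chrom, seq) for hi, hap in enumerate(haplotypes) for chrom, seq in hap.items()]
    lens = np.array([s[2].size for s in segs], dtype=np.int64)
    total = int(lens.sum())
    if (lens < params.insert_mean).all():
        raise ValueError("all sequences shorter than the mean insert")
    rl = params.read_len
    n = math.ceil(params.coverage * total / (2 * rl))
    rng = np.random.default_rng(seed)

    big = np.concatenate([s[2] for s in segs])
    offsets = np.concatenate([[0], np.cumsum(lens)])
    weights = lens / total

    inserts = np.rint(rng.normal(params.insert_mean, params.insert_sd, size=n)).astype(np.int64)
    np.clip(inserts, rl, None, out=inserts)
    seg_idx = rng.choice(len(segs), size=n, p=weights)
    starts = np.empty(n, dtype=np.int64)
    todo = np.arange(n)
    while todo.size:
        room = lens[seg_idx[todo]] - inserts[todo]
        ok = room >= 0
        good = todo[ok]
        starts[good] = np.floor(rng.random(good.size) * (room[ok] + 1)).astype(np.int64)
        bad = todo[~ok]
        if bad.size:
            seg_idx[bad] = rng.choice(len(segs), size=bad.size, p=weights)
        todo = bad

    g1 = offsets[seg_idx] + starts
    span = np.arange(rl, dtype=np.int64)
    r1 = big[g1[:, None] + span]
    g2 = offsets[seg_idx] + starts + inserts - rl
    r2 = (3 - big[g2[:, None] + span][:, ::-1]).astype(np.uint8)

    if params.error_rate > 0:
        for mat in (r1, r2):
            mask = rng.random(mat.shape) < params.error_rate
            shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
            mat[mask] = (mat[mask] + shift) % 4

    return ReadSet(
        r1=r1,
        r2=r2,
        params=params,
        hap=np.array([segs[i][0] for i in seg_idx], dtype=np.int16),
        chrom=[segs[i][1] for i in seg_idx],
        start=starts,
        insert=inserts,
    )
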