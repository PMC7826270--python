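"""Crossover and noncrossover gene-conversion calling from offspring genomes.

Each informative SNP marker is assigned to one of the two parental
haplotypes (from a read pileup or from genotype records); the resulting
per-chromosome haplotype vector is segmented into blocks. A short internal
block of the minority haplotype flanked on both sides by enough markers of
the other haplotype is a noncrossover gene conversion (NCO-GC); a
transition between two terminal-reaching blocks is a crossover (CO). A
depth-based karyotype classifier flags sex-chromosome aneuploidies (X0,
XXY) from normalized per-chromosome coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .delscan import UNGAPPED, AlignmentSet
from .genestats import one_sample_test, percent_reduction
from .synthgenome import SnpTable

__all__ = [
    "HaplotypeVector",
    "RecombEvent",
    "KaryotypeCall",
    "EventSummary",
    "genotype_snps",
    "informative_markers",
    "call_events",
    "classify_karyotype",
    "event_summary",
]


@dataclass
class HaplotypeVector:
    """Parental assignment of informative markers along one chromosome.

    ``calls`` holds 'A', 'B' or '.' (missing/uninformative) per marker.
    """

    chrom: str
    pos: np.ndarray
    calls: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.pos) <= 0):
            raise ValueError("marker positions must be strictly increasing")
        if not set(np.unique(self.calls)) <= {"A", "B", "."}:
            raise ValueError("calls must be 'A', 'B' or '.'")

    def __len__(self) -> int:
        return int(self.pos.size)


@dataclass
class RecombEvent:
    """A called crossover or gene-conversion tract.

    For a CO, ``breakpoint_interval`` is the (left, right) marker position
    pair bounding the haplotype switch. For an NCO-GC, ``tract_min`` spans
    the converted markers and ``tract_max`` the flanking opposite-haplotype
    markers.
    """

    kind: str  # 'CO' | 'NCO_GC'
    chrom: str
    breakpoint_interval: tuple[int, int] | None = None
    tract_min: tuple[int, int] | None = None
    tract_max: tuple[int, int] | None = None
    n_support_markers: int = 1
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("CO", "NCO_GC"):
            raise ValueError("kind must be 'CO' or 'NCO_GC'")
        if self.n_support_markers < 1:
            raise ValueError("n_support_markers must be >= 1")
        if self.kind == "NCO_GC" and self.tract_min and self.tract_max:
            if not (self.tract_max[0] <= self.tract_min[0] <= self.tract_min[1] <= self.tract_max[1]):
                raise ValueError("tract_min must lie within tract_max")


# ---------------------------------------------------------------------------
# genotyping and marker assignment


def genotype_snps(
    alns: AlignmentSet,
    snps: SnpTable,
    min_allele_reads: int = 2,
    min_alt_frac: float = 0.1,
) -> pd.DataFrame:
    """Pileup genotypes at the parental SNP sites from ungapped alignments.

    Returns a frame with per-site counts of the two parental alleles and a
    ``call`` column: 'B' when the alternate parental allele is supported by
    >= ``min_allele_reads`` reads at >= ``min_alt_frac`` of covering reads,
    'A' when the reference-parent allele is supported and no B-parent read
    was seen, '.' otherwise. A site with a single stray B read is left
    missing rather than forced to 'A': at a true B marker the male-derived
    reference reads dominate only through a coverage fluctuation, and a
    forced 'A' there would fabricate a one-marker conversion tract.
    """
    idx = alns.index
    L = alns.read_len
    sel = alns.status == UNGAPPED
    starts = alns.gpos[sel]
    seqs = alns.seqs[sel]
    order = np.argsort(starts, kind="stable")
    starts, seqs = starts[order], seqs[order]

    rows = []
    for chrom in snps.chroms():
        if chrom not in idx.ref.names:
            raise KeyError(f"chromosome {chrom!r} absent from the reference index")
        pos = snps.positions(chrom)
        a = snps.codes_a(chrom)
        b = snps.codes_b(chrom)
        base_g = idx.global_pos(chrom, 0)
        for i, p in enumerate(pos):
            gp = base_g + int(p)
            lo = np.searchsorted(starts, gp - L + 1)
            hi = np.searchsorted(starts, gp, side="right")
            obs = seqs[np.arange(lo, hi), gp - starts[lo:hi]]
            n_a = int((obs == a[i]).sum())
            n_b = int((obs == b[i]).sum())
            n_other = int(obs.size - n_a - n_b)
            cov = n_a + n_b + n_other
            if n_b >= min_allele_reads and cov > 0 and n_b / cov >= min_alt_frac:
                call = "B"
            elif n_a >= min_allele_reads and n_b == 0:
                call = "A"
            else:
                call = "."
            rows.append((chrom, int(p), n_a, n_b, n_other, call))
    return pd.DataFrame(rows, columns=["chrom", "pos", "n_a", "n_b", "n_other", "call"])


def informative_markers(genotypes: pd.DataFrame, parents: SnpTable) -> dict[str, HaplotypeVector]:
    """Build per-chromosome haplotype vectors from offspring genotypes.

    ``genotypes`` either carries a ``call`` column (from
    :func:`genotype_snps`) or an ``allele`` column of observed bases, which
    are matched against the parental alleles ('A' if allele_a, 'B' if
    allele_b, missing otherwise). Sites absent from the genotypes are
    missing; chromosomes absent from the parental table raise ``KeyError``.
    """
    parent_chroms = set(parents.chroms())
    for chrom in genotypes["chrom"].unique():
        if chrom not in parent_chroms:
            raise KeyError(f"chromosome {chrom!r} not in the parental SNP table")
    vectors = {}
    for chrom in parents.chroms():
        pos = parents.positions(chrom)
        sub = genotypes[genotypes["chrom"] == chrom]
        calls = np.full(pos.size, ".", dtype="U1")
        lookup = dict(zip(pos.tolist(), range(pos.size)))
        if "call" in sub.columns:
            for p, c in zip(sub["pos"], sub["call"]):
                if p in lookup:
                    calls[lookup[p]] = c if c in ("A", "B") else "."
        else:
            pa = dict(zip(parents.df[parents.df.chrom == chrom]["pos"], parents.df[parents.df.chrom == chrom]["allele_a"]))
            pb = dict(zip(parents.df[parents.df.chrom == chrom]["pos"], parents.df[parents.df.chrom == chrom]["allele_b"]))
            for p, allele in zip(sub["pos"], sub["allele"]):
                if p not in lookup:
                    continue
                if allele == pa[p]:
                    calls[lookup[p]] = "A"
                elif allele == pb[p]:
                    calls[lookup[p]] = "B"
        vectors[chrom] = HaplotypeVector(chrom, pos.copy(), calls)
    return vectors


# ---------------------------------------------------------------------------
# segmentation


@dataclass
class _Block:
    call: str
    i0: int
    i1: int  # inclusive marker indices into the non-missing arrays

    @property
    def n(self) -> int:
        return self.i1 - self.i0 + 1


def _blocks(calls: np.ndarray) -> list[_Block]:
    out: list[_Block] = []
    for i, c in enumerate(calls):
        if out and out[-1].call == c:
            out[-1].i1 = i
        else:
            out.append(_Block(c, i, i))
    return out


def _merge_adjacent(blocks: list[_Block]) -> list[_Block]:
    out: list[_Block] = []
    for b in blocks:
        if out and out[-1].call == b.call:
            out[-1].i1 = b.i1
        else:
            out.append(_Block(b.call, b.i0, b.i1))
    return out


def call_events(
    v: HaplotypeVector, min_flank_markers: int = 2, max_gc_span: int = 10_000
) -> list[RecombEvent]:
    """Segment a haplotype vector into CO and NCO-GC events.

    Missing calls never terminate a block. Internal blocks whose marker
    span is <= ``max_gc_span`` and whose flanks carry >=
    ``min_flank_markers`` opposite markers each are gene conversions and
    are excised iteratively; remaining transitions between blocks are
    crossovers. Weak internal blocks (< ``min_flank_markers``) that fail
    the GC span rule collapse their two transitions into a single event
    flagged ``ambiguous``; transitions involving a weak terminal block are
    flagged ``terminal``.
    """
    keep = v.calls != "."
    pos = v.pos[keep]
    calls = v.calls[keep]
    if pos.size == 0:
        raise ValueError("all-missing haplotype vector")
    events: list[RecombEvent] = []
    blocks = _blocks(calls)

    changed = True
    while changed:
        changed = False
        for bi in range(1, len(blocks) - 1):
            b, left, right = blocks[bi], blocks[bi - 1], blocks[bi + 1]
            span = int(pos[b.i1] - pos[b.i0])
            if span <= max_gc_span and left.n >= min_flank_markers and right.n >= min_flank_markers:
                events.append(
                    RecombEvent(
                        kind="NCO_GC",
                        chrom=v.chrom,
                        tract_min=(int(pos[b.i0]), int(pos[b.i1])),
                        tract_max=(int(pos[left.i1]), int(pos[right.i0])),
                        n_support_markers=b.n,
                    )
                )
                del blocks[bi]
                blocks = _merge_adjacent(blocks)
                changed = True
                break

    if len(blocks) < 2:
        return events

    current = blocks[0]
    pending: list[_Block] = []
    for bi in range(1, len(blocks)):
        b = blocks[bi]
        if b.n < min_flank_markers and bi < len(blocks) - 1:
            pending.append(b)
            continue
        if pending:
            n_sup = sum(p.n for p in pending)
            if current.call == b.call:
                events.append(
                    RecombEvent(
                        kind="NCO_GC",
                        chrom=v.chrom,
                        tract_min=(int(pos[pending[0].i0]), int(pos[pending[-1].i1])),
                        tract_max=(int(pos[current.i1]), int(pos[b.i0])),
                        n_support_markers=n_sup,
                        flags=("ambiguous",),
                    )
                )
            else:
                events.append(
                    RecombEvent(
                        kind="CO",
                        chrom=v.chrom,
                        breakpoint_interval=(int(pos[current.i1]), int(pos[b.i0])),
                        n_support_markers=n_sup,
                        flags=("ambiguous",),
                    )
                )
            pending = []
        elif b.call != current.call:
            flags = []
            if (current is blocks[0] and current.n < min_flank_markers) or (
                bi == len(blocks) - 1 and b.n < min_flank_markers
            ):
                flags.append("terminal")
            events.append(
                RecombEvent(
                    kind="CO",
                    chrom=v.chrom,
                    breakpoint_interval=(int(pos[current.i1]), int(pos[b.i0])),
                    n_support_markers=min(current.n, b.n),
                    flags=tuple(flags),
                )
            )
        current = b
    return events


# ---------------------------------------------------------------------------
# karyotype


@dataclass
class KaryotypeThresholds:
    near_zero: float = 0.05
    half: tuple[float, float] = (0.3, 0.7)
    full: float = 0.8


@dataclass
class KaryotypeCall:
    sample: str
    ratios: dict[str, float]
    klass: str  # 'XY' | 'X0' | 'XXY' | 'other'


def classify_karyotype(
    depths: dict[str, float],
    thresholds: KaryotypeThresholds | None = None,
    x: str = "X",
    y: str = "Y",
    sample: str = "",
) -> KaryotypeCall:
    """Classify sex-chromosome karyotype from normalized per-chromosome depth.

    Ratios are depth relative to the mean autosomal depth: an XY male has
    r_X ~ 0.5 and r_Y > 0, an X0 male r_X ~ 0.5 and r_Y ~ 0, an XXY
    individual r_X ~ 1 and r_Y > 0.
    """
    th = thresholds or KaryotypeThresholds()
    auto = [d for c, d in depths.items() if c not in (x, y)]
    if not auto or np.mean(auto) <= 0:
        raise ValueError("missing autosomal depth baseline")
    base = float(np.mean(auto))
    r_x = depths.get(x, 0.0) / base
    r_y = depths.get(y, 0.0) / base
    if th.half[0] <= r_x <= th.half[1]:
        klass = "XY" if r_y > th.near_zero else "X0"
    elif r_x >= th.full and r_y > th.near_zero:
        klass = "XXY"
    else:
        klass = "other"
    return KaryotypeCall(sample, {x: r_x, y: r_y}, klass)


# ---------------------------------------------------------------------------
# cohort summary


@dataclass
class EventSummary:
    table: pd.DataFrame
    per_chromosome: pd.DataFrame
    n: int
    co_total: int
    nco_total: int
    co_reduction: int
    nco_reduction: int
    co_test: tuple[float, float]
    nco_test: tuple[float, float]


def event_summary(
    events_by_offspring: list[list[RecombEvent]],
    expected_per_fly: tuple[float, float],
    n: int | None = None,
) -> EventSummary:
    """Cohort totals, per-fly means, percent reduction and one-sample tests.

    ``expected_per_fly`` is the (CO, NCO-GC) mean per offspring expected
    from a reference cross; reductions compare observed totals against
    ``expected * n``.
    """
    n = len(events_by_offspring) if n is None else n
    if n < 1:
        raise ValueError("n must be >= 1")
    co_counts = np.array(
        [sum(e.kind == "CO" for e in evs) for evs in events_by_offspring], dtype=float
    )
    nco_counts = np.array(
        [sum(e.kind == "NCO_GC" for e in evs) for evs in events_by_offspring], dtype=float
    )
    exp_co, exp_nco = expected_per_fly
    co_total, nco_total = int(co_counts.sum()), int(nco_counts.sum())
    table = pd.DataFrame(
        {
            "kind": ["CO", "NCO_GC"],
            "observed_total": [co_total, nco_total],
            "observed_mean": [co_counts.mean(), nco_counts.mean()],
            "expected_mean": [exp_co, exp_nco],
            "expected_total": [exp_co * n, exp_nco * n],
            "percent_reduction": [
                percent_reduction(exp_co * n, co_total) if exp_co > 0 else np.nan,
                percent_reduction(exp_nco * n, nco_total) if exp_nco > 0 else np.nan,
            ],
        }
    )
    chrom_rows: dict[tuple[str, str], int] = {}
    for evs in events_by_offspring:
        for e in evs:
            chrom_rows[(e.chrom, e.kind)] = chrom_rows.get((e.chrom, e.kind), 0) + 1
    per_chrom = pd.DataFrame(
        [(c, k, v) for (c, k), v in sorted(chrom_rows.items())],
        columns=["chrom", "kind", "count"],
    )
    return EventSummary(
        table=table,
        per_chromosome=per_chrom,
        n=n,
        co_total=co_total,
        nco_total=nco_total,
        co_reduction=int(table["percent_reduction"][0]) if exp_co > 0 else 0,
        nco_reduction=int(table["percent_reduction"][1]) if exp_nco > 0 else 0,
        co_test=one_sample_test(co_counts, exp_co),
        nco_test=one_sample_test(nco_counts, exp_nco),
    )
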