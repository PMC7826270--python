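"""De novo deletion detection from simulated paired-end reads.

A deterministic, self-contained short-read pipeline at desk scale:

* :class:`KmerIndex` / :func:`map_reads` — exact unique k-mer anchors with
  ungapped extension; reads whose seeds disagree on the diagonal are
  resolved as one-gap (small deletion) or split (large deletion)
  alignments; reads that cannot be placed full length are kept as
  soft-clipped anchors.
* :func:`call_small_deletions` — clusters gapped alignments on (start,
  size), then re-genotypes soft-clipped reads against the candidate
  deletion allele so junction reads with short flanks still count as
  support.
* :func:`call_large_deletions` — split-read breakpoint voting corroborated
  by discordant insert-size pairs.
* :func:`estimate_sensitivity` — spikes deletions into simulated diploid
  genomes, sequences one sampled offspring per genome, runs the callers and
  reports per-size-bin and overall detection sensitivity.
* :func:`expected_deletions` — the closed-form expected-deletion arithmetic
  (DSBs per meiosis x HR reduction / 4 chromatids x progeny x sensitivity).

Synthetic references here are near-uniform random sequence, so 21-mer
anchors are effectively unique; ambiguous k-mers are dropped from the index
and multi-mapping is not rescued.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthgenome import (
    DEFAULT_CHROM_SPEC,
    ReadSet,
    ReadSimParams,
    ReferenceGenome,
    build_reference,
    make_male_genome,
    place_snps,
    spike_deletions,
)
from ._encode import SENTINEL, pack_columns, pack_kmers

__all__ = [
    "MapParams",
    "KmerIndex",
    "Alignment",
    "AlignmentSet",
    "DeletionCall",
    "SensitivityConfig",
    "SensitivityReport",
    "ExpectedDeletions",
    "map_reads",
    "call_small_deletions",
    "call_large_deletions",
    "call_deletions",
    "match_deletion_calls",
    "estimate_sensitivity",
    "expected_deletions",
]

UNMAPPED, UNGAPPED, GAPPED, SPLIT, CLIPPED = 0, 1, 2, 3, 4


@dataclass
class MapParams:
    k: int = 21
    max_mismatch: int = 5
    small_gap_max: int = 50
    max_split_gap: int = 100_000

    def seed_offsets(self, read_len: int) -> list[int]:
        # four non-overlapping anchors tiling the read
        k = self.k
        if read_len < 2 * k:
            return [0]
        n = min(4, read_len // k)
        step = (read_len - k) / (n - 1) if n > 1 else 0
        return [int(round(i * step)) for i in range(n)]


class KmerIndex:
    """Exact-match index of unique reference k-mers (global coordinates).

    Chromosomes are concatenated with sentinel padding so alignment windows
    never cross a boundary; positions are stored on the padded axis and
    converted to per-chromosome coordinates on output.
    """

    def __init__(self, ref: ReferenceGenome, k: int = 21, pad: int = 200):
        if not ref.names:
            raise ValueError("empty reference")
        self.ref = ref
        self.k = int(k)
        self.pad = int(pad)
        parts, starts = [], []
        cursor = 0
        for name in ref.names:
            parts.append(np.full(pad, SENTINEL, dtype=np.uint8))
            cursor += pad
            starts.append(cursor)
            parts.append(ref.seqs[name])
            cursor += ref.length(name)
        parts.append(np.full(pad, SENTINEL, dtype=np.uint8))
        self.genome = np.concatenate(parts)
        self.chrom_start = np.array(starts, dtype=np.int64)
        self.chrom_len = np.array([ref.length(n) for n in ref.names], dtype=np.int64)

        kmer_list, pos_list = [], []
        for name, start in zip(ref.names, self.chrom_start):
            km = pack_kmers(ref.seqs[name], self.k)
            kmer_list.append(km)
            pos_list.append(start + np.arange(km.size, dtype=np.int64))
        kmers = np.concatenate(kmer_list)
        pos = np.concatenate(pos_list)
        order = np.argsort(kmers, kind="stable")
        kmers, pos = kmers[order], pos[order]
        uniq, first, counts = np.unique(kmers, return_index=True, return_counts=True)
        keep = counts == 1
        self.kmers = uniq[keep]
        self.pos = pos[first[keep]]
        self.n_ambiguous = int((~keep).sum())

    def lookup(self, queries: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.kmers, queries)
        idx[idx >= self.kmers.size] = 0
        hit = self.kmers[idx] == queries
        out = np.where(hit, self.pos[idx], -1)
        return out

    def global_pos(self, chrom: str, pos: int) -> int:
        ci = self.ref.names.index(chrom)
        return int(self.chrom_start[ci] + pos)

    def to_local(self, gpos: int) -> tuple[str, int]:
        ci = int(np.searchsorted(self.chrom_start, gpos, side="right") - 1)
        return self.ref.names[ci], int(gpos - self.chrom_start[ci])


@dataclass
class Alignment:
    """One read placement (query-side CIGAR; ops M, D and S)."""

    read_index: int
    chrom: str | None
    start: int | None
    strand: str
    cigar: list[tuple[str, int]]
    mismatches: int
    status: int


@dataclass
class _GapRec:
    row: int
    read_gstart: int
    q: int
    gap_gpos: int
    gap_size: int
    mm: int


@dataclass
class _ClipRec:
    row: int
    diag: int


class AlignmentSet:
    """Vectorized alignments for one read set (rows 0..N-1 = mate 1)."""

    def __init__(self, index: KmerIndex, n_pairs: int, read_len: int):
        self.index = index
        self.n_pairs = n_pairs
        self.read_len = read_len
        n = 2 * n_pairs
        self.status = np.zeros(n, dtype=np.uint8)
        self.gpos = np.full(n, -1, dtype=np.int64)
        self.strand = np.zeros(n, dtype=np.int8)
        self.mm = np.zeros(n, dtype=np.int16)
        self.seqs = None  # oriented (forward-strand) read codes
        self.gapped: list[_GapRec] = []
        self.splits: list[_GapRec] = []
        self.clipped: list[_ClipRec] = []

    def __len__(self) -> int:
        return 2 * self.n_pairs

    def mapped_mask(self) -> np.ndarray:
        return (self.status == UNGAPPED) | (self.status == GAPPED) | (self.status == SPLIT)

    def end_gpos(self) -> np.ndarray:
        """Reference end (exclusive) of each mapped read."""
        end = np.where(self.gpos >= 0, self.gpos + self.read_len, -1)
        for rec in self.gapped + self.splits:
            end[rec.row] = rec.read_gstart + self.read_len + rec.gap_size
        return end

    def pair_inserts(self) -> np.ndarray:
        """Outer fragment span per pair on the reference (nan if unpaired)."""
        n = self.n_pairs
        out = np.full(n, np.nan)
        m = self.mapped_mask()
        ok = m[:n] & m[n:]
        ok &= self.strand[:n] != self.strand[n:]
        end = self.end_gpos()
        lo = np.minimum(self.gpos[:n], self.gpos[n:])
        hi = np.maximum(end[:n], end[n:])
        out[ok] = (hi - lo)[ok]
        return out

    def depth_per_chrom(self) -> dict[str, float]:
        idx = self.index
        m = self.mapped_mask()
        g = self.gpos[m]
        ci = np.searchsorted(idx.chrom_start, g, side="right") - 1
        counts = np.bincount(ci, minlength=len(idx.ref.names))
        return {
            name: counts[i] * self.read_len / idx.chrom_len[i]
            for i, name in enumerate(idx.ref.names)
        }

    def __iter__(self):
        gap_by_row = {rec.row: rec for rec in self.gapped + self.splits}
        L = self.read_len
        for i in range(len(self)):
            st = int(self.status[i])
            strand = "-" if self.strand[i] else "+"
            if st in (GAPPED, SPLIT):
                rec = gap_by_row[i]
                chrom, start = self.index.to_local(rec.read_gstart)
                cigar = [("M", rec.q), ("D", rec.gap_size), ("M", L - rec.q)]
                yield Alignment(i, chrom, start, strand, cigar, int(rec.mm), st)
            elif st == UNGAPPED:
                chrom, start = self.index.to_local(int(self.gpos[i]))
                yield Alignment(i, chrom, start, strand, [("M", L)], int(self.mm[i]), st)
            elif st == CLIPPED:
                chrom, start = self.index.to_local(int(self.gpos[i]))
                yield Alignment(i, chrom, start, strand, [("S", L)], int(self.mm[i]), st)
            else:
                yield Alignment(i, None, None, strand, [], 0, st)


def _seed_diags(mat: np.ndarray, index: KmerIndex, offsets: list[int]) -> np.ndarray:
    diags = np.full((mat.shape[0], len(offsets)), -1, dtype=np.int64)
    for j, off in enumerate(offsets):
        hits = index.lookup(pack_columns(mat, off, index.k))
        diags[:, j] = np.where(hits >= 0, hits - off, -1)
    return diags


def map_reads(reads: ReadSet, index: KmerIndex, params: MapParams | None = None) -> AlignmentSet:
    """Map both mates of a read set; deterministic for fixed input.

    Mate orientation is resolved by trying the forward sequence first and
    the reverse complement if no seed hits. Reads whose seeds agree on one
    diagonal are verified ungapped (<= ``max_mismatch``); two diagonals are
    resolved into a gapped (deletion <= ``small_gap_max``) or split
    alignment with the junction placed to maximize matches and the gap
    left-normalized.
    """
    params = MapParams() if params is None else params
    L = reads.params.read_len
    if params.k > L // 3 + 1:
        raise ValueError("k must be <= read_len / 3")
    offsets = params.seed_offsets(L)
    n = len(reads)
    out = AlignmentSet(index, n, L)
    seqs = np.vstack([reads.r1, reads.r2])

    diags = _seed_diags(seqs, index, offsets)
    none = (diags < 0).all(axis=1)
    if none.any():
        rc = (3 - seqs[none][:, ::-1]).astype(np.uint8)
        diags_rc = _seed_diags(rc, index, offsets)
        got = (diags_rc >= 0).any(axis=1)
        rows = np.flatnonzero(none)[got]
        seqs = seqs.copy()
        seqs[rows] = rc[got]
        diags[rows] = diags_rc[got]
        out.strand[rows] = 1
    out.seqs = seqs

    valid = diags >= 0
    any_valid = valid.any(axis=1)
    big = np.where(valid, diags, np.iinfo(np.int64).max)
    dmin = big.min(axis=1)
    small = np.where(valid, diags, np.iinfo(np.int64).min)
    dmax = small.max(axis=1)

    G = index.genome
    span = np.arange(L, dtype=np.int64)
    single = any_valid & (dmin == dmax)
    rows = np.flatnonzero(single)
    if rows.size:
        starts = dmin[rows]
        ok = (starts >= 0) & (starts + L <= G.size)
        rows, starts = rows[ok], starts[ok]
        mm = (seqs[rows] != G[starts[:, None] + span]).sum(axis=1)
        good = mm <= params.max_mismatch
        grows = rows[good]
        out.status[grows] = UNGAPPED
        out.gpos[grows] = starts[good]
        out.mm[grows] = mm[good]
        for r, d in zip(rows[~good], starts[~good]):
            out.status[r] = CLIPPED
            out.gpos[r] = d
            out.clipped.append(_ClipRec(int(r), int(d)))

    multi = any_valid & (dmax > dmin)
    for r in np.flatnonzero(multi):
        ds = [int(d) for d in diags[r] if d >= 0]
        distinct = sorted(set(ds))
        if len(distinct) != 2 or ds != sorted(ds):
            continue  # inconsistent anchors; leave unmapped
        dL, dR = distinct
        delta = dR - dL
        if delta > params.max_split_gap:
            continue
        if dL < 0 or dR + L > G.size:
            continue
        cL, lL = index.to_local(dL)
        cR, _ = index.to_local(dR + L - 1)
        if cL != cR:
            continue
        seq = seqs[r]
        mmL = np.concatenate([[0], np.cumsum(seq != G[dL : dL + L])])
        mmR = np.concatenate([[0], np.cumsum(seq != G[dR : dR + L])])
        # matches if junction at q: left part on dL, right part on dR
        score = (np.arange(L + 1) - mmL) + ((L - mmR[L]) - (np.arange(L + 1) - mmR))
        q = int(np.argmax(score[1:L]) + 1)
        mm_tot = int(mmL[q] + mmR[L] - mmR[q])
        if mm_tot > params.max_mismatch:
            out.status[r] = CLIPPED
            out.gpos[r] = dL
            out.clipped.append(_ClipRec(int(r), int(dL)))
            continue
        gs = dL + q
        while q > 1 and G[gs - 1] == G[gs + delta - 1]:
            gs -= 1
            q -= 1
        rec = _GapRec(int(r), int(dL), q, int(gs), delta, mm_tot)
        if delta <= params.small_gap_max:
            out.status[r] = GAPPED
            out.gapped.append(rec)
        else:
            out.status[r] = SPLIT
            out.splits.append(rec)
        out.gpos[r] = dL
    return out


# ---------------------------------------------------------------------------
# deletion calling


@dataclass
class DeletionCall:
    """A called deletion (0-based half-open, chromosome coordinates)."""

    chrom: str
    start: int
    end: int
    size: int
    evidence: str  # 'gapped' | 'split' | 'insert'
    n_support: int
    genotype: str = "het"

    def __post_init__(self) -> None:
        if self.end - self.start != self.size or self.size < 1:
            raise ValueError("inconsistent deletion interval")


def _cluster_gaps(records: list[_GapRec], tol: int):
    """Group gap records by (position, size) within ``tol``; consensus is the
    most frequent exact (position, size) pair of the cluster."""
    counts = Counter((rec.gap_gpos, rec.gap_size) for rec in records)
    clusters: list[dict] = []
    for (gpos, size), cnt in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        home = None
        for cl in clusters:
            if abs(gpos - cl["gpos"]) <= tol and abs(size - cl["size"]) <= tol:
                home = cl
                break
        if home is None:
            clusters.append({"gpos": gpos, "size": size, "keys": {(gpos, size)}, "n": cnt})
        else:
            home["keys"].add((gpos, size))
            home["n"] += cnt
    for cl in clusters:
        cl["rows"] = [rec.row for rec in records if (rec.gap_gpos, rec.gap_size) in cl["keys"]]
    return clusters


def _mismatches(a: np.ndarray, b: np.ndarray) -> int:
    return int((a != b).sum())


def call_small_deletions(
    alns: AlignmentSet,
    min_support: int = 3,
    cluster_tol: int = 2,
    max_mismatch: int | None = None,
) -> list[DeletionCall]:
    """Call deletions from gapped alignments (consensus over >= min_support).

    Soft-clipped reads anchored near a candidate are re-genotyped against
    the deletion allele (both anchor interpretations are tried) and added
    to the support count; each read supports at most one candidate.
    """
    max_mm = 5 if max_mismatch is None else max_mismatch
    G = alns.index.genome
    L = alns.read_len
    clusters = _cluster_gaps(alns.gapped, cluster_tol)
    clusters.sort(key=lambda cl: -cl["n"])
    pool = list(alns.clipped)
    calls = []
    ungapped_starts = np.sort(alns.gpos[alns.status == UNGAPPED])
    for cl in clusters:
        s, d = cl["gpos"], cl["size"]
        support = len(set(cl["rows"]))
        remaining = []
        for clip in pool:
            seq = alns.seqs[clip.row]
            matched = False
            for a in (clip.diag, clip.diag - d):  # anchor on left or right segment
                q = s - a
                if 1 <= q <= L - 1 and a >= 0 and s + d + (L - q) <= G.size:
                    mm = _mismatches(seq[:q], G[a : a + q]) + _mismatches(
                        seq[q:], G[s + d : s + d + L - q]
                    )
                    if mm <= max_mm:
                        matched = True
                        break
            if matched:
                support += 1
            else:
                remaining.append(clip)
        pool = remaining
        if support < min_support:
            continue
        chrom, start = alns.index.to_local(s)
        lo = np.searchsorted(ungapped_starts, s - L + 5)
        hi = np.searchsorted(ungapped_starts, s - 5, side="right")
        genotype = "het" if hi - lo >= 2 else "hom"
        calls.append(DeletionCall(chrom, start, start + d, d, "gapped", support, genotype))
    return calls


def call_large_deletions(
    alns: AlignmentSet,
    min_support: int = 3,
    cluster_tol: int = 5,
    insert_mean: float = 400.0,
    insert_sd: float = 40.0,
) -> list[DeletionCall]:
    """Call large deletions from split reads and discordant insert pairs.

    Split-read breakpoints vote within ``cluster_tol``; discordant pairs
    (observed fragment span > mean + 3 sd) corroborate a split cluster or,
    in groups of >= ``min_support`` with mutually consistent inner
    intervals, support an insert-evidence call on their own.
    """
    L = alns.read_len
    n = alns.n_pairs
    calls: list[DeletionCall] = []

    inserts = alns.pair_inserts()
    cutoff = insert_mean + 3.0 * insert_sd
    disc = np.flatnonzero(~np.isnan(inserts) & (inserts > cutoff))
    end = alns.end_gpos()
    inner = []
    for p in disc:
        i, j = p, p + n
        lo = int(min(alns.gpos[i], alns.gpos[j]))
        hi = int(max(end[i], end[j]))
        inner.append((lo + L, hi - L, float(inserts[p]) - insert_mean))
    inner.sort()

    used = [False] * len(inner)
    for cl in sorted(_cluster_gaps(alns.splits, cluster_tol), key=lambda c: -c["n"]):
        s, d = cl["gpos"], cl["size"]
        support = len(set(cl["rows"]))
        n_disc = 0
        for idx, (lo, hi, _est) in enumerate(inner):
            if used[idx]:
                continue
            if lo <= s + cluster_tol and hi >= s + d - cluster_tol:
                n_disc += 1
                used[idx] = True
        if support >= min_support or (support >= 1 and support + n_disc >= min_support):
            chrom, start = alns.index.to_local(s)
            calls.append(DeletionCall(chrom, start, start + d, d, "split", support))

    # discordant-only clusters (no split support, e.g. a junction missed by
    # anchoring) — coarse breakpoints, matched downstream by overlap. The
    # implied size must clear the insert-length noise floor: random pairs
    # pass the 3-sd discordance cut at ~0.1% and can collide, so a
    # standalone call needs a median size well beyond the tail.
    min_size = 4.5 * insert_sd
    group: list[tuple[int, int, float]] = []
    lo_run = hi_run = 0

    def flush():
        if len(group) >= min_support:
            size = int(np.median([g[2] for g in group]))
            if size >= min_size:
                mid = (lo_run + hi_run) // 2
                gstart = mid - size // 2
                chrom, start = alns.index.to_local(int(gstart))
                cand = DeletionCall(chrom, start, start + size, size, "insert", len(group))
                # split evidence nearby supersedes the coarse insert estimate
                if not any(
                    c.chrom == cand.chrom and c.start < cand.end and cand.start < c.end
                    for c in calls
                ):
                    calls.append(cand)

    for idx, (lo, hi, est) in enumerate(inner):
        if used[idx]:
            continue
        if not group or lo > hi_run or min(hi, hi_run) <= max(lo, lo_run):
            flush()
            group, lo_run, hi_run = [], lo, hi
        group.append((lo, hi, est))
        lo_run, hi_run = max(lo_run, lo), min(hi_run, hi)
    flush()
    return calls


def _reciprocal_overlap(a: DeletionCall, b: DeletionCall) -> float:
    if a.chrom != b.chrom:
        return 0.0
    ov = min(a.end, b.end) - max(a.start, b.start)
    return max(0.0, ov) / max(a.size, b.size)


def merge_deletion_calls(*groups: list[DeletionCall], min_reciprocal: float = 0.5):
    """Dedupe calls across callers by reciprocal overlap >= ``min_reciprocal``;
    gapped evidence beats split beats insert."""
    rank = {"gapped": 0, "split": 1, "insert": 2}
    allc = sorted(
        (c for g in groups for c in g), key=lambda c: (rank[c.evidence], -c.n_support)
    )
    kept: list[DeletionCall] = []
    for c in allc:
        if not any(_reciprocal_overlap(c, k) >= min_reciprocal for k in kept):
            kept.append(c)
    kept.sort(key=lambda c: (c.chrom, c.start))
    return kept


def call_deletions(
    alns: AlignmentSet,
    min_support: int = 3,
    insert_mean: float = 400.0,
    insert_sd: float = 40.0,
) -> list[DeletionCall]:
    small = call_small_deletions(alns, min_support=min_support)
    large = call_large_deletions(
        alns, min_support=min_support, insert_mean=insert_mean, insert_sd=insert_sd
    )
    return merge_deletion_calls(small, large)


def match_deletion_calls(
    calls: list[DeletionCall],
    truth: pd.DataFrame,
    breakpoint_tol: int = 10,
    min_reciprocal: float = 0.5,
) -> np.ndarray:
    """Boolean per truth row: matched by a call (each call matches once).

    A call matches a truth deletion if both breakpoints lie within
    ``breakpoint_tol`` or the reciprocal overlap is >= ``min_reciprocal``.
    """
    matched = np.zeros(len(truth), dtype=bool)
    free = list(range(len(calls)))
    for t_i, row in enumerate(truth.itertuples(index=False)):
        best, best_key = None, None
        for c_i in free:
            c = calls[c_i]
            if c.chrom != row.chrom:
                continue
            bp_ok = abs(c.start - row.start) <= breakpoint_tol and abs(c.end - row.end) <= breakpoint_tol
            ov = min(c.end, row.end) - max(c.start, row.start)
            recip = max(0, ov) / max(c.size, row.size)
            if bp_ok or recip >= min_reciprocal:
                key = (-recip, abs(c.start - row.start))
                if best is None or key < best_key:
                    best, best_key = c_i, key
        if best is not None:
            matched[t_i] = True
            free.remove(best)
    return matched


# ---------------------------------------------------------------------------
# sensitivity harness


@dataclass
class SensitivityConfig:
    """Study conditions of the deletion-sensitivity simulation."""

    chrom_spec: list = field(default_factory=lambda: list(DEFAULT_CHROM_SPEC))
    mean_spacing: float = 500.0
    n_deletions: tuple[int, int] = (5, 25)
    read: ReadSimParams = field(default_factory=ReadSimParams)
    map: MapParams = field(default_factory=MapParams)
    min_support: int = 3
    breakpoint_tol: int = 10
    min_reciprocal: float = 0.5


@dataclass
class SensitivityReport:
    """Per-size-bin and overall deletion-detection sensitivity."""

    table: pd.DataFrame  # bin_lo, bin_hi, n_truth, n_detected, sensitivity, ci_lo, ci_hi
    overall: float
    ci: tuple[float, float]
    n_truth: int
    n_detected: int
    truth_sizes: np.ndarray
    detected_sizes: np.ndarray

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def plot(self, path, bin_width: int = 50) -> None:
        """Histogram of detected deletion sizes (50-bp bins by default)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        hi = max(int(self.truth_sizes.max()), bin_width)
        edges = np.arange(0, hi + bin_width, bin_width)
        fig, ax = plt.subplots(figsize=(6, 3.5))
        ax.hist(self.detected_sizes, bins=edges, color="#4477aa")
        ax.set_xlabel("deletion size (bp)")
        ax.set_ylabel("detected")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def _proportion_ci(k: int, n: int) -> tuple[float, float]:
    from scipy.stats import binomtest

    ci = binomtest(k, n).proportion_ci(confidence_level=0.95, method="exact")
    return float(ci.low), float(ci.high)


def estimate_sensitivity(
    n_genomes: int = 20,
    size_range: tuple[int, int] = (1, 20),
    seed: int = 0,
    config: SensitivityConfig | None = None,
    bin_width: int = 50,
    ref: ReferenceGenome | None = None,
    index: KmerIndex | None = None,
) -> SensitivityReport:
    """Spike, sequence, map, call, and score deletion-detection sensitivity.

    For each simulated genome: deletions are spiked onto one of four
    haplotypes, one haplotype is sampled as the offspring, which is
    sequenced (together with the male haplotype contribution) and run
    through the deletion callers; calls are matched to the truth deletions
    carried by the offspring. Sensitivity is pooled over genomes.
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    cfg = SensitivityConfig() if config is None else config
    rng = np.random.default_rng(seed)

    if ref is None:
        ref = build_reference(cfg.chrom_spec, int(rng.integers(2**31 - 1)))
    if index is None:
        index = KmerIndex(ref, k=cfg.map.k)

    truth_sizes, matched_all = [], []
    for _ in range(n_genomes):
        s1, s2, s3, s4 = (int(rng.integers(2**31 - 1)) for _ in range(4))
        snps = place_snps(ref, cfg.mean_spacing, s1, chroms=ref.female_chroms())
        spike = spike_deletions(ref, cfg.n_deletions, size_range, s2, snps=snps)
        male = make_male_genome(ref, s3, cfg.mean_spacing, exclude=snps)
        offspring = spike.haplotypes[spike.offspring].materialize()
        reads = simulate_reads_pair(offspring, male.genome, cfg.read, s4)
        alns = map_reads(reads, index, cfg.map)
        calls = call_deletions(
            alns,
            min_support=cfg.min_support,
            insert_mean=cfg.read.insert_mean,
            insert_sd=cfg.read.insert_sd,
        )
        truth = spike.offspring_truth()
        m = match_deletion_calls(calls, truth, cfg.breakpoint_tol, cfg.min_reciprocal)
        truth_sizes.append(truth["size"].to_numpy())
        matched_all.append(m)

    sizes = np.concatenate(truth_sizes)
    matched = np.concatenate(matched_all)
    if sizes.size == 0:
        raise ValueError("no truth deletions: sensitivity undefined")

    bins = (sizes - 1) // bin_width
    rows = []
    for b in range(int(bins.max()) + 1):
        sel = bins == b
        nt, nd = int(sel.sum()), int(matched[sel].sum())
        if nt == 0:
            continue
        lo, hi = _proportion_ci(nd, nt)
        rows.append((b * bin_width + 1, (b + 1) * bin_width, nt, nd, nd / nt, lo, hi))
    table = pd.DataFrame(
        rows,
        columns=["bin_lo", "bin_hi", "n_truth", "n_detected", "sensitivity", "ci_lo", "ci_hi"],
    )
    k, n = int(matched.sum()), int(sizes.size)
    return SensitivityReport(
        table=table,
        overall=k / n,
        ci=_proportion_ci(k, n),
        n_truth=n,
        n_detected=k,
        truth_sizes=sizes,
        detected_sizes=sizes[matched],
    )


def simulate_reads_pair(hap_a, hap_b, read_params: ReadSimParams, seed: int) -> ReadSet:
    """Paired-end reads over a diploid genome given as two genome dicts."""
    from .synthgenome import simulate_reads

    return simulate_reads([hap_a, hap_b], read_params, seed)


# ---------------------------------------------------------------------------
# expected-deletion arithmetic


@dataclass
class ExpectedDeletions:
    """Closed-form expectation for NHEJ-scar recovery in a sequenced cohort."""

    n_dsbs: float
    hr_reduction: float
    n_progeny: int
    n_chromatids: int
    nhej_per_meiosis: float
    per_progeny_mean: float
    cohort_total: float
    expected_detected_small: int | None
    expected_detected_large: int | None


def expected_deletions(
    n_dsbs: float,
    hr_reduction: float,
    n_progeny: int,
    sens_small: float | None = None,
    sens_large: float | None = None,
) -> ExpectedDeletions:
    """Expected NHEJ deletions in a cohort and how many should be detected.

    Each meiosis makes ``n_dsbs`` DSBs of which a fraction ``hr_reduction``
    cannot complete homologous recombination and are repaired by NHEJ; each
    offspring inherits one of four chromatids, so the per-progeny mean is
    ``n_dsbs * hr_reduction / 4``. Expected detected counts apply a
    detection sensitivity and round down (a conservative floor).
    """
    if n_dsbs < 0 or n_progeny < 0:
        raise ValueError("inputs must be >= 0")
    for frac in (hr_reduction, sens_small, sens_large):
        if frac is not None and not 0.0 <= frac <= 1.0:
            raise ValueError("fractions must be in [0, 1]")
    nhej = n_dsbs * hr_reduction
    per_progeny = nhej / 4.0
    cohort = per_progeny * n_progeny
    det = lambda s: None if s is None else int(math.floor(cohort * s))
    return ExpectedDeletions(
        n_dsbs=n_dsbs,
        hr_reduction=hr_reduction,
        n_progeny=n_progeny,
        n_chromatids=4,
        nhej_per_meiosis=nhej,
        per_progeny_mean=per_progeny,
        cohort_total=cohort,
        expected_detected_small=det(sens_small),
        expected_detected_large=det(sens_large),
    )
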