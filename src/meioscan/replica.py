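"""End-to-end cohort replica: simulation -> calling -> statistics report.

Simulates a cohort of offspring from females in which a configurable
fraction of DSBs cannot complete homologous recombination (the
heterosynapsis mutant condition), sequences each offspring together with
the male haplotype contribution, calls crossovers, gene conversions and de
novo deletions from the reads, and assembles a report of event counts,
percent reductions against a wild-type-derived expectation, the
expected-deletion table and per-sample karyotypes. Fully seeded; two runs
with the same config produce identical reports.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .delscan import (
    KmerIndex,
    call_deletions,
    expected_deletions,
    map_reads,
    MapParams,
)
from .recombcall import (
    EventSummary,
    RecombEvent,
    call_events,
    classify_karyotype,
    event_summary,
    genotype_snps,
    informative_markers,
)
from .synthgenome import (
    DEFAULT_CHROM_SPEC,
    MeiosisParams,
    ParentalGenomes,
    ReadSimParams,
    build_reference,
    make_male_genome,
    place_snps,
    simulate_meiosis,
    simulate_reads,
)

__all__ = ["ReplicaConfig", "ReplicaReport", "run_paper_replica", "verify_report"]


@dataclass
class ReplicaConfig:
    seed: int = 0
    n_mutant: int = 28
    n_wildtype: int = 196
    chrom_spec: list = field(default_factory=lambda: list(DEFAULT_CHROM_SPEC))
    mean_spacing: float = 500.0
    wildtype: MeiosisParams = field(default_factory=MeiosisParams)
    mutant: MeiosisParams = field(
        default_factory=lambda: MeiosisParams(hr_fail_prob=0.8, nhej_deletion_range=(0, 0))
    )
    read: ReadSimParams = field(default_factory=ReadSimParams)
    map: MapParams = field(default_factory=MapParams)
    min_support: int = 3
    min_flank_markers: int = 2
    max_gc_span: int = 10_000
    # expected-deletion table inputs (the conservative DSB assumption and
    # the simulation-derived detection sensitivities)
    assumed_dsbs: float = 15.0
    assumed_hr_reduction: float = 0.8
    sens_small: float = 0.85
    sens_large: float = 0.65


@dataclass
class ReplicaReport:
    config: ReplicaConfig
    report: dict
    events_by_offspring: list[list[RecombEvent]]
    deletion_calls: list
    karyotypes: list
    summary: EventSummary


def _wildtype_expectation(parents, params, n, rng):
    """Per-fly CO and detectable NCO-GC means on the sampled chromatid."""
    snps = parents.snps
    co, nco = 0, 0
    for _ in range(n):
        m = simulate_meiosis(parents, params, int(rng.integers(2**31 - 1)))
        co += m.truth.co_on_offspring()
        k = m.truth.offspring_chromatid
        for chrom, start, end, chromatid in m.truth.nco:
            if chromatid != k:
                continue
            pos = snps.positions(chrom)
            if np.searchsorted(pos, end) - np.searchsorted(pos, start) >= 1:
                nco += 1
    return co / n, nco / n


def run_paper_replica(config: ReplicaConfig | None = None, outdir=None) -> ReplicaReport:
    """Run the full simulated-cohort analysis and assemble the report."""
    cfg = ReplicaConfig() if config is None else config
    rng = np.random.default_rng(cfg.seed)

    ref = build_reference(cfg.chrom_spec, int(rng.integers(2**31 - 1)))
    index = KmerIndex(ref, k=cfg.map.k)
    snps = place_snps(ref, cfg.mean_spacing, int(rng.integers(2**31 - 1)), chroms=ref.female_chroms())
    male = make_male_genome(ref, int(rng.integers(2**31 - 1)), cfg.mean_spacing, exclude=snps)
    parents = ParentalGenomes.from_reference(ref, snps)

    exp_co, exp_nco = _wildtype_expectation(parents, cfg.wildtype, cfg.n_wildtype, rng)

    events_by_offspring: list[list[RecombEvent]] = []
    deletion_calls = []
    karyotypes = []
    del_rows = []
    for sample_i in range(cfg.n_mutant):
        m = simulate_meiosis(parents, cfg.mutant, int(rng.integers(2**31 - 1)))
        offspring = m.offspring_genome()
        reads = simulate_reads([offspring, male.genome], cfg.read, int(rng.integers(2**31 - 1)))
        alns = map_reads(reads, index, cfg.map)

        genotypes = genotype_snps(alns, snps)
        vectors = informative_markers(genotypes, snps)
        events: list[RecombEvent] = []
        for chrom, v in vectors.items():
            if int((v.calls != ".").sum()) >= 2:
                events.extend(call_events(v, cfg.min_flank_markers, cfg.max_gc_span))
        events_by_offspring.append(events)

        dels = call_deletions(
            alns,
            min_support=cfg.min_support,
            insert_mean=cfg.read.insert_mean,
            insert_sd=cfg.read.insert_sd,
        )
        deletion_calls.extend(dels)
        for d in dels:
            del_rows.append((f"sample{sample_i:02d}", d.chrom, d.start, d.end, d.size, d.evidence, d.n_support))

        karyotypes.append(
            classify_karyotype(
                alns.depth_per_chrom(),
                x=ref.x_name() or "X",
                y=ref.y_name() or "Y",
                sample=f"sample{sample_i:02d}",
            )
        )

    summary = event_summary(events_by_offspring, (exp_co, exp_nco))
    expected = expected_deletions(
        cfg.assumed_dsbs,
        cfg.assumed_hr_reduction,
        cfg.n_mutant,
        sens_small=cfg.sens_small,
        sens_large=cfg.sens_large,
    )
    report = {
        "seed": cfg.seed,
        "config_hash": mio.config_hash(cfg),
        "n_mutant": cfg.n_mutant,
        "n_wildtype": cfg.n_wildtype,
        "expected_per_fly": {"co": exp_co, "nco_gc": exp_nco},
        "co": {
            "observed_total": summary.co_total,
            "expected_total": exp_co * cfg.n_mutant,
            "percent_reduction": summary.co_reduction,
            "one_sample_t": list(summary.co_test),
        },
        "nco_gc": {
            "observed_total": summary.nco_total,
            "expected_total": exp_nco * cfg.n_mutant,
            "percent_reduction": summary.nco_reduction,
            "one_sample_t": list(summary.nco_test),
        },
        "deletions": {"n_calls": len(deletion_calls)},
        "expected_deletions": dataclasses.asdict(expected),
        "karyotypes": {k.sample: k.klass for k in karyotypes},
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ev_rows = []
        for i, events in enumerate(events_by_offspring):
            for e in events:
                lo, hi = e.breakpoint_interval if e.kind == "CO" else e.tract_min
                ev_rows.append(
                    (f"sample{i:02d}", e.chrom, e.kind, lo, hi, e.n_support_markers, ",".join(e.flags))
                )
        pd.DataFrame(
            ev_rows,
            columns=["sample", "chrom", "kind", "start", "end", "n_support_markers", "flags"],
        ).to_csv(outdir / "events.tsv", sep="\t", index=False)
        pd.DataFrame(
            del_rows,
            columns=["sample", "chrom", "start", "end", "size", "evidence", "n_support"],
        ).to_csv(outdir / "deletions.tsv", sep="\t", index=False)
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        mio.write_manifest(outdir, cfg, cfg.seed)

    return ReplicaReport(cfg, report, events_by_offspring, deletion_calls, karyotypes, summary)


def verify_report(outdir) -> bool:
    """Recompute the report's totals from the raw event tables.

    An independent check over the emitted TSVs: CO/NCO-GC totals and the
    deletion-call count in report.json must equal the column tallies.
    """
    outdir = Path(outdir)
    report = json.loads((outdir / "report.json").read_text())
    events = pd.read_csv(outdir / "events.tsv", sep="\t")
    dels = pd.read_csv(outdir / "deletions.tsv", sep="\t")
    co = int((events["kind"] == "CO").sum()) if len(events) else 0
    nco = int((events["kind"] == "NCO_GC").sum()) if len(events) else 0
    return (
        co == report["co"]["observed_total"]
        and nco == report["nco_gc"]["observed_total"]
        and len(dels) == report["deletions"]["n_calls"]
    )
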