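"""End-to-end simulation study: does the filter cascade plus cosegregation
fine-mapping recover a planted causal mutation?

Each replicate plants a semidominant causal SNP on a stand-in wheat genome
among a background of EMS mutations, simulates a backcross-then-self (BC1F2)
family, pools phenotype-selected bulks, samples exome-like read depths,
runs the three-bulk filter, and fine-maps with error-free marker calls on
the same family.  The report records, per replicate, whether the causal
mutation survived the filter and whether it lies inside the narrowed
interval.

Determinism: one master seed is split per replicate index with
``numpy.random.SeedSequence`` spawning, then per stage within a replicate,
so results are independent of execution order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import bulkfilter, finemap, simcross
from ._records import MutationRecord
from .bulkfilter import FilterConfig, HET_BULK, HOM_BULK, WT_BULK
from .finemap import Call, Interval, MarkerCall, phenotype_class_of
from .simcross import (
    BACKCROSS,
    SELF,
    CausalSpec,
    CrossPlan,
    GenomeModel,
    Individual,
    MutagenesisConfig,
    ReadDepthModel,
    default_wheat_genome,
)

__all__ = ["RunConfig", "RecoveryReport", "ReplicateResult", "run_end_to_end", "write_report", "read_report"]

logger = logging.getLogger("spikemap")

SCHEMA_VERSION = 1

_DOSAGE_TO_CALL = {0: Call.HOM_REF, 1: Call.HET, 2: Call.HOM_ALT}


@dataclass
class RunConfig:
    """Full configuration of one simulation study.

    Defaults describe the study conditions: ~2500 induced mutations at 98%
    EMS spectrum on a three-chromosome group-1 stand-in genome, a BC1F2
    family of 200 plants, three 20-plant bulks sequenced to a mean 180x
    pooled depth with a 1e-3 per-read error rate, the 0.4-0.6 / 0.9-1.0
    frequency windows, and a 79.5-Mb fine-mapping search radius.
    """

    # genome: list of (name, length, cM/Mb); None = group-1 stand-in
    chromosomes: Optional[list[tuple[str, int, float]]] = None
    mutations_per_line: int = 2500
    ems_fraction: float = 0.98
    causal_chromosome: str = "1D"
    causal_position: int = 217_644_011
    cross_steps: tuple[str, ...] = (BACKCROSS, SELF)
    progeny_per_step: int = 200
    family_size: int = 200
    bulk_size: int = 20
    mean_depth: float = 180.0
    error_rate: float = 0.001
    filter: FilterConfig = field(default_factory=FilterConfig)
    use_parent_whitelist: bool = True
    finemap_radius: int = 79_500_000
    n_replicates: int = 100
    seed: int = 1

    def genome(self) -> GenomeModel:
        if self.chromosomes is None:
            return default_wheat_genome()
        return GenomeModel(
            [simcross.Chromosome(n, int(l), float(r)) for n, l, r in self.chromosomes]
        )

    # -- round-trippable file form ------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cross_steps"] = list(self.cross_steps)
        d["filter"] = {
            **dataclasses.asdict(self.filter),
            "whitelist": None
            if self.filter.whitelist is None
            else sorted(list(k) for k in self.filter.whitelist),
            "het_window": list(self.filter.het_window),
            "hom_window": list(self.filter.hom_window),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "filter" in d and isinstance(d["filter"], dict):
            f = dict(d["filter"])
            if f.get("whitelist") is not None:
                f["whitelist"] = frozenset(
                    (str(c), int(p), r, a) for c, p, r, a in f["whitelist"]
                )
            f["het_window"] = tuple(f.get("het_window", (0.4, 0.6)))
            f["hom_window"] = tuple(f.get("hom_window", (0.9, 1.0)))
            d["filter"] = FilterConfig(**f)
        if d.get("chromosomes") is not None:
            d["chromosomes"] = [tuple(c) for c in d["chromosomes"]]
        if "cross_steps" in d:
            d["cross_steps"] = tuple(d["cross_steps"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ReplicateResult:
    replicate: int
    n_mutations: int = 0
    n_retained: int = 0
    causal_retained: bool = False
    interval_start: Optional[int] = None
    interval_end: Optional[int] = None
    causal_in_interval: bool = False
    error: Optional[str] = None


@dataclass
class RecoveryReport:
    """Aggregate outcome of the simulation study."""

    n_replicates: int
    n_causal_retained: int
    n_causal_in_final_interval: int
    mean_candidates_after_filter: float
    rows: list[ReplicateResult]
    config: dict = field(default_factory=dict)
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if not 0 <= self.n_causal_retained <= self.n_replicates:
            raise ValueError("n_causal_retained out of range")


def _stage_seed(ss: np.random.SeedSequence) -> int:
    # keep derived seeds below 2**31 for portability of config files
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _plant_causal(
    mutations: list[MutationRecord],
    config: RunConfig,
    genome: GenomeModel,
) -> tuple[list[MutationRecord], int]:
    """Insert the causal G>A missense SNP, replacing any colliding site."""
    causal = MutationRecord(
        id="causal",
        chromosome=config.causal_chromosome,
        position=config.causal_position,
        ref="G",
        alt="A",
        gene_id="HB-D2",
        effect_class="missense",
    )
    kept = [
        m
        for m in mutations
        if not (m.chromosome == causal.chromosome and m.position == causal.position)
    ]
    kept.append(causal)
    order = {n: i for i, n in enumerate(genome.names)}
    kept.sort(key=lambda m: (order[m.chromosome], m.position))
    return kept, kept.index(causal)


def _run_replicate(rep: int, config: RunConfig, ss: np.random.SeedSequence) -> ReplicateResult:
    result = ReplicateResult(replicate=rep)
    genome = config.genome()
    s_mut, s_cross, s_bulk, s_reads, s_phen = ss.spawn(5)

    mutations = simcross.simulate_ems_mutations(
        genome,
        MutagenesisConfig(
            mutations_per_line=config.mutations_per_line,
            ems_fraction=config.ems_fraction,
            seed=_stage_seed(s_mut),
        ),
    )
    if not mutations:
        result.error = "no mutations simulated"
        return result
    mutations, causal_index = _plant_causal(mutations, config, genome)
    causal = mutations[causal_index]
    result.n_mutations = len(mutations)

    founder = Individual.f1_heterozygote(len(mutations))
    plan = CrossPlan(config.cross_steps, config.progeny_per_step)
    family = simcross.simulate_cross(
        plan,
        mutations,
        genome,
        founder,
        n_progeny=config.family_size,
        seed=_stage_seed(s_cross),
        carrier_index=causal_index,
    )
    spec = CausalSpec(causal_mutation_id=causal.id)
    simcross.assign_phenotypes(family, spec, mutations, seed=_stage_seed(s_phen))

    selectors = {
        WT_BULK: lambda i: i.spikelet_phenotype == simcross.Spikelet.WILD_TYPE,
        HET_BULK: lambda i: i.spikelet_phenotype == simcross.Spikelet.PAIRED
        and i.leaf_phenotype == simcross.Leaf.NORMAL,
        HOM_BULK: lambda i: i.spikelet_phenotype == simcross.Spikelet.PAIRED
        and i.leaf_phenotype == simcross.Leaf.CURLED,
    }
    bulk_seeds = dict(zip(sorted(selectors), s_bulk.spawn(len(selectors))))
    read_seeds = dict(zip(sorted(selectors), s_reads.spawn(len(selectors))))
    counts_by_bulk = {}
    for bulk_id, selector in selectors.items():
        bulk = simcross.build_bulks(
            family,
            selector,
            config.bulk_size,
            seed=_stage_seed(bulk_seeds[bulk_id]),
            bulk_id=bulk_id,
        )
        model = ReadDepthModel(
            mean_depth=config.mean_depth,
            error_rate=config.error_rate,
            seed=_stage_seed(read_seeds[bulk_id]),
        )
        counts = simcross.sample_bulk_reads(bulk, mutations, model)
        counts_by_bulk[bulk_id] = {c.mutation_id: c for c in counts}

    fconfig = config.filter
    if config.use_parent_whitelist and fconfig.whitelist is None:
        fconfig = dataclasses.replace(
            fconfig, whitelist=frozenset(m.key for m in mutations)
        )
    candidates = bulkfilter.filter_three_bulk(mutations, counts_by_bulk, fconfig)
    result.n_retained = len(candidates.retained)
    result.causal_retained = causal.id in candidates.retained_ids
    if not candidates.retained:
        result.error = "empty candidate set"
        return result

    # Fine-mapping: anchor the search window at the best-supported candidate
    # chromosome, score all non-intron/non-silent parent mutations in the
    # window against the family with error-free marker calls, and narrow.
    chrom_votes: dict[str, int] = {}
    for m in candidates.retained:
        chrom_votes[m.chromosome] = chrom_votes.get(m.chromosome, 0) + 1
    target_chrom = max(chrom_votes, key=lambda c: (chrom_votes[c], c))
    anchor = int(
        np.median(
            [m.position for m in candidates.retained if m.chromosome == target_chrom]
        )
    )
    in_window = finemap.mutations_in_window(
        mutations, target_chrom, anchor, config.finemap_radius
    )
    markers, _ = finemap.exclude_by_effect(in_window)
    if not markers:
        result.error = "no markers after effect exclusion"
        return result
    index_of = {m.id: i for i, m in enumerate(mutations)}
    results_by_marker = {}
    positions = {}
    for marker in markers:
        mi = index_of[marker.id]
        calls = [
            MarkerCall(
                line_id=f"line_{j:04d}",
                marker_id=marker.id,
                call=_DOSAGE_TO_CALL[int(ind.dosages[mi])],
                phenotype_class=phenotype_class_of(
                    ind.spikelet_phenotype, ind.leaf_phenotype
                ),
            )
            for j, ind in enumerate(family)
        ]
        results_by_marker[marker.id] = finemap.cosegregation(calls)
        positions[marker.id] = marker.position
    chrom_len = genome.chromosome(target_chrom).length
    window = Interval(
        target_chrom,
        max(1, anchor - config.finemap_radius),
        min(chrom_len, anchor + config.finemap_radius),
    )
    interval = finemap.narrow_interval(results_by_marker, positions, window)
    result.interval_start = interval.start
    result.interval_end = interval.end
    result.causal_in_interval = (
        causal.chromosome == interval.chromosome
        and interval.contains(causal.position)
    )
    return result


def run_end_to_end(config: RunConfig) -> RecoveryReport:
    """Run the full simulation study and aggregate a recovery report.

    Stage errors are recorded per replicate and the run continues.
    """
    rows: list[ReplicateResult] = []
    t0 = time.time()
    for rep in range(config.n_replicates):
        rep_ss = np.random.SeedSequence(config.seed, spawn_key=(rep,))
        try:
            row = _run_replicate(rep, config, rep_ss)
        except Exception as exc:  # stage failures must not kill the study
            row = ReplicateResult(replicate=rep, error=f"{type(exc).__name__}: {exc}")
        rows.append(row)
        logger.debug("replicate %d: %s", rep, row)
    n_ret = sum(r.causal_retained for r in rows)
    n_in = sum(r.causal_in_interval for r in rows)
    mean_cand = (
        float(np.mean([r.n_retained for r in rows])) if rows else 0.0
    )
    logger.info(
        "study done in %.1fs: causal retained %d/%d, in interval %d/%d",
        time.time() - t0,
        n_ret,
        len(rows),
        n_in,
        len(rows),
    )
    return RecoveryReport(
        n_replicates=len(rows),
        n_causal_retained=n_ret,
        n_causal_in_final_interval=n_in,
        mean_candidates_after_filter=mean_cand,
        rows=rows,
        config=config.to_dict(),
    )


def write_report(report: RecoveryReport, outdir) -> dict[str, Path]:
    """Write the machine report (JSON), the per-replicate table (TSV), and a log.

    Returns the paths written, keyed by artifact name.
    """
    import pandas as pd

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "json": out / "report.json",
        "tsv": out / "replicates.tsv",
        "log": out / "run.log",
    }
    payload = {
        "schema_version": report.schema_version,
        "n_replicates": report.n_replicates,
        "n_causal_retained": report.n_causal_retained,
        "n_causal_in_final_interval": report.n_causal_in_final_interval,
        "mean_candidates_after_filter": report.mean_candidates_after_filter,
        "config": report.config,
        "rows": [dataclasses.asdict(r) for r in report.rows],
    }
    try:
        with open(paths["json"], "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
        pd.DataFrame([dataclasses.asdict(r) for r in report.rows]).to_csv(
            paths["tsv"], sep="\t", index=False
        )
        with open(paths["log"], "w") as fh:
            fh.write(f"spikemap study report (schema v{report.schema_version})\n")
            fh.write(f"effective config: {json.dumps(report.config, sort_keys=True)}\n")
            fh.write(
                f"causal retained {report.n_causal_retained}/{report.n_replicates}; "
                f"in final interval {report.n_causal_in_final_interval}/"
                f"{report.n_replicates}\n"
            )
    except OSError as exc:
        raise OSError(f"failed writing report under {out}: {exc}") from exc
    return paths


def read_report(path) -> RecoveryReport:
    """Read back a JSON machine report written by :func:`write_report`."""
    with open(path) as fh:
        payload = json.load(fh)
    rows = [ReplicateResult(**r) for r in payload["rows"]]
    return RecoveryReport(
        n_replicates=payload["n_replicates"],
        n_causal_retained=payload["n_causal_retained"],
        n_causal_in_final_interval=payload["n_causal_in_final_interval"],
        mean_candidates_after_filter=payload["mean_candidates_after_filter"],
        rows=rows,
        config=payload.get("config", {}),
        schema_version=payload.get("schema_version", SCHEMA_VERSION),
    )
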