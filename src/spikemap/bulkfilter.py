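"""Candidate-mutation filter cascade over per-bulk allele depths.

Bulked-segregant exome data for a semidominant locus gives a characteristic
frequency signature: the mutant allele is absent from the wild-type bulk,
near 0.5 in the bulk of heterozygous-phenotype plants, and near 1.0 in the
bulk of homozygous-phenotype plants.  This module applies that signature as
a deterministic rule cascade, in a three-bulk mode (WT / HET / HOM) and a
two-bulk mode (WT / MUT, mutant-bulk frequency strictly above a threshold).

Rules are evaluated in a fixed order so the rejection log is deterministic;
the retained set itself is order-independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from ._records import MutationRecord, SiteReadCounts, VALID_BASES

__all__ = [
    "FilterConfig",
    "CandidateSet",
    "Zygosity",
    "is_ems_type",
    "allele_frequency",
    "classify_zygosity",
    "filter_three_bulk",
    "filter_two_bulk",
    "index_counts",
    "read_counts_tsv",
    "read_counts_vcf",
    "write_candidates_tsv",
    "write_run_report",
    "WT_BULK",
    "HET_BULK",
    "HOM_BULK",
    "MUT_BULK",
]

WT_BULK = "WT"
HET_BULK = "HET"
HOM_BULK = "HOM"
MUT_BULK = "MUT"

EMS_PAIRS = {("G", "A"), ("C", "T")}

# Rejection reasons, in cascade order.
RULE_NOT_EMS = "not_ems_type"
RULE_NOT_WHITELISTED = "not_in_whitelist"
RULE_WT_ALT = "alt_reads_in_wt_bulk"
RULE_HET_WINDOW = "het_frequency_outside_window"
RULE_HOM_WINDOW = "hom_frequency_outside_window"
RULE_MUT_FREQ = "mut_frequency_below_threshold"
RULE_DEPTH = "insufficient_depth"
RULE_MISSING = "missing_counts"


def is_ems_type(ref: str, alt: str) -> bool:
    """True iff the substitution is an EMS transition: G>A or C>T."""
    for base in (ref, alt):
        if base not in VALID_BASES:
            raise ValueError(f"expected a single upper-case base in ACGT, got {base!r}")
    return (ref, alt) in EMS_PAIRS


def allele_frequency(counts: SiteReadCounts) -> Optional[float]:
    """Alt-allele frequency alt/(ref+alt); None when depth is zero.

    The undefined-frequency signal is distinct from 0.0: a site covered by
    188 reference reads has frequency 0.0, a site with no reads has none.
    """
    return counts.frequency


class Zygosity:
    REFERENCE = "reference"
    HETEROZYGOUS = "heterozygous"
    HOMOZYGOUS = "homozygous"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the filter cascade.

    ``het_window`` and ``hom_window`` are closed intervals of alt-allele
    frequency.  ``whitelist`` is a set of (chromosome, position, ref, alt)
    keys of previously predicted mutations of the parent line; ``None``
    disables the rule.  ``wt_max_alt_reads`` tolerates sequencing-error alt
    reads in the wild-type bulk.  The two-bulk mutant threshold is strict
    (frequency must exceed it).
    """

    mode: str = "three_bulk"
    ems_only: bool = True
    whitelist: Optional[frozenset[tuple[str, int, str, str]]] = None
    wt_max_alt_reads: int = 2
    het_window: tuple[float, float] = (0.4, 0.6)
    hom_window: tuple[float, float] = (0.9, 1.0)
    mutant_bulk_min_freq: float = 0.8
    min_depth: int = 10
    reference_tolerance: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("three_bulk", "two_bulk"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for lo, hi in (self.het_window, self.hom_window):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"invalid frequency window [{lo}, {hi}]")
        if self.het_window[1] >= self.hom_window[0]:
            raise ValueError("het and hom windows overlap")
        if not 0.0 <= self.mutant_bulk_min_freq <= 1.0:
            raise ValueError("mutant_bulk_min_freq must be in [0, 1]")
        if self.wt_max_alt_reads < 0 or self.min_depth < 0:
            raise ValueError("count thresholds must be >= 0")
        if self.whitelist is not None and not isinstance(self.whitelist, frozenset):
            object.__setattr__(self, "whitelist", frozenset(self.whitelist))


def classify_zygosity(freq: float, config: FilterConfig) -> str:
    """Classify an alt frequency as reference / het / hom / ambiguous.

    Windows are closed at both ends; a frequency at or below the reference
    tolerance (default exactly 0) is called reference.
    """
    if not 0.0 <= freq <= 1.0:
        raise ValueError(f"frequency must be in [0, 1], got {freq}")
    if freq <= config.reference_tolerance:
        return Zygosity.REFERENCE
    if config.het_window[0] <= freq <= config.het_window[1]:
        return Zygosity.HETEROZYGOUS
    if config.hom_window[0] <= freq <= config.hom_window[1]:
        return Zygosity.HOMOZYGOUS
    return Zygosity.AMBIGUOUS


@dataclass
class CandidateSet:
    """Filter output: retained records with per-bulk frequencies, plus the
    first failing rule for every rejected input mutation."""

    retained: list[MutationRecord]
    frequencies: dict[str, dict[str, Optional[float]]]
    rejection_log: dict[str, str]

    @property
    def retained_ids(self) -> set[str]:
        return {m.id for m in self.retained}

    def rule_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rule in self.rejection_log.values():
            counts[rule] = counts.get(rule, 0) + 1
        return counts


def index_counts(
    counts: Sequence[SiteReadCounts],
) -> dict[str, dict[str, SiteReadCounts]]:
    """Index a flat count list as bulk_id -> mutation_id -> counts."""
    out: dict[str, dict[str, SiteReadCounts]] = {}
    for c in counts:
        out.setdefault(c.bulk_id, {})[c.mutation_id] = c
    return out


def _check_bulks(
    counts_by_bulk: Mapping[str, Mapping[str, SiteReadCounts]],
    expected: set[str],
) -> None:
    got = set(counts_by_bulk)
    if got != expected:
        raise ValueError(
            f"bulk id mismatch: expected {sorted(expected)}, got {sorted(got)}"
        )


def _first_failure_three(
    m: MutationRecord,
    per_bulk: dict[str, Optional[SiteReadCounts]],
    config: FilterConfig,
) -> Optional[str]:
    """First failing rule for one mutation in three-bulk mode, or None."""
    if any(per_bulk[b] is None for b in (WT_BULK, HET_BULK, HOM_BULK)):
        return RULE_MISSING
    if config.ems_only and not is_ems_type(m.ref, m.alt):
        return RULE_NOT_EMS
    if config.whitelist is not None and m.key not in config.whitelist:
        return RULE_NOT_WHITELISTED
    wt, het, hom = per_bulk[WT_BULK], per_bulk[HET_BULK], per_bulk[HOM_BULK]
    if wt.alt_reads > config.wt_max_alt_reads:
        return RULE_WT_ALT
    # Cross-bulk consistency: a het call in the HET bulk must pair with a
    # hom call in the HOM bulk; a frequency needs depth to be defined.
    f_het = het.frequency
    if f_het is None:
        return RULE_DEPTH
    if not config.het_window[0] <= f_het <= config.het_window[1]:
        return RULE_HET_WINDOW
    f_hom = hom.frequency
    if f_hom is None:
        return RULE_DEPTH
    if not config.hom_window[0] <= f_hom <= config.hom_window[1]:
        return RULE_HOM_WINDOW
    if any(per_bulk[b].depth < config.min_depth for b in (WT_BULK, HET_BULK, HOM_BULK)):
        return RULE_DEPTH
    return None


def _first_failure_two(
    m: MutationRecord,
    per_bulk: dict[str, Optional[SiteReadCounts]],
    config: FilterConfig,
) -> Optional[str]:
    """First failing rule for one mutation in two-bulk mode, or None."""
    if any(per_bulk[b] is None for b in (WT_BULK, MUT_BULK)):
        return RULE_MISSING
    if config.ems_only and not is_ems_type(m.ref, m.alt):
        return RULE_NOT_EMS
    if config.whitelist is not None and m.key not in config.whitelist:
        return RULE_NOT_WHITELISTED
    mut = per_bulk[MUT_BULK]
    f_mut = mut.frequency
    if f_mut is None:
        return RULE_DEPTH
    if not f_mut > config.mutant_bulk_min_freq:
        return RULE_MUT_FREQ
    if per_bulk[WT_BULK].alt_reads > config.wt_max_alt_reads:
        return RULE_WT_ALT
    if any(per_bulk[b].depth < config.min_depth for b in (WT_BULK, MUT_BULK)):
        return RULE_DEPTH
    return None


def _run_filter(
    mutations: Sequence[MutationRecord],
    counts_by_bulk: Mapping[str, Mapping[str, SiteReadCounts]],
    config: FilterConfig,
    bulk_ids: set[str],
    first_failure,
) -> CandidateSet:
    _check_bulks(counts_by_bulk, bulk_ids)
    retained: list[MutationRecord] = []
    rejection_log: dict[str, str] = {}
    frequencies: dict[str, dict[str, Optional[float]]] = {}
    for m in mutations:
        per_bulk = {b: counts_by_bulk[b].get(m.id) for b in bulk_ids}
        frequencies[m.id] = {
            b: (c.frequency if c is not None else None) for b, c in per_bulk.items()
        }
        rule = first_failure(m, per_bulk, config)
        if rule is None:
            retained.append(m)
        else:
            rejection_log[m.id] = rule
    return CandidateSet(
        retained=retained, frequencies=frequencies, rejection_log=rejection_log
    )


def filter_three_bulk(
    mutations: Sequence[MutationRecord],
    counts_by_bulk: Mapping[str, Mapping[str, SiteReadCounts]],
    config: FilterConfig,
) -> CandidateSet:
    """Three-bulk cascade (WT / HET / HOM bulks).

    A mutation is retained iff it is EMS-type (when ``ems_only``), in the
    whitelist (when provided), essentially absent from the wild-type bulk,
    heterozygous-frequency in the HET bulk, homozygous-frequency in the HOM
    bulk, and covered to at least ``min_depth`` in every bulk.
    """
    return _run_filter(
        mutations,
        counts_by_bulk,
        config,
        {WT_BULK, HET_BULK, HOM_BULK},
        _first_failure_three,
    )


def filter_two_bulk(
    mutations: Sequence[MutationRecord],
    counts_by_bulk: Mapping[str, Mapping[str, SiteReadCounts]],
    config: FilterConfig,
) -> CandidateSet:
    """Two-bulk cascade (WT / MUT bulks).

    Retained iff EMS/whitelist rules pass, the mutant-bulk frequency
    strictly exceeds ``mutant_bulk_min_freq``, the wild-type bulk carries at
    most ``wt_max_alt_reads`` alternate reads, and depth is sufficient.
    """
    return _run_filter(
        mutations, counts_by_bulk, config, {WT_BULK, MUT_BULK}, _first_failure_two
    )


# ---------------------------------------------------------------------------
# I/O


def read_counts_tsv(path):
    """Read mutations and bulk counts from the flat TSV written by simcross.

    Returns (mutations, counts_by_bulk) with counts indexed for filtering.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    mutations: dict[str, MutationRecord] = {}
    counts: list[SiteReadCounts] = []
    for row in df.itertuples(index=False):
        if row.id not in mutations:
            mutations[row.id] = MutationRecord(
                id=row.id,
                chromosome=str(row.chrom),
                position=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                gene_id=None if getattr(row, "gene_id", ".") in (".", None) else row.gene_id,
                effect_class=getattr(row, "effect_class", "unknown"),
            )
        counts.append(
            SiteReadCounts(
                mutation_id=row.id,
                bulk_id=str(row.bulk),
                ref_reads=int(row.ref_reads),
                alt_reads=int(row.alt_reads),
            )
        )
    return list(mutations.values()), index_counts(counts)


def read_counts_vcf(path):
    """Read mutations and per-sample AD counts from a VCF 4.2 file.

    Each VCF sample is treated as one bulk.  Returns
    (mutations, counts_by_bulk).
    """
    import pysam

    mutations: list[MutationRecord] = []
    counts: list[SiteReadCounts] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            mid = rec.id or f"{rec.chrom}_{rec.pos}"
            info_gene = rec.info.get("GENE")
            info_eff = rec.info.get("EFF", "unknown")
            mutations.append(
                MutationRecord(
                    id=mid,
                    chromosome=rec.chrom,
                    position=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    gene_id=None if info_gene in (None, ".") else info_gene,
                    effect_class=info_eff if info_eff in
                    {"missense", "silent", "intron", "splice", "stop", "noncoding"}
                    else "unknown",
                )
            )
            for s in samples:
                ad = rec.samples[s].get("AD")
                if ad is None or ad[0] is None:
                    continue
                counts.append(
                    SiteReadCounts(
                        mutation_id=mid,
                        bulk_id=s,
                        ref_reads=int(ad[0]),
                        alt_reads=int(ad[1]),
                    )
                )
    return mutations, index_counts(counts)


def write_candidates_tsv(path, candidates: CandidateSet) -> None:
    """Write retained candidates (with per-bulk frequencies) as TSV."""
    import pandas as pd

    rows = []
    for m in candidates.retained:
        row = {
            "id": m.id,
            "chrom": m.chromosome,
            "pos": m.position,
            "ref": m.ref,
            "alt": m.alt,
            "gene_id": m.gene_id or ".",
            "effect_class": m.effect_class,
        }
        for bulk, freq in sorted(candidates.frequencies[m.id].items()):
            row[f"freq_{bulk}"] = "." if freq is None else f"{freq:.4f}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_run_report(path, candidates: CandidateSet, config: FilterConfig) -> None:
    """Write a JSON run report: config echo plus per-rule rejection counts."""
    report = {
        "schema_version": 1,
        "config": {
            "mode": config.mode,
            "ems_only": config.ems_only,
            "whitelist_size": None
            if config.whitelist is None
            else len(config.whitelist),
            "wt_max_alt_reads": config.wt_max_alt_reads,
            "het_window": list(config.het_window),
            "hom_window": list(config.hom_window),
            "mutant_bulk_min_freq": config.mutant_bulk_min_freq,
            "min_depth": config.min_depth,
        },
        "n_retained": len(candidates.retained),
        "n_rejected": len(candidates.rejection_log),
        "rejections_by_rule": candidates.rule_counts(),
    }
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
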