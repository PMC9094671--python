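"""Recombinant fine mapping by marker-phenotype cosegregation.

Given genotype calls of segregating lines at candidate markers, a marker
cosegregates completely when every scored line's call matches the call
expected for its phenotype class under the semidominant model (wild type ->
homozygous reference, paired spikelets with normal leaves -> heterozygous,
paired spikelets with curled leaves -> homozygous alternate).  Recombinant
lines break cosegregation at flanking markers, and the causal interval is
narrowed to the span between the nearest discordant markers on either side
of the fully cosegregating block.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

from ._records import MutationRecord, EFFECT_CLASSES
from .simcross import Spikelet, Leaf

__all__ = [
    "Interval",
    "Call",
    "PhenotypeClass",
    "MarkerCall",
    "CosegregationResult",
    "DEFAULT_EXPECTED_CALLS",
    "mutations_in_window",
    "exclude_by_effect",
    "cosegregation",
    "narrow_interval",
    "count_in_interval",
    "phenotype_class_of",
    "read_marker_tsv",
    "write_interval_bed",
]


@dataclass(frozen=True)
class Interval:
    """A 1-based inclusive genomic interval."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def to_bed_fields(self) -> tuple[str, int, int]:
        """Convert to BED convention (0-based half-open)."""
        return (self.chromosome, self.start - 1, self.end)


class Call(str, enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


class PhenotypeClass(str, enum.Enum):
    WILD_TYPE = "wild_type"
    PAIRED_NORMAL_LEAF = "paired_normal_leaf"
    PAIRED_CURLED = "paired_curled"


#: Expected genotype call per phenotype class under the semidominant model.
DEFAULT_EXPECTED_CALLS: dict[PhenotypeClass, Call] = {
    PhenotypeClass.WILD_TYPE: Call.HOM_REF,
    PhenotypeClass.PAIRED_NORMAL_LEAF: Call.HET,
    PhenotypeClass.PAIRED_CURLED: Call.HOM_ALT,
}


def phenotype_class_of(spikelet: Spikelet, leaf: Leaf) -> PhenotypeClass:
    """Map the two scored traits onto the three-genotype phenotype class."""
    if spikelet == Spikelet.WILD_TYPE:
        return PhenotypeClass.WILD_TYPE
    if leaf == Leaf.CURLED:
        return PhenotypeClass.PAIRED_CURLED
    return PhenotypeClass.PAIRED_NORMAL_LEAF


@dataclass(frozen=True)
class MarkerCall:
    """Genotype call of one line at one marker, with its phenotype class."""

    line_id: str
    marker_id: str
    call: Call
    phenotype_class: PhenotypeClass


@dataclass(frozen=True)
class CosegregationResult:
    marker_id: str
    n_scored: int
    n_discordant: int

    def __post_init__(self) -> None:
        if self.n_discordant > self.n_scored:
            raise ValueError("n_discordant cannot exceed n_scored")

    @property
    def complete(self) -> bool:
        """Complete cosegregation: at least one scored line, none discordant."""
        return self.n_scored > 0 and self.n_discordant == 0


def mutations_in_window(
    mutations: Sequence[MutationRecord],
    chromosome: str,
    center: int,
    radius: int,
) -> list[MutationRecord]:
    """Mutations on ``chromosome`` with |position - center| <= radius, sorted."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    hits = [
        m
        for m in mutations
        if m.chromosome == chromosome and abs(m.position - center) <= radius
    ]
    return sorted(hits, key=lambda m: m.position)


def exclude_by_effect(
    mutations: Sequence[MutationRecord],
    excluded_classes: Iterable[str] = ("intron", "silent"),
) -> tuple[list[MutationRecord], list[MutationRecord]]:
    """Partition mutations into (retained, excluded) by effect class.

    Intron and silent mutations are excluded a priori by default since they
    cannot plausibly cause a dominant gain-of-function phenotype.
    """
    excluded_set = set(excluded_classes)
    unknown = excluded_set - EFFECT_CLASSES
    if unknown:
        raise ValueError(f"unknown effect class labels: {sorted(unknown)}")
    retained = [m for m in mutations if m.effect_class not in excluded_set]
    excluded = [m for m in mutations if m.effect_class in excluded_set]
    return retained, excluded


def cosegregation(
    calls: Sequence[MarkerCall],
    expected: Optional[Mapping[PhenotypeClass, Call]] = None,
) -> CosegregationResult:
    """Score one marker's cosegregation with the phenotype classes.

    Missing calls are skipped (failed genotyping assays are routine and
    carry no linkage information).  Raises if no line is scored.
    """
    if expected is None:
        expected = DEFAULT_EXPECTED_CALLS
    missing_classes = set(PhenotypeClass) - set(expected)
    if missing_classes:
        raise ValueError(
            f"expected-call map lacks classes: {sorted(c.value for c in missing_classes)}"
        )
    marker_ids = {c.marker_id for c in calls}
    if len(marker_ids) > 1:
        raise ValueError(f"calls span multiple markers: {sorted(marker_ids)}")
    scored = [c for c in calls if c.call != Call.MISSING]
    if not scored:
        raise ValueError("no scored (non-missing) calls for this marker")
    n_discordant = sum(1 for c in scored if c.call != expected[c.phenotype_class])
    return CosegregationResult(
        marker_id=scored[0].marker_id,
        n_scored=len(scored),
        n_discordant=n_discordant,
    )


def narrow_interval(
    results: Mapping[str, CosegregationResult],
    positions: Mapping[str, int],
    window: Interval,
) -> Interval:
    """Narrow ``window`` using per-marker cosegregation results.

    The returned interval runs from 1 bp above the nearest discordant
    marker below the completely cosegregating block to 1 bp below the
    nearest discordant marker above it; where no discordant marker flanks a
    side, the window boundary is kept.  Raises when no marker cosegregates
    completely, or when a discordant marker falls inside the block (which
    would require a double recombinant and indicates a genotyping error).
    """
    scored = [
        (positions[mid], res)
        for mid, res in results.items()
        if mid in positions and window.contains(positions[mid])
    ]
    complete_pos = sorted(p for p, r in scored if r.complete)
    if not complete_pos:
        raise ValueError("no cosegregating marker")
    discordant_pos = sorted(p for p, r in scored if not r.complete)
    lo, hi = complete_pos[0], complete_pos[-1]
    inside = [p for p in discordant_pos if lo <= p <= hi]
    if inside:
        raise ValueError(
            f"discordant marker(s) at {inside} inside the cosegregating block "
            f"[{lo}, {hi}]"
        )
    below = [p for p in discordant_pos if p < lo]
    above = [p for p in discordant_pos if p > hi]
    start = (max(below) + 1) if below else window.start
    end = (min(above) - 1) if above else window.end
    return Interval(window.chromosome, start, end)


def count_in_interval(
    features: Sequence[Union[int, MutationRecord]],
    interval: Interval,
) -> int:
    """Count features inside the inclusive interval.

    Accepts bare positions (assumed on the interval's chromosome) or
    :class:`MutationRecord` objects (chromosome checked).
    """
    n = 0
    for f in features:
        if isinstance(f, MutationRecord):
            if f.chromosome == interval.chromosome and interval.contains(f.position):
                n += 1
        else:
            if interval.contains(int(f)):
                n += 1
    return n


# ---------------------------------------------------------------------------
# I/O


def read_marker_tsv(path) -> list[MarkerCall]:
    """Read marker calls from TSV (line_id, marker_id, call, phenotype_class)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [
        MarkerCall(
            line_id=str(row.line_id),
            marker_id=str(row.marker_id),
            call=Call(row.call),
            phenotype_class=PhenotypeClass(row.phenotype_class),
        )
        for row in df.itertuples(index=False)
    ]


def write_interval_bed(path, intervals: Sequence[Interval], names=None) -> None:
    """Write intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for i, interval in enumerate(intervals):
            chrom, start, end = interval.to_bed_fields()
            name = names[i] if names else f"interval_{i + 1}"
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")
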