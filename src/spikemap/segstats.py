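"""Mendelian expectations and segregation statistics for a semidominant locus.

An F2 from a self-pollinated heterozygote segregates 1:2:1 for genotype
dosage, hence 1:3 wild-type:affected under a semidominant phenotype (both
het and hom dosages are affected), with one-third of affected plants
showing the homozygote-only leaf trait.  Expected ratios are obtained by
enumerating gamete combinations rather than hard-coding fractions, and
observed counts are tested with a chi-square goodness-of-fit test
(df = k - 1, no continuity correction).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PhenotypeCounts",
    "RatioHypothesis",
    "ChiSquareResult",
    "expected_ratio",
    "enumerate_offspring",
    "chisq_gof",
    "bin_spikelet_positions",
    "SELF_OF_HET",
    "BACKCROSS_HET_X_WT",
]

SELF_OF_HET = "self_of_het"
BACKCROSS_HET_X_WT = "backcross_het_x_wt"

AFFECTED_VS_WT = "affected_vs_wt"
GENOTYPE_CLASSES = "genotype_classes"
CURLED_AMONG_AFFECTED = "curled_among_affected"


@dataclass(frozen=True)
class PhenotypeCounts:
    """Observed counts per phenotype (or genotype) category."""

    labels: tuple[str, ...]
    observed: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.observed):
            raise ValueError("labels and observed counts differ in length")
        if len(self.labels) < 2:
            raise ValueError("need at least two categories")
        if any(o < 0 for o in self.observed):
            raise ValueError("counts must be non-negative")
        if sum(self.observed) == 0:
            raise ValueError("total count must be > 0")

    @property
    def total(self) -> int:
        return sum(self.observed)


@dataclass(frozen=True)
class RatioHypothesis:
    """Expected proportions per category under a Mendelian hypothesis."""

    labels: tuple[str, ...]
    proportions: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.proportions):
            raise ValueError("labels and proportions differ in length")
        if any(p <= 0 for p in self.proportions):
            raise ValueError("all expected proportions must be > 0")
        if abs(sum(self.proportions) - 1.0) > 1e-12:
            raise ValueError("proportions must sum to 1")


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float

    def __post_init__(self) -> None:
        if self.statistic < 0 or not 0.0 <= self.p_value <= 1.0:
            raise ValueError("invalid chi-square result")


def enumerate_offspring(cross: str) -> dict[int, float]:
    """Exact offspring dosage distribution by enumerating gamete combinations.

    A heterozygote produces gametes 0 and 1 with equal probability; the
    recurrent wild-type parent produces only gamete 0.
    """
    het_gametes = [0, 1]
    if cross == SELF_OF_HET:
        pairs = [(a, b) for a in het_gametes for b in het_gametes]
    elif cross == BACKCROSS_HET_X_WT:
        pairs = [(a, 0) for a in het_gametes]
    else:
        raise ValueError(f"unsupported cross {cross!r}")
    counts = Counter(a + b for a, b in pairs)
    total = len(pairs)
    return {dosage: counts[dosage] / total for dosage in sorted(counts)}


def expected_ratio(
    cross: str,
    partition: str,
    model: str = "semidominant",
) -> RatioHypothesis:
    """Expected category proportions for a cross/partition combination.

    Proportions are derived from :func:`enumerate_offspring` under the
    semidominant phenotype map (dosage 0 wild type; dosage 1 paired
    spikelets with normal leaves; dosage 2 paired spikelets with curled
    leaves).
    """
    if model != "semidominant":
        raise ValueError(f"unsupported model {model!r}")
    dist = enumerate_offspring(cross)
    p0 = dist.get(0, 0.0)
    p1 = dist.get(1, 0.0)
    p2 = dist.get(2, 0.0)
    if partition == AFFECTED_VS_WT:
        return RatioHypothesis(("wild_type", "affected"), (p0, p1 + p2))
    if partition == GENOTYPE_CLASSES:
        if p2 == 0.0:
            return RatioHypothesis(("hom_ref", "het"), (p0, p1))
        return RatioHypothesis(("hom_ref", "het", "hom_alt"), (p0, p1, p2))
    if partition == CURLED_AMONG_AFFECTED:
        affected = p1 + p2
        if p2 == 0.0 or affected == 0.0:
            raise ValueError(
                f"partition {partition!r} is degenerate for cross {cross!r}"
            )
        return RatioHypothesis(
            ("normal_leaf", "curled"), (p1 / affected, p2 / affected)
        )
    raise ValueError(f"unsupported partition {partition!r}")


def chisq_gof(counts: PhenotypeCounts, hypothesis: RatioHypothesis) -> ChiSquareResult:
    """Chi-square goodness of fit of observed counts against a ratio.

    statistic = sum (obs - exp)^2 / exp with exp = total * proportion;
    df = k - 1; p from the upper tail of the chi-square distribution.
    Proportions are renormalised first, so scaling a ratio uniformly (e.g.
    passing 1:3 as 2:6) does not change the result.
    """
    if counts.labels != hypothesis.labels:
        raise ValueError(
            f"category mismatch: observed {counts.labels} vs "
            f"expected {hypothesis.labels}"
        )
    props = np.asarray(hypothesis.proportions, dtype=float)
    props = props / props.sum()
    expected = counts.total * props
    obs = np.asarray(counts.observed, dtype=float)
    statistic, p_value = stats.chisquare(obs, f_exp=expected)
    return ChiSquareResult(
        statistic=float(statistic),
        df=len(counts.labels) - 1,
        p_value=float(p_value),
    )


def bin_spikelet_positions(
    secondary_node_indices: Sequence[int],
    total_nodes: int,
) -> np.ndarray:
    """Bin secondary-spikelet rachis node indices into 10 normalised deciles.

    Node index i of n maps to normalised position i/n in (0, 1], assigned to
    bins (0, 0.1], (0.1, 0.2], ..., (0.9, 1]; the first bin is the base of
    the inflorescence and the last the apex.  Returns the 10 bin counts.
    """
    if total_nodes < 1:
        raise ValueError("total_nodes must be >= 1")
    counts = np.zeros(10, dtype=np.int64)
    for idx in secondary_node_indices:
        if not 1 <= idx <= total_nodes:
            raise ValueError(
                f"node index {idx} out of range [1, {total_nodes}]"
            )
        # integer ceil of 10*i/n, minus 1: right-closed decile bins
        b = (10 * idx + total_nodes - 1) // total_nodes - 1
        counts[b] += 1
    return counts
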