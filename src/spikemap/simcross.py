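"""Forward-genetic cross simulator for bulked-segregant mapping studies.

This module generates ground-truth data for every downstream stage of the
mapping pipeline: an EMS-mutagenised parent line (G>A / C>T biased point
mutations), backcross/self pedigrees with crossover recombination under the
Haldane map function, a single semidominant causal locus (heterozygotes form
paired spikelets, homozygotes additionally curl their leaves),
phenotype-selected DNA bulks, and binomial read sampling at Poisson depth.

All stochastic operations are bit-reproducible under a fixed seed.  One
master seed per run is split into per-stage child seeds with
``numpy.random.SeedSequence`` spawning so stages can be re-run independently.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from ._records import MutationRecord, SiteReadCounts, EFFECT_CLASSES

__all__ = [
    "Chromosome",
    "GenomeModel",
    "MutagenesisConfig",
    "CausalSpec",
    "CrossPlan",
    "Individual",
    "ReadDepthModel",
    "Bulk",
    "Spikelet",
    "Leaf",
    "simulate_ems_mutations",
    "simulate_cross",
    "assign_phenotypes",
    "build_bulks",
    "sample_bulk_reads",
    "write_bulk_vcf",
    "write_bulk_tsv",
    "write_truth_tsv",
]

# EMS alkylates guanine, so the canonical induced spectrum is G>A on one
# strand or C>T on the other.
EMS_PAIRS = (("G", "A"), ("C", "T"))
_NON_EMS_PAIRS = tuple(
    (r, a)
    for r in "ACGT"
    for a in "ACGT"
    if r != a and (r, a) not in EMS_PAIRS
)

# Default effect-class mix for induced exonic/near-exonic SNPs.  Chosen to
# give a realistic majority of missense calls with a substantial silent and
# intronic fraction so the a-priori effect filter has work to do.
DEFAULT_EFFECT_PROBS: dict[str, float] = {
    "missense": 0.45,
    "silent": 0.25,
    "intron": 0.18,
    "noncoding": 0.07,
    "stop": 0.03,
    "splice": 0.02,
}


class Spikelet(str, enum.Enum):
    """Inflorescence phenotype class."""

    WILD_TYPE = "wild_type"
    PAIRED = "paired"


class Leaf(str, enum.Enum):
    """Leaf phenotype class."""

    NORMAL = "normal"
    CURLED = "curled"


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int  # bp
    recombination_rate: float = 1.0  # cM per Mb

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome length must be > 0, got {self.length}")
        if self.recombination_rate < 0:
            raise ValueError("recombination rate must be >= 0")


@dataclass(frozen=True)
class GenomeModel:
    """Stand-in genome: a list of chromosomes with uniform recombination rates."""

    chromosomes: tuple[Chromosome, ...]

    def __init__(self, chromosomes: Iterable[Chromosome]):
        chroms = tuple(chromosomes)
        names = [c.name for c in chroms]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        object.__setattr__(self, "chromosomes", chroms)

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.chromosomes)

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"no chromosome named {name!r}")


def default_wheat_genome() -> GenomeModel:
    """A three-chromosome stand-in for homoeologous group 1 of hexaploid wheat.

    Lengths approximate the assembled 1A/1B/1D pseudomolecules; the uniform
    1 cM/Mb rate is a deliberately simple, analytically checkable map.
    """
    return GenomeModel(
        [
            Chromosome("1A", 594_000_000, 1.0),
            Chromosome("1B", 689_000_000, 1.0),
            Chromosome("1D", 495_000_000, 1.0),
        ]
    )


@dataclass(frozen=True)
class MutagenesisConfig:
    """Induced mutation load of the mutagenised parent line."""

    mutations_per_line: int = 2500
    ems_fraction: float = 0.98
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mutations_per_line < 0:
            raise ValueError("mutations_per_line must be >= 0")
        if not 0.0 <= self.ems_fraction <= 1.0:
            raise ValueError("ems_fraction must be in [0, 1]")


def _default_phenotype_map() -> dict[int, tuple[Spikelet, Leaf]]:
    return {
        0: (Spikelet.WILD_TYPE, Leaf.NORMAL),
        1: (Spikelet.PAIRED, Leaf.NORMAL),
        2: (Spikelet.PAIRED, Leaf.CURLED),
    }


@dataclass(frozen=True)
class CausalSpec:
    """Semidominant causal locus and its dosage-to-phenotype map.

    The default map encodes the study model: one mutant dose produces paired
    spikelets with normal leaves, two doses add leaf curling.
    """

    causal_mutation_id: str
    dominance: str = "semidominant"
    phenotype_map: dict[int, tuple[Spikelet, Leaf]] = field(
        default_factory=_default_phenotype_map
    )
    penetrance: float = 1.0

    def __post_init__(self) -> None:
        if self.dominance != "semidominant":
            raise ValueError("only the semidominant model is supported")
        if set(self.phenotype_map) != {0, 1, 2}:
            raise ValueError("phenotype_map must have dosage keys exactly {0, 1, 2}")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must be in [0, 1]")


BACKCROSS = "backcross_to_recurrent"
SELF = "self"


@dataclass(frozen=True)
class CrossPlan:
    """Ordered pedigree steps applied to a founder individual."""

    steps: tuple[str, ...]
    progeny_per_step: int = 200

    def __init__(self, steps: Iterable[str], progeny_per_step: int = 200):
        steps = tuple(steps)
        if not steps:
            raise ValueError("a cross plan needs at least one step")
        for s in steps:
            if s not in (BACKCROSS, SELF):
                raise ValueError(f"unknown cross step {s!r}")
        if progeny_per_step <= 0:
            raise ValueError("progeny_per_step must be > 0")
        object.__setattr__(self, "steps", steps)
        object.__setattr__(self, "progeny_per_step", progeny_per_step)


@dataclass
class Individual:
    """A diploid individual as two binary haplotypes over the mutation set."""

    haplotypes: tuple[np.ndarray, np.ndarray]
    spikelet_phenotype: Optional[Spikelet] = None
    leaf_phenotype: Optional[Leaf] = None

    @property
    def dosages(self) -> np.ndarray:
        """Alt-allele dosage in {0, 1, 2} at each mutation."""
        return (
            self.haplotypes[0].astype(np.int16) + self.haplotypes[1].astype(np.int16)
        )

    @classmethod
    def from_dosages(cls, dosages: Sequence[int]) -> "Individual":
        """Build an individual from a dosage vector, phasing het sites arbitrarily."""
        d = np.asarray(dosages, dtype=np.int16)
        if d.size and (d.min() < 0 or d.max() > 2):
            raise ValueError("dosages must be in {0, 1, 2}")
        h0 = (d >= 1).astype(np.uint8)
        h1 = (d == 2).astype(np.uint8)
        return cls((h0, h1))

    @classmethod
    def homozygous(cls, n_mutations: int, dosage: int) -> "Individual":
        if dosage not in (0, 2):
            raise ValueError("homozygous individuals have dosage 0 or 2")
        v = np.full(n_mutations, dosage // 2, dtype=np.uint8)
        return cls((v.copy(), v.copy()))

    @classmethod
    def f1_heterozygote(cls, n_mutations: int) -> "Individual":
        """F1 of mutant line x recurrent parent: het at every induced mutation."""
        return cls(
            (
                np.ones(n_mutations, dtype=np.uint8),
                np.zeros(n_mutations, dtype=np.uint8),
            )
        )


@dataclass(frozen=True)
class ReadDepthModel:
    """Pooled-sequencing depth model: Poisson depth, per-read miscall rate."""

    mean_depth: float = 180.0
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")


@dataclass
class Bulk:
    """A phenotype-selected DNA pool."""

    bulk_id: str
    member_indices: np.ndarray
    allele_fractions: np.ndarray  # pooled alt fraction per mutation, in [0, 1]

    @property
    def size(self) -> int:
        return int(self.member_indices.size)


# ---------------------------------------------------------------------------
# mutagenesis


def simulate_ems_mutations(
    genome: GenomeModel,
    config: MutagenesisConfig,
    effect_probs: Optional[dict[str, float]] = None,
) -> list[MutationRecord]:
    """Draw the induced mutation set of one mutagenised line.

    Positions are uniform over the genome and unique; each mutation is
    EMS-type (G>A or C>T) with probability ``config.ems_fraction`` by an
    independent Bernoulli draw, otherwise one of the ten remaining
    substitutions uniformly.  Records are sorted by (chromosome, position)
    and deterministic given ``config.seed``.
    """
    if not genome.chromosomes:
        raise ValueError("genome has no chromosomes")
    n = config.mutations_per_line
    total = genome.total_length
    if n > total:
        raise ValueError(
            f"cannot place {n} unique mutations on a {total}-bp genome"
        )
    if effect_probs is None:
        effect_probs = DEFAULT_EFFECT_PROBS
    classes = sorted(effect_probs)
    probs = np.array([effect_probs[c] for c in classes], dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("effect_probs must sum to 1")
    for c in classes:
        if c not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect class {c!r}")

    rng = np.random.default_rng(config.seed)
    if n == 0:
        return []

    # Rejection-sample global 1-based offsets until n unique positions.
    chosen: np.ndarray = np.empty(0, dtype=np.int64)
    while chosen.size < n:
        draw = rng.integers(1, total + 1, size=2 * (n - chosen.size))
        chosen = np.unique(np.concatenate([chosen, draw]))
    # Deterministic thinning to exactly n (unique() sorts, so subsample).
    if chosen.size > n:
        keep = rng.choice(chosen.size, size=n, replace=False)
        chosen = np.sort(chosen[keep])

    # Map global offsets to (chromosome, position).
    bounds = np.cumsum([c.length for c in genome.chromosomes])
    chrom_idx = np.searchsorted(bounds, chosen, side="left")
    starts = np.concatenate([[0], bounds[:-1]])
    positions = chosen - starts[chrom_idx]

    is_ems = rng.random(n) < config.ems_fraction
    ems_pick = rng.integers(0, len(EMS_PAIRS), size=n)
    other_pick = rng.integers(0, len(_NON_EMS_PAIRS), size=n)
    effect_pick = rng.choice(len(classes), size=n, p=probs)

    records = []
    width = len(str(max(n, 1)))
    for i in range(n):
        chrom = genome.chromosomes[int(chrom_idx[i])]
        if is_ems[i]:
            ref, alt = EMS_PAIRS[int(ems_pick[i])]
        else:
            ref, alt = _NON_EMS_PAIRS[int(other_pick[i])]
        effect = classes[int(effect_pick[i])]
        gene = (
            None
            if effect == "noncoding"
            else f"gene_{chrom.name}_{int(positions[i]) // 100_000:05d}"
        )
        records.append(
            MutationRecord(
                id=f"mut_{i + 1:0{width}d}",
                chromosome=chrom.name,
                position=int(positions[i]),
                ref=ref,
                alt=alt,
                gene_id=gene,
                effect_class=effect,
            )
        )
    records.sort(key=lambda m: (genome.names.index(m.chromosome), m.position))
    return records


# ---------------------------------------------------------------------------
# meiosis and pedigrees


def _locus_layout(
    mutations: Sequence[MutationRecord], genome: GenomeModel
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Group loci per chromosome; precompute adjacent recombination fractions.

    Returns a list of (index_array, r_array) where r_array[j] is the Haldane
    recombination fraction between adjacent loci j and j+1:
    r = (1 - exp(-2 d_Morgan)) / 2 with d derived from the chromosome's
    cM/Mb rate and the physical distance.
    """
    by_chrom: dict[str, list[int]] = {}
    for i, m in enumerate(mutations):
        if m.chromosome not in genome.names:
            raise ValueError(f"mutation {m.id} on unknown chromosome {m.chromosome!r}")
        chrom = genome.chromosome(m.chromosome)
        if not 1 <= m.position <= chrom.length:
            raise ValueError(
                f"mutation {m.id} at {m.chromosome}:{m.position} is off-genome"
            )
        by_chrom.setdefault(m.chromosome, []).append(i)
    layout = []
    for name, idx_list in by_chrom.items():
        chrom = genome.chromosome(name)
        idx = np.array(
            sorted(idx_list, key=lambda i: mutations[i].position), dtype=np.int64
        )
        pos = np.array([mutations[i].position for i in idx], dtype=np.float64)
        d_morgan = chrom.recombination_rate * np.diff(pos) / 1e6 / 100.0
        r = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))
        layout.append((idx, r))
    return layout


def _gametes(
    parent: Individual,
    n: int,
    layout: list[tuple[np.ndarray, np.ndarray]],
    rng: np.random.Generator,
    n_loci: int,
) -> np.ndarray:
    """Sample ``n`` recombinant gametes (n x n_loci uint8 matrix)."""
    out = np.empty((n, n_loci), dtype=np.uint8)
    h = np.stack([parent.haplotypes[0], parent.haplotypes[1]])
    for idx, r in layout:
        k = idx.size
        start = rng.integers(0, 2, size=(n, 1))
        if k > 1:
            crossovers = (rng.random((n, k - 1)) < r).astype(np.int64)
            switches = np.concatenate(
                [np.zeros((n, 1), dtype=np.int64), np.cumsum(crossovers, axis=1)],
                axis=1,
            )
            sel = (start + switches) % 2
        else:
            sel = np.broadcast_to(start, (n, k))
        out[:, idx] = np.where(sel == 0, h[0, idx], h[1, idx])
    return out


def simulate_cross(
    plan: CrossPlan,
    mutations: Sequence[MutationRecord],
    genome: GenomeModel,
    founder: Individual,
    n_progeny: Optional[int] = None,
    seed: int = 0,
    carrier_index: Optional[int] = None,
) -> list[Individual]:
    """Run a pedigree from ``founder`` and return the final generation.

    Each ``backcross_to_recurrent`` step crosses the current carrier to the
    recurrent (all-reference) parent; each ``self`` step self-pollinates it.
    Between steps one progeny heterozygous at ``carrier_index`` (when given,
    mirroring phenotype-based selection of a paired-spikelet plant) is
    advanced; with no carrier locus a random progeny is advanced.
    ``n_progeny`` overrides the plan's progeny count for the final step.
    """
    n_loci = len(mutations)
    for hap in founder.haplotypes:
        if hap.shape != (n_loci,):
            raise ValueError("founder haplotype length must equal mutation count")
    layout = _locus_layout(mutations, genome)
    rng = np.random.default_rng(seed)

    current = founder
    progeny: list[Individual] = []
    for step_i, step in enumerate(plan.steps):
        last = step_i == len(plan.steps) - 1
        n = n_progeny if (last and n_progeny is not None) else plan.progeny_per_step
        if n <= 0:
            raise ValueError("progeny count must be > 0")
        if step == BACKCROSS:
            g = _gametes(current, n, layout, rng, n_loci)
            ref = np.zeros(n_loci, dtype=np.uint8)
            progeny = [Individual((g[i].copy(), ref.copy())) for i in range(n)]
        else:  # SELF
            g1 = _gametes(current, n, layout, rng, n_loci)
            g2 = _gametes(current, n, layout, rng, n_loci)
            progeny = [Individual((g1[i].copy(), g2[i].copy())) for i in range(n)]
        if not last:
            if carrier_index is not None:
                hets = [
                    p for p in progeny if p.dosages[carrier_index] == 1
                ]
                if not hets:
                    raise RuntimeError(
                        f"no heterozygous carrier at locus {carrier_index} "
                        f"among {n} progeny of step {step!r}"
                    )
                current = hets[int(rng.integers(0, len(hets)))]
            else:
                current = progeny[int(rng.integers(0, n))]
    return progeny


def assign_phenotypes(
    individuals: Sequence[Individual],
    spec: CausalSpec,
    mutations: Sequence[MutationRecord],
    seed: int = 0,
) -> list[Individual]:
    """Set phenotypes in place from dosage at the causal locus; returns input.

    With ``penetrance < 1`` a mutant-dosage individual expresses the
    wild-type phenotype pair with probability ``1 - penetrance``.
    """
    try:
        causal_index = next(
            i for i, m in enumerate(mutations) if m.id == spec.causal_mutation_id
        )
    except StopIteration:
        raise KeyError(
            f"causal mutation {spec.causal_mutation_id!r} not in mutation list"
        ) from None
    rng = np.random.default_rng(seed)
    for ind in individuals:
        dosage = int(ind.dosages[causal_index])
        if dosage > 0 and spec.penetrance < 1.0 and rng.random() > spec.penetrance:
            dosage = 0
        spike, leaf = spec.phenotype_map[dosage]
        ind.spikelet_phenotype = spike
        ind.leaf_phenotype = leaf
    return list(individuals)


def build_bulks(
    individuals: Sequence[Individual],
    selector: Callable[[Individual], bool],
    bulk_size: int,
    seed: int = 0,
    bulk_id: str = "bulk",
) -> Bulk:
    """Pool ``bulk_size`` individuals matching ``selector`` into one DNA bulk.

    The pooled alt fraction at each site is (sum of dosages) / (2 * size).
    """
    if bulk_size <= 0:
        raise ValueError("bulk_size must be > 0")
    matching = [i for i, ind in enumerate(individuals) if selector(ind)]
    if len(matching) < bulk_size:
        raise ValueError(
            f"only {len(matching)} individuals match the selector; "
            f"need {bulk_size} for bulk {bulk_id!r}"
        )
    rng = np.random.default_rng(seed)
    members = np.sort(rng.choice(matching, size=bulk_size, replace=False))
    dosage_sum = np.sum(
        [individuals[int(i)].dosages for i in members], axis=0, dtype=np.int64
    )
    fractions = dosage_sum / (2.0 * bulk_size)
    return Bulk(bulk_id=bulk_id, member_indices=members, allele_fractions=fractions)


def sample_bulk_reads(
    bulk: Bulk,
    mutations: Sequence[MutationRecord],
    model: ReadDepthModel,
) -> list[SiteReadCounts]:
    """Sample per-site read counts for a bulk.

    Depth at each site is Poisson(``mean_depth``); alt reads are
    Binomial(depth, p') with p' = p(1-e) + (1-p)e where p is the pooled alt
    fraction and e the per-read miscall rate.  Zero-depth sites are kept
    (their frequency is undefined downstream).
    """
    if len(mutations) != bulk.allele_fractions.size:
        raise ValueError("mutation list does not match bulk site count")
    rng = np.random.default_rng(model.seed)
    p = bulk.allele_fractions
    p_eff = p * (1.0 - model.error_rate) + (1.0 - p) * model.error_rate
    depth = rng.poisson(model.mean_depth, size=p.size)
    alt = rng.binomial(depth, p_eff)
    return [
        SiteReadCounts(
            mutation_id=m.id,
            bulk_id=bulk.bulk_id,
            ref_reads=int(depth[i] - alt[i]),
            alt_reads=int(alt[i]),
        )
        for i, m in enumerate(mutations)
    ]


# ---------------------------------------------------------------------------
# writers


def write_bulk_tsv(
    path,
    mutations: Sequence[MutationRecord],
    counts_by_bulk: dict[str, Sequence[SiteReadCounts]],
) -> None:
    """Write per-bulk allele depths as a flat TSV."""
    import pandas as pd

    by_id = {m.id: m for m in mutations}
    rows = []
    for bulk_id, counts in counts_by_bulk.items():
        for c in counts:
            m = by_id[c.mutation_id]
            rows.append(
                {
                    "id": m.id,
                    "chrom": m.chromosome,
                    "pos": m.position,
                    "ref": m.ref,
                    "alt": m.alt,
                    "gene_id": m.gene_id or ".",
                    "effect_class": m.effect_class,
                    "bulk": bulk_id,
                    "ref_reads": c.ref_reads,
                    "alt_reads": c.alt_reads,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_bulk_vcf(
    path,
    mutations: Sequence[MutationRecord],
    counts_by_bulk: dict[str, Sequence[SiteReadCounts]],
    genome: Optional[GenomeModel] = None,
) -> None:
    """Write bulk allele depths as VCF 4.2, one sample per bulk (FORMAT AD)."""
    bulk_ids = list(counts_by_bulk)
    indexed = {
        b: {c.mutation_id: c for c in counts} for b, counts in counts_by_bulk.items()
    }
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=spikemap\n")
        if genome is not None:
            for c in genome.chromosomes:
                fh.write(f"##contig=<ID={c.name},length={c.length}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">\n')
        fh.write(
            '##INFO=<ID=EFF,Number=1,Type=String,Description="Effect class">\n'
        )
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths for the ref and alt alleles">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(bulk_ids)
            + "\n"
        )
        for m in mutations:
            info = f"GENE={m.gene_id or '.'};EFF={m.effect_class}"
            samples = []
            for b in bulk_ids:
                c = indexed[b].get(m.id)
                samples.append("." if c is None else f"{c.ref_reads},{c.alt_reads}")
            fh.write(
                f"{m.chromosome}\t{m.position}\t{m.id}\t{m.ref}\t{m.alt}\t.\t.\t"
                f"{info}\tAD\t" + "\t".join(samples) + "\n"
            )


def write_truth_tsv(
    path,
    mutations: Sequence[MutationRecord],
    individuals: Sequence[Individual],
    spec: CausalSpec,
) -> None:
    """Write the ground truth (causal id, per-line genotype and phenotypes)."""
    import pandas as pd

    causal_index = next(
        i for i, m in enumerate(mutations) if m.id == spec.causal_mutation_id
    )
    rows = [
        {
            "line": f"line_{i + 1:04d}",
            "causal_id": spec.causal_mutation_id,
            "causal_dosage": int(ind.dosages[causal_index]),
            "spikelet_phenotype": ind.spikelet_phenotype.value
            if ind.spikelet_phenotype
            else ".",
            "leaf_phenotype": ind.leaf_phenotype.value if ind.leaf_phenotype else ".",
        }
        for i, ind in enumerate(individuals)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
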