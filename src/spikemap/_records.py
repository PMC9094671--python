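"""Core record types shared by the simulation and filtering layers.

Coordinates are 1-based inclusive genomic positions throughout; they are
converted to 0-based half-open only at BED boundaries (see :mod:`spikemap.finemap`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

VALID_BASES = frozenset("ACGT")

#: Predicted consequence of a SNP on its gene; used to exclude a-priori
#: non-causal candidates during fine mapping.
EFFECT_CLASSES = frozenset(
    {"missense", "silent", "intron", "splice", "stop", "noncoding", "unknown"}
)


@dataclass(frozen=True)
class MutationRecord:
    """One induced single-nucleotide mutation.

    Parameters
    ----------
    id : str
        Unique identifier of the mutation (e.g. ``mut_00042``).
    chromosome : str
        Chromosome name.
    position : int
        1-based genomic position.
    ref, alt : str
        Single-base reference and alternate alleles (upper case).
    gene_id : str, optional
        Gene the mutation falls in, if any.
    effect_class : str
        One of :data:`EFFECT_CLASSES`.
    """

    id: str
    chromosome: str
    position: int
    ref: str
    alt: str
    gene_id: Optional[str] = None
    effect_class: str = "unknown"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for base in (self.ref, self.alt):
            if base not in VALID_BASES:
                raise ValueError(f"alleles must be single bases in ACGT, got {base!r}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect class {self.effect_class!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Site key used for whitelist membership: (chrom, pos, ref, alt)."""
        return (self.chromosome, self.position, self.ref, self.alt)


@dataclass(frozen=True)
class SiteReadCounts:
    """Reference/alternate read depths for one mutation in one DNA bulk."""

    mutation_id: str
    bulk_id: str
    ref_reads: int
    alt_reads: int

    def __post_init__(self) -> None:
        if self.ref_reads < 0 or self.alt_reads < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def depth(self) -> int:
        return self.ref_reads + self.alt_reads

    @property
    def frequency(self) -> Optional[float]:
        """Alternate-allele frequency alt/(ref+alt), or None at zero depth."""
        if self.depth == 0:
            return None
        return self.alt_reads / self.depth
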