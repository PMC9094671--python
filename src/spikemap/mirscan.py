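"""Plant miRNA complementary-site scanning and codon-effect annotation.

Plant miRNAs such as miR165/166 direct cleavage of near-perfectly
complementary segments of their target mRNAs; a SNP inside the
complementary site can make the transcript miRNA-resistant while also
changing the encoded protein.  This module scans a coding sequence for
complementary sites with the standard plant scoring convention (mismatch
1.0, G:U wobble 0.5, penalties doubled at miRNA positions 2-13 from the 5'
end), annotates whether a SNP falls inside a site and how it changes the
penalty, and reports the codon-level amino acid effect.

U and T are unified to T internally; FASTA input may use either alphabet.
Only the sense strand of the CDS is scanned (miRNAs target mRNA).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

__all__ = [
    "NucleotideSequence",
    "SiteMatch",
    "SnpSiteAnnotation",
    "CodonEffect",
    "reverse_complement",
    "scan_sites",
    "annotate_snp",
    "codon_effect",
    "CORE_START",
    "CORE_END",
    "MISMATCH_PENALTY",
    "WOBBLE_PENALTY",
]

# Core of the miRNA:target duplex (positions from the miRNA 5' end) where
# pairing defects are penalised twice as heavily.
CORE_START = 2
CORE_END = 13
MISMATCH_PENALTY = 1.0
WOBBLE_PENALTY = 0.5

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# Penalty matrix indexed [miRNA base, target base]: 0 for Watson-Crick
# pairing, 0.5 for a G:U wobble (miRNA G with target U, or miRNA U with
# target G), 1 otherwise.
_PENALTY = np.full((4, 4), MISMATCH_PENALTY)
for _m, _t in (("A", "T"), ("C", "G"), ("G", "C"), ("T", "A")):
    _PENALTY[_BASE_INDEX[_m], _BASE_INDEX[_t]] = 0.0
_PENALTY[_BASE_INDEX["G"], _BASE_INDEX["T"]] = WOBBLE_PENALTY
_PENALTY[_BASE_INDEX["T"], _BASE_INDEX["G"]] = WOBBLE_PENALTY


def canonicalize(residues: str) -> str:
    """Upper-case and unify U -> T; reject anything outside {A, C, G, T, U}."""
    seq = residues.upper().replace("U", "T")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"invalid bases in sequence: {sorted(bad)}")
    if not seq:
        raise ValueError("empty sequence")
    return seq


@dataclass(frozen=True)
class NucleotideSequence:
    """A named nucleotide sequence stored in the DNA (T) alphabet."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", canonicalize(self.residues))

    def __len__(self) -> int:
        return len(self.residues)


def reverse_complement(seq: str) -> str:
    """Reverse complement in the T alphabet (accepts U input)."""
    s = canonicalize(seq)
    return "".join(_COMPLEMENT[b] for b in reversed(s))


@dataclass(frozen=True)
class SiteMatch:
    """A miRNA complementary site on a target, 1-based inclusive coords.

    ``score`` is the summed pairing penalty; 0 means perfect complement.
    """

    target_start: int
    target_end: int
    mismatches: int
    gu_wobbles: int
    score: float

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("score must be >= 0")

    def contains(self, position: int) -> bool:
        return self.target_start <= position <= self.target_end


@dataclass(frozen=True)
class SnpSiteAnnotation:
    snp_position: int
    in_site: bool
    offset_in_site: Optional[int]
    score_ref: float
    score_alt: float

    @property
    def delta(self) -> float:
        """score_alt - score_ref: positive when the SNP worsens complementarity."""
        return self.score_alt - self.score_ref


@dataclass(frozen=True)
class CodonEffect:
    codon_index: int
    ref_aa: str  # three-letter code, e.g. "Gly"
    alt_aa: str

    @property
    def synonymous(self) -> bool:
        return self.ref_aa == self.alt_aa


def _position_weights(m: int) -> np.ndarray:
    w = np.ones(m)
    w[CORE_START - 1 : min(CORE_END, m)] = 2.0
    return w


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8).copy().view(np.uint8)


_ENCODE_LUT = np.zeros(256, dtype=np.int8)
for _b, _i in _BASE_INDEX.items():
    _ENCODE_LUT[ord(_b)] = _i


def _score_window(window_codes: np.ndarray, mir_codes: np.ndarray) -> tuple[float, int, int]:
    """Score one target window (already reversed to pair with the miRNA 5'->3')."""
    pen = _PENALTY[mir_codes, window_codes]
    w = _position_weights(mir_codes.size)
    score = float(np.sum(w * pen))
    mismatches = int(np.sum(pen == MISMATCH_PENALTY))
    wobbles = int(np.sum(pen == WOBBLE_PENALTY))
    return score, mismatches, wobbles


def scan_sites(
    target: NucleotideSequence,
    mirna: NucleotideSequence,
    max_score: float = 4.0,
) -> list[SiteMatch]:
    """Find every target window whose pairing penalty is <= ``max_score``.

    The miRNA binds its target antiparallel: miRNA position k (from the 5'
    end) pairs with the k-th base from the 3' end of the site.  Windows of
    miRNA length are scored with the penalty matrix and core doubling, and
    matches are returned sorted by (score, position).
    """
    t, m = target.residues, mirna.residues
    if len(m) > len(t):
        raise ValueError("miRNA longer than target")
    t_codes = _ENCODE_LUT[_encode(t)].astype(np.intp)
    m_codes = _ENCODE_LUT[_encode(m)].astype(np.intp)
    L = len(m)
    windows = np.lib.stride_tricks.sliding_window_view(t_codes, L)
    rev = windows[:, ::-1]  # align target 3'->5' with miRNA 5'->3'
    pen = _PENALTY[m_codes[None, :], rev]
    w = _position_weights(L)
    scores = pen @ w
    hits = np.nonzero(scores <= max_score)[0]
    matches = []
    for s in hits:
        mism = int(np.sum(pen[s] == MISMATCH_PENALTY))
        wob = int(np.sum(pen[s] == WOBBLE_PENALTY))
        matches.append(
            SiteMatch(
                target_start=int(s) + 1,
                target_end=int(s) + L,
                mismatches=mism,
                gu_wobbles=wob,
                score=float(scores[s]),
            )
        )
    matches.sort(key=lambda x: (x.score, x.target_start))
    return matches


def annotate_snp(
    site: SiteMatch,
    snp_position: int,
    ref: str,
    alt: str,
    target: NucleotideSequence,
    mirna: NucleotideSequence,
) -> SnpSiteAnnotation:
    """Annotate a SNP against one complementary site.

    ``offset_in_site`` is 1-based from the site's 5' end on the target.
    ``score_alt`` rescans the site window with the alternate base applied;
    a SNP outside the site leaves the score unchanged by construction.
    """
    ref, alt = canonicalize(ref), canonicalize(alt)
    t = target.residues
    if not 1 <= snp_position <= len(t):
        raise ValueError(f"SNP position {snp_position} outside target")
    if t[snp_position - 1] != ref:
        raise ValueError(
            f"reference allele mismatch at position {snp_position}: "
            f"target has {t[snp_position - 1]}, SNP says {ref}"
        )
    in_site = site.contains(snp_position)
    if not in_site:
        return SnpSiteAnnotation(
            snp_position=snp_position,
            in_site=False,
            offset_in_site=None,
            score_ref=site.score,
            score_alt=site.score,
        )
    window = t[site.target_start - 1 : site.target_end]
    offset = snp_position - site.target_start + 1
    alt_window = window[: offset - 1] + alt + window[offset:]
    m_codes = _ENCODE_LUT[_encode(mirna.residues)].astype(np.intp)
    alt_codes = _ENCODE_LUT[_encode(alt_window)].astype(np.intp)[::-1]
    score_alt, _, _ = _score_window(alt_codes, m_codes)
    return SnpSiteAnnotation(
        snp_position=snp_position,
        in_site=True,
        offset_in_site=offset,
        score_ref=site.score,
        score_alt=score_alt,
    )


def codon_effect(cds: NucleotideSequence, position: int, alt: str) -> CodonEffect:
    """Amino acid change of a substitution at a 1-based CDS position.

    The codon index is floor((position - 1) / 3) + 1; amino acids come from
    the standard genetic code (three-letter codes, 'Ter' for stop).
    """
    seq = cds.residues
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} is not a multiple of 3")
    if not 1 <= position <= len(seq):
        raise ValueError(f"position {position} outside CDS of length {len(seq)}")
    alt = canonicalize(alt)
    ref = seq[position - 1]
    if alt == ref:
        raise ValueError("alt allele equals the reference base")
    codon_index = (position - 1) // 3 + 1
    start = 3 * (codon_index - 1)
    codon = seq[start : start + 3]
    within = position - 1 - start
    alt_codon = codon[:within] + alt + codon[within + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    return CodonEffect(
        codon_index=codon_index,
        ref_aa=seq3(ref_aa),
        alt_aa=seq3(alt_aa),
    )


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path) -> list[NucleotideSequence]:
    """Read sequences from FASTA (DNA or RNA alphabet)."""
    from Bio import SeqIO

    return [
        NucleotideSequence(id=rec.id, residues=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_sites_tsv(path, sites: Sequence[SiteMatch], target_id: str, mirna_id: str) -> None:
    import pandas as pd

    rows = [
        {
            "target": target_id,
            "mirna": mirna_id,
            "start": s.target_start,
            "end": s.target_end,
            "mismatches": s.mismatches,
            "gu_wobbles": s.gu_wobbles,
            "score": s.score,
        }
        for s in sites
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
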