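"""Linked-read molecule reconstruction and somatic haplotype assignment.

Short reads sharing a droplet barcode derive from one long DNA molecule,
so barcoded allele observations can be chained into molecules, each
molecule can be assigned to a germline haplotype by comparing its
alleles at phased heterozygous sites, and a somatic mutation can be
placed on the haplotype its alt-carrying molecules vote for.  For two
somatic mutations on one chromosome, molecules covering both positions
reveal whether the mutations co-occur on the same molecules (cis — the
same lineage) or are only ever seen separately (independent subclones).
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter

import numpy as np
import pandas as pd

from .syndata import PhasedBlock, Variant

__all__ = [
    "Molecule",
    "HaplotypeAssignment",
    "PairClassification",
    "build_molecules",
    "assign_haplotype",
    "classify_pair",
]


@dataclass
class Molecule:
    """A barcode-defined DNA molecule with per-locus consensus alleles."""

    barcode: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    alleles: dict[int, str]  # pos -> consensus allele (ties dropped)

    def covers(self, pos: int) -> bool:
        return self.start <= pos <= self.end


def build_molecules(
    observations: pd.DataFrame, max_gap_bp: int = 50_000
) -> list[Molecule]:
    """Chain barcoded allele observations into molecules.

    Observations sharing a barcode on one chromosome belong to one
    molecule as long as consecutive observed positions are at most
    ``max_gap_bp`` apart; a larger gap starts a new molecule (distant
    barcode collisions split naturally).  The consensus allele at each
    locus is the majority over that molecule's observations there; tied
    loci are dropped.
    """
    molecules: list[Molecule] = []
    for (barcode, chrom), sub in observations.groupby(
        ["barcode", "chrom"], sort=True
    ):
        sub = sub.sort_values("pos", kind="stable")
        positions = sub["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(positions) > max_gap_bp) + 1
        for chunk in np.split(np.arange(len(sub)), breaks):
            piece = sub.iloc[chunk]
            alleles: dict[int, str] = {}
            for pos, grp in piece.groupby("pos"):
                counts = Counter(grp["allele"])
                top = counts.most_common()
                if len(top) > 1 and top[0][1] == top[1][1]:
                    continue
                alleles[int(pos)] = top[0][0]
            molecules.append(
                Molecule(
                    barcode=str(barcode),
                    chrom=str(chrom),
                    start=int(piece["pos"].min()),
                    end=int(piece["pos"].max()),
                    alleles=alleles,
                )
            )
    return molecules


@dataclass
class HaplotypeAssignment:
    """Aggregate haplotype verdict for one somatic variant."""

    haplotype: int | str  # 1, 2, or "ambiguous"
    votes_hap1: int
    votes_hap2: int
    n_alt_molecules: int


def _molecule_haplotype(mol: Molecule, block: PhasedBlock) -> int | None:
    """Haplotype a molecule matches at the majority of its covered hets.

    Returns 1 or 2, or None when the molecule covers no het or the
    match counts tie.
    """
    match1 = match2 = 0
    lo = np.searchsorted(block.positions, mol.start)
    hi = np.searchsorted(block.positions, mol.end, side="right")
    for i in range(lo, hi):
        pos = int(block.positions[i])
        allele = mol.alleles.get(pos)
        if allele is None:
            continue
        if allele == str(block.hap1[i]):
            match1 += 1
        elif allele == str(block.hap2[i]):
            match2 += 1
    if match1 == match2:
        return None
    return 1 if match1 > match2 else 2


def assign_haplotype(
    molecules: list[Molecule],
    phased_block: PhasedBlock,
    somatic_variant: Variant,
    min_votes: int = 2,
    purity_thresh: float = 0.8,
) -> HaplotypeAssignment:
    """Vote a somatic variant onto a germline haplotype.

    Each molecule carrying the somatic alternate allele votes for the
    haplotype matching the majority of its covered phased hets (tied or
    het-less molecules abstain).  The aggregate call is the majority
    haplotype when the total votes reach ``min_votes`` and the winning
    fraction reaches ``purity_thresh``; otherwise "ambiguous".
    """
    if somatic_variant.chrom != phased_block.chrom:
        raise ValueError("somatic variant not on the phased block's chromosome")
    votes = {1: 0, 2: 0}
    n_alt = 0
    for mol in molecules:
        if mol.chrom != somatic_variant.chrom:
            continue
        if mol.alleles.get(somatic_variant.pos) != somatic_variant.alt:
            continue
        n_alt += 1
        hap = _molecule_haplotype(mol, phased_block)
        if hap is not None:
            votes[hap] += 1
    total = votes[1] + votes[2]
    if total >= min_votes:
        winner = 1 if votes[1] > votes[2] else 2
        if votes[winner] / total >= purity_thresh and votes[1] != votes[2]:
            return HaplotypeAssignment(winner, votes[1], votes[2], n_alt)
    return HaplotypeAssignment("ambiguous", votes[1], votes[2], n_alt)


@dataclass
class PairClassification:
    """Relationship verdict for a somatic mutation pair."""

    relationship: str  # "cis", "independent", or "unresolved"
    n_covering_both: int
    n_both_alt: int
    n_a_only: int
    n_b_only: int
    n_neither: int


def classify_pair(
    molecules: list[Molecule],
    var_a: Variant,
    var_b: Variant,
    min_cover: int = 3,
    min_cis_molecules: int = 1,
) -> PairClassification:
    """Classify two somatic mutations as cis or independent subclones.

    Over molecules whose consensus covers both positions: if at least
    ``min_cis_molecules`` carry both alternate alleles the pair is
    "cis" (same lineage).  Otherwise, if each variant's alternate is
    observed among the both-covering molecules and their number reaches
    ``min_cover``, the mutations segregate on disjoint molecules —
    "independent" subclones.  Anything weaker is "unresolved".
    """
    if var_a.chrom != var_b.chrom:
        raise ValueError("pair classification requires one chromosome")
    n_both = n_a = n_b = n_neither = n_cover = 0
    for mol in molecules:
        if mol.chrom != var_a.chrom:
            continue
        a = mol.alleles.get(var_a.pos)
        b = mol.alleles.get(var_b.pos)
        if a is None or b is None:
            continue
        n_cover += 1
        a_alt = a == var_a.alt
        b_alt = b == var_b.alt
        if a_alt and b_alt:
            n_both += 1
        elif a_alt:
            n_a += 1
        elif b_alt:
            n_b += 1
        else:
            n_neither += 1
    if n_both >= min_cis_molecules and n_both >= 1:
        rel = "cis"
    elif n_a >= 1 and n_b >= 1 and n_cover >= min_cover:
        rel = "independent"
    else:
        rel = "unresolved"
    return PairClassification(rel, n_cover, n_both, n_a, n_b, n_neither)
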