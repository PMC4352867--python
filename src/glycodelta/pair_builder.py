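"""Construction of GP/P and P/P structure-pair corpora.

GP/P pairs match a glycosylated chain with a sequence-identical
deglycosylated chain; P/P pairs are unordered combinations of
deglycosylated chains whose sequence also occurs in the GP/P set, giving
a glycan-free baseline for crystallographic variability.  Before pairing,
chains are filtered per entry at a 90% sequence-identity redundancy
cutoff and a minimum length of 50 amino acids (shorter chains rarely have
a well-defined tertiary structure).

The 100% matcher is exact string equality on one-letter sequences, which
is the same contract as a strict-identity sequence search; chains
containing 'X' (nonstandard residues) only match sequences with 'X' at
the same positions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from Bio import Align

from .glycan_annotation import GlycosylationSite
from .structure_io import ChainModel

__all__ = [
    "ChainRecord",
    "PairClass",
    "StructurePair",
    "PairCluster",
    "sequence_identity",
    "filter_redundant",
    "filter_short",
    "build_pairs",
    "cluster_pairs",
]


class PairClass(str, Enum):
    GP_P = "GP_P"
    P_P = "P_P"


@dataclass
class ChainRecord:
    """One protein chain in the corpus, with its glycosylation status."""

    entry_id: str
    chain_id: str
    sequence: str
    glycosylated: bool = False
    sites: list[GlycosylationSite] = field(default_factory=list)
    chain: Optional[ChainModel] = None  # coordinates, when available

    def __post_init__(self) -> None:
        if self.glycosylated != bool(self.sites):
            raise ValueError("glycosylated flag must match presence of sites")

    @property
    def label(self) -> str:
        return f"{self.entry_id}{self.chain_id}"


@dataclass
class StructurePair:
    """Two chains with identical polymer sequence; the unit of scoring."""

    record_a: ChainRecord
    record_b: ChainRecord
    pair_class: PairClass
    correspondence: Optional[list[tuple[tuple[int, str], tuple[int, str]]]] = None

    def __post_init__(self) -> None:
        if self.record_a.sequence != self.record_b.sequence:
            raise ValueError("pair members must have identical sequences")
        if self.pair_class is PairClass.GP_P:
            if not self.record_a.glycosylated or self.record_b.glycosylated:
                raise ValueError("GP/P pair needs glycosylated A, deglycosylated B")
        else:
            if self.record_a.glycosylated or self.record_b.glycosylated:
                raise ValueError("P/P pair members must both be deglycosylated")

    @property
    def sequence(self) -> str:
        return self.record_a.sequence

    @property
    def pair_id(self) -> str:
        return f"{self.record_a.label}-{self.record_b.label}"


@dataclass
class PairCluster:
    key: tuple
    pairs: list[StructurePair] = field(default_factory=list)


def _identity_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    # small gap penalty so gaps are only opened when they buy matches;
    # end gaps are penalized too (they count against identity)
    aligner.open_gap_score = -0.1
    aligner.extend_gap_score = -0.1
    return aligner


_IDENTITY_ALIGNER = _identity_aligner()


def sequence_identity(a: str, b: str) -> float:
    """Global-alignment sequence identity: matches / alignment length.

    Gap columns (including terminal gaps) count against identity, which
    makes the measure conservative for fragments.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if a == b:
        return 1.0
    alignment = _IDENTITY_ALIGNER.align(a, b)[0]
    counts = alignment.counts()
    return counts.identities / alignment.length


def filter_redundant(chains: list[ChainRecord], cutoff: float = 0.90) -> list[ChainRecord]:
    """Remove redundant chains within each entry (greedy, file order).

    Iterating in input order, a chain is dropped when its identity to any
    already-retained chain of the same entry is >= ``cutoff``.
    """
    retained: list[ChainRecord] = []
    kept_by_entry: dict[str, list[ChainRecord]] = {}
    for rec in chains:
        kept = kept_by_entry.setdefault(rec.entry_id, [])
        if any(sequence_identity(rec.sequence, other.sequence) >= cutoff
               for other in kept):
            continue
        kept.append(rec)
        retained.append(rec)
    return retained


def filter_short(chains: list[ChainRecord], min_len: int = 50) -> list[ChainRecord]:
    """Retain chains with at least ``min_len`` amino acids."""
    return [rec for rec in chains if len(rec.sequence) >= min_len]


def build_pairs(glyco: list[ChainRecord], deglyco: list[ChainRecord],
                pair_class: PairClass) -> list[StructurePair]:
    """Enumerate GP/P or P/P pairs over filtered chain sets.

    GP/P: every (glycosylated, deglycosylated) combination with exactly
    identical sequences.  P/P: every unordered deglycosylated pair whose
    shared sequence occurs among the glycosylated chains (i.e. belongs to
    the GP/P set); no self-pairs.
    """
    pairs: list[StructurePair] = []
    if pair_class is PairClass.GP_P:
        for g in glyco:
            for d in deglyco:
                if g.sequence == d.sequence:
                    pairs.append(StructurePair(g, d, PairClass.GP_P))
    else:
        gp_sequences = {g.sequence for g in glyco}
        by_seq: dict[str, list[ChainRecord]] = {}
        for d in deglyco:
            by_seq.setdefault(d.sequence, []).append(d)
        for seq in sorted(by_seq):
            if seq not in gp_sequences:
                continue
            for d1, d2 in itertools.combinations(by_seq[seq], 2):
                pairs.append(StructurePair(d1, d2, PairClass.P_P))
    return pairs


def cluster_pairs(pairs: list[StructurePair],
                  key: str = "sequence") -> list[PairCluster]:
    """Partition pairs by exact sequence (or sequence + glycosylation site).

    With ``key='sequence_and_site'`` a pair carrying several sites joins
    one cluster per site (local-shell analyses score each site
    separately).  Clusters are returned in lexicographic key order.
    """
    if key not in ("sequence", "sequence_and_site"):
        raise ValueError(f"unknown cluster key: {key!r}")
    clusters: dict[tuple, PairCluster] = {}
    for pair in pairs:
        if key == "sequence":
            keys = [(pair.sequence,)]
        else:
            sites = pair.record_a.sites or pair.record_b.sites
            keys = [(pair.sequence, s.residue_number, s.icode) for s in sites]
            if not keys:
                keys = [(pair.sequence, -1, "")]
        for k in keys:
            clusters.setdefault(k, PairCluster(key=k)).pairs.append(pair)
    return [clusters[k] for k in sorted(clusters)]
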