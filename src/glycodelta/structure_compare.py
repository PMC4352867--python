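"""Global and local structural similarity scoring for chain pairs.

Global similarity is the Cα RMSD after optimal least-squares (Kabsch)
superposition, plus the size-independent TM-score.  Local similarity is
the RMSD over a concentric shell of residues within a fixed radius
(default 15 Å) of a glycosylated Asn's Cα, superposed on the shell
residues only.  Because pair members have identical sequences, the
residue alignment is fixed by a global sequence alignment and only the
superposition / score optimization is performed here.

TM-score definition (for a fixed residue correspondence)::

    TM = max over superpositions of (1/L) * sum_i 1 / (1 + (d_i/d0)^2)
    d0(L) = 1.24 * (L - 15)^(1/3) - 1.8        (floored at 0.5 Å)

with L the normalization length (the deglycosylated member's length) and
d_i the per-residue Cα distances after superposition.  The maximization
uses the standard iterative scheme: initial superpositions from the full
alignment and contiguous fragments, then repeated "superpose on residues
closer than a cutoff, rescore" refinement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio import Align

from .glycan_annotation import GlycosylationSite
from .pair_builder import StructurePair
from .structure_io import ChainModel

__all__ = [
    "SuperpositionResult",
    "TMScoreResult",
    "LocalShell",
    "kabsch_superpose",
    "map_equivalent_residues",
    "global_rmsd",
    "tm_score",
    "tm_d0",
    "extract_local_shell",
    "local_rmsd",
    "cumulative_histogram",
]

ResidueId = tuple[int, str]


@dataclass
class SuperpositionResult:
    """Optimal rigid superposition of a mobile onto a fixed point set.

    ``rotation`` is a proper rotation (det = +1); the transform
    ``rotation @ x + translation`` maps mobile coordinates onto the fixed
    frame.  ``degenerate`` flags (near-)collinear point sets, where the
    rotation is not unique although the RMSD still is.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int
    degenerate: bool = False

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class TMScoreResult:
    score: float
    l_target: int
    d0: float


@dataclass
class LocalShell:
    site: GlycosylationSite
    radius: float
    member_ids: list[ResidueId]


def kabsch_superpose(fixed: np.ndarray, mobile: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition (Kabsch, SVD form).

    Finds the proper rotation + translation minimizing the RMSD between
    the mobile and fixed point sets (1:1 correspondence by index);
    reflections are corrected by flipping the smallest singular vector.
    """
    fixed = np.asarray(fixed, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    if fixed.shape != mobile.shape or fixed.ndim != 2 or fixed.shape[1] != 3:
        raise ValueError("point sets must be matching N x 3 arrays")
    n = fixed.shape[0]
    if n < 3:
        raise ValueError("at least 3 points are required for superposition")
    mu_f = fixed.mean(axis=0)
    mu_m = mobile.mean(axis=0)
    x = mobile - mu_m
    y = fixed - mu_f
    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = mu_f - rotation @ mu_m
    moved = mobile @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - fixed) ** 2, axis=1))))
    # rank deficiency of the covariance => collinear/planar-degenerate input
    degenerate = bool(np.sum(s > 1e-8 * max(s[0], 1e-300)) < 2)
    return SuperpositionResult(rotation=rotation, translation=translation,
                               rmsd=rmsd, n_atoms=n, degenerate=degenerate)


def _mapping_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    return aligner


_MAPPING_ALIGNER = _mapping_aligner()


def map_equivalent_residues(chain_a: ChainModel,
                            chain_b: ChainModel) -> list[tuple[ResidueId, ResidueId]]:
    """Equivalent-residue correspondence via global sequence alignment.

    Residue numbering in crystal structures is unreliable (offsets,
    missing loops), so equivalence is established by Needleman-Wunsch
    alignment of the one-letter sequences; only identically-matching
    aligned columns enter the correspondence, keyed by author residue
    ids.
    """
    aa_a = chain_a.amino_acid_residues()
    aa_b = chain_b.amino_acid_residues()
    if not aa_a or not aa_b:
        raise ValueError("cannot map residues of an empty chain")
    seq_a = "".join(r.one_letter for r in aa_a)
    seq_b = "".join(r.one_letter for r in aa_b)
    if seq_a == seq_b:
        return [(ra.id, rb.id) for ra, rb in zip(aa_a, aa_b)]
    alignment = _MAPPING_ALIGNER.align(seq_a, seq_b)[0]
    mapping: list[tuple[ResidueId, ResidueId]] = []
    for (a_start, a_end), (b_start, b_end) in zip(*alignment.aligned):
        for ia, ib in zip(range(a_start, a_end), range(b_start, b_end)):
            if seq_a[ia] == seq_b[ib]:
                mapping.append((aa_a[ia].id, aa_b[ib].id))
    return mapping


def _ca_lookup(chain: ChainModel) -> dict[ResidueId, np.ndarray]:
    out = {}
    for res in chain.amino_acid_residues():
        ca = res.atom("CA")
        if ca is not None:
            out[res.id] = ca.xyz
    return out


def _require_chains(pair: StructurePair) -> tuple[ChainModel, ChainModel]:
    if pair.record_a.chain is None or pair.record_b.chain is None:
        raise ValueError("pair records must carry chain coordinates for scoring")
    return pair.record_a.chain, pair.record_b.chain


def _pair_correspondence(pair: StructurePair) -> list[tuple[ResidueId, ResidueId]]:
    if pair.correspondence is None:
        chain_a, chain_b = _require_chains(pair)
        pair.correspondence = map_equivalent_residues(chain_a, chain_b)
    return pair.correspondence


def _mapped_ca(pair: StructurePair,
               subset_a: Optional[set[ResidueId]] = None) -> tuple[np.ndarray, np.ndarray]:
    """Cα coordinate arrays over the mapped residues (A first, B second).

    Mapped residues lacking a Cα in either member are dropped.
    """
    chain_a, chain_b = _require_chains(pair)
    ca_a = _ca_lookup(chain_a)
    ca_b = _ca_lookup(chain_b)
    xs, ys = [], []
    for ida, idb in _pair_correspondence(pair):
        if subset_a is not None and ida not in subset_a:
            continue
        if ida in ca_a and idb in ca_b:
            xs.append(ca_a[ida])
            ys.append(ca_b[idb])
    return np.array(xs), np.array(ys)


def global_rmsd(pair: StructurePair) -> float:
    """Cα RMSD over all mapped residues after Kabsch superposition."""
    xa, xb = _mapped_ca(pair)
    if len(xa) < 3:
        raise ValueError("fewer than 3 mapped Cα pairs")
    return kabsch_superpose(xa, xb).rmsd


def tm_d0(l_target: int) -> float:
    """TM-score distance scale for normalization length ``l_target``."""
    if l_target < 20:
        raise ValueError("TM-score normalization length must be >= 20")
    return max(1.24 * (l_target - 15) ** (1.0 / 3.0) - 1.8, 0.5)


def _tm_sum(d2: np.ndarray, d0: float) -> float:
    return float(np.sum(1.0 / (1.0 + d2 / d0 ** 2)))


def tm_score(pair: StructurePair, max_iter: int = 20) -> TMScoreResult:
    """TM-score of a pair under its fixed residue correspondence.

    Normalized by the deglycosylated member's amino-acid length.  The
    superposition maximizing the score is searched by seeding from the
    full-alignment Kabsch fit plus contiguous fragments (L, L/2, L/4
    windows) and iterating inclusion-threshold refinement from each seed.
    """
    xa, xb = _mapped_ca(pair)
    n = len(xa)
    if n < 3:
        raise ValueError("fewer than 3 mapped Cα pairs")
    l_target = len(pair.record_b.sequence)
    d0 = tm_d0(l_target)

    def score_for(idx: np.ndarray) -> tuple[float, np.ndarray]:
        sup = kabsch_superpose(xa[idx], xb[idx])
        moved = sup.transform(xb)
        d2 = np.sum((moved - xa) ** 2, axis=1)
        return _tm_sum(d2, d0) / l_target, d2

    seeds: list[np.ndarray] = [np.arange(n)]
    for frac in (2, 4):
        w = max(n // frac, 3)
        step = max(w // 2, 1)
        for start in range(0, n - w + 1, step):
            seeds.append(np.arange(start, start + w))

    best = -1.0
    for seed in seeds:
        idx = seed
        prev: Optional[frozenset[int]] = None
        for _ in range(max_iter):
            score, d2 = score_for(idx)
            best = max(best, score)
            d_cut = max(d0, 2.0)
            included = np.where(d2 < d_cut ** 2)[0]
            while len(included) < 3:
                d_cut += 0.5
                included = np.where(d2 < d_cut ** 2)[0]
            key = frozenset(included.tolist())
            if key == prev:
                break
            prev = key
            idx = included
    return TMScoreResult(score=best, l_target=l_target, d0=d0)


def extract_local_shell(glyco_chain: ChainModel, site: GlycosylationSite,
                        radius: float = 15.0) -> LocalShell:
    """Residues whose Cα lies within ``radius`` (inclusive) of the site Cα.

    The shell is defined on the glycosylated member only, anchored at the
    glycosylated Asn's Cα.
    """
    site_res = glyco_chain.residue(site.residue_number, site.icode)
    if site_res is None:
        raise ValueError(
            f"site residue {site.residue_number}{site.icode} not in chain")
    site_ca = site_res.atom("CA")
    if site_ca is None:
        raise ValueError("site residue lacks a Cα atom")
    members = []
    for res in glyco_chain.amino_acid_residues():
        ca = res.atom("CA")
        if ca is None:
            continue
        if np.linalg.norm(ca.xyz - site_ca.xyz) <= radius:
            members.append(res.id)
    return LocalShell(site=site, radius=radius, member_ids=members)


def local_rmsd(pair: StructurePair, site: GlycosylationSite,
               radius: float = 15.0, superpose: str = "shell") -> float:
    """Cα RMSD over the site's local shell.

    With ``superpose='shell'`` (default) the least-squares fit uses the
    shell residues only; ``superpose='global'`` fits on all mapped
    residues and measures the deviation over the shell.
    """
    # record A is the glycosylated member of a GP/P pair; for P/P pairs the
    # shell is anchored on member A at the site inherited from the GP set
    glyco_chain = pair.record_a.chain
    if glyco_chain is None:
        raise ValueError("pair lacks coordinates")
    shell = extract_local_shell(glyco_chain, site, radius=radius)
    subset = set(shell.member_ids)
    xa, xb = _mapped_ca(pair, subset_a=subset)
    if len(xa) < 3:
        raise ValueError("fewer than 3 mapped shell residues")
    if superpose == "shell":
        return kabsch_superpose(xa, xb).rmsd
    if superpose == "global":
        ga, gb = _mapped_ca(pair)
        sup = kabsch_superpose(ga, gb)
        moved = sup.transform(xb)
        return float(np.sqrt(np.mean(np.sum((moved - xa) ** 2, axis=1))))
    raise ValueError(f"unknown superpose mode: {superpose!r}")


def cumulative_histogram(cluster_means: Sequence[float],
                         thresholds: Sequence[float],
                         direction: str = "le") -> np.ndarray:
    """Accumulated fraction of cluster means at each threshold.

    ``direction='le'`` (RMSD convention) counts means <= t;
    ``direction='ge'`` (TM-score convention) counts means >= t.
    """
    means = np.asarray(cluster_means, dtype=float)
    if means.size == 0:
        raise ValueError("no cluster means supplied")
    thresholds = np.asarray(thresholds, dtype=float)
    if direction == "le":
        return np.array([(means <= t).mean() for t in thresholds])
    if direction == "ge":
        return np.array([(means >= t).mean() for t in thresholds])
    raise ValueError(f"unknown direction: {direction!r}")
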