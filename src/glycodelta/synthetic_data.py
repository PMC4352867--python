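"""Synthetic glycoprotein structures, perturbation pairs, corpora and
trajectories with known ground truth.

Everything the pipeline consumes can be generated here deterministically
from a seed: toy Cα-trace proteins with minimal backbones and Asn/Ser/Thr
side-chain attachment atoms, mock linear glycans wired with covalent-range
geometry and CONECT hints, controlled structural perturbations
(rigid-body, Gaussian noise, loop displacement, domain rotation), pair
corpora with combinatorial truth manifests, and Cα trajectories whose
per-residue fluctuation amplitudes are specified exactly.

Mock sugars are geometric placeholders carrying NAG codes: site detection
keys on names, distances and connectivity, not on carbohydrate chemistry.
Trajectory fluctuations are iid Gaussian per frame, so the expected RMSF
has the closed form sigma * sqrt(3) for per-component amplitude sigma.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .glycan_annotation import classify_saccharides
from .structure_io import (
    Atom,
    ChainModel,
    Residue,
    ResidueKind,
    StructureModel,
    write_structure,
    models_to_multimodel_pdb,
)
from .trajectory_analysis import Trajectory

__all__ = [
    "SiteSpec",
    "SyntheticSpec",
    "GaussianNoise",
    "LoopShift",
    "DomainRotation",
    "TrajectorySpec",
    "ConformationalShift",
    "CorpusSequenceSpec",
    "generate_toy_protein",
    "attach_mock_glycan",
    "delete_glycans",
    "perturb",
    "generate_trajectory",
    "generate_pair_corpus",
]

# one-letter filler alphabet; excludes N/P/S/T so sequon context is fully
# controlled by the site specification
_FILLER = "ADEFGHIKLMQRVW"
_ONE_TO_THREE = {
    "A": "ALA", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY", "H": "HIS",
    "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "Q": "GLN", "R": "ARG",
    "V": "VAL", "W": "TRP", "N": "ASN", "P": "PRO", "S": "SER", "T": "THR",
}

HELIX_RISE = 1.5          # angstrom per residue
HELIX_TWIST = 100.0       # degrees per residue
HELIX_RADIUS = 2.28       # gives consecutive Ca-Ca ~= 3.8 angstrom


@dataclass
class SiteSpec:
    """A designated N-glycosylation site on a toy protein."""

    residue: int              # author number, 1-based
    n_sugars: int = 2
    sequon: bool = True       # False plants Pro at i+1, violating the sequon


@dataclass
class SyntheticSpec:
    n_residues: int
    geometry: str = "helix"   # helix | extended | two_domain
    sites: list[SiteSpec] = field(default_factory=list)
    seed: int = 0
    hinge: Optional[int] = None   # two_domain only; default n_residues // 2
    chain_id: str = "A"
    entry_id: str = "TOY"


@dataclass
class GaussianNoise:
    sigma: float


@dataclass
class LoopShift:
    start: int
    end: int                  # inclusive author-number range
    delta: float              # angstrom
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)


@dataclass
class DomainRotation:
    hinge: int                # residues with number > hinge rotate
    angle_deg: float
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)


@dataclass
class ConformationalShift:
    """A sustained, glycan-independent displacement of a residue block.

    Emulates loop movement / domain rearrangement that separates a
    trajectory from its initial structure without being a fluctuation.
    """

    start_index: int          # selection indices, inclusive
    end_index: int
    delta: float
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)


@dataclass
class TrajectorySpec:
    base: np.ndarray                      # N x 3 reference coordinates
    residue_ids: list[tuple[int, str]]
    sigma: Union[float, np.ndarray]       # per-component amplitude(s), angstrom
    n_frames: int
    dt_ns: float = 0.24
    seed: int = 0
    n_replicates: int = 1
    rigid_drift: bool = False
    shift: Optional[ConformationalShift] = None


def _sequence_for(spec: SyntheticSpec) -> str:
    rng = np.random.default_rng(spec.seed)
    letters = [_FILLER[i] for i in rng.integers(0, len(_FILLER), spec.n_residues)]
    for site in spec.sites:
        i = site.residue - 1
        if not 0 <= i < spec.n_residues:
            raise ValueError(f"site residue {site.residue} outside chain")
        letters[i] = "N"
        if i + 1 < spec.n_residues:
            letters[i + 1] = "P" if not site.sequon else "G"
        if i + 2 < spec.n_residues:
            letters[i + 2] = "T" if site.sequon else "A"
    return "".join(letters)


def _ca_positions(spec: SyntheticSpec) -> np.ndarray:
    n = spec.n_residues
    k = np.arange(n)
    if spec.geometry == "helix":
        theta = np.deg2rad(HELIX_TWIST) * k
        return np.column_stack([HELIX_RADIUS * np.cos(theta),
                                HELIX_RADIUS * np.sin(theta),
                                HELIX_RISE * k])
    if spec.geometry == "extended":
        return np.column_stack([3.8 * k, 0.5 * (k % 2), np.zeros(n)])
    if spec.geometry == "two_domain":
        hinge = spec.hinge if spec.hinge is not None else n // 2
        if not 1 <= hinge < n:
            raise ValueError("hinge outside chain")
        theta = np.deg2rad(HELIX_TWIST) * k
        pos = np.column_stack([HELIX_RADIUS * np.cos(theta),
                               HELIX_RADIUS * np.sin(theta),
                               HELIX_RISE * k])
        # fold the second rigid body 90 degrees about x through the hinge Ca
        pivot = pos[hinge - 1]
        rot = _rotation_matrix((1.0, 0.0, 0.0), 90.0)
        pos[hinge:] = (pos[hinge:] - pivot) @ rot.T + pivot
        return pos
    raise ValueError(f"unknown geometry: {spec.geometry!r}")


def _rotation_matrix(axis: Sequence[float], angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    x, y, z = axis
    return np.array([
        [c + x * x * (1 - c), x * y * (1 - c) - z * s, x * z * (1 - c) + y * s],
        [y * x * (1 - c) + z * s, c + y * y * (1 - c), y * z * (1 - c) - x * s],
        [z * x * (1 - c) - y * s, z * y * (1 - c) + x * s, c + z * z * (1 - c)],
    ])


def generate_toy_protein(spec: SyntheticSpec) -> StructureModel:
    """Build a deterministic toy protein with backbone + site side chains.

    Geometry is an ideal helix (1.5 Å rise, 100°/residue), an extended
    chain, or an L-shaped two-domain helix.  Residues get N, CA, C, O
    backbone atoms; designated Asn sites additionally carry CB/CG/OD1/ND2
    pointing outward so a glycan can be attached at covalent range, and
    the sequon partner Thr carries OG1.
    """
    if spec.n_residues < 5:
        raise ValueError("toy proteins need at least 5 residues")
    seq = _sequence_for(spec)
    ca = _ca_positions(spec)
    chain = ChainModel(chain_id=spec.chain_id)
    serial = 0
    for i, letter in enumerate(seq):
        res = Residue(name=_ONE_TO_THREE[letter], number=i + 1,
                      kind=ResidueKind.AMINO_ACID)
        prev_dir = ca[i] - ca[i - 1] if i > 0 else ca[i] - ca[i + 1]
        next_dir = ca[i + 1] - ca[i] if i < len(seq) - 1 else ca[i] - ca[i - 1]
        prev_dir = prev_dir / np.linalg.norm(prev_dir)
        next_dir = next_dir / np.linalg.norm(next_dir)
        # outward direction: radial for helical geometries, +z for extended
        if spec.geometry == "extended":
            out = np.array([0.0, 0.0, 1.0])
        else:
            radial = ca[i] - np.array([0.0, 0.0, ca[i][2]])
            nrm = np.linalg.norm(radial)
            out = radial / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
        atoms = [
            ("N", "N", ca[i] - prev_dir * 1.45),
            ("CA", "C", ca[i]),
            ("C", "C", ca[i] + next_dir * 1.52),
            ("O", "O", ca[i] + next_dir * 1.52 + out * 1.23),
        ]
        if letter == "N":
            atoms += [
                ("CB", "C", ca[i] + out * 1.53),
                ("CG", "C", ca[i] + out * 3.0),
                ("OD1", "O", ca[i] + out * 3.0 + prev_dir * 1.23),
                ("ND2", "N", ca[i] + out * 4.3),
            ]
        elif letter == "S":
            atoms += [("CB", "C", ca[i] + out * 1.53), ("OG", "O", ca[i] + out * 2.9)]
        elif letter == "T":
            atoms += [("CB", "C", ca[i] + out * 1.53), ("OG1", "O", ca[i] + out * 2.9)]
        for name, element, xyz in atoms:
            serial += 1
            res.atoms.append(Atom(name=name, element=element, xyz=np.asarray(xyz),
                                  serial=serial))
        chain.residues.append(res)
    return StructureModel(id=spec.entry_id, chains=[chain])


def _next_serial(model: StructureModel) -> int:
    return max((a.serial for _, _, a in model.atoms()), default=0) + 1


def attach_mock_glycan(model: StructureModel, residue_number: int,
                       n_sugars: int, chain_id: Optional[str] = None) -> StructureModel:
    """Attach a linear chain of NAG placeholders at an Asn ND2 (in place).

    The first sugar's C1 sits 1.45 Å from ND2; successive sugars are
    bridged by a glycosidic O3(i)-C1(i+1) contact of 1.43 Å.  CONECT
    hints are emitted for the attachment and the inter-sugar bonds.
    """
    if n_sugars < 1:
        raise ValueError("need at least one sugar residue")
    chain = model.chain(chain_id) if chain_id else model.chains[0]
    if chain is None:
        raise ValueError(f"chain {chain_id!r} not found")
    res = chain.residue(residue_number)
    if res is None or res.name != "ASN":
        raise ValueError(f"residue {residue_number} is not an Asn")
    nd2 = res.atom("ND2")
    ca = res.atom("CA")
    if nd2 is None or ca is None:
        raise ValueError("Asn residue lacks ND2/CA atoms")
    u = nd2.xyz - ca.xyz
    u = u / np.linalg.norm(u)
    v = np.cross(u, [0.0, 0.0, 1.0])
    if np.linalg.norm(v) < 1e-6:
        v = np.cross(u, [1.0, 0.0, 0.0])
    v = v / np.linalg.norm(v)

    serial = _next_serial(model)
    number = max(r.number for r in chain.residues) + 1
    prev_o3_serial = None
    for i in range(n_sugars):
        p = nd2.xyz + u * (1.45 + 3.7 * i)
        sugar = Residue(name="NAG", number=number + i, kind=ResidueKind.OTHER)
        for name, element, xyz in [
            ("C1", "C", p),
            ("C2", "C", p + 0.75 * u + 0.7 * v),
            ("O5", "O", p + 0.75 * u - 0.7 * v),
            ("C3", "C", p + 1.5 * u),
            ("O3", "O", p + 2.27 * u),
        ]:
            sugar.atoms.append(Atom(name=name, element=element, xyz=xyz, serial=serial))
            serial += 1
        chain.residues.append(sugar)
        c1_serial = sugar.atom("C1").serial
        if i == 0:
            model.conect.add(frozenset((nd2.serial, c1_serial)))
        else:
            model.conect.add(frozenset((prev_o3_serial, c1_serial)))
        prev_o3_serial = sugar.atom("O3").serial
    return model


def delete_glycans(model: StructureModel) -> StructureModel:
    """Remove every saccharide residue and its bond hints (in place).

    Protein coordinates are untouched; deleting from an unglycosylated
    model is the identity.
    """
    classify_saccharides(model)
    removed_serials: set[int] = set()
    for chain in model.chains:
        keep = []
        for res in chain.residues:
            if res.kind is ResidueKind.SACCHARIDE:
                removed_serials.update(a.serial for a in res.atoms)
            else:
                keep.append(res)
        chain.residues = keep
    model.chains = [c for c in model.chains if c.residues]
    model.conect = {p for p in model.conect if not (p & removed_serials)}
    return model


def perturb(model: StructureModel, perturbation, seed: int = 0) -> StructureModel:
    """Return a perturbed deep copy of a model.

    ``GaussianNoise`` adds iid N(0, sigma^2) per coordinate to every atom;
    ``LoopShift`` translates an inclusive author-number range along a
    fixed axis; ``DomainRotation`` rotates all residues past the hinge
    about an axis through the hinge residue's Cα.
    """
    out = copy.deepcopy(model)
    if perturbation is None:
        return out
    if isinstance(perturbation, GaussianNoise):
        rng = np.random.default_rng(seed)
        for _, _, atom in out.atoms():
            atom.xyz = atom.xyz + rng.normal(0.0, perturbation.sigma, 3)
        return out
    if isinstance(perturbation, LoopShift):
        axis = np.asarray(perturbation.axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        hit = False
        for chain in out.chains:
            for res in chain.residues:
                if perturbation.start <= res.number <= perturbation.end:
                    hit = True
                    for atom in res.atoms:
                        atom.xyz = atom.xyz + axis * perturbation.delta
        if not hit:
            raise ValueError("loop range matches no residues")
        return out
    if isinstance(perturbation, DomainRotation):
        rot = _rotation_matrix(perturbation.axis, perturbation.angle_deg)
        pivot = None
        for chain in out.chains:
            res = chain.residue(perturbation.hinge)
            if res is not None and res.atom("CA") is not None:
                pivot = res.atom("CA").xyz.copy()
                break
        if pivot is None:
            raise ValueError("hinge residue not found (or lacks Cα)")
        for chain in out.chains:
            for res in chain.residues:
                if res.number > perturbation.hinge:
                    for atom in res.atoms:
                        atom.xyz = rot @ (atom.xyz - pivot) + pivot
        return out
    raise TypeError(f"unknown perturbation: {perturbation!r}")


def generate_trajectory(tspec: TrajectorySpec) -> list[Trajectory]:
    """Synthesize replicate Cα trajectories with known fluctuations.

    Each frame is ``base + sustained shift + iid Gaussian displacement``
    with per-residue, per-component amplitude sigma_j; an optional slow
    rigid drift (rotation + translation growing linearly with the frame
    index) exercises the superposition step of downstream analyses.
    Replicate seeds are spawned deterministically from ``tspec.seed``.
    """
    if tspec.n_frames < 2:
        raise ValueError("need at least 2 frames")
    base = np.asarray(tspec.base, dtype=float)
    n = base.shape[0]
    if base.shape != (n, 3) or n != len(tspec.residue_ids):
        raise ValueError("base coordinates must be N x 3 matching residue ids")
    sigma = np.broadcast_to(np.asarray(tspec.sigma, dtype=float), (n,)).copy()
    if np.any(sigma < 0):
        raise ValueError("amplitudes must be non-negative")

    shifted = base.copy()
    if tspec.shift is not None:
        s = tspec.shift
        axis = np.asarray(s.axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        if not 0 <= s.start_index <= s.end_index < n:
            raise ValueError("shift index range outside selection")
        shifted[s.start_index:s.end_index + 1] += axis * s.delta

    seeds = np.random.SeedSequence(tspec.seed).spawn(tspec.n_replicates)
    trajectories = []
    for rep_seed in seeds:
        rng = np.random.default_rng(rep_seed)
        frames = np.empty((tspec.n_frames, n, 3))
        for f in range(tspec.n_frames):
            frame = shifted + rng.normal(0.0, 1.0, (n, 3)) * sigma[:, None]
            if tspec.rigid_drift:
                rot = _rotation_matrix((0.0, 0.0, 1.0), 0.05 * f)
                frame = frame @ rot.T + np.array([0.01, -0.005, 0.002]) * f
            frames[f] = frame
        times = tspec.dt_ns * np.arange(1, tspec.n_frames + 1)
        trajectories.append(Trajectory(residue_ids=list(tspec.residue_ids),
                                       frames=frames, times=times))
    return trajectories


# --------------------------------------------------------------------------
# pair corpora

@dataclass
class CorpusSequenceSpec:
    """One distinct protein sequence in a synthetic corpus."""

    name: str
    n_residues: int = 60
    n_glyco: int = 1              # glycosylated entries (one chain each)
    n_deglyco: int = 2            # carbohydrate-free entries
    sites: list[SiteSpec] = field(default_factory=lambda: [SiteSpec(residue=20)])
    noise_sigma: float = 0.3      # crystal-condition variability, angstrom
    n_redundant_chains: int = 0   # extra same-sequence chains inside entry 1
    seed_offset: int = 0

    @property
    def passes_filters(self) -> bool:
        return self.n_residues >= 50


def generate_pair_corpus(specs: Sequence[CorpusSequenceSpec], seed: int,
                         out_dir: Union[str, Path]) -> dict:
    """Write a corpus of glycosylated/deglycosylated PDB files + truth.

    For each sequence spec, ``n_glyco`` glycoprotein entries and
    ``n_deglyco`` carbohydrate-free entries are written (each entry one
    file), every chain carrying small Gaussian coordinate noise to mimic
    independent crystallographic determinations.  Redundant extra chains
    (same sequence, different chain id) exercise the per-entry redundancy
    filter; short sequences exercise the length filter.  The returned
    (and JSON-serialized) truth manifest holds the combinatorial pair
    counts implied by the filter rules.
    """
    if not specs:
        raise ValueError("corpus needs at least one sequence spec")
    out_dir = Path(out_dir)
    glyco_dir = out_dir / "glyco"
    deglyco_dir = out_dir / "deglyco"
    glyco_dir.mkdir(parents=True, exist_ok=True)
    deglyco_dir.mkdir(parents=True, exist_ok=True)

    truth_rows = []
    gp_p_total = 0
    p_p_total = 0
    glyco_retained = 0
    deglyco_retained = 0
    for si, sspec in enumerate(specs):
        base_seed = seed + 1000 * (si + 1) + sspec.seed_offset
        proto = SyntheticSpec(n_residues=sspec.n_residues, geometry="helix",
                              sites=list(sspec.sites), seed=base_seed,
                              entry_id=sspec.name)
        for g in range(sspec.n_glyco):
            entry = f"{sspec.name}G{g}"
            base = generate_toy_protein(proto)
            noisy = perturb(base, GaussianNoise(sspec.noise_sigma),
                            seed=base_seed + 10 + g)
            noisy.id = entry
            for site in sspec.sites:
                attach_mock_glycan(noisy, site.residue, site.n_sugars)
            if g == 0 and sspec.n_redundant_chains:
                for extra in range(sspec.n_redundant_chains):
                    dup_spec = copy.deepcopy(proto)
                    dup_spec.chain_id = chr(ord("B") + extra)
                    dup = generate_toy_protein(dup_spec)
                    dup = perturb(dup, GaussianNoise(sspec.noise_sigma),
                                  seed=base_seed + 500 + extra)
                    dup_chain = dup.chains[0]
                    # re-serial to avoid collisions inside the entry
                    offset = _next_serial(noisy)
                    for r in dup_chain.residues:
                        for a in r.atoms:
                            a.serial += offset
                    noisy.chains.append(dup_chain)
            write_structure(noisy, glyco_dir / f"{entry}.pdb")
        for d in range(sspec.n_deglyco):
            entry = f"{sspec.name}D{d}"
            base = generate_toy_protein(proto)
            noisy = perturb(base, GaussianNoise(sspec.noise_sigma),
                            seed=base_seed + 100 + d)
            noisy.id = entry
            write_structure(noisy, deglyco_dir / f"{entry}.pdb")

        if sspec.passes_filters:
            gp_p = sspec.n_glyco * sspec.n_deglyco
            p_p = math.comb(sspec.n_deglyco, 2) if sspec.n_glyco else 0
            glyco_retained += sspec.n_glyco
            deglyco_retained += sspec.n_deglyco
        else:
            gp_p = p_p = 0
        gp_p_total += gp_p
        p_p_total += p_p
        truth_rows.append({
            "sequence_name": sspec.name,
            "n_residues": sspec.n_residues,
            "passes_filters": sspec.passes_filters,
            "n_glyco": sspec.n_glyco,
            "n_deglyco": sspec.n_deglyco,
            "n_sites": len(sspec.sites),
            "gp_p_pairs": gp_p,
            "p_p_pairs": p_p,
        })

    manifest = {
        "seed": seed,
        "sequences": truth_rows,
        "expected": {
            "glyco_chains_retained": glyco_retained,
            "deglyco_chains_retained": deglyco_retained,
            "gp_p_pairs": gp_p_total,
            "p_p_pairs": p_p_total,
        },
    }
    (out_dir / "truth.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def write_trajectory_pdb(model: StructureModel, traj: Trajectory,
                         path: Union[str, Path]) -> Path:
    """Serialize a Cα trajectory as a multi-model PDB over a template model.

    The template must contain exactly the trajectory's residue selection;
    each frame replaces the Cα coordinates.
    """
    frames = []
    for f in range(traj.n_frames):
        m = copy.deepcopy(model)
        idx = {rid: i for i, rid in enumerate(traj.residue_ids)}
        for chain in m.chains:
            for res in chain.residues:
                if res.id in idx and res.atom("CA") is not None:
                    ca = res.atom("CA")
                    ca.xyz = traj.frames[f][idx[res.id]]
        frames.append(m)
    text = models_to_multimodel_pdb(frames)
    path = Path(path)
    path.write_text(text)
    return path
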