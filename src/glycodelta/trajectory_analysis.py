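"""Trajectory fluctuation analysis: RMSD time series and per-residue RMSF.

The RMSD series is measured against the initial (frame-0 or supplied)
structure after superposing each frame.  RMSF uses the average structure
of a trailing window (default the last quarter of the run, mirroring a
last-50-of-200-ns convention) as the reference: each window frame is
superposed onto the average and the per-residue root-mean-square
deviation from it is accumulated.  Replicate runs are summarized by a
grand mean and the standard error over replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .glycan_annotation import GlycosylationSite
from .structure_compare import kabsch_superpose
from .structure_io import StructureModel, parse_models

__all__ = [
    "Trajectory",
    "RMSFProfile",
    "ReplicateSummary",
    "load_trajectory",
    "rmsd_series",
    "window_average_structure",
    "rmsf_profile",
    "aggregate_replicates",
    "max_delta_residue",
]

ResidueId = tuple[int, str]


@dataclass
class Trajectory:
    """Ordered Cα frames for a fixed residue selection."""

    residue_ids: list[ResidueId]
    frames: np.ndarray          # F x N x 3, angstrom
    times: np.ndarray           # ns, strictly increasing

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be F x N x 3")
        if self.frames.shape[1] != len(self.residue_ids):
            raise ValueError("frame width must match selection size")
        if len(self.times) != self.frames.shape[0]:
            raise ValueError("one time per frame required")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


@dataclass
class RMSFProfile:
    residue_ids: list[ResidueId]
    values: np.ndarray          # angstrom, >= 0
    reference: str = "trailing-window average structure"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.residue_ids):
            raise ValueError("one RMSF value per residue required")
        if np.any(self.values < -1e-12):
            raise ValueError("RMSF values must be non-negative")

    @property
    def mean(self) -> float:
        return float(self.values.mean())


@dataclass
class ReplicateSummary:
    replicate_means: list[float]
    mean: float = field(init=False)
    se: float = field(init=False)
    single_replicate: bool = field(init=False)

    def __post_init__(self) -> None:
        if not self.replicate_means:
            raise ValueError("at least one replicate required")
        vals = np.asarray(self.replicate_means, dtype=float)
        self.mean = float(vals.mean())
        self.single_replicate = len(vals) == 1
        self.se = 0.0 if self.single_replicate else float(
            vals.std(ddof=1) / np.sqrt(len(vals)))


def _model_ca(model: StructureModel,
              residue_range: Optional[tuple[int, int]] = None
              ) -> tuple[list[ResidueId], np.ndarray]:
    ids, coords = [], []
    for chain in model.chains:
        for res in chain.amino_acid_residues():
            if residue_range is not None and not (
                    residue_range[0] <= res.number <= residue_range[1]):
                continue
            ca = res.atom("CA")
            if ca is not None:
                ids.append(res.id)
                coords.append(ca.xyz)
    return ids, np.array(coords)


def load_trajectory(source: Union[str, Path],
                    residue_range: Optional[tuple[int, int]] = None,
                    dt_ns: float = 0.24) -> Trajectory:
    """Load a multi-model PDB as a Cα trajectory.

    ``residue_range`` restricts the selection to an inclusive author-number
    interval before any analysis (used to limit weakly coupled multi-domain
    systems to their glycan-bearing domain).  Frame times default to a
    uniform ``dt_ns`` spacing starting at ``dt_ns``.
    """
    models = parse_models(source)
    ids0, coords0 = _model_ca(models[0], residue_range)
    if not ids0:
        raise ValueError("empty Cα selection")
    frames = [coords0]
    for m in models[1:]:
        ids, coords = _model_ca(m, residue_range)
        if ids != ids0:
            raise ValueError("atom selection differs between frames")
        frames.append(coords)
    times = dt_ns * np.arange(1, len(frames) + 1)
    return Trajectory(residue_ids=ids0, frames=np.array(frames), times=times)


def rmsd_series(traj: Trajectory,
                reference: np.ndarray) -> list[tuple[float, float]]:
    """Cα RMSD of each frame against a reference structure.

    Each frame is rigid-body superposed onto the reference before the
    deviation is measured, so global rotation/translation does not
    register as structural change.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (traj.n_atoms, 3):
        raise ValueError("reference selection does not match trajectory")
    out = []
    for t, frame in zip(traj.times, traj.frames):
        out.append((float(t), kabsch_superpose(reference, frame).rmsd))
    return out


def _window(traj: Trajectory, window_fraction: float) -> np.ndarray:
    if not 0 < window_fraction <= 1:
        raise ValueError("window_fraction must be in (0, 1]")
    n = max(int(round(traj.n_frames * window_fraction)), 1)
    if n < 2:
        raise ValueError("trailing window must contain at least 2 frames")
    return traj.frames[-n:]


def window_average_structure(traj: Trajectory,
                             window_fraction: float = 0.25,
                             refine_passes: int = 2) -> np.ndarray:
    """Average structure of the trailing window.

    Window frames are superposed onto the window's first frame and
    averaged per atom; the fit target is then refined by re-superposing
    onto the running average and re-averaging (two passes converge on
    the fixtures used here).
    """
    window = _window(traj, window_fraction)
    ref = window[0]
    avg = None
    for _ in range(1 + refine_passes):
        fitted = np.array([kabsch_superpose(ref, f).transform(f) for f in window])
        avg = fitted.mean(axis=0)
        ref = avg
    return avg


def rmsf_profile(traj: Trajectory,
                 reference: Optional[np.ndarray] = None,
                 window_fraction: float = 0.25) -> RMSFProfile:
    """Per-residue RMSF over the trailing window.

    Each window frame is superposed onto the reference (by default the
    trailing-window average structure) and

        RMSF_j = sqrt( mean_f |x_j(f) - ref_j|^2 )
    """
    if reference is None:
        reference = window_average_structure(traj, window_fraction)
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (traj.n_atoms, 3):
        raise ValueError("reference selection does not match trajectory")
    window = _window(traj, window_fraction)
    sq = np.zeros(traj.n_atoms)
    for frame in window:
        fitted = kabsch_superpose(reference, frame).transform(frame)
        sq += np.sum((fitted - reference) ** 2, axis=1)
    values = np.sqrt(sq / len(window))
    return RMSFProfile(residue_ids=list(traj.residue_ids), values=values)


def aggregate_replicates(values: Sequence[float]) -> ReplicateSummary:
    """Grand mean and standard error (sd/sqrt(R)) over replicate means."""
    return ReplicateSummary(replicate_means=list(values))


def max_delta_residue(profile_gp: RMSFProfile, profile_p: RMSFProfile,
                      model: StructureModel, site: GlycosylationSite
                      ) -> tuple[ResidueId, float, float]:
    """Residue with the largest RMSF increase upon deglycosylation.

    Returns ``(residue id, RMSF_P - RMSF_GP, Cα distance to the site)``.
    Glycosylation's dynamic footprint is often allosteric, so the
    distance reports how far the strongest effect sits from the glycan.
    Ties break toward the lowest residue number.
    """
    idx_p = {rid: i for i, rid in enumerate(profile_p.residue_ids)}
    shared = [rid for rid in profile_gp.residue_ids if rid in idx_p]
    if not shared:
        raise ValueError("profiles share no residues")
    idx_gp = {rid: i for i, rid in enumerate(profile_gp.residue_ids)}
    deltas = [(profile_p.values[idx_p[rid]] - profile_gp.values[idx_gp[rid]], rid)
              for rid in shared]
    best_delta = max(d for d, _ in deltas)
    best_rid = min(rid for d, rid in deltas if d == best_delta)

    site_ca = None
    target_ca = None
    for chain in model.chains:
        res = chain.residue(site.residue_number, site.icode)
        if res is not None and chain.chain_id == site.chain_id and res.atom("CA") is not None:
            site_ca = res.atom("CA").xyz
        res2 = chain.residue(best_rid[0], best_rid[1])
        if res2 is not None and res2.atom("CA") is not None:
            target_ca = res2.atom("CA").xyz
    if site_ca is None or target_ca is None:
        raise ValueError("site or target residue lacks a Cα in the model")
    distance = float(np.linalg.norm(site_ca - target_ca))
    return best_rid, float(best_delta), distance
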