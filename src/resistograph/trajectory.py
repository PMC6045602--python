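"""Trajectory superposition, RMSD analytics and essential-dynamics PCA.

Frames are least-squares superposed with the Kabsch algorithm (SVD route,
reflections corrected so rotations are always proper). RMSD series support a
burn-in cutoff in time units; window averages give mean structures; PCA
diagonalizes the covariance of 3N coordinate fluctuations (via thin SVD of
the centered frame matrix, which is the same eigensystem) to extract the
dominant collective modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "SuperpositionResult",
    "PCAResult",
    "kabsch_superpose",
    "rmsd_series",
    "average_structure",
    "segment_rmsd",
    "covariance_pca",
    "variance_explained",
    "read_trajectory_tsv",
    "write_trajectory_tsv",
]


@dataclass
class Trajectory:
    times: np.ndarray  # ps, strictly increasing
    coords: np.ndarray  # frames × atoms × 3, Å
    atom_labels: list[tuple[str, int, str]] = field(default_factory=list)  # (chain, resnum, atom name)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be frames × atoms × 3")
        if self.times.shape[0] != self.coords.shape[0]:
            raise ValueError("times must parallel frames")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not self.atom_labels:
            self.atom_labels = [("A", i + 1, "CA") for i in range(self.coords.shape[1])]

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class PCAResult:
    mean_coords: np.ndarray  # atoms × 3
    eigenvalues: np.ndarray  # Å², descending
    eigenvectors: np.ndarray  # components × 3N, orthonormal rows
    variance_fraction: np.ndarray
    projections: np.ndarray  # frames × components


def _as_selection(selection, n_atoms: int) -> np.ndarray:
    if selection is None:
        return np.arange(n_atoms)
    sel = np.asarray(selection)
    if sel.dtype == bool:
        sel = np.flatnonzero(sel)
    return sel


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray, selection: Sequence[int] | None = None
) -> SuperpositionResult:
    """Optimal proper rotation + translation of ``mobile`` onto ``reference``.

    Solved by SVD of the cross-covariance with the determinant sign corrected,
    so the returned rotation is always proper (no reflections). RMSD is
    evaluated over the fit selection after the transform.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference must have the same shape")
    sel = _as_selection(selection, mobile.shape[0])
    if sel.size < 3:
        raise ValueError("need at least 3 atoms to superpose")
    p = mobile[sel]
    q = reference[sel]
    cp, cq = p.mean(axis=0), q.mean(axis=0)
    p0, q0 = p - cp, q - cq
    if np.linalg.matrix_rank(p0, tol=1e-10) < 2:
        raise ValueError("degenerate (collinear) geometry: rotation not determined")
    h = p0.T @ q0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cq - rot @ cp
    moved = p @ rot.T + trans
    rmsd = float(np.sqrt(((moved - q) ** 2).sum(axis=1).mean()))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def rmsd_series(
    traj: Trajectory,
    reference: np.ndarray | int = 0,
    selection: Sequence[int] | None = None,
    burn_in: float = 0.0,
) -> tuple[np.ndarray, float]:
    """Per-frame RMSD to a reference after superposition, plus the mean over
    frames with time strictly greater than ``burn_in`` (ps)."""
    ref = traj.coords[reference] if isinstance(reference, (int, np.integer)) else np.asarray(reference, dtype=float)
    if burn_in >= traj.times[-1]:
        raise ValueError("burn-in leaves no frames")
    series = np.array(
        [kabsch_superpose(frame, ref, selection=selection).rmsd for frame in traj.coords]
    )
    post = traj.times > burn_in
    if not post.any():
        raise ValueError("burn-in leaves no frames")
    return series, float(series[post].mean())


def average_structure(
    traj: Trajectory,
    window: tuple[float, float] | None = None,
    reference: np.ndarray | int = 0,
    selection: Sequence[int] | None = None,
) -> np.ndarray:
    """Per-atom mean of superposed frames whose times fall in ``window``."""
    ref = traj.coords[reference] if isinstance(reference, (int, np.integer)) else np.asarray(reference, dtype=float)
    if window is None:
        mask = np.ones(traj.n_frames, dtype=bool)
    else:
        t0, t1 = window
        mask = (traj.times >= t0) & (traj.times <= t1)
    if not mask.any():
        raise ValueError("window contains no frames")
    fitted = np.array(
        [kabsch_superpose(frame, ref, selection=selection).apply(frame) for frame in traj.coords[mask]]
    )
    return fitted.mean(axis=0)


def segment_rmsd(
    struct_a: np.ndarray,
    struct_b: np.ndarray,
    atom_labels: Sequence[tuple[str, int, str]],
    residue_range: tuple[int, int],
    align_on: str = "full",
) -> float:
    """RMSD over a residue segment after aligning on the full structure or on
    the segment itself. Both structures must share the atom labelling."""
    struct_a = np.asarray(struct_a, dtype=float)
    struct_b = np.asarray(struct_b, dtype=float)
    if struct_a.shape != struct_b.shape or struct_a.shape[0] != len(atom_labels):
        raise ValueError("structures and labels must be congruent")
    lo, hi = residue_range
    seg = np.array([lo <= resnum <= hi for _, resnum, _ in atom_labels])
    if not seg.any():
        raise KeyError(f"no atoms in residue range {lo}-{hi}")
    if align_on == "full":
        fit_sel = None
    elif align_on == "segment":
        fit_sel = np.flatnonzero(seg)
    else:
        raise ValueError("align_on must be 'full' or 'segment'")
    sup = kabsch_superpose(struct_a, struct_b, selection=fit_sel)
    moved = sup.apply(struct_a)
    return float(np.sqrt(((moved[seg] - struct_b[seg]) ** 2).sum(axis=1).mean()))


def covariance_pca(
    traj: Trajectory,
    selection: Sequence[int] | None = None,
    superpose: bool = True,
    reference: int = 0,
    weights: np.ndarray | None = None,
) -> PCAResult:
    """Essential-dynamics PCA of coordinate fluctuations.

    Frames are optionally superposed to the reference frame (removing overall
    rotation/translation), flattened to 3N vectors, centered on the mean
    structure, and decomposed by thin SVD — equivalent to diagonalizing the
    3N×3N covariance matrix, with eigenvalues s²/(n−1) in Å². ``weights``
    (per atom, e.g. masses) scale coordinates by √w before decomposition.
    """
    if traj.n_frames < 2:
        raise ValueError("PCA needs more than one frame")
    sel = _as_selection(selection, traj.n_atoms)
    if superpose:
        ref = traj.coords[reference]
        frames = np.array(
            [kabsch_superpose(f, ref, selection=sel).apply(f)[sel] for f in traj.coords]
        )
    else:
        frames = traj.coords[:, sel, :]
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float))[None, sel, None]
        frames = frames * w
    n = frames.shape[0]
    x = frames.reshape(n, -1)
    mean = x.mean(axis=0)
    xc = x - mean
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    eigenvalues = np.clip(s**2 / (n - 1), 0.0, None)
    total = eigenvalues.sum()
    fractions = eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    projections = xc @ vt.T
    return PCAResult(
        mean_coords=mean.reshape(-1, 3),
        eigenvalues=eigenvalues,
        eigenvectors=vt,
        variance_fraction=fractions,
        projections=projections,
    )


def variance_explained(pca: PCAResult, k: int) -> float:
    """Cumulative variance fraction of the first k components."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > pca.eigenvalues.size:
        raise ValueError(f"k={k} exceeds {pca.eigenvalues.size} components")
    return float(pca.variance_fraction[:k].sum())


def write_trajectory_tsv(traj: Trajectory, path) -> None:
    """Long-format TSV: one row per (frame, atom) with time and labels."""
    rows = []
    for f in range(traj.n_frames):
        for a, (chain, resnum, name) in enumerate(traj.atom_labels):
            x, y, z = traj.coords[f, a]
            rows.append((traj.times[f], chain, resnum, name, x, y, z))
    pd.DataFrame(rows, columns=["time_ps", "chain", "resnum", "atom", "x", "y", "z"]).to_csv(
        path, sep="\t", index=False
    )


def read_trajectory_tsv(path) -> Trajectory:
    df = pd.read_csv(path, sep="\t")
    needed = {"time_ps", "chain", "resnum", "atom", "x", "y", "z"}
    if not needed <= set(df.columns):
        raise ValueError(f"trajectory table missing columns: {sorted(needed - set(df.columns))}")
    times = np.array(sorted(df["time_ps"].unique()))
    first = df[df["time_ps"] == times[0]]
    labels = [(str(r.chain), int(r.resnum), str(r.atom)) for r in first.itertuples()]
    coords = np.empty((len(times), len(labels), 3))
    for i, t in enumerate(times):
        frame = df[df["time_ps"] == t]
        if len(frame) != len(labels):
            raise ValueError(f"frame at t={t} has {len(frame)} atoms, expected {len(labels)}")
        coords[i] = frame[["x", "y", "z"]].to_numpy()
    return Trajectory(times=times, coords=coords, atom_labels=labels)
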