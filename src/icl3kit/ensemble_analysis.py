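"""Conformational-ensemble analysis of dihedral trajectories.

Mirrors the trajectory-analysis workflow used to map the ICL3 conformational
landscape: backbone phi/psi dihedrals of the receptor are embedded as
(sin, cos) pairs, projected onto the two slowest time-correlated independent
components (tICA, lag 2 ns by default in time units), a free-energy surface
is built from the inverse of the population density over that projection
(F = -kT ln rho/rho_max, so the deepest occupied bin sits at 0), and frames
are decomposed into metastable states with mini-batch k-means — four basin
clusters, one of which may be split into two subclusters for a five-state
decomposition. Centre-of-mass distances between ICL3 (or three-residue
segments of it) and the ICL1/ICL2 reference loops quantify how closely the
loop packs against the rest of the intracellular face.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import numpy.ma as ma
import pandas as pd
from scipy.linalg import eigh
from sklearn.cluster import MiniBatchKMeans

__all__ = [
    "DihedralTrajectory",
    "TicaProjection",
    "FreeEnergySurface",
    "ClusterModel",
    "CoordinateFrame",
    "SegmentSpec",
    "featurize_dihedrals",
    "fit_tica",
    "free_energy_surface",
    "cluster_states",
    "subcluster_basin",
    "com_distance",
    "parse_segment_spec",
    "segment_distance_profile",
    "frame_from_pdb",
]

#: Boltzmann constant in kcal/(mol K); kT at 310 K ~ 0.616 kcal/mol.
KB_KCAL_PER_MOL_K = 0.0019872041
SIMULATION_TEMPERATURE_K = 310.0

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


@dataclass
class DihedralTrajectory:
    """Frames x channels matrix of backbone dihedral angles in radians."""

    angles: np.ndarray
    frame_interval_ns: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.angles = np.atleast_2d(np.asarray(self.angles, dtype=float))
        if not np.all(np.isfinite(self.angles)):
            raise ValueError("angles must be finite")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.angles.shape[1])]

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]


@dataclass
class TicaProjection:
    components: np.ndarray  # (n_features, n_kept) eigenvectors
    eigenvalues: np.ndarray  # descending
    projection: np.ndarray  # (n_frames, n_kept)
    lag: int
    feature_means: np.ndarray | None = None


@dataclass
class FreeEnergySurface:
    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: ma.MaskedArray  # kT units; occupied minimum is exactly 0
    kT: float = 1.0


@dataclass
class ClusterModel:
    centers: np.ndarray
    labels: np.ndarray
    inertia: float
    seed: int

    @property
    def k(self) -> int:
        return len(self.centers)


@dataclass
class CoordinateFrame:
    """Per-particle positions (Angstrom) with residue metadata and masses."""

    positions: np.ndarray  # (n, 3)
    resid: np.ndarray
    resname: np.ndarray | None = None
    mass: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.resid = np.asarray(self.resid, dtype=int)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.mass is None:
            self.mass = np.ones(len(self.resid), dtype=float)
        else:
            self.mass = np.asarray(self.mass, dtype=float)
            if np.any(self.mass <= 0):
                raise ValueError("masses must be positive")
        if self.resname is not None:
            self.resname = np.asarray(self.resname, dtype=str)

    def select(self, start: int, end: int) -> np.ndarray:
        """Boolean mask of particles with start <= resid <= end (inclusive)."""
        return (self.resid >= start) & (self.resid <= end)


@dataclass
class SegmentSpec:
    """Slash-delimited subsegment spec, e.g. '241-HVQ/NLS/QVE/QDG/RT-254'."""

    anchor_start: int
    anchor_end: int
    subsegments: list[str]
    ranges: list[tuple[int, int]]


def featurize_dihedrals(traj: DihedralTrajectory) -> np.ndarray:
    """Embed each periodic angle channel as (sin, cos) and mean-centre columns."""
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    ang = traj.angles
    feats = np.empty((ang.shape[0], 2 * ang.shape[1]))
    feats[:, 0::2] = np.sin(ang)
    feats[:, 1::2] = np.cos(ang)
    return feats - feats.mean(axis=0)


def fit_tica(
    features: np.ndarray,
    lag: int,
    dim: int = 2,
    ridge: float = 1e-6,
) -> TicaProjection:
    """Time-correlated independent component analysis.

    Solves the generalized eigenproblem C(lag) v = lambda C(0) v with the
    time-lagged covariance symmetrized as (C + C^T)/2 and the instantaneous
    covariance ridge-regularized on the diagonal. Eigenvalues come back in
    descending order; the projection keeps the top ``dim`` components.
    """
    X = np.asarray(features, dtype=float)
    n = X.shape[0]
    if not 1 <= lag < n:
        raise ValueError(f"lag must satisfy 1 <= lag < n_frames ({n})")
    mean = X.mean(axis=0)
    X = X - mean
    X0, Xt = X[:-lag], X[lag:]
    m = X0.shape[0]
    c0 = (X0.T @ X0 + Xt.T @ Xt) / (2.0 * m)
    ct = (X0.T @ Xt + Xt.T @ X0) / (2.0 * m)
    c0reg = c0 + ridge * np.eye(c0.shape[0])
    try:
        evals, evecs = eigh(ct, c0reg)
    except np.linalg.LinAlgError as err:  # pragma: no cover
        raise np.linalg.LinAlgError(
            f"singular covariance ({err}); increase the ridge parameter"
        ) from err
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    kept = evecs[:, :dim]
    return TicaProjection(
        components=evecs,
        eigenvalues=evals,
        projection=X @ kept,
        lag=lag,
        feature_means=mean,
    )


def free_energy_surface(
    projection: np.ndarray,
    bins: int = 100,
    kT: float = 1.0,
    range_: tuple | None = None,
) -> FreeEnergySurface:
    """Free energy from the inverse of the population density.

    F(bin) = -kT ln(count / max count): the most populated bin sits at 0 and
    empty bins are masked rather than assigned a number. Use
    ``kT = KB_KCAL_PER_MOL_K * 310`` for kcal/mol at the simulation
    temperature.
    """
    proj = np.asarray(projection, dtype=float)
    if proj.ndim != 2 or proj.shape[1] < 2:
        raise ValueError("projection must be (n_frames, >=2)")
    if proj.shape[0] == 0:
        raise ValueError("no samples")
    counts, xe, ye = np.histogram2d(proj[:, 0], proj[:, 1], bins=bins, range=range_)
    if counts.max() == 0:
        raise ValueError("no occupied bins")
    with np.errstate(divide="ignore"):
        fes = -kT * np.log(counts / counts.max())
    return FreeEnergySurface(
        x_edges=xe,
        y_edges=ye,
        free_energy=ma.masked_array(fes, mask=(counts == 0)),
        kT=kT,
    )


def cluster_states(projection: np.ndarray, k: int, seed: int = 0) -> ClusterModel:
    """Mini-batch k-means decomposition of the projected frames.

    After the mini-batch pass, centers are refined once over the full data
    (each center becomes the exact mean of its assigned frames), so k=1
    returns the data mean and inertia is the true within-cluster sum of
    squares. Deterministic for a fixed seed.
    """
    proj = np.atleast_2d(np.asarray(projection, dtype=float))
    if k < 1:
        raise ValueError("k must be >= 1")
    if proj.shape[0] < k:
        raise ValueError(f"k={k} exceeds number of frames {proj.shape[0]}")
    km = MiniBatchKMeans(n_clusters=k, random_state=seed, n_init=10, batch_size=1024)
    labels = km.fit_predict(proj)
    centers = km.cluster_centers_.copy()
    for c in range(k):
        mask = labels == c
        if np.any(mask):
            centers[c] = proj[mask].mean(axis=0)
        else:  # pragma: no cover - rare with refinement
            warnings.warn(f"cluster {c} is empty")
    # reassign once against refined centers for a consistent labeling
    d2 = ((proj[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    inertia = float(d2[np.arange(proj.shape[0]), labels].sum())
    return ClusterModel(centers=centers, labels=labels, inertia=inertia, seed=seed)


def subcluster_basin(
    projection: np.ndarray, model: ClusterModel, basin: int, k_sub: int = 2, seed: int = 0
) -> ClusterModel:
    """Two-pass workflow: split one basin of an existing clustering.

    Frames of ``basin`` are re-clustered into ``k_sub`` subclusters; the
    returned model has k + k_sub - 1 states (e.g. 4 basins with one split in
    two gives the five-state decomposition).
    """
    proj = np.atleast_2d(np.asarray(projection, dtype=float))
    mask = model.labels == basin
    if mask.sum() < k_sub:
        raise ValueError(f"basin {basin} has fewer frames than k_sub={k_sub}")
    sub = cluster_states(proj[mask], k_sub, seed=seed)
    labels = model.labels.copy()
    new_ids = [basin] + list(range(model.k, model.k + k_sub - 1))
    labels[mask] = np.array(new_ids)[sub.labels]
    centers = np.vstack([model.centers, sub.centers[1:]])
    centers[basin] = sub.centers[0]
    inertia = float(
        sum(
            np.sum((proj[labels == c] - centers[c]) ** 2)
            for c in range(len(centers))
        )
    )
    return ClusterModel(centers=centers, labels=labels, inertia=inertia, seed=seed)


def _com(frame: CoordinateFrame, mask: np.ndarray) -> np.ndarray:
    if not np.any(mask):
        raise ValueError("empty selection")
    m = frame.mass[mask]
    return (frame.positions[mask] * m[:, None]).sum(axis=0) / m.sum()


def com_distance(frame: CoordinateFrame, selection_a, selection_b) -> float:
    """Distance (Angstrom) between the mass-weighted centroids of two selections.

    Selections are boolean masks or inclusive ``(start_resid, end_resid)``
    tuples.
    """
    def as_mask(sel):
        if isinstance(sel, tuple):
            return frame.select(*sel)
        return np.asarray(sel, dtype=bool)

    return float(
        np.linalg.norm(_com(frame, as_mask(selection_a)) - _com(frame, as_mask(selection_b)))
    )


def parse_segment_spec(spec: str) -> SegmentSpec:
    """Parse a spec like '241-HVQ/NLS/QVE/QDG/RT-254' into residue ranges.

    The flanking numbers anchor the first and last residues; the
    slash-delimited residue strings partition the anchor span in order, so
    their lengths must sum to anchor_end - anchor_start + 1.
    """
    import re

    m = re.fullmatch(r"(\d+)-(.+)-(\d+)", spec)
    if m is None:
        raise ValueError(f"malformed segment spec {spec!r}")
    anchor_start, anchor_end = int(m.group(1)), int(m.group(3))
    segments = m.group(2).split("/")
    if any(not s.isalpha() for s in segments):
        raise ValueError(f"malformed subsegments in {spec!r}")
    total = sum(len(s) for s in segments)
    span = anchor_end - anchor_start + 1
    if total != span:
        raise ValueError(
            f"subsegment lengths sum to {total}, anchor span is {span} ({spec!r})"
        )
    ranges = []
    pos = anchor_start
    for seg in segments:
        ranges.append((pos, pos + len(seg) - 1))
        pos += len(seg)
    return SegmentSpec(anchor_start, anchor_end, segments, ranges)


def segment_distance_profile(
    frames: Sequence[CoordinateFrame],
    spec: SegmentSpec | str,
    reference_selection,
    validate_sequence: bool = True,
) -> pd.DataFrame:
    """Per-subsegment centre-of-mass distance distributions to a reference loop.

    Returns a tidy frame (frame index, subsegment label, distance); the
    quartiles per subsegment are attached as ``df.attrs['quartiles']``. When
    frames carry residue names, each subsegment's letters are checked against
    them ('X' in the spec matches any residue).
    """
    if isinstance(spec, str):
        spec = parse_segment_spec(spec)
    if not frames:
        raise ValueError("no frames")
    if validate_sequence and frames[0].resname is not None:
        f0 = frames[0]
        for seg, (start, end) in zip(spec.subsegments, spec.ranges):
            for offset, letter in enumerate(seg):
                if letter == "X":
                    continue
                sel = f0.resid == start + offset
                if not np.any(sel):
                    raise ValueError(f"residue {start + offset} absent from frame")
                name = str(f0.resname[sel][0])
                one = THREE_TO_ONE.get(name.upper(), name.upper()[:1])
                if one != letter:
                    raise ValueError(
                        f"residue {start + offset} is {name}, spec says {letter}"
                    )
    rows = []
    for i, frame in enumerate(frames):
        for seg, rng in zip(spec.subsegments, spec.ranges):
            label = f"{seg}{rng[0]}-{rng[1]}"
            rows.append(
                {
                    "frame": i,
                    "subsegment": label,
                    "distance": com_distance(frame, rng, reference_selection),
                }
            )
    df = pd.DataFrame(rows)
    df.attrs["quartiles"] = (
        df.groupby("subsegment", sort=False)["distance"]
        .quantile([0.25, 0.5, 0.75])
        .unstack()
    )
    return df


def frame_from_pdb(path) -> CoordinateFrame:
    """Load a coordinate frame from a PDB file (masses from element guessing).

    Requires MDAnalysis (optional dependency).
    """
    import MDAnalysis as mda  # lazy: optional heavy dependency

    u = mda.Universe(str(path))
    atoms = u.atoms
    return CoordinateFrame(
        positions=atoms.positions.astype(float),
        resid=atoms.resids,
        resname=atoms.resnames,
        mass=atoms.masses.astype(float),
    )
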