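"""Per-frame residue features from structure + trajectory files.

Two feature streams feed the communication network: Ca-Ca distances
(contacts) and side-chain center-of-mass displacements relative to the
time-average position (motion correlation).  Side-chain COM uses heavy
atoms only, mass-weighted; glycine and any residue without side-chain
heavy atoms falls back to its Ca.  Residues are keyed by
``(chain_id, residue_number)`` with the author numbering preserved.

Frames are superposed onto a common reference (by default the iterated
time-average structure) with a rigid-body Kabsch fit before
displacements are computed, so rigid drift of the whole protein does not
masquerade as internal motion.  Input trajectories are assumed whole
(no periodic-boundary unwrapping is attempted).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "TrajectoryEnsemble",
    "ResidueRegion",
    "load_trajectory",
    "superpose_frames",
    "compute_ca_distances",
    "compute_displacements",
]

# backbone + terminal atoms excluded from the side-chain COM
_BACKBONE = {"N", "CA", "C", "O", "OXT", "OT1", "OT2"}


@dataclass
class TrajectoryEnsemble:
    """Per-frame Ca and side-chain COM coordinates with residue metadata."""

    residues: list[tuple[str, int, str]]  # (chain_id, residue_number, residue_name)
    ca_coords: np.ndarray  # (n_frames, n_residues, 3), Angstrom
    sidechain_com: np.ndarray  # (n_frames, n_residues, 3), Angstrom

    def __post_init__(self) -> None:
        ca = np.asarray(self.ca_coords, dtype=float)
        sc = np.asarray(self.sidechain_com, dtype=float)
        n_res = len(self.residues)
        if ca.ndim != 3 or ca.shape[2] != 3 or ca.shape[1] != n_res:
            raise ValueError("ca_coords must have shape (frames, residues, 3)")
        if sc.shape != ca.shape:
            raise ValueError("sidechain_com must match ca_coords in shape")
        if not (np.isfinite(ca).all() and np.isfinite(sc).all()):
            raise ValueError("coordinates must be finite")
        keys = [(c, r) for c, r, _ in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain_id, residue_number) keys")
        self.ca_coords = ca
        self.sidechain_com = sc

    @property
    def n_frames(self) -> int:
        return self.ca_coords.shape[0]

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def residue_keys(self) -> list[tuple[str, int]]:
        return [(c, r) for c, r, _ in self.residues]

    def index_of(self, chain_id: str, residue_number: int) -> int:
        return self.residue_keys.index((chain_id, residue_number))


@dataclass(frozen=True)
class ResidueRegion:
    """Named set of residues, e.g. the S4 helix of each subunit."""

    name: str
    members: frozenset[tuple[str, int]]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"region {self.name!r} is empty")
        object.__setattr__(self, "members", frozenset(self.members))

    def validate_against(self, traj: TrajectoryEnsemble) -> None:
        missing = self.members - set(traj.residue_keys)
        if missing:
            raise ValueError(
                f"region {self.name!r} references residues not in the "
                f"trajectory: {sorted(missing)}"
            )


def load_trajectory(
    topology_path,
    coords_path=None,
    selection: str = "protein",
    stride: int = 1,
    start: int = 0,
    stop: int | None = None,
) -> TrajectoryEnsemble:
    """Read a PDB topology plus DCD/XTC coordinates into residue features.

    Parameters
    ----------
    topology_path, coords_path
        Structure and (optional) trajectory files readable by MDAnalysis;
        with no coordinate file the topology's own frames are used.
    selection
        MDAnalysis selection string restricting the residues analyzed.
    stride, start, stop
        Frame window and stride of the analysis.
    """
    import MDAnalysis as mda

    try:
        if coords_path is None:
            u = mda.Universe(str(topology_path))
        else:
            u = mda.Universe(str(topology_path), str(coords_path))
    except (ValueError, OSError) as exc:  # atom-count mismatch, bad format
        raise ValueError(f"could not load trajectory: {exc}") from exc

    atoms = u.select_atoms(selection)
    if atoms.n_atoms == 0:
        raise ValueError(f"selection {selection!r} matched no atoms")
    residues = atoms.residues
    if residues.n_residues == 0:
        raise ValueError(f"selection {selection!r} matched no residues")

    meta: list[tuple[str, int, str]] = []
    ca_groups = []
    sc_groups = []
    for res in residues:
        chain = str(getattr(res, "segid", "") or getattr(res, "chainID", "") or "A")
        meta.append((chain, int(res.resid), str(res.resname)))
        ca = res.atoms.select_atoms("name CA")
        if ca.n_atoms != 1:
            raise ValueError(
                f"residue {chain}:{res.resid} has {ca.n_atoms} CA atoms"
            )
        ca_groups.append(ca)
        heavy_sc = res.atoms.select_atoms(
            "not name " + " ".join(sorted(_BACKBONE)) + " and not name H*"
        )
        # glycine fallback: no side-chain heavy atoms -> use Ca
        sc_groups.append(heavy_sc if heavy_sc.n_atoms > 0 else ca)

    n_res = len(meta)
    frames = u.trajectory[start:stop:stride]
    ca_all = []
    sc_all = []
    for _ in frames:
        ca_all.append(np.array([g.positions[0] for g in ca_groups]))
        sc_all.append(np.array([g.center_of_mass() for g in sc_groups]))
    if not ca_all:
        raise ValueError("no frames in the requested window")
    return TrajectoryEnsemble(
        residues=meta,
        ca_coords=np.asarray(ca_all).reshape(-1, n_res, 3),
        sidechain_com=np.asarray(sc_all).reshape(-1, n_res, 3),
    )


def _kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Rotation matrix minimizing RMSD of centered P onto centered Q."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def superpose_frames(
    traj: TrajectoryEnsemble,
    reference_frame: int | str = "mean",
    selection: list[tuple[str, int]] | None = None,
    n_iter: int = 2,
) -> TrajectoryEnsemble:
    """Rigid-body least-squares superposition of every frame.

    Each frame is fitted on its Ca atoms (restricted to ``selection`` if
    given) onto the reference: either a frame index or ``"mean"``, the
    time-average structure re-estimated ``n_iter`` times.  The same
    rotation/translation is applied to the side-chain COM coordinates,
    so all internal distances are preserved.
    """
    if selection is None:
        idx = np.arange(traj.n_residues)
    else:
        idx = np.array([traj.index_of(c, r) for c, r in selection])
    if idx.size < 3:
        raise ValueError("superposition needs at least 3 selected residues")

    ca = traj.ca_coords.copy()
    sc = traj.sidechain_com.copy()

    if reference_frame == "mean":
        ref = ca[:, idx].mean(axis=0)
        iterations = max(int(n_iter), 1)
    else:
        ref = ca[int(reference_frame), idx]
        iterations = 1

    for it in range(iterations):
        ref_c = ref - ref.mean(axis=0)
        for f in range(ca.shape[0]):
            sel = ca[f, idx]
            centroid = sel.mean(axis=0)
            R = _kabsch_rotation(sel - centroid, ref_c)
            shift = ref.mean(axis=0)
            ca[f] = (ca[f] - centroid) @ R.T + shift
            sc[f] = (sc[f] - centroid) @ R.T + shift
        if reference_frame == "mean" and it < iterations - 1:
            ref = ca[:, idx].mean(axis=0)

    return replace(traj, ca_coords=ca, sidechain_com=sc)


def compute_ca_distances(traj: TrajectoryEnsemble) -> np.ndarray:
    """Per-frame symmetric Ca-Ca distance matrices, Angstrom.

    Returns an array of shape ``(n_frames, n_residues, n_residues)``.
    """
    diff = traj.ca_coords[:, :, None, :] - traj.ca_coords[:, None, :, :]
    return np.linalg.norm(diff, axis=-1)


def compute_displacements(
    traj: TrajectoryEnsemble, per_component: bool = False
) -> np.ndarray:
    """Side-chain COM displacement from the time-average position.

    The default is the scalar magnitude of the 3D deviation vector per
    residue and frame, shape ``(n_frames, n_residues)``; with
    ``per_component=True`` the raw deviation vectors are returned
    (shape ``(n_frames, n_residues, 3)``), preserving directionality.

    The trajectory should be superposed first; the mean position is taken
    over the full analyzed window.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least two frames to define displacements")
    dev = traj.sidechain_com - traj.sidechain_com.mean(axis=0, keepdims=True)
    if per_component:
        return dev
    return np.linalg.norm(dev, axis=-1)
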