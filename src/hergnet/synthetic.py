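"""Synthetic fixtures with known ground truth for both analysis arms.

Trajectory arm: a "planted chain" ensemble — a line of residues whose
side-chain pseudo-atoms share a smooth latent motion (an AR(1) process,
lag-1 correlation 0.9, unit stationary SD) in tunable proportion, buried
among residues that move with independent Gaussian noise only.  The
geometry guarantees that consecutive chain residues sit within the
contact cut-off while everything else is mostly beyond it, so the
minimal communication path between the chain endpoints is the chain
itself.  This emulates the correlated side-chain displacements a real
MD ensemble would show along an allosteric path; it does not emulate
solvent, membrane, or realistic protein geometry.

Electrophysiology arm: two-state Boltzmann conductance/availability
samples at stated (z, V1/2), plus tail-current and triple-pulse current
traces with mono-exponential decay phases, so the peak extraction,
deactivation correction and fitting machinery can be validated against
exact ground truth.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .gating import (
    VoltageProtocol,
    boltzmann_activation,
    boltzmann_availability,
)
from .network import DEFAULT_CONTACT_CUTOFF
from .trajectory import TrajectoryEnsemble

__all__ = [
    "ChainPlantSpec",
    "SyntheticClampSpec",
    "generate_chain_trajectory",
    "write_trajectory",
    "write_ground_truth",
    "generate_boltzmann_currents",
    "generate_tail_traces",
    "generate_triple_pulse_traces",
    "DEFAULT_GV_PROTOCOL",
    "DEFAULT_TRIPLE_PULSE_PROTOCOL",
]

AR1_PHI = 0.9  # lag-1 autocorrelation of the shared latent motion
LATENT_SD = 1.0  # Angstrom, stationary SD of the latent process
SIDECHAIN_OFFSET = np.array([0.0, 0.0, 1.5])  # pseudo side chain relative to Ca
OFFCHAIN_LATERAL = 6.5  # Angstrom, rail offset of the decoy residues
N_RAILS = 4  # decoy rails around the chain axis

DEFAULT_GV_PROTOCOL = VoltageProtocol(
    segments=(("P1", None, 500.0), ("P2", -100.0, 300.0)), holding_mV=-100.0
)
DEFAULT_TRIPLE_PULSE_PROTOCOL = VoltageProtocol(
    segments=(("P1", 20.0, 1000.0), ("P2", None, 30.0), ("P3", 20.0, 600.0)),
    holding_mV=-100.0,
)


@dataclass(frozen=True)
class ChainPlantSpec:
    """Ground-truth description of a planted-chain trajectory."""

    n_residues: int = 30
    chain_indices: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    coupling_strength: float = 0.8
    spatial_spacing: float = 6.0  # Angstrom between consecutive chain residues
    noise_sd: float = 0.3  # Angstrom, per component
    n_frames: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.chain_indices)
        if len(set(idx)) != len(idx) or len(idx) < 2:
            raise ValueError("chain_indices must be >= 2 distinct indices")
        if min(idx) < 0 or max(idx) >= self.n_residues:
            raise ValueError("chain_indices out of range")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must lie in [0, 1]")
        if self.spatial_spacing < 0.5:
            raise ValueError(
                "geometry error: chain residues closer than 0.5 Angstrom"
            )
        if self.spatial_spacing >= DEFAULT_CONTACT_CUTOFF:
            raise ValueError(
                "consecutive chain residues must sit within the contact cut-off"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_frames < 2:
            raise ValueError("need at least two frames")


def _ar1(rng: np.random.Generator, n: int, phi: float = AR1_PHI) -> np.ndarray:
    """Stationary AR(1) series with unit marginal variance."""
    x = np.empty(n)
    x[0] = rng.standard_normal()
    innov = rng.standard_normal(n - 1) * np.sqrt(1.0 - phi * phi)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + innov[t - 1]
    return x


def _base_geometry(spec: ChainPlantSpec) -> np.ndarray:
    """Static Ca positions: chain along x, decoys on rails around it.

    Decoys sit on four rails laterally offset from the chain axis, at
    the chain's own spacing along x.  Every decoy contacts its rail
    neighbours and the nearest chain residue, but only the chain carries
    correlated motion, so the chain is both the minimal endpoint-to-
    endpoint path and the main thoroughfare for decoy-to-decoy traffic.
    """
    pos = np.zeros((spec.n_residues, 3))
    for k, idx in enumerate(spec.chain_indices):
        pos[idx] = (k * spec.spatial_spacing, 0.0, 0.0)
    others = [i for i in range(spec.n_residues) if i not in set(spec.chain_indices)]
    if others:
        per_rail = int(np.ceil(len(others) / N_RAILS))
        offsets = [
            (OFFCHAIN_LATERAL, 0.0),
            (-OFFCHAIN_LATERAL, 0.0),
            (0.0, OFFCHAIN_LATERAL),
            (0.0, -OFFCHAIN_LATERAL),
        ]
        for k, idx in enumerate(others):
            rail, slot = k % N_RAILS, k // N_RAILS
            dy, dz = offsets[rail]
            pos[idx] = (slot * spec.spatial_spacing, dy, dz)
        del per_rail
    return pos


def generate_chain_trajectory(spec: ChainPlantSpec) -> TrajectoryEnsemble:
    """Multi-frame ensemble with a planted chain of co-moving side chains.

    Chain residues' side-chain pseudo-atoms move as
    ``coupling_strength * latent(t) * x_hat + noise``; every other
    residue (and every Ca) carries independent noise only.
    """
    rng = np.random.default_rng(spec.seed)
    base = _base_geometry(spec)
    F, R = spec.n_frames, spec.n_residues

    ca = np.broadcast_to(base, (F, R, 3)).copy()
    sc = ca + SIDECHAIN_OFFSET

    latent = _ar1(rng, F) * LATENT_SD
    motion = rng.normal(0.0, spec.noise_sd, size=(F, R, 3))
    chain = np.array(spec.chain_indices)
    motion[:, chain, 0] += spec.coupling_strength * latent[:, None]
    sc = sc + motion

    residues = [("A", i + 1, "ALA") for i in range(R)]
    return TrajectoryEnsemble(residues=residues, ca_coords=ca, sidechain_com=sc)


def write_trajectory(
    traj: TrajectoryEnsemble, pdb_path, dcd_path
) -> tuple[Path, Path]:
    """Write the ensemble as a PDB topology plus a DCD coordinate file.

    Each residue is represented by two pseudo-atoms, CA at the Ca
    position and CB at the side-chain COM, so the files round-trip
    through the standard readers.
    """
    import MDAnalysis as mda

    n_res = traj.n_residues
    u = mda.Universe.empty(
        n_atoms=2 * n_res,
        n_residues=n_res,
        n_segments=1,
        atom_resindex=np.repeat(np.arange(n_res), 2),
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", ["CA", "CB"] * n_res)
    u.add_TopologyAttr("resnames", [r[2] for r in traj.residues])
    u.add_TopologyAttr("resids", [r[1] for r in traj.residues])
    u.add_TopologyAttr("segids", [traj.residues[0][0]])
    u.add_TopologyAttr("masses", [12.011, 12.011] * n_res)

    coords = np.empty((traj.n_frames, 2 * n_res, 3), dtype=np.float32)
    coords[:, 0::2, :] = traj.ca_coords
    coords[:, 1::2, :] = traj.sidechain_com
    u.load_new(coords, order="fac")

    pdb_path, dcd_path = Path(pdb_path), Path(dcd_path)
    u.trajectory[0]
    u.atoms.write(str(pdb_path))
    with mda.Writer(str(dcd_path), n_atoms=u.atoms.n_atoms) as w:
        for _ in u.trajectory:
            w.write(u.atoms)
    return pdb_path, dcd_path


def write_ground_truth(spec, path) -> Path:
    """JSON sidecar recording the generating parameters."""
    path = Path(path)
    payload = asdict(spec)
    payload["spec_type"] = type(spec).__name__
    path.write_text(json.dumps(payload, indent=2, default=list) + "\n")
    return path


@dataclass(frozen=True)
class SyntheticClampSpec:
    """Ground truth for synthetic voltage-clamp data.

    Defaults mirror the fitted wild-type activation parameters
    (z = 2.8, V1/2 = -24.6 mV); pass the inactivation values
    (z = 0.9, V1/2 = -61.8 mV) for availability data.
    """

    z_true: float = 2.8
    v_half_true: float = -24.6  # mV
    voltages: tuple[float, ...] = tuple(float(v) for v in range(-100, 61, 10))
    noise_sd: float = 0.02  # fraction of full scale
    n_sweeps_per_voltage: int = 4  # mirrors n = 4 independent cells
    tau_decay: float = 10.0  # ms, decay phases
    temperature: float = 290.65  # K
    seed: int = 0

    def __post_init__(self) -> None:
        v = tuple(float(x) for x in self.voltages)
        if len(v) == 0:
            raise ValueError("voltage list must not be empty")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("voltages must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.tau_decay <= 0:
            raise ValueError("tau_decay must be positive")
        if self.n_sweeps_per_voltage < 1:
            raise ValueError("need at least one sweep per voltage")


def generate_boltzmann_currents(
    spec: SyntheticClampSpec, kind: str = "activation"
) -> pd.DataFrame:
    """Normalized conductance (or availability) samples per voltage.

    Columns: ``voltage_mV, sweep, value``; the mean at each voltage
    equals the two-state Boltzmann at (z_true, v_half_true) up to noise.
    """
    fn = boltzmann_activation if kind == "activation" else boltzmann_availability
    rng = np.random.default_rng(spec.seed)
    rows = []
    for v in spec.voltages:
        mu = fn(v, spec.z_true, spec.v_half_true, spec.temperature)
        for s in range(spec.n_sweeps_per_voltage):
            rows.append(
                {
                    "voltage_mV": v,
                    "sweep": s,
                    "value": mu + rng.normal(0.0, spec.noise_sd),
                }
            )
    return pd.DataFrame(rows)


def _segment_rows(sweep, segment, v_sweep, t, i, experiment):
    return pd.DataFrame(
        {
            "experiment": experiment,
            "sweep": sweep,
            "segment": segment,
            "time_ms": t,
            "current": i,
            "voltage": v_sweep,
        }
    )


def generate_tail_traces(
    spec: SyntheticClampSpec,
    protocol: VoltageProtocol = DEFAULT_GV_PROTOCOL,
    scale: float = 1.0,
    artifact: bool = True,
    dt_ms: float = 1.0,
    experiment: int = 0,
) -> pd.DataFrame:
    """Two-pulse sweeps whose tail-current peaks trace the G-V curve.

    The tail segment decays with ``5 * tau_decay``; an optional
    capacitive-like spike in the first millisecond exercises the guard
    interval of the peak picker.  ``scale`` sets the absolute current
    scale of the experiment (normalization must cancel it).
    """
    rng = np.random.default_rng(spec.seed + 7 * experiment)
    d1 = protocol.duration_ms("P1")
    d2 = protocol.duration_ms("P2")
    tau_tail = 5.0 * spec.tau_decay
    frames = []
    for sweep, v in enumerate(spec.voltages):
        g = boltzmann_activation(v, spec.z_true, spec.v_half_true, spec.temperature)
        t1 = np.arange(0.0, d1, max(dt_ms, 10.0))
        i1 = g * scale + rng.normal(0.0, spec.noise_sd * scale, t1.size)
        frames.append(_segment_rows(sweep, "P1", v, t1, i1, experiment))
        t2 = np.arange(0.0, d2, dt_ms)
        i2 = -g * scale * np.exp(-t2 / tau_tail)
        if artifact:
            i2 = i2 + np.where(t2 < 1.0, 3.0 * scale, 0.0)
        i2 = i2 + rng.normal(0.0, spec.noise_sd * scale, t2.size)
        frames.append(_segment_rows(sweep, "P2", v, t2, i2, experiment))
    return pd.concat(frames, ignore_index=True)


def generate_triple_pulse_traces(
    spec: SyntheticClampSpec,
    protocol: VoltageProtocol = DEFAULT_TRIPLE_PULSE_PROTOCOL,
    deactivate: bool = True,
    deact_threshold_mV: float = -120.0,
    dt_ms: float = 0.5,
    experiment: int = 0,
    tau_reinact: float = 300.0,
) -> pd.DataFrame:
    """Triple-pulse sweeps exercising the deactivation correction.

    The conditioning pulse (P2) current decays mono-exponentially with
    ``tau_decay`` at voltages below ``deact_threshold_mV`` (channels
    deactivate) and is flat otherwise; the test-pulse (P3) peak follows
    the availability curve at the P2 voltage, attenuated by the same
    deactivation factor, then plateaus 5 ms before re-inactivating with
    ``tau_reinact``.  With ``deactivate=False`` no attenuation occurs
    and the extrapolation correction is a no-op.
    """
    rng = np.random.default_rng(spec.seed + 13 * experiment)
    d1 = protocol.duration_ms("P1")
    d2 = protocol.duration_ms("P2")
    d3 = protocol.duration_ms("P3")
    frames = []
    for sweep, v in enumerate(spec.voltages):
        avail = boltzmann_availability(
            v, spec.z_true, spec.v_half_true, spec.temperature
        )
        deactivating = deactivate and v < deact_threshold_mV

        t1 = np.arange(0.0, d1, max(dt_ms, 10.0))
        i1 = np.ones_like(t1) + rng.normal(0.0, spec.noise_sd, t1.size)
        frames.append(_segment_rows(sweep, "P1", v, t1, i1, experiment))

        t2 = np.arange(0.0, d2, dt_ms)
        i2 = np.exp(-t2 / spec.tau_decay) if deactivating else np.ones_like(t2)
        i2 = i2 + rng.normal(0.0, spec.noise_sd, t2.size)
        frames.append(_segment_rows(sweep, "P2", v, t2, i2, experiment))

        survival = float(np.exp(-d2 / spec.tau_decay)) if deactivating else 1.0
        peak = avail * survival
        t3 = np.arange(0.0, d3, dt_ms)
        i3 = peak * np.exp(-np.maximum(t3 - 5.0, 0.0) / tau_reinact)
        i3 = i3 + rng.normal(0.0, spec.noise_sd, t3.size)
        frames.append(_segment_rows(sweep, "P3", v, t3, i3, experiment))
    return pd.concat(frames, ignore_index=True)


def write_conductance_csv(table: pd.DataFrame, path) -> Path:
    """Conductance samples as CSV (voltage_mV, sweep, value)."""
    path = Path(path)
    table.to_csv(path, index=False)
    return path
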