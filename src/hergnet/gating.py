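"""Voltage-clamp gating energetics for two-state channels.

Normalized conductance (activation) and availability (steady-state
inactivation) curves are fitted with two-state Boltzmann functions

    G(V)     = 1 / (1 + exp( zG F/(RT) (V_G1/2 - V)))      (increasing)
    I/Imax(V)= 1 / (1 + exp(-zI F/(RT) (V_I1/2 - V)))      (decreasing)

yielding an apparent valence ``z`` (elementary charges times field
fraction) and a midpoint ``V1/2`` (mV).  Gating free energies follow as
``dG = z F V1/2`` (F = 23.061 kcal mol^-1 V^-1, V1/2 in volts), mutant
perturbations as ``ddG = dG_mut - dG_wt``, and the propagated error per
channel as ``F * sqrt((dz V1/2)^2 + (dV1/2 z)^2)``; WT and mutant error
terms are additionally combined in quadrature.

Raw records enter as long-format tables (experiment, sweep, segment,
time_ms, current, voltage): tail-current peaks give G-V points, and a
triple-pulse protocol gives availability points, with the peak after the
conditioning pulse corrected for deactivation by extrapolating the
falling phase of the conditioning-pulse current back to its start.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lmfit import Model
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = [
    "FARADAY_KCAL_PER_MOL_V",
    "GAS_CONSTANT_KCAL",
    "DEFAULT_TEMPERATURE_K",
    "VoltageProtocol",
    "BoltzmannFit",
    "boltzmann_activation",
    "boltzmann_availability",
    "extract_gv_points",
    "fit_gv",
    "fit_inactivation",
    "correct_inactivation_peaks",
    "gating_free_energy",
    "gating_free_energy_error",
    "ddG",
    "ddG_error",
    "combine_errors",
    "energy_table",
]

FARADAY_KCAL_PER_MOL_V = 23.061  # kcal mol^-1 V^-1
GAS_CONSTANT_KCAL = 1.987204259e-3  # kcal mol^-1 K^-1
DEFAULT_TEMPERATURE_K = 290.65  # recording room temperature, ~17.5 C


@dataclass(frozen=True)
class VoltageProtocol:
    """Ordered pulse segments: (label, voltage_mV or None if varied, duration_ms)."""

    segments: tuple[tuple[str, float | None, float], ...]
    holding_mV: float = -100.0

    def __post_init__(self) -> None:
        labels = [s[0] for s in self.segments]
        if len(set(labels)) != len(labels):
            raise ValueError("segment labels must be unique")
        for label, _, dur in self.segments:
            if dur <= 0:
                raise ValueError(f"segment {label!r} has non-positive duration")

    def duration_ms(self, label: str) -> float:
        for lab, _, dur in self.segments:
            if lab == label:
                return dur
        raise KeyError(f"no segment labelled {label!r}")

    def voltage_mV(self, label: str) -> float | None:
        for lab, v, _ in self.segments:
            if lab == label:
                return v
        raise KeyError(f"no segment labelled {label!r}")


@dataclass
class BoltzmannFit:
    """Two-state Boltzmann parameters with asymptotic standard errors."""

    kind: str  # "activation" | "inactivation"
    z: float
    v_half: float  # mV
    z_se: float
    v_half_se: float
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.kind not in ("activation", "inactivation"):
            raise ValueError("kind must be 'activation' or 'inactivation'")
        if not self.z > 0:
            raise ValueError("apparent valence must be positive")

    def predict(self, v_mV):
        fn = boltzmann_activation if self.kind == "activation" else boltzmann_availability
        return fn(v_mV, self.z, self.v_half, self.temperature)


def _zf_rt_per_mV(z: float, temperature: float) -> float:
    return z * FARADAY_KCAL_PER_MOL_V / (GAS_CONSTANT_KCAL * temperature) / 1000.0


def boltzmann_activation(v_mV, z, v_half_mV, temperature=DEFAULT_TEMPERATURE_K):
    """Normalized conductance of a two-state channel; increasing in V."""
    v = np.asarray(v_mV, dtype=float)
    out = 1.0 / (1.0 + np.exp(_zf_rt_per_mV(z, temperature) * (v_half_mV - v)))
    return out if out.ndim else float(out)


def boltzmann_availability(v_mV, z, v_half_mV, temperature=DEFAULT_TEMPERATURE_K):
    """Fraction of channels not inactivated; decreasing in V."""
    v = np.asarray(v_mV, dtype=float)
    out = 1.0 / (1.0 + np.exp(-_zf_rt_per_mV(z, temperature) * (v_half_mV - v)))
    return out if out.ndim else float(out)


def _as_points(points) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(points, pd.DataFrame):
        vcol = "voltage_mV" if "voltage_mV" in points.columns else "voltage"
        ycol = next(
            c for c in ("value", "g", "g_mean", "availability", "mean") if c in points.columns
        )
        return points[vcol].to_numpy(float), points[ycol].to_numpy(float)
    v, y = points
    return np.asarray(v, float), np.asarray(y, float)


def _fit_boltzmann(points, kind: str, temperature: float) -> BoltzmannFit:
    v, y = _as_points(points)
    if v.size < 4:
        raise ValueError("need at least 4 voltages spanning the transition")
    fn = boltzmann_activation if kind == "activation" else boltzmann_availability
    model = Model(
        lambda v_mV, z, v_half: fn(v_mV, z, v_half, temperature),
        independent_vars=["v_mV"],
    )
    # midpoint initial guess: voltage where the curve crosses 0.5
    order = np.argsort(v)
    yv = y[order]
    crossing = np.argmin(np.abs(yv - 0.5))
    params = model.make_params(
        z=dict(value=2.0 if kind == "activation" else 1.0, min=1e-3),
        v_half=float(v[order][crossing]),
    )
    result = model.fit(y, params, v_mV=v)
    if not result.success:
        raise RuntimeError(
            f"Boltzmann fit did not converge: {result.message}; "
            f"residual norm {np.linalg.norm(result.residual):.3g}"
        )
    z = float(result.params["z"].value)
    v_half = float(result.params["v_half"].value)
    z_se = result.params["z"].stderr
    v_se = result.params["v_half"].stderr
    return BoltzmannFit(
        kind=kind,
        z=z,
        v_half=v_half,
        z_se=float(z_se) if z_se is not None else 0.0,
        v_half_se=float(v_se) if v_se is not None else 0.0,
        temperature=temperature,
    )


def fit_gv(points, temperature: float = DEFAULT_TEMPERATURE_K) -> BoltzmannFit:
    """Fit an increasing Boltzmann to (voltage, normalized conductance) points."""
    return _fit_boltzmann(points, "activation", temperature)


def fit_inactivation(points, temperature: float = DEFAULT_TEMPERATURE_K) -> BoltzmannFit:
    """Fit a decreasing Boltzmann to (voltage, availability) points."""
    return _fit_boltzmann(points, "inactivation", temperature)


def _segment_peak(seg: pd.DataFrame, guard_ms: float, window_ms: float | None) -> float:
    """Sign-aware extremum of a segment's current inside the guarded window."""
    t = seg["time_ms"].to_numpy(float)
    i = seg["current"].to_numpy(float)
    t0 = t.min()
    hi = t0 + guard_ms + window_ms if window_ms is not None else np.inf
    in_win = (t >= t0 + guard_ms) & (t <= hi)
    if not in_win.any():
        raise ValueError("peak window contains no samples")
    iw = i[in_win]
    return float(iw[np.argmax(np.abs(iw))])


def extract_gv_points(
    traces: pd.DataFrame,
    protocol: VoltageProtocol | None = None,
    tail_label: str = "P2",
    guard_ms: float = 2.0,
    window_ms: float | None = None,
) -> pd.DataFrame:
    """Tail-current G-V points from a two-pulse protocol.

    For each sweep the peak tail current (sign-aware extremum inside a
    guard-delayed window, which skips any residual capacitive transient)
    is taken from the ``tail_label`` segment; peaks are normalized per
    experiment by their maximum magnitude, then averaged across
    experiments at each test-pulse voltage.

    ``traces`` columns: ``sweep, segment, time_ms, current, voltage``
    (the test-pulse voltage of the sweep) and optionally ``experiment``.
    """
    if tail_label not in set(traces["segment"]):
        raise ValueError(f"traces contain no {tail_label!r} (tail) segment")
    df = traces.copy()
    if "experiment" not in df.columns:
        df["experiment"] = 0
    rows = []
    for (exp, sweep), grp in df[df["segment"] == tail_label].groupby(
        ["experiment", "sweep"]
    ):
        rows.append(
            {
                "experiment": exp,
                "sweep": sweep,
                "voltage_mV": float(grp["voltage"].iloc[0]),
                "peak": _segment_peak(grp, guard_ms, window_ms),
            }
        )
    peaks = pd.DataFrame(rows)
    peaks["g"] = peaks.groupby("experiment")["peak"].transform(
        lambda p: np.abs(p) / np.abs(p).max()
    )
    out = (
        peaks.groupby("voltage_mV")["g"]
        .agg(value="mean", sd="std", n="count")
        .reset_index()
        .sort_values("voltage_mV", ignore_index=True)
    )
    return out


def _fit_decay(t: np.ndarray, i: np.ndarray) -> tuple[float, float]:
    """Mono-exponential fit i(t) = A exp(-t/tau); t relative to segment start.

    Returns (A, tau).  Raises if the segment does not decay.
    """
    sign = np.sign(i[np.argmax(np.abs(i))]) or 1.0
    y = sign * i
    if y[-1] >= y[0] or np.any(y <= 0):
        raise ValueError("segment is not a positive decaying phase")
    # log-linear seed, refined by nonlinear least squares
    slope, intercept = np.polyfit(t, np.log(y), 1)
    if slope >= 0:
        raise ValueError("segment is not decaying")
    p0 = (float(np.exp(intercept)), float(-1.0 / slope))
    popt, _ = curve_fit(lambda tt, A, tau: A * np.exp(-tt / tau), t, y, p0=p0, maxfev=5000)
    A, tau = popt
    if tau <= 0 or A <= 0:
        raise ValueError("decay fit produced non-physical parameters")
    return float(sign * A), float(tau)


def correct_inactivation_peaks(
    traces: pd.DataFrame,
    protocol: VoltageProtocol,
    deact_threshold_mV: float = -120.0,
    p2_label: str = "P2",
    p3_label: str = "P3",
    guard_ms: float = 2.0,
    fit_start_frac: float = 0.3,
) -> pd.DataFrame:
    """Availability peaks from a triple-pulse protocol, deactivation-corrected.

    The raw availability signal is the peak current of the test pulse
    (``p3_label``).  At conditioning voltages below ``deact_threshold_mV``
    channels deactivate during the conditioning pulse (``p2_label``),
    attenuating the test-pulse peak; the falling phase of the
    conditioning-pulse current is fitted with a mono-exponential and
    extrapolated back to the start of that pulse, and the ratio
    extrapolated-start / fitted-end rescales the raw peak.  Where the
    decay fit fails the raw peak is kept, with a warning.

    Returns one row per (experiment, sweep): voltage, raw and corrected
    peak, fitted tau (NaN if uncorrected), and a ``corrected`` flag.
    """
    for lab in (p2_label, p3_label):
        if lab not in set(traces["segment"]):
            raise ValueError(f"traces contain no {lab!r} segment")
    df = traces.copy()
    if "experiment" not in df.columns:
        df["experiment"] = 0
    d2 = protocol.duration_ms(p2_label)
    rows = []
    for (exp, sweep), grp in df.groupby(["experiment", "sweep"]):
        v = float(grp["voltage"].iloc[0])
        p3 = grp[grp["segment"] == p3_label]
        raw = _segment_peak(p3, guard_ms, None)
        corrected = raw
        tau = np.nan
        did = False
        if v < deact_threshold_mV:
            p2 = grp[grp["segment"] == p2_label].sort_values("time_ms")
            t = p2["time_ms"].to_numpy(float)
            t = t - t.min()
            keep = t >= fit_start_frac * d2
            try:
                A, tau = _fit_decay(t[keep], p2["current"].to_numpy(float)[keep])
                # ratio of extrapolated start amplitude to fitted end amplitude
                corrected = raw * float(np.exp(d2 / tau))
                did = True
            except (ValueError, RuntimeError) as exc:
                warnings.warn(
                    f"decay fit failed for sweep {sweep} at {v:g} mV ({exc}); "
                    "using raw peak",
                    stacklevel=2,
                )
                tau = np.nan
        rows.append(
            {
                "experiment": exp,
                "sweep": sweep,
                "voltage_mV": v,
                "raw_peak": raw,
                "corrected_peak": corrected,
                "tau_ms": tau,
                "corrected": did,
            }
        )
    return pd.DataFrame(rows).sort_values("voltage_mV", ignore_index=True)


def availability_points(peaks: pd.DataFrame) -> pd.DataFrame:
    """Normalize corrected peaks per experiment and average per voltage."""
    df = peaks.copy()
    df["rel"] = df.groupby("experiment")["corrected_peak"].transform(
        lambda p: np.abs(p) / np.abs(p).max()
    )
    return (
        df.groupby("voltage_mV")["rel"]
        .agg(value="mean", sd="std", n="count")
        .reset_index()
        .sort_values("voltage_mV", ignore_index=True)
    )


def gating_free_energy(fit_or_z, v_half_mV: float | None = None) -> float:
    """dG = z F V1/2 in kcal/mol (V1/2 converted from mV to V).

    Accepts a :class:`BoltzmannFit` or explicit ``(z, v_half_mV)``.
    """
    if isinstance(fit_or_z, BoltzmannFit):
        z, v_half_mV = fit_or_z.z, fit_or_z.v_half
    else:
        z = float(fit_or_z)
        if v_half_mV is None:
            raise TypeError("v_half_mV required when passing z directly")
    return z * FARADAY_KCAL_PER_MOL_V * (v_half_mV / 1000.0)


def ddG_error(z: float, z_se: float, v_half_mV: float, v_half_se_mV: float) -> float:
    """Per-channel propagated energy error, kcal/mol.

    ``F * sqrt((dz * V1/2)^2 + (dV1/2 * z)^2)`` with voltages in volts.
    """
    if z_se < 0 or v_half_se_mV < 0:
        raise ValueError("standard errors must be non-negative")
    v = v_half_mV / 1000.0
    dv = v_half_se_mV / 1000.0
    return FARADAY_KCAL_PER_MOL_V * float(np.hypot(z_se * v, dv * z))


# per-channel dG error uses the same propagation formula
gating_free_energy_error = ddG_error


def combine_errors(*errs: float) -> float:
    """Quadrature combination of independent error terms."""
    return float(np.sqrt(np.sum(np.square(errs))))


def ddG(dg_mut: float, dg_wt: float, kind_mut: str | None = None,
        kind_wt: str | None = None) -> float:
    """Mutant-minus-WT gating free-energy perturbation, kcal/mol."""
    if kind_mut is not None and kind_wt is not None and kind_mut != kind_wt:
        raise ValueError(
            f"cannot compare {kind_mut!r} against {kind_wt!r} energies"
        )
    return dg_mut - dg_wt


def energy_table(
    fits: pd.DataFrame,
    reference: str = "WT",
) -> pd.DataFrame:
    """Per-construct dG, ddG vs the reference and propagated errors.

    ``fits`` columns: ``construct, kind, z, z_se, v_half, v_half_se``
    (voltages in mV); one row per construct and process kind.  Output
    adds ``dG, dG_err, ddG, ddG_err, ddG_err_combined`` (kcal/mol); the
    reference rows carry ddG = 0 with the combined error sqrt(2)*dG_err.
    """
    required = {"construct", "kind", "z", "z_se", "v_half", "v_half_se"}
    missing = required - set(fits.columns)
    if missing:
        raise ValueError(f"fit table missing columns: {sorted(missing)}")
    df = fits.copy()
    df["dG"] = [
        gating_free_energy(z, v) for z, v in zip(df["z"], df["v_half"])
    ]
    df["dG_err"] = [
        ddG_error(z, zs, v, vs)
        for z, zs, v, vs in zip(df["z"], df["z_se"], df["v_half"], df["v_half_se"])
    ]
    out = []
    for kind, grp in df.groupby("kind", sort=False):
        ref = grp[grp["construct"] == reference]
        if len(ref) != 1:
            raise ValueError(
                f"expected exactly one {reference!r} row for kind {kind!r}"
            )
        ref_dg = float(ref["dG"].iloc[0])
        ref_err = float(ref["dG_err"].iloc[0])
        g = grp.copy()
        g["ddG"] = g["dG"] - ref_dg
        g["ddG_err"] = g["dG_err"]
        g["ddG_err_combined"] = [
            combine_errors(e, ref_err) for e in g["dG_err"]
        ]
        out.append(g)
    return pd.concat(out, ignore_index=True)
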