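"""Residue-coupling matrices: Gaussian contact map, normalized mutual
information of side-chain displacements, and the -log edge weights that
turn both into a communication network.

The edge weight between residues i and j is

    w_ij = -log(C_ij * M'_ij)

where ``C_ij`` is the time-averaged truncated-Gaussian contact kernel of
the Ca-Ca distance and ``M'_ij`` is the mutual information of the two
residues' side-chain displacement magnitudes normalized by their joint
Shannon entropy.  Both factors live in [0, 1], so weights are
non-negative and can feed Dijkstra / Brandes machinery directly.

Sampling variability of the weights is estimated by block analysis: the
trajectory is cut into ``N_B`` contiguous blocks, the full weight
pipeline is re-run per block, and the per-edge spread is

    sigma(w_ij) = sqrt( 1/(N_B (N_B - 1)) * sum_B (w_ij^B - wbar_ij)^2 )

i.e. the standard-error-of-the-mean form.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ContactMap",
    "MutualInformationMatrix",
    "WeightMatrix",
    "BlockStats",
    "gaussian_kernel",
    "solve_kernel_width",
    "compute_contact_map",
    "estimate_mutual_information",
    "build_weight_matrix",
    "block_weights",
    "block_std_from_weights",
    "block_weight_std",
]

DEFAULT_CONTACT_CUTOFF = 7.0  # Angstrom
DEFAULT_KERNEL_DCUT = 10.0  # Angstrom: distance where the kernel is "negligible"
DEFAULT_KERNEL_TARGET = 1e-5
DEFAULT_N_BINS = 20
DEFAULT_FLOOR_EPS = 1e-12


@dataclass
class ContactMap:
    """Time-averaged truncated-Gaussian contact kernel over residue pairs."""

    C: np.ndarray
    c: float
    sigma: float
    n_frames_used: int

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("contact map must be square")
        if not np.allclose(C, C.T, atol=1e-12):
            raise ValueError("contact map must be symmetric")
        if C.min() < -1e-12 or C.max() > 1 + 1e-12:
            raise ValueError("contact map entries must lie in [0, 1]")
        self.C = np.clip((C + C.T) / 2.0, 0.0, 1.0)


@dataclass
class MutualInformationMatrix:
    """Plug-in mutual information of displacement series, raw and normalized."""

    M: np.ndarray
    H_joint: np.ndarray
    M_norm: np.ndarray
    n_bins: int
    log_base: float

    def __post_init__(self) -> None:
        for name in ("M", "H_joint", "M_norm"):
            a = np.asarray(getattr(self, name), dtype=float)
            if a.ndim != 2 or a.shape[0] != a.shape[1]:
                raise ValueError(f"{name} must be square")
            setattr(self, name, (a + a.T) / 2.0)
        if self.M.min() < -1e-9:
            raise ValueError("mutual information must be non-negative")
        if self.M_norm.min() < -1e-9 or self.M_norm.max() > 1 + 1e-9:
            raise ValueError("normalized MI must lie in [0, 1]")
        self.M = np.maximum(self.M, 0.0)
        self.M_norm = np.clip(self.M_norm, 0.0, 1.0)


@dataclass
class WeightMatrix:
    """Symmetric -log coupling weights with an explicit finite-edge mask."""

    W: np.ndarray
    edge_mask: np.ndarray
    floor_eps: float = DEFAULT_FLOOR_EPS

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        mask = np.asarray(self.edge_mask, dtype=bool)
        if W.shape != mask.shape or W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("W and edge_mask must be square and conformable")
        if np.any(W[mask] < -1e-12):
            raise ValueError("edge weights must be non-negative")
        self.W = np.where(mask, np.maximum(W, 0.0), np.inf)
        self.edge_mask = mask

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]


@dataclass
class BlockStats:
    """Per-edge weight variability from block analysis."""

    sigma_w: np.ndarray
    n_blocks: int
    block_length: int
    block_weights: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n_blocks < 2:
            raise ValueError("block analysis needs at least two blocks")
        s = np.asarray(self.sigma_w, dtype=float)
        if np.any(s[np.isfinite(s)] < 0):
            raise ValueError("sigma_w must be non-negative")
        self.sigma_w = s


def gaussian_kernel(d, c: float = DEFAULT_CONTACT_CUTOFF, sigma: float = 1.48):
    """Truncated Gaussian contact kernel.

    Equals 1 for d <= c and ``exp(-(d^2 - c^2) / (2 sigma^2))`` beyond the
    cut-off; continuous at ``d = c`` and monotone non-increasing in ``d``.

    Parameters
    ----------
    d : float or array
        Ca-Ca distance(s), Angstrom.
    c : float
        Contact cut-off, Angstrom.
    sigma : float
        Width of the Gaussian tail, Angstrom.
    """
    d = np.asarray(d, dtype=float)
    if c <= 0 or sigma <= 0:
        raise ValueError("cut-off and width must be positive")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    out = np.where(d <= c, 1.0, np.exp(-(d * d - c * c) / (2.0 * sigma * sigma)))
    return out if out.ndim else float(out)


def solve_kernel_width(
    c: float = DEFAULT_CONTACT_CUTOFF,
    d_cut: float = DEFAULT_KERNEL_DCUT,
    target: float = DEFAULT_KERNEL_TARGET,
) -> float:
    """Width sigma such that the kernel decays to ``target`` at ``d_cut``.

    Closed form: ``sigma = sqrt((d_cut^2 - c^2) / (-2 ln target))``.
    """
    if d_cut <= c:
        raise ValueError("d_cut must exceed the contact cut-off c")
    if not 0.0 < target < 1.0:
        raise ValueError("target kernel value must lie in (0, 1)")
    return math.sqrt((d_cut * d_cut - c * c) / (-2.0 * math.log(target)))


def compute_contact_map(
    distances: np.ndarray,
    c: float = DEFAULT_CONTACT_CUTOFF,
    sigma: float | None = None,
) -> ContactMap:
    """Average the contact kernel over all frames.

    Parameters
    ----------
    distances : (n_frames, n_res, n_res) array
        Per-frame symmetric Ca-Ca distance matrices.
    c, sigma : float
        Kernel parameters; ``sigma`` defaults to the width calibrated so
        the kernel reaches 1e-5 at 10 A.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 3 or d.shape[1] != d.shape[2]:
        raise ValueError("distances must have shape (n_frames, n_res, n_res)")
    if d.shape[0] < 1:
        raise ValueError("need at least one frame")
    if sigma is None:
        sigma = solve_kernel_width(c)
    C = gaussian_kernel(d, c, sigma).mean(axis=0)
    np.fill_diagonal(C, 1.0)
    return ContactMap(C=C, c=c, sigma=sigma, n_frames_used=d.shape[0])


def _discretize(series: np.ndarray, n_bins: int) -> tuple[np.ndarray, bool]:
    """Equal-width binning over the observed range of one residue's series.

    Returns integer codes in [0, n_bins) and a degeneracy flag for
    constant series (zero range, hence zero entropy).
    """
    lo = series.min()
    hi = series.max()
    if not hi > lo:
        return np.zeros(series.shape, dtype=np.intp), True
    codes = ((series - lo) * (n_bins / (hi - lo))).astype(np.intp)
    return np.minimum(codes, n_bins - 1), False


def _entropy(p: np.ndarray, log_base: float) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / math.log(log_base))


def estimate_mutual_information(
    displacements: np.ndarray,
    n_bins: int = DEFAULT_N_BINS,
    log_base: float = math.e,
) -> MutualInformationMatrix:
    """Pairwise plug-in MI of residue displacement series.

    Each residue's series is discretized on ``n_bins`` equal-width bins
    spanning its own observed range; MI comes from the joint histogram as
    ``M = H_i + H_j - H_ij`` and is normalized by the joint entropy,
    ``M' = M / H_ij`` (defined as 0 where the joint entropy vanishes).

    Parameters
    ----------
    displacements : (n_frames, n_res) array
        Scalar displacement series per residue.
    """
    X = np.asarray(displacements, dtype=float)
    if X.ndim != 2:
        raise ValueError("displacements must have shape (n_frames, n_res)")
    n_frames, n_res = X.shape
    if n_frames < 2:
        raise ValueError("need at least two frames to estimate MI")
    if n_bins < 2:
        raise ValueError("need at least two bins")

    codes = np.empty((n_res, n_frames), dtype=np.intp)
    degenerate = np.zeros(n_res, dtype=bool)
    marginal_H = np.zeros(n_res)
    for i in range(n_res):
        codes[i], degenerate[i] = _discretize(X[:, i], n_bins)
        counts = np.bincount(codes[i], minlength=n_bins) / n_frames
        marginal_H[i] = _entropy(counts, log_base)
    if degenerate.any():
        logger.warning(
            "%d constant displacement series: normalized MI set to 0 for "
            "pairs involving them",
            int(degenerate.sum()),
        )

    M = np.zeros((n_res, n_res))
    H_joint = np.zeros((n_res, n_res))
    M_norm = np.zeros((n_res, n_res))
    for i in range(n_res):
        if degenerate[i]:
            continue
        M[i, i] = marginal_H[i]
        H_joint[i, i] = marginal_H[i]
        M_norm[i, i] = 1.0
        for j in range(i + 1, n_res):
            joint = (
                np.bincount(codes[i] * n_bins + codes[j], minlength=n_bins * n_bins)
                / n_frames
            )
            h_ij = _entropy(joint, log_base)
            m_ij = max(marginal_H[i] + marginal_H[j] - h_ij, 0.0)
            M[i, j] = M[j, i] = m_ij
            H_joint[i, j] = H_joint[j, i] = h_ij
            if h_ij > 0.0 and not degenerate[j]:
                M_norm[i, j] = M_norm[j, i] = min(m_ij / h_ij, 1.0)
    return MutualInformationMatrix(
        M=M, H_joint=H_joint, M_norm=M_norm, n_bins=n_bins, log_base=log_base
    )


def build_weight_matrix(
    contacts: ContactMap | np.ndarray,
    M_norm: MutualInformationMatrix | np.ndarray,
    floor_eps: float = DEFAULT_FLOOR_EPS,
    log_base: float = math.e,
) -> WeightMatrix:
    """Combine contacts and normalized MI into -log edge weights.

    ``w_ij = -log(C_ij * M'_ij)``; pairs whose product falls below
    ``floor_eps`` (numerically "no communication") carry no edge, and the
    diagonal is excluded (no self-loops).
    """
    C = contacts.C if isinstance(contacts, ContactMap) else np.asarray(contacts, float)
    Mn = (
        M_norm.M_norm
        if isinstance(M_norm, MutualInformationMatrix)
        else np.asarray(M_norm, float)
    )
    if C.shape != Mn.shape:
        raise ValueError("contact and MI matrices are not conformable")
    if np.any(C < 0) or np.any(Mn < 0):
        raise ValueError("contact/MI matrices must be non-negative")
    product = C * Mn
    mask = product >= floor_eps
    np.fill_diagonal(mask, False)
    with np.errstate(divide="ignore"):
        W = np.where(mask, -np.log(np.maximum(product, floor_eps)), np.inf)
    W = W / math.log(log_base)
    return WeightMatrix(W=np.where(mask, np.maximum(W, 0.0), 0.0), edge_mask=mask,
                        floor_eps=floor_eps)


def block_weights(
    distances: np.ndarray,
    displacements: np.ndarray,
    block_length: int,
    *,
    c: float = DEFAULT_CONTACT_CUTOFF,
    sigma: float | None = None,
    n_bins: int = DEFAULT_N_BINS,
    log_base: float = math.e,
    floor_eps: float = DEFAULT_FLOOR_EPS,
) -> np.ndarray:
    """Re-run the full weight pipeline on contiguous trajectory blocks.

    Returns an array of shape ``(n_blocks, n_res, n_res)``; entries where
    a block carries no edge (product below the floor) are NaN.  Trailing
    frames that do not fill a complete block are discarded.
    """
    d = np.asarray(distances, float)
    X = np.asarray(displacements, float)
    n_frames = d.shape[0]
    if X.shape[0] != n_frames:
        raise ValueError("distance and displacement streams disagree on frames")
    if block_length < 2:
        raise ValueError("block_length must be at least 2 frames")
    if block_length > n_frames:
        raise ValueError("block longer than trajectory")
    n_blocks = n_frames // block_length
    if n_blocks < 2:
        raise ValueError("trajectory too short for two blocks of this length")
    out = []
    for b in range(n_blocks):
        sl = slice(b * block_length, (b + 1) * block_length)
        Cb = compute_contact_map(d[sl], c=c, sigma=sigma)
        Mb = estimate_mutual_information(X[sl], n_bins=n_bins, log_base=log_base)
        Wb = build_weight_matrix(Cb, Mb, floor_eps=floor_eps, log_base=log_base)
        out.append(np.where(Wb.edge_mask, Wb.W, np.nan))
    return np.stack(out)


def block_std_from_weights(w_blocks: np.ndarray) -> np.ndarray:
    """Per-edge sigma(w) from stacked block weights, SE-of-the-mean form.

    ``sqrt( 1/(N_B (N_B-1)) * sum_B (w^B - wbar)^2 )`` with ``wbar`` the
    mean over blocks.  Any edge missing (NaN) in some block is NaN.
    """
    w = np.asarray(w_blocks, dtype=float)
    if w.ndim < 2:
        w = w.reshape(w.shape[0], -1)
    n_b = w.shape[0]
    if n_b < 2:
        raise ValueError("need at least two blocks")
    mean = w.mean(axis=0)
    return np.sqrt(((w - mean) ** 2).sum(axis=0) / (n_b * (n_b - 1)))


def block_weight_std(
    distances: np.ndarray,
    displacements: np.ndarray,
    block_length: int,
    **pipeline_params,
) -> BlockStats:
    """Block-analysis uncertainty of every edge weight.

    Convenience wrapper: :func:`block_weights` followed by
    :func:`block_std_from_weights`.
    """
    wB = block_weights(distances, displacements, block_length, **pipeline_params)
    sigma = block_std_from_weights(wB)
    return BlockStats(
        sigma_w=sigma,
        n_blocks=wB.shape[0],
        block_length=block_length,
        block_weights=wB,
    )
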