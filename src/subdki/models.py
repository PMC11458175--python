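"""Forward signal models and closed-form diffusivity/kurtosis transforms.

The anomalous (sub-)diffusion signal model for powder-averaged DW-MRI is

    S(q, dbar) = S0 * E_beta(-D_beta * q^2 * dbar^beta)

with ``E_beta`` the Mittag-Leffler function, ``D_beta`` the anomalous
diffusion coefficient in mm^2/s^beta, ``beta`` in (0, 1] the fractional
order, and ``dbar = Delta - delta/3`` the effective diffusion time.  With
``b = q^2 * dbar`` this is ``S(b) = S0 * E_beta(-b * D_SUB)`` where
``D_SUB = D_beta * dbar^(beta-1)`` carries standard diffusivity units.

The model implies closed forms for the kurtosis-model (DKI) metrics:

    D* = D_SUB / Gamma(1+beta)
    K* = 6 * Gamma(1+beta)^2 / Gamma(1+2*beta) - 3

``K*`` depends on ``beta`` alone and is diffusion-time independent, which is
what makes the sub-diffusion route to mean kurtosis attractive.

Unit convention: all internal time arguments are seconds; interfaces that
accept diffusion times in milliseconds say so in their names.  ``D_beta`` is
stored in mm^2/s^beta and b-values in s/mm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import gamma as _gamma

from .mittleff import ml_e

__all__ = [
    "GAMMA_PROTON",
    "AcquisitionScheme",
    "SubDiffParams",
    "DKIParams",
    "b_from_protocol",
    "connectome_scheme",
    "connectome_b_table",
    "d_sub",
    "d_star",
    "k_star",
    "k_star_inverse",
    "sub_signal_q",
    "sub_signal_b",
    "dki_signal",
    "read_scheme",
    "write_scheme",
]

#: proton gyromagnetic ratio, rad s^-1 T^-1
GAMMA_PROTON = 2.6752e8

#: b-values (s/mm^2) below this are treated as b=0 volumes
B0_THRESHOLD = 1.0

#: nominal Connectome 1.0 b-value tables (s/mm^2) per diffusion time
CONNECTOME_B_D19 = (50.0, 350.0, 800.0, 1500.0, 2400.0, 3450.0, 4750.0, 6000.0)
CONNECTOME_B_D49 = (200.0, 950.0, 2300.0, 4250.0, 6750.0, 9850.0, 13500.0, 17800.0)

#: gradient-amplitude ladder (mT/m) that generated the Connectome b-tables
CONNECTOME_G_LADDER_MT = (31.0, 68.0, 105.0, 142.0, 179.0, 216.0, 253.0, 290.0)

CONNECTOME_DELTA_MS = (19.0, 49.0)
CONNECTOME_SMALL_DELTA_MS = 8.0


def b_from_protocol(gamma: float, delta_small_s: float, G_T_per_m: float,
                    delta_big_s: float) -> float:
    """b-value (s/mm^2) from pulse parameters: ``(gamma*delta*G)^2 (Delta - delta/3)``.

    ``gamma`` in rad s^-1 T^-1, pulse duration ``delta_small_s`` and
    diffusion time ``delta_big_s`` in seconds, gradient amplitude in T/m.
    The (gamma*delta*G)^2 factor is in 1/m^2, hence the 1e-6 conversion from
    s/m^2 to s/mm^2.
    """
    if delta_big_s <= delta_small_s / 3.0:
        raise ValueError("effective diffusion time Delta - delta/3 must be positive")
    q_per_m = gamma * delta_small_s * G_T_per_m
    return q_per_m ** 2 * (delta_big_s - delta_small_s / 3.0) * 1e-6


@dataclass(frozen=True)
class SubDiffParams:
    """Per-voxel sub-diffusion parameters ``(S0, D_beta, beta)``."""

    d_beta: float  # mm^2 / s^beta
    beta: float
    s0: float = 1.0

    def __post_init__(self):
        if not self.d_beta > 0:
            raise ValueError("D_beta must be positive")
        if not (0.0 < self.beta <= 1.0):
            raise ValueError("beta must be in (0, 1]")
        if not self.s0 > 0:
            raise ValueError("S0 must be positive")

    @property
    def k_star(self) -> float:
        return k_star(self.beta)

    def d_sub(self, delta_bar_s: float) -> float:
        return d_sub(self.d_beta, self.beta, delta_bar_s)

    def d_star(self, delta_bar_s: float) -> float:
        return d_star(self.d_sub(delta_bar_s), self.beta)


@dataclass(frozen=True)
class DKIParams:
    """Per-voxel apparent diffusivity and kurtosis from the quadratic model."""

    d_dki: float  # mm^2/s
    k_dki: float
    s0: float = 1.0

    def __post_init__(self):
        if not self.d_dki > 0:
            raise ValueError("D_DKI must be positive")
        if not (0.0 < self.k_dki <= 3.0):
            raise ValueError("K_DKI must be in (0, 3]")
        if not self.s0 > 0:
            raise ValueError("S0 must be positive")


@dataclass
class AcquisitionScheme:
    """Per-volume description of a multi-shell, multi-diffusion-time protocol.

    Arrays are one entry per acquired volume.  Nominal b-values are treated
    as authoritative (as they are for acquired data); ``q`` is derived from
    ``b`` unless supplied, in which case consistency with ``b = q^2 * dbar``
    is enforced to 0.5%.
    """

    b: np.ndarray                      # s/mm^2
    big_delta_ms: np.ndarray           # Delta
    small_delta_ms: np.ndarray         # delta
    n_dirs: np.ndarray = None          # directions per volume's shell
    bvecs: np.ndarray | None = None    # (3, n) unit vectors
    q: np.ndarray | None = field(default=None)  # 1/mm

    def __post_init__(self):
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        n = self.b.size
        self.big_delta_ms = np.broadcast_to(
            np.asarray(self.big_delta_ms, dtype=float), (n,)).copy()
        self.small_delta_ms = np.broadcast_to(
            np.asarray(self.small_delta_ms, dtype=float), (n,)).copy()
        if self.n_dirs is None:
            self.n_dirs = np.ones(n, dtype=int)
        self.n_dirs = np.broadcast_to(
            np.asarray(self.n_dirs, dtype=int), (n,)).copy()
        if np.any(self.b < 0):
            raise ValueError("b-values must be non-negative")
        if np.any(self.n_dirs < 1):
            raise ValueError("n_dirs must be >= 1")
        if np.any(self.big_delta_ms <= self.small_delta_ms / 3.0):
            raise ValueError("need Delta > delta/3 for every volume")
        if self.bvecs is not None:
            self.bvecs = np.asarray(self.bvecs, dtype=float)
            if self.bvecs.shape != (3, n):
                raise ValueError(
                    f"bvecs must have shape (3, {n}), got {self.bvecs.shape}")
        if self.q is not None:
            self.q = np.atleast_1d(np.asarray(self.q, dtype=float))
            if self.q.shape != self.b.shape:
                raise ValueError("q must match b in shape")
            expect = self.q ** 2 * self.delta_bar_s
            dwi = self.b > B0_THRESHOLD
            if np.any(np.abs(expect[dwi] - self.b[dwi]) > 5e-3 * self.b[dwi]):
                raise ValueError("q and b are inconsistent with b = q^2 * dbar "
                                 "beyond 0.5% relative")

    def __len__(self) -> int:
        return self.b.size

    @property
    def delta_bar_s(self) -> np.ndarray:
        """Effective diffusion time ``Delta - delta/3`` in seconds."""
        return (self.big_delta_ms - self.small_delta_ms / 3.0) * 1e-3

    @property
    def is_b0(self) -> np.ndarray:
        return self.b < B0_THRESHOLD

    @property
    def q_values(self) -> np.ndarray:
        """q-space values (1/mm); derived from b unless supplied."""
        if self.q is not None:
            return self.q
        return np.sqrt(self.b / self.delta_bar_s)

    def shell_ids(self, b_rtol: float = 0.01) -> np.ndarray:
        """Integer shell label per volume, grouping by (b, Delta).

        b-values within ``b_rtol`` relative are one shell; Delta is matched
        exactly.  b=0 volumes form their own shell per Delta.
        """
        ids = np.full(len(self), -1, dtype=int)
        next_id = 0
        for i in range(len(self)):
            if ids[i] >= 0:
                continue
            same_delta = self.big_delta_ms == self.big_delta_ms[i]
            if self.b[i] < B0_THRESHOLD:
                same_b = self.b < B0_THRESHOLD
            else:
                same_b = np.abs(self.b - self.b[i]) <= b_rtol * self.b[i]
            grp = same_delta & same_b & (ids < 0)
            ids[grp] = next_id
            next_id += 1
        return ids

    def subset(self, indices) -> "AcquisitionScheme":
        idx = np.asarray(indices)
        return AcquisitionScheme(
            b=self.b[idx],
            big_delta_ms=self.big_delta_ms[idx],
            small_delta_ms=self.small_delta_ms[idx],
            n_dirs=self.n_dirs[idx],
            bvecs=None if self.bvecs is None else self.bvecs[:, idx],
            q=None if self.q is None else self.q[idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "volume": np.arange(len(self)),
            "b": self.b,
            "big_delta_ms": self.big_delta_ms,
            "small_delta_ms": self.small_delta_ms,
            "n_dirs": self.n_dirs,
        })


def connectome_b_table() -> pd.DataFrame:
    """The 16-entry multi-diffusion-time b-table (8 per Delta), no b=0 row."""
    rows = [(b, 19.0) for b in CONNECTOME_B_D19]
    rows += [(b, 49.0) for b in CONNECTOME_B_D49]
    return pd.DataFrame(rows, columns=["b", "big_delta_ms"])


def connectome_scheme(include_b0: bool = True,
                      n_dirs: int | None = None) -> AcquisitionScheme:
    """Connectome-style two-diffusion-time acquisition scheme.

    Delta = 19 and 49 ms, delta = 8 ms, nominal b-values as acquired.  When
    ``n_dirs`` is None the acquisition rule of 32 directions for b < 2400
    s/mm^2 and 64 for b >= 2400 s/mm^2 is applied; passing an integer uses it
    for every shell.
    """
    b, delta = [], []
    if include_b0:
        b.append(0.0)
        delta.append(19.0)
    for bb in CONNECTOME_B_D19:
        b.append(bb)
        delta.append(19.0)
    for bb in CONNECTOME_B_D49:
        b.append(bb)
        delta.append(49.0)
    b = np.asarray(b)
    if n_dirs is None:
        nd = np.where(b < 2400.0, 32, 64)
        nd[b < B0_THRESHOLD] = 1
    else:
        nd = np.full(b.size, int(n_dirs))
    return AcquisitionScheme(b=b, big_delta_ms=np.asarray(delta),
                             small_delta_ms=CONNECTOME_SMALL_DELTA_MS,
                             n_dirs=nd)


# ---------------------------------------------------------------------------
# closed-form transforms

def d_sub(d_beta: float, beta: float, delta_bar_s) -> float | np.ndarray:
    """Apparent diffusivity ``D_SUB = D_beta * dbar^(beta-1)`` in mm^2/s."""
    delta_bar_s = np.asarray(delta_bar_s, dtype=float)
    if np.any(delta_bar_s <= 0):
        raise ValueError("delta_bar_s must be positive")
    out = d_beta * delta_bar_s ** (beta - 1.0)
    return float(out) if out.ndim == 0 else out


def d_star(d_sub_value, beta: float):
    """Kurtosis-model diffusivity ``D* = D_SUB / Gamma(1+beta)``."""
    if not (0.0 < beta <= 1.0):
        raise ValueError("beta must be in (0, 1]")
    return d_sub_value / _gamma(1.0 + beta)


def k_star(beta):
    """Mean kurtosis ``K* = 6 Gamma(1+beta)^2 / Gamma(1+2 beta) - 3``.

    Dimensionless, diffusion-time independent, strictly decreasing in beta
    with ``K*(1) = 0``.
    """
    beta_arr = np.asarray(beta, dtype=float)
    if np.any(beta_arr <= 0) or np.any(beta_arr > 1):
        raise ValueError("beta must be in (0, 1]")
    out = 6.0 * _gamma(1.0 + beta_arr) ** 2 / _gamma(1.0 + 2.0 * beta_arr) - 3.0
    return float(out) if out.ndim == 0 else out


def k_star_inverse(K: float, tol: float = 1e-10) -> float:
    """Fractional order ``beta`` with ``k_star(beta) = K``, on beta in [0.5, 1].

    Bracketing root find; valid for ``0 <= K <= k_star(0.5)`` (~1.7124),
    the range spanned by the simulation truth draws.
    """
    k_max = k_star(0.5)
    if not (0.0 <= K <= k_max):
        raise ValueError(f"K must be in [0, {k_max:.4f}], got {K!r}")
    if K == 0.0:
        return 1.0
    if K == k_max:
        return 0.5
    return brentq(lambda b: k_star(b) - K, 0.5, 1.0, xtol=tol)


# ---------------------------------------------------------------------------
# forward signals

def sub_signal_q(params: SubDiffParams, q, delta_bar_s):
    """Sub-diffusion signal ``S0 * E_beta(-D_beta q^2 dbar^beta)``.

    ``q`` in 1/mm, ``delta_bar_s`` in seconds.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be non-negative")
    dbar = np.asarray(delta_bar_s, dtype=float)
    if np.any(dbar <= 0):
        raise ValueError("delta_bar_s must be positive")
    z = -params.d_beta * q ** 2 * dbar ** params.beta
    return params.s0 * ml_e(params.beta, z)


def sub_signal_b(params: SubDiffParams, b, delta_bar_s):
    """Sub-diffusion signal in b-space: ``S0 * E_beta(-b D_SUB)``."""
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b must be non-negative")
    dsub = d_sub(params.d_beta, params.beta, delta_bar_s)
    z = -b * dsub
    return params.s0 * ml_e(params.beta, z)


def dki_signal(params: DKIParams, b):
    """Quadratic kurtosis-model signal ``S0 exp(-b D + b^2 D^2 K / 6)``."""
    b = np.asarray(b, dtype=float)
    out = params.s0 * np.exp(-b * params.d_dki
                             + b ** 2 * params.d_dki ** 2 * params.k_dki / 6.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# scheme serialization: FSL-style bval/bvec plus a timing sidecar

TIMING_COLUMNS = ["volume", "big_delta_ms", "small_delta_ms", "n_dirs"]


def write_scheme(scheme: AcquisitionScheme, stem: str | Path) -> dict:
    """Write ``<stem>.bval``, ``<stem>.bvec`` and ``<stem>_timing.csv``.

    bval/bvec carry no diffusion-time information, so per-volume (Delta,
    delta) pairs live in a CSV sidecar keyed by volume index.
    """
    stem = Path(stem)
    paths = {
        "bval": stem.with_suffix(".bval"),
        "bvec": stem.with_suffix(".bvec"),
        "timing": stem.parent / (stem.name + "_timing.csv"),
    }
    np.savetxt(paths["bval"], scheme.b[None, :], fmt="%.6g")
    bvecs = scheme.bvecs
    if bvecs is None:
        bvecs = np.zeros((3, len(scheme)))
    np.savetxt(paths["bvec"], bvecs, fmt="%.10g")
    scheme.to_dataframe()[TIMING_COLUMNS].to_csv(paths["timing"], index=False)
    return paths


def read_scheme(bval_path, bvec_path, timing_path) -> AcquisitionScheme:
    """Read the bval/bvec/timing triplet written by :func:`write_scheme`."""
    b = np.loadtxt(bval_path, ndmin=2).ravel()
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    n = b.size
    if bvecs.shape == (n, 3) and n != 3:
        import warnings

        warnings.warn("bvec file is N x 3; transposing to the 3 x N convention",
                      stacklevel=2)
        bvecs = bvecs.T
    if bvecs.shape != (3, n):
        raise ValueError(
            f"bvec shape {bvecs.shape} inconsistent with {n} b-values")
    timing = pd.read_csv(timing_path)
    missing = set(TIMING_COLUMNS[:3]) - set(timing.columns)
    if missing:
        raise ValueError(f"timing sidecar missing columns: {sorted(missing)}")
    timing = timing.sort_values("volume")
    if not np.array_equal(timing["volume"].to_numpy(), np.arange(n)):
        raise ValueError(
            f"timing sidecar must map every volume 0..{n - 1} exactly once")
    n_dirs = timing["n_dirs"].to_numpy() if "n_dirs" in timing else None
    if np.allclose(bvecs, 0.0):
        bvecs = None
    return AcquisitionScheme(
        b=b,
        big_delta_ms=timing["big_delta_ms"].to_numpy(),
        small_delta_ms=timing["small_delta_ms"].to_numpy(),
        n_dirs=n_dirs,
        bvecs=bvecs,
    )
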