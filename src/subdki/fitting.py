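"""Powder averaging and bounded nonlinear least-squares parameter estimation.

The multi-diffusion-time sub-diffusion fit minimises

    sum_ij [ S_ij - S0 * E_beta(-D_beta q_j^2 dbar_i^beta) ]^2

jointly over all diffusion times, which is what lets two modest acquisitions
at different Delta stand in for a much longer single-Delta protocol.  The
comparator is the standard quadratic kurtosis (DKI) fit, which is only valid
for a single diffusion time and for b-values up to ~2500 s/mm^2.

All fits use a bounded trust-region-reflective least-squares solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .mittleff import ml_e
from .models import (
    AcquisitionScheme,
    B0_THRESHOLD,
    DKIParams,
    SubDiffParams,
    d_star,
    d_sub,
    k_star,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "powder_average",
    "fit_subdiffusion",
    "fit_dki",
    "fit_volume",
]


@dataclass(frozen=True)
class FitConfig:
    """Solver settings and parameter boxes for the voxelwise fits.

    ``tol_fun``/``tol_x`` mirror the objective- and step-tolerance settings
    of trust-region curve fitting; defaults 1e-4 / 1e-6.  Bounds keep
    ``D_beta > 0`` and ``0 < beta <= 1`` for the sub-diffusion model and
    ``D > 0``, ``0 < K <= 3`` for the DKI comparator; the finite boxes are a
    solver requirement, generous around plausible brain-tissue values.
    ``max_dki_b`` rejects shells beyond the validity range of the quadratic
    model (2000-3000 s/mm^2); default 2500.
    """

    tol_fun: float = 1e-4
    tol_x: float = 1e-6
    d_beta_bounds: tuple[float, float] = (1e-6, 5e-2)
    beta_bounds: tuple[float, float] = (1e-3, 1.0)
    d_dki_bounds: tuple[float, float] = (1e-6, 5e-2)
    k_dki_bounds: tuple[float, float] = (1e-6, 3.0)
    s0_bounds: tuple[float, float] = (1e-6, 10.0)
    init_d_beta: float = 5e-4
    init_beta: float = 0.8
    init_d_dki: float = 1e-3
    init_k_dki: float = 1.0
    max_dki_b: float = 2500.0
    normalize: bool = True   # divide by b=0 and fix S0 = 1 when possible
    n_restarts: int = 0      # extra perturbed starts on non-convergence

    def __post_init__(self):
        for lo, hi in (self.d_beta_bounds, self.beta_bounds,
                       self.d_dki_bounds, self.k_dki_bounds, self.s0_bounds):
            if not (0 < lo < hi):
                raise ValueError("bounds must satisfy 0 < low < high")
        if self.beta_bounds[1] > 1.0:
            raise ValueError("beta upper bound cannot exceed 1")


@dataclass
class FitResult:
    """Outcome of one voxel-level fit."""

    params: SubDiffParams | DKIParams
    rmse: float
    converged: bool
    n_obs: int
    at_bounds: bool = False
    cost: float = float("nan")


def powder_average(signals_by_direction, floor: float | None = None):
    """Per-shell geometric mean over diffusion-encoding directions.

    Parameters
    ----------
    signals_by_direction : sequence of 1-D arrays
        One array per shell holding that shell's per-direction signals.
    floor : float, optional
        Values are clipped from below at this level before taking logs
        (real-valued data can contain non-positive voxels).  ``None``
        demands strictly positive inputs.

    Returns
    -------
    ndarray
        One geometric mean per shell.
    """
    out = np.empty(len(signals_by_direction))
    for i, shell in enumerate(signals_by_direction):
        arr = np.asarray(shell, dtype=float)
        if arr.size == 0:
            raise ValueError(f"shell {i} has no directions")
        if floor is not None:
            arr = np.clip(arr, floor, None)
        elif np.any(arr <= 0):
            raise ValueError(
                f"shell {i} has non-positive signals; pass floor= to clip")
        out[i] = np.exp(np.mean(np.log(arr)))
    return out


def _run_lsq(residual, x0, bounds, cfg: FitConfig, x_scale):
    res = least_squares(residual, x0, bounds=bounds, method="trf",
                        ftol=cfg.tol_fun, xtol=cfg.tol_x, gtol=1e-12,
                        x_scale=x_scale)
    return res


def fit_subdiffusion(signals, scheme: AcquisitionScheme,
                     cfg: FitConfig | None = None) -> FitResult:
    """Fit ``(D_beta, beta)`` (and S0 when unnormalised) to powder-averaged signals.

    ``signals`` holds one value per scheme volume (already powder averaged).
    With a b=0 volume present and ``cfg.normalize`` true, data are divided by
    the mean b=0 signal and S0 is fixed at 1; otherwise S0 is free.  The
    objective sums squared residuals over every (Delta, b) observation, so
    any number of diffusion times enters one joint fit.
    """
    cfg = cfg or FitConfig()
    s = np.asarray(signals, dtype=float).ravel()
    if s.size != len(scheme):
        raise ValueError(f"got {s.size} signals for {len(scheme)} scheme volumes")
    if s.size < 3:
        raise ValueError("need at least 3 observations to fit (D_beta, beta)")

    b0 = scheme.is_b0
    fix_s0 = cfg.normalize and bool(np.any(b0))
    if fix_s0:
        s0_ref = float(np.mean(s[b0]))
        if s0_ref <= 0:
            raise ValueError("b=0 signal must be positive for normalisation")
        s = s / s0_ref
    b = scheme.b
    dbar = scheme.delta_bar_s
    dbar_pow = {}  # beta -> dbar**(beta-1), tiny memo per solver iterate

    def model(d_beta, beta, s0):
        p = dbar_pow.get(beta)
        if p is None:
            dbar_pow.clear()
            p = dbar_pow[beta] = dbar ** (beta - 1.0)
        return s0 * ml_e(beta, -b * d_beta * p)

    if fix_s0:
        def residual(x):
            return model(x[0], x[1], 1.0) - s
        x0 = np.array([cfg.init_d_beta, cfg.init_beta])
        lo = [cfg.d_beta_bounds[0], cfg.beta_bounds[0]]
        hi = [cfg.d_beta_bounds[1], cfg.beta_bounds[1]]
        x_scale = [1e-3, 1.0]
    else:
        def residual(x):
            return model(x[0], x[1], x[2]) - s
        s_guess = float(np.median(s[b0])) if np.any(b0) else float(np.max(s))
        x0 = np.array([cfg.init_d_beta, cfg.init_beta, max(s_guess, 1e-3)])
        lo = [cfg.d_beta_bounds[0], cfg.beta_bounds[0], cfg.s0_bounds[0]]
        hi = [cfg.d_beta_bounds[1], cfg.beta_bounds[1], cfg.s0_bounds[1]]
        x_scale = [1e-3, 1.0, max(float(np.max(s)), 1e-3)]

    res = _run_lsq(residual, x0, (lo, hi), cfg, x_scale)
    for attempt in range(cfg.n_restarts):
        if res.success:
            break
        rng = np.random.default_rng(attempt)
        x0_r = np.clip(x0 * rng.uniform(0.5, 1.5, size=x0.size), lo, hi)
        alt = _run_lsq(residual, x0_r, (lo, hi), cfg, x_scale)
        if alt.cost < res.cost:
            res = alt

    d_beta_hat, beta_hat = float(res.x[0]), float(res.x[1])
    s0_hat = 1.0 if fix_s0 else float(res.x[2])
    params = SubDiffParams(d_beta=d_beta_hat, beta=beta_hat, s0=s0_hat)
    rmse = float(np.sqrt(np.mean(res.fun ** 2)))
    at_lo = np.isclose(d_beta_hat, cfg.d_beta_bounds[0])
    return FitResult(params=params, rmse=rmse, converged=bool(res.success),
                     n_obs=int(s.size), at_bounds=bool(at_lo),
                     cost=float(res.cost))


def fit_dki(signals, b, cfg: FitConfig | None = None,
            fix_s0: bool = False) -> FitResult:
    """Fit the quadratic kurtosis model ``S0 exp(-bD + b^2 D^2 K/6)``.

    Single diffusion time only (D_DKI is time dependent, so mixing Deltas in
    one quadratic fit is meaningless); every b must satisfy
    ``b <= cfg.max_dki_b``.
    """
    cfg = cfg or FitConfig()
    s = np.asarray(signals, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if s.size != b.size:
        raise ValueError("signals and b must have matching length")
    if s.size < 3:
        raise ValueError("need at least 3 observations to fit (S0, D, K)")
    bad = b > cfg.max_dki_b
    if np.any(bad):
        raise ValueError(
            f"b-values {sorted(set(b[bad]))} exceed max_dki_b={cfg.max_dki_b}; "
            "the quadratic kurtosis model is invalid there")

    def model(d, k, s0):
        return s0 * np.exp(-b * d + b ** 2 * d ** 2 * k / 6.0)

    if fix_s0:
        def residual(x):
            return model(x[0], x[1], 1.0) - s
        x0 = np.array([cfg.init_d_dki, cfg.init_k_dki])
        lo = [cfg.d_dki_bounds[0], cfg.k_dki_bounds[0]]
        hi = [cfg.d_dki_bounds[1], cfg.k_dki_bounds[1]]
        x_scale = [1e-3, 1.0]
    else:
        def residual(x):
            return model(x[0], x[1], x[2]) - s
        s_guess = float(s[np.argmin(b)])
        x0 = np.array([cfg.init_d_dki, cfg.init_k_dki, max(s_guess, 1e-3)])
        lo = [cfg.d_dki_bounds[0], cfg.k_dki_bounds[0], cfg.s0_bounds[0]]
        hi = [cfg.d_dki_bounds[1], cfg.k_dki_bounds[1], cfg.s0_bounds[1]]
        x_scale = [1e-3, 1.0, max(float(np.max(s)), 1e-3)]

    res = _run_lsq(residual, x0, (lo, hi), cfg, x_scale)
    d_hat, k_hat = float(res.x[0]), float(res.x[1])
    s0_hat = 1.0 if fix_s0 else float(res.x[2])
    params = DKIParams(d_dki=d_hat, k_dki=k_hat, s0=s0_hat)
    rmse = float(np.sqrt(np.mean(res.fun ** 2)))
    return FitResult(params=params, rmse=rmse, converged=bool(res.success),
                     n_obs=int(s.size), cost=float(res.cost))


def fit_volume(data, scheme: AcquisitionScheme, mask=None,
               model: str = "subdiffusion",
               cfg: FitConfig | None = None,
               signal_floor: float = 1e-6) -> dict[str, np.ndarray]:
    """Voxelwise powder average + fit over a 4-D volume.

    ``data`` is (x, y, z, volume) with the 4th axis matching the scheme.
    Volumes are first reduced to one powder-averaged value per (b, Delta)
    shell (geometric mean across same-shell volumes, floored at
    ``signal_floor`` times the voxel b=0 level), then fitted per voxel.

    Returns a dict of 3-D maps.  Sub-diffusion: ``Dbeta``, ``beta``,
    ``Kstar``, plus ``Dsub_d<Delta>ms`` / ``Dstar_d<Delta>ms`` per distinct
    diffusion time, and ``rmse``.  DKI: ``Ddki``, ``Kdki``, ``S0``, ``rmse``.
    Voxels outside the mask are NaN.
    """
    cfg = cfg or FitConfig()
    data = np.asarray(data, dtype=float)
    if data.ndim != 4:
        raise ValueError("data must be 4-D (x, y, z, volume)")
    if data.shape[3] != len(scheme):
        raise ValueError(
            f"data has {data.shape[3]} volumes but scheme has {len(scheme)}")
    grid = data.shape[:3]
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid:
        raise ValueError(f"mask shape {mask.shape} != data grid {grid}")

    if model not in ("subdiffusion", "dki"):
        raise ValueError("model must be 'subdiffusion' or 'dki'")

    # reduce same-shell volumes to their geometric mean
    ids = scheme.shell_ids()
    shell_rows = [np.nonzero(ids == k)[0] for k in range(ids.max() + 1)]
    rep = np.array([rows[0] for rows in shell_rows])
    shell_scheme = scheme.subset(rep)

    if model == "dki":
        dwi = ~shell_scheme.is_b0
        if np.any(shell_scheme.b[dwi] > cfg.max_dki_b):
            raise ValueError(
                "scheme contains shells beyond max_dki_b; subset it first")
        deltas = np.unique(shell_scheme.big_delta_ms[dwi])
        if deltas.size > 1:
            raise ValueError(
                "DKI fits need a single diffusion time; subset the scheme")

    names: list[str]
    deltas_ms = np.unique(shell_scheme.big_delta_ms)
    if model == "subdiffusion":
        names = ["Dbeta", "beta", "Kstar", "rmse"]
        names += [f"Dsub_d{d:g}ms" for d in deltas_ms]
        names += [f"Dstar_d{d:g}ms" for d in deltas_ms]
    else:
        names = ["Ddki", "Kdki", "S0", "rmse"]
    maps = {name: np.full(grid, np.nan) for name in names}

    b0_ref_rows = np.nonzero(scheme.is_b0)[0]
    for idx in np.ndindex(grid):
        if not mask[idx]:
            continue
        vox = data[idx]
        ref = np.mean(vox[b0_ref_rows]) if b0_ref_rows.size else np.max(vox)
        floor = signal_floor * max(ref, np.finfo(float).tiny)
        shell_sig = powder_average([vox[rows] for rows in shell_rows],
                                   floor=floor)
        if model == "subdiffusion":
            fr = fit_subdiffusion(shell_sig, shell_scheme, cfg)
            p = fr.params
            maps["Dbeta"][idx] = p.d_beta
            maps["beta"][idx] = p.beta
            maps["Kstar"][idx] = k_star(p.beta)
            for d in deltas_ms:
                dbar = (d - shell_scheme.small_delta_ms[0] / 3.0) * 1e-3
                ds = d_sub(p.d_beta, p.beta, dbar)
                maps[f"Dsub_d{d:g}ms"][idx] = ds
                maps[f"Dstar_d{d:g}ms"][idx] = d_star(ds, p.beta)
        else:
            fr = fit_dki(shell_sig, shell_scheme.b, cfg)
            p = fr.params
            maps["Ddki"][idx] = p.d_dki
            maps["Kdki"][idx] = p.k_dki
            maps["S0"][idx] = p.s0
        maps["rmse"][idx] = fr.rmse
    return maps
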