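"""Pixel-wise mono-exponential T2 fitting with adjusted-R² quality gating.

The signal model is the standard spin-echo decay

    S(TE) = S0 * exp(-TE / T2)

fitted per voxel by nonlinear least squares (Levenberg–Marquardt,
vectorized over voxels). Fit quality is judged by the coefficient of
determination adjusted for the model's degrees of freedom,

    R²_adj = 1 - (1 - R²) (n - 1) / (n - p - 1),

with n the number of echoes and p = 2 parameters; only voxels with
R²_adj at or above the configured threshold (default 0.9) and T2 inside
the configured bounds are marked valid. Invalid voxels carry NaN, never
zero, so they can never bias ROI means.

An optional 3-parameter variant with a constant noise-floor offset
(S0·exp(-TE/T2) + C) is available behind a config flag; the default is
the plain 2-parameter model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .io import MultiEchoVolume, T2Map

__all__ = ["FitConfig", "RoiSummary", "fit_t2_pixelwise", "summarize_roi"]


@dataclass
class FitConfig:
    """Settings for the pixel-wise T2 fit.

    r2_threshold : adjusted-R² validity gate, in [0, 1].
    t2_bounds : admissible T2 range in ms.
    max_iterations : Levenberg–Marquardt iteration cap per voxel.
    init_strategy : "log_linear" seeds from a log-space regression of
        ln S on TE; "fixed" starts every voxel at the bound midpoint.
    use_offset : fit the 3-parameter noise-floor model instead.
    drop_first_echo : exclude echo 1 from the fit (stimulated-echo
        contamination mitigation); off by default.
    """

    r2_threshold: float = 0.9
    t2_bounds: tuple[float, float] = (1.0, 2000.0)
    max_iterations: int = 50
    init_strategy: Literal["log_linear", "fixed"] = "log_linear"
    use_offset: bool = False
    drop_first_echo: bool = False
    tol: float = 1e-10

    def __post_init__(self) -> None:
        lo, hi = self.t2_bounds
        if not (0 < lo < hi):
            raise ValueError(f"t2_bounds must be ordered positive, got {self.t2_bounds}")
        if not (0.0 <= self.r2_threshold <= 1.0):
            raise ValueError("r2_threshold must lie in [0, 1]")


def _log_linear_init(y: np.ndarray, te: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Seed (S0, T2) from the slope/intercept of ln S vs TE.

    Nonpositive samples are excluded voxel-wise via masked least squares;
    voxels with < 2 usable echoes fall back to a crude guess.
    """
    pos = y > 0
    n = pos.sum(axis=1)
    logy = np.where(pos, np.log(np.maximum(y, 1e-300)), 0.0)
    sx = (te * pos).sum(axis=1)
    sy = logy.sum(axis=1)
    sxx = (te**2 * pos).sum(axis=1)
    sxy = (te * logy).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = n * sxx - sx**2
        slope = (n * sxy - sx * sy) / denom
        intercept = (sy - slope * sx) / n
    s0 = np.exp(np.clip(intercept, -300, 300))
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = -1.0 / slope
    bad = (n < 2) | ~np.isfinite(t2) | (t2 <= 0) | ~np.isfinite(s0)
    t2 = np.where(bad, (te[0] + te[-1]) / 2.0, t2)
    s0 = np.where(bad, np.maximum(y.max(axis=1), 1e-6), s0)
    return s0, t2


def _lm_fit(y: np.ndarray, te: np.ndarray, s0: np.ndarray, t2: np.ndarray,
            cfg: FitConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Batched Levenberg–Marquardt for S(TE) = S0 exp(-TE/T2).

    Parameterized in (S0, R=1/T2) for conditioning. Returns (s0, t2,
    residual sum of squares, converged flag).
    """
    lo, hi = cfg.t2_bounds
    r = 1.0 / np.clip(t2, lo / 10, hi * 10)
    s0 = s0.copy()
    lam = np.full(y.shape[0], 1e-3)
    active = np.ones(y.shape[0], dtype=bool)
    converged = np.zeros(y.shape[0], dtype=bool)

    def cost(s0v, rv):
        f = s0v[:, None] * np.exp(-te[None, :] * rv[:, None])
        d = f - y
        return (d * d).sum(axis=1), f

    c, _ = cost(s0, r)
    for _ in range(cfg.max_iterations):
        if not active.any():
            break
        idx = np.nonzero(active)[0]
        s0a, ra, ya, ca = s0[idx], r[idx], y[idx], c[idx]
        e = np.exp(-te[None, :] * ra[:, None])
        f = s0a[:, None] * e
        res = ya - f
        j0 = e                                  # df/dS0
        j1 = -s0a[:, None] * te[None, :] * e    # df/dR
        a00 = (j0 * j0).sum(axis=1)
        a01 = (j0 * j1).sum(axis=1)
        a11 = (j1 * j1).sum(axis=1)
        g0 = (j0 * res).sum(axis=1)
        g1 = (j1 * res).sum(axis=1)
        la = lam[idx]
        d00 = a00 * (1 + la)
        d11 = a11 * (1 + la)
        det = d00 * d11 - a01 * a01
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        ds0 = (d11 * g0 - a01 * g1) / det
        dr = (d00 * g1 - a01 * g0) / det
        s0n = s0a + ds0
        rn = np.clip(ra + dr, 1.0 / (hi * 10), 1.0 / (lo / 10))
        fn = s0n[:, None] * np.exp(-te[None, :] * rn[:, None])
        dn = fn - ya
        cn = (dn * dn).sum(axis=1)
        better = cn <= ca
        s0[idx[better]] = s0n[better]
        r[idx[better]] = rn[better]
        c[idx[better]] = cn[better]
        lam[idx[better]] = np.maximum(la[better] * 0.3, 1e-12)
        lam[idx[~better]] = np.minimum(la[~better] * 10.0, 1e12)
        scale = np.maximum(ca, 1e-30)
        done = better & ((ca - cn) <= cfg.tol * scale)
        stuck = ~better & (lam[idx] >= 1e11)  # local minimum: no step improves
        converged[idx[done | stuck]] = True
        active[idx[done | stuck]] = False
    converged &= np.isfinite(c) & np.isfinite(s0) & np.isfinite(r)
    return s0, 1.0 / r, c, converged


def _lm_fit_offset(y: np.ndarray, te: np.ndarray, s0: np.ndarray, t2: np.ndarray,
                   cfg: FitConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """3-parameter variant S(TE) = S0 exp(-TE/T2) + C via batched LM."""
    lo, hi = cfg.t2_bounds
    n = y.shape[0]
    p = np.stack([s0, 1.0 / np.clip(t2, lo / 10, hi * 10), np.zeros(n)], axis=1)
    lam = np.full(n, 1e-3)
    converged = np.zeros(n, dtype=bool)

    def model(pp):
        return pp[:, 0:1] * np.exp(-te[None, :] * pp[:, 1:2]) + pp[:, 2:3]

    c = ((model(p) - y) ** 2).sum(axis=1)
    eye = np.eye(3)[None]
    for _ in range(cfg.max_iterations):
        e = np.exp(-te[None, :] * p[:, 1:2])
        f = p[:, 0:1] * e + p[:, 2:3]
        res = y - f
        J = np.stack([e, -p[:, 0:1] * te[None, :] * e, np.ones_like(e)], axis=2)
        A = np.einsum("nej,nek->njk", J, J)
        g = np.einsum("nej,ne->nj", J, res)
        diag = np.maximum(np.diagonal(A, axis1=1, axis2=2), 1e-12)
        Ad = A + lam[:, None, None] * eye * diag[:, :, None]
        try:
            step = np.linalg.solve(Ad, g)
        except np.linalg.LinAlgError:
            step = np.zeros_like(g)
        pn = p + step
        pn[:, 1] = np.clip(pn[:, 1], 1.0 / (hi * 10), 1.0 / (lo / 10))
        cn = ((model(pn) - y) ** 2).sum(axis=1)
        better = cn <= c
        p[better] = pn[better]
        lam = np.where(better, np.maximum(lam * 0.3, 1e-12), np.minimum(lam * 10, 1e12))
        done = better & ((c - cn) <= cfg.tol * np.maximum(c, 1e-30))
        converged |= done
        c = np.where(better, cn, c)
        if converged.all():
            break
    return p[:, 0], 1.0 / p[:, 1], c, converged | (c <= cfg.tol)


def fit_t2_pixelwise(
    volume: MultiEchoVolume,
    roi: np.ndarray | None = None,
    cfg: FitConfig | None = None,
) -> T2Map:
    """Fit the mono-exponential decay model at every ROI voxel.

    Parameters
    ----------
    volume : MultiEchoVolume
        The 4D multi-echo acquisition (>= 3 echoes after any exclusion).
    roi : boolean ndarray matching the spatial grid, optional
        Voxels to fit; voxels outside stay invalid with NaN. Default all.
    cfg : FitConfig, optional

    Returns
    -------
    T2Map
        With ``valid`` true only where the fit converged, adjusted R²
        meets the threshold and T2 lies inside the bounds. Degenerate
        voxels (constant signal, zero total sum of squares) are invalid;
        no exception is raised for them.
    """
    cfg = cfg or FitConfig()
    te = volume.echo_times
    sig = volume.signal
    if cfg.drop_first_echo:
        te, sig = te[1:], sig[1:]
    n_echo = len(te)
    n_par = 3 if cfg.use_offset else 2
    if n_echo < n_par + 1:
        raise ValueError(f"need >= {n_par + 1} echoes for the {n_par}-parameter model")
    shape = volume.spatial_shape
    if roi is None:
        roi = np.ones(shape, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != shape:
        raise ValueError(f"roi shape {roi.shape} != volume shape {shape}")

    t2 = np.full(shape, np.nan)
    s0 = np.full(shape, np.nan)
    r2a = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    if not roi.any():
        return T2Map(t2, s0, r2a, valid, volume.voxel_spacing, cfg.r2_threshold)

    y = sig[:, roi].T  # (n_voxels, n_echoes)
    ss_tot = ((y - y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    degenerate = ss_tot <= 0

    if cfg.init_strategy == "log_linear":
        s0_i, t2_i = _log_linear_init(y, te)
    else:
        mid = float(np.sqrt(cfg.t2_bounds[0] * cfg.t2_bounds[1]))
        s0_i = np.maximum(y.max(axis=1), 1e-6)
        t2_i = np.full(y.shape[0], mid)

    fitter = _lm_fit_offset if cfg.use_offset else _lm_fit
    s0_f, t2_f, rss, converged = fitter(y, te, s0_i, t2_i, cfg)

    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - rss / ss_tot
        r2_adj = 1.0 - (1.0 - r2) * (n_echo - 1) / (n_echo - n_par - 1)
    r2_adj[degenerate] = np.nan

    lo, hi = cfg.t2_bounds
    ok = (
        converged
        & ~degenerate
        & np.isfinite(t2_f)
        & (t2_f >= lo)
        & (t2_f <= hi)
        & (r2_adj >= cfg.r2_threshold)
    )
    t2_out = np.where(ok, t2_f, np.nan)
    s0_out = np.where(ok, s0_f, np.nan)
    t2[roi] = t2_out
    s0[roi] = s0_out
    r2a[roi] = r2_adj
    valid[roi] = ok
    return T2Map(t2, s0, r2a, valid, volume.voxel_spacing, cfg.r2_threshold)


@dataclass
class RoiSummary:
    """Summary statistics over the valid voxels of one ROI."""

    mean: float
    sd: float
    median: float
    n_valid: int
    n_total: int
    hist_counts: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    hist_edges: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def empty(self) -> bool:
        return self.n_valid == 0


def summarize_roi(
    t2map: T2Map,
    roi: np.ndarray,
    hist_range: tuple[float, float] = (0.0, 80.0),
    bin_width: float = 1.0,
) -> RoiSummary:
    """Mean/SD/median T2 and a histogram over an ROI's valid voxels.

    The histogram spans 0–80 ms by default (the display range used for
    T2 color maps of ligament). Zero valid voxels yields an empty-summary
    sentinel (NaN statistics) with a warning, not an exception.
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("roi is empty")
    sel = roi & t2map.valid
    n_valid = int(sel.sum())
    edges = np.arange(hist_range[0], hist_range[1] + bin_width / 2, bin_width)
    if n_valid == 0:
        warnings.warn("ROI contains no valid voxels; returning empty summary")
        return RoiSummary(np.nan, np.nan, np.nan, 0, int(roi.sum()),
                          np.zeros(len(edges) - 1, dtype=int), edges)
    vals = t2map.t2[sel]
    counts, _ = np.histogram(vals, bins=edges)
    sd = float(np.std(vals, ddof=1)) if n_valid > 1 else 0.0
    return RoiSummary(
        mean=float(np.mean(vals)),
        sd=sd,
        median=float(np.median(vals)),
        n_valid=n_valid,
        n_total=int(roi.sum()),
        hist_counts=counts,
        hist_edges=edges,
    )
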