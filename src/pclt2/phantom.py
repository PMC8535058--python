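"""Synthetic paired-loading phantom cohorts with full ground truth.

Each phantom is a curved-tube "ligament" voxelized on the acquisition
grid of the study protocol (0.4 x 0.4 mm in-plane, 3.2 mm center-to-
center slices; 5 echoes at 13.8/27.6/41.4/55.2/69.0 ms). The tube
follows a planar circular arc whose length is the target ligament
length; loading (d0 -> d1) is emulated by scaling the arc length at
fixed radius and substituting the loaded subregion T2 values — the
pipeline under test only needs paired data with the right statistical
structure, not a biomechanical simulation.

The T2 field is piecewise-constant over the proximal/central/distal
subregions (defaults: 41.1/34.7/32.7 ms unloaded, 45.7/36.5/33.4 ms
loaded) with 2 mm smoothed transitions, plus a voxel-wise truncated-
normal texture field (floor 2 ms, per-subregion mean-recentred so the
ground-truth subregion means equal the targets by construction). Short-
T2 bone blocks abut both tube ends across planar interfaces, providing
the insertion-site geometry. Signals are S0 exp(-TE/T2) with seeded
magnitude noise (Gaussian-magnitude by default, Rician optionally).

Cohorts draw one shared specimen-level offset per metric (length,
subregion T2 means), applied to both configurations, so the paired
d1 - d0 contrast is preserved while specimens vary realistically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .io import (
    Configuration,
    LabelMask,
    ManifestRecord,
    MultiEchoVolume,
    StudyManifest,
    write_mask,
    write_multiecho,
)

__all__ = ["PhantomSpec", "GroundTruth", "SpecimenData", "CohortVariation",
           "generate_phantom", "generate_cohort", "ECHO_TIMES_MS"]

#: Multi spin-echo sampling of the acquisition protocol (ms).
ECHO_TIMES_MS = (13.8, 27.6, 41.4, 55.2, 69.0)


@dataclass
class PhantomSpec:
    """Generator parameters; defaults are the study's conditions."""

    shape: tuple[int, int, int] = (9, 160, 220)          # (nz, ny, nx)
    voxel_spacing: tuple[float, float, float] = (3.2, 0.4, 0.4)
    echo_times: tuple[float, ...] = ECHO_TIMES_MS
    arc_radius: float = 45.0                             # mm, ligament curvature
    tube_radius: float = 3.0                             # mm
    unloaded_length: float = 37.8                        # mm
    loaded_length: float = 44.0                          # mm
    # subregion T2 means (PR, CR, DR), ms
    t2_means_d0: tuple[float, float, float] = (41.1, 34.7, 32.7)
    t2_means_d1: tuple[float, float, float] = (45.7, 36.5, 33.4)
    # voxel-wise within-ROI texture SD (PR, CR, DR), ms
    t2_texture_sd_d0: tuple[float, float, float] = (25.7, 22.8, 20.8)
    t2_texture_sd_d1: tuple[float, float, float] = (26.5, 21.4, 21.6)
    transition_mm: float = 2.0                           # subregion boundary smoothing
    bone_t2: float = 5.0                                 # ms, short-T2 bone
    bone_depth: float = 6.0                              # mm beyond the interface
    bone_halfwidth: float = 9.0                          # mm along the interface
    interface_angle_deg: float = 0.0                     # tilt vs the end-normal
    s0: float = 1000.0                                   # signal units
    noise_model: str = "gaussian"                        # or "rician"
    noise_sigma_frac: float = 0.02                       # sigma as fraction of s0
    t2_floor: float = 2.0                                # ms, physical floor
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loaded_length < self.unloaded_length:
            raise ValueError("loaded length must be >= unloaded length")
        if min(*self.t2_means_d0, *self.t2_means_d1, self.bone_t2) <= 0:
            raise ValueError("all T2 values must be positive")
        if self.noise_sigma_frac < 0:
            raise ValueError("noise sigma must be nonnegative")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


@dataclass
class GroundTruth:
    """Generator-side truth aligned to the emitted grid."""

    t2_field: np.ndarray                 # NaN outside labeled structures
    subregion_labels: np.ndarray         # 0 none, 1 PR, 2 CR, 3 DR
    curve_points: np.ndarray             # dense centerline, (M, 3) mm, proximal first
    length: float                        # arc length, mm
    subregion_means: tuple[float, float, float]
    interfaces: dict[str, dict]          # site -> {point, normal (into bone)}
    spec: PhantomSpec
    configuration: Configuration


@dataclass
class SpecimenData:
    """One specimen's paired phantoms, in memory."""

    specimen_id: str
    d0: tuple[MultiEchoVolume, LabelMask, GroundTruth]
    d1: tuple[MultiEchoVolume, LabelMask, GroundTruth]


@dataclass
class CohortVariation:
    """Between-specimen SDs for the cohort generator (study-scale values)."""

    length_sd: float = 1.8                                    # mm
    t2_mean_sd: tuple[float, float, float] = (1.7, 0.7, 1.5)  # (PR, CR, DR) ms


def _arc_curve(spec: PhantomSpec, length: float, n: int = 1200) -> tuple[np.ndarray, np.ndarray]:
    """Dense planar arc of the requested length, centered in the grid.

    Returns (points (n,3) mm proximal-first, arclength (n,)). The curve
    lies in the central slice plane; the proximal (femoral) end is the
    first point.
    """
    nz, ny, nx = spec.shape
    dz, dy, dx = spec.voxel_spacing
    zc = (nz // 2) * dz
    yc, xc = (ny - 1) * dy / 2, (nx - 1) * dx / 2
    R = spec.arc_radius
    theta = length / R
    phi = np.linspace(-theta / 2, theta / 2, n)
    y = (yc + R) - R * np.cos(phi) - R * (1 - np.cos(theta / 2)) / 2  # recenter sagitta
    x = xc + R * np.sin(phi)
    pts = np.column_stack([np.full(n, zc), y, x])
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    return pts, s


def _smooth_profile(s: np.ndarray, length: float, values: tuple[float, float, float],
                    transition: float) -> np.ndarray:
    """Arc-length plateau profile with linear ramps of width ``transition``
    centered at the 25% and 75% boundaries."""
    b1, b2 = 0.25 * length, 0.75 * length
    h = transition / 2.0
    v1, v2, v3 = values
    out = np.empty_like(s)
    out[:] = v2
    out[s < b1 - h] = v1
    out[s > b2 + h] = v3
    ramp1 = (s >= b1 - h) & (s <= b1 + h)
    out[ramp1] = v1 + (v2 - v1) * (s[ramp1] - (b1 - h)) / transition
    ramp2 = (s >= b2 - h) & (s <= b2 + h)
    out[ramp2] = v2 + (v3 - v2) * (s[ramp2] - (b2 - h)) / transition
    return out


def generate_phantom(
    spec: PhantomSpec,
    configuration: Configuration | str = Configuration.UNLOADED_D0,
    specimen_id: str = "phantom",
    rng: np.random.Generator | None = None,
    noise_margin_mm: float = 4.0,
) -> tuple[MultiEchoVolume, LabelMask, GroundTruth]:
    """Voxelize one phantom for one loading configuration.

    Noise is drawn inside a ``noise_margin_mm`` bounding box around the
    labeled structures; the remote background stays exactly zero (no
    analysis stage ever touches it). Same spec + rng state => identical
    output.
    """
    configuration = Configuration(configuration)
    loaded = configuration == Configuration.LOADED_D1
    rng = rng or np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    spacing = np.asarray(spec.voxel_spacing)
    length = spec.loaded_length if loaded else spec.unloaded_length
    t2_means = spec.t2_means_d1 if loaded else spec.t2_means_d0
    t2_sds = spec.t2_texture_sd_d1 if loaded else spec.t2_texture_sd_d0

    curve, s_curve = _arc_curve(spec, length, n=800)
    dz = spacing[0]
    # per-axis extents the phantom needs (tube plus bone blocks)
    bone_reach = spec.bone_depth + spec.bone_halfwidth
    need = np.array([
        1.5 * dz + spec.tube_radius,                 # z half-extent of bone slab
        spec.tube_radius + bone_reach,
        spec.tube_radius + bone_reach,
    ])
    lo_need = curve.min(axis=0) - need
    hi_need = curve.max(axis=0) + need
    if np.any(lo_need < -0.5 * spacing) or np.any(
        hi_need > (np.asarray(spec.shape) - 0.5) * spacing
    ):
        raise ValueError("phantom geometry does not fit inside the grid with margin")

    def subgrid(lo_pt: np.ndarray, hi_pt: np.ndarray):
        lo_idx = np.maximum(np.floor(lo_pt / spacing).astype(int), 0)
        hi_idx = np.minimum(np.ceil(hi_pt / spacing).astype(int) + 1, spec.shape)
        axes = [np.arange(lo_idx[a], hi_idx[a]) * spacing[a] for a in range(3)]
        zz, yy, xx = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([zz, yy, xx], axis=-1).reshape(-1, 3)
        sl = tuple(slice(lo_idx[a], hi_idx[a]) for a in range(3))
        return pts, sl, zz.shape

    labels = np.zeros(spec.shape, dtype=np.int16)
    t2_field = np.full(spec.shape, np.nan)
    subreg = np.zeros(spec.shape, dtype=np.int8)

    pad = spec.tube_radius + 1.0
    sub_pts, sub_slice, sub_shape = subgrid(curve.min(axis=0) - pad, curve.max(axis=0) + pad)
    dist, nearest = cKDTree(curve).query(sub_pts)
    interior = (nearest > 0) & (nearest < len(curve) - 1)  # flat end caps
    tube = (dist <= spec.tube_radius) & interior
    s_vox = s_curve[nearest]

    tube3 = tube.reshape(sub_shape)
    labels[sub_slice][tube3] = 1  # PCL

    s_tube = s_vox[tube]
    base = _smooth_profile(s_tube, length, t2_means, spec.transition_mm)
    sd = _smooth_profile(s_tube, length, t2_sds, spec.transition_mm)
    noise_t2 = rng.normal(0.0, 1.0, s_tube.shape) * sd
    t2_tube = np.maximum(base + noise_t2, spec.t2_floor)
    # recenter per subregion so ground-truth means hit the targets
    frac = s_tube / length
    sub_code = np.where(frac < 0.25, 1, np.where(frac < 0.75, 2, 3))
    for code, target in zip((1, 2, 3), t2_means):
        sel = sub_code == code
        if sel.any():
            t2_tube[sel] -= t2_tube[sel].mean() - target
    t2_tube = np.maximum(t2_tube, spec.t2_floor / 2)

    t2_sub = np.full(sub_shape, np.nan)
    t2_sub[tube3] = t2_tube
    sub_lab = np.zeros(sub_shape, dtype=np.int8)
    sub_lab[tube3] = sub_code
    t2_field[sub_slice] = t2_sub
    subreg[sub_slice] = sub_lab

    # bone blocks across planar interfaces at both tube ends
    interfaces: dict[str, dict] = {}
    tilt = np.deg2rad(spec.interface_angle_deg)
    for site, endpoint, tangent, bone_label in (
        ("femoral", curve[0], curve[0] - curve[1], 3),
        ("tibial", curve[-1], curve[-1] - curve[-2], 4),
    ):
        t_hat = tangent / np.linalg.norm(tangent)
        # in-plane rotation of the outward normal by the interface tilt
        c, snt = np.cos(tilt), np.sin(tilt)
        n_hat = np.array([
            t_hat[0],
            c * t_hat[1] - snt * t_hat[2],
            snt * t_hat[1] + c * t_hat[2],
        ])
        half = np.array([1.5 * spacing[0] + spec.tube_radius, bone_reach, bone_reach])
        pts_b, sl_b, shape_b = subgrid(endpoint - half, endpoint + half)
        rel = pts_b - endpoint
        along = rel @ n_hat
        perp = rel - np.outer(along, n_hat)
        in_block = (
            (along > 0)
            & (along <= spec.bone_depth)
            & (np.linalg.norm(perp * np.array([0, 1, 1]), axis=1) <= spec.bone_halfwidth)
            & (np.abs(rel[:, 0]) <= 1.5 * spacing[0] + spec.tube_radius)
        )
        blk = in_block.reshape(shape_b) & (labels[sl_b] == 0)
        labels[sl_b][blk] = bone_label
        tf = t2_field[sl_b]
        tf[blk] = spec.bone_t2
        t2_field[sl_b] = tf
        interfaces[site] = {"point": endpoint.tolist(), "normal": n_hat.tolist()}

    # signal synthesis
    te = np.asarray(spec.echo_times)
    signal = np.zeros((len(te),) + spec.shape)
    labeled = labels > 0
    t2_all = t2_field[labeled]
    decay = spec.s0 * np.exp(-te[:, None] / t2_all)
    signal[:, labeled] = decay

    sigma = spec.noise_sigma_frac * spec.s0
    if sigma > 0:
        # noise within an inflated bounding box around the labeled voxels
        pad = np.ceil(noise_margin_mm / spacing).astype(int)
        nzi = np.argwhere(labeled)
        blo = np.maximum(nzi.min(axis=0) - pad, 0)
        bhi = np.minimum(nzi.max(axis=0) + pad + 1, spec.shape)
        box = (slice(None),) + tuple(slice(blo[a], bhi[a]) for a in range(3))
        shape_box = signal[box].shape
        if spec.noise_model == "gaussian":
            signal[box] = np.abs(signal[box] + rng.normal(0, sigma, shape_box))
        else:  # rician magnitude
            re = signal[box] + rng.normal(0, sigma, shape_box)
            im = rng.normal(0, sigma, shape_box)
            signal[box] = np.hypot(re, im)

    volume = MultiEchoVolume(
        signal=signal, echo_times=te, voxel_spacing=spec.voxel_spacing,
        specimen_id=specimen_id, configuration=configuration,
    )
    mask = LabelMask(labels=labels, voxel_spacing=spec.voxel_spacing)
    gt_means = tuple(float(t2_tube[sub_code == c].mean()) for c in (1, 2, 3))
    truth = GroundTruth(
        t2_field=t2_field, subregion_labels=subreg, curve_points=curve,
        length=float(s_curve[-1]), subregion_means=gt_means,
        interfaces=interfaces, spec=spec, configuration=configuration,
    )
    return volume, mask, truth


def generate_cohort(
    spec: PhantomSpec,
    n: int = 10,
    variation: CohortVariation | None = None,
    seed: int | None = None,
    out_dir: Path | str | None = None,
    null_loading: bool = False,
) -> list[SpecimenData] | StudyManifest:
    """Generate a paired cohort of ``n`` specimens.

    Each specimen draws one shared offset per metric (length, subregion
    T2 means) from the between-specimen distribution and applies it to
    both configurations; child RNGs are spawned deterministically from
    the master seed. With ``null_loading`` the loaded configuration
    reuses the unloaded parameters (no true effect), for type-I-error
    checks.

    Returns in-memory :class:`SpecimenData` records, or, when
    ``out_dir`` is given, writes volumes/masks/sidecars plus a manifest
    CSV and returns the :class:`StudyManifest`.
    """
    if n < 2:
        raise ValueError("cohort needs n >= 2")
    variation = variation or CohortVariation()
    master = np.random.SeedSequence(spec.seed if seed is None else seed)
    specimens: list[SpecimenData] = []
    records: list[ManifestRecord] = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    for i, child in enumerate(master.spawn(n)):
        rng = np.random.default_rng(child)
        sid = f"S{i + 1:02d}"
        dlen = rng.normal(0, variation.length_sd)
        dt2 = rng.normal(0, variation.t2_mean_sd)
        means_d0 = tuple(np.array(spec.t2_means_d0) + dt2)
        means_d1 = tuple(np.array(spec.t2_means_d1) + dt2)
        s = replace(
            spec,
            unloaded_length=spec.unloaded_length + dlen,
            loaded_length=spec.loaded_length + dlen,
            t2_means_d0=means_d0,
            t2_means_d1=means_d1 if not null_loading else means_d0,
        )
        if null_loading:
            s = replace(s, loaded_length=s.unloaded_length,
                        t2_texture_sd_d1=s.t2_texture_sd_d0)
        d0 = generate_phantom(s, Configuration.UNLOADED_D0, sid, rng)
        d1 = generate_phantom(s, Configuration.LOADED_D1, sid, rng)
        specimens.append(SpecimenData(specimen_id=sid, d0=d0, d1=d1))
        if out is not None:
            for cfg_name, (vol, msk, _) in (("d0", d0), ("d1", d1)):
                vpath = out / f"{sid}_{cfg_name}_echo.nii"
                mpath = out / f"{sid}_{cfg_name}_mask.nii"
                write_multiecho(vol, vpath)
                write_mask(msk, mpath)
                records.append(ManifestRecord(sid, Configuration(cfg_name), vpath, mpath))

    if out is not None:
        manifest = StudyManifest(records)
        manifest.to_csv(out / "manifest.csv")
        return manifest
    return specimens
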