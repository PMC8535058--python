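"""Masked gray-level co-occurrence matrices and Haralick texture features.

GLCMs are accumulated slice-by-slice over an ROI of the T2 map at a
1-pixel offset in the four in-plane orientations (0°, 45°, 90°, 135°);
a pair counts only when both pixels are valid ROI members. Counts are
pooled (summed) across orientations and slices before normalization,
and symmetric accumulation records each pair in both orders. Offsets
are in-plane only: the ~8x slice anisotropy of the acquisition makes
through-plane co-occurrence non-comparable.

Quantization default is INTEGER_MS: T2 rounded to the nearest
millisecond and saturated to [0, 80] ms, so gray levels are ms and the
GLCM marginal variance sits on the same scale as the squared ROI SD.

Features (p = counts / n_pairs, i, j gray levels, px the row marginal,
mu its mean):

    entropy     = -sum p log2 p          (bits; 0 log 0 = 0)
    contrast    =  sum (i - j)^2 p
    homogeneity =  sum p / (1 + |i - j|)
    variance    =  sum (i - mu)^2 px
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import T2Map

__all__ = ["GlcmConfig", "GlcmAccumulator", "TextureFeatures",
           "accumulate_glcm", "texture_features", "quantize_t2"]

# orientation -> (dy, dx) pixel offset for the "forward" pair direction
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass
class GlcmConfig:
    orientations: tuple[int, ...] = (0, 45, 90, 135)
    offset: int = 1
    quantization: str = "integer_ms"  # or "fixed_bins"
    n_bins: int = 81
    t2_range: tuple[float, float] = (0.0, 80.0)
    symmetric: bool = True
    log_base: float = 2.0

    def __post_init__(self) -> None:
        if self.offset < 1:
            raise ValueError("offset must be >= 1")
        if not self.orientations:
            raise ValueError("need at least one orientation")
        for o in self.orientations:
            if o not in _OFFSETS:
                raise ValueError(f"unsupported orientation {o}; use 0/45/90/135")


@dataclass
class GlcmAccumulator:
    """Pooled co-occurrence counts over gray levels.

    ``levels[i]`` is the gray value of row/column i; with INTEGER_MS
    quantization levels are 0..80 ms.
    """

    counts: np.ndarray
    levels: np.ndarray

    @property
    def n_pairs(self) -> int:
        return int(self.counts.sum())

    @property
    def empty(self) -> bool:
        return self.n_pairs == 0

    def probabilities(self) -> np.ndarray:
        if self.empty:
            raise ValueError("empty accumulator has no probability distribution")
        return self.counts / self.counts.sum()


@dataclass
class TextureFeatures:
    entropy: float
    contrast: float
    homogeneity: float
    variance: float

    def as_dict(self) -> dict[str, float]:
        return {"entropy": self.entropy, "contrast": self.contrast,
                "homogeneity": self.homogeneity, "variance": self.variance}


def quantize_t2(t2: np.ndarray, cfg: GlcmConfig) -> np.ndarray:
    """Map T2 values (ms) to integer gray levels; NaN-safe (NaN -> 0, to
    be masked out by validity)."""
    lo, hi = cfg.t2_range
    vals = np.nan_to_num(t2, nan=lo)
    if cfg.quantization == "integer_ms":
        return np.clip(np.rint(vals), lo, hi).astype(np.int64) - int(lo)
    if cfg.quantization == "fixed_bins":
        scaled = (vals - lo) / (hi - lo) * cfg.n_bins
        return np.clip(scaled.astype(np.int64), 0, cfg.n_bins - 1)
    raise ValueError(f"unknown quantization {cfg.quantization!r}")


def _n_levels(cfg: GlcmConfig) -> int:
    if cfg.quantization == "integer_ms":
        return int(cfg.t2_range[1] - cfg.t2_range[0]) + 1
    return cfg.n_bins


def accumulate_glcm(
    t2map: T2Map,
    roi: np.ndarray,
    cfg: GlcmConfig | None = None,
) -> GlcmAccumulator:
    """Accumulate co-occurrence counts over all slices of an ROI.

    Pairs require both members valid and inside the ROI; counts from the
    four orientations and all slices are summed into one matrix. If no
    two adjacent valid pixels exist in any orientation, returns an empty
    accumulator with a warning.
    """
    cfg = cfg or GlcmConfig()
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("roi is empty")
    ok = roi & t2map.valid
    L = _n_levels(cfg)
    q = quantize_t2(t2map.t2, cfg)
    counts = np.zeros((L, L), dtype=np.int64)
    d = cfg.offset
    for z in range(ok.shape[0]):
        m = ok[z]
        if m.sum() < 2:
            continue
        g = q[z]
        for o in cfg.orientations:
            dy, dx = (_OFFSETS[o][0] * d, _OFFSETS[o][1] * d)
            ys = slice(max(0, -dy), m.shape[0] - max(0, dy))
            xs = slice(max(0, -dx), m.shape[1] - max(0, dx))
            ys2 = slice(max(0, dy), m.shape[0] - max(0, -dy))
            xs2 = slice(max(0, dx), m.shape[1] - max(0, -dx))
            both = m[ys, xs] & m[ys2, xs2]
            if not both.any():
                continue
            a = g[ys, xs][both]
            b = g[ys2, xs2][both]
            np.add.at(counts, (a, b), 1)
            if cfg.symmetric:
                np.add.at(counts, (b, a), 1)
    if counts.sum() == 0:
        warnings.warn("no valid co-occurring pixel pairs in ROI; empty GLCM")
    levels = np.arange(L, dtype=np.float64) + (cfg.t2_range[0] if cfg.quantization == "integer_ms" else 0.0)
    return GlcmAccumulator(counts=counts, levels=levels)


def texture_features(acc: GlcmAccumulator, log_base: float = 2.0) -> TextureFeatures:
    """The four Haralick-style features of a normalized GLCM.

    Raises on an empty accumulator. For a constant image all mass sits
    on the diagonal cell: entropy 0, contrast 0, homogeneity 1,
    variance 0.
    """
    if acc.empty:
        raise ValueError("cannot compute texture features of an empty GLCM")
    p = acc.probabilities()
    i = acc.levels[:, None]
    j = acc.levels[None, :]
    nz = p > 0
    entropy = float(-(p[nz] * np.log(p[nz]) / np.log(log_base)).sum())
    contrast = float(((i - j) ** 2 * p).sum())
    homogeneity = float((p / (1.0 + np.abs(i - j))).sum())
    px = p.sum(axis=1)
    mu = float((acc.levels * px).sum())
    variance = float(((acc.levels - mu) ** 2 * px).sum())
    return TextureFeatures(entropy=entropy, contrast=contrast,
                           homogeneity=homogeneity, variance=variance)
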