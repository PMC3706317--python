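"""Comparison Map Profile (CMP): multiscale moving-window map comparison.

Two co-registered rasters are compared inside a circular window centred on
every valid cell, at window radii ("scales") 1..max_scale.  Three indices
are supported:

``kappa``
    Cohen's kappa between two presence/absence maps — chance-corrected
    agreement within the window.
``D``
    Mean absolute difference between two standardized continuous maps —
    absolute disagreement, 0 (identical) to 1 (opposite extremes).
``CC``
    Pearson cross-correlation of the paired window values — shared
    gradients and pattern, regardless of absolute level.

Each scale yields a *monoscale map* (the index at every window centre);
averaging a monoscale map over its defined centres gives one point of the
*index profile*; averaging the monoscale maps pixel by pixel gives the
*multiscale map*.  Monoscale 0 denotes the single whole-map statistic
(pixel-by-pixel comparison), reported separately as ``global_0`` — a
radius-0 window cannot support kappa or a correlation.

Windowed sums are computed by convolution with the disc kernel (FFT-backed
for large grids); integer counts are recovered exactly by rounding.  The
contract is the brute-force window-enumeration result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .evaluation import cohen_kappa, confusion
from .grids import BinaryMap, ScoreMap, assert_coregistered

__all__ = [
    "WindowSpec",
    "CmpResult",
    "window_offsets",
    "disc_kernel",
    "window_extent_degrees",
    "monoscale_kappa",
    "monoscale_distance",
    "monoscale_cc",
    "global_index",
    "run_cmp",
    "INDEX_NAMES",
]

INDEX_NAMES = ("kappa", "D", "CC")

#: a window centre is defined only if at least this fraction of the full
#: disc is valid ...
DEFAULT_MIN_VALID_FRACTION = 0.5
#: ... and never with fewer than this many valid cells.
MIN_VALID_CELLS = 3

# relative guard against spurious variance from convolution round-off when
# deciding that a window is constant (CC undefined there)
_VAR_EPS = 1e-9


def disc_kernel(scale: int) -> np.ndarray:
    """Boolean (2*scale+1)^2 stencil of the Euclidean disc d^2 <= scale^2."""
    if scale < 0:
        raise ValueError("scale must be >= 0")
    r = np.arange(-scale, scale + 1)
    dr, dc = np.meshgrid(r, r, indexing="ij")
    return (dr * dr + dc * dc) <= scale * scale


@dataclass(frozen=True)
class WindowSpec:
    """The circular window at one scale: radius plus its integer offsets."""

    scale: int
    offsets: tuple[tuple[int, int], ...]

    @property
    def size(self) -> int:
        return len(self.offsets)


def window_offsets(scale: int) -> WindowSpec:
    """All integer (d_row, d_col) with d_row^2 + d_col^2 <= scale^2.

    Scale 0 is the single centre cell; scale 1 adds the 4-neighbourhood
    (5 offsets); scale 2 has 13.
    """
    k = disc_kernel(scale)
    rows, cols = np.nonzero(k)
    offs = tuple(
        (int(r) - scale, int(c) - scale) for r, c in zip(rows, cols)
    )
    return WindowSpec(scale=scale, offsets=offs)


def window_extent_degrees(scale: int, cell_size: float) -> float:
    """Edge length in degrees of the bounding box of the scale-s window.

    ``(2*scale + 1) * cell_size``: at 10-arcmin cells the scale-1 window
    spans 0.5 degrees and the scale-20 window about 7 degrees (the "8 x 8
    degree" order of magnitude quoted for continental-scale gradients).
    """
    return (2 * scale + 1) * cell_size


# ---------------------------------------------------------------------------
# windowed sums
# ---------------------------------------------------------------------------

def _conv(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    # the disc is symmetric, so convolution equals correlation
    return signal.convolve(x, kernel.astype(float), mode="same", method="auto")


def _counts(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Exact integer windowed sums of a 0/1 field."""
    return np.rint(_conv(x.astype(float), kernel))


def _quota(scale: int, min_valid_fraction: float) -> int:
    full = int(disc_kernel(scale).sum())
    return max(MIN_VALID_CELLS, math.ceil(min_valid_fraction * full))


def _check_scale(scale: int) -> None:
    if scale < 1:
        raise ValueError("monoscale maps require scale >= 1")


def monoscale_kappa(
    a: BinaryMap,
    b: BinaryMap,
    scale: int,
    min_valid_fraction: float = DEFAULT_MIN_VALID_FRACTION,
) -> np.ndarray:
    """Window-wise Cohen's kappa at one scale; NaN where undefined.

    Windows are clipped at the grid edge and invalid cells are excluded;
    a centre with fewer valid cells than the quota, or itself invalid, is
    NaN.  When both window samples are constant *and identical* kappa is 1
    (and 0 when constant but different), matching the whole-map degenerate
    rule.
    """
    assert_coregistered(a, b)
    _check_scale(scale)
    k = disc_kernel(scale)
    m = a.mask.astype(float)
    av = a.values.astype(float) * m
    bv = b.values.astype(float) * m
    n = _counts(m, k)
    na = _counts(av, k)
    nb = _counts(bv, k)
    n11 = _counts(av * bv, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_o = (n11 + (n - na - nb + n11)) / n
        p_e = (na * nb + (n - na) * (n - nb)) / (n * n)
        kappa = (p_o - p_e) / (1.0 - p_e)
    both_constant_same = ((na == 0) & (nb == 0)) | ((na == n) & (nb == n))
    kappa = np.where(both_constant_same, 1.0, kappa)
    defined = a.mask & (n >= _quota(scale, min_valid_fraction))
    return np.where(defined, kappa, np.nan)


def monoscale_distance(
    a: ScoreMap,
    b: ScoreMap,
    scale: int,
    min_valid_fraction: float = DEFAULT_MIN_VALID_FRACTION,
) -> np.ndarray:
    """Window-wise mean absolute difference at one scale; NaN where undefined."""
    assert_coregistered(a, b)
    _check_scale(scale)
    k = disc_kernel(scale)
    m = a.mask.astype(float)
    n = _counts(m, k)
    s = _conv(np.abs(a.values - b.values) * m, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = s / n
    defined = a.mask & (n >= _quota(scale, min_valid_fraction))
    return np.where(defined, d, np.nan)


def monoscale_cc(
    a: ScoreMap,
    b: ScoreMap,
    scale: int,
    min_valid_fraction: float = DEFAULT_MIN_VALID_FRACTION,
) -> np.ndarray:
    """Window-wise Pearson correlation at one scale; NaN where undefined.

    A centre is additionally undefined when either window sample has
    (numerically) zero variance.
    """
    assert_coregistered(a, b)
    _check_scale(scale)
    k = disc_kernel(scale)
    m = a.mask.astype(float)
    av = a.values * m
    bv = b.values * m
    n = _counts(m, k)
    sa = _conv(av, k)
    sb = _conv(bv, k)
    saa = _conv(av * av, k)
    sbb = _conv(bv * bv, k)
    sab = _conv(av * bv, k)
    var_a = n * saa - sa * sa
    var_b = n * sbb - sb * sb
    cov = n * sab - sa * sb
    guard = _VAR_EPS * np.maximum(n * n, 1.0)
    nondegenerate = (var_a > guard) & (var_b > guard)
    with np.errstate(invalid="ignore", divide="ignore"):
        cc = cov / np.sqrt(np.where(nondegenerate, var_a * var_b, 1.0))
    cc = np.clip(cc, -1.0, 1.0)
    defined = a.mask & (n >= _quota(scale, min_valid_fraction)) & nondegenerate
    return np.where(defined, cc, np.nan)


# ---------------------------------------------------------------------------
# whole-map (monoscale 0) statistics
# ---------------------------------------------------------------------------

def global_index(
    a: ScoreMap | BinaryMap, b: ScoreMap | BinaryMap, index_name: str
) -> float:
    """The pixel-by-pixel (monoscale 0) statistic over all valid cells.

    kappa_0 = whole-map Cohen's kappa; D_0 = mean |a - b|; CC_0 = whole-map
    Pearson correlation (zero variance in either map raises).
    """
    assert_coregistered(a, b)
    if index_name == "kappa":
        return cohen_kappa(confusion(_as_binary(a), _as_binary(b)))
    va = a.valid_values().astype(float)
    vb = b.valid_values().astype(float)
    if index_name == "D":
        return float(np.abs(va - vb).mean())
    if index_name == "CC":
        if va.std() == 0 or vb.std() == 0:
            raise ValueError("CC_0 undefined: a map has zero variance")
        return float(np.corrcoef(va, vb)[0, 1])
    raise ValueError(f"unknown index {index_name!r}; expected one of {INDEX_NAMES}")


def _as_binary(m: ScoreMap | BinaryMap) -> BinaryMap:
    if isinstance(m, BinaryMap):
        return m
    return BinaryMap(m.meta, np.rint(m.values).astype(np.int8), m.mask)


# ---------------------------------------------------------------------------
# the full profile
# ---------------------------------------------------------------------------

_MONOSCALE_FN = {
    "kappa": monoscale_kappa,
    "D": monoscale_distance,
    "CC": monoscale_cc,
}


@dataclass
class CmpResult:
    """Output of one CMP run for a single index.

    Attributes
    ----------
    index_name
        "kappa", "D" or "CC".
    scales
        The window radii computed, 1..max_scale.
    monoscale_maps
        One 2-D array per scale, NaN at undefined centres.
    profile
        Per-scale mean over defined centres.
    multiscale_map
        Pixel-wise mean over the scales where the pixel is defined; NaN
        where undefined at every scale.
    global_0
        The whole-map (monoscale 0) statistic.
    """

    index_name: str
    scales: list[int]
    monoscale_maps: list[np.ndarray]
    profile: np.ndarray
    multiscale_map: np.ndarray
    global_0: float
    mask: np.ndarray = field(repr=False, default=None)

    @property
    def profile_mean(self) -> float:
        """Mean of the profile over all computed scales ("Kappa_mean" etc.)."""
        return float(np.nanmean(self.profile))

    def profile_over(self, min_scale: int) -> float:
        """Mean profile value over scales >= ``min_scale``."""
        sel = [p for s, p in zip(self.scales, self.profile) if s >= min_scale]
        return float(np.nanmean(sel))

    def to_frame(self):
        """The profile as a (scale, index) pandas DataFrame for CSV export."""
        import pandas as pd

        return pd.DataFrame({"scale": self.scales, self.index_name: self.profile})


def run_cmp(
    a: ScoreMap | BinaryMap,
    b: ScoreMap | BinaryMap,
    index_name: str,
    max_scale: int = 20,
    min_valid_fraction: float = DEFAULT_MIN_VALID_FRACTION,
) -> CmpResult:
    """Run the full CMP for one index over scales 1..max_scale.

    ``kappa`` expects two binary maps; ``D`` and ``CC`` expect standardized
    continuous maps.  The profile entry at each scale is the mean of the
    monoscale map over its defined centres; profile and profile_mean cover
    scales 1..max_scale only, with the pixel-by-pixel statistic reported
    separately as ``global_0``.
    """
    if index_name not in INDEX_NAMES:
        raise ValueError(f"unknown index {index_name!r}; expected one of {INDEX_NAMES}")
    if max_scale < 1:
        raise ValueError("max_scale must be >= 1")
    if index_name == "kappa":
        a, b = _as_binary(a), _as_binary(b)
    fn = _MONOSCALE_FN[index_name]
    scales = list(range(1, max_scale + 1))
    maps: list[np.ndarray] = []
    profile = np.empty(len(scales))
    for i, s in enumerate(scales):
        ms = fn(a, b, s, min_valid_fraction)
        maps.append(ms)
        defined = ~np.isnan(ms)
        profile[i] = ms[defined].mean() if defined.any() else np.nan
    stack = np.stack(maps)
    n_defined = (~np.isnan(stack)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        multiscale = np.where(
            n_defined > 0, np.nansum(stack, axis=0) / n_defined, np.nan
        )
    return CmpResult(
        index_name=index_name,
        scales=scales,
        monoscale_maps=maps,
        profile=profile,
        multiscale_map=multiscale,
        global_0=global_index(a, b, index_name),
        mask=a.mask.copy(),
    )
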