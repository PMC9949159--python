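"""Rolony spot detection in 4-channel sequencing image stacks.

Rolonies appear as 3–7 px diffraction-limited blobs whose z-profile is
continuous (the brightest planes are neighbours), which distinguishes them
from fixed-pattern noise.  The detector therefore works on a *floor-
subtracted* projection (max over z minus the 3rd-lowest plane, per pixel),
standardizes channel intensities by z-scoring against sampled local maxima,
and accepts a local maximum as a dot only if

1. the brightest z-plane at the pixel neighbours the 2nd (or 3rd) brightest,
2. its channel is the brightest of the four both before and after
   intensity correction,
3. the channel-purity ratio (2nd-max channel / max channel) is < 0.95, and
4. the corrected intensity passes a threshold.

Accepted dots get subpixel positions from quadratic interpolation of the
3×3 neighbourhood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.feature import peak_local_max
from skimage.morphology import disk


@dataclass
class ImageStack:
    """One 4-channel z-stack: ``intensities`` shape (4, z, y, x)."""

    intensities: np.ndarray
    pixel_size: float = 0.55  # μm
    z_step: float = 3.0  # μm
    tile_id: int = 0
    cycle_id: int = 1

    def __post_init__(self) -> None:
        a = np.asarray(self.intensities, dtype=float)
        if a.ndim != 4 or a.shape[0] != 4:
            raise ValueError("intensities must have shape (4, z, y, x)")
        if np.any(a < 0):
            raise ValueError("intensities must be non-negative")
        self.intensities = a


@dataclass
class DetectParams:
    """Detection knobs; defaults mirror the standard acquisition."""

    suppression_diameter: int = 5  # px, local-maximum neighbourhood
    ratio_max: float = 0.95  # strict upper bound on 2nd-max/max channel
    # accept maxima within 3 SD below the typical local-maximum intensity;
    # after z-scoring the maxima sample sits at ~N(0, 1)
    threshold: float = -3.0
    min_maxima_for_correction: int = 50
    neighbor_mode: str = "either"  # z-criterion: 1st max adjacent to 2nd OR 3rd ("both" available)
    correction: "ChannelCorrection | None" = None


def floor_subtracted_projection(stack: ImageStack) -> np.ndarray:
    """Per channel and pixel: max over z minus the 3rd-lowest plane, >= 0.

    Pixels without a rolony have a discontinuous/flat z-profile, so this
    local background subtraction removes fixed-pattern noise, nuclear and
    tissue background while preserving blob peaks.
    """
    a = stack.intensities
    if a.shape[1] < 3:
        raise ValueError("floor subtraction needs at least 3 z-planes")
    part = np.partition(a, 2, axis=1)
    floor3 = part[:, 2]  # 3rd-smallest along z
    return np.clip(a.max(axis=1) - floor3, 0, None)


@dataclass
class ChannelCorrection:
    """Per-channel standardization (and optional linear unmixing)."""

    mean: np.ndarray  # (4,)
    sd: np.ndarray  # (4,)
    mixing: np.ndarray | None = None  # (4, 4), columns = source channel
    identity: bool = False

    def apply(self, images: np.ndarray) -> np.ndarray:
        """Correct (4, y, x) channel images: unmix, then z-score."""
        out = np.asarray(images, dtype=float)
        if self.mixing is not None:
            flat = out.reshape(4, -1)
            out = np.clip(np.linalg.solve(self.mixing, flat), 0, None).reshape(out.shape)
        if self.identity:
            return out
        return (out - self.mean[:, None, None]) / self.sd[:, None, None]


def _local_maxima(img: np.ndarray, diameter: int) -> np.ndarray:
    foot = disk(diameter // 2)
    peaks = peak_local_max(img, footprint=foot, exclude_border=False,
                           threshold_abs=None, threshold_rel=None)
    # deterministic order: (y, x) lexicographic
    if len(peaks):
        peaks = peaks[np.lexsort((peaks[:, 1], peaks[:, 0]))]
    return peaks


def correct_channel_intensities(
    images: np.ndarray,
    min_maxima: int = 50,
    suppression_diameter: int = 5,
    unmix: bool = False,
    purity_ratio: float = 0.5,
) -> tuple[np.ndarray, ChannelCorrection]:
    """Standardize channel images by the statistics of their local maxima.

    Local-maxima intensities are sampled per channel; each channel is then
    z-scored by the sample mean/SD, removing channel-to-channel and
    batch-to-batch intensity differences.  With ``unmix=True``, a linear
    bleed-through matrix is estimated from maxima whose off-channel ratio
    is below ``purity_ratio`` and inverted before standardization.  When a
    channel yields fewer than ``min_maxima`` maxima the correction falls
    back to identity (with a warning).
    """
    images = np.asarray(images, dtype=float)
    samples: list[np.ndarray] = []
    coords: list[np.ndarray] = []
    for c in range(4):
        peaks = _local_maxima(images[c], suppression_diameter)
        coords.append(peaks)
        samples.append(images[c][peaks[:, 0], peaks[:, 1]] if len(peaks) else np.array([]))

    mixing = None
    if unmix:
        M = np.eye(4)
        for c in range(4):
            pk = coords[c]
            if len(pk) == 0:
                continue
            vals = images[:, pk[:, 0], pk[:, 1]]  # (4, n)
            dominant = np.argmax(vals, axis=0) == c
            with np.errstate(divide="ignore", invalid="ignore"):
                ratios = vals / vals[c]
            off = np.delete(np.arange(4), c)
            pure = dominant & (np.nanmax(ratios[off], axis=0) < purity_ratio)
            if pure.sum() >= 5:
                M[:, c] = np.nanmedian(ratios[:, pure], axis=1)
                M[c, c] = 1.0
        mixing = M

    n_min = min(len(s) for s in samples)
    if n_min < min_maxima or any(np.std(s) == 0 for s in samples if len(s)):
        warnings.warn(
            f"only {n_min} local maxima in the weakest channel; "
            "falling back to identity intensity correction",
            stacklevel=2,
        )
        corr = ChannelCorrection(mean=np.zeros(4), sd=np.ones(4),
                                 mixing=mixing, identity=True)
    else:
        corr = ChannelCorrection(
            mean=np.array([s.mean() for s in samples]),
            sd=np.array([s.std() for s in samples]),
            mixing=mixing,
        )
    return corr.apply(images), corr


def _subpixel_offset(patch: np.ndarray) -> tuple[float, float]:
    """Quadratic (parabolic) peak interpolation on a 3×3 neighbourhood."""
    def axis_offset(m1: float, c0: float, p1: float) -> float:
        denom = m1 - 2 * c0 + p1
        if denom >= 0:  # not a concave peak; stay on the pixel
            return 0.0
        return float(np.clip(0.5 * (m1 - p1) / denom, -0.5, 0.5))

    dy = axis_offset(patch[0, 1], patch[1, 1], patch[2, 1])
    dx = axis_offset(patch[1, 0], patch[1, 1], patch[1, 2])
    return dy, dx


def _z_criterion(zprof: np.ndarray, mode: str) -> bool:
    order = np.argsort(zprof, kind="stable")[::-1]
    p1, p2, p3 = int(order[0]), int(order[1]), int(order[2]) if len(order) > 2 else int(order[1])
    adj2 = abs(p1 - p2) == 1
    adj3 = abs(p1 - p3) == 1
    if mode == "both":
        return adj2 and adj3
    return adj2 or adj3


def write_image_stack(path, stack: ImageStack) -> None:
    """Write a 4-channel z-stack as a multi-page TIFF (CZYX page order)."""
    import tifffile

    tifffile.imwrite(path, stack.intensities.astype(np.float32),
                     metadata={"axes": "CZYX", "pixel_size_um": stack.pixel_size,
                               "z_step_um": stack.z_step})


def read_image_stack(path, pixel_size: float = 0.55, z_step: float = 3.0,
                     tile_id: int = 0, cycle_id: int = 1) -> ImageStack:
    """Read a multi-page TIFF written by :func:`write_image_stack`."""
    import tifffile

    arr = np.asarray(tifffile.imread(path), dtype=float)
    return ImageStack(intensities=arr, pixel_size=pixel_size, z_step=z_step,
                      tile_id=tile_id, cycle_id=cycle_id)


def detect_dots(stack: ImageStack, params: DetectParams | None = None) -> pd.DataFrame:
    """Detect rolony dots in one stack.

    Returns a DataFrame with columns x, y (subpixel, pixels), channel
    (1..4), intensity (corrected value at the peak), ratio2nd, cycle, tile.
    All four acceptance criteria from the module docstring are enforced; no
    two returned dots of the same channel are closer than the suppression
    diameter.
    """
    if params is None:
        params = DetectParams()
    raw_proj = floor_subtracted_projection(stack)
    if params.correction is not None:
        corrected = params.correction.apply(raw_proj)
    else:
        corrected, _ = correct_channel_intensities(
            raw_proj, min_maxima=params.min_maxima_for_correction,
            suppression_diameter=params.suppression_diameter,
        )
    H, W = raw_proj.shape[1:]
    rows = []
    for c in range(4):
        peaks = _local_maxima(corrected[c], params.suppression_diameter)
        for py, px in peaks:
            if raw_proj[c, py, px] <= 0:
                continue  # flat/zero plateau, not a real peak
            zprof = stack.intensities[c, :, py, px]
            if not _z_criterion(zprof, params.neighbor_mode):
                continue  # criterion 1: brightest planes must neighbour
            raw_ch = raw_proj[:, py, px]
            cor_ch = corrected[:, py, px]
            if np.argmax(raw_ch) != c or np.argmax(cor_ch) != c:
                continue  # criterion 2: dominant before and after correction
            top = raw_ch[c]
            second = np.partition(raw_ch, 2)[2]
            ratio2nd = float(np.clip(second / top, 0, 1)) if top > 0 else 1.0
            if not ratio2nd < params.ratio_max:
                continue  # criterion 3, strict inequality
            if cor_ch[c] < params.threshold:
                continue  # criterion 4
            y0, y1 = max(py - 1, 0), min(py + 2, H)
            x0, x1 = max(px - 1, 0), min(px + 2, W)
            patch = np.zeros((3, 3))
            patch[y0 - py + 1:y1 - py + 1, x0 - px + 1:x1 - px + 1] = \
                raw_proj[c, y0:y1, x0:x1]
            dy, dx = _subpixel_offset(patch)
            rows.append((px + dx, py + dy, c + 1, float(cor_ch[c]), ratio2nd))
    out = pd.DataFrame(rows, columns=["x", "y", "channel", "intensity", "ratio2nd"])
    out["cycle"] = stack.cycle_id
    out["tile"] = stack.tile_id
    return out
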