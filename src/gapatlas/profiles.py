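"""Extraction of 1-D expression profiles from embryo images.

Given a 2-D intensity image and a binary embryo mask, the antero-posterior
(A-P) axis is found as the principal axis of the mask, a strip covering a
fixed fraction (default 10%) of the local dorso-ventral extent is taken
along the D-V midline, and the strip intensity is binned into a profile on
a percent-egg-length grid (0% = anterior pole).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "EmbryoImage",
    "IntensityProfile",
    "AxisFrame",
    "find_ap_axis",
    "extract_strip",
    "profile_from_strip",
    "normalise_profile",
    "extract_profile",
]


@dataclass
class IntensityProfile:
    """Expression intensity versus % A-P position for one embryo/gene."""

    positions: np.ndarray
    values: np.ndarray
    gene: str = "unknown"
    embryo_id: str = "unknown"
    time_class: str | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values must have the same length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def spacing(self) -> float:
        return float(np.median(np.diff(self.positions)))


@dataclass
class EmbryoImage:
    """A 2-D embryo image with its binary mask and staging metadata.

    ``inverted_stain`` marks bright-field images of dark (colorimetric)
    stains, where low pixel values mean high expression.
    """

    pixels: np.ndarray
    mask: np.ndarray
    gene: str = "unknown"
    embryo_id: str = "unknown"
    time_class: str | None = None
    anterior_left: bool = True
    dorsal_up: bool = True
    inverted_stain: bool = False

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.pixels.shape != self.mask.shape:
            raise ValueError("pixels and mask must share dimensions")
        if not self.mask.any():
            raise ValueError("mask is empty")


@dataclass
class AxisFrame:
    """The embryo's A-P coordinate frame.

    ``u`` is the unit vector (drow, dcol) along the A-P axis pointing from
    anterior to posterior; ``origin`` the mask centroid. ``s_min``/``s_max``
    bound the projections of mask pixels on ``u`` (anterior tip at
    ``s_min``). ``midline`` maps binned A-P stations to the D-V coordinate
    of the local mask midpoint.
    """

    origin: np.ndarray
    u: np.ndarray
    v: np.ndarray
    s_min: float
    s_max: float
    midline_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    midline_t: np.ndarray = field(default_factory=lambda: np.empty(0))
    extent_t: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def length(self) -> float:
        return self.s_max - self.s_min

    @property
    def anterior_point(self) -> np.ndarray:
        return self.origin + self.s_min * self.u

    @property
    def posterior_point(self) -> np.ndarray:
        return self.origin + self.s_max * self.u

    @property
    def angle_deg(self) -> float:
        """Axis orientation in the image plane (atan2 of drow/dcol)."""
        return float(np.degrees(np.arctan2(self.u[0], self.u[1])))


def _mask_coords(mask: np.ndarray) -> np.ndarray:
    rr, cc = np.nonzero(mask)
    return np.column_stack([rr, cc]).astype(float)


def _is_connected(mask: np.ndarray) -> bool:
    from scipy import ndimage
    _, n = ndimage.label(mask)
    return n == 1


def find_ap_axis(image: EmbryoImage, min_aspect: float = 1.2) -> AxisFrame:
    """Locate the A-P axis as the principal axis of the mask and the D-V
    midline as the locus of local mask midpoints along it.

    Raises for a near-circular mask (aspect ratio below ``min_aspect``)
    whose major axis is ambiguous, or a disconnected mask.
    """
    if not _is_connected(image.mask):
        raise ValueError("mask must be a single connected region")
    pts = _mask_coords(image.mask)
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    cov = centred.T @ centred / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    aspect = float(np.sqrt(evals[1] / max(evals[0], 1e-12)))
    if aspect < min_aspect:
        raise ValueError(
            f"mask aspect ratio {aspect:.2f} < {min_aspect}: axis ambiguous")
    u = evecs[:, 1]
    if u[1] < 0:  # point towards increasing column (image right)
        u = -u
    if not image.anterior_left:
        u = -u  # anterior is on the right: flip so u runs anterior->posterior
    v = np.array([-u[1], u[0]])
    s = centred @ u
    t = centred @ v
    s_min, s_max = float(s.min()), float(s.max())

    # midline: D-V midpoint per 1-pixel A-P station
    nbins = max(int(np.ceil(s_max - s_min)), 1)
    edges = np.linspace(s_min, s_max, nbins + 1)
    which = np.clip(np.digitize(s, edges) - 1, 0, nbins - 1)
    mid_s, mid_t, ext_t = [], [], []
    for b in range(nbins):
        sel = which == b
        if not sel.any():
            continue
        lo, hi = t[sel].min(), t[sel].max()
        mid_s.append(0.5 * (edges[b] + edges[b + 1]))
        mid_t.append(0.5 * (lo + hi))
        ext_t.append(hi - lo + 1.0)  # pixel extent
    return AxisFrame(
        origin=centroid, u=u, v=v, s_min=s_min, s_max=s_max,
        midline_s=np.asarray(mid_s), midline_t=np.asarray(mid_t),
        extent_t=np.asarray(ext_t),
    )


@dataclass
class Strip:
    """Pixels of the D-V midline strip with their axis coordinates."""

    s: np.ndarray        # A-P coordinate (pixels, anterior at s_min)
    t: np.ndarray        # D-V coordinate relative to midline
    values: np.ndarray
    frame: AxisFrame
    strip_fraction: float


def extract_strip(image: EmbryoImage, frame: AxisFrame,
                  strip_fraction: float = 0.10) -> Strip:
    """Select pixels within ``strip_fraction`` of the local D-V mask extent,
    centred on the midline, at every A-P station."""
    if not (0.0 < strip_fraction <= 0.5):
        raise ValueError("strip_fraction must lie in (0, 0.5]")
    pts = _mask_coords(image.mask)
    centred = pts - frame.origin
    s = centred @ frame.u
    t = centred @ frame.v
    mid = np.interp(s, frame.midline_s, frame.midline_t)
    ext = np.interp(s, frame.midline_s, frame.extent_t)
    half = 0.5 * strip_fraction * ext
    if strip_fraction * np.median(frame.extent_t) < 1.0:
        raise ValueError(
            "strip narrower than one pixel row over most of the embryo: "
            "geometry unusable at this strip fraction")
    # the mask tapers to a point at the poles; keep at least the midline row
    half = np.maximum(half, 0.5)
    keep = np.abs(t - mid) <= half
    vals = image.pixels[image.mask][keep]
    if image.inverted_stain:
        vals = vals.max() - vals
    return Strip(s=s[keep], t=(t - mid)[keep], values=vals,
                 frame=frame, strip_fraction=strip_fraction)


def profile_from_strip(strip: Strip, n_bins: int = 100,
                       max_empty_fraction: float = 0.10) -> IntensityProfile:
    """Bin strip pixels into equal-%EL A-P bins (centres 0.5, 1.5, ... for
    ``n_bins=100``); bin value = mean strip intensity; empty interior bins
    are linearly interpolated. Fails when more than 10% of bins are empty.
    """
    frame = strip.frame
    frac = (strip.s - frame.s_min) / max(frame.length, 1e-12)
    pos = np.clip(frac, 0.0, 1.0) * 100.0
    edges = np.linspace(0.0, 100.0, n_bins + 1)
    which = np.clip(np.digitize(pos, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(which, weights=strip.values, minlength=n_bins)
    counts = np.bincount(which, minlength=n_bins)
    empty = counts == 0
    if empty.mean() > max_empty_fraction:
        raise ValueError(
            f"{empty.sum()}/{n_bins} empty bins exceeds "
            f"{max_empty_fraction:.0%} threshold")
    values = np.full(n_bins, np.nan)
    values[~empty] = sums[~empty] / counts[~empty]
    if empty.any():
        centres_all = 0.5 * (edges[:-1] + edges[1:])
        values[empty] = np.interp(centres_all[empty], centres_all[~empty],
                                  values[~empty])
    centres = 0.5 * (edges[:-1] + edges[1:])
    return IntensityProfile(positions=centres, values=values)


def normalise_profile(profile: IntensityProfile,
                      background_pct: float = 5.0,
                      scale_pct: float = 95.0) -> IntensityProfile:
    """Subtract the background (low percentile), rescale so the high
    percentile maps to 1, and clip to [0, 1]. Affine-invariant: any
    a*v + b (a > 0) normalises to the same output."""
    v = profile.values
    lo = np.percentile(v, background_pct)
    hi = np.percentile(v, scale_pct)
    if hi - lo <= 1e-12:
        raise ValueError("profile has no dynamic range")
    out = np.clip((v - lo) / (hi - lo), 0.0, 1.0)
    return replace(profile, values=out)


def extract_profile(image: EmbryoImage, strip_fraction: float = 0.10,
                    n_bins: int = 100, normalise: bool = True,
                    background_pct: float = 5.0,
                    scale_pct: float = 95.0) -> IntensityProfile:
    """Full extraction chain: axis -> strip -> binned profile
    (-> normalisation)."""
    frame = find_ap_axis(image)
    strip = extract_strip(image, frame, strip_fraction)
    prof = profile_from_strip(strip, n_bins=n_bins)
    prof.gene = image.gene
    prof.embryo_id = image.embryo_id
    prof.time_class = image.time_class
    if normalise:
        prof = normalise_profile(prof, background_pct, scale_pct)
    return prof
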