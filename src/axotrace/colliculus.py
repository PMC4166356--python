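"""Anterograde (CTB) and structural (ERRbeta) label quantification in
serial coronal sections of the superior colliculus (SC).

Each section carries an outline of the retinorecipient layers (the ROI) and a
reference region of non-retinorecipient tissue used to set background. A
pixel counts as labeled iff it is strictly brighter than
``mean + k * SD`` of the reference region of its own section.

Two summaries are produced:

* a mediolateral **density profile** per section — the ROI columns are split
  into contiguous near-equal bins and each bin reports the fraction of its
  ROI pixels above background — which, stacked over sections ordered
  rostral -> caudal, gives the retinotopic **density map** rendered with a
  0% (blue) -> 100% (red) colormap; and
* the whole-structure **percent area fraction intact**: the pooled fraction
  of ROI pixels above background over all sections, x100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    InvalidImageError,
    InvalidParameterError,
    MissingReferenceError,
    NoDataError,
)

__all__ = [
    "SCSection",
    "DensityProfile",
    "DensityMap",
    "estimate_background",
    "bin_density_profile",
    "build_density_map",
    "sc_intact_fraction",
    "render_density_map",
]


@dataclass(frozen=True)
class SCSection:
    """One coronal SC section with its analysis regions.

    ``flip`` mirrors the mediolateral axis; left and right colliculi mirror
    each other, and profiles are always reported medial -> lateral.
    """

    pixels: np.ndarray
    roi_mask: np.ndarray
    background_roi: np.ndarray
    rostrocaudal_index: int = 0
    flip: bool = False

    def __post_init__(self):
        pixels = np.asarray(self.pixels, dtype=np.float64)
        roi = np.asarray(self.roi_mask).astype(bool)
        bg = np.asarray(self.background_roi).astype(bool)
        if pixels.ndim != 2 or roi.shape != pixels.shape or bg.shape != pixels.shape:
            raise InvalidImageError("section image and masks must share one 2-D shape")
        if (roi & bg).any():
            raise InvalidImageError("roi_mask and background_roi must be disjoint")
        object.__setattr__(self, "pixels", pixels)
        object.__setattr__(self, "roi_mask", roi)
        object.__setattr__(self, "background_roi", bg)


@dataclass
class DensityProfile:
    """Per-bin fraction of above-background ROI pixels, medial -> lateral.

    Bins whose mediolateral span contains no ROI pixel hold NaN (flagged
    missing, never silently zero).
    """

    bin_fractions: np.ndarray
    threshold_used: float
    rostrocaudal_index: int = 0

    def __post_init__(self):
        self.bin_fractions = np.asarray(self.bin_fractions, dtype=float)

    @property
    def n_bins(self) -> int:
        return self.bin_fractions.size


@dataclass
class DensityMap:
    """Sections x bins matrix of percent labeled, rostral -> caudal rows."""

    values_pct: np.ndarray
    section_indices: list[int] = field(default_factory=list)
    channel: str = ""


def estimate_background(section: SCSection, k: float = 2.0) -> float:
    """Background threshold: mean + k x sample SD of the reference region.

    A pixel counts as signal iff strictly greater than this value. With a
    single reference pixel the SD is taken as 0.
    """
    vals = section.pixels[section.background_roi]
    if vals.size == 0:
        raise MissingReferenceError("background reference region is empty")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return float(np.mean(vals)) + k * sd


def _ml_columns(section: SCSection) -> np.ndarray:
    """ROI column index per ROI pixel, in medial -> lateral order."""
    _, cols = np.nonzero(section.roi_mask)
    if section.flip:
        cols = section.pixels.shape[1] - 1 - cols
    return cols


def bin_density_profile(
    section: SCSection, threshold: float, n_bins: int = 100
) -> DensityProfile:
    """Fraction of ROI pixels above ``threshold`` in each mediolateral bin.

    The ROI's column extent is partitioned into ``n_bins`` contiguous
    near-equal-width spans; bin i covers columns assigned by an even split of
    the extent. Empty spans yield NaN.
    """
    if n_bins < 1:
        raise InvalidParameterError("n_bins must be >= 1")
    if not section.roi_mask.any():
        raise NoDataError("roi_mask is empty")

    cols = _ml_columns(section)
    above = (section.pixels > threshold)[section.roi_mask]

    cmin, cmax = int(cols.min()), int(cols.max())
    extent = cmax - cmin + 1
    # column -> bin by proportional position; guarantees contiguous
    # near-equal-width spans for any extent/n_bins combination
    bin_of_col = np.minimum(
        ((np.arange(extent)) * n_bins) // extent, n_bins - 1
    )
    b = bin_of_col[cols - cmin]

    total = np.bincount(b, minlength=n_bins).astype(float)
    hits = np.bincount(b, weights=above.astype(float), minlength=n_bins)
    with np.errstate(invalid="ignore"):
        fractions = np.where(total > 0, hits / np.maximum(total, 1), np.nan)
    fractions[total == 0] = np.nan
    return DensityProfile(
        bin_fractions=fractions,
        threshold_used=float(threshold),
        rostrocaudal_index=section.rostrocaudal_index,
    )


def build_density_map(
    profiles: list[DensityProfile], n_bins_out: int = 100, channel: str = ""
) -> DensityMap:
    """Stack per-section profiles into a retinotopic percent map.

    Each profile is linearly resampled to ``n_bins_out`` bins on the
    normalized mediolateral axis (bins at ``linspace(0, 1, n)``, so the
    medial and lateral endpoints are preserved exactly under any
    down/up resampling); rows are ordered by rostrocaudal index; values are
    scaled to percent. Profiles already of length ``n_bins_out`` pass through
    unchanged. NaN bins are interpolated over when neighbors exist, and a
    fully missing profile stays NaN.
    """
    if not profiles:
        raise NoDataError("no profiles to assemble")
    if n_bins_out < 1:
        raise InvalidParameterError("n_bins_out must be >= 1")

    def axis(n: int) -> np.ndarray:
        return np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.5])

    ordered = sorted(profiles, key=lambda p: p.rostrocaudal_index)
    x_out = axis(n_bins_out)
    rows = []
    for prof in ordered:
        vals = prof.bin_fractions
        if vals.size == n_bins_out:
            row = vals.copy()
        else:
            x_in = axis(vals.size)
            good = np.isfinite(vals)
            if good.sum() == 0:
                row = np.full(n_bins_out, np.nan)
            else:
                row = np.interp(x_out, x_in[good], vals[good])
        rows.append(row * 100.0)
    return DensityMap(
        values_pct=np.vstack(rows),
        section_indices=[p.rostrocaudal_index for p in ordered],
        channel=channel,
    )


def sc_intact_fraction(sections: list[SCSection], k: float = 2.0) -> float:
    """Whole-structure percent area fraction of intact label.

    Pools above-background ROI pixels over all sections, each section
    thresholded against its own reference region:
    ``100 * sum(above) / sum(roi pixels)``.
    """
    if not sections:
        raise NoDataError("no sections")
    total = 0
    above = 0
    for sec in sections:
        if not sec.roi_mask.any():
            continue
        thr = estimate_background(sec, k)
        roi_vals = sec.pixels[sec.roi_mask]
        total += roi_vals.size
        above += int(np.count_nonzero(roi_vals > thr))
    if total == 0:
        raise NoDataError("all ROIs are empty")
    return 100.0 * above / total


def render_density_map(dmap: DensityMap, path) -> None:
    """Save the colorimetric (blue = 0% -> red = 100%) map as a PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    im = ax.imshow(dmap.values_pct, cmap="jet", vmin=0, vmax=100,
                   aspect="auto", interpolation="nearest")
    ax.set_xlabel("medial → lateral bin")
    ax.set_ylabel("rostral → caudal section")
    title = f"{dmap.channel} label density" if dmap.channel else "label density"
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="% pixels above background")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
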