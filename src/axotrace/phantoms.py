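"""Synthetic imaging phantoms with known ground truth.

Every downstream stage of the package is exercised on data from this module:

* **Retina phantoms** — a disc-shaped whole-mount mask (with narrow
  triangular notches emulating the radial relieving cuts of a flattened
  whole-mount), populated with bright round somata rendered as Gaussian
  blobs, optionally with wedge-shaped ("sectorial") dropout regions devoid
  of cells — the signature geometry of glaucomatous retrograde-label loss.
* **SC section stacks** — serial coronal sections with a superficial labeled
  band over a dimmer background, with per-section mediolateral intervals
  where the label is absent.
* **Measure-level cohorts** — per-projection tables of the four transport
  measures with configurable group means/SDs and within-projection
  cross-measure correlation, emulating the 3-label x 5-group study design.

All generators are driven by a single integer seed through one
``numpy.random.default_rng`` stream per call; identical (spec, seed) input
yields bit-identical arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import InvalidSpecError, PackingError
from .retina import RetinaImage
from .colliculus import SCSection

__all__ = [
    "RetinaPhantomSpec",
    "SCPhantomSpec",
    "CohortSpec",
    "PhantomTruth",
    "SectionStack",
    "generate_retina_phantom",
    "generate_sc_stack",
    "generate_cohort",
    "spans_to_bin_fractions",
    "quantized_bin_fractions",
    "n_cells_for_density",
    "StudySpec",
    "GroupSpec",
    "generate_study",
]

MEASURES = ("fg_density", "fg_intact_pct", "ctb_intact_pct", "errb_intact_pct")
STUDY_GROUPS = ("D2G", "D3", "D9-10", "D11-12", "D13")


# --------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class RetinaPhantomSpec:
    """Parameters of a whole-mount retina phantom.

    ``dropout_wedges`` is a sequence of ``(center_angle_deg, half_angle_deg)``
    circular sectors of the disc in which no cells are placed. Angles are
    taken mod 360. ``soma_peak_intensity`` is the blob amplitude *above*
    ``background_level`` (the soma contrast).
    """

    image_size_px: tuple[int, int] = (1024, 1024)
    pixel_size_um: float = 1.5
    n_cells: int = 2000
    soma_radius_um: float = 6.0
    soma_radius_jitter: float = 0.05
    soma_peak_intensity: float = 100.0
    background_level: float = 20.0
    noise_sd: float = 10.0
    dropout_wedges: tuple[tuple[float, float], ...] = ()
    radial_cuts: int = 4
    edge_clearance_um: float = 15.0

    def __post_init__(self):
        h, w = self.image_size_px
        if h <= 0 or w <= 0:
            raise InvalidSpecError("image_size_px must be positive")
        if not self.pixel_size_um > 0:
            raise InvalidSpecError("pixel_size_um must be positive")
        if self.n_cells < 0:
            raise InvalidSpecError("n_cells must be >= 0")
        if not self.soma_radius_um > 0:
            raise InvalidSpecError("soma_radius_um must be positive")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        if not 0 <= self.soma_radius_jitter < 1:
            raise InvalidSpecError("soma_radius_jitter must lie in [0, 1)")
        if self.radial_cuts < 0:
            raise InvalidSpecError("radial_cuts must be >= 0")
        for center, half in self.dropout_wedges:
            if half < 0 or half > 180:
                raise InvalidSpecError("wedge half-angle must lie in [0, 180]")

    def dropout_area_fraction(self) -> float:
        """Analytic fraction of the disc covered by the dropout wedges."""
        if not self.dropout_wedges:
            return 0.0
        # union of angular intervals on the circle, in degrees
        intervals = []
        for center, half in self.dropout_wedges:
            lo = (center - half) % 360.0
            hi = lo + 2 * half
            if hi <= 360.0:
                intervals.append((lo, hi))
            else:
                intervals.append((lo, 360.0))
                intervals.append((0.0, hi - 360.0))
        intervals.sort()
        covered = 0.0
        cur_lo, cur_hi = intervals[0]
        for lo, hi in intervals[1:]:
            if lo > cur_hi:
                covered += cur_hi - cur_lo
                cur_lo, cur_hi = lo, hi
            else:
                cur_hi = max(cur_hi, hi)
        covered += cur_hi - cur_lo
        return min(covered / 360.0, 1.0)


@dataclass(frozen=True)
class SCPhantomSpec:
    """Parameters of a serial SC section-stack phantom.

    ``deficit_spans[i]`` lists non-overlapping mediolateral fractional
    intervals ``(lo, hi) in [0, 1]`` of section ``i`` in which the
    superficial band carries no signal. ``superficial_band_rows`` and
    ``background_rows`` are half-open row ranges for the retinorecipient
    band and the non-retinorecipient reference region.
    """

    n_sections: int = 8
    section_size_px: tuple[int, int] = (160, 220)
    superficial_band_rows: tuple[int, int] = (20, 60)
    background_rows: tuple[int, int] = (100, 140)
    signal_level: float = 120.0
    background_level: float = 30.0
    noise_sd: float = 8.0
    deficit_spans: tuple[tuple[tuple[float, float], ...], ...] = ()
    column_margin_px: int = 10

    def __post_init__(self):
        if self.n_sections < 1:
            raise InvalidSpecError("n_sections must be >= 1")
        h, w = self.section_size_px
        r0, r1 = self.superficial_band_rows
        b0, b1 = self.background_rows
        if not (0 <= r0 < r1 <= h):
            raise InvalidSpecError("superficial_band_rows out of image")
        if not (0 <= b0 < b1 <= h):
            raise InvalidSpecError("background_rows out of image")
        if max(r0, b0) < min(r1, b1):
            raise InvalidSpecError("band and background rows overlap")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        if self.deficit_spans and len(self.deficit_spans) != self.n_sections:
            raise InvalidSpecError("deficit_spans must have one entry per section")
        for spans in self.deficit_spans:
            prev_hi = -1.0
            for lo, hi in sorted(spans):
                if not (0.0 <= lo <= hi <= 1.0):
                    raise InvalidSpecError("deficit spans must lie within [0, 1]")
                if lo < prev_hi:
                    raise InvalidSpecError("deficit spans overlap")
                prev_hi = hi

    def spans_for_section(self, i: int) -> tuple[tuple[float, float], ...]:
        return self.deficit_spans[i] if self.deficit_spans else ()


@dataclass(frozen=True)
class CohortSpec:
    """Measure-level cohort: group sizes, true means/SDs, cross-correlation.

    ``means[label]`` and ``sds[label]`` are 4-vectors over
    (fg_density, fg_intact_pct, ctb_intact_pct, errb_intact_pct).
    ``rho`` is the common pairwise correlation of the four measures within a
    projection.
    """

    groups: tuple[tuple[str, int], ...]
    means: dict
    sds: dict
    rho: float = 0.0

    def __post_init__(self):
        if not self.groups:
            raise InvalidSpecError("at least one group required")
        for label, n in self.groups:
            if n < 1:
                raise InvalidSpecError(f"group {label!r} has n < 1")
            if label not in self.means or label not in self.sds:
                raise InvalidSpecError(f"missing means/sds for group {label!r}")
            m = np.asarray(self.means[label], dtype=float)
            s = np.asarray(self.sds[label], dtype=float)
            if m.shape != (4,) or s.shape != (4,):
                raise InvalidSpecError("means/sds must be 4-vectors per group")
            if (s < 0).any():
                raise InvalidSpecError("SDs must be >= 0")
            if (m[1:] < 0).any() or (m[1:] > 100).any():
                raise InvalidSpecError("percent means must lie in [0, 100]")
        if not -1.0 <= self.rho <= 1.0:
            raise InvalidSpecError("|rho| must be <= 1")

    @classmethod
    def default_study(cls, rho: float = 0.8) -> "CohortSpec":
        """Cohort patterned on the dual-tracer DBA/2J study design.

        Group sizes (D2G=8, D3=6, D9-10=6, D11-12=9, D13=6) and means
        encode the deficit pattern reported for this mouse model —
        anterograde label down ~69% at 9-10 months against a ~23%
        retrograde reduction, structural label persisting until a late
        collapse (>90% transport loss, ~86% structural loss) — around a
        ~95% intact baseline. Absolute group means are not available, so
        these values are package configuration, not ground truth.
        """
        means = {
            #          fg_dens  fg%   ctb%  errb%
            "D2G":    (3400.0, 92.0, 95.0, 95.0),
            "D3":     (3400.0, 92.0, 95.0, 95.0),
            "D9-10":  (2600.0, 71.0, 29.0, 93.0),
            "D11-12": (2400.0, 65.0, 25.0, 88.0),
            "D13":    ( 350.0,  9.0,  8.0, 13.0),
        }
        sds = {g: (450.0, 12.0, 12.0, 10.0) for g in means}
        groups = (("D2G", 8), ("D3", 6), ("D9-10", 6), ("D11-12", 9), ("D13", 6))
        return cls(groups=groups, means=means, sds=sds, rho=rho)


@dataclass
class PhantomTruth:
    """Seeded ground truth attached to every phantom."""

    cell_centroids_um: np.ndarray | None = None
    true_density_cells_per_mm2: float | None = None
    true_intact_fraction_pct: float | None = None
    mask_area_mm2: float | None = None
    section_bin_fractions: list[np.ndarray] | None = None
    sc_deficit_spans: list[tuple] | None = None

    def to_jsonable(self) -> dict:
        d = {}
        if self.cell_centroids_um is not None:
            d["cell_centroids_um"] = np.asarray(self.cell_centroids_um).tolist()
        if self.true_density_cells_per_mm2 is not None:
            d["true_density_cells_per_mm2"] = self.true_density_cells_per_mm2
        if self.true_intact_fraction_pct is not None:
            d["true_intact_fraction_pct"] = self.true_intact_fraction_pct
        if self.mask_area_mm2 is not None:
            d["mask_area_mm2"] = self.mask_area_mm2
        if self.section_bin_fractions is not None:
            d["section_bin_fractions"] = [
                np.asarray(v).tolist() for v in self.section_bin_fractions
            ]
        if self.sc_deficit_spans is not None:
            d["sc_deficit_spans"] = [list(map(list, s)) for s in self.sc_deficit_spans]
        return d

    @classmethod
    def from_jsonable(cls, d: dict) -> "PhantomTruth":
        t = cls()
        if "cell_centroids_um" in d:
            t.cell_centroids_um = np.asarray(d["cell_centroids_um"], dtype=float)
        t.true_density_cells_per_mm2 = d.get("true_density_cells_per_mm2")
        t.true_intact_fraction_pct = d.get("true_intact_fraction_pct")
        t.mask_area_mm2 = d.get("mask_area_mm2")
        if "section_bin_fractions" in d:
            t.section_bin_fractions = [
                np.asarray(v, dtype=float) for v in d["section_bin_fractions"]
            ]
        if "sc_deficit_spans" in d:
            t.sc_deficit_spans = [
                tuple(tuple(x) for x in s) for s in d["sc_deficit_spans"]
            ]
        return t


@dataclass
class SectionStack:
    """An ordered list of phantom SC sections (one channel)."""

    sections: list[SCSection]

    def __len__(self) -> int:
        return len(self.sections)


# --------------------------------------------------------------------------
# retina phantom


def _disc_geometry(spec: RetinaPhantomSpec):
    h, w = spec.image_size_px
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    radius_px = 0.46 * min(h, w)
    yy, xx = np.mgrid[0:h, 0:w]
    dy = yy - cy
    dx = xx - cx
    rr = np.hypot(dy, dx)
    theta = np.degrees(np.arctan2(dy, dx)) % 360.0
    return cy, cx, radius_px, rr, theta


def _angular_distance(theta: np.ndarray, center: float) -> np.ndarray:
    d = np.abs((theta - center + 180.0) % 360.0 - 180.0)
    return d


def retina_mask_and_dropout(spec: RetinaPhantomSpec):
    """Disc mask with radial-cut notches, plus the wedge dropout mask."""
    cy, cx, radius_px, rr, theta = _disc_geometry(spec)
    mask = rr <= radius_px

    # relieving cuts: narrow triangular notches from the rim toward center
    cut_half_deg = 1.5
    cut_inner = 0.35 * radius_px
    for i in range(spec.radial_cuts):
        ang = (360.0 / spec.radial_cuts) * i + 45.0
        notch = (_angular_distance(theta, ang) <= cut_half_deg) & (rr >= cut_inner)
        mask &= ~notch

    dropout = np.zeros_like(mask)
    for center, half in spec.dropout_wedges:
        dropout |= _angular_distance(theta, center % 360.0) <= half
    dropout &= mask
    return mask, dropout


def _place_cells(
    allowed: np.ndarray,
    n_cells: int,
    min_spacing_px: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Uniform rejection sampling with a hard minimum center spacing.

    Returns (n, 2) array of subpixel (row, col) centers. Uses an occupancy
    grid of cell size = spacing so each candidate checks at most 9 buckets.
    """
    coords = np.argwhere(allowed)
    if n_cells == 0:
        return np.zeros((0, 2))
    if coords.shape[0] == 0:
        raise PackingError("no pixels available for cell placement")

    cell = max(min_spacing_px, 1.0)
    h, w = allowed.shape
    ngy = int(h / cell) + 2
    ngx = int(w / cell) + 2
    buckets: dict[tuple[int, int], list[tuple[float, float]]] = {}

    placed = np.empty((n_cells, 2))
    n_placed = 0
    max_attempts = 300 * n_cells + 1000
    attempts = 0
    batch = None
    batch_pos = 0
    sp2 = min_spacing_px**2
    while n_placed < n_cells and attempts < max_attempts:
        if batch is None or batch_pos >= len(batch):
            idx = rng.integers(0, coords.shape[0], size=4096)
            jit = rng.uniform(-0.5, 0.5, size=(4096, 2))
            batch = coords[idx] + jit
            batch_pos = 0
        y, x = batch[batch_pos]
        batch_pos += 1
        attempts += 1
        gy, gx = int(y / cell), int(x / cell)
        ok = True
        for by in range(gy - 1, gy + 2):
            for bx in range(gx - 1, gx + 2):
                for (py, px_) in buckets.get((by, bx), ()):
                    if (py - y) ** 2 + (px_ - x) ** 2 < sp2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if not ok:
            continue
        placed[n_placed] = (y, x)
        buckets.setdefault((gy, gx), []).append((y, x))
        n_placed += 1
    if n_placed < n_cells:
        raise PackingError(
            f"placed only {n_placed}/{n_cells} cells at spacing "
            f"{min_spacing_px:.1f} px; reduce density or spacing"
        )
    return placed


def _render_somata(
    shape: tuple[int, int],
    centers_px: np.ndarray,
    radii_px: np.ndarray,
    peak: float,
) -> np.ndarray:
    """Additive Gaussian-profile blobs, sigma = radius/2, truncated at 3 sigma."""
    img = np.zeros(shape, dtype=np.float64)
    h, w = shape
    for (cy, cx), r in zip(centers_px, radii_px):
        sigma = r / 2.0
        cut = 3.0 * sigma
        y0 = max(int(np.floor(cy - cut)), 0)
        y1 = min(int(np.ceil(cy + cut)) + 1, h)
        x0 = max(int(np.floor(cx - cut)), 0)
        x1 = min(int(np.ceil(cx + cut)) + 1, w)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        blob = peak * np.exp(-d2 / (2.0 * sigma**2))
        blob[d2 > cut**2] = 0.0
        img[y0:y1, x0:x1] += blob
    return img


def generate_retina_phantom(
    spec: RetinaPhantomSpec, seed: int
) -> tuple[RetinaImage, PhantomTruth]:
    """Render a whole-mount retina phantom with seeded ground truth.

    Cells are placed by uniform rejection sampling inside the mask, outside
    the dropout wedges, at least ``edge_clearance_um`` from the mask
    boundary, with a hard minimum center spacing of 1.5 soma radii. Somata
    are Gaussian blobs (sigma = radius/2, truncated at 3 sigma) added on a
    flat background; Gaussian noise is added last and the image clipped at 0.
    """
    rng = np.random.default_rng(seed)
    px = spec.pixel_size_um
    mask, dropout = retina_mask_and_dropout(spec)

    from scipy import ndimage as ndi  # local import keeps module load light

    clearance_px = spec.edge_clearance_um / px
    interior = ndi.distance_transform_edt(mask) >= clearance_px
    allowed = mask & ~dropout & interior

    spacing_px = 1.5 * spec.soma_radius_um / px
    centers = _place_cells(allowed, spec.n_cells, spacing_px, rng)

    j = spec.soma_radius_jitter
    radii_um = spec.soma_radius_um * rng.uniform(1.0 - j, 1.0 + j, size=len(centers))
    img = _render_somata(spec.image_size_px, centers, radii_um / px,
                         spec.soma_peak_intensity)
    img += spec.background_level
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, None)
    img[~mask] = 0.0
    img = img.astype(np.float32)

    mask_area_mm2 = mask.sum() * px**2 / 1e6
    intact_pct = 100.0 * (mask.sum() - dropout.sum()) / mask.sum()
    centroids_um = np.column_stack([centers[:, 1] * px, centers[:, 0] * px])

    truth = PhantomTruth(
        cell_centroids_um=centroids_um,
        true_density_cells_per_mm2=len(centers) / mask_area_mm2,
        true_intact_fraction_pct=float(intact_pct),
        mask_area_mm2=float(mask_area_mm2),
    )
    return RetinaImage(pixels=img, pixel_size_um=px, mask=mask), truth


def n_cells_for_density(spec: RetinaPhantomSpec, density_cells_per_mm2: float) -> int:
    """Cell count giving a target whole-mask density for this geometry."""
    mask, _ = retina_mask_and_dropout(spec)
    area_mm2 = mask.sum() * spec.pixel_size_um**2 / 1e6
    return int(round(density_cells_per_mm2 * area_mm2))


# --------------------------------------------------------------------------
# SC stack phantom


def spans_to_bin_fractions(spans, n_bins: int) -> np.ndarray:
    """Analytic intact fraction per mediolateral bin given deficit spans.

    Bin i covers [i/n, (i+1)/n); the intact fraction is 1 minus the covered
    deficit length within the bin divided by the bin width.
    """
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    out = np.ones(n_bins)
    width = 1.0 / n_bins
    for lo, hi in spans:
        overlap = np.clip(np.minimum(edges[1:], hi) - np.maximum(edges[:-1], lo),
                          0.0, None)
        out -= overlap / width
    out = np.clip(out, 0.0, 1.0)
    # snap float residue at the exact-coverage limits
    out[np.abs(out) < 1e-9] = 0.0
    out[np.abs(out - 1.0) < 1e-9] = 1.0
    return out


def quantized_bin_fractions(spans, width_px: int, n_bins: int) -> np.ndarray:
    """Intact fraction per bin as actually rendered on a pixel grid.

    Columns are signal-free iff their center fraction lies in a deficit
    span; columns map to bins with the same proportional rule the profiler
    uses. This is the pixel-accurate counterpart of
    :func:`spans_to_bin_fractions` (the two agree to within pixelization).
    """
    frac = (np.arange(width_px) + 0.5) / width_px
    intact = np.ones(width_px, dtype=float)
    for lo, hi in spans:
        intact[(frac >= lo) & (frac < hi)] = 0.0
    b = np.minimum((np.arange(width_px) * n_bins) // width_px, n_bins - 1)
    total = np.bincount(b, minlength=n_bins).astype(float)
    hits = np.bincount(b, weights=intact, minlength=n_bins)
    return hits / np.maximum(total, 1.0)


def generate_sc_stack(
    spec: SCPhantomSpec, seed: int
) -> tuple[SectionStack, PhantomTruth]:
    """Render a serial SC section stack with seeded ground truth.

    Each section is a flat ``background_level`` field with a superficial
    band at ``signal_level`` above background except in the deficit spans,
    plus Gaussian noise clipped at 0. The ROI is the band (inset by
    ``column_margin_px`` columns); the reference region is the
    ``background_rows`` block.
    """
    rng = np.random.default_rng(seed)
    h, w = spec.section_size_px
    r0, r1 = spec.superficial_band_rows
    b0, b1 = spec.background_rows
    m = spec.column_margin_px
    c0, c1 = m, w - m
    if c1 <= c0:
        raise InvalidSpecError("column margin leaves no ROI columns")

    sections = []
    truth_fracs = []
    spans_all = []
    roi_width = c1 - c0
    for i in range(spec.n_sections):
        spans = spec.spans_for_section(i)
        img = np.full((h, w), spec.background_level, dtype=np.float64)
        sig = np.zeros(roi_width, dtype=bool)
        sig[:] = True
        frac = (np.arange(roi_width) + 0.5) / roi_width
        for lo, hi in spans:
            sig &= ~((frac >= lo) & (frac < hi))
        img[r0:r1, c0:c1][:, sig] += spec.signal_level
        if spec.noise_sd > 0:
            img += rng.normal(0.0, spec.noise_sd, size=img.shape)
        img = np.clip(img, 0.0, None).astype(np.float32)

        roi = np.zeros((h, w), dtype=bool)
        roi[r0:r1, c0:c1] = True
        bg = np.zeros((h, w), dtype=bool)
        bg[b0:b1, c0:c1] = True
        sections.append(SCSection(pixels=img, roi_mask=roi, background_roi=bg,
                                  rostrocaudal_index=i))
        truth_fracs.append(spans_to_bin_fractions(spans, n_bins=100))
        spans_all.append(tuple(spans))

    deficit = [sum(hi - lo for lo, hi in s) for s in spans_all]
    truth = PhantomTruth(
        section_bin_fractions=truth_fracs,
        sc_deficit_spans=spans_all,
        true_intact_fraction_pct=100.0 * (1.0 - float(np.mean(deficit))),
    )
    return SectionStack(sections=sections), truth


# --------------------------------------------------------------------------
# measure-level cohort


def generate_cohort(spec: CohortSpec, seed: int) -> pd.DataFrame:
    """Simulate a per-projection measure table.

    One row per projection with columns ``projection_id, group, fg_density,
    fg_intact_pct, ctb_intact_pct, errb_intact_pct``. The four measures are
    drawn from a multivariate normal with common pairwise correlation
    ``rho``; percent measures are clipped to [0, 100] and density to >= 0.
    """
    rng = np.random.default_rng(seed)
    corr = np.full((4, 4), spec.rho)
    np.fill_diagonal(corr, 1.0)
    chol = np.linalg.cholesky(corr)

    rows = []
    pid = 0
    for label, n in spec.groups:
        mean = np.asarray(spec.means[label], dtype=float)
        sd = np.asarray(spec.sds[label], dtype=float)
        z = rng.standard_normal((n, 4))
        samples = mean + (z @ chol.T) * sd
        samples[:, 0] = np.clip(samples[:, 0], 0.0, None)
        samples[:, 1:] = np.clip(samples[:, 1:], 0.0, 100.0)
        for row in samples:
            rows.append((f"P{pid:04d}", label, *row))
            pid += 1
    return pd.DataFrame(rows, columns=["projection_id", "group", *MEASURES])


# --------------------------------------------------------------------------
# whole-study image-level phantom


@dataclass(frozen=True)
class GroupSpec:
    """Per-group image-level phantom parameters (fractions of area lost)."""

    label: str
    n_projections: int
    fg_dropout_frac: float = 0.0
    ctb_deficit_frac: float = 0.0
    errb_deficit_frac: float = 0.0
    frac_sd: float = 0.03

    def __post_init__(self):
        if self.n_projections < 1:
            raise InvalidSpecError("n_projections must be >= 1")
        for name in ("fg_dropout_frac", "ctb_deficit_frac", "errb_deficit_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.95:
                raise InvalidSpecError(f"{name} must lie in [0, 0.95]")


@dataclass(frozen=True)
class StudySpec:
    """An image-level cohort: one retina + two SC channel stacks per projection."""

    groups: tuple[GroupSpec, ...]
    retina: RetinaPhantomSpec = field(default_factory=RetinaPhantomSpec)
    sc: SCPhantomSpec = field(default_factory=lambda: SCPhantomSpec(n_sections=4))

    @classmethod
    def small_study(cls, n_per_group: int = 2,
                    retina: RetinaPhantomSpec | None = None,
                    sc: SCPhantomSpec | None = None) -> "StudySpec":
        """Compact five-group study with the glaucoma-model deficit pattern."""
        pat = {
            #            fg     ctb    errb
            "D2G":    (0.00, 0.00, 0.00),
            "D3":     (0.00, 0.00, 0.00),
            "D9-10":  (0.23, 0.69, 0.03),
            "D11-12": (0.30, 0.73, 0.08),
            "D13":    (0.90, 0.92, 0.86),
        }
        groups = tuple(
            GroupSpec(label=g, n_projections=n_per_group,
                      fg_dropout_frac=f, ctb_deficit_frac=c, errb_deficit_frac=e)
            for g, (f, c, e) in pat.items()
        )
        kwargs = {}
        if retina is not None:
            kwargs["retina"] = retina
        if sc is not None:
            kwargs["sc"] = sc
        return cls(groups=groups, **kwargs)


@dataclass
class ProjectionPhantom:
    """In-memory bundle of one synthetic projection (eye + contralateral SC)."""

    projection_id: str
    group: str
    retina_image: RetinaImage
    retina_truth: PhantomTruth
    ctb_stack: SectionStack
    ctb_truth: PhantomTruth
    errb_stack: SectionStack
    errb_truth: PhantomTruth


def _study_wedge(frac: float, rng: np.random.Generator):
    if frac <= 0:
        return ()
    center = rng.uniform(0.0, 360.0)
    return ((float(center), float(frac * 180.0)),)


def _study_spans(frac: float, n_sections: int, rng: np.random.Generator):
    if frac <= 0:
        return ()
    spans = []
    for _ in range(n_sections):
        f = min(frac, 0.98)
        start = rng.uniform(0.0, 1.0 - f)
        spans.append(((float(start), float(start + f)),))
    return tuple(spans)


def generate_study(spec: StudySpec, seed: int) -> list[ProjectionPhantom]:
    """Generate a full image-level cohort of projection phantoms.

    Per projection, the group's deficit fractions (jittered by ``frac_sd``)
    set the retina dropout wedge and the per-channel SC deficit spans; every
    projection gets independent substreams of the single seeded generator.
    """
    rng = np.random.default_rng(seed)
    out = []
    pid = 0
    for g in spec.groups:
        for _ in range(g.n_projections):
            fg = float(np.clip(rng.normal(g.fg_dropout_frac, g.frac_sd), 0.0, 0.95))
            ctb = float(np.clip(rng.normal(g.ctb_deficit_frac, g.frac_sd), 0.0, 0.95))
            errb = float(np.clip(rng.normal(g.errb_deficit_frac, g.frac_sd), 0.0, 0.95))

            retina_spec = RetinaPhantomSpec(
                **{**asdict(spec.retina), "dropout_wedges": _study_wedge(fg, rng)}
            )
            retina_spec = RetinaPhantomSpec(
                **{**asdict(retina_spec),
                   "n_cells": int(round(spec.retina.n_cells * (1.0 - fg)))}
            )
            r_seed = int(rng.integers(0, 2**31 - 1))
            retina_img, retina_truth = generate_retina_phantom(retina_spec, r_seed)

            ctb_spec = SCPhantomSpec(**{
                **asdict(spec.sc),
                "deficit_spans": _study_spans(ctb, spec.sc.n_sections, rng),
            })
            errb_spec = SCPhantomSpec(**{
                **asdict(spec.sc),
                "deficit_spans": _study_spans(errb, spec.sc.n_sections, rng),
            })
            ctb_stack, ctb_truth = generate_sc_stack(
                ctb_spec, int(rng.integers(0, 2**31 - 1)))
            errb_stack, errb_truth = generate_sc_stack(
                errb_spec, int(rng.integers(0, 2**31 - 1)))

            out.append(ProjectionPhantom(
                projection_id=f"P{pid:04d}", group=g.label,
                retina_image=retina_img, retina_truth=retina_truth,
                ctb_stack=ctb_stack, ctb_truth=ctb_truth,
                errb_stack=errb_stack, errb_truth=errb_truth,
            ))
            pid += 1
    return out
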