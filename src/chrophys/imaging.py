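"""Confocal image quantification: soma counting, expression positivity,
and membrane-targeting line profiles.

Somata are segmented on the context channel with Otsu's threshold and
gated by area, equivalent diameter and circularity.  Expression
positivity is called against a Gaussian-mixture threshold (mean plus
twice the SD of the lowest-mean component, components chosen by BIC).
Membrane targeting is quantified from inward line profiles perpendicular
to the membrane mask: the mean GFP fluorescence 0.4-0.6 µm inside the
membrane divided by that at 1.4-1.6 µm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from sklearn.cluster import MeanShift
from sklearn.mixture import GaussianMixture

from chrophys.datatypes import ImageStack

# segmentation gates (in physical units)
AREA_GATE_UM2 = (50.0, 500.0)
DIAMETER_GATE_UM = (8.0, 25.0)
CIRCULARITY_GATE = 0.6
MEANSHIFT_BANDWIDTH_UM = 6.5
PROFILE_STEP_UM = 0.1
PROFILE_LENGTH_UM = 3.0
N_RAYS = 12
MIN_RAYS = 3
MEMBRANE_BAND_UM = (0.4, 0.6)
INTRACELL_BAND_UM = (1.4, 1.6)


@dataclass
class CellRecord:
    """One segmented soma with brightness, positivity and profile summary."""

    id: int
    centroid: tuple[float, float, float]  # z, y, x (px)
    mask: np.ndarray  # boolean, central plane
    area_um2: float
    equiv_diameter_um: float
    circularity: float
    median_gfp: float
    positive: bool | None = None
    n_profiles: int = 0
    profile: np.ndarray | None = None  # mean GFP vs distance from membrane
    profile_distance_um: np.ndarray | None = None
    membrane_ratio: float = float("nan")
    excluded: bool = False
    exclusion_reason: str = ""


@dataclass
class ExpressionSummary:
    """Counts, expression rate and GMM threshold for one stack."""

    n_context_positive: int
    n_gfp_positive: int
    expression_rate: float  # percent
    density_per_mm2: float
    gmm_means: np.ndarray
    gmm_sds: np.ndarray
    gmm_weights: np.ndarray
    threshold: float


def central_plane(stack: ImageStack) -> int:
    """Z-plane with the most context signal (the section midplane)."""
    return int(np.argmax(stack.context.sum(axis=(1, 2))))


def segment_somata(
    stack: ImageStack,
    area_gate_um2: tuple[float, float] = AREA_GATE_UM2,
    diameter_gate_um: tuple[float, float] = DIAMETER_GATE_UM,
    circularity_gate: float = CIRCULARITY_GATE,
) -> list[CellRecord]:
    """Otsu-threshold the context channel and gate connected components.

    Segmentation runs on the central z-plane; components must satisfy
    the area, equivalent-diameter and circularity (4*pi*A/P^2) gates.
    Median GFP brightness is measured inside each kept mask.
    """
    z = central_plane(stack)
    plane = stack.context[z].astype(float)
    if plane.max() <= plane.min():
        return []
    thr = threshold_otsu(plane)
    binary = plane > thr
    if not binary.any():
        return []
    labels = label(binary)
    px = stack.pixel_size
    gfp_plane = stack.gfp[z]
    records: list[CellRecord] = []
    for rp in regionprops(labels):
        area_um2 = rp.area * px**2
        diam_um = rp.equivalent_diameter_area * px
        circ = 4.0 * np.pi * rp.area / rp.perimeter**2 if rp.perimeter > 0 else 0.0
        circ = min(circ, 1.0)
        if not (area_gate_um2[0] <= area_um2 <= area_gate_um2[1]):
            continue
        if not (diameter_gate_um[0] <= diam_um <= diameter_gate_um[1]):
            continue
        if circ < circularity_gate:
            continue
        mask = labels == rp.label
        records.append(
            CellRecord(
                id=len(records) + 1,
                centroid=(float(z), float(rp.centroid[0]), float(rp.centroid[1])),
                mask=mask,
                area_um2=float(area_um2),
                equiv_diameter_um=float(diam_um),
                circularity=float(circ),
                median_gfp=float(np.median(gfp_plane[mask])),
            )
        )
    return records


def expression_threshold(
    median_brightnesses: np.ndarray,
    max_components: int = 3,
    seed: int = 0,
) -> tuple[float, GaussianMixture]:
    """GMM positivity threshold: mu_low + 2 sigma_low of the fitted mixture.

    Mixtures with 1..max_components components are fitted with
    quantile-seeded initialization; the component count is chosen by BIC
    (ties toward fewer components).  The threshold is the mean plus twice
    the SD of the lowest-mean component.
    """
    x = np.asarray(median_brightnesses, dtype=float).reshape(-1, 1)
    if x.size < 10:
        raise ValueError("need at least 10 cells for the mixture fit")
    if np.ptp(x) == 0:
        warnings.warn("degenerate brightness distribution; all cells non-positive")
        gm = GaussianMixture(n_components=1).fit(x + np.random.default_rng(0).normal(0, 1e-9, x.shape))
        return float(x[0, 0]), gm
    best, best_bic = None, np.inf
    for k in range(1, max_components + 1):
        means = np.quantile(x, np.linspace(0.1, 0.9, k)).reshape(-1, 1)
        gm = GaussianMixture(
            n_components=k,
            means_init=means,
            n_init=10,
            random_state=seed,
            reg_covar=1e-6,
        ).fit(x)
        bic = gm.bic(x)
        if bic < best_bic - 1e-9:  # strict improvement: ties keep fewer components
            best, best_bic = gm, bic
    low = int(np.argmin(best.means_.ravel()))
    mu = float(best.means_.ravel()[low])
    sd = float(np.sqrt(best.covariances_.ravel()[low]))
    return mu + 2.0 * sd, best


def call_positivity(records: list[CellRecord], threshold: float) -> None:
    """Set the ``positive`` flag: median GFP brightness above threshold."""
    for rec in records:
        rec.positive = bool(rec.median_gfp > threshold)


def expression_rate_and_density(
    records: list[CellRecord],
    region_area_mm2: float,
    gmm: GaussianMixture | None = None,
    threshold: float = float("nan"),
) -> ExpressionSummary:
    """Expression rate (%) and soma density from called records."""
    n_ctx = len(records)
    n_pos = sum(1 for r in records if r.positive)
    rate = 100.0 * n_pos / n_ctx if n_ctx else float("nan")
    density = n_ctx / region_area_mm2 if region_area_mm2 > 0 else float("nan")
    if gmm is not None:
        means = gmm.means_.ravel()
        sds = np.sqrt(gmm.covariances_.ravel())
        weights = gmm.weights_.ravel()
    else:
        means = sds = weights = np.empty(0)
    return ExpressionSummary(
        n_context_positive=n_ctx,
        n_gfp_positive=n_pos,
        expression_rate=rate,
        density_per_mm2=density,
        gmm_means=means,
        gmm_sds=sds,
        gmm_weights=weights,
        threshold=threshold,
    )


def find_centroids_meanshift(
    stack: ImageStack, bandwidth_um: float = MEANSHIFT_BANDWIDTH_UM
) -> np.ndarray:
    """Mean-shift soma centroids on the central context plane.

    Above-background pixels (Otsu) are clustered with a physical
    bandwidth (default 6.5 µm converted to pixels); returns (y, x)
    centres in pixels.
    """
    z = central_plane(stack)
    plane = stack.context[z].astype(float)
    if plane.max() <= plane.min():
        return np.empty((0, 2))
    thr = threshold_otsu(plane)
    coords = np.column_stack(np.nonzero(plane > thr)).astype(float)
    if coords.shape[0] == 0:
        return np.empty((0, 2))
    bw_px = bandwidth_um / stack.pixel_size
    ms = MeanShift(bandwidth=bw_px, bin_seeding=True, min_bin_freq=5)
    ms.fit(coords)
    return ms.cluster_centers_


def membrane_mask(
    stack: ImageStack, background_sd_mult: float = 3.0
) -> np.ndarray:
    """Fixed-threshold cell mask on the central context plane.

    The threshold is the background mean plus ``background_sd_mult``
    background SDs, background taken as pixels below Otsu.
    """
    z = central_plane(stack)
    plane = stack.context[z].astype(float)
    otsu = threshold_otsu(plane)
    bg = plane[plane <= otsu]
    thr = bg.mean() + background_sd_mult * bg.std()
    return plane > thr


def has_nucleus(stack: ImageStack, rec: CellRecord, dip_frac: float = 0.7) -> bool:
    """Automated nucleus surrogate: central-plane interior GFP dip.

    True when the minimum GFP inside the eroded mask falls below
    ``dip_frac`` of the cytoplasm median.
    """
    z = int(rec.centroid[0])
    gfp = stack.gfp[z].astype(float)
    from scipy.ndimage import binary_erosion

    interior = binary_erosion(rec.mask, iterations=3)
    if not interior.any():
        return False
    vals = gfp[interior]
    med = np.median(vals)
    return bool(med > 0 and vals.min() < dip_frac * med)


def line_profiles(
    stack: ImageStack,
    rec: CellRecord,
    all_masks: np.ndarray | None = None,
    n_rays: int = N_RAYS,
    require_nucleus: bool = True,
) -> CellRecord:
    """Inward line profiles perpendicular to the membrane mask boundary.

    ``n_rays`` radial rays leave the centroid; each is anchored at the
    outermost crossing of the cell mask (the membrane) and sampled
    inward at 0.1 µm steps on the GFP channel.  Rays whose outward
    extension touches another cell's mask are discarded; cells with
    fewer than three surviving rays, without a membrane mask, or (when
    ``require_nucleus``) without a detectable nuclear dip are excluded.
    The kept profile is the mean over surviving rays; the membrane ratio
    is filled in from it.
    """
    if not rec.mask.any():
        rec.excluded, rec.exclusion_reason = True, "no membrane mask"
        return rec
    if require_nucleus and not has_nucleus(stack, rec):
        rec.excluded, rec.exclusion_reason = True, "no discernible nucleus"
        return rec

    z = int(rec.centroid[0])
    gfp = stack.gfp[z].astype(float)
    px = stack.pixel_size
    cy, cx = rec.centroid[1], rec.centroid[2]
    step_px = PROFILE_STEP_UM / px
    n_steps = int(PROFILE_LENGTH_UM / PROFILE_STEP_UM) + 1
    ny, nx = rec.mask.shape
    others = None
    if all_masks is not None:
        others = all_masks & ~rec.mask

    kept = []
    max_r_px = np.sqrt(rec.mask.sum() / np.pi) * 2.5 + 5
    for ang in np.linspace(0.0, 2.0 * np.pi, n_rays, endpoint=False):
        dy, dx = np.sin(ang), np.cos(ang)
        # outermost crossing of the mask along the outward ray
        rr = np.arange(0.0, max_r_px, 0.25)
        mask_vals = map_coordinates(
            rec.mask.astype(float),
            np.vstack([cy + rr * dy, cx + rr * dx]),
            order=1,
            mode="constant",
        )
        inside = mask_vals >= 0.5
        if not inside.any():
            continue
        j = int(np.nonzero(inside)[0][-1])
        # subpixel membrane position: linear crossing of the 0.5 level
        if j + 1 < rr.size and mask_vals[j] != mask_vals[j + 1]:
            frac = (mask_vals[j] - 0.5) / (mask_vals[j] - mask_vals[j + 1])
            r_edge = rr[j] + frac * (rr[j + 1] - rr[j])
        else:
            r_edge = rr[j]
        # discard rays whose neighbourhood crosses another cell
        if others is not None:
            rr_out = np.arange(0.0, r_edge + 2.0 / px, 0.5)
            yo = np.clip(np.round(cy + rr_out * dy).astype(int), 0, ny - 1)
            xo = np.clip(np.round(cx + rr_out * dx).astype(int), 0, nx - 1)
            if others[yo, xo].any():
                continue
        # sample inward from the membrane
        dist_px = r_edge - np.arange(n_steps) * step_px
        if dist_px[-1] < 0:
            continue
        yy = cy + dist_px * dy
        xx = cx + dist_px * dx
        vals = map_coordinates(gfp, np.vstack([yy, xx]), order=1, mode="nearest")
        kept.append(vals)

    rec.n_profiles = len(kept)
    if rec.n_profiles < MIN_RAYS:
        rec.excluded = True
        rec.exclusion_reason = f"fewer than {MIN_RAYS} clean line profiles"
        return rec
    rec.profile = np.mean(kept, axis=0)
    rec.profile_distance_um = np.arange(n_steps) * PROFILE_STEP_UM
    rec.membrane_ratio = membrane_ratio(rec.profile, rec.profile_distance_um)
    return rec


def membrane_ratio(
    profile: np.ndarray,
    distance_um: np.ndarray,
    membrane_band: tuple[float, float] = MEMBRANE_BAND_UM,
    intracellular_band: tuple[float, float] = INTRACELL_BAND_UM,
    background: float = 0.0,
) -> float:
    """Mean fluorescence 0.4-0.6 µm inside the membrane over 1.4-1.6 µm.

    The distance axis starts at the membrane (0 µm) and runs inward and
    must extend to at least the outer edge of the intracellular band.
    Returns NaN (flagged by the caller) when the denominator does not
    exceed background.
    """
    profile = np.asarray(profile, dtype=float)
    d = np.asarray(distance_um, dtype=float)
    if d.max() < intracellular_band[1] - 1e-9:
        raise ValueError("profile must extend to at least 1.6 µm")
    mem = profile[(d >= membrane_band[0]) & (d <= membrane_band[1])].mean()
    intra = profile[(d >= intracellular_band[0]) & (d <= intracellular_band[1])].mean()
    if intra <= background:
        return float("nan")
    return float(mem / intra)


def peak_normalized(profile: np.ndarray) -> np.ndarray:
    """Profile scaled to unit maximum (for population overlays)."""
    m = np.max(profile)
    return profile / m if m > 0 else profile
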