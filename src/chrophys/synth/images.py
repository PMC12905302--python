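"""Synthetic two-channel confocal stacks of labelled neuron somata.

The context channel (e.g. parvalbumin) shows filled disks; the GFP
channel shows either a bright membrane ring over a dimmer interior
(membrane-targeted construct, "positive" cells) or a dim uniform fill
(negative cells).  Somata are placed by rejection sampling with a
minimum centre distance of 2.2 x radius so they never overlap, median
brightness is drawn from a configurable (typically bimodal) mixture, and
one z-plane carries a central nuclear dip so the nucleus surrogate check
has something to find.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from chrophys.datatypes import ImageStack


@dataclass
class ImageSimParams:
    """Planted parameters for one synthetic stack."""

    image_shape: tuple[int, int, int] = (5, 512, 512)  # z, y, x
    pixel_size: float = 0.15  # µm/px in-plane
    z_step: float = 1.0  # µm
    n_cells: int = 50
    soma_radius_um: float = 5.0
    membrane_thickness_um: float = 0.8
    membrane_gain: float = 2.0  # ring / interior GFP for positive cells
    frac_positive: float = 0.835
    # (mean, sd, weight) of median GFP brightness for negative / positive cells
    brightness_components: tuple[tuple[float, float, float], ...] = (
        (10.0, 2.0, 1.0),
        (100.0, 10.0, 1.0),
    )
    context_brightness: float = 200.0
    nucleus_drop: float = 0.5  # fractional dip at the nuclear z-plane
    nucleus_radius_frac: float = 0.4
    background_sd: float = 0.0
    min_spacing_factor: float = 2.2
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 0.0 <= self.frac_positive <= 1.0:
            raise ValueError("frac_positive must lie in [0, 1]")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.membrane_gain <= 0:
            raise ValueError("membrane_gain must be positive")
        if len(self.brightness_components) < 2:
            raise ValueError("need negative and positive brightness components")


def _place_centers(
    params: ImageSimParams, rng: np.random.Generator
) -> np.ndarray:
    """Rejection-sample non-overlapping (y, x) centres in pixels."""
    _, ny, nx = params.image_shape
    r_px = params.soma_radius_um / params.pixel_size
    min_d = params.min_spacing_factor * r_px
    margin = r_px + 3
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < params.n_cells:
        attempts += 1
        if attempts > 200_000:
            raise RuntimeError("could not place all cells; image too small")
        y = rng.uniform(margin, ny - margin)
        x = rng.uniform(margin, nx - margin)
        if all((y - cy) ** 2 + (x - cx) ** 2 >= min_d**2 for cy, cx in centers):
            centers.append((y, x))
    return np.asarray(centers)


def gen_image_stack(params: ImageSimParams, seed: int) -> ImageStack:
    """Generate a stack with planted masks, positivity labels and ratios.

    ``truth`` holds per-cell centres (px), the label image of the central
    plane, positivity flags, drawn median brightnesses and the planted
    membrane/interior ratio (``membrane_gain`` for positives, 1.0 for
    negatives).
    """
    params.validate()
    rng = np.random.default_rng(seed)
    nz, ny, nx = params.image_shape
    centers = _place_centers(params, rng)
    n = params.n_cells
    n_pos = int(round(params.frac_positive * n))
    positive = np.zeros(n, dtype=bool)
    positive[rng.permutation(n)[:n_pos]] = True

    neg_mean, neg_sd, _ = params.brightness_components[0]
    pos_mean, pos_sd, _ = params.brightness_components[1]
    brightness = np.where(
        positive,
        rng.normal(pos_mean, pos_sd, n),
        rng.normal(neg_mean, neg_sd, n),
    )
    brightness = np.clip(brightness, 0.5, None)

    r_px = params.soma_radius_um / params.pixel_size
    ring_px = params.membrane_thickness_um / params.pixel_size
    z_mid = nz // 2
    yy, xx = np.mgrid[0:ny, 0:nx]

    context = np.zeros((nz, ny, nx), dtype=np.float32)
    gfp = np.zeros((nz, ny, nx), dtype=np.float32)
    labels = np.zeros((ny, nx), dtype=np.int32)

    for k, (cy, cx) in enumerate(centers):
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        for z in range(nz):
            # spherical cap: radius shrinks away from the central plane
            dz_um = abs(z - z_mid) * params.z_step
            rz2 = params.soma_radius_um**2 - dz_um**2
            if rz2 <= 0:
                continue
            rz_px = np.sqrt(rz2) / params.pixel_size
            disk = d2 <= rz_px**2
            context[z][disk] = params.context_brightness
            if z == z_mid:
                labels[disk] = k + 1
            if positive[k]:
                # interior carries the drawn median brightness; the ring is
                # membrane_gain times brighter, so ratio truth == gain
                inner = d2 <= (rz_px - ring_px) ** 2
                ring = disk & ~inner
                gfp[z][ring] = np.maximum(
                    gfp[z][ring], brightness[k] * params.membrane_gain
                )
                gfp[z][inner] = np.maximum(gfp[z][inner], brightness[k])
                if z == z_mid and params.nucleus_drop > 0:
                    nuc = d2 <= (params.nucleus_radius_frac * rz_px) ** 2
                    gfp[z][nuc] = brightness[k] * (1.0 - params.nucleus_drop)
            else:
                gfp[z][disk] = np.maximum(gfp[z][disk], brightness[k])
                if z == z_mid and params.nucleus_drop > 0:
                    nuc = d2 <= (params.nucleus_radius_frac * rz_px) ** 2
                    gfp[z][nuc] = brightness[k] * (1.0 - params.nucleus_drop)

    data = np.stack([context, gfp]).astype(np.float32)
    if params.background_sd > 0:
        data = data + rng.normal(0.0, params.background_sd, size=data.shape).astype(
            np.float32
        )

    truth = {
        "centers_px": centers,
        "labels_central": labels,
        "central_plane": z_mid,
        "positive": positive,
        "median_brightness": brightness,
        "membrane_ratio": np.where(positive, params.membrane_gain, 1.0),
        "frac_positive": n_pos / n if n else np.nan,
        "soma_radius_um": params.soma_radius_um,
    }
    return ImageStack(
        data=data,
        pixel_size=params.pixel_size,
        z_step=params.z_step,
        meta=dict(params.meta),
        truth=truth,
    )
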