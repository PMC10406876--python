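"""Ground-truthed synthetic data generators.

Three generators with known ground truth:

* two-channel nuclear foci images with a planted colocalized fraction,
  PSF blur and camera noise, for correlation-based colocalization tests;
* z-stacks of well-separated bright puncta for spot-counting tests;
* per-cell cohort tables (counts + fractions) drawn from group-level
  means/SDs for statistics tests.

Every generator takes an explicit seed and is bit-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PlacementError, ValidationError
from .io_masks import MultiChannelImage
from .pla import SpotStack


@dataclass
class NoiseModel:
    """Camera noise: Poisson shot noise and/or additive Gaussian read noise."""

    poisson: bool = True
    gaussian_sigma: float = 0.0

    def apply(self, img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = np.asarray(img, dtype=float)
        if self.poisson:
            out = rng.poisson(np.clip(out, 0, None)).astype(float)
        if self.gaussian_sigma > 0:
            out = out + rng.normal(0.0, self.gaussian_sigma, size=out.shape)
        return np.clip(out, 0, None)


NO_NOISE = NoiseModel(poisson=False, gaussian_sigma=0.0)


@dataclass
class FociSimParams:
    """Parameters for the two-channel nuclear foci simulator."""

    image_size_px: tuple[int, int] = (128, 128)
    nucleus_center: tuple[float, float] | None = None  # (y, x); default image center
    nucleus_semi_axes: tuple[float, float] = (50.0, 58.0)  # (a_y, a_x)
    n_foci_a: int = 50
    n_foci_b: int = 50
    f_true: float = 0.5
    psf_sigma_px: float = 2.0
    amplitude_mean: float = 100.0
    amplitude_cv: float = 0.3
    background: float = 5.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    jitter_nm: float = 0.0
    pixel_size_nm: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_true <= 1.0):
            raise ValidationError("f_true must be in [0, 1]")
        if self.n_foci_a < 1 or self.n_foci_b < 1:
            raise ValidationError("need at least one focus per channel")
        if self.psf_sigma_px <= 0:
            raise ValidationError("psf_sigma_px must be positive")
        if self.amplitude_mean <= 0 or self.amplitude_cv < 0:
            raise ValidationError("amplitude parameters must be positive")
        if self.background < 0:
            raise ValidationError("background must be >= 0")
        h, w = self.image_size_px
        cy, cx = self.center
        ay, ax = self.nucleus_semi_axes
        if cy - ay < 0 or cy + ay > h or cx - ax < 0 or cx + ax > w:
            raise ValidationError("nucleus ellipse must fit inside the image")
        # crude packing heuristic: each focus needs ~psf_sigma^2 of area
        area = np.pi * ay * ax
        if max(self.n_foci_a, self.n_foci_b) > area / max(1.0, self.psf_sigma_px**2):
            raise ValidationError("foci count exceeds nucleus area heuristic")

    @property
    def center(self) -> tuple[float, float]:
        if self.nucleus_center is not None:
            return self.nucleus_center
        return (self.image_size_px[0] / 2.0, self.image_size_px[1] / 2.0)


@dataclass
class CohortParams:
    """Group-level cohort spec: (name, n_cells, pla_mean, pla_sd, f_mean, f_sd)."""

    groups: list[tuple[str, int, float, float, float, float]]
    seed: int = 0

    def __post_init__(self) -> None:
        names = [g[0] for g in self.groups]
        if len(set(names)) != len(names):
            raise ValidationError("group names must be unique")
        for name, n_cells, _, pla_sd, _, f_sd in self.groups:
            if n_cells < 2:
                raise ValidationError(f"group {name}: n_cells must be >= 2")
            if pla_sd < 0 or f_sd < 0:
                raise ValidationError(f"group {name}: SDs must be >= 0")


@dataclass
class GroundTruth:
    """Planted object coordinates and support for recovery tests."""

    foci_coords_a: np.ndarray | None = None  # (n, 2) of (y, x)
    foci_coords_b: np.ndarray | None = None
    shared_indices: list[tuple[int, int]] = field(default_factory=list)
    nucleus_mask_true: np.ndarray | None = None
    planted_spot_coords: np.ndarray | None = None  # (n, 3) of (z, y, x)


def _lognormal_amplitudes(
    rng: np.random.Generator, n: int, mean: float, cv: float
) -> np.ndarray:
    if cv == 0:
        return np.full(n, mean)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=n)


def _uniform_in_ellipse(
    rng: np.random.Generator,
    n: int,
    center: tuple[float, float],
    semi_axes: tuple[float, float],
) -> np.ndarray:
    """n points uniform inside an axis-aligned ellipse, as (y, x) rows."""
    u = np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0, 2 * np.pi, size=n)
    y = center[0] + semi_axes[0] * u * np.sin(theta)
    x = center[1] + semi_axes[1] * u * np.cos(theta)
    return np.column_stack([y, x])


def _render_gaussians_2d(
    shape: tuple[int, int],
    coords: np.ndarray,
    amplitudes: np.ndarray,
    sigma: float,
) -> np.ndarray:
    """Sum of isotropic 2D Gaussians, each evaluated on a +/- 5 sigma window."""
    img = np.zeros(shape, dtype=float)
    half = int(np.ceil(5 * sigma))
    for (y0, x0), amp in zip(coords, amplitudes):
        yc = int(round(y0))
        xc = int(round(x0))
        ylo, yhi = max(0, yc - half), min(shape[0], yc + half + 1)
        xlo, xhi = max(0, xc - half), min(shape[1], xc + half + 1)
        if ylo >= yhi or xlo >= xhi:
            continue
        yy = np.arange(ylo, yhi)[:, None]
        xx = np.arange(xlo, xhi)[None, :]
        img[ylo:yhi, xlo:xhi] += amp * np.exp(
            -((yy - y0) ** 2 + (xx - x0) ** 2) / (2 * sigma**2)
        )
    return img


def ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    semi_axes: tuple[float, float],
) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((yy - center[0]) / semi_axes[0]) ** 2 + (
        (xx - center[1]) / semi_axes[1]
    ) ** 2 <= 1.0


def simulate_two_channel(
    params: FociSimParams,
) -> tuple[MultiChannelImage, GroundTruth]:
    """Render a two-channel nuclear foci image with a planted coloc fraction.

    ``round(f_true * min(n_a, n_b))`` foci are placed at identical
    coordinates in both channels (with optional sub-PSF jitter); the rest
    are placed independently, uniformly inside the nucleus ellipse.  The
    shared foci reuse one amplitude draw in both channels, modeling a
    single labeled complex, so amplitude scatter does not dilute the
    planted cross-correlation amplitude.
    """
    rng = np.random.default_rng(params.seed)
    n_shared = round(params.f_true * min(params.n_foci_a, params.n_foci_b))
    shared = _uniform_in_ellipse(
        rng, n_shared, params.center, params.nucleus_semi_axes
    )
    only_a = _uniform_in_ellipse(
        rng, params.n_foci_a - n_shared, params.center, params.nucleus_semi_axes
    )
    only_b = _uniform_in_ellipse(
        rng, params.n_foci_b - n_shared, params.center, params.nucleus_semi_axes
    )
    coords_a = np.vstack([shared, only_a])
    coords_b_shared = shared.copy()
    if params.jitter_nm > 0 and n_shared:
        coords_b_shared += rng.normal(
            0.0, params.jitter_nm / params.pixel_size_nm, size=coords_b_shared.shape
        )
    coords_b = np.vstack([coords_b_shared, only_b])

    amp_shared = _lognormal_amplitudes(
        rng, n_shared, params.amplitude_mean, params.amplitude_cv
    )
    amp_a = np.concatenate(
        [
            amp_shared,
            _lognormal_amplitudes(
                rng, len(only_a), params.amplitude_mean, params.amplitude_cv
            ),
        ]
    )
    amp_b = np.concatenate(
        [
            amp_shared,
            _lognormal_amplitudes(
                rng, len(only_b), params.amplitude_mean, params.amplitude_cv
            ),
        ]
    )

    shape = params.image_size_px
    mask = ellipse_mask(shape, params.center, params.nucleus_semi_axes)
    img_a = _render_gaussians_2d(shape, coords_a, amp_a, params.psf_sigma_px)
    img_b = _render_gaussians_2d(shape, coords_b, amp_b, params.psf_sigma_px)
    img_a += params.background * mask
    img_b += params.background * mask
    img_a = params.noise.apply(img_a, rng)
    img_b = params.noise.apply(img_b, rng)

    image = MultiChannelImage(
        channels=[img_a, img_b],
        pixel_size_nm=params.pixel_size_nm,
        channel_labels=["A", "B"],
    )
    truth = GroundTruth(
        foci_coords_a=coords_a,
        foci_coords_b=coords_b,
        shared_indices=[(i, i) for i in range(n_shared)],
        nucleus_mask_true=mask,
    )
    return image, truth


def simulate_pla_stack(
    n_spots: int,
    stack_size: tuple[int, int, int] = (12, 64, 64),
    psf_sigma: tuple[float, float] = (1.0, 1.5),
    min_separation_px: float = 10.0,
    amplitude: float = 100.0,
    background: float = 5.0,
    noise: NoiseModel | None = None,
    seed: int = 0,
    max_tries: int = 10000,
) -> tuple[SpotStack, GroundTruth]:
    """Render a z-stack of well-separated Gaussian puncta.

    Spot centers are rejection-sampled until every pair is at least
    ``min_separation_px`` apart (Euclidean, in voxel units, with the z
    axis unscaled); exceeding the retry cap raises ``PlacementError``.
    """
    if n_spots < 0:
        raise ValidationError("n_spots must be >= 0")
    rng = np.random.default_rng(seed)
    nz, ny, nx = stack_size
    sz, sxy = psf_sigma
    margin_z = max(1.0, 2 * sz)
    margin_xy = max(1.0, 2 * sxy)
    coords: list[np.ndarray] = []
    tries = 0
    while len(coords) < n_spots:
        tries += 1
        if tries > max_tries:
            raise PlacementError(
                f"could not place {n_spots} spots at separation "
                f">= {min_separation_px} within {max_tries} tries"
            )
        cand = np.array(
            [
                rng.uniform(margin_z, nz - margin_z),
                rng.uniform(margin_xy, ny - margin_xy),
                rng.uniform(margin_xy, nx - margin_xy),
            ]
        )
        if all(np.linalg.norm(cand - c) >= min_separation_px for c in coords):
            coords.append(cand)
    vol = np.full(stack_size, float(background))
    zz = np.arange(nz)[:, None, None]
    yy = np.arange(ny)[None, :, None]
    xx = np.arange(nx)[None, None, :]
    for z0, y0, x0 in coords:
        vol += amplitude * np.exp(
            -((zz - z0) ** 2) / (2 * sz**2)
            - ((yy - y0) ** 2 + (xx - x0) ** 2) / (2 * sxy**2)
        )
    noise_model = noise if noise is not None else NoiseModel()
    vol = noise_model.apply(vol, rng)
    stack = SpotStack(voxels=vol)
    truth = GroundTruth(
        planted_spot_coords=(
            np.array(coords) if coords else np.empty((0, 3))
        )
    )
    return stack, truth


def simulate_cohort(params: CohortParams) -> pd.DataFrame:
    """Draw a per-cell cohort table of (group, cell_id, pla_count, f_iccs).

    PLA counts: normal(mean, sd), rounded, floored at 0.  Fractions:
    normal(mean, sd) clamped to [0, 1].  Normal draws are the minimal
    assumption consistent with the group-level mean +/- SD summaries
    being emulated.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    for name, n_cells, pla_mean, pla_sd, f_mean, f_sd in params.groups:
        counts = np.maximum(
            0, np.rint(rng.normal(pla_mean, pla_sd, size=n_cells))
        ).astype(int)
        fracs = np.clip(rng.normal(f_mean, f_sd, size=n_cells), 0.0, 1.0)
        for i in range(n_cells):
            rows.append(
                {
                    "group": name,
                    "cell_id": i,
                    "pla_count": int(counts[i]),
                    "f_iccs": float(fracs[i]),
                }
            )
    return pd.DataFrame(rows, columns=["group", "cell_id", "pla_count", "f_iccs"])
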