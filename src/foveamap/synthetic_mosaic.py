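"""Seeded synthetic foveolar cone mosaics: ground-truth coordinates + rendered
confocal-AOSLO-like images.

The generator emulates the statistical structure of foveal cone montages:
quasi-hexagonal packing with a steep central density peak and exponential
radial falloff, per-cone reflectivity variation with occasional near-dark
cells (wave-guiding dropout), diffraction-limited Gaussian blur and detector
noise. All randomness is driven by the spec's seed, so a (spec, seed) pair
determines the sample bit-exactly.

Positions are produced by density-weighted dart throwing followed by Lloyd
(centroidal) relaxation sweeps: darts are thrown with an exclusion distance of
0.7x the local perfect-hexagon spacing until the target count (the integral of
the density profile over the field) is reached, and relaxation then pushes the
configuration toward hexagonal regularity without changing the count. Throwing
darts at the full hexagon spacing would jam well below the target density
(random sequential adsorption saturates near 55% coverage), so the count, not
the radius, carries the density; relaxation restores the spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .core import ConeSet

SQRT3 = math.sqrt(3.0)

__all__ = [
    "MosaicSpec",
    "SyntheticSample",
    "generate_positions",
    "render",
    "make_dataset",
    "hex_spacing",
]


@dataclass(frozen=True)
class MosaicSpec:
    """Generative parameters of a synthetic foveal mosaic.

    Densities are in cones/deg^2; the default profile (peak 15,000, base
    6,000, falloff 0.5 deg) is of the physiological order of foveal cone
    topography but is a synthetic choice, not a measured profile.
    """

    field_size_px: tuple[int, int] = (600, 600)  # (height, width)
    scale_px_per_deg: float = 600.0
    peak_density_deg2: float = 15_000.0
    base_density_deg2: float = 6_000.0
    falloff_scale_deg: float = 0.5
    reflectivity_cv: float = 0.3
    dropout_fraction: float = 0.03
    psf_fwhm_px: float = 3.0
    noise_sd: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        h, w = self.field_size_px
        if h <= 0 or w <= 0:
            raise ValueError("field_size_px must be positive")
        if self.scale_px_per_deg <= 0:
            raise ValueError("scale_px_per_deg must be positive")
        if self.peak_density_deg2 <= 0 or self.base_density_deg2 < 0:
            raise ValueError("densities must be positive (peak) / non-negative (base)")
        if self.peak_density_deg2 < self.base_density_deg2:
            raise ValueError("peak_density_deg2 must be >= base_density_deg2")
        if self.falloff_scale_deg <= 0:
            raise ValueError("falloff_scale_deg must be positive")
        if self.reflectivity_cv < 0:
            raise ValueError("reflectivity_cv must be >= 0")
        if not (0.0 <= self.dropout_fraction < 1.0):
            raise ValueError("dropout_fraction must be in [0, 1)")
        if self.psf_fwhm_px <= 0:
            raise ValueError("psf_fwhm_px must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        peak_px2 = self.peak_density_deg2 / self.scale_px_per_deg**2
        if hex_spacing(peak_px2) < 1.0:
            raise ValueError(
                "peak density implies a cone spacing below 1 px at this scale; "
                "the mosaic is unresolvable — lower the density or raise the scale"
            )

    def density_px2(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Local density in cones/px^2 at pixel positions (x, y)."""
        h, w = self.field_size_px
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
        r_deg = np.hypot(x - cx, y - cy) / self.scale_px_per_deg
        rho_deg2 = self.base_density_deg2 + (
            self.peak_density_deg2 - self.base_density_deg2
        ) * np.exp(-r_deg / self.falloff_scale_deg)
        return rho_deg2 / self.scale_px_per_deg**2


@dataclass
class SyntheticSample:
    """A rendered mosaic image in [0, 1] with its ground-truth cone centers."""

    image: np.ndarray
    cones: ConeSet
    spec: MosaicSpec


def hex_spacing(density: float | np.ndarray) -> float | np.ndarray:
    """Perfect-hexagon nearest-neighbor spacing for a given point density.

    A hexagonal lattice with spacing s has density 2/(sqrt(3)*s^2), so
    s = sqrt(2/(sqrt(3)*rho)).
    """
    return np.sqrt(2.0 / (SQRT3 * np.asarray(density, dtype=float)))


def _dart_throw(spec: MosaicSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.field_size_px
    yy, xx = np.mgrid[0:h, 0:w]
    rho = spec.density_px2(xx.ravel().astype(float), yy.ravel().astype(float))
    n_target = int(round(rho.sum()))
    if n_target < 1:
        raise ValueError("density profile integrates to fewer than one cone")
    rho_max = float(rho.max())

    pts: list[np.ndarray] = []
    accepted = np.empty((0, 2))
    max_attempts = 400 * n_target + 10_000
    attempts = 0
    batch = max(256, n_target)
    while len(pts) < n_target and attempts < max_attempts:
        cand = rng.uniform(size=(batch, 2)) * np.array([w - 1.0, h - 1.0])
        u = rng.uniform(size=batch)
        attempts += batch
        rho_c = spec.density_px2(cand[:, 0], cand[:, 1])
        keep = u < rho_c / rho_max
        for c, r in zip(cand[keep], rho_c[keep]):
            excl = 0.7 * hex_spacing(r)
            if accepted.shape[0]:
                if np.min(np.hypot(accepted[:, 0] - c[0], accepted[:, 1] - c[1])) < excl:
                    continue
            pts.append(c)
            accepted = np.asarray(pts)
            if len(pts) >= n_target:
                break
    return np.asarray(pts)


def _lloyd_relax(points: np.ndarray, spec: MosaicSpec, sweeps: int = 30) -> np.ndarray:
    """Density-weighted discrete centroidal relaxation on the pixel grid."""
    h, w = spec.field_size_px
    yy, xx = np.mgrid[0:h, 0:w]
    px = np.column_stack([xx.ravel().astype(float), yy.ravel().astype(float)])
    wgt = spec.density_px2(px[:, 0], px[:, 1])
    pts = points.copy()
    n = pts.shape[0]
    for _ in range(sweeps):
        _, owner = cKDTree(pts).query(px)
        sw = np.bincount(owner, weights=wgt, minlength=n)
        sx = np.bincount(owner, weights=wgt * px[:, 0], minlength=n)
        sy = np.bincount(owner, weights=wgt * px[:, 1], minlength=n)
        nz = sw > 0
        pts[nz, 0] = sx[nz] / sw[nz]
        pts[nz, 1] = sy[nz] / sw[nz]
    return pts


def generate_positions(spec: MosaicSpec, relax_sweeps: int = 30) -> ConeSet:
    """Generate ground-truth cone centers following the spec's density profile.

    Local point density follows rho(r) = base + (peak - base) * exp(-r / falloff)
    within sampling tolerance; packing is quasi-hexagonal after relaxation.
    Deterministic given the spec (including its seed).
    """
    spec.validate()
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([spec.seed, 0])))
    pts = _dart_throw(spec, rng)
    if relax_sweeps > 0 and pts.shape[0] >= 4:
        pts = _lloyd_relax(pts, spec, sweeps=relax_sweeps)
    h, w = spec.field_size_px
    pts[:, 0] = np.clip(pts[:, 0], 0.0, w - 1.0)
    pts[:, 1] = np.clip(pts[:, 1], 0.0, h - 1.0)
    return ConeSet(pts, scale_px_per_deg=spec.scale_px_per_deg)


def render(cones: ConeSet, spec: MosaicSpec) -> SyntheticSample:
    """Render a confocal-like image of the mosaic.

    Per-cone amplitudes are lognormal with unit mean and CV =
    ``reflectivity_cv``; a ``dropout_fraction`` subset is scaled to 5%
    amplitude (wave-guiding reflectivity loss). Sub-pixel impulses are splatted
    bilinearly, blurred with a Gaussian PSF of the given FWHM, detector noise
    is added, and the result is min-max normalized to [0, 1].
    """
    spec.validate()
    if len(cones) == 0:
        raise ValueError("cannot render an empty cone set")
    h, w = spec.field_size_px
    xy = cones.xy
    if np.any(xy[:, 0] < 0) or np.any(xy[:, 0] > w - 1) or np.any(
        xy[:, 1] < 0
    ) or np.any(xy[:, 1] > h - 1):
        raise ValueError("cone coordinates outside the field")

    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([spec.seed, 1])))
    n = len(cones)
    if spec.reflectivity_cv > 0:
        sigma2 = math.log(1.0 + spec.reflectivity_cv**2)
        amps = rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=n)
    else:
        amps = np.ones(n)
    if spec.dropout_fraction > 0:
        n_drop = int(round(spec.dropout_fraction * n))
        drop_idx = rng.choice(n, size=n_drop, replace=False)
        amps[drop_idx] *= 0.05

    img = np.zeros((h, w), dtype=float)
    x0 = np.clip(np.floor(xy[:, 0]).astype(int), 0, w - 2) if w > 1 else np.zeros(n, int)
    y0 = np.clip(np.floor(xy[:, 1]).astype(int), 0, h - 2) if h > 1 else np.zeros(n, int)
    fx, fy = xy[:, 0] - x0, xy[:, 1] - y0
    np.add.at(img, (y0, x0), amps * (1 - fx) * (1 - fy))
    np.add.at(img, (y0, np.minimum(x0 + 1, w - 1)), amps * fx * (1 - fy))
    np.add.at(img, (np.minimum(y0 + 1, h - 1), x0), amps * (1 - fx) * fy)
    np.add.at(img, (np.minimum(y0 + 1, h - 1), np.minimum(x0 + 1, w - 1)), amps * fx * fy)

    sigma = spec.psf_fwhm_px / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    img = gaussian_filter(img, sigma=sigma, mode="constant")
    if spec.noise_sd > 0:
        img = img + rng.normal(scale=spec.noise_sd * img.max(), size=img.shape)
    lo, hi = img.min(), img.max()
    if hi > lo:
        img = (img - lo) / (hi - lo)
    else:
        img = np.zeros_like(img)
    return SyntheticSample(image=img, cones=cones, spec=spec)


def make_dataset(n: int, spec: MosaicSpec, seed: int) -> list[SyntheticSample]:
    """Generate ``n`` independent samples with per-sample derived seeds."""
    if n < 1:
        raise ValueError("n must be >= 1")
    spec.validate()
    child_seeds = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    samples = []
    for s in child_seeds:
        sub = replace(spec, seed=int(s) % (2**31))
        cones = generate_positions(sub)
        samples.append(render(cones, sub))
    return samples
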