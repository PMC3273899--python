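"""Synthetic nucleus generator: lamina shells with known geometry and intensity.

Real confocal stacks of GFP-tagged lamina are not generally available with
ground truth, so every downstream stage (segmentation, curvature, features,
classification) is validated against simulated nuclei whose surface geometry,
Gaussian curvature and intensity distribution are known analytically or
semi-analytically.

A nucleus is modelled as a star-shaped closed surface given by a radial
function over sphere directions,

    r(theta, phi) = r_ellipsoid(theta, phi) * (1 + wrinkles + blebs),

where the wrinkle field is a band-limited random real spherical-harmonic
expansion (degrees 2..L) and blebs are localised Gaussian radial bumps.  The
lamina is rasterised as a shell of finite thickness at elevated intensity over
a dim nucleoplasm interior, optionally with contiguous high-intensity hotspot
patches (spherical caps), then passed through a simple microscope model
(anisotropic Gaussian blur, Poisson shot noise, Gaussian read noise, constant
background).

Three phenotype templates emulate the cell states of interest:

``fresh``
    near-ellipsoidal smooth shell, bright lamina over dim nucleoplasm;
``senescent``
    wrinkled shell with local lamin accumulation (hotspots) and a reduced
    lamina-to-nucleoplasm intensity ratio (lamin redistributes inward);
``apoptotic``
    strongly folded shell with blebs and the highest curvature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator
from scipy.special import sph_harm_y
import trimesh

from .stack_io import ImageStack, write_stack

__all__ = [
    "NucleusPhenotype",
    "GroundTruth",
    "PHENOTYPE_TEMPLATES",
    "make_surface",
    "rasterize",
    "apply_microscope",
    "simulate_population",
]

#: nucleoplasm baseline intensity in arbitrary counts; the lamina shell is
#: ``lamina_to_nucleoplasm_ratio`` times brighter
BASE_INTENSITY = 100.0


@dataclass(frozen=True)
class NucleusPhenotype:
    """Geometry and intensity template for one cell state.

    Parameters
    ----------
    semiaxes
        Ellipsoid semi-axes (a, b, c) in nm along (x, y, z); hMSC nuclei are
        oblate, so c (axial) is the smallest.
    wrinkle_amplitude
        RMS radial perturbation as a fraction of the local radius; 0 disables.
    wrinkle_degree_max
        Spherical-harmonic band limit L; wrinkle power lives in degrees 2..L.
    n_blebs
        Number of localised Gaussian protrusions.
    bleb_amplitude, bleb_width_rad
        Height (fraction of radius) and angular sigma of each bleb.
    hotspot_fraction
        Fraction of the shell surface covered by high-intensity caps.
    n_hotspots
        Number of caps the hotspot area is split into.
    hotspot_gain
        Multiplicative intensity factor inside hotspot caps (>= 1).
    lamina_to_nucleoplasm_ratio
        Shell / interior intensity ratio (> 1).
    shell_thickness
        Radial lamina thickness in nm.
    """

    semiaxes: tuple[float, float, float] = (2200.0, 1900.0, 1400.0)
    wrinkle_amplitude: float = 0.0
    wrinkle_degree_max: int = 8
    n_blebs: int = 0
    bleb_amplitude: float = 0.2
    bleb_width_rad: float = 0.35
    hotspot_fraction: float = 0.0
    n_hotspots: int = 2
    hotspot_gain: float = 1.0
    lamina_to_nucleoplasm_ratio: float = 4.0
    shell_thickness: float = 300.0

    def validate(self) -> None:
        if any(a <= 0 for a in self.semiaxes):
            raise ValueError("semiaxes must be > 0")
        if not 0.0 <= self.wrinkle_amplitude < 0.5:
            raise ValueError("wrinkle_amplitude must be in [0, 0.5)")
        if self.wrinkle_degree_max < 2:
            raise ValueError("wrinkle_degree_max must be >= 2")
        if self.hotspot_gain < 1.0:
            raise ValueError("hotspot_gain must be >= 1")
        if not 0.0 <= self.hotspot_fraction < 1.0:
            raise ValueError("hotspot_fraction must be in [0, 1)")
        if self.lamina_to_nucleoplasm_ratio <= 1.0:
            raise ValueError("lamina_to_nucleoplasm_ratio must be > 1")
        if self.shell_thickness <= 0 or self.n_blebs < 0 or self.n_hotspots < 1:
            raise ValueError("invalid phenotype parameters")


#: templates for the simulated cell states; see module docstring
PHENOTYPE_TEMPLATES: dict[str, NucleusPhenotype] = {
    "fresh": NucleusPhenotype(
        semiaxes=(2200.0, 1900.0, 1400.0),
        wrinkle_amplitude=0.01,
        wrinkle_degree_max=4,
        lamina_to_nucleoplasm_ratio=5.0,
    ),
    "senescent": NucleusPhenotype(
        semiaxes=(2100.0, 1800.0, 1500.0),
        wrinkle_amplitude=0.08,
        wrinkle_degree_max=8,
        hotspot_fraction=0.2,
        hotspot_gain=2.0,
        lamina_to_nucleoplasm_ratio=3.0,
    ),
    "apoptotic": NucleusPhenotype(
        semiaxes=(1600.0, 1400.0, 1200.0),
        wrinkle_amplitude=0.16,
        wrinkle_degree_max=10,
        n_blebs=4,
        hotspot_fraction=0.1,
        hotspot_gain=1.6,
        lamina_to_nucleoplasm_ratio=3.0,
    ),
}

# parametric grid resolution (theta midpoint rule avoids the poles)
_N_THETA = 180
_N_PHI = 360


def _grid() -> tuple[np.ndarray, np.ndarray]:
    theta = (np.arange(_N_THETA) + 0.5) * np.pi / _N_THETA
    phi = np.arange(_N_PHI) * 2 * np.pi / _N_PHI
    return theta, phi


def _directions(theta: np.ndarray, phi: np.ndarray) -> tuple[np.ndarray, ...]:
    """Unit vectors (ux, uy, uz) on the theta x phi grid."""
    st, ct = np.sin(theta)[:, None], np.cos(theta)[:, None]
    return st * np.cos(phi)[None, :], st * np.sin(phi)[None, :], ct * np.ones_like(phi)[None, :]


def _ellipsoid_radius(ux, uy, uz, semiaxes) -> np.ndarray:
    a, b, c = semiaxes
    return 1.0 / np.sqrt((ux / a) ** 2 + (uy / b) ** 2 + (uz / c) ** 2)


def ellipsoid_gaussian_curvature(points: np.ndarray, semiaxes) -> np.ndarray:
    """Closed-form Gaussian curvature of an ellipsoid at on-surface points.

    K = 1 / (a^2 b^2 c^2 * (x^2/a^4 + y^2/b^4 + z^2/c^4)^2), in nm^-2.
    """
    a, b, c = semiaxes
    x, y, z = points[..., 0], points[..., 1], points[..., 2]
    s = x**2 / a**4 + y**2 / b**4 + z**2 / c**4
    return 1.0 / (a**2 * b**2 * c**2 * s**2)


def _real_sph_harm_field(rng: np.random.Generator, lmax: int, theta, phi) -> np.ndarray:
    """Random real spherical-harmonic field, degrees 2..lmax, ~unit RMS.

    Each degree gets equal expected power (coefficients ~ N(0, 1/(2l+1))), so
    the band limit controls roughness scale without one degree dominating.
    """
    th = theta[:, None] * np.ones_like(phi)[None, :]
    ph = np.ones_like(theta)[:, None] * phi[None, :]
    out = np.zeros_like(th)
    for l in range(2, lmax + 1):
        sd = 1.0 / np.sqrt(2 * l + 1)
        for m in range(0, l + 1):
            ylm = sph_harm_y(l, m, th, ph)
            if m == 0:
                out += rng.normal(0.0, sd) * ylm.real
            else:
                base = np.sqrt(2.0) * (-1.0) ** m
                out += rng.normal(0.0, sd) * base * ylm.real
                out += rng.normal(0.0, sd) * base * ylm.imag
    return out


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _pad_pole(f: np.ndarray) -> np.ndarray:
    """Pad a (theta, phi) grid by one row across each pole (phi shifted by pi)."""
    shift = _N_PHI // 2
    top = np.roll(f[0:1], shift, axis=1)
    bot = np.roll(f[-1:], shift, axis=1)
    return np.concatenate([top, f, bot], axis=0)


def _fundamental_forms(r: np.ndarray, theta, phi):
    """First/second fundamental forms of x = r(theta,phi)*u via finite differences.

    Returns (E, F, G, L, M, N, dA-element sqrt(EG-F^2)).  phi is periodic;
    theta is padded across the poles with the antipodal phi shift.
    """
    dth = theta[1] - theta[0]
    dph = phi[1] - phi[0]
    th_p = np.concatenate([[theta[0] - dth], theta, [theta[-1] + dth]])
    ux, uy, uz = _directions(th_p, phi)
    rp = _pad_pole(r)
    x = np.stack([rp * ux, rp * uy, rp * uz], axis=-1)
    # wrap phi for periodic differences
    xw = np.concatenate([x[:, -1:], x, x[:, :1]], axis=1)
    x_t = (xw[2:, 1:-1] - xw[:-2, 1:-1]) / (2 * dth)
    x_p = (xw[1:-1, 2:] - xw[1:-1, :-2]) / (2 * dph)
    x_tt = (xw[2:, 1:-1] - 2 * xw[1:-1, 1:-1] + xw[:-2, 1:-1]) / dth**2
    x_pp = (xw[1:-1, 2:] - 2 * xw[1:-1, 1:-1] + xw[1:-1, :-2]) / dph**2
    x_tp = (xw[2:, 2:] - xw[2:, :-2] - xw[:-2, 2:] + xw[:-2, :-2]) / (4 * dth * dph)

    E = np.einsum("ijk,ijk->ij", x_t, x_t)
    F = np.einsum("ijk,ijk->ij", x_t, x_p)
    G = np.einsum("ijk,ijk->ij", x_p, x_p)
    n = np.cross(x_t, x_p)
    norm = np.linalg.norm(n, axis=-1)
    n = n / norm[..., None]
    L = np.einsum("ijk,ijk->ij", x_tt, n)
    M = np.einsum("ijk,ijk->ij", x_tp, n)
    N = np.einsum("ijk,ijk->ij", x_pp, n)
    return E, F, G, L, M, N, norm


@dataclass
class GroundTruth:
    """A star-shaped closed surface with analytic per-sample Gaussian curvature.

    The radial function and curvature are tabulated on a (theta, phi) midpoint
    grid; :meth:`radius` and :meth:`curvature` interpolate to arbitrary
    directions.  Quadrature-based summaries (volume, area, mean |K|) use the
    grid directly.
    """

    theta: np.ndarray
    phi: np.ndarray
    r_grid: np.ndarray
    k_grid: np.ndarray
    label: str = ""
    hotspot_centers: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    hotspot_cap_radius: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        # periodic phi + pole-padded theta for interpolation
        dth = self.theta[1] - self.theta[0]
        th = np.concatenate([[self.theta[0] - dth], self.theta, [self.theta[-1] + dth]])
        ph = np.concatenate([self.phi, [self.phi[0] + 2 * np.pi]])
        self._interp_r = RegularGridInterpolator(
            (th, ph), np.concatenate([_pad_pole(self.r_grid), _pad_pole(self.r_grid)[:, :1]], axis=1),
            method="linear", bounds_error=False, fill_value=None,
        )
        self._interp_k = RegularGridInterpolator(
            (th, ph), np.concatenate([_pad_pole(self.k_grid), _pad_pole(self.k_grid)[:, :1]], axis=1),
            method="linear", bounds_error=False, fill_value=None,
        )

    # -- evaluation ---------------------------------------------------------
    def radius(self, directions: np.ndarray) -> np.ndarray:
        """Radial distance to the surface along unit ``directions`` (n, 3) in (x,y,z)."""
        d = np.asarray(directions, dtype=np.float64)
        th = np.arccos(np.clip(d[..., 2], -1.0, 1.0))
        ph = np.mod(np.arctan2(d[..., 1], d[..., 0]), 2 * np.pi)
        return self._interp_r(np.stack([th, ph], axis=-1))

    def curvature(self, directions: np.ndarray) -> np.ndarray:
        """Gaussian curvature (nm^-2) at the surface point along each direction."""
        d = np.asarray(directions, dtype=np.float64)
        th = np.arccos(np.clip(d[..., 2], -1.0, 1.0))
        ph = np.mod(np.arctan2(d[..., 1], d[..., 0]), 2 * np.pi)
        return self._interp_k(np.stack([th, ph], axis=-1))

    def in_hotspot(self, directions: np.ndarray) -> np.ndarray:
        """Boolean mask: direction falls inside one of the hotspot caps."""
        d = np.asarray(directions, dtype=np.float64)
        if len(self.hotspot_centers) == 0:
            return np.zeros(d.shape[:-1], dtype=bool)
        cosang = d @ self.hotspot_centers.T
        return np.any(cosang >= np.cos(self.hotspot_cap_radius), axis=-1)

    # -- quadrature summaries ------------------------------------------------
    def _area_element(self) -> np.ndarray:
        *_, dA = _fundamental_forms(self.r_grid, self.theta, self.phi)
        return dA * (self.theta[1] - self.theta[0]) * (self.phi[1] - self.phi[0])

    @property
    def enclosed_volume(self) -> float:
        """nm^3, exact quadrature of the radial volume integral r^3 sin(theta)/3."""
        dth = self.theta[1] - self.theta[0]
        dph = self.phi[1] - self.phi[0]
        return float(np.sum(self.r_grid**3 / 3.0 * np.sin(self.theta)[:, None]) * dth * dph)

    @property
    def surface_area(self) -> float:
        return float(self._area_element().sum())

    @property
    def mean_abs_curvature(self) -> float:
        """Area-weighted mean |K| over the surface, nm^-2."""
        dA = self._area_element()
        return float(np.sum(np.abs(self.k_grid) * dA) / dA.sum())

    def total_curvature(self) -> float:
        """Gauss-Bonnet integral of signed K dA; 4*pi for a genus-0 surface."""
        return float(np.sum(self.k_grid * self._area_element()))

    def max_radius(self) -> float:
        return float(self.r_grid.max())

    def to_mesh(self, subdivisions: int = 4) -> tuple[trimesh.Trimesh, np.ndarray]:
        """Triangulate by radial displacement of an icosphere.

        Returns the mesh (vertices in nm, (x, y, z)) and the analytic Gaussian
        curvature sampled at each vertex.
        """
        ico = trimesh.creation.icosphere(subdivisions=subdivisions)
        u = ico.vertices / np.linalg.norm(ico.vertices, axis=1, keepdims=True)
        r = self.radius(u)
        mesh = trimesh.Trimesh(vertices=u * r[:, None], faces=ico.faces, process=False)
        return mesh, self.curvature(u)


def make_surface(phenotype: NucleusPhenotype, seed: int) -> GroundTruth:
    """Build the ground-truth surface for one nucleus, deterministically per seed.

    The radial function is the ellipsoid radius modulated by the wrinkle field
    and bleb bumps.  Gaussian curvature is attached in closed form for the
    unperturbed ellipsoid and by finite differences on the parametric surface
    otherwise.  Perturbations large enough to destroy star-shapedness (radius
    dropping below 20% of the smallest semi-axis) are rejected.
    """
    phenotype.validate()
    rng = np.random.default_rng(seed)
    theta, phi = _grid()
    ux, uy, uz = _directions(theta, phi)
    r_ell = _ellipsoid_radius(ux, uy, uz, phenotype.semiaxes)

    pert = np.zeros_like(r_ell)
    if phenotype.wrinkle_amplitude > 0:
        f = _real_sph_harm_field(rng, phenotype.wrinkle_degree_max, theta, phi)
        w = np.broadcast_to(np.sin(theta)[:, None], f.shape)
        rms = np.sqrt(np.sum(f**2 * w) / np.sum(w))
        pert += phenotype.wrinkle_amplitude * f / rms
    if phenotype.n_blebs > 0:
        centers = _random_unit_vectors(rng, phenotype.n_blebs)
        u = np.stack([ux, uy, uz], axis=-1)
        for c in centers:
            ang = np.arccos(np.clip(u @ c, -1.0, 1.0))
            pert += phenotype.bleb_amplitude * np.exp(-(ang**2) / (2 * phenotype.bleb_width_rad**2))

    r = r_ell * (1.0 + pert)
    if r.min() <= 0.2 * min(phenotype.semiaxes):
        raise ValueError("perturbation too large: surface would self-intersect")

    if phenotype.wrinkle_amplitude == 0 and phenotype.n_blebs == 0:
        pts = np.stack([r * ux, r * uy, r * uz], axis=-1)
        k = ellipsoid_gaussian_curvature(pts, phenotype.semiaxes)
    else:
        E, F, G, L, M, N, _ = _fundamental_forms(r, theta, phi)
        k = (L * N - M**2) / (E * G - F**2)

    if phenotype.hotspot_fraction > 0:
        centers = _random_unit_vectors(rng, phenotype.n_hotspots)
        frac_per_cap = phenotype.hotspot_fraction / phenotype.n_hotspots
        cap_radius = float(np.arccos(1.0 - 2.0 * frac_per_cap))
    else:
        centers = np.zeros((0, 3))
        cap_radius = 0.0

    return GroundTruth(theta, phi, r, k, hotspot_centers=centers,
                       hotspot_cap_radius=cap_radius, seed=seed)


def rasterize(
    truth: GroundTruth,
    phenotype: NucleusPhenotype,
    spacing: tuple[float, float, float] = (50.0, 50.0, 50.0),
    shape: tuple[int, int, int] = (128, 128, 128),
) -> ImageStack:
    """Noiseless voxelisation of the lamina shell on a (z, y, x) grid.

    Shell voxels (radial distance within ``shell_thickness`` inside the
    surface) get the lamina intensity, multiplied by ``hotspot_gain`` inside
    hotspot caps; interior voxels get the nucleoplasm intensity; exterior is 0.
    """
    t = phenotype.shell_thickness
    if t < 2.0 * max(spacing):
        raise ValueError(
            f"shell thickness {t} nm is thinner than 2x the coarsest spacing "
            f"{max(spacing)} nm; the shell would be under-sampled"
        )
    half_extent = min(n * s for n, s in zip(shape, spacing)) / 2.0
    if truth.max_radius() >= half_extent - max(spacing):
        raise ValueError("surface does not fit inside the image volume")

    axes_nm = [(np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)]
    zz, yy, xx = np.meshgrid(*axes_nm, indexing="ij")
    dist = np.sqrt(xx**2 + yy**2 + zz**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.stack([xx, yy, zz], axis=-1) / np.maximum(dist, 1e-9)[..., None]
    r = truth.radius(d.reshape(-1, 3)).reshape(shape)

    shell = (dist >= r - t) & (dist <= r)
    interior = dist < r - t
    lamina = BASE_INTENSITY * phenotype.lamina_to_nucleoplasm_ratio
    img = np.zeros(shape, dtype=np.float64)
    img[interior] = BASE_INTENSITY
    img[shell] = lamina
    if phenotype.hotspot_fraction > 0 and phenotype.hotspot_gain > 1:
        hot = truth.in_hotspot(d.reshape(-1, 3)).reshape(shape)
        img[shell & hot] *= phenotype.hotspot_gain
    return ImageStack(img, spacing, channel_label=f"synthetic lamina ({truth.label})")


def apply_microscope(
    stack: ImageStack,
    psf_sigma: tuple[float, float, float] = (250.0, 100.0, 100.0),
    photon_scale: float = 1.0,
    read_noise_sd: float = 2.0,
    background: float = 5.0,
    seed: int = 0,
) -> ImageStack:
    """Confocal-like forward model: blur, shot noise, read noise, background.

    ``psf_sigma`` is the Gaussian PSF sigma per axis in nm (z, y, x); axial
    blur exceeds lateral blur as in a real confocal.  Shot noise is a Poisson
    draw of ``photon_scale * intensity`` rescaled back, so a constant image c
    keeps mean c with variance c / photon_scale.
    """
    if photon_scale <= 0:
        raise ValueError("photon_scale must be > 0")
    if any(s < 0 for s in psf_sigma):
        raise ValueError("psf_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    img = stack.voxels
    sig_vox = [p / s for p, s in zip(psf_sigma, stack.spacing)]
    if any(s > 0 for s in sig_vox):
        img = ndimage.gaussian_filter(img, sigma=sig_vox)
    if np.isfinite(photon_scale):
        img = rng.poisson(img * photon_scale).astype(np.float64) / photon_scale
    if read_noise_sd > 0:
        img = img + rng.normal(0.0, read_noise_sd, size=img.shape)
    img = np.clip(img + background, 0.0, None)
    return ImageStack(img, stack.spacing, stack.channel_label)


def _jitter_phenotype(
    template: NucleusPhenotype, jitter: float, rng: np.random.Generator
) -> NucleusPhenotype:
    """Perturb continuous template parameters multiplicatively (relative sd = jitter)."""
    if jitter <= 0:
        return template

    def j(v, lo=None, hi=None):
        # draws clipped at 1.5 sigma so jittered nuclei always fit the field of view
        draw = float(np.clip(jitter * rng.standard_normal(), -1.5 * jitter, 1.5 * jitter))
        out = v * (1.0 + draw)
        if lo is not None:
            out = max(out, lo)
        if hi is not None:
            out = min(out, hi)
        return out

    return replace(
        template,
        semiaxes=tuple(j(a) for a in template.semiaxes),
        wrinkle_amplitude=j(template.wrinkle_amplitude, 0.0, 0.45),
        hotspot_fraction=j(template.hotspot_fraction, 0.0, 0.5),
        hotspot_gain=j(template.hotspot_gain, 1.0),
        lamina_to_nucleoplasm_ratio=j(template.lamina_to_nucleoplasm_ratio, 1.2),
    )


def simulate_population(
    phenotypes: dict[str, NucleusPhenotype],
    n_per_label: int,
    jitter: float = 0.1,
    seed: int = 0,
    spacing: tuple[float, float, float] = (50.0, 50.0, 50.0),
    shape: tuple[int, int, int] = (128, 128, 128),
    psf_sigma: tuple[float, float, float] = (250.0, 100.0, 100.0),
    photon_scale: float = 1.0,
    read_noise_sd: float = 2.0,
    background: float = 5.0,
) -> list[tuple[ImageStack, GroundTruth]]:
    """Simulate ``n_per_label`` imaged nuclei per phenotype template.

    Per-cell phenotype parameters are drawn around each label's template with
    relative spread ``jitter``; all randomness (parameter draw, wrinkle phases,
    noise) descends from ``seed`` via spawned generators, so identical seeds
    give bit-identical output.
    """
    if n_per_label < 1:
        raise ValueError("n_per_label must be >= 1")
    ss = np.random.SeedSequence(seed)
    cells: list[tuple[ImageStack, GroundTruth]] = []
    for label in sorted(phenotypes):
        template = phenotypes[label]
        for i in range(n_per_label):
            child = ss.spawn(1)[0]
            rng = np.random.default_rng(child)
            pheno = _jitter_phenotype(template, jitter, rng)
            noise_seed = int(rng.integers(0, 2**31 - 1))
            truth = None
            for _ in range(5):  # rare rejection (self-intersecting draw): retry deterministically
                surf_seed = int(rng.integers(0, 2**31 - 1))
                try:
                    truth = make_surface(pheno, surf_seed)
                    break
                except ValueError:
                    continue
            if truth is None:
                raise ValueError(f"could not draw a valid {label!r} surface after 5 attempts")
            truth.label = label
            stack = rasterize(truth, pheno, spacing=spacing, shape=shape)
            stack = apply_microscope(
                stack, psf_sigma=psf_sigma, photon_scale=photon_scale,
                read_noise_sd=read_noise_sd, background=background, seed=noise_seed,
            )
            cells.append((stack, truth))
    return cells


def save_cell(stack: ImageStack, truth: GroundTruth, phenotype: NucleusPhenotype,
              path_prefix) -> None:
    """Write an OME-TIFF plus a sidecar JSON with phenotype and analytic summary."""
    prefix = Path(path_prefix)
    write_stack(stack, prefix.with_suffix(".ome.tif"))
    sidecar = {
        "label": truth.label,
        "seed": truth.seed,
        "phenotype": {
            "semiaxes": list(phenotype.semiaxes),
            "wrinkle_amplitude": phenotype.wrinkle_amplitude,
            "wrinkle_degree_max": phenotype.wrinkle_degree_max,
            "n_blebs": phenotype.n_blebs,
            "hotspot_fraction": phenotype.hotspot_fraction,
            "hotspot_gain": phenotype.hotspot_gain,
            "lamina_to_nucleoplasm_ratio": phenotype.lamina_to_nucleoplasm_ratio,
            "shell_thickness": phenotype.shell_thickness,
        },
        "true_mean_abs_curvature_nm-2": truth.mean_abs_curvature,
        "true_surface_area_nm2": truth.surface_area,
        "true_volume_nm3": truth.enclosed_volume,
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
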