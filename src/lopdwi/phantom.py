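"""Crossing-fiber digital phantom with a two-compartment signal model.

The phantom rasterizes straight (or piecewise-linear) fiber bundles onto a
voxel grid inside a spherical domain.  Per voxel, each intersecting bundle
contributes a fiber direction (the local centerline tangent) and a volume
fraction proportional to its sub-voxel occupancy; the remainder diffuses
isotropically.  White-matter signal follows a stick + zeppelin
two-compartment model per fiber: an intra-axonal stick (diffusion only
along the fiber) with fraction ``nu`` and an extra-axonal axially
symmetric tensor (zeppelin) with fraction ``1 - nu``:

    E(b, d) / E0 = sum_i f_i * [ nu * exp(-b lpar (d.u_i)^2)
                               + (1-nu) * exp(-b (lperp + (lpar-lperp)(d.u_i)^2)) ]
                   + (1 - sum_i f_i) * exp(-b D_iso)

Rician noise is added at a prescribed SNR relative to the unweighted
signal S0: each noisy sample is ``sqrt((s + n1)^2 + n2^2)`` with
``n1, n2 ~ N(0, sigma^2)`` and ``sigma = S0 / SNR``.

Default tissue parameters are standard white-matter literature values:
``nu = 0.4``, ``lambda_par = 1.7e-3``, ``lambda_perp = 0.3e-3`` and
``D_iso = 3.0e-3`` mm^2/s.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .core import DWIVolume
from .sampling import GradientScheme

__all__ = [
    "AcquisitionParams",
    "FiberBundle",
    "PhantomSpec",
    "GroundTruthVolume",
    "default_test_spec",
    "spherical_27_bundle_spec",
    "spec_to_yaml",
    "spec_from_yaml",
    "build_ground_truth",
    "simulate_signal",
    "bvalue_from_pulse",
    "add_rician_noise",
]

logger = logging.getLogger(__name__)

MAX_FIBERS = 3  # per voxel; smaller fractions beyond this are dropped


@dataclasses.dataclass
class AcquisitionParams:
    """Stejskal-Tanner acquisition parameters.

    b in s/mm^2; Delta (diffusion time) and delta (pulse length) in s;
    gamma in rad/(s T); G in T/mm; S0 is the unweighted signal level.
    """

    b: float = 0.0
    Delta: float | None = None
    delta: float | None = None
    gamma: float | None = None
    G: float | None = None
    S0: float = 1.0


@dataclasses.dataclass
class FiberBundle:
    """A tubular fiber bundle around a piecewise-linear centerline (mm)."""

    centerline: np.ndarray  # (K, 3) control points, K >= 2
    radius: float
    intra_fraction: float = 0.4
    lambda_par: float = 1.7e-3   # mm^2/s
    lambda_perp: float = 0.3e-3  # mm^2/s

    def __post_init__(self) -> None:
        self.centerline = np.atleast_2d(np.asarray(self.centerline, dtype=float))
        if self.centerline.shape[0] < 2 or self.centerline.shape[1] != 3:
            raise ValueError("centerline needs at least two 3D control points")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not (0.0 <= self.intra_fraction <= 1.0):
            raise ValueError("intra_fraction must be in [0, 1]")
        if not (self.lambda_par >= self.lambda_perp > 0):
            raise ValueError("need lambda_par >= lambda_perp > 0")


@dataclasses.dataclass
class PhantomSpec:
    """Geometry of the digital phantom."""

    shape: tuple[int, int, int] = (16, 16, 16)
    voxel_size: float = 1.0  # mm
    domain_radius: float = 7.5  # mm; voxels outside are background (signal 0)
    bundles: list[FiberBundle] = dataclasses.field(default_factory=list)
    iso_diffusivity: float = 3.0e-3  # mm^2/s, non-fiber tissue

    @property
    def center(self) -> np.ndarray:
        return np.asarray(self.shape, dtype=float) * self.voxel_size / 2.0


@dataclasses.dataclass
class GroundTruthVolume:
    """Per-voxel fiber geometry of a rasterized phantom.

    ``directions[x, y, z, i]`` is the unit direction of fiber ``i`` and
    ``fractions[x, y, z, i]`` its volume fraction (descending, summing to
    at most 1); unused slots are zero.  ``mask`` is the spherical domain.
    """

    directions: np.ndarray  # (X, Y, Z, MAX_FIBERS, 3)
    fractions: np.ndarray   # (X, Y, Z, MAX_FIBERS)
    mask: np.ndarray        # (X, Y, Z) bool, inside-domain
    spec: PhantomSpec
    # per-fiber tissue parameters (intra fraction, lambda_par, lambda_perp)
    tissue: np.ndarray = None  # (X, Y, Z, MAX_FIBERS, 3)

    def fiber_counts(self, min_fraction: float = 0.25) -> np.ndarray:
        """Number of fibers per voxel, counting fractions >= ``min_fraction``.

        A fiber occupying less than a quarter of a voxel contributes too
        little signal to be a fair reconstruction target, so by default it
        is not counted in the ground-truth fiber number.
        """
        return (self.fractions >= min_fraction).sum(axis=-1)

    def fiber_mask(self, min_fraction: float = 0.25) -> np.ndarray:
        """Voxels containing at least one counted fiber."""
        return self.fiber_counts(min_fraction) >= 1


def default_test_spec(radius: float = 1.5) -> PhantomSpec:
    """Desk-scale three-bundle phantom on a 16^3 grid.

    Three thin straight bundles through the domain center: two mutually
    orthogonal (along x and z) and a third in the x-y plane at 60 degrees
    to the first (and 90 degrees to the second), producing 1-, 2- and
    3-fiber voxels.  The thin radius keeps the white-matter fill sparse
    (thin tubes in a sphere, as in brain-like tube phantoms) so that most
    domain voxels are isotropic tissue; the 90 degree crossings are resolvable
    by the Q-ball pipeline at both b-values, while the 60 degree crossing
    contributes the low-angle under-estimation regime at high SNR.
    """
    spec = PhantomSpec()
    c = spec.center
    h = 0.75  # half-length relative to domain radius scale
    ext = spec.domain_radius + 2.0
    for u in (np.array([1.0, 0.0, 0.0]),
              np.array([0.0, 0.0, 1.0]),
              np.array([0.5, np.sqrt(3.0) / 2.0, 0.0])):
        spec.bundles.append(FiberBundle(
            centerline=np.array([c - h * ext * u, c + h * ext * u]),
            radius=radius))
    return spec


def spherical_27_bundle_spec(shape: tuple[int, int, int] = (32, 32, 32),
                             voxel_size: float = 1.0,
                             seed: int = 20140290) -> PhantomSpec:
    """A 27-bundle configuration of straight chords in a spherical domain.

    Chord orientations and offsets are drawn reproducibly from ``seed``;
    every centerline control point lies inside the domain sphere.
    """
    spec = PhantomSpec(shape=shape, voxel_size=voxel_size,
                       domain_radius=min(shape) * voxel_size / 2.0 - 0.5)
    rng = np.random.default_rng(seed)
    c = spec.center
    r_dom = spec.domain_radius
    for _ in range(27):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        # offset perpendicular to the chord, keeping it well inside the sphere
        perp = np.cross(u, rng.normal(size=3))
        perp /= np.linalg.norm(perp)
        off = perp * rng.uniform(0.0, 0.5 * r_dom)
        half = 0.95 * np.sqrt(max(r_dom ** 2 - off @ off, 0.0))
        spec.bundles.append(FiberBundle(
            centerline=np.array([c + off - half * u, c + off + half * u]),
            radius=rng.uniform(1.0, 2.0)))
    return spec


def spec_to_yaml(spec: PhantomSpec, path) -> None:
    """Write a phantom spec as a YAML config file."""
    import yaml

    payload = {
        "shape": list(spec.shape),
        "voxel_size": float(spec.voxel_size),
        "domain_radius": float(spec.domain_radius),
        "iso_diffusivity": float(spec.iso_diffusivity),
        "bundles": [{
            "centerline": np.asarray(b.centerline).tolist(),
            "radius": float(b.radius),
            "intra_fraction": float(b.intra_fraction),
            "lambda_par": float(b.lambda_par),
            "lambda_perp": float(b.lambda_perp),
        } for b in spec.bundles],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def spec_from_yaml(path) -> PhantomSpec:
    """Load a phantom spec from a YAML config file."""
    import yaml

    with open(path) as fh:
        payload = yaml.safe_load(fh)
    bundles = [FiberBundle(centerline=np.asarray(b["centerline"], dtype=float),
                           radius=b["radius"],
                           intra_fraction=b.get("intra_fraction", 0.4),
                           lambda_par=b.get("lambda_par", 1.7e-3),
                           lambda_perp=b.get("lambda_perp", 0.3e-3))
               for b in payload["bundles"]]
    return PhantomSpec(shape=tuple(payload["shape"]),
                       voxel_size=payload.get("voxel_size", 1.0),
                       domain_radius=payload["domain_radius"],
                       bundles=bundles,
                       iso_diffusivity=payload.get("iso_diffusivity", 3.0e-3))


def _point_segment_distance(points: np.ndarray, a: np.ndarray,
                            b: np.ndarray) -> np.ndarray:
    ab = b - a
    t = np.clip((points - a) @ ab / (ab @ ab), 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def _bundle_occupancy(bundle: FiberBundle, centers: np.ndarray,
                      offsets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Occupancy fraction and local tangent of a bundle at voxel centers.

    Occupancy is the fraction of sub-voxel sample points (centers +
    offsets) within ``radius`` of the centerline.  The tangent is the
    direction of the nearest centerline segment at the voxel center.
    """
    pts = (centers[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    n_seg = bundle.centerline.shape[0] - 1
    dmin = np.full(pts.shape[0], np.inf)
    dmin_c = np.full(centers.shape[0], np.inf)
    seg_idx = np.zeros(centers.shape[0], dtype=int)
    for s in range(n_seg):
        a, b = bundle.centerline[s], bundle.centerline[s + 1]
        d = _point_segment_distance(pts, a, b)
        dmin = np.minimum(dmin, d)
        dc = _point_segment_distance(centers, a, b)
        closer = dc < dmin_c
        dmin_c[closer] = dc[closer]
        seg_idx[closer] = s
    inside = (dmin <= bundle.radius).reshape(centers.shape[0], offsets.shape[0])
    occ = inside.mean(axis=1)
    tangents = bundle.centerline[seg_idx + 1] - bundle.centerline[seg_idx]
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    return occ, tangents


def build_ground_truth(spec: PhantomSpec, seed: int = 0,
                       supersample: int = 3) -> GroundTruthVolume:
    """Rasterize the bundles of ``spec`` onto its voxel grid.

    A voxel inside ``k`` bundles gets ``k`` fiber directions with
    fractions proportional to sub-voxel occupancy (normalized to sum to
    at most 1); at most :data:`MAX_FIBERS` fibers are kept per voxel,
    dropping the smallest fractions.  The construction is deterministic;
    ``seed`` is part of the API for forward compatibility with stochastic
    geometry and is unused by the current straight-bundle rasterizer.
    """
    if not spec.bundles:
        raise ValueError("phantom spec must contain at least one bundle")
    for b in spec.bundles:
        if np.any(np.linalg.norm(b.centerline - spec.center, axis=1)
                  > spec.domain_radius + 1e-9):
            raise ValueError("bundle centerline leaves the spherical domain")
    shape = tuple(spec.shape)
    idx = np.indices(shape).reshape(3, -1).T
    centers = (idx + 0.5) * spec.voxel_size
    mask = np.linalg.norm(centers - spec.center, axis=1) <= spec.domain_radius

    ss = max(1, int(supersample))
    grid1d = (np.arange(ss) + 0.5) / ss - 0.5
    offsets = (np.stack(np.meshgrid(grid1d, grid1d, grid1d, indexing="ij"), axis=-1)
               .reshape(-1, 3) * spec.voxel_size)

    nb = len(spec.bundles)
    occ = np.zeros((centers.shape[0], nb))
    tan = np.zeros((centers.shape[0], nb, 3))
    for j, bundle in enumerate(spec.bundles):
        occ[:, j], tan[:, j] = _bundle_occupancy(bundle, centers, offsets)
    occ[~mask] = 0.0

    # pad to at least MAX_FIBERS slots, then keep the largest fractions
    bundle_params = np.array([[b.intra_fraction, b.lambda_par, b.lambda_perp]
                              for b in spec.bundles])
    if nb < MAX_FIBERS:
        occ = np.pad(occ, ((0, 0), (0, MAX_FIBERS - nb)))
        tan = np.pad(tan, ((0, 0), (0, MAX_FIBERS - nb), (0, 0)))
        bundle_params = np.pad(bundle_params, ((0, MAX_FIBERS - nb), (0, 0)))
    order = np.argsort(-occ, axis=1, kind="stable")[:, :MAX_FIBERS]
    rows = np.arange(centers.shape[0])[:, None]
    frac = occ[rows, order]
    dirs = tan[rows, order]
    tissue = bundle_params[order]  # (V, MAX_FIBERS, 3)
    total = frac.sum(axis=1, keepdims=True)
    over = total[:, 0] > 1.0
    frac[over] /= total[over]
    dirs[frac <= 0.0] = 0.0

    return GroundTruthVolume(
        directions=dirs.reshape(*shape, MAX_FIBERS, 3),
        fractions=frac.reshape(*shape, MAX_FIBERS),
        mask=mask.reshape(shape),
        spec=spec,
        tissue=tissue.reshape(*shape, MAX_FIBERS, 3))


def simulate_signal(gt: GroundTruthVolume, scheme: GradientScheme,
                    acq: AcquisitionParams | None = None) -> DWIVolume:
    """Noise-free two-compartment signal of the phantom over ``scheme``.

    Uses the scheme's per-direction b-values when set, otherwise
    ``acq.b``.  Background voxels (outside the domain sphere) get zero
    signal; b0 volumes are ``S0`` inside the domain.
    """
    acq = acq or AcquisitionParams()
    b = np.asarray(scheme.bvalues, dtype=float)
    if not np.any(b > 0):
        b = np.full(scheme.n, float(acq.b))
    if np.any(b < 0) or acq.b < 0:
        raise ValueError("b-values must be nonnegative")

    spec = gt.spec
    shape = gt.fractions.shape[:3]
    d = scheme.directions  # (N, 3)
    frac = gt.fractions.reshape(-1, MAX_FIBERS)
    u = gt.directions.reshape(-1, MAX_FIBERS, 3)

    tissue = gt.tissue.reshape(-1, MAX_FIBERS, 3)
    nu = tissue[..., 0:1]                                # (V, F, 1)
    lpar = tissue[..., 1:2]
    lperp = tissue[..., 2:3]

    cos2 = np.einsum("vfi,ni->vfn", u, d) ** 2          # (V, F, N)
    stick = np.exp(-b[None, None, :] * lpar * cos2)
    zeppelin = np.exp(-b[None, None, :] * (lperp + (lpar - lperp) * cos2))
    fiber = nu * stick + (1.0 - nu) * zeppelin
    signal = np.einsum("vf,vfn->vn", frac, fiber)
    iso_frac = np.clip(1.0 - frac.sum(axis=1), 0.0, 1.0)
    signal += iso_frac[:, None] * np.exp(-b[None, :] * spec.iso_diffusivity)
    signal *= acq.S0

    mask = gt.mask.reshape(-1)
    signal[~mask] = 0.0
    data = signal.reshape(*shape, scheme.n)
    if scheme.n_b0:
        b0 = np.where(gt.mask[..., None], acq.S0, 0.0)
        b0 = np.repeat(b0, scheme.n_b0, axis=-1)
        data = np.concatenate([b0, data], axis=-1)
    return DWIVolume(data=data, scheme=scheme)


def bvalue_from_pulse(acq: AcquisitionParams) -> float:
    """Stejskal-Tanner b-value, gamma^2 G^2 delta^2 (Delta - delta/3).

    Units: gamma in rad/(s T), G in T/mm, times in s -> b in s/mm^2.
    """
    if acq.Delta is None or acq.delta is None or acq.gamma is None or acq.G is None:
        raise ValueError("Delta, delta, gamma and G must all be set")
    if acq.delta >= acq.Delta:
        logger.warning("pulse length delta >= diffusion time Delta "
                       "(delta=%g, Delta=%g)", acq.delta, acq.Delta)
    return acq.gamma ** 2 * acq.G ** 2 * acq.delta ** 2 * (acq.Delta - acq.delta / 3.0)


def add_rician_noise(vol: DWIVolume, snr: float, seed: int,
                     S0: float = 1.0) -> DWIVolume:
    """Corrupt a volume with Rician noise at a prescribed SNR.

    ``sigma = S0 / snr``; each sample becomes the magnitude of the true
    signal perturbed by a complex Gaussian.  ``snr = inf`` returns an
    exact copy.
    """
    if not snr > 0:
        raise ValueError("snr must be positive")
    if np.isinf(snr):
        return vol.copy()
    sigma = S0 / float(snr)
    rng = np.random.default_rng(seed)
    n1 = rng.normal(scale=sigma, size=vol.data.shape)
    n2 = rng.normal(scale=sigma, size=vol.data.shape)
    noisy = np.sqrt((vol.data + n1) ** 2 + n2 ** 2)
    return DWIVolume(data=noisy, scheme=vol.scheme, affine=vol.affine.copy())
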