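"""Diffusion-gradient sampling schemes on the unit sphere.

Gradient directions for HARDI are points on the unit sphere; because the
diffusion-weighted signal is antipodally symmetric, E(b, d) = E(b, -d), a
scheme effectively lives on a hemisphere.  This module generates three
families of schemes:

* an analytically exact spherical spiral with equal arc-length spacing
  (near-uniform density, continuous acquisition order),
* an uneven periodic spiral with a fixed azimuthal step per sample,
* an electrostatic-repulsion scheme (antipodally symmetrized Coulomb
  energy minimization).

The spiral acquisition order (``order_index``) is what makes the per-voxel
signal in the gradient direction domain smooth, and therefore filterable
by a Fourier low-pass (see :mod:`lopdwi.gdd_filter`).
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq, minimize

__all__ = [
    "GradientScheme",
    "UniformityReport",
    "generate_exact_spiral",
    "generate_uneven_spiral",
    "generate_electrostatic",
    "to_hemisphere",
    "uniformity_metrics",
    "read_bvals_bvecs",
    "write_bvals_bvecs",
    "read_scheme",
    "write_scheme",
]

KIND_EXACT_SPIRAL = "exact_spiral"
KIND_UNEVEN_SPIRAL = "uneven_spiral"
KIND_ELECTROSTATIC = "electrostatic"
KIND_UNKNOWN = "unknown"

#: scheme kinds whose acquisition order traverses a continuous spiral,
#: i.e. the kinds the gradient-direction-domain filter accepts.
SPIRAL_KINDS = frozenset({KIND_EXACT_SPIRAL, KIND_UNEVEN_SPIRAL})

_UNIT_TOL = 1e-12


@dataclasses.dataclass(frozen=True)
class GradientScheme:
    """An ordered set of unit gradient directions with b-values.

    Parameters
    ----------
    directions : (N, 3) float array
        Unit vectors, one per diffusion-weighted volume, in storage order.
    bvalues : (N,) float array
        b-value of each direction, s/mm^2.
    order_index : (N,) int array
        Acquisition position of each stored direction along the spiral
        (0-based, a permutation of ``0..N-1``).
    kind : str
        One of ``exact_spiral``, ``uneven_spiral``, ``electrostatic`` or
        ``unknown``.
    n_b0 : int
        Number of unweighted (b=0) volumes associated with the scheme.
        b0 volumes are not listed in ``directions``.
    """

    directions: np.ndarray
    bvalues: np.ndarray
    order_index: np.ndarray
    kind: str
    n_b0: int = 0

    def __post_init__(self) -> None:
        d = np.asarray(self.directions, dtype=float)
        if d.ndim != 2 or d.shape[1] != 3:
            raise ValueError("directions must be an (N, 3) array")
        norms = np.linalg.norm(d, axis=1)
        if not np.all(np.abs(norms - 1.0) < 1e-6):
            raise ValueError("all gradient directions must be unit vectors")
        # tighten to exact unit norm so downstream dot products are clean
        d = d / norms[:, None]
        b = np.broadcast_to(np.asarray(self.bvalues, dtype=float), (d.shape[0],)).copy()
        if np.any(b < 0):
            raise ValueError("b-values must be nonnegative")
        oi = np.asarray(self.order_index, dtype=int)
        if sorted(oi.tolist()) != list(range(d.shape[0])):
            raise ValueError("order_index must be a permutation of 0..N-1")
        if self.n_b0 < 0:
            raise ValueError("n_b0 must be nonnegative")
        object.__setattr__(self, "directions", d)
        object.__setattr__(self, "bvalues", b)
        object.__setattr__(self, "order_index", oi)

    @property
    def n(self) -> int:
        """Number of diffusion-weighted directions."""
        return self.directions.shape[0]

    def acquisition_order(self) -> np.ndarray:
        """Storage indices sorted by acquisition position."""
        return np.argsort(self.order_index, kind="stable")

    def with_bvalue(self, b: float) -> "GradientScheme":
        return dataclasses.replace(self, bvalues=np.full(self.n, float(b)))

    def with_b0(self, n_b0: int) -> "GradientScheme":
        return dataclasses.replace(self, n_b0=int(n_b0))


@dataclasses.dataclass(frozen=True)
class UniformityReport:
    """Uniformity diagnostics of a scheme (antipodally symmetrized)."""

    min_pairwise_angle: float  # degrees, between distinct axes
    electrostatic_energy: float  # sum over pairs of 1/|pi-pj| + 1/|pi+pj|
    max_consecutive_step: float  # degrees, between consecutive axes in order


def _spherical_to_cart(theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    st = np.sin(theta)
    return np.stack([st * np.cos(phi), st * np.sin(phi), np.cos(theta)], axis=-1)


def _arc_length(c: float, theta: float) -> float:
    """Arc length of the spherical spiral phi = c*theta from 0 to theta."""
    val, _ = quad(lambda t: math.sqrt(1.0 + c * c * math.sin(t) ** 2), 0.0, theta,
                  limit=200)
    return val


def auto_turns(n_total: int) -> int:
    """Turn count that equates along-spiral spacing with inter-turn spacing."""
    return max(1, round(math.sqrt(n_total * math.pi) / 2.0))


def generate_exact_spiral(n_total: int, turns: float | str = "auto",
                          bvalue: float = 0.0) -> GradientScheme:
    """Antipodally symmetric, equal-arc-length spherical spiral scheme.

    ``n_total / 2`` points are placed at equal arc-length intervals along
    the spiral ``phi = c * theta`` (``c = 2 * turns``) on the upper
    hemisphere (``theta`` from 0 to pi/2, pole to equator); their antipodes
    are appended in reverse order so the full sequence runs continuously
    from the north pole to the south pole and the point set is exactly
    antipodally symmetric.  The arc length
    ``s(theta) = integral_0^theta sqrt(1 + c^2 sin^2 t) dt`` is computed by
    numerical quadrature and inverted by root-finding.

    Parameters
    ----------
    n_total : int
        Total number of points on the full sphere; even, >= 4.
    turns : float or "auto"
        Number of spiral turns over the full sphere.  ``"auto"`` picks
        ``round(sqrt(n_total * pi) / 2)``, which matches the spacing along
        the spiral to the spacing between adjacent turns.
    bvalue : float
        b-value stamped on every direction (s/mm^2).
    """
    if n_total < 4:
        raise ValueError("n_total must be at least 4")
    if n_total % 2 != 0:
        raise ValueError("n_total must be even (antipodally symmetric scheme)")
    if turns == "auto":
        turns = auto_turns(n_total)
    turns = float(turns)
    if turns <= 0:
        raise ValueError("turns must be positive")

    c = 2.0 * turns
    m = n_total // 2
    s_half = _arc_length(c, math.pi / 2.0)
    targets = np.linspace(0.0, s_half, m)
    thetas = np.empty(m)
    thetas[0] = 0.0
    thetas[-1] = math.pi / 2.0
    for k in range(1, m - 1):
        thetas[k] = brentq(lambda th, s=targets[k]: _arc_length(c, th) - s,
                           0.0, math.pi / 2.0, xtol=1e-13)
    phis = c * thetas
    upper = _spherical_to_cart(thetas, phis)
    lower = -upper[::-1]  # antipodes, ordered so theta keeps increasing
    directions = np.vstack([upper, lower])
    return GradientScheme(directions=directions,
                          bvalues=np.full(n_total, float(bvalue)),
                          order_index=np.arange(n_total),
                          kind=KIND_EXACT_SPIRAL)


def generate_uneven_spiral(n: int, azimuth_step: float,
                           bvalue: float = 0.0) -> GradientScheme:
    """Uneven periodic spiral: fixed azimuthal step, linear polar sweep.

    Point ``k`` has azimuth ``k * azimuth_step`` (mod 360 deg) and polar
    angle ``k * 90 / (n - 1)`` degrees, sweeping pole to equator on a
    hemisphere.  Samples cluster near the pole, hence "uneven".
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    if not (0.0 < azimuth_step < 360.0):
        raise ValueError("azimuth_step must be in (0, 360) degrees")
    k = np.arange(n)
    theta = np.deg2rad(k * (90.0 / (n - 1)))
    phi = np.deg2rad((k * azimuth_step) % 360.0)
    return GradientScheme(directions=_spherical_to_cart(theta, phi),
                          bvalues=np.full(n, float(bvalue)),
                          order_index=k.copy(),
                          kind=KIND_UNEVEN_SPIRAL)


def _sym_coulomb_energy_grad(x: np.ndarray, n: int) -> tuple[float, np.ndarray]:
    p = x.reshape(n, 3)
    norms = np.linalg.norm(p, axis=1, keepdims=True)
    u = p / norms
    diff = u[:, None, :] - u[None, :, :]
    summ = u[:, None, :] + u[None, :, :]
    dd = np.linalg.norm(diff, axis=-1)
    ds = np.linalg.norm(summ, axis=-1)
    iu = np.triu_indices(n, k=1)
    energy = float(np.sum(1.0 / dd[iu]) + np.sum(1.0 / ds[iu]))
    # dE/du_i = -sum_j (u_i - u_j)/|.|^3 - sum_j (u_i + u_j)/|.|^3
    np.fill_diagonal(dd, np.inf)
    np.fill_diagonal(ds, np.inf)
    g_u = -(diff / dd[..., None] ** 3).sum(axis=1) - (summ / ds[..., None] ** 3).sum(axis=1)
    # chain rule through normalization: (I - u u^T)/|p|
    g_p = (g_u - (g_u * u).sum(axis=1, keepdims=True) * u) / norms
    return energy, g_p.ravel()


def generate_electrostatic(n: int, seed: int, iterations: int = 1000,
                           bvalue: float = 0.0) -> GradientScheme:
    """Even hemisphere scheme by antipodally symmetrized charge repulsion.

    Minimizes ``sum_{i<j} 1/|p_i - p_j| + 1/|p_i + p_j|`` over unit
    vectors, starting from a random configuration drawn from ``seed``.
    Deterministic given ``(n, seed, iterations)``.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    rng = np.random.default_rng(seed)
    p0 = rng.normal(size=(n, 3))
    p0 /= np.linalg.norm(p0, axis=1, keepdims=True)
    res = minimize(_sym_coulomb_energy_grad, p0.ravel(), args=(n,), jac=True,
                   method="L-BFGS-B",
                   options={"maxiter": int(iterations), "ftol": 1e-14, "gtol": 1e-10})
    p = res.x.reshape(n, 3)
    p /= np.linalg.norm(p, axis=1, keepdims=True)
    p = _canonical_hemisphere(p)
    return GradientScheme(directions=p,
                          bvalues=np.full(n, float(bvalue)),
                          order_index=np.arange(n),
                          kind=KIND_ELECTROSTATIC)


def _canonical_hemisphere(d: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Map each direction to its canonical antipodal representative.

    Keeps z > 0; on the z = 0 great circle keeps x > 0, then y > 0.
    """
    d = np.array(d, dtype=float, copy=True)
    z = d[:, 2]
    flip = z < -tol
    on_eq = np.abs(z) <= tol
    flip |= on_eq & (d[:, 0] < -tol)
    flip |= on_eq & (np.abs(d[:, 0]) <= tol) & (d[:, 1] < 0)
    d[flip] *= -1.0
    return d


def to_hemisphere(scheme: GradientScheme, dedupe_tol: float = 1e-6) -> GradientScheme:
    """Reduce a scheme to a hemisphere, collapsing antipodal duplicates.

    Every direction with z < 0 is replaced by its antipode (valid because
    the DWI signal is antipodally symmetric); directions that then
    coincide within ``dedupe_tol`` (radians) keep only their earliest
    acquisition position.  The acquisition order of the survivors is
    re-packed contiguously, preserving the original relative order.
    """
    canon = _canonical_hemisphere(scheme.directions)
    # small-angle form: cos(t) ~ 1 - t^2/2 stays representable where
    # math.cos(t) would round to exactly 1.0
    cos_tol = 1.0 - 0.5 * dedupe_tol ** 2
    kept_storage: list[int] = []
    kept_dirs: list[np.ndarray] = []
    for i in scheme.acquisition_order():
        d = canon[i]
        if any(float(np.dot(d, k)) >= cos_tol for k in kept_dirs):
            continue
        kept_storage.append(int(i))
        kept_dirs.append(d)
    dirs = np.array(kept_dirs)
    return GradientScheme(directions=dirs,
                          bvalues=scheme.bvalues[kept_storage],
                          order_index=np.arange(len(kept_storage)),
                          kind=scheme.kind,
                          n_b0=scheme.n_b0)


def _axis_angles_deg(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    cosang = np.clip(np.abs(a @ b.T), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def uniformity_metrics(scheme: GradientScheme) -> UniformityReport:
    """Pairwise uniformity diagnostics over points and their antipodes.

    Pairs representing the same axis (e.g. a point and its antipode in a
    full-sphere scheme) carry no angular information and are excluded.
    """
    d = scheme.directions
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 directions")
    iu = np.triu_indices(n, k=1)
    ang = _axis_angles_deg(d, d)[iu]
    distinct = ang > 1e-3  # degrees; duplicate axes carry no information
    if not distinct.any():
        raise ValueError("all directions lie on a single axis")
    min_angle = float(ang[distinct].min())

    diff = d[:, None, :] - d[None, :, :]
    summ = d[:, None, :] + d[None, :, :]
    dd = np.linalg.norm(diff, axis=-1)[iu][distinct]
    ds = np.linalg.norm(summ, axis=-1)[iu][distinct]
    energy = float(np.sum(1.0 / dd) + np.sum(1.0 / ds))

    ordered = d[scheme.acquisition_order()]
    cons = np.clip(np.abs(np.sum(ordered[:-1] * ordered[1:], axis=1)), -1.0, 1.0)
    max_step = float(np.degrees(np.arccos(cons)).max())
    return UniformityReport(min_pairwise_angle=min_angle,
                            electrostatic_energy=energy,
                            max_consecutive_step=max_step)


# ---------------------------------------------------------------------------
# file formats


def write_bvals_bvecs(scheme: GradientScheme, bval_path, bvec_path) -> None:
    """Write FSL-dialect bval (one row) and bvec (3 rows) files.

    b0 volumes, if any, are written first with zero vectors.
    """
    order = scheme.acquisition_order()
    b = np.concatenate([np.zeros(scheme.n_b0), scheme.bvalues[order]])
    v = np.vstack([np.zeros((scheme.n_b0, 3)), scheme.directions[order]])
    np.savetxt(bval_path, b[None, :], fmt="%.6g")
    np.savetxt(bvec_path, v.T, fmt="%.12g")


def read_bvals_bvecs(bval_path, bvec_path) -> tuple[np.ndarray, np.ndarray]:
    """Read FSL bval/bvec; accepts both 3xN and Nx3 bvec layouts.

    Returns ``(bvals (M,), bvecs (M, 3))`` with nonzero vectors normalized
    and zero vectors (b0 markers) preserved.
    """
    bvals = np.atleast_1d(np.loadtxt(bval_path).ravel()).astype(float)
    bvecs = np.atleast_2d(np.loadtxt(bvec_path)).astype(float)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape[0] != 3 and bvecs.shape[1] == 3:
        pass
    elif bvecs.shape == (3, 3):
        # ambiguous; FSL convention is 3 rows x N columns
        bvecs = bvecs.T
    if bvecs.shape[0] != bvals.shape[0]:
        raise ValueError(
            f"gradient table mismatch: {bvals.shape[0]} b-values vs "
            f"{bvecs.shape[0]} vectors")
    norms = np.linalg.norm(bvecs, axis=1)
    nz = norms > 1e-8
    bvecs[nz] /= norms[nz, None]
    bvecs[~nz] = 0.0
    return bvals, bvecs


def write_scheme(scheme: GradientScheme, path) -> None:
    """Write the scheme text format: '# key: value' header, 'x y z b' rows
    in acquisition order."""
    order = scheme.acquisition_order()
    with open(path, "w") as fh:
        fh.write(f"# kind: {scheme.kind}\n")
        fh.write(f"# n_b0: {scheme.n_b0}\n")
        for i in order:
            x, y, z = scheme.directions[i]
            fh.write(f"{x:.15g} {y:.15g} {z:.15g} {scheme.bvalues[i]:.8g}\n")


def read_scheme(path) -> GradientScheme:
    kind = KIND_UNKNOWN
    n_b0 = 0
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, val = (s.strip() for s in body.split(":", 1))
                if key == "kind":
                    kind = val
                elif key == "n_b0":
                    n_b0 = int(val)
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"malformed scheme line: {line!r}")
        rows.append([float(p) for p in parts])
    arr = np.array(rows)
    return GradientScheme(directions=arr[:, :3], bvalues=arr[:, 3],
                          order_index=np.arange(arr.shape[0]),
                          kind=kind, n_b0=n_b0)
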