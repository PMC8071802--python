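"""Synthetic systems: analytic free-energy functionals with exact chemical
potentials, constructed membrane-shaped density fields, and a toy restrained
Langevin sampler.

These generators make the whole string/umbrella/thermodynamic-integration
pipeline exercisable without molecular dynamics.  Analytic functionals play
the role of the (unknown) coarse-grained free-energy function: the string
method only ever consumes the chemical potential μ(c) = δF/(ΔV δm(c)), which
these providers return in closed form.  Constructed tanh-profile fields play
the role of averaged bilayer/vesicle/stalk densities and carry their
ground-truth geometry (threshold crossings, gaps, waist radii) as metadata so
tests never re-derive them by eye.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Protocol

import numpy as np

from .grids import DensityField, GridSpec, ParticleConfiguration, map_density
from .umbrella import ChemicalPotentialField, UmbrellaParams, umbrella_forces

# MARTINI-like defaults for constructed fields
DEFAULT_BULK_DENSITY = 5.0  # hydrophobic tail-bead bulk density, nm^-3
DEFAULT_THRESHOLD = 2.2  # interface iso-density, nm^-3


class ChemicalPotentialProvider(Protocol):
    """Maps a target density field to its chemical potential on the same grid.

    Implementations must be deterministic given identical input (and seed,
    where sampling is involved).
    """

    grid: GridSpec
    deterministic: bool

    def mu(self, target: DensityField) -> ChemicalPotentialField: ...


# ---------------------------------------------------------------------------
# analytic functionals
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnalyticFunctionalSpec:
    """Parameters of an analytic free-energy functional F[m] (units k_BT).

    family "quadratic":   f(m) = (a/2)(m − m1)²
    family "double_well": f(m) = a (m − m1)² (m − m2)²

    plus a square-gradient penalty (kappa_grad/2)|∇m|² with periodic
    forward differences.  F[m] = ΔV Σ_c [ f(m(c)) + (kappa_grad/2)|∇m|²(c) ].
    """

    grid: GridSpec
    family: Literal["quadratic", "double_well"] = "double_well"
    a: float = 1.0
    m1: float = 0.0
    m2: float = 1.0
    kappa_grad: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("quartic/curvature strength a must be positive")
        if self.kappa_grad < 0:
            raise ValueError("kappa_grad must be non-negative")
        if self.family == "double_well" and self.m1 == self.m2:
            raise ValueError("double well requires two distinct well positions")


class AnalyticProvider:
    """Exact chemical potential of an :class:`AnalyticFunctionalSpec`.

    μ(c) = δF/(ΔV δm(c)) = f'(m(c)) − kappa_grad ∇²m(c), with the discrete
    periodic Laplacian consistent with the forward-difference gradient energy.
    """

    deterministic = True

    def __init__(self, spec: AnalyticFunctionalSpec):
        self.spec = spec
        self.grid = spec.grid

    def _fprime(self, m: np.ndarray) -> np.ndarray:
        s = self.spec
        if s.family == "quadratic":
            return s.a * (m - s.m1)
        d1, d2 = m - s.m1, m - s.m2
        return 2.0 * s.a * d1 * d2 * (d1 + d2)

    def _fvals(self, m: np.ndarray) -> np.ndarray:
        s = self.spec
        if s.family == "quadratic":
            return 0.5 * s.a * (m - s.m1) ** 2
        return s.a * (m - s.m1) ** 2 * (m - s.m2) ** 2

    def _laplacian(self, m: np.ndarray) -> np.ndarray:
        lap = np.zeros_like(m)
        dl = self.grid.cell_lengths
        for ax in range(3):
            lap += (np.roll(m, -1, axis=ax) - 2 * m + np.roll(m, 1, axis=ax)) / dl[
                ax
            ] ** 2
        return lap

    def free_energy(self, target: DensityField) -> float:
        """F[m] in k_BT, by explicit summation."""
        self.grid.require_same(target.grid)
        m = target.values
        dv = self.grid.cell_volume
        total = np.sum(self._fvals(m))
        if self.spec.kappa_grad > 0:
            dl = self.grid.cell_lengths
            for ax in range(3):
                grad = (np.roll(m, -1, axis=ax) - m) / dl[ax]
                total += 0.5 * self.spec.kappa_grad * np.sum(grad**2)
        return float(dv * total)

    def mu(self, target: DensityField) -> ChemicalPotentialField:
        self.grid.require_same(target.grid)
        m = target.values
        vals = self._fprime(m)
        if self.spec.kappa_grad > 0:
            vals = vals - self.spec.kappa_grad * self._laplacian(m)
        return ChemicalPotentialField(self.grid, vals)


def make_analytic_provider(spec: AnalyticFunctionalSpec) -> AnalyticProvider:
    """Exact-gradient provider for an analytic functional."""
    return AnalyticProvider(spec)


def two_cell_grid(cell_volume: float = 1.0) -> GridSpec:
    """A 1×1×2 grid whose cells act as two scalar degrees of freedom."""
    side = cell_volume ** (1.0 / 3.0)
    return GridSpec((1, 1, 2), (side, side, 2 * side))


class CurvedDoubleWellLandscape:
    """Two-variable double-well free energy with a curved transition channel.

        F(x, y) = (x² − 1)² + c (y − x²/2)²       [k_BT]

    Minima at (±1, 1/2) with F = 0; saddle at (0, 0) with F = 1.  The two
    "cells" of a 1×1×2 grid carry (x, y), so the full string pipeline runs on
    it while the stationary points remain analytically accessible.  The
    minimum free-energy path follows the parabola y ≈ x²/2, which makes the
    landscape a genuine test of tangent estimation and reparameterization.
    """

    deterministic = True

    def __init__(self, c: float = 2.0, grid: GridSpec | None = None):
        self.c = float(c)
        self.grid = grid if grid is not None else two_cell_grid()
        if self.grid.n_total != 2:
            raise ValueError("landscape needs a two-cell grid")

    # stationary points (exact)
    @property
    def minima(self) -> tuple[np.ndarray, np.ndarray]:
        return np.array([-1.0, 0.5]), np.array([1.0, 0.5])

    @property
    def saddle(self) -> np.ndarray:
        return np.array([0.0, 0.0])

    def f_xy(self, x: float, y: float) -> float:
        return float((x**2 - 1.0) ** 2 + self.c * (y - x**2 / 2.0) ** 2)

    def grad_xy(self, x: float, y: float) -> np.ndarray:
        gx = 4.0 * x * (x**2 - 1.0) - 2.0 * self.c * x * (y - x**2 / 2.0)
        gy = 2.0 * self.c * (y - x**2 / 2.0)
        return np.array([gx, gy])

    def field_from_xy(self, x: float, y: float) -> DensityField:
        return DensityField(self.grid, np.array([[[x, y]]]))

    def xy_from_field(self, f: DensityField) -> tuple[float, float]:
        flat = f.values.ravel()
        return float(flat[0]), float(flat[1])

    def free_energy(self, target: DensityField) -> float:
        return self.f_xy(*self.xy_from_field(target))

    def mu(self, target: DensityField) -> ChemicalPotentialField:
        # μ = ∂F/(ΔV ∂m)
        x, y = self.xy_from_field(target)
        g = self.grad_xy(x, y) / self.grid.cell_volume
        return ChemicalPotentialField(
            self.grid, g.reshape(self.grid.shape)
        )


# ---------------------------------------------------------------------------
# mock sampler: closes the umbrella estimator loop exactly
# ---------------------------------------------------------------------------


class MockSampler:
    """Sampling engine whose restrained mean is algebraically exact.

    Yields fields with ⟨m̂⟩ = m − μ_exact/λ (λ = kappa·ΔV/k_BT), so that the
    strong-restraint estimator recovers the provider's μ exactly — this tests
    the estimator plumbing end-to-end with zero statistical noise.
    """

    def __init__(self, provider, params: UmbrellaParams):
        self.provider = provider
        self.params = params

    def sample_fields(
        self, target: DensityField, n_samples: int, n_discard: int, seed: int
    ):
        lam = self.params.lambda_fup(target.grid.cell_volume)
        mu = self.provider.mu(target)
        mean = DensityField(target.grid, target.values - mu.values / lam)
        for _ in range(n_samples):
            yield mean.copy()


def make_mock_sampler(provider, params: UmbrellaParams) -> MockSampler:
    return MockSampler(provider, params)


# ---------------------------------------------------------------------------
# constructed membrane density fields (tanh interfaces)
# ---------------------------------------------------------------------------


def _slab_profile(dist_from_center: np.ndarray, half_thickness: float, width: float,
                  bulk: float) -> np.ndarray:
    """ρ = (bulk/2)[tanh((t/2 − |dz|)/w) + 1]; sharp step in the w → 0 limit."""
    if width <= 0:
        return np.where(dist_from_center <= half_thickness, bulk, 0.0)
    return 0.5 * bulk * (np.tanh((half_thickness - dist_from_center) / width) + 1.0)


def tanh_crossing_offset(interface_width: float, threshold: float, bulk: float) -> float:
    """Signed distance from the half-thickness surface to the iso-density level.

    The profile ρ(d) = (bulk/2)[tanh((t/2 − d)/w) + 1] crosses ``threshold``
    at d = t/2 − w·artanh(2·threshold/bulk − 1); for threshold < bulk/2 the
    crossing lies *outside* the half-thickness surface by |offset|.
    """
    if not (0 < threshold < bulk):
        raise ValueError("threshold must lie inside (0, bulk)")
    if interface_width <= 0:
        return 0.0
    return -interface_width * np.arctanh(2.0 * threshold / bulk - 1.0)


def _periodic_delta(coord: np.ndarray, center: float, length: float) -> np.ndarray:
    d = coord - center
    return d - length * np.round(d / length)


def make_bilayer_field(
    grid: GridSpec,
    z_centers: tuple[float, float],
    thickness: float = 3.0,
    interface_width: float = 0.15,
    bulk_density: float = DEFAULT_BULK_DENSITY,
    threshold: float = DEFAULT_THRESHOLD,
) -> DensityField:
    """Two apposed planar tanh slabs normal to z.

    The iso-density crossings at ``threshold`` are closed-form and stored in
    ``metadata`` (per slab, lower/upper z), along with the intermembrane gap
    between the inner crossings.
    """
    z1, z2 = sorted(float(z) for z in z_centers)
    off = tanh_crossing_offset(interface_width, threshold, bulk_density)
    half = thickness / 2.0
    inner_gap = (z2 - half - off) - (z1 + half + off)
    if inner_gap <= 0:
        raise ValueError(
            f"slabs at {z1}, {z2} overlap at threshold level (gap {inner_gap:.3f})"
        )
    zc = grid.cell_centers(2)
    lz = grid.box_lengths[2]
    prof = np.zeros_like(zc)
    for z0 in (z1, z2):
        prof += _slab_profile(
            np.abs(_periodic_delta(zc, z0, lz)), half, interface_width, bulk_density
        )
    values = np.broadcast_to(
        prof[None, None, :], grid.shape
    ).copy()
    meta = {
        "kind": "bilayer_pair",
        "z_centers": (z1, z2),
        "thickness": thickness,
        "interface_width": interface_width,
        "bulk_density": bulk_density,
        "threshold": threshold,
        "crossings": {
            "slab1": (z1 - half - off, z1 + half + off),
            "slab2": (z2 - half - off, z2 + half + off),
        },
        "gap": inner_gap,
    }
    return DensityField(grid, values, meta)


def bilayer_centers_for_gap(
    gap: float,
    thickness: float = 3.0,
    interface_width: float = 0.15,
    bulk_density: float = DEFAULT_BULK_DENSITY,
    threshold: float = DEFAULT_THRESHOLD,
    z_mid: float = 0.0,
) -> tuple[float, float]:
    """Slab centers, symmetric about ``z_mid``, whose threshold-level gap is ``gap``."""
    off = tanh_crossing_offset(interface_width, threshold, bulk_density)
    sep = gap + thickness + 2.0 * off
    return (z_mid - sep / 2.0, z_mid + sep / 2.0)


def make_vesicle_pair_field(
    grid: GridSpec,
    R_v: float,
    thickness: float = 3.0,
    interface_width: float = 0.15,
    gap: float | None = None,
    bulk_density: float = DEFAULT_BULK_DENSITY,
    threshold: float = DEFAULT_THRESHOLD,
) -> DensityField:
    """Spherical tanh shell (a vesicle) whose periodic image provides the partner.

    The shell is centered in the box with its outer iso-density surface at
    radius ``R_v``; the gap to the periodic image along z is then
    L_z − 2·R_v.  If ``gap`` is given it must agree with that value to within
    one z cell, otherwise the geometry is impossible on this grid.
    """
    off = tanh_crossing_offset(interface_width, threshold, bulk_density)
    r_mid = R_v - thickness / 2.0 - off  # half-max mid-surface radius
    if r_mid <= thickness / 2.0:
        raise ValueError("vesicle too small for the requested thickness")
    lz = grid.box_lengths[2]
    actual_gap = lz - 2.0 * R_v
    if actual_gap <= 0:
        raise ValueError("vesicle outer surfaces overlap across the periodic boundary")
    if gap is not None and abs(actual_gap - gap) > grid.cell_lengths[2]:
        raise ValueError(
            f"requested gap {gap} nm impossible: box and R_v give {actual_gap:.3f} nm"
        )
    center = 0.5 * np.asarray(grid.box_lengths)
    box = np.asarray(grid.box_lengths)
    axes = [grid.cell_centers(a) for a in range(3)]
    dx = _periodic_delta(axes[0], center[0], box[0])[:, None, None]
    dy = _periodic_delta(axes[1], center[1], box[1])[None, :, None]
    dz = _periodic_delta(axes[2], center[2], box[2])[None, None, :]
    r = np.sqrt(dx**2 + dy**2 + dz**2)
    values = _slab_profile(np.abs(r - r_mid), thickness / 2.0, interface_width,
                           bulk_density)
    meta = {
        "kind": "vesicle_pair",
        "center": tuple(center),
        "R_outer": R_v,
        "R_inner": R_v - thickness - 2.0 * off,
        "thickness": thickness,
        "interface_width": interface_width,
        "bulk_density": bulk_density,
        "threshold": threshold,
        "gap": actual_gap,
    }
    return DensityField(grid, values, meta)


def make_stalk_field(
    base: DensityField,
    neck_radius: float,
    neck_scale: float = 2.0,
    axis_xy: tuple[float, float] | None = None,
    interface_width: float | None = None,
) -> DensityField:
    """Union of a base (bilayer/vesicle pair) field with an hourglass bridge.

    The bridge is an axisymmetric catenoid-like waist about a vertical axis:
    its half-max radius at height z is r(z) = neck_radius·cosh((z − z*)/c),
    where z* is the gap center recorded in the base field's metadata and c is
    ``neck_scale``.  ``neck_radius = 0`` returns the base field unchanged.
    The union is taken pointwise (maximum), which leaves the closed-form
    threshold geometry of both parts intact.
    """
    grid = base.grid
    meta = dict(base.metadata)
    if neck_radius < 0:
        raise ValueError("neck_radius must be non-negative")
    if neck_radius == 0:
        out = base.copy()
        out.metadata["kind"] = meta.get("kind", "field") + "+no_stalk"
        return out
    w = interface_width if interface_width is not None else meta.get(
        "interface_width", 0.15
    )
    bulk = meta.get("bulk_density", DEFAULT_BULK_DENSITY)
    box = np.asarray(grid.box_lengths)
    if meta.get("kind") == "bilayer_pair":
        z1, z2 = meta["z_centers"]
        z_star = 0.5 * (z1 + z2)
        gap = meta["gap"]
    elif meta.get("kind") == "vesicle_pair":
        # the gap sits across the periodic boundary in z
        z_star = (meta["center"][2] + box[2] / 2.0) % box[2]
        gap = meta["gap"]
    else:
        raise ValueError("base field must be a bilayer_pair or vesicle_pair fixture")
    if neck_radius > min(box[0], box[1]) / 2.0:
        raise ValueError("neck does not fit laterally in the box")
    cx, cy = axis_xy if axis_xy is not None else (box[0] / 2.0, box[1] / 2.0)
    axes = [grid.cell_centers(a) for a in range(3)]
    dx = _periodic_delta(axes[0], cx, box[0])[:, None, None]
    dy = _periodic_delta(axes[1], cy, box[1])[None, :, None]
    rad = np.sqrt(dx**2 + dy**2)
    dz = _periodic_delta(axes[2], z_star, box[2])[None, None, :]
    r_wall = neck_radius * np.cosh(dz / neck_scale)
    # tanh wall in the radial direction
    if w > 0:
        bridge = 0.5 * bulk * (np.tanh((r_wall - rad) / w) + 1.0)
    else:
        bridge = np.where(rad <= r_wall, bulk, 0.0)
    # restrict the bridge to the vicinity of the gap so it does not leak far
    # into the membrane interiors (the union would hide it there anyway)
    extent = gap / 2.0 + meta.get("thickness", 3.0)
    bridge = np.where(np.abs(dz) <= extent, bridge, 0.0)
    values = np.maximum(base.values, bridge)
    thr = meta.get("threshold", DEFAULT_THRESHOLD)
    off = tanh_crossing_offset(w, thr, bulk)
    meta.update(
        {
            "kind": meta.get("kind", "base") + "+stalk",
            "neck_radius": neck_radius,
            "neck_scale": neck_scale,
            "axis_xy": (cx, cy),
            "z_star": z_star,
            "waist_radius_at_threshold": neck_radius + off,
            "stalk_diameter_at_threshold": 2.0 * (neck_radius + off),
        }
    )
    return DensityField(grid, values, meta)


# ---------------------------------------------------------------------------
# toy overdamped Langevin sampler
# ---------------------------------------------------------------------------


@dataclass
class HarmonicTrap:
    """Isotropic harmonic external potential U = (k/2)|r − r0|² (kJ/mol)."""

    center: np.ndarray
    k: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.k < 0:
            raise ValueError("trap stiffness must be non-negative")

    def energy(self, positions: np.ndarray, box: np.ndarray) -> float:
        d = positions - self.center
        return float(0.5 * self.k * np.sum(d * d))

    def forces(self, positions: np.ndarray, box: np.ndarray) -> np.ndarray:
        return -self.k * (positions - self.center)


@dataclass
class ToyLangevinSpec:
    """Overdamped Langevin dynamics of point particles in a periodic box.

    r(t+dt) = r(t) + (dt/γ)·F + sqrt(2 k_BT dt/γ)·ξ,  ξ ~ N(0, 1).

    Forces combine an external potential with (optionally) the umbrella
    restraint toward a target field.  The timestep must satisfy
    dt < γ/k_stiff for the stiffest harmonic mode; the constructor enforces
    this bound for :class:`HarmonicTrap` potentials.
    """

    n_particles: int
    box_lengths: tuple[float, float, float]
    potential: HarmonicTrap | None = None
    friction: float = 1.0  # γ in kJ/mol·ps/nm²
    temperature: float = 300.0  # K
    timestep: float = 0.01  # ps
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("need at least one particle")
        if self.timestep <= 0 or self.friction <= 0:
            raise ValueError("timestep and friction must be positive")
        if isinstance(self.potential, HarmonicTrap) and self.potential.k > 0:
            if self.timestep >= self.friction / self.potential.k:
                raise ValueError(
                    "unstable timestep: require dt < friction/k for the trap"
                )

    def initial_positions(self, rng: np.random.Generator) -> np.ndarray:
        if self.potential is not None:
            return np.tile(self.potential.center, (self.n_particles, 1)).astype(float)
        box = np.asarray(self.box_lengths)
        return rng.uniform(0.0, 1.0, size=(self.n_particles, 3)) * box


def run_toy_langevin(
    spec: ToyLangevinSpec,
    n_steps: int,
    seed: int | None = None,
    target: DensityField | None = None,
    params: UmbrellaParams | None = None,
    stride: int = 10,
) -> list[ParticleConfiguration]:
    """Integrate the toy Langevin dynamics; emit configurations every ``stride``.

    When a target field and umbrella parameters are given, the umbrella force
    toward the target is added at every step (the restrained-sampling
    stand-in).  Fully reproducible under a fixed seed.
    """
    from .umbrella import thermal_energy

    rng = np.random.default_rng(spec.seed if seed is None else seed)
    box = np.asarray(spec.box_lengths)
    pos = spec.initial_positions(rng)
    kbt = thermal_energy(spec.temperature)
    mob = spec.timestep / spec.friction
    noise_amp = np.sqrt(2.0 * kbt * mob)
    out: list[ParticleConfiguration] = []
    for step in range(1, n_steps + 1):
        f = np.zeros_like(pos)
        if spec.potential is not None:
            f += spec.potential.forces(pos, box)
        if target is not None and params is not None:
            cfg = ParticleConfiguration(pos, tuple(box))
            f += umbrella_forces(target, cfg, params)
        if not np.all(np.isfinite(f)):
            raise FloatingPointError(f"force divergence at step {step}")
        pos = pos + mob * f
        if spec.temperature > 0:
            pos = pos + noise_amp * rng.standard_normal(pos.shape)
        if step % stride == 0:
            out.append(ParticleConfiguration(pos.copy(), tuple(box)))
    return out


class LangevinEngine:
    """Sampling-engine adapter around :func:`run_toy_langevin`."""

    def __init__(self, spec: ToyLangevinSpec, params: UmbrellaParams,
                 stride: int = 10):
        self.spec = spec
        self.params = params
        self.stride = stride

    def sample_fields(
        self, target: DensityField, n_samples: int, n_discard: int, seed: int
    ):
        confs = run_toy_langevin(
            self.spec,
            n_steps=(n_samples + n_discard) * self.stride,
            seed=seed,
            target=target,
            params=self.params,
            stride=self.stride,
        )
        for cfg in confs[n_discard:]:
            yield map_density(cfg, target.grid)
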