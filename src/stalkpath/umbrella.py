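"""Field-theoretic umbrella sampling: restraint energy, forces, and the
chemical-potential estimator.

The harmonic restraint couples the instantaneous mapped density ``m̂`` of a
particle system to a target collective field ``m``.  In per-cell bead-count
form (n(c) = m(c)·ΔV):

    ΔH = (kappa/2) Σ_c (n(c) − n̂(c))²                      [kJ/mol]

with the restraint strength ``kappa`` in kJ/mol per squared count deviation
(default 50).  This is algebraically the ΔH/k_BT = (λ/2) ΔV Σ (m − m̂)² form
with λ ≡ kappa·ΔV/k_BT.  In the strong-restraint limit the mean deviation of
the sampled density from the target yields the spatially varying chemical
potential

    μ(c) = ∂F/(ΔV ∂m(c)) ≈ (kappa·ΔV/k_BT) · [m(c) − ⟨m̂(c)⟩],

in units of k_BT·nm³ (k_BT per unit density), accurate up to order 1/kappa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

from .grids import (
    DensityField,
    GridMismatchError,
    GridSpec,
    ParticleConfiguration,
    _cic_indices_weights,
    map_density,
)

#: molar gas constant in kJ/(mol·K)
GAS_CONSTANT_KJ_PER_MOL_K = 0.00831446261815324


def thermal_energy(temperature: float = 300.0) -> float:
    """k_BT in kJ/mol at the given temperature (2.494 kJ/mol at 300 K)."""
    return GAS_CONSTANT_KJ_PER_MOL_K * temperature


@dataclass(frozen=True)
class UmbrellaParams:
    """Strength and temperature of the field-theoretic umbrella restraint.

    ``kappa`` is the per-cell count-form force constant in kJ/mol (the quoted
    λ/ΔV in GROMACS units); ``temperature`` in K.
    """

    kappa: float = 50.0
    temperature: float = 300.0

    def __post_init__(self) -> None:
        if not (self.kappa > 0):
            raise ValueError("kappa must be positive")
        if not (self.temperature > 0):
            raise ValueError("temperature must be positive")

    @property
    def kBT(self) -> float:
        return thermal_energy(self.temperature)

    def lambda_fup(self, cell_volume: float) -> float:
        """Dimensionless field coupling λ = kappa·ΔV/k_BT for a given ΔV."""
        return self.kappa * cell_volume / self.kBT


@dataclass
class ChemicalPotentialField:
    """μ(c) = ∂F/(ΔV ∂m(c)) on a grid, in k_BT·nm³ per unit density."""

    grid: GridSpec
    values: np.ndarray
    stderr: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("mu field shape does not match grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite chemical potential")
        if self.stderr is not None:
            self.stderr = np.asarray(self.stderr, dtype=float)
            if self.stderr.shape != self.grid.shape:
                raise ValueError("stderr shape does not match grid")


def umbrella_energy(
    target: DensityField, mapped: DensityField, params: UmbrellaParams
) -> float:
    """Restraint energy (kJ/mol) between a target and a mapped density."""
    target.grid.require_same(mapped.grid)
    dv = target.grid.cell_volume
    dn = (target.values - mapped.values) * dv
    return float(0.5 * params.kappa * np.sum(dn * dn))


def umbrella_forces(
    target: DensityField, config: ParticleConfiguration, params: UmbrellaParams
) -> np.ndarray:
    """Per-particle forces −∂ΔH/∂r_i (kJ/mol/nm) from the umbrella restraint.

    The linear assignment kernel has piecewise-constant slope ±1/ΔL_α per
    axis, so the force on particle i is an 8-cell sum of count deviations
    weighted by the kernel derivative.  Unmasked particles feel no force.
    Exactly at kernel kinks the left-limit derivative is used.
    """
    grid = target.grid
    if not np.allclose(config.box_lengths, grid.box_lengths, rtol=1e-9, atol=0.0):
        raise GridMismatchError("configuration box does not match target grid")
    mapped = map_density(config, grid)
    dv = grid.cell_volume
    # deviation in counts: n(c) − n̂(c)
    dev = (target.values - mapped.values) * dv
    forces = np.zeros_like(config.positions)
    pos = config.wrapped_positions()[config.mask]
    if len(pos) == 0:
        return forces
    i0, frac = _cic_indices_weights(pos, grid)
    n = np.asarray(grid.n_cells)
    dl = grid.cell_lengths
    f = np.zeros((len(pos), 3))
    # weight product over the 8 neighbours; derivative along one axis replaces
    # that axis' weight by ∓1/ΔL
    for ox in (0, 1):
        wx = (1.0 - frac[:, 0]) if ox == 0 else frac[:, 0]
        gx = (-1.0 if ox == 0 else 1.0) / dl[0]
        ix = np.mod(i0[:, 0] + ox, n[0])
        for oy in (0, 1):
            wy = (1.0 - frac[:, 1]) if oy == 0 else frac[:, 1]
            gy = (-1.0 if oy == 0 else 1.0) / dl[1]
            iy = np.mod(i0[:, 1] + oy, n[1])
            for oz in (0, 1):
                wz = (1.0 - frac[:, 2]) if oz == 0 else frac[:, 2]
                gz = (-1.0 if oz == 0 else 1.0) / dl[2]
                iz = np.mod(i0[:, 2] + oz, n[2])
                d = dev[ix, iy, iz]
                # F_i = kappa Σ_c (n−n̂) ∂Π/∂r_i
                f[:, 0] += d * gx * wy * wz
                f[:, 1] += d * wx * gy * wz
                f[:, 2] += d * wx * wy * gz
    forces[config.mask] = params.kappa * f
    return forces


def estimate_chemical_potential(
    target: DensityField,
    mean_mapped: DensityField,
    params: UmbrellaParams,
    mean_stderr: np.ndarray | None = None,
) -> ChemicalPotentialField:
    """Strong-restraint chemical-potential estimate from the mean deviation.

    μ(c) = (kappa·ΔV/k_BT)·[m(c) − ⟨m̂(c)⟩], accurate to O(1/kappa).  When the
    standard error of the sampled mean is supplied it is propagated linearly.
    """
    target.grid.require_same(mean_mapped.grid)
    lam = params.lambda_fup(target.grid.cell_volume)
    mu = lam * (target.values - mean_mapped.values)
    err = None if mean_stderr is None else lam * np.asarray(mean_stderr, dtype=float)
    return ChemicalPotentialField(
        target.grid,
        mu,
        stderr=err,
        metadata={"kappa": params.kappa, "temperature": params.temperature},
    )


class SamplingEngine(Protocol):
    """Contract for a restrained sampler of mapped densities.

    ``sample_fields`` must yield ``n_samples`` mapped DensityFields drawn with
    the umbrella restraint toward ``target`` active, after discarding
    ``n_discard`` equilibration samples.  Implementations must be reproducible
    under a fixed seed.  A molecular-dynamics engine can be adapted to this
    contract; this package ships analytic and Langevin toy engines
    (:mod:`stalkpath.synthetic`).
    """

    def sample_fields(
        self, target: DensityField, n_samples: int, n_discard: int, seed: int
    ):  # pragma: no cover - protocol
        ...


class SamplingDivergenceError(RuntimeError):
    """The sampling engine produced non-finite output."""


def restrained_average(
    sampler: SamplingEngine,
    target: DensityField,
    n_samples: int,
    n_discard: int = 0,
    seed: int = 0,
) -> DensityField:
    """Time-averaged mapped density under the umbrella restraint.

    Runs the sampling engine toward ``target``, discards the first
    ``n_discard`` samples, and averages the rest.  The per-cell standard error
    of the mean and sampling provenance are stored in the result metadata.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    total = np.zeros(target.grid.shape)
    total_sq = np.zeros(target.grid.shape)
    count = 0
    for sample in sampler.sample_fields(target, n_samples, n_discard, seed):
        if not np.all(np.isfinite(sample.values)):
            raise SamplingDivergenceError(
                f"non-finite sample after {count} accumulated samples"
            )
        total += sample.values
        total_sq += sample.values**2
        count += 1
    mean = total / count
    if count > 1:
        var = np.maximum(total_sq / count - mean**2, 0.0)
        stderr = np.sqrt(var / count)
    else:
        stderr = np.zeros_like(mean)
    out = DensityField(target.grid, mean)
    out.metadata.update(
        {"seed": seed, "n_samples": count, "n_discard": n_discard, "stderr": stderr}
    )
    return out
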