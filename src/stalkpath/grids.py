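"""Collocation grid, density order parameter, and particle-to-grid mapping.

The collective order parameter used throughout this package is the number
density of hydrophobic (lipid-tail) particles on a regular collocation grid.
A microscopic configuration ``{r_i}`` is mapped onto the grid with a linear
("cloud-in-cell") assignment kernel

    m̂(c) = (1/ΔV) Σ_i Π(c, r_i),
    Π(c, r) = ∏_α π_α(|r_α − c_α|),
    π_α(d)  = 1 − |d|/ΔL_α  for |d| ≤ ΔL_α, else 0,

so that each particle deposits its unit weight onto (at most) the 8 cells
surrounding it and Σ_c m̂(c)·ΔV equals the particle count exactly (partition
of unity).  Distances are minimum-image on periodic axes; cell centers sit at
(i + 1/2)·ΔL_α.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class GridMismatchError(ValueError):
    """Two fields (or a field and a configuration) live on incompatible grids."""


@dataclass(frozen=True)
class GridSpec:
    """Regular collocation grid over a (possibly periodic) orthorhombic box.

    Parameters
    ----------
    n_cells : tuple of 3 int
        Number of cells along x, y, z.
    box_lengths : tuple of 3 float
        Box edge lengths in nm.  Cell lengths are always derived as
        ``ΔL_α = L_α / n_α`` so the grid tiles the box exactly.
    periodic : tuple of 3 bool
        Periodicity flag per axis (default fully periodic).
    """

    n_cells: tuple[int, int, int]
    box_lengths: tuple[float, float, float]
    periodic: tuple[bool, bool, bool] = (True, True, True)

    def __post_init__(self) -> None:
        n = tuple(int(v) for v in self.n_cells)
        box = tuple(float(v) for v in self.box_lengths)
        if len(n) != 3 or any(v < 1 for v in n):
            raise ValueError(f"n_cells must be three positive integers, got {n}")
        if len(box) != 3 or any(not np.isfinite(v) or v <= 0 for v in box):
            raise ValueError(f"box_lengths must be three positive lengths, got {box}")
        object.__setattr__(self, "n_cells", n)
        object.__setattr__(self, "box_lengths", box)
        object.__setattr__(self, "periodic", tuple(bool(v) for v in self.periodic))

    @property
    def cell_lengths(self) -> np.ndarray:
        """ΔL per axis (nm)."""
        return np.asarray(self.box_lengths) / np.asarray(self.n_cells)

    @property
    def cell_volume(self) -> float:
        """ΔV = ΔL_x·ΔL_y·ΔL_z (nm³)."""
        return float(np.prod(self.cell_lengths))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.n_cells

    @property
    def n_total(self) -> int:
        return int(np.prod(self.n_cells))

    def cell_centers(self, axis: int) -> np.ndarray:
        """Center coordinates (i + 1/2)·ΔL along one axis (nm)."""
        dl = self.cell_lengths[axis]
        return (np.arange(self.n_cells[axis]) + 0.5) * dl

    def compatible_with(self, other: "GridSpec", rtol: float = 1e-9) -> bool:
        return (
            self.n_cells == other.n_cells
            and self.periodic == other.periodic
            and np.allclose(self.box_lengths, other.box_lengths, rtol=rtol, atol=0.0)
        )

    def require_same(self, other: "GridSpec") -> None:
        if not self.compatible_with(other):
            raise GridMismatchError(f"grids differ: {self} vs {other}")


@dataclass
class ParticleConfiguration:
    """Particle positions (nm) in a periodic box with a hydrophobic mask.

    ``mask`` selects the particles that carry the order parameter (lipid tail
    beads for MARTINI systems); unmasked particles are ignored by the density
    mapping and receive no umbrella force.
    """

    positions: np.ndarray
    box_lengths: tuple[float, float, float]
    mask: np.ndarray | None = None
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite positions")
        self.box_lengths = tuple(float(v) for v in self.box_lengths)
        if self.mask is None:
            self.mask = np.ones(len(self.positions), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (len(self.positions),):
                raise ValueError("mask length must match particle count")

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    def wrapped_positions(self) -> np.ndarray:
        """Positions wrapped into [0, L) per axis."""
        box = np.asarray(self.box_lengths)
        return np.mod(self.positions, box)

    def translated(self, shift: np.ndarray) -> "ParticleConfiguration":
        return ParticleConfiguration(
            self.positions + np.asarray(shift, dtype=float),
            self.box_lengths,
            mask=self.mask.copy(),
            names=self.names,
        )


@dataclass
class DensityField:
    """An order-parameter field m(c) (nm⁻³) on a collocation grid."""

    grid: GridSpec
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"field shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite field values")

    @classmethod
    def zeros(cls, grid: GridSpec) -> "DensityField":
        return cls(grid, np.zeros(grid.shape))

    def copy(self) -> "DensityField":
        return DensityField(self.grid, self.values.copy(), dict(self.metadata))

    def total_mass(self) -> float:
        """Σ_c m(c)·ΔV — the particle count the field represents."""
        return float(self.values.sum() * self.grid.cell_volume)

    def __add__(self, other: "DensityField") -> "DensityField":
        self.grid.require_same(other.grid)
        return DensityField(self.grid, self.values + other.values)

    def __sub__(self, other: "DensityField") -> "DensityField":
        self.grid.require_same(other.grid)
        return DensityField(self.grid, self.values - other.values)

    def __mul__(self, scalar: float) -> "DensityField":
        return DensityField(self.grid, self.values * float(scalar))

    __rmul__ = __mul__


def _axis_distance(d: np.ndarray, length: float, periodic: bool) -> np.ndarray:
    d = np.abs(d)
    if periodic:
        d = np.minimum(d, length - d)
    return d


def assignment_weight(
    cell_center: np.ndarray, position: np.ndarray, grid: GridSpec
) -> float:
    """Linear assignment weight Π(c, r) of one particle to one cell.

    Product over axes of the tent kernel π_α(d) = 1 − d/ΔL_α for d ≤ ΔL_α.
    Minimum-image distance is used on periodic axes.
    """
    cell_center = np.asarray(cell_center, dtype=float)
    position = np.asarray(position, dtype=float)
    if not (np.all(np.isfinite(cell_center)) and np.all(np.isfinite(position))):
        raise ValueError("non-finite inputs to assignment_weight")
    dl = grid.cell_lengths
    box = np.asarray(grid.box_lengths)
    w = 1.0
    for a in range(3):
        d = _axis_distance(position[a] - cell_center[a], box[a], grid.periodic[a])
        if d > dl[a]:
            return 0.0
        w *= 1.0 - d / dl[a]
    return float(w)


def _cic_indices_weights(positions: np.ndarray, grid: GridSpec):
    """Cloud-in-cell lower cell index, fraction, per axis.

    Returns (i0, frac) arrays of shape (N, 3): the particle sits a fraction
    ``frac`` of a cell length past the center of cell ``i0``; weights are
    (1−frac) to i0 and frac to i0+1 (wrapped on periodic axes).
    """
    box = np.asarray(grid.box_lengths)
    n = np.asarray(grid.n_cells)
    dl = grid.cell_lengths
    u = np.mod(positions, box) / dl - 0.5  # position in units of cell centers
    i0 = np.floor(u).astype(np.int64)
    frac = u - i0
    return i0, frac


def map_density(config: ParticleConfiguration, grid: GridSpec) -> DensityField:
    """Map a particle configuration onto the grid (Cloud-in-Cell, Eq m̂).

    Each masked particle deposits weight 1 split linearly over the 8
    surrounding cells; the result is divided by the cell volume so the field
    has units nm⁻³ and ``Σ_c m̂(c)·ΔV`` equals the masked particle count.
    """
    if not np.allclose(config.box_lengths, grid.box_lengths, rtol=1e-9, atol=0.0):
        raise GridMismatchError(
            f"configuration box {config.box_lengths} does not match grid box "
            f"{grid.box_lengths}"
        )
    pos = config.wrapped_positions()[config.mask]
    counts = np.zeros(grid.shape)
    if len(pos):
        i0, frac = _cic_indices_weights(pos, grid)
        n = np.asarray(grid.n_cells)
        for ox in (0, 1):
            wx = (1.0 - frac[:, 0]) if ox == 0 else frac[:, 0]
            ix = np.mod(i0[:, 0] + ox, n[0])
            for oy in (0, 1):
                wy = (1.0 - frac[:, 1]) if oy == 0 else frac[:, 1]
                iy = np.mod(i0[:, 1] + oy, n[1])
                for oz in (0, 1):
                    wz = (1.0 - frac[:, 2]) if oz == 0 else frac[:, 2]
                    iz = np.mod(i0[:, 2] + oz, n[2])
                    np.add.at(counts, (ix, iy, iz), wx * wy * wz)
    return DensityField(grid, counts / grid.cell_volume)


def field_difference_norm(a: DensityField, b: DensityField) -> float:
    """Euclidean norm sqrt(Σ_c (a − b)²) between two fields on one grid."""
    a.grid.require_same(b.grid)
    return float(np.sqrt(np.sum((a.values - b.values) ** 2)))
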