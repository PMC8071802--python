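"""File formats and configuration: GRO/XYZ particle input, OpenDX and HDF5
field containers, path checkpoints, CSV exports, and the run configuration
schema.

Particle files are read through MDAnalysis (lengths converted from Å to nm);
fields and string paths round-trip bit-exactly through HDF5.
"""

from __future__ import annotations

import json
import hashlib
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from .grids import DensityField, GridSpec, ParticleConfiguration
from .string import StringPath
from .free_energy import FreeEnergyProfile

CHECKPOINT_VERSION = 1

#: default MARTINI POPC tail-bead names (the hydrophobic selection)
DEFAULT_TAIL_BEADS = ("C1A", "D2A", "C3A", "C4A", "C1B", "C2B", "C3B", "C4B")


class ParticleFileError(ValueError):
    """A particle file failed to parse or yielded an empty selection."""


class CheckpointError(RuntimeError):
    """A checkpoint file is unreadable or has an incompatible version."""


# ---------------------------------------------------------------------------
# particle configurations
# ---------------------------------------------------------------------------


def read_particles(
    path,
    fmt: str | None = None,
    selection: tuple[str, ...] | None = DEFAULT_TAIL_BEADS,
    box_lengths: tuple[float, float, float] | None = None,
) -> ParticleConfiguration:
    """Read a particle configuration from GRO or XYZ (positions in nm).

    ``selection`` is a tuple of atom names forming the hydrophobic mask
    (default: MARTINI POPC tail beads); pass None to select everything.  XYZ
    files carry no box, so ``box_lengths`` (nm) is required for them.
    """
    import warnings

    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise ParticleFileError(f"no such file: {path}")
    fmt = (fmt or path.suffix.lstrip(".")).upper()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), format=fmt)
        positions = u.atoms.positions.astype(float) / 10.0  # Å → nm
        names = [str(n) for n in u.atoms.names]
    except ParticleFileError:
        raise
    except Exception as exc:  # MDAnalysis raises format-specific errors
        raise ParticleFileError(f"cannot parse {path}: {exc}") from exc
    if box_lengths is None:
        dims = u.dimensions
        if dims is None or not np.all(dims[:3] > 0):
            raise ParticleFileError(
                f"{path} carries no box; pass box_lengths explicitly"
            )
        box_lengths = tuple(float(v) / 10.0 for v in dims[:3])
    if selection is None:
        mask = np.ones(len(positions), dtype=bool)
    else:
        mask = np.isin(names, list(selection))
        if not mask.any():
            raise ParticleFileError(
                f"selection {selection} matches no atoms in {path}"
            )
    return ParticleConfiguration(positions, box_lengths, mask=mask, names=names)


def write_particles(path, config: ParticleConfiguration, fmt: str | None = None):
    """Write a configuration to GRO or XYZ via MDAnalysis (nm → Å)."""
    import warnings

    import MDAnalysis as mda

    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).upper()
    n = len(config.positions)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n, trajectory=True)
        names = config.names if config.names is not None else ["X"] * n
        u.add_TopologyAttr("names", names)
        u.add_TopologyAttr("resnames", ["SYS"])
        u.add_TopologyAttr("resids", [1])
        u.atoms.positions = config.positions * 10.0
        u.dimensions = [
            config.box_lengths[0] * 10.0,
            config.box_lengths[1] * 10.0,
            config.box_lengths[2] * 10.0,
            90.0,
            90.0,
            90.0,
        ]
        u.atoms.write(str(path))


# ---------------------------------------------------------------------------
# HDF5 field / path / profile containers
# ---------------------------------------------------------------------------


def _write_grid_attrs(group, grid: GridSpec) -> None:
    group.attrs["n_cells"] = grid.n_cells
    group.attrs["box_lengths"] = grid.box_lengths
    group.attrs["periodic"] = grid.periodic
    group.attrs["version"] = CHECKPOINT_VERSION


def _read_grid_attrs(group) -> GridSpec:
    return GridSpec(
        tuple(int(v) for v in group.attrs["n_cells"]),
        tuple(float(v) for v in group.attrs["box_lengths"]),
        tuple(bool(v) for v in group.attrs["periodic"]),
    )


def _check_version(obj) -> None:
    v = obj.attrs.get("version", None)
    if v is not None and int(v) != CHECKPOINT_VERSION:
        raise CheckpointError(
            f"checkpoint version {v} not supported (expect {CHECKPOINT_VERSION}); "
            "re-create the file with this package version"
        )


def write_field_group(group, field: DensityField) -> None:
    _write_grid_attrs(group, field.grid)
    group.create_dataset("values", data=field.values)
    meta = {
        k: v for k, v in field.metadata.items()
        if isinstance(v, (int, float, str, bool, tuple, list, dict))
    }
    group.attrs["metadata_json"] = json.dumps(meta, default=str)
    if "stderr" in field.metadata and isinstance(
        field.metadata["stderr"], np.ndarray
    ):
        group.create_dataset("stderr", data=field.metadata["stderr"])


def read_field_group(group) -> DensityField:
    _check_version(group)
    grid = _read_grid_attrs(group)
    meta = json.loads(group.attrs.get("metadata_json", "{}"))
    field = DensityField(grid, group["values"][...], meta)
    if "stderr" in group:
        field.metadata["stderr"] = group["stderr"][...]
    return field


def write_field(path, field: DensityField, name: str = "field") -> None:
    with h5py.File(path, "w") as fh:
        write_field_group(fh.create_group(name), field)


def read_field(path, name: str = "field") -> DensityField:
    try:
        with h5py.File(path, "r") as fh:
            return read_field_group(fh[name])
    except (OSError, KeyError) as exc:
        raise CheckpointError(f"cannot read field from {path}: {exc}") from exc


def write_path_checkpoint(
    path_file,
    string_path: StringPath,
    diagnostics: pd.DataFrame | None = None,
    mu_values: np.ndarray | None = None,
    provenance: dict | None = None,
) -> None:
    """Write a string path (plus optional μ fields and diagnostics) to HDF5."""
    with h5py.File(path_file, "w") as fh:
        fh.attrs["version"] = CHECKPOINT_VERSION
        fh.attrs["n_replicas"] = string_path.n_replicas
        fh.attrs["s"] = string_path.s
        if provenance:
            fh.attrs["provenance_json"] = json.dumps(provenance, default=str)
        for i, rep in enumerate(string_path.replicas):
            write_field_group(fh.create_group(f"replica_{i:03d}"), rep)
        if mu_values is not None:
            fh.create_dataset("mu_values", data=np.asarray(mu_values))
        if diagnostics is not None:
            g = fh.create_group("diagnostics")
            for col in diagnostics.columns:
                g.create_dataset(col, data=diagnostics[col].to_numpy())
            g.attrs["converged"] = bool(diagnostics.attrs.get("converged", False))


def read_path_checkpoint(path_file):
    """Read (StringPath, diagnostics | None, mu_values | None) from HDF5."""
    try:
        with h5py.File(path_file, "r") as fh:
            _check_version(fh)
            n = int(fh.attrs["n_replicas"])
            s = np.asarray(fh.attrs["s"], dtype=float)
            reps = [read_field_group(fh[f"replica_{i:03d}"]) for i in range(n)]
            mu_values = fh["mu_values"][...] if "mu_values" in fh else None
            diag = None
            if "diagnostics" in fh:
                g = fh["diagnostics"]
                diag = pd.DataFrame({k: g[k][...] for k in g})
                diag.attrs["converged"] = bool(g.attrs.get("converged", False))
            return StringPath(reps, s=s), diag, mu_values
    except (OSError, KeyError) as exc:
        raise CheckpointError(f"cannot read checkpoint {path_file}: {exc}") from exc


def write_profile_csv(path, profile: FreeEnergyProfile) -> None:
    """CSV with columns s, delta_F_kBT (and stderr_kBT when available)."""
    profile.to_frame().to_csv(path, index=False)


def write_profile(path, profile: FreeEnergyProfile) -> None:
    """Bit-exact HDF5 container for a free-energy profile."""
    with h5py.File(path, "w") as fh:
        fh.attrs["version"] = CHECKPOINT_VERSION
        fh.create_dataset("s", data=profile.s)
        fh.create_dataset("delta_F", data=profile.delta_F)
        if profile.stderr is not None:
            fh.create_dataset("stderr", data=profile.stderr)


def read_profile(path) -> FreeEnergyProfile:
    try:
        with h5py.File(path, "r") as fh:
            _check_version(fh)
            return FreeEnergyProfile(
                fh["s"][...],
                fh["delta_F"][...],
                stderr=fh["stderr"][...] if "stderr" in fh else None,
            )
    except (OSError, KeyError) as exc:
        raise CheckpointError(f"cannot read profile {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# OpenDX volumetric export
# ---------------------------------------------------------------------------


def write_opendx(path, field: DensityField) -> None:
    """Write the field as an OpenDX scalar volume (origin at cell centers)."""
    grid = field.grid
    nx, ny, nz = grid.n_cells
    dl = grid.cell_lengths
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {dl[0] / 2:.6f} {dl[1] / 2:.6f} {dl[2] / 2:.6f}\n")
        fh.write(f"delta {dl[0]:.6f} 0 0\n")
        fh.write(f"delta 0 {dl[1]:.6f} 0\n")
        fh.write(f"delta 0 0 {dl[2]:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {grid.n_total} "
            "data follows\n"
        )
        flat = field.values.ravel()  # z fastest, DX convention
        for i in range(0, len(flat), 3):
            fh.write(" ".join(f"{v:.6g}" for v in flat[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')


def export_slice_csv(path, field: DensityField, axis=2, coord: float | None = None):
    """CSV of one 2D slice (in-plane coordinates in nm + density)."""
    from .geometry import _axis_index

    ax = _axis_index(axis)
    grid = field.grid
    if coord is None:
        coord = grid.box_lengths[ax] / 2.0
    idx = int(round(coord / grid.cell_lengths[ax] - 0.5)) % grid.n_cells[ax]
    slc = [slice(None)] * 3
    slc[ax] = idx
    plane = field.values[tuple(slc)]
    keep = [a for a in range(3) if a != ax]
    c0 = field.grid.cell_centers(keep[0])
    c1 = field.grid.cell_centers(keep[1])
    g0, g1 = np.meshgrid(c0, c1, indexing="ij")
    pd.DataFrame(
        {"coord0_nm": g0.ravel(), "coord1_nm": g1.ravel(), "density_nm3": plane.ravel()}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


class GridConfig(BaseModel):
    n_cells: tuple[int, int, int] = (20, 20, 20)
    box_lengths: tuple[float, float, float] = (6.0, 6.0, 6.0)
    periodic: tuple[bool, bool, bool] = (True, True, True)

    def build(self) -> GridSpec:
        return GridSpec(self.n_cells, self.box_lengths, self.periodic)


class UmbrellaConfig(BaseModel):
    kappa: float = Field(50.0, gt=0, description="restraint strength, kJ/mol")
    temperature: float = Field(300.0, gt=0, description="temperature, K")


class StringRunConfig(BaseModel):
    n_replicas: int = Field(24, ge=3)
    epsilon: float | None = Field(
        None, description="Allen-Cahn step; default from eps*lambda/dV = 0.03"
    )
    max_iterations: int = Field(400, ge=1)
    tol_disp: float = Field(1e-4, gt=0)
    tol_F: float = Field(1e-3, gt=0)
    endpoint_mode: str = "evolve"
    clip_negative: bool = True

    @field_validator("endpoint_mode")
    @classmethod
    def _mode(cls, v):
        if v not in ("evolve", "pinned"):
            raise ValueError("endpoint_mode must be 'evolve' or 'pinned'")
        return v


class RunConfig(BaseModel):
    """Declarative configuration of a full pipeline run.

    Defaults mirror the reference protocol: 24 replicas (19 for small planar
    boxes), kappa = 50 kJ/mol, Allen-Cahn step ε·λ/ΔV = 0.03, interface
    threshold 2.2 nm⁻³.
    """

    grid: GridConfig = GridConfig()
    umbrella: UmbrellaConfig = UmbrellaConfig()
    string: StringRunConfig = StringRunConfig()
    geometry_threshold: float = Field(2.2, gt=0)
    seed: int = 0
    output_dir: str = "."

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def string_config(self):
        from .string import StringConfig, default_epsilon

        eps = self.string.epsilon
        if eps is None:
            eps = default_epsilon(self.umbrella.kappa, self.umbrella.temperature)
        return StringConfig(
            epsilon=eps,
            max_iterations=self.string.max_iterations,
            tol_disp=self.string.tol_disp,
            tol_F=self.string.tol_F,
            seed=self.seed,
            endpoint_mode=self.string.endpoint_mode,
            clip_negative=self.string.clip_negative,
        )


def write_provenance(path, config: RunConfig | None = None, **extra) -> None:
    """JSON provenance block: config hash, seeds, package version."""
    from . import __version__

    block = {"stalkpath_version": __version__}
    if config is not None:
        block["config_hash"] = config.config_hash()
        block["seed"] = config.seed
    block.update(extra)
    with open(path, "w") as fh:
        json.dump(block, fh, indent=2, default=str)
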