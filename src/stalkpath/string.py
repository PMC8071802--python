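"""The string method for minimum free-energy paths in density-field space.

A transformation path is discretized into n replicas m_{s_i}(c) with contour
parameter s ∈ [0, 1].  The algorithm alternates (1) an Allen-Cahn relaxation
step m ← m − ε·μ on every replica, where μ(c) = ∂F/(ΔV ∂m(c)) is supplied by
a chemical-potential provider (analytic or sampled), and (2) redistribution
of the replicas to uniform arc length along a per-cell cubic-spline
parameterization of the string.  At convergence the chemical potential
perpendicular to the path vanishes and the string is the MFEP through the
saddle point.

The model-style entry point is :class:`StringMFEP` whose :meth:`~StringMFEP.fit`
returns a :class:`StringMFEPResults` carrying the converged path, the
free-energy profile from thermodynamic integration, and diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .grids import DensityField, GridSpec
from .umbrella import ChemicalPotentialField, UmbrellaParams

logger = logging.getLogger(__name__)


class DegeneratePathError(ValueError):
    """The path has zero total length (all replicas identical)."""


def default_epsilon(kappa: float = 50.0, temperature: float = 300.0,
                    step: float = 0.03) -> float:
    """Allen-Cahn step ε from the protocol constant ε·λ/ΔV = 0.03.

    With the dimensionless umbrella coupling λ = kappa·ΔV/k_BT this gives
    ε = step·k_BT/kappa, independent of the cell volume.
    """
    from .umbrella import thermal_energy

    return step * thermal_energy(temperature) / kappa


@dataclass
class StringPath:
    """Ordered sequence of density-field replicas with contour parameters."""

    replicas: list[DensityField]
    s: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.replicas) < 2:
            raise ValueError("a path needs at least two replicas")
        grid = self.replicas[0].grid
        for r in self.replicas[1:]:
            grid.require_same(r.grid)
        if self.s is None:
            self.s = np.linspace(0.0, 1.0, len(self.replicas))
        else:
            self.s = np.asarray(self.s, dtype=float)
            if self.s.shape != (len(self.replicas),):
                raise ValueError("s must have one value per replica")
            if not (np.all(np.diff(self.s) > 0) and self.s[0] == 0.0
                    and self.s[-1] == 1.0):
                raise ValueError("s must be strictly increasing from 0 to 1")

    @property
    def grid(self) -> GridSpec:
        return self.replicas[0].grid

    @property
    def n_replicas(self) -> int:
        return len(self.replicas)

    def stacked(self) -> np.ndarray:
        """(n, N) array of per-replica flattened field values."""
        return np.stack([r.values.ravel() for r in self.replicas])

    @classmethod
    def from_stacked(cls, grid: GridSpec, stacked: np.ndarray,
                     s: np.ndarray | None = None) -> "StringPath":
        reps = [DensityField(grid, row.reshape(grid.shape)) for row in stacked]
        return cls(reps, s=s)

    def copy(self) -> "StringPath":
        return StringPath([r.copy() for r in self.replicas], s=self.s.copy())


@dataclass(frozen=True)
class StringConfig:
    """Knobs of the string iteration.

    ``epsilon`` is the Allen-Cahn step (default from the protocol constant
    ε·λ/ΔV = 0.03 at kappa = 50, T = 300 K); ``tol_disp`` is relative to the
    maximum field magnitude; ``tol_F`` is the relative change of the barrier
    between iterations.  ``endpoint_mode`` "evolve" relaxes the endpoints too
    (true minima are fixed points of the relaxation), "pinned" freezes them.
    """

    epsilon: float = default_epsilon()
    max_iterations: int = 400
    tol_disp: float = 1e-4
    tol_F: float = 1e-3
    seed: int = 0
    endpoint_mode: str = "evolve"
    clip_negative: bool = True
    reparam_tol: float = 1e-3
    reparam_max_passes: int = 5

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.tol_disp <= 0 or self.tol_F <= 0:
            raise ValueError("tolerances must be positive")
        if self.endpoint_mode not in ("evolve", "pinned"):
            raise ValueError("endpoint_mode must be 'evolve' or 'pinned'")


def initialize_path(start: DensityField, end: DensityField, n: int) -> StringPath:
    """Pointwise linear interpolation between the two endpoint fields."""
    if n < 3:
        raise ValueError("need at least 3 replicas")
    start.grid.require_same(end.grid)
    t = np.linspace(0.0, 1.0, n)
    reps = [
        DensityField(start.grid, (1.0 - ti) * start.values + ti * end.values)
        for ti in t
    ]
    reps[0] = start.copy()
    reps[-1] = end.copy()
    return StringPath(reps)


def allen_cahn_step(
    path: StringPath,
    mu: list[ChemicalPotentialField],
    config: StringConfig,
) -> StringPath:
    """One relaxation step m ← m − ε·μ per replica.

    Endpoints move too unless ``endpoint_mode`` is "pinned".  Negative
    densities are clipped to zero (and counted in the log) when
    ``clip_negative`` — the order parameter is a physical density; disable
    for analytic landscapes where negative values are meaningful.
    """
    if len(mu) != path.n_replicas:
        raise ValueError("need one chemical-potential field per replica")
    new_reps = []
    n_clipped = 0
    for i, (rep, m) in enumerate(zip(path.replicas, mu)):
        if not np.all(np.isfinite(m.values)):
            raise FloatingPointError(f"non-finite chemical potential at replica {i}")
        pinned = config.endpoint_mode == "pinned" and i in (0, path.n_replicas - 1)
        if pinned:
            new_reps.append(rep.copy())
            continue
        vals = rep.values - config.epsilon * m.values
        if config.clip_negative:
            neg = vals < 0.0
            n_clipped += int(neg.sum())
            vals = np.where(neg, 0.0, vals)
        new_reps.append(DensityField(rep.grid, vals, dict(rep.metadata)))
    if n_clipped:
        logger.info("allen_cahn_step clipped %d negative cells", n_clipped)
    return StringPath(new_reps, s=path.s.copy())


def replica_distances(path: StringPath) -> np.ndarray:
    """Normalized segment lengths Δᵢ with Σᵢ Δᵢ = 1.

    Δᵢ² ∝ Σ_c [m_{s_{i+1}}(c) − m_{s_i}(c)]², normalized to unit total.
    """
    y = path.stacked()
    seg = np.sqrt(np.sum(np.diff(y, axis=0) ** 2, axis=1))
    total = seg.sum()
    if total == 0.0:
        raise DegeneratePathError("all replicas identical; path has zero length")
    return seg / total


def _arc_params(path: StringPath) -> np.ndarray:
    d = replica_distances(path)
    return np.concatenate([[0.0], np.cumsum(d)])


def reparameterize(path: StringPath, tol: float = 1e-3,
                   max_passes: int = 5) -> StringPath:
    """Redistribute replicas to uniform arc length along the string.

    Each cell's sequence of values across replicas is fit by a natural cubic
    spline against the cumulative normalized arc length, then re-evaluated at
    uniform positions i/(n−1).  Endpoints are returned bit-identical.  Passes
    repeat (up to ``max_passes``) until the recomputed Δᵢ are uniform to
    ``tol`` relative.
    """
    current = path
    n = path.n_replicas
    target = 1.0 / (n - 1)
    for _ in range(max_passes):
        t = _arc_params(current)
        y = current.stacked()
        spline = CubicSpline(t, y, axis=0, bc_type="natural")
        u = np.linspace(0.0, 1.0, n)
        new_y = spline(u)
        new_y[0] = path.replicas[0].values.ravel()
        new_y[-1] = path.replicas[-1].values.ravel()
        current = StringPath.from_stacked(path.grid, new_y)
        current.replicas[0] = path.replicas[0].copy()
        current.replicas[-1] = path.replicas[-1].copy()
        d = replica_distances(current)
        if np.max(np.abs(d - target)) / target < tol:
            break
    return current


def path_tangents(path: StringPath) -> np.ndarray:
    """dm/ds at each replica from the natural-spline path representation."""
    t = _arc_params(path)
    y = path.stacked()
    spline = CubicSpline(t, y, axis=0, bc_type="natural")
    return spline(t, 1)


def perpendicular_mu(
    path: StringPath, mu: list[ChemicalPotentialField]
) -> list[ChemicalPotentialField]:
    """Component of μ perpendicular to the path tangent at each replica.

    μ⊥ = μ − (dm/ds)·[Σ_c μ·(dm/ds)] / [Σ_c (dm/ds)²]; at the MFEP this
    vanishes at every interior replica.
    """
    if len(mu) != path.n_replicas:
        raise ValueError("need one chemical-potential field per replica")
    tangents = path_tangents(path)
    out = []
    for i, m in enumerate(mu):
        tan = tangents[i]
        norm2 = float(np.dot(tan, tan))
        if norm2 == 0.0:
            raise DegeneratePathError(f"zero tangent at replica {i}")
        mv = m.values.ravel()
        proj = float(np.dot(mv, tan)) / norm2
        out.append(
            ChemicalPotentialField(
                path.grid, (mv - proj * tan).reshape(path.grid.shape)
            )
        )
    return out


def run_string(
    initial: StringPath,
    provider,
    config: StringConfig | None = None,
) -> tuple[StringPath, pd.DataFrame]:
    """Iterate Allen-Cahn relaxation + reparameterization to convergence.

    Stops when both the maximum per-cell displacement of one iteration drops
    below ``tol_disp``·max|m| and the barrier estimate changes by less than
    ``tol_F`` relative, or at ``max_iterations`` (then a warning is logged and
    the diagnostics mark the run unconverged — no exception).  Returns the
    final path and a per-iteration diagnostics table (displacement, max |μ⊥|,
    barrier estimate, provider calls).
    """
    from .free_energy import integrate_profile

    config = config or StringConfig()
    path = initial.copy()
    records = []
    prev_barrier = None
    converged = False
    provider_calls = 0
    for it in range(1, config.max_iterations + 1):
        mu = [provider.mu(rep) for rep in path.replicas]
        provider_calls += path.n_replicas
        try:
            mu_perp = perpendicular_mu(path, mu)
        except DegeneratePathError:
            mu_perp = mu  # zero-length path: no tangent to project out
        max_mu_perp = max(float(np.max(np.abs(m.values))) for m in mu_perp)
        profile = integrate_profile(path, mu, n_dense=201)
        barrier = profile.barrier
        stepped = allen_cahn_step(path, mu, config)
        try:
            new_path = reparameterize(
                stepped, tol=config.reparam_tol, max_passes=config.reparam_max_passes
            )
        except DegeneratePathError:
            new_path = stepped
        disp = float(np.max(np.abs(new_path.stacked() - path.stacked())))
        scale = float(np.max(np.abs(new_path.stacked()))) or 1.0
        rel_dF = (
            abs(barrier - prev_barrier) / max(abs(barrier), 1e-300)
            if prev_barrier is not None
            else np.inf
        )
        records.append(
            {
                "iteration": it,
                "max_displacement": disp,
                "max_mu_perp": max_mu_perp,
                "barrier": barrier,
                "rel_barrier_change": rel_dF,
                "provider_calls": provider_calls,
            }
        )
        path = new_path
        if disp < config.tol_disp * scale and rel_dF < config.tol_F:
            converged = True
            break
        prev_barrier = barrier
    if not converged:
        logger.warning(
            "string did not converge in %d iterations (disp %.3g, dF %.3g)",
            config.max_iterations,
            records[-1]["max_displacement"],
            records[-1]["rel_barrier_change"],
        )
    diag = pd.DataFrame.from_records(records)
    diag.attrs["converged"] = converged
    diag.attrs["provider_calls"] = provider_calls
    return path, diag


class StringMFEP:
    """Minimum free-energy path model for a free-energy landscape.

    Built from a chemical-potential provider and either an initial path or a
    pair of endpoint fields (linearly interpolated into ``n_replicas``
    replicas).  :meth:`fit` runs the string iteration and returns a
    :class:`StringMFEPResults`.

    Examples
    --------
    >>> spec = AnalyticFunctionalSpec(grid, family="double_well")
    >>> model = StringMFEP(make_analytic_provider(spec), start=a, end=b, n_replicas=19)
    >>> res = model.fit()
    >>> res.barrier, res.stalk_excess
    """

    def __init__(
        self,
        provider,
        initial_path: StringPath | None = None,
        start: DensityField | None = None,
        end: DensityField | None = None,
        n_replicas: int = 24,
        config: StringConfig | None = None,
        umbrella_params: UmbrellaParams | None = None,
    ):
        if initial_path is None:
            if start is None or end is None:
                raise ValueError("supply initial_path or start+end fields")
            initial_path = initialize_path(start, end, n_replicas)
        self.provider = provider
        self.initial_path = initial_path
        self.config = config or StringConfig()
        self.umbrella_params = umbrella_params

    def fit(self, n_dense: int = 401) -> "StringMFEPResults":
        from .free_energy import integrate_profile

        path, diag = run_string(self.initial_path, self.provider, self.config)
        mu = [self.provider.mu(rep) for rep in path.replicas]
        profile = integrate_profile(path, mu, n_dense=n_dense)
        return StringMFEPResults(self, path, mu, profile, diag)


@dataclass
class StringMFEPResults:
    """Converged string, its free-energy profile, and run diagnostics."""

    model: StringMFEP
    path: StringPath
    mu_fields: list[ChemicalPotentialField]
    profile: "FreeEnergyProfile"  # noqa: F821
    diagnostics: pd.DataFrame

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.attrs.get("converged", False))

    @property
    def n_iterations(self) -> int:
        return len(self.diagnostics)

    @property
    def barrier(self) -> float:
        """ΔF_b = max_s ΔF(s), in k_BT."""
        return self.profile.barrier

    @property
    def s_barrier(self) -> float:
        return self.profile.s_barrier

    @property
    def stalk_excess(self) -> float:
        """ΔF at s = 1 — excess free energy of the final state, in k_BT."""
        return self.profile.stalk_excess

    def field_at(self, s: float) -> DensityField:
        """Spline-interpolated path field at contour parameter s."""
        t = _arc_params(self.path)
        spline = CubicSpline(t, self.path.stacked(), axis=0, bc_type="natural")
        return DensityField(
            self.path.grid, spline(float(s)).reshape(self.path.grid.shape)
        )

    def summary(self) -> str:
        lines = [
            "Minimum Free-Energy Path (string method)",
            "=" * 48,
            f"replicas               : {self.path.n_replicas}",
            f"grid                   : {self.path.grid.n_cells}",
            f"iterations             : {self.n_iterations}",
            f"converged              : {self.converged}",
            f"provider calls         : {self.diagnostics.attrs.get('provider_calls')}",
            f"barrier  dF_b  [kBT]   : {self.barrier:.6g}",
            f"barrier position s_b   : {self.s_barrier:.4f}",
            f"endpoint excess [kBT]  : {self.stalk_excess:.6g}",
        ]
        if self.profile.stderr is not None:
            lines.append(
                f"barrier stderr [kBT]   : {self.profile.barrier_stderr:.3g}"
            )
        return "\n".join(lines)

    def plot_profile(self, ax=None):
        return self.profile.plot(ax=ax)
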