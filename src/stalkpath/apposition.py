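"""Zeroth-stage apposition: hydration-repulsion dehydration free energies.

Bringing two membranes to an intermembrane distance d_w costs work against
the short-ranged hydration repulsion, modeled as exponential in d_w:

    Δf_flat(d_w) = A · exp(−d_w / λ_hyd)          [k_BT/nm², planar, per area]

with decay length λ_hyd = 0.28 nm for POPC.  For two equal spheres of outer
radius R_v the Derjaguin approximation converts the planar free-energy
density into a finite total:

    ΔF_dehydr(d_w) = π · R_v · λ_hyd · Δf_flat(d_w)      [k_BT]

The planar excess is proportional to the contact area and therefore diverges
with it — only the vesicle-vesicle result is area-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .umbrella import thermal_energy

#: hydration-repulsion decay length of POPC, nm
POPC_DECAY_LENGTH = 0.28


@dataclass(frozen=True)
class AppositionModel:
    """Exponential hydration repulsion with a Derjaguin vesicle formula.

    ``amplitude`` is the planar repulsion free-energy density extrapolated to
    contact (d_w = 0), in k_BT/nm²; ``lambda_hyd`` the decay length in nm.
    Build via :meth:`calibrate` from a single (d_w, Δf_flat) anchor (the
    usual case) or :meth:`calibrate_least_squares` from several.
    """

    amplitude: float
    lambda_hyd: float = POPC_DECAY_LENGTH

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.lambda_hyd <= 0:
            raise ValueError("amplitude and lambda_hyd must be positive")

    @classmethod
    def calibrate(
        cls,
        reference_dw: float,
        reference_f: float,
        lambda_hyd: float = POPC_DECAY_LENGTH,
    ) -> "AppositionModel":
        """Anchor the exponential at one measured (d_w, Δf_flat) pair."""
        if reference_f <= 0 or reference_dw < 0 or lambda_hyd <= 0:
            raise ValueError("calibration inputs must be positive")
        return cls(
            amplitude=reference_f * float(np.exp(reference_dw / lambda_hyd)),
            lambda_hyd=lambda_hyd,
        )

    @classmethod
    def calibrate_least_squares(
        cls, dw: np.ndarray, f_flat: np.ndarray, lambda_hyd: float | None = None
    ) -> "AppositionModel":
        """Log-linear least squares over several (d_w, Δf_flat) pairs.

        When ``lambda_hyd`` is given only the amplitude is fit; otherwise the
        decay length is fit too (slope of log Δf vs d_w).
        """
        dw = np.asarray(dw, dtype=float)
        lf = np.log(np.asarray(f_flat, dtype=float))
        if lambda_hyd is None:
            slope, intercept = np.polyfit(dw, lf, 1)
            if slope >= 0:
                raise ValueError("data do not decay with distance")
            return cls(amplitude=float(np.exp(intercept)), lambda_hyd=-1.0 / slope)
        amp = float(np.exp(np.mean(lf + dw / lambda_hyd)))
        return cls(amplitude=amp, lambda_hyd=lambda_hyd)

    def f_flat(self, d_w) -> np.ndarray | float:
        """Planar hydration-repulsion free-energy density (k_BT/nm²)."""
        return self.amplitude * np.exp(-np.asarray(d_w, dtype=float) / self.lambda_hyd)

    def planar_patch_energy(self, area: float, d_w) -> float:
        """Dehydration free energy of a planar patch: area · Δf_flat (k_BT)."""
        if area <= 0:
            raise ValueError("area must be positive")
        return float(area * self.f_flat(d_w))

    def vesicle_pair_energy(self, R_v: float, d_w) -> float:
        """Derjaguin dehydration free energy of two equal vesicles (k_BT)."""
        if R_v <= 0:
            raise ValueError("vesicle radius must be positive")
        return float(np.pi * R_v * self.lambda_hyd * self.f_flat(d_w))

    def energy_curve(
        self, d_w: np.ndarray, R_v: float | None = None, area: float | None = None
    ) -> pd.DataFrame:
        """ΔF vs d_w table for a vesicle pair and/or a planar patch."""
        d_w = np.asarray(d_w, dtype=float)
        data = {"d_w_nm": d_w, "f_flat_kBT_nm2": self.f_flat(d_w)}
        if R_v is not None:
            data["vesicle_pair_kBT"] = np.pi * R_v * self.lambda_hyd * self.f_flat(d_w)
        if area is not None:
            data["planar_patch_kBT"] = area * self.f_flat(d_w)
        return pd.DataFrame(data)


def to_kj_per_mol(energy_kbt: float, temperature: float = 300.0) -> float:
    """Convert an energy from k_BT units to kJ/mol at the given temperature."""
    return energy_kbt * thermal_energy(temperature)


def calibrate(
    reference_dw: float, reference_f: float, lambda_hyd: float = POPC_DECAY_LENGTH
) -> AppositionModel:
    """Functional alias for :meth:`AppositionModel.calibrate`."""
    return AppositionModel.calibrate(reference_dw, reference_f, lambda_hyd)
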