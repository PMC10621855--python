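"""Field-dependent tissue electrical conductivity.

Irreversible electroporation opens pores in the cell membrane, which
raises the bulk conductivity of cell-rich tissue from its low-frequency
(intact-membrane) value ``sigma0`` to its high-frequency-like
(permeabilized) value ``sigma1``.  The transition with local field
magnitude E is modeled by a sigmoid,

    sigma(E) = sigma0 + (sigma1 - sigma0) / (1 + A * exp(-(E - Ec) / Es))

with A = 10, Ec = 58 kV/m and Es = 3 kV/m by default.  Tissues without a
capacitive cell population (scar, fat, blood, connective tissue) have
sigma0 = sigma1 and are field-independent.

Default conductivities (S/m): myocardium 0.4 -> 0.6, scar/fibrosis 0.85,
fat 0.08, blood 0.6, connective tissue 0.115.  An alternative fat value
of 0.015 S/m circulates in the literature; it can be selected with
``TissueProperties.with_fat(0.015)`` for sensitivity runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .geometry import TissueLabel

__all__ = ["TissueProperties", "sigma_of_E", "half_rise_field"]

_DEFAULT_SIGMAS: dict[str, tuple[float, float]] = {
    "MYOCARDIUM": (0.4, 0.6),
    "FIBROSIS": (0.85, 0.85),
    "FAT": (0.08, 0.08),
    "BLOOD": (0.6, 0.6),
    "CONNECTIVE": (0.115, 0.115),
    # devices: the electrode is a Dirichlet surface and the shaft is
    # excluded from the conductive domain; values are placeholders.
    "ELECTRODE": (0.0, 0.0),
    "INSULATED_SHAFT": (0.0, 0.0),
}


@dataclass(frozen=True)
class TissueProperties:
    """Per-tissue pre/post-electroporation conductivities and sigmoid constants."""

    sigmas: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_SIGMAS))
    E_center: float = 58000.0  # V/m
    E_slope: float = 3000.0    # V/m
    prefactor: float = 10.0

    def __post_init__(self) -> None:
        for name, (s0, s1) in self.sigmas.items():
            if not (0.0 <= s0 <= s1):
                raise ValueError(
                    f"need 0 <= sigma0 <= sigma1 for {name}, got ({s0}, {s1})")
        if self.E_slope <= 0 or self.prefactor <= 0:
            raise ValueError("E_slope and prefactor must be > 0")

    def sigma0(self, label: TissueLabel) -> float:
        return self.sigmas[TissueLabel(label).name][0]

    def sigma1(self, label: TissueLabel) -> float:
        return self.sigmas[TissueLabel(label).name][1]

    def with_fat(self, sigma_fat: float) -> "TissueProperties":
        """Copy with a different (field-independent) fat conductivity."""
        s = dict(self.sigmas)
        s["FAT"] = (sigma_fat, sigma_fat)
        return replace(self, sigmas=s)

    def sigma0_array(self) -> np.ndarray:
        """sigma0 indexed by TissueLabel integer value."""
        return np.array([self.sigmas[lab.name][0] for lab in TissueLabel])

    def sigma1_array(self) -> np.ndarray:
        return np.array([self.sigmas[lab.name][1] for lab in TissueLabel])

    # -- serialization ---------------------------------------------------
    def to_config(self) -> str:
        d = {
            "sigmas_S_per_m": {k: list(v) for k, v in self.sigmas.items()},
            "E_center_V_per_m": self.E_center,
            "E_slope_V_per_m": self.E_slope,
            "prefactor": self.prefactor,
        }
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_config(cls, text: str) -> "TissueProperties":
        d = yaml.safe_load(text)
        return cls(
            sigmas={k: tuple(v) for k, v in d["sigmas_S_per_m"].items()},
            E_center=float(d["E_center_V_per_m"]),
            E_slope=float(d["E_slope_V_per_m"]),
            prefactor=float(d["prefactor"]),
        )


def sigma_of_E(label: TissueLabel | np.ndarray, E_mag: float | np.ndarray,
               props: TissueProperties | None = None) -> float | np.ndarray:
    """Conductivity (S/m) of ``label`` at local field magnitude ``E_mag`` (V/m).

    Vectorized over both arguments; ``label`` may be an integer array of
    TissueLabel values.  Tissues with sigma0 == sigma1 return the constant
    for any field.
    """
    props = props or TissueProperties()
    E = np.asarray(E_mag, dtype=float)
    if np.any(E < 0):
        raise ValueError("E_mag must be >= 0")
    lab = np.asarray(label, dtype=int)
    s0 = props.sigma0_array()[lab]
    s1 = props.sigma1_array()[lab]
    # clip the exponent: far below the transition the sigmoid is sigma0
    x = np.clip(-(E - props.E_center) / props.E_slope, -700.0, 700.0)
    sig = s0 + (s1 - s0) / (1.0 + props.prefactor * np.exp(x))
    if np.isscalar(E_mag) and np.isscalar(label) or (
            np.ndim(label) == 0 and np.ndim(E_mag) == 0):
        return float(sig)
    return sig


def half_rise_field(props: TissueProperties | None = None) -> float:
    """Field (V/m) at which sigma reaches the midpoint (sigma0 + sigma1) / 2.

    Closed form: Ec + Es * ln(prefactor).
    """
    props = props or TissueProperties()
    return props.E_center + props.E_slope * float(np.log(props.prefactor))
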