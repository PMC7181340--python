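"""Global reactivity descriptors from ionization potential and electron affinity.

Conceptual DFT condenses a molecule's response to electron gain/loss into a
handful of global descriptors. Two standard routes to the underlying IP/EA
are implemented:

* **orbital (Koopmans)** — IP ≈ −E(HOMO), EA ≈ −E(LUMO) from the frontier
  orbitals of the neutral molecule;
* **energy (ΔSCF)** — IP = E(cation) − E(neutral), EA = E(neutral) − E(anion)
  from separately computed charge states.

From either pair: hardness η = (IP−EA)/2, electronegativity χ = (IP+EA)/2,
softness S = 1/(2η), chemical potential μ = −χ and electrophilicity
ω = μ²/(2η). All in eV. The HOMO–LUMO gap additionally sets the lowest
optical excitation, converted to a wavelength via λ = hc/E.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass

from .units import EV_NM_PRODUCT, round_half_up

__all__ = [
    "Method",
    "ReactivityDescriptors",
    "koopmans_ip_ea",
    "energy_ip_ea",
    "global_descriptors",
    "gap_to_wavelength",
    "DegenerateGapWarning",
]


class Method(str, enum.Enum):
    ORBITAL = "orbital"
    ENERGY = "energy"


class DegenerateGapWarning(UserWarning):
    """IP equals EA: softness and electrophilicity are undefined (infinite)."""


@dataclass(frozen=True)
class ReactivityDescriptors:
    """The η/S/χ/μ/ω bundle with its IP/EA provenance (all eV, S in 1/eV)."""

    method: Method
    ip: float
    ea: float
    hardness: float
    softness: float
    electronegativity: float
    chemical_potential: float
    electrophilicity: float

    @property
    def degenerate(self) -> bool:
        """True when IP = EA left softness/electrophilicity infinite."""
        return not math.isfinite(self.softness)

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Report-boundary view: descriptor values rounded half-up."""
        out = {"method": self.method.value}
        for name in (
            "ip",
            "ea",
            "hardness",
            "softness",
            "electronegativity",
            "chemical_potential",
            "electrophilicity",
        ):
            val = getattr(self, name)
            out[name] = round_half_up(val, ndigits) if math.isfinite(val) else val
        return out


def _require_finite(**values: float) -> None:
    for name, val in values.items():
        if not math.isfinite(val):
            raise ValueError(f"{name} must be finite, got {val!r}")


def koopmans_ip_ea(homo: float, lumo: float) -> tuple[float, float]:
    """Frontier-orbital (Koopmans) estimates: IP = −E(HOMO), EA = −E(LUMO)."""
    _require_finite(homo=homo, lumo=lumo)
    return -homo, -lumo


def energy_ip_ea(e_neutral: float, e_cation: float, e_anion: float) -> tuple[float, float]:
    """ΔSCF estimates from charge-state energies in a common unit (eV)."""
    _require_finite(e_neutral=e_neutral, e_cation=e_cation, e_anion=e_anion)
    return e_cation - e_neutral, e_neutral - e_anion


def global_descriptors(ip: float, ea: float, method: Method | str) -> ReactivityDescriptors:
    """Derive the global descriptor bundle from an IP/EA pair.

    A degenerate pair (IP = EA, zero hardness) yields infinite softness and
    electrophilicity flagged by :class:`DegenerateGapWarning` rather than an
    exception, so batch tables survive degenerate rows.
    """
    _require_finite(ip=ip, ea=ea)
    method = Method(method)
    hardness = (ip - ea) / 2.0
    electronegativity = (ip + ea) / 2.0
    chemical_potential = -electronegativity
    if hardness == 0.0:
        warnings.warn(
            "IP equals EA: hardness is zero, softness and electrophilicity "
            "are reported as infinite",
            DegenerateGapWarning,
            stacklevel=2,
        )
        softness = math.inf
        electrophilicity = math.inf if electronegativity != 0 else math.nan
    else:
        softness = 1.0 / (2.0 * hardness)
        electrophilicity = chemical_potential**2 / (2.0 * hardness)
    return ReactivityDescriptors(
        method=method,
        ip=ip,
        ea=ea,
        hardness=hardness,
        softness=softness,
        electronegativity=electronegativity,
        chemical_potential=chemical_potential,
        electrophilicity=electrophilicity,
    )


def gap_to_wavelength(gap: float) -> float:
    """Convert a HOMO–LUMO gap (eV) to its photon wavelength (nm)."""
    if not (math.isfinite(gap) and gap > 0):
        raise ValueError(f"gap must be positive and finite, got {gap!r}")
    return EV_NM_PRODUCT / gap
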