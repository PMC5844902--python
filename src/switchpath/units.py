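"""Unit conventions.

Two unit systems are supported and never mixed within a run:

* ``"real"`` — kcal/mol energies, Å lengths, ps times, temperature in K.
* ``"reduced"`` — k_BT = 1 energies, Å lengths, arbitrary time unit.
"""

from __future__ import annotations

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL_PER_MOL_K: float = 1.987e-3

#: Default simulation temperature (20 °C) in K.
DEFAULT_TEMPERATURE_K: float = 293.15


def thermal_energy(temperature: float = DEFAULT_TEMPERATURE_K,
                   units: str = "real") -> float:
    """Return k_BT in the energy unit of the chosen unit system."""
    if units == "reduced":
        return 1.0
    if units == "real":
        return R_KCAL_PER_MOL_K * temperature
    raise ValueError(f"unknown unit system {units!r} (use 'real' or 'reduced')")
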