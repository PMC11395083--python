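"""Material definitions: element compositions, densities, mean excitation energies.

The registry ships with the four materials the simulations need: liquid
water, a four-component (H/C/N/O) human soft tissue, gold, and aluminum
(used only as the beam-filtration medium).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

__all__ = ["Element", "Material", "get_material", "list_materials", "get_element"]


@dataclass(frozen=True)
class Element:
    symbol: str
    Z: int
    A: float


@dataclass(frozen=True)
class Material:
    """A homogeneous mixture of elements.

    ``composition`` maps element symbols to mass fractions, which must sum
    to one.  ``mean_excitation_energy_eV`` is the I-value entering the
    Bethe stopping-power formulas.
    """

    name: str
    density_g_cm3: float
    composition: dict[str, float] = field(default_factory=dict)
    mean_excitation_energy_eV: float = 75.0

    def __post_init__(self) -> None:
        if self.density_g_cm3 <= 0:
            raise ValueError("density must be positive")
        if self.mean_excitation_energy_eV <= 0:
            raise ValueError("mean excitation energy must be positive")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"mass fractions of {self.name!r} sum to {total}, expected 1"
            )

    @property
    def electrons_per_gram(self) -> float:
        """Electron density per gram, N_A * sum(w_i Z_i / A_i)."""
        from .constants import CONSTANTS

        zoa = sum(
            w * get_element(sym).Z / get_element(sym).A
            for sym, w in self.composition.items()
        )
        return CONSTANTS.avogadro_per_mol * zoa

    @property
    def z_over_a(self) -> float:
        return sum(
            w * get_element(sym).Z / get_element(sym).A
            for sym, w in self.composition.items()
        )


def _load_registry() -> tuple[dict[str, Element], dict[str, Material]]:
    text = (
        resources.files("nanodose.data").joinpath("materials.json").read_text()
    )
    doc = json.loads(text)
    elements = {
        sym: Element(sym, spec["Z"], spec["A"])
        for sym, spec in doc["elements"].items()
    }
    materials = {
        name: Material(
            name=name,
            density_g_cm3=spec["density_g_cm3"],
            composition=dict(spec["composition"]),
            mean_excitation_energy_eV=spec["mean_excitation_energy_eV"],
        )
        for name, spec in doc["materials"].items()
    }
    return elements, materials


_ELEMENTS, _MATERIALS = _load_registry()


def get_element(symbol: str) -> Element:
    try:
        return _ELEMENTS[symbol]
    except KeyError:
        raise KeyError(f"unknown element {symbol!r}") from None


def get_material(name: str) -> Material:
    try:
        return _MATERIALS[name]
    except KeyError:
        raise KeyError(
            f"unknown material {name!r}; available: {sorted(_MATERIALS)}"
        ) from None


def list_materials() -> list[str]:
    return sorted(_MATERIALS)
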