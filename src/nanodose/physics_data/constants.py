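"""Physical constants used throughout the package (CODATA values)."""

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants, immutable after load.

    Units follow the conventions of the package: energies in keV unless a
    suffix says otherwise, lengths in SI where a constant is only used in
    closed-form expressions (e.g. the Coulomb potential).
    """

    elementary_charge_C: float = 1.602176634e-19
    vacuum_permittivity_F_per_m: float = 8.8541878128e-12
    electron_rest_energy_keV: float = 510.99895
    classical_electron_radius_m: float = 2.8179403262e-15
    avogadro_per_mol: float = 6.02214076e23

    def __post_init__(self) -> None:
        for name, value in vars(self).items():
            if not value > 0:
                raise ValueError(f"constant {name} must be positive")


CONSTANTS = PhysicalConstants()

#: Thomson cross-section (barn), the low-energy limit of Klein-Nishina.
THOMSON_CROSS_SECTION_BARN = 0.66524587
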