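"""Global conceptual-DFT reactivity indices from three-state energies.

Vertical ionization potential and electron affinity are taken as total-energy
differences between the neutral species and its ions at the neutral geometry
(not Koopmans estimates from orbital energies):

    IP = E(N−1) − E(N)          EA = E(N) − E(N+1)

The derived set follows the finite-difference conventions

    χ = (IP + EA)/2     µ = −χ      η = IP − EA     S = 1/η
    ω = χ²/(2η)         ε = 1/ω

``convention="halved"`` selects the textbook variant η = (IP − EA)/2 instead;
the default unhalved hardness is the convention under which the bundled
reference dataset's printed values are internally consistent
(e.g. 7.93 − (−0.35) = 8.28 eV for L-hyoscyamine).

Negative electron affinities (unbound vertical anion) are accepted as-is.
"""

from __future__ import annotations

from typing import Literal

from pydantic import BaseModel

from .records import MoleculeRecord

__all__ = [
    "GlobalIndices",
    "vertical_ip",
    "vertical_ea",
    "band_gap",
    "global_indices",
    "DegenerateHardnessError",
]


class DegenerateHardnessError(ValueError):
    """Hardness ≤ 0: softness and electrophilicity are undefined."""


class GlobalIndices(BaseModel):
    """Derived global reactivity descriptor set for one species (eV-based)."""

    name: str
    ip: float
    ea: float
    gap: float | None
    electronegativity: float
    chemical_potential: float
    hardness: float
    softness: float
    electrophilicity: float
    nucleophilicity: float


def vertical_ip(e_neutral: float, e_cation: float) -> float:
    """Vertical ionization potential, IP = E(N−1) − E(N), in eV."""
    return e_cation - e_neutral


def vertical_ea(e_neutral: float, e_anion: float) -> float:
    """Vertical electron affinity, EA = E(N) − E(N+1), in eV.

    Negative values (the vertical anion lies above the neutral) are returned
    unclamped.
    """
    return e_neutral - e_anion


def band_gap(e_homo: float, e_lumo: float) -> float:
    """HOMO–LUMO gap, E_LUMO − E_HOMO, in eV.

    Raises ``ValueError`` if the orbitals are mis-ordered.
    """
    if e_lumo < e_homo:
        raise ValueError(f"e_lumo ({e_lumo}) below e_homo ({e_homo})")
    return e_lumo - e_homo


def global_indices(
    record: MoleculeRecord,
    convention: Literal["unhalved", "halved"] = "unhalved",
) -> GlobalIndices:
    """Compute the full global reactivity descriptor set for ``record``.

    Requires the three state energies; the gap is reported only when both
    frontier-orbital energies are present.
    """
    if not record.has_three_states():
        raise ValueError(f"{record.name}: anion/cation state energies required")
    ip = vertical_ip(record.e_neutral, record.e_cation)
    ea = vertical_ea(record.e_neutral, record.e_anion)
    chi = (ip + ea) / 2.0
    eta = ip - ea
    if convention == "halved":
        eta = eta / 2.0
    if eta <= 0:
        raise DegenerateHardnessError(
            f"{record.name}: hardness {eta} eV is not positive"
        )
    softness = 1.0 / eta
    omega = chi * chi / (2.0 * eta)
    epsilon = float("inf") if omega == 0 else 1.0 / omega
    gap = None
    if record.e_homo is not None and record.e_lumo is not None:
        gap = band_gap(record.e_homo, record.e_lumo)
    return GlobalIndices(
        name=record.name,
        ip=ip,
        ea=ea,
        gap=gap,
        electronegativity=chi,
        chemical_potential=-chi,
        hardness=eta,
        softness=softness,
        electrophilicity=omega,
        nucleophilicity=epsilon,
    )
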