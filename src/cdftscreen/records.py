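"""Core data model for QM-summary records.

A :class:`MoleculeRecord` bundles everything the descriptor layers consume for
one chemical species: total electronic energies of the neutral, anion (N+1
electrons) and cation (N−1 electrons) states at the *neutral* geometry
(vertical states), frontier-orbital energies, per-atom charges in the three
states, and an optional thermochemical block.  All energies are eV; atomic
charges are in units of the elementary charge; atom indices are 1-based so
they can be cross-referenced against published per-atom tables verbatim.

Every record carries a mandatory ``theory`` label (e.g. ``"B3LYP/6-31G"``).
Operations that difference total energies between records — binding energies
in particular — refuse to mix theory labels, because totals from different
functionals/basis sets are not on a common absolute scale.
"""

from __future__ import annotations

import math
from typing import Optional

from pydantic import BaseModel, Field, model_validator

from .constants import STANDARD_TEMPERATURE_K, ev_to_cal_per_mol

__all__ = [
    "ChargeStateTriplet",
    "ThermoRecord",
    "MoleculeRecord",
    "CompositePose",
    "AdmeFlags",
    "ValidationFailure",
]


class ValidationFailure(ValueError):
    """An invariant of the data model was violated by an input file."""


class ChargeStateTriplet(BaseModel):
    """Atomic charge of one atom in the neutral, anion and cation states."""

    atom_index: int = Field(ge=1)
    element: str
    q_neutral: float
    q_anion: float
    q_cation: float


class ThermoRecord(BaseModel):
    """Thermochemical block for one species.

    ``zpe``, ``enthalpy`` and ``free_energy`` are eV (thermal corrections as
    reported by the electronic-structure code); ``heat_capacity`` and
    ``entropy`` are cal·mol⁻¹·K⁻¹.
    """

    zpe: float = Field(ge=0.0)
    enthalpy: float
    free_energy: float
    heat_capacity: float = Field(gt=0.0)
    entropy: float = Field(gt=0.0)
    temperature: float = Field(default=STANDARD_TEMPERATURE_K, gt=0.0)

    def entropy_residual(self) -> float:
        """Signed difference (cal·mol⁻¹·K⁻¹) between the stored entropy and
        the entropy implied by (H − G)/T."""
        implied = ev_to_cal_per_mol(self.enthalpy - self.free_energy) / self.temperature
        return implied - self.entropy

    def check_consistency(self, tol: float = 0.1) -> None:
        """Raise :class:`ValidationFailure` if H, G, T and S disagree.

        The default tolerance of 0.1 cal·mol⁻¹·K⁻¹ absorbs printing precision
        of tabulated values.
        """
        residual = self.entropy_residual()
        if abs(residual) > tol:
            raise ValidationFailure(
                f"entropy inconsistent with (H-G)/T: residual {residual:.4f} "
                f"cal/mol/K exceeds tolerance {tol}"
            )


class MoleculeRecord(BaseModel):
    """One species: three-state energies, orbitals, charges, thermochemistry."""

    name: str
    theory: str
    e_neutral: float
    e_anion: Optional[float] = None
    e_cation: Optional[float] = None
    e_homo: Optional[float] = None
    e_lumo: Optional[float] = None
    charges: list[ChargeStateTriplet] = Field(default_factory=list)
    thermo: Optional[ThermoRecord] = None
    dipole: Optional[float] = None
    structure: Optional[str] = None  # SMILES

    @model_validator(mode="after")
    def _invariants(self) -> "MoleculeRecord":
        for field in ("e_neutral", "e_anion", "e_cation"):
            value = getattr(self, field)
            if value is not None and not math.isfinite(value):
                raise ValueError(f"{self.name}: {field} is not finite")
        if self.e_homo is not None and self.e_lumo is not None:
            if self.e_lumo < self.e_homo:
                raise ValueError(
                    f"{self.name}: e_lumo ({self.e_lumo}) below e_homo ({self.e_homo})"
                )
        if self.charges:
            indices = [t.atom_index for t in self.charges]
            if indices != list(range(1, len(indices) + 1)):
                raise ValueError(
                    f"{self.name}: charge atom indices must be contiguous from 1"
                )
        return self

    @property
    def n_atoms(self) -> int:
        return len(self.charges)

    def has_three_states(self) -> bool:
        return self.e_anion is not None and self.e_cation is not None

    def charge_sums(self) -> tuple[float, float, float]:
        """Summed (q_neutral, q_anion, q_cation) over all atoms."""
        return (
            sum(t.q_neutral for t in self.charges),
            sum(t.q_anion for t in self.charges),
            sum(t.q_cation for t in self.charges),
        )

    def check_charge_closure(self, net_charge: float = 0.0, tol: float = 0.02) -> None:
        """Validate that the three charge columns sum to the net molecular
        charge, net−1 (anion) and net+1 (cation) within ``tol``.

        ``tol`` defaults to ±0.02, the accumulated rounding of per-atom
        charges printed to 3 decimals over a few tens of atoms.
        """
        if not self.charges:
            return
        sn, sa, sc = self.charge_sums()
        for label, value, expected in (
            ("q_neutral", sn, net_charge),
            ("q_anion", sa, net_charge - 1.0),
            ("q_cation", sc, net_charge + 1.0),
        ):
            if abs(value - expected) > tol:
                raise ValidationFailure(
                    f"{self.name}: sum of {label} is {value:.3f}, expected "
                    f"{expected:+.1f} within ±{tol}"
                )


class CompositePose(BaseModel):
    """Geometry metadata for one modeled non-covalent composite pose."""

    pose_id: str
    genistein_site: str
    hyoscyamine_site: str
    bond_label: str
    pre_opt_length: float = Field(gt=0.0)  # Å
    post_opt_length: float = Field(gt=0.0)  # Å
    donor_element: str = "H"
    acceptor_element: str = "O"


#: Allowed vocabulary for externally supplied categorical ADME flags.
GI_ABSORPTION_LEVELS = {"high", "low"}
SOLUBILITY_CLASSES = {"soluble", "moderately_soluble", "poorly_soluble", "insoluble"}


class AdmeFlags(BaseModel):
    """Externally supplied ADME endpoints (machine-learned or proprietary),
    consumed as inputs and never recomputed."""

    pgp_substrate: bool
    gi_absorption: str
    solubility_class: str
    consensus_logp: Optional[float] = None
    synthetic_accessibility: Optional[float] = None

    @model_validator(mode="after")
    def _vocab(self) -> "AdmeFlags":
        if self.gi_absorption not in GI_ABSORPTION_LEVELS:
            raise ValueError(f"gi_absorption must be one of {sorted(GI_ABSORPTION_LEVELS)}")
        if self.solubility_class not in SOLUBILITY_CLASSES:
            raise ValueError(
                f"solubility_class must be one of {sorted(SOLUBILITY_CLASSES)}"
            )
        return self
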