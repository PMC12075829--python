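"""Composite binding energies, thermochemistry checks and contact classes.

The binding energy of a non-covalent composite is the supermolecule
difference BE = E(complex) − Σ E(fragments), negative when association is
favorable.  Because absolute totals are only comparable within one level of
theory, the operation refuses to mix records whose ``theory`` labels differ —
the reason composite studies re-optimize parent fragments at the composite's
level before differencing.

The thermochemical consistency check recomputes the entropy implied by the
enthalpy/free-energy pair, S = (H − G)/T, and compares it with the reported
entropy; agreement to ~0.1 cal·mol⁻¹·K⁻¹ at 298.15 K validates both the
transcription of a table and the assumed temperature.

Contacts are classified from the optimized contact length: H···O/H···N
contacts up to ``hb_cutoff`` are hydrogen bonds, anything up to
``vdw_cutoff`` a van der Waals contact, else none.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import pandas as pd

from .constants import STANDARD_TEMPERATURE_K, ev_to_cal_per_mol
from .global_reactivity import band_gap
from .records import CompositePose, MoleculeRecord

__all__ = [
    "CompositeSet",
    "TheoryMismatchError",
    "binding_energy",
    "entropy_from_hg",
    "classify_contact",
    "energetics_table",
    "HB_CUTOFF",
    "VDW_CUTOFF",
]

#: Default donor–H···acceptor distance cutoffs (Å).
HB_CUTOFF: float = 2.5
VDW_CUTOFF: float = 3.6

#: Acceptor elements that can form a hydrogen bond with an H donor atom.
_HB_ACCEPTORS = {"O", "N"}

logger = logging.getLogger(__name__)


class TheoryMismatchError(ValueError):
    """Records computed at different levels of theory were combined."""


@dataclass
class CompositeSet:
    """A complex record, its fragment records and the pose metadata."""

    complex: MoleculeRecord
    fragments: list[MoleculeRecord]
    pose: CompositePose

    def __post_init__(self) -> None:
        if len(self.fragments) < 2:
            raise ValueError("a composite needs at least 2 fragments")
        labels = {self.complex.theory, *(f.theory for f in self.fragments)}
        if len(labels) != 1:
            raise TheoryMismatchError(
                f"mixed theory labels in composite {self.pose.pose_id}: {sorted(labels)}"
            )


def binding_energy(cs: CompositeSet) -> float:
    """BE = E(complex) − Σ E(fragments), in eV."""
    return cs.complex.e_neutral - sum(f.e_neutral for f in cs.fragments)


def entropy_from_hg(
    enthalpy: float,
    free_energy: float,
    temperature: float = STANDARD_TEMPERATURE_K,
) -> float:
    """Entropy (cal·mol⁻¹·K⁻¹) implied by S = (H − G)/T, with H, G in eV.

    A negative result (G above H at positive T) is returned but logged as a
    warning rather than rejected.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    entropy = ev_to_cal_per_mol(enthalpy - free_energy) / temperature
    if entropy < 0:
        logger.warning(
            "negative implied entropy %.3f cal/mol/K (G > H at T=%.2f K)",
            entropy,
            temperature,
        )
    return entropy


def classify_contact(
    post_opt_length: float,
    donor_acceptor: tuple[str, str],
    hb_cutoff: float = HB_CUTOFF,
    vdw_cutoff: float = VDW_CUTOFF,
) -> Literal["hydrogen_bond", "van_der_waals", "none"]:
    """Classify an optimized intermolecular contact by length and elements."""
    if post_opt_length <= 0:
        raise ValueError("contact length must be positive")
    donor, acceptor = donor_acceptor
    if donor == "H" and acceptor in _HB_ACCEPTORS and post_opt_length <= hb_cutoff:
        return "hydrogen_bond"
    if post_opt_length <= vdw_cutoff:
        return "van_der_waals"
    return "none"


def energetics_table(sets: Sequence[CompositeSet]) -> pd.DataFrame:
    """Energetics/thermochemistry summary, one row per pose, sorted by pose id.

    Columns: pose_id, total_energy, gap, binding_energy, dipole, zpe,
    enthalpy, free_energy, heat_capacity, entropy, entropy_recomputed,
    contact_class.
    """
    if not sets:
        raise ValueError("no composite sets supplied")
    rows = []
    for cs in sets:
        rec = cs.complex
        gap = None
        if rec.e_homo is not None and rec.e_lumo is not None:
            gap = band_gap(rec.e_homo, rec.e_lumo)
        thermo = rec.thermo
        entropy_recomputed = None
        if thermo is not None:
            entropy_recomputed = entropy_from_hg(
                thermo.enthalpy, thermo.free_energy, thermo.temperature
            )
        rows.append(
            {
                "pose_id": cs.pose.pose_id,
                "total_energy": rec.e_neutral,
                "gap": gap,
                "binding_energy": binding_energy(cs),
                "dipole": rec.dipole,
                "zpe": thermo.zpe if thermo else None,
                "enthalpy": thermo.enthalpy if thermo else None,
                "free_energy": thermo.free_energy if thermo else None,
                "heat_capacity": thermo.heat_capacity if thermo else None,
                "entropy": thermo.entropy if thermo else None,
                "entropy_recomputed": entropy_recomputed,
                "contact_class": classify_contact(
                    cs.pose.post_opt_length,
                    (cs.pose.donor_element, cs.pose.acceptor_element),
                ),
            }
        )
    return pd.DataFrame(rows).sort_values("pose_id", kind="mergesort").reset_index(drop=True)
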