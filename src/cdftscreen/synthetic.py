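"""Synthetic QM-summary generator with known ground-truth descriptors.

The generator emulates only the *algebraic* structure the descriptor layers
consume — three-state energy triples with prescribed vertical IP/EA, orbital
pairs with a prescribed gap, per-atom charge triplets whose differences
recover a prescribed Fukui profile exactly, thermochemical blocks satisfying
G = H − T·S, and composite/fragment energy sets with a prescribed binding
energy.  No attempt is made to mimic real electron densities or geometries.

Construction rules (all exact, no noise on the targets):

* ``e_cation = e_neutral + target_ip``, ``e_anion = e_neutral − target_ea``
* ``e_lumo = e_homo + target_gap``
* ``q_neutral`` is a zero-sum transform of uniform noise (net charge exactly
  0); ``q_cation = q_neutral + f⁻`` and ``q_anion = q_neutral − f⁺``, so the
  charge-difference Fukui convention returns the prescribed profiles and the
  column sums close exactly (Σq_cation = +1, Σq_anion = −1)
* ``free_energy = enthalpy − T·S`` with S unit-converted from
  cal·mol⁻¹·K⁻¹ to eV·K⁻¹

A single integer seed drives one reproducible NumPy generator per record.
``round_to_printed`` emulates table-style printing (round half away from
zero at a fixed number of decimals) so tolerance policies can be exercised
against rounded data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .constants import EV_TO_CAL_PER_MOL, STANDARD_TEMPERATURE_K
from .energetics import CompositeSet, TheoryMismatchError
from .records import ChargeStateTriplet, CompositePose, MoleculeRecord, ThermoRecord

__all__ = ["SyntheticSpec", "GroundTruth", "gen_molecule", "gen_composite_set",
           "round_to_printed"]


class SyntheticSpec(BaseModel):
    """Targets for one synthetic molecule record."""

    seed: int
    n_atoms: int = Field(ge=1, default=10)
    name: str = "synthetic"
    theory: str = "SYNTH/TEST"
    target_ip: float = 7.0
    target_ea: float = 0.5
    target_gap: float = 4.0
    target_entropy: float = 230.0  # cal/mol/K
    temperature: float = STANDARD_TEMPERATURE_K
    fukui_minus: Optional[list[float]] = None  # per-atom f-, sums to 1
    fukui_plus: Optional[list[float]] = None  # per-atom f+, sums to 1
    binding_energy: float = 0.0  # eV, used by gen_composite_set
    rounding_dp: Optional[int] = None

    @model_validator(mode="after")
    def _consistent(self) -> "SyntheticSpec":
        if self.target_ip <= self.target_ea:
            raise ValueError("target_ip must exceed target_ea")
        if self.target_gap <= 0:
            raise ValueError("target_gap must be positive")
        if self.target_entropy <= 0:
            raise ValueError("target_entropy must be positive")
        for label, profile in (("fukui_minus", self.fukui_minus),
                               ("fukui_plus", self.fukui_plus)):
            if profile is not None:
                if len(profile) != self.n_atoms:
                    raise ValueError(f"{label} length must equal n_atoms")
                if abs(sum(profile) - 1.0) > 1e-12:
                    raise ValueError(f"{label} must sum to 1 within 1e-12")
        return self


@dataclass(frozen=True)
class GroundTruth:
    """Targets actually built into a generated record."""

    ip: float
    ea: float
    gap: float
    entropy: float
    fukui_minus: np.ndarray
    fukui_plus: np.ndarray
    binding_energy: float = 0.0


def _dirichlet_profile(rng: np.random.Generator, n: int) -> np.ndarray:
    profile = rng.dirichlet(np.ones(n))
    # renormalize so the sum is 1 at machine precision
    return profile / profile.sum()


def gen_molecule(spec: SyntheticSpec) -> tuple[MoleculeRecord, GroundTruth]:
    """Generate one record whose derived descriptors equal the spec targets."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_atoms
    f_minus = (np.asarray(spec.fukui_minus, dtype=float)
               if spec.fukui_minus is not None else _dirichlet_profile(rng, n))
    f_plus = (np.asarray(spec.fukui_plus, dtype=float)
              if spec.fukui_plus is not None else _dirichlet_profile(rng, n))

    noise = rng.uniform(-0.2, 0.2, size=n)
    q_neutral = noise - noise.mean()  # net charge exactly 0
    q_cation = q_neutral + f_minus
    q_anion = q_neutral - f_plus
    elements = rng.choice(["C", "O", "N", "H"], size=n)
    charges = [
        ChargeStateTriplet(
            atom_index=i + 1,
            element=str(elements[i]),
            q_neutral=float(q_neutral[i]),
            q_anion=float(q_anion[i]),
            q_cation=float(q_cation[i]),
        )
        for i in range(n)
    ]

    # modest magnitude keeps (E± − E) differences exact to well below 1e-12
    e_neutral = float(rng.uniform(-2000.0, -500.0))
    e_homo = float(rng.uniform(-8.0, -5.0))
    enthalpy = float(rng.uniform(10.0, 20.0))
    ts_ev = spec.target_entropy * spec.temperature / EV_TO_CAL_PER_MOL
    thermo = ThermoRecord(
        zpe=float(rng.uniform(5.0, 9.0)),
        enthalpy=enthalpy,
        free_energy=enthalpy - ts_ev,
        heat_capacity=float(rng.uniform(100.0, 200.0)),
        entropy=spec.target_entropy,
        temperature=spec.temperature,
    )
    record = MoleculeRecord(
        name=spec.name,
        theory=spec.theory,
        e_neutral=e_neutral,
        e_anion=e_neutral - spec.target_ea,
        e_cation=e_neutral + spec.target_ip,
        e_homo=e_homo,
        e_lumo=e_homo + spec.target_gap,
        charges=charges,
        thermo=thermo,
        dipole=float(rng.uniform(0.0, 8.0)),
    )
    truth = GroundTruth(
        ip=spec.target_ip,
        ea=spec.target_ea,
        gap=spec.target_gap,
        entropy=spec.target_entropy,
        fukui_minus=f_minus,
        fukui_plus=f_plus,
    )
    return record, truth


def gen_composite_set(
    spec_complex: SyntheticSpec, spec_fragments: list[SyntheticSpec]
) -> tuple[CompositeSet, GroundTruth]:
    """Generate a complex plus fragments with an exact prescribed BE.

    The complex's three state energies are shifted rigidly so that
    ``e_neutral = Σ fragment e_neutral + binding_energy`` holds exactly while
    the complex's IP/EA targets are preserved.
    """
    if len(spec_fragments) < 2:
        raise ValueError("at least 2 fragment specs required")
    tags = {spec_complex.theory, *(s.theory for s in spec_fragments)}
    if len(tags) != 1:
        raise TheoryMismatchError(f"mixed theory tags in specs: {sorted(tags)}")

    fragments = []
    fragment_sum = 0.0
    for spec in spec_fragments:
        record, _ = gen_molecule(spec)
        fragments.append(record)
        fragment_sum += record.e_neutral

    complex_record, complex_truth = gen_molecule(spec_complex)
    target_total = fragment_sum + spec_complex.binding_energy
    complex_record = complex_record.model_copy(
        update={
            "e_neutral": target_total,
            "e_anion": target_total - spec_complex.target_ea,
            "e_cation": target_total + spec_complex.target_ip,
        }
    )

    rng = np.random.default_rng(spec_complex.seed)
    pose = CompositePose(
        pose_id=spec_complex.name,
        genistein_site="synthetic-donor",
        hyoscyamine_site="synthetic-acceptor",
        bond_label="H...O",
        pre_opt_length=float(rng.uniform(0.9, 2.4)),
        post_opt_length=float(rng.uniform(1.5, 3.5)),
        donor_element="H",
        acceptor_element="O",
    )
    truth = GroundTruth(
        ip=complex_truth.ip,
        ea=complex_truth.ea,
        gap=complex_truth.gap,
        entropy=complex_truth.entropy,
        fukui_minus=complex_truth.fukui_minus,
        fukui_plus=complex_truth.fukui_plus,
        binding_energy=spec_complex.binding_energy,
    )
    return CompositeSet(complex=complex_record, fragments=fragments, pose=pose), truth


def _round_half_away(value: float, dp: int) -> float:
    scale = 10.0 ** dp
    return math.copysign(math.floor(abs(value) * scale + 0.5), value) / scale


def round_to_printed(record: MoleculeRecord, dp: int) -> MoleculeRecord:
    """Round every numeric field half away from zero to ``dp`` decimals,
    emulating how tabulated values are printed."""
    if dp < 0:
        raise ValueError("dp must be >= 0")

    def r(value: float | None) -> float | None:
        return None if value is None else _round_half_away(value, dp)

    thermo = record.thermo
    if thermo is not None:
        thermo = ThermoRecord(
            zpe=r(thermo.zpe),
            enthalpy=r(thermo.enthalpy),
            free_energy=r(thermo.free_energy),
            heat_capacity=r(thermo.heat_capacity),
            entropy=r(thermo.entropy),
            temperature=thermo.temperature,
        )
    charges = [
        ChargeStateTriplet(
            atom_index=t.atom_index,
            element=t.element,
            q_neutral=r(t.q_neutral),
            q_anion=r(t.q_anion),
            q_cation=r(t.q_cation),
        )
        for t in record.charges
    ]
    return record.model_copy(
        update={
            "e_neutral": r(record.e_neutral),
            "e_anion": r(record.e_anion),
            "e_cation": r(record.e_cation),
            "e_homo": r(record.e_homo),
            "e_lumo": r(record.e_lumo),
            "dipole": r(record.dipole),
            "charges": charges,
            "thermo": thermo,
        }
    )
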