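"""Rule-based oral-bioavailability descriptors from molecular structure.

Everything here is a deterministic function of the 2-D structure (SMILES):
Ertl topological polar surface area, Wildman–Crippen atomic logP, H-bond
donor/acceptor counts, molecular weight, rotatable bonds, Lipinski and Veber
rule outcomes, and the Martin bioavailability score.  Descriptor primitives
are delegated to RDKit, whose TPSA and MolLogP are the reference
implementations of the Ertl and Wildman–Crippen schemes.

Machine-learned or consensus endpoints (Pgp substrate, solubility class, GI
absorption class, consensus logP, synthetic accessibility) are *not*
computed; they enter the pipeline as externally supplied :class:`AdmeFlags`
and are passed through with provenance ``supplied``.

The Martin score maps a compound to one of five bioavailability-probability
bins {0.11, 0.17, 0.55, 0.56, 0.85}: anions are scored by TPSA bands
(<75 Å² → 0.85, 75–150 → 0.56, ≥150 → 0.11); all other charge classes score
0.55 when they have at most one Lipinski violation and 0.17 otherwise.
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

from .records import AdmeFlags

__all__ = [
    "AdmeProfileResult",
    "StructureError",
    "parse_smiles",
    "tpsa",
    "logp_atomic",
    "lipinski_violations",
    "bioavailability_score",
    "adme_profile",
]

ChargeClass = Literal["neutral", "anion", "cation", "zwitterion"]


class StructureError(ValueError):
    """The supplied structure could not be parsed or is empty."""


class AdmeProfileResult(BaseModel):
    """Computed rule-based descriptors plus pass-through external flags."""

    name: str
    tpsa: float
    logp_atomic: float
    mol_weight: float
    hbd: int
    hba: int
    rotatable_bonds: int
    lipinski_violations: list[str]
    lipinski_pass: bool
    veber_pass: bool
    charge_class: ChargeClass
    bioavailability_score: float
    external: Optional[AdmeFlags] = None
    #: field name -> "computed" | "supplied"
    provenance: dict[str, str] = {}


def parse_smiles(smiles: str) -> Chem.Mol:
    """Parse a SMILES string, raising :class:`StructureError` on failure."""
    mol = Chem.MolFromSmiles(smiles) if smiles else None
    if mol is None or mol.GetNumAtoms() == 0:
        raise StructureError(f"unparseable or empty structure: {smiles!r}")
    return mol


def _as_mol(structure: str | Chem.Mol) -> Chem.Mol:
    if isinstance(structure, Chem.Mol):
        if structure.GetNumAtoms() == 0:
            raise StructureError("structure has no atoms")
        return structure
    return parse_smiles(structure)


def tpsa(structure: str | Chem.Mol) -> float:
    """Ertl topological polar surface area (Å²), N/O contributions."""
    return Descriptors.TPSA(_as_mol(structure))


def logp_atomic(structure: str | Chem.Mol) -> float:
    """Wildman–Crippen atomic-contribution logP estimate."""
    return Crippen.MolLogP(_as_mol(structure))


def lipinski_violations(mol: Chem.Mol, logp: float | None = None) -> list[str]:
    """Names of violated Lipinski rule-of-five conditions."""
    logp = Crippen.MolLogP(mol) if logp is None else logp
    violations = []
    if Descriptors.MolWt(mol) > 500:
        violations.append("mol_weight>500")
    if logp > 5:
        violations.append("logp>5")
    if Lipinski.NumHDonors(mol) > 5:
        violations.append("hbd>5")
    if Lipinski.NumHAcceptors(mol) > 10:
        violations.append("hba>10")
    return violations


def detect_charge_class(mol: Chem.Mol) -> ChargeClass:
    """Charge class from explicit formal charges (neutral if none)."""
    positives = sum(1 for a in mol.GetAtoms() if a.GetFormalCharge() > 0)
    negatives = sum(1 for a in mol.GetAtoms() if a.GetFormalCharge() < 0)
    if positives and negatives:
        return "zwitterion"
    if negatives:
        return "anion"
    if positives:
        return "cation"
    return "neutral"


def bioavailability_score(
    tpsa_value: float,
    n_lipinski_violations: int,
    charge_class: ChargeClass = "neutral",
) -> float:
    """Martin bioavailability score (probability bin).

    Anions: TPSA < 75 → 0.85, 75 ≤ TPSA < 150 → 0.56, TPSA ≥ 150 → 0.11.
    Neutral/cation/zwitterion: ≤1 Lipinski violation → 0.55, else 0.17.
    """
    if charge_class == "anion":
        if tpsa_value < 75.0:
            return 0.85
        if tpsa_value < 150.0:
            return 0.56
        return 0.11
    return 0.55 if n_lipinski_violations <= 1 else 0.17


def adme_profile(
    structure: str | Chem.Mol,
    name: str = "",
    external_flags: AdmeFlags | None = None,
) -> AdmeProfileResult:
    """Full rule-based ADME profile for one structure.

    External flags are attached untouched; the ``provenance`` map labels each
    reported field as computed here or supplied from outside.
    """
    mol = _as_mol(structure)
    tpsa_value = Descriptors.TPSA(mol)
    logp = Crippen.MolLogP(mol)
    violations = lipinski_violations(mol, logp)
    rotatable = rdMolDescriptors.CalcNumRotatableBonds(mol)
    charge_class = detect_charge_class(mol)
    veber = rotatable <= 10 and tpsa_value <= 140.0
    provenance = {
        field: "computed"
        for field in (
            "tpsa",
            "logp_atomic",
            "mol_weight",
            "hbd",
            "hba",
            "rotatable_bonds",
            "lipinski_pass",
            "veber_pass",
            "bioavailability_score",
        )
    }
    if external_flags is not None:
        provenance.update(
            {flag: "supplied" for flag in external_flags.model_dump(exclude_none=True)}
        )
    return AdmeProfileResult(
        name=name,
        tpsa=tpsa_value,
        logp_atomic=logp,
        mol_weight=Descriptors.MolWt(mol),
        hbd=Lipinski.NumHDonors(mol),
        hba=Lipinski.NumHAcceptors(mol),
        rotatable_bonds=rotatable,
        lipinski_violations=violations,
        lipinski_pass=len(violations) <= 1,
        veber_pass=veber,
        charge_class=charge_class,
        bioavailability_score=bioavailability_score(
            tpsa_value, len(violations), charge_class
        ),
        external=external_flags,
        provenance=provenance,
    )
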