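"""Reading and writing the QM-summary, charge-table and report formats.

QM summary: a JSON file holding a top-level list of molecule objects::

    {"name": ..., "theory": ...,
     "energies": {"neutral": ..., "anion": ..., "cation": ...,
                  "homo": ..., "lumo": ..., "unit": "eV"},
     "thermo": {"zpe": ..., "enthalpy": ..., "free_energy": ...,
                "heat_capacity": ..., "entropy": ..., "temperature": ...}
       | null,
     "dipole": ... | null, "smiles": ... | null}

Charge tables: TSV with columns atom_index, element, q_neutral, q_anion,
q_cation (atom_index 1-based and contiguous).

Screening reports serialize to JSON (lossless round trip) or TSV (one row
per ranked candidate, stable column order).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import pandas as pd

from .records import ChargeStateTriplet, MoleculeRecord, ThermoRecord, ValidationFailure
from .screening import ScreeningReport

__all__ = [
    "read_summary",
    "write_summary",
    "read_charges",
    "write_charges",
    "write_report",
    "read_report",
    "SummaryParseError",
]

_CHARGE_COLUMNS = ["atom_index", "element", "q_neutral", "q_anion", "q_cation"]


class SummaryParseError(ValueError):
    """The summary or charge file does not conform to the documented schema."""


def _record_from_obj(obj: dict, index: int) -> MoleculeRecord:
    where = f"molecule #{index}"
    if not isinstance(obj, dict):
        raise SummaryParseError(f"{where}: expected an object")
    name = obj.get("name")
    where = f"molecule {name!r}" if name else where
    for key in ("name", "theory", "energies"):
        if key not in obj:
            raise SummaryParseError(f"{where}: missing field {key!r}")
    energies = obj["energies"]
    if not isinstance(energies, dict) or "neutral" not in energies:
        raise SummaryParseError(f"{where}: energies.neutral is required")
    unit = energies.get("unit", "eV")
    if unit != "eV":
        raise SummaryParseError(f"{where}: unsupported energy unit {unit!r}")
    thermo = obj.get("thermo")
    try:
        return MoleculeRecord(
            name=name,
            theory=obj["theory"],
            e_neutral=energies["neutral"],
            e_anion=energies.get("anion"),
            e_cation=energies.get("cation"),
            e_homo=energies.get("homo"),
            e_lumo=energies.get("lumo"),
            thermo=ThermoRecord(**thermo) if thermo else None,
            dipole=obj.get("dipole"),
            structure=obj.get("smiles"),
        )
    except (ValueError, TypeError) as exc:
        raise ValidationFailure(f"{where}: {exc}") from exc


def read_summary(path: str | Path) -> list[MoleculeRecord]:
    """Read a QM-summary JSON file into validated records.

    An empty molecule list yields an empty result.  Schema violations raise
    :class:`SummaryParseError` naming the molecule and field; data-model
    violations raise :class:`ValidationFailure`.
    """
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SummaryParseError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(payload, list):
        raise SummaryParseError(f"{path}: top level must be a list of molecules")
    return [_record_from_obj(obj, i) for i, obj in enumerate(payload)]


def write_summary(records: list[MoleculeRecord], path: str | Path) -> None:
    """Write records to the QM-summary JSON schema (stable key order)."""
    payload = []
    for rec in records:
        payload.append(
            {
                "name": rec.name,
                "theory": rec.theory,
                "energies": {
                    "neutral": rec.e_neutral,
                    "anion": rec.e_anion,
                    "cation": rec.e_cation,
                    "homo": rec.e_homo,
                    "lumo": rec.e_lumo,
                    "unit": "eV",
                },
                "thermo": rec.thermo.model_dump() if rec.thermo else None,
                "dipole": rec.dipole,
                "smiles": rec.structure,
            }
        )
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_charges(path: str | Path) -> list[ChargeStateTriplet]:
    """Read a charge-table TSV into triplets (validated column set)."""
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in _CHARGE_COLUMNS if c not in frame.columns]
    if missing:
        raise SummaryParseError(f"{path}: charge table missing columns {missing}")
    return [
        ChargeStateTriplet(
            atom_index=int(row.atom_index),
            element=str(row.element),
            q_neutral=float(row.q_neutral),
            q_anion=float(row.q_anion),
            q_cation=float(row.q_cation),
        )
        for row in frame.itertuples()
    ]


def write_charges(triplets: list[ChargeStateTriplet], path: str | Path) -> None:
    lines = ["\t".join(_CHARGE_COLUMNS)]
    for t in triplets:
        lines.append(
            f"{t.atom_index}\t{t.element}\t{t.q_neutral!r}\t{t.q_anion!r}\t{t.q_cation!r}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_report(
    report: ScreeningReport, path: str | Path, format: Literal["tsv", "json"] = "json"
) -> None:
    """Serialize a screening report deterministically.

    JSON is lossless (``read_report`` reproduces the report); TSV renders one
    row per ranked candidate with per-criterion scores in criterion order.
    """
    path = Path(path)
    if format == "json":
        path.write_text(report.model_dump_json(indent=1) + "\n")
        return
    if format != "tsv":
        raise ValueError(f"unknown report format {format!r}")
    criteria = [c.name for c in report.config.criteria]
    header = ["pose_id", "rank", "weighted_total", *[f"score_{c}" for c in criteria],
              "in_pareto_front", "selected"]
    lines = ["\t".join(header)]
    for rank, pose in enumerate(report.ranking, start=1):
        row = [pose, str(rank), repr(report.weighted_total[pose])]
        row += [repr(report.scores[pose][c]) for c in criteria]
        row.append(str(pose in report.pareto_front))
        row.append(str(pose in report.selected))
        lines.append("\t".join(row))
    for pose, filter_name in report.excluded:
        lines.append("\t".join([pose, "excluded", filter_name]))
    path.write_text("\n".join(lines) + "\n")


def read_report(path: str | Path) -> ScreeningReport:
    """Read back a JSON screening report."""
    return ScreeningReport.model_validate_json(Path(path).read_text())
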