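"""Condensed Fukui functions and the condensed dual descriptor.

Per-atom Fukui indices are condensed from atomic charges of the vertical
N−1/N/N+1 electron states.  With q the *atomic charge* (not the electron
population) the implemented convention is

    f⁻(k) = q(N−1, k) − q(N, k)     susceptibility to electrophilic attack
    f⁺(k) = q(N, k) − q(N+1, k)     susceptibility to nucleophilic attack
    f⁰(k) = (f⁻ + f⁺)/2             radical attack
    CDD(k) = f⁺ − f⁻                condensed dual descriptor

Equivalently, in terms of electron populations p = Z − q, f⁻ = p(N) − p(N−1)
and f⁺ = p(N+1) − p(N): the classical population-difference definitions.
Published per-atom tables in this area sometimes state the population formula
while printing charge columns, which flips every sign; this module pins the
convention that makes Σf⁻ = Σf⁺ = +1 for the bundled charge tables and
records it in the table metadata.

A positive CDD marks an atom prone to nucleophilic attack, a negative CDD
one prone to electrophilic attack; atoms are flagged when |CDD| exceeds a
threshold ``tau`` (default 0.05 e).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, NamedTuple

import pandas as pd

from .records import ChargeStateTriplet, MoleculeRecord

__all__ = [
    "FukuiIndices",
    "FukuiTable",
    "fukui_from_charges",
    "cdd",
    "fukui_table",
    "top_k_sites",
    "DEFAULT_TAU",
    "CONVENTION_NOTE",
]

#: Default |CDD| threshold (e) above which an atom is flagged as a site.
DEFAULT_TAU: float = 0.05

CONVENTION_NOTE = (
    "charge-difference convention: f- = q(N-1)-q(N), f+ = q(N)-q(N+1); "
    "equivalent to population differences with p = Z - q"
)


class FukuiIndices(NamedTuple):
    f_minus: float
    f_plus: float
    f_zero: float


def fukui_from_charges(triplet: ChargeStateTriplet) -> FukuiIndices:
    """Condensed Fukui indices (f⁻, f⁺, f⁰) for one atom from its charges."""
    f_minus = triplet.q_cation - triplet.q_neutral
    f_plus = triplet.q_neutral - triplet.q_anion
    return FukuiIndices(f_minus, f_plus, (f_minus + f_plus) / 2.0)


def cdd(f_plus: float, f_minus: float) -> float:
    """Condensed dual descriptor, f⁺ − f⁻."""
    return f_plus - f_minus


@dataclass
class FukuiTable:
    """Per-atom Fukui indices, dual descriptor and site flags for one species.

    ``frame`` columns: atom_index, element, f_minus, f_plus, f_zero, cdd, site
    (site ∈ {nucleophilic_site, electrophilic_site, none}).
    """

    name: str
    frame: pd.DataFrame
    tau: float
    convention: str = field(default=CONVENTION_NOTE)

    def sites(self, kind: Literal["nucleophilic_site", "electrophilic_site"]) -> list[int]:
        """Atom indices flagged with the given site kind."""
        mask = self.frame["site"] == kind
        return self.frame.loc[mask, "atom_index"].tolist()

    def atom(self, atom_index: int) -> pd.Series:
        """Row for a 1-based atom index."""
        return self.frame.set_index("atom_index").loc[atom_index]


def fukui_table(record: MoleculeRecord, tau: float = DEFAULT_TAU) -> FukuiTable:
    """Condensed Fukui table with site classification for every atom.

    Atoms with CDD > +tau are flagged nucleophilic-attack sites, CDD < −tau
    electrophilic-attack sites.
    """
    if not record.charges:
        raise ValueError(f"{record.name}: no atomic charges present")
    rows = []
    for triplet in record.charges:
        fm, fp, f0 = fukui_from_charges(triplet)
        value = cdd(fp, fm)
        if value > tau:
            site = "nucleophilic_site"
        elif value < -tau:
            site = "electrophilic_site"
        else:
            site = "none"
        rows.append(
            {
                "atom_index": triplet.atom_index,
                "element": triplet.element,
                "f_minus": fm,
                "f_plus": fp,
                "f_zero": f0,
                "cdd": value,
                "site": site,
            }
        )
    return FukuiTable(name=record.name, frame=pd.DataFrame(rows), tau=tau)


def top_k_sites(
    table: FukuiTable,
    which: Literal["f_minus", "f_plus", "cdd"],
    k: int,
) -> list[int]:
    """Atom indices of the ``k`` strongest sites for one index column.

    For ``cdd`` atoms are ranked by |CDD| (both attack modes are 'strong');
    for the Fukui columns by signed value.  Ties break on ascending atom
    index.  ``k`` beyond the atom count is truncated.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    frame = table.frame
    if k > len(frame):
        logging.getLogger(__name__).info(
            "top_k_sites: k=%d exceeds %d atoms, truncating", k, len(frame)
        )
    key = frame[which].abs() if which == "cdd" else frame[which]
    order = (
        pd.DataFrame({"key": key, "atom_index": frame["atom_index"]})
        .sort_values(["key", "atom_index"], ascending=[False, True], kind="mergesort")
    )
    return order["atom_index"].head(min(k, len(frame))).tolist()
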