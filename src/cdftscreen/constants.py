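"""Unit conversions and tolerance policy.

Every energy in the pipeline is stored in eV; all conversions route through
the two factors below so values cannot drift between modules.
"""

from __future__ import annotations

#: 1 Hartree in eV (CODATA 2018).
HARTREE_TO_EV: float = 27.211386245988

#: 1 eV in kcal·mol⁻¹.
EV_TO_KCAL_PER_MOL: float = 23.060548

#: 1 eV in cal·mol⁻¹.
EV_TO_CAL_PER_MOL: float = EV_TO_KCAL_PER_MOL * 1000.0

#: Standard temperature (K) assumed by the thermochemistry consistency checks.
STANDARD_TEMPERATURE_K: float = 298.15

#: Named tolerance levels for comparisons against values printed at a given
#: decimal precision.  A table cell printed to 2 decimals can disagree with a
#: recomputed value by half a unit in the last place plus accumulated rounding
#: of its inputs, hence the levels below rather than a single epsilon.
TOLERANCE = {
    "printed_2dp": 0.01,
    "printed_3dp": 0.005,
    "full_precision": 1e-6,
    "computed": 1e-12,
}


def hartree_to_ev(value_ha: float) -> float:
    """Convert a Hartree energy to eV."""
    return value_ha * HARTREE_TO_EV


def ev_to_cal_per_mol(value_ev: float) -> float:
    """Convert an eV energy to cal·mol⁻¹."""
    return value_ev * EV_TO_CAL_PER_MOL
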