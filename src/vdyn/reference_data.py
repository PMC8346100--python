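"""Published per-variant reference values consumed as inputs.

These are the printed MM-GBSA binding-energy terms and mdpocket catalytic
pocket volumes reported for the CYP3A5 wild type and six missense variants
in complex with ritonavir and artemether.  They are *inputs* to the
term-combination, shrinkage, and volume-affinity regression stages; nothing
in this package recomputes them from trajectories.

All energies in kcal/mol, volumes in Angstrom^3.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["binding_energy_table", "pocket_volumes", "VARIANTS"]

#: Variant order used throughout (wild type first).
VARIANTS = ("WT", "R28C", "Y53C", "L82R", "I149T", "V238A", "I276T")

# drug, variant, dG_binding, <E_int>, -T*dS, dG_solv
_BINDING_ROWS = [
    ("ritonavir", "WT", -8.72, -58.46, 11.01, 38.72),
    ("ritonavir", "R28C", -10.51, -65.18, 14.01, 40.66),
    ("ritonavir", "Y53C", -1.89, -64.09, 21.08, 41.11),
    ("ritonavir", "L82R", -11.33, -60.87, 12.69, 36.84),
    ("ritonavir", "I149T", -2.75, -57.84, 15.29, 39.79),
    ("ritonavir", "V238A", 1.44, -55.97, 19.45, 37.96),
    ("ritonavir", "I276T", -12.06, -60.85, 13.58, 35.20),
    ("artemether", "WT", -13.26, -29.57, 7.75, 8.55),
    ("artemether", "R28C", -8.22, -33.16, 12.08, 12.85),
    ("artemether", "Y53C", -14.93, -29.31, 6.13, 8.24),
    ("artemether", "L82R", -10.26, -30.71, 10.36, 10.08),
    ("artemether", "I149T", -15.45, -31.00, 7.66, 7.88),
    ("artemether", "V238A", -13.41, -29.59, 8.43, 7.74),
    ("artemether", "I276T", -10.83, -29.80, 9.47, 9.49),
]

# mean catalytic-pocket volume per simulated variant (mdpocket, equilibrated phase)
_POCKET_VOLUMES = {
    "WT": 1970.70,
    "Y53C": 2019.04,
    "L82R": 1805.27,
    "I276T": 1793.63,
    "R28C": 1625.61,
    "I149T": 1479.37,
    "V238A": 1438.22,
}


def binding_energy_table() -> pd.DataFrame:
    """Published binding free energies and their components, per complex.

    Columns: ``drug``, ``variant``, ``g_binding``, ``e_int_mean``,
    ``minus_tds``, ``g_solv`` (kcal/mol).
    """
    return pd.DataFrame(
        _BINDING_ROWS,
        columns=["drug", "variant", "g_binding", "e_int_mean", "minus_tds", "g_solv"],
    )


def pocket_volumes() -> pd.Series:
    """Published mean catalytic pocket volume per variant (Angstrom^3)."""
    return pd.Series(_POCKET_VOLUMES, name="volume").loc[list(VARIANTS)]
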