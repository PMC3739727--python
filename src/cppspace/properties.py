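"""Atomic property tables used to weight molecular descriptors.

Descriptor families in this package (Geary autocorrelation, 3D-MoRSE, WHIM,
mean polarizability) weight atoms by physical properties — atomic mass,
Sanderson electronegativity, polarizability, van der Waals volume — always
scaled on the carbon atom so that w(C) = 1 for every property.  The table is
shipped as a CSV data file so additional elements can be added without a code
change.
"""

from __future__ import annotations

from importlib import resources
from typing import Mapping

import pandas as pd

#: Weighting-scheme codes used in descriptor names (Dragon convention):
#: u = unit weights, m = atomic mass, v = van der Waals volume,
#: e = Sanderson electronegativity, p = polarizability.
WEIGHT_SCHEMES = ("u", "m", "v", "e", "p")

_SCHEME_COLUMN = {
    "m": "mass",
    "v": "vdw_volume",
    "e": "sanderson_en",
    "p": "polarizability",
}


class AtomPropertyTable:
    """Per-element atomic properties with carbon-scaled accessors."""

    def __init__(self, table: pd.DataFrame):
        if "element" in table.columns:
            table = table.set_index("element")
        if (table <= 0).any().any():
            raise ValueError("atomic properties must be strictly positive")
        self._table = table

    @classmethod
    def default(cls) -> "AtomPropertyTable":
        path = resources.files("cppspace.data").joinpath("atom_properties.csv")
        with resources.as_file(path) as p:
            return cls(pd.read_csv(p))

    @property
    def elements(self) -> list[str]:
        return list(self._table.index)

    def value(self, element: str, prop: str) -> float:
        try:
            return float(self._table.loc[element, prop])
        except KeyError:
            raise KeyError(
                f"element {element!r} missing from the atom property table"
            ) from None

    def carbon_scaled(self, element: str, prop: str) -> float:
        """Property of *element* divided by the same property of carbon."""
        return self.value(element, prop) / self.value("C", prop)

    def weights(self, elements: list[str], scheme: str) -> list[float]:
        """Carbon-scaled weights for a list of element symbols.

        Scheme ``u`` yields unit weights for every atom.
        """
        if scheme == "u":
            return [1.0] * len(elements)
        if scheme not in _SCHEME_COLUMN:
            raise ValueError(f"unknown weighting scheme {scheme!r}")
        col = _SCHEME_COLUMN[scheme]
        return [self.carbon_scaled(el, col) for el in elements]


_default: AtomPropertyTable | None = None


def default_properties() -> AtomPropertyTable:
    """Module-level cached default table."""
    global _default
    if _default is None:
        _default = AtomPropertyTable.default()
    return _default


def scheme_weights(elements: list[str], scheme: str,
                   table: AtomPropertyTable | Mapping | None = None) -> list[float]:
    table = table if table is not None else default_properties()
    return table.weights(elements, scheme)
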