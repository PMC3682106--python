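"""Israelachvili critical packing parameter and molecular shape classes.

For a single-chain amphiphile the hydrocarbon-chain volume and critical
(fully extended) length follow the Tanford-style increments

    V   = 27.4 + 26.9·n_c   [Å³]      (CH₃ cap + n_c CH₂ volumes)
    l_c = 1.5  + 1.265·n_c  [Å]       (CH₃ radius + n_c C–C bond projections)

with n_c the number of chain carbons counted as methylene units past the cap
(for an n-alkyl chain of N carbons this convention gives n_c = N − 1, e.g. 15
for hexadecyl, 17 for octadecyl).  The dimensionless critical packing
parameter is

    s = V / (a · l_c)

with a the headgroup area (Å²).  Shape classes follow the standard banding:
s < 1/3 cone, 1/3 ≤ s < 1 truncated cone (with a ±0.05 band around 1 read as
cylinder), s > 1.05 inverted truncated cone.  Opposite shapes (cone-family
with inverted truncated cone) pack complementarily, which rationalizes the
strong attraction between single-chain phosphocholine drugs and cholesterol;
this is a qualitative geometric heuristic, not a thermodynamic prediction.

Multi-chain or unsaturated lipids (DPPC, POPC, erucyl chains with a cis
double bond) are not reproduced by the single-chain increments; their V and
l_c are accepted as explicit overrides, as in the bundled reference table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

__all__ = [
    "MoleculeGeometry",
    "chain_volume",
    "chain_length",
    "packing_parameter",
    "classify_shape",
    "complementarity",
    "reference_geometries",
    "reference_table",
]

CH3_VOLUME = 27.4     # Å³
CH2_VOLUME = 26.9     # Å³
CC_BOND_LENGTH = 1.265  # Å, projected C–C bond
CH3_RADIUS = 1.5      # Å

SHAPE_CONE = "cone"
SHAPE_TRUNCATED_CONE = "truncated_cone"
SHAPE_CYLINDER = "cylinder"
SHAPE_INVERTED = "inverted_truncated_cone"


def chain_volume(n_c: int) -> float:
    """Hydrocarbon chain volume, Å³: 27.4 + 26.9·n_c."""
    if int(n_c) != n_c or n_c < 1:
        raise ValueError("n_c must be a positive integer carbon count")
    return CH3_VOLUME + CH2_VOLUME * int(n_c)


def chain_length(n_c: int) -> float:
    """Critical (extended) chain length, Å: 1.5 + 1.265·n_c."""
    if int(n_c) != n_c or n_c < 1:
        raise ValueError("n_c must be a positive integer carbon count")
    return CH3_RADIUS + CC_BOND_LENGTH * int(n_c)


def packing_parameter(V: float, a: float, l_c: float) -> float:
    """Critical packing parameter s = V / (a·l_c), dimensionless."""
    if V <= 0 or a <= 0 or l_c <= 0:
        raise ValueError("V, a and l_c must all be positive")
    return V / (a * l_c)


def classify_shape(s: float, cylinder_band: float = 0.05, cone_band: float = 0.005) -> str:
    """Shape class from s: cone < 1/3 ≤ truncated cone < 1 (±band cylinder) < inverted.

    Values within ``cone_band`` of the 1/3 boundary are read as truncated
    cones: a chain whose s rounds to 0.33 is conventionally assigned the
    denser class, and the hard boundary would flip on the last printed digit.
    """
    if s <= 0:
        raise ValueError("s must be positive")
    if s < 1.0 / 3.0 - cone_band:
        return SHAPE_CONE
    if s < 1.0 - cylinder_band:
        return SHAPE_TRUNCATED_CONE
    if s <= 1.0 + cylinder_band:
        return SHAPE_CYLINDER
    return SHAPE_INVERTED


@dataclass(frozen=True)
class MoleculeGeometry:
    """Headgroup area, chain geometry and the resulting packing descriptor."""

    name: str
    a: float       # headgroup area, Å²
    l_c: float     # chain critical length, Å
    V: float       # chain volume, Å³
    s: float       # V / (a·l_c)
    shape: str
    n_c: Optional[int] = None   # chain carbons used, when derived
    chains: int = 1

    def __post_init__(self) -> None:
        if self.a <= 0 or self.l_c <= 0 or self.V <= 0:
            raise ValueError("a, l_c and V must be positive")
        if abs(self.s - self.V / (self.a * self.l_c)) > 1e-12:
            raise ValueError("stored s must equal V/(a*l_c)")
        if self.shape != classify_shape(self.s):
            raise ValueError("stored shape inconsistent with s banding")

    @classmethod
    def from_chain(cls, name: str, a: float, n_c: int, chains: int = 1) -> "MoleculeGeometry":
        """Derive geometry from a chain carbon count via the increment formulas.

        For ``chains`` > 1 the volume is per-molecule (chains × single-chain
        volume) while l_c is the single-chain critical length.
        """
        V = chains * chain_volume(n_c)
        l_c = chain_length(n_c)
        s = packing_parameter(V, a, l_c)
        return cls(name=name, a=a, l_c=l_c, V=V, s=s, shape=classify_shape(s),
                   n_c=int(n_c), chains=chains)

    @classmethod
    def explicit(cls, name: str, a: float, l_c: float, V: float) -> "MoleculeGeometry":
        """Build from explicit (a, l_c, V), e.g. literature values."""
        s = packing_parameter(V, a, l_c)
        return cls(name=name, a=a, l_c=l_c, V=V, s=s, shape=classify_shape(s))


def complementarity(g1: MoleculeGeometry, g2: MoleculeGeometry) -> str:
    """Qualitative packing complementarity of a molecular pair.

    A cone or truncated cone paired with an inverted truncated cone fills
    space ("complementary"); same-class pairs and cone/truncated-cone pairs do
    not; cylinders pack complementarily only with cylinders.
    """
    pair = {g1.shape, g2.shape}
    if pair == {SHAPE_CYLINDER}:
        return "complementary"
    if SHAPE_INVERTED in pair and (SHAPE_CONE in pair or SHAPE_TRUNCATED_CONE in pair):
        return "complementary"
    return "non-complementary"


# ---------------------------------------------------------------------------
# bundled reference geometries
# ---------------------------------------------------------------------------

#: literature headgroup areas: 71.7 Å² for the phosphocholine head, 19 Å² for
#: cholesterol's hydroxyl.  DPPC/POPC volumes and the erucyl (C22:1) chain are
#: explicit literature overrides (not derivable from the saturated-chain
#: increments); HePC (hexadecyl) and OcPC (octadecyl) use n_c = 15 and 17.
_REFERENCE_ROWS = (
    ("cholesterol", 19.0, 17.250, 400.0),
    ("DPPC", 71.7, 20.475, 847.0),
    ("POPC", 71.7, 20.475, 910.0),
    ("HePC", 71.7, 20.475, 430.9),
    ("OcPC", 71.7, 23.005, 484.7),
    ("ErPC", 71.7, 24.400, 582.9),
)


def reference_geometries() -> dict[str, MoleculeGeometry]:
    """Bundled geometries of the studied membrane lipids and APC drugs."""
    return {
        name: MoleculeGeometry.explicit(name, a, l_c, V)
        for name, a, l_c, V in _REFERENCE_ROWS
    }


def reference_table() -> pd.DataFrame:
    """The reference geometries as a table (name, a, l_c, V, s, shape)."""
    rows = []
    for g in reference_geometries().values():
        rows.append(
            {"name": g.name, "a_A2": g.a, "l_c_A": g.l_c, "V_A3": g.V,
             "s": g.s, "shape": g.shape}
        )
    return pd.DataFrame(rows)
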