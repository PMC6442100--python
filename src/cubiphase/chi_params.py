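"""Flory–Huggins interaction parameters for the five-bead formulation model.

The coarse-grained model splits glyceryl monooleate (GMO) into a hydrophilic
head fragment ``A`` (glycerol + carboxyl) and a hydrophobic tail fragment
``B`` (the oleyl chain), and represents water, ethanol and metformin
hydrochloride (``MET``) as single bead species.  Pairwise mixing energetics
are carried as dimensionless Flory–Huggins parameters :math:`\\chi_{ij}` and
mapped linearly onto DPD conservative repulsion amplitudes
:math:`a_{ij} = a_{ii} + k(\\rho)\\,\\chi_{ij}` with the Groot–Warren
coefficient :math:`k(3) = 3.27` at bead density :math:`\\rho = 3`.

Three χ values are treated as authoritative measurements of the system
(B/water = 5.1, B/ethanol = 0.5, water/A = −1.1); the remaining pairs ship
with documented defaults and are flagged as such in the matrix provenance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Mapping, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "SPECIES_IDS",
    "Species",
    "ChiMatrix",
    "SolubilityInput",
    "default_species_table",
    "default_chi_matrix",
    "chi_from_solubility",
    "chi_to_repulsion",
    "read_chi_matrix",
    "write_chi_matrix",
    "GROOT_WARREN_CHI_COEFF",
]

#: Canonical species ordering used everywhere a matrix index is needed.
SPECIES_IDS: Tuple[str, ...] = ("A", "B", "WATER", "ETHANOL", "MET")

#: Groot–Warren mapping coefficient k(rho) at rho = 3.
GROOT_WARREN_CHI_COEFF: float = 3.27

#: Molar gas constant, J mol^-1 K^-1.
_R_GAS = 8.314


@dataclass(frozen=True)
class Species:
    """One bead species of the coarse-grained formulation model.

    Parameters
    ----------
    id
        One of :data:`SPECIES_IDS`.
    molar_mass
        Mass represented by one mole of this species in a composition,
        g/mol.  For ``A``/``B`` this is the fragment mass (their sum is the
        GMO molar mass); the two always occur as a bonded dimer.
    hbonding
        Whether the species can act as a hydrogen-bond partner.  Pairs
        where both partners hydrogen-bond may carry negative χ.
    """

    id: str
    molar_mass: float
    hbonding: bool

    def __post_init__(self) -> None:
        if self.id not in SPECIES_IDS:
            raise ValueError(f"unknown species id {self.id!r}; expected one of {SPECIES_IDS}")
        if not self.molar_mass > 0:
            raise ValueError(f"molar mass of {self.id} must be positive, got {self.molar_mass}")


def default_species_table() -> Dict[str, Species]:
    """Species table with the fragment masses of the GMO/ethanol/water/Met system.

    GMO (356.5 g/mol) is split into the glycerol/carboxyl head ``A`` and the
    oleyl tail ``B``; metformin hydrochloride is 165.6 g/mol.
    """
    return {
        "A": Species("A", 118.1, True),
        "B": Species("B", 238.4, False),
        "WATER": Species("WATER", 18.0, True),
        "ETHANOL": Species("ETHANOL", 46.1, True),
        "MET": Species("MET", 165.6, True),
    }


def _pair_key(i: str, j: str) -> FrozenSet[str]:
    if i not in SPECIES_IDS or j not in SPECIES_IDS:
        bad = i if i not in SPECIES_IDS else j
        raise KeyError(f"unknown species {bad!r}; expected one of {SPECIES_IDS}")
    return frozenset((i, j))


@dataclass
class ChiMatrix:
    """Symmetric pairwise Flory–Huggins parameter matrix.

    ``chi`` maps unordered species pairs to χ values; the diagonal is
    implicitly zero.  ``provenance`` records, per pair, whether the value is
    a measured/reported one (``"reported"``), a shipped default (``"default"``)
    or user-supplied (``"user"``/``"file"``/``"solubility"``).
    """

    chi: Dict[FrozenSet[str], float] = field(default_factory=dict)
    temperature: float = 298.0
    provenance: Dict[FrozenSet[str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")
        for key, value in self.chi.items():
            if not np.isfinite(value):
                raise ValueError(f"non-finite chi for pair {sorted(key)}")

    def get(self, i: str, j: str) -> float:
        """χ between species *i* and *j* (0 on the diagonal)."""
        if i == j:
            _pair_key(i, i)
            return 0.0
        return self.chi[_pair_key(i, j)]

    def set(self, i: str, j: str, value: float, provenance: str = "user") -> None:
        if i == j:
            if value != 0.0:
                raise ValueError("diagonal chi entries must be 0")
            return
        key = _pair_key(i, j)
        if not np.isfinite(value):
            raise ValueError(f"non-finite chi for pair {sorted(key)}")
        self.chi[key] = float(value)
        self.provenance[key] = provenance

    def is_complete(self) -> bool:
        """True when every off-diagonal pair has a value."""
        n = len(SPECIES_IDS)
        return len(self.chi) == n * (n - 1) // 2

    def to_array(self, order: Iterable[str] = SPECIES_IDS) -> np.ndarray:
        """Dense symmetric matrix in the given species order."""
        order = tuple(order)
        out = np.zeros((len(order), len(order)))
        for a, i in enumerate(order):
            for b, j in enumerate(order):
                if a != b:
                    out[a, b] = self.get(i, j)
        return out

    def to_frame(self) -> pd.DataFrame:
        arr = self.to_array()
        return pd.DataFrame(arr, index=SPECIES_IDS, columns=SPECIES_IDS)


#: χ values reported for the system (fragment-B/water, fragment-B/ethanol,
#: water/fragment-A); authoritative inputs to the screen.
REPORTED_CHI: Dict[FrozenSet[str], float] = {
    frozenset(("B", "WATER")): 5.1,
    frozenset(("B", "ETHANOL")): 0.5,
    frozenset(("WATER", "A")): -1.1,
}

#: Shipped defaults for the pairs without a reported value, chosen to respect
#: the qualitative miscibility picture (Met/ethanol and A/ethanol miscible,
#: B strongly hydrophobic, A and B weakly incompatible).  Overridable.
DEFAULT_CHI: Dict[FrozenSet[str], float] = {
    frozenset(("WATER", "ETHANOL")): -0.3,
    frozenset(("ETHANOL", "MET")): -0.5,
    frozenset(("WATER", "MET")): -0.5,
    frozenset(("A", "ETHANOL")): -0.2,
    frozenset(("A", "MET")): -0.3,
    frozenset(("A", "B")): 2.0,
    frozenset(("B", "MET")): 4.0,
}


def default_chi_matrix(temperature: float = 298.0,
                       overrides: Mapping[Tuple[str, str], float] | None = None) -> ChiMatrix:
    """The shipped χ matrix: reported values where available, defaults elsewhere.

    Parameters
    ----------
    temperature
        Temperature tag of the matrix, K.
    overrides
        Optional ``{(i, j): chi}`` replacements; overridden entries are
        flagged ``"user"`` in the provenance.
    """
    m = ChiMatrix(temperature=temperature)
    for key, value in REPORTED_CHI.items():
        i, j = tuple(key)
        m.set(i, j, value, provenance="reported")
    for key, value in DEFAULT_CHI.items():
        i, j = tuple(key)
        m.set(i, j, value, provenance="default")
    if overrides:
        for (i, j), value in overrides.items():
            m.set(i, j, value, provenance="user")
    assert m.is_complete()
    return m


@dataclass(frozen=True)
class SolubilityInput:
    """Hildebrand solubility parameters for the regular-solution χ estimate.

    ``delta`` maps species id → δ in (J/cm³)^1/2, ``v_ref`` is the reference
    molar volume in cm³/mol.
    """

    delta: Mapping[str, float]
    v_ref: float
    temperature: float = 298.0

    def __post_init__(self) -> None:
        if not self.v_ref > 0:
            raise ValueError("v_ref must be positive")
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")
        for sp, d in self.delta.items():
            if d < 0:
                raise ValueError(f"solubility parameter of {sp} must be non-negative")


def chi_from_solubility(inp: SolubilityInput, i: str, j: str) -> float:
    """Regular-solution estimate χ = v_ref (δ_i − δ_j)² / (R T).

    Non-negative by construction: this route cannot reproduce negative χ
    values of hydrogen-bonding pairs (a warning is emitted when both species
    in the default table hydrogen-bond).
    """
    for sp in (i, j):
        if sp not in inp.delta:
            raise KeyError(f"species {sp!r} missing from solubility input")
    table = default_species_table()
    if i in table and j in table and table[i].hbonding and table[j].hbonding and i != j:
        warnings.warn(
            "regular-solution chi is non-negative; hydrogen-bonding pairs "
            f"({i}/{j}) may in reality have negative chi",
            stacklevel=2,
        )
    d = inp.delta[i] - inp.delta[j]
    # v_ref [cm^3/mol] * delta^2 [J/cm^3] / (R T) [J/mol] -> dimensionless
    return inp.v_ref * d * d / (_R_GAS * inp.temperature)


def chi_to_repulsion(chi: ChiMatrix, a_ii: float = 25.0, rho: float = 3.0,
                     coeff: float | None = None,
                     order: Iterable[str] = SPECIES_IDS) -> np.ndarray:
    """Map a χ matrix to the DPD repulsion matrix a_ij = a_ii + k(ρ)·χ_ij.

    The linear coefficient is only calibrated at ρ = 3 (k = 3.27); for any
    other density the caller must supply ``coeff`` explicitly.
    """
    if not a_ii > 0:
        raise ValueError("a_ii must be positive")
    if not rho > 0:
        raise ValueError("rho must be positive")
    if coeff is None:
        if not np.isclose(rho, 3.0):
            raise ValueError(
                f"chi->a mapping coefficient is only known for rho=3 (k=3.27); "
                f"supply coeff explicitly for rho={rho}"
            )
        coeff = GROOT_WARREN_CHI_COEFF
    a = a_ii + coeff * chi.to_array(order)
    np.fill_diagonal(a, a_ii)
    return a


def write_chi_matrix(matrix: ChiMatrix, path) -> None:
    """Write the matrix as delimited text (header row/column of species ids)."""
    matrix.to_frame().to_csv(path)


def read_chi_matrix(path, temperature: float = 298.0, atol: float = 1e-9) -> ChiMatrix:
    """Read a χ matrix from delimited text, validating symmetry and zero diagonal."""
    df = pd.read_csv(path, index_col=0)
    df.index = [str(s).strip().upper() for s in df.index]
    df.columns = [str(s).strip().upper() for s in df.columns]
    missing = set(SPECIES_IDS) - set(df.index)
    if missing or set(df.index) != set(df.columns):
        raise ValueError(f"chi matrix file must cover species {SPECIES_IDS}; missing {sorted(missing)}")
    arr = df.loc[list(SPECIES_IDS), list(SPECIES_IDS)].to_numpy(dtype=float)
    if not np.allclose(arr, arr.T, atol=atol):
        raise ValueError("chi matrix file is not symmetric")
    if not np.allclose(np.diag(arr), 0.0, atol=atol):
        raise ValueError("chi matrix diagonal must be zero")
    m = ChiMatrix(temperature=temperature)
    for a, i in enumerate(SPECIES_IDS):
        for b in range(a + 1, len(SPECIES_IDS)):
            m.set(i, SPECIES_IDS[b], float(arr[a, b]), provenance="file")
    return m
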