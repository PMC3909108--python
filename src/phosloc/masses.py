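"""Monoisotopic mass bookkeeping and theoretical b/y fragment ladders.

Phosphopeptide site localization works entirely in m/z space: every candidate
placement of the phosphate groups produces its own theoretical spectrum of
b- and y-type fragment ions, each optionally stripped of a neutral molecule
(water, ammonia, phosphoric acid, or phosphoric acid plus one of the former)
and observed in one of several charge states.  This module owns the mass
arithmetic for those ladders.

All masses are monoisotopic.  Residue masses and the elemental-composition
constants come from :mod:`pyteomics.mass`; the charged m/z convention is
``(neutral + z * proton) / z``.

Notation used throughout the package: a peptide of length ``L`` yields b ions
of index ``1..L-1`` (N-terminal prefixes) and y ions of index ``1..L-1``
(C-terminal suffixes).  The 12-member ion-type set is the cross product of
``{b, y}`` with ``{none, -H2O, -NH3, -P, -P-H2O, -P-NH3}`` where ``P`` denotes
neutral loss of phosphoric acid (H3PO4).  Phosphoric-acid losses are only
generated from fragments that actually carry a phosphate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

from pyteomics import mass as _pt_mass

__all__ = [
    "PROTON_MASS",
    "WATER_MASS",
    "AMMONIA_MASS",
    "PHOSPHORIC_ACID_MASS",
    "PHOSPHO_MOD_MASS",
    "CARBAMIDOMETHYL_MOD_MASS",
    "PHOSPHORYLATABLE",
    "STANDARD_AA",
    "Loss",
    "LOSSES",
    "MassTable",
    "DEFAULT_MASS_TABLE",
    "ModifiedPeptide",
    "IonSpec",
    "TheoreticalIon",
    "residue_mass",
    "b_ion_mz",
    "y_ion_mz",
    "apply_neutral_loss",
    "fragment_ladder",
]

PROTON_MASS: float = _pt_mass.nist_mass["H+"][0][0]
WATER_MASS: float = _pt_mass.calculate_mass(formula="H2O")
AMMONIA_MASS: float = _pt_mass.calculate_mass(formula="NH3")
PHOSPHORIC_ACID_MASS: float = _pt_mass.calculate_mass(formula="H3PO4")
#: Mass shift of the phospho modification (HPO3), +79.966 Da at 3 decimals.
PHOSPHO_MOD_MASS: float = _pt_mass.calculate_mass(formula="HPO3")
#: Mass shift of carbamidomethylation (C2H3NO), +57.021 Da at 3 decimals.
CARBAMIDOMETHYL_MOD_MASS: float = _pt_mass.calculate_mass(formula="C2H3NO")

STANDARD_AA: str = "ACDEFGHIKLMNPQRSTVWY"
PHOSPHORYLATABLE: frozenset[str] = frozenset("STY")


class Loss(Enum):
    """Neutral-loss species attached to a fragment ion."""

    NONE = "none"
    H2O = "H2O"
    NH3 = "NH3"
    P = "P"
    P_H2O = "P+H2O"
    P_NH3 = "P+NH3"

    @property
    def requires_phospho(self) -> bool:
        """Phosphoric-acid losses only exist for phospho-bearing fragments."""
        return self in (Loss.P, Loss.P_H2O, Loss.P_NH3)


#: Canonical loss ordering (drives deterministic ladder and scoring order).
LOSSES: tuple[Loss, ...] = tuple(Loss)
_LOSS_INDEX: dict[Loss, int] = {loss: i for i, loss in enumerate(LOSSES)}


@dataclass(frozen=True)
class MassTable:
    """Monoisotopic constants used by every m/z computation.

    The defaults are derived from elemental compositions at import time; a
    table with alternative constants (e.g. rounded legacy values) can be
    built with :meth:`from_dict` or plain construction.
    """

    residue_masses: Mapping[str, float] = field(
        default_factory=lambda: {aa: _pt_mass.std_aa_mass[aa] for aa in STANDARD_AA}
    )
    proton_mass: float = PROTON_MASS
    water_mass: float = WATER_MASS
    ammonia_mass: float = AMMONIA_MASS
    phosphoric_acid_mass: float = PHOSPHORIC_ACID_MASS
    phospho_mod_mass: float = PHOSPHO_MOD_MASS
    carbamidomethyl_mod_mass: float = CARBAMIDOMETHYL_MOD_MASS

    def __post_init__(self) -> None:
        for aa, m in self.residue_masses.items():
            if m <= 0:
                raise ValueError(f"non-positive residue mass for {aa!r}")
        for name in (
            "proton_mass",
            "water_mass",
            "ammonia_mass",
            "phosphoric_acid_mass",
            "phospho_mod_mass",
            "carbamidomethyl_mod_mass",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"non-positive {name}")

    def loss_mass(self, loss: Loss) -> float:
        """Neutral mass removed by ``loss`` (0 for :attr:`Loss.NONE`)."""
        if loss is Loss.NONE:
            return 0.0
        if loss is Loss.H2O:
            return self.water_mass
        if loss is Loss.NH3:
            return self.ammonia_mass
        if loss is Loss.P:
            return self.phosphoric_acid_mass
        if loss is Loss.P_H2O:
            return self.phosphoric_acid_mass + self.water_mass
        if loss is Loss.P_NH3:
            return self.phosphoric_acid_mass + self.ammonia_mass
        raise ValueError(f"unknown loss {loss!r}")

    @classmethod
    def from_dict(cls, overrides: Mapping[str, float]) -> "MassTable":
        """Build a table with selected constants overridden.

        Keys match the field names; residue masses are overridden per letter
        via a nested ``residue_masses`` mapping merged over the defaults.
        """
        kwargs: dict = dict(overrides)
        residues = {aa: _pt_mass.std_aa_mass[aa] for aa in STANDARD_AA}
        residues.update(kwargs.pop("residue_masses", {}))
        return cls(residue_masses=residues, **kwargs)


DEFAULT_MASS_TABLE = MassTable()


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide sequence with modifications and a phosphate placement.

    Positions are 1-based.  ``fixed_mods`` and ``variable_mods`` carry
    non-phospho mass shifts (e.g. carbamidomethyl, oxidation) as
    ``(position, shift)`` pairs; phosphates are carried separately in
    ``phospho_positions`` so that alternative placements can be enumerated
    without touching the other modifications.
    """

    sequence: str
    precursor_charge: int = 2
    fixed_mods: tuple[tuple[int, float], ...] = ()
    variable_mods: tuple[tuple[int, float], ...] = ()
    phospho_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        for ch in self.sequence:
            if ch not in STANDARD_AA:
                raise ValueError(f"unknown amino-acid code {ch!r}")
        if self.precursor_charge < 1:
            raise ValueError("precursor charge must be >= 1")
        pos = tuple(sorted(self.phospho_positions))
        object.__setattr__(self, "phospho_positions", pos)
        if len(set(pos)) != len(pos):
            raise ValueError("duplicate phospho positions")
        for p in pos:
            if not 1 <= p <= len(self.sequence):
                raise ValueError(f"phospho position {p} outside [1, {len(self.sequence)}]")
            if self.sequence[p - 1] not in PHOSPHORYLATABLE:
                raise ValueError(
                    f"phospho position {p} is {self.sequence[p - 1]!r}, not S/T/Y"
                )
        for kind in (self.fixed_mods, self.variable_mods):
            for p, _shift in kind:
                if not 1 <= p <= len(self.sequence):
                    raise ValueError(f"modification position {p} out of range")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def site_positions(self) -> tuple[int, ...]:
        """1-based positions of all phosphorylatable (S/T/Y) residues."""
        return tuple(
            i for i, aa in enumerate(self.sequence, start=1) if aa in PHOSPHORYLATABLE
        )

    def position_masses(self, table: MassTable = DEFAULT_MASS_TABLE) -> list[float]:
        """Per-position residue masses with all modification shifts applied."""
        masses = [table.residue_masses[aa] for aa in self.sequence]
        for p, shift in (*self.fixed_mods, *self.variable_mods):
            masses[p - 1] += shift
        for p in self.phospho_positions:
            masses[p - 1] += table.phospho_mod_mass
        return masses

    def neutral_mass(self, table: MassTable = DEFAULT_MASS_TABLE) -> float:
        """Neutral monoisotopic mass of the whole (modified) peptide."""
        return sum(self.position_masses(table)) + table.water_mass

    def with_phospho(self, positions: Iterable[int]) -> "ModifiedPeptide":
        return replace(self, phospho_positions=tuple(positions))


@dataclass(frozen=True, slots=True)
class IonSpec:
    """Identity of one theoretical fragment ion (without its m/z)."""

    series: str  # 'b' or 'y'
    index: int  # 1-based fragment length
    loss: Loss
    charge: int

    def __post_init__(self) -> None:
        if self.series not in ("b", "y"):
            raise ValueError(f"series must be 'b' or 'y', got {self.series!r}")
        if self.index < 1:
            raise ValueError("ion index must be >= 1")
        if self.charge < 1:
            raise ValueError("ion charge must be >= 1")

    @property
    def sort_key(self) -> tuple:
        """Deterministic ladder order: b before y, index, loss order, charge."""
        return (self.series, self.index, _LOSS_INDEX[self.loss], self.charge)

    def __str__(self) -> str:
        loss = "" if self.loss is Loss.NONE else f"-{self.loss.value}"
        return f"{self.series}{self.index}{loss}^{self.charge}+"


@dataclass(slots=True)
class TheoreticalIon:
    """One fragment ion of a specific configuration's theoretical spectrum."""

    spec: IonSpec
    mz: float
    contains_phospho: bool
    site_determining: bool = False


def residue_mass(
    code: str,
    mods: Sequence[float] = (),
    table: MassTable = DEFAULT_MASS_TABLE,
) -> float:
    """Monoisotopic residue mass of ``code`` plus the given modification shifts.

    Raises
    ------
    ValueError
        If ``code`` is not a standard one-letter amino-acid code.
    """
    try:
        base = table.residue_masses[code]
    except KeyError:
        raise ValueError(f"unknown amino-acid code {code!r}") from None
    return base + sum(mods)


def _check_fragment_index(peptide: ModifiedPeptide, index: int) -> None:
    if not 1 <= index <= len(peptide) - 1:
        raise ValueError(
            f"fragment index {index} outside [1, {len(peptide) - 1}] "
            f"for peptide of length {len(peptide)}"
        )


def _check_fragment_charge(peptide: ModifiedPeptide, charge: int) -> None:
    if not 1 <= charge <= peptide.precursor_charge:
        raise ValueError(
            f"fragment charge {charge} outside [1, precursor charge "
            f"{peptide.precursor_charge}]"
        )


def _b_neutral(peptide: ModifiedPeptide, index: int, table: MassTable) -> float:
    return sum(peptide.position_masses(table)[:index])


def _y_neutral(peptide: ModifiedPeptide, index: int, table: MassTable) -> float:
    return sum(peptide.position_masses(table)[len(peptide) - index :]) + table.water_mass


def b_ion_mz(
    peptide: ModifiedPeptide,
    index: int,
    charge: int,
    table: MassTable = DEFAULT_MASS_TABLE,
) -> float:
    """m/z of the b ion spanning the first ``index`` residues."""
    _check_fragment_index(peptide, index)
    _check_fragment_charge(peptide, charge)
    return (_b_neutral(peptide, index, table) + charge * table.proton_mass) / charge


def y_ion_mz(
    peptide: ModifiedPeptide,
    index: int,
    charge: int,
    table: MassTable = DEFAULT_MASS_TABLE,
) -> float:
    """m/z of the y ion spanning the last ``index`` residues."""
    _check_fragment_index(peptide, index)
    _check_fragment_charge(peptide, charge)
    return (_y_neutral(peptide, index, table) + charge * table.proton_mass) / charge


def apply_neutral_loss(
    base_mz: float,
    loss: Loss,
    charge: int,
    table: MassTable = DEFAULT_MASS_TABLE,
) -> float:
    """Shift ``base_mz`` down by the neutral-loss mass divided by ``charge``."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return base_mz - table.loss_mass(loss) / charge


def fragment_ladder(
    peptide: ModifiedPeptide,
    max_fragment_charge: int | None = None,
    table: MassTable = DEFAULT_MASS_TABLE,
) -> list[TheoreticalIon]:
    """Enumerate the full theoretical ion ladder of ``peptide``.

    All (series, index, loss, charge) combinations are generated, except that
    phosphoric-acid losses are omitted for fragments carrying no phosphate.
    Fragment charge runs from 1 to ``max_fragment_charge`` (default: the
    precursor charge; capped at the precursor charge in any case).

    The list is emitted in canonical ladder order (b before y, ascending
    index, loss order as in :data:`LOSSES`, ascending charge) and its length
    is bounded by ``(L - 1) * 12 * max_fragment_charge``.
    """
    L = len(peptide)
    if L < 2:
        raise ValueError("peptide of length < 2 yields no fragments")
    max_z = peptide.precursor_charge if max_fragment_charge is None else max_fragment_charge
    if max_z < 1:
        raise ValueError("max_fragment_charge must be >= 1")
    max_z = min(max_z, peptide.precursor_charge)

    masses = peptide.position_masses(table)
    phospho = set(peptide.phospho_positions)

    ladder: list[TheoreticalIon] = []
    for series in ("b", "y"):
        running = 0.0
        for index in range(1, L):
            if series == "b":
                running += masses[index - 1]
                neutral = running
                has_p = any(p <= index for p in phospho)
            else:
                running += masses[L - index]
                neutral = running + table.water_mass
                has_p = any(p > L - index for p in phospho)
            for loss in LOSSES:
                if loss.requires_phospho and not has_p:
                    continue
                lost = table.loss_mass(loss)
                for z in range(1, max_z + 1):
                    mz = (neutral - lost + z * table.proton_mass) / z
                    ladder.append(
                        TheoreticalIon(
                            spec=IonSpec(series=series, index=index, loss=loss, charge=z),
                            mz=mz,
                            contains_phospho=has_p,
                        )
                    )
    return ladder
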