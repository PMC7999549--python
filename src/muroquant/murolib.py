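"""Theoretical muropeptide species and their monoisotopic masses.

A muropeptide is a muramidase-digestion product of peptidoglycan: a
GlcNAc-MurNAc disaccharide carrying a stem peptide, possibly crosslinked to
further disaccharide-peptide subunits into dimers, trimers, or tetramers.
This module enumerates such species for the canonical Gram-negative
chemotype (stem = L-Ala, D-iGlu, meso-DAP, D-Ala(s); D,D 4-3 crosslinks),
computes neutral monoisotopic masses and positive-mode m/z values, and
serialises the resulting compound library to/from CSV.

Chemistry conventions
---------------------
* Residue formulas are the condensed forms (free molecule minus one water).
* A connected linear oligomer of R residues carries exactly one water in
  total (equivalently: one water per subunit, minus one per crosslink).
* A 1,6-anhydro-MurNAc terminus (glycan chain end mark) lacks one further
  water relative to MurNAc.
* Borohydride reduction adds two hydrogens per free (non-anhydro) MurNAc
  reducing end; anhydro termini have no free reducing end and are not
  reduced.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

# Monoisotopic atomic masses (Da), CODATA/IUPAC values.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
}

#: Mass of a proton (Da), used for positive-mode protonation.
PROTON_MASS = 1.007276

ORDER_LETTER = {1: "M", 2: "D", 3: "T", 4: "Q"}
_LETTER_ORDER = {v: k for k, v in ORDER_LETTER.items()}


def formula_mass(formula: Mapping[str, int]) -> float:
    """Monoisotopic mass of an elemental formula given as {element: count}."""
    try:
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in formula.items())
    except KeyError as exc:  # pragma: no cover - guarded by ResidueSpec
        raise KeyError(f"unknown element {exc}") from None


WATER_MASS = formula_mass({"H": 2, "O": 1})  # 18.010565 Da
_H2_MASS = 2 * MONOISOTOPIC_MASS["H"]


@dataclass(frozen=True)
class ResidueSpec:
    """A condensed residue: name, elemental formula, monoisotopic mass."""

    name: str
    formula: Mapping[str, int]
    residue_mass: float

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.formula.values()):
            raise ValueError(f"negative element count in residue {self.name!r}")
        expected = formula_mass(self.formula)
        if abs(expected - self.residue_mass) > 1e-6:
            raise ValueError(
                f"residue {self.name!r}: mass {self.residue_mass} does not match "
                f"formula mass {expected}"
            )


def _residue(name: str, **counts: int) -> ResidueSpec:
    return ResidueSpec(name, dict(counts), formula_mass(counts))


#: Canonical Gram-negative residues, condensed (minus one water each).
RESIDUES: dict[str, ResidueSpec] = {
    "GlcNAc": _residue("GlcNAc", C=8, H=13, N=1, O=5),
    "MurNAc": _residue("MurNAc", C=11, H=17, N=1, O=7),
    # 1,6-anhydro-MurNAc: MurNAc minus one water (intramolecular ring).
    "anhMurNAc": _residue("anhMurNAc", C=11, H=15, N=1, O=6),
    "Ala": _residue("Ala", C=3, H=5, N=1, O=1),
    "iGlu": _residue("iGlu", C=5, H=7, N=1, O=3),
    "mDAP": _residue("mDAP", C=7, H=12, N=2, O=3),
}

#: Stem peptide residue sequence by stem length (di- to pentapeptide).
STEM_RESIDUES: dict[int, tuple[str, ...]] = {
    2: ("Ala", "iGlu"),
    3: ("Ala", "iGlu", "mDAP"),
    4: ("Ala", "iGlu", "mDAP", "Ala"),
    5: ("Ala", "iGlu", "mDAP", "Ala", "Ala"),
}


@dataclass(frozen=True)
class MuropeptideComposition:
    """Composition of a linear muropeptide oligomer.

    Parameters
    ----------
    n_subunits : int
        Oligomer order, 1 (monomer) to 4 (tetramer). Each subunit carries one
        GlcNAc and one MurNAc.
    stem_lengths : tuple of int
        Stem peptide length per subunit, each in {2, 3, 4, 5}.
    n_anhydro : int
        Number of 1,6-anhydro-MurNAc termini (0 .. n_subunits).
    reduced : bool
        Whether free reducing ends are borohydride-reduced.
    """

    n_subunits: int
    stem_lengths: tuple[int, ...]
    n_anhydro: int = 0
    reduced: bool = True

    def __post_init__(self) -> None:
        # canonical subunit order (descending stem length): mass and naming
        # are invariant to it, so compositions compare by content
        object.__setattr__(
            self, "stem_lengths", tuple(sorted(self.stem_lengths, reverse=True))
        )
        if not 1 <= self.n_subunits <= 4:
            raise ValueError("n_subunits must be 1-4 (empty molecule is invalid)")
        if len(self.stem_lengths) != self.n_subunits:
            raise ValueError("need one stem length per subunit")
        for s in self.stem_lengths:
            if s not in STEM_RESIDUES:
                raise ValueError(f"unsupported stem length {s}")
        if not 0 <= self.n_anhydro <= self.n_subunits:
            raise ValueError("n_anhydro must be within 0..n_subunits")

    @property
    def n_crosslinks(self) -> int:
        """Linear oligomers only: one crosslink less than subunits."""
        return self.n_subunits - 1

    @property
    def n_reduced_termini(self) -> int:
        return (self.n_subunits - self.n_anhydro) if self.reduced else 0

    def residue_names(self) -> list[str]:
        """All condensed residues of the molecule (anhydro MurNAc substituted)."""
        names: list[str] = []
        for i, stem in enumerate(self.stem_lengths):
            murnac = "anhMurNAc" if i < self.n_anhydro else "MurNAc"
            names.append("GlcNAc")
            names.append(murnac)
            names.extend(STEM_RESIDUES[stem])
        return names


def molecular_formula(composition: MuropeptideComposition) -> dict[str, int]:
    """Full elemental formula of the neutral (possibly reduced) molecule."""
    counts: dict[str, float] = {}
    for name in composition.residue_names():
        for el, n in RESIDUES[name].formula.items():
            counts[el] = counts.get(el, 0) + n
    n_waters = composition.n_subunits - composition.n_crosslinks
    counts["H"] = counts.get("H", 0) + 2 * n_waters + 2 * composition.n_reduced_termini
    counts["O"] = counts.get("O", 0) + n_waters
    return {el: int(n) for el, n in sorted(counts.items())}


def neutral_mass(composition: MuropeptideComposition) -> float:
    """Neutral monoisotopic mass (Da) of a muropeptide composition.

    Sum of condensed residue masses, plus one water per free molecule
    terminus pair (n_subunits), minus one water per crosslink, plus 2 H per
    reduced reducing end. The anhydro water loss is carried by the
    anhMurNAc residue formula itself.
    """
    mass = sum(RESIDUES[name].residue_mass for name in composition.residue_names())
    mass += (composition.n_subunits - composition.n_crosslinks) * WATER_MASS
    mass += composition.n_reduced_termini * _H2_MASS
    return mass


def mz_for_charge(neutral: float, z: int) -> float:
    """m/z of the [M + zH]^z+ ion in positive mode."""
    if z < 1:
        raise ValueError("charge must be a positive integer")
    return (neutral + z * PROTON_MASS) / z


def canonical_name(composition: MuropeptideComposition) -> str:
    """Canonical species name: order letter + stem digits (descending) + 'N' per anhydro.

    Examples: ``M4`` (monomer, tetrapeptide stem), ``D44N`` (4-3 crosslinked
    dimer of two tetrapeptide stems with one anhydro terminus).
    """
    letter = ORDER_LETTER[composition.n_subunits]
    stems = "".join(str(s) for s in sorted(composition.stem_lengths, reverse=True))
    return letter + stems + "N" * composition.n_anhydro


def parse_name(name: str, reduced: bool = True) -> MuropeptideComposition:
    """Inverse of :func:`canonical_name`."""
    if not name or name[0] not in _LETTER_ORDER:
        raise ValueError(f"cannot parse muropeptide name {name!r}")
    order = _LETTER_ORDER[name[0]]
    body = name[1:]
    n_anh = len(body) - len(body.rstrip("N"))
    digits = body[: len(body) - n_anh]
    stems = tuple(int(d) for d in digits)
    if len(stems) != order:
        raise ValueError(f"name {name!r}: {len(stems)} stems for order {order}")
    return MuropeptideComposition(order, stems, n_anh, reduced)


@dataclass(frozen=True)
class MuropeptideRecord:
    """A library entry: composition plus derived mass and charge-state m/z."""

    composition: MuropeptideComposition
    name: str
    neutral_mass: float
    mz_by_charge: Mapping[int, float]
    retention_time: float | None = None

    def with_retention_time(self, rt: float) -> "MuropeptideRecord":
        return replace(self, retention_time=rt)


def make_record(
    composition: MuropeptideComposition,
    retention_time: float | None = None,
    charges: Sequence[int] = (1, 2, 3),
) -> MuropeptideRecord:
    mass = neutral_mass(composition)
    return MuropeptideRecord(
        composition=composition,
        name=canonical_name(composition),
        neutral_mass=mass,
        mz_by_charge={z: mz_for_charge(mass, z) for z in charges},
        retention_time=retention_time,
    )


def build_library(
    max_order: int = 4,
    stem_lengths: Iterable[int] = (3, 4, 5),
    allow_anhydro: bool = True,
    reduced: bool = True,
) -> list[MuropeptideRecord]:
    """Enumerate one record per distinct composition.

    The enumeration is the cartesian product of oligomer order (1..max_order),
    stem-length multiset of that order, and anhydro count (0..order when
    allowed). Output is sorted by name and deterministic.
    """
    if not 1 <= max_order <= 4:
        raise ValueError("max_order must be 1-4")
    stems = sorted(set(stem_lengths))
    if not stems:
        raise ValueError("stem_lengths must be non-empty")
    records = []
    for order in range(1, max_order + 1):
        for combo in itertools.combinations_with_replacement(stems, order):
            anh_max = order if allow_anhydro else 0
            for n_anh in range(anh_max + 1):
                comp = MuropeptideComposition(order, combo, n_anh, reduced)
                records.append(make_record(comp))
    records.sort(key=lambda r: r.name)
    return records


def library_to_frame(records: Sequence[MuropeptideRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "name": r.name,
                "order": r.composition.n_subunits,
                "stems": "-".join(
                    str(s) for s in sorted(r.composition.stem_lengths, reverse=True)
                ),
                "n_anhydro": r.composition.n_anhydro,
                "reduced": r.composition.reduced,
                "neutral_mass": r.neutral_mass,
                "mz_z1": r.mz_by_charge.get(1),
                "mz_z2": r.mz_by_charge.get(2),
                "mz_z3": r.mz_by_charge.get(3),
                "rt": r.retention_time,
            }
        )
    return pd.DataFrame(rows)


def save_library(records: Sequence[MuropeptideRecord], path) -> None:
    library_to_frame(records).to_csv(path, index=False)


def load_library(path) -> list[MuropeptideRecord]:
    """Read a library CSV; masses are recomputed from the composition columns."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        stems = tuple(int(s) for s in str(row["stems"]).split("-"))
        comp = MuropeptideComposition(
            int(row["order"]), stems, int(row["n_anhydro"]), bool(row["reduced"])
        )
        rt = row.get("rt")
        rt = None if rt is None or pd.isna(rt) else float(rt)
        records.append(make_record(comp, retention_time=rt))
    return records
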