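"""Monoisotopic mass and elemental-composition arithmetic for peptides,
modifications, disulfide links and low-molecular-weight thiol adducts.

All printed masses in this package derive from one authoritative constant
table: the NIST element masses and natural-isotope abundances shipped with
:mod:`pyteomics` (``pyteomics.mass.nist_mass``) and the standard amino-acid
residue compositions (``pyteomics.mass.std_aa_comp``).  Masses are carried
at full double precision; rounding to the 3–4 decimals customary in
proteomics reports happens only at the reporting layer.

The chemistry encoded here is deliberately small:

* a peptide's composition is the sum of its residue compositions plus one
  water;
* forming a disulfide bridge between two cysteine thiols removes two
  hydrogen atoms (−2.015650 Da) once per bridge;
* a thiol adduct (cysteine, homocysteine, cysteinylglycine, glutathione …)
  contributes the free compound's monoisotopic mass minus the same two
  hydrogens;
* carbamidomethylation (iodoacetamide alkylation) adds +57.02146 Da to a
  cysteine and blocks disulfide formation.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from typing import Optional, Union

import pandas as pd
from pyteomics import mass as _ptmass

__all__ = [
    "PROTON_MASS",
    "HYDROGEN_MASS",
    "WATER_MASS",
    "DISULFIDE_DELTA",
    "ISOTOPE_SPACING",
    "ElementalFormula",
    "MassDelta",
    "PeptideSpecies",
    "ADDUCT_LIBRARY",
    "CARBAMIDOMETHYL",
    "DIOXIDATION",
    "TRIOXIDATION",
    "element_mass",
    "residue_formula",
    "peptide_formula",
    "peptide_mono_mass",
    "disulfide_mass",
    "adduct_delta",
    "mz",
    "ppm_error",
    "library_table",
    "write_library",
]

#: Mass of a proton (charge carrier in positive-mode ESI), Da.
PROTON_MASS = 1.00727646677
#: Monoisotopic mass of hydrogen (1H), Da.
HYDROGEN_MASS = _ptmass.nist_mass["H"][0][0]  # 1.00782503207
#: Monoisotopic mass of water, Da.
WATER_MASS = 2 * HYDROGEN_MASS + _ptmass.nist_mass["O"][0][0]
#: Mass change of forming one disulfide bridge (−2 H), Da.
DISULFIDE_DELTA = -2.0 * HYDROGEN_MASS
#: Average spacing between adjacent isotopologue peaks of a peptide, Da.
ISOTOPE_SPACING = 1.00336

_CANONICAL_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")


def element_mass(element: str) -> float:
    """Monoisotopic mass of an element's most abundant isotope, Da."""
    try:
        return _ptmass.nist_mass[element][0][0]
    except KeyError:
        raise ValueError(f"unknown element symbol: {element!r}") from None


class ElementalFormula(Mapping):
    """Integer element counts of a molecule or residue.

    Behaves as an immutable mapping ``{element: count}`` with ``+``, ``-``
    and integer ``*``.  Counts are never negative: subtraction that would
    drive any element below zero raises ``ValueError``, so composition
    algebra cannot silently produce impossible molecules.  Signed
    *differences* (for modification deltas) are plain dicts, handled by
    :class:`MassDelta`.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Optional[Mapping[str, int]] = None, **kw: int):
        merged: dict[str, int] = {}
        for src in (counts or {}), kw:
            for el, n in src.items():
                merged[el] = merged.get(el, 0) + int(n)
        for el, n in merged.items():
            if n < 0:
                raise ValueError(f"negative count for element {el!r}: {n}")
        self._counts = {el: n for el, n in sorted(merged.items()) if n}

    @classmethod
    def from_formula(cls, formula: str) -> "ElementalFormula":
        """Parse a Hill-style formula string such as ``'C10H17N3O6S'``."""
        return cls(dict(_ptmass.Composition(formula=formula)))

    # Mapping protocol -----------------------------------------------------
    def __getitem__(self, el: str) -> int:
        return self._counts.get(el, 0)

    def __iter__(self):
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, el) -> bool:
        return el in self._counts

    # Algebra --------------------------------------------------------------
    def __add__(self, other: Mapping[str, int]) -> "ElementalFormula":
        out = dict(self._counts)
        for el, n in other.items():
            out[el] = out.get(el, 0) + n
        return ElementalFormula(out)

    def __sub__(self, other: Mapping[str, int]) -> "ElementalFormula":
        out = dict(self._counts)
        for el, n in other.items():
            out[el] = out.get(el, 0) - n
        return ElementalFormula(out)

    def __mul__(self, n: int) -> "ElementalFormula":
        if not isinstance(n, int) or n < 0:
            raise ValueError("formula can only be scaled by a non-negative integer")
        return ElementalFormula({el: c * n for el, c in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other) -> bool:
        if isinstance(other, ElementalFormula):
            return self._counts == other._counts
        if isinstance(other, Mapping):
            return self._counts == {k: v for k, v in other.items() if v}
        return NotImplemented

    def __hash__(self) -> int:
        return hash(tuple(self._counts.items()))

    @property
    def mono_mass(self) -> float:
        """Monoisotopic mass, Da."""
        return sum(element_mass(el) * n for el, n in self._counts.items())

    def __repr__(self) -> str:
        body = "".join(f"{el}{n if n != 1 else ''}" for el, n in self._counts.items())
        return f"ElementalFormula({body})"


def _signed_mass(change: Mapping[str, int]) -> float:
    return sum(element_mass(el) * n for el, n in change.items())


@dataclass(frozen=True)
class MassDelta:
    """A named mass modification with its elemental composition change.

    ``formula_change`` is a signed dict (a disulfide-type delta carries the
    −2 H of bridge formation).  ``delta`` is always recomputed from the
    composition, so the printed value and the chemistry cannot drift apart.
    ``sites`` restricts which residues the delta may attach to (``None``
    means anywhere).
    """

    name: str
    formula_change: Mapping[str, int]
    sites: Optional[str] = None

    @property
    def delta(self) -> float:
        """Mass change, Da (signed)."""
        return _signed_mass(self.formula_change)

    def allowed_on(self, residue: str) -> bool:
        return self.sites is None or residue in self.sites

    def __repr__(self) -> str:
        return f"MassDelta({self.name}, {self.delta:+.4f} Da)"


# --- modification / adduct library ---------------------------------------

def _thiol_adduct(name: str, free_formula: str) -> MassDelta:
    """Delta of a LMW thiol joined to a peptide cysteine by a disulfide.

    The change equals the free compound's composition minus 2 H (one from
    each thiol of the new S–S bond); attachment requires a cysteine.
    """
    change = dict(_ptmass.Composition(formula=free_formula))
    change["H"] = change.get("H", 0) - 2
    return MassDelta(name, change, sites="C")


def _thiol_dimer_adduct(name: str, free_formula: str) -> MassDelta:
    """Delta of a disulfide-linked thiol dimer hung off a peptide cysteine
    (peptide–S–S–X–S–S–X): two free compounds minus two bridges' worth of H.
    """
    single = _ptmass.Composition(formula=free_formula)
    change = {el: 2 * n for el, n in single.items()}
    change["H"] -= 4
    return MassDelta(name, change, sites="C")


CARBAMIDOMETHYL = MassDelta("carbamidomethyl", {"C": 2, "H": 3, "N": 1, "O": 1}, sites="C")
DIOXIDATION = MassDelta("dioxidation", {"O": 2}, sites="CMW")
TRIOXIDATION = MassDelta("trioxidation", {"O": 3}, sites="C")

#: Built-in plasma thiol adducts and cysteine chemistry.  Deltas for the
#: four LMW thiols reproduce the values a high-resolution instrument sees
#: for mixed disulfides: Cys +119.0041, homoCys +133.0198, CysGly +176.0255
#: (computed 176.0256), GSH +305.0682 Da.
ADDUCT_LIBRARY: dict[str, MassDelta] = {
    "Cys": _thiol_adduct("Cys", "C3H7NO2S"),
    "homoCys": _thiol_adduct("homoCys", "C4H9NO2S"),
    "CysGly": _thiol_adduct("CysGly", "C5H10N2O3S"),
    "GSH": _thiol_adduct("GSH", "C10H17N3O6S"),
    "Cys-dimer": _thiol_dimer_adduct("Cys-dimer", "C3H7NO2S"),
    "homoCys-dimer": _thiol_dimer_adduct("homoCys-dimer", "C4H9NO2S"),
    "CysGly-dimer": _thiol_dimer_adduct("CysGly-dimer", "C5H10N2O3S"),
    "GSH-dimer": _thiol_dimer_adduct("GSH-dimer", "C10H17N3O6S"),
    "dioxidation": DIOXIDATION,
    "trioxidation": TRIOXIDATION,
    "carbamidomethyl": CARBAMIDOMETHYL,
}


def adduct_delta(name: str) -> MassDelta:
    """Look up a modification in the built-in library by name."""
    try:
        return ADDUCT_LIBRARY[name]
    except KeyError:
        known = ", ".join(sorted(ADDUCT_LIBRARY))
        raise ValueError(f"unknown adduct {name!r}; library holds: {known}") from None


def library_table(library: Optional[Mapping[str, MassDelta]] = None) -> pd.DataFrame:
    """The modification library as a plain table (name, delta, formula, sites)."""
    library = ADDUCT_LIBRARY if library is None else library
    rows = []
    for name, d in library.items():
        formula = "".join(
            f"{el}{n:+d}" for el, n in sorted(d.formula_change.items()) if n
        )
        rows.append({"name": name, "delta_da": round(d.delta, 5),
                     "formula_change": formula, "sites": d.sites or "*"})
    return pd.DataFrame(rows)


def write_library(path, library: Optional[Mapping[str, MassDelta]] = None) -> None:
    library_table(library).to_csv(path, sep="\t", index=False)


# --- peptides -------------------------------------------------------------

def residue_formula(residue: str) -> ElementalFormula:
    """Composition of one amino-acid *residue* (free amino acid minus water)."""
    if residue not in _CANONICAL_RESIDUES:
        raise ValueError(f"unknown amino-acid code: {residue!r}")
    return ElementalFormula(dict(_ptmass.std_aa_comp[residue]))


Modification = Union[MassDelta, tuple]


def _normalize_modifications(
    sequence: str, modifications: Iterable[Modification]
) -> list[tuple[Optional[int], MassDelta]]:
    """Validate site constraints; positions are 1-based when given."""
    out: list[tuple[Optional[int], MassDelta]] = []
    for m in modifications:
        if isinstance(m, MassDelta):
            pos, delta = None, m
        else:
            pos, delta = m
        if pos is not None:
            if not 1 <= pos <= len(sequence):
                raise ValueError(
                    f"modification {delta.name} at position {pos} outside "
                    f"sequence of length {len(sequence)}"
                )
            if not delta.allowed_on(sequence[pos - 1]):
                raise ValueError(
                    f"modification {delta.name} not allowed on residue "
                    f"{sequence[pos - 1]!r} at position {pos}"
                )
        elif delta.sites is not None and not any(r in delta.sites for r in sequence):
            raise ValueError(
                f"modification {delta.name} requires a residue in "
                f"{delta.sites!r}; none present in {sequence!r}"
            )
        out.append((pos, delta))
    return out


def peptide_formula(
    sequence: str, modifications: Iterable[Modification] = ()
) -> ElementalFormula:
    """Elemental composition of a (modified) peptide: residues + one water."""
    if not sequence:
        raise ValueError("empty peptide sequence")
    total = ElementalFormula({"H": 2, "O": 1})
    for r in sequence:
        total = total + residue_formula(r)
    for _pos, delta in _normalize_modifications(sequence, modifications):
        total = total + dict(delta.formula_change)
    return total


def peptide_mono_mass(
    sequence: str, modifications: Iterable[Modification] = ()
) -> float:
    """Monoisotopic mass of a (modified) peptide, Da."""
    return peptide_formula(sequence, modifications).mono_mass


@dataclass(frozen=True)
class PeptideSpecies:
    """A peptide with positioned modifications and an optional link partner.

    The link is either ``None`` (free peptide), a disulfide partner (another
    :class:`PeptideSpecies`) or a thiol adduct (:class:`MassDelta`).  The
    monoisotopic mass is always recomputed from sequence + modifications +
    link, never stored independently.
    """

    sequence: str
    modifications: tuple = ()
    disulfide_partner: Optional["PeptideSpecies"] = None
    adduct: Optional[MassDelta] = None
    label: str = ""

    def __post_init__(self):
        if self.disulfide_partner is not None and self.adduct is not None:
            raise ValueError("species may carry a disulfide partner or an adduct, not both")
        if self.disulfide_partner is not None:
            if "C" not in self.sequence or "C" not in self.disulfide_partner.sequence:
                raise ValueError("a disulfide link requires a cysteine in both partners")
        if self.adduct is not None and not self.adduct.allowed_on("C"):
            # non-cysteine adducts (oxidations) are modifications, not links
            raise ValueError(f"{self.adduct.name} is not a cysteine-linkable adduct")
        if self.adduct is not None and "C" not in self.sequence:
            raise ValueError("a thiol adduct requires a cysteine in the peptide")
        if not self.label:
            object.__setattr__(self, "label", self._default_label())

    def _default_label(self) -> str:
        base = self.sequence
        for _pos, d in _normalize_modifications(self.sequence, self.modifications):
            base += f"[{d.name}]"
        if self.disulfide_partner is not None:
            return f"{base}--SS--{self.disulfide_partner.label}"
        if self.adduct is not None:
            return f"{base}+{self.adduct.name}"
        return base

    def formula(self) -> ElementalFormula:
        """Full elemental composition including modifications and link."""
        f = peptide_formula(self.sequence, self.modifications)
        if self.disulfide_partner is not None:
            f = f + self.disulfide_partner.formula() - {"H": 2}
        if self.adduct is not None:
            f = f + dict(self.adduct.formula_change)
        return f

    @property
    def mono_mass(self) -> float:
        """Monoisotopic mass, Da, recomputed from the composition."""
        return self.formula().mono_mass


def disulfide_mass(peptide_a, peptide_b) -> float:
    """Mass of two cysteine peptides joined by one disulfide bridge, Da.

    Accepts sequences or :class:`PeptideSpecies`; symmetric in its
    arguments: ``mass_a + mass_b − 2 × 1.0078250``.
    """
    masses = []
    for p in (peptide_a, peptide_b):
        seq = p.sequence if isinstance(p, PeptideSpecies) else p
        if "C" not in seq:
            raise ValueError(f"no cysteine in {seq!r}: cannot form a disulfide bridge")
        masses.append(p.mono_mass if isinstance(p, PeptideSpecies) else peptide_mono_mass(p))
    return masses[0] + masses[1] + DISULFIDE_DELTA


def mz(mass: float, charge: int) -> float:
    """m/z of the [M + charge·H]^charge+ ion."""
    if mass <= 0:
        raise ValueError(f"mass must be positive, got {mass}")
    if not isinstance(charge, int) or charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge}")
    return (mass + charge * PROTON_MASS) / charge


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error, parts per million."""
    return (observed - theoretical) / theoretical * 1e6
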