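"""Candidate-species enumeration and ppm-tolerance mass assignment.

The identification logic works at the precursor-mass level: a species is
"found" when an observed monoisotopic mass falls within a ppm tolerance of
a candidate's theoretical mass.  Candidates cover the free analyte, its
disulfide conjugates with cysteine-containing carrier fragments, mixed
disulfides with plasma LMW thiols, the analyte homodimer, oxidation forms
and the carbamidomethylated (alkylated) control forms.

A reduction/alkylation control backs each crosslink call: after DTT
reduction and iodoacetamide alkylation the crosslink mass must disappear
and the carbamidomethylated carrier fragment must appear.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .digestion import DigestFragment
from .masses import (
    ADDUCT_LIBRARY,
    CARBAMIDOMETHYL,
    DIOXIDATION,
    TRIOXIDATION,
    MassDelta,
    PeptideSpecies,
    adduct_delta,
    peptide_mono_mass,
    ppm_error,
)

__all__ = [
    "SpeciesCandidate",
    "MassMatch",
    "MatchResult",
    "ControlResult",
    "enumerate_conjugates",
    "enumerate_adducts",
    "match_masses",
    "reduction_control",
    "component_sum_report",
    "candidate_table",
    "match_table",
]

_OXIDATIONS = {1: None, 2: DIOXIDATION, 3: TRIOXIDATION}


@dataclass(frozen=True)
class SpeciesCandidate:
    """A theoretical species considered during mass assignment."""

    species: PeptideSpecies
    species_class: str  # free | crosslink | adduct | dimer | oxidized | alkylated
    provenance: tuple[str, ...] = ()

    @property
    def mono_mass(self) -> float:
        return self.species.mono_mass

    @property
    def label(self) -> str:
        return self.species.label

    def __repr__(self) -> str:
        return f"SpeciesCandidate({self.label}, {self.mono_mass:.4f} Da, {self.species_class})"


@dataclass(frozen=True)
class MassMatch:
    """An observed mass assigned to a candidate, with signed ppm error."""

    observed: float
    candidate: SpeciesCandidate
    ppm: float


@dataclass
class MatchResult:
    """Matches plus the observed masses nothing matched (never dropped)."""

    matches: list[MassMatch]
    unmatched: list[float]
    tolerance_ppm: float


def _as_species(fragment: Union[DigestFragment, PeptideSpecies, str]) -> PeptideSpecies:
    if isinstance(fragment, PeptideSpecies):
        return fragment
    if isinstance(fragment, DigestFragment):
        return PeptideSpecies(fragment.sequence)
    return PeptideSpecies(fragment)


def enumerate_conjugates(
    carrier_fragments: Iterable[Union[DigestFragment, PeptideSpecies, str]],
    analyte_fragments: Iterable[Union[DigestFragment, PeptideSpecies, str]],
) -> list[SpeciesCandidate]:
    """Disulfide-linked candidates: carrier × analyte cysteine fragments.

    Only pairwise links are enumerated (no 3+ assemblies, no intra-peptide
    bridges).  Output is deduplicated on the sequence pair and sorted by
    theoretical mass.
    """
    carriers = [_as_species(f) for f in carrier_fragments]
    analytes = [_as_species(f) for f in analyte_fragments]
    seen: set[tuple[str, str]] = set()
    out: list[SpeciesCandidate] = []
    for c in carriers:
        for a in analytes:
            key = (c.sequence, a.sequence)
            if key in seen:
                continue
            seen.add(key)
            species = PeptideSpecies(c.sequence, disulfide_partner=a)
            out.append(
                SpeciesCandidate(
                    species,
                    "crosslink",
                    provenance=(f"carrier:{c.sequence}", f"analyte:{a.sequence}"),
                )
            )
    out.sort(key=lambda s: s.mono_mass)
    return out


def enumerate_adducts(
    analyte: Union[PeptideSpecies, str],
    adducts: Sequence[str] = ("Cys", "homoCys", "CysGly", "GSH"),
    include_dimer: bool = True,
    include_free: bool = True,
    include_alkylated: bool = False,
    max_oxidation: int = 3,
    oxidation_on_adducts: int = 0,
) -> list[SpeciesCandidate]:
    """LMW thiol adducts, homodimer, oxidation and alkylated forms.

    Disulfide-class species (adducts, dimer) require a free cysteine in the
    analyte.  Oxidation is generated on the free peptide up to
    ``max_oxidation`` oxygens (covers the +31.99 and +47.98 Da forms) and,
    at depth ``oxidation_on_adducts``, stacked on adducts (default 0 to
    avoid combinatorial blow-up).
    """
    base = _as_species(analyte)
    needs_thiol = bool(adducts) or include_dimer
    if needs_thiol and "C" not in base.sequence:
        raise ValueError(
            f"analyte {base.sequence!r} has no cysteine: disulfide-class "
            "adducts and dimers cannot form"
        )
    out: list[SpeciesCandidate] = []
    seen: set[str] = set()

    def _add(species: PeptideSpecies, cls: str, prov: tuple[str, ...]):
        if species.label not in seen:
            seen.add(species.label)
            out.append(SpeciesCandidate(species, cls, provenance=prov))

    if include_free:
        _add(base, "free", (f"analyte:{base.sequence}",))
        for n_ox in range(2, max_oxidation + 1):
            delta = _OXIDATIONS.get(n_ox)
            if delta is None:
                continue
            _add(
                PeptideSpecies(base.sequence, modifications=base.modifications + (delta,)),
                "oxidized",
                (f"analyte:{base.sequence}", f"ox:{n_ox}O"),
            )
    for name in adducts:
        delta = adduct_delta(name)
        species = PeptideSpecies(base.sequence, modifications=base.modifications, adduct=delta)
        _add(species, "adduct", (f"analyte:{base.sequence}", f"adduct:{name}"))
        for n_ox in range(2, oxidation_on_adducts + 1):
            ox = _OXIDATIONS.get(n_ox)
            if ox is None:
                continue
            _add(
                PeptideSpecies(
                    base.sequence,
                    modifications=base.modifications + (ox,),
                    adduct=delta,
                ),
                "adduct",
                (f"analyte:{base.sequence}", f"adduct:{name}", f"ox:{n_ox}O"),
            )
    if include_dimer:
        dimer = PeptideSpecies(base.sequence, disulfide_partner=base)
        _add(dimer, "dimer", (f"analyte:{base.sequence}", "homodimer"))
    if include_alkylated:
        cam = PeptideSpecies(
            base.sequence, modifications=base.modifications + (CARBAMIDOMETHYL,)
        )
        _add(cam, "alkylated", (f"analyte:{base.sequence}", "carbamidomethyl"))
    out.sort(key=lambda s: s.mono_mass)
    return out


def match_masses(
    observed: Sequence[float],
    candidates: Sequence[SpeciesCandidate],
    tolerance_ppm: float = 20.0,
) -> MatchResult:
    """Assign observed monoisotopic masses to candidates within tolerance.

    Every (observed, candidate) pair within tolerance is reported — ties are
    kept and ranked by |ppm|, never silently resolved.  Observed masses with
    no candidate within tolerance are listed in ``unmatched``.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance must be positive")
    matches: list[MassMatch] = []
    unmatched: list[float] = []
    for obs in observed:
        hits = []
        for cand in candidates:
            err = ppm_error(obs, cand.mono_mass)
            if abs(err) <= tolerance_ppm:
                hits.append(MassMatch(obs, cand, err))
        if hits:
            hits.sort(key=lambda m: abs(m.ppm))
            matches.extend(hits)
        else:
            unmatched.append(obs)
    return MatchResult(matches=matches, unmatched=unmatched, tolerance_ppm=tolerance_ppm)


@dataclass
class ControlResult:
    """Outcome of the reduction/alkylation consistency check for one crosslink."""

    crosslink_label: str
    crosslink_mass: float
    status: str  # "pass" | "fail" | "not evaluated"
    crosslink_absent_after_reduction: Optional[bool] = None
    cam_fragment_label: str = ""
    cam_fragment_mass: Optional[float] = None
    cam_fragment_found: Optional[bool] = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def reduction_control(
    crosslink_matches: Iterable[MassMatch],
    reduced_observed: Optional[Sequence[float]],
    carrier_fragments: Iterable[Union[DigestFragment, PeptideSpecies, str]],
    tolerance_ppm: float = 20.0,
) -> list[ControlResult]:
    """Check each crosslink call against the reduced + alkylated condition.

    A crosslink passes when (a) its mass is absent from the reduced run and
    (b) the carbamidomethylated carrier fragment is present there.  With no
    reduced-condition data the control is marked "not evaluated" — never
    silently passed.
    """
    carriers = [_as_species(f) for f in carrier_fragments if "C" in _as_species(f).sequence]
    cam_forms = [
        PeptideSpecies(c.sequence, modifications=tuple(
            (i + 1, CARBAMIDOMETHYL) for i, r in enumerate(c.sequence) if r == "C"
        ))
        for c in carriers
    ]
    results: list[ControlResult] = []
    for m in crosslink_matches:
        if m.candidate.species_class != "crosslink":
            continue
        res = ControlResult(
            crosslink_label=m.candidate.label, crosslink_mass=m.candidate.mono_mass,
            status="not evaluated",
        )
        if reduced_observed is None:
            results.append(res)
            continue
        res.crosslink_absent_after_reduction = not any(
            abs(ppm_error(obs, m.candidate.mono_mass)) <= tolerance_ppm
            for obs in reduced_observed
        )
        # carrier partner of this crosslink, CAM-modified, must reappear
        carrier_seq = next(
            (p.split(":", 1)[1] for p in m.candidate.provenance if p.startswith("carrier:")),
            None,
        )
        best_found = False
        for cam in cam_forms:
            if carrier_seq is not None and cam.sequence != carrier_seq:
                continue
            found = any(
                abs(ppm_error(obs, cam.mono_mass)) <= tolerance_ppm
                for obs in reduced_observed
            )
            if found or not best_found:
                res.cam_fragment_label = cam.label
                res.cam_fragment_mass = cam.mono_mass
            best_found = best_found or found
        res.cam_fragment_found = best_found
        res.status = (
            "pass" if (res.crosslink_absent_after_reduction and best_found) else "fail"
        )
        results.append(res)
    return results


def component_sum_report(
    printed_mass: float,
    carrier_sequence: str,
    analyte_fragment: str,
    tolerance_ppm: float = 20.0,
) -> dict:
    """Arithmetic audit of a printed composite (crosslink) mass.

    Recomputes the disulfide-linked mass from its stated components and
    reports the difference against the printed value; used to surface
    internally inconsistent literature values rather than forcing a match.
    """
    carrier_mass = peptide_mono_mass(carrier_sequence)
    analyte_mass = peptide_mono_mass(analyte_fragment)
    from .masses import DISULFIDE_DELTA

    theoretical = carrier_mass + analyte_mass + DISULFIDE_DELTA
    diff = printed_mass - theoretical
    return {
        "printed_mass": printed_mass,
        "carrier_sequence": carrier_sequence,
        "carrier_mass": carrier_mass,
        "analyte_fragment": analyte_fragment,
        "analyte_mass": analyte_mass,
        "theoretical_crosslink_mass": theoretical,
        "difference_da": diff,
        "difference_ppm": ppm_error(printed_mass, theoretical),
        "consistent": abs(ppm_error(printed_mass, theoretical)) <= tolerance_ppm,
    }


def candidate_table(candidates: Iterable[SpeciesCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "label": c.label,
                "class": c.species_class,
                "mono_mass": round(c.mono_mass, 4),
                "provenance": ";".join(c.provenance),
            }
            for c in candidates
        ]
    )


def match_table(result: MatchResult) -> pd.DataFrame:
    rows = [
        {
            "observed": m.observed,
            "label": m.candidate.label,
            "class": m.candidate.species_class,
            "theoretical": round(m.candidate.mono_mass, 4),
            "ppm": round(m.ppm, 3),
        }
        for m in result.matches
    ]
    return pd.DataFrame(rows)
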