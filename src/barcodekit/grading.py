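"""A-E reliability grading of reference-library species.

Each reference species receives one grade:

* **A** — externally corroborated: a concordant match (>= identity floor)
  against an independent snapshot of published barcodes, with intraspecific
  divergence within 2%.
* **B** — internally concordant only: at least 3 specimens within 2% of one
  another, but no external match available.
* **C** — deep intraspecific divergence: >2% among at least 3 specimens.
* **D** — thin evidence: 1-2 specimens and no external match (a 2-specimen
  species split by >2% is D with an explicit flag, since the >2% rule
  requires 3 specimens).
* **E** — discordant: an external match naming a different species, or the
  species is not monophyletic on the reference tree.

Precedence is E > C > A > B > D: discordance overrides sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .assignment import identity_search
from .distances import DistanceMatrix
from .io import BarcodeLibrary

DEFAULT_GRADE_THRESHOLD = 0.02
DEFAULT_IDENTITY_FLOOR = 98.0


@dataclass
class ExternalMatch:
    """Best hit of a reference species against an external barcode snapshot."""

    species: str
    matched_species: str
    identity: float
    source: str = "snapshot"
    discordant_specimens: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class SpeciesGrade:
    species: str
    grade: str
    n_specimens: int
    max_intra: Optional[float]      # percent; None if <2 specimens
    rationale_code: str


@dataclass
class GradeTable:
    """species -> grade with machine-readable rationale."""

    table: dict[str, SpeciesGrade]

    def __getitem__(self, species: str) -> SpeciesGrade:
        return self.table[species]

    def __iter__(self):
        return iter(self.table.values())

    def __len__(self) -> int:
        return len(self.table)

    def grade_of(self, species: str) -> str:
        return self.table[species].grade

    def species_with_grades(self, grades: set[str]) -> set[str]:
        return {s for s, g in self.table.items() if g.grade in grades}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"species": g.species, "grade": g.grade, "n": g.n_specimens,
             "max_intra_pct": (round(g.max_intra, 2)
                               if g.max_intra is not None else ""),
             "rationale": g.rationale_code}
            for g in sorted(self.table.values(), key=lambda g: g.species)
        ]
        return pd.DataFrame(rows)


def compute_external_matches(reference: BarcodeLibrary,
                             snapshot: BarcodeLibrary,
                             identity_floor: float = DEFAULT_IDENTITY_FLOOR,
                             source: str = "snapshot"
                             ) -> dict[str, ExternalMatch]:
    """Best external hit per reference species, with per-specimen outliers.

    Every specimen is searched against the snapshot; the species-level
    match is the highest-identity hit over its specimens, and any specimen
    whose own top hit (at or above the floor) names a different species is
    recorded as discordant.
    """
    by_species: dict[str, list] = {}
    for rec in reference:
        by_species.setdefault(rec.species, []).append(rec)

    out: dict[str, ExternalMatch] = {}
    for species, recs in by_species.items():
        best: Optional[tuple[float, str]] = None
        discordant: list[str] = []
        for rec in recs:
            hits = identity_search(rec.sequence, snapshot,
                                   min_identity=identity_floor)
            if not hits:
                continue
            top = hits[0]
            if top.passes and top.candidate_species != species:
                discordant.append(rec.specimen_id)
            if top.passes and (best is None or top.identity > best[0]):
                best = (top.identity, top.candidate_species)
        if best is not None:
            out[species] = ExternalMatch(
                species=species, matched_species=best[1], identity=best[0],
                source=source, discordant_specimens=discordant,
            )
    return out


def grade_library(library: BarcodeLibrary, matrix: DistanceMatrix,
                  monophyly: dict[str, str],
                  external_matches: Optional[dict[str, ExternalMatch]] = None,
                  threshold: float = DEFAULT_GRADE_THRESHOLD,
                  identity_floor: float = DEFAULT_IDENTITY_FLOOR) -> GradeTable:
    """Grade every reference species (see module docstring for the rules).

    ``threshold`` is the intraspecific divergence bound on the proportion
    scale (default 0.02, compared inclusively for the A/B rule and strictly
    for the C rule); ``external_matches`` may be empty when no snapshot is
    available, in which case no species can reach grade A or E-by-mismatch.
    """
    external_matches = external_matches or {}
    threshold_pct = threshold * 100.0

    by_species: dict[str, list[str]] = {}
    for rec in library:
        by_species.setdefault(rec.species, []).append(rec.specimen_id)

    matrix_ids = set(matrix.ids)
    table: dict[str, SpeciesGrade] = {}
    for species, members in sorted(by_species.items()):
        missing = [m for m in members if m not in matrix_ids]
        if missing:
            raise ValueError(f"specimens of {species} absent from matrix: "
                             f"{missing}")
        n = len(members)
        max_intra = matrix.max_among(members) * 100.0 if n >= 2 else None
        ext = external_matches.get(species)

        discordant = ext is not None and (
            ext.discordant_specimens or
            (ext.matched_species != species and ext.identity >= identity_floor)
        )
        non_mono = monophyly.get(species) == "non_monophyletic"
        concordant_ext = (ext is not None and not discordant and
                          ext.matched_species == species and
                          ext.identity >= identity_floor)
        deep = max_intra is not None and max_intra > threshold_pct

        if discordant or non_mono:
            grade, code = "E", ("non_monophyletic" if non_mono
                                else "discordant_match")
        elif n >= 3 and deep:
            grade, code = "C", "deep_intraspecific_divergence"
        elif n == 2 and deep:
            grade, code = "D", "two_specimens_deep_split"
        elif concordant_ext:
            grade, code = "A", "external_concordance"
        elif n >= 3:
            grade, code = "B", "internal_concordance"
        else:
            grade, code = "D", "few_specimens_no_match"

        table[species] = SpeciesGrade(species, grade, n, max_intra, code)
    return GradeTable(table)


def apply_grades(library: BarcodeLibrary, grades: GradeTable) -> None:
    """Stamp each record's ``grade`` field from its species' grade."""
    for rec in library:
        if rec.species in grades.table:
            rec.grade = grades.grade_of(rec.species)
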