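"""Blind species assignment of query barcodes and deep-divergence flagging.

The two-stage protocol: a query is first assigned by cluster membership —
if it falls inside a <2% monophyletic cluster whose reference members all
carry one species name, it takes that name.  Queries left unassigned fall
back to a nearest-neighbour identity search against a snapshot of published
barcodes, accepting hits of at least 98% identity over (effectively) the
whole barcode, ties at the top identity across distinct species counting as
ambiguous.  Morphology labels enter only afterwards, to audit the outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .distances import encode, _align_pair
from .io import BarcodeLibrary, BARCODE_LENGTH
from .tree import Cluster

DEFAULT_MIN_IDENTITY = 98.0
DEFAULT_MIN_COVERAGE = 0.95

OUTCOMES = ("confirmed", "mismatch", "ambiguous", "no_match", "new_record")


@dataclass(frozen=True)
class IdentityHit:
    candidate_species: str
    candidate_id: str
    identity: float       # percent over compared positions
    coverage: float       # compared positions / barcode length
    passes: bool          # meets both identity and coverage floors


def sequence_identity(seq_a: str, seq_b: str) -> tuple[float, int]:
    """Percent identity and compared-site count for two sequences.

    Unequal lengths are aligned end-gap-free first; sites with gaps or
    ambiguity codes on either side are excluded from the comparison.
    """
    if len(seq_a) != len(seq_b):
        seq_a, seq_b = _align_pair(seq_a, seq_b)
    a, b = encode(seq_a), encode(seq_b)
    valid = (a != 255) & (b != 255)
    n = int(valid.sum())
    if n == 0:
        return 0.0, 0
    matches = int((valid & (a == b)).sum())
    return 100.0 * matches / n, n


def identity_search(query_sequence: str, candidates: BarcodeLibrary,
                    min_identity: float = DEFAULT_MIN_IDENTITY,
                    min_coverage: float = DEFAULT_MIN_COVERAGE,
                    barcode_length: int = BARCODE_LENGTH
                    ) -> list[IdentityHit]:
    """Rank candidate species by identity to the query (best specimen each).

    Hits below the identity or coverage floor are retained but flagged
    ``passes=False`` so callers can report the best below-threshold match.
    """
    if len(candidates) == 0:
        raise ValueError("candidate library is empty")

    cand = list(candidates)
    q = query_sequence.upper()
    same_len = all(len(c.sequence) == len(q) for c in cand)
    best: dict[str, IdentityHit] = {}

    if same_len:
        qe = encode(q)
        enc = np.stack([encode(c.sequence) for c in cand])
        valid = (enc != 255) & (qe != 255)
        n = valid.sum(axis=1)
        matches = (valid & (enc == qe)).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ident = np.where(n > 0, 100.0 * matches / n, 0.0)
        cov = n / barcode_length
        for rec, idn, cv in zip(cand, ident, cov):
            hit = IdentityHit(rec.species, rec.specimen_id, float(idn),
                              float(cv),
                              bool(idn >= min_identity and cv >= min_coverage))
            prev = best.get(rec.species)
            if prev is None or hit.identity > prev.identity:
                best[rec.species] = hit
    else:
        for rec in cand:
            idn, n = sequence_identity(q, rec.sequence)
            cv = n / barcode_length
            hit = IdentityHit(rec.species, rec.specimen_id, idn, cv,
                              idn >= min_identity and cv >= min_coverage)
            prev = best.get(rec.species)
            if prev is None or hit.identity > prev.identity:
                best[rec.species] = hit

    return sorted(best.values(),
                  key=lambda h: (-h.identity, h.candidate_species))


@dataclass(frozen=True)
class Provisional:
    """Cluster-rule verdict for one query, before any identity fallback."""

    query_id: str
    status: str                       # assigned / unassigned / ambiguous
    species: Optional[str]
    cluster_id: str


def assign_by_cluster(query_ids: Sequence[str], clusters: list[Cluster]
                      ) -> dict[str, Provisional]:
    """Apply the cluster-membership rule to each query.

    A query is assigned iff its cluster's reference members (the members
    carrying a species label in the cluster composition) are species-pure;
    clusters with no reference member leave their queries unassigned
    (candidate first-time barcodes) and clusters mixing reference species
    yield an ambiguous verdict.
    """
    member_of: dict[str, Cluster] = {}
    for cl in clusters:
        for m in cl.member_ids:
            member_of[m] = cl

    out: dict[str, Provisional] = {}
    for qid in query_ids:
        cl = member_of.get(qid)
        if cl is None:
            raise ValueError(f"query {qid} is not on the tree/cluster partition")
        ref_species = sorted(s for s in cl.species_composition if s)
        if not ref_species:
            out[qid] = Provisional(qid, "unassigned", None, cl.cluster_id)
        elif len(ref_species) == 1:
            out[qid] = Provisional(qid, "assigned", ref_species[0],
                                   cl.cluster_id)
        else:
            out[qid] = Provisional(qid, "ambiguous", None, cl.cluster_id)
    return out


@dataclass
class AssignmentResult:
    query_id: str
    outcome: str
    assigned_species: Optional[str]
    morphology_species: str
    cluster_id: str = ""
    identity: Optional[float] = None
    evidence: str = ""

    def __post_init__(self) -> None:
        assert self.outcome in OUTCOMES


def classify_outcome(provisional: Provisional,
                     hits: Optional[list[IdentityHit]],
                     morphology_species: str) -> AssignmentResult:
    """Audit one query's verdict against its morphology label.

    ``hits`` is the fallback identity ranking (None when no candidate
    snapshot exists).  Outcomes: *confirmed* (assignment equals morphology),
    *mismatch* (both set, different), *ambiguous* (mixed cluster or exact
    identity tie between distinct species), *no_match* (searched, nothing at
    or above the floor — reported with the best below-threshold hit) and
    *new_record* (no cluster match and nothing to search: a first-time
    barcode).
    """
    qid = provisional.query_id
    if provisional.status == "assigned":
        outcome = ("confirmed" if provisional.species == morphology_species
                   else "mismatch")
        return AssignmentResult(qid, outcome, provisional.species,
                                morphology_species,
                                cluster_id=provisional.cluster_id,
                                evidence="cluster")
    if provisional.status == "ambiguous":
        return AssignmentResult(qid, "ambiguous", None, morphology_species,
                                cluster_id=provisional.cluster_id,
                                evidence="mixed_reference_cluster")

    # Unassigned by the cluster rule: identity fallback.
    if hits is None:
        return AssignmentResult(qid, "new_record", None, morphology_species,
                                cluster_id=provisional.cluster_id,
                                evidence="no_reference_cluster")
    passing = [h for h in hits if h.passes]
    if not passing:
        bestline = (f"best_below_threshold:{hits[0].candidate_species}"
                    f"({hits[0].identity:.1f}%)" if hits else "no_hits")
        return AssignmentResult(qid, "no_match", None, morphology_species,
                                cluster_id=provisional.cluster_id,
                                identity=hits[0].identity if hits else None,
                                evidence=bestline)
    top = passing[0]
    tied = [h for h in passing if h.identity == top.identity]
    if len({h.candidate_species for h in tied}) > 1:
        names = ",".join(sorted(h.candidate_species for h in tied))
        return AssignmentResult(qid, "ambiguous", None, morphology_species,
                                cluster_id=provisional.cluster_id,
                                identity=top.identity,
                                evidence=f"identity_tie:{names}")
    outcome = ("confirmed" if top.candidate_species == morphology_species
               else "mismatch")
    return AssignmentResult(qid, outcome, top.candidate_species,
                            morphology_species,
                            cluster_id=provisional.cluster_id,
                            identity=top.identity,
                            evidence=f"identity:{top.candidate_id}")


def assign_queries(query_library: BarcodeLibrary, clusters: list[Cluster],
                   snapshot: Optional[BarcodeLibrary] = None,
                   min_identity: float = DEFAULT_MIN_IDENTITY,
                   min_coverage: float = DEFAULT_MIN_COVERAGE
                   ) -> list[AssignmentResult]:
    """Run both assignment stages for every query and audit the outcomes.

    The fallback search runs only for queries the cluster rule left
    unassigned, mirroring the two-stage protocol.
    """
    provisionals = assign_by_cluster(query_library.ids, clusters)
    results = []
    for rec in query_library:
        prov = provisionals[rec.specimen_id]
        hits = None
        if prov.status == "unassigned" and snapshot is not None and len(snapshot):
            hits = identity_search(rec.sequence, snapshot,
                                   min_identity=min_identity,
                                   min_coverage=min_coverage)
        results.append(classify_outcome(prov, hits, rec.species))
    return results


def results_frame(results: list[AssignmentResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {"query_id": r.query_id, "outcome": r.outcome,
         "assigned_species": r.assigned_species or "",
         "morphology_species": r.morphology_species,
         "cluster_id": r.cluster_id,
         "identity": "" if r.identity is None else round(r.identity, 2),
         "evidence": r.evidence}
        for r in results
    ])


@dataclass(frozen=True)
class FlaggedSpecies:
    """A species whose intraspecific divergence exceeds the 2% screen."""

    species: str
    max_intra: float            # percent
    n_subclusters: int
    geographic_sorting: bool
    between_group_mean: float   # percent; NaN when <2 subclusters


def flag_deep_divergences(library: BarcodeLibrary, matrix,
                          clusters: list[Cluster],
                          threshold: float = 0.02) -> list[FlaggedSpecies]:
    """Flag species with intraspecific K2P above ``threshold``.

    Sub-cluster structure comes from restricting the cluster partition to
    the species' specimens; geographic sorting holds when every sub-cluster
    is region-pure and the sub-clusters' regions are pairwise distinct.
    The mean between-sub-cluster distance is reported alongside the maximum
    so both the within-species and between-lineage readings are available.
    """
    species_members: dict[str, list[str]] = {}
    for rec in library:
        species_members.setdefault(rec.species, []).append(rec.specimen_id)
    regions = library.region_map()

    flagged: list[FlaggedSpecies] = []
    for species, members in sorted(species_members.items()):
        if len(members) < 2:
            continue
        max_intra = matrix.max_among(members)
        if max_intra <= threshold:
            continue
        member_set = set(members)
        groups = [sorted(member_set & set(cl.member_ids)) for cl in clusters]
        groups = [g for g in groups if g]
        pure = [len({regions[m] for m in g}) == 1 for g in groups]
        group_regions = [regions[g[0]] for g in groups]
        sorting = (len(groups) >= 2 and all(pure)
                   and len(set(group_regions)) == len(groups))
        if len(groups) >= 2:
            between = []
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    between.extend(matrix.get(a, b)
                                   for a in groups[i] for b in groups[j])
            between_mean = 100.0 * float(np.mean(between))
        else:
            between_mean = float("nan")
        flagged.append(FlaggedSpecies(
            species=species, max_intra=100.0 * max_intra,
            n_subclusters=len(groups), geographic_sorting=sorting,
            between_group_mean=between_mean,
        ))
    return flagged


def flags_frame(flags: list[FlaggedSpecies]) -> pd.DataFrame:
    return pd.DataFrame([
        {"species": f.species, "max_intra_pct": round(f.max_intra, 2),
         "n_subclusters": f.n_subclusters,
         "geographic_sorting": f.geographic_sorting,
         "between_group_mean_pct": (round(f.between_group_mean, 2)
                                    if np.isfinite(f.between_group_mean)
                                    else "")}
        for f in flags
    ])
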