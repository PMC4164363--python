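"""Kimura 2-parameter distances and taxonomic-rank distance summaries.

The K2P model corrects the raw mismatch proportion for multiple hits while
distinguishing transitions (A<->G, C<->T) from transversions:

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

with P and Q the transition and transversion proportions over sites where
both sequences carry an unambiguous base (pairwise deletion).  The transform
is undefined when either logarithm argument is non-positive (saturation);
such pairs are flagged rather than silently dropped.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .io import BarcodeLibrary

#: Minimum shared unambiguous sites for a defined distance.
DEFAULT_MIN_OVERLAP = 100

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_PURINE = {0: True, 2: True, 1: False, 3: False}

RANKS = ("conspecific", "congeneric", "confamilial")


@dataclass(frozen=True)
class SitePatternCounts:
    """Shared-site, transition and transversion counts for one sequence pair."""

    n_compared: int
    transitions: int
    transversions: int

    @property
    def p(self) -> float:
        return self.transitions / self.n_compared if self.n_compared else math.nan

    @property
    def q(self) -> float:
        return self.transversions / self.n_compared if self.n_compared else math.nan


def encode(sequence: str) -> np.ndarray:
    """Encode a nucleotide string as uint8; non-ACGT symbols become 255."""
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


def _align_pair(a: str, b: str) -> tuple[str, str]:
    """End-gap-free global alignment of two unequal-length sequences."""
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=-1,
        open_gap_score=-2,
        extend_gap_score=-0.5,
        end_insertion_score=0,
        end_deletion_score=0,
    )
    aln = aligner.align(a.upper(), b.upper())[0]
    return str(aln[0]), str(aln[1])


def count_site_patterns(seq_a: str, seq_b: str) -> SitePatternCounts:
    """Count compared sites, transitions and transversions for a pair.

    Sites where either sequence carries a gap or ambiguity symbol are
    excluded (pairwise deletion).  Sequences of unequal length are first
    put on a common coordinate by an end-gap-free global alignment.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    if len(seq_a) != len(seq_b):
        seq_a, seq_b = _align_pair(seq_a, seq_b)
    a, b = encode(seq_a), encode(seq_b)
    valid = (a != 255) & (b != 255)
    diff = valid & (a != b)
    # Purines are A(0)/G(2): even codes.  A<->G and C<->T keep parity.
    ts = diff & ((a % 2) == (b % 2))
    return SitePatternCounts(
        n_compared=int(valid.sum()),
        transitions=int(ts.sum()),
        transversions=int(diff.sum() - ts.sum()),
    )


def k2p(counts: SitePatternCounts,
        min_overlap: int = DEFAULT_MIN_OVERLAP) -> float:
    """Kimura 2-parameter distance from site-pattern counts.

    Returns ``nan`` (the undefined flag) when fewer than ``min_overlap``
    sites were compared or when the transform leaves its real domain,
    i.e. ``(1 - 2P - Q) <= 0`` or ``(1 - 2Q) <= 0``.
    """
    if counts.n_compared < min_overlap:
        return math.nan
    p, q = counts.p, counts.q
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    return -0.5 * math.log(w1 * math.sqrt(w2))


def k2p_pairwise(seq_a: str, seq_b: str,
                 min_overlap: int = DEFAULT_MIN_OVERLAP) -> float:
    """Convenience wrapper: K2P distance straight from two sequences."""
    return k2p(count_site_patterns(seq_a, seq_b), min_overlap=min_overlap)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with undefined-entry tracking."""

    ids: list[str]
    d: np.ndarray
    undefined_pairs: set[frozenset]

    def __post_init__(self) -> None:
        self._index = {sid: i for i, sid in enumerate(self.ids)}

    def get(self, a: str, b: str) -> float:
        return float(self.d[self._index[a], self._index[b]])

    def max_among(self, ids: Iterable[str]) -> float:
        """Max defined pairwise distance among ``ids`` (0 for <2 ids)."""
        idx = [self._index[i] for i in ids]
        if len(idx) < 2:
            return 0.0
        sub = self.d[np.ix_(idx, idx)]
        vals = sub[np.triu_indices(len(idx), k=1)]
        vals = vals[~np.isnan(vals)]
        return float(vals.max()) if vals.size else 0.0

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self._index[i] for i in ids]
        sub = self.d[np.ix_(idx, idx)]
        undef = {p for p in self.undefined_pairs if p <= set(ids)}
        return DistanceMatrix(list(ids), sub, undef)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    def write_phylip(self, path: str | Path) -> None:
        """Square PHYLIP-style matrix (undefined entries as -1)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            filled = np.where(np.isnan(self.d), -1.0, self.d)
            for sid, row in zip(self.ids, filled):
                fh.write(sid + "  " + " ".join(f"{x:.8f}" for x in row) + "\n")

    def condensed(self) -> np.ndarray:
        return self.d[np.triu_indices(len(self.ids), k=1)]


def k2p_matrix_encoded(enc: np.ndarray,
                       min_overlap: int = DEFAULT_MIN_OVERLAP,
                       clip: bool = False) -> tuple[np.ndarray, set[tuple[int, int]]]:
    """K2P distance matrix from an (n, L) encoded alignment.

    Returns the symmetric matrix and the set of undefined index pairs.
    With ``clip=True`` out-of-domain log arguments are clipped to a tiny
    positive value instead of flagged, yielding large finite distances —
    used for bootstrap replicates where a full matrix is required.
    """
    n = enc.shape[0]
    d = np.zeros((n, n))
    undefined: set[tuple[int, int]] = set()
    valid = enc != 255
    parity = enc % 2
    eps = 1e-10
    for i in range(n - 1):
        v = valid[i] & valid[i + 1:]                   # (m, L)
        diff = v & (enc[i] != enc[i + 1:])
        ts = diff & (parity[i] == parity[i + 1:])
        nc = v.sum(axis=1).astype(float)
        tsc = ts.sum(axis=1)
        tvc = diff.sum(axis=1) - tsc
        with np.errstate(divide="ignore", invalid="ignore"):
            p = tsc / nc
            q = tvc / nc
            w1 = 1.0 - 2.0 * p - q
            w2 = 1.0 - 2.0 * q
            if clip:
                w1 = np.clip(w1, eps, None)
                w2 = np.clip(w2, eps, None)
            dist = -0.5 * np.log(w1 * np.sqrt(w2))
        bad = (nc < min_overlap) | ~np.isfinite(dist)
        dist[bad] = np.nan
        d[i, i + 1:] = dist
        for j in np.nonzero(bad)[0]:
            undefined.add((i, i + 1 + int(j)))
    d = d + d.T
    np.fill_diagonal(d, 0.0)
    return d, undefined


def distance_matrix(library: BarcodeLibrary | list,
                    min_overlap: int = DEFAULT_MIN_OVERLAP) -> DistanceMatrix:
    """All pairwise K2P distances over a library's records.

    Equal-length record sets are treated as pre-aligned on the barcode
    coordinate and computed with a vectorised row sweep; mixed-length sets
    fall back to per-pair alignment.
    """
    records = list(library)
    if len(records) < 2:
        raise ValueError("need at least 2 records for a distance matrix")
    ids = [r.specimen_id for r in records]
    seqs = [r.sequence for r in records]
    n = len(ids)
    d = np.zeros((n, n))
    undefined: set[frozenset] = set()

    if len({len(s) for s in seqs}) == 1:
        enc = np.stack([encode(s) for s in seqs])          # (n, L)
        d, undef_idx = k2p_matrix_encoded(enc, min_overlap=min_overlap)
        undefined = {frozenset({ids[i], ids[j]}) for i, j in undef_idx}
    else:
        for i, j in itertools.combinations(range(n), 2):
            val = k2p_pairwise(seqs[i], seqs[j], min_overlap=min_overlap)
            d[i, j] = d[j, i] = val
            if math.isnan(val):
                undefined.add(frozenset({ids[i], ids[j]}))

    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids, d, undefined)


@dataclass(frozen=True)
class RankLevelStats:
    """Distance statistics for one taxonomic comparison level (percent)."""

    n_pairs: int
    min: float
    mean: float
    se: float
    max: float


@dataclass
class RankDistanceSummary:
    """Per-level distance summary: conspecific / congeneric / confamilial."""

    levels: dict[str, Optional[RankLevelStats]]
    n_records: int
    n_species: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        names = {"conspecific": "Species", "congeneric": "Genus",
                 "confamilial": "Family"}
        for level in RANKS:
            st = self.levels.get(level)
            if st is None:
                continue
            rows.append({
                "Comparison": names[level],
                "N": st.n_pairs,
                "Minimum Distance": round(st.min, 2),
                "Mean Distance": round(st.mean, 2),
                "SE": round(st.se, 2),
                "Maximum Distance": round(st.max, 2),
            })
        return pd.DataFrame(rows)


def _pair_levels(meta: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean (n, n) masks for conspecific/congeneric/confamilial pairs."""
    sp = meta["species"].to_numpy()
    ge = meta["genus"].to_numpy()
    fa = meta["family"].to_numpy()
    same_sp = sp[:, None] == sp[None, :]
    same_ge = ge[:, None] == ge[None, :]
    same_fa = fa[:, None] == fa[None, :]
    return same_sp, same_ge & ~same_sp, same_fa & ~same_ge


def summarize_ranks(matrix: DistanceMatrix, library: BarcodeLibrary,
                    grades: Optional[set[str]] = None) -> RankDistanceSummary:
    """Distance summary at the three comparison levels, in percent.

    ``grades`` restricts the summary to records carrying one of the given
    reliability grades (the graded-subset re-analysis); ``None`` uses all
    records in the matrix.  Undefined pairs are excluded.  ``se`` is the
    sample standard deviation of pair distances divided by sqrt(n_pairs).
    """
    meta = library.metadata_frame().set_index("specimen_id")
    ids = [i for i in matrix.ids if i in meta.index]
    if grades is not None:
        ids = [i for i in ids if meta.loc[i, "grade"] in grades]
    sub = matrix.submatrix(ids)
    meta = meta.loc[ids]
    for col in ("species", "genus", "family"):
        if (meta[col] == "").any():
            raise ValueError(f"every specimen needs a {col} label")

    masks = dict(zip(RANKS, _pair_levels(meta)))
    iu = np.triu_indices(len(ids), k=1)
    dist_pct = sub.d * 100.0

    levels: dict[str, Optional[RankLevelStats]] = {}
    for level in RANKS:
        sel = masks[level][iu]
        vals = dist_pct[iu][sel]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            levels[level] = None
            continue
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        levels[level] = RankLevelStats(
            n_pairs=int(vals.size),
            min=float(vals.min()),
            mean=float(vals.mean()),
            se=sd / math.sqrt(vals.size),
            max=float(vals.max()),
        )
    return RankDistanceSummary(levels, n_records=len(ids),
                               n_species=meta["species"].nunique())


def species_divergence_profile(matrix: DistanceMatrix,
                               library: BarcodeLibrary) -> tuple[pd.DataFrame,
                                                                 pd.DataFrame]:
    """Per-species and per-genus divergence profiles (percent scale).

    Species with fewer than two specimens are marked not evaluable
    (``NaN`` statistics).  Genus rows summarise between-species pairs
    within the genus.
    """
    meta = library.metadata_frame().set_index("specimen_id")
    ids = [i for i in matrix.ids if i in meta.index]
    sub = matrix.submatrix(ids)
    meta = meta.loc[ids]
    dist_pct = sub.d * 100.0
    sp = meta["species"].to_numpy()
    ge = meta["genus"].to_numpy()

    sp_rows = []
    for species in sorted(set(sp)):
        idx = np.nonzero(sp == species)[0]
        if len(idx) < 2:
            sp_rows.append({"species": species, "n": len(idx),
                            "max_intra": np.nan, "mean_intra": np.nan,
                            "evaluable": False})
            continue
        vals = dist_pct[np.ix_(idx, idx)][np.triu_indices(len(idx), k=1)]
        vals = vals[~np.isnan(vals)]
        sp_rows.append({
            "species": species, "n": len(idx),
            "max_intra": float(vals.max()) if vals.size else np.nan,
            "mean_intra": float(vals.mean()) if vals.size else np.nan,
            "evaluable": bool(vals.size),
        })

    ge_rows = []
    for genus in sorted(set(ge)):
        idx = np.nonzero(ge == genus)[0]
        mask = sp[idx][:, None] != sp[idx][None, :]
        vals = dist_pct[np.ix_(idx, idx)][mask & np.triu(np.ones_like(mask), k=1).astype(bool)]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            continue
        ge_rows.append({"genus": genus, "min": float(vals.min()),
                        "mean": float(vals.mean()), "max": float(vals.max()),
                        "n_pairs": int(vals.size)})

    return pd.DataFrame(sp_rows), pd.DataFrame(ge_rows)
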