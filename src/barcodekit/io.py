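"""Reading, writing and quality control of COI-5P barcode libraries.

A *library* couples a FASTA file of nucleotide barcodes with a tab-separated
metadata table (specimen id, Linnean taxonomy, sampling region, reference/query
role, optional reliability grade).  Every record is screened with the standard
barcode quality rules for fish COI-5P: an open reading frame free of stop
codons under the vertebrate mitochondrial code, no internal gap characters,
and a length compatible with the 652 bp 5' barcode fragment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("barcodekit")

#: Stop codons of the vertebrate mitochondrial genetic code.
VERTEBRATE_MITO_STOPS = frozenset({"TAA", "TAG", "AGA", "AGG"})

#: Canonical length of the COI-5P barcode fragment (bp).
BARCODE_LENGTH = 652

#: Shortest fragment still accepted as a usable barcode (bp).
DEFAULT_MIN_LENGTH = 500

REGIONS = ("NEA", "MED", "OTHER")
ROLES = ("reference", "query")
GRADES = ("A", "B", "C", "D", "E", "ungraded")

METADATA_COLUMNS = [
    "specimen_id",
    "species",
    "genus",
    "family",
    "order",
    "region",
    "role",
    "grade",
]

_ACGT = frozenset("ACGT")


class BarcodeError(ValueError):
    """Raised for malformed libraries (duplicate ids, bad metadata, ...)."""


@dataclass(frozen=True)
class QCResult:
    """Outcome of the barcode quality screen for one sequence.

    Attributes
    ----------
    passed : bool
        True when the sequence is usable as a barcode.
    reading_frame : int or None
        Frame (0, 1 or 2) minimising the stop-codon count; ties resolve to
        the lowest frame index.  None when no frame could be evaluated.
    stop_codons : int
        Stop-codon count in the chosen frame.
    length_ok : bool
        Length within ``[min_len, 652]``.
    ambiguity_fraction : float
        Proportion of symbols outside A/C/G/T.
    reason : str
        Machine-readable failure code; empty when passed.
    """

    passed: bool
    reading_frame: Optional[int]
    stop_codons: int
    length_ok: bool
    ambiguity_fraction: float
    reason: str = ""


@dataclass
class BarcodeRecord:
    """One specimen's barcode sequence plus its taxonomy and provenance."""

    specimen_id: str
    sequence: str
    species: str
    genus: str
    family: str
    order: str
    region: str = "OTHER"
    role: str = "reference"
    grade: str = "ungraded"
    qc: Optional[QCResult] = None

    def __post_init__(self) -> None:
        if not self.specimen_id:
            raise BarcodeError("specimen_id must be non-empty")
        if not self.sequence:
            raise BarcodeError(f"{self.specimen_id}: empty sequence")
        self.sequence = self.sequence.upper()
        if self.region not in REGIONS:
            raise BarcodeError(f"{self.specimen_id}: unknown region {self.region!r}")
        if self.role not in ROLES:
            raise BarcodeError(f"{self.specimen_id}: unknown role {self.role!r}")
        if self.grade not in GRADES:
            raise BarcodeError(f"{self.specimen_id}: unknown grade {self.grade!r}")
        # A binomial must carry its genus as the first epithet.
        if self.species and self.genus and " " in self.species:
            if self.species.split()[0] != self.genus:
                raise BarcodeError(
                    f"{self.specimen_id}: species {self.species!r} does not "
                    f"start with genus {self.genus!r}"
                )


def count_stop_codons(sequence: str, frame: int,
                      stops: frozenset[str] = VERTEBRATE_MITO_STOPS) -> int:
    """Count stop codons of ``sequence`` read in ``frame`` (0, 1 or 2).

    Codons containing ambiguity symbols are skipped.
    """
    seq = sequence.upper()
    n = 0
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i:i + 3]
        if set(codon) <= _ACGT and codon in stops:
            n += 1
    return n


def qc_record(record: BarcodeRecord | str,
              min_len: int = DEFAULT_MIN_LENGTH,
              max_len: int = BARCODE_LENGTH,
              stops: frozenset[str] = VERTEBRATE_MITO_STOPS) -> QCResult:
    """Screen a barcode sequence for stop codons, indels and length.

    The reading frame is the one (of 0/1/2) minimising the stop-codon count,
    ties resolving to the lowest index.  A sequence passes when that minimum
    is zero, the length lies within ``[min_len, max_len]``, there is no
    internal gap character (the operational reading of "no insertions or
    deletions") and fewer than half of the symbols are ambiguous.
    """
    seq = (record.sequence if isinstance(record, BarcodeRecord) else record).upper()
    ambiguous = sum(1 for c in seq if c not in _ACGT)
    amb_frac = ambiguous / len(seq)
    length_ok = min_len <= len(seq) <= max_len

    if amb_frac > 0.5:
        return QCResult(False, None, 0, length_ok, amb_frac, "excess_ambiguity")

    stops_per_frame = [count_stop_codons(seq, f, stops) for f in (0, 1, 2)]
    best = min(stops_per_frame)
    frame = stops_per_frame.index(best)

    reason = ""
    if best > 0:
        reason = "stop_codons"
    elif "-" in seq:
        reason = "internal_gaps"
    elif not length_ok:
        reason = "length"
    passed = reason == ""
    return QCResult(passed, frame, best, length_ok, amb_frac, reason)


@dataclass
class BarcodeLibrary:
    """Ordered collection of barcode records with a taxonomy index."""

    records: list[BarcodeRecord] = field(default_factory=list)
    rejected: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.specimen_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise BarcodeError(f"duplicate specimen ids: {dup}")
        self._by_id = {r.specimen_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[BarcodeRecord]:
        return iter(self.records)

    def __getitem__(self, specimen_id: str) -> BarcodeRecord:
        return self._by_id[specimen_id]

    def __contains__(self, specimen_id: str) -> bool:
        return specimen_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [r.specimen_id for r in self.records]

    @property
    def species(self) -> list[str]:
        return sorted({r.species for r in self.records})

    @property
    def taxonomy_index(self) -> dict[str, tuple[str, str, str]]:
        """species -> (genus, family, order)."""
        return {r.species: (r.genus, r.family, r.order) for r in self.records}

    def subset(self, ids: Iterable[str]) -> "BarcodeLibrary":
        keep = set(ids)
        return BarcodeLibrary([r for r in self.records if r.specimen_id in keep])

    def by_role(self, role: str) -> "BarcodeLibrary":
        return BarcodeLibrary([r for r in self.records if r.role == role])

    def references(self) -> "BarcodeLibrary":
        return self.by_role("reference")

    def queries(self) -> "BarcodeLibrary":
        return self.by_role("query")

    def qc_passed(self) -> "BarcodeLibrary":
        return BarcodeLibrary(
            [r for r in self.records if r.qc is not None and r.qc.passed]
        )

    def species_map(self) -> dict[str, str]:
        """specimen id -> species name."""
        return {r.specimen_id: r.species for r in self.records}

    def region_map(self) -> dict[str, str]:
        return {r.specimen_id: r.region for r in self.records}

    def metadata_frame(self) -> pd.DataFrame:
        rows = [
            {
                "specimen_id": r.specimen_id,
                "species": r.species,
                "genus": r.genus,
                "family": r.family,
                "order": r.order,
                "region": r.region,
                "role": r.role,
                "grade": r.grade,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=METADATA_COLUMNS)

    def stripped(self) -> "BarcodeLibrary":
        """Copy with taxonomic labels removed (blind-assignment protocol)."""
        blank = [
            replace(r, species="", genus="", family="", order="")
            for r in self.records
        ]
        return BarcodeLibrary(blank)


def read_library(fasta_path: str | Path, metadata_path: str | Path,
                 min_len: int = DEFAULT_MIN_LENGTH,
                 max_len: int = BARCODE_LENGTH) -> BarcodeLibrary:
    """Read a FASTA + metadata TSV pair into a :class:`BarcodeLibrary`.

    Every FASTA id must resolve to exactly one metadata row; sequences whose
    id is absent from the table are rejected (and listed on
    ``library.rejected``), while duplicate ids are a hard error.  QC is
    computed for every accepted record.
    """
    fasta_path, metadata_path = Path(fasta_path), Path(metadata_path)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str).fillna("")
    missing_cols = set(METADATA_COLUMNS[:7]) - set(meta.columns)
    if missing_cols:
        raise BarcodeError(f"metadata missing columns: {sorted(missing_cols)}")
    if meta["specimen_id"].duplicated().any():
        dup = meta.loc[meta["specimen_id"].duplicated(), "specimen_id"].tolist()
        raise BarcodeError(f"duplicate metadata ids: {dup}")
    meta_by_id = meta.set_index("specimen_id")

    records: list[BarcodeRecord] = []
    rejected: list[str] = []
    seen: set[str] = set()
    for seq_rec in SeqIO.parse(str(fasta_path), "fasta"):
        sid = seq_rec.id
        if sid in seen:
            raise BarcodeError(f"duplicate FASTA id: {sid}")
        seen.add(sid)
        if sid not in meta_by_id.index:
            logger.warning("no metadata row for %s: record rejected", sid)
            rejected.append(sid)
            continue
        row = meta_by_id.loc[sid]
        rec = BarcodeRecord(
            specimen_id=sid,
            sequence=str(seq_rec.seq),
            species=row["species"],
            genus=row["genus"],
            family=row["family"],
            order=row["order"],
            region=row["region"] or "OTHER",
            role=row["role"] or "reference",
            grade=(row.get("grade", "") or "ungraded"),
        )
        rec.qc = qc_record(rec, min_len=min_len, max_len=max_len)
        records.append(rec)

    lib = BarcodeLibrary(records)
    lib.rejected = rejected
    return lib


def write_library(library: BarcodeLibrary, out_dir: str | Path,
                  stem: str = "library") -> tuple[Path, Path]:
    """Write a library as ``<stem>.fasta`` + ``<stem>.tsv`` under ``out_dir``.

    The pair round-trips through :func:`read_library` to an equal record set.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta_path = out_dir / f"{stem}.fasta"
    tsv_path = out_dir / f"{stem}.tsv"

    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.specimen_id, description="")
        for r in library.records
    ]
    SeqIO.write(seq_records, str(fasta_path), "fasta")
    library.metadata_frame().to_csv(tsv_path, sep="\t", index=False)
    return fasta_path, tsv_path
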