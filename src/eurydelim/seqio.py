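"""Alignment I/O, validation, site-class statistics, coding-sequence screening,
and multi-marker concatenation.

Aligned DNA sequences are held in :class:`Alignment`; specimen metadata
(locality, basin, coordinates, depth, multiplicity, per-marker accessions) in
:class:`SpecimenTable`, a thin wrapper over a pandas DataFrame whose TSV
dialect uses ``n.d.`` for missing values.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "SequenceRecord",
    "Alignment",
    "SpecimenTable",
    "SiteClassCounts",
    "PseudogeneReport",
    "AlignmentError",
    "read_fasta",
    "write_fasta",
    "read_metadata",
    "write_metadata",
    "count_site_classes",
    "check_coding",
    "concatenate",
]

#: Unambiguous nucleotide states.
BASES = "ACGT"
#: IUPAC ambiguity codes (everything that is neither an unambiguous base nor a gap).
AMBIGUITY_CODES = set("RYSWKMBDHVN")
#: Full residue alphabet accepted on input.
ALPHABET = set(BASES) | AMBIGUITY_CODES | {"-"}

MISSING = "n.d."


class AlignmentError(ValueError):
    """Raised when sequences violate alignment invariants."""


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned sequence: specimen id, marker label, uppercase residues."""

    id: str
    marker: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise AlignmentError("sequence record with empty id")
        if not self.residues:
            raise AlignmentError(f"sequence {self.id!r} has no residues")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise AlignmentError(
                f"sequence {self.id!r} contains non-IUPAC residues: {sorted(bad)}"
            )


@dataclass(frozen=True)
class Alignment:
    """An ordered set of equal-length sequences for one marker."""

    records: tuple[SequenceRecord, ...]
    marker: str = ""

    def __post_init__(self):
        if not self.records:
            raise AlignmentError("empty alignment")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) > 1:
            by_len: dict[int, list[str]] = {}
            for r in self.records:
                by_len.setdefault(len(r.residues), []).append(r.id)
            raise AlignmentError(f"unequal sequence lengths: {by_len}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dupes}")
        markers = {r.marker for r in self.records}
        if len(markers) > 1:
            raise AlignmentError(f"mixed markers in one alignment: {sorted(markers)}")

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def n_columns(self) -> int:
        return len(self.records[0].residues)

    def __len__(self) -> int:
        return len(self.records)

    def sequence(self, seq_id: str) -> str:
        for r in self.records:
            if r.id == seq_id:
                return r.residues
        raise KeyError(seq_id)

    def to_matrix(self) -> np.ndarray:
        """Residues as a (n, L) byte matrix of ASCII codes."""
        return np.frombuffer(
            "".join(r.residues for r in self.records).encode(), dtype=np.uint8
        ).reshape(len(self.records), self.n_columns)

    def subset(self, ids) -> "Alignment":
        wanted = set(ids)
        recs = tuple(r for r in self.records if r.id in wanted)
        return Alignment(recs, marker=self.marker)


def _make_alignment(records, marker):
    recs = tuple(
        SequenceRecord(r.id, marker, str(r.seq).upper(), r.description)
        for r in records
    )
    if not recs:
        raise AlignmentError("empty FASTA file")
    return Alignment(recs, marker=marker)


def read_fasta(path, marker_label: str = "") -> Alignment:
    """Read an aligned FASTA file; residues are uppercased, order preserved."""
    return _make_alignment(list(SeqIO.parse(str(path), "fasta")), marker_label)


def read_fasta_string(text: str, marker_label: str = "") -> Alignment:
    return _make_alignment(list(SeqIO.parse(io.StringIO(text), "fasta")), marker_label)


def write_fasta(aln: Alignment, path, wrap: int = 80) -> None:
    """Write FASTA with ids verbatim, wrapped at `wrap` columns."""
    with open(path, "w") as fh:
        for r in aln.records:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.residues), wrap):
                fh.write(r.residues[i : i + wrap] + "\n")


METADATA_COLUMNS = [
    "id", "locality", "basin", "lat", "lon", "depth_m",
    "source", "multiplicity", "acc_coi", "acc_16s", "acc_28s",
]


@dataclass
class SpecimenTable:
    """Specimen metadata table.

    Columns follow the TSV dialect
    ``id locality basin lat lon depth_m source multiplicity acc_*``; depth is
    metres, positive downward; ``multiplicity`` counts the number of specimens
    a row represents (several deposited haplotypes stand for many specimens).
    """

    df: pd.DataFrame

    def __post_init__(self):
        if "id" not in self.df.columns:
            raise ValueError("metadata table lacks an 'id' column")
        if self.df["id"].duplicated().any():
            dupes = sorted(self.df.loc[self.df["id"].duplicated(), "id"])
            raise ValueError(f"duplicate specimen ids: {dupes}")
        if "multiplicity" not in self.df.columns:
            self.df["multiplicity"] = 1
        self.df["multiplicity"] = self.df["multiplicity"].fillna(1).astype(int)
        if (self.df["multiplicity"] < 1).any():
            raise ValueError("multiplicity must be >= 1")
        if "depth_m" in self.df.columns:
            depths = pd.to_numeric(self.df["depth_m"], errors="coerce")
            if (depths.dropna() <= 0).any():
                bad = sorted(self.df.loc[depths <= 0, "id"])
                raise ValueError(f"non-positive depths for: {bad}")
            self.df["depth_m"] = depths
        self.df = self.df.set_index("id", drop=False)

    @property
    def ids(self) -> list[str]:
        return list(self.df["id"])

    def depth(self, specimen_id: str) -> float | None:
        if "depth_m" not in self.df.columns:
            return None
        v = self.df.loc[specimen_id, "depth_m"]
        return None if pd.isna(v) else float(v)

    def multiplicity(self, specimen_id: str) -> int:
        return int(self.df.loc[specimen_id, "multiplicity"])

    def group_value(self, specimen_id: str, column: str):
        if column not in self.df.columns:
            return None
        v = self.df.loc[specimen_id, column]
        return None if pd.isna(v) else v


def read_metadata(path) -> SpecimenTable:
    """Read the tab-separated specimen table; ``n.d.`` parses as missing."""
    df = pd.read_csv(path, sep="\t", na_values=[MISSING], dtype={"id": str})
    return SpecimenTable(df)


def write_metadata(table: SpecimenTable, path) -> None:
    df = table.df.reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING)


@dataclass(frozen=True)
class SiteClassCounts:
    """Per-column classification of an alignment.

    A column is classified on its unambiguous bases (A/C/G/T) only: *variable*
    if at least two distinct bases occur, *parsimony-informative* if at least
    two distinct bases each occur in at least two sequences, *singleton* if
    variable but not informative. Columns with fewer than two distinct
    unambiguous bases (including all-gap columns) count as constant.
    """

    n_sites: int
    n_constant: int
    n_variable: int
    n_singleton: int
    n_parsimony_informative: int


def count_site_classes(aln: Alignment) -> SiteClassCounts:
    if len(aln) < 2:
        raise AlignmentError("site classification needs at least 2 sequences")
    mat = aln.to_matrix()
    n_var = n_inf = n_single = 0
    base_codes = np.frombuffer(BASES.encode(), dtype=np.uint8)
    for col in mat.T:
        counts = [(col == b).sum() for b in base_codes]
        present = [c for c in counts if c > 0]
        if len(present) >= 2:
            n_var += 1
            if sum(c >= 2 for c in present) >= 2:
                n_inf += 1
            else:
                n_single += 1
    n_sites = aln.n_columns
    return SiteClassCounts(
        n_sites=n_sites,
        n_constant=n_sites - n_var,
        n_variable=n_var,
        n_singleton=n_single,
        n_parsimony_informative=n_inf,
    )


@dataclass(frozen=True)
class PseudogeneReport:
    """Stop-codon screen of a protein-coding alignment (one row per sequence)."""

    marker: str
    code_table: int
    frame: int
    rows: tuple[dict, ...]  # id, frame, has_internal_stop, n_ambiguous_calls

    @property
    def any_internal_stop(self) -> bool:
        return any(r["has_internal_stop"] for r in self.rows)


def _count_stops(residues: str, frame: int, table: CodonTable.CodonTable) -> int:
    coding = residues[frame:].replace("-", "")
    coding = coding[: len(coding) - len(coding) % 3]
    aa = str(Seq(coding).translate(table=table.id))
    return aa[:-1].count("*")  # terminal position is allowed to be a stop


def check_coding(aln: Alignment, code_table: int = 5, frame: int | None = None) -> PseudogeneReport:
    """Screen a coding alignment for internal stop codons.

    ``code_table`` is an NCBI translation-table number (default 5, the
    invertebrate mitochondrial code, appropriate for arthropod COI). When
    ``frame`` is None the reading frame (0/1/2) minimising the total number of
    internal stops across all sequences is chosen.
    """
    if frame is not None and frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    table = CodonTable.unambiguous_dna_by_id[code_table]
    if frame is None:
        totals = {
            f: sum(_count_stops(r.residues, f, table) for r in aln.records)
            for f in (0, 1, 2)
        }
        frame = min(totals, key=lambda f: (totals[f], f))
    rows = []
    for r in aln.records:
        n_stops = _count_stops(r.residues, frame, table)
        n_ambig = sum(r.residues.count(c) for c in AMBIGUITY_CODES)
        rows.append(
            {
                "id": r.id,
                "frame": frame,
                "has_internal_stop": n_stops > 0,
                "n_internal_stops": n_stops,
                "n_ambiguous_calls": n_ambig,
            }
        )
    return PseudogeneReport(aln.marker, code_table, frame, tuple(rows))


@dataclass(frozen=True)
class ConcatenatedAlignment:
    """Alignment plus provenance: which output columns came from which marker."""

    alignment: Alignment
    blocks: tuple[tuple[str, int, int], ...]  # (marker, start, stop) half-open

    def column_marker(self, column: int) -> str:
        for marker, start, stop in self.blocks:
            if start <= column < stop:
                return marker
        raise IndexError(column)


def concatenate(alignments, join_policy: str = "drop", missing_char: str = "N") -> ConcatenatedAlignment:
    """Concatenate per-marker alignments by shared specimen id.

    ``join_policy='drop'`` keeps only specimens present in every marker (the
    combined analysis of the study uses fully sequenced specimens only);
    ``'pad'`` keeps all specimens and fills absent markers with
    ``missing_char``.
    """
    alignments = list(alignments)
    if not alignments:
        raise AlignmentError("no alignments to concatenate")
    if join_policy not in ("drop", "pad"):
        raise ValueError(f"unknown join_policy {join_policy!r}")
    id_sets = [set(a.ids) for a in alignments]
    if join_policy == "drop":
        keep = set.intersection(*id_sets)
        if not keep:
            raise AlignmentError("no specimen id shared by all markers")
    else:
        keep = set.union(*id_sets)
    # order: first alignment's order, then new ids in order of appearance
    ordered: list[str] = []
    for a in alignments:
        for i in a.ids:
            if i in keep and i not in ordered:
                ordered.append(i)
    blocks = []
    start = 0
    parts: dict[str, list[str]] = {i: [] for i in ordered}
    for a in alignments:
        lookup = {r.id: r.residues for r in a.records}
        for i in ordered:
            parts[i].append(lookup.get(i, missing_char * a.n_columns))
        blocks.append((a.marker, start, start + a.n_columns))
        start += a.n_columns
    marker = "+".join(a.marker or "?" for a in alignments)
    recs = tuple(
        SequenceRecord(i, marker, "".join(parts[i])) for i in ordered
    )
    return ConcatenatedAlignment(Alignment(recs, marker=marker), tuple(blocks))
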