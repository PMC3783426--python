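"""Haplotype collapsing, multiplicity expansion, and sharing reports.

Specimens with byte-identical aligned sequences share a haplotype; a gap is a
state, while sequences containing ambiguity codes are conservatively kept
distinct (an N may hide either a match or a mismatch) and flagged with a
warning. Deposited haplotypes that stand for several sampled specimens carry a
multiplicity in the metadata table, so haplotype frequencies can be
reconstructed without duplicating sequence records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .seqio import AMBIGUITY_CODES, Alignment, SequenceRecord, SpecimenTable

__all__ = ["Haplotype", "HaplotypeTable", "collapse", "expand_multiplicities", "shared_haplotypes"]


@dataclass(frozen=True)
class Haplotype:
    label: str
    residues: str
    members: tuple[str, ...]
    total_multiplicity: int


@dataclass(frozen=True)
class HaplotypeTable:
    """Unique haplotypes with their member specimens and total multiplicity."""

    haplotypes: tuple[Haplotype, ...]
    marker: str = ""

    def __len__(self) -> int:
        return len(self.haplotypes)

    @property
    def labels(self) -> list[str]:
        return [h.label for h in self.haplotypes]

    def by_label(self, label: str) -> Haplotype:
        for h in self.haplotypes:
            if h.label == label:
                return h
        raise KeyError(label)

    def member_haplotype(self, specimen_id: str) -> Haplotype:
        for h in self.haplotypes:
            if specimen_id in h.members:
                return h
        raise KeyError(specimen_id)

    @property
    def total_multiplicity(self) -> int:
        return sum(h.total_multiplicity for h in self.haplotypes)

    def to_alignment(self) -> Alignment:
        """Representative sequences as an alignment keyed by haplotype label."""
        recs = tuple(
            SequenceRecord(h.label, self.marker, h.residues) for h in self.haplotypes
        )
        return Alignment(recs, marker=self.marker)

    def to_tsv(self, path) -> None:
        rows = [
            {
                "haplotype": h.label,
                "representative": h.residues,
                "members": ",".join(h.members),
                "total": h.total_multiplicity,
            }
            for h in self.haplotypes
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _label_and_sort(groups: list[tuple[str, list[str], int]]) -> tuple[Haplotype, ...]:
    # order: descending total multiplicity, ties by smallest member id
    ordered = sorted(groups, key=lambda g: (-g[2], min(g[1])))
    width = max(2, len(str(len(ordered))))
    return tuple(
        Haplotype(f"H{k:0{width}d}", residues, tuple(sorted(members)), total)
        for k, (residues, members, total) in enumerate(ordered, start=1)
    )


def collapse(aln: Alignment, table: SpecimenTable | None = None) -> HaplotypeTable:
    """Collapse identical aligned sequences into unique haplotypes.

    Identity is exact string equality over all columns. Sequences containing
    IUPAC ambiguity codes never merge (not even with an identical string) and
    trigger a warning. Labels ``H01, H02, ...`` are assigned by descending
    total multiplicity, ties broken by the smallest member id, so the result
    is invariant to input order.
    """
    def mult(i: str) -> int:
        if table is None or i not in table.df.index:
            return 1
        return table.multiplicity(i)

    buckets: dict[str, list[str]] = {}
    singletons: list[tuple[str, list[str], int]] = []
    ambiguous_ids = []
    for r in sorted(aln.records, key=lambda r: r.id):
        if set(r.residues) & AMBIGUITY_CODES:
            ambiguous_ids.append(r.id)
            singletons.append((r.residues, [r.id], mult(r.id)))
        else:
            buckets.setdefault(r.residues, []).append(r.id)
    if ambiguous_ids:
        warnings.warn(
            "sequences with ambiguity codes kept as distinct haplotypes: "
            + ", ".join(ambiguous_ids)
        )
    groups = [
        (res, members, sum(mult(m) for m in members))
        for res, members in buckets.items()
    ] + singletons
    return HaplotypeTable(_label_and_sort(groups), marker=aln.marker)


def expand_multiplicities(table: HaplotypeTable, metadata: SpecimenTable) -> HaplotypeTable:
    """Recompute total multiplicities from the metadata table.

    Sequence content and membership are unchanged; labels are reassigned under
    the same ordering rule because totals may change.
    """
    groups = []
    for h in table.haplotypes:
        total = 0
        for m in h.members:
            mult = metadata.multiplicity(m)
            if mult < 1:
                raise ValueError(f"multiplicity < 1 for specimen {m}")
            total += mult
        groups.append((h.residues, list(h.members), total))
    return HaplotypeTable(_label_and_sort(groups), marker=table.marker)


def shared_haplotypes(
    table: HaplotypeTable,
    metadata: SpecimenTable,
    group_by: str = "basin",
    depth_cut: float = 3000.0,
) -> list[dict]:
    """Haplotypes whose members span at least two groups.

    ``group_by`` is a metadata column name, or ``'depth_stratum'`` to group by
    bathyal (< depth_cut) vs abyssal (>= depth_cut). Members with a missing
    group value are excluded with a warning.
    """
    out = []
    for h in table.haplotypes:
        groups = set()
        for m in h.members:
            if m not in metadata.df.index:
                warnings.warn(f"specimen {m} missing from metadata; excluded")
                continue
            if group_by == "depth_stratum":
                d = metadata.depth(m)
                if d is None:
                    warnings.warn(f"specimen {m} lacks a depth; excluded")
                    continue
                groups.add("bathyal" if d < depth_cut else "abyssal")
            else:
                v = metadata.group_value(m, group_by)
                if v is None:
                    warnings.warn(f"specimen {m} lacks {group_by!r}; excluded")
                    continue
                groups.add(v)
        if len(groups) >= 2:
            out.append({"haplotype": h.label, "groups": sorted(groups)})
    return out
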