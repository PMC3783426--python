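"""Distance-based species-delimitation decisions.

Given a pairwise divergence matrix and a partition of specimens into putative
clades, this module answers the questions a barcoding survey asks: is there a
barcoding gap (an empty interval between the largest within-clade and the
smallest between-clade distance)?  Do all clade pairs satisfy the 4x rule
(minimum between-clade distance strictly greater than four times the larger of
the two within-clade maxima)?  Does some depth threshold cleanly separate the
clades into bathyal and abyssal sets?
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distances import DistanceMatrix
from .seqio import SpecimenTable

__all__ = [
    "Partition",
    "GapReport",
    "FourXReport",
    "DepthBreakReport",
    "barcoding_gap",
    "four_x",
    "threshold_clusters",
    "merge_clades",
    "compare_partitions",
    "depth_break",
    "detect_distance_gap",
]


@dataclass(frozen=True)
class Partition:
    """Total assignment of specimen ids to clade labels."""

    assignment: tuple[tuple[str, str], ...]  # (id, clade)

    @classmethod
    def from_dict(cls, mapping: dict) -> "Partition":
        return cls(tuple(sorted(mapping.items())))

    @property
    def mapping(self) -> dict:
        return dict(self.assignment)

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.assignment]

    @property
    def clades(self) -> list[str]:
        seen = []
        for _, c in self.assignment:
            if c not in seen:
                seen.append(c)
        return sorted(seen)

    def clade_of(self, specimen_id: str) -> str:
        return self.mapping[specimen_id]

    def members(self, clade: str) -> list[str]:
        return [i for i, c in self.assignment if c == clade]

    def labels_for(self, ids) -> list[str]:
        m = self.mapping
        missing = [i for i in ids if i not in m]
        if missing:
            raise KeyError(f"ids without clade assignment: {missing}")
        return [m[i] for i in ids]

    def restrict(self, ids) -> "Partition":
        wanted = set(ids)
        return Partition(tuple((i, c) for i, c in self.assignment if i in wanted))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.assignment, columns=["id", "clade"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def read_tsv(cls, path) -> "Partition":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls.from_dict(dict(zip(df["id"], df["clade"])))


def _pair_classes(dm: DistanceMatrix, partition: Partition):
    labels = partition.labels_for(dm.ids)
    v = dm.values
    intra, inter = [], []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            (intra if labels[i] == labels[j] else inter).append(v[i, j])
    return np.asarray(intra), np.asarray(inter)


@dataclass(frozen=True)
class GapReport:
    """Barcoding-gap test outcome.

    `status` is 'present', 'absent', or 'undecidable' (no within-clade pairs,
    e.g. all clades are singletons).
    """

    max_intra: float | None
    min_inter: float | None
    status: str

    @property
    def gap_present(self) -> bool:
        return self.status == "present"

    @property
    def gap_interval(self) -> tuple[float, float] | None:
        if self.gap_present:
            return (self.max_intra, self.min_inter)
        return None


def barcoding_gap(dm: DistanceMatrix, partition: Partition) -> GapReport:
    """Test for a gap between the largest intra- and smallest inter-clade distance."""
    if len(partition.clades) < 2:
        raise ValueError("barcoding gap needs at least 2 clades")
    intra, inter = _pair_classes(dm, partition)
    min_inter = float(inter.min()) if inter.size else None
    if intra.size == 0:
        return GapReport(None, min_inter, "undecidable")
    max_intra = float(intra.max())
    status = "present" if min_inter > max_intra else "absent"
    return GapReport(max_intra, min_inter, status)


@dataclass(frozen=True)
class FourXReport:
    """Pairwise 4x-rule outcomes.

    One row per unordered clade pair: the minimum between-pair distance, the
    larger of the two within-clade maxima (0 for singletons), their ratio, and
    a strict `min_inter > 4 * max_intra` pass flag.
    """

    pairs: tuple[dict, ...]

    @property
    def global_pass(self) -> bool:
        return all(p["pass"] for p in self.pairs)

    def pair(self, a: str, b: str) -> dict:
        key = frozenset((a, b))
        for p in self.pairs:
            if frozenset((p["clade_a"], p["clade_b"])) == key:
                return p
        raise KeyError((a, b))


def four_x(dm: DistanceMatrix, partition: Partition) -> FourXReport:
    """Apply the 4x criterion to every clade pair (strict inequality)."""
    labels = partition.labels_for(dm.ids)
    clades = partition.clades
    v = dm.values
    idx = {c: [k for k, l in enumerate(labels) if l == c] for c in clades}
    max_intra = {}
    for c, members in idx.items():
        if len(members) < 2:
            max_intra[c] = 0.0
        else:
            sub = v[np.ix_(members, members)]
            max_intra[c] = float(sub.max())
    pairs = []
    for a_i, a in enumerate(clades):
        for b in clades[a_i + 1:]:
            between = v[np.ix_(idx[a], idx[b])]
            min_inter = float(between.min())
            mi = max(max_intra[a], max_intra[b])
            ratio = float("inf") if mi == 0 and min_inter > 0 else (
                float("nan") if mi == 0 else min_inter / mi
            )
            pairs.append(
                {
                    "clade_a": a,
                    "clade_b": b,
                    "min_inter": min_inter,
                    "max_intra": mi,
                    "ratio": ratio,
                    "pass": min_inter > 4.0 * mi,
                }
            )
    return FourXReport(tuple(pairs))


def threshold_clusters(dm: DistanceMatrix, threshold: float) -> Partition:
    """Single-linkage clusters: connected components of the d <= t graph.

    Cluster labels are ``C1, C2, ...`` ordered by decreasing size, ties broken
    by the smallest member id.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    adj = csr_matrix(dm.values <= threshold)
    n_comp, comp = connected_components(adj, directed=False)
    groups: dict[int, list[str]] = {}
    for seq_id, c in zip(dm.ids, comp):
        groups.setdefault(int(c), []).append(seq_id)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), min(g)))
    mapping = {}
    for k, members in enumerate(ordered, start=1):
        for m in members:
            mapping[m] = f"C{k}"
    return Partition.from_dict(mapping)


def merge_clades(partition: Partition, labels_to_merge, new_label: str | None = None) -> Partition:
    """Relabel the given clades as one; all other clades untouched."""
    labels_to_merge = list(labels_to_merge)
    unknown = [l for l in labels_to_merge if l not in partition.clades]
    if unknown:
        raise KeyError(f"unknown clade labels: {unknown}")
    if new_label is None:
        new_label = "+".join(sorted(labels_to_merge))
    merged = set(labels_to_merge)
    return Partition(
        tuple((i, new_label if c in merged else c) for i, c in partition.assignment)
    )


def compare_partitions(p_a: Partition, p_b: Partition) -> dict:
    """Co-membership comparison of two partitions on their shared ids.

    Returns a relation in {'equal', 'a_refines_b', 'b_refines_a', 'conflict'}
    and the list of id pairs grouped in one partition but split in the other.
    """
    shared = sorted(set(p_a.ids) & set(p_b.ids))
    if not shared:
        raise ValueError("partitions share no ids")
    a = p_a.mapping
    b = p_b.mapping
    split_in_b = []  # together in a, apart in b
    split_in_a = []
    for i, x in enumerate(shared):
        for y in shared[i + 1:]:
            same_a = a[x] == a[y]
            same_b = b[x] == b[y]
            if same_a and not same_b:
                split_in_b.append((x, y))
            elif same_b and not same_a:
                split_in_a.append((x, y))
    if not split_in_a and not split_in_b:
        relation = "equal"
    elif not split_in_a:
        relation = "b_refines_a"  # b splits nothing; a groups pairs b splits
    elif not split_in_b:
        relation = "a_refines_b"
    else:
        relation = "conflict"
    return {
        "relation": relation,
        "n_shared": len(shared),
        "pairs_split_only_in_a": split_in_a,
        "pairs_split_only_in_b": split_in_b,
    }


@dataclass(frozen=True)
class DepthBreakReport:
    """Bathymetric-break scan outcome.

    `interval` is the widest open depth interval (d_lo, d_hi) in metres such
    that every cut inside it separates the clades into disjoint shallow/deep
    sets; None when no cut works. `clade_depth_ranges` maps clade -> (min
    depth, max depth); `violations` maps each failing candidate cut to the
    clades spanning it.
    """

    interval: tuple[float, float] | None
    clade_depth_ranges: dict
    violations: dict
    status: str  # 'break', 'no-break', 'degenerate'

    @property
    def break_found(self) -> bool:
        return self.status == "break"


def depth_break(partition: Partition, metadata: SpecimenTable, thresholds=None) -> DepthBreakReport:
    """Scan depth cuts for one separating all clades into above/below sets.

    Candidate cuts default to midpoints between consecutive distinct specimen
    depths. A clade spans a cut iff it has members strictly above and strictly
    below it; ids without depth are excluded with a warning.
    """
    depths = {}
    for i in partition.ids:
        d = metadata.depth(i) if i in metadata.df.index else None
        if d is None:
            warnings.warn(f"specimen {i} lacks a depth; excluded from depth-break scan")
        else:
            depths[i] = d
    ranges = {}
    for clade in partition.clades:
        vals = [depths[m] for m in partition.members(clade) if m in depths]
        if vals:
            ranges[clade] = (min(vals), max(vals))
    if len(ranges) <= 1:
        return DepthBreakReport(None, ranges, {}, "degenerate")
    distinct = sorted({d for d in depths.values()})
    if len(distinct) < 2:
        return DepthBreakReport(None, ranges, {}, "no-break")
    if thresholds is None:
        thresholds = [(a + b) / 2 for a, b in zip(distinct, distinct[1:])]
    thresholds = sorted(thresholds)
    valid = []
    violations = {}
    for t in thresholds:
        spanning = [c for c, (lo, hi) in ranges.items() if lo < t < hi]
        if spanning:
            violations[t] = spanning
        else:
            valid.append(t)
    if not valid:
        return DepthBreakReport(None, ranges, violations, "no-break")
    # widest depth interval bracketing a maximal run of valid cuts
    best = None
    for t in valid:
        lo = max((hi for (_, hi) in ranges.values() if hi < t), default=None)
        hi = min((lo_ for (lo_, _) in ranges.values() if lo_ > t), default=None)
        if lo is None or hi is None:
            continue
        if best is None or (hi - lo) > (best[1] - best[0]):
            best = (lo, hi)
    if best is None:
        # valid cuts exist only outside all clade ranges (everything same side)
        return DepthBreakReport(None, ranges, violations, "no-break")
    return DepthBreakReport(best, ranges, violations, "break")


def detect_distance_gap(dm: DistanceMatrix) -> float | None:
    """Midpoint of the widest empty interval in the pairwise-distance distribution.

    A de novo threshold proposal when no clade labels are supplied: sort all
    pairwise distances and return the midpoint of the largest gap between
    consecutive values. None when fewer than two distinct distances exist.
    """
    iu = np.triu_indices(len(dm.ids), k=1)
    vals = np.unique(dm.values[iu])
    if len(vals) < 2:
        return None
    gaps = np.diff(vals)
    k = int(np.argmax(gaps))
    return float((vals[k] + vals[k + 1]) / 2)
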