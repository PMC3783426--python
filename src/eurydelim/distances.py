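"""Pairwise sequence divergences and clade-level summaries.

The workhorse is the Kimura two-parameter (K2P) distance

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

with P and Q the proportions of transitional (A<->G, C<->T) and transversional
differences over the sites where both sequences carry an unambiguous base
(pairwise deletion). An uncorrected p-distance is provided for comparison;
`intra_inter_summary` produces the within/between-clade range-and-mean tables
used for barcoding-gap style species delimitation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .seqio import Alignment

__all__ = [
    "SubstitutionCounts",
    "DistanceMatrix",
    "CladeDivergenceTable",
    "SaturationError",
    "count_substitutions",
    "k2p",
    "p_distance",
    "distance_matrix",
    "intra_inter_summary",
]

_A, _C, _G, _T = (ord(b) for b in "ACGT")


class SaturationError(ValueError):
    """K2P distance undefined: substitution saturation (log argument <= 0)."""


@dataclass(frozen=True)
class SubstitutionCounts:
    """Transition/transversion tallies for one sequence pair.

    `n_compared` counts sites where both residues are unambiguous bases;
    P = transitions / n_compared, Q = transversions / n_compared.
    """

    n_compared: int
    n_transitions: int
    n_transversions: int

    @property
    def P(self) -> float:
        return self.n_transitions / self.n_compared

    @property
    def Q(self) -> float:
        return self.n_transversions / self.n_compared


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _counts_from_codes(a: np.ndarray, b: np.ndarray) -> SubstitutionCounts:
    base = np.array([_A, _C, _G, _T], dtype=np.uint8)
    ok = np.isin(a, base) & np.isin(b, base)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no comparable sites (all gapped or ambiguous)")
    diff = ok & (a != b)
    purine_a = (a == _A) | (a == _G)
    purine_b = (b == _A) | (b == _G)
    ti = int((diff & (purine_a == purine_b)).sum())
    tv = int((diff & (purine_a != purine_b)).sum())
    return SubstitutionCounts(n, ti, tv)


def count_substitutions(a: str, b: str) -> SubstitutionCounts:
    """Tally transitions/transversions between two aligned sequences.

    Sites where either residue is a gap or an ambiguity code are excluded
    (pairwise deletion).
    """
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    return _counts_from_codes(_encode(a.upper()), _encode(b.upper()))


def k2p(counts: SubstitutionCounts) -> float:
    """Kimura two-parameter distance in substitutions/site."""
    P, Q = counts.P, counts.Q
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"distance undefined (saturated): P={P:.4f}, Q={Q:.4f}"
        )
    return -0.5 * math.log(w1 * math.sqrt(w2)) + 0.0  # normalise -0.0


def p_distance(counts: SubstitutionCounts) -> float:
    """Uncorrected proportion of differing comparable sites."""
    return (counts.n_transitions + counts.n_transversions) / counts.n_compared


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise divergence matrix with model and gap-policy tags."""

    ids: tuple[str, ...]
    values: np.ndarray
    model: str = "K2P"
    gap_policy: str = "pairwise-deletion"

    def __post_init__(self):
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(v, v.T, atol=0):
            raise ValueError("matrix is not exactly symmetric")
        if np.diag(v).any():
            raise ValueError("matrix diagonal must be zero")
        if not np.isfinite(v).all() or (v < 0).any():
            raise ValueError("matrix values must be finite and nonnegative")

    def index(self, seq_id: str) -> int:
        return self.ids.index(seq_id)

    def get(self, id_a: str, id_b: str) -> float:
        return float(self.values[self.index(id_a), self.index(id_b)])

    def submatrix(self, ids) -> "DistanceMatrix":
        idx = [self.index(i) for i in ids]
        return DistanceMatrix(
            tuple(ids), self.values[np.ix_(idx, idx)].copy(), self.model, self.gap_policy
        )

    def to_tsv(self, path) -> None:
        """Square TSV, ids in first row and column."""
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.ids) + "\n")
            for i, name in enumerate(self.ids):
                row = "\t".join(f"{v:.6f}" for v in self.values[i])
                fh.write(f"{name}\t{row}\n")

    def to_phylip(self, path) -> None:
        """PHYLIP square distance format."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, name in enumerate(self.ids):
                row = " ".join(f"{v:.6f}" for v in self.values[i])
                fh.write(f"{name:<10s} {row}\n")


def distance_matrix(aln: Alignment, model: str = "K2P", on_saturation: str = "error") -> DistanceMatrix:
    """All-pairs divergence matrix under `model` ('K2P' or 'p').

    Saturated pairs (K2P log argument <= 0) raise an aggregate
    :class:`SaturationError` naming every offending pair, or are masked with
    NaN replaced by the maximum finite distance when ``on_saturation='mask'``.
    """
    if len(aln) < 2:
        raise ValueError("distance matrix needs at least 2 sequences")
    if model not in ("K2P", "p"):
        raise ValueError(f"unknown model {model!r}")
    mat = aln.to_matrix()
    n = len(aln)
    out = np.zeros((n, n))
    saturated = []
    for i in range(n):
        for j in range(i + 1, n):
            counts = _counts_from_codes(mat[i], mat[j])
            if model == "p":
                d = p_distance(counts)
            else:
                try:
                    d = k2p(counts)
                except SaturationError:
                    saturated.append((aln.ids[i], aln.ids[j]))
                    d = np.nan
            out[i, j] = out[j, i] = d
    if saturated:
        if on_saturation == "error":
            raise SaturationError(f"saturated pairs: {saturated}")
        out[np.isnan(out)] = np.nanmax(out)
    return DistanceMatrix(tuple(aln.ids), out, model=model)


@dataclass(frozen=True)
class CladeDivergenceTable:
    """Range and mean of intra- and interclade distances, one row per clade.

    Intraclade statistics cover within-clade pairs (absent for singleton
    clades); interclade statistics pool the distances from clade members to
    all non-members. Means are unweighted over pairs.
    """

    rows: tuple[dict, ...]

    def row(self, clade: str) -> dict:
        for r in self.rows:
            if r["clade"] == clade:
                return r
        raise KeyError(clade)

    def to_records(self) -> list[dict]:
        return [dict(r) for r in self.rows]


def _stats(values) -> dict | None:
    if len(values) == 0:
        return None
    arr = np.asarray(values, dtype=float)
    return {"min": float(arr.min()), "max": float(arr.max()), "mean": float(arr.mean())}


def intra_inter_summary(dm: DistanceMatrix, partition) -> CladeDivergenceTable:
    """Per-clade intra/inter divergence summary (range-and-mean table)."""
    labels = partition.labels_for(dm.ids)
    rows = []
    ids = list(dm.ids)
    for clade in partition.clades:
        members = [i for i, l in zip(ids, labels) if l == clade]
        others = [i for i, l in zip(ids, labels) if l != clade]
        midx = [dm.index(i) for i in members]
        oidx = [dm.index(i) for i in others]
        intra = [
            dm.values[a, b] for k, a in enumerate(midx) for b in midx[k + 1:]
        ]
        inter = [dm.values[a, b] for a in midx for b in oidx]
        rows.append(
            {
                "clade": clade,
                "n_members": len(members),
                "intra": _stats(intra),
                "inter": _stats(inter),
            }
        )
    return CladeDivergenceTable(tuple(rows))
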