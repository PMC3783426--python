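"""Statistical-parsimony haplotype networks with a 95% connection limit.

Haplotypes are joined by single-substitution edges when their mutational
distance does not exceed the connection limit: the largest number of steps j
for which the estimated probability that j observed differences reflect
exactly j substitutions (no superimposed changes) still meets the probability
threshold. Gaps may be scored as a fifth character state or as missing data.

The parsimony probability is estimated under a symmetric finite-sites model:
per-site substitution counts are Poisson with intensity solved from the
observed fraction of differing sites, substitutions move among ``n_states``
equally exchangeable states, and

    P_parsimony(j) = Pr(exactly 1 change | site differs)^j
                     * Pr(0 changes | site identical)^(L - j).

This estimator is deterministic, decreases in j, and grows with sequence
length; a ``fixed_limit`` bypass is available when a limit from another tool
should be imposed instead.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import networkx as nx

from .haplotypes import HaplotypeTable
from .seqio import AMBIGUITY_CODES, SpecimenTable

__all__ = [
    "ConnectionLimit",
    "HaplotypeNetwork",
    "parsimony_probability",
    "connection_limit",
    "hap_distance",
    "build_networks",
    "network_summary",
]


def parsimony_probability(j: int, n_sites: int, n_states: int = 4) -> float:
    """Probability that j observed differences arose from exactly j substitutions.

    Equal-rate sites, symmetric ``n_states``-state substitution, per-site
    change counts Poisson with intensity matched to the observed difference
    fraction j/n_sites.
    """
    if j <= 0:
        return 1.0
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    s = n_states
    frac = j / n_sites
    ceiling = (s - 1) / s
    if frac >= ceiling:
        return 0.0
    lam = -ceiling * math.log1p(-frac / ceiling)
    p_differ = ceiling * (1.0 - math.exp(-lam / ceiling))
    p_same = 1.0 - p_differ
    p_one = lam * math.exp(-lam)  # a single change always alters the state
    p_zero = math.exp(-lam)
    return (p_one / p_differ) ** j * (p_zero / p_same) ** (n_sites - j)


@dataclass(frozen=True)
class ConnectionLimit:
    """Maximum number of mutational steps connectable at the given threshold."""

    j_max: int
    threshold: float
    n_sites: int
    probabilities: tuple[float, ...]  # P_parsimony(j) for j = 1 .. j_max + 1


def connection_limit(
    n_sites: int,
    threshold: float = 0.95,
    n_states: int = 4,
    fixed_limit: int | None = None,
) -> ConnectionLimit:
    """Largest j whose parsimony probability is at least `threshold`.

    ``fixed_limit`` bypasses the estimator and imposes the given number of
    steps (the probability curve is still reported for reference).
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    probs = []
    j = 0
    while True:
        p = parsimony_probability(j + 1, n_sites, n_states)
        probs.append(p)
        if p < threshold:
            break
        j += 1
        if j > n_sites:  # safety stop; cannot exceed the number of sites
            break
    j_max = fixed_limit if fixed_limit is not None else j
    if fixed_limit is not None:
        probs = [parsimony_probability(k, n_sites, n_states) for k in range(1, fixed_limit + 2)]
    return ConnectionLimit(j_max, threshold, n_sites, tuple(probs))


def hap_distance(a: str, b: str, gap_mode: str = "fifth_state") -> int:
    """Mutational steps between two aligned haplotypes.

    Under ``fifth_state`` a gap is an ordinary character state, so a gap
    opposite a base (or a different residue) counts as one step; under
    ``missing`` any site with a gap in either sequence is excluded. Sites with
    an ambiguity code in either sequence are always excluded.
    """
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    if gap_mode not in ("fifth_state", "missing"):
        raise ValueError(f"unknown gap_mode {gap_mode!r}")
    steps = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in AMBIGUITY_CODES or y in AMBIGUITY_CODES:
            continue
        if gap_mode == "missing" and ("-" in (x, y)):
            continue
        if x != y:
            steps += 1
    return steps


@dataclass
class HaplotypeNetwork:
    """One connected component of the statistical-parsimony graph.

    `graph` holds observed haplotypes as nodes (attributes: multiplicity,
    observed=True) plus unlabeled hypothetical intermediates subdividing
    multi-step edges; every edge then represents a single substitution.
    """

    component_id: int
    members: tuple[str, ...]  # observed haplotype labels
    graph: nx.Graph
    j_max: int

    @property
    def n_observed(self) -> int:
        return len(self.members)

    @property
    def is_singleton(self) -> bool:
        return self.n_observed == 1

    @property
    def total_multiplicity(self) -> int:
        return sum(
            d.get("multiplicity", 0)
            for _, d in self.graph.nodes(data=True)
            if d.get("observed")
        )

    def to_edge_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("from\tto\tsteps\n")
            for u, v in sorted(self.graph.edges()):
                fh.write(f"{u}\t{v}\t1\n")

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def _mutational_distances(table: HaplotypeTable, gap_mode: str):
    labels = table.labels
    seqs = {h.label: h.residues for h in table.haplotypes}
    dist = {}
    for a, b in itertools.combinations(sorted(labels), 2):
        dist[(a, b)] = hap_distance(seqs[a], seqs[b], gap_mode)
    return dist


def build_networks(
    table: HaplotypeTable,
    limit: ConnectionLimit | int,
    gap_mode: str = "fifth_state",
) -> list[HaplotypeNetwork]:
    """Assemble parsimony networks from collapsed haplotypes.

    Pairs are processed in order of increasing step distance (ties by label);
    an edge is retained when its endpoints are not already connected through
    strictly shorter edges, so all minimal alternative connections (loops) are
    kept. Edges of k > 1 steps are subdivided by k-1 hypothetical nodes.
    Components are returned sorted by decreasing observed size (ties by the
    smallest member label); singletons are one-node networks.
    """
    j_max = limit.j_max if isinstance(limit, ConnectionLimit) else int(limit)
    dist = _mutational_distances(table, gap_mode)
    mult = {h.label: h.total_multiplicity for h in table.haplotypes}

    backbone = nx.Graph()
    backbone.add_nodes_from(table.labels)
    edges = sorted(
        ((d, a, b) for (a, b), d in dist.items() if 0 < d <= j_max)
    )
    for d, group in itertools.groupby(edges, key=lambda e: e[0]):
        # connectivity snapshot from strictly shorter edges only, so that all
        # minimal alternative connections at this step count are retained
        reachable = {n: c for c in nx.connected_components(backbone) for n in c}
        for _, a, b in group:
            if reachable[a] is not reachable[b]:
                backbone.add_edge(a, b, steps=d)

    nets = []
    components = sorted(
        nx.connected_components(backbone), key=lambda c: (-len(c), min(c))
    )
    for cid, comp in enumerate(components, start=1):
        sub = backbone.subgraph(comp)
        g = nx.Graph()
        for n in comp:
            g.add_node(n, observed=True, multiplicity=mult[n])
        hyp = itertools.count(1)
        for a, b, data in sub.edges(data=True):
            k = data["steps"]
            if k == 1:
                g.add_edge(a, b)
            else:
                prev = a
                for _ in range(k - 1):
                    node = f"hyp{cid}.{next(hyp)}"
                    g.add_node(node, observed=False, multiplicity=0)
                    g.add_edge(prev, node)
                    prev = node
                g.add_edge(prev, b)
        nets.append(
            HaplotypeNetwork(cid, tuple(sorted(comp)), g, j_max)
        )
    return nets


def network_summary(
    networks: list[HaplotypeNetwork],
    table: HaplotypeTable,
    metadata: SpecimenTable,
    depth_cut: float = 3000.0,
) -> list[dict]:
    """Per-network membership summary with a bathyal/abyssal stratum call.

    Classification against ``depth_cut``: 'bathyal' when every member depth is
    above (shallower than) the cut, 'abyssal' when every depth is below,
    'spans cut' otherwise, 'unknown' if no member has a depth.
    """
    out = []
    for net in networks:
        specimens = [m for h in net.members for m in table.by_label(h).members]
        basins = set()
        depths = []
        for s in specimens:
            if s not in metadata.df.index:
                warnings.warn(f"specimen {s} missing from metadata; excluded")
                continue
            b = metadata.group_value(s, "basin")
            if b is not None:
                basins.add(b)
            d = metadata.depth(s)
            if d is None:
                warnings.warn(f"specimen {s} lacks a depth; excluded from stratum call")
            else:
                depths.append(d)
        if not depths:
            stratum = "unknown"
        elif max(depths) < depth_cut:
            stratum = "bathyal"
        elif min(depths) >= depth_cut:
            stratum = "abyssal"
        else:
            stratum = "spans cut"
        out.append(
            {
                "component_id": net.component_id,
                "n_haplotypes": net.n_observed,
                "total_multiplicity": net.total_multiplicity,
                "basins": sorted(basins),
                "depth_min": min(depths) if depths else None,
                "depth_max": max(depths) if depths else None,
                "stratum": stratum,
            }
        )
    return out
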