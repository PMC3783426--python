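"""Single-threshold general mixed Yule-coalescent (GMYC) species delimitation.

The model locates a threshold time T on an ultrametric tree separating
between-species (Yule-like) branching from within-species (coalescent)
branching. The branching *times* of the tree are modelled as one
inhomogeneous point process whose intensity sums the active processes:

    b(t) = lambda1 * n_div(t)^p1  +  lambda2 * sum_k [c_k(t) * (c_k(t)-1)]^p2

where n_div counts the diversification lineages (all branches older than T;
below T the species lineages persist without branching, so the count freezes
at the number of delimited entities) and c_k counts the lineages of the k-th
within-species cluster (the subtree hanging below T that the branch crossing
T subtends). Each inter-event waiting time x contributes b * exp(-b * x)
with b evaluated piecewise when an interval straddles the threshold.
With p1 = 1 the diversification term is the Yule process; with p2 = 1 the
within-species term is proportional to the Kingman coalescent rate
c(c-1)/2, the 1/2 and the population-size scaling absorbed in lambda2, and a
cluster reduced to a single lineage carries no within-species rate. The
exponents let the fit deviate from either idealisation.

The null model (one species: a single b = lambda * n^p process over the
whole tree) is reproduced exactly at the T = 0 boundary, so the models are
nested and compared by a likelihood-ratio test against a chi-square
reference (default 3 degrees of freedom: the threshold plus one extra rate
and one extra exponent).

At the single-process boundary the rate is profiled out analytically and the
exponent maximised by a bounded one-dimensional search; at interior
thresholds the below-threshold event factors couple the two processes, so
all four parameters are maximised jointly (L-BFGS-B on log rates and
exponents, three deterministic starts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import chi2

from .distances import DistanceMatrix

__all__ = [
    "Node",
    "UltrametricTree",
    "BranchingSchedule",
    "NullFit",
    "GMYCFit",
    "LRTResult",
    "upgma",
    "branching_schedule",
    "fit_null",
    "fit_gmyc_single",
    "mixed_loglik",
    "lrt",
    "lrt_from_likelihoods",
]

RATE_BOUNDS = (1e-8, 1e6)
EXPONENT_BOUNDS = (0.0, 10.0)


@dataclass(frozen=True)
class Node:
    """Tree node with a height (time before present); tips have height 0."""

    height: float
    children: tuple["Node", ...] = ()
    label: str | None = None

    @property
    def is_tip(self) -> bool:
        return not self.children


class UltrametricTree:
    """Rooted binary ultrametric tree (all tips equidistant from the root).

    Polytomies are resolved deterministically (children ordered by their
    smallest tip label, combined left to right) with the intermediate nodes
    displaced by a relative 1e-10 of tree height so node heights stay strictly
    ordered along every path.
    """

    def __init__(self, root: Node, ultra_tol: float = 1e-6):
        root = _resolve_polytomies(root)
        if root.height <= 0:
            raise ValueError("tree has zero height")
        root = _strictify(root, 1e-10 * root.height)
        self.root = root
        h = root.height
        for tip in self.tips():
            if abs(tip.height) > ultra_tol * h:
                raise ValueError(
                    f"tree is not ultrametric: tip {tip.label!r} at height {tip.height!r}"
                )
        for node in self.preorder():
            for c in node.children:
                if not c.is_tip and c.height >= node.height:
                    raise ValueError("child node height must be below its parent")

    # -- traversal -----------------------------------------------------------
    def preorder(self):
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(n.children)

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_tip]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    @property
    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]

    def internal_heights(self) -> np.ndarray:
        """Internal node heights, sorted from the root down."""
        hs = [n.height for n in self.preorder() if not n.is_tip]
        return np.sort(np.asarray(hs))[::-1]

    # -- newick i/o ----------------------------------------------------------
    @classmethod
    def from_newick(cls, source: str, ultra_tol: float = 1e-6) -> "UltrametricTree":
        """Parse a Newick string or file path (branch lengths required)."""
        text = source
        try:
            with open(source) as fh:
                text = fh.read()
        except (OSError, ValueError):
            pass
        dtree = dendropy.Tree.get(data=text, schema="newick")
        dtree.calc_node_root_distances(return_leaf_distances_only=False)
        depth_max = max(leaf.root_distance for leaf in dtree.leaf_node_iter())

        def convert(dnode) -> Node:
            height = depth_max - dnode.root_distance
            if dnode.is_leaf():
                return Node(height, label=dnode.taxon.label if dnode.taxon else None)
            return Node(height, tuple(convert(c) for c in dnode.child_nodes()))

        return cls(convert(dtree.seed_node), ultra_tol=ultra_tol)

    def to_newick(self) -> str:
        def render(node: Node, parent_height: float) -> str:
            bl = parent_height - node.height
            if node.is_tip:
                return f"{node.label}:{bl:.10g}"
            inner = ",".join(render(c, node.height) for c in node.children)
            return f"({inner}):{bl:.10g}"

        inner = ",".join(render(c, self.root.height) for c in self.root.children)
        return f"({inner});"

    # -- cluster structure at a threshold ------------------------------------
    def entities_at(self, T: float) -> list[Node]:
        """Branches crossing time T: the delimited species-level entities.

        Each entity is the root node of a maximal subtree entirely below
        (younger than) T. T = 0 delimits every tip as its own entity.
        """
        if T >= self.root.height:
            return [self.root]
        out = []

        def walk(node: Node):
            for c in node.children:
                if c.height <= T:
                    out.append(c)
                else:
                    walk(c)

        walk(self.root)
        return out


def _min_tip_label(node: Node) -> str:
    if node.is_tip:
        return node.label or ""
    return min(_min_tip_label(c) for c in node.children)


def _resolve_polytomies(node: Node, eps_abs: float | None = None) -> Node:
    if eps_abs is None:
        eps_abs = 1e-10 * max(node.height, 1e-300)
    if node.is_tip:
        return node
    children = [_resolve_polytomies(c, eps_abs) for c in node.children]
    children.sort(key=_min_tip_label)
    while len(children) > 2:
        a = children.pop(0)
        b = children.pop(0)
        h = node.height - eps_abs
        h = max(h, max(a.height, b.height))
        merged = Node(h, (a, b))
        children.insert(0, merged)
        children.sort(key=_min_tip_label)
    if len(children) == 1:
        return children[0]
    return Node(node.height, tuple(children), label=node.label)


def _strictify(node: Node, eps: float) -> Node:
    """Separate tied internal-node heights (zero-length internal edges) by a
    relative 1e-10 of tree height, working from the tips up so that chains of
    simultaneous nodes (e.g. a collapsed within-species genealogy) resolve."""
    if node.is_tip:
        return node
    children = tuple(_strictify(c, eps) for c in node.children)
    floor = max((c.height for c in children if not c.is_tip), default=-math.inf)
    h = node.height if node.height > floor else floor + eps
    return Node(h, children, node.label)


# ---------------------------------------------------------------------------
# UPGMA fallback tree builder
# ---------------------------------------------------------------------------

def upgma(dm: DistanceMatrix) -> UltrametricTree:
    """Average-linkage clustering; node height = half the merge distance.

    Ties are broken by the smallest member label of the candidate pair so the
    topology is reproducible.
    """
    n = len(dm.ids)
    if n < 2:
        raise ValueError("UPGMA needs at least 2 ids")
    clusters: dict[int, Node] = {i: Node(0.0, label=dm.ids[i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    mins = {i: dm.ids[i] for i in range(n)}
    dist = {
        (i, j): float(dm.values[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    next_id = n
    while len(clusters) > 1:
        (i, j), d = min(
            dist.items(),
            key=lambda kv: (kv[1], min(mins[kv[0][0]], mins[kv[0][1]]),
                            max(mins[kv[0][0]], mins[kv[0][1]])),
        )
        a, b = clusters.pop(i), clusters.pop(j)
        node = Node(max(d / 2.0, a.height, b.height), (a, b))
        clusters[next_id] = node
        sizes[next_id] = sizes[i] + sizes[j]
        mins[next_id] = min(mins[i], mins[j])
        for k in list(clusters):
            if k == next_id:
                continue
            dik = dist.pop((min(i, k), max(i, k)))
            djk = dist.pop((min(j, k), max(j, k)))
            dist[(min(k, next_id), max(k, next_id))] = (
                sizes[i] * dik + sizes[j] * djk
            ) / (sizes[i] + sizes[j])
        del dist[(i, j)], sizes[i], sizes[j], mins[i], mins[j]
        next_id += 1
    (root,) = clusters.values()
    return UltrametricTree(root)


# ---------------------------------------------------------------------------
# Branching schedule and likelihood engine
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Interval:
    """One inter-event slice of the tree, ending in a branching event.

    `x_div` is the part of the waiting time above the threshold (the
    diversification process counts all `n_lineages` crossing branches there);
    `x_frozen` the part below it, where the diversification count is frozen
    at the number of entities; `coal_counts` are the per-cluster lineage
    counts during the below-threshold part; `event_process` is 'div' or
    'coal'. `event_counts` are the per-cluster lineage counts just below
    (younger than) the terminating event — the coalescing pair is counted on
    the younger side, as in the Kingman process.
    """

    n_lineages: int
    x_div: float
    x_frozen: float
    coal_counts: tuple[int, ...]
    event_process: str
    event_counts: tuple[int, ...] = ()


@dataclass(frozen=True)
class BranchingSchedule:
    """Event heights, lineage counts, and process assignment at a threshold.

    `clusters` holds, per delimited entity, its tip count and its internal
    node heights sorted from the present towards the threshold (empty for
    singleton entities).
    """

    threshold: float
    heights: tuple[float, ...]  # internal node heights, root first
    intervals: tuple[_Interval, ...]
    clusters: tuple[tuple[int, tuple[float, ...]], ...]
    n_entities: int
    n_clusters: int

    @property
    def lineages_through_time(self) -> list[int]:
        return [iv.n_lineages for iv in self.intervals] + [len(self.heights) + 1]


def branching_schedule(tree: UltrametricTree, T: float) -> BranchingSchedule:
    """Classify the tree's branching events relative to threshold T.

    Nodes older than T are diversification events; nodes at or below T are
    coalescent events within the cluster (crossing branch) they fall in.
    """
    heights = tree.internal_heights()
    entities = tree.entities_at(T)
    n_clusters = sum(1 for e in entities if not e.is_tip)
    clusters = []
    cluster_heights = []
    for e in entities:
        nodes = list(_subtree_preorder(e))
        hs = sorted(n.height for n in nodes if not n.is_tip)
        n_tips = sum(1 for n in nodes if n.is_tip)
        clusters.append((n_tips, tuple(hs)))
        cluster_heights.append(np.asarray(hs[::-1]))
    intervals = []
    for i in range(len(heights) - 1):
        top, bot = float(heights[i]), float(heights[i + 1])
        n_lin = i + 2
        x_div = max(0.0, top - max(bot, T))
        x_frozen = max(0.0, min(top, T) - bot)
        if x_frozen > 0 or bot <= T:
            counts = tuple(1 + int((ch >= top).sum()) for ch in cluster_heights)
        else:
            counts = ()
        if bot > T:
            process, ev_counts = "div", ()
        else:
            process = "coal"
            ev_counts = tuple(1 + int((ch >= bot).sum()) for ch in cluster_heights)
        intervals.append(
            _Interval(n_lin, x_div, x_frozen, counts, process, ev_counts)
        )
    return BranchingSchedule(
        T, tuple(float(h) for h in heights), tuple(intervals), tuple(clusters),
        n_entities=len(entities), n_clusters=n_clusters,
    )


def _subtree_preorder(node: Node):
    stack = [node]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)


def _fit_single_process(event_ns: np.ndarray, ns: np.ndarray, xs: np.ndarray):
    """MLE of the one-process model b = lambda * n^p on waiting times.

    The rate is profiled analytically (lambda = E / S(p)); the exponent is
    maximised by a deterministic grid scan plus bounded local refinement.
    """
    E = len(event_ns)
    log_ne = float(np.log(event_ns).sum()) if E else 0.0

    def value(p: float) -> tuple[float, float]:
        S = float((ns ** p * xs).sum())
        if E == 0:
            return -RATE_BOUNDS[0] * S, RATE_BOUNDS[0]
        if S <= 0:
            return -np.inf, RATE_BOUNDS[0]
        lam = min(max(E / S, RATE_BOUNDS[0]), RATE_BOUNDS[1])
        return E * math.log(lam) + p * log_ne - lam * S, lam

    lo, hi = EXPONENT_BOUNDS
    grid = np.linspace(lo, hi, 21)
    vals = [value(p)[0] for p in grid]
    k = int(np.argmax(vals))
    a, b = grid[max(0, k - 1)], grid[min(len(grid) - 1, k + 1)]
    if a == b or not np.isfinite(vals[k]):
        best_p = float(grid[k])
    else:
        res = minimize_scalar(
            lambda p: -value(p)[0], bounds=(a, b), method="bounded",
            options={"xatol": 1e-7},
        )
        best_p = float(res.x) if -res.fun >= vals[k] else float(grid[k])
    best_val, best_lam = value(best_p)
    return best_val, best_lam, best_p


def _loglik_builder(schedule: BranchingSchedule):
    """Precompute arrays and return the negative log-likelihood callable."""
    ivs = schedule.intervals
    n_ent = float(schedule.n_entities)
    div_ns = np.array([iv.n_lineages for iv in ivs], dtype=float)
    div_xs = np.array([iv.x_div for iv in ivs], dtype=float)
    froz_xs = np.array([iv.x_frozen for iv in ivs], dtype=float)
    div_event_ns = np.array(
        [iv.n_lineages for iv in ivs if iv.event_process == "div"], dtype=float
    )
    # below-threshold survival: per interval, the f = c*(c-1) values of
    # clusters with >= 2 lineages, flattened with interval indices
    below = [k for k, iv in enumerate(ivs) if iv.x_frozen > 0 or iv.event_process == "coal"]
    fvals, fidx = [], []
    for row, k in enumerate(below):
        for c in ivs[k].coal_counts:
            if c >= 2:
                fvals.append(c * (c - 1))
                fidx.append(row)
    fvals = np.array(fvals, dtype=float)
    fidx = np.array(fidx, dtype=int)
    below_x = np.array([ivs[k].x_frozen for k in below], dtype=float)
    below_is_event = np.array(
        [ivs[k].event_process == "coal" for k in below], dtype=bool
    )
    n_below = len(below)
    n_coal_events = int(below_is_event.sum())

    logf = np.log(fvals) if fvals.size else fvals
    log_div_event = float(np.log(div_event_ns).sum()) if div_event_ns.size else 0.0
    n_div_events = len(div_event_ns)

    def negloglik(params: np.ndarray) -> float:
        loglam1, p1, loglam2, p2 = params
        lam1, lam2 = math.exp(loglam1), math.exp(loglam2)
        div_S = lam1 * (
            float((div_ns ** p1 * div_xs).sum()) + n_ent ** p1 * float(froz_xs.sum())
        )
        sumf = (
            np.bincount(fidx, weights=np.exp(p2 * logf), minlength=n_below)
            if fvals.size
            else np.zeros(n_below)
        )
        coal_S = lam2 * float((sumf * below_x).sum())
        event_rate = lam1 * n_ent ** p1 + lam2 * sumf[below_is_event]
        if np.any(event_rate <= 0):
            return np.inf
        lnL = (
            n_div_events * loglam1
            + p1 * log_div_event
            + float(np.log(event_rate).sum())
            - div_S
            - coal_S
        )
        return -lnL

    # moment-matched starting rates for the optimiser
    tot_div_time = float((div_ns * div_xs).sum() + n_ent * froz_xs.sum()) or 1.0
    tot_coal_time = float((below_x * np.bincount(
        fidx, weights=fvals, minlength=n_below)).sum()) if fvals.size else 0.0
    lam1_0 = max(n_div_events, 1) / tot_div_time
    lam2_0 = max(n_coal_events, 1) / max(tot_coal_time, 1e-12)
    return negloglik, n_below, lam1_0, lam2_0


def mixed_loglik(
    schedule: BranchingSchedule,
    lam1: float,
    p1: float,
    lam2: float,
    p2: float,
) -> float:
    """Mixed-model log-likelihood at the given parameters (no fitting)."""
    negloglik, _, _, _ = _loglik_builder(schedule)
    return -negloglik(np.array([math.log(lam1), p1, math.log(lam2), p2]))


def _fit_schedule(schedule: BranchingSchedule):
    """Maximise the mixed-intensity likelihood for a fixed threshold.

    The intensity b(t) = lambda1 * n_div^p1 + lambda2 * sum_k f_k^p2 (with
    f_k = c_k*(c_k - 1)) couples the rates through the below-threshold event
    factors, so the four parameters are optimised jointly (L-BFGS-B on log
    rates, three deterministic starts). With no coalescent data the model
    collapses to the single-process form, which is fitted exactly by
    profiling.
    """
    negloglik, n_below, lam1_0, lam2_0 = _loglik_builder(schedule)
    if n_below == 0:  # boundary threshold: single process, exact profile fit
        ivs = schedule.intervals
        div_event_ns = np.array(
            [iv.n_lineages for iv in ivs if iv.event_process == "div"], dtype=float
        )
        div_ns = np.array([iv.n_lineages for iv in ivs], dtype=float)
        div_xs = np.array([iv.x_div for iv in ivs], dtype=float)
        lnL, lam1, p1 = _fit_single_process(div_event_ns, div_ns, div_xs)
        return lnL, (lam1, p1, RATE_BOUNDS[0], 1.0)

    lo_l, hi_l = math.log(RATE_BOUNDS[0]), math.log(RATE_BOUNDS[1])
    starts = [
        (math.log(lam1_0), 1.0, math.log(lam2_0), 1.0),
        (math.log(lam1_0), 0.5, math.log(lam2_0), 2.0),
        (math.log(lam1_0), 2.0, math.log(max(lam2_0 * 0.1, RATE_BOUNDS[0])), 0.5),
    ]
    bounds = [(lo_l, hi_l), EXPONENT_BOUNDS, (lo_l, hi_l), EXPONENT_BOUNDS]
    best = None
    for x0 in starts:
        res = minimize(
            negloglik, np.array(x0), method="L-BFGS-B", bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
    loglam1, p1, loglam2, p2 = best.x
    return -float(best.fun), (math.exp(loglam1), p1, math.exp(loglam2), p2)


@dataclass(frozen=True)
class NullFit:
    """Single-process (one-species) fit: rate lambda, exponent p, log-likelihood."""

    lam: float
    p: float
    lnL: float
    n_tips: int


def fit_null(tree: UltrametricTree) -> NullFit:
    """Fit the one-process null model b = lambda * n^p to all branching events."""
    if tree.n_tips < 3:
        raise ValueError("null fit needs at least 3 tips")
    schedule = branching_schedule(tree, 0.0)  # all events diversification
    lnL, (lam, p, _, _) = _fit_schedule(schedule)
    if not np.isfinite(lnL):
        raise RuntimeError("null-model optimisation failed (non-finite likelihood)")
    return NullFit(lam, p, lnL, tree.n_tips)


@dataclass(frozen=True)
class GMYCFit:
    """Single-threshold GMYC fit.

    `n_clusters` counts delimited groups with at least two tips; `n_entities`
    adds singleton lineages crossing the threshold. `support_thresholds` are
    the candidate thresholds within 2 log-likelihood units of the maximum.
    """

    lam1: float
    p1: float
    lam2: float
    p2: float
    threshold: float
    lnL: float
    n_clusters: int
    n_entities: int
    support_thresholds: tuple[float, ...]
    profile: tuple[tuple[float, float], ...]  # (threshold, lnL) per candidate

    @property
    def entity_range_in_support(self) -> tuple[int, int]:
        lo = min(e for _, e in self._support_entities)
        hi = max(e for _, e in self._support_entities)
        return lo, hi


def fit_gmyc_single(tree: UltrametricTree) -> GMYCFit:
    """Profile the mixed-model likelihood over candidate thresholds.

    Candidates are T = 0 (every tip its own entity) plus the midpoints between
    consecutive distinct internal node heights; the returned fit maximises the
    profile likelihood.
    """
    if tree.n_tips < 4:
        raise ValueError("GMYC fit needs at least 4 tips")
    heights = np.unique(tree.internal_heights())[::-1]
    candidates = sorted(
        {0.0}
        | {(heights[i] + heights[i + 1]) / 2.0 for i in range(len(heights) - 1)}
    )
    profile = []
    best = None
    for T in candidates:
        schedule = branching_schedule(tree, T)
        lnL, params = _fit_schedule(schedule)
        profile.append((T, lnL))
        if np.isfinite(lnL) and (best is None or lnL > best[0]):
            best = (lnL, T, params, schedule)
    if best is None:
        raise RuntimeError("GMYC optimisation failed at every candidate threshold")
    lnL, T, (lam1, p1, lam2, p2), schedule = best
    support = tuple(t for t, v in profile if v >= lnL - 2.0)
    fit = GMYCFit(
        lam1, p1, lam2, p2, T, lnL,
        n_clusters=schedule.n_clusters,
        n_entities=schedule.n_entities,
        support_thresholds=support,
        profile=tuple(profile),
    )
    object.__setattr__(
        fit, "_support_entities",
        tuple((t, branching_schedule(tree, t).n_entities) for t in support),
    )
    return fit


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio test of the GMYC model against the one-species null."""

    statistic: float
    df: int
    p_value: float


def lrt(null: NullFit, alt, df: int = 3) -> LRTResult:
    """2 * (lnL_alt - lnL_null) against a chi-square with `df` degrees of freedom."""
    lnl_alt = alt.lnL if hasattr(alt, "lnL") else float(alt)
    stat = 2.0 * (lnl_alt - null.lnL)
    if stat < -1e-6:
        raise ValueError(
            f"negative LRT statistic ({stat:.3g}): alternative fit failed to "
            "reach the null likelihood"
        )
    stat = max(stat, 0.0)
    return LRTResult(stat, df, float(chi2.sf(stat, df)))


def lrt_from_likelihoods(lnl_null: float, lnl_alt: float, df: int = 3) -> LRTResult:
    """LRT arithmetic from two reported log-likelihoods."""
    stat = 2.0 * (lnl_alt - lnl_null)
    if stat < 0:
        raise ValueError("alternative log-likelihood below the null")
    return LRTResult(stat, df, float(chi2.sf(stat, df)))
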