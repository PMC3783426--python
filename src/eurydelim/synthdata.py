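"""Synthetic multi-marker datasets with species/population structure.

The generator emulates the statistical structure a distance-based species
survey assumes: a modest number of species-level clades whose between-clade
divergences are an order of magnitude larger than within-clade diversity,
each clade confined to a bathyal or abyssal depth stratum. Genealogies are a
Yule species tree with an independent within-species Kingman coalescent
grafted at each species tip; sequences evolve along the genealogy under the
Kimura two-parameter (K80) substitution model, matching the K2P distances the
analysis applies. Time is measured in expected substitutions per site on the
reference (COI-like) marker; slower markers use a relative rate multiplier.

All randomness flows from the single seed in :class:`SimConfig`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from .delimit import Partition
from .gmyc import Node, UltrametricTree
from .seqio import Alignment, SequenceRecord, SpecimenTable, write_fasta, write_metadata

__all__ = ["SimConfig", "SyntheticDataset", "simulate_tree", "evolve_sequences",
           "make_dataset", "paper_like_config"]

#: Depth ranges (m) of the two strata: continental-slope bathyal vs abyssal,
#: mirroring the sampled range of the study system (839-4,693 m with a faunal
#: break near 3,000 m).
STRATA = {"bathyal": (839.0, 2743.0), "abyssal": (3070.0, 4693.0)}


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    ``theta`` is the expected within-species pairwise divergence
    (substitutions/site on the reference marker); ``birth_rate`` the Yule
    speciation rate per lineage per unit time (same units);
    ``min_split_height`` a separation floor added to every species split so
    that clades are fully separated lineages rather than incipient splits;
    ``kappa`` the transition/transversion *rate* ratio of the K80 model;
    ``marker_lengths`` and ``relative_rates`` are per-marker; ``strata``
    assigns each species a depth stratum label from :data:`STRATA`.
    """

    n_species: int = 9
    samples_per_species: tuple[int, ...] | int = 3
    marker_lengths: dict = field(
        default_factory=lambda: {"COI": 658, "16S": 489, "28S": 1274}
    )
    relative_rates: dict = field(
        default_factory=lambda: {"COI": 1.0, "16S": 0.4, "28S": 0.05}
    )
    kappa: float = 3.0
    birth_rate: float = 50.0
    theta: float = 0.002
    min_split_height: float = 0.04
    strata: tuple[str, ...] | None = None  # per-species labels; default 2 bathyal + rest abyssal
    depth_jitter: float = 200.0
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if isinstance(self.samples_per_species, int):
            object.__setattr__(
                self, "samples_per_species",
                tuple([self.samples_per_species] * self.n_species),
            )
        if len(self.samples_per_species) != self.n_species:
            raise ValueError("need one sample size per species")
        if any(n < 1 for n in self.samples_per_species):
            raise ValueError("sample sizes must be >= 1")
        if any(L < 10 for L in self.marker_lengths.values()):
            raise ValueError("marker lengths must be >= 10")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.strata is None:
            n_bathyal = min(2, self.n_species)
            labels = ["bathyal"] * n_bathyal + ["abyssal"] * (self.n_species - n_bathyal)
            object.__setattr__(self, "strata", tuple(labels))
        if len(self.strata) != self.n_species:
            raise ValueError("need one stratum label per species")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=list)

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = json.load(fh)
        raw["samples_per_species"] = tuple(raw["samples_per_species"])
        if raw.get("strata") is not None:
            raw["strata"] = tuple(raw["strata"])
        return cls(**raw)


def paper_like_config(seed: int = 0, **overrides) -> SimConfig:
    """The default study-structure preset: 9 species, 2 bathyal + 7 abyssal,
    three markers of 658/489/1274 sites, within/between divergence ratio well
    above an order of magnitude."""
    return replace(SimConfig(seed=seed), **overrides) if overrides else SimConfig(seed=seed)


def _coalescent(labels: list[str], theta: float, rng: np.random.Generator) -> Node:
    """Kingman coalescent genealogy for one species' samples.

    Pairwise coalescence rate 2/theta, so the expected pairwise time is
    theta/2 and the expected pairwise divergence (twice the time) is theta.
    """
    nodes = [Node(0.0, label=l) for l in labels]
    if len(nodes) == 1:
        return nodes[0]
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        if theta <= 0:
            dt = 0.0
        else:
            rate = k * (k - 1) / 2.0 * (2.0 / theta)
            dt = rng.exponential(1.0 / rate)
        t += dt
        i, j = sorted(rng.choice(k, size=2, replace=False))
        merged = Node(t, (nodes[i], nodes[j]))
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)]
        nodes.append(merged)
    return nodes[0]


def _species_skeleton(config: SimConfig, rng: np.random.Generator):
    """Yule species tree as a nested ('join', height, a, b) structure.

    Split heights come from forward waiting times Exp(k * birth_rate) for
    k = 1..S-1 lineages plus an Exp(S * birth_rate) tail from the last split
    to the present; the ranked topology joins random lineage pairs backward
    (the Yule and Kingman ranked-shape distributions coincide).
    """
    S = config.n_species
    species = [f"SP{i+1}" for i in range(S)]
    if S == 1:
        return species[0]
    waits = rng.exponential(1.0 / (np.arange(1, S) * config.birth_rate))
    tail = rng.exponential(1.0 / (S * config.birth_rate))
    # the separation floor shifts every split deeper, modelling fully
    # separated (non-incipient) species-level lineages
    heights = config.min_split_height + tail + np.concatenate(
        [[0.0], np.cumsum(waits[:0:-1])]
    )
    nodes: list = list(species)
    for h in np.sort(heights):  # most recent join first
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)]
        nodes.append(("join", float(h), a, b))
    (skeleton,) = nodes
    return skeleton


def _graft_samples(skeleton, config: SimConfig, rng: np.random.Generator):
    """Attach a fresh within-species coalescent under each species tip.

    Genealogies deeper than the species' attachment point are redrawn (at
    most 20 times, then rescaled below the ceiling) to keep the composite
    tree valid; with the strongly separated defaults this is rare.
    """
    species = [f"SP{i+1}" for i in range(config.n_species)]
    sample_labels = {
        sp: [f"{sp}-{j+1:02d}" for j in range(config.samples_per_species[i])]
        for i, sp in enumerate(species)
    }

    def graft(sp: str, ceiling: float) -> Node:
        g = _coalescent(sample_labels[sp], config.theta, rng)
        for _ in range(20):
            if g.height < ceiling:
                return g
            g = _coalescent(sample_labels[sp], config.theta, rng)
        scale = 0.9 * ceiling / g.height

        def rescale(n: Node) -> Node:
            return Node(n.height * scale, tuple(rescale(c) for c in n.children), n.label)

        return rescale(g)

    def build(entry, ceiling: float) -> Node:
        if isinstance(entry, str):
            return graft(entry, ceiling)
        _, h, a, b = entry
        return Node(h, (build(a, h), build(b, h)))

    root = build(skeleton, float("inf"))
    mapping = {l: sp for sp, labels in sample_labels.items() for l in labels}
    return UltrametricTree(root), Partition.from_dict(mapping)


def simulate_tree(config: SimConfig, rng: np.random.Generator | None = None):
    """Simulate the coalescent-within-Yule genealogy.

    Returns ``(UltrametricTree, Partition)`` where the partition maps each
    sample id (``SP3-02`` style) to its species.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    skeleton = _species_skeleton(config, rng)
    return _graft_samples(skeleton, config, rng)


# --- K80 sequence evolution -------------------------------------------------

_TRANSITION = np.array([2, 3, 0, 1])  # A<->G, C<->T with coding A,C,G,T=0..3
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])


def _k80_probs(d: float, kappa: float):
    """K80 substitution probabilities after branch length d (subs/site).

    Rates normalised so d is the expected number of substitutions:
    alpha = kappa*beta (transitions), beta (each transversion),
    alpha + 2*beta = 1.
    """
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = np.exp(-4.0 * beta * d)
    e2 = np.exp(-2.0 * (alpha + beta) * d)
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ti = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv_each = 0.25 - 0.25 * e1
    return p_same, p_ti, p_tv_each


def _evolve_along(seq: np.ndarray, d: float, kappa: float, rng) -> np.ndarray:
    p_same, p_ti, p_tv = _k80_probs(d, kappa)
    u = rng.random(seq.shape)
    out = seq.copy()
    ti_mask = (u >= p_same) & (u < p_same + p_ti)
    out[ti_mask] = _TRANSITION[seq[ti_mask]]
    tv_mask = u >= p_same + p_ti
    which = (u[tv_mask] - p_same - p_ti < p_tv).astype(int) ^ 1
    out[tv_mask] = _TRANSVERSIONS[seq[tv_mask], which]
    return out


def evolve_sequences(
    tree: UltrametricTree,
    length: int,
    kappa: float = 3.0,
    rate: float = 1.0,
    seed: int | np.random.Generator = 0,
    marker: str = "",
) -> Alignment:
    """Simulate a K80 alignment along the tree.

    ``rate`` scales branch lengths, so the expected K2P distance between two
    tips approximates ``rate`` times their path length. The root state is
    uniform over A/C/G/T.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    records = []

    def walk(node: Node, parent_height: float, seq: np.ndarray):
        d = (parent_height - node.height) * rate
        seq = _evolve_along(seq, d, kappa, rng) if d > 0 else seq.copy()
        if node.is_tip:
            records.append(
                SequenceRecord(node.label, marker, "".join(bases[seq]))
            )
        else:
            for c in node.children:
                walk(c, node.height, seq)

    root_seq = rng.integers(0, 4, size=length)
    for c in tree.root.children:
        walk(c, tree.root.height, root_seq)
    if not tree.root.children:  # single-tip tree
        records.append(SequenceRecord(tree.root.label, marker, "".join(bases[root_seq])))
    records.sort(key=lambda r: r.id)
    return Alignment(tuple(records), marker=marker)


@dataclass(frozen=True)
class SyntheticDataset:
    """Simulated alignments plus the generating truth."""

    alignments: dict
    metadata: SpecimenTable
    true_partition: Partition
    true_tree: UltrametricTree
    config: SimConfig

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for marker, aln in self.alignments.items():
            write_fasta(aln, outdir / f"{marker}.fasta")
        write_metadata(self.metadata, outdir / "metadata.tsv")
        self.true_partition.to_tsv(outdir / "true_partition.tsv")
        (outdir / "true_tree.nwk").write_text(self.true_tree.to_newick() + "\n")
        self.config.to_json(outdir / "config.json")


def make_dataset(config: SimConfig) -> SyntheticDataset:
    """Simulate genealogy, per-marker alignments, and a metadata table.

    Marker genealogies share the species tree but redraw the within-species
    coalescent independently per marker (free recombination between loci).
    Specimen depths are a clade property: each species gets a centre inside
    its stratum and specimens jitter uniformly around it, clipped to the
    stratum range.
    """
    import pandas as pd

    rng = np.random.default_rng(config.seed)
    skeleton = _species_skeleton(config, rng)
    tree, partition = _graft_samples(skeleton, config, rng)
    alignments = {}
    for marker, L in config.marker_lengths.items():
        # same species tree, marker-specific within-species genealogy
        mtree, _ = _graft_samples(skeleton, config, rng)
        alignments[marker] = evolve_sequences(
            mtree, L, kappa=config.kappa,
            rate=config.relative_rates.get(marker, 1.0),
            seed=rng, marker=marker,
        )
    # depths: species-level centres, per-specimen jitter within the stratum
    rows = []
    species = sorted(set(partition.mapping.values()), key=lambda s: int(s[2:]))
    for i, sp in enumerate(species):
        lo, hi = STRATA[config.strata[i]]
        centre = rng.uniform(lo + config.depth_jitter, hi - config.depth_jitter)
        for member in partition.members(sp):
            depth = np.clip(
                centre + rng.uniform(-config.depth_jitter, config.depth_jitter), lo, hi
            )
            rows.append(
                {
                    "id": member,
                    "locality": f"{config.strata[i]} station {i+1}",
                    "basin": f"Basin-{i+1}",
                    "lat": round(float(rng.uniform(-65, 80)), 3),
                    "lon": round(float(rng.uniform(-180, 180)), 3),
                    "depth_m": round(float(depth), 1),
                    "source": "synthetic",
                    "multiplicity": 1,
                }
            )
    metadata = SpecimenTable(pd.DataFrame(rows))
    return SyntheticDataset(alignments, metadata, partition, tree, config)
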