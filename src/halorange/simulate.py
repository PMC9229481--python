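"""Synthetic inputs with known ground truth for every pipeline stage.

Generators for: Yule (pure-birth) phylogenies; binary traits evolved forward
along a tree under the symmetric CTMC, returning the true change history;
genomes from a low-order Markov model with specified motifs scrubbed from both
strands; and spot/plaque screening tables with a known susceptibility matrix
and halocin-style false-positive inhibition. All generators are deterministic
under a fixed seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .genome_signature import GenomeRecord, reverse_complement
from .trait_signal import CharacterHistory, TreeIndex

__all__ = [
    "SimulationConfig",
    "simulate_clade_structured_dataset",
    "simulate_yule_tree",
    "simulate_trait_history",
    "simulate_avoided_genome",
    "simulate_infection_tables",
]

_BASES = np.array(list("ACGT"))


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic datasets.

    Defaults mirror the scale of the real screen: trees of a few dozen taxa,
    a trait flip rate giving a handful of changes per tree, ~30 kb genomes,
    and a 25-virus × 10-host screen with log10 titers centred at 9 (sd 1) to
    span the observed 1e3–1e12 pfu/mL range.
    """

    seed: int = 0
    # tree
    n_tips: int = 32
    birth_rate: float = 1.0
    # trait
    mu_true: float = 0.5
    # genome
    genome_length: int = 30_000
    markov_order: int = 0
    base_freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25)
    avoided_motifs: Sequence[str] = ("CTAG", "GATC", "AGCT")
    # screen
    n_viruses: int = 25
    n_hosts: int = 10
    susceptibility: float = 0.15
    halocin_rate: float = 0.3
    log10_titer_mean: float = 9.0
    log10_titer_sd: float = 1.0

    def __post_init__(self) -> None:
        for p in (self.susceptibility, self.halocin_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0, 1]: {p!r}")
        if self.genome_length < 1000:
            raise ValueError("genome_length must be >= 1000")


# ---------------------------------------------------------------------------
# trees


def simulate_yule_tree(
    n_tips: int, birth_rate: float, rng: np.random.Generator | int | None = None
) -> dendropy.Tree:
    """Pure-birth tree: exponential waiting times, uniform choice of splitter.

    The process starts from the root split (two lineages at time 0); after the
    (n_tips)-th lineage appears, a final Exp(n_tips · birth_rate) hold time is
    appended so pendant edges have positive length. Tips are labelled
    ``t1..t<n>`` in birth order.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = _as_rng(rng)

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node.birth_time = 0.0
    first, second = dendropy.Node(), dendropy.Node()
    for child in (first, second):
        child.birth_time = 0.0
        tree.seed_node.add_child(child)
    active = [first, second]
    now = 0.0
    while len(active) < n_tips:
        now += rng.exponential(1.0 / (birth_rate * len(active)))
        k = int(rng.integers(len(active)))
        node = active.pop(k)
        node.edge.length = now - node.birth_time
        left, right = dendropy.Node(), dendropy.Node()
        for child in (left, right):
            child.birth_time = now
            node.add_child(child)
        active.extend([left, right])
    now += rng.exponential(1.0 / (birth_rate * n_tips))
    for i, node in enumerate(active):
        node.edge.length = now - node.birth_time
        node.taxon = taxa.new_taxon(label=f"t{i + 1}")
    tree.seed_node.edge.length = None
    return tree


# ---------------------------------------------------------------------------
# traits


def simulate_trait_history(
    tree: dendropy.Tree | TreeIndex,
    mu_true: float,
    rng: np.random.Generator | int | None = None,
) -> tuple[dict[str, int], CharacterHistory]:
    """Forward CTMC simulation of a binary trait down every branch.

    Root state from the stationary (1/2, 1/2) prior; state flips at Poisson
    (rate ``mu_true``) event times along each branch. Returns the tip states
    and the full true history with its jump count.
    """
    if mu_true <= 0:
        raise ValueError("mu_true must be positive")
    idx = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    rng = _as_rng(rng)

    states = np.zeros(idx.n_nodes, dtype=np.int8)
    events: dict[str, list[float]] = {}
    states[idx.root] = int(rng.random() < 0.5)
    for i in range(idx.n_nodes - 2, -1, -1):  # preorder
        t = idx.edge_length[i]
        n = int(rng.poisson(mu_true * t)) if t > 0 else 0
        if n:
            events[idx.branch_key[i]] = sorted(rng.random(n) * t)
        states[i] = (states[idx.parent[i]] + n) % 2
    traits = {label: int(states[i]) for i, label in idx.tip_label.items()}
    history = CharacterHistory(
        node_states={i: int(states[i]) for i in range(idx.n_nodes)},
        branch_events=events,
    )
    return traits, history


def simulate_clade_structured_dataset(
    n_tips: int = 32,
    birth_rate: float = 1.0,
    rng: np.random.Generator | int | None = None,
    within_clade_scale: float = 0.3,
    root_branch_boost: float = 5.0,
    min_clade_size: int | None = None,
    max_attempts: int = 200,
) -> tuple[dendropy.Tree, dict[str, int]]:
    """A tree and binary trait with maximal phylogenetic signal.

    Yule trees are drawn until both root clades have at least
    ``min_clade_size`` tips (default ``n_tips // 3`` — a badly unbalanced root
    split gives a near-monomorphic trait, which carries no signal by
    construction). Branch lengths are scaled down by ``within_clade_scale``
    and the two root-adjacent branches elongated by ``root_branch_boost``,
    so a single state change on a long basal branch explains the trait: tips
    in one root clade get state 0, the other state 1.
    """
    if n_tips < 4:
        raise ValueError("need at least 4 tips")
    rng = _as_rng(rng)
    if min_clade_size is None:
        min_clade_size = max(2, n_tips // 3)
    for _ in range(max_attempts):
        tree = simulate_yule_tree(n_tips, birth_rate, rng)
        root_children = tree.seed_node.child_nodes()
        sizes = [sum(1 for _ in child.leaf_iter()) for child in root_children]
        if min(sizes) >= min_clade_size:
            break
    else:
        raise RuntimeError("no sufficiently balanced root split found")
    for nd in tree.preorder_node_iter():
        if nd.edge.length is not None:
            nd.edge.length *= within_clade_scale
    for child in root_children:
        child.edge.length += root_branch_boost
    left = {leaf.taxon.label for leaf in root_children[0].leaf_iter()}
    traits = {t.label: (0 if t.label in left else 1) for t in tree.taxon_namespace}
    return tree, traits


# ---------------------------------------------------------------------------
# genomes


def _draw_sequence(
    length: int,
    order: int,
    freqs: Mapping[str, Sequence[float]] | Sequence[float] | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sequence from an order-0 or order-2 Markov model as an index array."""
    if order == 0:
        p = np.asarray(freqs if freqs is not None else [0.25] * 4, dtype=float)
        p = p / p.sum()
        return rng.choice(4, size=length, p=p)
    if order != 2:
        raise ValueError("markov_order must be 0 or 2")
    # order 2: freqs maps dinucleotide context -> probs over ACGT; missing
    # contexts fall back to uniform
    table = np.full((4, 4, 4), 0.25)
    if freqs:
        b2i = {b: i for i, b in enumerate("ACGT")}
        for ctx, probs in freqs.items():
            probs = np.asarray(probs, dtype=float)
            table[b2i[ctx[0]], b2i[ctx[1]]] = probs / probs.sum()
    seq = np.empty(length, dtype=np.int64)
    seq[:2] = rng.choice(4, size=2)
    u = rng.random(length)
    for i in range(2, length):
        cdf = np.cumsum(table[seq[i - 2], seq[i - 1]])
        seq[i] = int(np.searchsorted(cdf, u[i]))
    return seq


def simulate_avoided_genome(
    length: int,
    order: int = 0,
    freqs: Mapping[str, Sequence[float]] | Sequence[float] | None = None,
    avoided_motifs: Sequence[str] = (),
    rng: np.random.Generator | int | None = None,
    genome_id: str = "synthetic",
    max_sweeps: int = 200,
    max_regenerations: int = 5,
) -> GenomeRecord:
    """A Markov-model genome with the given motifs absent from both strands.

    The sequence is drawn from the model, then every remaining occurrence of
    an avoided motif (or its reverse complement) has its window locally
    resampled from the model's marginal base composition; sweeps repeat until
    clean. If a bounded number of sweeps fails, the whole genome is
    regenerated; exhausting that budget too raises (infeasible avoidance).
    """
    rng = _as_rng(rng)
    motifs = {m.upper() for m in avoided_motifs}
    for m in motifs:
        if not m or not set(m) <= set("ACGT"):
            raise ValueError(f"avoided motif must be non-empty over ACGT: {m!r}")
    targets = sorted(motifs | {reverse_complement(m) for m in motifs})

    if order == 0:
        p = np.asarray(freqs if freqs is not None else [0.25] * 4, dtype=float)
        marginal = p / p.sum()
    else:
        marginal = np.full(4, 0.25)

    for _ in range(max_regenerations):
        arr = _draw_sequence(length, order, freqs, rng)
        seq = "".join(_BASES[arr])
        for _ in range(max_sweeps):
            hits: list[tuple[int, int]] = []
            for m in targets:
                start = seq.find(m)
                while start != -1:
                    hits.append((start, len(m)))
                    start = seq.find(m, start + 1)
            if not hits:
                return GenomeRecord(genome_id, seq)
            for start, k in hits:
                arr[start:start + k] = rng.choice(4, size=k, p=marginal)
            seq = "".join(_BASES[arr])
        # sweep budget exhausted: regenerate from scratch
    raise RuntimeError(
        f"could not scrub motifs {targets} from a {length} nt genome "
        f"within {max_regenerations} regenerations"
    )


# ---------------------------------------------------------------------------
# screening tables


def simulate_infection_tables(
    config: SimulationConfig, rng: np.random.Generator | int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Spot and plaque assay tables with a known truth matrix.

    Every truly susceptible pair shows spot inhibition and a lognormal plaque
    titer; every resistant pair shows spot inhibition with probability
    ``halocin_rate`` (a halocin false positive) and never plaques. The two
    tables share the ``virus_id, host_id, assay, titer`` grammar of the
    host-range readers, so concatenating them round-trips through
    :meth:`halorange.hostrange.HostRangeMatrix.from_tables`.

    Returns ``(spot_table, plaque_table, truth)`` with ``truth`` a boolean
    virus × host frame.
    """
    rng = _as_rng(rng)
    viruses = [f"V{i + 1}" for i in range(config.n_viruses)]
    hosts = [f"H{j + 1}" for j in range(config.n_hosts)]
    truth = rng.random((config.n_viruses, config.n_hosts)) < config.susceptibility
    halocin = rng.random((config.n_viruses, config.n_hosts)) < config.halocin_rate
    log_titers = rng.normal(
        config.log10_titer_mean, config.log10_titer_sd,
        size=(config.n_viruses, config.n_hosts),
    )

    spot_rows, plaque_rows = [], []
    for i, j in itertools.product(range(config.n_viruses), range(config.n_hosts)):
        infected = bool(truth[i, j])
        inhibition = infected or bool(halocin[i, j])
        spot_rows.append(
            {"virus_id": viruses[i], "host_id": hosts[j], "assay": "spot",
             "titer": "+" if inhibition else "-"}
        )
        titer = f"{10.0 ** log_titers[i, j]:.3e}" if infected else "-"
        plaque_rows.append(
            {"virus_id": viruses[i], "host_id": hosts[j], "assay": "plaque",
             "titer": titer}
        )
    truth_frame = pd.DataFrame(truth, index=viruses, columns=hosts)
    return pd.DataFrame(spot_rows), pd.DataFrame(plaque_rows), truth_frame
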