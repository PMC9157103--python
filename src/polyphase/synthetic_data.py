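"""Synthetic polyploid datasets with full ground truth.

Generates everything the inference modules consume — a rooted species tree,
a phasing path over ordered pillars, homoeolog presence/absence under the
irreversible loss models, per-branch synonymous-divergence (Ks) tables with
an inflated root mode, gene-conversion likelihood tables and essentiality
labels — so the whole pipeline is testable without external genomes.

What the generator emulates: an ancestral gene order fragmented by synteny
breaks; subgenome-phasing paths that switch between adjacent syntenic
pillars with probability theta; presence/absence generated by the loss-model
CTMC along the tree (root branch included); per-branch Ks values drawn from
lognormals whose root-branch mode is inflated by the allopolyploid
progenitor divergence, with an optional second (homoeologous-exchange) mode;
and independent essentiality labels with optional planted enrichment.

Default study conditions: four tetraploid genomes, 5,000 pillars, switch
probability theta = 0.05, per-genome break probability 0.02 per adjacent
pair, loss-model parameters epsilon = 0.6, gamma = 0.05, delta = 0.1, branch
lengths of 0.3 (root and tips) and 0.2 (internals) on the alpha*t scale,
root-branch Ks log-mean -0.9 vs -1.6 elsewhere (log-sd 0.45), and an
essentiality base rate of 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .loss_models import (
    LossGenerator,
    WGDModelSpec,
    build_generator,
    transition_matrix,
)
from .orthology_hmm import Pillar, SpeciesTree, phasing_states

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_phasing_path",
    "simulate_pillar_losses",
    "simulate_divergence_table",
    "simulate_essentiality",
    "generate_dataset",
    "default_tree",
]


def default_tree(n_taxa: int = 4, tip: float = 0.3, internal: float = 0.2,
                 root: float = 0.3) -> SpeciesTree:
    """A ladder (caterpillar) tree over G1..Gn with the given lengths."""
    names = [f"G{i + 1}" for i in range(n_taxa)]
    if n_taxa == 1:
        return SpeciesTree.from_newick(f"({names[0]}:{tip}):{root};")
    core = f"{names[0]}:{tip}"
    for nm in names[1:-1]:
        core = f"({core},{nm}:{tip}):{internal}"
    core = f"({core},{names[-1]}:{tip})"
    return SpeciesTree.from_newick(f"{core}:{root};")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset (see module docstring)."""

    seed: int
    n_taxa: int = 4
    m: int = 5000
    model: object = field(default_factory=lambda: WGDModelSpec(
        epsilon=0.6, gamma=0.05, delta=0.1))
    tree: SpeciesTree | None = None
    theta: float = 0.05
    break_prob: float = 0.02
    # Ks lognormal parameters (log scale)
    ks_log_mean: float = -1.6
    ks_log_sd: float = 0.45
    ks_root_log_mean: float = -0.9
    ks_root_log_sd: float = 0.45
    he_weight: float = 0.0          # homoeologous-exchange mode weight
    he_log_mean_shift: float = -2.0  # HE mode log-mean offset from the root mode
    essential_rate: float = 0.2
    conversion_exceed_frac: float = 0.05  # pillars with conv lnL > species lnL
    sole_homolog_prob: float = 0.8

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        for name in ("theta", "break_prob", "he_weight", "essential_rate",
                     "conversion_exceed_frac", "sole_homolog_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0) or (name == "theta" and v > 0.5):
                raise ValueError(f"{name} out of range: {v}")

    def resolved_tree(self) -> SpeciesTree:
        return self.tree if self.tree is not None else default_tree(self.n_taxa)


@dataclass
class GroundTruth:
    """Everything the generator knows that the observables hide."""

    phasing_states: np.ndarray            # (m,) canonical state index
    break_flags: np.ndarray               # (n_genomes, m) True = break
    node_states: np.ndarray               # (m, n_nodes) loss-model state index
    config: SimulationConfig
    genomes: list[str]
    state_labels: list[str]
    rgl_truth: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    essentiality: dict[str, bool] = field(default_factory=dict)
    dropped_resims: int = 0


def simulate_phasing_path(m: int, theta: float, break_prob, n_genomes: int,
                          seed: int, ploidy: int = 2):
    """Markov phasing path and per-genome break flags.

    Each genome independently keeps its assignment with probability 1-theta
    between syntenic neighbors (switching uniformly otherwise) and is fully
    randomized at a break (probability ``break_prob`` per genome per pair).
    Returns ``(per_genome_assignments (n, m), break_flags (n, m))``.
    """
    if not (0.0 <= theta <= 0.5):
        raise ValueError(f"theta must be in [0, 0.5], got {theta}")
    rng = np.random.default_rng(seed)
    import math
    a = math.factorial(ploidy)
    if np.isscalar(break_prob):
        break_prob = np.full(n_genomes, float(break_prob))
    assign = np.zeros((n_genomes, m), dtype=np.int64)
    breaks = np.zeros((n_genomes, m), dtype=bool)
    assign[:, 0] = rng.integers(a, size=n_genomes)
    for i in range(1, m):
        brk = rng.random(n_genomes) < break_prob
        breaks[:, i] = brk
        for g in range(n_genomes):
            if brk[g]:
                assign[g, i] = rng.integers(a)
            elif rng.random() < theta:
                others = [x for x in range(a) if x != assign[g, i - 1]]
                assign[g, i] = others[rng.integers(a - 1)]
            else:
                assign[g, i] = assign[g, i - 1]
    return assign, breaks


def _sample_node_states(tree: SpeciesTree, gen: LossGenerator, m: int,
                        rng: np.random.Generator,
                        root_gen: LossGenerator | None = None) -> np.ndarray:
    """Exact endpoint sampling of the loss CTMC at every tree node.

    States are drawn from the matrix-exponential transition probabilities
    per branch (root branch included, starting from the generator's root
    distribution), which has exactly the node-state law of a jump-process
    simulation while vectorizing over pillars.  ``root_gen`` optionally
    substitutes root-branch-specific rates.
    """
    s = gen.n_states
    rg = root_gen if root_gen is not None else gen
    node_states = np.zeros((m, tree.n_nodes), dtype=np.int64)
    p_root = transition_matrix(rg, tree.root_length)
    root_draw = rng.choice(s, size=m, p=rg.root_dist)
    # state at the first-speciation node
    cum = p_root.cumsum(axis=1)
    u = rng.random(m)
    node_states[:, tree.root] = (u[:, None] > cum[root_draw]).sum(axis=1)
    # preorder down the tree
    order = [tree.root]
    stack = [tree.root]
    while stack:
        nd = stack.pop()
        for c in tree.children[nd]:
            order.append(c)
            stack.append(c)
    for nd in order:
        for c in tree.children[nd]:
            p = transition_matrix(gen, tree.lengths[c])
            cum = p.cumsum(axis=1)
            u = rng.random(m)
            parent = node_states[:, nd]
            node_states[:, c] = (u[:, None] > cum[parent]).sum(axis=1)
    return node_states


def simulate_pillar_losses(tree: SpeciesTree, gen: LossGenerator,
                           phasing, breaks, seed: int, *,
                           root_gen: LossGenerator | None = None,
                           config: SimulationConfig | None = None):
    """Presence/absence pillars from the loss model plus ground truth.

    ``phasing``/``breaks`` are the (n_genomes, m) arrays from
    :func:`simulate_phasing_path`.  Pillars that violate the at-least-one-
    gene-per-genome rule are resimulated (drop count recorded) so the output
    always has the requested m.
    """
    rng = np.random.default_rng(seed)
    n_genomes, m = phasing.shape
    genomes = list(tree.leaves)
    if len(genomes) != n_genomes:
        raise ValueError("phasing path genome count does not match the tree")
    import math
    ploidy = gen.n_subgenomes
    perms = list(__import__("itertools").permutations(range(ploidy)))
    inv_perms = [np.argsort(p) for p in perms]
    leaf_node = {tree.names[i]: i for i in tree.leaf_indices}
    obs = np.array(gen.obs_map)  # (S, ploidy)

    node_states = _sample_node_states(tree, gen, m, rng, root_gen)
    dropped = 0
    # resimulate rows with an all-absent genome (possible only if the model
    # had a zero-copy state; none of the shipped models do, but stay safe)
    for _ in range(100):
        bad = np.zeros(m, dtype=bool)
        for g in genomes:
            tip = node_states[:, leaf_node[g]]
            if np.any(obs[tip].sum(axis=1) == 0):
                bad |= obs[tip].sum(axis=1) == 0
        if not bad.any():
            break
        dropped += int(bad.sum())
        node_states[bad] = _sample_node_states(tree, gen, int(bad.sum()), rng,
                                               root_gen)
    else:
        raise RuntimeError("could not satisfy the >=1-gene-per-genome rule")

    pillars: list[Pillar] = []
    for i in range(m):
        genes = {}
        adj = {}
        for g_i, g in enumerate(genomes):
            tip_state = node_states[i, leaf_node[g]]
            sub_pat = obs[tip_state]  # presence per subgenome
            perm = perms[phasing[g_i, i]]  # track j -> subgenome perm[j]
            track_pat = tuple(int(sub_pat[perm[j]]) for j in range(ploidy))
            genes[g] = tuple(
                f"{g}_{i:05d}_t{j}" if track_pat[j] else None
                for j in range(ploidy))
            adj[g] = not breaks[g_i, i] if i > 0 else True
        pillars.append(Pillar(f"P{i:05d}", genes, adj))

    # canonical phasing state index per pillar
    a = math.factorial(ploidy)
    canon = np.zeros(m, dtype=np.int64)
    for g_i in range(n_genomes):
        canon = canon * a + phasing[g_i]
    _, labels, _ = phasing_states(n_genomes, ploidy)
    truth = GroundTruth(canon, breaks.copy(), node_states,
                        config, genomes, labels, dropped_resims=dropped)
    # reciprocal-loss truth per genome pair: both genomes single copy on
    # different subgenomes at the tips
    for x in range(n_genomes):
        for y in range(x + 1, n_genomes):
            key = (genomes[x], genomes[y])
            lst = []
            for i in range(m):
                sx = obs[node_states[i, leaf_node[genomes[x]]]]
                sy = obs[node_states[i, leaf_node[genomes[y]]]]
                if sx.sum() == 1 and sy.sum() == 1 and sx.argmax() != sy.argmax():
                    lst.append(pillars[i].pillar_id)
            truth.rgl_truth[key] = lst
    return pillars, truth


def simulate_divergence_table(tree: SpeciesTree, config: SimulationConfig,
                              pillar_ids: list[str], seed: int) -> pd.DataFrame:
    """Per-pillar per-branch Ks (and Ka) records.

    Every branch draws from a lognormal with the configured log-mean/log-sd;
    the root branch uses the inflated mode, optionally mixed with a smaller
    homoeologous-exchange mode at weight ``he_weight``.  Ka/Ks is drawn from
    a Beta(2, 8) (mean 0.2) so selective constraint is realistic but
    uninformative unless a test plants structure.
    """
    if config.ks_log_sd <= 0 or config.ks_root_log_sd <= 0:
        raise ValueError("Ks log-sd parameters must be positive")
    rng = np.random.default_rng(seed)
    labels = tree.branch_labels()
    rows = []
    n = len(pillar_ids)
    for b in range(tree.n_nodes):
        is_root = b == tree.root
        if is_root:
            he = rng.random(n) < config.he_weight
            mu = np.where(he, config.ks_root_log_mean + config.he_log_mean_shift,
                          config.ks_root_log_mean)
            ks = np.exp(rng.normal(mu, config.ks_root_log_sd))
        else:
            ks = np.exp(rng.normal(config.ks_log_mean, config.ks_log_sd, size=n))
        ratio = rng.beta(2.0, 8.0, size=n)
        for pid, k, r in zip(pillar_ids, ks, ratio):
            rows.append((pid, labels[b], float(k), float(k * r), float(r)))
    return pd.DataFrame(rows, columns=["pillar_id", "branch_id", "Ks", "Ka",
                                       "Ka_over_Ks"])


def simulate_essentiality(genes: list[str], base_rate: float, seed: int, *,
                          enriched: list[str] | None = None,
                          enrichment: float = 1.0) -> dict[str, bool]:
    """Independent essentiality labels at ``base_rate``; genes in
    ``enriched`` use ``min(1, base_rate * enrichment)`` instead."""
    if not (0.0 <= base_rate <= 1.0):
        raise ValueError(f"base rate must be in [0, 1], got {base_rate}")
    rng = np.random.default_rng(seed)
    enriched_set = set(enriched or ())
    out = {}
    for g in genes:
        r = min(1.0, base_rate * enrichment) if g in enriched_set else base_rate
        out[g] = bool(rng.random() < r)
    return out


def simulate_conversion_table(pillar_ids: list[str], exceed_frac: float,
                              seed: int) -> pd.DataFrame:
    """Species-tree vs gene-conversion-tree log-likelihood table; a fraction
    ``exceed_frac`` of pillars gets a higher conversion likelihood."""
    rng = np.random.default_rng(seed)
    base = rng.normal(-2000.0, 50.0, size=len(pillar_ids))
    exceed = rng.random(len(pillar_ids)) < exceed_frac
    delta = np.where(exceed, rng.uniform(0.5, 10.0, len(pillar_ids)),
                     -rng.uniform(0.5, 30.0, len(pillar_ids)))
    return pd.DataFrame({
        "pillar_id": pillar_ids,
        "lnL_species": base,
        "lnL_conversion": base + delta,
    })


def generate_dataset(config: SimulationConfig, out_dir=None):
    """Full synthetic bundle: pillars, tree, Ks table, conversion table,
    essentiality labels and ground truth.

    Sub-seeds are spawned deterministically from ``config.seed``.  If
    ``out_dir`` is given the bundle is also written to disk in the formats
    the inference modules read (see :mod:`polyphase.io`).
    """
    tree = config.resolved_tree()
    gen = build_generator(config.model)
    root_gen = None
    model = config.model
    if (getattr(model, "root_epsilon", None) is not None
            or getattr(model, "root_spec", None) is not None):
        root_gen = build_generator(model, root_branch=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(6)]

    import math
    ploidy = gen.n_subgenomes
    phasing, breaks = simulate_phasing_path(
        config.m, config.theta, config.break_prob, len(tree.leaves),
        seeds[0], ploidy=ploidy)
    pillars, truth = simulate_pillar_losses(tree, gen, phasing, breaks,
                                            seeds[1], root_gen=root_gen,
                                            config=config)
    ks = simulate_divergence_table(tree, config, [p.pillar_id for p in pillars],
                                   seeds[2])
    conv = simulate_conversion_table([p.pillar_id for p in pillars],
                                     config.conversion_exceed_frac, seeds[3])
    all_genes = [g for p in pillars for tr in p.genes.values()
                 for g in tr if g is not None]
    truth.essentiality = simulate_essentiality(all_genes, config.essential_rate,
                                               seeds[4])
    # sole-homolog bookkeeping for the RGL filter: most single-copy genes are
    # the only homolog of their pillar's outgroup gene
    rng = np.random.default_rng(seeds[5])
    for p in pillars:
        counts = {}
        for g, tracks in p.genes.items():
            n_present = sum(t is not None for t in tracks)
            if n_present == 1 and rng.random() < config.sole_homolog_prob:
                counts[g] = 1
            else:
                counts[g] = max(n_present, 2)
        p.homolog_counts = counts

    bundle = {"pillars": pillars, "tree": tree, "ks": ks, "conversion": conv,
              "truth": truth, "config": config}
    if out_dir is not None:
        from . import io as pio
        pio.write_bundle(bundle, out_dir)
    return bundle
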