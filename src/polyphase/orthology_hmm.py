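"""Hidden-Markov inference of subgenome orthology across polyploid genomes.

Each pillar (ancestral locus) shows a presence/absence pattern of homoeologs
over up to N tracks per genome.  The hidden state of a pillar is its phasing:
the assignment of each genome's tracks to the N parental subgenomes (2^n
states for n tetraploid genomes).  Emission probabilities come from
Felsenstein pruning of an irreversible loss model over the species tree,
including a distinguished root branch between the polyploidy event and the
first speciation.  Adjacent, syntenic pillars are coupled by a per-genome
switch probability theta (0.5 at synteny breaks, decoupling neighbors); the
forward recurrence is

    L_i | D_i..D_0 = (Theta . L_{i-1} | D_{i-1}..D_0)  (elementwise *)  L^i

with base case L_0 | D_0 = L_0 and total likelihood the sum of the final
vector's elements.  Posterior decoding (forward-backward) yields per-pillar
marginal phasing probabilities; model parameters, branch lengths and theta
are estimated by bounded maximum likelihood.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import optimize, stats

from .loss_models import (
    LossGenerator,
    WGDModelSpec,
    WGTModelSpec,
    WGQModelSpec,
    build_generator,
    spec_from_name,
    transition_matrix,
)

__all__ = [
    "SpeciesTree",
    "Pillar",
    "CompiledPillars",
    "compile_pillars",
    "phasing_states",
    "phasing_transition_matrix",
    "emission_matrix",
    "emission_likelihood",
    "forward_loglikelihood",
    "posterior_decode",
    "PosteriorTable",
    "FitResult",
    "fit_model",
    "param_variance",
    "observed_information",
    "likelihood_ratio_test",
    "search_topology",
    "root_loss_probability",
    "phase_wgq",
    "WGQPhasing",
]


# ---------------------------------------------------------------------------
# species tree


class SpeciesTree:
    """A rooted tree over the polyploid taxa with branch lengths in
    expected-loss (alpha*t) units and a distinguished root branch above the
    first speciation node.

    Internally stored as parallel arrays in postorder (root node last):
    ``children[i]`` lists child indices of node i, ``lengths[i]`` is the
    length of the edge above node i, with the root node's entry holding the
    root-branch length.
    """

    def __init__(self, children: list[list[int]], names: list[str | None],
                 lengths: np.ndarray):
        self.children = children
        self.names = names
        self.lengths = np.asarray(lengths, dtype=float)
        if np.any(self.lengths < 0):
            raise ValueError("branch lengths must be >= 0")
        self.n_nodes = len(children)
        self.root = self.n_nodes - 1
        self.leaf_indices = [i for i, c in enumerate(children) if not c]
        self.leaves = [names[i] for i in self.leaf_indices]
        if len(set(self.leaves)) != len(self.leaves):
            raise ValueError("leaf labels must be unique")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        """Parse a Newick string; the root edge length (``...):x;``) is the
        root-branch length (0 if absent)."""
        import dendropy

        try:
            t = dendropy.Tree.get(data=newick, schema="newick",
                                  suppress_internal_node_taxa=True)
        except Exception as exc:
            raise ValueError(f"could not parse Newick tree: {exc}") from exc
        children: list[list[int]] = []
        names: list[str | None] = []
        lengths: list[float] = []

        def rec(node) -> int:
            kids = [rec(c) for c in node.child_nodes()]
            children.append(kids)
            names.append(node.taxon.label if node.taxon is not None else None)
            lengths.append(node.edge.length if node.edge.length is not None else 0.0)
            return len(children) - 1

        rec(t.seed_node)
        return cls(children, names, np.array(lengths))

    def to_newick(self) -> str:
        def rec(i: int) -> str:
            if not self.children[i]:
                core = self.names[i]
            else:
                core = "(" + ",".join(rec(c) for c in self.children[i]) + ")"
            return f"{core}:{self.lengths[i]:.6g}"

        return rec(self.root) + ";"

    def with_lengths(self, lengths: np.ndarray) -> "SpeciesTree":
        return SpeciesTree(self.children, self.names, np.asarray(lengths, float))

    @property
    def root_length(self) -> float:
        """Length of the root branch (polyploidy to first speciation)."""
        return float(self.lengths[self.root])

    def branch_labels(self) -> list[str]:
        """Human-readable label per node edge (leaf name, or the sorted leaf
        set under an internal node; the last entry is the root branch)."""
        labels = []
        below: list[list[str]] = [None] * self.n_nodes
        for i in range(self.n_nodes):
            if not self.children[i]:
                below[i] = [self.names[i]]
                labels.append(self.names[i])
            else:
                below[i] = sorted(sum((below[c] for c in self.children[i]), []))
                labels.append("+".join(below[i]))
        labels[self.root] = "root"
        return labels


# ---------------------------------------------------------------------------
# pillars


@dataclass
class Pillar:
    """One ancestral locus: per genome, N track slots holding a gene id or
    None (absence), plus a per-genome adjacency flag to the previous pillar
    (True = synteny maintained, False = break).  ``homolog_counts`` optionally
    records, per genome, how many homologs of the pillar's outgroup gene
    exist in that genome (used by the sole-homolog RGL filter)."""

    pillar_id: str
    genes: dict[str, tuple[str | None, ...]]
    adjacency: dict[str, bool]
    homolog_counts: dict[str, int] | None = None

    def pattern(self, genome: str) -> tuple[int, ...]:
        return tuple(0 if g is None else 1 for g in self.genes[genome])

    def n_present(self, genome: str) -> int:
        return sum(self.pattern(genome))


@dataclass
class CompiledPillars:
    """Array form of an ordered pillar list, ready for the HMM.

    pattern_idx[g, i] indexes ``patterns`` for genome g at pillar i;
    maintained[g, i] is True when genome g keeps synteny between pillars
    i-1 and i (entry 0 is unused).
    """

    genomes: list[str]
    ploidy: int
    patterns: list[tuple[int, ...]]
    pattern_idx: np.ndarray
    maintained: np.ndarray
    pillar_ids: list[str]
    pillars: list[Pillar]

    @property
    def m(self) -> int:
        return self.pattern_idx.shape[1]

    @property
    def n_genomes(self) -> int:
        return len(self.genomes)


def compile_pillars(pillars: list[Pillar], genomes: list[str] | None = None,
                    ploidy: int = 2) -> CompiledPillars:
    if not pillars:
        raise ValueError("pillar list must not be empty")
    if genomes is None:
        genomes = sorted(pillars[0].genes)
    m = len(pillars)
    pattern_index: dict[tuple[int, ...], int] = {}
    patterns: list[tuple[int, ...]] = []
    pidx = np.zeros((len(genomes), m), dtype=np.int64)
    maint = np.ones((len(genomes), m), dtype=bool)
    for i, p in enumerate(pillars):
        for g_i, g in enumerate(genomes):
            pat = p.pattern(g)
            if len(pat) != ploidy:
                raise ValueError(
                    f"pillar {p.pillar_id}: genome {g} has {len(pat)} tracks, expected {ploidy}")
            if sum(pat) == 0:
                raise ValueError(
                    f"pillar {p.pillar_id}: genome {g} has no present gene")
            if pat not in pattern_index:
                pattern_index[pat] = len(patterns)
                patterns.append(pat)
            pidx[g_i, i] = pattern_index[pat]
            maint[g_i, i] = p.adjacency.get(g, True)
    return CompiledPillars(list(genomes), ploidy, patterns, pidx, maint,
                           [p.pillar_id for p in pillars], list(pillars))


def _as_compiled(pillars, ploidy: int = 2, genomes=None) -> CompiledPillars:
    if isinstance(pillars, CompiledPillars):
        return pillars
    return compile_pillars(list(pillars), genomes=genomes, ploidy=ploidy)


# ---------------------------------------------------------------------------
# phasing states


def _perms(ploidy: int) -> list[tuple[int, ...]]:
    return list(itertools.permutations(range(ploidy)))


def phasing_states(n_genomes: int, ploidy: int = 2):
    """Enumerate global phasing states in canonical order.

    A state is a tuple of per-genome track->subgenome permutations; the
    canonical integer index treats genome 0 as the most significant digit in
    base ploidy!.  For a WGD the per-genome digit is the subgenome of track
    0, so labels read "00".."11" for two genomes.
    """
    perms = _perms(ploidy)
    states = list(itertools.product(range(len(perms)), repeat=n_genomes))
    if ploidy == 2:
        labels = ["".join(str(perms[a][0]) for a in s) for s in states]
    else:
        labels = ["|".join("".join(map(str, perms[a])) for a in s) for s in states]
    return states, labels, perms


def phasing_transition_matrix(theta: float, break_flags, n: int,
                              ploidy: int = 2) -> np.ndarray:
    """Transition matrix between phasing states of adjacent pillars.

    The kernel is the Kronecker product over genomes of per-genome switch
    kernels: a genome whose adjacency is maintained keeps its assignment
    with probability 1-theta and switches to each of the other assignments
    with probability theta/(A-1) (A = ploidy! assignments, so A=2 for a WGD
    gives the (1-theta, theta) kernel); a genome with a broken adjacency uses
    the uniform kernel (switch probability 0.5 for a WGD).
    """
    if not (0.0 <= theta <= 0.5):
        raise ValueError(f"theta must be in [0, 0.5], got {theta}")
    a = math.factorial(ploidy)
    kern_keep = np.full((a, a), theta / (a - 1))
    np.fill_diagonal(kern_keep, 1.0 - theta)
    kern_break = np.full((a, a), 1.0 / a)
    out = np.ones((1, 1))
    for g in range(n):
        k = kern_break if break_flags[g] else kern_keep
        out = np.kron(out, k)
    return out


# ---------------------------------------------------------------------------
# emissions (pruning over the loss-model state space)


def _tip_table(patterns, perms, gen: LossGenerator) -> np.ndarray:
    """Indicator table (n_assignments, n_patterns, n_states): 1 where a loss
    state's subgenome pattern, viewed through the track->subgenome
    permutation, matches the observed track pattern."""
    t = np.zeros((len(perms), len(patterns), gen.n_states))
    for a, perm in enumerate(perms):
        for p, pat in enumerate(patterns):
            for s, omap in enumerate(gen.obs_map):
                if all(pat[j] == omap[perm[j]] for j in range(len(perm))):
                    t[a, p, s] = 1.0
    return t


def _top_partials(cp: CompiledPillars, tree: SpeciesTree, gen: LossGenerator,
                  root_gen: LossGenerator | None = None):
    """Pruned partial likelihoods at the first-speciation node.

    Returns ``(partials, w, state_order)`` where ``partials`` has shape
    (K, m, S) over canonical phasing states, ``w[s] = sum_r root_dist[r] *
    P_root[r, s]`` folds in the root branch and root distribution, and the
    emission matrix is ``partials @ w``.
    """
    states, labels, perms = phasing_states(cp.n_genomes, cp.ploidy)
    tip = _tip_table(cp.patterns, perms, gen)
    a = len(perms)
    genome_pos = {g: i for i, g in enumerate(cp.genomes)}

    p_mats = [transition_matrix(gen, tree.lengths[i]) for i in range(tree.n_nodes)]
    rg = root_gen if root_gen is not None else gen
    p_root = transition_matrix(rg, tree.root_length)
    w = rg.root_dist @ p_root

    def rec(node: int):
        """Return (leaf genome positions in recursion order, partials
        (A^k, m, S)) below ``node``, excluding its own edge."""
        if not tree.children[node]:
            g = genome_pos[tree.names[node]]
            return [g], tip[:, cp.pattern_idx[g], :]
        leaf_order: list[int] = []
        acc = None
        for c in tree.children[node]:
            sub_leaves, sub = rec(c)
            contrib = sub @ p_mats[c].T
            if acc is None:
                leaf_order, acc = sub_leaves, contrib
            else:
                na, nb = acc.shape[0], contrib.shape[0]
                acc = (acc[:, None, :, :] * contrib[None, :, :, :]).reshape(
                    na * nb, acc.shape[1], acc.shape[2])
                leaf_order = leaf_order + sub_leaves
        return leaf_order, acc

    leaf_order, partials = rec(tree.root)
    if set(leaf_order) != set(range(cp.n_genomes)):
        raise ValueError("tree leaves do not match the pillar genomes")

    # reorder recursion-order assignment tuples into canonical genome order
    k_total = a ** cp.n_genomes
    reorder = np.empty(k_total, dtype=np.int64)
    n = cp.n_genomes
    for k, state in enumerate(states):
        rec_idx = 0
        for pos in leaf_order:
            rec_idx = rec_idx * a + state[pos]
        reorder[k] = rec_idx
    return partials[reorder], w, (states, labels, perms)


def emission_matrix(pillars, tree: SpeciesTree, gen: LossGenerator, *,
                    root_gen: LossGenerator | None = None,
                    ploidy: int | None = None) -> np.ndarray:
    """Per-pillar emission likelihoods over canonical phasing states (m, K)."""
    cp = _as_compiled(pillars, ploidy=ploidy or gen.n_subgenomes)
    partials, w, _ = _top_partials(cp, tree, gen, root_gen)
    return (partials @ w).T.copy()


def emission_likelihood(pillar: Pillar, state, tree: SpeciesTree,
                        gen: LossGenerator,
                        root_gen: LossGenerator | None = None) -> float:
    """Emission likelihood of one pillar under one phasing state.

    ``state`` is either a canonical state index or a tuple of per-genome
    assignment indices.  Patterns impossible under the irreversible model
    return 0.0.
    """
    cp = compile_pillars([pillar], ploidy=gen.n_subgenomes)
    e = emission_matrix(cp, tree, gen, root_gen=root_gen)
    if isinstance(state, tuple):
        states, _, _ = phasing_states(cp.n_genomes, cp.ploidy)
        state = states.index(state)
    return float(e[0, state])


# ---------------------------------------------------------------------------
# forward / backward


@njit(cache=True)
def _forward_core(emis, kernels, kidx):  # pragma: no cover - numba
    m, k = emis.shape
    fwd = np.empty((m, k))
    logs = np.empty(m)
    f = emis[0].copy()
    s = f.sum()
    if s <= 0.0:
        return -np.inf, fwd, logs
    f /= s
    fwd[0] = f
    logs[0] = np.log(s)
    for i in range(1, m):
        ker = kernels[kidx[i]]
        g = np.empty(k)
        for b in range(k):
            acc = 0.0
            for a_ in range(k):
                acc += ker[a_, b] * f[a_]
            g[b] = acc * emis[i, b]
        s = g.sum()
        if s <= 0.0:
            return -np.inf, fwd, logs
        g /= s
        f = g
        fwd[i] = f
        logs[i] = np.log(s)
    return logs.sum(), fwd, logs


@njit(cache=True)
def _backward_core(emis, kernels, kidx):  # pragma: no cover - numba
    m, k = emis.shape
    bwd = np.empty((m, k))
    b = np.ones(k)
    bwd[m - 1] = b
    for i in range(m - 2, -1, -1):
        ker = kernels[kidx[i + 1]]
        nb = np.empty(k)
        for a_ in range(k):
            acc = 0.0
            for c in range(k):
                acc += ker[a_, c] * emis[i + 1, c] * b[c]
            nb[a_] = acc
        s = nb.sum()
        if s <= 0.0:
            s = 1.0
        nb /= s
        b = nb
        bwd[i] = b
    return bwd


def _hmm_kernels(cp: CompiledPillars, theta: float):
    """Unique per-pillar transition kernels and the per-pillar kernel index.

    Kernels depend only on which genomes break synteny at a pillar, so they
    are deduplicated across pillars.
    """
    m, n = cp.m, cp.n_genomes
    combos: dict[tuple[bool, ...], int] = {}
    kidx = np.zeros(m, dtype=np.int64)
    kernel_list = []
    for i in range(m):
        breaks = tuple(not cp.maintained[g, i] for g in range(n))
        if breaks not in combos:
            combos[breaks] = len(kernel_list)
            kernel_list.append(
                phasing_transition_matrix(theta, breaks, n, cp.ploidy))
        kidx[i] = combos[breaks]
    return np.ascontiguousarray(np.stack(kernel_list)), kidx


def forward_loglikelihood(pillars, tree: SpeciesTree, gen: LossGenerator,
                          theta: float, *,
                          root_gen: LossGenerator | None = None,
                          emissions: np.ndarray | None = None) -> float:
    """Log-likelihood of the ordered pillar data under the phasing HMM."""
    cp = _as_compiled(pillars, ploidy=gen.n_subgenomes)
    if emissions is None:
        emissions = emission_matrix(cp, tree, gen, root_gen=root_gen)
    kernels, kidx = _hmm_kernels(cp, theta)
    ll, _, _ = _forward_core(np.ascontiguousarray(emissions), kernels, kidx)
    return float(ll)


@dataclass
class PosteriorTable:
    """Per-pillar marginal posterior over phasing states."""

    pillar_ids: list[str]
    genomes: list[str]
    state_labels: list[str]
    states: list[tuple[int, ...]]
    perms: list[tuple[int, ...]]
    probs: np.ndarray          # (m, K)
    best_index: np.ndarray     # (m,)
    best_prob: np.ndarray      # (m,)

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.probs, columns=self.state_labels)
        df.insert(0, "pillar_id", self.pillar_ids)
        df.insert(1, "best_state", [self.state_labels[i] for i in self.best_index])
        df.insert(2, "posterior", self.best_prob)
        return df


def posterior_decode(pillars, tree: SpeciesTree, gen: LossGenerator,
                     theta: float, *,
                     root_gen: LossGenerator | None = None) -> PosteriorTable:
    """Forward-backward marginal posteriors per pillar; argmax ties break
    toward the lowest canonical state index."""
    cp = _as_compiled(pillars, ploidy=gen.n_subgenomes)
    emis = emission_matrix(cp, tree, gen, root_gen=root_gen)
    kernels, kidx = _hmm_kernels(cp, theta)
    emis = np.ascontiguousarray(emis)
    ll, fwd, _ = _forward_core(emis, kernels, kidx)
    if not np.isfinite(ll):
        raise ValueError("data have zero likelihood under this model")
    bwd = _backward_core(emis, kernels, kidx)
    post = fwd * bwd
    post /= post.sum(axis=1, keepdims=True)
    states, labels, perms = phasing_states(cp.n_genomes, cp.ploidy)
    best = post.argmax(axis=1)  # argmax takes the first maximum: lowest index
    return PosteriorTable(cp.pillar_ids, list(cp.genomes), labels, states,
                          perms, post, best, post[np.arange(cp.m), best])


# ---------------------------------------------------------------------------
# maximum-likelihood fitting


@dataclass
class FitResult:
    """Outcome of a bounded maximum-likelihood fit."""

    loglik: float
    theta: float
    branch_lengths: np.ndarray
    spec: object
    params: dict[str, float]
    param_names: list[str]
    x: np.ndarray
    bounds: list[tuple[float, float]]
    converged: bool
    n_evals: int
    tree: SpeciesTree
    model: str | None = None
    _objective: object = field(default=None, repr=False)

    def generator(self) -> LossGenerator:
        return build_generator(self.spec)

    def root_generator(self) -> LossGenerator | None:
        if isinstance(self.spec, WGDModelSpec) and self.spec.root_epsilon is not None:
            return build_generator(self.spec, root_branch=True)
        if isinstance(self.spec, WGTModelSpec) and self.spec.root_spec is not None:
            return build_generator(self.spec, root_branch=True)
        return None

    def fitted_tree(self) -> SpeciesTree:
        return self.tree.with_lengths(self.branch_lengths)


def _free_model_params(spec) -> list[tuple[str, float, float, float]]:
    """(name, init, lo, hi) for each free model parameter; the WGT f pair is
    reparameterized as (f13, f23/f13) so the box enforces f23 <= f13 <= 1."""
    out = []
    if isinstance(spec, WGDModelSpec):
        if spec.free_epsilon:
            out.append(("epsilon", spec.epsilon if spec.epsilon < 1 else 0.8, 1e-3, 1.0))
        if spec.free_gamma:
            out.append(("gamma", max(spec.gamma, 0.05), 0.0, 10.0))
        if spec.free_delta:
            out.append(("delta", max(spec.delta, 0.05), 0.0, 10.0))
        if spec.free_root_epsilon:
            init = spec.root_epsilon if spec.root_epsilon is not None else 0.8
            if init >= 1.0:  # do not start on the box boundary
                init = 0.8
            out.append(("root_epsilon", init, 1e-3, 1.0))
    elif isinstance(spec, WGTModelSpec):
        if spec.free_f:
            out.append(("f13", min(spec.f13, 1.0), 1e-3, 1.0))
            out.append(("f23_ratio", min(spec.f23 / spec.f13, 1.0), 1e-3, 1.0))
        if spec.free_sigma:
            for s in ("sigma1", "sigma2", "sigma3"):
                out.append((s, getattr(spec, s), 1e-3, 10.0))
    elif isinstance(spec, WGQModelSpec):
        if spec.free_delta:
            out.append(("delta", spec.delta, 1e-3, 10.0))
        if spec.free_sigma:
            out.append(("sigma", spec.sigma, 1e-3, 10.0))
        if spec.free_lam:
            out.append(("lam", max(spec.lam, 0.1), 0.0, 10.0))
    else:
        raise TypeError(f"unsupported spec type {type(spec).__name__}")
    return out


def _apply_model_params(spec, values: dict[str, float]):
    from dataclasses import replace

    if isinstance(spec, WGTModelSpec) and "f23_ratio" in values:
        values = dict(values)
        f13 = values.get("f13", spec.f13)
        values["f23"] = f13 * values.pop("f23_ratio")
    return replace(spec, **values)


def fit_model(pillars, tree: SpeciesTree, model="wgd-null", *,
              free_theta: bool = True, theta: float = 0.1,
              fit_branch_lengths: bool = True,
              free_branches: list[int] | None = None,
              n_restarts: int = 5, seed: int = 0,
              maxiter: int = 200,
              warm_start: "FitResult | None" = None) -> FitResult:
    """Maximize the HMM log-likelihood over theta, branch lengths and the
    model family's free parameters under box constraints.

    ``model`` is a model name (see :func:`polyphase.loss_models.spec_from_name`)
    or a spec instance whose ``free_*`` flags mark the free parameters.
    ``free_branches`` restricts which node edges are optimized (default: all,
    including the root branch).  Multi-start local optimization (L-BFGS-B)
    with ``n_restarts`` seeded starts; deterministic given ``seed``.
    ``warm_start`` seeds shared parameters (theta, branch lengths, any model
    parameter of the same name) from a previous fit -- useful when fitting a
    nested model pair, so the alternative never scores below the null.
    """
    spec0 = spec_from_name(model) if isinstance(model, str) else model
    cp = _as_compiled(pillars, ploidy=build_generator(spec0).n_subgenomes)
    rng = np.random.default_rng(seed)

    names: list[str] = []
    inits: list[float] = []
    bounds: list[tuple[float, float]] = []
    if free_theta:
        names.append("theta")
        inits.append(min(max(theta, 1e-4), 0.5))
        bounds.append((1e-4, 0.5))
    if fit_branch_lengths:
        if free_branches is None:
            # every node edge, including the root branch
            free_branches = list(range(tree.n_nodes))
        for b in free_branches:
            names.append(f"t_{b}")
            inits.append(max(tree.lengths[b], 1e-3))
            bounds.append((1e-4, 20.0))
    else:
        free_branches = []
    model_params = _free_model_params(spec0)
    for nm, init, lo, hi in model_params:
        names.append(nm)
        inits.append(init)
        bounds.append((lo, hi))

    warm_init = None
    if warm_start is not None:
        warm = dict(warm_start.params)
        warm.setdefault("theta", warm_start.theta)
        for b in range(len(warm_start.branch_lengths)):
            warm.setdefault(f"t_{b}", warm_start.branch_lengths[b])
        # two extra starts are derived from the previous fit: one keeping
        # the new free parameters at their generic inits, and one keeping
        # them at their current (null) values so the nested optimum is
        # reproducible even if the optimizer cannot leave a boundary
        current = {nm: getattr(spec0, nm, None) for nm, *_ in model_params}
        warm_init = list(inits)
        for i, nm in enumerate(names):
            lo, hi = bounds[i]
            if nm in warm:
                inits[i] = min(max(warm[nm], lo), hi)
                warm_init[i] = inits[i]
            elif current.get(nm) is not None:
                warm_init[i] = min(max(current[nm], lo), hi)

    base_lengths = tree.lengths.copy()
    n_evals = [0]

    def unpack(x: np.ndarray):
        j = 0
        th = theta
        if free_theta:
            th = x[j]
            j += 1
        lengths = base_lengths.copy()
        for b in free_branches:
            lengths[b] = x[j]
            j += 1
        vals = {}
        for nm, *_ in model_params:
            vals[nm] = x[j]
            j += 1
        spec = _apply_model_params(spec0, vals) if vals else spec0
        return th, lengths, spec

    def objective(x: np.ndarray) -> float:
        n_evals[0] += 1
        th, lengths, spec = unpack(x)
        t = tree.with_lengths(lengths)
        gen = build_generator(spec)
        rg = None
        if isinstance(spec, WGDModelSpec) and spec.root_epsilon is not None:
            rg = build_generator(spec, root_branch=True)
        if isinstance(spec, WGTModelSpec) and spec.root_spec is not None:
            rg = build_generator(spec, root_branch=True)
        ll = forward_loglikelihood(cp, t, gen, th, root_gen=rg)
        if not np.isfinite(ll):
            return 1e12
        return -ll

    x0 = np.array(inits)
    starts = [x0]
    if warm_init is not None:
        starts.append(np.array(warm_init))
    for _ in range(max(0, n_restarts - 1)):
        starts.append(np.array([rng.uniform(lo, hi) for lo, hi in bounds]))

    best = None
    any_converged = False
    for s in starts:
        res = optimize.minimize(objective, s, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": maxiter, "ftol": 1e-11})
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    # the optimizer can drift a hair above a start point under tight
    # tolerances; never return worse than the best start
    for s in starts[: 2 if warm_init is not None else 1]:
        f_s = objective(s)
        if f_s < best.fun:
            best.x, best.fun = s, f_s

    th, lengths, spec = unpack(best.x)
    params = dict(zip(names, best.x))
    return FitResult(
        loglik=-float(best.fun), theta=float(th), branch_lengths=lengths,
        spec=spec, params=params, param_names=names, x=best.x.copy(),
        bounds=bounds, converged=any_converged, n_evals=n_evals[0], tree=tree,
        model=model if isinstance(model, str) else None, _objective=objective)


def param_variance(fit: FitResult, param: str, *,
                   method: str = "single") -> float | None:
    """Wald variance of one fitted parameter from the observed Fisher
    information at the MLE.

    ``method="single"`` (default) uses a single-dimension central finite
    difference of the negative log-likelihood, ignoring covariances with the
    other parameters; this conditional variance is what feeds the
    loss-rate-per-Ks ratio intervals.  ``method="marginal"`` inverts the full
    observed-information matrix (see :func:`observed_information`) and reads
    off the diagonal entry: the proper marginal Wald variance, wider when
    parameters are correlated (as the loss-model parameters are with the
    branch lengths), and the one to use for parameter-recovery coverage.

    Returns None (flagged unavailable) when the estimate sits on a box
    boundary or the curvature is nonpositive.
    """
    if param not in fit.param_names:
        raise KeyError(f"unknown parameter {param!r}; have {fit.param_names}")
    i = fit.param_names.index(param)
    est = fit.x[i]
    h = max(1e-4, 1e-4 * abs(est))
    lo, hi = fit.bounds[i]
    if est - h < lo or est + h > hi:
        return None
    if method == "marginal":
        info = observed_information(fit)
        cov = np.linalg.inv(info)
        v = float(cov[i, i])
        return v if v > 0.0 else None
    if method != "single":
        raise ValueError(f"method must be 'single' or 'marginal', got {method!r}")
    f0 = fit._objective(fit.x)
    xp = fit.x.copy(); xp[i] += h
    xm = fit.x.copy(); xm[i] -= h
    curv = (fit._objective(xp) - 2.0 * f0 + fit._objective(xm)) / h**2
    if curv <= 0.0:
        return None
    return 1.0 / curv


def observed_information(fit: FitResult, *, rel_step: float = 1e-3) -> np.ndarray:
    """Full observed Fisher information (Hessian of the negative
    log-likelihood) at the MLE by central finite differences."""
    f = fit._objective
    x = fit.x
    n = len(x)
    h = np.maximum(1e-4, rel_step * np.abs(x))
    hess = np.zeros((n, n))
    f0 = f(x)
    fp = np.zeros(n)
    fm = np.zeros(n)
    for i in range(n):
        xp = x.copy(); xp[i] += h[i]; fp[i] = f(xp)
        xm = x.copy(); xm[i] -= h[i]; fm[i] = f(xm)
        hess[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / h[i] ** 2
    for i in range(n):
        for j in range(i + 1, n):
            xpp = x.copy(); xpp[i] += h[i]; xpp[j] += h[j]
            xmm = x.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
            hess[i, j] = hess[j, i] = (
                f(xpp) - fp[i] - fp[j] + 2.0 * f0 - fm[i] - fm[j] + f(xmm)
            ) / (2.0 * h[i] * h[j])
    return hess


def likelihood_ratio_test(null_fit: FitResult, alt_fit: FitResult, df: int,
                          *, boundary_correction: bool = False):
    """2*delta(lnL) statistic and chi-square p-value for nested fits.

    ``boundary_correction`` applies the 50:50 mixture of chi2_0 and chi2_df
    appropriate when the null pins a parameter at a box boundary; by default
    the plain chi-square is used.
    """
    stat = 2.0 * (alt_fit.loglik - null_fit.loglik)
    if stat < -1e-6:
        raise ValueError(
            f"alternative log-likelihood ({alt_fit.loglik:.6f}) is below the "
            f"null ({null_fit.loglik:.6f}); fits are not nested or not converged")
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df))
    if boundary_correction:
        p = 0.5 * p if stat > 0 else 1.0
    return stat, p


# ---------------------------------------------------------------------------
# exhaustive topology search


def _rooted_topologies(taxa: list[str]):
    """All rooted binary topologies on the taxa, as nested tuples
    ((2n-3)!! of them)."""
    def insert(tree, x):
        yield (tree, x)
        if isinstance(tree, tuple):
            for i in range(2):
                for sub in insert(tree[i], x):
                    yield (sub, tree[1]) if i == 0 else (tree[0], sub)

    tops = [taxa[0]]
    for x in taxa[1:]:
        tops = [t for base in tops for t in insert(base, x)]
    return tops


def _has_sister_pair(top, pair: tuple[str, str]) -> bool:
    if not isinstance(top, tuple):
        return False
    if set(top) == set(pair):
        return True
    return any(_has_sister_pair(c, pair) for c in top)


def _topology_to_newick(top, branch: float, root: float) -> str:
    def rec(t):
        if isinstance(t, tuple):
            return "(" + ",".join(f"{rec(c)}:{branch}" for c in t) + ")"
        return t

    return f"{rec(top)}:{root};"


def search_topology(pillars, taxa: list[str], model="wgd-bfc-nb", *,
                    constraint: tuple[str, str] | None = None,
                    init_branch: float = 0.25, init_root: float = 0.25,
                    seed: int = 0, n_restarts: int = 1, maxiter: int = 200):
    """Exhaustive maximum-likelihood search over rooted topologies (<= 6 taxa).

    ``constraint`` optionally fixes a sister pair, restricting the candidate
    set to topologies consistent with it.  Returns ``(best_tree, best_fit,
    all_fits)`` with every topology's fit logged.
    """
    if len(taxa) > 6 and constraint is None:
        raise ValueError(
            "exhaustive search is limited to 6 taxa; supply a constraint or "
            "fix the topology externally")
    tops = _rooted_topologies(list(taxa))
    if constraint is not None:
        tops = [t for t in tops if _has_sister_pair(t, constraint)]
    all_fits = []
    best = None
    for k, top in enumerate(tops):
        tree = SpeciesTree.from_newick(_topology_to_newick(top, init_branch, init_root))
        fit = fit_model(pillars, tree, model, seed=seed + k,
                        n_restarts=n_restarts, maxiter=maxiter)
        all_fits.append((top, fit))
        if best is None or fit.loglik > best[1].loglik:
            best = (top, fit)
    return best[1].fitted_tree(), best[1], all_fits


# ---------------------------------------------------------------------------
# node-state posteriors and WGQ phasing


def root_loss_probability(pillars, tree: SpeciesTree, gen: LossGenerator,
                          decoded_states: np.ndarray, *,
                          root_gen: LossGenerator | None = None) -> np.ndarray:
    """Per-pillar probability that the locus was already single-copy at the
    end of the root branch (i.e. the homoeolog was lost before the first
    speciation), conditional on each pillar's decoded phasing state."""
    cp = _as_compiled(pillars, ploidy=gen.n_subgenomes)
    partials, w, _ = _top_partials(cp, tree, gen, root_gen)
    # P(node state = s | data, k) prop to w[s] * partial[k, i, s]
    sel = partials[decoded_states, np.arange(cp.m), :]  # (m, S)
    joint = sel * w[None, :]
    total = joint.sum(axis=1)
    total[total == 0.0] = np.nan
    return joint[:, gen.single_copy_states].sum(axis=1) / total


@dataclass
class WGQPhasing:
    """Result of splitting WGQ pillars into paired WGD-style pillars.

    ``first_event_pairs`` holds pillars with genes surviving from both
    first-event duplicated regions; ``singles`` holds the (common, under the
    formation model) pillars whose genes all descend from one first-event
    region, emitted as a single WGD-style pillar.
    """

    first_event_pairs: list[tuple[str, Pillar, Pillar]]
    singles: list[tuple[str, Pillar]]
    dropped: list[tuple[str, str]]  # (pillar_id, reason)
    gene_assignments: dict[str, dict[str, int]]  # pillar -> genome -> gene -> subgenome


def phase_wgq(posteriors: PosteriorTable, pillars, *,
              confidence: float = 0.99) -> WGQPhasing:
    """Phase octoploid pillars into pairs of tetraploid pillars.

    For each extant gene, the posterior probability that it descends from
    the same first-event duplicated region as a per-pillar reference track
    (the first present track of the first genome) is the sum of
    phasing-state posteriors co-assigning the two tracks to the same
    first-event subgenome pair ({1,2} vs {3,4}).  The absolute pair labels
    are not identifiable -- the model is symmetric under swapping the two
    first-event pairs -- so each state's labeling is aligned to the
    reference track before summing.  Pillars where every gene's pair
    assignment reaches ``confidence`` are emitted as two parallel WGD-style
    pillars (one per first-event pair); others are dropped with a reason
    code.
    """
    if not (0.5 < confidence <= 1.0):
        raise ValueError(f"confidence must be in (0.5, 1], got {confidence}")
    cp = _as_compiled(pillars, ploidy=4)
    probs = posteriors.probs
    states = posteriors.states
    perms = posteriors.perms
    n = cp.n_genomes

    # group[k, g, j]: first-event pair (0 = subgenomes {1,2}, 1 = {3,4}) of
    # track j in genome g under phasing state k
    k_total = len(states)
    group = np.zeros((k_total, n, 4), dtype=np.int8)
    for k, st in enumerate(states):
        for g in range(n):
            perm = perms[st[g]]
            for j in range(4):
                group[k, g, j] = 0 if perm[j] in (0, 1) else 1

    pairs: list[tuple[str, Pillar, Pillar]] = []
    singles: list[tuple[str, Pillar]] = []
    dropped: list[tuple[str, str]] = []
    assignments: dict[str, dict[str, int]] = {}
    swap_pair = {0: 2, 1: 3, 2: 0, 3: 1}
    for i, pillar in enumerate(cp.pillars):
        ref_track = pillar.pattern(cp.genomes[0]).index(1)
        flip = group[:, 0, ref_track]  # (K,) label alignment per state
        pk = probs[i]
        map_k = int(posteriors.best_index[i])
        ok = True
        reason = ""
        gene_sg: dict[str, dict[str, int]] = {}
        for g_i, g in enumerate(cp.genomes):
            map_perm = perms[states[map_k][g_i]]
            map_flip = flip[map_k]
            for j, gene in enumerate(pillar.genes[g]):
                if gene is None:
                    continue
                p_same = float(pk[(group[:, g_i, j] ^ flip) == 0].sum())
                if max(p_same, 1.0 - p_same) < confidence:
                    ok = False
                    reason = "below-confidence"
                    break
                sg = map_perm[j]
                gene_sg.setdefault(g, {})[gene] = swap_pair[sg] if map_flip else sg
            if not ok:
                break
        if not ok:
            dropped.append((pillar.pillar_id, reason))
            continue
        genes_a: dict[str, list[str | None]] = {}
        genes_b: dict[str, list[str | None]] = {}
        for g in cp.genomes:
            slots = [None, None, None, None]
            for gene, sg in gene_sg.get(g, {}).items():
                slots[sg] = gene
            genes_a[g] = slots[0:2]
            genes_b[g] = slots[2:4]
        # a side is usable only when every genome contributes a gene to it
        a_ok = all(any(x is not None for x in genes_a[g]) for g in cp.genomes)
        b_ok = all(any(x is not None for x in genes_b[g]) for g in cp.genomes)
        if not (a_ok or b_ok):
            dropped.append((pillar.pillar_id, "missing-genome-in-pair"))
            continue
        pa = Pillar(pillar.pillar_id + "/12",
                    {g: tuple(genes_a[g]) for g in cp.genomes},
                    dict(pillar.adjacency))
        pb = Pillar(pillar.pillar_id + "/34",
                    {g: tuple(genes_b[g]) for g in cp.genomes},
                    dict(pillar.adjacency))
        assignments[pillar.pillar_id] = {g: dict(d) for g, d in gene_sg.items()}
        if a_ok and b_ok:
            pairs.append((pillar.pillar_id, pa, pb))
        else:
            singles.append((pillar.pillar_id, pa if a_ok else pb))
    return WGQPhasing(pairs, singles, dropped, assignments)
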