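"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from polyphase.loss_models import WGDModelSpec, build_wgd_generator
from polyphase.orthology_hmm import (
    CompiledPillars,
    Pillar,
    SpeciesTree,
    compile_pillars,
    emission_matrix,
    phasing_states,
    phasing_transition_matrix,
)


@pytest.fixture
def two_taxon_tree() -> SpeciesTree:
    return SpeciesTree.from_newick("(A:0.3,B:0.5):0.25;")


@pytest.fixture
def four_taxon_tree() -> SpeciesTree:
    return SpeciesTree.from_newick(
        "(((G1:0.3,G2:0.3):0.2,G3:0.3):0.2,G4:0.3):0.3;")


def random_wgd_pillars(m: int, genomes: list[str], seed: int,
                       break_prob: float = 0.2) -> list[Pillar]:
    """Random presence/absence pillars (no model structure): every pattern
    with at least one present gene, random adjacency flags."""
    rng = np.random.default_rng(seed)
    pats = [(1, 1), (1, 0), (0, 1)]
    out = []
    for i in range(m):
        genes = {}
        adj = {}
        for g in genomes:
            pat = pats[rng.integers(3)]
            genes[g] = tuple(f"{g}_{i}_t{j}" if pat[j] else None for j in range(2))
            adj[g] = bool(rng.random() > break_prob)
        out.append(Pillar(f"p{i}", genes, adj))
    return out


def enumerate_path_likelihood(cp: CompiledPillars, tree: SpeciesTree, gen,
                              theta: float):
    """Brute-force HMM oracle: sum over every phasing-state path.

    Returns (log-likelihood, per-pillar marginal posteriors).  Exponential in
    the pillar count; use only for m <= 6, n = 2.
    """
    emis = emission_matrix(cp, tree, gen)
    m, k = emis.shape
    total = 0.0
    marg = np.zeros((m, k))
    for path in itertools.product(range(k), repeat=m):
        term = emis[0, path[0]]
        for i in range(1, m):
            breaks = [not cp.maintained[g, i] for g in range(cp.n_genomes)]
            ker = phasing_transition_matrix(theta, breaks, cp.n_genomes,
                                            cp.ploidy)
            term *= ker[path[i - 1], path[i]] * emis[i, path[i]]
        total += term
        for i, s in enumerate(path):
            marg[i, s] += term
    return np.log(total), marg / total


def enumerate_emission(pillar: Pillar, state_idx: int, tree: SpeciesTree,
                       gen) -> float:
    """Brute-force emission oracle: sum over every assignment of loss-model
    states to all tree nodes (the pruning recursion unrolled)."""
    from polyphase.loss_models import transition_matrix

    genomes = sorted(pillar.genes)
    states, _, perms = phasing_states(len(genomes), gen.n_subgenomes)
    state = states[state_idx]
    p_mats = [transition_matrix(gen, tree.lengths[i]) for i in range(tree.n_nodes)]
    p_root = transition_matrix(gen, tree.root_length)
    leaf_of = {tree.names[i]: i for i in tree.leaf_indices}
    nodes = list(range(tree.n_nodes))
    parent = {}
    for i in nodes:
        for c in tree.children[i]:
            parent[c] = i

    def tip_ok(g_i: int, s: int) -> bool:
        pat = pillar.pattern(genomes[g_i])
        perm = perms[state[g_i]]
        omap = gen.obs_map[s]
        return all(pat[j] == omap[perm[j]] for j in range(len(perm)))

    total = 0.0
    for assign in itertools.product(range(gen.n_states), repeat=tree.n_nodes):
        ok = True
        for g_i, g in enumerate(genomes):
            if not tip_ok(g_i, assign[leaf_of[g]]):
                ok = False
                break
        if not ok:
            continue
        # root branch from the event to the first-speciation node
        term = float(gen.root_dist @ p_root[:, assign[tree.root]])
        for c, par in parent.items():
            term *= p_mats[c][assign[par], assign[c]]
        total += term
    return total
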