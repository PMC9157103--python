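"""Reciprocal gene loss (RGL) detection between polyploid genomes.

Two genomes that retain alternative members of a homoeolog pair at the same
pillar are separated by a reciprocal gene loss: a diploid hybrid between
them would segregate gametes lacking the gene entirely, so RGLs at essential
genes are candidate hybridization barriers.  For a pair of single-copy genes
from two genomes, the probability that they are paralogs (created by the
polyploidy) rather than orthologs is the posterior mass on phasing states
assigning them to different parental subgenomes.  Calls at or above a
confidence threshold (default 0.95) pass through two structural filters
designed to exclude annotation artifacts:

(a) synteny-hole: the surviving gene and the empty track are flanked on both
    sides by pillars that maintain adjacency in that genome, so the missing
    homoeolog's position is bracketed by conserved synteny; or
(b) sole-homolog: the single-copy gene is the only homolog of the pillar's
    outgroup gene in its genome, so no unplaced copy could fill the hole.

An optional veto list (e.g. from a noncoding-sequence search for unannotated
homoeologs) can discard calls post hoc; without one, calls carry an
"external filter not applied" marker.  Essentiality enrichment among RGL
genes is tested with Fisher's exact test against the other single-copy
genes of the same genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RGLCall",
    "paralogy_probability",
    "call_rgls",
    "rgl_frequency_table",
    "essentiality_enrichment",
]


@dataclass
class RGLCall:
    genome_a: str
    genome_b: str
    pillar_id: str
    gene_a: str
    gene_b: str
    probability: float
    synteny_hole_pass: bool
    sole_homolog_pass: bool
    external_pass: bool | None  # None = external filter not applied
    vetoed: bool = False


def _single_track(pillar, genome: str) -> int:
    pat = pillar.pattern(genome)
    if sum(pat) != 1:
        raise ValueError(
            f"pillar {pillar.pillar_id}: genome {genome} is not single-copy")
    return pat.index(1)


def paralogy_probability(pillar, genome_a: str, genome_b: str,
                         posteriors, index: int) -> float:
    """Posterior probability that the two single-copy genes at ``pillar``
    are paralogs (descend from different parental subgenomes).

    ``index`` is the pillar's row in the posterior table.  Sums posterior
    mass over phasing states whose track-to-subgenome maps send the two
    surviving tracks to different subgenomes.
    """
    ja = _single_track(pillar, genome_a)
    jb = _single_track(pillar, genome_b)
    ga = posteriors.genomes.index(genome_a)
    gb = posteriors.genomes.index(genome_b)
    perms = posteriors.perms
    mass = 0.0
    for k, st in enumerate(posteriors.states):
        if perms[st[ga]][ja] != perms[st[gb]][jb]:
            mass += posteriors.probs[index, k]
    return float(mass)


def call_rgls(pillars, posteriors, genome_a: str, genome_b: str, *,
              threshold: float = 0.95,
              veto: set[str] | None = None) -> list[RGLCall]:
    """RGL calls between a genome pair at the given confidence threshold.

    A call is emitted when both genomes are single-copy at the pillar, the
    paralogy probability reaches ``threshold``, and the pillar passes the
    synteny-hole filter (adjacency maintained to both neighboring pillars in
    both genomes) OR the sole-homolog filter (the surviving gene is its
    genome's only homolog of the outgroup gene).  Calls whose genes appear
    in ``veto`` (e.g. with unannotated homoeolog matches in noncoding
    sequence) are kept in the output with ``vetoed=True`` so every veto is
    logged; pass ``veto=None`` to mark the external filter as not applied.
    """
    if not (0.5 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0.5, 1], got {threshold}")
    pillars = list(pillars)
    calls: list[RGLCall] = []
    m = len(pillars)
    for i, p in enumerate(pillars):
        pat_a, pat_b = p.pattern(genome_a), p.pattern(genome_b)
        if sum(pat_a) != 1 or sum(pat_b) != 1:
            continue
        prob = paralogy_probability(p, genome_a, genome_b, posteriors, i)
        if prob < threshold:
            continue
        # (a) synteny-hole: flanked on both sides by maintained adjacency
        hole = 0 < i < m - 1
        if hole:
            for g in (genome_a, genome_b):
                if not (pillars[i].adjacency.get(g, False)
                        and pillars[i + 1].adjacency.get(g, False)):
                    hole = False
                    break
        # (b) sole-homolog
        def sole(genome: str) -> bool:
            if p.homolog_counts is None:
                return False
            return p.homolog_counts.get(genome, 0) == 1

        sole_ok = sole(genome_a) and sole(genome_b)
        if not (hole or sole_ok):
            continue
        gene_a = next(g for g in p.genes[genome_a] if g is not None)
        gene_b = next(g for g in p.genes[genome_b] if g is not None)
        vetoed = veto is not None and (gene_a in veto or gene_b in veto)
        calls.append(RGLCall(
            genome_a, genome_b, p.pillar_id, gene_a, gene_b, prob,
            synteny_hole_pass=hole, sole_homolog_pass=sole_ok,
            external_pass=None if veto is None else not vetoed,
            vetoed=vetoed))
    return calls


def rgl_frequency_table(calls_by_pair: dict[tuple[str, str], list[RGLCall]],
                        n_pillars: int,
                        pairwise_ks: dict[tuple[str, str], float] | None = None,
                        ) -> pd.DataFrame:
    """Per-pair RGL counts normalized by the number of pillars analyzed.

    ``pairwise_ks`` optionally supplies each pair's summed mean Ks along the
    tree path connecting the two taxa.  No regression is fitted: the pairs
    share evolutionary history, so the points are not independent.
    """
    if n_pillars <= 0:
        raise ValueError("number of pillars must be positive")
    rows = []
    for (a, b), calls in sorted(calls_by_pair.items()):
        ks = pairwise_ks.get((a, b)) if pairwise_ks else None
        kept = [c for c in calls if not c.vetoed]
        rows.append((a, b, len(kept), len(kept) / n_pillars, ks))
    return pd.DataFrame(rows, columns=["genome_a", "genome_b", "n_rgl",
                                       "rgl_frequency", "pairwise_mean_ks"])


def essentiality_enrichment(rgl_genes, other_single_copy_genes,
                            essentiality: dict[str, bool]):
    """Fisher's exact test (two-sided) for essentiality enrichment among
    RGL genes versus the other single-copy genes of the same genome.

    Genes without a label are dropped (count reported).  Returns
    ``(table, odds_ratio, p_value, n_unlabeled)`` with ``table`` the 2x2
    [[RGL essential, RGL nonessential], [other essential, other non]].
    A zero margin yields p = 1 with a warning.
    """
    rgl_genes = [g for g in rgl_genes]
    others = [g for g in other_single_copy_genes]
    if not rgl_genes or not others:
        raise ValueError("both gene sets must be nonempty")
    n_unlabeled = sum(1 for g in rgl_genes + others if g not in essentiality)
    rgl_l = [essentiality[g] for g in rgl_genes if g in essentiality]
    oth_l = [essentiality[g] for g in others if g in essentiality]
    table = np.array([
        [sum(rgl_l), len(rgl_l) - sum(rgl_l)],
        [sum(oth_l), len(oth_l) - sum(oth_l)],
    ])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        import warnings

        warnings.warn("degenerate 2x2 table (zero margin); p set to 1")
        return table, np.nan, 1.0, n_unlabeled
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return table, float(odds), float(p), n_unlabeled
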