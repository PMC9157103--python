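"""Pillar construction: N:1 homolog assignment and synteny-aware ordering.

Starting from a homology table between an outgroup genome (which lacks the
polyploidy) and a polyploid genome, this module assigns the polyploid
homologs of each outgroup gene to ordered pillars (at most N per pillar for
an N-fold polyploidy), searching over assignments and pillar orders by
simulated annealing to maximize the number of retained synteny relations.
Two genes are in synteny when they are neighbors in their genome after
masking genes that have no homolog.  Per-genome pillar sets are then merged
(keeping only pillars with at least one homologous, syntenic gene from every
polyploid genome) and a second annealing pass finds a global pillar order
minimizing synteny breaks, emitting the per-genome adjacency flags the
phasing HMM consumes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .orthology_hmm import Pillar

__all__ = [
    "HomologyTable",
    "GenomeGeneOrder",
    "PillarAssignment",
    "AnnealSchedule",
    "count_synteny_relations",
    "anneal_assignment",
    "merge_blocks",
    "anneal_global_order",
    "count_breaks",
]


@dataclass
class HomologyTable:
    """Pairs (outgroup gene, polyploid gene) with an optional similarity
    score (higher is better; used only for deterministic tie-breaking)."""

    pairs: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        seen = set()
        for og, pg, _ in self.pairs:
            if (og, pg) in seen:
                raise ValueError(f"duplicate homology pair ({og}, {pg})")
            seen.add((og, pg))

    @property
    def outgroup_genes(self) -> list[str]:
        seen = dict.fromkeys(og for og, _, _ in self.pairs)
        return list(seen)

    def by_polyploid(self) -> dict[str, list[tuple[str, float]]]:
        out: dict[str, list[tuple[str, float]]] = {}
        for og, pg, sc in self.pairs:
            out.setdefault(pg, []).append((og, sc))
        return out

    def by_outgroup(self) -> dict[str, list[tuple[str, float]]]:
        out: dict[str, list[tuple[str, float]]] = {}
        for og, pg, sc in self.pairs:
            out.setdefault(og, []).append((pg, sc))
        return out


class GenomeGeneOrder:
    """Ordered gene lists per chromosome/scaffold of one genome."""

    def __init__(self, chromosomes: dict[str, list[str]]):
        self.chromosomes = chromosomes
        self.position: dict[str, tuple[str, int]] = {}
        for chrom, genes in chromosomes.items():
            for i, g in enumerate(genes):
                if g in self.position:
                    raise ValueError(f"gene {g} appears more than once")
                self.position[g] = (chrom, i)

    def masked_neighbors(self, gene: str, keep: set[str]) -> set[str]:
        """Nearest genes on either side of ``gene`` after dropping genes not
        in ``keep`` (neighbors are defined ignoring genes without
        homologs)."""
        if gene not in self.position:
            raise KeyError(f"unknown gene {gene!r}")
        chrom, idx = self.position[gene]
        genes = self.chromosomes[chrom]
        out: set[str] = set()
        for step in (-1, 1):
            j = idx + step
            while 0 <= j < len(genes):
                if genes[j] in keep:
                    out.add(genes[j])
                    break
                j += step
        return out


@dataclass
class PillarAssignment:
    """Ordered pillars, each with one outgroup gene and <= N polyploid
    homologs; each polyploid gene is used at most once."""

    outgroup_order: list[str]
    members: dict[str, list[str]]  # outgroup gene -> polyploid genes
    n: int
    score: int | None = None

    def __post_init__(self) -> None:
        used: set[str] = set()
        for og, genes in self.members.items():
            if len(genes) > self.n:
                raise ValueError(f"pillar {og} holds {len(genes)} genes (> N={self.n})")
            for g in genes:
                if g in used:
                    raise ValueError(f"polyploid gene {g} assigned twice")
                used.add(g)


@dataclass
class AnnealSchedule:
    """Geometric cooling schedule.

    ``moves_per_temp`` proposals are made at each temperature, the
    temperature then multiplied by ``cooling``; the search stops after
    ``patience`` temperature levels without improvement of the best score
    (or when ``max_levels`` is exhausted).  A zero-iteration schedule
    returns the scored initial state unchanged.
    """

    moves_per_temp: int = 200
    cooling: float = 0.95
    patience: int = 50
    max_levels: int = 400
    probe_moves: int = 200


def count_synteny_relations(assignment: PillarAssignment,
                            orders: dict[str, GenomeGeneOrder],
                            homology: HomologyTable) -> int:
    """Number of gene pairs in adjacent pillars that are chromosomal
    neighbors (after masking genes without homologs)."""
    keep = {pg for _, pg, _ in homology.pairs}
    order_objs = list(orders.values())

    def find_order(gene: str) -> GenomeGeneOrder:
        for o in order_objs:
            if gene in o.position:
                return o
        raise KeyError(f"unknown gene {gene!r}")

    score = 0
    seq = assignment.outgroup_order
    for i in range(len(seq) - 1):
        a = assignment.members.get(seq[i], [])
        b = set(assignment.members.get(seq[i + 1], []))
        for g in a:
            nb = find_order(g).masked_neighbors(g, keep)
            score += len(nb & b)
    return score


def _greedy_initial(homology: HomologyTable, n: int) -> PillarAssignment:
    """Deterministic initial assignment: outgroup genes in table order; each
    polyploid gene goes to its best-scoring candidate pillar with spare
    capacity (ties by score then lexicographic gene id)."""
    members: dict[str, list[str]] = {og: [] for og in homology.outgroup_genes}
    by_pg = homology.by_polyploid()
    for pg in sorted(by_pg):
        cands = sorted(by_pg[pg], key=lambda t: (-t[1], t[0]))
        for og, _ in cands:
            if len(members[og]) < n:
                members[og].append(pg)
                break
    return PillarAssignment(homology.outgroup_genes, members, n)


def _anneal(state, score_fn, proposals, schedule: AnnealSchedule, rng,
            maximize: bool = True):
    """Generic simulated-annealing loop; returns the best-visited state and
    score (never worse than the initial one)."""
    sign = 1.0 if maximize else -1.0
    cur = state
    cur_score = score_fn(cur)
    best, best_score = cur, cur_score
    if schedule.moves_per_temp <= 0 or schedule.max_levels <= 0:
        return best, best_score

    # probe moves tune the initial temperature to ~50% acceptance
    deltas = []
    probe = cur
    for _ in range(schedule.probe_moves):
        cand = proposals(probe, rng)
        if cand is None:
            continue
        deltas.append(abs(score_fn(cand) - cur_score))
    t = max(np.median(deltas) / np.log(2.0), 1e-6) if deltas else 1.0

    stale = 0
    for _level in range(schedule.max_levels):
        improved = False
        for _ in range(schedule.moves_per_temp):
            cand = proposals(cur, rng)
            if cand is None:
                continue
            cand_score = score_fn(cand)
            d = sign * (cand_score - cur_score)
            if d >= 0 or rng.random() < np.exp(d / t):
                cur, cur_score = cand, cand_score
                if sign * (cur_score - best_score) > 0:
                    best, best_score = cur, cur_score
                    improved = True
        t *= schedule.cooling
        stale = 0 if improved else stale + 1
        if stale >= schedule.patience:
            break
    return best, best_score


def anneal_assignment(homology: HomologyTable,
                      orders: dict[str, GenomeGeneOrder], n: int,
                      schedule: AnnealSchedule | None = None,
                      seed: int = 0) -> PillarAssignment:
    """Simulated-annealing search over homolog-to-pillar assignments and
    pillar orderings maximizing :func:`count_synteny_relations`."""
    if n not in (2, 3, 4):
        raise ValueError(f"polyploidy order N must be 2, 3 or 4, got {n}")
    if not homology.pairs:
        raise ValueError("homology table is empty")
    schedule = schedule or AnnealSchedule()
    rng = np.random.default_rng(seed)
    by_pg = homology.by_polyploid()
    ambiguous = [pg for pg, cands in by_pg.items() if len(cands) > 1]

    def score_fn(a: PillarAssignment) -> int:
        return count_synteny_relations(a, orders, homology)

    def proposals(a: PillarAssignment, rng):
        order = list(a.outgroup_order)
        members = {k: list(v) for k, v in a.members.items()}
        kind = rng.integers(3 if ambiguous else 2)
        if ambiguous and kind == 2:  # reassign an ambiguous homolog
            pg = ambiguous[rng.integers(len(ambiguous))]
            cur_home = next((og for og, gs in members.items() if pg in gs), None)
            cands = [og for og, _ in by_pg[pg] if og != cur_home]
            if not cands:
                return None
            dest = cands[rng.integers(len(cands))]
            if len(members[dest]) >= a.n:
                return None
            if cur_home is not None:
                members[cur_home].remove(pg)
            members[dest].append(pg)
        elif kind == 0:  # swap two pillars
            i, j = rng.integers(len(order)), rng.integers(len(order))
            order[i], order[j] = order[j], order[i]
        else:  # relocate a short pillar block
            ln = int(rng.integers(1, min(3, len(order)) + 1))
            i = int(rng.integers(len(order) - ln + 1))
            block = order[i:i + ln]
            rest = order[:i] + order[i + ln:]
            j = int(rng.integers(len(rest) + 1))
            order = rest[:j] + block + rest[j:]
        return PillarAssignment(order, members, a.n)

    init = _greedy_initial(homology, n)
    best, best_score = _anneal(init, score_fn, proposals, schedule, rng,
                               maximize=True)
    best.score = best_score
    return best


def merge_blocks(assignments: dict[str, PillarAssignment]):
    """Merge per-genome pillar assignments by outgroup gene.

    Only pillars with at least one gene from every polyploid genome are
    kept; the dropped count is reported.  Returns ``(merged, n_dropped)``
    where ``merged`` is a list of dicts ``{outgroup, genes: {genome: [...]}}``
    in the first genome's pillar order.
    """
    genomes = list(assignments)
    if not genomes:
        raise ValueError("no assignments to merge")
    key_sets = [set(a.members) for a in assignments.values()]
    if any(ks != key_sets[0] for ks in key_sets[1:]):
        raise ValueError("assignments are not keyed to the same outgroup gene set")
    order = assignments[genomes[0]].outgroup_order
    merged = []
    dropped = 0
    for og in order:
        genes = {g: list(assignments[g].members.get(og, [])) for g in genomes}
        if all(genes[g] for g in genomes):
            merged.append({"outgroup": og, "genes": genes})
        else:
            dropped += 1
    if not merged:
        import warnings

        warnings.warn("no pillars survive merging; genomes share no pillars")
    return merged, dropped


def count_breaks(merged: list[dict], orders: dict[str, GenomeGeneOrder]) -> int:
    """Total synteny breaks over all genomes for a merged pillar order."""
    return sum(int(not f) for flags in _adjacency_flags(merged, orders).values()
               for f in flags[1:])


def _adjacency_flags(merged: list[dict],
                     orders: dict[str, GenomeGeneOrder]) -> dict[str, list[bool]]:
    """Per-genome adjacency flags: synteny maintained between consecutive
    pillars iff some gene pair across them are neighbors in that genome
    after masking genes outside the pillar set."""
    genomes = list(orders)
    keep = {g: {gene for p in merged for gene in p["genes"].get(g, [])}
            for g in genomes}
    flags = {g: [True] * len(merged) for g in genomes}
    for g in genomes:
        o = orders[g]
        for i in range(1, len(merged)):
            prev = merged[i - 1]["genes"].get(g, [])
            cur = set(merged[i]["genes"].get(g, []))
            ok = False
            for gene in prev:
                if o.masked_neighbors(gene, keep[g]) & cur:
                    ok = True
                    break
            flags[g][i] = ok
    return flags


def anneal_global_order(merged: list[dict], orders: dict[str, GenomeGeneOrder],
                        schedule: AnnealSchedule | None = None,
                        seed: int = 0, ploidy: int = 2):
    """Anneal the global pillar order to minimize total synteny breaks.

    Returns ``(pillars, n_breaks)`` where ``pillars`` are
    :class:`~polyphase.orthology_hmm.Pillar` objects in the optimized order
    with per-genome adjacency flags set.
    """
    if not merged:
        raise ValueError("merged pillar set is empty")
    schedule = schedule or AnnealSchedule()
    rng = np.random.default_rng(seed)

    def score_fn(seq: tuple[int, ...]) -> int:
        return count_breaks([merged[i] for i in seq], orders)

    def proposals(seq: tuple[int, ...], rng):
        order = list(seq)
        kind = rng.integers(3)
        if kind == 0:
            i, j = rng.integers(len(order)), rng.integers(len(order))
            order[i], order[j] = order[j], order[i]
        elif kind == 1:  # relocate a block
            ln = int(rng.integers(1, min(3, len(order)) + 1))
            i = int(rng.integers(len(order) - ln + 1))
            block = order[i:i + ln]
            rest = order[:i] + order[i + ln:]
            j = int(rng.integers(len(rest) + 1))
            order = rest[:j] + block + rest[j:]
        else:  # reverse a block
            i, j = sorted((int(rng.integers(len(order))),
                           int(rng.integers(len(order)))))
            order[i:j + 1] = order[i:j + 1][::-1]
        return tuple(order)

    init = tuple(range(len(merged)))
    best_seq, best_breaks = _anneal(init, score_fn, proposals, schedule, rng,
                                    maximize=False)
    ordered = [merged[i] for i in best_seq]
    flags = _adjacency_flags(ordered, orders)
    genomes = list(orders)
    pillars = []
    for i, p in enumerate(ordered):
        genes = {}
        for g in genomes:
            gs = p["genes"].get(g, [])[:ploidy]
            genes[g] = tuple(gs + [None] * (ploidy - len(gs)))
        adjacency = {g: (True if i == 0 else flags[g][i]) for g in genomes}
        pillars.append(Pillar(p["outgroup"], genes, adjacency))
    return pillars, int(best_breaks)
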