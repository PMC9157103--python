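"""Irreversible continuous-time Markov models of homoeolog loss after polyploidy.

After a whole-genome duplication (WGD), triplication (WGT) or quadruplication
(WGQ), each ancestral locus ("pillar") carries several homoeologous gene
copies, one per parental subgenome.  Over time copies are lost, and the loss
process can be biased toward one subgenome (biased fractionation), can commit
a locus to permanent duplicate retention (fixation), or can predispose
independent lineages to lose the same copy (convergent loss).  This module
builds the state spaces, rate generators and transition-probability matrices
for those processes.  All rates are relative to a base loss rate of 1, so a
branch length in these models is the expected number of base-rate loss events
(the "alpha*t" scale).

The WGD model has six states:

    U  -- undifferentiated duplicate (both copies present, none committed)
    C1 -- converging: committed to keep only the subgenome-1 copy
    C2 -- converging: committed to keep only the subgenome-2 copy
    F  -- fixed duplicate (both copies permanently retained)
    S1 -- single copy, subgenome 1 survives
    S2 -- single copy, subgenome 2 survives

U exits to S1 at rate 1, to S2 at rate epsilon (<=1: subgenome 1 is by
convention the less fractionated one), to C1 and C2 each at rate delta and to
F at rate gamma.  C1 -> S1 and C2 -> S2 proceed at the base rate 1 (an
optional variant biases the C2 exit by epsilon).  F, S1 and S2 are absorbing.
The null model is gamma = delta = 0, epsilon = 1.

The WGT model tracks three subgenomes through state T (triplicated), the
duplicated states D_{x,y} and single-copy states S_x; loss of copy 3 (to
D_{1,2}) proceeds at the base rate, losses to D_{1,3} and D_{2,3} at the
relative rates f13 and f23, and D -> S exits at per-subgenome rates sigma_x.

The WGQ model tracks four exchangeable subgenomes (Q, four T states, six D
states, four S states) with relative rates delta (T -> D) and sigma (D -> S).
A two-step formation model replaces the all-mass-on-Q root distribution with
a mixture over {Q, D_{1,2}, D_{3,4}} governed by the symmetric inter-event
loss rate lambda.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

__all__ = [
    "WGDModelSpec",
    "WGTModelSpec",
    "WGQModelSpec",
    "LossGenerator",
    "build_wgd_generator",
    "build_wgt_generator",
    "build_wgq_generator",
    "build_generator",
    "wgq_formation_distribution",
    "transition_matrix",
    "spec_from_name",
    "MODEL_NAMES",
]


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass
class WGDModelSpec:
    """Parameters of the tetraploid (WGD) loss model.

    epsilon: fractionation-bias multiplier, 0 < epsilon <= 1.
    gamma:   relative rate of duplicate fixation (U -> F), >= 0.
    delta:   relative rate of convergent commitment (U -> C1/C2), >= 0.
    biased_c: if True, the C2 -> S2 exit is also scaled by epsilon
        (the "biased converging states" variant); by default the C exits
        are unbiased, which fits observed loss data equally well.
    root_epsilon: optional separate fractionation bias on the root branch
        (the interval between the polyploidy and the first speciation).
    free_*: which parameters are free in a maximum-likelihood fit.
    """

    epsilon: float = 1.0
    gamma: float = 0.0
    delta: float = 0.0
    biased_c: bool = False
    root_epsilon: float | None = None
    free_epsilon: bool = False
    free_gamma: bool = False
    free_delta: bool = False
    free_root_epsilon: bool = False

    def __post_init__(self) -> None:
        _check(0.0 < self.epsilon <= 1.0, f"epsilon must be in (0, 1], got {self.epsilon}")
        _check(self.gamma >= 0.0, f"gamma must be >= 0, got {self.gamma}")
        _check(self.delta >= 0.0, f"delta must be >= 0, got {self.delta}")
        if self.root_epsilon is not None:
            _check(
                0.0 < self.root_epsilon <= 1.0,
                f"root_epsilon must be in (0, 1], got {self.root_epsilon}",
            )

    @property
    def is_null(self) -> bool:
        return self.epsilon == 1.0 and self.gamma == 0.0 and self.delta == 0.0

    @classmethod
    def null(cls) -> "WGDModelSpec":
        return cls()


@dataclass
class WGTModelSpec:
    """Parameters of the hexaploid (WGT) loss model.

    f13, f23: relative rates of the T -> D_{1,3} and T -> D_{2,3} losses
        (the T -> D_{1,2} loss has the base rate 1); subgenome 1 is favored,
        so f23 <= f13 <= 1 in the fitted models.
    sigma1..sigma3: relative per-subgenome loss rates from duplicated to
        single-copy states (D_{x,y} -> S_x at sigma_x).
    root_spec: optional separate parameter set for the root branch.
    """

    f13: float = 1.0
    f23: float = 1.0
    sigma1: float = 1.0
    sigma2: float = 1.0
    sigma3: float = 1.0
    root_spec: "WGTModelSpec | None" = None
    free_f: bool = False
    free_sigma: bool = False

    def __post_init__(self) -> None:
        for name in ("f13", "f23", "sigma1", "sigma2", "sigma3"):
            _check(getattr(self, name) > 0.0, f"{name} must be positive, got {getattr(self, name)}")

    @property
    def sigmas(self) -> tuple[float, float, float]:
        return (self.sigma1, self.sigma2, self.sigma3)

    @classmethod
    def null(cls) -> "WGTModelSpec":
        return cls()


@dataclass
class WGQModelSpec:
    """Parameters of the octoploid (WGQ) loss model.

    delta: relative triplicated -> duplicated loss rate.
    sigma: relative duplicated -> single-copy loss rate.
    lam:   symmetric inter-event loss rate of the two-step formation model.
    formation: if True, the root distribution is the formation mixture over
        {Q, D_{1,2}, D_{3,4}}; otherwise all mass starts on Q.
    """

    delta: float = 1.0
    sigma: float = 1.0
    lam: float = 0.0
    formation: bool = False
    free_delta: bool = False
    free_sigma: bool = False
    free_lam: bool = False

    def __post_init__(self) -> None:
        _check(self.delta > 0.0, f"delta must be positive, got {self.delta}")
        _check(self.sigma > 0.0, f"sigma must be positive, got {self.sigma}")
        _check(self.lam >= 0.0, f"lam must be >= 0, got {self.lam}")

    @classmethod
    def null(cls) -> "WGQModelSpec":
        return cls()


@dataclass(frozen=True)
class LossGenerator:
    """A rate generator over an ordered, irreversible loss-state space.

    states:      state labels, topologically ordered (a transition i -> j
                 implies i < j, so the rate matrix is strictly upper
                 triangular off the diagonal).
    rate_matrix: square generator (rows sum to zero; absorbing rows all-zero).
    obs_map:     per state, the presence(1)/absence(0) pattern over subgenome
                 copies that the state emits.
    root_dist:   distribution over states at the polyploidy event.
    """

    states: tuple[str, ...]
    rate_matrix: np.ndarray
    obs_map: tuple[tuple[int, ...], ...]
    root_dist: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.rate_matrix, dtype=float)
        n = len(self.states)
        _check(q.shape == (n, n), "rate matrix shape must match the state count")
        _check(np.allclose(q.sum(axis=1), 0.0, atol=1e-12), "generator rows must sum to zero")
        _check(np.all(np.tril(q, -1) == 0.0), "generator must be irreversible (upper triangular)")
        _check(len(self.obs_map) == n, "observation map must cover every state")
        r = np.asarray(self.root_dist, dtype=float)
        _check(r.shape == (n,) and abs(r.sum() - 1.0) < 1e-12 and np.all(r >= 0.0),
               "root distribution must be a probability vector over the states")
        object.__setattr__(self, "rate_matrix", q)
        object.__setattr__(self, "root_dist", r)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_subgenomes(self) -> int:
        return len(self.obs_map[0])

    def state_index(self, label: str) -> int:
        return self.states.index(label)

    @property
    def absorbing(self) -> np.ndarray:
        """Boolean mask of absorbing states (all-zero rows)."""
        return np.all(self.rate_matrix == 0.0, axis=1)

    @property
    def single_copy_states(self) -> np.ndarray:
        """Boolean mask of states emitting exactly one surviving copy."""
        return np.array([sum(p) == 1 for p in self.obs_map])


def build_wgd_generator(spec: WGDModelSpec, *, root_branch: bool = False) -> LossGenerator:
    """Six-state WGD loss generator over {U, C1, C2, F, S1, S2}.

    With ``root_branch=True`` and a root-specific epsilon in the spec, the
    root value replaces the shared one (all other parameters are shared).
    """
    eps = spec.epsilon
    if root_branch and spec.root_epsilon is not None:
        eps = spec.root_epsilon
    states = ("U", "C1", "C2", "F", "S1", "S2")
    q = np.zeros((6, 6))
    # U exits
    q[0, 4] = 1.0          # U -> S1 at the base rate
    q[0, 5] = eps          # U -> S2, biased by epsilon
    q[0, 1] = spec.delta   # U -> C1
    q[0, 2] = spec.delta   # U -> C2
    q[0, 3] = spec.gamma   # U -> F
    # converging states commit at the base rate (optionally biased)
    q[1, 4] = 1.0
    q[2, 5] = eps if spec.biased_c else 1.0
    np.fill_diagonal(q, -q.sum(axis=1))
    root = np.zeros(6)
    root[0] = 1.0
    obs = ((1, 1), (1, 1), (1, 1), (1, 1), (1, 0), (0, 1))
    return LossGenerator(states, q, obs, root)


def build_wgt_generator(spec: WGTModelSpec, *, root_branch: bool = False) -> LossGenerator:
    """Seven-state WGT loss generator over {T, D12, D13, D23, S1, S2, S3}."""
    if root_branch and spec.root_spec is not None:
        spec = spec.root_spec
    states = ("T", "D12", "D13", "D23", "S1", "S2", "S3")
    pairs = {"D12": (0, 1), "D13": (0, 2), "D23": (1, 2)}
    sig = spec.sigmas
    q = np.zeros((7, 7))
    q[0, 1] = 1.0       # T -> D12 (copy 3 lost) at the base rate
    q[0, 2] = spec.f13  # T -> D13 (copy 2 lost)
    q[0, 3] = spec.f23  # T -> D23 (copy 1 lost)
    for name, (x, y) in pairs.items():
        i = states.index(name)
        q[i, 4 + x] = sig[x]
        q[i, 4 + y] = sig[y]
    np.fill_diagonal(q, -q.sum(axis=1))
    root = np.zeros(7)
    root[0] = 1.0
    obs = [(1, 1, 1)]
    for x, y in pairs.values():
        obs.append(tuple(1 if k in (x, y) else 0 for k in range(3)))
    for x in range(3):
        obs.append(tuple(1 if k == x else 0 for k in range(3)))
    return LossGenerator(states, q, tuple(obs), root)


def _wgq_states() -> list[frozenset[int]]:
    """States of the WGQ model as retained-subgenome subsets, by size 4..1."""
    out: list[frozenset[int]] = [frozenset(range(4))]
    for size in (3, 2, 1):
        out.extend(frozenset(c) for c in itertools.combinations(range(4), size))
    return out


def _wgq_label(s: frozenset[int]) -> str:
    digits = "".join(str(i + 1) for i in sorted(s))
    return {4: "Q", 3: "T", 2: "D", 1: "S"}[len(s)] + (digits if len(s) < 4 else "")


def build_wgq_generator(spec: WGQModelSpec, *, root_branch: bool = False) -> LossGenerator:
    """Fifteen-state WGQ loss generator over {Q, T_xyz, D_xy, S_x}.

    Q loses each copy at the base rate 1; triplicated states lose each
    remaining copy at rate delta; duplicated states at rate sigma.  With the
    formation model enabled, the root distribution is the two-step mixture
    over {Q, D12, D34} at rate lam (see :func:`wgq_formation_distribution`).
    """
    subsets = _wgq_states()
    index = {s: i for i, s in enumerate(subsets)}
    states = tuple(_wgq_label(s) for s in subsets)
    rate_by_size = {4: 1.0, 3: spec.delta, 2: spec.sigma}
    n = len(subsets)
    q = np.zeros((n, n))
    for s, i in index.items():
        if len(s) == 1:
            continue
        r = rate_by_size[len(s)]
        for g in s:
            q[i, index[s - {g}]] = r
    np.fill_diagonal(q, -q.sum(axis=1))
    if spec.formation:
        root = wgq_formation_distribution(spec.lam)
    else:
        root = np.zeros(n)
        root[0] = 1.0
    obs = tuple(tuple(1 if k in s else 0 for k in range(4)) for s in subsets)
    return LossGenerator(states, q, obs, root)


def wgq_formation_distribution(lam: float) -> np.ndarray:
    """Root-state distribution of the two-step octoploid formation model.

    The intermediate tetraploid (state D13 relative to the final four
    subgenomes) can lose the subgenome-1 or subgenome-3 copy, each at rate
    lam, during the unobserved interval between the two doublings.  A pillar
    with no such loss becomes quadruplicated (Q) at the second doubling; a
    pillar that lost one copy doubles into D12 or D34, symmetrically.
    Returns the full 15-state distribution with mass on {Q, D12, D34}.
    """
    _check(lam >= 0.0, f"lam must be >= 0, got {lam}")
    subsets = _wgq_states()
    index = {s: i for i, s in enumerate(subsets)}
    p_q = np.exp(-2.0 * lam)
    root = np.zeros(len(subsets))
    root[0] = p_q
    root[index[frozenset({0, 1})]] = (1.0 - p_q) / 2.0
    root[index[frozenset({2, 3})]] = (1.0 - p_q) / 2.0
    return root


def transition_matrix(gen: LossGenerator, branch_length: float) -> np.ndarray:
    """Transition probabilities over a branch of the given expected-loss length.

    Dense scaling-and-squaring matrix exponential of ``Q * t``; the state
    spaces are small (<= 15 states) so no structure beyond validation is
    exploited.
    """
    _check(branch_length >= 0.0, f"branch length must be >= 0, got {branch_length}")
    if branch_length == 0.0:
        return np.eye(gen.n_states)
    p = expm(gen.rate_matrix * branch_length)
    p = np.clip(p, 0.0, 1.0)
    # renormalize away roundoff so downstream likelihoods stay stochastic
    return p / p.sum(axis=1, keepdims=True)


MODEL_NAMES = (
    "wgd-null", "wgd-b", "wgd-bf", "wgd-bc", "wgd-bfc-nb", "wgd-bfc",
    "wgd-bf-roote", "wgt-g3", "wgq-null", "wgq-form",
)


def spec_from_name(name: str):
    """Map a model name to a spec with the matching free-parameter flags.

    The WGD family is nested: ``wgd-null`` (no free loss parameters),
    ``wgd-b`` (free epsilon), ``wgd-bf`` (epsilon, gamma), ``wgd-bc``
    (epsilon, delta), ``wgd-bfc-nb`` (epsilon, gamma, delta; unbiased C
    states), ``wgd-bfc`` (additionally biasing the C2 exit by epsilon) and
    ``wgd-bf-roote`` (wgd-bf with a separate root-branch epsilon).
    """
    wgd = {
        "wgd-null": dict(),
        "wgd-b": dict(free_epsilon=True),
        "wgd-bf": dict(free_epsilon=True, free_gamma=True),
        "wgd-bc": dict(free_epsilon=True, free_delta=True),
        "wgd-bfc-nb": dict(free_epsilon=True, free_gamma=True, free_delta=True),
        "wgd-bfc": dict(free_epsilon=True, free_gamma=True, free_delta=True, biased_c=True),
        "wgd-bf-roote": dict(free_epsilon=True, free_gamma=True,
                             free_root_epsilon=True, root_epsilon=1.0),
    }
    if name in wgd:
        return WGDModelSpec(**wgd[name])
    if name == "wgt-g3":
        return WGTModelSpec(free_f=True, free_sigma=True)
    if name == "wgq-null":
        return WGQModelSpec(free_delta=True, free_sigma=True)
    if name == "wgq-form":
        return WGQModelSpec(formation=True, free_delta=True, free_sigma=True, free_lam=True)
    raise ValueError(f"unknown model name {name!r}; choose from {MODEL_NAMES}")


def build_generator(spec, *, root_branch: bool = False) -> LossGenerator:
    """Dispatch to the family-specific builder based on the spec type."""
    if isinstance(spec, WGDModelSpec):
        return build_wgd_generator(spec, root_branch=root_branch)
    if isinstance(spec, WGTModelSpec):
        return build_wgt_generator(spec, root_branch=root_branch)
    if isinstance(spec, WGQModelSpec):
        return build_wgq_generator(spec, root_branch=root_branch)
    raise TypeError(f"unsupported model spec type {type(spec).__name__}")
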