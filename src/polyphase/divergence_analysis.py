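"""Synonymous-divergence (Ks) analyses of post-polyploidy evolution.

Given per-pillar, per-branch Ks/Ka tables (estimated upstream from codon
models on mirrored gene trees) and the orthology posteriors, this module

* selects the "nearly fully duplicated" pillars eligible for divergence
  estimation (per-event missing-copy rules),
* filters pillars showing strong evidence of homoeolog gene conversion
  (conversion-tree likelihood exceeding the species-tree likelihood),
* summarizes Ks per branch, halving root-branch values so the shared
  internal branch of a mirrored gene tree is comparable to the others,
* fits 1- vs 2-component lognormal mixtures to root-branch Ks (a second,
  smaller mode would indicate homoeologous exchange), selecting by BIC,
* forms the loss-rate-per-synonymous-divergence ratio alpha*t / mean(Ks)
  per branch with Monte-Carlo confidence intervals, and
* compares selective constraint (Ka/Ks) across five classes of pillars
  defined by where the duplicate losses happened.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "KS_MIN",
    "KS_MAX",
    "BranchSummary",
    "MixtureFit",
    "RatioCI",
    "select_duplicate_pillars",
    "filter_gene_conversion",
    "branch_ks_summary",
    "fit_root_ks_mixture",
    "loss_rate_ratio",
    "constraint_by_class",
    "CONSTRAINT_CLASSES",
]

# Ks window: values below KS_MIN carry no synonymous signal, values above
# KS_MAX are saturated; both are excluded before mixture fitting.
KS_MIN = 5e-3
KS_MAX = 2.0


# ---------------------------------------------------------------------------
# pillar selection


_PROFILES = {
    # max missing copies per duplicated subtree, max total missing
    "default": (1, 2),    # tetraploidies: <=1 missing per subtree, 2 total
    "relaxed": (2, 4),    # yeast WGD / teleost duplication: <=2 per subtree
    "triplicated": (0, 0),  # hexaploidy: fully triplicated pillars only
}


def select_duplicate_pillars(pillars, posteriors, profile: str = "default", *,
                             confidence: float = 0.95) -> list[str]:
    """Pillar ids eligible for divergence estimation.

    For each pillar the decoded phasing assigns every missing copy to a
    subgenome; the per-subgenome ("per gene subtree") missing counts must not
    exceed the profile's limits, and the decoded state's posterior must reach
    ``confidence``.
    """
    if profile not in _PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(_PROFILES)}")
    per_subtree, total_max = _PROFILES[profile]
    states = posteriors.states
    perms = posteriors.perms
    out = []
    for i, p in enumerate(pillars):
        if posteriors.best_prob[i] < confidence:
            continue
        st = states[posteriors.best_index[i]]
        missing = None
        for g_i, g in enumerate(posteriors.genomes):
            tracks = p.genes[g]
            perm = perms[st[g_i]]
            if missing is None:
                missing = [0] * len(perm)
            for j, gene in enumerate(tracks):
                if gene is None:
                    missing[perm[j]] += 1
        if missing is None:
            continue
        if max(missing) <= per_subtree and sum(missing) <= total_max:
            out.append(p.pillar_id)
    return out


def filter_gene_conversion(table: pd.DataFrame) -> tuple[list[str], int]:
    """Drop pillars whose gene-conversion-tree likelihood exceeds the
    species-tree likelihood; ties are retained.

    ``table`` needs columns pillar_id, lnL_species, lnL_conversion.
    Returns ``(retained_ids, n_dropped)``.
    """
    for col in ("pillar_id", "lnL_species", "lnL_conversion"):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    keep = table["lnL_conversion"] <= table["lnL_species"]
    return list(table.loc[keep, "pillar_id"]), int((~keep).sum())


# ---------------------------------------------------------------------------
# per-branch summaries and ratios


@dataclass
class BranchSummary:
    branch_id: str
    mean_ks: float
    var_ks: float | None   # sample variance of the (root-halved) Ks values
    n: int
    is_root: bool
    alpha_t: float | None = None
    var_alpha_t: float | None = None


def branch_ks_summary(records: pd.DataFrame, root_branch_id: str = "root",
                      ) -> dict[str, BranchSummary]:
    """Per-branch mean and sample variance of Ks.

    Root-branch values are halved before averaging (the shared internal
    branch of a mirrored gene tree spans the divergence twice).  Branches
    with fewer than 2 records are flagged (no variance).
    """
    out: dict[str, BranchSummary] = {}
    for branch, grp in records.groupby("branch_id"):
        ks = grp["Ks"].to_numpy(dtype=float)
        is_root = branch == root_branch_id
        if is_root:
            ks = ks / 2.0
        n = len(ks)
        out[branch] = BranchSummary(
            branch_id=branch,
            mean_ks=float(ks.mean()),
            var_ks=float(ks.var(ddof=1)) if n >= 2 else None,
            n=n,
            is_root=is_root,
        )
    return out


@dataclass
class RatioCI:
    ratio: float
    lo: float
    hi: float
    draws: int
    n_redrawn: int


def loss_rate_ratio(alpha_t: float, var_alpha_t: float, mean_ks: float,
                    var_mean_ks: float, *, draws: int = 1000,
                    seed: int = 0) -> RatioCI:
    """Monte-Carlo 95% CI for the loss rate per unit synonymous divergence.

    Numerator (the alpha*t branch length MLE) and denominator (the branch
    mean Ks) are treated as independent normal variables at their estimates;
    ``draws`` ratio samples (default 1,000) are sorted and the empirical
    2.5%/97.5% quantiles taken.  Nonpositive denominator draws are redrawn
    (count reported) so exactly ``draws`` ratios enter the quantiles.
    """
    if mean_ks <= 0:
        raise ValueError(f"mean Ks must be positive, got {mean_ks}")
    if var_alpha_t < 0 or var_mean_ks < 0:
        raise ValueError("variances must be nonnegative")
    rng = np.random.default_rng(seed)
    num = rng.normal(alpha_t, np.sqrt(var_alpha_t), size=draws)
    den = rng.normal(mean_ks, np.sqrt(var_mean_ks), size=draws)
    n_redrawn = 0
    if var_mean_ks > 0:
        bad = den <= 0
        while bad.any():
            n_redrawn += int(bad.sum())
            den[bad] = rng.normal(mean_ks, np.sqrt(var_mean_ks), size=int(bad.sum()))
            bad = den <= 0
    ratios = np.sort(num / den)
    lo, hi = np.quantile(ratios, [0.025, 0.975])
    return RatioCI(alpha_t / mean_ks, float(lo), float(hi), draws, n_redrawn)


# ---------------------------------------------------------------------------
# lognormal mixture on the root branch


@dataclass
class MixtureFit:
    k: int                       # selected component count (1 or 2)
    bic1: float
    bic2: float
    means: np.ndarray            # log-scale means, sorted ascending
    sds: np.ndarray              # log-scale standard deviations
    weights: np.ndarray          # mixing weights (sum to 1)
    p: float | None              # weight of the larger-Ks component if k == 2
    n_used: int
    n_excluded: int


def fit_root_ks_mixture(values, *, seed: int = 0, n_restarts: int = 20,
                        min_n: int = 20, ks_min: float = KS_MIN,
                        ks_max: float = KS_MAX) -> MixtureFit:
    """Fit 1- vs 2-component lognormal mixtures to root-branch Ks values.

    Values outside the (ks_min, ks_max) window -- no synonymous signal or
    saturated divergence, respectively -- are excluded first.  Each
    component count is fit by EM on log-values with ``n_restarts`` seeded
    restarts (one quantile-based start plus random starts) and the winner
    chosen by BIC = -2 lnL + (#params) ln(n) with 2 parameters for k=1 and 5
    for k=2.  ``p`` reports the mixing weight of the larger-divergence mode.
    """
    from sklearn.mixture import GaussianMixture

    values = np.asarray(values, dtype=float)
    inside = (values > ks_min) & (values < ks_max)
    x = np.log(values[inside])[:, None]
    n_excluded = int((~inside).sum())
    if len(x) < min_n:
        raise ValueError(
            f"only {len(x)} Ks values inside the ({ks_min}, {ks_max}) window; "
            f"need at least {min_n}")

    def best_fit(k: int) -> GaussianMixture:
        best = None
        quantiles = np.quantile(x[:, 0], np.linspace(0.25, 0.75, k))[:, None]
        starts = [GaussianMixture(k, means_init=quantiles, random_state=seed)]
        for r in range(n_restarts - 1):
            starts.append(GaussianMixture(k, init_params="random",
                                          random_state=seed + r + 1))
        for gm in starts:
            gm.fit(x)
            if best is None or gm.lower_bound_ > best.lower_bound_:
                best = gm
        return best

    g1, g2 = best_fit(1), best_fit(2)
    bic1, bic2 = float(g1.bic(x)), float(g2.bic(x))
    chosen = g1 if bic1 <= bic2 else g2
    order = np.argsort(chosen.means_[:, 0])
    means = chosen.means_[order, 0]
    sds = np.sqrt(chosen.covariances_[order, 0, 0])
    weights = chosen.weights_[order]
    k = chosen.n_components
    return MixtureFit(k=k, bic1=bic1, bic2=bic2, means=means, sds=sds,
                      weights=weights,
                      p=float(weights[-1]) if k == 2 else None,
                      n_used=len(x), n_excluded=n_excluded)


# ---------------------------------------------------------------------------
# selective-constraint classes


CONSTRAINT_CLASSES = {
    1: "single-copy everywhere, lost on the root branch",
    2: "single-copy everywhere, lost after the first speciation",
    3: "duplicate surviving in exactly one species",
    4: "duplicate surviving in all but one species",
    5: "duplicate surviving in every species",
}


@dataclass
class ClassSummary:
    label: str
    n: int
    mean: float | None
    lo: float | None
    hi: float | None


def constraint_by_class(pillars, posteriors, ka_ks: pd.DataFrame,
                        root_loss_prob: np.ndarray, *,
                        threshold: float = 0.95) -> dict:
    """Mean Ka/Ks with normal-approximation CIs for five pillar classes.

    A pillar's duplicate count is the number of genomes retaining both
    copies.  Fully single-copy pillars split on whether the posterior
    probability of root-branch loss (``root_loss_prob``, aligned with
    ``pillars``) reaches ``threshold`` (class 1) or not (class 2); pillars
    with duplicates in an intermediate number of genomes are reported in the
    "unassignable" bin.  ``ka_ks`` needs pillar_id and Ka_over_Ks columns
    (a pillar's records are averaged first).
    """
    per_pillar = ka_ks.groupby("pillar_id")["Ka_over_Ks"].mean()
    assign: dict[str, int | None] = {}
    for i, p in enumerate(pillars):
        n_taxa = len(p.genes)
        dup = sum(1 for tracks in p.genes.values()
                  if sum(t is not None for t in tracks) > 1)
        if dup == n_taxa:
            cls = 5
        elif dup == 0:
            cls = 1 if root_loss_prob[i] >= threshold else 2
        elif dup == 1:
            cls = 3
        elif dup == n_taxa - 1:
            cls = 4
        else:
            cls = None
        assign[p.pillar_id] = cls

    out: dict = {"unassignable": []}
    for c, label in CONSTRAINT_CLASSES.items():
        ids = [pid for pid, cl in assign.items() if cl == c]
        vals = per_pillar.reindex(ids).dropna().to_numpy()
        if len(vals) == 0:
            out[c] = ClassSummary(label, 0, None, None, None)
            continue
        mean = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        out[c] = ClassSummary(label, len(vals), mean,
                              mean - 1.96 * se, mean + 1.96 * se)
    out["unassignable"] = [pid for pid, cl in assign.items() if cl is None]
    out["assignment"] = assign
    return out
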