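"""Phasing HMM: oracle equivalence, closed forms, fitting and decoding."""

import itertools

import numpy as np
import pytest

from conftest import (
    enumerate_emission,
    enumerate_path_likelihood,
    random_wgd_pillars,
)
from polyphase.loss_models import (
    WGDModelSpec,
    WGQModelSpec,
    build_generator,
    build_wgd_generator,
)
from polyphase.orthology_hmm import (
    Pillar,
    SpeciesTree,
    compile_pillars,
    emission_likelihood,
    emission_matrix,
    fit_model,
    forward_loglikelihood,
    likelihood_ratio_test,
    observed_information,
    param_variance,
    phase_wgq,
    phasing_states,
    phasing_transition_matrix,
    posterior_decode,
    search_topology,
    _rooted_topologies,
)


class TestSpeciesTree:
    def test_newick_round_trip_and_root_branch(self):
        t = SpeciesTree.from_newick("((A:0.1,B:0.2):0.3,C:0.4):0.5;")
        assert sorted(t.leaves) == ["A", "B", "C"]
        assert t.root_length == 0.5
        t2 = SpeciesTree.from_newick(t.to_newick())
        assert np.allclose(sorted(t2.lengths), sorted(t.lengths))

    def test_duplicate_leaves_rejected(self):
        with pytest.raises(ValueError):
            SpeciesTree.from_newick("(A:0.1,A:0.2):0.3;")


class TestPhasingTransitionMatrix:
    def test_wgd_state_space_has_four_states_for_two_genomes(self):
        states, labels, _ = phasing_states(2, 2)
        assert len(states) == 4
        assert labels == ["00", "01", "10", "11"]

    def test_break_kernel_is_uniform(self):
        k = phasing_transition_matrix(0.1, [True, True], 2)
        assert np.allclose(k, 0.25)
        # theta = 0.5 decouples even without breaks
        k2 = phasing_transition_matrix(0.5, [False, False], 2)
        assert np.allclose(k2, 0.25)

    def test_zero_theta_is_identity(self):
        assert np.array_equal(phasing_transition_matrix(0.0, [False, False], 2),
                              np.eye(4))

    def test_entries_by_number_of_switching_genomes(self):
        k = phasing_transition_matrix(0.1, [False, False], 2)
        assert k[0, 0] == pytest.approx(0.81)   # both maintained
        assert k[0, 1] == pytest.approx(0.09)   # one genome switches
        assert k[0, 3] == pytest.approx(0.01)   # both switch
        assert np.allclose(k.sum(axis=1), 1.0)

    def test_mixed_break_flags(self):
        k = phasing_transition_matrix(0.1, [True, False], 2)
        assert k[0, 0] == pytest.approx(0.5 * 0.9)
        assert k[0, 1] == pytest.approx(0.5 * 0.1)

    def test_theta_out_of_range(self):
        with pytest.raises(ValueError):
            phasing_transition_matrix(0.7, [False], 1)


class TestEmissions:
    def test_single_genome_closed_form(self):
        # pure-death: P(lost to S1 by total time T)= (1 - e^(-2T)) / 2
        gen = build_wgd_generator(WGDModelSpec.null())
        tree = SpeciesTree.from_newick("(A:0.4):0.2;")
        p = Pillar("p", {"A": ("x", None)}, {"A": True})
        lik = emission_likelihood(p, (0,), tree, gen)
        assert lik == pytest.approx((1 - np.exp(-1.2)) / 2, abs=1e-12)

    def test_fully_duplicated_pillar_is_phasing_invariant(self, two_taxon_tree):
        gen = build_wgd_generator(WGDModelSpec(epsilon=0.4, gamma=0.3, delta=0.2))
        p = Pillar("p", {"A": ("a0", "a1"), "B": ("b0", "b1")},
                   {"A": True, "B": True})
        e = emission_matrix([p], two_taxon_tree, gen)
        assert np.allclose(e, e[0, 0])

    def test_emissions_match_node_state_enumeration(self, two_taxon_tree):
        gen = build_wgd_generator(WGDModelSpec(epsilon=0.6, gamma=0.1, delta=0.2))
        pats = [(1, 1), (1, 0), (0, 1)]
        for pa, pb in itertools.product(pats, repeat=2):
            p = Pillar("p", {
                "A": tuple("a" if x else None for x in pa),
                "B": tuple("b" if x else None for x in pb),
            }, {"A": True, "B": True})
            e = emission_matrix([p], two_taxon_tree, gen)
            for k in range(4):
                oracle = enumerate_emission(p, k, two_taxon_tree, gen)
                assert e[0, k] == pytest.approx(oracle, rel=1e-10)

    def test_impossible_pattern_returns_zero(self):
        # gamma=delta=0: duplicated tips under an ancestor forced single-copy
        gen = build_wgd_generator(WGDModelSpec.null())
        tree = SpeciesTree.from_newick("(A:0.1):50.0;")
        p = Pillar("p", {"A": ("x", "y")}, {"A": True})
        e = emission_matrix([p], tree, gen)
        assert np.all(e >= 0) and e.max() < 1e-10


class TestForwardAndPosterior:
    def test_single_pillar_likelihood_is_sum_of_emissions(self, two_taxon_tree):
        gen = build_wgd_generator(WGDModelSpec(epsilon=0.7))
        pillars = random_wgd_pillars(1, ["A", "B"], seed=1)
        cp = compile_pillars(pillars, ["A", "B"])
        e = emission_matrix(cp, two_taxon_tree, gen)
        ll = forward_loglikelihood(cp, two_taxon_tree, gen, 0.2)
        assert ll == pytest.approx(np.log(e.sum()), rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_forward_matches_path_enumeration(self, two_taxon_tree, seed):
        rng = np.random.default_rng(seed)
        gen = build_wgd_generator(WGDModelSpec(
            epsilon=rng.uniform(0.2, 1.0), gamma=rng.uniform(0, 0.5),
            delta=rng.uniform(0, 0.5)))
        theta = rng.uniform(0.0, 0.5)
        pillars = random_wgd_pillars(5, ["A", "B"], seed=seed + 10)
        cp = compile_pillars(pillars, ["A", "B"])
        ll = forward_loglikelihood(cp, two_taxon_tree, gen, theta)
        ll_oracle, _ = enumerate_path_likelihood(cp, two_taxon_tree, gen, theta)
        assert ll == pytest.approx(ll_oracle, rel=1e-10)

    def test_pillars_decouple_at_theta_half(self, two_taxon_tree):
        gen = build_wgd_generator(WGDModelSpec(epsilon=0.7))
        pillars = random_wgd_pillars(4, ["A", "B"], seed=5)
        cp = compile_pillars(pillars, ["A", "B"])
        e = emission_matrix(cp, two_taxon_tree, gen)
        ll = forward_loglikelihood(cp, two_taxon_tree, gen, 0.5)
        # kernel at 0.5 contributes a 1/4 normalization per step
        expected = np.log(e.sum(axis=1)).sum() + (len(pillars) - 1) * np.log(0.25)
        assert ll == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_posteriors_match_path_enumeration(self, two_taxon_tree, seed):
        gen = build_wgd_generator(WGDModelSpec(epsilon=0.5, gamma=0.2, delta=0.1))
        pillars = random_wgd_pillars(5, ["A", "B"], seed=seed)
        cp = compile_pillars(pillars, ["A", "B"])
        post = posterior_decode(cp, two_taxon_tree, gen, 0.15)
        _, marg = enumerate_path_likelihood(cp, two_taxon_tree, gen, 0.15)
        assert np.allclose(post.probs, marg, atol=1e-10)
        assert np.allclose(post.probs.sum(axis=1), 1.0, atol=1e-9)

    def test_fully_duplicated_pillars_have_uniform_posteriors(self, two_taxon_tree):
        gen = build_wgd_generator(WGDModelSpec(epsilon=0.6, gamma=0.2))
        p = [Pillar(f"p{i}", {"A": ("a", "b"), "B": ("c", "d")},
                    {"A": True, "B": True}) for i in range(3)]
        post = posterior_decode(compile_pillars(p, ["A", "B"]),
                                two_taxon_tree, gen, 0.1)
        assert np.allclose(post.probs, 0.25, atol=1e-9)

    def test_concordant_single_copy_run_is_confidently_phased(self, two_taxon_tree):
        # a run of pillars single-copy on the same track in both genomes
        gen = build_wgd_generator(WGDModelSpec(epsilon=0.9))
        p = [Pillar(f"p{i}", {"A": (f"a{i}", None), "B": (f"b{i}", None)},
                    {"A": True, "B": True}) for i in range(4)]
        post = posterior_decode(compile_pillars(p, ["A", "B"]),
                                two_taxon_tree, gen, 0.02)
        concordant = [0, 3]  # states 00 and 11 keep the two genomes matched
        assert (post.probs[:, concordant].sum(axis=1) > 0.9).all()

    def test_symmetric_model_invariant_under_subgenome_relabel(self, two_taxon_tree):
        gen = build_wgd_generator(WGDModelSpec.null())
        pillars = random_wgd_pillars(6, ["A", "B"], seed=3)
        cp = compile_pillars(pillars, ["A", "B"])
        flipped = [
            Pillar(p.pillar_id,
                   {g: tr[::-1] for g, tr in p.genes.items()},
                   dict(p.adjacency)) for p in pillars]
        cpf = compile_pillars(flipped, ["A", "B"])
        ll = forward_loglikelihood(cp, two_taxon_tree, gen, 0.1)
        llf = forward_loglikelihood(cpf, two_taxon_tree, gen, 0.1)
        assert ll == pytest.approx(llf, rel=1e-12)

    def test_adding_a_break_never_improves_break_free_data(self, two_taxon_tree):
        gen = build_wgd_generator(WGDModelSpec(epsilon=0.7))
        pillars = random_wgd_pillars(6, ["A", "B"], seed=8, break_prob=0.0)
        cp = compile_pillars(pillars, ["A", "B"])
        base = forward_loglikelihood(cp, two_taxon_tree, gen, 0.05)
        broken = [Pillar(p.pillar_id, p.genes,
                         {g: (False if (i == 3) else f)
                          for g, f in p.adjacency.items()})
                  for i, p in enumerate(pillars)]
        cpb = compile_pillars(broken, ["A", "B"])
        assert forward_loglikelihood(cpb, two_taxon_tree, gen, 0.05) <= base + 1e-9


class TestFitting:
    def test_single_branch_mle_matches_closed_form(self):
        # k of m pillars single-copy under the null model, theta = 0.5:
        # the MLE of the total branch length solves e^(-2t) = (m-k)/m
        m, k = 40, 15
        tree = SpeciesTree.from_newick("(A:0.0):0.3;")
        pillars = []
        for i in range(m):
            single = i < k
            pillars.append(Pillar(
                f"p{i}", {"A": ("x", None) if single else ("x", "y")},
                {"A": True}))
        cp = compile_pillars(pillars, ["A"])
        fit = fit_model(cp, tree, "wgd-null", free_theta=False, theta=0.5,
                        free_branches=[tree.root], n_restarts=2, seed=0)
        t_hat = fit.branch_lengths[tree.root]
        assert t_hat == pytest.approx(-0.5 * np.log((m - k) / m), abs=1e-4)

    def test_epsilon_recovery_on_simulated_data(self):
        from polyphase.synthetic_data import SimulationConfig, generate_dataset

        b = generate_dataset(SimulationConfig(
            seed=11, n_taxa=2, m=2000,
            model=WGDModelSpec(epsilon=0.6, gamma=0.0, delta=0.0)))
        cp = compile_pillars(b["pillars"], genomes=b["tree"].leaves)
        fit = fit_model(cp, b["tree"], "wgd-b", n_restarts=1, seed=0)
        assert fit.converged
        assert abs(fit.spec.epsilon - 0.6) < 0.1

    def test_wgt_fit_recovers_loss_ordering(self):
        from polyphase.loss_models import WGTModelSpec
        from polyphase.synthetic_data import (SimulationConfig, default_tree,
                                              generate_dataset)

        spec = WGTModelSpec(f13=0.7, f23=0.4)
        cfg = SimulationConfig(seed=17, n_taxa=2, m=700, model=spec,
                               theta=0.03,
                               tree=default_tree(2, tip=0.35, root=0.35))
        b = generate_dataset(cfg)
        cp = compile_pillars(b["pillars"], genomes=b["tree"].leaves, ploidy=3)
        fit = fit_model(cp, b["tree"], "wgt-g3", n_restarts=1, seed=0)
        assert fit.converged
        # the reparameterized box guarantees the favored-genome ordering
        assert fit.spec.f23 <= fit.spec.f13 <= 1.0
        assert abs(fit.spec.f23 - 0.4) < 0.25

    def test_root_specific_epsilon_is_recovered(self):
        from polyphase.synthetic_data import SimulationConfig, generate_dataset

        cfg = SimulationConfig(seed=18, n_taxa=3, m=2500,
                               model=WGDModelSpec(epsilon=0.9, gamma=0.05,
                                                  root_epsilon=0.4))
        b = generate_dataset(cfg)
        cp = compile_pillars(b["pillars"], genomes=b["tree"].leaves)
        fit = fit_model(cp, b["tree"], "wgd-bf-roote", n_restarts=1, seed=0)
        # stronger fractionation bias on the root branch than elsewhere
        assert fit.spec.root_epsilon < fit.spec.epsilon
        assert abs(fit.spec.root_epsilon - 0.4) < 0.2

    def test_lrt_statistic_and_pvalue(self):
        null = _stub_fit(-1000.0)
        alt = _stub_fit(-1000.0 + 3.841 / 2)
        stat, p = likelihood_ratio_test(null, alt, 1)
        assert stat == pytest.approx(3.841, abs=1e-9)
        assert p == pytest.approx(0.05, abs=1e-3)
        stat, p = likelihood_ratio_test(null, null, 1)
        assert stat == 0.0 and p == 1.0
        with pytest.raises(ValueError):
            likelihood_ratio_test(alt, null, 1)

    def test_param_variance_on_quadratic_objective(self):
        # -lnL = (x - 2)^2 / (2 * 0.09): curvature 1/0.09
        fit = _stub_fit(0.0)
        fit.param_names = ["x"]
        fit.x = np.array([2.0])
        fit.bounds = [(0.0, 10.0)]
        fit._objective = lambda v: (v[0] - 2.0) ** 2 / (2 * 0.09)
        assert param_variance(fit, "x") == pytest.approx(0.09, rel=1e-4)

    def test_param_variance_boundary_flagged(self):
        fit = _stub_fit(0.0)
        fit.param_names = ["epsilon"]
        fit.x = np.array([1.0])
        fit.bounds = [(1e-3, 1.0)]
        fit._objective = lambda v: (v[0] - 1.0) ** 2
        assert param_variance(fit, "epsilon") is None

    def test_single_dim_variance_matches_hessian_diagonal(self, two_taxon_tree):
        pillars = random_wgd_pillars(60, ["A", "B"], seed=2)
        cp = compile_pillars(pillars, ["A", "B"])
        fit = fit_model(cp, two_taxon_tree, "wgd-b", n_restarts=1, seed=0)
        v = param_variance(fit, "epsilon")
        if v is None:
            pytest.skip("epsilon on boundary for this random draw")
        info = observed_information(fit)
        i = fit.param_names.index("epsilon")
        assert v == pytest.approx(1.0 / info[i, i], rel=0.05)


def _stub_fit(loglik: float):
    from polyphase.orthology_hmm import FitResult

    return FitResult(loglik=loglik, theta=0.1, branch_lengths=np.array([0.1]),
                     spec=WGDModelSpec.null(), params={}, param_names=[],
                     x=np.array([]), bounds=[], converged=True, n_evals=0,
                     tree=None)


class TestTopologySearch:
    def test_topology_counts(self):
        assert len(_rooted_topologies(["A", "B"])) == 1
        assert len(_rooted_topologies(["A", "B", "C"])) == 3
        assert len(_rooted_topologies(["A", "B", "C", "D"])) == 15

    def test_constraint_filters_to_consistent_topologies(self):
        tops = _rooted_topologies(["A", "B", "C", "D"])
        from polyphase.orthology_hmm import _has_sister_pair

        kept = [t for t in tops if _has_sister_pair(t, ("A", "B"))]
        assert len(kept) == 3  # the three rooted placements of the other taxa

    def test_recovers_simulated_topology(self):
        from polyphase.synthetic_data import SimulationConfig, generate_dataset

        true_tree = SpeciesTree.from_newick(
            "((A:0.3,B:0.3):0.25,C:0.3):0.3;")
        b = generate_dataset(SimulationConfig(
            seed=21, n_taxa=3, m=1500, tree=true_tree,
            model=WGDModelSpec(epsilon=0.6, gamma=0.05, delta=0.1)))
        best_tree, best_fit, fits = search_topology(
            b["pillars"], ["A", "B", "C"], "wgd-bfc-nb", seed=0)
        assert len(fits) == 3
        # A and B must come out as sisters
        from polyphase.orthology_hmm import _has_sister_pair

        best_top = max(fits, key=lambda tf: tf[1].loglik)[0]
        assert _has_sister_pair(best_top, ("A", "B"))

    def test_too_many_taxa_refused(self):
        with pytest.raises(ValueError):
            search_topology([], list("ABCDEFG"), "wgd-null")


@pytest.fixture(scope="module")
def wgq_setup():
    from polyphase.synthetic_data import (SimulationConfig, default_tree,
                                          generate_dataset)

    spec = WGQModelSpec(formation=True, lam=2.0)
    cfg = SimulationConfig(seed=5, n_taxa=2, m=250, model=spec,
                           theta=0.01, break_prob=0.005,
                           tree=default_tree(2, tip=0.25, root=0.25))
    b = generate_dataset(cfg)
    cp = compile_pillars(b["pillars"], genomes=b["tree"].leaves, ploidy=4)
    gen = build_generator(spec)
    post = posterior_decode(cp, b["tree"], gen, 0.01)
    return b, cp, post


class TestPhaseWGQ:
    def test_confidence_threshold_logic(self, wgq_setup):
        b, cp, post = wgq_setup
        ph = phase_wgq(post, cp, confidence=0.99)
        assert len(ph.first_event_pairs) + len(ph.singles) + len(ph.dropped) == cp.m
        for pid, reason in ph.dropped:
            assert reason in ("below-confidence", "missing-genome-in-pair")
        with pytest.raises(ValueError):
            phase_wgq(post, cp, confidence=0.4)

    def test_emitted_partitions_match_truth(self, wgq_setup):
        b, cp, post = wgq_setup
        ph = phase_wgq(post, cp, confidence=0.99)
        perms = list(itertools.permutations(range(4)))
        truth = b["truth"]
        assert len(ph.gene_assignments) >= 0.5 * cp.m
        correct = total = 0
        for pid, assigns in ph.gene_assignments.items():
            i = cp.pillar_ids.index(pid)
            tg, ig = {}, {}
            for g_i, g in enumerate(cp.genomes):
                tp = perms[truth.phasing_states[i] // (24 ** (1 - g_i)) % 24]
                for j, gene in enumerate(b["pillars"][i].genes[g]):
                    if gene is None:
                        continue
                    tg[gene] = 0 if tp[j] in (0, 1) else 1
                    ig[gene] = 0 if assigns[g][gene] in (0, 1) else 1
            total += 1
            genes = list(tg)
            correct += (all(tg[x] == ig[x] for x in genes)
                        or all(tg[x] != ig[x] for x in genes))
        assert correct / total >= 0.95
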