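"""Network construction, NMA posterior correctness, SUCRA contracts."""

import itertools

import numpy as np
import pandas as pd
import pytest

from glycorank.effects import PairwiseEffect
from glycorank.nma import (
    EvidenceNetwork,
    NetworkMetaAnalysis,
    NmaConfig,
    build_network,
    sucra_ranks,
)


def edge(a, b, ate, se, balanced=True, cohort="A"):
    return PairwiseEffect(
        cohort=cohort, case=a, comparator=b, ate=ate, se=se,
        ci95=(ate - 2 * se, ate + 2 * se), n_case=100, n_comp=100,
        all_balanced=balanced,
    )


def consistent_edges(d, se, rng=None):
    """All pairwise edges implied by basic parameters d (optionally noisy)."""
    out = []
    for a, b in itertools.combinations(d, 2):
        obs = d[a] - d[b]
        if rng is not None:
            obs += rng.normal(0, se)
        out.append(edge(a, b, obs, se))
    return out


class TestBuildNetwork:
    def test_node_threshold_is_strict(self):
        counts = {"metformin": 100, "x": 36, "y": 35}
        net = build_network([edge("x", "metformin", -0.5, 0.1)], counts)
        assert set(net.nodes) == {"metformin", "x"}
        assert any(
            e["reason"] == "n_le_35" and e["regimen"] == "y" for e in net.excluded
        )

    def test_unbalanced_edges_trimmed_but_path_remains(self):
        counts = {"metformin": 100, "x": 100, "y": 100}
        edges = [
            edge("x", "metformin", -0.5, 0.1),
            edge("y", "metformin", -0.3, 0.1, balanced=False),
            edge("x", "y", -0.2, 0.1),
        ]
        net = build_network(edges, counts)
        assert len(net.edges) == 2
        assert set(net.nodes) == {"metformin", "x", "y"}  # y estimable via x

    def test_all_edges_unbalanced_gives_empty_network(self):
        counts = {"metformin": 100, "x": 100}
        net = build_network([edge("x", "metformin", -0.5, 0.1, balanced=False)],
                            counts)
        assert net.edges == []

    def test_disconnected_component_dropped(self):
        counts = {"metformin": 100, "x": 100, "y": 100, "z": 100}
        edges = [edge("x", "metformin", -0.5, 0.1), edge("y", "z", -0.1, 0.1)]
        net = build_network(edges, counts)
        assert set(net.nodes) == {"metformin", "x"}
        assert {e["regimen"] for e in net.excluded
                if e["reason"] == "disconnected"} == {"y", "z"}

    def test_missing_baseline_substituted_with_largest_arm(self):
        counts = {"x": 100, "y": 150}
        net = build_network([edge("x", "y", -0.5, 0.1)], counts)
        assert net.baseline == "y"
        assert net.baseline_substituted


class TestNmaPosterior:
    def test_single_edge_matches_conjugate_normal_solution(self):
        """With tau fixed at 0 the model is conjugate: posterior of d_T is
        Normal with precision 1/se^2 + 1/prior_var."""
        net = build_network([edge("T", "metformin", -0.5, 0.1)],
                            {"metformin": 100, "T": 100})
        m = NetworkMetaAnalysis(NmaConfig(seed=1, tau_prior_scale=0.0)).fit(net)
        prior_var, se2 = 100.0, 0.01
        post_var = 1.0 / (1.0 / prior_var + 1.0 / se2)
        post_mean = -0.5 * (1.0 / se2) * post_var
        mcse = m.mcse_mean()["d[T]"]
        d = m.d_draws_[:, 1]
        assert m.converged_
        assert abs(d.mean() - post_mean) < 3 * mcse
        assert d.std(ddof=1) == pytest.approx(np.sqrt(post_var), rel=0.05)

    def test_triangle_recovers_basic_parameters(self):
        d_true = {"metformin": 0.0, "X": -0.8, "Y": -0.3}
        net = build_network(
            consistent_edges(d_true, 0.08),
            {k: 200 for k in d_true},
        )
        m = NetworkMetaAnalysis(NmaConfig(seed=3)).fit(net)
        assert m.converged_
        for name, j in (("X", 1), ("Y", 2)):
            draws = m.d_draws_[:, m.treatments_.index(name)]
            assert abs(draws.mean() - d_true[name]) < 2 * draws.std(ddof=1)

    def test_baseline_relabeling_shifts_by_constant(self):
        """Pairwise contrasts are invariant to the choice of baseline."""
        d_true = {"metformin": 0.0, "X": -0.8, "Y": -0.3}
        edges = consistent_edges(d_true, 0.05)
        counts = {k: 200 for k in d_true}
        m1 = NetworkMetaAnalysis(NmaConfig(seed=5)).fit(
            build_network(edges, counts, baseline="metformin"))
        m2 = NetworkMetaAnalysis(NmaConfig(seed=5)).fit(
            build_network(edges, counts, baseline="X"))
        c1 = (m1.summary_.set_index("regimen").d_mean["X"]
              - m1.summary_.set_index("regimen").d_mean["Y"])
        c2 = (m2.summary_.set_index("regimen").d_mean["X"]
              - m2.summary_.set_index("regimen").d_mean["Y"])
        sd = m1.summary_.d_sd.max() + m2.summary_.d_sd.max()
        assert abs(c1 - c2) < 0.5 * sd

    def test_indirect_only_estimate_agrees_with_direct(self):
        """Delete the direct X-baseline edge; the indirect path through Y
        reproduces the direct estimate within 2 pooled posterior sds."""
        d_true = {"metformin": 0.0, "X": -0.9, "Y": -0.4}
        rng = np.random.default_rng(11)
        edges = consistent_edges(d_true, 0.06, rng)
        counts = {k: 200 for k in d_true}
        full = NetworkMetaAnalysis(NmaConfig(seed=7)).fit(
            build_network(edges, counts))
        indirect_edges = [e for e in edges
                          if {e.case, e.comparator} != {"X", "metformin"}]
        indirect = NetworkMetaAnalysis(NmaConfig(seed=9)).fit(
            build_network(indirect_edges, counts))
        jf = full.treatments_.index("X")
        ji = indirect.treatments_.index("X")
        mf, sf = full.d_draws_[:, jf].mean(), full.d_draws_[:, jf].std(ddof=1)
        mi, si = indirect.d_draws_[:, ji].mean(), indirect.d_draws_[:, ji].std(ddof=1)
        assert abs(mf - mi) < 2 * np.sqrt(sf**2 + si**2)

    def test_empty_or_single_node_network_rejected(self):
        net = EvidenceNetwork(cohort="A", nodes={"metformin": 100}, edges=[],
                              baseline="metformin")
        with pytest.raises(ValueError):
            NetworkMetaAnalysis(NmaConfig(seed=1)).fit(net)

    def test_deterministic_given_seed(self):
        net = build_network([edge("T", "metformin", -0.5, 0.1)],
                            {"metformin": 100, "T": 100})
        cfg = NmaConfig(seed=13, n_warmup=300, n_draws=300)
        m1 = NetworkMetaAnalysis(cfg).fit(net)
        m2 = NetworkMetaAnalysis(NmaConfig(seed=13, n_warmup=300, n_draws=300)).fit(net)
        assert np.array_equal(m1.d_draws_, m2.d_draws_)


def _synthetic_model(d_draws, tau_draws, treatments):
    """NMA model object with a hand-constructed posterior."""
    m = NetworkMetaAnalysis(NmaConfig())
    m.treatments_ = treatments
    m.baseline_ = treatments[0]
    m.d_draws_ = d_draws
    m.tau_draws_ = tau_draws
    m.converged_ = True
    m.summary_ = pd.DataFrame({
        "regimen": treatments,
        "d_mean": d_draws.mean(axis=0),
        "d_sd": d_draws.std(axis=0, ddof=1),
        "d_lo": np.percentile(d_draws, 2.5, axis=0),
        "d_median": np.percentile(d_draws, 50, axis=0),
        "d_hi": np.percentile(d_draws, 97.5, axis=0),
    })
    return m


def _network_for(treatments, cohort="A"):
    return EvidenceNetwork(cohort=cohort,
                           nodes={k: 100 for k in treatments},
                           edges=[], baseline=treatments[0])


class TestSucra:
    def test_always_first_and_always_last_endpoints(self):
        treatments = ["metformin", "best", "worst"]
        n = 4000
        d = np.column_stack([np.zeros(n), np.full(n, -5.0), np.full(n, 5.0)])
        m = _synthetic_model(d, np.zeros(n), treatments)
        tab = sucra_ranks(m, _network_for(treatments), n_draws=2000, seed=1,
                          include_tau=False)
        s = tab.set_index("regimen").sucra
        assert s["best"] == 1.0
        assert s["worst"] == 0.0
        assert s["metformin"] == 0.5

    def test_exchangeable_treatments_score_half(self):
        treatments = ["metformin", "a", "b", "c"]
        n = 4000
        d = np.zeros((n, 4))
        m = _synthetic_model(d, np.full(n, 0.5), treatments)
        tab = sucra_ranks(m, _network_for(treatments), n_draws=4000, seed=2)
        # the baseline has no heterogeneity draw, so exchangeability holds
        # among the non-baseline treatments
        nonbase = tab.set_index("regimen").sucra[["a", "b", "c"]]
        assert np.allclose(nonbase, 0.5, atol=0.05)

    def test_sucra_sum_is_half_the_treatment_count(self):
        treatments = ["metformin", "a", "b", "c", "d"]
        n = 2000
        rng = np.random.default_rng(3)
        d = np.column_stack([np.zeros(n)] + [rng.normal(0, 1, n) for _ in range(4)])
        m = _synthetic_model(d, np.abs(rng.normal(0, 0.3, n)), treatments)
        tab = sucra_ranks(m, _network_for(treatments), n_draws=2000, seed=4)
        assert tab.sucra.sum() == pytest.approx(len(treatments) / 2, abs=1e-9)

    def test_well_separated_effects_rank_in_true_order(self):
        d_true = {"metformin": 0.0, "a": -0.5, "b": -1.0, "c": -1.5}
        rng = np.random.default_rng(5)
        net = build_network(consistent_edges(d_true, 0.05, rng),
                            {k: 200 for k in d_true})
        m = NetworkMetaAnalysis(NmaConfig(seed=6)).fit(net)
        tab = sucra_ranks(m, net, n_draws=4000, seed=7, force=True)
        assert list(tab.regimen) == ["c", "b", "a", "metformin"]

    def test_ranking_sorted_by_descending_sucra(self):
        d_true = {"metformin": 0.0, "a": -0.5, "b": -1.0}
        net = build_network(consistent_edges(d_true, 0.05),
                            {k: 200 for k in d_true})
        m = NetworkMetaAnalysis(NmaConfig(seed=8)).fit(net)
        tab = sucra_ranks(m, net, seed=9, force=True)
        assert (np.diff(tab.sucra) <= 0).all()
        assert list(tab["rank"]) == [1, 2, 3]

    def test_unconverged_posterior_refused_unless_forced(self):
        treatments = ["metformin", "a"]
        d = np.column_stack([np.zeros(100), np.linspace(-1, 1, 100)])
        m = _synthetic_model(d, np.zeros(100), treatments)
        m.converged_ = False
        with pytest.raises(RuntimeError):
            sucra_ranks(m, _network_for(treatments), seed=1)
        tab = sucra_ranks(m, _network_for(treatments), seed=1, force=True)
        assert len(tab) == 2
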