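"""Bayesian random-effects network meta-analysis and SUCRA ranking.

Treatments (regimens) are nodes; each balanced pairwise study contributes
an edge carrying an observed ATE and its standard error. The model places
a basic parameter ``d_k`` (network-synthesized HbA1c change vs the
baseline treatment, metformin monotherapy) on every node, with
``d_baseline = 0``. A study of case *a* vs comparator *b* observes

    ate_e ~ Normal(theta_e, se_e^2),   theta_e ~ Normal(d_a - d_b, tau^2)

with a single heterogeneity SD ``tau`` shared across edges. The per-edge
latent ``theta_e`` is marginalized analytically (normal-normal), leaving
``ate_e ~ Normal(d_a - d_b, se_e^2 + tau^2)``, and the posterior over
``(d, tau)`` is sampled with an affine-invariant ensemble sampler.
Priors: d_k ~ Normal(0, 10^2) on the %HbA1c scale, tau ~ HalfNormal(5) —
effectively uninformative for effects of order 1.

Rankings: for each posterior draw, a predictive ATE vs baseline is drawn
per treatment (``d_k`` plus, by default, a new-study heterogeneity term
``Normal(0, tau^2)``; the baseline's ATE is identically 0), treatments are
ranked in ascending order of ATE (most negative = rank 1 = largest
reduction), and the SUCRA score is the normalized mean rank
``(T - mean_rank) / (T - 1)`` — 1 for a treatment that always ranks first,
0 for always last.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
import emcee
from scipy import stats

__all__ = [
    "NODE_MIN_SNAPSHOTS",
    "EvidenceNetwork",
    "build_network",
    "NmaConfig",
    "NetworkMetaAnalysis",
    "sucra_ranks",
]

logger = logging.getLogger(__name__)

#: A regimen enters a cohort's network only with more snapshots than this
#: (strict inequality: 36 is in, 35 is out).
NODE_MIN_SNAPSHOTS = 35

DEFAULT_BASELINE = "metformin"


@dataclass
class EvidenceNetwork:
    """Trimmed per-cohort evidence graph.

    ``nodes`` maps regimen -> snapshot count (only regimens above the node
    threshold and connected to the baseline); ``edges`` are the surviving
    balanced studies between retained nodes. ``excluded`` records trimmed
    nodes and edges with machine-readable reasons.
    """

    cohort: str
    nodes: dict
    edges: list
    baseline: str
    baseline_substituted: bool = False
    excluded: list = field(default_factory=list)

    @property
    def treatments(self):
        return [self.baseline] + sorted(k for k in self.nodes if k != self.baseline)

    def to_json_dict(self) -> dict:
        return {
            "cohort": self.cohort,
            "baseline": self.baseline,
            "baseline_substituted": self.baseline_substituted,
            "nodes": [
                {"regimen": k, "n_snapshots": int(v)} for k, v in sorted(self.nodes.items())
            ],
            "edges": [
                {
                    "case": e.case,
                    "comparator": e.comparator,
                    "ate": e.ate,
                    "se": e.se,
                    "n_case": e.n_case,
                    "n_comp": e.n_comp,
                }
                for e in self.edges
            ],
            "excluded": self.excluded,
        }


def build_network(effects, cohort_counts: dict, cohort: str = "",
                  baseline: str = DEFAULT_BASELINE,
                  node_min: int = NODE_MIN_SNAPSHOTS) -> EvidenceNetwork:
    """Trim the pairwise-study list into an analyzable evidence network.

    Nodes are regimens with snapshot count strictly above ``node_min``;
    edges are studies with every covariate balanced whose endpoints are
    both retained. When the graph is disconnected only the component
    containing the baseline is analyzed; when the baseline itself is not a
    retained node, the largest-arm retained regimen substitutes and the
    substitution is recorded.
    """
    excluded = []
    nodes = {k: int(n) for k, n in cohort_counts.items() if n > node_min}
    for k, n in sorted(cohort_counts.items()):
        if n <= node_min:
            excluded.append({"kind": "node", "regimen": k, "reason": "n_le_35",
                             "n": int(n)})

    edges = []
    for e in effects:
        if e.case not in nodes or e.comparator not in nodes:
            excluded.append(
                {"kind": "edge", "case": e.case, "comparator": e.comparator,
                 "reason": "endpoint_trimmed"}
            )
            continue
        if not e.all_balanced:
            excluded.append(
                {"kind": "edge", "case": e.case, "comparator": e.comparator,
                 "reason": "unbalanced"}
            )
            continue
        edges.append(e)

    sub = baseline not in nodes
    base = baseline
    if sub and nodes:
        base = max(sorted(nodes), key=lambda k: nodes[k])
        logger.warning(
            "cohort %s: baseline %s absent; substituting %s", cohort, baseline, base
        )

    # Restrict to the connected component containing the baseline.
    if nodes:
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from((e.case, e.comparator) for e in edges)
        component = nx.node_connected_component(g, base)
        for k in sorted(set(nodes) - component):
            excluded.append(
                {"kind": "node", "regimen": k, "reason": "disconnected",
                 "n": nodes[k]}
            )
        nodes = {k: n for k, n in nodes.items() if k in component}
        edges = [e for e in edges if e.case in component and e.comparator in component]

    return EvidenceNetwork(
        cohort=cohort,
        nodes=nodes,
        edges=edges,
        baseline=base if nodes else baseline,
        baseline_substituted=bool(sub and nodes),
        excluded=excluded,
    )


@dataclass
class NmaConfig:
    """Sampler settings for the random-effects NMA posterior."""

    n_walkers: int = 24
    n_warmup: int = 3000
    n_draws: int = 3000
    prior_d_scale: float = 10.0
    tau_prior_scale: float = 5.0
    rhat_threshold: float = 1.05
    seed: int = 0


class NetworkMetaAnalysis:
    """Estimator-style wrapper: ``fit(network)`` samples the NMA posterior.

    Fitted attributes: ``treatments_`` (baseline first), ``d_draws_``
    (draws x treatments, baseline column identically 0), ``tau_draws_``,
    ``rhat_`` per free parameter, ``converged_``, and ``summary_``.
    Deterministic given the config seed.
    """

    def __init__(self, config: NmaConfig | None = None, **overrides):
        cfg = config or NmaConfig()
        for k, v in overrides.items():
            if not hasattr(cfg, k):
                raise TypeError(f"unknown NMA option {k!r}")
            setattr(cfg, k, v)
        self.config = cfg

    def get_params(self, deep=True):
        return {"config": self.config}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, network: EvidenceNetwork):
        if len(network.nodes) < 2:
            raise ValueError("network needs at least 2 connected treatments")
        if not network.edges:
            raise ValueError("network has no edges")
        cfg = self.config
        treatments = network.treatments
        index = {k: i for i, k in enumerate(treatments)}
        K = len(treatments)
        fixed_tau = cfg.tau_prior_scale == 0.0
        ndim = (K - 1) if fixed_tau else K  # d_1..d_{K-1} (+ tau)

        a_idx = np.array([index[e.case] for e in network.edges])
        b_idx = np.array([index[e.comparator] for e in network.edges])
        ate = np.array([e.ate for e in network.edges])
        se2 = np.array([e.se for e in network.edges]) ** 2
        d_var = cfg.prior_d_scale**2
        tau_scale = cfg.tau_prior_scale

        def log_prob(theta):
            # Vectorized over walkers: theta is (n_walkers, ndim). The
            # heterogeneity SD is sampled as u = log(tau) with the
            # HalfNormal prior transported through the Jacobian, which
            # removes the boundary at tau = 0 and mixes well on sparse
            # networks.
            theta = np.atleast_2d(theta)
            nw = theta.shape[0]
            if fixed_tau:
                dfree = theta
                tau2 = np.zeros(nw)
            else:
                dfree = theta[:, :-1]
                u = theta[:, -1]
                tau2 = np.exp(2.0 * u)
            d = np.column_stack([np.zeros(nw), dfree])
            mean = d[:, a_idx] - d[:, b_idx]
            var = se2[None, :] + tau2[:, None]
            ll = -0.5 * np.sum(
                (ate[None, :] - mean) ** 2 / var + np.log(2 * np.pi * var), axis=1
            )
            lp = -0.5 * np.sum(dfree**2, axis=1) / d_var
            if not fixed_tau:
                lp = lp - 0.5 * tau2 / tau_scale**2 + u  # HalfNormal + Jacobian
            return ll + lp

        rng = np.random.default_rng(cfg.seed)
        n_walkers = max(cfg.n_walkers, 2 * ndim + 2)
        cols = [rng.normal(0.0, 0.5, size=n_walkers) for _ in range(K - 1)]
        if not fixed_tau:
            cols.append(rng.normal(np.log(0.1 * tau_scale), 0.5, size=n_walkers))
        p0 = np.column_stack(cols)
        moves = [
            (emcee.moves.StretchMove(), 0.7),
            (emcee.moves.DEMove(), 0.2),
            (emcee.moves.DESnookerMove(), 0.1),
        ]
        sampler = emcee.EnsembleSampler(
            n_walkers, ndim, log_prob, vectorize=True, moves=moves
        )
        sampler.random_state = np.random.RandomState(cfg.seed).get_state()
        state = sampler.run_mcmc(
            p0, cfg.n_warmup, progress=False,
            skip_initial_state_check=True,
        )
        sampler.reset()
        sampler.run_mcmc(state, cfg.n_draws, progress=False,
                         skip_initial_state_check=True)

        chain = sampler.get_chain()  # (n_draws, n_walkers, ndim)
        flat = chain.reshape(-1, ndim)
        self.treatments_ = treatments
        self.baseline_ = network.baseline
        self.d_draws_ = np.column_stack([np.zeros(len(flat)), flat[:, : K - 1]])
        self.tau_draws_ = (
            np.zeros(len(flat)) if fixed_tau else np.exp(flat[:, -1])
        )
        self.chain_ = chain

        # Split-chain R-hat over walkers (arviz convention: chains first).
        from arviz import rhat as az_rhat
        posterior = np.moveaxis(chain, 1, 0)  # (walkers, draws, dim)
        rhats = np.array(
            [float(az_rhat(np.ascontiguousarray(posterior[:, :, j])))
             for j in range(ndim)]
        )
        names = [f"d[{k}]" for k in treatments[1:]]
        if not fixed_tau:
            names.append("tau")
        self.rhat_ = pd.Series(rhats, index=names)
        self.converged_ = bool(np.all(rhats <= cfg.rhat_threshold))
        if not self.converged_:
            logger.warning(
                "cohort %s NMA flagged unconverged (max rhat %.3f)",
                network.cohort, rhats.max(),
            )

        q = np.percentile(self.d_draws_, [2.5, 50, 97.5], axis=0)
        self.summary_ = pd.DataFrame(
            {
                "regimen": treatments,
                "d_mean": self.d_draws_.mean(axis=0),
                "d_sd": self.d_draws_.std(axis=0, ddof=1),
                "d_lo": q[0],
                "d_median": q[1],
                "d_hi": q[2],
            }
        )
        return self

    def mcse_mean(self) -> pd.Series:
        """Monte-Carlo standard error of each posterior mean (ESS-based,
        with walkers treated as chains)."""
        from arviz import ess as az_ess

        chains = np.moveaxis(self.chain_, 1, 0)  # (walkers, draws, ndim)
        out = {}
        for j, name in enumerate(self.rhat_.index):
            draws = np.ascontiguousarray(chains[:, :, j])
            e = float(az_ess(draws))
            out[name] = draws.std(ddof=1) / np.sqrt(max(e, 1.0))
        return pd.Series(out)


def sucra_ranks(model: NetworkMetaAnalysis, network: EvidenceNetwork,
                n_draws: int = 2000, seed: int = 0,
                include_tau: bool = True, force: bool = False) -> pd.DataFrame:
    """SUCRA ranking table from the fitted NMA posterior.

    Per draw: sample a predictive ATE vs baseline for every non-baseline
    treatment (``d_k`` + heterogeneity noise if ``include_tau``), set the
    baseline's ATE to 0, rank ascending (ties get average ranks), then
    normalize the mean rank to SUCRA = (T - mean_rank)/(T - 1). Refuses
    unconverged posteriors unless ``force``.
    """
    if not getattr(model, "converged_", False) and not force:
        raise RuntimeError("posterior flagged unconverged; pass force=True to rank")
    treatments = model.treatments_
    T = len(treatments)
    if T < 2:
        raise ValueError("ranking needs at least 2 treatments")
    rng = np.random.default_rng(seed)
    total = len(model.tau_draws_)
    take = rng.choice(total, size=min(n_draws, total), replace=n_draws > total)
    d = model.d_draws_[take]
    tau = model.tau_draws_[take]
    ates = d.copy()
    if include_tau:
        noise = rng.normal(size=(len(take), T)) * tau[:, None]
        noise[:, 0] = 0.0  # baseline ATE is identically 0
        ates = ates + noise
    ranks = stats.rankdata(ates, axis=1, method="average")
    mean_rank = ranks.mean(axis=0)
    sucra = (T - mean_rank) / (T - 1)

    counts = network.nodes
    table = pd.DataFrame(
        {
            "regimen": treatments,
            "sucra": sucra,
            "mean_rank": mean_rank,
            "n_snapshots": [counts.get(k, 0) for k in treatments],
        }
    ).merge(model.summary_, on="regimen")
    table = table.sort_values(
        ["sucra", "regimen"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, T + 1))
    table["cohort"] = network.cohort
    return table
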