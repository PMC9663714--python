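"""IPTW average treatment effects with bootstrap uncertainty.

Each unordered pair of eligible regimens inside a clinical cohort defines
one case-comparator observational study: a BCAUS propensity model is fit on
snapshots assigned to exactly one of the two regimens, IPTW weights are
formed, and the ATE on the change in HbA1c is the Hajek (normalized-weight)
difference of weighted arm means. Standard errors and 95% intervals come
from a stratified (within-arm) bootstrap; by default replicates reuse the
fitted propensities and only recompute the weighted means, with a full
model refit per replicate available by config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from glycorank.propensity import BcausClassifier, check_balance

__all__ = ["EffectConfig", "PairwiseEffect", "iptw_ate", "naive_ate",
           "bootstrap_effect", "run_all_pairs", "effects_to_frame"]

logger = logging.getLogger(__name__)


def iptw_ate(y, t, w) -> float:
    """Hajek IPTW ATE: difference of weighted outcome means, case - comparator."""
    y = np.asarray(y, dtype=float)
    t = np.asarray(t)
    w = np.asarray(w, dtype=float)
    if not (len(y) == len(t) == len(w)):
        raise ValueError("y, t, w must have equal length")
    case, comp = t == 1, t == 0
    if not case.any() or not comp.any():
        raise ValueError("both arms must be present")
    m1 = np.sum(w[case] * y[case]) / np.sum(w[case])
    m0 = np.sum(w[comp] * y[comp]) / np.sum(w[comp])
    return float(m1 - m0)


def naive_ate(y, t) -> float:
    """Unadjusted difference in arm means (the confounded contrast)."""
    y = np.asarray(y, dtype=float)
    t = np.asarray(t)
    return float(y[t == 1].mean() - y[t == 0].mean())


@dataclass
class EffectConfig:
    """Study-level settings for propensity fitting and the bootstrap."""

    bootstrap_b: int = 200
    refit_per_replicate: bool = False
    propensity: dict = field(default_factory=dict)  # BcausClassifier kwargs
    seed: int = 0


@dataclass
class PairwiseEffect:
    """One case-comparator study result (the NMA edge payload)."""

    cohort: str
    case: str
    comparator: str
    ate: float
    se: float
    ci95: tuple
    n_case: int
    n_comp: int
    all_balanced: bool
    naive: float = np.nan

    def swapped(self) -> "PairwiseEffect":
        """The same study with case and comparator exchanged (ATE negated)."""
        return PairwiseEffect(
            cohort=self.cohort,
            case=self.comparator,
            comparator=self.case,
            ate=-self.ate,
            se=self.se,
            ci95=(-self.ci95[1], -self.ci95[0]),
            n_case=self.n_comp,
            n_comp=self.n_case,
            all_balanced=self.all_balanced,
            naive=-self.naive if np.isfinite(self.naive) else np.nan,
        )


def bootstrap_effect(y, t, X, config: EffectConfig, cohort: str = "",
                     case: str = "case", comparator: str = "comparator",
                     model: BcausClassifier | None = None) -> PairwiseEffect:
    """Point estimate plus stratified-bootstrap SE and percentile 95% CI.

    Resamples snapshots with replacement within each arm ``bootstrap_b``
    times; each replicate recomputes IPTW weights from the fitted
    propensities (or refits the model when ``refit_per_replicate``) and
    re-evaluates the Hajek ATE. Stratified resampling guarantees both arms
    survive in every replicate.
    """
    if config.bootstrap_b < 1:
        raise ValueError("bootstrap_b must be >= 1")
    y = np.asarray(y, dtype=float)
    t = np.asarray(t)
    X = np.asarray(X, dtype=float)
    case_idx = np.flatnonzero(t == 1)
    comp_idx = np.flatnonzero(t == 0)
    if len(case_idx) < 2 or len(comp_idx) < 2:
        raise ValueError("each arm needs at least 2 snapshots")

    if model is None:
        model = BcausClassifier(**config.propensity).fit(X, t)
    w = model.iptw_weights(X, t)
    point = iptw_ate(y, t, w)
    balance = check_balance(X, t, w, threshold=model.balance_threshold)

    rng = np.random.default_rng(config.seed)
    reps = np.empty(config.bootstrap_b)
    e_full = model.propensity(X)
    for b in range(config.bootstrap_b):
        ci = rng.choice(case_idx, size=len(case_idx), replace=True)
        ki = rng.choice(comp_idx, size=len(comp_idx), replace=True)
        idx = np.concatenate([ci, ki])
        tb = t[idx]
        if config.refit_per_replicate:
            mb = BcausClassifier(**config.propensity).fit(X[idx], tb)
            wb = mb.iptw_weights(X[idx], tb)
        else:
            eb = e_full[idx]
            wb = np.where(tb == 1, 1.0 / eb, 1.0 / (1.0 - eb))
        reps[b] = iptw_ate(y[idx], tb, wb)

    se = float(np.std(reps, ddof=1)) if config.bootstrap_b > 1 else float("nan")
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return PairwiseEffect(
        cohort=cohort,
        case=case,
        comparator=comparator,
        ate=point,
        se=se,
        ci95=(float(lo), float(hi)),
        n_case=len(case_idx),
        n_comp=len(comp_idx),
        all_balanced=balance.all_balanced,
        naive=naive_ate(y, t),
    )


def run_all_pairs(snapshots: pd.DataFrame, eligible, confounder_cols,
                  config: EffectConfig, cohort: str = "",
                  failures: list | None = None):
    """One pairwise study per unordered pair of eligible regimens.

    Each study restricts to snapshots assigned exactly one of the two
    regimens; the lexicographically smaller regimen is the case arm so the
    pairing is deterministic. Studies whose arms are too small are skipped
    with a recorded reason.
    """
    eligible = sorted(set(eligible))
    if len(eligible) < 2:
        logger.warning("cohort %s: fewer than 2 eligible regimens", cohort)
        return []
    results = []
    ss = np.random.SeedSequence(config.seed)
    pair_seeds = {
        (a, b): int(s.generate_state(1)[0] % 2**31)
        for (a, b), s in zip(
            [(a, b) for i, a in enumerate(eligible) for b in eligible[i + 1:]],
            ss.spawn(len(eligible) * (len(eligible) - 1) // 2),
        )
    }
    for (a, b), seed in pair_seeds.items():
        sub = snapshots[snapshots.regimen.isin([a, b])]
        t = (sub.regimen == a).to_numpy().astype(int)
        n1, n0 = int(t.sum()), int((1 - t).sum())
        if min(n1, n0) < 2:
            if failures is not None:
                failures.append(
                    {"cohort": cohort, "case": a, "comparator": b,
                     "reason": "arm_too_small"}
                )
            continue
        pair_cfg = EffectConfig(
            bootstrap_b=config.bootstrap_b,
            refit_per_replicate=config.refit_per_replicate,
            propensity=dict(config.propensity),
            seed=seed,
        )
        pair_cfg.propensity.setdefault("random_state", seed)
        try:
            eff = bootstrap_effect(
                sub.delta_hba1c.to_numpy(),
                t,
                sub[list(confounder_cols)].to_numpy(),
                pair_cfg,
                cohort=cohort,
                case=a,
                comparator=b,
            )
        except ValueError as err:
            if failures is not None:
                failures.append(
                    {"cohort": cohort, "case": a, "comparator": b,
                     "reason": str(err)}
                )
            continue
        results.append(eff)
    return results


def effects_to_frame(effects) -> pd.DataFrame:
    """Tidy edge table (the NMA input format)."""
    rows = [
        {
            "cohort": e.cohort,
            "case": e.case,
            "comparator": e.comparator,
            "ate": e.ate,
            "se": e.se,
            "ci_lo": e.ci95[0],
            "ci_hi": e.ci95[1],
            "n_case": e.n_case,
            "n_comp": e.n_comp,
            "all_balanced": e.all_balanced,
        }
        for e in effects
    ]
    return pd.DataFrame(
        rows,
        columns=["cohort", "case", "comparator", "ate", "se", "ci_lo", "ci_hi",
                 "n_case", "n_comp", "all_balanced"],
    )
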