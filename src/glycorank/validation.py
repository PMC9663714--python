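"""Concordance-based validation of the treatment rankings.

Do snapshots whose prescribed regimen matches a top-ranked recommendation
actually fare better? Each cohort is split into a *concordant* group
(regimen equals one of the top-3 ranked regimens) and a *non-concordant*
group; group mean changes in HbA1c are compared with a Welch two-sample
t-test, and where the difference is significant (p < 0.05) a
confounder-adjusted case-comparator study is run with concordance as the
binary "treatment", yielding an IPTW ATE with a bootstrap CI. A
sensitivity analysis repeats the contrast across rank tiers (1-3 vs 11+,
4-10 vs 11+), and rank-trajectory descriptives summarize how patients move
through the ranking across consecutive snapshots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from glycorank.effects import EffectConfig, bootstrap_effect

__all__ = [
    "ConcordanceResult",
    "concordance_split",
    "evaluate_concordance",
    "sensitivity_tiers",
    "rank_trajectories",
]

logger = logging.getLogger(__name__)


def concordance_split(snapshots: pd.DataFrame, ranking: pd.DataFrame,
                      top_k: int = 3):
    """Split snapshots into (concordant, non-concordant) by the ranking.

    Concordant iff the snapshot's regimen equals (set equality, via the
    canonical sorted string) one of the ``top_k`` top-ranked regimens.
    Regimens absent from the ranking table (too few arms to rank) are
    non-concordant.
    """
    if not len(ranking):
        raise ValueError("empty ranking table")
    top = set(ranking.sort_values("rank").regimen.head(top_k))
    mask = snapshots.regimen.isin(top)
    return snapshots[mask], snapshots[~mask]


@dataclass
class ConcordanceResult:
    cohort: str
    dataset: str
    n_concordant: int
    n_nonconcordant: int
    mean_concordant: float
    mean_nonconcordant: float
    t_statistic: float
    p_value: float
    significant: bool
    adjusted_ate: float | None = None
    adjusted_ci95: tuple | None = None
    reason: str | None = None

    def to_dict(self) -> dict:
        d = {
            "cohort": self.cohort,
            "dataset": self.dataset,
            "n_concordant": self.n_concordant,
            "n_nonconcordant": self.n_nonconcordant,
            "mean_concordant": self.mean_concordant,
            "mean_nonconcordant": self.mean_nonconcordant,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "significant": self.significant,
            "adjusted_ate": self.adjusted_ate,
            "adjusted_ci_lo": self.adjusted_ci95[0] if self.adjusted_ci95 else None,
            "adjusted_ci_hi": self.adjusted_ci95[1] if self.adjusted_ci95 else None,
            "reason": self.reason,
        }
        return d


def evaluate_concordance(snapshots: pd.DataFrame, ranking: pd.DataFrame,
                         confounder_cols, config: EffectConfig,
                         cohort: str = "", dataset: str = "test",
                         top_k: int = 3, alpha: float = 0.05) -> ConcordanceResult:
    """Concordant-vs-non-concordant contrast for one cohort and dataset.

    Welch (unequal-variance) two-sample t-test on the change in HbA1c; if
    significant at ``alpha``, an additional confounder-adjusted study is
    run with concordance as the treatment indicator and its IPTW ATE
    (concordant minus non-concordant) and bootstrap CI are reported.
    """
    conc, nonc = concordance_split(snapshots, ranking, top_k=top_k)
    base = dict(
        cohort=cohort,
        dataset=dataset,
        n_concordant=len(conc),
        n_nonconcordant=len(nonc),
        mean_concordant=float(conc.delta_hba1c.mean()) if len(conc) else np.nan,
        mean_nonconcordant=float(nonc.delta_hba1c.mean()) if len(nonc) else np.nan,
    )
    if len(conc) < 2 or len(nonc) < 2:
        return ConcordanceResult(
            **base, t_statistic=np.nan, p_value=np.nan, significant=False,
            reason="group_too_small",
        )
    tt = stats.ttest_ind(conc.delta_hba1c, nonc.delta_hba1c, equal_var=False)
    significant = bool(tt.pvalue < alpha)
    result = ConcordanceResult(
        **base, t_statistic=float(tt.statistic), p_value=float(tt.pvalue),
        significant=significant,
    )
    if significant:
        t = np.concatenate([np.ones(len(conc), dtype=int),
                            np.zeros(len(nonc), dtype=int)])
        joined = pd.concat([conc, nonc], ignore_index=True)
        eff = bootstrap_effect(
            joined.delta_hba1c.to_numpy(), t,
            joined[list(confounder_cols)].to_numpy(), config,
            cohort=cohort, case="concordant", comparator="non-concordant",
        )
        result.adjusted_ate = eff.ate
        result.adjusted_ci95 = eff.ci95
    return result


#: Rank tiers of the internal-consistency sensitivity analysis.
TIERS = {"top": (1, 3), "middle": (4, 10), "bottom": (11, None)}


def sensitivity_tiers(snapshots: pd.DataFrame, ranking: pd.DataFrame,
                      confounder_cols, config: EffectConfig,
                      cohort: str = "") -> pd.DataFrame:
    """Confounder-adjusted ATEs of top-vs-bottom and middle-vs-bottom tiers.

    Tiers by ranking position: top = ranks 1-3, middle = 4-10, bottom =
    11 and below. With fewer than 11 ranked treatments the tiers truncate
    and comparisons with an empty tier are skipped (reported with a
    reason).
    """
    ranking = ranking.sort_values("rank")
    if len(ranking) < 11:
        logger.warning(
            "cohort %s: only %d ranked treatments; tiers truncate",
            cohort, len(ranking),
        )
    members = {}
    for name, (lo, hi) in TIERS.items():
        sel = ranking[
            (ranking["rank"] >= lo)
            & ((ranking["rank"] <= hi) if hi is not None else True)
        ]
        regs = set(sel.regimen)
        members[name] = snapshots[snapshots.regimen.isin(regs)]

    rows = []
    for name in ("top", "middle"):
        row = {"cohort": cohort, "comparison": f"{name}_vs_bottom"}
        a, b = members[name], members["bottom"]
        if len(a) < 2 or len(b) < 2:
            row.update(ate=np.nan, se=np.nan, ci_lo=np.nan, ci_hi=np.nan,
                       n_case=len(a), n_comp=len(b), reason="empty_tier")
            rows.append(row)
            continue
        t = np.concatenate([np.ones(len(a), dtype=int), np.zeros(len(b), dtype=int)])
        joined = pd.concat([a, b], ignore_index=True)
        eff = bootstrap_effect(
            joined.delta_hba1c.to_numpy(), t,
            joined[list(confounder_cols)].to_numpy(), config,
            cohort=cohort, case=name, comparator="bottom",
        )
        row.update(ate=eff.ate, se=eff.se, ci_lo=eff.ci95[0], ci_hi=eff.ci95[1],
                   n_case=eff.n_case, n_comp=eff.n_comp, reason=None)
        rows.append(row)
    return pd.DataFrame(rows)


def rank_trajectories(snapshots: pd.DataFrame, ranking: pd.DataFrame | dict,
                      ) -> dict:
    """Descriptives of how patients move through the ranking over time.

    ``ranking`` is either one ranking table or a mapping cohort -> table
    (each snapshot is scored against its own cohort's ranking). Regimens
    absent from a ranking get position ``len(ranking) + 1``. Reports the
    mean assigned rank per snapshot, the fraction of consecutive
    same-patient snapshot pairs that switch regimen, and, among switches,
    the fractions improving/worsening rank and the mean rank movement
    (negative = toward better ranks).
    """
    if isinstance(ranking, pd.DataFrame):
        tables = {None: ranking}
        cohort_of = lambda row: None  # noqa: E731
    else:
        tables = ranking
        cohort_of = lambda row: row.cohort  # noqa: E731

    positions = {
        c: dict(zip(tab.regimen, tab["rank"])) for c, tab in tables.items()
    }
    fallback = {c: len(tab) + 1 for c, tab in tables.items()}

    df = snapshots.sort_values(["patient_id", "index_day"], kind="stable")
    ranks = np.array(
        [
            positions.get(cohort_of(row), {}).get(
                row.regimen, fallback.get(cohort_of(row), np.nan)
            )
            for row in df.itertuples()
        ],
        dtype=float,
    )
    same_patient = df.patient_id.to_numpy()[1:] == df.patient_id.to_numpy()[:-1]
    switched = (df.regimen.to_numpy()[1:] != df.regimen.to_numpy()[:-1]) & same_patient
    n_pairs = int(same_patient.sum())
    movement = ranks[1:] - ranks[:-1]

    out = {
        "mean_rank": float(np.nanmean(ranks)) if len(ranks) else np.nan,
        "n_consecutive_pairs": n_pairs,
        "switch_incidence": float(switched.sum() / n_pairs) if n_pairs else 0.0,
    }
    moves = movement[switched]
    moves = moves[np.isfinite(moves)]
    if len(moves):
        out["frac_improved"] = float((moves < 0).mean())
        out["frac_worsened"] = float((moves > 0).mean())
        out["mean_rank_change"] = float(moves.mean())
        out["mean_improvement"] = (
            float(-moves[moves < 0].mean()) if (moves < 0).any() else 0.0
        )
        out["mean_worsening"] = (
            float(moves[moves > 0].mean()) if (moves > 0).any() else 0.0
        )
    else:
        out.update(frac_improved=0.0, frac_worsened=0.0, mean_rank_change=0.0,
                   mean_improvement=0.0, mean_worsening=0.0)
    return out
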