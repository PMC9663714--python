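"""Stage orchestration: simulate -> cohort -> rank -> validate.

Each stage reads its predecessor's on-disk artifacts and writes its own
under ``outdir``; a run manifest records the config hash, seed, package
version and per-stage row counts. A single global seed is expanded into
per-stage substreams with ``numpy.random.SeedSequence`` so stages are
independently rerunnable and the whole run is reproducible byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import glycorank
from glycorank import simulate as sim
from glycorank import cohorts as coh
from glycorank.effects import EffectConfig, effects_to_frame, run_all_pairs
from glycorank.nma import NmaConfig, NetworkMetaAnalysis, build_network, sucra_ranks
from glycorank.validation import evaluate_concordance, rank_trajectories

__all__ = ["PipelineConfig", "run", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "cohort", "rank", "validate")

_STAGE_INPUTS = {
    "cohort": ("tables/labs.csv", "simulate"),
    "rank": ("snapshots_train.csv", "cohort"),
    "validate": ("rankings.csv", "rank"),
}


@dataclass
class PipelineConfig:
    outdir: str = "glycorank_run"
    seed: int = 0
    simulation: dict = field(default_factory=dict)      # SimulationConfig kwargs
    train_fraction: float = 0.8
    split_by_patient: bool = False
    effects: dict = field(default_factory=dict)         # EffectConfig kwargs
    nma: dict = field(default_factory=dict)             # NmaConfig kwargs
    ranking_draws: int = 2000
    top_k: int = 3

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        def fallback(o):
            if isinstance(o, (set, frozenset)):
                return sorted(o)
            return repr(o)

        blob = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=fallback
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage_seeds(seed: int) -> dict:
    streams = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {
        name: int(s.generate_state(1)[0] % 2**31)
        for name, s in zip(STAGES, streams)
    }


def _require(outdir: Path, stage: str) -> None:
    rel, prior = _STAGE_INPUTS[stage]
    if not (outdir / rel).exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs artifacts from stage '{prior}' "
            f"(missing {outdir / rel}); run '{prior}' first"
        )


def _update_manifest(outdir: Path, config: PipelineConfig, stage: str,
                     counts: dict) -> None:
    path = outdir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {
        "config_digest": config.digest(),
        "seed": config.seed,
        "version": glycorank.__version__,
        "stages": {},
    }
    manifest["stages"][stage] = counts
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run(command: str, config: PipelineConfig) -> dict:
    """Run one stage or ``all``. Returns the per-stage row-count summary."""
    if command not in STAGES and command != "all":
        raise ValueError(f"unknown command {command!r}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    todo = list(STAGES) if command == "all" else [command]
    summary = {}
    for stage in todo:
        counts = _RUNNERS[stage](outdir, config, seeds[stage])
        _update_manifest(outdir, config, stage, counts)
        summary[stage] = counts
        logger.info("stage %s: %s", stage, counts)
    return summary


def _run_simulate(outdir: Path, config: PipelineConfig, seed: int) -> dict:
    sim_cfg = sim.SimulationConfig(**{"seed": seed, **config.simulation})
    histories, truth = sim.simulate_population(sim_cfg)
    sim.write_tables(histories, outdir / "tables")
    sim.write_ground_truth(truth, outdir / "ground_truth")
    tables = sim.histories_to_tables(histories)
    return {
        "n_patients": len(histories),
        **{f"n_{name}_rows": len(df) for name, df in tables.items()},
    }


def _run_cohort(outdir: Path, config: PipelineConfig, seed: int) -> dict:
    _require(outdir, "cohort")
    histories = sim.read_tables(outdir / "tables")
    drop_log: list = []
    kept = coh.apply_exclusions(histories, drop_log=drop_log)
    snap_log: list = []
    snapshots = coh.build_snapshot_table(kept, drop_log=snap_log)
    if not len(snapshots):
        raise RuntimeError("no snapshots survived filtering")
    train, test, smd_report = coh.split_train_test(
        snapshots, fraction=config.train_fraction, seed=seed,
        by_patient=config.split_by_patient,
    )
    # Imputation means are learned on the training set, per cohort, and
    # applied to both sides.
    train_parts, test_parts = [], []
    for label in coh.COHORT_LABELS:
        tr = train[train.cohort == label]
        te = test[test.cohort == label]
        if not len(tr):
            if len(te):
                test_parts.append(coh.ConfounderImputer().fit_transform(te))
            continue
        imp = coh.ConfounderImputer().fit(tr)
        train_parts.append(imp.transform(tr))
        if len(te):
            test_parts.append(imp.transform(te))
    train = pd.concat(train_parts, ignore_index=True) if train_parts else train
    test = pd.concat(test_parts, ignore_index=True) if test_parts else test

    snapshots.to_csv(outdir / "snapshots.csv", index=False)
    train.to_csv(outdir / "snapshots_train.csv", index=False)
    test.to_csv(outdir / "snapshots_test.csv", index=False)
    coh.cohort_summary(snapshots).to_csv(outdir / "cohort_summary.csv", index=False)
    smd_report.to_csv(outdir / "split_balance.csv", index=False)
    pd.DataFrame(drop_log, columns=["patient_id", "reason"]).to_csv(
        outdir / "dropped_patients.csv", index=False
    )
    pd.DataFrame(snap_log, columns=["patient_id", "index_day", "reason"]).to_csv(
        outdir / "dropped_snapshots.csv", index=False
    )
    return {
        "n_patients_kept": len(kept),
        "n_patients_dropped": len(drop_log),
        "n_snapshots": len(snapshots),
        "n_snapshots_dropped": len(snap_log),
        "n_train": len(train),
        "n_test": len(test),
    }


def _run_rank(outdir: Path, config: PipelineConfig, seed: int) -> dict:
    _require(outdir, "rank")
    train = pd.read_csv(outdir / "snapshots_train.csv")
    confounders = coh.imputed_confounder_columns(train)
    cohort_seeds = np.random.SeedSequence(seed).spawn(len(coh.COHORT_LABELS))
    all_edges, rankings, failures, networks = [], [], [], {}
    for label, ss in zip(coh.COHORT_LABELS, cohort_seeds):
        sub = train[train.cohort == label]
        if not len(sub):
            failures.append({"cohort": label, "case": "", "comparator": "",
                             "reason": "empty_cohort"})
            continue
        counts = sub.regimen.value_counts().to_dict()
        eligible = [k for k, n in counts.items() if n > config.nma.get(
            "node_min", 35)]
        s_int = int(ss.generate_state(1)[0] % 2**31)
        eff_cfg = EffectConfig(**{"seed": s_int, **config.effects})
        effects = run_all_pairs(sub, eligible, confounders, eff_cfg,
                                cohort=label, failures=failures)
        all_edges.extend(effects)
        nma_kwargs = {k: v for k, v in config.nma.items() if k != "node_min"}
        network = build_network(effects, counts, cohort=label,
                                node_min=config.nma.get("node_min", 35))
        networks[label] = network
        if len(network.nodes) < 2 or not network.edges:
            failures.append({"cohort": label, "case": "", "comparator": "",
                             "reason": "network_too_small"})
            continue
        model = NetworkMetaAnalysis(NmaConfig(**{"seed": s_int, **nma_kwargs}))
        model.fit(network)
        table = sucra_ranks(model, network, n_draws=config.ranking_draws,
                            seed=s_int, force=not model.converged_)
        table["converged"] = model.converged_
        rankings.append(table)

    effects_to_frame(all_edges).to_csv(outdir / "effects.csv", index=False)
    pd.DataFrame(failures).to_csv(outdir / "study_failures.csv", index=False)
    with open(outdir / "networks.json", "w") as fh:
        json.dump({c: n.to_json_dict() for c, n in networks.items()}, fh, indent=2)
    ranking_df = (
        pd.concat(rankings, ignore_index=True)
        if rankings
        else pd.DataFrame(columns=["rank", "regimen", "sucra", "cohort"])
    )
    ranking_df.to_csv(outdir / "rankings.csv", index=False)
    return {
        "n_studies": len(all_edges),
        "n_failures": len(failures),
        "n_cohorts_ranked": len(rankings),
        "n_ranking_rows": len(ranking_df),
    }


def _run_validate(outdir: Path, config: PipelineConfig, seed: int) -> dict:
    _require(outdir, "validate")
    rankings = pd.read_csv(outdir / "rankings.csv")
    results = []
    ranking_by_cohort = {
        c: g.reset_index(drop=True) for c, g in rankings.groupby("cohort")
    }
    cohort_seeds = np.random.SeedSequence(seed).spawn(len(coh.COHORT_LABELS))
    for (label, ss), dataset in (
        (pair, ds)
        for pair in zip(coh.COHORT_LABELS, cohort_seeds)
        for ds in ("train", "test")
    ):
        if label not in ranking_by_cohort:
            continue
        df = pd.read_csv(outdir / f"snapshots_{dataset}.csv")
        sub = df[df.cohort == label]
        if not len(sub):
            continue
        confounders = coh.imputed_confounder_columns(sub)
        s_int = int(ss.generate_state(1)[0] % 2**31)
        cfg = EffectConfig(**{"seed": s_int, **config.effects})
        res = evaluate_concordance(
            sub, ranking_by_cohort[label], confounders, cfg,
            cohort=label, dataset=dataset, top_k=config.top_k,
        )
        results.append(res.to_dict())
    concordance = pd.DataFrame(results)
    concordance.to_csv(outdir / "concordance.csv", index=False)

    train = pd.read_csv(outdir / "snapshots_train.csv")
    traj = rank_trajectories(
        train[train.cohort.isin(ranking_by_cohort)], ranking_by_cohort
    ) if ranking_by_cohort else {}
    with open(outdir / "rank_trajectories.json", "w") as fh:
        json.dump(traj, fh, indent=2)
    return {
        "n_concordance_rows": len(concordance),
        "n_significant": int(concordance.significant.sum()) if len(concordance) else 0,
    }


_RUNNERS = {
    "simulate": _run_simulate,
    "cohort": _run_cohort,
    "rank": _run_rank,
    "validate": _run_validate,
}
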