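"""Seeded end-to-end replications of the simulation studies.

One replication runs the full pipeline: generate an item pool and ability
sample per the design, assign replenished items to examinee groups,
administer the adaptive test to the cohort, fit the penalized paths on the
recorded responses (with MAP ability estimates, and optionally with the
true abilities as a benchmark), select patterns by BIC, refit relaxed item
parameters under the detected patterns, and evaluate every index:
CSR, AME/RMSE of abilities, AME of item parameters, exposure chi-square
and test overlap ratio.

Randomness is hierarchical: replication ``r`` uses child seed
``base_seed + r``; within a replication, SeedSequence spawning splits the
stream into pool / abilities / assignment / cohort components, so each
stage is independently reproducible and replications can run in parallel
without sharing state.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from catlasso.evaluation import (
    ExposureSummary,
    ame_item,
    ame_theta,
    csr,
    exposure_chi_square,
    rmse_theta,
    test_overlap_ratio,
)
from catlasso.mcat import PriorSpec, run_cohort
from catlasso.patterns import detect_patterns, lambda_grid
from catlasso.pools import (
    StudyDesign,
    generate_abilities,
    generate_item_pool,
    make_group_assignment,
    study_design,
)

__all__ = [
    "RunConfig",
    "run_replication",
    "run_study",
    "run_from_manifest",
    "pattern_benchmark_replication",
]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one simulated condition.

    ``stopping`` is ``("fixed", Z0)`` or ``("variable", se_threshold,
    max_items)``.  ``prior_mode`` chooses the MAP/selection prior
    covariance: ``"identity"`` (the default) or ``"true"`` (the generating
    ability covariance).
    """

    study: str = "study1"
    discrimination: str = "high"
    correlated: bool = False
    criterion: Literal["D", "bayesA"] = "D"
    stopping: tuple = ("fixed", 50)
    grid_T: float = 120.0
    grid_W: int = 80
    replications: int = 5
    base_seed: int = 0
    N: int = 2000
    selection_mode: Literal["joint", "per_item"] = "joint"
    bic_mode: Literal["shrunken", "refit"] = "refit"
    prior_mode: Literal["identity", "true"] = "identity"
    run_benchmark: bool = False
    detect: bool = True

    def design(self) -> StudyDesign:
        kind = self.stopping[0]
        if kind == "fixed":
            Z0: int | None = int(self.stopping[1])
        elif kind == "variable":
            Z0 = None
        else:
            raise ValueError(f"unknown stopping rule {self.stopping!r}")
        return study_design(
            self.study, discrimination=self.discrimination,
            correlated=self.correlated, Z0=Z0, N=self.N,
        )

    def prior(self, design: StudyDesign) -> PriorSpec:
        if self.prior_mode == "identity":
            return PriorSpec.identity(design.K)
        if self.prior_mode == "true":
            return PriorSpec(mean=np.zeros(design.K), cov=design.ability_cov)
        raise ValueError(f"unknown prior_mode {self.prior_mode!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "stopping" in d and isinstance(d["stopping"], (list, tuple)):
            d["stopping"] = tuple(d["stopping"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _replication_seeds(base_seed: int, rep_index: int) -> list[np.random.SeedSequence]:
    """Split a replication's seed into pool/abilities/assignment/cohort streams."""
    root = np.random.SeedSequence(base_seed + rep_index)
    return root.spawn(4)


def run_replication(config: RunConfig, rep_index: int) -> dict:
    """Run one seeded replication end-to-end; returns a row of indices.

    The row carries the seven evaluation indices plus, when
    ``config.run_benchmark`` is set, the CSR/AME values obtained by feeding
    the true abilities (instead of the MAP estimates) to the penalized
    fits.
    """
    design = config.design()
    prior = config.prior(design)
    ss_pool, ss_ab, ss_asg, ss_cohort = _replication_seeds(config.base_seed, rep_index)
    pool = generate_item_pool(design, np.random.default_rng(ss_pool))
    abilities = generate_abilities(
        design.N, design.ability_cov, np.random.default_rng(ss_ab)
    )
    assignment = make_group_assignment(design, np.random.default_rng(ss_asg))

    kwargs = {}
    if design.Z0 is None:
        kwargs = {"se_threshold": float(config.stopping[1]),
                  "max_items": int(config.stopping[2])}
    cohort = run_cohort(
        pool, abilities, assignment, design, config.criterion, prior,
        ss_cohort, **kwargs,
    )

    row: dict = {
        "rep_index": rep_index,
        "ame_theta": ame_theta(abilities, cohort.theta_hat),
        "rmse_theta": rmse_theta(abilities, cohort.theta_hat),
        "mean_test_length": float(cohort.test_lengths.mean()),
    }
    op = pool.operational_ids
    rates = cohort.exposure_counts[op] / design.N
    summary = ExposureSummary(
        exposure_rates=rates, N=design.N,
        Z0=float(cohort.test_lengths.mean()), J0=op.size,
    )
    row["chi_square"] = exposure_chi_square(summary)
    row["tor"] = test_overlap_ratio(summary)

    if config.detect:
        grid = lambda_grid(config.grid_T, config.grid_W)
        rep_ids = sorted(cohort.replenished)
        responses = [cohort.replenished[j][1] for j in rep_ids]
        scores_hat = [cohort.theta_hat[cohort.replenished[j][0]] for j in rep_ids]
        Q_true = pool.Q[rep_ids]
        a_true, b_true = pool.a[rep_ids], pool.b[rep_ids]

        result = detect_patterns(
            responses, scores_hat, grid, item_ids=rep_ids,
            selection_mode=config.selection_mode, bic_mode=config.bic_mode,
        )
        row["csr"] = csr(Q_true, result.patterns)
        row["ame_a"], row["ame_b"] = ame_item(
            a_true, result.a_refit, b_true, result.b_refit
        )
        if config.run_benchmark:
            scores_true = [abilities[cohort.replenished[j][0]] for j in rep_ids]
            bench = detect_patterns(
                responses, scores_true, grid, item_ids=rep_ids,
                selection_mode=config.selection_mode, bic_mode=config.bic_mode,
            )
            row["csr_benchmark"] = csr(Q_true, bench.patterns)
            row["ame_a_benchmark"], row["ame_b_benchmark"] = ame_item(
                a_true, bench.a_refit, b_true, bench.b_refit
            )
    return row


def pattern_benchmark_replication(config: RunConfig, rep_index: int) -> dict:
    """Pattern detection fed with true abilities, skipping the adaptive test.

    Generates the pool, abilities and assignment exactly as
    ``run_replication`` would, simulates the replenished-item responses at
    the true abilities, and runs the penalized path + BIC selection with
    the true abilities as scores.  Used for the true-ability benchmark
    column of the study tables.
    """
    design = config.design()
    ss_pool, ss_ab, ss_asg, ss_cohort = _replication_seeds(config.base_seed, rep_index)
    pool = generate_item_pool(design, np.random.default_rng(ss_pool))
    abilities = generate_abilities(
        design.N, design.ability_cov, np.random.default_rng(ss_ab)
    )
    assignment = make_group_assignment(design, np.random.default_rng(ss_asg))

    # replenished responses use the same dedicated child stream as a cohort
    from scipy.special import expit

    rng_rep = np.random.default_rng(ss_cohort.spawn(design.N + 1)[design.N])
    responses, scores, rep_ids = [], [], []
    for g in range(assignment.n_groups):
        ex = assignment.examinee_groups[g]
        items = assignment.item_groups[g]
        P = expit(abilities[ex] @ pool.a[items].T + pool.b[items])
        y = (rng_rep.random(P.shape) < P).astype(int)
        for col, item_id in enumerate(items):
            rep_ids.append(int(item_id))
            responses.append(y[:, col])
            scores.append(abilities[ex])
    order = np.argsort(rep_ids)
    rep_ids = [rep_ids[i] for i in order]
    responses = [responses[i] for i in order]
    scores = [scores[i] for i in order]

    grid = lambda_grid(config.grid_T, config.grid_W)
    result = detect_patterns(
        responses, scores, grid, item_ids=rep_ids,
        selection_mode=config.selection_mode, bic_mode=config.bic_mode,
    )
    Q_true = pool.Q[rep_ids]
    ame_a, ame_b = ame_item(
        pool.a[rep_ids], result.a_refit, pool.b[rep_ids], result.b_refit
    )
    return {
        "rep_index": rep_index,
        "csr": csr(Q_true, result.patterns),
        "ame_a": ame_a,
        "ame_b": ame_b,
    }


def run_study(
    config: RunConfig,
    out_dir=None,
    n_jobs: int = 1,
) -> tuple[pd.DataFrame, pd.Series]:
    """Run all replications of a condition and aggregate the indices.

    Returns ``(per-replication DataFrame, across-replication means)``.
    With ``out_dir`` set, writes ``replications.csv``, ``aggregate.csv``
    and a run manifest (config + seeds + version).  Replications use
    independent child seeds, so parallel and serial execution agree.
    """
    reps = range(config.replications)
    if n_jobs == 1:
        rows = [run_replication(config, r) for r in reps]
    else:
        from joblib import Parallel, delayed

        rows = Parallel(n_jobs=n_jobs)(
            delayed(run_replication)(config, r) for r in reps
        )
    table = pd.DataFrame(rows).set_index("rep_index")
    aggregate = table.mean(axis=0)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "replications.csv")
        aggregate.to_frame("mean").to_csv(out / "aggregate.csv")
        from catlasso import __version__

        manifest = {
            "config": _config_dict(config),
            "seeds": [config.base_seed + r for r in reps],
            "version": __version__,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return table, aggregate


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["stopping"] = list(d["stopping"])
    return d


def run_from_manifest(path) -> tuple[pd.DataFrame, pd.Series]:
    """Re-run a study from a written manifest (reproducibility round-trip)."""
    with open(path) as fh:
        manifest = json.load(fh)
    return run_study(RunConfig.from_dict(manifest["config"]))
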