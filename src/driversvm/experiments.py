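"""Benchmark experiments on synthetic cohorts.

Self-contained procedures that exercise the whole method under controlled
conditions and report its headline numbers:

``planted_driver_recovery``
    Train on a planted-driver cohort and measure how well the held-out
    planted drivers are prioritised: median per-sample AUC of planted
    drivers over the rest, the fraction of samples where planted drivers
    are enriched more than two-fold over expectation in the top five, and
    the top-up coverage of the cohort.

``stability_scaling``
    Train several models on disjoint sub-cohorts of two sizes and compare
    the stability of their top-five gene lists on a common evaluation
    cohort via median pairwise rank-biased overlap.  Larger training
    cohorts are expected to give more stable rankings.

``simulator_fidelity``
    Simulate a cohort from fixture donors and verify the resampling
    contract: burden and ploidy inside the matching windows and per-gene
    damaging-alteration frequencies correlated with the donors'.

All randomness derives from a single integer seed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from . import metrics
from .features import build_molecular_features, join_features
from .model import KernelConfig, TrainedModel, build_parameter_grid, reduced_grid, score_predictions, train
from .pipeline import call_drivers
from .simulate import (
    FixtureCohort,
    FixtureSpec,
    SimulationSpec,
    alteration_frequencies,
    donors_from_tables,
    generate_fixture_cohort,
    simulate_cohort,
)


def _features_for(cohort: FixtureCohort) -> pd.DataFrame:
    molecular = build_molecular_features(cohort.mutations, cohort.cnvs, cohort.ploidy)
    features, _ = join_features(molecular, cohort.properties)
    return features


def _train_quiet(features, annotation, grid, max_iterations, window, seed) -> TrainedModel:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # fixture cohorts have constant binary columns
        return train(features, annotation, grid=grid, max_iterations=max_iterations, window=window, seed=seed)


def truth_metrics(predictions: pd.DataFrame, driver_genes: set[str], k: int = 5) -> pd.DataFrame:
    """Per-sample AUC and top-k O/E of ground-truth planted drivers.

    Positives are planted drivers present in the sample's prediction pool;
    samples without one have undefined values (NaN).
    """
    rows = []
    for sample, grp in predictions.sort_values(["sample", "rank"]).groupby("sample"):
        cats = ["driver" if g in driver_genes else "rest" for g in grp["gene"]]
        rows.append(
            {
                "sample": sample,
                "auc_drivers_vs_rest": metrics.sample_auc(cats, "driver", "rest"),
                "oe_drivers_topk": metrics.oe_ratio(cats, "driver", k=k),
            }
        )
    return pd.DataFrame(rows)


def planted_driver_recovery(
    seed: int,
    spec: FixtureSpec | None = None,
    grid: dict[str, list[KernelConfig]] | None = None,
    max_iterations: int = 50,
    window: int = 25,
    k: int = 5,
) -> dict:
    """Full train -> predict -> evaluate run on a planted-driver cohort."""
    rng = np.random.default_rng(seed)
    spec = spec or FixtureSpec(seed=int(rng.integers(2**31 - 1)))
    grid = grid or reduced_grid()
    cohort = generate_fixture_cohort(spec)
    features = _features_for(cohort)
    model = _train_quiet(
        features, cohort.annotation, grid, max_iterations, window, seed=int(rng.integers(2**31 - 1))
    )
    predictions = score_predictions(model, features)
    per_sample = truth_metrics(predictions, set(cohort.driver_genes), k=k)

    aucs = per_sample["auc_drivers_vs_rest"].dropna()
    oes = per_sample["oe_drivers_topk"].dropna()
    calls = call_drivers(features, predictions, cohort.annotation, target=k)
    damaged_per_sample = features.groupby("sample")["gene"].nunique()
    eligible = [c for c in calls if damaged_per_sample[c.sample_id] >= k]
    exactly_k = [c for c in eligible if len(c.genes) == k or c.n_canonical >= k]
    return {
        "median_auc_drivers_vs_rest": float(aucs.median()),
        "n_samples_auc_defined": int(len(aucs)),
        "frac_samples_driver_oe_gt2": float((oes > 2).mean()),
        "n_samples_oe_defined": int(len(oes)),
        "frac_covered_samples_with_full_list": float(len(exactly_k) / len(eligible)) if eligible else float("nan"),
        "n_samples": int(spec.n_samples),
        "n_training_entries": len(model.training_roster),
        "kernel_sensitivities": model.sensitivities,
    }


def _pairwise_rbo_median(prediction_tables: list[pd.DataFrame], p: float = 0.9, depth: int = 5) -> float:
    scores = []
    for i in range(len(prediction_tables)):
        for j in range(i + 1, len(prediction_tables)):
            scores.extend(metrics.pairwise_rbo(prediction_tables[i], prediction_tables[j], p=p, depth=depth).values)
    return float(np.median(scores))


def stability_scaling(
    seed: int,
    n_models: int = 5,
    large_size: int = 100,
    small_size: int = 10,
    n_eval: int = 50,
    grid: dict[str, list[KernelConfig]] | None = None,
    max_iterations: int = 25,
    window: int = 15,
) -> dict:
    """Ranking stability of models trained on disjoint cohorts of two sizes.

    One synthetic universe (gene properties, annotation, alteration process)
    is generated; its samples are partitioned into `n_models` disjoint
    training cohorts of each size plus a shared evaluation cohort.  Every
    model ranks the evaluation samples and the median pairwise rank-biased
    overlap of top-`depth` lists is reported per training-cohort size.
    """
    rng = np.random.default_rng(seed)
    total = n_models * (large_size + small_size) + n_eval
    spec = FixtureSpec(n_samples=total, seed=int(rng.integers(2**31 - 1)))
    cohort = generate_fixture_cohort(spec)
    features = _features_for(cohort)
    # narrower grid than the recovery run: ten trainings must stay desk-scale
    grid = grid or build_parameter_grid(
        nu_values=(0.05, 0.1, 0.2, 0.3), gamma_values=(2.0**-7, 2.0**-4), degrees=(2,), coef0_values=(1.0,)
    )

    samples = sorted(features["sample"].unique())
    assert len(samples) == total
    chunks: dict[int, list[list[str]]] = {large_size: [], small_size: []}
    pos = 0
    for size in (large_size, small_size):
        for _ in range(n_models):
            chunks[size].append(samples[pos : pos + size])
            pos += size
    eval_samples = samples[pos:]
    eval_features = features[features["sample"].isin(eval_samples)]

    medians: dict[int, float] = {}
    for size in (large_size, small_size):
        tables = []
        for chunk in chunks[size]:
            sub = features[features["sample"].isin(chunk)]
            model = _train_quiet(
                sub, cohort.annotation, grid, max_iterations, window, seed=int(rng.integers(2**31 - 1))
            )
            tables.append(score_predictions(model, eval_features))
        medians[size] = _pairwise_rbo_median(tables)
    return {
        "median_rbo_large": medians[large_size],
        "median_rbo_small": medians[small_size],
        "large_size": large_size,
        "small_size": small_size,
        "n_models": n_models,
        "n_eval_samples": len(eval_samples),
    }


def simulator_fidelity(
    seed: int,
    n_donor_samples: int = 100,
    n_simulated: int = 500,
) -> dict:
    """Resampling-contract check: windows honoured, frequencies preserved."""
    rng = np.random.default_rng(seed)
    donor_spec = FixtureSpec(n_samples=n_donor_samples, seed=int(rng.integers(2**31 - 1)))
    cohort = generate_fixture_cohort(donor_spec)
    donors = donors_from_tables(cohort.mutations, cohort.cnvs, cohort.ploidy)
    sim_spec = SimulationSpec(n_samples=n_simulated, seed=int(rng.integers(2**31 - 1)))
    sim_mut, sim_cnv, sim_pl, targets = simulate_cohort(donors, sim_spec, with_targets=True)

    sim_burdens = (
        pd.DataFrame({"sample": sim_mut["sample"], "gene": sim_mut["gene"]})
        .groupby("sample")["gene"]
        .nunique()
        .reindex(targets["sample"], fill_value=0)
    )
    burden_ok = (sim_burdens.values == targets["target_burden"].values).all()
    ploidy_dev = np.abs(sim_pl.set_index("sample")["ploidy"].reindex(targets["sample"]).values
                        - targets["target_ploidy"].values)

    freq_d = alteration_frequencies(cohort.mutations, cohort.cnvs, n_donor_samples)
    freq_s = alteration_frequencies(sim_mut, sim_cnv, n_simulated)
    union = freq_d.index.union(freq_s.index)
    r = float(stats.pearsonr(freq_d.reindex(union, fill_value=0.0), freq_s.reindex(union, fill_value=0.0))[0])
    return {
        "all_burdens_equal_target": bool(burden_ok),
        "max_ploidy_deviation_from_target": float(ploidy_dev.max()),
        "gene_frequency_pearson_r": r,
        "n_simulated": n_simulated,
        "n_donors": n_donor_samples,
    }
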