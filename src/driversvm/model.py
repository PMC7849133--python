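"""Multi-kernel one-class SVM engine for driver prioritisation.

Training positives are the damaged canonical drivers of a cohort, restricted
to mode-of-action-consistent alterations: oncogenes kept only with
gain-of-function alterations (amplification, hotspot or non-truncating
damaging mutations), tumour suppressors only with loss-of-function ones
(truncating mutations or deletion), dual-role genes with any damaging
alteration.  One-class SVMs with four kernels (linear, radial, sigmoid,
polynomial) are fitted on these positives; per-kernel hyper-parameters are
chosen by iterated three-fold cross-validated sensitivity — the fraction of
held-out canonical drivers predicted in-class — and the converged mean
sensitivity of each kernel becomes its weight in the combined score used to
rank every other damaged gene within each patient.

Features are un-centred but scaled to unit standard deviation, with divisors
computed on the training set and reused verbatim at prediction time.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.svm import OneClassSVM

from .annotation import GeneAnnotation
from .errors import InputError
from .features import ALL_FEATURES

logger = logging.getLogger(__name__)

KERNELS = ("linear", "radial", "sigmoid", "polynomial")
_SKLEARN_KERNEL = {"linear": "linear", "radial": "rbf", "sigmoid": "sigmoid", "polynomial": "poly"}

MODEL_FORMAT_VERSION = 1


def assemble_training_set(features: pd.DataFrame, annotation: GeneAnnotation) -> pd.DataFrame:
    """Select the training positives: damaged canonical drivers with
    mode-of-action-consistent alterations.

    Oncogene entries are kept iff amplified or carrying a hotspot or
    non-truncating damaging mutation; tumour-suppressor entries iff carrying
    a truncating mutation or deleted; dual-role genes with any damaging
    alteration.  Canonical drivers without an OG/TSG role are excluded from
    training (they stay in the prediction set for assessment).
    """
    roles = features["gene"].map(lambda g: annotation.role(g) if annotation.category(g) == "canonical" else None)
    gof = features["is_amplified"] | (features["n_hotspot"] > 0) | (features["n_nontrunc_damaging"] > 0)
    lof = (features["n_truncating"] > 0) | features["is_deleted"]
    keep = ((roles == "OG") & gof) | ((roles == "TSG") & lof) | ((roles == "both") & (gof | lof))
    training = features[keep.fillna(False)].reset_index(drop=True)
    if training.empty:
        raise InputError("empty training set: no damaged canonical driver passes the gain/loss-of-function filter")
    return training


def scale_features(
    training: pd.DataFrame, prediction: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame | None, pd.Series]:
    """Scale feature columns to unit sample standard deviation, no centering.

    Divisors are the per-column sample SDs (ddof=1) of the training table and
    are reused verbatim for the prediction table.  Zero-SD (constant) columns
    are divided by 1 with a warning.
    """
    cols = [c for c in ALL_FEATURES if c in training.columns]
    train_mat = training[cols].astype(float)
    if not np.isfinite(train_mat.to_numpy()).all():
        raise InputError("non-finite values in training features")
    divisors = train_mat.std(ddof=1)
    zero = divisors[(divisors == 0) | divisors.isna()].index.tolist()
    if zero:
        warnings.warn(f"constant feature columns left unscaled: {zero}", stacklevel=2)
        divisors[zero] = 1.0
    scaled_train = training.copy()
    scaled_train[cols] = train_mat / divisors
    scaled_pred = None
    if prediction is not None:
        pred_mat = prediction[cols].astype(float)
        if not np.isfinite(pred_mat.to_numpy()).all():
            raise InputError("non-finite values in prediction features")
        scaled_pred = prediction.copy()
        scaled_pred[cols] = pred_mat / divisors
    return scaled_train, scaled_pred, divisors


@dataclass(frozen=True)
class KernelConfig:
    """Hyper-parameters of one one-class SVM; only fields applicable to the
    kernel are set."""

    kernel: str
    nu: float
    gamma: float | None = None
    degree: int | None = None
    coef0: float | None = None

    def __post_init__(self) -> None:
        if self.kernel not in KERNELS:
            raise InputError(f"unknown kernel {self.kernel!r}")
        if not 0 < self.nu <= 1:
            raise InputError("nu must be in (0, 1]")

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}

    def make_estimator(self) -> OneClassSVM:
        kwargs: dict = {"kernel": _SKLEARN_KERNEL[self.kernel], "nu": self.nu}
        if self.gamma is not None:
            kwargs["gamma"] = self.gamma
        if self.degree is not None:
            kwargs["degree"] = self.degree
        if self.coef0 is not None:
            kwargs["coef0"] = self.coef0
        return OneClassSVM(**kwargs)


DEFAULT_NU = (0.05, 0.1, 0.2, 0.3)
DEFAULT_GAMMA = tuple(float(2.0**e) for e in range(-7, 4))
DEFAULT_DEGREE = (2, 3, 4)
DEFAULT_COEF0 = (0.0, 1.0)


def build_parameter_grid(
    nu_values=DEFAULT_NU,
    gamma_values=DEFAULT_GAMMA,
    degrees=DEFAULT_DEGREE,
    coef0_values=DEFAULT_COEF0,
    kernels=KERNELS,
) -> dict[str, list[KernelConfig]]:
    """Enumerate kernel configurations deterministically.

    Only parameters applicable to each kernel are varied: linear uses nu
    alone; radial adds gamma; sigmoid adds gamma and coef0; polynomial adds
    gamma, degree and coef0.  Ordering is the nested loop order of the value
    tuples, so identical specs give identical grids.
    """
    if not nu_values:
        raise InputError("empty nu grid")
    grid: dict[str, list[KernelConfig]] = {}
    for kernel in kernels:
        configs: list[KernelConfig] = []
        for nu in nu_values:
            if kernel == "linear":
                configs.append(KernelConfig("linear", nu))
                continue
            for gamma in gamma_values:
                if kernel == "radial":
                    configs.append(KernelConfig("radial", nu, gamma=gamma))
                elif kernel == "sigmoid":
                    for c0 in coef0_values:
                        configs.append(KernelConfig("sigmoid", nu, gamma=gamma, coef0=c0))
                else:
                    for degree in degrees:
                        for c0 in coef0_values:
                            configs.append(KernelConfig("polynomial", nu, gamma=gamma, degree=degree, coef0=c0))
        if not configs:
            raise InputError(f"empty grid for kernel {kernel!r}")
        grid[kernel] = configs
    return grid


def reduced_grid() -> dict[str, list[KernelConfig]]:
    """A small grid (at most 24 configurations per kernel) for desk-scale runs.

    Spans the low-to-mid part of the default gamma range (large gammas
    saturate the sigmoid kernel on un-centred data) and keeps the
    inhomogeneous polynomial (coef0 = 1) only.
    """
    grid = build_parameter_grid(
        nu_values=(0.05, 0.1, 0.2, 0.3),
        gamma_values=(2.0**-7, 2.0**-4, 2.0**-1),
        degrees=(2, 3),
        coef0_values=(0.0, 1.0),
    )
    grid["polynomial"] = [c for c in grid["polynomial"] if c.coef0 == 1.0]
    return grid


def _feature_matrix(table: pd.DataFrame) -> np.ndarray:
    cols = [c for c in ALL_FEATURES if c in table.columns]
    return table[cols].to_numpy(dtype=float)


def cv_sensitivity(config: KernelConfig, X: np.ndarray, folds: int = 3, seed: int = 0) -> float:
    """Pooled in-class fraction of held-out training genes under `folds`-fold CV."""
    if len(X) < folds:
        raise InputError(f"need at least {folds} training entries for {folds}-fold cross-validation")
    splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    in_class = 0
    total = 0
    for train_idx, test_idx in splitter.split(X):
        try:
            est = config.make_estimator()
            est.fit(X[train_idx])
            pred = est.predict(X[test_idx])
        except Exception as exc:
            logger.info("fit failed for %s: %s; sensitivity recorded as 0", config, exc)
            return 0.0
        in_class += int((pred == 1).sum())
        total += len(test_idx)
    return in_class / total


@dataclass
class SelectionResult:
    config: KernelConfig
    sensitivity: float
    iterations: int
    converged: bool


def select_parameters(
    kernel: str,
    grid: list[KernelConfig],
    training: pd.DataFrame,
    max_iterations: int = 2000,
    window: int = 100,
    folds: int = 3,
    seed: int = 0,
) -> SelectionResult:
    """Pick the kernel configuration with the highest mean cross-validated
    sensitivity over repeated fold splits.

    Each iteration draws a fresh 3-fold partition (shared across the grid so
    configurations are compared on identical splits) and updates each
    configuration's running mean sensitivity.  Selection converges when the
    identity of the best configuration is unchanged over `window` consecutive
    iterations; ties prefer lower nu, then grid order.  If `max_iterations`
    is exhausted first, the current best is returned flagged unconverged.
    """
    if not grid:
        raise InputError(f"empty parameter grid for kernel {kernel!r}")
    X = _feature_matrix(training)
    rng = np.random.default_rng(seed)
    sums = np.zeros(len(grid))
    best_idx: int | None = None
    stable = 0
    iteration = 0
    order = np.array([(cfg.nu, i) for i, cfg in enumerate(grid)], dtype=[("nu", float), ("i", int)])
    while iteration < max_iterations:
        iteration += 1
        fold_seed = int(rng.integers(2**31 - 1))
        for i, cfg in enumerate(grid):
            sums[i] += cv_sensitivity(cfg, X, folds=folds, seed=fold_seed)
        means = sums / iteration
        top = means.max()
        tied = np.flatnonzero(means == top)
        # ties broken by lower nu then original grid order
        current = int(min(tied, key=lambda i: (order["nu"][i], order["i"][i])))
        if current == best_idx:
            stable += 1
        else:
            best_idx = current
            stable = 1
        if stable >= window:
            return SelectionResult(grid[best_idx], float(means[best_idx]), iteration, True)
    return SelectionResult(grid[best_idx], float(sums[best_idx] / iteration), iteration, False)


@dataclass
class TrainedModel:
    """Fitted per-kernel one-class SVMs plus everything needed to score.

    ``sensitivities`` are the converged mean cross-validated sensitivities
    used as kernel weights; ``divisors`` are the training-set scaling SDs;
    ``training_roster`` lists the (sample, gene) entries used for training so
    they can be excluded from prediction.
    """

    configs: dict[str, KernelConfig]
    estimators: dict[str, OneClassSVM]
    sensitivities: dict[str, float]
    divisors: pd.Series
    feature_names: list[str]
    training_roster: list[tuple[str, str]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.configs) != set(KERNELS):
            raise InputError(f"model must carry all four kernels, got {sorted(self.configs)}")

    @property
    def weights(self) -> dict[str, float]:
        total = sum(self.sensitivities.values())
        if total == 0:
            raise InputError("untrained model: all kernel sensitivities are zero")
        return {k: s / total for k, s in self.sensitivities.items()}

    def save(self, path: str | Path) -> None:
        """Serialise to a versioned binary with a JSON sidecar of configs,
        weights and scaling divisors."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": self}, path)
        sidecar = {
            "format_version": MODEL_FORMAT_VERSION,
            "configs": {k: c.to_dict() for k, c in self.configs.items()},
            "sensitivities": self.sensitivities,
            "divisors": {k: float(v) for k, v in self.divisors.items()},
            "feature_names": self.feature_names,
            "n_training_entries": len(self.training_roster),
            "provenance": self.provenance,
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        payload = joblib.load(path)
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise InputError(f"unsupported model format version in {path}")
        return payload["model"]


def train_final(
    selections: dict[str, SelectionResult],
    training: pd.DataFrame,
    divisors: pd.Series,
    provenance: dict | None = None,
) -> TrainedModel:
    """Refit each selected kernel on the full (scaled) training table."""
    if set(selections) != set(KERNELS):
        raise InputError(f"need selections for all four kernels, got {sorted(selections)}")
    X = _feature_matrix(training)
    estimators: dict[str, OneClassSVM] = {}
    for kernel, sel in selections.items():
        try:
            est = sel.config.make_estimator()
            est.fit(X)
        except Exception as exc:
            raise InputError(f"final fit failed for kernel {kernel!r}: {exc}") from exc
        estimators[kernel] = est
    roster = list(zip(training["sample"], training["gene"]))
    cols = [c for c in ALL_FEATURES if c in training.columns]
    return TrainedModel(
        configs={k: s.config for k, s in selections.items()},
        estimators=estimators,
        sensitivities={k: s.sensitivity for k, s in selections.items()},
        divisors=divisors,
        feature_names=cols,
        training_roster=roster,
        provenance=provenance or {},
    )


def train(
    features: pd.DataFrame,
    annotation: GeneAnnotation,
    grid: dict[str, list[KernelConfig]] | None = None,
    max_iterations: int = 2000,
    window: int = 100,
    seed: int = 0,
) -> TrainedModel:
    """End-to-end training: assemble positives, scale, select, refit."""
    grid = grid or build_parameter_grid()
    training = assemble_training_set(features, annotation)
    scaled_train, _, divisors = scale_features(training)
    selections: dict[str, SelectionResult] = {}
    rng = np.random.default_rng(seed)
    for kernel in KERNELS:
        kseed = int(rng.integers(2**31 - 1))
        selections[kernel] = select_parameters(
            kernel, grid[kernel], scaled_train, max_iterations=max_iterations, window=window, seed=kseed
        )
        logger.info(
            "kernel %s: %s sensitivity=%.3f iterations=%d converged=%s",
            kernel,
            selections[kernel].config,
            selections[kernel].sensitivity,
            selections[kernel].iterations,
            selections[kernel].converged,
        )
    provenance = {
        "seed": seed,
        "max_iterations": max_iterations,
        "window": window,
        "grid_sizes": {k: len(v) for k, v in grid.items()},
        "iterations": {k: s.iterations for k, s in selections.items()},
        "converged": {k: s.converged for k, s in selections.items()},
    }
    return train_final(selections, scaled_train, divisors, provenance)


def score_predictions(model: TrainedModel, features: pd.DataFrame) -> pd.DataFrame:
    """Score and rank prediction-set genes within each sample.

    The raw feature table is scaled with the model's stored divisors and the
    model's own training (sample, gene) entries are excluded.  Each kernel's
    continuous decision values are standardised to zero mean / unit SD across
    the whole prediction table, and the combined score is the
    sensitivity-weighted sum of the standardised kernel scores.  Within each
    sample, genes are ranked 1..n by descending combined score, ties broken
    by gene symbol.
    """
    weights = model.weights  # raises on the all-zero case
    roster = set(model.training_roster)
    mask = [((s, g) not in roster) for s, g in zip(features["sample"], features["gene"])]
    pred = features[mask].reset_index(drop=True)
    if pred.empty:
        raise InputError("empty prediction set after excluding training entries")
    mat = pred[model.feature_names].astype(float) / model.divisors[model.feature_names]
    X = mat.to_numpy(dtype=float)

    out = pred[["sample", "gene"]].copy()
    combined = np.zeros(len(pred))
    for kernel in KERNELS:
        raw = model.estimators[kernel].decision_function(X)
        sd = raw.std(ddof=0)
        z = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)
        out[f"score_{kernel}"] = raw
        out[f"z_{kernel}"] = z
        combined += weights[kernel] * z
    out["combined_score"] = combined
    out = out.sort_values(["sample", "combined_score", "gene"], ascending=[True, False, True], kind="mergesort")
    out["rank"] = out.groupby("sample").cumcount() + 1
    return out.reset_index(drop=True)
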