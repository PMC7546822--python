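"""Outcome prediction from regional perfusion: PCA + linear regression
under leave-one-out cross-validation.

Part B of the analysis.  Features are the normalized regional perfusion
values of regions found significant in the group comparisons: experiment 1
uses the control-vs-HIE/MRI⊖ contrast (comparison 1) and predicts outcomes
in the HIE/MRI⊖ group; experiment 2 concatenates the regions from the
within-HIE contrast (comparison 2) and the control-vs-all-HIE contrast
(comparison 4) and predicts outcomes in the combined HIE group.

For each left-out unit, standardization, PCA and the ordinary-least-squares
fit are computed on the training units only (no leakage).  The PCA
dimensionality k is chosen by grid search: by default the k maximizing the
pooled out-of-fold Pearson r (post-hoc selection, whose optimism on null
data is documented in the methods note); a nested variant selecting k
inside each training fold is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import LinearRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "CVConfig",
    "PredictionResult",
    "build_features",
    "loocv_predict",
    "run_experiment",
    "EXPERIMENT_GROUPS",
    "EXPERIMENT_COMPARISONS",
]

OUTCOME_NAMES = ("cognitive", "language", "motor")

#: prediction cohort per experiment
EXPERIMENT_GROUPS: Mapping[int, tuple[str, ...]] = {1: ("hie_neg",), 2: ("hie_neg", "hie_pos")}

#: which comparison result sets feed each experiment's feature vector
EXPERIMENT_COMPARISONS: Mapping[int, tuple[int, ...]] = {1: (1,), 2: (2, 4)}


@dataclass
class CVConfig:
    unit: str = "subject"  # or "record"
    k_grid: tuple[int, ...] = (1, 2, 3, 4, 5)
    seed: int = 0
    k_selection: str = "pooled"  # or "nested"

    def __post_init__(self) -> None:
        if self.unit not in ("subject", "record"):
            raise ValueError(f"unknown CV unit {self.unit!r}")
        if not self.k_grid or any(k < 1 for k in self.k_grid):
            raise ValueError("k_grid must be nonempty with every k >= 1")
        if self.k_selection not in ("pooled", "nested"):
            raise ValueError(f"unknown k_selection {self.k_selection!r}")


@dataclass
class PredictionResult:
    outcome_name: str
    unit_ids: list[str]
    observed: np.ndarray
    predicted: np.ndarray
    pearson_r: float
    p_value: float
    chosen_k: int
    per_k_r: dict[int, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"unit": self.unit_ids, "observed": self.observed, "predicted": self.predicted}
        )


def build_features(
    table: pd.DataFrame,
    comparisons: Mapping[int, pd.DataFrame],
    experiment: int,
) -> tuple[pd.DataFrame, dict[str, list[int]]]:
    """Assemble the feature matrix of significant regions for an experiment.

    Returns a subject-indexed DataFrame (one column per selected region,
    values = normalized regional CBF) and a provenance map recording which
    comparison(s) selected each column.  Duplicate regions across sources
    are kept once.
    """
    if experiment not in EXPERIMENT_COMPARISONS:
        raise ValueError(f"experiment must be 1 or 2, got {experiment}")
    needed = EXPERIMENT_COMPARISONS[experiment]
    missing = [c for c in needed if c not in comparisons]
    if missing:
        raise ValueError(f"experiment {experiment} requires comparison(s) {missing}")

    provenance: dict[str, list[int]] = {}
    for comp_id in needed:
        result = comparisons[comp_id]
        for name in result.loc[result["significant"], "name"]:
            provenance.setdefault(name, []).append(comp_id)
    if not provenance:
        raise ValueError(
            f"no significant regions available for experiment {experiment}; "
            "consider widening alpha"
        )
    columns = list(provenance)
    features = table.set_index("subject_id")[columns]
    if features.isna().any().any():
        raise ValueError("feature matrix contains missing regional values")
    return features, provenance


def _pearson(observed: np.ndarray, predicted: np.ndarray) -> tuple[float, float]:
    """Pearson r with its two-sided p from the t-transform
    r*sqrt((n-2)/(1-r^2))."""
    r, p = stats.pearsonr(observed, predicted)
    return float(r), float(p)


def _fit_predict(
    x_train: np.ndarray, y_train: np.ndarray, x_test: np.ndarray, k: int
) -> np.ndarray:
    model = make_pipeline(StandardScaler(), PCA(n_components=k), LinearRegression())
    model.fit(x_train, y_train)
    return model.predict(x_test)


def _loocv_predictions(
    x: np.ndarray, y: np.ndarray, unit_of_row: np.ndarray, units: list, k: int
) -> np.ndarray:
    """Out-of-fold predictions leaving one unit (all its rows) out at a time."""
    predicted = np.empty_like(y, dtype=float)
    for unit in units:
        test = unit_of_row == unit
        predicted[test] = _fit_predict(x[~test], y[~test], x[test], k)
    return predicted


def loocv_predict(
    features: pd.DataFrame,
    outcomes: pd.DataFrame,
    outcome_name: str,
    cv: CVConfig | None = None,
) -> PredictionResult:
    """Leave-one-out prediction of one outcome from regional perfusion.

    ``features`` is subject-indexed (one row per subject); ``outcomes`` has
    a ``subject_id`` column and one column per outcome and may contain
    several records per subject.  With ``cv.unit == "subject"`` all of a
    subject's records leave the fold together; with ``"record"`` each
    record is its own unit.
    """
    cv = cv or CVConfig()
    if outcome_name not in outcomes.columns:
        raise ValueError(f"outcomes table has no column {outcome_name!r}")

    merged = outcomes.merge(
        features, left_on="subject_id", right_index=True, how="inner", validate="m:1"
    ).reset_index(drop=True)
    if merged.empty:
        raise ValueError("no outcome records match the feature matrix subjects")

    x = merged[features.columns].to_numpy(dtype=float)
    y = merged[outcome_name].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError(f"outcome {outcome_name!r} is constant; correlation undefined")

    if cv.unit == "subject":
        unit_of_row = merged["subject_id"].to_numpy()
    else:
        unit_of_row = np.arange(len(merged))
    units = list(pd.unique(unit_of_row))
    n_units = len(units)
    if n_units < 5:
        raise ValueError(f"need at least 5 prediction units, got {n_units}")

    k_max = min(n_units - 2, x.shape[1])
    k_grid = [k for k in cv.k_grid if k <= k_max]
    if not k_grid:
        raise ValueError(f"no k in k_grid={cv.k_grid} is feasible (max {k_max})")

    if cv.k_selection == "pooled":
        per_k_r: dict[int, float] = {}
        per_k_pred: dict[int, np.ndarray] = {}
        for k in k_grid:
            predicted = _loocv_predictions(x, y, unit_of_row, units, k)
            per_k_pred[k] = predicted
            r = np.corrcoef(y, predicted)[0, 1] if np.ptp(predicted) > 0 else 0.0
            per_k_r[k] = float(r)
        chosen_k = max(per_k_r, key=lambda k: per_k_r[k])
        predicted = per_k_pred[chosen_k]
    else:  # nested: choose k inside each training fold
        per_k_r = {}
        predicted = np.empty_like(y)
        for unit in units:
            test = unit_of_row == unit
            x_tr, y_tr = x[~test], y[~test]
            rows_tr = unit_of_row[~test]
            units_tr = list(pd.unique(rows_tr))
            inner_best, inner_k = -np.inf, k_grid[0]
            for k in k_grid:
                if k > min(len(units_tr) - 2, x_tr.shape[1]):
                    continue
                inner_pred = _loocv_predictions(x_tr, y_tr, rows_tr, units_tr, k)
                r = np.corrcoef(y_tr, inner_pred)[0, 1] if np.ptp(inner_pred) > 0 else 0.0
                if r > inner_best:
                    inner_best, inner_k = r, k
            predicted[test] = _fit_predict(x_tr, y_tr, x[test], inner_k)
        chosen_k = -1  # varies per fold

    pearson_r, p_value = _pearson(y, predicted)
    return PredictionResult(
        outcome_name=outcome_name,
        unit_ids=[str(u) for u in unit_of_row],
        observed=y,
        predicted=predicted,
        pearson_r=pearson_r,
        p_value=p_value,
        chosen_k=chosen_k,
        per_k_r=per_k_r,
    )


def run_experiment(
    table: pd.DataFrame,
    comparisons: Mapping[int, pd.DataFrame],
    outcomes: pd.DataFrame,
    experiment: int,
    cv: CVConfig | None = None,
) -> dict[str, PredictionResult]:
    """Run one prediction experiment: three outcomes, restricted cohort."""
    cv = cv or CVConfig()
    features, provenance = build_features(table, comparisons, experiment)

    groups = EXPERIMENT_GROUPS[experiment]
    eligible = set(table.loc[table["group"].isin(groups), "subject_id"])
    features = features.loc[features.index.isin(eligible)]
    records = outcomes[outcomes["subject_id"].isin(features.index)]
    if records.empty:
        raise ValueError(f"no outcome records for experiment {experiment} cohort")

    results: dict[str, PredictionResult] = {}
    for name in OUTCOME_NAMES:
        if name not in records.columns:
            continue
        result = loocv_predict(features, records, name, cv)
        result.per_k_r = dict(result.per_k_r)
        results[name] = result
    if not results:
        raise ValueError("outcomes table contains none of the expected score columns")
    for res in results.values():
        res.provenance = provenance  # type: ignore[attr-defined]
    return results


def plot_predictions(
    results: Mapping[str, PredictionResult], path, title: str | None = None
) -> None:
    """Predicted-vs-observed scatter panel, one subplot per outcome."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(results), figsize=(4 * len(results), 4))
    if len(results) == 1:
        axes = [axes]
    for ax, (name, res) in zip(np.atleast_1d(axes), results.items()):
        ax.scatter(res.observed, res.predicted, s=18, alpha=0.8)
        lo = min(res.observed.min(), res.predicted.min())
        hi = max(res.observed.max(), res.predicted.max())
        ax.plot([lo, hi], [lo, hi], "k--", lw=0.8)
        ax.set_xlabel(f"observed {name}")
        ax.set_ylabel(f"predicted {name}")
        ax.set_title(f"{name}: r={res.pearson_r:.2f}, p={res.p_value:.3g}")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
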