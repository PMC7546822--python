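"""Atlas-based regional statistics and permutation group comparison.

Part A of the analysis: per-subject regional mean CBF, normalization to the
subject's own whole-brain mean (the quantity analyzed is therefore
*relative* perfusion), ordinary-least-squares removal of age and sex
effects, and a two-sided permutation test on the difference of group means
per region.  Exhaustive enumeration is used whenever the number of
relabelings is small enough; otherwise seeded Monte-Carlo with add-one
smoothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .quantify import CBFMap
from .synthetic import ToyAtlas

__all__ = [
    "ComparisonSpec",
    "PermutationResult",
    "regionalize",
    "whole_brain_mean",
    "normalize_to_whole_brain",
    "build_regional_table",
    "residualize",
    "permutation_test",
    "compare_groups",
]

DEMOGRAPHIC_COLUMNS = ("subject_id", "age_days", "sex", "group", "whole_brain_mean")


@dataclass
class ComparisonSpec:
    """One two-group comparison.

    ``group_b`` (or ``group_a``) may be a tuple of group names, in which
    case those groups are pooled — used for the control vs all-HIE contrast.
    """

    group_a: str | tuple[str, ...]
    group_b: str | tuple[str, ...]
    n_permutations: int = 10000
    alpha: float = 0.05
    adjust_covariates: bool = True
    seed: int = 0
    statistic: str = "mean_diff"  # or "welch_t"
    correction: str = "none"  # or "bh"
    exhaustive_limit: int = 20000

    def __post_init__(self) -> None:
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        groups_a = {self.group_a} if isinstance(self.group_a, str) else set(self.group_a)
        groups_b = {self.group_b} if isinstance(self.group_b, str) else set(self.group_b)
        if groups_a & groups_b:
            raise ValueError("comparison groups must be disjoint")
        if self.statistic not in ("mean_diff", "welch_t"):
            raise ValueError(f"unknown statistic {self.statistic!r}")


@dataclass
class PermutationResult:
    p_value: float
    statistic: float
    mode: str  # "exhaustive" or "monte_carlo"
    n_used: int


def regionalize(cbf: CBFMap | np.ndarray, atlas: ToyAtlas) -> dict[int, float]:
    """Mean CBF per atlas region over the region's defined voxels."""
    volume = cbf.volume if isinstance(cbf, CBFMap) else np.asarray(cbf, float)
    if volume.shape != atlas.label_volume.shape:
        raise ValueError(
            f"CBF grid {volume.shape} does not match atlas grid {atlas.label_volume.shape}"
        )
    out: dict[int, float] = {}
    for rid in atlas.region_ids:
        values = volume[atlas.region_mask(rid)]
        values = values[np.isfinite(values)]
        if values.size == 0:
            warnings.warn(
                f"region {rid} ({atlas.region_names[rid]}) has no defined voxels",
                RuntimeWarning,
                stacklevel=2,
            )
            out[rid] = float("nan")
        else:
            out[rid] = float(values.mean())
    return out


def whole_brain_mean(cbf: CBFMap) -> float:
    """Mean CBF over defined brain-mask voxels."""
    values = cbf.volume[cbf.mask]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("no defined voxels inside the brain mask")
    return float(values.mean())


def normalize_to_whole_brain(
    regional: Mapping[int, float], cbf: CBFMap
) -> dict[int, float]:
    """Divide each regional mean by the subject's whole-brain mean CBF."""
    wb = whole_brain_mean(cbf)
    if wb <= 0:
        raise ValueError(f"whole-brain mean CBF must be positive, got {wb}")
    return {rid: value / wb for rid, value in regional.items()}


def build_regional_table(
    cbf_maps: Mapping[str, CBFMap],
    atlas: ToyAtlas,
    demographics: pd.DataFrame,
) -> pd.DataFrame:
    """Subjects x regions table of normalized mean CBF plus demographics.

    One row per subject; region columns are named by atlas region name.
    The region voxel counts are attached as ``table.attrs["region_voxels"]``
    so voxel-weighted invariants can be checked downstream.
    """
    required = {"subject_id", "age_days", "sex", "group"}
    missing = required - set(demographics.columns)
    if missing:
        raise ValueError(f"demographics table lacks columns {sorted(missing)}")

    rows = []
    for _, demo in demographics.iterrows():
        sid = demo["subject_id"]
        if sid not in cbf_maps:
            raise KeyError(f"no CBF map supplied for subject {sid!r}")
        cbf = cbf_maps[sid]
        regional = regionalize(cbf, atlas)
        normalized = normalize_to_whole_brain(regional, cbf)
        row = {
            "subject_id": sid,
            "age_days": float(demo["age_days"]),
            "sex": str(demo["sex"]),
            "group": str(demo["group"]),
            "whole_brain_mean": whole_brain_mean(cbf),
        }
        row.update({atlas.region_names[rid]: normalized[rid] for rid in atlas.region_ids})
        rows.append(row)
    table = pd.DataFrame(rows)
    table.attrs["region_voxels"] = {
        atlas.region_names[rid]: count for rid, count in atlas.voxel_counts().items()
    }
    table.attrs["region_ids"] = {
        atlas.region_names[rid]: rid for rid in atlas.region_ids
    }
    return table


def _region_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in DEMOGRAPHIC_COLUMNS]


def residualize(table: pd.DataFrame, adjust_covariates: bool = True) -> pd.DataFrame:
    """Remove age and sex effects from every region column by OLS.

    The fit is performed over all rows of ``table`` (pooled across the
    groups being compared, so group contrasts survive); each value is
    replaced by its residual plus the column grand mean.
    """
    if not adjust_covariates:
        return table.copy()
    if len(table) < 3:
        raise ValueError("covariate adjustment needs at least 3 subjects")

    age = table["age_days"].to_numpy(dtype=float)
    sex_f = (table["sex"].to_numpy() == "F").astype(float)
    design = np.column_stack([np.ones(len(table)), age, sex_f])
    if np.linalg.matrix_rank(design) < 2 or np.ptp(age) == 0:
        warnings.warn(
            "design is rank deficient (constant age and sex); skipping adjustment",
            RuntimeWarning,
            stacklevel=2,
        )
        return table.copy()

    out = table.copy()
    for col in _region_columns(table):
        y = table[col].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        residuals = y - design @ beta
        out[col] = residuals + y.mean()
    return out


# ---------------------------------------------------------------------------
# permutation machinery

_TIE_RTOL = 1e-12


def _mean_diff_from_sums(sum_a, n_a, total_sum, n_total):
    sum_b = total_sum - sum_a
    return sum_b / (n_total - n_a) - sum_a / n_a


def permutation_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    spec: ComparisonSpec | None = None,
    rng: np.random.Generator | None = None,
) -> PermutationResult:
    """Two-sided permutation test on T = mean(b) − mean(a).

    All C(n_a+n_b, n_a) relabelings are enumerated when their count does not
    exceed ``spec.exhaustive_limit``; the exhaustive p is the exact fraction
    of relabelings with |T| >= |T_obs| (the identity relabeling included, so
    p > 0 and no add-one smoothing is applied).  Otherwise ``n_permutations``
    Monte-Carlo relabelings are drawn and p = (1 + exceedances) / (1 + N).
    A tolerance of 1e-12 relative to |T_obs| absorbs floating-point rounding
    of exactly tied relabelings.
    """
    spec = spec or ComparisonSpec(group_a="a", group_b="b")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")

    pooled = np.concatenate([a, b])
    n_a, n = a.size, a.size + b.size
    total = pooled.sum()
    t_obs = _mean_diff_from_sums(a.sum(), n_a, total, n)
    threshold = abs(t_obs) - _TIE_RTOL * (1.0 + abs(t_obs))

    if np.ptp(pooled) == 0:
        return PermutationResult(p_value=1.0, statistic=float(t_obs), mode="degenerate", n_used=0)

    n_splits = comb(n, n_a)
    if n_splits <= spec.exhaustive_limit:
        idx = np.fromiter(
            (i for c in combinations(range(n), n_a) for i in c), dtype=np.intp
        ).reshape(n_splits, n_a)
        sums_a = pooled[idx].sum(axis=1)
        t_perm = _mean_diff_from_sums(sums_a, n_a, total, n)
        count = int(np.count_nonzero(np.abs(t_perm) >= threshold))
        return PermutationResult(
            p_value=count / n_splits, statistic=float(t_obs), mode="exhaustive", n_used=n_splits
        )

    rng = rng or np.random.default_rng(spec.seed)
    n_perm = spec.n_permutations
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    sums_a = pooled[order[:, :n_a]].sum(axis=1)
    t_perm = _mean_diff_from_sums(sums_a, n_a, total, n)
    count = int(np.count_nonzero(np.abs(t_perm) >= threshold))
    return PermutationResult(
        p_value=(1 + count) / (1 + n_perm),
        statistic=float(t_obs),
        mode="monte_carlo",
        n_used=n_perm,
    )


def _welch_t(a: np.ndarray, b: np.ndarray) -> float:
    va = a.var(ddof=1) / a.size
    vb = b.var(ddof=1) / b.size
    denom = np.sqrt(va + vb)
    return float((b.mean() - a.mean()) / denom) if denom > 0 else 0.0


def _permutation_test_welch(
    a: np.ndarray, b: np.ndarray, spec: ComparisonSpec, rng: np.random.Generator
) -> PermutationResult:
    pooled = np.concatenate([a, b])
    n_a, n = a.size, a.size + b.size
    t_obs = _welch_t(a, b)
    threshold = abs(t_obs) - _TIE_RTOL * (1.0 + abs(t_obs))
    if np.ptp(pooled) == 0:
        return PermutationResult(1.0, t_obs, "degenerate", 0)
    n_splits = comb(n, n_a)
    if n_splits <= spec.exhaustive_limit:
        count = 0
        for c in combinations(range(n), n_a):
            sel = np.zeros(n, dtype=bool)
            sel[list(c)] = True
            if abs(_welch_t(pooled[sel], pooled[~sel])) >= threshold:
                count += 1
        return PermutationResult(count / n_splits, t_obs, "exhaustive", n_splits)
    count = 0
    for _ in range(spec.n_permutations):
        perm = rng.permutation(pooled)
        if abs(_welch_t(perm[:n_a], perm[n_a:])) >= threshold:
            count += 1
    return PermutationResult(
        (1 + count) / (1 + spec.n_permutations), t_obs, "monte_carlo", spec.n_permutations
    )


def _select_group(table: pd.DataFrame, group: str | tuple[str, ...]) -> pd.DataFrame:
    names = (group,) if isinstance(group, str) else tuple(group)
    present = set(table["group"])
    for name in names:
        if name not in present:
            raise ValueError(f"group {name!r} not present in table")
    return table[table["group"].isin(names)]


def compare_groups(table: pd.DataFrame, spec: ComparisonSpec) -> pd.DataFrame:
    """Per-region permutation comparison of two (possibly pooled) groups.

    Group means/SDs are reported on the normalized scale before covariate
    adjustment (matching how regional tables are conventionally presented);
    p-values are computed on covariate-adjusted values when
    ``spec.adjust_covariates`` is set.  Rows are sorted by p-value.
    """
    sub_a = _select_group(table, spec.group_a)
    sub_b = _select_group(table, spec.group_b)
    if len(sub_a) < 2 or len(sub_b) < 2:
        raise ValueError(
            f"each comparison group needs >= 2 subjects "
            f"(got {len(sub_a)} vs {len(sub_b)})"
        )

    pooled = pd.concat([sub_a, sub_b], ignore_index=True)
    adjusted = residualize(pooled, spec.adjust_covariates)
    in_a = np.arange(len(pooled)) < len(sub_a)

    region_ids = table.attrs.get("region_ids", {})
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(len(_region_columns(table)))

    rows = []
    for col, child in zip(_region_columns(table), children):
        raw_a = sub_a[col].to_numpy(dtype=float)
        raw_b = sub_b[col].to_numpy(dtype=float)
        adj = adjusted[col].to_numpy(dtype=float)
        rng = np.random.default_rng(child)
        if spec.statistic == "welch_t":
            result = _permutation_test_welch(adj[in_a], adj[~in_a], spec, rng)
        else:
            result = permutation_test(adj[in_a], adj[~in_a], spec, rng=rng)
        rows.append(
            {
                "region_id": region_ids.get(col, -1),
                "name": col,
                "mean_a": raw_a.mean(),
                "sd_a": raw_a.std(ddof=1),
                "mean_b": raw_b.mean(),
                "sd_b": raw_b.std(ddof=1),
                "p_value": result.p_value,
                "direction": "decreased" if raw_b.mean() < raw_a.mean() else "increased",
                "mode": result.mode,
            }
        )
    results = pd.DataFrame(rows)
    if spec.correction == "bh":
        results["p_adjusted"] = _benjamini_hochberg(results["p_value"].to_numpy())
        results["significant"] = results["p_adjusted"] < spec.alpha
    else:
        results["significant"] = results["p_value"] < spec.alpha
    return results.sort_values("p_value", kind="stable").reset_index(drop=True)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(ranked, 1.0)
    return out
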