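"""Multigenerational competitive fitness from abundance trajectories.

Each strain's relative abundance A_i is followed across serial-transfer
generations (one generation per expansion). Growth is summarised by the
fold-change rate, the mean log2 change in abundance per generation:

    FCR = log2(A_end / A_0) / G_eff

under the model A_{i+1} = A_i * 2^FCR. Strains falling to the abundance
floor stop accruing generations at the first floor contact (G_eff is the
index of the first generation at or below the floor); otherwise G_eff is
the full trajectory length. Mean FCR over replicates (pooled across
conditions) places each strain in one of five fitness classes:

    class 0 — failed to thrive: starting abundance below 2.5e-3
    class 1 — FCR below b1;   class 2 — [b1, b2);   class 3 — [b2, b3);
    class 4 — FCR at or above b3

with default boundaries (-0.4315, -0.0985, 0.2327). These correspond,
under a 10-generation model starting from abundance 0.02, to final
abundances of 1e-3, 1e-2 and 1e-1; ``class_bounds_from_model`` recomputes
them as log2(cutoff / a0) / generations.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

START_MIN_DEFAULT = 2.5e-3
FLOOR_DEFAULT = 1.0e-3


@dataclass
class Trajectory:
    """Per-replicate abundance series A_0..A_G for one strain."""

    strain_id: str
    replicate_id: str
    condition: str
    abundances: list[float]

    def __post_init__(self):
        if len(self.abundances) < 2:
            raise ValueError("trajectory needs at least A_0 and A_1")
        if any(a < 0 or a > 1 for a in self.abundances):
            raise ValueError("abundances must lie in [0, 1]")


@dataclass
class FoldChangeResult:
    strain_id: str
    replicate_id: str
    condition: str
    total_log2_fold_change: float
    effective_generations: int
    fcr: float


@dataclass
class ClassBounds:
    """Fitness-class boundaries on the mean fold-change rate scale."""

    a0: float = 0.02
    generations: int = 10
    a_final_cutoffs: tuple = (1e-3, 1e-2, 1e-1)
    fcr_bounds: tuple = (-0.4315, -0.0985, 0.2327)

    def __post_init__(self):
        if not all(a < b for a, b in zip(self.fcr_bounds, self.fcr_bounds[1:])):
            raise ValueError("fcr_bounds must be strictly increasing")

    @classmethod
    def from_model(cls, a0: float = 0.02, generations: int = 10,
                   cutoffs=(1e-3, 1e-2, 1e-1)) -> "ClassBounds":
        bounds = tuple(class_bounds_from_model(a0, cutoffs, generations))
        return cls(a0=a0, generations=generations, a_final_cutoffs=tuple(cutoffs),
                   fcr_bounds=bounds)


@dataclass
class StrainFitnessSummary:
    strain_id: str
    mean_fcr: float
    sd_fcr: float
    n_replicates: int
    fitness_class: int

    @property
    def growth_multiplier(self) -> float:
        return 2.0 ** self.mean_fcr


def filter_low_start(trajectories, threshold: float = START_MIN_DEFAULT):
    """Split strains into (retained trajectories, class-0 strain set).

    A strain whose starting abundance — averaged over its replicates'
    generation-0 samples — is strictly below ``threshold`` never thrived in
    the initial expansion and is excluded from fold-change analysis.
    """
    start_by_strain: dict[str, list[float]] = {}
    for t in trajectories:
        start_by_strain.setdefault(t.strain_id, []).append(t.abundances[0])
    class0 = {s for s, starts in start_by_strain.items()
              if float(np.mean(starts)) < threshold}
    return [t for t in trajectories if t.strain_id not in class0], class0


def apply_floor(trajectory: Trajectory, floor: float = FLOOR_DEFAULT) -> Trajectory:
    """Clamp abundances below the floor up to it (log2 needs a positive value)."""
    return Trajectory(
        strain_id=trajectory.strain_id,
        replicate_id=trajectory.replicate_id,
        condition=trajectory.condition,
        abundances=[max(a, floor) for a in trajectory.abundances],
    )


def fold_change_rate(trajectory: Trajectory, floor: float = FLOOR_DEFAULT) -> FoldChangeResult:
    """FCR of a floored trajectory, with the negative-trajectory endpoint rule.

    If the trajectory ever touches the floor, the effective number of
    generations is the index of the first generation at or below it — the
    strain may be extinct from then on, so later flat samples carry no
    information. Otherwise all G generations count.
    """
    a = [max(x, floor) for x in trajectory.abundances]
    if a[0] <= floor:
        raise ValueError(
            f"strain {trajectory.strain_id}: zero effective generations "
            "(should have been start-filtered)"
        )
    eff = len(a) - 1
    for i, x in enumerate(a[1:], start=1):
        if x <= floor:
            eff = i
            break
    if eff == 0:
        raise ValueError(
            f"strain {trajectory.strain_id}: zero effective generations "
            "(should have been start-filtered)"
        )
    total = float(np.log2(a[eff] / a[0]))
    return FoldChangeResult(
        strain_id=trajectory.strain_id,
        replicate_id=trajectory.replicate_id,
        condition=trajectory.condition,
        total_log2_fold_change=total,
        effective_generations=eff,
        fcr=total / eff,
    )


def mean_fcr(results) -> dict[str, StrainFitnessSummary]:
    """Pool replicate FCRs per strain (unweighted, across all conditions).

    Fitness class is left unset (-1); see :func:`classify`.
    """
    by_strain: dict[str, list[float]] = {}
    for r in results:
        by_strain.setdefault(r.strain_id, []).append(r.fcr)
    out = {}
    for strain_id in sorted(by_strain):
        vals = by_strain[strain_id]
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        out[strain_id] = StrainFitnessSummary(
            strain_id=strain_id, mean_fcr=float(np.mean(vals)), sd_fcr=sd,
            n_replicates=len(vals), fitness_class=-1,
        )
    return out


def class_bounds_from_model(a0: float, cutoffs, generations: int):
    """FCR boundaries implied by the growth model A_{i+1} = A_i * 2^FCR:
    the rate at which a strain starting at ``a0`` reaches each final-
    abundance cutoff after ``generations`` generations."""
    if a0 <= 0 or any(c <= 0 for c in cutoffs):
        raise ValueError("a0 and cutoffs must be positive")
    return [float(np.log2(c / a0)) / generations for c in cutoffs]


def classify(mean_fcr_value: float, bounds: ClassBounds | None = None) -> int:
    """Fitness class 1-4 from mean FCR (class 0 is assigned by the start
    filter, not here). Boundaries are half-open: class k+1 starts at b_k."""
    bounds = bounds or ClassBounds()
    b1, b2, b3 = bounds.fcr_bounds
    if mean_fcr_value < b1:
        return 1
    if mean_fcr_value < b2:
        return 2
    if mean_fcr_value < b3:
        return 3
    return 4


def growth_multiplier(fcr: float) -> float:
    """Per-generation population multiplier implied by an FCR: 2**FCR."""
    return 2.0 ** fcr


def summarize_strains(results, class0=(), bounds: ClassBounds | None = None) -> pd.DataFrame:
    """Per-strain summary table: mean FCR, SD, n, class, growth multiplier."""
    bounds = bounds or ClassBounds()
    summaries = mean_fcr(results)
    rows = []
    for s in summaries.values():
        cls = classify(s.mean_fcr, bounds)
        rows.append((s.strain_id, s.mean_fcr, s.sd_fcr, s.n_replicates, cls,
                     growth_multiplier(s.mean_fcr)))
    for strain_id in sorted(class0):
        rows.append((strain_id, float("nan"), float("nan"), 0, 0, float("nan")))
    return pd.DataFrame(rows, columns=["strain_id", "mean_fcr", "sd_fcr",
                                       "n_replicates", "fitness_class",
                                       "growth_multiplier"])


def relative_difference(a: float, b: float) -> float:
    """|a-b| scaled by the larger-magnitude value; scale-free across
    positive and negative FCRs. 0 when both are 0."""
    denom = max(abs(a), abs(b))
    if denom == 0:
        return 0.0
    return abs(a - b) / denom


def compare_conditions(results, rel_diff_threshold: float = 0.20,
                       absolute: bool = False) -> pd.DataFrame:
    """Flag strains whose mean FCR differs between conditions and test them.

    For every strain with >= 2 replicates in each of two conditions, the
    pair is tested (two-sided Wilcoxon rank-sum on replicate FCRs) when the
    mean difference exceeds the threshold — relative difference by default,
    absolute with ``absolute=True``. P-values are Benjamini-Hochberg
    adjusted over all tested pairs. Identical samples get p = 1.
    """
    df = pd.DataFrame([(r.strain_id, r.condition, r.fcr) for r in results],
                      columns=["strain_id", "condition", "fcr"])
    rows = []
    for strain_id, grp in df.groupby("strain_id", sort=True):
        by_cond = {c: g["fcr"].to_numpy() for c, g in grp.groupby("condition")}
        for c1, c2 in itertools.combinations(sorted(by_cond), 2):
            x, y = by_cond[c1], by_cond[c2]
            if len(x) < 2 or len(y) < 2:
                continue
            m1, m2 = float(np.mean(x)), float(np.mean(y))
            diff = abs(m1 - m2) if absolute else relative_difference(m1, m2)
            if diff <= rel_diff_threshold:
                continue
            if np.array_equal(np.sort(x), np.sort(y)):
                p = 1.0
            else:
                p = float(stats.ranksums(x, y).pvalue)
            rows.append((strain_id, c1, c2, m1, m2, diff, p))
    out = pd.DataFrame(rows, columns=["strain_id", "condition_a", "condition_b",
                                      "mean_fcr_a", "mean_fcr_b", "difference",
                                      "pvalue"])
    if len(out):
        out["pvalue_adj"] = stats.false_discovery_control(out["pvalue"], method="bh")
    else:
        out["pvalue_adj"] = pd.Series(dtype=float)
    return out


def pca_composition(matrix: pd.DataFrame, groups=None):
    """PCA of a samples x strains abundance matrix, centered and scaled.

    Zero-variance columns are dropped with a warning before unit-variance
    scaling (SD with n-1 denominator, as in R's prcomp(scale.=TRUE)).
    Returns (scores, loadings, centroids, explained_variance_ratio);
    centroids are mean scores per group label, or None when no groups are
    given. Loading signs are fixed so each component's largest-magnitude
    loading is positive.
    """
    if len(matrix) < 2:
        raise ValueError("PCA needs at least 2 samples")
    X = matrix.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = list(matrix.columns[~keep])
        warnings.warn(f"dropping zero-variance columns: {dropped}", stacklevel=2)
    cols = matrix.columns[keep]
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each PC positive
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    n_pc = min(X.shape)
    pc_names = [f"PC{i + 1}" for i in range(n_pc)]
    scores = pd.DataFrame(u[:, :n_pc] * s[:n_pc], index=matrix.index, columns=pc_names)
    loadings = pd.DataFrame(vt[:n_pc].T, index=cols, columns=pc_names)
    evr = s[:n_pc] ** 2 / np.sum(s ** 2)
    centroids = None
    if groups is not None:
        centroids = scores.groupby(pd.Series(list(groups), index=scores.index)).mean()
    return scores, loadings, centroids, evr


def build_trajectories(abundance: pd.DataFrame, sheet: pd.DataFrame) -> list[Trajectory]:
    """Join an abundance table (library_id, strain_id, mean_abundance) with a
    sample sheet (library_id, pool_id, replicate_id, condition, generation)
    into per-(pool, replicate, strain) trajectories ordered by generation.

    A strain missing from a replicate's generation-0 sample is excluded
    from that replicate only.
    """
    merged = abundance.merge(sheet, on="library_id", how="inner")
    trajectories = []
    grouping = ["pool_id", "replicate_id", "condition", "strain_id"]
    for (pool, rep, cond, strain), grp in merged.groupby(grouping, sort=True):
        grp = grp.sort_values("generation")
        gens = grp["generation"].to_list()
        if not gens or gens[0] != 0 or len(gens) < 2:
            continue
        trajectories.append(Trajectory(
            strain_id=strain,
            replicate_id=f"{pool}:{rep}:{cond}",
            condition=cond,
            abundances=[float(x) for x in grp["mean_abundance"]],
        ))
    return trajectories


def fitness_pipeline(trajectories, start_min: float = START_MIN_DEFAULT,
                     floor: float = FLOOR_DEFAULT,
                     bounds: ClassBounds | None = None):
    """Start filter -> floor -> per-replicate FCR -> per-strain summary.

    Returns (per_replicate FoldChangeResult list, summary DataFrame).
    """
    bounds = bounds or ClassBounds()
    retained, class0 = filter_low_start(trajectories, start_min)
    results = [fold_change_rate(apply_floor(t, floor), floor) for t in retained]
    summary = summarize_strains(results, class0, bounds)
    return results, summary
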