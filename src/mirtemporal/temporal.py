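"""Temporal expression profiles over post-conception age.

The pipeline is: raw counts -> expression filter (>= ``min_reads`` mapped
reads in *every* sample) -> counts-per-million -> log2(CPM + 1) -> samples
ordered by transformed age -> sliding-window smoothing (mean over samples
within +/- ``window`` of each sample's transformed age) -> per-feature
z-scores.  Transformed age is log2(age in days + 280), i.e. log
post-conception age, which spreads the dense early-life samples and
compresses adulthood.

Per-feature z-score profiles feed the clustering stage; per-stage mean
z-scores converted to two-sided normal p-values give the "significant
developmental stage" calls (p < 0.05 and at least 2 samples in the stage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io import ExpressionMatrix, SampleTable

__all__ = [
    "DAYS_PER_YEAR",
    "GESTATION_DAYS",
    "DEFAULT_STAGES",
    "TemporalProfileSet",
    "StageCall",
    "cpm_normalize",
    "filter_expressed",
    "transform_age",
    "smooth_profiles",
    "zscore_profiles",
    "stage_significance",
    "stage_of_age",
    "age_bin",
    "build_profiles",
]

DAYS_PER_YEAR = 365.25
GESTATION_DAYS = 280.0

#: developmental stage boundaries in post-natal years, [lo, hi).
DEFAULT_STAGES: list[tuple[str, float, float]] = [
    ("fetal", -0.75, 0.0),
    ("infant", 0.0, 1.0),
    ("toddler", 1.0, 3.0),
    ("preschool", 3.0, 6.0),
    ("prepuberty", 6.0, 12.0),
    ("adolescent", 12.0, 18.0),
    ("young_adult", 18.0, 40.0),
    ("adult", 40.0, 60.0),
    ("senior", 60.0, np.inf),
]

#: adult age bins used as a covariate in the case/control models.
ADULT_AGE_BINS: list[tuple[str, float, float]] = [
    ("young_adult", 18.0, 40.0),
    ("adult", 40.0, 60.0),
    ("senior", 60.0, np.inf),
]


def transform_age(age_years) -> np.ndarray | float:
    """log2(age in days + 280): post-conception age on a log scale."""
    age_years = np.asarray(age_years, dtype=float)
    days = age_years * DAYS_PER_YEAR + GESTATION_DAYS
    if np.any(days <= 0):
        raise ValueError("age gives non-positive post-conception days")
    out = np.log2(days)
    return float(out) if out.ndim == 0 else out


def stage_of_age(age_years: float, stages=None) -> str:
    stages = DEFAULT_STAGES if stages is None else stages
    for name, lo, hi in stages:
        if lo <= age_years < hi:
            return name
    raise ValueError(f"age {age_years} outside all stage bins")


def age_bin(age_years: float) -> str:
    """Adult age bin (young_adult 18-39 / adult 40-60 / senior >60)."""
    for name, lo, hi in ADULT_AGE_BINS:
        if lo <= age_years < hi:
            return name
    raise ValueError(f"age {age_years} is not adult (>= 18 years)")


def cpm_normalize(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Counts per million: scale each sample column to sum to 1e6."""
    if counts.kind != "counts":
        raise ValueError(f"expected counts matrix, got kind={counts.kind!r}")
    libsize = counts.values.sum(axis=0).astype(float)
    zero = libsize == 0
    if np.any(zero):
        bad = [s for s, z in zip(counts.sample_ids, zero) if z]
        raise ValueError(f"zero library size for samples: {bad[:5]}")
    cpm = counts.values * (1e6 / libsize)
    return ExpressionMatrix(counts.feature_ids, counts.sample_ids, cpm, kind="cpm")


def filter_expressed(counts: ExpressionMatrix, min_reads: int = 10) -> ExpressionMatrix:
    """Keep features with >= ``min_reads`` in every sample."""
    if counts.kind != "counts":
        raise ValueError(f"expected counts matrix, got kind={counts.kind!r}")
    keep = np.all(counts.values >= min_reads, axis=1)
    if not keep.any():
        warnings.warn("no features pass the expression filter")
    kept = [f for f, k in zip(counts.feature_ids, keep) if k]
    return ExpressionMatrix(kept, counts.sample_ids, counts.values[keep], counts.kind)


def smooth_profiles(
    matrix: np.ndarray,
    transformed_ages: Sequence[float],
    window: float = 0.3,
) -> np.ndarray:
    """Average each sample with all samples within +/- ``window`` of its
    transformed age (inclusive endpoints, the sample itself included).

    Column order of the input is preserved; the neighbourhood is defined by
    age, not by position, so the result is invariant to sample input order.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    matrix = np.asarray(matrix, dtype=float)
    ages = np.asarray(transformed_ages, dtype=float)
    if matrix.shape[1] != ages.shape[0]:
        raise ValueError("transformed_ages must align with matrix columns")
    # boolean neighbourhood mask; n_samples is modest (hundreds)
    diff = np.abs(ages[:, None] - ages[None, :]) <= window
    weights = diff.astype(float)
    weights /= weights.sum(axis=1, keepdims=True)
    return matrix @ weights.T


def zscore_profiles(smoothed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature z-scores with sample (ddof=1) standard deviation.

    Returns ``(zscores, degenerate)``: zero-variance features get an
    all-zero row and a True flag instead of NaNs.
    """
    smoothed = np.asarray(smoothed, dtype=float)
    if smoothed.shape[1] < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    mean = smoothed.mean(axis=1, keepdims=True)
    sd = smoothed.std(axis=1, ddof=1, keepdims=True)
    degenerate = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (smoothed - mean) / safe_sd
    z[degenerate, :] = 0.0
    return z, degenerate


@dataclass
class TemporalProfileSet:
    """Smoothed, z-scored profiles with samples ordered by transformed age."""

    feature_ids: list[str]
    sample_ids: list[str]
    transformed_ages: np.ndarray
    smoothed: np.ndarray
    zscores: np.ndarray
    degenerate: np.ndarray = field(default=None)  # type: ignore[assignment]
    ages_years: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.transformed_ages = np.asarray(self.transformed_ages, dtype=float)
        if np.any(np.diff(self.transformed_ages) < 0):
            raise ValueError("samples must be ordered by transformed age")
        if self.degenerate is None:
            self.degenerate = np.zeros(len(self.feature_ids), dtype=bool)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)


@dataclass
class StageCall:
    feature_id: str
    stage: str
    n_samples: int
    mean_z: float
    p_value: float
    direction: str  # "+" or "-"
    significant: bool


def stage_significance(
    profiles: TemporalProfileSet,
    stage_map: Mapping[str, str] | None = None,
    alpha: float = 0.05,
    min_samples: int = 2,
    scale_by_sqrt_n: bool = False,
) -> list[StageCall]:
    """Per-(feature, stage) significance of the mean z-score.

    The stage mean z is converted to a two-sided normal p-value,
    p = 2(1 - Phi(|z|)); a stage is significant for a feature iff p < alpha
    and the stage holds at least ``min_samples`` samples.  ``stage_map``
    maps sample_id -> stage; by default stages are derived from sample ages.
    ``scale_by_sqrt_n`` multiplies the mean z by sqrt(n) before conversion
    (off by default; smoothed z-scores are strongly correlated within a
    stage, so the unscaled mean is the conservative choice).
    """
    if stage_map is None:
        if profiles.ages_years is None:
            raise ValueError("no stage_map given and profiles carry no ages_years")
        stage_map = {
            s: stage_of_age(a)
            for s, a in zip(profiles.sample_ids, profiles.ages_years)
        }
    if not stage_map:
        raise ValueError("empty stage map")
    missing = [s for s in profiles.sample_ids if s not in stage_map]
    if missing:
        raise ValueError(f"samples without stage assignment: {missing[:5]}")

    stage_names = list(dict.fromkeys(stage_map[s] for s in profiles.sample_ids))
    cols_by_stage = {
        st: [i for i, s in enumerate(profiles.sample_ids) if stage_map[s] == st]
        for st in stage_names
    }
    calls: list[StageCall] = []
    for fi, fid in enumerate(profiles.feature_ids):
        z = profiles.zscores[fi]
        for st in stage_names:
            cols = cols_by_stage[st]
            zbar = float(np.mean(z[cols]))
            stat = zbar * np.sqrt(len(cols)) if scale_by_sqrt_n else zbar
            p = float(2.0 * stats.norm.sf(abs(stat)))
            calls.append(
                StageCall(
                    feature_id=fid,
                    stage=st,
                    n_samples=len(cols),
                    mean_z=zbar,
                    p_value=p,
                    direction="+" if zbar >= 0 else "-",
                    significant=bool(p < alpha and len(cols) >= min_samples),
                )
            )
    return calls


def build_profiles(
    counts: ExpressionMatrix,
    samples: SampleTable,
    min_reads: int = 10,
    window: float = 0.3,
    log_transform: bool = True,
) -> TemporalProfileSet:
    """Full profile pipeline: filter -> CPM -> log2(CPM+1) -> order by
    transformed age -> smooth -> z-score."""
    meta = samples.data.set_index("sample_id").loc[counts.sample_ids]
    ages = meta["age_years"].to_numpy(dtype=float)
    t_age = transform_age(ages)

    filtered = filter_expressed(counts, min_reads=min_reads)
    cpm = cpm_normalize(filtered)
    expr = np.log2(cpm.values + 1.0) if log_transform else cpm.values

    order = np.lexsort((np.asarray(counts.sample_ids, dtype=object), t_age))
    expr = expr[:, order]
    t_sorted = t_age[order]
    sample_sorted = [counts.sample_ids[i] for i in order]
    ages_sorted = ages[order]

    smoothed = smooth_profiles(expr, t_sorted, window=window)
    z, degenerate = zscore_profiles(smoothed)
    return TemporalProfileSet(
        feature_ids=filtered.feature_ids,
        sample_ids=sample_sorted,
        transformed_ages=t_sorted,
        smoothed=smoothed,
        zscores=z,
        degenerate=degenerate,
        ages_years=ages_sorted,
    )
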