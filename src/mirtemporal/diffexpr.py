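"""Case/control differential expression of miRNA counts.

Per feature, a negative-binomial log-linear model is fitted with a
log-library-size offset and dummy-coded covariates (diagnosis, race, sex,
adult age bin, batch, ...).  The NB dispersion is estimated per feature by
maximum likelihood and shrunk toward a mean-dispersion trend (log-linear in
log mean CPM) with a prior-degrees-of-freedom weight, after which the
coefficient of interest is tested with a likelihood-ratio test against the
reduced model.  Fold changes are reported as case-minus-control on the
log2 scale.

Medication sensitivity analyses reuse the same machinery on cases only:
patients are binned by thirds of the *dose range* (not subject tertiles)
of a chlorpromazine-equivalent dose field, and high-vs-low / high-vs-medium
contrasts are tested.  Smoking analyses are plain covariate swaps
(cotinine as a continuous covariate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, SampleTable
from .temporal import age_bin

__all__ = [
    "DesignSpec",
    "DiffExprResult",
    "build_design",
    "nb_glm_test",
    "bh_adjust",
    "dose_sensitivity",
    "range_bins",
]

LN2 = float(np.log(2.0))


@dataclass
class DesignSpec:
    """Covariate specification for the per-feature GLM.

    ``interest`` names the column whose coefficient is tested (categorical
    two-level columns are coded 0/1 with the first sorted level as
    reference, so for diagnosis control->0, case->1).  ``covariates`` are
    adjusted for; categorical ones are dummy-coded dropping the first
    level.  ``derive_age_bin`` adds the adult age bin (young_adult /
    adult / senior) computed from age_years.
    """

    interest: str = "diagnosis"
    covariates: tuple[str, ...] = ("race", "sex", "age_bin", "batch")
    derive_age_bin: bool = True
    #: reference level of the interest column (coefficient is the other
    #: level vs this one); for diagnosis the convention is case vs control.
    interest_reference: str | None = "control"


def _encode(series: pd.Series, name: str, reference: str | None = None) -> pd.DataFrame:
    if series.dtype.kind in "fib" and series.nunique() > 2:
        return pd.DataFrame({name: series.astype(float)})
    levels = sorted(series.astype(str).unique())
    if len(levels) < 2:
        raise ValueError(f"covariate {name!r} has a single level")
    if reference is not None:
        if reference not in levels:
            raise ValueError(f"reference level {reference!r} absent from {name!r}")
        levels = [reference] + [l for l in levels if l != reference]
    cols = {}
    for lev in levels[1:]:
        cols[f"{name}[{lev}]"] = (series.astype(str) == lev).astype(float)
    return pd.DataFrame(cols)


def build_design(
    samples: SampleTable, design: DesignSpec
) -> tuple[np.ndarray, list[str], int]:
    """Dummy-coded design matrix with intercept; returns (X, column names,
    index of the interest coefficient)."""
    df = samples.data.copy()
    if design.derive_age_bin and "age_bin" in design.covariates:
        df["age_bin"] = [age_bin(a) for a in df["age_years"]]
    blocks = [pd.DataFrame({"Intercept": np.ones(len(df))})]
    for cov in design.covariates:
        if cov not in df.columns:
            raise ValueError(f"covariate {cov!r} not in sample table")
        blocks.append(_encode(df[cov], cov))
    ref = design.interest_reference
    if ref is not None and ref not in set(df[design.interest].astype(str)):
        ref = None
    interest_block = _encode(df[design.interest], design.interest, reference=ref)
    if interest_block.shape[1] != 1:
        raise ValueError(
            f"interest column {design.interest!r} must have exactly 2 levels "
            "or be continuous"
        )
    blocks.append(interest_block)
    X = pd.concat(blocks, axis=1)
    arr = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return arr, list(X.columns), arr.shape[1] - 1


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB2 log-likelihood with mean mu and Var = mu + alpha mu^2."""
    size = 1.0 / alpha
    return float(
        np.sum(
            special.gammaln(y + size)
            - special.gammaln(size)
            - special.gammaln(y + 1.0)
            + size * np.log(size / (size + mu))
            + y * np.log(mu / (size + mu))
        )
    )


def _estimate_alpha(y: np.ndarray, mu: np.ndarray) -> float:
    """Per-feature ML dispersion at fixed fitted means (two-step scheme)."""
    mu = np.maximum(mu, 1e-8)

    def nll(log_alpha: float) -> float:
        return -_nb_loglik(y, mu, float(np.exp(log_alpha)))

    res = optimize.minimize_scalar(nll, bounds=(-12.0, 5.0), method="bounded")
    return float(np.exp(res.x))


def _fit_glm(y, X, offset, alpha):
    fam = sm.families.NegativeBinomial(alpha=alpha)
    model = sm.GLM(y, X, family=fam, offset=offset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(maxiter=100, tol=1e-8)


@dataclass
class DiffExprResult:
    feature_id: str
    log2_fold_change: float
    p_value: float
    fdr: float = np.nan
    dispersion: float = np.nan
    converged: bool = True


def nb_glm_test(
    counts: ExpressionMatrix,
    samples: SampleTable,
    design: DesignSpec | None = None,
    prior_df: float = 10.0,
    lib_size: np.ndarray | None = None,
) -> list[DiffExprResult]:
    """Likelihood-ratio NB-GLM test of the interest coefficient, per
    feature, with trended dispersion shrinkage (prior_df pseudo-features
    pull each ML dispersion toward the log-linear mean-dispersion trend).
    ``lib_size`` overrides the default column-sum library sizes (e.g. with
    externally normalised ones).  Non-converged fits are flagged and their
    p left missing."""
    if counts.kind != "counts":
        raise ValueError("nb_glm_test needs a counts matrix")
    design = design or DesignSpec()
    if samples.sample_ids != counts.sample_ids:
        samples = SampleTable(
            samples.data.set_index("sample_id").loc[counts.sample_ids].reset_index()
        )
    diag = samples.data[design.interest]
    if design.interest == "diagnosis":
        n_arm = diag.value_counts()
        if n_arm.min() < 2 or len(n_arm) < 2:
            raise ValueError("need >= 2 samples per diagnosis arm")
    X, colnames, i_int = build_design(samples, design)
    X_red = np.delete(X, i_int, axis=1)
    if lib_size is None:
        libsize = counts.values.sum(axis=0).astype(float)
    else:
        libsize = np.asarray(lib_size, dtype=float)
        if libsize.shape != (counts.n_samples,) or np.any(libsize <= 0):
            raise ValueError("lib_size must be positive, one per sample")
    offset = np.log(libsize)
    Y = counts.values.astype(float)

    # step 1: per-feature ML dispersion at Poisson-fitted means
    alphas = np.empty(counts.n_features)
    mus = []
    for i in range(counts.n_features):
        y = Y[i]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pois = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
            mu = np.maximum(pois.fittedvalues, 1e-8)
        except Exception:
            mu = np.full_like(y, max(y.mean(), 1e-8))
        mus.append(mu)
        alphas[i] = _estimate_alpha(y, mu)

    # step 2: trend log(alpha) ~ log(mean CPM), then shrink
    mean_cpm = (Y / libsize[None, :] * 1e6).mean(axis=1)
    lx = np.log(np.maximum(mean_cpm, 1e-8))
    la = np.log(np.maximum(alphas, 1e-8))
    if counts.n_features >= 5:
        A = np.column_stack([np.ones_like(lx), lx])
        coef, *_ = np.linalg.lstsq(A, la, rcond=None)
        la_trend = A @ coef
    else:
        la_trend = np.full_like(la, la.mean())
    resid_df = max(counts.n_samples - X.shape[1], 1)
    w = resid_df / (resid_df + prior_df)
    alpha_shrunk = np.exp(w * la + (1.0 - w) * la_trend)

    results: list[DiffExprResult] = []
    for i, fid in enumerate(counts.feature_ids):
        y = Y[i]
        a = float(np.clip(alpha_shrunk[i], 1e-6, 100.0))
        try:
            full = _fit_glm(y, X, offset, a)
            red = _fit_glm(y, X_red, offset, a)
            lrt = max(2.0 * (full.llf - red.llf), 0.0)
            p = float(stats.chi2.sf(lrt, df=1))
            lfc = float(full.params[i_int] / LN2)
            ok = bool(full.converged and red.converged and np.isfinite(p))
            results.append(
                DiffExprResult(fid, lfc, p if ok else np.nan, dispersion=a, converged=ok)
            )
        except Exception:
            results.append(DiffExprResult(fid, np.nan, np.nan, dispersion=a, converged=False))

    ps = np.array([r.p_value for r in results])
    valid = np.isfinite(ps)
    if valid.any():
        fdr = np.full_like(ps, np.nan)
        fdr[valid] = bh_adjust(ps[valid])
        for r, f in zip(results, fdr):
            r.fdr = float(f)
    return results


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def range_bins(doses: np.ndarray, n_bins: int = 3) -> np.ndarray:
    """Bin by equal thirds of the dose *range*: low / medium / high.

    Edges at lo + (hi-lo) * i/n; each bin is (edge, edge] except the first
    which is closed below, so range-based bins can be empty.
    """
    doses = np.asarray(doses, dtype=float)
    if np.any(~np.isfinite(doses)):
        raise ValueError("dose missing for some included cases")
    lo, hi = doses.min(), doses.max()
    if lo == hi:
        raise ValueError("degenerate dose range")
    edges = lo + (hi - lo) * np.arange(1, n_bins) / n_bins
    labels = np.array(["low", "medium", "high"][:n_bins])
    idx = np.searchsorted(edges, doses, side="left")
    return labels[idx]


@dataclass
class DoseContrast:
    feature_id: str
    contrast: str  # "high_vs_low" / "high_vs_medium"
    log2_fold_change: float
    p_value: float
    fdr: float = np.nan


def dose_sensitivity(
    counts: ExpressionMatrix,
    cases: SampleTable,
    dose_field: str,
    n_bins: int = 3,
    covariates: tuple[str, ...] = (),
    prior_df: float = 10.0,
    lib_size: np.ndarray | None = None,
) -> list[DoseContrast]:
    """Antipsychotic-dose sensitivity: cases binned by thirds of the dose
    range, NB-GLM with the bin factor, Wald contrasts high-vs-low and
    high-vs-medium.  Contrasts against an empty bin are skipped with a
    warning.  FDR is BH within each contrast family."""
    if dose_field not in cases.data.columns:
        raise ValueError(f"unknown dose field {dose_field!r}")
    sub = counts.select_samples(cases.sample_ids)
    doses = cases.data[dose_field].to_numpy(dtype=float)
    bins = range_bins(doses, n_bins)
    present = set(bins.tolist())
    contrasts = []
    for name, other in [("high_vs_low", "low"), ("high_vs_medium", "medium")]:
        if "high" not in present or other not in present:
            warnings.warn(f"empty dose bin: contrast {name} skipped")
        else:
            contrasts.append((name, other))
    if not contrasts:
        return []

    df = cases.data.copy()
    df["dose_bin"] = bins
    table = SampleTable(df)

    X_cols = [pd.DataFrame({"Intercept": np.ones(len(df))})]
    for cov in covariates:
        X_cols.append(_encode(df[cov], cov))
    order = [l for l in ["low", "medium", "high"] if l in present]
    bin_cols = {}
    for lev in order[1:]:
        bin_cols[lev] = (bins == lev).astype(float)
    X = np.column_stack(
        [pd.concat(X_cols, axis=1).to_numpy(dtype=float)] + [bin_cols[l] for l in order[1:]]
    )
    col_of = {lev: X.shape[1] - len(order[1:]) + j for j, lev in enumerate(order[1:])}
    if lib_size is None:
        libsize = sub.values.sum(axis=0).astype(float)
    else:
        libsize = np.asarray(lib_size, dtype=float)
    offset = np.log(libsize)

    results: list[DoseContrast] = []
    for i, fid in enumerate(sub.feature_ids):
        y = sub.values[i].astype(float)
        mu = np.maximum(y.mean(), 1e-8) * np.ones_like(y)
        a = float(np.clip(_estimate_alpha(y, mu), 1e-6, 100.0))
        try:
            fit = _fit_glm(y, X, offset, a)
            cov_b = fit.cov_params()
            for name, other in contrasts:
                c = np.zeros(X.shape[1])
                c[col_of["high"]] = 1.0
                if other != order[0]:
                    c[col_of[other]] -= 1.0
                est = float(c @ fit.params)
                se = float(np.sqrt(c @ cov_b @ c))
                z = est / se if se > 0 else np.nan
                p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
                results.append(DoseContrast(fid, name, est / LN2, p))
        except Exception:
            for name, _ in contrasts:
                results.append(DoseContrast(fid, name, np.nan, np.nan))

    for name, _ in contrasts:
        rows = [r for r in results if r.contrast == name and np.isfinite(r.p_value)]
        if rows:
            fdr = bh_adjust([r.p_value for r in rows])
            for r, f in zip(rows, fdr):
                r.fdr = float(f)
    return results
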