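"""miRNA - target-mRNA expression correlation with a shuffled-label null.

Pearson r is computed across samples for every (miRNA, gene) pair in the
target map, with two-sided t-distribution p-values and BH-FDR over all
pairs.  Pairs are classified positive (r > 0.49, FDR < 0.05), negative
(r < -0.49, FDR < 0.05) or none.  The chance level of those fractions is
estimated by permuting the mRNA matrix's sample labels and re-running the
analysis: planted miRNA->gene coupling should put the observed significant
fraction far above the shuffled one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scipy import stats

from .diffexpr import bh_adjust
from .io import ExpressionMatrix, TargetMap

__all__ = [
    "PairCorrelation",
    "NullFractionSummary",
    "pair_correlations",
    "shuffled_null",
    "classify",
]

R_THRESHOLD = 0.49
FDR_THRESHOLD = 0.05


@dataclass
class PairCorrelation:
    mirna_id: str
    gene_id: str
    r: float
    p_value: float
    fdr: float
    cls: str  # "positive" / "negative" / "none"


def classify(r: float, fdr: float, r_threshold: float = R_THRESHOLD,
             fdr_threshold: float = FDR_THRESHOLD) -> str:
    if fdr < fdr_threshold and r > r_threshold:
        return "positive"
    if fdr < fdr_threshold and r < -r_threshold:
        return "negative"
    return "none"


def _aligned(mirna_expr: ExpressionMatrix, mrna_expr: ExpressionMatrix):
    shared = [s for s in mirna_expr.sample_ids if s in set(mrna_expr.sample_ids)]
    if len(shared) < 4:
        raise ValueError("need >= 4 shared samples for correlation")
    return mirna_expr.select_samples(shared), mrna_expr.select_samples(shared)


def _pair_table(
    x: np.ndarray,
    y: np.ndarray,
    mi: np.ndarray,
    gi: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r and two-sided p for pre-indexed pairs; NaN for
    zero-variance rows."""
    n = x.shape[1]
    xs = x - x.mean(axis=1, keepdims=True)
    ys = y - y.mean(axis=1, keepdims=True)
    xn = np.sqrt((xs**2).sum(axis=1))
    yn = np.sqrt((ys**2).sum(axis=1))
    num = (xs[mi] * ys[gi]).sum(axis=1)
    den = xn[mi] * yn[gi]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, np.nan)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return r, p


def pair_correlations(
    mirna_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    target_map: TargetMap,
    r_threshold: float = R_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
) -> list[PairCorrelation]:
    """Correlate every target-map (miRNA, gene) pair present in both
    matrices across the shared samples; BH-FDR over all computable pairs.
    Zero-variance series are skipped with a warning."""
    mx, gx = _aligned(mirna_expr, mrna_expr)
    m_index = {m: i for i, m in enumerate(mx.feature_ids)}
    g_index = {g: i for i, g in enumerate(gx.feature_ids)}
    pairs = target_map.pairs()
    keep = pairs["mirna_id"].isin(m_index) & pairs["gene_id"].isin(g_index)
    pairs = pairs.loc[keep].reset_index(drop=True)
    if len(pairs) == 0:
        return []
    mi = pairs["mirna_id"].map(m_index).to_numpy()
    gi = pairs["gene_id"].map(g_index).to_numpy()
    r, p = _pair_table(mx.values.astype(float), gx.values.astype(float), mi, gi)
    ok = np.isfinite(r) & np.isfinite(p)
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} pairs skipped (zero-variance series)")
    fdr = np.full_like(p, np.nan)
    if ok.any():
        fdr[ok] = bh_adjust(p[ok])
    out = []
    for j in range(len(pairs)):
        if not ok[j]:
            continue
        out.append(
            PairCorrelation(
                mirna_id=str(pairs["mirna_id"][j]),
                gene_id=str(pairs["gene_id"][j]),
                r=float(r[j]),
                p_value=float(p[j]),
                fdr=float(fdr[j]),
                cls=classify(float(r[j]), float(fdr[j]), r_threshold, fdr_threshold),
            )
        )
    return out


@dataclass
class NullFractionSummary:
    n_shuffles: int
    n_pairs: int
    positive_fractions: np.ndarray
    negative_fractions: np.ndarray

    @property
    def mean_positive(self) -> float:
        return float(self.positive_fractions.mean())

    @property
    def mean_negative(self) -> float:
        return float(self.negative_fractions.mean())

    @property
    def sd_positive(self) -> float:
        return float(self.positive_fractions.std(ddof=1)) if self.n_shuffles > 1 else 0.0

    @property
    def sd_negative(self) -> float:
        return float(self.negative_fractions.std(ddof=1)) if self.n_shuffles > 1 else 0.0


def shuffled_null(
    mirna_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    target_map: TargetMap,
    n_shuffles: int,
    seed: int | None = None,
    r_threshold: float = R_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
) -> NullFractionSummary:
    """Shuffled-label null for the correlated-pair fractions: per shuffle,
    the mRNA matrix's sample labels are permuted once (breaking every
    miRNA-mRNA pairing), the correlation analysis re-run, and the fraction
    of pairs in each class recorded."""
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    mx, gx = _aligned(mirna_expr, mrna_expr)
    pos = np.empty(n_shuffles)
    neg = np.empty(n_shuffles)
    n_pairs = 0
    for s in range(n_shuffles):
        perm = rng.permutation(gx.n_samples)
        shuffled = ExpressionMatrix(
            gx.feature_ids, gx.sample_ids, gx.values[:, perm], gx.kind
        )
        res = pair_correlations(mx, shuffled, target_map, r_threshold, fdr_threshold)
        n_pairs = len(res)
        if n_pairs == 0:
            pos[s] = neg[s] = 0.0
            continue
        pos[s] = sum(r.cls == "positive" for r in res) / n_pairs
        neg[s] = sum(r.cls == "negative" for r in res) / n_pairs
    return NullFractionSummary(n_shuffles, n_pairs, pos, neg)
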