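"""Gene-set and target-site enrichment.

Three families of tests:

* **Preranked GSEA** of the temporal miRNA groups against the case/control
  fold-change ranking: weighted running-sum enrichment score (hit
  increments proportional to |score|^weight, miss decrements 1/(N - Nh)),
  null by random same-size member sets, NES = ES / mean |null ES| of
  matching sign, BH-FDR across sets.

* **MRE enrichment** of miRNA binding sites in a transcript.  The 2x2
  site-count table (group vs non-group miRNAs, tested transcript vs all
  others) yields either the hypergeometric point probability

      P = C(n11+n21, n11) C(n12+n22, n12) / C(n11+n12+n21+n22, n11+n12)

  or the one-sided Fisher enrichment tail (default).  A gene is a
  co-regulated (CoR) gene if any transcript is MRE-enriched at FDR < 0.05
  *and* the gene is targeted by at least 2 distinct miRNAs of the group.

* **Gene-set targeting**: upper-tail hypergeometric probability that the
  genes targeted by a miRNA group over-represent a gene set (GWAS / CNV /
  SNV / synaptic sets), and two-sample Kolmogorov-Smirnov comparison of a
  set's per-gene enrichment p-values against the targeted background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .io import GeneSet, GeneSetCollection, TargetMap

__all__ = [
    "EnrichmentResult",
    "ContingencyTable",
    "CoRResult",
    "enrichment_score",
    "preranked_gsea",
    "mre_enrichment_p",
    "cor_gene_test",
    "ks_set_enrichment",
    "set_targeting_test",
]


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_value: float
    fdr: float = np.nan
    n_members: int = 0


def _ordered_ranking(ranked) -> tuple[list[str], np.ndarray]:
    if isinstance(ranked, pd.DataFrame):
        pairs = list(zip(ranked.iloc[:, 0].astype(str), ranked.iloc[:, 1].astype(float)))
    else:
        pairs = [(str(f), float(s)) for f, s in ranked]
    ids = [f for f, _ in pairs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate features in ranking")
    pairs = sorted(pairs, key=lambda t: (-t[1], t[0]))
    return [f for f, _ in pairs], np.array([s for _, s in pairs])


def enrichment_score(
    hit_mask: np.ndarray, scores: np.ndarray, weight: float = 1.0
) -> float:
    """Running-sum enrichment score for one set on an ordered ranking.

    The running sum gains |score|^weight / (sum over hits) at each member
    and loses 1/(N - Nh) at each non-member; ES is the extremum (largest
    absolute deviation, sign kept).
    """
    hit_mask = np.asarray(hit_mask, dtype=bool)
    n = len(hit_mask)
    nh = int(hit_mask.sum())
    if nh == 0 or nh == n:
        raise ValueError("set must be a proper non-empty subset of the ranking")
    w = np.abs(scores) ** weight
    hit_w = np.where(hit_mask, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        hit_w = hit_mask.astype(float)
        denom = float(nh)
    steps = np.where(hit_mask, hit_w / denom, -1.0 / (n - nh))
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def _es_for_positions(
    pos: np.ndarray, w: np.ndarray, n: int
) -> np.ndarray:
    """Vectorised ES for rows of hit positions (each row sorted ascending).

    The running maximum occurs just after a hit and the minimum just
    before one; both are evaluated in closed form from the cumulative hit
    weights and the miss count before each hit.
    """
    nh = pos.shape[1]
    miss_step = 1.0 / (n - nh)
    wp = w[pos]
    cumw = np.cumsum(wp, axis=1)
    denom = cumw[:, -1:]
    denom = np.where(denom == 0, 1.0, denom)
    j = np.arange(nh)[None, :]
    misses_before = pos - j
    after = cumw / denom - misses_before * miss_step
    before = (cumw - wp) / denom - misses_before * miss_step
    hi = after.max(axis=1)
    lo = np.minimum(before.min(axis=1), 0.0)
    return np.where(hi >= -lo, hi, lo)


def preranked_gsea(
    ranked,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int | None = None,
    min_size: int = 1,
) -> list[EnrichmentResult]:
    """Preranked GSEA with a gene-label permutation null.

    Members outside the ranked universe are dropped with a warning; sets
    smaller than ``min_size`` after dropping (or empty / as large as the
    universe) are skipped.  NES = ES / mean(|null ES| of matching sign);
    the nominal p is the matching-sign permutation tail; FDR is BH across
    the tested sets.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ids, scores = _ordered_ranking(ranked)
    index = {f: i for i, f in enumerate(ids)}
    n = len(ids)
    w = np.abs(scores) ** weight
    rng = np.random.default_rng(seed)

    results: list[EnrichmentResult] = []
    for gs in sets:
        members = [m for m in gs.members if m in index]
        dropped = len(gs.members) - len(members)
        if dropped:
            warnings.warn(f"set {gs.name!r}: {dropped} members outside ranking dropped")
        if len(gs.members) > n:
            raise ValueError(f"set {gs.name!r} larger than the ranked universe")
        nh = len(members)
        if nh < max(min_size, 1) or nh >= n:
            continue
        mask = np.zeros(n, dtype=bool)
        mask[[index[m] for m in members]] = True
        es = enrichment_score(mask, scores, weight)

        null_pos = np.sort(
            rng.random((n_perm, n)).argsort(axis=1)[:, :nh], axis=1
        )
        null_es = _es_for_positions(null_pos, w, n)
        same = null_es >= 0 if es >= 0 else null_es < 0
        n_same = int(same.sum())
        if n_same:
            nes = es / np.mean(np.abs(null_es[same]))
            p = (1.0 + np.sum(np.abs(null_es[same]) >= abs(es))) / (n_same + 1.0)
        else:
            nes = es / max(np.mean(np.abs(null_es)), 1e-12)
            p = 1.0 / (n_perm + 1.0)
        results.append(EnrichmentResult(gs.name, es, float(nes), float(p), n_members=nh))

    if results:
        fdr = bh_adjust([r.p_value for r in results])
        for r, f in zip(results, fdr):
            r.fdr = float(f)
    return results


@dataclass
class ContingencyTable:
    """Site counts: group vs non-group miRNAs x tested transcript vs rest."""

    n11: int  # group sites in the tested transcript
    n12: int  # non-group sites in the tested transcript
    n21: int  # group sites in all other transcripts
    n22: int  # non-group sites in all other transcripts

    def __post_init__(self) -> None:
        for v in (self.n11, self.n12, self.n21, self.n22):
            if v < 0:
                raise ValueError("contingency counts must be >= 0")


def mre_enrichment_p(table: ContingencyTable, mode: str = "tail") -> float:
    """Probability that the tested transcript's sites over-represent the
    group's sites.

    ``mode="point"`` is the hypergeometric point-probability term;
    ``mode="tail"`` (default) is the one-sided Fisher enrichment tail
    P(X >= n11).  Degenerate margins give p = 1.
    """
    t = table
    N = t.n11 + t.n12 + t.n21 + t.n22
    K = t.n11 + t.n21  # group sites overall
    n = t.n11 + t.n12  # sites in the tested transcript
    if N == 0 or K == 0 or n == 0 or K == N or n == N:
        return 1.0
    if mode == "point":
        return float(stats.hypergeom.pmf(t.n11, N, K, n))
    if mode == "tail":
        return float(min(stats.hypergeom.sf(t.n11 - 1, N, K, n), 1.0))
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class CoRResult:
    gene_id: str
    best_p: float
    fdr: float
    n_group_mirnas_targeting: int
    is_cor: bool


def cor_gene_test(
    target_map: TargetMap,
    group_mirnas,
    alpha: float = 0.05,
    mode: str = "tail",
) -> list[CoRResult]:
    """Identify co-regulated (CoR) genes of a miRNA group.

    Every transcript gets a 2x2 site-count table and an enrichment p;
    BH-FDR is taken across *all* tested transcripts in the run; a gene is
    a CoR gene iff its best (minimum-FDR) transcript passes FDR < alpha
    and >= 2 distinct group miRNAs target the gene.
    """
    group = set(getattr(group_mirnas, "members", group_mirnas))
    if not group:
        raise ValueError("empty miRNA group")
    unknown = group - target_map.mirnas
    if unknown:
        warnings.warn(f"{len(unknown)} group miRNAs absent from the target map")
    rec = target_map.records
    in_group = rec["mirna_id"].isin(group)
    per_tx = rec.groupby("transcript_id").agg(gene_id=("gene_id", "first"))
    grp_sites = rec.loc[in_group].groupby("transcript_id")["n_sites"].sum()
    all_sites = rec.groupby("transcript_id")["n_sites"].sum()
    per_tx["group_sites"] = grp_sites.reindex(per_tx.index, fill_value=0)
    per_tx["all_sites"] = all_sites.reindex(per_tx.index, fill_value=0)
    total_group = int(grp_sites.sum())
    total_all = int(all_sites.sum())

    ps = []
    for tx, row in per_tx.iterrows():
        n11 = int(row["group_sites"])
        n12 = int(row["all_sites"]) - n11
        n21 = total_group - n11
        n22 = (total_all - total_group) - n12
        ps.append(mre_enrichment_p(ContingencyTable(n11, n12, n21, n22), mode=mode))
    per_tx["p"] = ps
    per_tx["fdr"] = bh_adjust(per_tx["p"].to_numpy())

    n_group_mirnas = (
        rec.loc[in_group].groupby("gene_id")["mirna_id"].nunique()
    )
    results: list[CoRResult] = []
    for gene, sub in per_tx.groupby("gene_id"):
        best = sub.loc[sub["fdr"].idxmin()]
        n_mir = int(n_group_mirnas.get(gene, 0))
        results.append(
            CoRResult(
                gene_id=str(gene),
                best_p=float(best["p"]),
                fdr=float(best["fdr"]),
                n_group_mirnas_targeting=n_mir,
                is_cor=bool(best["fdr"] < alpha and n_mir >= 2),
            )
        )
    results.sort(key=lambda r: r.gene_id)
    return results


def ks_set_enrichment(
    p_gene: dict[str, float], gene_set, background
) -> tuple[float, float, str]:
    """Two-sample KS comparison of a gene set's enrichment p-values against
    the targeted background; returns (D, p, direction) where direction
    'enriched' means the set's p-values sit lower than the background's."""
    set_genes = set(getattr(gene_set, "members", gene_set))
    bg_genes = set(getattr(background, "members", background))
    set_p = np.array([p_gene[g] for g in sorted(set_genes) if g in p_gene])
    bg_p = np.array([p_gene[g] for g in sorted(bg_genes) if g in p_gene])
    if len(set_p) == 0 or len(bg_p) == 0:
        raise ValueError("gene set or background disjoint from the p-value map")
    method = "auto"
    if len(set_p) < 3:
        warnings.warn("gene set smaller than 3: exact small-sample KS p")
        method = "exact"
    res = stats.ks_2samp(set_p, bg_p, method=method)
    direction = "enriched" if np.median(set_p) < np.median(bg_p) else "depleted"
    return float(res.statistic), float(res.pvalue), direction


def set_targeting_test(
    target_map: TargetMap,
    group_mirnas,
    gene_set,
    universe,
) -> float:
    """Upper-tail hypergeometric probability that the genes targeted by
    the group over-represent the gene set within the universe of genes
    targeted by any expressed miRNA."""
    group = set(getattr(group_mirnas, "members", group_mirnas))
    gset = set(getattr(gene_set, "members", gene_set))
    uni = set(getattr(universe, "members", universe))
    if not group:
        raise ValueError("empty miRNA group")
    K_set = gset & uni
    if not K_set:
        raise ValueError("gene set disjoint from the universe")
    rec = target_map.records
    targeted = set(rec.loc[rec["mirna_id"].isin(group), "gene_id"]) & uni
    N = len(uni)
    K = len(K_set)
    n = len(targeted)
    k = len(targeted & K_set)
    if n == 0:
        return 1.0
    return float(min(stats.hypergeom.sf(k - 1, N, K, n), 1.0))
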