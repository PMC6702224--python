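"""Synthetic cohorts with the statistical structure of a postmortem
brain miRNA study.

The generator emulates a lifespan DLPFC cohort: controls spanning the
second trimester (negative ages) to the mid-seventies plus an adult
schizophrenia case group, miRNA read counts that follow temporal group
templates on the log post-conception age scale with negative-binomial
noise, multiplicative batch effects and optional planted case/control
shifts, a continuous mRNA matrix with optional miRNA->gene coupling, and a
TargetScan-style bipartite target map with optional planted co-regulated
(CoR) genes.

Control ages are sampled stratified-uniformly on the transformed
log2(days + 280) scale so every developmental stage holds samples; case
ages are uniform over the adult range, mirroring a case/control design in
which only adult patients are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SampleTable, TargetMap
from .temporal import transform_age

__all__ = [
    "TemporalTemplate",
    "PlantedCoR",
    "CohortConfig",
    "default_templates",
    "generate_cohort",
    "generate_mirna_counts",
    "generate_mrna_matrix",
    "generate_target_map",
    "mirna_group_assignment",
    "mirna_group_sets",
    "coupling_slope_for_r",
]


def _gauss(mu: float, sd: float) -> Callable[[np.ndarray], np.ndarray]:
    return lambda t: np.exp(-((t - mu) ** 2) / (2.0 * sd**2))


def _sigmoid(center: float, scale: float) -> Callable[[np.ndarray], np.ndarray]:
    return lambda t: 1.0 / (1.0 + np.exp((t - center) / scale))


@dataclass(frozen=True)
class TemporalTemplate:
    """A bounded mean log2-expression shape over transformed age.

    ``shape`` maps transformed age (log2 post-conception days) to a value
    in roughly [-1, 1]; ``amplitude`` (log2 units) scales it.
    """

    name: str
    shape: Callable[[np.ndarray], np.ndarray]
    amplitude: float = 2.0

    def mean_log_expression(self, t: np.ndarray) -> np.ndarray:
        return self.amplitude * np.asarray(self.shape(np.asarray(t, dtype=float)))


# transformed-age landmarks (log2 post-conception days)
_T_FETAL = transform_age(-0.25)       # ~7.56
_T_INFANT = transform_age(0.5)        # ~8.87
_T_TODDLER = transform_age(2.0)       # ~9.99
_T_PRESCHOOL = transform_age(4.5)     # ~10.92
_T_PREPUBERTY = transform_age(9.0)    # ~11.79


def default_templates(amplitude: float = 2.0) -> list[TemporalTemplate]:
    """Nine temporal shapes: fetal highs/lows, infant and toddler peaks,
    a prepubertal wave, and an early-life plateau, echoing the variety of
    trajectories bulk brain miRNAs show across the lifespan."""
    specs: list[tuple[str, Callable[[np.ndarray], np.ndarray]]] = [
        (
            "fetal_preschool_low",
            lambda t: -_gauss(_T_FETAL, 0.5)(t) - _gauss(_T_PRESCHOOL, 0.45)(t),
        ),
        ("fetal_high", _gauss(_T_FETAL - 0.15, 0.6)),
        ("toddler_low", lambda t: -_gauss(_T_TODDLER, 0.5)(t)),
        (
            "fetal_toddler_low",
            lambda t: -_gauss(_T_FETAL, 0.5)(t) - _gauss(_T_TODDLER, 0.45)(t),
        ),
        ("fetal_infant_high", _sigmoid(9.4, 0.35)),
        ("prepuberty_wave", _gauss(11.3, 0.7)),
        ("toddler_peak", _gauss(_T_TODDLER, 0.45)),
        ("infant_peak", _gauss(_T_INFANT, 0.4)),
        (
            "toddler_peak_adult_low",
            lambda t: _gauss(_T_TODDLER, 0.45)(t)
            - 0.8 * (1.0 - _sigmoid(12.5, 0.5)(t)),
        ),
    ]
    return [TemporalTemplate(name, fn, amplitude) for name, fn in specs]


@dataclass(frozen=True)
class PlantedCoR:
    """Planted co-regulated genes: each listed gene receives ``n_sites``
    binding sites from ``n_mirnas`` distinct miRNAs of temporal group
    ``group`` (1-based)."""

    group: int
    genes: tuple[str, ...]
    # default excess calibrated so a planted gene is unambiguously
    # MRE-enriched against the background site density
    n_mirnas: int = 4
    n_sites: int = 4


@dataclass(frozen=True)
class CohortConfig:
    """Everything the generators need; defaults mirror the study layout
    (109 lifespan controls, 34 adult cases) at a feature count scaled for
    simulation studies."""

    n_control: int = 109
    n_case: int = 34
    age_range_years: tuple[float, float] = (-0.44, 73.3)
    case_age_range_years: tuple[float, float] = (18.0, 72.0)
    n_mirna: int = 270
    n_mrna: int = 400
    n_groups: int = 9
    templates: tuple[TemporalTemplate, ...] = tuple(default_templates())
    baseline_log2_cpm_range: tuple[float, float] = (5.0, 9.0)
    library_size_log_mean: float = float(np.log(2e6))
    library_size_log_sd: float = 0.4
    dispersion: float = 0.1
    batch_effect_sd: float = 0.15
    n_batches: int = 2
    planted_de: tuple[tuple[str, float], ...] = ()
    group_shift: tuple[tuple[int, float], ...] = ()  # (group 1-based, log2fc)
    coupling: tuple[tuple[str, str, float], ...] = ()  # (mirna, gene, slope)
    mrna_noise_sd: float = 1.0
    target_density: float = 0.02
    planted_cor: PlantedCoR | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control <= 0:
            raise ValueError("n_control must be > 0")
        if self.n_case < 0:
            raise ValueError("n_case must be >= 0")
        lo, hi = self.age_range_years
        if not lo < hi:
            raise ValueError("empty age range")
        if lo <= -0.75:
            raise ValueError("age range start must exceed -0.75")
        if self.n_groups != len(self.templates):
            raise ValueError("n_groups must equal len(templates)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        mirnas = set(self.mirna_ids())
        for mid, _ in self.planted_de:
            if mid not in mirnas:
                raise ValueError(f"planted_de miRNA {mid!r} does not exist")
        for g, _ in self.group_shift:
            if not 1 <= g <= self.n_groups:
                raise ValueError(f"group_shift group {g} out of range")
        genes = set(self.gene_ids())
        for mid, gid, _ in self.coupling:
            if mid not in mirnas:
                raise ValueError(f"coupling miRNA {mid!r} does not exist")
            if gid not in genes:
                raise ValueError(f"coupling gene {gid!r} does not exist")
        if self.planted_cor is not None:
            if len(self.planted_cor.genes) > self.n_mrna:
                raise ValueError("planted CoR gene count exceeds n_mrna")
            if not 1 <= self.planted_cor.group <= self.n_groups:
                raise ValueError("planted CoR group out of range")
            for gid in self.planted_cor.genes:
                if gid not in genes:
                    raise ValueError(f"planted CoR gene {gid!r} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        """Load a config from YAML.  Templates are described by
        ``template_amplitude`` (the default nine shapes at that amplitude);
        callable shapes themselves are not serialisable."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        amplitude = raw.pop("template_amplitude", None)
        for key in ("age_range_years", "case_age_range_years", "baseline_log2_cpm_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        for key in ("planted_de", "group_shift", "coupling"):
            if key in raw:
                raw[key] = tuple(tuple(item) for item in raw[key])
        if "planted_cor" in raw and raw["planted_cor"] is not None:
            pc = raw["planted_cor"]
            raw["planted_cor"] = PlantedCoR(
                group=int(pc["group"]),
                genes=tuple(pc["genes"]),
                n_mirnas=int(pc.get("n_mirnas", 4)),
                n_sites=int(pc.get("n_sites", 4)),
            )
        if amplitude is not None:
            raw["templates"] = tuple(default_templates(float(amplitude)))
            raw.setdefault("n_groups", 9)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import yaml

        out = {
            "n_control": self.n_control,
            "n_case": self.n_case,
            "age_range_years": list(self.age_range_years),
            "case_age_range_years": list(self.case_age_range_years),
            "n_mirna": self.n_mirna,
            "n_mrna": self.n_mrna,
            "n_groups": self.n_groups,
            "template_amplitude": float(self.templates[0].amplitude),
            "baseline_log2_cpm_range": list(self.baseline_log2_cpm_range),
            "library_size_log_mean": self.library_size_log_mean,
            "library_size_log_sd": self.library_size_log_sd,
            "dispersion": self.dispersion,
            "batch_effect_sd": self.batch_effect_sd,
            "n_batches": self.n_batches,
            "planted_de": [list(t) for t in self.planted_de],
            "group_shift": [list(t) for t in self.group_shift],
            "coupling": [list(t) for t in self.coupling],
            "mrna_noise_sd": self.mrna_noise_sd,
            "target_density": self.target_density,
            "seed": self.seed,
        }
        if self.planted_cor is not None:
            out["planted_cor"] = {
                "group": self.planted_cor.group,
                "genes": list(self.planted_cor.genes),
                "n_mirnas": self.planted_cor.n_mirnas,
                "n_sites": self.planted_cor.n_sites,
            }
        with open(path, "w") as fh:
            yaml.safe_dump(out, fh, sort_keys=False)

    def mirna_ids(self) -> list[str]:
        return [f"miR-{i + 1:04d}" for i in range(self.n_mirna)]

    def gene_ids(self) -> list[str]:
        return [f"GENE{i + 1:04d}" for i in range(self.n_mrna)]

    def with_(self, **kwargs) -> "CohortConfig":
        return replace(self, **kwargs)


def mirna_group_assignment(config: CohortConfig) -> np.ndarray:
    """1-based temporal group label per miRNA (contiguous, near-equal blocks)."""
    base, extra = divmod(config.n_mirna, config.n_groups)
    sizes = [base + (1 if g < extra else 0) for g in range(config.n_groups)]
    return np.repeat(np.arange(1, config.n_groups + 1), sizes)


def mirna_group_sets(config: CohortConfig) -> dict[str, list[str]]:
    """Group name -> member miRNA ids (``Group1`` .. ``GroupN``)."""
    labels = mirna_group_assignment(config)
    ids = config.mirna_ids()
    return {
        f"Group{g}": [m for m, l in zip(ids, labels) if l == g]
        for g in range(1, config.n_groups + 1)
    }


def _rng(config: CohortConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def generate_cohort(config: CohortConfig) -> SampleTable:
    """Sample donor metadata: stratified control ages on the transformed
    scale, adult case ages, categorical sex/race/batch, doses for cases."""
    rng = _rng(config, 1)
    lo, hi = config.age_range_years
    t_lo, t_hi = transform_age(lo), transform_age(hi)
    n_ctl = config.n_control
    # stratified-uniform on transformed age: one draw per equal-width stratum
    u = (np.arange(n_ctl) + rng.uniform(size=n_ctl)) / n_ctl
    t_ctl = t_lo + u * (t_hi - t_lo)
    age_ctl = (2.0**t_ctl - 280.0) / 365.25

    c_lo, c_hi = config.case_age_range_years
    age_case = rng.uniform(c_lo, c_hi, size=config.n_case)

    ages = np.concatenate([age_ctl, age_case])
    n = len(ages)
    diagnosis = ["control"] * n_ctl + ["case"] * config.n_case
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    sex = rng.choice(["M", "F"], size=n, p=[0.55, 0.45])
    race = rng.choice(["AA", "CAUC"], size=n, p=[0.55, 0.45])
    batch = rng.integers(1, config.n_batches + 1, size=n)
    ph = rng.normal(6.5, 0.25, size=n).round(2)
    pmi = np.abs(rng.normal(27.0, 15.0, size=n)).round(1)

    df = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "age_years": ages,
            "diagnosis": diagnosis,
            "sex": sex,
            "race": race,
            "batch": [f"b{b}" for b in batch],
            "ph": ph,
            "pmi_hours": pmi,
            "cpze_lifetime": np.nan,
            "cpze_daily": np.nan,
            "cpze_last": np.nan,
            "antidepressant": pd.array([pd.NA] * n, dtype="boolean"),
            "cotinine": np.nan,
        }
    )
    if config.n_case > 0:
        is_case = df["diagnosis"] == "case"
        n_case = int(is_case.sum())
        df.loc[is_case, "cpze_lifetime"] = np.exp(rng.normal(10.0, 1.0, n_case)).round(0)
        df.loc[is_case, "cpze_daily"] = np.exp(rng.normal(6.0, 0.8, n_case)).round(0)
        df.loc[is_case, "cpze_last"] = np.exp(rng.normal(5.5, 0.9, n_case)).round(0)
        df.loc[is_case, "antidepressant"] = rng.uniform(size=n_case) < 0.5
    fetal = df["age_years"] < 0
    df.loc[fetal, "cotinine"] = np.where(
        rng.uniform(size=int(fetal.sum())) < 0.3,
        np.exp(rng.normal(3.0, 1.0, int(fetal.sum()))).round(1),
        0.0,
    )
    return SampleTable(df)


def _mean_log2_cpm(
    cohort: SampleTable, config: CohortConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-(feature, sample) mean log2 relative expression before
    library-size scaling."""
    ages = cohort.data["age_years"].to_numpy(dtype=float)
    t = transform_age(ages)
    groups = mirna_group_assignment(config)
    b_lo, b_hi = config.baseline_log2_cpm_range
    baseline = rng.uniform(b_lo, b_hi, size=config.n_mirna)

    log2 = np.empty((config.n_mirna, len(ages)))
    for g in range(1, config.n_groups + 1):
        rows = groups == g
        log2[rows, :] = baseline[rows, None] + config.templates[g - 1].mean_log_expression(t)[None, :]

    # batch: multiplicative per-(batch, miRNA) log-normal offset
    batches = cohort.data["batch"].to_numpy()
    for b in np.unique(batches):
        offset = rng.normal(0.0, config.batch_effect_sd, size=config.n_mirna)
        log2[:, batches == b] += offset[:, None]

    # case-only shifts
    is_case = (cohort.data["diagnosis"] == "case").to_numpy()
    if is_case.any():
        mid_index = {m: i for i, m in enumerate(config.mirna_ids())}
        shift = np.zeros(config.n_mirna)
        for g, lfc in config.group_shift:
            shift[groups == g] += lfc
        for mid, lfc in config.planted_de:
            shift[mid_index[mid]] += lfc
        log2[:, is_case] += shift[:, None]
    return log2


def generate_mirna_counts(cohort: SampleTable, config: CohortConfig) -> ExpressionMatrix:
    """Negative-binomial read counts whose expected CPM follows each
    miRNA's temporal template, with batch offsets and case-only planted
    effects; mean = library size x relative abundance."""
    if len(cohort) != config.n_control + config.n_case:
        raise ValueError("cohort size does not match config")
    rng = _rng(config, 2)
    log2 = _mean_log2_cpm(cohort, config, rng)
    rel = 2.0**log2
    frac = rel / rel.sum(axis=0, keepdims=True)
    libsize = np.exp(
        rng.normal(config.library_size_log_mean, config.library_size_log_sd, size=len(cohort))
    )
    mu = frac * libsize[None, :]
    # gamma-Poisson mixture: var = mu + dispersion * mu^2
    alpha = config.dispersion
    lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
    counts = rng.poisson(lam)
    return ExpressionMatrix(config.mirna_ids(), cohort.sample_ids, counts, kind="counts")


def coupling_slope_for_r(
    target_r: float, mirna_log_cpm_sd: float, noise_sd: float
) -> float:
    """Slope giving expected Pearson r = ``target_r`` between a coupled
    gene and its miRNA's log-CPM, for the given predictor spread and
    Gaussian noise: slope = r * sigma / (sd_x * sqrt(1 - r^2))."""
    if not -1.0 < target_r < 1.0:
        raise ValueError("target_r must be in (-1, 1)")
    if mirna_log_cpm_sd <= 0 or noise_sd < 0:
        raise ValueError("sds must be positive")
    return target_r * noise_sd / (mirna_log_cpm_sd * np.sqrt(1.0 - target_r**2))


def generate_mrna_matrix(
    cohort: SampleTable,
    config: CohortConfig,
    mirna_log_cpm: ExpressionMatrix | None = None,
) -> ExpressionMatrix:
    """Continuous mRNA expression; genes named in ``config.coupling`` are
    slope x (miRNA log2 CPM) + Gaussian noise, the rest are independent of
    the miRNAs."""
    if len(cohort) != config.n_control + config.n_case:
        raise ValueError("cohort size does not match config")
    rng = _rng(config, 3)
    n = len(cohort)
    genes = config.gene_ids()
    values = rng.normal(8.0, 1.0, size=(config.n_mrna, 1)) + rng.normal(
        0.0, config.mrna_noise_sd, size=(config.n_mrna, n)
    )
    if config.coupling:
        if mirna_log_cpm is None:
            counts = generate_mirna_counts(cohort, config)
            cpm = counts.values * (1e6 / counts.values.sum(axis=0, keepdims=True))
            mirna_log_cpm = ExpressionMatrix(
                counts.feature_ids, counts.sample_ids, np.log2(cpm + 1.0), kind="log_cpm"
            )
        if mirna_log_cpm.sample_ids != cohort.sample_ids:
            raise ValueError("mirna matrix samples do not match cohort")
        m_index = {m: i for i, m in enumerate(mirna_log_cpm.feature_ids)}
        g_index = {g: i for i, g in enumerate(genes)}
        for mid, gid, slope in config.coupling:
            if mid not in m_index:
                raise ValueError(f"coupling miRNA {mid!r} not in expression matrix")
            x = mirna_log_cpm.values[m_index[mid]]
            gi = g_index[gid]
            values[gi, :] = (
                8.0 + slope * (x - x.mean())
                + rng.normal(0.0, config.mrna_noise_sd, size=n)
            )
    return ExpressionMatrix(genes, cohort.sample_ids, values, kind="continuous")


def generate_target_map(config: CohortConfig) -> TargetMap:
    """Random bipartite miRNA->transcript site table (one transcript per
    gene) plus, if configured, planted CoR genes that carry excess sites
    from >= 2 distinct miRNAs of one temporal group."""
    if config.n_mirna <= 0 or config.n_mrna <= 0:
        raise ValueError("n_mirna and n_mrna must be > 0")
    rng = _rng(config, 4)
    mirnas = config.mirna_ids()
    genes = config.gene_ids()
    edge = rng.uniform(size=(config.n_mirna, config.n_mrna)) < config.target_density
    n_sites = np.where(edge, 1 + rng.poisson(0.3, size=edge.shape), 0)

    if config.planted_cor is not None:
        pc = config.planted_cor
        group_rows = np.flatnonzero(mirna_group_assignment(config) == pc.group)
        if pc.n_mirnas > len(group_rows):
            raise ValueError("planted CoR n_mirnas exceeds group size")
        g_index = {g: i for i, g in enumerate(genes)}
        for gid in pc.genes:
            rows = rng.choice(group_rows, size=pc.n_mirnas, replace=False)
            for r in rows:
                n_sites[r, g_index[gid]] += pc.n_sites

    rr, cc = np.nonzero(n_sites)
    if len(rr) == 0:
        raise ValueError("degenerate target map: every gene has 0 sites")
    df = pd.DataFrame(
        {
            "mirna_id": [mirnas[r] for r in rr],
            "gene_id": [genes[c] for c in cc],
            "transcript_id": [f"T_{genes[c]}_1" for c in cc],
            "n_sites": n_sites[rr, cc],
        }
    )
    return TargetMap(df)
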