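"""Seeded synthetic cohort generation.

The study data behind the printed cohort tables are not publicly deposited,
so this module generates surrogate cohorts whose *marginal* structure is
transcribed from the published group summaries (mean ± SD rows as truncated
normals, median (Q1–Q3) rows as log-normals) and whose dependence structure
is a Gaussian copula with a documented default latent correlation matrix.
The default correlations encode only the qualitative directions the
literature asserts (adiposity, insulin resistance, dysglycemia, liver
enzymes and inflammation positively associated; HDL negatively) at moderate
magnitudes (|ρ| 0.15–0.8); they are assumptions, not estimates of the
unpublished study correlations, and are fully overridable.

Sampling is inverse-CDF through the copula: a latent multivariate normal
draw is mapped coordinate-wise through each marginal's quantile function.
Truncation floors are applied inside the quantile function (equivalent in
distribution to rejection resampling, deterministic, and exactly
rank-preserving, so configured Spearman correlations survive truncation).
Body weight is derived from the generated BMI and height rather than
sampled; the fatty liver index is never generated, always computed
downstream from Tg/BMI/GGT/waist.

Dysglycemia subgroups (IFG / IGT / newly discovered DM) are induced after
copula sampling by overwriting the OGTT glucose values of a randomly chosen
fraction of records, matching the published prevalences per age group.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DomainError

#: 75th-percentile standard-normal quantile used to invert median/IQR reporting
Z75 = 0.6744897501960817

EIG_FLOOR = 1e-6


@dataclass(frozen=True)
class MarginalSpec:
    """One variable's marginal distribution.

    ``family='normal'``: mean/sd, optionally truncated below at
    ``lower_bound``. ``family='lognormal'``: parameterized by the reported
    median and quartiles (see :func:`lognormal_from_quartiles`).
    """

    name: str
    family: str
    mean: Optional[float] = None
    sd: Optional[float] = None
    median: Optional[float] = None
    q1: Optional[float] = None
    q3: Optional[float] = None
    lower_bound: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family == "normal":
            if self.mean is None or self.sd is None or not self.sd > 0:
                raise ConfigError(f"{self.name}: normal marginal needs mean and sd > 0")
            if self.lower_bound is not None and self.lower_bound >= self.mean:
                raise ConfigError(f"{self.name}: truncation floor must lie below the mean")
        elif self.family == "lognormal":
            lognormal_from_quartiles(self.median, self.q1, self.q3)  # validates
        else:
            raise ConfigError(f"{self.name}: unknown family {self.family!r}")

    def mu_sigma(self) -> Tuple[float, float]:
        if self.family != "lognormal":
            raise ConfigError(f"{self.name} is not lognormal")
        return lognormal_from_quartiles(self.median, self.q1, self.q3)

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Quantile function, truncation floor included."""
        if self.family == "normal":
            if self.lower_bound is not None:
                a = (self.lower_bound - self.mean) / self.sd
                return stats.truncnorm.ppf(u, a, np.inf, loc=self.mean, scale=self.sd)
            return stats.norm.ppf(u, loc=self.mean, scale=self.sd)
        mu, sigma = self.mu_sigma()
        x = np.exp(mu + sigma * stats.norm.ppf(u))
        if self.lower_bound is not None:
            x = np.maximum(x, self.lower_bound)
        return x

    def theoretical_mean_sd(self) -> Tuple[float, float]:
        """Mean and SD of the marginal actually sampled (truncation included)."""
        if self.family == "normal":
            if self.lower_bound is not None:
                a = (self.lower_bound - self.mean) / self.sd
                m, v = stats.truncnorm.stats(a, np.inf, loc=self.mean, scale=self.sd,
                                             moments="mv")
                return float(m), float(np.sqrt(v))
            return self.mean, self.sd
        mu, sigma = self.mu_sigma()
        m = np.exp(mu + sigma**2 / 2)
        v = (np.exp(sigma**2) - 1) * np.exp(2 * mu + sigma**2)
        return float(m), float(np.sqrt(v))


def lognormal_from_quartiles(median: float, q1: float, q3: float) -> Tuple[float, float]:
    """Invert median (Q1–Q3) reporting to log-normal (mu, sigma).

    mu = ln(median); sigma = (ln Q3 − ln Q1) / (2·z₀.₇₅). The implied
    distribution reproduces the three input quartiles exactly.
    """
    if median is None or q1 is None or q3 is None:
        raise ConfigError("lognormal marginal needs median, q1 and q3")
    if not (0 < q1 <= median <= q3):
        raise DomainError(
            f"quartiles must satisfy 0 < q1 <= median <= q3, got ({q1}, {median}, {q3})"
        )
    mu = float(np.log(median))
    sigma = float((np.log(q3) - np.log(q1)) / (2.0 * Z75))
    return mu, sigma


@dataclass
class GeneratorConfig:
    n: int
    seed: int
    marginals: List[MarginalSpec]
    correlation: np.ndarray  # latent Gaussian scale, aligned with `marginals`
    sex_ratio: float = 0.5  # fraction male
    age_range: Tuple[float, float] = (16.0, 75.0)
    age_group: str = "older"
    ifg_fraction: float = 0.0
    igt_fraction: float = 0.0
    dm_fraction: float = 0.0
    lipid_therapy_fraction: float = 0.0
    antihypertensive_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ConfigError("n must be non-negative")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ConfigError("sex_ratio must lie in [0, 1]")
        fracs = (self.ifg_fraction, self.igt_fraction, self.dm_fraction)
        if any(f < 0 or f > 1 for f in fracs) or sum(fracs) >= 1.0 + 1e-12:
            raise ConfigError("subgroup fractions must lie in [0,1] and sum below 1")
        self.correlation = np.asarray(self.correlation, dtype=float)
        k = len(self.marginals)
        if self.correlation.shape != (k, k):
            raise ConfigError(
                f"correlation must be {k}x{k} to match the {k} marginals"
            )

    @property
    def variable_names(self) -> List[str]:
        return [m.name for m in self.marginals]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["correlation"] = self.correlation.tolist()
        return d


def repair_correlation(matrix: np.ndarray) -> np.ndarray:
    """Nearest-PD adjustment: clip eigenvalues at a small floor, rescale to
    unit diagonal. Idempotent on already-positive-definite input."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise DomainError("correlation matrix must be square")
    if not np.allclose(m, m.T, atol=1e-10):
        raise DomainError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(m), 1.0, atol=1e-10):
        raise DomainError("correlation matrix must have unit diagonal")
    w, v = np.linalg.eigh(m)
    if w.min() > EIG_FLOOR:
        return m.copy()
    w_clipped = np.clip(w, EIG_FLOOR, None)
    repaired = (v * w_clipped) @ v.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return (repaired + repaired.T) / 2.0


# ---------------------------------------------------------------------------
# default configuration transcribed from the published group summaries

# (name, family, young params, older params, floor)
# normal rows: (mean, sd); lognormal rows: (median, q1, q3)
_DEFAULT_MARGINALS: List[tuple] = [
    ("height", "normal", (173.1, 9.0), (169.7, 9.0), 120.0),
    ("bmi", "normal", (33.35, 7.07), (33.18, 6.85), 12.0),
    ("waist", "normal", (104.0, 17.7), (104.6, 15.4), 55.0),
    ("sbp", "normal", (124.8, 14.9), (130.9, 17.4), 80.0),
    ("dbp", "normal", (81.6, 10.5), (84.7, 11.9), 45.0),
    ("cholesterol", "normal", (5.1, 1.1), (6.1, 1.2), 2.0),
    ("hdl", "normal", (1.2, 0.4), (1.3, 0.3), 0.4),
    ("ldl", "normal", (3.2, 0.9), (3.8, 1.2), 1.0),
    ("triglycerides", "lognormal", (1.39, 1.05, 2.05), (1.70, 1.24, 2.35), None),
    ("glucose_0", "normal", (4.9, 0.7), (5.2, 1.1), 2.5),
    ("glucose_30", "normal", (7.4, 1.5), (8.2, 1.9), 3.0),
    ("glucose_120", "normal", (4.9, 1.3), (5.4, 2.5), 2.2),
    ("insulin_0", "lognormal", (22.6, 17.5, 35.3), (18.3, 13.2, 25.7), None),
    ("insulin_30", "lognormal", (86.5, 47.0, 149.2), (60.3, 39.3, 102.0), None),
    ("insulin_120", "lognormal", (26.75, 17.30, 67.90), (27.15, 17.0, 51.05), None),
    ("hba1c", "normal", (5.17, 0.48), (5.60, 0.77), 3.5),
    ("crp", "lognormal", (4.4, 2.2, 7.3), (3.5, 1.9, 7.2), None),
    ("urea", "normal", (4.3, 1.1), (4.9, 1.3), 1.5),
    ("creatinine", "normal", (83.4, 23.5), (80.9, 16.9), 30.0),
    ("creatinine_clearance", "normal", (124.1, 50.0), (113.3, 51.4), 20.0),
    ("microalbuminuria", "lognormal", (37.9, 9.2, 47.8), (17.85, 8.80, 56.3), None),
    ("alt", "lognormal", (26.0, 18.0, 40.0), (23.0, 18.0, 32.0), None),
    ("ast", "lognormal", (21.0, 18.0, 28.0), (21.0, 18.0, 24.0), None),
    ("ggt", "lognormal", (24.0, 16.0, 33.0), (23.0, 16.0, 32.0), None),
    ("uric_acid", "normal", (337.0, 90.6), (316.2, 82.4), 100.0),
    ("homocysteine", "normal", (11.3, 3.6), (12.7, 3.5), 3.0),
    ("pai1", "normal", (6.4, 1.3), (5.8, 1.8), 1.0),
]

#: default latent correlations — qualitative directions at moderate magnitude
DEFAULT_CORRELATIONS: List[Tuple[str, str, float]] = [
    ("bmi", "waist", 0.6),
    ("height", "waist", 0.15),
    ("waist", "insulin_0", 0.35), ("waist", "insulin_30", 0.3), ("waist", "insulin_120", 0.3),
    ("bmi", "insulin_0", 0.35), ("bmi", "insulin_30", 0.3), ("bmi", "insulin_120", 0.3),
    ("waist", "glucose_0", 0.25), ("bmi", "glucose_0", 0.25),
    ("waist", "triglycerides", 0.3), ("bmi", "triglycerides", 0.3),
    ("waist", "hdl", -0.3), ("bmi", "hdl", -0.3),
    ("waist", "sbp", 0.3), ("waist", "dbp", 0.25),
    ("bmi", "sbp", 0.3), ("bmi", "dbp", 0.25),
    ("sbp", "dbp", 0.6),
    ("cholesterol", "ldl", 0.8), ("cholesterol", "triglycerides", 0.3),
    ("cholesterol", "hdl", 0.15), ("ldl", "triglycerides", 0.2),
    ("triglycerides", "hdl", -0.35), ("triglycerides", "ggt", 0.3),
    ("triglycerides", "alt", 0.25), ("triglycerides", "uric_acid", 0.25),
    ("triglycerides", "pai1", 0.25),
    ("hdl", "insulin_0", -0.25), ("hdl", "uric_acid", -0.2), ("hdl", "pai1", -0.2),
    ("glucose_0", "glucose_30", 0.5), ("glucose_0", "glucose_120", 0.45),
    ("glucose_30", "glucose_120", 0.5),
    ("glucose_0", "hba1c", 0.5), ("glucose_120", "hba1c", 0.4), ("glucose_30", "hba1c", 0.35),
    ("glucose_0", "insulin_0", 0.3), ("glucose_30", "insulin_30", 0.3),
    ("glucose_120", "insulin_120", 0.3),
    ("insulin_0", "insulin_30", 0.6), ("insulin_0", "insulin_120", 0.55),
    ("insulin_30", "insulin_120", 0.6),
    ("insulin_0", "crp", 0.2), ("waist", "crp", 0.3), ("bmi", "crp", 0.3),
    ("alt", "ast", 0.6), ("alt", "ggt", 0.5), ("ast", "ggt", 0.4),
    ("alt", "insulin_0", 0.25), ("ggt", "insulin_0", 0.2),
    ("alt", "waist", 0.25), ("ggt", "waist", 0.25),
    ("uric_acid", "waist", 0.25), ("uric_acid", "insulin_0", 0.25),
    ("homocysteine", "sbp", 0.2), ("homocysteine", "creatinine", 0.3),
    ("urea", "creatinine", 0.4), ("creatinine", "creatinine_clearance", -0.4),
    ("microalbuminuria", "glucose_0", 0.2), ("microalbuminuria", "sbp", 0.2),
    ("pai1", "waist", 0.25), ("pai1", "insulin_0", 0.25),
]

#: published dysglycemia prevalences per age group
_GROUP_FRACTIONS = {
    "young": {"ifg_fraction": 0.024, "igt_fraction": 0.048, "dm_fraction": 0.0},
    "older": {"ifg_fraction": 0.014, "igt_fraction": 0.018, "dm_fraction": 0.057},
}
_GROUP_N = {"young": 167, "older": 284}
_GROUP_AGE_RANGE = {"young": (16.0, 30.0), "older": (31.0, 75.0)}
# therapy prevalences are not published; modest age-dependent assumptions
_GROUP_THERAPY = {
    "young": {"lipid_therapy_fraction": 0.02, "antihypertensive_fraction": 0.03},
    "older": {"lipid_therapy_fraction": 0.10, "antihypertensive_fraction": 0.15},
}


def default_marginals(age_group: str) -> List[MarginalSpec]:
    if age_group not in ("young", "older"):
        raise ConfigError(f"age_group must be 'young' or 'older', got {age_group!r}")
    idx = 0 if age_group == "young" else 1
    specs = []
    for name, family, young, older, floor in _DEFAULT_MARGINALS:
        params = (young, older)[idx]
        if family == "normal":
            specs.append(MarginalSpec(name, "normal", mean=params[0], sd=params[1],
                                      lower_bound=floor))
        else:
            specs.append(MarginalSpec(name, "lognormal", median=params[0], q1=params[1],
                                      q3=params[2], lower_bound=floor))
    return specs


def build_correlation(
    names: Sequence[str],
    pairs: Sequence[Tuple[str, str, float]] = DEFAULT_CORRELATIONS,
) -> np.ndarray:
    """Assemble (and PD-repair) a latent correlation matrix from sparse pairs."""
    index = {n: i for i, n in enumerate(names)}
    m = np.eye(len(names))
    for a, b, rho in pairs:
        if a in index and b in index:
            m[index[a], index[b]] = m[index[b], index[a]] = rho
    return repair_correlation(m)


def default_config(age_group: str, n: Optional[int] = None, seed: int = 0) -> GeneratorConfig:
    """Generator configuration transcribed from the published age-group column."""
    marginals = default_marginals(age_group)
    cfg = GeneratorConfig(
        n=_GROUP_N[age_group] if n is None else n,
        seed=seed,
        marginals=marginals,
        correlation=build_correlation([m.name for m in marginals]),
        sex_ratio=0.5,
        age_range=_GROUP_AGE_RANGE[age_group],
        age_group=age_group,
        **_GROUP_FRACTIONS[age_group],
        **_GROUP_THERAPY[age_group],
    )
    return cfg


def generate_cohort(config: GeneratorConfig, id_prefix: str = "S") -> pd.DataFrame:
    """Draw a cohort of ``config.n`` records as a raw-measurement table.

    Deterministic for a given config (seed included); derived scores and
    labels are *not* attached here — use :func:`simscore.scores.score_dataframe`
    and :func:`simscore.classify.classify_dataframe`.
    """
    names = config.variable_names
    corr = repair_correlation(config.correlation)
    w = np.linalg.eigvalsh(corr)
    if w.min() <= 0:
        raise ConfigError("correlation matrix is not positive definite after repair")

    rng = np.random.default_rng(config.seed)
    k = len(names)
    z = rng.multivariate_normal(np.zeros(k), corr, size=config.n, method="cholesky")
    u = stats.norm.cdf(z)
    # keep uniforms strictly inside (0,1)
    u = np.clip(u, 1e-12, 1 - 1e-12)

    data: Dict[str, np.ndarray] = {}
    for j, spec in enumerate(config.marginals):
        data[spec.name] = spec.ppf(u[:, j])

    df = pd.DataFrame(data)
    df.insert(0, "id", [f"{id_prefix}{i:05d}" for i in range(config.n)])
    sex = np.where(rng.random(config.n) < config.sex_ratio, "male", "female")
    df.insert(1, "sex", sex)
    lo, hi = config.age_range
    df.insert(2, "age", np.round(rng.uniform(lo, hi + 1.0, size=config.n) - 0.5).clip(lo, hi))

    # weight follows from generated BMI and height
    if "bmi" in df.columns and "height" in df.columns:
        df["weight"] = df["bmi"] * (df["height"] / 100.0) ** 2

    df["on_lipid_therapy"] = rng.random(config.n) < config.lipid_therapy_fraction
    df["on_antihypertensive_therapy"] = rng.random(config.n) < config.antihypertensive_fraction
    df["known_dm2"] = False

    _induce_dysglycemia(df, config, rng)
    return df


def _induce_dysglycemia(df: pd.DataFrame, config: GeneratorConfig,
                        rng: np.random.Generator) -> None:
    """Overwrite OGTT glucose for randomly chosen disjoint subsets so the
    cohort carries the configured IFG / IGT / newly-discovered-DM fractions.

    IGT members also receive a moderately elevated fasting glucose
    (dysglycemia co-occurs across the OGTT curve), which is what makes their
    siMS scores exceed the normoglycemic background on average.
    """
    n = len(df)
    fractions = (config.ifg_fraction, config.igt_fraction, config.dm_fraction)
    total = sum(fractions)
    if n == 0 or total <= 0:
        return
    counts = [int(round(f * n)) for f in fractions]
    if sum(counts) > n:
        raise ConfigError("subgroup fractions exceed cohort size")
    chosen = rng.permutation(n)[: sum(counts)]
    i0 = 0
    subsets = []
    for c in counts:
        subsets.append(chosen[i0 : i0 + c])
        i0 += c
    ifg_idx, igt_idx, dm_idx = subsets

    if "glucose_0" in df.columns and "glucose_120" in df.columns:
        g0 = df["glucose_0"].to_numpy(copy=True)
        g120 = df["glucose_120"].to_numpy(copy=True)
        g0[ifg_idx] = rng.uniform(5.6, 6.9, size=len(ifg_idx))
        g120[ifg_idx] = np.minimum(g120[ifg_idx], 7.7)
        g0[igt_idx] = rng.uniform(5.2, 6.9, size=len(igt_idx))
        g120[igt_idx] = rng.uniform(7.8, 11.0, size=len(igt_idx))
        g0[dm_idx] = rng.uniform(7.0, 10.0, size=len(dm_idx))
        g120[dm_idx] = rng.uniform(11.1, 18.0, size=len(dm_idx))
        df["glucose_0"] = g0
        df["glucose_120"] = g120
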