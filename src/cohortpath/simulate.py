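"""Synthetic longitudinal attainment cohorts with known generating truth.

Emulates the statistical structure of selection-based educational cohorts:

* a latent multivariate-normal "simplex" of stage scores, where the
  correlation between stages i and k is the product of the lag-1
  correlations in between (the signature of a stage-wise causal chain);
* selection of entrants on an early stage score, producing restriction of
  range in the selected group;
* imperfect observation of each stage — measurement noise, ceiling
  censoring of grade points (a configurable fraction piled at the maximum),
  ordinal grouping with stated category proportions, or a binary end-state;
* outcome-dependent uptake of later examinations: the probability of
  attempting a post-graduate exam rises with earlier latent attainment, so
  later columns are missing not-at-random.

Every draw flows from a single seed, and the generating truth (latent
correlation matrix, selection rule, censoring points, thresholds, uptake
coefficients) is retained alongside the table so estimators can be scored
against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .latentcorr import VariableSpec

__all__ = [
    "StageObservation",
    "SyntheticConfig",
    "SyntheticTruth",
    "simplex_correlation",
    "generate_latent",
    "apply_selection",
    "observe_stage",
    "apply_uptake",
    "generate_cohort",
    "uclms_like",
    "cohort_1990_like",
]


@dataclass(frozen=True)
class StageObservation:
    """How one latent stage score is recorded.

    mode ``continuous``: optional Gaussian measurement noise, parameterised
    by ``reliability`` (variance share of the latent signal in the observed
    score; 1.0 means noise-free).
    mode ``ceiling``: values above the ``ceiling_quantile`` of the observed
    column are recorded at the ceiling value and flagged censored.
    mode ``ordinal``: categories 1..K cut at the cumulative ``proportions``.
    mode ``binary``: one threshold at 1 - ``prevalence``.
    """

    mode: str = "continuous"
    reliability: float = 1.0
    ceiling_quantile: float | None = None
    proportions: tuple[float, ...] | None = None
    prevalence: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("continuous", "ceiling", "ordinal", "binary"):
            raise ValueError(f"unknown observation mode {self.mode!r}")
        if not 0.0 < self.reliability <= 1.0:
            raise ValueError("reliability must be in (0, 1]")
        if self.mode == "ceiling" and not (self.ceiling_quantile and 0 < self.ceiling_quantile < 1):
            raise ValueError("ceiling mode needs ceiling_quantile in (0, 1)")
        if self.mode == "ordinal":
            if not self.proportions or len(self.proportions) < 3:
                raise ValueError("ordinal mode needs >= 3 category proportions")
            if abs(sum(self.proportions) - 1.0) > 1e-8:
                raise ValueError(f"proportions must sum to 1, got {sum(self.proportions)}")
        if self.mode == "binary" and not (self.prevalence and 0 < self.prevalence < 1):
            raise ValueError("binary mode needs prevalence in (0, 1)")


@dataclass(frozen=True)
class Uptake:
    """Logistic exam-uptake model: P(attempt stage) =
    expit(intercept + slope * latent score at ``on_stage``)."""

    stage: str
    on_stage: str
    intercept: float
    slope: float


@dataclass
class SyntheticConfig:
    n_applicants: int = 2000
    stages: list[str] = field(default_factory=lambda: ["stage1", "stage2", "stage3"])
    lag1: list[float] | None = None          # simplex lag-1 correlations
    corr_matrix: np.ndarray | None = None    # or an explicit PD matrix
    selection_stage: str | None = None
    selected_fraction: float = 1.0
    selection_mode: str = "truncation"       # or "logistic"
    observation: dict[str, StageObservation] = field(default_factory=dict)
    uptake: list[Uptake] = field(default_factory=list)
    covariate_effects: dict[str, float] | None = None  # per-stage mean shift
    covariate_prevalence: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lag1 is None and self.corr_matrix is None:
            self.lag1 = [0.6] * (len(self.stages) - 1)
        if self.lag1 is not None:
            if len(self.lag1) != len(self.stages) - 1:
                raise ValueError("need one lag-1 correlation per adjacent stage pair")
            if any(abs(r) >= 1 for r in self.lag1):
                raise ValueError("lag-1 correlations must lie in (-1, 1)")
        if not 0.0 < self.selected_fraction <= 1.0:
            raise ValueError("selected fraction must be in (0, 1]")
        if self.selection_stage is not None and self.selection_stage not in self.stages:
            raise ValueError(f"unknown selection stage {self.selection_stage!r}")


@dataclass
class SyntheticTruth:
    """Everything needed to score an estimator against the generator."""

    corr_matrix: np.ndarray
    stages: list[str]
    selection_stage: str | None
    selected_fraction: float
    censoring_points: dict[str, float]
    thresholds: dict[str, np.ndarray]
    uptake: list[Uptake]
    seed: int

    def latent_corr(self, a: str, b: str) -> float:
        i, j = self.stages.index(a), self.stages.index(b)
        return float(self.corr_matrix[i, j])

    def to_dict(self) -> dict:
        return {
            "corr_matrix": self.corr_matrix.tolist(),
            "stages": self.stages,
            "selection_stage": self.selection_stage,
            "selected_fraction": self.selected_fraction,
            "censoring_points": self.censoring_points,
            "thresholds": {k: list(map(float, v)) for k, v in self.thresholds.items()},
            "uptake": [
                {"stage": u.stage, "on_stage": u.on_stage,
                 "intercept": u.intercept, "slope": u.slope}
                for u in self.uptake
            ],
            "seed": self.seed,
        }


def simplex_correlation(lag1: list[float]) -> np.ndarray:
    """Correlation matrix with corr(i, j) = product of intervening lag-1
    values — the simplex structure of a stage-wise Markov chain."""
    k = len(lag1) + 1
    m = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            m[i, j] = m[j, i] = float(np.prod(lag1[i:j]))
    return m


def generate_latent(config: SyntheticConfig) -> pd.DataFrame:
    """Draw applicant latent stage scores from the configured MVN."""
    if config.corr_matrix is not None:
        m = np.asarray(config.corr_matrix, dtype=float)
        try:
            chol = np.linalg.cholesky(m)
        except np.linalg.LinAlgError:
            raise ValueError("supplied correlation matrix is not positive definite") from None
    else:
        m = simplex_correlation(config.lag1)
        chol = np.linalg.cholesky(m)
    rng = np.random.default_rng(config.seed)
    z = rng.standard_normal((config.n_applicants, len(config.stages))) @ chol.T
    df = pd.DataFrame(z, columns=config.stages)
    if config.covariate_effects:
        group = (rng.uniform(size=config.n_applicants) < config.covariate_prevalence).astype(int)
        df["group"] = group
        for stage, shift in config.covariate_effects.items():
            df[stage] += shift * group
    return df


def apply_selection(latent: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """Keep entrants: top fraction on the selection stage (deterministic
    truncation, the default) or logistic selection on the same score.

    The applicant index is preserved on the returned subset, so membership
    in the entrant frame is the applicant flag.
    """
    if config.selection_stage is None or config.selected_fraction == 1.0:
        return latent.copy()
    score = latent[config.selection_stage]
    if config.selection_mode == "truncation":
        cut = score.quantile(1.0 - config.selected_fraction)
        keep = (score >= cut).to_numpy()
    elif config.selection_mode == "logistic":
        # slope 2 on the standardised score; intercept set so the expected
        # acceptance rate matches the requested fraction
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
        icpt = _calibrate_intercept(2.0, config.selected_fraction)
        keep = rng.uniform(size=len(score)) < expit(icpt + 2.0 * score.to_numpy())
    else:
        raise ValueError(f"unknown selection mode {config.selection_mode!r}")
    return latent[keep].copy()


def observe_stage(
    latent: pd.Series,
    spec: StageObservation,
    name: str,
    rng: np.random.Generator,
    causal_order: int = 0,
) -> tuple[pd.Series, VariableSpec, dict]:
    """Record one latent column under its observation model.

    Returns (observed column, VariableSpec for downstream estimation,
    truth fragment with censoring point / thresholds actually used).
    """
    x = latent.to_numpy(dtype=float).copy()
    if spec.reliability < 1.0:
        noise_sd = math.sqrt(1.0 / spec.reliability - 1.0) * np.nanstd(x)
        x = x + rng.standard_normal(x.size) * noise_sd
    truth: dict = {}
    if spec.mode == "continuous":
        vspec = VariableSpec(name, "continuous", causal_order=causal_order)
        return pd.Series(x, index=latent.index), vspec, truth
    if spec.mode == "ceiling":
        c = float(np.nanquantile(x, spec.ceiling_quantile))
        x = np.minimum(x, c)
        vspec = VariableSpec(name, "censored_continuous", ceiling=c, causal_order=causal_order)
        truth["censoring_point"] = c
        return pd.Series(x, index=latent.index), vspec, truth
    if spec.mode == "ordinal":
        cum = np.cumsum(spec.proportions)[:-1]
        cuts = np.nanquantile(x, cum)
        cats = np.searchsorted(cuts, x) + 1.0
        vspec = VariableSpec(
            name, "ordinal", n_categories=len(spec.proportions), causal_order=causal_order
        )
        truth["thresholds"] = cuts
        return pd.Series(cats, index=latent.index), vspec, truth
    # binary
    cut = float(np.nanquantile(x, 1.0 - spec.prevalence))
    vspec = VariableSpec(name, "binary", causal_order=causal_order)
    truth["thresholds"] = np.array([cut])
    return pd.Series((x >= cut).astype(float) + 1.0, index=latent.index), vspec, truth


def _calibrate_intercept(
    slope: float,
    target_rate: float,
    rho_sel: float = 0.0,
    sel_fraction: float = 1.0,
) -> float:
    """Intercept of a logistic uptake model so the marginal attempt rate
    equals ``target_rate`` among entrants.

    The conditioning score among entrants is not standard normal when the
    cohort was selected on an earlier correlated stage: with selection on
    the top ``sel_fraction`` of a stage correlated ``rho_sel`` with the
    conditioning score, the score decomposes as rho*S + sqrt(1-rho^2)*eps
    with S truncated normal.  The expected rate is evaluated by
    Gauss–Legendre over the truncated selection score and Gauss–Hermite
    over the independent part, then inverted by bisection.
    """
    gh_nodes, gh_w = np.polynomial.hermite_e.hermegauss(40)
    gh_w = gh_w / gh_w.sum()
    if sel_fraction < 1.0 and rho_sel != 0.0:
        q = norm.ppf(1.0 - sel_fraction)
        # Gauss-Legendre on the truncated normal for the selection score
        gl_x, gl_w = np.polynomial.legendre.leggauss(80)
        hi = 8.0
        s = q + (gl_x + 1.0) * (hi - q) / 2.0
        dens = norm.pdf(s) * (hi - q) / 2.0 * gl_w
        dens = dens / dens.sum()
        resid = math.sqrt(max(1.0 - rho_sel**2, 0.0))

        def rate(icpt: float) -> float:
            grid = icpt + slope * (rho_sel * s[:, None] + resid * gh_nodes[None, :])
            return float(dens @ (expit(grid) @ gh_w))

    else:

        def rate(icpt: float) -> float:
            return float(np.sum(gh_w * expit(icpt + slope * gh_nodes)))

    lo, hi = -20.0, 20.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if rate(mid) < target_rate:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def apply_uptake(
    table: pd.DataFrame,
    latent: pd.DataFrame,
    uptake: list[Uptake],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Mask later-stage observations for individuals who did not attempt
    the exam; attempt probability is logistic in the earlier latent score."""
    out = table.copy()
    stages = list(table.columns)
    for u in uptake:
        if stages.index(u.on_stage) >= stages.index(u.stage):
            raise ValueError(f"uptake for {u.stage!r} must depend on an earlier stage")
        p = expit(u.intercept + u.slope * latent[u.on_stage].to_numpy())
        attempted = rng.uniform(size=len(out)) < p
        out.loc[~attempted, u.stage] = np.nan
        out[f"{u.stage}_attempted"] = attempted
    return out


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, dict[str, VariableSpec], SyntheticTruth]:
    """Full generator: latent draws -> selection -> observation -> uptake.

    Returns the entrant cohort table, the per-column measurement specs
    consumed by the estimators, and the retained generating truth.
    """
    latent_all = generate_latent(config)
    entrants = apply_selection(latent_all, config)
    latent_cols = entrants[config.stages]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    observed = {}
    specs: dict[str, VariableSpec] = {}
    censoring: dict[str, float] = {}
    thresholds: dict[str, np.ndarray] = {}
    for i, stage in enumerate(config.stages):
        ospec = config.observation.get(stage, StageObservation())
        col, vspec, truth = observe_stage(latent_cols[stage], ospec, stage, rng, causal_order=i)
        observed[stage] = col
        specs[stage] = vspec
        if "censoring_point" in truth:
            censoring[stage] = truth["censoring_point"]
        if "thresholds" in truth:
            thresholds[stage] = truth["thresholds"]
    table = pd.DataFrame(observed)
    table = apply_uptake(table, latent_cols, config.uptake, rng)
    if "group" in entrants.columns:
        table["group"] = entrants["group"].to_numpy()

    m = (
        np.asarray(config.corr_matrix, dtype=float)
        if config.corr_matrix is not None
        else simplex_correlation(config.lag1)
    )
    truth_rec = SyntheticTruth(
        corr_matrix=m,
        stages=list(config.stages),
        selection_stage=config.selection_stage,
        selected_fraction=config.selected_fraction,
        censoring_points=censoring,
        thresholds=thresholds,
        uptake=list(config.uptake),
        seed=config.seed,
    )
    return table, specs, truth_rec


# ---------------------------------------------------------------------------
# preset cohorts

def uclms_like(n_entrants: int = 729, seed: int = 0) -> SyntheticConfig:
    """A modern-cohort preset: entrants only, heavy A-level ceiling (62.5%
    at the maximum), five z-scored undergraduate years collapsed to two
    composites, and post-graduate exam uptake of about 34.6% that rises
    with undergraduate attainment."""
    stages = ["gcse", "alevel", "bms", "clinical", "mrcp_part1"]
    return SyntheticConfig(
        n_applicants=2 * n_entrants,
        stages=stages,
        lag1=[0.7, 0.55, 0.65, 0.55],
        selection_stage="alevel",
        selected_fraction=0.5,
        observation={
            "gcse": StageObservation("ceiling", reliability=0.9, ceiling_quantile=0.7),
            "alevel": StageObservation("ceiling", reliability=0.9, ceiling_quantile=0.375),
            "bms": StageObservation("continuous", reliability=0.9),
            "clinical": StageObservation("continuous", reliability=0.9),
            "mrcp_part1": StageObservation("continuous", reliability=0.85),
        },
        uptake=[
            Uptake(
                "mrcp_part1", "clinical",
                # selection on alevel correlates 0.55*0.65 with clinical
                intercept=_calibrate_intercept(
                    0.75, 0.346, rho_sel=0.55 * 0.65, sel_fraction=0.5
                ),
                slope=0.75,
            )
        ],
        seed=seed,
    )


def cohort_1990_like(n_applicants: int = 6901, seed: int = 0) -> SyntheticConfig:
    """A selection-era preset: applicant pool with ~48% entering, censored
    O-level/GCSE and A-level points, a 4-category ordinal pre-clinical
    outcome with proportions (11.7, 53.3, 28.3, 6.7)%, and a binary
    specialist-register end state."""
    stages = ["olevel_gcse", "alevel", "bms_outcome", "finals", "register"]
    return SyntheticConfig(
        n_applicants=n_applicants,
        stages=stages,
        lag1=[0.65, 0.5, 0.6, 0.45],
        selection_stage="alevel",
        selected_fraction=0.483,
        observation={
            "olevel_gcse": StageObservation("ceiling", reliability=0.9, ceiling_quantile=0.85),
            "alevel": StageObservation("ceiling", reliability=0.9, ceiling_quantile=0.787),
            "bms_outcome": StageObservation(
                "ordinal", proportions=(0.067, 0.283, 0.533, 0.117)
            ),
            "finals": StageObservation("continuous", reliability=0.9),
            "register": StageObservation("binary", prevalence=0.554),
        },
        seed=seed,
    )
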