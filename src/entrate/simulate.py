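"""Synthetic interaction sessions and dyad cohorts.

Two generators make every downstream stage testable without observational
data:

* **Sessions** — state paths from a one-parameter family of transition
  matrices ``P = (1 - alpha) * C + alpha * U`` (``C`` a deterministic
  cycle, ``U`` uniform off-diagonal), converted to per-channel signal
  events with exponential dwell times.  ``alpha`` sweeps the true entropy
  rate continuously from 0 to ``log2(k - 1)``.
* **Cohorts** — dyad tables whose marginal moments, covariate–outcome
  correlations, sex effect size and sex-specific exposure–outcome slopes
  are calibrated analytically to configurable targets, defaulting to the
  distributional structure typical of mother–child free-play cohorts
  (entropy rate ≈ .89 ± .17 bits; child effortful control ≈ 5.46 ± .74 on
  a 1–7 scale; sex difference d ≈ .62; male-specific exposure slope
  r ≈ −.289 vs female r ≈ −.007).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .events import CHANNELS, N_STATES, SessionRecord, SignalEvent
from .markov import TransitionModel

__all__ = [
    "SessionSimConfig",
    "CohortSimConfig",
    "CovariateSpec",
    "COHORT_COLUMNS",
    "make_generator_matrix",
    "generator_entropy",
    "simulate_state_path",
    "simulate_session",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
]


@dataclass(frozen=True)
class SessionSimConfig:
    """Parameters of one simulated coded session.

    ``alpha`` mixes a deterministic cycle (0 → perfectly predictable) with
    the uniform off-diagonal kernel (1 → maximally unpredictable); the
    generator entropy is continuous and nondecreasing in ``alpha``.
    """

    alpha: float
    n_transitions: int
    n_states: int = N_STATES
    mean_dwell: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if self.n_transitions < 1:
            raise ValueError("n_transitions must be >= 1")
        if self.mean_dwell <= 0:
            raise ValueError("mean_dwell must be > 0")


@dataclass(frozen=True)
class CovariateSpec:
    """One continuous dyad covariate: truncated-normal marginal + target r."""

    mean: float
    sd: float
    lower: float
    upper: float
    r_outcome: float = 0.0


#: Default covariate marginals (means/SDs and theoretical ranges of the
#: scales) and their target correlations with the child outcome.
DEFAULT_COVARIATES: dict[str, CovariateSpec] = {
    "economic_satisfaction": CovariateSpec(6.15, 2.31, 0.0, 10.0, 0.126),
    "maternal_ec": CovariateSpec(4.64, 0.76, 1.0, 7.0, 0.136),
    "maternal_sensitivity": CovariateSpec(5.34, 1.40, 1.0, 7.0, 0.128),
    "maternal_anxiety": CovariateSpec(4.63, 5.81, 0.0, 40.0, 0.0),
    "maternal_depression": CovariateSpec(5.19, 4.97, 0.0, 30.0, 0.0),
}

COHORT_COLUMNS = [
    "dyad_id",
    "entropy_rate",
    "economic_satisfaction",
    "maternal_ec",
    "maternal_sensitivity",
    "maternal_anxiety",
    "maternal_depression",
    "child_sex",
    "child_ec",
]


@dataclass(frozen=True)
class CohortSimConfig:
    """Calibration targets for a synthetic dyad cohort.

    The outcome (child effortful control, 1–7) is generated as

    ``y = mu_sex + b_sex * (H - mu_H) + sum_j c_j * z_j + eps_sex``

    with entropy exposure ``H`` truncated-normal on [0, 2.807],
    standardized covariates ``z_j`` mutually independent, slopes
    ``b_sex = r_sex * sigma_w / sigma_H`` chosen so the sex-stratified
    exposure–outcome correlations hit ``male_slope_r`` / ``female_slope_r``
    at large n, loadings ``c_j = r_j * outcome_sd`` hitting the marginal
    covariate correlations, and sex means separated by
    ``sex_effect_d * sigma_w`` (females higher).  ``sigma_w`` is the
    within-sex outcome SD implied by the marginal ``outcome_sd`` and the
    sex effect.  Residual variances are solved per sex; a negative
    solution means the requested correlation structure is not positive
    semi-definite and raises at construction.
    """

    n_dyads: int
    entropy_mean: float = 0.89
    entropy_sd: float = 0.17
    entropy_bounds: tuple[float, float] = (0.0, 2.807)
    sex_effect_d: float = 0.62
    male_slope_r: float = -0.289
    female_slope_r: float = -0.007
    outcome_mean: float = 5.46
    outcome_sd: float = 0.74
    outcome_bounds: tuple[float, float] = (1.0, 7.0)
    p_female: float = 0.474
    covariates: dict[str, CovariateSpec] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dyads < 1:
            raise ValueError("n_dyads must be >= 1")
        if not (0 < self.p_female < 1):
            raise ValueError("p_female must lie in (0, 1)")
        self.solve_structure()  # raises early on a non-PSD target structure

    def solve_structure(self) -> dict:
        """Analytic variance decomposition of the outcome model."""
        p_f = self.p_female
        p_m = 1.0 - p_f
        d = self.sex_effect_d
        sigma_y = self.outcome_sd
        # marginal var = within var + between-sex var: sy^2 = sw^2 (1 + pf pm d^2)
        sigma_w = sigma_y / np.sqrt(1.0 + p_f * p_m * d**2)
        delta = d * sigma_w  # female - male mean difference
        mu_m = self.outcome_mean - p_f * delta
        mu_f = mu_m + delta
        sigma_h = _truncnorm(
            self.entropy_mean, self.entropy_sd, *self.entropy_bounds
        ).std()
        slopes = {
            "male": self.male_slope_r * sigma_w / sigma_h,
            "female": self.female_slope_r * sigma_w / sigma_h,
        }
        loadings = {
            name: spec.r_outcome * sigma_y for name, spec in self.covariates.items()
        }
        c_var = sum(c**2 for c in loadings.values())
        resid = {}
        for sex, r in (("male", self.male_slope_r), ("female", self.female_slope_r)):
            v = sigma_w**2 * (1.0 - r**2) - c_var
            if v <= 0:
                raise ValueError(
                    "target correlation structure is not positive semi-definite: "
                    f"within-{sex} residual variance is {v:.4f} "
                    f"(slope r={r}, covariate loadings absorb {c_var:.4f} "
                    f"of within-sex variance {sigma_w**2:.4f})"
                )
            resid[sex] = float(np.sqrt(v))
        return {
            "sigma_w": float(sigma_w),
            "sigma_h": float(sigma_h),
            "mu_male": float(mu_m),
            "mu_female": float(mu_f),
            "slopes": slopes,
            "loadings": loadings,
            "resid_sd": resid,
        }


def make_generator_matrix(alpha: float, n_states: int = N_STATES) -> TransitionModel:
    """Cycle↔uniform mixture transition model with uniform stationary law.

    ``P = (1 - alpha) * C + alpha * U`` where ``C`` maps each state to its
    cyclic successor and ``U`` is uniform over the ``k - 1`` admissible
    next states.  By symmetry the stationary distribution is uniform, and
    the entropy rate sweeps ``[0, log2(k - 1)]`` as ``alpha`` goes 0 → 1.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    if n_states < 3:
        raise ValueError(
            "n_states must be >= 3: with self-transitions excluded a 2-state "
            "chain is always deterministic"
        )
    k = n_states
    cycle = np.zeros((k, k))
    cycle[np.arange(k), (np.arange(k) + 1) % k] = 1.0
    uniform = (np.ones((k, k)) - np.eye(k)) / (k - 1)
    probs = (1.0 - alpha) * cycle + alpha * uniform
    pi = np.full(k, 1.0 / k)
    return TransitionModel(counts=np.zeros((k, k)), probs=probs, state_dist=pi)


def generator_entropy(alpha: float, n_states: int = N_STATES) -> float:
    """Closed-form entropy rate (bits) of the cycle↔uniform generator."""
    k = n_states
    p_succ = (1.0 - alpha) + alpha / (k - 1)
    p_other = alpha / (k - 1)
    h = 0.0
    for p, m in ((p_succ, 1), (p_other, k - 2)):
        if p > 0:
            h -= m * p * np.log2(p)
    return float(h)


def simulate_state_path(
    probs: np.ndarray, n_transitions: int, rng: np.random.Generator,
    initial: int | None = None,
) -> np.ndarray:
    """Sample a state path of ``n_transitions + 1`` states from a chain."""
    k = probs.shape[0]
    cdf = np.cumsum(probs, axis=1)
    u = rng.random(n_transitions)
    path = np.empty(n_transitions + 1, dtype=np.int64)
    path[0] = rng.integers(k) if initial is None else initial
    s = path[0]
    for t in range(n_transitions):
        s = int(np.searchsorted(cdf[s], u[t], side="right"))
        path[t + 1] = s
    return path


def simulate_session(config: SessionSimConfig) -> SessionRecord:
    """Simulate one coded session from the cycle↔uniform generator.

    A state path is sampled, each state is held for an exponential dwell
    (mean ``mean_dwell`` seconds), and the path is converted back into
    per-channel signal events via the bitmask.  The change-point state
    sequence of the returned session reproduces the sampled path exactly.
    """
    rng = np.random.default_rng(config.seed)
    gen = make_generator_matrix(config.alpha, config.n_states)
    path = simulate_state_path(gen.probs, config.n_transitions, rng)
    dwell = rng.exponential(config.mean_dwell, size=len(path))
    dwell = np.maximum(dwell, 1e-9)
    edges = np.concatenate([[0.0], np.cumsum(dwell)])
    duration = float(edges[-1])
    events = []
    for i, channel in enumerate(CHANNELS):
        on = (path >> i) & 1
        padded = np.concatenate([[0], on, [0]])
        starts = np.flatnonzero(np.diff(padded) == 1)
        stops = np.flatnonzero(np.diff(padded) == -1)
        for a, b in zip(starts, stops):
            events.append(SignalEvent(channel, float(edges[a]), float(edges[b])))
    return SessionRecord(
        session_id=f"sim-a{config.alpha:g}-s{config.seed}",
        duration=duration,
        events=events,
        metadata={
            "alpha": config.alpha,
            "seed": config.seed,
            "true_entropy_bits": generator_entropy(config.alpha, config.n_states),
        },
    )


def _truncnorm(mean: float, sd: float, lower: float, upper: float):
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return stats.truncnorm(a, b, loc=mean, scale=sd)


def simulate_cohort(config: CohortSimConfig) -> pd.DataFrame:
    """Simulate a dyad cohort table calibrated to the configured targets.

    Returns a DataFrame with one row per mother–child pair and columns
    ``dyad_id, entropy_rate, economic_satisfaction, maternal_ec,
    maternal_sensitivity, maternal_anxiety, maternal_depression,
    child_sex, child_ec``.  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_dyads
    sol = config.solve_structure()

    h_dist = _truncnorm(config.entropy_mean, config.entropy_sd, *config.entropy_bounds)
    entropy = h_dist.ppf(rng.random(n))
    female = rng.random(n) < config.p_female
    sex = np.where(female, "female", "male")

    cov_raw: dict[str, np.ndarray] = {}
    cov_std: dict[str, np.ndarray] = {}
    for name, spec in config.covariates.items():
        dist = _truncnorm(spec.mean, spec.sd, spec.lower, spec.upper)
        x = dist.ppf(rng.random(n))
        cov_raw[name] = x
        cov_std[name] = (x - dist.mean()) / dist.std()

    mu = np.where(female, sol["mu_female"], sol["mu_male"])
    b = np.where(female, sol["slopes"]["female"], sol["slopes"]["male"])
    resid_sd = np.where(
        female, sol["resid_sd"]["female"], sol["resid_sd"]["male"]
    )
    y = mu + b * (entropy - h_dist.mean())
    for name in config.covariates:
        y = y + sol["loadings"][name] * cov_std[name]
    y = y + resid_sd * rng.standard_normal(n)
    y = np.clip(y, *config.outcome_bounds)

    df = pd.DataFrame(
        {
            "dyad_id": [f"dyad-{i:06d}" for i in range(n)],
            "entropy_rate": entropy,
            "child_sex": sex,
            "child_ec": y,
            **cov_raw,
        }
    )
    return df[COHORT_COLUMNS]


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort table as delimited text with the fixed header."""
    df.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort table, checking the fixed header."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing cohort column(s) {missing}")
    return df
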