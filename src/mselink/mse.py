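"""Three-list multiple systems estimation by log-linear Poisson models with
Bayesian model averaging.

The observed data are the seven capture-history cell counts x_ijk of a
three-list :class:`~mselink.records.ContingencyTable`. Each candidate model
is a log-linear Poisson model for the cell means,

    log m_ijk = b0 + bi*i + bj*j + bk*k + [pairwise interaction terms],

with an intercept, three list main effects, and any subset of the three
pairwise interactions; the three-way term is inestimable with three lists.
That yields exactly eight hierarchical models, from mutual independence
(no interactions, 3 residual df) to the saturated model (all three pairs,
0 df, perfect fit). Each model predicts the unobserved cell

    m_000 = m_111 m_100 m_010 m_001 / (m_110 m_101 m_011) = exp(b0),

the number of deaths appearing on no list, and the total is
N_hat = n_obs + m_000. Per-model uncertainty comes from the normalized
profile likelihood of m_000 (2.5th/97.5th percentiles); across models the
estimates are averaged with Schwarz (BIC) weights Pr_i ∝ exp(−BIC_i / 2)
under a uniform model prior, with BIC = G² − df·ln(n_obs) so that the
saturated model sits at 0 by construction.

The model-level interface follows the statsmodels convention: build a
:class:`ThreeListMSE` from a table, call :meth:`~ThreeListMSE.fit`, and work
with the returned :class:`MSEResults`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import round_half_up
from .records import CELL_ORDER, ContingencyTable

__all__ = [
    "ModelSpec",
    "FittedModel",
    "ModelWeights",
    "MSEResults",
    "SensitivityEstimate",
    "ThreeListMSE",
    "EstimationError",
    "BoundaryWarning",
    "fit_loglinear",
    "estimate_m000",
    "profile_interval",
    "model_bic",
    "posterior_probs",
    "model_average",
    "mse_estimate",
    "list_sensitivity",
]


class EstimationError(RuntimeError):
    """An estimator is undefined or could not be computed for this table."""


class BoundaryWarning(UserWarning):
    """A fitted model sits on the boundary of the parameter space."""


_PAIR_COLUMNS = {"ij": (0, 1), "ik": (0, 2), "jk": (1, 2)}
_CANONICAL_PAIRS = ("ij", "ik", "jk")
_H = np.array(CELL_ORDER, dtype=float)  # 7 x 3 membership indicators


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: which pairwise list interactions are included."""

    interactions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        terms = tuple(sorted(set(self.interactions), key=_CANONICAL_PAIRS.index))
        for t in terms:
            if t not in _PAIR_COLUMNS:
                raise ValueError(f"unknown interaction term {t!r}; valid: ij, ik, jk")
        object.__setattr__(self, "interactions", terms)

    @property
    def df(self) -> int:
        """Residual degrees of freedom: 7 cells − (4 + #interactions) params."""
        return 3 - len(self.interactions)

    @property
    def is_saturated(self) -> bool:
        return len(self.interactions) == 3

    def design_matrix(self) -> np.ndarray:
        """7 x p design over the observable cells: intercept, main effects,
        selected pairwise products."""
        cols = [np.ones(7), _H[:, 0], _H[:, 1], _H[:, 2]]
        for term in self.interactions:
            a, b = _PAIR_COLUMNS[term]
            cols.append(_H[:, a] * _H[:, b])
        return np.column_stack(cols)

    def label(self, list_labels: Sequence[str] = ("i", "j", "k")) -> str:
        if not self.interactions:
            return "no interactions"
        pretty = " + ".join(
            "[{} x {}]".format(*(list_labels[c] for c in _PAIR_COLUMNS[t]))
            for t in self.interactions
        )
        return pretty + (" (saturated)" if self.is_saturated else "")

    @staticmethod
    def all_specs() -> tuple["ModelSpec", ...]:
        """The eight-model family in canonical order: by number of
        interaction terms, then lexicographic (ij, ik, jk)."""
        singles = [ModelSpec((t,)) for t in _CANONICAL_PAIRS]
        pairs = [
            ModelSpec(("ij", "ik")),
            ModelSpec(("ij", "jk")),
            ModelSpec(("ik", "jk")),
        ]
        return tuple([ModelSpec(())] + singles + pairs + [ModelSpec(("ij", "ik", "jk"))])


@dataclass
class FittedModel:
    """One log-linear model fitted to a three-list table."""

    spec: ModelSpec
    fitted_cells: np.ndarray  # expected counts per cell, CELL_ORDER
    coefficients: np.ndarray
    m_000: float
    deviance_G2: float
    df: int
    bic: float
    converged: bool
    n_obs: int
    interval_m000: tuple[float, float] | None = None

    def cell(self, history: tuple[int, int, int]) -> float:
        return float(self.fitted_cells[CELL_ORDER.index(history)])

    # cell accessors mirroring the x_ijk naming
    @property
    def m_111(self) -> float:
        return self.cell((1, 1, 1))

    @property
    def m_110(self) -> float:
        return self.cell((1, 1, 0))

    @property
    def m_101(self) -> float:
        return self.cell((1, 0, 1))

    @property
    def m_011(self) -> float:
        return self.cell((0, 1, 1))

    @property
    def m_100(self) -> float:
        return self.cell((1, 0, 0))

    @property
    def m_010(self) -> float:
        return self.cell((0, 1, 0))

    @property
    def m_001(self) -> float:
        return self.cell((0, 0, 1))


@dataclass(frozen=True)
class ModelWeights:
    """Posterior model probabilities over the eight-model family."""

    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.probs)
        if np.any(p < 0):
            raise ValueError("posterior probabilities must be non-negative")
        if abs(float(p.sum()) - 1.0) > 1e-12:
            raise ValueError("posterior probabilities must sum to 1")

    @property
    def k(self) -> int:
        return len(self.probs)

    def __iter__(self):
        return iter(self.probs)

    def __len__(self) -> int:
        return len(self.probs)

    def __getitem__(self, idx: int) -> float:
        return self.probs[idx]


@dataclass(frozen=True)
class SensitivityEstimate:
    """Completeness of a source (or of all sources combined)."""

    scope: str
    n_captured: int
    sensitivity: float
    interval: tuple[float, float]

    def __post_init__(self) -> None:
        if not (0.0 <= self.sensitivity <= 1.0 + 1e-12):
            raise ValueError("sensitivity must lie in [0, 1]")
        if self.interval[0] > self.interval[1] + 1e-12:
            raise ValueError("interval must be ordered")

    @property
    def percent(self) -> int:
        return round_half_up(100.0 * self.sensitivity)

    @property
    def percent_interval(self) -> tuple[int, int]:
        return (
            round_half_up(100.0 * self.interval[0]),
            round_half_up(100.0 * self.interval[1]),
        )


# ---------------------------------------------------------------------------
# Poisson log-linear fitting (Newton with step halving)
# ---------------------------------------------------------------------------

def _poisson_loglik(x: np.ndarray, eta: np.ndarray) -> float:
    # constant term log(x!) omitted throughout: it cancels in deviances,
    # profiles and model comparisons
    return float(x @ eta - np.exp(eta).sum())


def _newton_poisson(
    X: np.ndarray,
    x: np.ndarray,
    offset: float = 0.0,
    beta0: np.ndarray | None = None,
    tol: float = 1e-10,
    maxiter: int = 500,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Maximize the Poisson likelihood of counts *x* with log-mean
    ``X @ beta + offset``. Converges when the largest fitted-cell change
    falls below *tol*. Returns (beta, mu, loglik, converged)."""
    if beta0 is None:
        with np.errstate(divide="ignore"):
            target = np.log(x + 0.5) - offset
        beta0, *_ = np.linalg.lstsq(X, target, rcond=None)
    beta = np.asarray(beta0, dtype=float).copy()
    eta = np.clip(X @ beta + offset, -500.0, 50.0)
    mu = np.exp(eta)
    ll = _poisson_loglik(x, eta)
    converged = False
    for _ in range(maxiter):
        grad = X.T @ (x - mu)
        hess = (X * mu[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step, *_ = np.linalg.lstsq(hess, grad, rcond=None)
        t = 1.0
        for _ in range(40):
            cand = beta + t * step
            eta_c = np.clip(X @ cand + offset, -500.0, 50.0)
            ll_c = _poisson_loglik(x, eta_c)
            if np.isfinite(ll_c) and ll_c >= ll - 1e-12:
                break
            t *= 0.5
        else:
            break
        mu_c = np.exp(eta_c)
        delta = float(np.max(np.abs(mu_c - mu)))
        beta, mu, ll = cand, mu_c, ll_c
        if delta < tol:
            converged = True
            break
    return beta, mu, ll, converged


def fit_loglinear(
    table: ContingencyTable,
    spec: ModelSpec,
    continuity: bool = False,
) -> FittedModel:
    """Fit one log-linear Poisson model to the seven observed cells.

    With flat priors the posterior mode coincides with the Poisson MLE, so
    the fit is by maximum likelihood (Newton iterations, converging when the
    largest fitted-cell change is below 1e-10, capped at 500 iterations).
    ``continuity=True`` adds 0.5 to every observed cell before fitting — an
    optional correction for degenerate (zero-cell) tables, off by default.
    """
    x = table.counts()
    if continuity:
        x = x + 0.5
    X = spec.design_matrix()
    suff = X.T @ x
    if np.any(suff[4:] == 0):
        warnings.warn(
            f"model {spec.label()} has a zero sufficient statistic; "
            "estimate lies on the boundary",
            BoundaryWarning,
            stacklevel=2,
        )
    beta, mu, _, converged = _newton_poisson(X, x)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_terms = np.where(x > 0, x * np.log(x / mu), 0.0)
    g2 = float(2.0 * ratio_terms.sum())
    if spec.is_saturated and np.all(x > 0):
        g2 = 0.0  # exact by construction; guards rounding noise
    n_obs = table.n_obs
    m000 = float(np.exp(beta[0]))
    return FittedModel(
        spec=spec,
        fitted_cells=mu,
        coefficients=beta,
        m_000=m000,
        deviance_G2=g2,
        df=spec.df,
        bic=model_bic(g2, spec.df, n_obs),
        converged=converged,
        n_obs=n_obs,
    )


def estimate_m000(fitted: FittedModel) -> float:
    """The predicted unobserved cell, as the fitted-cell cross-ratio
    m_111 m_100 m_010 m_001 / (m_110 m_101 m_011).

    With no three-way term this equals exp(intercept). Raises when a
    denominator cell is (numerically) zero — a boundary table.
    """
    for name in ("m_110", "m_101", "m_011"):
        if getattr(fitted, name) <= 1e-10:
            raise EstimationError(
                f"denominator cell {name} is zero; m_000 is undefined for this fit"
            )
    num = fitted.m_111 * fitted.m_100 * fitted.m_010 * fitted.m_001
    den = fitted.m_110 * fitted.m_101 * fitted.m_011
    return num / den


def model_bic(deviance_G2: float, df: int, n_obs: int) -> float:
    """BIC on the deviance scale: G² − df · ln(n_obs).

    Deviance is measured against the saturated model and unused degrees of
    freedom earn penalty credit, so the saturated model's BIC is 0 by
    construction and differences between models equal standard BIC
    differences.
    """
    if n_obs <= 0:
        raise ValueError("n_obs must be positive")
    return float(deviance_G2) - df * math.log(n_obs)


def posterior_probs(bics: Sequence[float]) -> ModelWeights:
    """Schwarz weights Pr_i = exp(−BIC_i/2) / Σ_k exp(−BIC_k/2).

    Posterior model probabilities under a uniform model prior; computed with
    a max-shift for numerical stability, hence invariant to adding any
    constant to all BICs.
    """
    b = np.asarray(bics, dtype=float)
    if not np.all(np.isfinite(b)):
        raise ValueError("all BIC values must be finite")
    s = np.exp(-(b - b.min()) / 2.0)
    w = s / s.sum()
    return ModelWeights(tuple(float(v) for v in w))


def model_average(estimates: Sequence[float], weights: ModelWeights) -> float:
    """Posterior-weighted average of per-model m_000 estimates."""
    est = np.asarray(estimates, dtype=float)
    if len(est) != len(weights):
        raise ValueError(
            f"{len(est)} estimates but {len(weights)} weights; misaligned inputs"
        )
    w = np.asarray(weights.probs)
    if np.any(~np.isfinite(est) & (w > 0)):
        raise EstimationError("a model with positive weight has a non-finite estimate")
    return float(np.dot(np.where(w > 0, est, 0.0), w))


# ---------------------------------------------------------------------------
# Profile likelihood of m_000
# ---------------------------------------------------------------------------

class _ProfileCurve:
    """Profile log-likelihood of the unobserved count on the grid 0..ceiling.

    For each integer g the table is completed with g individuals in the
    (0,0,0) cell, the model is refitted to all eight cells (warm-starting
    from the previous grid point), and the full Poisson log-likelihood —
    including the log g! term, which is what lets the profile reflect the
    count's own sampling variability — is recorded. The curve extends lazily
    so a common ceiling can be imposed across models.
    """

    def __init__(self, x: np.ndarray, spec: ModelSpec):
        self.x = x
        X7 = spec.design_matrix()
        zero_row = np.zeros(X7.shape[1])
        zero_row[0] = 1.0  # the 000 cell carries only the intercept
        self.X8 = np.vstack([X7, zero_row])
        self.lls: list[float] = []
        self._beta: np.ndarray | None = None

    def extend_to(self, ceiling: int) -> None:
        for g in range(len(self.lls), ceiling + 1):
            x8 = np.append(self.x, float(g))
            self._beta, _, ll, _ = _newton_poisson(self.X8, x8, beta0=self._beta)
            self.lls.append(ll - math.lgamma(g + 1.0))

    def loglik(self) -> np.ndarray:
        return np.asarray(self.lls)

    def tail_ok(self, rel_tol: float = 1e-8) -> bool:
        ll = self.loglik()
        return math.exp(ll[-1] - ll.max()) < rel_tol


def _pmf_from_loglik(lls: np.ndarray) -> np.ndarray:
    w = np.exp(lls - lls.max())
    return w / w.sum()


def _pmf_percentile(pmf: np.ndarray, q: float) -> float:
    """Percentile of a pmf on grid 0..len-1, linearly interpolated between
    consecutive integers of the cumulative sum."""
    cdf = np.cumsum(pmf)
    j = int(np.searchsorted(cdf, q))
    j = min(j, len(cdf) - 1)
    if j == 0:
        return 0.0
    lo, hi = cdf[j - 1], cdf[j]
    if hi <= lo:
        return float(j)
    return float((j - 1) + (q - lo) / (hi - lo))


def _grow_ceiling(
    curve: _ProfileCurve, ceiling: int, max_ceiling: int, what: str, strict: bool = True
) -> int:
    curve.extend_to(ceiling)
    while not curve.tail_ok():
        if ceiling >= max_ceiling:
            if strict:
                raise EstimationError(
                    f"profile likelihood of {what} is still truncated at "
                    f"ceiling {ceiling}; the estimate lies on the boundary"
                )
            warnings.warn(
                f"profile likelihood of {what} truncated at ceiling {ceiling}; "
                "its interval upper bound is a floor",
                BoundaryWarning,
                stacklevel=3,
            )
            return ceiling
        ceiling = min(2 * ceiling, max_ceiling)
        curve.extend_to(ceiling)
    return ceiling


def profile_interval(
    table: ContingencyTable,
    spec: ModelSpec,
    level: float = 0.95,
    ceiling: int | None = None,
    max_ceiling: int = 200_000,
    method: str = "percentile",
    continuity: bool = False,
) -> tuple[float, float]:
    """Interval for m_000 from the profile likelihood.

    The profile at integer g completes the table with g individuals on no
    list and re-maximizes the full eight-cell Poisson likelihood (with its
    g! term, so the interval carries the unseen count's own sampling
    variability as well as estimation noise). ``method="percentile"``
    (default): normalize the profile over the integer grid 0..ceiling to a
    distribution and take its (1−level)/2 and 1−(1−level)/2 percentiles.
    ``method="deviance"``: the classical cutoff
    {g : 2(ℓ_max − ℓ(g)) ≤ χ²₁(level)}. The grid ceiling defaults to
    max(50, 20 × point estimate) and doubles while the tail holds
    non-negligible mass.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    fitted = fit_loglinear(table, spec, continuity=continuity)
    x = table.counts() + (0.5 if continuity else 0.0)
    if ceiling is None:
        point = fitted.m_000 if math.isfinite(fitted.m_000) else 50.0
        ceiling = max(50, math.ceil(20.0 * max(point, 1.0)))
    curve = _ProfileCurve(x, spec)
    _grow_ceiling(curve, int(ceiling), max_ceiling, f"m_000 under {spec.label()}")
    lls = curve.loglik()
    if method == "percentile":
        pmf = _pmf_from_loglik(lls)
        alpha = (1.0 - level) / 2.0
        return (_pmf_percentile(pmf, alpha), _pmf_percentile(pmf, 1.0 - alpha))
    if method == "deviance":
        cut = stats.chi2.ppf(level, df=1) / 2.0
        ok = np.flatnonzero(lls >= lls.max() - cut)
        return (float(ok[0]), float(ok[-1]))
    raise ValueError(f"unknown interval method {method!r}")


# ---------------------------------------------------------------------------
# Results container and full pipeline
# ---------------------------------------------------------------------------

@dataclass
class MSEResults:
    """Model-averaged multiple systems estimate for one three-list table.

    Attributes hold unrounded values; ``summary()`` and the reported
    properties round to the presentation convention (nearest integer,
    halves away from zero).
    """

    table: ContingencyTable
    per_model: tuple[FittedModel, ...]
    weights: ModelWeights
    m_000_avg: float
    interval_m000: tuple[float, float]
    level: float

    def __post_init__(self) -> None:
        if self.interval_m000[0] > self.interval_m000[1] + 1e-9:
            raise ValueError("interval must be ordered")

    @property
    def n_obs(self) -> int:
        return self.table.n_obs

    @property
    def N_hat(self) -> float:
        return self.n_obs + self.m_000_avg

    @property
    def N_hat_rounded(self) -> int:
        return round_half_up(self.N_hat)

    @property
    def interval(self) -> tuple[float, float]:
        """Interval for the total N, shifted by the observed count."""
        return (self.n_obs + self.interval_m000[0], self.n_obs + self.interval_m000[1])

    def list_sensitivity(self, scope: str = "combined") -> SensitivityEstimate:
        return list_sensitivity(self.table, self, scope)

    def sensitivities(self) -> list[SensitivityEstimate]:
        return [self.list_sensitivity(lbl) for lbl in self.table.list_labels] + [
            self.list_sensitivity("combined")
        ]

    def to_frame(self) -> pd.DataFrame:
        """Per-model table (one row per candidate model plus the averaged
        row), mirroring the usual presentation of a three-list analysis."""
        labels = self.table.list_labels
        rows = []
        for fm, pr in zip(self.per_model, self.weights):
            lo, hi = fm.interval_m000 if fm.interval_m000 else (np.nan, np.nan)
            rows.append(
                {
                    "model": fm.spec.label(labels),
                    "df": fm.df,
                    "G2": fm.deviance_G2,
                    "BIC": fm.bic,
                    "m_000": fm.m_000,
                    "m_000_lo": lo,
                    "m_000_hi": hi,
                    "posterior_prob": pr,
                }
            )
        rows.append(
            {
                "model": "Bayesian model average",
                "df": np.nan,
                "G2": np.nan,
                "BIC": np.nan,
                "m_000": self.m_000_avg,
                "m_000_lo": self.interval_m000[0],
                "m_000_hi": self.interval_m000[1],
                "posterior_prob": 1.0,
            }
        )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Three-list multiple systems estimate (log-linear BMA)",
            "=" * 57,
            f"lists: {', '.join(self.table.list_labels)}"
            + (
                f"   period: [{self.table.period[0]}, {self.table.period[1]})"
                if self.table.period
                else ""
            ),
            f"observed on >=1 list: n = {self.n_obs}",
            "",
        ]
        frame = self.to_frame().copy()
        frame["G2"] = frame["G2"].map(lambda v: "" if pd.isna(v) else f"{v:.2f}")
        frame["BIC"] = frame["BIC"].map(lambda v: "" if pd.isna(v) else f"{v:.2f}")
        frame["df"] = frame["df"].map(lambda v: "" if pd.isna(v) else str(int(v)))
        frame["m_000 (95% CI)"] = [
            f"{round_half_up(m)} ({round_half_up(lo)}-{round_half_up(hi)})"
            for m, lo, hi in zip(frame["m_000"], frame["m_000_lo"], frame["m_000_hi"])
        ]
        frame["Pr"] = frame["posterior_prob"].map(lambda v: f"{v:.3f}")
        lines.append(
            frame[["model", "df", "G2", "BIC", "m_000 (95% CI)", "Pr"]].to_string(
                index=False
            )
        )
        lo, hi = self.interval
        lines += [
            "",
            f"N_hat = n + m_000 = {self.N_hat_rounded} "
            f"({100 * self.level:.0f}% CI {round_half_up(lo)}-{round_half_up(hi)})",
            "list sensitivities: "
            + "; ".join(
                f"{s.scope} {s.percent}% ({s.percent_interval[0]}-{s.percent_interval[1]}%)"
                for s in self.sensitivities()
            ),
        ]
        return "\n".join(lines)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def mse_estimate(
    table: ContingencyTable,
    level: float = 0.95,
    continuity: bool | str = False,
    profile_ceiling: int | None = None,
    max_ceiling: int = 4000,
) -> MSEResults:
    """Fit all eight models, average them by Schwarz weights, and attach
    profile-likelihood intervals.

    The model-averaged interval is formed from the posterior-weighted
    mixture of the per-model normalized profiles of m_000 (each model's
    profile acts as its within-model posterior; the mixture is the
    model-averaged posterior). ``continuity`` may be True, False, or
    ``"auto"`` — apply the +0.5 correction only when the table has an empty
    observed cell, which otherwise puts the saturated estimate at infinity.

    On near-boundary tables some models' profiles decay too slowly to
    normalize within ``max_ceiling``; those models keep a truncated profile
    (their interval upper bound is a floor) under a
    :class:`BoundaryWarning` rather than aborting the whole average.
    """
    if table.n_obs == 0:
        raise EstimationError("nothing observed: all seven cells are zero")
    if continuity == "auto":
        continuity = bool(np.any(table.counts() == 0))
    specs = ModelSpec.all_specs()
    fits = [fit_loglinear(table, s, continuity=continuity) for s in specs]
    weights = posterior_probs([f.bic for f in fits])
    m000s = [f.m_000 for f in fits]
    m_avg = model_average(m000s, weights)

    x = table.counts() + (0.5 if continuity else 0.0)
    finite = [m for m, w in zip(m000s, weights) if math.isfinite(m)]
    if profile_ceiling is None:
        profile_ceiling = max(50, math.ceil(20.0 * max(finite + [1.0])))
    ceiling = int(profile_ceiling)
    curves = [_ProfileCurve(x, s) for s in specs]
    for s, c in zip(specs, curves):
        ceiling = max(
            ceiling,
            _grow_ceiling(
                c, ceiling, max_ceiling, f"m_000 under {s.label()}", strict=False
            ),
        )
    for c in curves:
        c.extend_to(ceiling)

    alpha = (1.0 - level) / 2.0
    pmfs = []
    for fm, c in zip(fits, curves):
        pmf = _pmf_from_loglik(c.loglik())
        pmfs.append(pmf)
        fm.interval_m000 = (
            _pmf_percentile(pmf, alpha),
            _pmf_percentile(pmf, 1.0 - alpha),
        )
    mixture = np.zeros(ceiling + 1)
    for pmf, w in zip(pmfs, weights):
        mixture += w * pmf
    mixture /= mixture.sum()
    interval = (_pmf_percentile(mixture, alpha), _pmf_percentile(mixture, 1.0 - alpha))

    return MSEResults(
        table=table,
        per_model=tuple(fits),
        weights=weights,
        m_000_avg=m_avg,
        interval_m000=interval,
        level=level,
    )


def list_sensitivity(
    table: ContingencyTable,
    result: MSEResults,
    scope: str = "combined",
) -> SensitivityEstimate:
    """Completeness of one list (or of all lists combined): the fraction of
    the estimated total that the scope captured, with bounds obtained by
    dividing the captured count by the interval endpoints of N."""
    if result.N_hat <= 0:
        raise EstimationError("estimated total is zero; sensitivity undefined")
    n_cap = table.n_obs if scope == "combined" else table.captured_on(scope)
    n_lo, n_hi = result.interval
    sens = min(n_cap / result.N_hat, 1.0)
    lo = n_cap / n_hi if n_hi > 0 else 0.0
    hi = min(n_cap / n_lo, 1.0) if n_lo > 0 else 1.0
    return SensitivityEstimate(
        scope=scope, n_captured=n_cap, sensitivity=sens, interval=(lo, hi)
    )


class ThreeListMSE:
    """Three-list capture-recapture model (statsmodels-style entry point).

    Parameters
    ----------
    table:
        The seven observed capture-history counts.
    continuity:
        True, False, or "auto": add 0.5 to each cell before fitting (only
        ever needed for tables with empty observed cells).

    Examples
    --------
    >>> model = ThreeListMSE.from_counts(
    ...     {"111": 8, "110": 4, "101": 4, "011": 4, "100": 2, "010": 2, "001": 2}
    ... )
    >>> res = model.fit()
    >>> round(res.m_000_avg, 1)  # doctest: +SKIP
    1.2
    """

    def __init__(self, table: ContingencyTable, continuity: bool | str = False):
        self.table = table
        self.continuity = continuity

    @classmethod
    def from_counts(
        cls,
        counts: Mapping,
        list_labels: tuple[str, str, str] = ("A", "B", "C"),
        **kwargs,
    ) -> "ThreeListMSE":
        return cls(ContingencyTable.from_counts(counts, list_labels=list_labels), **kwargs)

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        list_labels: tuple[str, str, str] = ("A", "B", "C"),
        **kwargs,
    ) -> "ThreeListMSE":
        """Build from a DataFrame with columns i, j, k, count (the 000 row,
        if present, may have a missing count)."""
        counts = {}
        for _, row in frame.iterrows():
            h = (int(row["i"]), int(row["j"]), int(row["k"]))
            if h == (0, 0, 0):
                continue
            if pd.isna(row["count"]):
                raise ValueError(f"observable cell {h} has no count")
            counts[h] = int(row["count"])
        return cls.from_counts(counts, list_labels=list_labels, **kwargs)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "ThreeListMSE":
        return cls(ContingencyTable.read_csv(path), **kwargs)

    def fit(
        self,
        level: float = 0.95,
        profile_ceiling: int | None = None,
        max_ceiling: int = 4000,
    ) -> MSEResults:
        return mse_estimate(
            self.table,
            level=level,
            continuity=self.continuity,
            profile_ceiling=profile_ceiling,
            max_ceiling=max_ceiling,
        )
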