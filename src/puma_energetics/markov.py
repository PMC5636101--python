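"""Behavioral states, transition tables, hierarchical log-linear models, budgets.

Every 15-minute inter-fix interval is assigned one of two mutually exclusive
behavioral states, *active* or *inactive*, from the straight-line displacement
(cutoff 70 m, calibrated against the fraction of accelerometer measurements
classified mobile).  Consecutive interval pairs form first-order Markov
transitions (preceding state B, succeeding state A) annotated with the
covariates at the junction GPS acquisition: house proximity H, time of day T,
sex S, habitat L.  Multi-way contingency tables over these factors are
analyzed with hierarchical log-linear models fitted by iterative proportional
fitting (IPF); models are compared by likelihood-ratio tests on the G²
deviance and by a relative AIC, aic_rel = G² − 2·df, whose pairwise
differences equal ordinary AIC differences.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from statsmodels.stats.proportion import proportion_confint, proportions_ztest

ACTIVE, INACTIVE = "active", "inactive"
STATE_LEVELS = (INACTIVE, ACTIVE)

#: canonical level order for each contingency-table factor
FACTOR_LEVELS = {
    "B": STATE_LEVELS,
    "A": STATE_LEVELS,
    "H": (False, True),
    "T": ("day", "night"),
    "S": ("F", "M"),
    "L": ("forest", "shrubland"),
}

#: the candidate lattice for the four-way Before x After x House x Time table,
#: from the null (A depends only on B) up to the saturated model
DEFAULT_CANDIDATES = (
    ("BA", "BHT"),
    ("BAH", "BHT"),
    ("BAT", "BHT"),
    ("BAT", "BAH", "BHT"),
    ("BAHT",),
)


# ---------------------------------------------------------------------------
# state classification


def classify_by_distance(step_m: float, cutoff: float = 70.0) -> str:
    """Active iff the inter-fix displacement is >= ``cutoff`` meters.

    The exact-cutoff boundary classifies as active (documented convention).
    """
    if step_m < 0:
        raise ValueError("step distance cannot be negative")
    return ACTIVE if step_m >= cutoff else INACTIVE


def classify_by_activity(fraction: float, cutoff: float = 0.10) -> str:
    """Active iff the accelerometer activity fraction is >= ``cutoff``."""
    if not 0 <= fraction <= 1:
        raise ValueError("activity fraction must lie in [0, 1]")
    return ACTIVE if fraction >= cutoff else INACTIVE


@dataclass
class CutoffCalibration:
    """OLS calibration of the displacement cutoff against accelerometer activity."""

    cutoff_m: float
    slope: float
    intercept: float
    r: float
    activity_cutoff: float


def calibrate_cutoff(
    activity_fraction, step_m, activity_cutoff: float = 0.10
) -> CutoffCalibration:
    """Regress step length on activity fraction; return the step predicted at
    the activity cutoff (default 10%), plus the Pearson correlation r.
    """
    x = np.asarray(activity_fraction, dtype=float)
    y = np.asarray(step_m, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 (activity, step) pairs")
    if np.ptp(x) == 0:
        raise ValueError("activity fractions are constant; cutoff is undefined")
    res = stats.linregress(x, y)
    if res.slope == 0:
        raise ValueError("degenerate calibration: zero slope")
    return CutoffCalibration(
        cutoff_m=float(res.intercept + res.slope * activity_cutoff),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        activity_cutoff=activity_cutoff,
    )


def classify_intervals(fixes: pd.DataFrame, config, source: str = "distance_rule") -> pd.DataFrame:
    """Assign a behavioral state to every complete 15-minute inter-fix interval.

    An interval exists between two fixes of the same animal separated by
    exactly ``config.fix_interval_s``; segments spanning missing fixes are
    gaps and break the Markov chain.  ``source`` selects the classification
    rule: "distance_rule" (displacement >= 70 m) or "accelerometer_rule"
    (activity fraction at the interval's starting fix >= 10%).
    """
    if source not in ("distance_rule", "accelerometer_rule"):
        raise ValueError(f"unknown state source {source!r}")
    frames = []
    for animal, g in fixes.groupby("animal_id", sort=False):
        idx = g.index.to_numpy()
        t = pd.DatetimeIndex(g["timestamp"]).asi8
        xy = g[["x", "y"]].to_numpy(dtype=float)
        dt = np.diff(t) / 1e9
        ok = dt == config.fix_interval_s
        step = np.hypot(*(xy[1:] - xy[:-1]).T)
        if source == "distance_rule":
            if (step[ok] < 0).any():  # defensive; hypot is non-negative
                raise ValueError("negative step distance")
            state = np.where(step >= config.distance_cutoff_m, ACTIVE, INACTIVE)
        else:
            frac = g["activity_fraction"].to_numpy(dtype=float)[:-1]
            bad = ok & ~np.isnan(frac) & ((frac < 0) | (frac > 1))
            if bad.any():
                raise ValueError("activity fraction outside [0, 1]")
            ok = ok & ~np.isnan(frac)
            state = np.where(frac >= config.activity_cutoff, ACTIVE, INACTIVE)
        keep = np.flatnonzero(ok)
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": animal,
                    "start_idx": idx[keep],
                    "end_idx": idx[keep + 1],
                    "start": g["timestamp"].to_numpy()[keep],
                    "state": state[keep],
                    "step_m": step[keep],
                    "source": source,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["animal_id", "start_idx", "end_idx", "start", "state", "step_m", "source"]
        )
    return pd.concat(frames, ignore_index=True)


def build_transitions(intervals: pd.DataFrame, annotated: pd.DataFrame) -> pd.DataFrame:
    """Pair consecutive intervals into transition records.

    Two intervals of one animal form a record when the first ends at the fix
    where the second starts (i.e., the fixes are consecutive at the nominal
    cadence); gaps break the chain.  Covariates H, T (and S, L when present)
    are read from the annotated fix at the junction — the GPS acquisition
    between the two 15-minute intervals.
    """
    frames = []
    for animal, g in intervals.groupby("animal_id", sort=False):
        if len(g) < 2:
            continue
        end_idx = g["end_idx"].to_numpy()
        start_idx = g["start_idx"].to_numpy()
        states = g["state"].to_numpy()
        chained = end_idx[:-1] == start_idx[1:]
        junction = end_idx[:-1][chained]
        if junction.size == 0:
            continue
        jrows = annotated.loc[junction]
        rec = pd.DataFrame(
            {
                "animal_id": animal,
                "B": states[:-1][chained],
                "A": states[1:][chained],
                "H": jrows["near_house"].to_numpy(dtype=bool),
                "T": jrows["period"].to_numpy(),
            }
        )
        if "sex" in annotated.columns:
            rec["S"] = jrows["sex"].to_numpy()
        if "habitat" in annotated.columns:
            rec["L"] = jrows["habitat"].to_numpy()
        frames.append(rec)
    if not frames:
        return pd.DataFrame(columns=["animal_id", "B", "A", "H", "T"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# contingency tables


@dataclass
class ContingencyTable:
    """Integer counts over a cross-classification of single-letter factors."""

    dims: tuple[str, ...]
    counts: np.ndarray
    levels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dims = tuple(self.dims)
        if not self.levels:
            self.levels = {d: FACTOR_LEVELS[d] for d in self.dims}
        self.counts = np.asarray(self.counts, dtype=float)
        expected = tuple(len(self.levels[d]) for d in self.dims)
        if self.counts.shape != expected:
            raise ValueError(f"counts shape {self.counts.shape} != {expected} for dims {self.dims}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @classmethod
    def from_records(cls, records: pd.DataFrame, dims: str | tuple[str, ...]) -> "ContingencyTable":
        dims = tuple(dims)
        levels = {d: FACTOR_LEVELS[d] for d in dims}
        shape = tuple(len(levels[d]) for d in dims)
        counts = np.zeros(shape)
        codes = [
            pd.Categorical(records[d], categories=levels[d]).codes for d in dims
        ]
        for d, c in zip(dims, codes):
            if (np.asarray(c) < 0).any():
                raise ValueError(f"records contain a level of {d!r} outside {levels[d]}")
        np.add.at(counts, tuple(codes), 1)
        return cls(dims=dims, counts=counts, levels=levels)


def _parse_class(cls_spec, dims) -> tuple[int, ...]:
    """A generating class ("BHT" or ("B","H","T")) -> sorted axis indices."""
    letters = tuple(cls_spec)
    unknown = [c for c in letters if c not in dims]
    if unknown:
        raise ValueError(f"generating class {cls_spec!r} uses factors {unknown} not in {dims}")
    if len(set(letters)) != len(letters):
        raise ValueError(f"generating class {cls_spec!r} repeats a factor")
    return tuple(sorted(dims.index(c) for c in letters))


def format_model(classes) -> str:
    return "(" + ", ".join("".join(c) for c in classes) + ")"


# ---------------------------------------------------------------------------
# log-linear models via IPF


@dataclass
class LoglinearModel:
    """A hierarchical log-linear model fitted to a contingency table.

    ``g2`` is the deviance versus the saturated model; ``df`` the residual
    degrees of freedom by inclusion-exclusion over the generating classes;
    ``aic_rel = g2 − 2·df`` (differences equal ordinary AIC differences).
    """

    classes: tuple[tuple[str, ...], ...]
    table: ContingencyTable
    fitted: np.ndarray
    g2: float
    df: int
    aic_rel: float
    p_value: float
    n_iter: int
    converged: bool

    @property
    def name(self) -> str:
        return format_model(self.classes)


def model_df(table: ContingencyTable, classes) -> int:
    """Residual df = cells − free parameters.

    A hierarchical model's parameters are one per interaction subset (the
    empty set included) contained in at least one generating class, each
    worth the product of (levels − 1) over its factors.
    """
    dims = table.dims
    class_sets = [frozenset(tuple(c)) for c in classes]
    params = 0
    for r in range(len(dims) + 1):
        for subset in itertools.combinations(dims, r):
            if any(set(subset) <= cs for cs in class_sets):
                width = 1
                for d in subset:
                    width *= len(table.levels[d]) - 1
                params += width
    return int(table.counts.size - params)


def ipf_fit(
    table: ContingencyTable,
    classes,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> LoglinearModel:
    """Fit a hierarchical log-linear model by iterative proportional fitting.

    Sweeps margin adjustments over the generating classes until every
    generating-class margin of the fitted table matches the observed margin
    within ``tol``.  G² = 2 Σ obs·ln(obs/fit) over cells with obs > 0
    (observed zeros contribute nothing).
    """
    classes = tuple(tuple(c) for c in classes)
    axes_per_class = [_parse_class(c, table.dims) for c in classes]
    obs = table.counts
    n_axes = obs.ndim
    fit = np.full(obs.shape, obs.sum() / obs.size)
    margins_obs = []
    for axes in axes_per_class:
        other = tuple(a for a in range(n_axes) if a not in axes)
        margins_obs.append(obs.sum(axis=other, keepdims=True))
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        for axes, m_obs in zip(axes_per_class, margins_obs):
            other = tuple(a for a in range(n_axes) if a not in axes)
            m_fit = fit.sum(axis=other, keepdims=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(m_fit > 0, m_obs / np.where(m_fit > 0, m_fit, 1.0), 0.0)
            fit = fit * ratio
        err = 0.0
        for axes, m_obs in zip(axes_per_class, margins_obs):
            other = tuple(a for a in range(n_axes) if a not in axes)
            err = max(err, float(np.abs(fit.sum(axis=other, keepdims=True) - m_obs).max()))
        if err < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"IPF did not converge for {format_model(classes)}: margin error {err:.3e}"
        )
    pos = obs > 0
    with np.errstate(divide="ignore"):
        g2 = 2.0 * float(np.sum(obs[pos] * np.log(obs[pos] / fit[pos])))
    df = model_df(table, classes)
    p = float(stats.chi2.sf(g2, df)) if df > 0 else (1.0 if g2 <= 1e-8 else 0.0)
    return LoglinearModel(
        classes=classes,
        table=table,
        fitted=fit,
        g2=max(g2, 0.0),
        df=df,
        aic_rel=g2 - 2.0 * df,
        p_value=p,
        n_iter=n_iter,
        converged=converged,
    )


def is_nested(nested_classes, wider_classes) -> bool:
    """True when every generating class of ``nested`` is contained in one of ``wider``."""
    wider_sets = [frozenset(tuple(c)) for c in wider_classes]
    return all(any(set(tuple(c)) <= w for w in wider_sets) for c in nested_classes)


def lrt(nested: LoglinearModel, wider: LoglinearModel) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested log-linear model against a wider one.

    Returns (ΔG², Δdf, p) with p from the upper chi-square tail.
    """
    if not is_nested(nested.classes, wider.classes):
        raise ValueError(f"{nested.name} is not nested in {wider.name}")
    dg2 = max(nested.g2 - wider.g2, 0.0)
    ddf = nested.df - wider.df
    p = float(stats.chi2.sf(dg2, ddf)) if ddf > 0 else 1.0
    return dg2, ddf, p


def aic_rel(g2: float, df: int) -> float:
    """Relative AIC of a log-linear model from its deviance and residual df."""
    return g2 - 2.0 * df


@dataclass
class ModelSelection:
    """Outcome of fitting a candidate lattice to one contingency table."""

    models: list[LoglinearModel]
    comparison: pd.DataFrame
    best: LoglinearModel
    indistinguishable: list[tuple[str, str]]


def select_model(
    table: ContingencyTable,
    candidates=DEFAULT_CANDIDATES,
    indistinguishable_daic: float = 0.2,
) -> ModelSelection:
    """Fit all candidate models and select the minimum-aic_rel model.

    The comparison table reports, per model, G², residual df, aic_rel, ΔAIC
    to the best model, ΔG²/Δdf/p of the likelihood-ratio test against the
    null (first) candidate, and the model's own goodness-of-fit p-value.
    Pairs of models with |ΔAIC| below ``indistinguishable_daic`` are flagged
    as statistically indistinguishable.
    """
    models = [ipf_fit(table, c) for c in candidates]
    null = models[0]
    best = min(models, key=lambda m: m.aic_rel)
    rows = []
    for m in models:
        if m is null:
            dg2, ddf, p_lrt = np.nan, 0, np.nan
        else:
            dg2, ddf, p_lrt = lrt(null, m)
        rows.append(
            {
                "model": m.name,
                "g2": m.g2,
                "df": m.df,
                "aic_rel": m.aic_rel,
                "delta_aic": m.aic_rel - best.aic_rel,
                "delta_g2_vs_null": dg2,
                "delta_df_vs_null": ddf,
                "p_lrt_vs_null": p_lrt,
                "p_fit": m.p_value,
            }
        )
    comparison = pd.DataFrame(rows)
    pairs = []
    for a, b in itertools.combinations(models, 2):
        if abs(a.aic_rel - b.aic_rel) < indistinguishable_daic:
            pairs.append((a.name, b.name))
    return ModelSelection(models=models, comparison=comparison, best=best, indistinguishable=pairs)


# ---------------------------------------------------------------------------
# transition matrices and behavioral budgets


@dataclass
class TransitionMatrix:
    """Row-stochastic 2x2 transition probabilities and stationary budget.

    Row/column order is (inactive, active).  ``pi`` is the left eigenvector
    of the transition matrix at eigenvalue 1, normalized to sum to one — the
    long-run proportion of time in each state.
    """

    P: np.ndarray
    pi: np.ndarray
    counts: np.ndarray
    stratum: dict

    @property
    def p_active(self) -> float:
        """Stationary (long-run) proportion of time active."""
        return float(self.pi[1])


def stationary_closed_form(P: np.ndarray) -> np.ndarray:
    """Two-state closed form: pi(active) = P(I->A) / (P(I->A) + P(A->I))."""
    q, r = P[0, 1], P[1, 0]
    if q + r == 0:
        raise ValueError("degenerate chain: both states absorbing")
    return np.array([r / (q + r), q / (q + r)])


def stationary_eigen(P: np.ndarray) -> np.ndarray:
    """Stationary distribution as the left eigenvector at eigenvalue 1."""
    w, vl = linalg.eig(P, left=True, right=False)
    k = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(vl[:, k])
    pi = pi / pi.sum()
    return pi


def transition_matrix(table: ContingencyTable, stratum: dict | None = None) -> TransitionMatrix:
    """Row-normalized B->A matrix for one covariate stratum of the table.

    ``stratum`` maps covariate letters to levels (e.g. ``{"H": True,
    "T": "night"}``); unspecified covariates are summed over.  Both row
    totals must be positive.  The eigen-based stationary distribution is
    cross-checked against the two-state closed form to 1e-12.
    """
    stratum = dict(stratum or {})
    counts = table.counts
    dims = list(table.dims)
    for letter, level in stratum.items():
        ax = dims.index(letter)
        li = list(table.levels[letter]).index(level)
        counts = np.take(counts, li, axis=ax)
        dims.pop(ax)
    for letter in [d for d in dims if d not in ("B", "A")]:
        ax = dims.index(letter)
        counts = counts.sum(axis=ax)
        dims.pop(ax)
    counts = np.transpose(counts, (dims.index("B"), dims.index("A")))
    row_tot = counts.sum(axis=1)
    if (row_tot <= 0).any():
        raise ValueError(f"empty transition row in stratum {stratum}")
    P = counts / row_tot[:, None]
    pi = stationary_eigen(P)
    pi_cf = stationary_closed_form(P)
    if np.abs(pi - pi_cf).max() > 1e-12:
        raise AssertionError("eigen stationary deviates from the two-state closed form")
    return TransitionMatrix(P=P, pi=pi, counts=counts, stratum=stratum)


def effective_sample_size(n: int, P: np.ndarray) -> float:
    """Markov effective sample size for state-occupancy proportions.

    Serial dependence in a two-state chain inflates the variance of occupancy
    estimates by (1+ρ)/(1−ρ), where ρ = 1 − P(I→A) − P(A→I) is the second
    eigenvalue of the chain; the equivalent independent sample size is
    n·(1−ρ)/(1+ρ).
    """
    rho = 1.0 - P[0, 1] - P[1, 0]
    rho = min(max(rho, -0.999999), 0.999999)
    return n * (1.0 - rho) / (1.0 + rho)


def wilson_ci(successes: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    lo, hi = proportion_confint(successes, n, alpha=1 - confidence, method="wilson")
    return float(lo), float(hi)


def two_prop_z(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled two-sample z-test for proportions (two-sided).

    A degenerate pooled proportion of exactly 0 or 1 yields z = 0, p = 1
    with a warning.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        warnings.warn("degenerate pooled proportion; z set to 0", stacklevel=2)
        return 0.0, 1.0
    z, p = proportions_ztest([k1, k2], [n1, n2], alternative="two-sided")
    return float(z), float(p)
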