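"""Statistical layer: placement regression, odds arithmetic, and
circular-report precision.

The placement analysis is a logistic regression of the placed/not
outcome on cumulative viewing time, delay, their interaction, and the
positional covariates (trial number, viewing-session number, number of
views).  Uncertainty comes from participant-cluster bootstrap
resampling; nested models are compared with likelihood-ratio tests and
a BIC difference.

The forced-report analysis uses the chance-corrected precision of
angular errors — the reciprocal of the circular standard deviation
minus its expected value under uniform random responding, so that 0
means guessing — modeled linearly on presentation time, delay, and set
size.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LogisticFit",
    "PrecisionFit",
    "SeparationError",
    "fit_logistic",
    "likelihood_ratio_compare",
    "cluster_bootstrap_ci",
    "odds_update",
    "circular_sd",
    "precision_statistic",
    "chance_precision",
    "fit_precision_model",
]

PLACEMENT_TERMS = (
    "intercept",
    "viewing_time",
    "delay",
    "trial_index",
    "viewing_session_index",
    "n_views",
    "viewing_time:delay",
)

_TERM_COLUMNS = {
    "viewing_time": "viewing_time_s",
    "delay": "delay_s",
    "trial_index": "trial_index",
    "viewing_session_index": "viewing_session_index_of_last_view",
    "n_views": "n_views",
}

SEPARATION_LIMIT = 15.0  # |log-odds| beyond this flags (quasi-)separation


class SeparationError(RuntimeError):
    """The logistic likelihood is unbounded (perfect or quasi separation)."""


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic regression summary."""

    coefficients: dict
    standard_errors: dict
    log_likelihood: float
    n_rows: int
    terms: tuple

    @property
    def n_params(self) -> int:
        return len(self.terms)

    @property
    def bic(self) -> float:
        return self.n_params * math.log(self.n_rows) - 2.0 * self.log_likelihood

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": list(self.terms),
                "estimate": [self.coefficients[t] for t in self.terms],
                "std_error": [self.standard_errors[t] for t in self.terms],
            }
        )


def _model_matrix(rows: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    cols = []
    for term in terms:
        if term == "intercept":
            cols.append(np.ones(len(rows)))
        elif term == "viewing_time:delay":
            cols.append(
                rows["viewing_time_s"].to_numpy(float) * rows["delay_s"].to_numpy(float)
            )
        else:
            cols.append(rows[_TERM_COLUMNS[term]].to_numpy(float))
    return np.column_stack(cols)


def fit_logistic(
    rows: pd.DataFrame,
    include_interaction: bool = True,
    cluster_by_participant: bool = False,
    terms: Optional[Sequence[str]] = None,
) -> LogisticFit:
    """Fit the placement model by maximum likelihood (IRLS).

    The default fixed-effect structure is
    ``placed ~ viewing_time * delay + trial_index +
    viewing_session_index + n_views``; ``include_interaction=False``
    drops the product term.  ``cluster_by_participant`` switches the
    reported standard errors to cluster-robust (sandwich) estimates
    grouped by participant.

    Raises
    ------
    SeparationError
        If the outcome is single-class or any coefficient runs away
        (|estimate| > 15 on the logit scale).
    ValueError
        On a rank-deficient model matrix, naming the collinear terms.
    """
    import statsmodels.api as sm

    if terms is None:
        terms = [t for t in PLACEMENT_TERMS if include_interaction or t != "viewing_time:delay"]
    terms = tuple(terms)
    y = rows["placed"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise SeparationError("outcome has a single class; nothing to fit")
    X = _model_matrix(rows, terms)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending terms via pivoted QR
        _, _, piv = _pivoted_qr(X)
        bad = [terms[i] for i in piv[rank:]]
        raise ValueError(f"model matrix is rank deficient; collinear terms: {bad}")
    model = sm.GLM(y, X, family=sm.families.Binomial())
    if cluster_by_participant:
        res = model.fit(
            cov_type="cluster",
            cov_kwds={"groups": rows["participant_id"].to_numpy()},
        )
    else:
        res = model.fit()
    params = np.asarray(res.params)
    if np.any(np.abs(params) > SEPARATION_LIMIT):
        runaway = [t for t, b in zip(terms, params) if abs(b) > SEPARATION_LIMIT]
        raise SeparationError(
            f"coefficient(s) {runaway} exceed |{SEPARATION_LIMIT}| on the logit "
            "scale; the data are (quasi-)separated"
        )
    ses = np.asarray(res.bse)
    return LogisticFit(
        coefficients=dict(zip(terms, map(float, params))),
        standard_errors=dict(zip(terms, map(float, ses))),
        log_likelihood=float(res.llf),
        n_rows=len(rows),
        terms=terms,
    )


def _pivoted_qr(X: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(X, pivoting=True)
    return q, r, piv


def likelihood_ratio_compare(full: LogisticFit, reduced: LogisticFit):
    """Likelihood-ratio test of nested fits, plus a BIC difference.

    Returns ``(statistic, df, p, delta_bic)`` where the statistic is
    2 * (llf_full - llf_reduced), df is the parameter-count difference,
    and ``delta_bic = BIC_reduced - BIC_full`` (positive values favor
    the full model) — a rough surrogate for a Bayes factor via the
    Schwarz approximation.
    """
    if not set(reduced.terms) <= set(full.terms):
        raise ValueError("models are not nested: reduced terms must be a subset")
    if full.n_rows != reduced.n_rows:
        raise ValueError("models were fitted to different row counts")
    df = full.n_params - reduced.n_params
    statistic = max(2.0 * (full.log_likelihood - reduced.log_likelihood), 0.0)
    p = float(stats.chi2.sf(statistic, df)) if df > 0 else 1.0
    delta_bic = reduced.bic - full.bic
    return statistic, df, p, delta_bic


def cluster_bootstrap_ci(
    rows: pd.DataFrame,
    fit_spec: Callable[[pd.DataFrame], "LogisticFit"],
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> dict:
    """Participant-cluster percentile bootstrap intervals.

    ``fit_spec`` maps a data frame to any fitted object exposing a
    ``coefficients`` dict.  Participants are resampled with replacement
    (resampled copies get fresh ids so downstream grouping treats them
    as distinct clusters).  Deterministic under a fixed seed.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    participants = rows["participant_id"].unique()
    if len(participants) < 2:
        raise ValueError("cluster bootstrap needs at least 2 participants")
    rng = np.random.default_rng(seed)
    by_pid = {pid: df for pid, df in rows.groupby("participant_id")}
    draws: dict = {}
    for _ in range(n_boot):
        chosen = rng.choice(participants, size=len(participants), replace=True)
        parts = []
        for j, pid in enumerate(chosen):
            df = by_pid[pid].copy()
            df["participant_id"] = f"boot{j:04d}"
            parts.append(df)
        sample = pd.concat(parts, ignore_index=True)
        try:
            fit = fit_spec(sample)
        except (SeparationError, ValueError):
            continue
        for term, value in fit.coefficients.items():
            draws.setdefault(term, []).append(value)
    lo = 100 * (1 - ci_level) / 2
    return {
        term: (float(np.percentile(v, lo)), float(np.percentile(v, 100 - lo)))
        for term, v in draws.items()
    }


def odds_update(log_odds_coef: float, baseline_odds: float, delta: float = 1.0):
    """Update odds by ``delta`` units of a covariate with given log-odds slope.

    Returns ``(factor, new_odds, new_probability)`` with
    factor = exp(coef * delta), new_odds = baseline_odds * factor, and
    new_probability = new_odds / (1 + new_odds).  For example, a
    viewing-time slope of 0.60 log-odds per second multiplies the odds
    by exp(0.60) ~ 1.82 per extra second of viewing.
    """
    if baseline_odds <= 0:
        raise ValueError("baseline_odds must be positive")
    factor = math.exp(log_odds_coef * delta)
    new_odds = baseline_odds * factor
    return factor, new_odds, new_odds / (1.0 + new_odds)


def circular_sd(errors_deg: Sequence[float]) -> float:
    """Circular standard deviation of angular errors, in degrees.

    cSD = sqrt(-2 ln R) with R the mean resultant length; invariant to
    rotating all angles by a constant.  Returns +inf when R = 0.
    """
    e = np.asarray(errors_deg, dtype=float)
    if e.size == 0:
        raise ValueError("errors_deg must be nonempty")
    rad = np.radians(e)
    R = float(np.abs(np.mean(np.exp(1j * rad))))
    if R <= 1e-12:  # exactly balanced angles: resultant vanishes
        return math.inf
    if R >= 1.0:
        return 0.0
    return math.degrees(math.sqrt(-2.0 * math.log(R)))


def _csd_rad(rad: np.ndarray, axis=-1) -> np.ndarray:
    R = np.abs(np.mean(np.exp(1j * rad), axis=axis))
    with np.errstate(divide="ignore"):
        out = np.sqrt(-2.0 * np.log(np.clip(R, None, 1.0)))
    return out


_CHANCE_CACHE: dict = {}


def chance_precision(n: int, n_mc: int = 10000, seed: int = 1234) -> float:
    """E[1 / cSD] (radians) for ``n`` uniform-random angles, by Monte Carlo.

    The expectation is estimated once per (n, n_mc, seed) and cached;
    the fixed default seed makes the chance correction a deterministic
    function of the sample size.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if n_mc < 1000:
        raise ValueError("n_mc must be >= 1000")
    key = (int(n), int(n_mc), int(seed))
    if key not in _CHANCE_CACHE:
        rng = np.random.default_rng(seed)
        # chunk to bound memory for large n * n_mc
        chunk = max(1, int(5_000_000 // n))
        total = 0.0
        done = 0
        while done < n_mc:
            m = min(chunk, n_mc - done)
            rad = rng.uniform(-np.pi, np.pi, size=(m, n))
            total += float(np.sum(1.0 / _csd_rad(rad)))
            done += m
        _CHANCE_CACHE[key] = total / n_mc
    return _CHANCE_CACHE[key]


def precision_statistic(
    errors_deg: Sequence[float], n_mc: int = 10000, seed: int = 1234
) -> float:
    """Chance-corrected report precision: 1/cSD minus its uniform expectation.

    Both terms are computed on the radian scale; the expectation under
    purely random responding is estimated by seeded Monte Carlo at the
    same sample size (see :func:`chance_precision`), so a precision of
    0 corresponds to random guessing and higher is better.
    """
    e = np.asarray(errors_deg, dtype=float)
    if e.size < 2:
        raise ValueError("precision needs at least 2 errors")
    csd = _csd_rad(np.radians(e))
    chance = chance_precision(e.size, n_mc=n_mc, seed=seed)
    if csd <= 0.0:
        return math.inf
    return float(1.0 / csd - chance)


@dataclass
class PrecisionFit:
    """Linear model of condition-level precision."""

    coefficients: dict
    standard_errors: dict
    participant_intercepts: dict  # {"mean": ..., "sd": ...} of participant means
    n_records: int
    n_cells: int
    cell_table: pd.DataFrame = field(repr=False, default=None)

    def summary_frame(self) -> pd.DataFrame:
        terms = list(self.coefficients)
        return pd.DataFrame(
            {
                "term": terms,
                "estimate": [self.coefficients[t] for t in terms],
                "std_error": [self.standard_errors[t] for t in terms],
            }
        )


DEFAULT_PRECISION_FACTORS = (
    "presentation_s",
    "delay_s",
    "set_size",
    "presentation_s:delay_s",
)


def fit_precision_model(
    records: pd.DataFrame,
    factors: Sequence[str] = DEFAULT_PRECISION_FACTORS,
    n_mc: int = 10000,
    seed: int = 1234,
) -> PrecisionFit:
    """Least-squares model of per-participant, per-condition precision.

    The report errors are aggregated to one chance-corrected precision
    value per participant x presentation-time x delay (x set size)
    cell; cells with fewer than 2 trials are dropped with a warning.
    Terms that vary within participants are estimated on participant
    mean-centered precision (the grand mean is added back), absorbing
    additive participant differences; terms that are constant within
    every participant (e.g., a between-participants set size) are
    estimated from a participant-level regression of mean precision,
    since centering would absorb them.  Interaction terms are written
    ``"a:b"``; factors not present in ``records`` columns are errors.
    Slopes are in precision units per second (or per item).
    """
    base_cols = {f for term in factors for f in term.split(":")}
    missing = base_cols - set(records.columns)
    if missing:
        raise ValueError(f"records lack factor columns: {sorted(missing)}")
    group_cols = ["participant_id"] + sorted(
        base_cols & {"presentation_s", "delay_s", "set_size"}
    )
    cells = []
    dropped = 0
    for keys, grp in records.groupby(group_cols, observed=True):
        if len(grp) < 2:
            dropped += 1
            continue
        row = dict(zip(group_cols, keys if isinstance(keys, tuple) else (keys,)))
        row["n_trials"] = len(grp)
        row["precision"] = precision_statistic(
            grp["error_deg"].to_numpy(), n_mc=n_mc, seed=seed
        )
        cells.append(row)
    if dropped:
        warnings.warn(f"{dropped} cell(s) with < 2 trials dropped", stacklevel=2)
    if not cells:
        raise ValueError("no condition cell has >= 2 trials")
    cell_df = pd.DataFrame(cells)

    grand = cell_df["precision"].mean()
    participant_means = cell_df.groupby("participant_id")["precision"].transform("mean")
    by_pid = cell_df.groupby("participant_id")["precision"].mean()
    cell_df["precision_centered"] = cell_df["precision"] - participant_means + grand

    def term_column(df: pd.DataFrame, term: str) -> np.ndarray:
        col = np.ones(len(df))
        for f in term.split(":"):
            col = col * df[f].to_numpy(float)
        return col

    def is_between(term: str) -> bool:
        col = pd.Series(term_column(cell_df, term))
        spread = col.groupby(cell_df["participant_id"].to_numpy()).nunique()
        return bool((spread <= 1).all())

    within_terms = [t for t in factors if not is_between(t)]
    between_terms = [t for t in factors if is_between(t)]

    import statsmodels.api as sm

    terms = ["intercept"] + within_terms + between_terms
    coefficients: dict = {}
    standard_errors: dict = {}

    Xw = np.column_stack(
        [np.ones(len(cell_df))] + [term_column(cell_df, t) for t in within_terms]
    )
    res_w = sm.OLS(cell_df["precision_centered"].to_numpy(float), Xw).fit()
    for name, b, se in zip(["intercept"] + within_terms, res_w.params, res_w.bse):
        coefficients[name] = float(b)
        standard_errors[name] = float(se)

    if between_terms:
        pid_df = (
            cell_df.groupby("participant_id")
            .agg({f: "first" for f in base_cols} | {"precision": "mean"})
            .reset_index()
        )
        Xb = np.column_stack(
            [np.ones(len(pid_df))] + [term_column(pid_df, t) for t in between_terms]
        )
        if len(pid_df) > len(between_terms) + 1:
            res_b = sm.OLS(pid_df["precision"].to_numpy(float), Xb).fit()
            for name, b, se in zip(between_terms, res_b.params[1:], res_b.bse[1:]):
                coefficients[name] = float(b)
                standard_errors[name] = float(se)
        else:  # too few participants to estimate between effects
            for name in between_terms:
                coefficients[name] = math.nan
                standard_errors[name] = math.nan

    return PrecisionFit(
        coefficients=coefficients,
        standard_errors=standard_errors,
        participant_intercepts={
            "mean": float(by_pid.mean()),
            "sd": float(by_pid.std(ddof=1)) if len(by_pid) > 1 else 0.0,
        },
        n_records=len(records),
        n_cells=len(cell_df),
        cell_table=cell_df,
    )
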