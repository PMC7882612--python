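"""Clustered binary choice-experiment analysis via GEE.

Flies visiting an experimental array make sequential flower choices, so
choices within a fly are correlated.  Marginal preference is therefore
modeled with generalized estimating equations: a binomial logit model for
the probability of choosing an orange flower, an exchangeable working
correlation (all choices of one fly equally correlated), and variance
estimated by an approximate (one-step) leave-one-cluster-out jackknife.
Wald tests on model terms, estimated marginal means with 95% CIs on the
probability scale, first-choice chi-square tests, and conditioning-phase
contrasts complete the analysis surface.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .errors import ConvergenceError, InputError, RankError

logger = logging.getLogger(__name__)

#: Reference levels for treatment coding; fixed so coefficient signs are
#: reproducible across runs.
REFERENCE_LEVELS = {"species": "C_nigripes", "soil": "pale", "phase": "pre"}

#: Canonical level orderings (reference first) when all levels are present.
CANONICAL_LEVELS = {
    "species": ["C_nigripes", "M_capensis"],
    "soil": ["pale", "red"],
    "phase": ["pre", "post_1h", "post_1d"],
}

#: Column of the trials table each model factor is read from.
FACTOR_COLUMNS = {"species": "fly_species", "soil": "soil", "phase": "phase"}

MAX_GEE_ITER = 200
GEE_TOL = 1e-10


@dataclass
class ChoiceDesign:
    """Long-format design for a GEE fit: one row per recorded choice."""

    y: np.ndarray                    # 1 = orange chosen
    X: np.ndarray                    # includes intercept column
    cluster: np.ndarray              # integer cluster index per row
    colnames: List[str]
    terms: Dict[str, List[int]]      # term -> design column indices
    factors: Dict[str, List[str]]    # factor -> levels (reference first)
    excluded_flies: List[str] = field(default_factory=list)


@dataclass
class GEEFit:
    """Marginal logit model fitted by Liang-Zeger iteration."""

    coef: np.ndarray
    cov: np.ndarray                  # jackknife covariance
    cov_sandwich: np.ndarray
    alpha: float                     # exchangeable working correlation
    phi: float                       # dispersion
    colnames: List[str]
    terms: Dict[str, List[int]]
    factors: Dict[str, List[str]]
    n_clusters: int
    n_obs: int
    converged: bool
    n_iter: int
    excluded_flies: List[str] = field(default_factory=list)

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def _levels_present(trials: pd.DataFrame, factor: str) -> List[str]:
    col = FACTOR_COLUMNS[factor]
    present = list(pd.unique(trials[col].astype(str)))
    canonical = CANONICAL_LEVELS[factor]
    unknown = set(present) - set(canonical)
    if unknown:
        raise InputError(f"unknown {factor} level(s): {sorted(unknown)}")
    levels = [lv for lv in canonical if lv in present]
    ref = REFERENCE_LEVELS[factor]
    if ref in levels:  # reference first
        levels.remove(ref)
        levels.insert(0, ref)
    return levels


def _encode_row(values: Mapping[str, str], factors: Dict[str, List[str]],
                term_order: Sequence[str]) -> np.ndarray:
    """Treatment-coded design row for one factor combination."""
    cells = [1.0]
    for term in term_order:
        if ":" in term:
            a, b = term.split(":")
            for la in factors[a][1:]:
                for lb in factors[b][1:]:
                    cells.append(float(values[a] == la) * float(values[b] == lb))
        else:
            for lv in factors[term][1:]:
                cells.append(float(values[term] == lv))
    return np.array(cells)


def _column_names(factors: Dict[str, List[str]], term_order: Sequence[str]) -> Tuple[List[str], Dict[str, List[int]]]:
    names = ["intercept"]
    terms: Dict[str, List[int]] = {"intercept": [0]}
    for term in term_order:
        cols = []
        if ":" in term:
            a, b = term.split(":")
            for la in factors[a][1:]:
                for lb in factors[b][1:]:
                    cols.append(len(names))
                    names.append(f"{a}[{la}]:{b}[{lb}]")
        else:
            for lv in factors[term][1:]:
                cols.append(len(names))
                names.append(f"{term}[{lv}]")
        terms[term] = cols
    return names, terms


def build_design(
    trials: pd.DataFrame,
    terms: Sequence[str] = ("species", "soil", "species:soil"),
    require_both_soils: bool = True,
) -> ChoiceDesign:
    """Expand choice trials into a long-format GEE design.

    ``trials`` has one row per recorded choice with columns ``fly_id``,
    ``fly_species``, ``phase``, ``flower_color`` and ``soil``.  The response
    is 1 when the orange flower was chosen.  Flies that never visited flowers
    on both soil types are excluded when ``require_both_soils`` is set (they
    carry no information about the soil effect), with a log entry.
    """
    required = {"fly_id", "flower_color", "soil"}
    missing = required - set(trials.columns)
    if missing:
        raise InputError(f"trials table missing columns: {sorted(missing)}")
    bad_colors = set(trials["flower_color"].astype(str)) - {"orange", "white"}
    if bad_colors:
        raise InputError(f"unknown flower color(s): {sorted(bad_colors)}")

    trials = trials.copy()
    excluded: List[str] = []
    if require_both_soils:
        soils_per_fly = trials.groupby("fly_id")["soil"].nunique()
        excluded = sorted(str(f) for f in soils_per_fly.index[soils_per_fly < 2])
        if excluded:
            logger.warning(
                "excluding %d fly/flies that did not visit both soil types: %s",
                len(excluded), ", ".join(excluded),
            )
            trials = trials[~trials["fly_id"].astype(str).isin(excluded)]
    if trials.empty:
        raise InputError("no choices left after exclusions")

    base_factors = sorted({f for t in terms for f in t.split(":")})
    factors = {f: _levels_present(trials, f) for f in base_factors}
    term_order = [t for t in terms if ":" not in t] + [t for t in terms if ":" in t]
    colnames, term_cols = _column_names(factors, term_order)

    rows = []
    for _, rec in trials.iterrows():
        values = {f: str(rec[FACTOR_COLUMNS[f]]) for f in base_factors}
        rows.append(_encode_row(values, factors, term_order))
    X = np.vstack(rows) if rows else np.zeros((0, len(colnames)))
    y = (trials["flower_color"].astype(str) == "orange").to_numpy(dtype=float)
    fly_ids = trials["fly_id"].astype(str).to_numpy()
    _, cluster = np.unique(fly_ids, return_inverse=True)
    if np.unique(cluster).size < 2:
        raise InputError("GEE needs at least 2 clusters (flies)")
    return ChoiceDesign(
        y=y, X=X, cluster=cluster, colnames=colnames, terms=term_cols,
        factors=factors, excluded_flies=excluded,
    )


# ---------------------------------------------------------------------------
# GEE estimation
# ---------------------------------------------------------------------------

def _glm_logit(y: np.ndarray, X: np.ndarray, max_iter: int = 50) -> np.ndarray:
    """Independence logistic fit (IRLS) used to initialize the GEE."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        mu = expit(X @ beta)
        W = np.clip(mu * (1 - mu), 1e-10, None)
        score = X.T @ (y - mu)
        info = (X * W[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise RankError("design matrix is rank deficient") from exc
        beta = beta + step
        if np.linalg.norm(step) < 1e-12:
            break
        if np.max(np.abs(beta)) > 100:  # separation guard: stop drifting
            break
    return beta


def _cluster_slices(cluster: np.ndarray) -> List[np.ndarray]:
    return [np.flatnonzero(cluster == c) for c in np.unique(cluster)]


def _estimate_alpha(resid: np.ndarray, slices: List[np.ndarray], phi: float, p: int) -> float:
    num = 0.0
    n_pairs = 0
    for idx in slices:
        r = resid[idx]
        n = r.size
        if n < 2:
            continue
        num += (r.sum() ** 2 - (r**2).sum()) / 2.0
        n_pairs += n * (n - 1) // 2
    if n_pairs <= p:
        return 0.0
    return float(num / (phi * (n_pairs - p)))


def _exchangeable_inverse(n: int, alpha: float) -> np.ndarray:
    """Closed-form inverse of R = (1-a)I + aJ."""
    eye = np.eye(n)
    if n == 1:
        return eye
    return (eye - (alpha / (1 + (n - 1) * alpha)) * np.ones((n, n))) / (1 - alpha)


def gee_fit(
    y: np.ndarray,
    X: np.ndarray,
    cluster: np.ndarray,
    colnames: Optional[List[str]] = None,
    terms: Optional[Dict[str, List[int]]] = None,
    factors: Optional[Dict[str, List[str]]] = None,
    estimate_phi: bool = False,
    jackknife: str = "one-step",
    excluded_flies: Optional[List[str]] = None,
) -> GEEFit:
    """Fit a binomial-logit GEE with exchangeable working correlation.

    Liang-Zeger iteration: coefficients start at the independence GLM
    estimate; the working correlation alpha is moment-estimated from
    within-cluster Pearson residual cross-products (dispersion phi fixed at 1
    for binary data unless ``estimate_phi``); Fisher scoring then updates the
    coefficients on the estimating equations.  Variance is the approximate
    (one-step influence) leave-one-cluster-out jackknife by default;
    ``jackknife="full"`` refits without each cluster for cross-checking.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    cluster = np.asarray(cluster).ravel()
    if X.ndim != 2 or X.shape[0] != y.size or cluster.size != y.size:
        raise InputError("y, X, cluster must have matching lengths")
    slices = _cluster_slices(cluster)
    K = len(slices)
    if K < 2:
        raise InputError("GEE needs at least 2 clusters")
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise RankError("design matrix is rank deficient")
    max_n = max(idx.size for idx in slices)
    alpha_lo = -1.0 / (max_n - 1) + 1e-6 if max_n > 1 else 0.0

    beta = _glm_logit(y, X)
    alpha, phi = 0.0, 1.0
    converged = False
    it = 0
    for it in range(1, MAX_GEE_ITER + 1):
        mu = expit(X @ beta)
        v = np.clip(mu * (1 - mu), 1e-10, None)
        resid = (y - mu) / np.sqrt(v)
        phi = float((resid**2).sum() / (n - p)) if estimate_phi else 1.0
        alpha = _estimate_alpha(resid, slices, phi, p)
        hi = 1.0 - 1e-6
        if not (alpha_lo <= alpha <= hi):
            clipped = float(np.clip(alpha, alpha_lo, hi))
            logger.warning("working correlation %.4f outside admissible range; "
                           "clipped to %.4f", alpha, clipped)
            alpha = clipped

        H = np.zeros((p, p))
        U = np.zeros(p)
        for idx in slices:
            Xi, yi, mui, vi = X[idx], y[idx], mu[idx], v[idx]
            Di = Xi * vi[:, None]
            sv = np.sqrt(vi)
            Rinv = _exchangeable_inverse(idx.size, alpha)
            Vinv = Rinv / np.outer(sv, sv) / phi
            DtVinv = Di.T @ Vinv
            H += DtVinv @ Di
            U += DtVinv @ (yi - mui)
        try:
            step = np.linalg.solve(H, U)
        except np.linalg.LinAlgError as exc:
            raise RankError("GEE working information is singular") from exc
        beta = beta + step
        if np.linalg.norm(step) < GEE_TOL:
            converged = True
            break
    if not converged:
        raise ConvergenceError(f"GEE did not converge in {MAX_GEE_ITER} iterations")

    # Final per-cluster pieces at the solution.
    mu = expit(X @ beta)
    v = np.clip(mu * (1 - mu), 1e-10, None)
    H = np.zeros((p, p))
    Us, Hs = [], []
    for idx in slices:
        Xi, yi, mui, vi = X[idx], y[idx], mu[idx], v[idx]
        Di = Xi * vi[:, None]
        sv = np.sqrt(vi)
        Rinv = _exchangeable_inverse(idx.size, alpha)
        Vinv = Rinv / np.outer(sv, sv) / phi
        DtVinv = Di.T @ Vinv
        Hi = DtVinv @ Di
        Ui = DtVinv @ (yi - mui)
        H += Hi
        Us.append(Ui)
        Hs.append(Hi)
    Hinv = np.linalg.inv(H)
    meat = sum(np.outer(Ui, Ui) for Ui in Us)
    cov_sandwich = Hinv @ meat @ Hinv

    if jackknife == "one-step":
        betas = []
        for Ui, Hi in zip(Us, Hs):
            try:
                betas.append(beta + np.linalg.solve(H - Hi, Ui))
            except np.linalg.LinAlgError:
                betas.append(beta + Hinv @ Ui)
        betas = np.array(betas)
        center = betas.mean(axis=0)
        dev = betas - center
        cov = (K - p) / K * (dev.T @ dev)
    elif jackknife == "full":
        betas = []
        for drop in range(K):
            keep = np.concatenate([idx for j, idx in enumerate(slices) if j != drop])
            sub = gee_fit(y[keep], X[keep], cluster[keep], jackknife="none")
            betas.append(sub.coef)
        betas = np.array(betas)
        center = betas.mean(axis=0)
        dev = betas - center
        cov = (K - p) / K * (dev.T @ dev)
    elif jackknife == "none":
        cov = cov_sandwich
    else:
        raise InputError(f"unknown jackknife variant {jackknife!r}")

    return GEEFit(
        coef=beta, cov=cov, cov_sandwich=cov_sandwich, alpha=float(alpha),
        phi=float(phi), colnames=colnames or [f"b{j}" for j in range(p)],
        terms=terms or {}, factors=factors or {}, n_clusters=K, n_obs=n,
        converged=converged, n_iter=it,
        excluded_flies=excluded_flies or [],
    )


def fit_choice_model(
    trials: pd.DataFrame,
    terms: Sequence[str] = ("species", "soil", "species:soil"),
    require_both_soils: bool = True,
    **gee_kwargs,
) -> GEEFit:
    """Build the design from a trials table and fit the GEE in one call."""
    design = build_design(trials, terms=terms, require_both_soils=require_both_soils)
    return gee_fit(
        design.y, design.X, design.cluster, colnames=design.colnames,
        terms=design.terms, factors=design.factors,
        excluded_flies=design.excluded_flies, **gee_kwargs,
    )


# ---------------------------------------------------------------------------
# Inference on a fit
# ---------------------------------------------------------------------------

def wald_test(fit: GEEFit, term: str) -> Tuple[float, int, float]:
    """Wald chi-square test that all coefficients of ``term`` are zero,
    using the jackknife covariance.  Returns (statistic, df, p)."""
    if term not in fit.terms:
        raise InputError(f"term {term!r} not in fit (has {sorted(fit.terms)})")
    cols = fit.terms[term]
    if not cols:
        raise InputError(f"term {term!r} has no design columns")
    b = fit.coef[cols]
    V = fit.cov[np.ix_(cols, cols)]
    try:
        stat = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError as exc:
        raise RankError("singular covariance block in Wald test") from exc
    df = len(cols)
    return stat, df, float(stats.chi2.sf(stat, df))


def emmeans(
    fit: GEEFit,
    at: Mapping[str, str],
    level: float = 0.95,
) -> Tuple[float, Tuple[float, float]]:
    """Estimated marginal mean probability at a factor combination.

    Factors named in ``at`` are fixed; any other model factor is averaged
    over its levels with equal weight on the link scale.  The CI is the
    inverse-logit of eta +/- z * SE(eta) with the jackknife covariance, so
    endpoints always lie in (0, 1).
    """
    if not fit.factors:
        raise InputError("fit carries no factor metadata; fit via fit_choice_model")
    for f, lv in at.items():
        if f not in fit.factors:
            raise InputError(f"factor {f!r} not in model (has {sorted(fit.factors)})")
        if lv not in fit.factors[f]:
            raise InputError(
                f"level {lv!r} not observed for factor {f!r} "
                f"(has {fit.factors[f]})"
            )
    free = [f for f in fit.factors if f not in at]
    term_order = [t for t in fit.terms if t != "intercept"]
    combos = itertools.product(*[fit.factors[f] for f in free]) if free else [()]
    rows = []
    for combo in combos:
        values = dict(at)
        values.update(dict(zip(free, combo)))
        rows.append(_encode_row(values, fit.factors, term_order))
    row = np.mean(rows, axis=0)
    eta = float(row @ fit.coef)
    se = float(np.sqrt(row @ fit.cov @ row))
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    lo, hi = expit(eta - zcrit * se), expit(eta + zcrit * se)
    return float(expit(eta)), (float(lo), float(hi))


# ---------------------------------------------------------------------------
# First-choice and conditioning analyses
# ---------------------------------------------------------------------------

def first_choice_chisq(n_soil_a: int, n_soil_b: int) -> Tuple[float, int, float]:
    """Goodness-of-fit chi-square against equal soil-choice frequencies.

    With two cells and expected counts (a+b)/2 each, the statistic reduces to
    (a - b)^2 / (a + b) with 1 df.
    """
    a, b = n_soil_a, n_soil_b
    if a < 0 or b < 0:
        raise InputError("counts must be nonnegative")
    total = a + b
    if total < 1:
        raise InputError("need at least one first choice")
    stat = (a - b) ** 2 / total
    return float(stat), 1, float(stats.chi2.sf(stat, 1))


def conditioning_contrast(trials: pd.DataFrame, **gee_kwargs) -> Tuple[GEEFit, Tuple[float, int, float]]:
    """Test whether choices shift after conditioning on the non-preferred color.

    Fits a GEE with conditioning phase as the only predictor (one fly species
    at a time, clusters span a fly's pre and post choices) and returns the fit
    with the phase Wald test.
    """
    if "phase" not in trials.columns:
        raise InputError("trials table has no 'phase' column")
    phases = set(trials["phase"].astype(str))
    if len(phases) < 2:
        raise InputError("conditioning contrast needs both pre and post phases")
    for ph in phases:
        if trials.loc[trials["phase"].astype(str) == ph, "fly_id"].nunique() < 2:
            raise InputError(f"phase {ph!r} has fewer than 2 flies")
    fit = fit_choice_model(trials, terms=("phase",), **gee_kwargs)
    return fit, wald_test(fit, "phase")
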