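"""Landscape pollinator-mosaic association analysis.

Site-level fly densities (individuals per square meter) are assembled from
survey records as the sum over plant species of flies-per-flowerhead times
flowerheads-per-m2.  Whether site flower color (orange = 1, white = 0) is
predicted by fly density is then tested with logistic regression.  Because a
qualitative pollinator mosaic can produce complete separation (one color
occurring only where a fly species is absent), alongside the ordinary
maximum-likelihood fit the module provides Firth's bias-reduced logistic
regression, whose Jeffreys-prior penalty keeps estimates finite under
separation, with penalized likelihood-ratio inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConvergenceError,
    DegenerateResponseError,
    InputError,
    RankError,
)

#: |coefficient| beyond this in an MLE fit is treated as divergence (separation).
MLE_BETA_GUARD = 50.0
MAX_ITER = 100
SCORE_TOL = 1e-8


@dataclass(frozen=True)
class SurveyRecord:
    """One plant species' fly load and flowerhead density at one site."""

    site_id: str
    plant_species: str
    flies_per_flowerhead: float
    flowerheads_per_m2: float
    fly_species: str

    def __post_init__(self) -> None:
        for name in ("flies_per_flowerhead", "flowerheads_per_m2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise InputError(f"{name} must be finite and >= 0, got {v}")


@dataclass
class LogisticFit:
    """Result of an (ordinary or Firth-penalized) logistic regression."""

    method: str                     # "mle" | "firth"
    coef: np.ndarray                # intercept first
    se: np.ndarray
    z: np.ndarray                   # Wald z = coef / se
    p: np.ndarray                   # two-sided normal p per coefficient
    converged: bool
    n_iter: int
    loglik: float                   # penalized log-likelihood for firth fits
    names: List[str] = field(default_factory=list)
    lr_stat: Optional[np.ndarray] = None   # per-slope penalized LR statistic
    lr_p: Optional[np.ndarray] = None

    @property
    def separated(self) -> bool:
        return self.method == "mle" and not self.converged


# ---------------------------------------------------------------------------
# Densities and site coding
# ---------------------------------------------------------------------------

def fly_density_per_m2(
    records: Sequence[SurveyRecord], site_id: str, fly_species: str
) -> float:
    """Fly individuals per m2 at a site: sum over plant species of
    flies-per-flowerhead x flowerheads-per-m2 for the given fly species."""
    site_records = [r for r in records if r.site_id == site_id]
    if not site_records:
        raise InputError(f"no survey records for site {site_id!r}")
    return float(
        sum(
            r.flies_per_flowerhead * r.flowerheads_per_m2
            for r in site_records
            if r.fly_species == fly_species
        )
    )


def site_color_code(colors_present: Sequence[str]) -> Optional[int]:
    """Binary site color: 1 if only orange focal species present, 0 if only
    white, None if neither.  Mixed sites violate the non-overlap assumption
    the binary coding relies on and raise an error."""
    present = {c.lower() for c in colors_present}
    unknown = present - {"orange", "white"}
    if unknown:
        raise InputError(f"unknown flower colors: {sorted(unknown)}")
    if "orange" in present and "white" in present:
        raise InputError(
            "site has both orange and white focal species; binary color coding "
            "assumes non-overlapping colors"
        )
    if "orange" in present:
        return 1
    if "white" in present:
        return 0
    return None


def site_summaries(
    records: Sequence[SurveyRecord],
    site_colors: Dict[str, Sequence[str]],
    fly_species: str,
) -> pd.DataFrame:
    """Per-site density of one fly species plus the binary color code.

    Sites without any focal species color (code None) are excluded, mirroring
    a regression run on occupied sites only.
    """
    sites = sorted({r.site_id for r in records})
    rows = []
    for s in sites:
        code = site_color_code(site_colors.get(s, []))
        if code is None:
            continue
        rows.append(
            {
                "site_id": s,
                "fly_density": fly_density_per_m2(records, s, fly_species),
                "color_code": code,
            }
        )
    return pd.DataFrame(rows, columns=["site_id", "fly_density", "color_code"])


# ---------------------------------------------------------------------------
# Logistic regression (ordinary MLE)
# ---------------------------------------------------------------------------

def _design(y: np.ndarray, x: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise InputError("response must be binary 0/1")
    if y.sum() == 0 or y.sum() == y.size:
        raise DegenerateResponseError("response is all 0s or all 1s")
    if x is None:
        X = np.ones((y.size, 1))
    else:
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        X = np.column_stack([np.ones(x.shape[0]), x])
    if X.shape[0] != y.size:
        raise InputError("response and predictors have different lengths")
    if X.shape[0] < X.shape[1] + 1:
        raise InputError("need n >= p + 1 observations")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankError("design matrix is rank deficient")
    return y, X


def _loglik(y: np.ndarray, X: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # log(1 + e^eta) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def logistic_fit_mle(
    y: Sequence[float],
    x: Sequence[float] | np.ndarray | None,
    names: Sequence[str] | None = None,
) -> LogisticFit:
    """Newton-Raphson maximum-likelihood logistic fit with a separation guard.

    Instead of returning divergent estimates under (quasi-)separation, the fit
    is flagged non-converged when any |coefficient| exceeds ``MLE_BETA_GUARD``
    or the iteration budget is exhausted.
    """
    y, X = _design(np.asarray(y), None if x is None else np.asarray(x))
    p = X.shape[1]
    beta = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        info = (X * W[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise RankError("information matrix is singular") from exc
        # step-halving on the log-likelihood
        ll0 = _loglik(y, X, beta)
        scale = 1.0
        for _ in range(20):
            cand = beta + scale * step
            if _loglik(y, X, cand) >= ll0 - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        if np.max(np.abs(beta)) > MLE_BETA_GUARD:
            break
        if np.linalg.norm(score) < SCORE_TOL:
            converged = True
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    # Perfect prediction means the likelihood maximum lies at infinity
    # (complete separation); the score can vanish numerically long before the
    # coefficient guard trips, so flag it explicitly.
    if converged and np.max(np.abs(y - mu)) < 1e-4:
        converged = False
    info = (X * (mu * (1 - mu))[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return LogisticFit(
        method="mle", coef=beta, se=se, z=z, p=pvals,
        converged=converged, n_iter=it, loglik=_loglik(y, X, beta),
        names=list(names) if names else _default_names(p),
    )


def _default_names(p: int) -> List[str]:
    return ["intercept"] + [f"x{i}" for i in range(1, p)]


# ---------------------------------------------------------------------------
# Firth's bias-reduced logistic regression
# ---------------------------------------------------------------------------

def _firth_pieces(y, X, beta):
    """Return (penalized loglik, modified score, information) at beta."""
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    W = mu * (1.0 - mu)
    XW = X * W[:, None]
    info = XW.T @ X
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        raise RankError("information matrix is singular in Firth fit")
    # hat values of the weighted design: h_i = w_i * x_i' (X'WX)^-1 x_i
    try:
        half = np.linalg.solve(info, X.T)  # p x n
    except np.linalg.LinAlgError as exc:
        raise RankError("information matrix is singular in Firth fit") from exc
    h = W * np.einsum("ij,ji->i", X, half)
    score = X.T @ (y - mu + h * (0.5 - mu))
    pll = _loglik(y, X, beta) + 0.5 * logdet
    return pll, score, info


#: Firth fits get a larger budget: under separation the penalized surface is
#: very flat in the slope direction and Newton steps shrink slowly.
FIRTH_MAX_ITER = 500


def _firth_maximize(y, X, free: np.ndarray, max_iter: int = FIRTH_MAX_ITER) -> tuple[np.ndarray, float, int, bool]:
    """Maximize the Jeffreys-penalized log-likelihood over coefficients where
    ``free`` is True (others fixed at 0).  Returns (beta, pll, iters, ok).

    Convergence: modified-score norm below ``SCORE_TOL`` or an accepted step
    shorter than 1e-7 (the flat-ridge case under separation, where the score
    plateaus at a small value while the estimate has stabilized)."""
    p = X.shape[1]
    beta = np.zeros(p)
    pll, score, info = _firth_pieces(y, X, beta)
    it = 0
    for it in range(1, max_iter + 1):
        sub_info = info[np.ix_(free, free)]
        sub_score = score[free]
        try:
            step = np.linalg.solve(sub_info, sub_score)
        except np.linalg.LinAlgError as exc:
            raise RankError("information matrix is singular in Firth fit") from exc
        scale = 1.0
        accepted = (beta, pll, score, info)
        for _ in range(25):
            cand = beta.copy()
            cand[free] += scale * step
            try:
                cand_pll, cand_score, cand_info = _firth_pieces(y, X, cand)
            except RankError:
                scale *= 0.5
                continue
            accepted = (cand, cand_pll, cand_score, cand_info)
            if cand_pll >= pll - 1e-12:
                break
            scale *= 0.5
        new_beta, pll, score, info = accepted
        step_norm = np.linalg.norm(new_beta - beta)
        beta = new_beta
        if np.linalg.norm(score[free]) < SCORE_TOL or step_norm < 1e-7:
            return beta, pll, it, True
    return beta, pll, it, False


def logistic_fit_firth(
    y: Sequence[float],
    x: Sequence[float] | np.ndarray | None,
    names: Sequence[str] | None = None,
) -> LogisticFit:
    """Firth's bias-reduced logistic regression.

    Maximizes the penalized log-likelihood l*(b) = l(b) + 0.5 log det I(b)
    via modified-score Newton iterations with step-halving.  Estimates remain
    finite under complete separation.  For each slope, a penalized
    likelihood-ratio statistic is computed by refitting with that slope fixed
    at zero; Wald z/p are reported as secondary output.
    """
    y, X = _design(np.asarray(y), None if x is None else np.asarray(x))
    p = X.shape[1]
    free = np.ones(p, dtype=bool)
    beta, pll, it, ok = _firth_maximize(y, X, free)
    if not ok:
        raise ConvergenceError(f"Firth fit did not converge in {FIRTH_MAX_ITER} iterations")
    _, _, info = _firth_pieces(y, X, beta)
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))

    lr_stat = np.full(p, np.nan)
    lr_p = np.full(p, np.nan)
    for j in range(1, p):  # slopes only
        restricted = free.copy()
        restricted[j] = False
        _, pll0, _, ok0 = _firth_maximize(y, X, restricted)
        if not ok0:
            raise ConvergenceError("restricted Firth fit did not converge")
        lr = max(0.0, 2.0 * (pll - pll0))
        lr_stat[j] = lr
        lr_p[j] = stats.chi2.sf(lr, df=1)

    return LogisticFit(
        method="firth", coef=beta, se=se, z=z, p=pvals,
        converged=True, n_iter=it, loglik=pll,
        names=list(names) if names else _default_names(p),
        lr_stat=lr_stat, lr_p=lr_p,
    )
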