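"""Head-width -> total-length allometry with phylogenetic prediction.

The allometry is a log-log linear regression (log10 TL on log10 HW, both in
cm) fitted to extant crocodylians, with residuals structured by Brownian
motion on the time-calibrated tree under a Pagel-lambda transform
(off-diagonal covariances multiplied by lambda in [0, 1]).

Fossil total lengths are imputed by a Bayesian kriging scheme: a Gibbs
sampler draws the regression coefficients and residual variance from their
conjugate conditionals (flat prior on coefficients, vague inverse-gamma on
the variance), and at every retained draw the fossil's log10 TL is sampled
from the Brownian conditional distribution given the observed extant
residuals.  Back-transformed draws give the predictive mean and the 2.5/97.5
percentiles per fossil.

The phylogenetic covariance is scaled to unit mean diagonal so the residual
variance parameter is on the per-taxon scale regardless of tree depth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .io_formats import AllometryRecord

logger = logging.getLogger(__name__)

LOG_BASE = 10.0


class AllometryError(ValueError):
    pass


# ---------------------------------------------------------------------------
# phylogenetic covariance
# ---------------------------------------------------------------------------


def vcv_matrix(tree: dendropy.Tree, labels: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Brownian covariance: shared root-to-MRCA path length for each tip pair.

    Edge lengths are used as-is (durations, Myr); tips need not be
    contemporaneous.  Returns the matrix and the tip-label order.
    """
    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            el = nd.edge.length if nd.edge.length is not None else 0.0
            depth[id(nd)] = depth[id(nd.parent_node)] + el
    leaves = [lf for lf in tree.leaf_node_iter()]
    label_of = {id(lf): (lf.taxon.label if lf.taxon else lf.label) for lf in leaves}
    if labels is None:
        labels = sorted(label_of.values())
    pos = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    V = np.zeros((n, n))
    below: dict[int, list[int]] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            lab = label_of[id(nd)]
            below[id(nd)] = [pos[lab]] if lab in pos else []
            if lab in pos:
                V[pos[lab], pos[lab]] = depth[id(nd)]
        else:
            kid_sets = [below[id(c)] for c in nd.child_nodes()]
            d = depth[id(nd)]
            for a in range(len(kid_sets)):
                for b in range(a + 1, len(kid_sets)):
                    for i in kid_sets[a]:
                        for j in kid_sets[b]:
                            V[i, j] = V[j, i] = d
            below[id(nd)] = [i for s in kid_sets for i in s]
    missing = [lab for lab in labels if lab not in label_of.values()]
    if missing:
        raise AllometryError(f"taxa absent from tree: {missing}")
    return V, labels


def scaled_vcv(tree: dendropy.Tree, labels: list[str]) -> np.ndarray:
    """VCV scaled to unit mean diagonal (per-taxon variance scale)."""
    V, _ = vcv_matrix(tree, labels)
    scale = float(np.mean(np.diag(V)))
    if scale <= 0:
        raise AllometryError("tree has zero depth; cannot build covariance")
    return V / scale


def lambda_transform(V: np.ndarray, lam: float) -> np.ndarray:
    """Pagel transform: off-diagonal entries multiplied by lambda."""
    out = V * lam
    np.fill_diagonal(out, np.diag(V))
    return out


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------


@dataclass
class RegressionModel:
    """Log10-scale allometry: log10 TL = intercept + slope * log10 HW."""

    intercept: float
    slope: float
    sigma2: float
    lam: float | None
    taxa: list[str]
    mode: str = "OLS"

    def predict_log(self, log_hw: np.ndarray | float) -> np.ndarray | float:
        return self.intercept + self.slope * np.asarray(log_hw)


def taxon_log_means(
    records: list[AllometryRecord], require_tl: bool = True
) -> pd.DataFrame:
    """Per-taxon means of specimen log10 measurements.

    Specimens are averaged on the log scale (symmetric treatment of
    multiplicative measurement error).
    """
    rows = []
    for r in records:
        if require_tl and r.tl_cm is None:
            continue
        rows.append(
            {
                "taxon": r.taxon,
                "log_hw": math.log10(r.hw_cm),
                "log_tl": math.log10(r.tl_cm) if r.tl_cm is not None else np.nan,
            }
        )
    if not rows:
        raise AllometryError("no usable records (need both HW and TL)")
    df = pd.DataFrame(rows)
    return df.groupby("taxon", sort=True).mean()


def _gls(X: np.ndarray, y: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """GLS fit: returns (beta, rss_V, (X' V^-1 X)^-1)."""
    try:
        c, low = linalg.cho_factor(V)
    except linalg.LinAlgError as exc:
        raise AllometryError(
            "singular phylogenetic covariance; consider jittering zero-length branches"
        ) from exc
    Vi_X = linalg.cho_solve((c, low), X)
    Vi_y = linalg.cho_solve((c, low), y)
    XtViX = X.T @ Vi_X
    XtViX_inv = np.linalg.inv(XtViX)
    beta = XtViX_inv @ (X.T @ Vi_y)
    r = y - X @ beta
    rss = float(r @ linalg.cho_solve((c, low), r))
    return beta, rss, XtViX_inv


def _loglik_lambda(lam: float, X: np.ndarray, y: np.ndarray, V: np.ndarray) -> float:
    Vl = lambda_transform(V, lam)
    n = len(y)
    try:
        c, low = linalg.cho_factor(Vl)
    except linalg.LinAlgError:
        return -np.inf
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    Vi_X = linalg.cho_solve((c, low), X)
    Vi_y = linalg.cho_solve((c, low), y)
    beta = np.linalg.solve(X.T @ Vi_X, X.T @ Vi_y)
    r = y - X @ beta
    rss = float(r @ linalg.cho_solve((c, low), r))
    if rss <= 0:
        rss = 1e-300
    sigma2 = rss / n
    return -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)


def estimate_lambda(
    tree: dendropy.Tree,
    trait: dict[str, float] | pd.Series,
    design: np.ndarray | None = None,
) -> float:
    """Maximum-likelihood Pagel's lambda in [0, 1] for *trait* on *tree*.

    *design* defaults to an intercept-only column (phylogenetic signal of the
    trait itself); pass a regression design matrix to profile lambda for
    regression residual structure.  Raises on a constant trait, for which
    lambda is undefined.
    """
    trait = pd.Series(dict(trait)).sort_index()
    labels = list(trait.index)
    if len(labels) < 4:
        raise AllometryError("need at least 4 taxa to estimate lambda")
    y = trait.to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        raise AllometryError("trait is constant; lambda is undefined")
    X = design if design is not None else np.ones((len(y), 1))
    V = scaled_vcv(tree, labels)
    res = optimize.minimize_scalar(
        lambda lam: -_loglik_lambda(lam, X, y, V),
        bounds=(0.0, 1.0),
        method="bounded",
        options={"xatol": 1e-6},
    )
    candidates = [0.0, float(res.x), 1.0]
    lls = [_loglik_lambda(l, X, y, V) for l in candidates]
    return float(candidates[int(np.argmax(lls))])


def fit_regression(
    records: list[AllometryRecord],
    tree: dendropy.Tree | None = None,
    mode: str = "OLS",
    lam: float | str = "ml",
) -> RegressionModel:
    """Fit the extant HW->TL log-log regression by OLS or PGLS.

    PGLS uses the lambda-scaled Brownian covariance from *tree*; ``lam`` may
    be a number in [0, 1] or ``"ml"`` for profile maximum likelihood.
    """
    means = taxon_log_means(records, require_tl=True)
    if len(means) < 3:
        raise AllometryError(f"need >=3 extant taxa with HW and TL, got {len(means)}")
    labels = list(means.index)
    X = np.column_stack([np.ones(len(means)), means["log_hw"].to_numpy()])
    y = means["log_tl"].to_numpy()
    if mode == "OLS":
        V = np.eye(len(y))
        lam_out: float | None = None
    elif mode == "PGLS":
        if tree is None:
            raise AllometryError("PGLS requires a tree")
        V0 = scaled_vcv(tree, labels)
        if lam == "ml":
            lam_val = estimate_lambda(tree, means["log_tl"], design=X)
        else:
            lam_val = float(lam)
            if not 0.0 <= lam_val <= 1.0:
                raise AllometryError("lambda must lie in [0, 1]")
        V = lambda_transform(V0, lam_val)
        lam_out = lam_val
    else:
        raise ValueError("mode must be 'OLS' or 'PGLS'")
    beta, rss, _ = _gls(X, y, V)
    dof = max(len(y) - X.shape[1], 1)
    return RegressionModel(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        sigma2=rss / dof,
        lam=lam_out,
        taxa=labels,
        mode=mode,
    )


# ---------------------------------------------------------------------------
# Bayesian phylogenetic prediction
# ---------------------------------------------------------------------------


@dataclass
class McmcConfig:
    n_iter: int = 10_000
    burn_in: int = 1_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.n_iter > self.burn_in >= 0):
            raise ValueError("require n_iter > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class PredictionResult:
    """Predictive total-length summary for one fossil taxon, in cm."""

    taxon: str
    mean_cm: float
    q025_cm: float
    q975_cm: float
    ess: float

    def __post_init__(self) -> None:
        if not (self.q025_cm <= self.mean_cm <= self.q975_cm) or self.q025_cm <= 0:
            raise AllometryError(
                f"{self.taxon}: invalid predictive summary "
                f"({self.q025_cm}, {self.mean_cm}, {self.q975_cm})"
            )


def effective_sample_size(draws: np.ndarray) -> float:
    """Autocorrelation-based ESS (initial positive sequence truncation)."""
    x = np.asarray(draws, dtype=float)
    n = len(x)
    if n < 4 or np.allclose(x, x[0]):
        return float(n)
    x = x - x.mean()
    acf = np.correlate(x, x, mode="full")[n - 1 :] / (np.arange(n, 0, -1) * x.var())
    s = 0.0
    for k in range(1, n // 2):
        if acf[k] <= 0:
            break
        s += acf[k]
    return float(n / (1.0 + 2.0 * s))


def _resolve_polytomies(tree: dendropy.Tree) -> dendropy.Tree:
    poly = any(len(nd.child_nodes()) > 2 for nd in tree.preorder_internal_node_iter())
    if not poly:
        return tree
    logger.info("resolving polytomies with zero-length internal branches for prediction")
    clone = tree.clone(depth=1)
    clone.resolve_polytomies(limit=2, update_bipartitions=False)
    for nd in clone.preorder_node_iter():
        if nd.parent_node is not None and nd.edge.length is None:
            nd.edge.length = 0.0
    return clone


@dataclass
class PosteriorDraws:
    """Retained Gibbs draws: regression coefficients, residual variance and
    per-fossil log10 total lengths."""

    intercept: np.ndarray
    slope: np.ndarray
    sigma2: np.ndarray
    log10_tl: dict[str, np.ndarray]
    lam: float


def _usable_fossils(fossil_hw: dict[str, float]) -> list[tuple[str, float]]:
    """(taxon, log10 HW) pairs; fossils without a head width are skipped."""
    fossils: list[tuple[str, float]] = []
    for taxon, hw in fossil_hw.items():
        if hw is None or (isinstance(hw, float) and math.isnan(hw)):
            logger.warning("fossil %s has no head width; skipped", taxon)
            continue
        if not hw > 0:
            raise AllometryError(f"fossil {taxon}: head width must be positive")
        fossils.append((str(taxon), math.log10(float(hw))))
    return fossils


def sample_posterior(
    tree: dendropy.Tree,
    extant: list[AllometryRecord],
    fossil_hw: dict[str, float],
    model_mode: str = "PGLS",
    mcmc: McmcConfig | None = None,
    lam: float | None = None,
    jitter: float = 0.0,
) -> PosteriorDraws:
    """Gibbs sampler for the allometry with fossil imputation.

    Per iteration the regression coefficients and residual variance are
    sampled from their conjugate conditionals (flat prior on coefficients,
    inverse-gamma(0.001, 0.001) on the variance), and each fossil's log10 TL
    is drawn from the Brownian conditional given the extant residuals
    (kriging mean ``x_f b + C_fo C_oo^-1 (y - X b)`` and the matching
    conditional variance).  Deterministic given ``mcmc.seed``.
    """
    if mcmc is None:
        mcmc = McmcConfig()
    means = taxon_log_means(extant, require_tl=True)
    obs_labels = list(means.index)
    fossils = _usable_fossils(fossil_hw)
    work = _resolve_polytomies(tree)
    labels = obs_labels + [f for f, _ in fossils]
    V = scaled_vcv(work, labels)
    if jitter:
        V = V + jitter * np.eye(len(V))
    n_obs = len(obs_labels)
    X = np.column_stack([np.ones(n_obs), means["log_hw"].to_numpy()])
    y = means["log_tl"].to_numpy()

    if model_mode == "OLS":
        lam_val = 0.0
    elif model_mode == "PGLS":
        lam_val = (
            float(lam)
            if lam is not None
            else estimate_lambda(work, means["log_tl"], design=X)
        )
    else:
        raise ValueError("model_mode must be 'OLS' or 'PGLS'")
    Vl = lambda_transform(V, lam_val)
    V_oo = Vl[:n_obs, :n_obs]
    try:
        c, low = linalg.cho_factor(V_oo)
    except linalg.LinAlgError as exc:
        raise AllometryError(
            "singular phylogenetic covariance among extant taxa; "
            "pass jitter=1e-8 to regularize"
        ) from exc
    Vi_X = linalg.cho_solve((c, low), X)
    Vi_y = linalg.cho_solve((c, low), y)
    XtViX_inv = np.linalg.inv(X.T @ Vi_X)
    beta_hat = XtViX_inv @ (X.T @ Vi_y)
    chol_post = np.linalg.cholesky(XtViX_inv)
    r0 = y - X @ beta_hat
    rss0 = float(r0 @ linalg.cho_solve((c, low), r0))
    Vi = linalg.cho_solve((c, low), np.eye(n_obs))

    # per-fossil kriging weights and conditional-variance coefficients
    weights, var_coef, x_f = [], [], []
    for i, (taxon, log_hw) in enumerate(fossils):
        c_of = Vl[:n_obs, n_obs + i]
        w = Vi @ c_of
        weights.append(w)
        var_coef.append(max(float(Vl[n_obs + i, n_obs + i] - c_of @ w), 0.0))
        x_f.append(np.array([1.0, log_hw]))

    a0 = b0 = 0.001  # vague inverse-gamma prior on sigma^2
    rng = np.random.default_rng(mcmc.seed)
    sigma2 = max(rss0 / max(n_obs - 2, 1), 1e-12)
    draws: list[list[float]] = [[] for _ in fossils]
    beta_draws: list[np.ndarray] = []
    sigma2_draws: list[float] = []
    for it in range(mcmc.n_iter):
        beta = beta_hat + math.sqrt(sigma2) * (chol_post @ rng.standard_normal(2))
        r = y - X @ beta
        rss = float(r @ (Vi @ r))
        sigma2 = 1.0 / rng.gamma(a0 + 0.5 * n_obs, 1.0 / (b0 + 0.5 * rss))
        if it < mcmc.burn_in or (it - mcmc.burn_in) % mcmc.thin != 0:
            continue
        beta_draws.append(beta)
        sigma2_draws.append(sigma2)
        for k in range(len(fossils)):
            mu = float(x_f[k] @ beta + weights[k] @ r)
            sd = math.sqrt(sigma2 * var_coef[k])
            draws[k].append(mu + sd * rng.standard_normal())

    betas = np.asarray(beta_draws)
    return PosteriorDraws(
        intercept=betas[:, 0],
        slope=betas[:, 1],
        sigma2=np.asarray(sigma2_draws),
        log10_tl={taxon: np.asarray(draws[k]) for k, (taxon, _) in enumerate(fossils)},
        lam=lam_val,
    )


def predict_tl(
    tree: dendropy.Tree,
    extant: list[AllometryRecord],
    fossil_hw: dict[str, float],
    model_mode: str = "PGLS",
    mcmc: McmcConfig | None = None,
    lam: float | None = None,
    jitter: float = 0.0,
) -> list[PredictionResult]:
    """Impute fossil total lengths on the calibrated tree.

    Summarizes :func:`sample_posterior`: per fossil the mean and 2.5/97.5
    percentiles of the back-transformed (cm) predictive draws, with an
    autocorrelation-based effective sample size.
    """
    if not _usable_fossils(fossil_hw):
        return []
    draws = sample_posterior(
        tree, extant, fossil_hw, model_mode=model_mode, mcmc=mcmc, lam=lam, jitter=jitter
    )
    results = []
    for taxon in fossil_hw:
        taxon = str(taxon)
        if taxon not in draws.log10_tl:
            continue
        tl = np.power(LOG_BASE, draws.log10_tl[taxon])
        results.append(
            PredictionResult(
                taxon=taxon,
                mean_cm=float(tl.mean()),
                q025_cm=float(np.percentile(tl, 2.5)),
                q975_cm=float(np.percentile(tl, 97.5)),
                ess=effective_sample_size(np.log10(tl)),
            )
        )
    return results


def predictions_to_frame(results: list[PredictionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "taxon": r.taxon,
                "mean_cm": r.mean_cm,
                "q2.5_cm": r.q025_cm,
                "q97.5_cm": r.q975_cm,
                "ess": r.ess,
            }
            for r in results
        ],
        columns=["taxon", "mean_cm", "q2.5_cm", "q97.5_cm", "ess"],
    )
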