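"""Interval-level heterochiasmy statistics.

Outlier regions are called with Tukey fences on the raw sex difference
in recombination rate (never on the relative heterochiasmy index, which
can flag intervals with trivially small absolute differences).
Associations of the rescaled index |HI|/2 in [0, 1] with genomic
covariates are modelled with a zero-one-inflated beta (zoib) regression
fitted by maximum likelihood: boundary mass is Bernoulli (zoi = total
boundary probability, coi = share of boundary mass at 1) and interior
values follow a beta regression with a logit link on the mean.
Inference is on the 95% Wald interval of the covariate coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation (average ranks for ties, t-approximate p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    res = stats.spearmanr(x[ok], y[ok])
    return CorrelationResult(float(res.statistic), float(res.pvalue), int(ok.sum()))


def tukey_fences(values: np.ndarray, k: float = 1.5) -> dict:
    """Type-7 (linear interpolation) quartiles and the k x IQR fences."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 4:
        raise ValueError("need at least 4 finite values for fences")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return {
        "q1": float(q1),
        "q3": float(q3),
        "iqr": float(iqr),
        "lower": float(q1 - k * iqr),
        "upper": float(q3 + k * iqr),
        "k": k,
    }


def tukey_outliers(values, k: float = 1.5) -> tuple[pd.DataFrame, dict]:
    """Flag values outside the Tukey fences.

    On the female-minus-male rate difference, values below the lower
    fence are male-biased and values above the upper fence female-biased.
    """
    v = np.asarray(values, dtype=float)
    fences = tukey_fences(v, k)
    calls = []
    for i, val in enumerate(v):
        if not np.isfinite(val):
            continue
        if val < fences["lower"]:
            calls.append({"index": i, "value": float(val), "label": "male-biased"})
        elif val > fences["upper"]:
            calls.append({"index": i, "value": float(val), "label": "female-biased"})
    return pd.DataFrame(calls, columns=["index", "value", "label"]), fences


# --------------------------------------------------------------------------
# zero-one-inflated beta regression


@dataclass
class ZoibFit:
    """ML fit of the zoib model with a single covariate on the mean.

    beta0/beta1 are on the standardized-covariate scale when
    ``standardized`` is True; beta1_raw is per unit of the original
    covariate.  Confidence intervals are 95% Wald intervals from the
    inverse observed information of the interior beta component.
    """

    beta0: float
    beta1: float
    phi: float
    zoi: float
    coi: float
    ci_beta0: tuple[float, float]
    ci_beta1: tuple[float, float]
    beta1_raw: float
    ci_beta1_raw: tuple[float, float]
    converged: bool
    n: int
    n_interior: int
    loglik: float
    standardized: bool
    x_mean: float
    x_sd: float

    def excludes_zero(self) -> bool:
        lo, hi = self.ci_beta1
        return lo > 0 or hi < 0


def _beta_nll(theta: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
    b0, b1, log_phi = theta
    phi = np.exp(log_phi)
    eta = b0 + b1 * x
    mu = special.expit(eta)
    a = mu * phi
    b = (1.0 - mu) * phi
    ll = (
        special.gammaln(phi)
        - special.gammaln(a)
        - special.gammaln(b)
        + (a - 1.0) * np.log(y)
        + (b - 1.0) * np.log1p(-y)
    )
    val = -np.sum(ll)
    return val if np.isfinite(val) else 1e12


def _numeric_hessian(f, theta: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    p = len(theta)
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = eps
            ej[j] = eps
            H[i, j] = H[j, i] = (
                f(theta + ei + ej) - f(theta + ei - ej)
                - f(theta - ei + ej) + f(theta - ei - ej)
            ) / (4 * eps * eps)
    return H


def zoib_loglik(
    params: dict, x: np.ndarray, y: np.ndarray
) -> float:
    """Full-model log-likelihood at given parameters (for diagnostics)."""
    zoi, coi = params["zoi"], params["coi"]
    theta = np.array([params["beta0"], params["beta1"], np.log(params["phi"])])
    is0 = y == 0
    is1 = y == 1
    interior = ~(is0 | is1)
    ll = 0.0
    eps = 1e-300
    ll += np.log(max(zoi * (1 - coi), eps)) * is0.sum()
    ll += np.log(max(zoi * coi, eps)) * is1.sum()
    if interior.any():
        ll += np.log(max(1 - zoi, eps)) * interior.sum()
        ll -= _beta_nll(theta, x[interior], y[interior])
    return float(ll)


def zoib_fit(
    y,
    x,
    standardize: bool = True,
    n_starts: int = 5,
    seed: int = 0,
) -> ZoibFit:
    """Fit the zoib regression by maximum likelihood.

    The boundary parameters (zoi, coi) are intercept-only and separable
    from the interior beta regression, so they have closed-form MLEs;
    the beta component (logit-mean linear in x, common precision phi) is
    maximized numerically from multiple starts.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    n = len(y)
    if n < 50:
        raise ValueError("zoib_fit needs at least 50 observations")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("response must lie in [0, 1]")

    x_mean = float(x.mean())
    x_sd = float(x.std())
    if standardize:
        if x_sd == 0:
            raise ValueError("covariate is constant")
        xs = (x - x_mean) / x_sd
    else:
        xs = x

    boundary = (y == 0) | (y == 1)
    n_bound = int(boundary.sum())
    zoi = n_bound / n
    coi = float((y == 1).sum() / n_bound) if n_bound else 0.0

    yi = y[~boundary]
    xi = xs[~boundary]
    n_int = len(yi)
    if n_int == 0:
        raise ValueError("no interior (0, 1) values: beta component unidentifiable")

    # moment-based start
    m = yi.mean()
    v = max(yi.var(), 1e-6)
    phi0 = max(m * (1 - m) / v - 1.0, 1.0)
    starts = [np.array([special.logit(np.clip(m, 1e-3, 1 - 1e-3)), 0.0, np.log(phi0)])]
    rng = np.random.default_rng(seed)
    for _ in range(n_starts - 1):
        starts.append(starts[0] + rng.normal(0, [0.5, 0.5, 0.5]))

    best = None
    for s in starts:
        res = optimize.minimize(
            _beta_nll, s, args=(xi, yi), method="L-BFGS-B",
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    converged = bool(best.success)

    H = _numeric_hessian(lambda t: _beta_nll(t, xi, yi), theta)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(3, np.nan)
        converged = False
    z = 1.959963984540054
    ci0 = (theta[0] - z * se[0], theta[0] + z * se[0])
    ci1 = (theta[1] - z * se[1], theta[1] + z * se[1])

    scale = x_sd if standardize else 1.0
    fit = ZoibFit(
        beta0=float(theta[0]),
        beta1=float(theta[1]),
        phi=float(np.exp(theta[2])),
        zoi=float(zoi),
        coi=float(coi),
        ci_beta0=(float(ci0[0]), float(ci0[1])),
        ci_beta1=(float(ci1[0]), float(ci1[1])),
        beta1_raw=float(theta[1] / scale),
        ci_beta1_raw=(float(ci1[0] / scale), float(ci1[1] / scale)),
        converged=converged,
        n=n,
        n_interior=n_int,
        loglik=zoib_loglik(
            {
                "beta0": float(theta[0]),
                "beta1": float(theta[1]),
                "phi": float(np.exp(theta[2])),
                "zoi": zoi,
                "coi": coi,
            },
            xs,
            y,
        ),
        standardized=standardize,
        x_mean=x_mean,
        x_sd=x_sd,
    )
    return fit


def simulate_zoib(
    n: int,
    beta0: float,
    beta1: float,
    phi: float,
    zoi: float,
    coi: float,
    x: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (y, x) from the zoib model; used for calibration checks."""
    if rng is None:
        rng = np.random.default_rng(seed)
    if x is None:
        x = rng.normal(size=n)
    mu = special.expit(beta0 + beta1 * x)
    y = rng.beta(mu * phi, (1 - mu) * phi)
    is_bound = rng.random(n) < zoi
    y = np.where(is_bound, (rng.random(n) < coi).astype(float), y)
    return y, x


# --------------------------------------------------------------------------
# association suite


def association_suite(
    intervals: pd.DataFrame,
    fence: float = 1.5,
    extreme_fence: float = 3.0,
    zoib_seed: int = 0,
) -> dict:
    """The battery of interval-level tests.

    Spearman correlations of the sex-averaged rate and |diff| with gene
    density and distance to chromosome end; zoib regressions of the
    rescaled heterochiasmy index on the same covariates; and Tukey
    outlier summaries of the raw rate difference at the standard (1.5)
    and extreme (3.0) fences.
    """
    tab = intervals.dropna(subset=["rate_f", "rate_m", "rate_avg"]).reset_index(drop=True)
    out: dict = {"n_intervals": len(tab)}

    abs_diff = tab["diff"].abs()
    correlations = {
        ("rate_avg", "gene_count"): spearman(tab["rate_avg"], tab["gene_count"]),
        ("rate_avg", "dist_rel"): spearman(tab["rate_avg"], tab["dist_rel"]),
        ("abs_diff", "gene_count"): spearman(abs_diff, tab["gene_count"]),
        ("abs_diff", "dist_rel"): spearman(abs_diff, tab["dist_rel"]),
        ("abs_diff", "dist_bp"): spearman(abs_diff, tab["dist_bp"]),
    }
    out["spearman"] = pd.DataFrame(
        [
            {"response": a, "covariate": b, "rho": r.rho, "p_value": r.p_value, "n": r.n}
            for (a, b), r in correlations.items()
        ]
    )

    zoibs = {}
    for covariate in ("gene_count", "dist_bp", "dist_rel"):
        try:
            zoibs[covariate] = zoib_fit(
                tab["hi_rescaled"], tab[covariate], seed=zoib_seed
            )
        except ValueError as exc:  # degenerate landscapes (e.g. toy inputs)
            zoibs[covariate] = str(exc)
    out["zoib"] = zoibs

    for name, k in (("outliers", fence), ("extreme", extreme_fence)):
        calls, fences = tukey_outliers(tab["diff"].to_numpy(), k)
        detail = tab.iloc[calls["index"]].copy() if len(calls) else tab.iloc[[]].copy()
        detail["label"] = calls["label"].to_numpy() if len(calls) else []
        summary = (
            detail.groupby(["class", "label"]).size().rename("n_intervals").reset_index()
            if len(detail)
            else pd.DataFrame(columns=["class", "label", "n_intervals"])
        )
        out[name] = {"fences": fences, "calls": detail, "by_class": summary}
    return out
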