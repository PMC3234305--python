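"""Beta-binomial test for differentially expressed peptide clusters.

Spectral counts x out of per-replicate totals n are modeled as binomial
with a beta-distributed success proportion, giving the beta-binomial
marginal with mean n*pi and variance n*pi*(1-pi)*[1 + (n-1)*phi], where
phi = 1/(alpha+beta+1) in [0, 1) is the overdispersion between replicates.
The proportion is linked to a design matrix through pi = h(X b) (logit by
default); the group effect is tested with a likelihood-ratio test of the
group coefficient being zero, followed by Benjamini-Hochberg correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import betaln, expit, gammaln, logit
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "CountTable",
    "BetaBinomFit",
    "betabinom_logpmf",
    "fit_betabinom",
    "lrt_test",
    "wald_test",
    "bh_adjust",
    "run_dep",
]

_PHI_FLOOR = 1e-10
_EPS = 1e-12


@dataclass
class CountTable:
    """Clusters x replicates spectral counts with totals and group labels.

    ``n`` holds the per-replicate total spectral counts.  For tables built
    from a clustering these are the column sums of ``x`` over all clusters
    (computed before any filtering); tables sampled directly from the
    beta-binomial model carry the totals they were generated with.
    """

    x: np.ndarray
    n: np.ndarray
    replicate_keys: list[tuple[str, str]]
    groups: list[str]
    cluster_ids: list[str]
    occupancy: list[str]

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=int)
        self.n = np.asarray(self.n, dtype=int)
        if self.x.ndim != 2 or self.x.shape[1] != self.n.size:
            raise ValueError("count matrix and totals are inconsistent")
        if np.any(self.x < 0) or np.any(self.x > self.n[None, :]):
            raise ValueError("counts must satisfy 0 <= x <= n")
        if len(set(self.groups)) < 1:
            raise ValueError("at least one group required")

    @property
    def n_clusters(self) -> int:
        return self.x.shape[0]

    @property
    def group_levels(self) -> list[str]:
        return sorted(set(self.groups))

    def shared_mask(self) -> np.ndarray:
        return np.array([o == "shared" for o in self.occupancy], dtype=bool)

    def column_names(self) -> list[str]:
        return [f"{s}:{r}" for s, r in self.replicate_keys]

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.x, columns=self.column_names())
        df.insert(0, "cluster_id", self.cluster_ids)
        df.insert(1, "occupancy", self.occupancy)
        total = {"cluster_id": "TOTAL", "occupancy": ""}
        total.update(dict(zip(self.column_names(), self.n)))
        df = pd.concat([df, pd.DataFrame([total])], ignore_index=True)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CountTable":
        df = pd.read_csv(path, sep="\t", dtype={"cluster_id": str})
        df["occupancy"] = df["occupancy"].fillna("")
        count_cols = [c for c in df.columns if c not in ("cluster_id", "occupancy")]
        totals = df[df.cluster_id == "TOTAL"]
        body = df[df.cluster_id != "TOTAL"]
        if len(totals) != 1:
            raise ValueError("counts TSV must contain exactly one TOTAL row")
        keys = [tuple(c.split(":", 1)) for c in count_cols]
        return cls(
            x=body[count_cols].to_numpy(dtype=int),
            n=totals[count_cols].to_numpy(dtype=int)[0],
            replicate_keys=keys,
            groups=[k[0] for k in keys],
            cluster_ids=body.cluster_id.tolist(),
            occupancy=body.occupancy.tolist(),
        )


def betabinom_logpmf(x, n, pi, phi) -> np.ndarray | float:
    """Log of the beta-binomial pmf C(n,x) B(a+x, n+b-x) / B(a,b).

    Parameterized by the mean proportion pi = a/(a+b) and overdispersion
    phi = 1/(a+b+1); phi -> 0 is handled as the binomial limit.
    """
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    pi = np.asarray(pi, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any((x < 0) | (x > n)):
        raise ValueError("x must satisfy 0 <= x <= n")
    if np.any((pi <= 0) | (pi >= 1)):
        raise ValueError("pi must lie strictly inside (0, 1)")
    if np.any((phi < 0) | (phi >= 1)):
        raise ValueError("phi must lie in [0, 1)")
    choose = gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)
    binom = choose + x * np.log(pi) + (n - x) * np.log1p(-pi)
    if np.all(phi < _PHI_FLOOR):
        out = binom
    else:
        phi_s = np.maximum(phi, _PHI_FLOOR)
        alpha = pi * (1.0 - phi_s) / phi_s
        beta = (1.0 - pi) * (1.0 - phi_s) / phi_s
        bb = choose + betaln(alpha + x, n + beta - x) - betaln(alpha, beta)
        out = np.where(phi < _PHI_FLOOR, binom, bb)
    return float(out) if out.ndim == 0 else out


@dataclass
class BetaBinomFit:
    """Maximum-likelihood fit of the beta-binomial regression for one cluster."""

    b: np.ndarray
    phi: float
    loglik: float
    converged: bool
    pi: np.ndarray          # fitted proportion per replicate
    design: np.ndarray
    link: str = "logit"
    boundary_phi: bool = False

    @property
    def alpha_beta(self) -> tuple[np.ndarray, np.ndarray]:
        phi = max(self.phi, _PHI_FLOOR)
        return (self.pi * (1 - phi) / phi, (1 - self.pi) * (1 - phi) / phi)


def _inverse_link(eta: np.ndarray, link: str) -> np.ndarray:
    if link == "logit":
        pi = expit(eta)
    elif link == "cloglog":
        pi = 1.0 - np.exp(-np.exp(eta))
    else:
        raise ValueError(f"unknown link {link!r}")
    return np.clip(pi, _EPS, 1.0 - _EPS)


def _moment_phi(x: np.ndarray, n: np.ndarray) -> float:
    """Method-of-moments start for phi from the variance identity."""
    p = x / n
    pbar = float(np.clip(p.mean(), _EPS, 1 - _EPS))
    if p.size < 2:
        return 0.01
    excess = p.var(ddof=1) / (pbar * (1 - pbar)) - 1.0 / n.mean()
    phi = excess / max(1.0 - 1.0 / n.mean(), _EPS)
    return float(np.clip(phi, 1e-4, 0.9))


def fit_betabinom(
    x_row: np.ndarray,
    n: np.ndarray,
    design: np.ndarray,
    link: str = "logit",
    fix_phi: float | None = None,
) -> BetaBinomFit:
    """Maximize the marginal beta-binomial log-likelihood over (b, phi).

    phi is optimized on an unconstrained logit scale with deterministic
    multi-starts (moment estimate, a small-phi start, and per-group
    proportions when the design carries a group column), each polished
    with a derivative-free pass because finite-difference gradients are
    noisy near the phi boundary.  A fit pinned at the lower phi bound is
    reported as a binomial fit with ``boundary_phi`` set.  ``fix_phi``
    holds the overdispersion constant (0 gives the plain binomial model).
    """
    x_row = np.asarray(x_row, dtype=float)
    n = np.asarray(n, dtype=float)
    X = np.atleast_2d(np.asarray(design, dtype=float))
    n_coef = X.shape[1]
    choose = gammaln(n + 1) - gammaln(x_row + 1) - gammaln(n - x_row + 1)

    def loglik_at(pi: np.ndarray, phi: float) -> float:
        # lean unchecked objective; betabinom_logpmf is the public (checked) pmf
        if phi < _PHI_FLOOR:
            ll = choose + x_row * np.log(pi) + (n - x_row) * np.log1p(-pi)
        else:
            alpha = pi * (1.0 - phi) / phi
            beta = (1.0 - pi) * (1.0 - phi) / phi
            ll = choose + betaln(alpha + x_row, n + beta - x_row) - betaln(alpha, beta)
        return float(ll.sum())

    pbar = float(np.clip(x_row.sum() / n.sum(), 1e-6, 1 - 1e-6))
    b0 = np.zeros(n_coef)
    b0[0] = logit(pbar)
    b_starts = [b0]
    if n_coef == 2 and set(np.unique(X[:, 1])) <= {0.0, 1.0}:
        # start from the per-group observed proportions
        g = X[:, 1] == 1.0
        p0 = float(np.clip(x_row[~g].sum() / n[~g].sum(), 1e-6, 1 - 1e-6))
        p1 = float(np.clip(x_row[g].sum() / n[g].sum(), 1e-6, 1 - 1e-6))
        b_starts.append(np.array([logit(p0), logit(p1) - logit(p0)]))

    if fix_phi is not None:
        phi_fixed = float(fix_phi)

        def nll(b: np.ndarray) -> float:
            return -loglik_at(_inverse_link(X @ b, link), phi_fixed)

        best, success = None, False
        for b_s in b_starts:
            res = minimize(nll, b_s, method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-11,
                                    "maxiter": 4000})
            if best is None or res.fun < best.fun - 1e-12:
                best = res
            success = success or bool(res.success)
        b = best.x
        return BetaBinomFit(
            b=b, phi=phi_fixed, loglik=-float(best.fun), converged=success,
            pi=_inverse_link(X @ b, link), design=X, link=link,
            boundary_phi=phi_fixed == 0.0,
        )

    def nll(params: np.ndarray) -> float:
        pi = _inverse_link(X @ params[:-1], link)
        return -loglik_at(pi, max(float(expit(params[-1])), 1e-9))

    phi_starts = [logit(np.clip(_moment_phi(x_row, n), 1e-4, 0.9)), logit(0.01)]
    starts = [np.append(b_s, t) for b_s in b_starts for t in phi_starts]
    bounds = [(-30.0, 30.0)] * n_coef + [(logit(1e-6), logit(0.99))]
    best, success = None, False
    for s in starts:
        res_g = minimize(nll, s, method="L-BFGS-B", bounds=bounds,
                         options={"maxiter": 500, "ftol": 1e-11})
        res = minimize(nll, res_g.x, method="Nelder-Mead",
                       options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 3000})
        if best is None or res.fun < best.fun - 1e-12:
            best = res
        success = success or bool(res.success) or bool(res_g.success)
    b = np.clip(best.x[:-1], -30.0, 30.0)
    phi = float(expit(np.clip(best.x[-1], logit(1e-6), logit(0.99))))
    if phi <= 1.5e-6:
        # pinned at the lower bound: the logit-phi direction is flat there
        # and defeats the optimizers' stopping rules, so refit the
        # well-behaved binomial limit directly
        fit = fit_betabinom(x_row, n, X, link, fix_phi=0.0)
        fit.boundary_phi = True
        return fit
    return BetaBinomFit(
        b=b,
        phi=phi,
        loglik=-float(best.fun),
        converged=success and np.isfinite(best.fun),
        pi=_inverse_link(X @ b, link),
        design=X,
        link=link,
        boundary_phi=False,
    )


def _group_design(groups: list[str]) -> tuple[np.ndarray, list[str]]:
    levels = sorted(set(groups))
    if len(levels) != 2:
        raise ValueError("exactly two groups are required for the test")
    ind = np.array([1.0 if g == levels[1] else 0.0 for g in groups])
    return np.column_stack([np.ones(len(groups)), ind]), levels


def lrt_test(
    x_row: np.ndarray,
    n: np.ndarray,
    groups: list[str],
    link: str = "logit",
    fix_phi: float | None = None,
) -> tuple[float, float, BetaBinomFit, BetaBinomFit]:
    """Likelihood-ratio test of the group coefficient being zero.

    Returns (statistic, p, null fit, alternative fit); the statistic is
    floored at zero and referred to chi-squared with one degree of
    freedom.  With ``fix_phi=0`` the test reduces to the binomial LRT.
    """
    X_alt, _ = _group_design(groups)
    X_null = X_alt[:, :1]
    fit_null = fit_betabinom(x_row, n, X_null, link, fix_phi=fix_phi)
    fit_alt = fit_betabinom(x_row, n, X_alt, link, fix_phi=fix_phi)
    stat = max(0.0, 2.0 * (fit_alt.loglik - fit_null.loglik))
    return stat, float(chi2.sf(stat, df=1)), fit_null, fit_alt


def wald_test(
    x_row: np.ndarray,
    n: np.ndarray,
    groups: list[str],
    link: str = "logit",
) -> tuple[float, float]:
    """Wald z-test of the group coefficient, for comparison with the LRT.

    The standard error comes from a central-difference Hessian of the
    negative log-likelihood at the optimum.
    """
    X_alt, _ = _group_design(groups)
    fit = fit_betabinom(x_row, n, X_alt, link)
    phi = max(fit.phi, 1e-6)
    theta = np.append(fit.b, logit(phi))

    def nll(params):
        pi = _inverse_link(X_alt @ params[:-1], link)
        return -float(np.sum(betabinom_logpmf(x_row, n, pi, float(expit(params[-1])))))

    h = 1e-4
    k = theta.size
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.eye(k)[i] * h
            ej = np.eye(k)[j] * h
            H[i, j] = H[j, i] = (
                nll(theta + ei + ej) - nll(theta + ei - ej)
                - nll(theta - ei + ej) + nll(theta - ei - ej)
            ) / (4 * h * h)
    cov = np.linalg.pinv(H)
    se = np.sqrt(max(cov[1, 1], _EPS))
    z = fit.b[1] / se
    return float(z * z), float(chi2.sf(z * z, df=1))


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values; NaNs pass through."""
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def run_dep(
    table: CountTable,
    alpha: float = 0.05,
    link: str = "logit",
    shared_only: bool = True,
    cluster_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-cluster beta-binomial LRT with BH correction.

    By default only clusters observed in both sample groups are tested
    (group-exclusive clusters are reported descriptively elsewhere); an
    additional boolean ``cluster_mask`` (e.g. a retention-time CV pass
    filter) further restricts the testing universe.  Returns a frame with
    statistic, p, q, fitted group proportions and direction; rows with a
    failed fit carry NaN p and do not enter the BH universe.
    """
    mask = np.ones(table.n_clusters, dtype=bool)
    if shared_only:
        mask &= table.shared_mask()
    if cluster_mask is not None:
        mask &= np.asarray(cluster_mask, dtype=bool)
    idx = np.flatnonzero(mask)
    levels = table.group_levels
    rows = []
    for i in idx:
        stat, p, fit0, fit1 = lrt_test(table.x[i], table.n, table.groups, link)
        if not (fit0.converged and fit1.converged):
            stat, p = np.nan, np.nan
            logger.warning("fit did not converge for cluster %s", table.cluster_ids[i])
        g = np.asarray(table.groups)
        pi_by_level = [float(fit1.pi[g == lev].mean()) for lev in levels]
        rows.append(
            {
                "cluster_id": table.cluster_ids[i],
                "statistic": stat,
                "p": p,
                f"pi_{levels[0]}": pi_by_level[0],
                f"pi_{levels[1]}": pi_by_level[1],
                "phi": fit1.phi,
                "direction": (
                    f"up in {levels[0]}"
                    if pi_by_level[0] > pi_by_level[1]
                    else f"up in {levels[1]}"
                ),
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "statistic", "p",
            f"pi_{levels[0]}", f"pi_{levels[1]}", "phi", "direction",
        ],
    )
    if len(result):
        result["q"] = bh_adjust(result["p"].to_numpy())
        result["significant"] = result["q"] <= alpha
    else:
        result["q"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
    return result
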