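"""Association tests, calibration machinery and multiple-testing statistics.

Burden and dosage effects on degree HL are estimated by ordinary least
squares with sex, age, age^2 and genetic principal components as covariates;
binary contrasts use logistic regression.  Per-gene and per-variant scans are
run through a Frisch-Waugh-Lovell residualisation path that reproduces the
full-design OLS coefficient, standard error and Wald p exactly while
factoring the covariate projection out of the per-unit loop.  Calibration
utilities cover the genomic inflation factor lambda, permutation-based
selection of carrier/frequency thresholds, Benjamini-Hochberg FDR, and the
replication statistics (Bonferroni min-p rule, exact binomial tail).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

#: Median of the chi-square distribution with one degree of freedom.
CHI2_1_MEDIAN = 0.4549364231195724


def build_covariates(covariates: pd.DataFrame, n_pcs: int = 20) -> pd.DataFrame:
    """Standard covariate design: sex, age, age^2 and the first ``n_pcs`` PCs.

    ``age2`` is always derived from ``age`` here; supplying it independently
    is not supported.
    """
    cols = {"sex": covariates["sex"].astype(float), "age": covariates["age"].astype(float)}
    cols["age2"] = cols["age"] ** 2
    for i in range(1, n_pcs + 1):
        name = f"PC{i}"
        if name not in covariates.columns:
            raise ValueError(f"covariate table lacks {name}")
        cols[name] = covariates[name].astype(float)
    out = pd.DataFrame(cols)
    out.index = covariates.index
    return out


def _design(x: np.ndarray, covariates) -> tuple[np.ndarray, list[str]]:
    n = len(x)
    parts = [np.ones((n, 1)), np.asarray(x, float).reshape(n, 1)]
    names = ["const", "x"]
    if covariates is not None and np.size(covariates):
        cov = pd.DataFrame(covariates)
        parts.append(cov.to_numpy(float))
        names += [str(c) for c in cov.columns]
    return np.hstack(parts), names


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns lying (numerically) in the span of the preceding columns."""
    bad = []
    basis = np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        col = X[:, j : j + 1]
        if basis.shape[1]:
            resid = col - basis @ np.linalg.lstsq(basis, col, rcond=None)[0]
        else:
            resid = col
        if np.linalg.norm(resid) <= 1e-8 * max(np.linalg.norm(col), 1.0):
            bad.append(names[j])
        else:
            q = resid / np.linalg.norm(resid)
            basis = np.hstack([basis, q])
    return bad


def linear_test(y, x, covariates=None) -> dict:
    """OLS of ``y`` on ``x`` plus covariates; Wald test on the ``x`` coefficient.

    Returns ``{"beta", "se", "p", "n", "t"}``.  Complete cases only are the
    caller's responsibility.  A constant predictor or rank-deficient design
    raises ``ValueError`` (naming the collinear columns).
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: x has zero variance")
    X, names = _design(x, covariates)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient design; collinear columns: {_collinear_columns(X, names)}")
    fit = sm.OLS(y, X).fit()
    return {
        "beta": float(fit.params[1]),
        "se": float(fit.bse[1]),
        "t": float(fit.tvalues[1]),
        "p": float(fit.pvalues[1]),
        "n": int(len(y)),
    }


def linear_scan(y, X, covariates=None, names: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-column OLS scan of ``y`` on each column of ``X`` with shared covariates.

    Uses Frisch-Waugh-Lovell: ``y`` and every predictor are residualised
    against the covariate block (plus intercept), and the slope, classical
    SE and two-sided Wald p of the full model are recovered with the full
    model's residual degrees of freedom.  Columns with no residual variance
    yield NaN rows.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(y)
    Z = np.ones((n, 1))
    if covariates is not None and np.size(covariates):
        Z = np.hstack([Z, pd.DataFrame(covariates).to_numpy(float)])
    Q, _ = np.linalg.qr(Z)
    ry = y - Q @ (Q.T @ y)
    RX = X - Q @ (Q.T @ X)
    sxx = np.einsum("ij,ij->j", RX, RX)
    sxy = ry @ RX
    dof = n - Z.shape[1] - 1
    # a column absorbed by the covariates has (numerically) zero residual variance
    degenerate = sxx <= 1e-12 * np.einsum("ij,ij->j", X, X) + 1e-300
    sxx = np.where(degenerate, np.nan, sxx)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(~degenerate, sxy / np.where(degenerate, 1.0, sxx), np.nan)
        rss = ry @ ry - beta**2 * sxx
        sigma2 = rss / dof
        se = np.sqrt(sigma2 / np.where(sxx > 0, sxx, np.nan))
        t = beta / se
    p = 2 * st.t.sf(np.abs(t), dof)
    out = pd.DataFrame({"beta": beta, "se": se, "t": t, "p": p, "n": n})
    if names is not None:
        out.insert(0, "unit", list(names))
    return out


def logistic_test(y, x, covariates=None, maxiter: int = 100, tol: float = 1e-8) -> dict:
    """Logistic regression of binary ``y`` on ``x`` plus covariates.

    Maximum likelihood by Newton iteration; non-convergence or a diverging
    coefficient is reported as complete separation: the result carries
    ``separation=True`` and a missing p-value.
    """
    y = np.asarray(y, float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    X, names = _design(x, covariates)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=maxiter, tol=tol, warn_convergence=False)
        except Exception:
            return {"beta": np.nan, "se": np.nan, "p": np.nan, "n": len(y), "separation": True}
    converged = bool(fit.mle_retvals.get("converged", True))
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    if not converged or not np.isfinite(se) or abs(beta) > 15:
        return {"beta": beta, "se": np.nan, "p": np.nan, "n": len(y), "separation": True}
    return {"beta": beta, "se": se, "p": float(fit.pvalues[1]), "n": int(len(y)), "separation": False}


def degree_level_effects(
    phenotypes: pd.DataFrame,
    burdens_by_stratum: Mapping[str, pd.Series],
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Logistic contrast of each degree HL 1-4 against degree 0.

    For each degree ``k`` the model is fit on the subset with degree in
    ``{0, k}`` (phecode-derived 0s included), outcome = (degree == k), for
    each variant stratum's burden (e.g. all / ClinVar-only / non-ClinVar).
    Empty degree groups are skipped with a warning.
    """
    phen = phenotypes[phenotypes["included"]].set_index("individual_id")
    deg = phen["degree_hl"].astype(float)
    rows = []
    for k in (1, 2, 3, 4):
        sel = deg.index[(deg == 0) | (deg == k)]
        yk = (deg.loc[sel] == k).astype(float)
        if yk.sum() == 0 or yk.sum() == len(yk):
            warnings.warn(f"degree {k}: empty contrast group, skipped")
            continue
        for stratum, burden in burdens_by_stratum.items():
            res = logistic_test(
                yk.to_numpy(),
                burden.reindex(sel).to_numpy(float),
                covariates.loc[sel],
            )
            rows.append({"degree": k, "stratum": stratum, **res})
    return pd.DataFrame(rows)


def fisher_carrier_test(table) -> float:
    """Two-sided Fisher exact p for a 2x2 carrier table.

    The two-sided p sums hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed the observed table's.
    A zero margin is degenerate: p = 1 by convention (with a warning).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a 2x2 table of nonnegative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("zero margin in 2x2 table; p = 1 by convention")
        return 1.0
    return float(st.fisher_exact(t, alternative="two-sided")[1])


def gwas(
    dosages: np.ndarray,
    variants: pd.DataFrame,
    y,
    covariates=None,
    maf_min: float = 0.01,
    rsq_min: float = 0.30,
) -> pd.DataFrame:
    """Additive-model common-variant scan with MAF and imputation-R^2 filters.

    ``variants`` needs ``variant_id`` and ``rsq`` columns; MAF is computed
    from the dosage matrix (individuals x variants, dosages in [0,2]).
    Variants failing ``MAF > maf_min`` or ``R^2 > rsq_min`` are absent from
    the output.
    """
    D = np.asarray(dosages, float)
    af = D.mean(axis=0) / 2.0
    maf = np.minimum(af, 1 - af)
    keep = (maf > maf_min) & (variants["rsq"].to_numpy(float) > rsq_min)
    kept = variants.loc[keep].reset_index(drop=True)
    res = linear_scan(y, D[:, keep], covariates, names=kept["variant_id"])
    res["maf"] = maf[keep]
    return res


def genomic_lambda(p_values) -> float:
    """Genomic inflation factor: median association chi^2 over the null median.

    Each p is converted to its one-degree-of-freedom chi-square quantile;
    lambda = median(chi^2) / 0.4549 (the chi^2_1 median), so uniform p-values
    give lambda = 1.
    """
    p = np.asarray(p_values, float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = st.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def bh_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``m`` is the effective number of tests; it defaults to ``len(p_values)``
    but can be larger when only the smallest p-values are supplied (the
    implicit remainder behaves as p = 1 and cannot lower any step-up
    minimum).  q_(i) = min_{j >= i} m p_(j) / j, capped at 1, returned in
    the input order.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    k = p.size
    if m is None:
        m = k
    if m < k:
        raise ValueError("effective m cannot be smaller than the number of p-values")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, k + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(k)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def bonferroni_min_p_replication(p_values, alpha: float = 0.05) -> dict:
    """Min-p Bonferroni replication rule over a battery of models.

    A gene replicates when the smallest p-value across the ``m`` models is
    below ``alpha / m``.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    m = p.size
    min_p = float(np.min(p))
    threshold = alpha / m
    return {"replicated": bool(min_p < threshold), "min_p": min_p, "threshold": threshold, "m": m}


def binomial_replication(k: int, n: int, p0: float = 0.05) -> float:
    """Exact upper-tail binomial test: P(X >= k) for X ~ Binomial(n, p0).

    Used to ask whether more previously-reported association signals
    re-appear at p < 0.05 than expected by chance.
    """
    if not (0 < p0 < 1):
        raise ValueError("p0 must lie in (0, 1)")
    if not (0 <= k <= n):
        raise ValueError("k must lie in [0, n]")
    return float(st.binom.sf(k - 1, n, p0))


@dataclass
class CalibrationReport:
    """Outcome of a permutation threshold calibration.

    ``trajectory`` records (threshold, permuted-phenotype lambda, number of
    tests run) in increasing threshold order; ``chosen_threshold`` is the
    first threshold with lambda <= ``lambda_max``, or None if the grid is
    exhausted.
    """

    trajectory: list = field(default_factory=list)
    chosen_threshold: float | None = None
    lambda_max: float = 1.05
    n_perms: int = 10
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.trajectory, columns=["threshold", "lambda", "n_tests"])


def permutation_calibration(
    test_runner: Callable[[float, np.ndarray], np.ndarray],
    phenotype,
    thresholds: Sequence[float] | None = None,
    start: float = 0.0,
    increment: float = 5.0,
    stop: float = 50.0,
    lambda_max: float = 1.05,
    n_perms: int = 10,
    seed: int | None = None,
) -> CalibrationReport:
    """Pick the smallest filter threshold with no permuted-phenotype inflation.

    The phenotype vector is randomly permuted (covariates stay attached to
    individuals — only the outcome is shuffled, which preserves every null
    except the phenotype-genotype link); ``test_runner(threshold, permuted)``
    re-runs the scan and returns its p-value vector.  Lambda is averaged over
    ``n_perms`` permutations per threshold, walking the grid from its floor
    upward by ``increment`` (or over an explicit ``thresholds`` sequence,
    e.g. a MAF grid for the common-variant scan) and stopping at the first
    threshold with average lambda <= ``lambda_max``.
    """
    if thresholds is None:
        thresholds = list(np.arange(start, stop + 0.5 * increment, increment))
    if not len(thresholds):
        raise ValueError("empty threshold grid")
    rng = np.random.default_rng(seed)
    y = np.asarray(phenotype, float)
    report = CalibrationReport(lambda_max=lambda_max, n_perms=n_perms, seed=seed)
    perms = [rng.permutation(len(y)) for _ in range(n_perms)]
    for thr in thresholds:
        lams, n_tests = [], 0
        for perm in perms:
            p = np.asarray(test_runner(thr, y[perm]), float)
            p = p[np.isfinite(p)]
            if p.size == 0:
                continue
            n_tests = max(n_tests, p.size)
            lams.append(genomic_lambda(p))
        lam = float(np.mean(lams)) if lams else np.nan
        report.trajectory.append((float(thr), lam, int(n_tests)))
        if np.isfinite(lam) and lam <= lambda_max:
            report.chosen_threshold = float(thr)
            break
    return report
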