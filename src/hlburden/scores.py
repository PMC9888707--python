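"""Polygenic and burden risk-score application and evaluation.

PRS weights are externally estimated per-allele effects; the score is the
weighted sum of effect-allele dosages.  Predictive power is summarised as
incremental R^2 — the gain in the coefficient of determination when the
score is added to a covariate-only OLS of degree HL — with a bootstrap
standard error over individuals, overall and within ancestry / audiogram
strata.  Top-quantile risk stratification reports the odds ratio of
moderate-or-worse hearing loss for individuals high on both scores.
"""

from __future__ import annotations

import warnings
from typing import Callable, Mapping

import numpy as np
import pandas as pd


def apply_prs(
    dosages: np.ndarray,
    variants: pd.DataFrame,
    weights: pd.DataFrame,
    afs: np.ndarray | None = None,
) -> tuple[np.ndarray, dict]:
    """Per-individual polygenic score from a per-allele weight table.

    ``variants`` describes the dosage columns (``variant_id, ref, alt``) and
    ``weights`` has ``variant_id, effect_allele, other_allele, weight``.  The
    dosage convention is alt-allele dose in [0, 2]; when the effect allele is
    the reference allele the dosage is flipped as ``2 - d``.  Weight rows
    whose variant is absent, or whose alleles cannot be reconciled by a flip,
    are skipped and counted.  Missing dosages (NaN) are imputed as twice the
    effect-allele frequency (``afs`` are alt-allele frequencies; computed
    from the matrix when not given).

    Returns ``(scores, report)`` with match/flip/skip counts.
    """
    D = np.asarray(dosages, float)
    n = D.shape[0]
    if afs is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            afs = np.nanmean(D, axis=0) / 2.0
    col = {v: j for j, v in enumerate(variants["variant_id"])}
    ref = variants["ref"].to_numpy()
    alt = variants["alt"].to_numpy()
    scores = np.zeros(n)
    matched = flipped = skipped = 0
    for row in weights.itertuples(index=False):
        j = col.get(row.variant_id)
        if j is None:
            skipped += 1
            continue
        if row.effect_allele == alt[j] and row.other_allele == ref[j]:
            d = D[:, j]
            eaf = afs[j]
        elif row.effect_allele == ref[j] and row.other_allele == alt[j]:
            d = 2.0 - D[:, j]
            eaf = 1.0 - afs[j]
            flipped += 1
        else:
            skipped += 1
            continue
        d = np.where(np.isnan(d), 2.0 * eaf, d)
        scores += row.weight * d
        matched += 1
    report = {"matched": matched, "flipped": flipped, "skipped": skipped}
    return scores, report


def _r2(y: np.ndarray, X: np.ndarray) -> float:
    """Classical in-sample R^2 of OLS with intercept."""
    Xc = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    resid = y - Xc @ beta
    tss = np.sum((y - y.mean()) ** 2)
    if tss == 0:
        return 0.0
    return float(1.0 - resid @ resid / tss)


def incremental_r2(y, covariates, score) -> float:
    """Incremental R^2 of a score over the covariate-only model.

    Delta R^2 = R^2(covariates + score) - R^2(covariates), both by OLS on the
    same complete cases.  A constant score yields 0 with a warning.
    """
    y = np.asarray(y, float)
    C = pd.DataFrame(covariates).to_numpy(float)
    s = np.asarray(score, float)
    if np.ptp(s) == 0:
        warnings.warn("score is constant; incremental R^2 is 0")
        return 0.0
    return _r2(y, np.column_stack([C, s])) - _r2(y, C)


def bootstrap_se(
    evaluator: Callable[[np.ndarray], float],
    n: int,
    B: int = 1000,
    seed: int | None = None,
) -> float:
    """Bootstrap SE of a statistic over resampled individuals.

    ``evaluator(idx)`` computes the statistic on the rows indexed by ``idx``;
    the SE is the standard deviation over ``B`` resamples with replacement.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap resamples")
    if n < 10:
        raise ValueError("too few individuals to bootstrap")
    rng = np.random.default_rng(seed)
    stats = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        stats[b] = evaluator(idx)
    return float(np.std(stats, ddof=1))


def incremental_r2_with_se(y, covariates, score, B: int = 1000, seed: int | None = None):
    """Incremental R^2 together with its bootstrap standard error."""
    y = np.asarray(y, float)
    C = pd.DataFrame(covariates).to_numpy(float)
    s = np.asarray(score, float)
    delta = incremental_r2(y, C, s)

    def _eval(idx):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return incremental_r2(y[idx], C[idx], s[idx])

    se = bootstrap_se(_eval, len(y), B=B, seed=seed)
    return delta, se


def stratified_evaluation(
    y,
    covariates: pd.DataFrame,
    scores: Mapping[str, np.ndarray],
    strata: Mapping[str, np.ndarray],
    min_size: int = 50,
    B: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Incremental R^2 per score kind and stratum (layout of a predictive-power table).

    ``strata`` maps a label (e.g. "all", "EUR", "AFR", "audiogram:EUR") to a
    boolean mask over individuals.  Strata smaller than ``min_size`` are
    reported with missing values.  With ``B > 0`` a bootstrap SE is added.
    """
    y = np.asarray(y, float)
    C = pd.DataFrame(covariates).to_numpy(float)
    rows = []
    for kind, score in scores.items():
        s = np.asarray(score, float)
        for label, mask in strata.items():
            mask = np.asarray(mask, bool)
            row = {"score": kind, "stratum": label, "n": int(mask.sum())}
            if mask.sum() < min_size:
                row["delta_r2"] = np.nan
                row["se"] = np.nan
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    row["delta_r2"] = incremental_r2(y[mask], C[mask], s[mask])
                    if B > 0:
                        _, row["se"] = incremental_r2_with_se(
                            y[mask], C[mask], s[mask], B=B, seed=seed
                        )
                    else:
                        row["se"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def top_decile_or(
    score_a,
    phenotypes,
    score_b=None,
    q: float = 0.90,
    hl_threshold: float = 2,
) -> dict:
    """Odds ratio of degree HL >= threshold for the top score quantile group.

    Exposure = score_a above its empirical ``q``-quantile (strict ``>``),
    intersected with the same condition on ``score_b`` when given; outcome =
    degree HL >= ``hl_threshold``.  The OR uses the Haldane-Anscombe 0.5
    continuity correction when a cell is zero, with a Woolf log-OR normal CI.
    """
    a = np.asarray(score_a, float)
    deg = np.asarray(phenotypes, float)
    exposed = a > np.quantile(a, q)
    if score_b is not None:
        b = np.asarray(score_b, float)
        exposed &= b > np.quantile(b, q)
    if not exposed.any():
        raise ValueError("empty exposure group")
    outcome = deg >= hl_threshold
    n11 = int(np.sum(exposed & outcome))
    n10 = int(np.sum(exposed & ~outcome))
    n01 = int(np.sum(~exposed & outcome))
    n00 = int(np.sum(~exposed & ~outcome))
    cells = np.array([n11, n10, n01, n00], float)
    corrected = cells + 0.5 if (cells == 0).any() else cells
    orr = (corrected[0] * corrected[3]) / (corrected[1] * corrected[2])
    se_log = float(np.sqrt(np.sum(1.0 / corrected)))
    ci = (float(np.exp(np.log(orr) - 1.959964 * se_log)), float(np.exp(np.log(orr) + 1.959964 * se_log)))
    return {
        "odds_ratio": float(orr),
        "ci95": ci,
        "table": {"exposed_case": n11, "exposed_ctrl": n10, "rest_case": n01, "rest_ctrl": n00},
        "quantile": q,
        "hl_threshold": hl_threshold,
        "n_exposed": int(exposed.sum()),
    }
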