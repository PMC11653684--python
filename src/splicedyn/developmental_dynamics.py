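"""Developmentally dynamic exon detection via quasi-binomial GLMs.

Inclusion (PSI) per sample is modelled on the logit scale with junction
totals as prior weights.  A full model (natural cubic spline of stage rank)
is compared with an intercept-only null by a quasi-likelihood F-test:

    F = ((D0 - D1) / df_num) / phi_full,   phi = Pearson chi^2 / (n - p)

with the denominator degrees of freedom taken from the full model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

_EPS = 1e-10


@dataclass
class GlmFit:
    """Result of one iteratively-reweighted least-squares fit."""

    coefficients: np.ndarray
    fitted: np.ndarray
    deviance: float
    pearson: float
    dispersion: float  # Pearson chi^2 / (n - p)
    df_resid: int
    rank: int
    converged: bool
    n_iter: int


def _binomial_deviance(y: np.ndarray, mu: np.ndarray, w: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        term2 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
    return float(2.0 * np.sum(w * (term1 + term2)))


def fit_quasibinomial_glm(
    response: np.ndarray,
    design: np.ndarray,
    weights: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> GlmFit:
    """Fit a logit-link quasi-binomial GLM by IRLS.

    ``response`` holds proportions in [0, 1]; ``weights`` are the binomial
    totals backing each proportion (1 where no count evidence exists, e.g.
    imputed cells).
    """
    y = np.asarray(response, dtype=float)
    X = np.atleast_2d(np.asarray(design, dtype=float))
    if X.shape[0] != y.size:
        raise ValueError("design and response lengths differ")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("response values must lie in [0, 1]")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError(f"rank-deficient design matrix (rank {rank} < {p} columns)")
    if n <= p:
        raise ValueError("more parameters than observations")

    # shrunken start keeps the first working response finite at y in {0, 1}
    mu = (w * y + 0.5) / (w + 1.0)
    eta = np.log(mu / (1 - mu))
    deviance = _binomial_deviance(y, mu, w)
    converged = False
    it = 0
    beta = np.zeros(p)
    for it in range(1, max_iter + 1):
        variance = mu * (1 - mu)
        working_w = w * variance
        z = eta + (y - mu) / variance
        sw = np.sqrt(working_w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, _EPS, 1 - _EPS)
        new_deviance = _binomial_deviance(y, mu, w)
        if abs(new_deviance - deviance) / (abs(new_deviance) + 0.1) < tol:
            deviance = new_deviance
            converged = True
            break
        deviance = new_deviance

    pearson = float(np.sum(w * (y - mu) ** 2 / (mu * (1 - mu))))
    df_resid = n - p
    dispersion = pearson / df_resid if df_resid > 0 else np.nan
    return GlmFit(
        coefficients=beta,
        fitted=mu,
        deviance=deviance,
        pearson=pearson,
        dispersion=dispersion,
        df_resid=df_resid,
        rank=rank,
        converged=converged,
        n_iter=it,
    )


def quasi_f_test(null_fit: GlmFit, full_fit: GlmFit) -> tuple[float, int, int, float]:
    """Quasi-likelihood ratio F-test of a nested pair of fits.

    Returns (F, df_num, df_den, pvalue); dispersion is taken from the full
    model.
    """
    df_num = null_fit.df_resid - full_fit.df_resid
    df_den = full_fit.df_resid
    if df_num <= 0 or df_den <= 0:
        raise ValueError("models are not nested with positive degrees of freedom")
    phi = full_fit.dispersion
    if not np.isfinite(phi) or phi <= 0:
        return np.nan, df_num, df_den, np.nan
    delta = max(null_fit.deviance - full_fit.deviance, 0.0)
    f_stat = (delta / df_num) / phi
    pvalue = float(stats.f.sf(f_stat, df_num, df_den))
    return float(f_stat), df_num, df_den, pvalue


def natural_spline_basis(x: np.ndarray, df: int) -> np.ndarray:
    """Natural cubic spline basis (no intercept column) with ``df`` columns.

    Knots sit at evenly spaced quantiles of the distinct values of ``x``
    (boundary knots at min and max); beyond the boundary the basis is
    linear, as required for a natural spline.
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    if df == 1:
        return x[:, None]
    distinct = np.unique(x)
    n_knots = df + 1
    if distinct.size < n_knots:
        raise ValueError(
            f"need at least {n_knots} distinct values for df={df}, "
            f"got {distinct.size}"
        )
    knots = np.quantile(distinct, np.linspace(0, 1, n_knots))

    def truncated_cubic(k: float) -> np.ndarray:
        return np.maximum(x - k, 0.0) ** 3

    last, penult = knots[-1], knots[-2]

    def d(k: float) -> np.ndarray:
        return (truncated_cubic(k) - truncated_cubic(last)) / (last - k)

    columns = [x] + [d(knots[j]) - d(penult) for j in range(n_knots - 2)]
    return np.column_stack(columns)


def qlrt_devtest(
    psi_matrix,
    stages: np.ndarray | None = None,
    spline_df: int = 3,
) -> pd.DataFrame:
    """Quasi-likelihood ratio test for stage-dependent inclusion, per event.

    ``stages`` defaults to the ``stage`` field of the matrix metadata.
    Stage values enter as dense ranks; ``spline_df`` is capped at
    (#distinct stages - 1).  Returns one row per event with the F statistic,
    degrees of freedom, dispersion, p-value and BH-adjusted p-value
    (``adjusted_pvalue``); non-convergent fits get NaN p-values and are
    excluded from adjustment.
    """
    from .differential_splicing import benjamini_hochberg

    if stages is None:
        if psi_matrix.metadata is None:
            raise ValueError("no stages given and matrix carries no metadata")
        stages = np.array([m.stage for m in psi_matrix.metadata], dtype=float)
        if np.isnan(stages).any():
            raise ValueError("stage undefined for some samples")
    stages = np.asarray(stages, dtype=float)
    if stages.size != len(psi_matrix.sample_ids):
        raise ValueError("stage vector length does not match sample count")
    n_distinct = np.unique(stages).size
    if n_distinct < 3:
        raise ValueError(f"need at least 3 distinct stages, got {n_distinct}")
    df = min(spline_df, n_distinct - 1)

    ranks = stats.rankdata(stages, method="dense").astype(float)
    basis = natural_spline_basis(ranks, df)
    n = stages.size
    design_full = np.column_stack([np.ones(n), basis])
    design_null = np.ones((n, 1))

    weights = _evidence_weights(psi_matrix)

    rows = []
    for i, event_id in enumerate(psi_matrix.event_ids):
        y = psi_matrix.psi[i]
        w = weights[i]
        if np.ptp(y) == 0.0:
            # constant inclusion carries no stage signal by convention
            rows.append(
                dict(event_id=event_id, f_statistic=0.0, df_num=df,
                     df_den=n - df - 1, dispersion=np.nan, pvalue=1.0,
                     converged=True)
            )
            continue
        null_fit = fit_quasibinomial_glm(y, design_null, w)
        full_fit = fit_quasibinomial_glm(y, design_full, w)
        if not (null_fit.converged and full_fit.converged):
            warnings.warn(f"IRLS did not converge for event {event_id}", stacklevel=2)
            rows.append(
                dict(event_id=event_id, f_statistic=np.nan, df_num=df,
                     df_den=full_fit.df_resid, dispersion=full_fit.dispersion,
                     pvalue=np.nan, converged=False)
            )
            continue
        f_stat, df_num, df_den, pvalue = quasi_f_test(null_fit, full_fit)
        rows.append(
            dict(event_id=event_id, f_statistic=f_stat, df_num=df_num,
                 df_den=df_den, dispersion=full_fit.dispersion, pvalue=pvalue,
                 converged=True)
        )
    results = pd.DataFrame(rows)
    adjusted = np.full(len(results), np.nan)
    tested = results["pvalue"].notna().to_numpy()
    if tested.any():
        adjusted[tested] = benjamini_hochberg(results.loc[tested, "pvalue"].to_numpy())
    results["adjusted_pvalue"] = adjusted
    return results


def _evidence_weights(psi_matrix) -> np.ndarray:
    """Totals (L+S) where counts were observed, 1 elsewhere (imputed cells)."""
    n_events = len(psi_matrix.event_ids)
    n_samples = len(psi_matrix.sample_ids)
    if psi_matrix.L is None or psi_matrix.S is None:
        return np.ones((n_events, n_samples))
    totals = (psi_matrix.L + psi_matrix.S).astype(float)
    weights = np.where(psi_matrix.missing_mask | (totals <= 0), 1.0, totals)
    return weights


def call_devses(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Apply the adjusted-p threshold (inclusive, <=) and label directions."""
    out = results.copy()
    adjusted = out["adjusted_pvalue"]
    out["is_devse"] = adjusted.notna() & (adjusted <= alpha)
    return out


def devse_fraction(results: pd.DataFrame) -> float:
    """Percentage of tested events called developmentally dynamic."""
    from .io_formats import summarize_overlap

    tested = results["pvalue"].notna()
    return summarize_overlap(int(results.loc[tested, "is_devse"].sum()), int(tested.sum()))
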