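"""Downstream stages: bootstrap stepwise selection, Cox regression on
incident events, the PCA effective-components Bonferroni rule, and the
covariate-adjusted metabolite / risk-factor correlation matrix."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .mwas import design_matrix


# ----------------------------------------------------------------------
# stepwise selection on bootstrap resamples


def _ols_rss(x: np.ndarray, y: np.ndarray) -> float:
    coef, residues, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < x.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design")
    resid = y - x @ coef
    return float(resid @ resid)


def _aic(rss: float, n: int, k: int) -> float:
    # Gaussian log-likelihood up to constants; penalty 2 per parameter
    return n * math.log(max(rss, 1e-300) / n) + 2 * (k + 1)


def _stepwise(z: np.ndarray, candidates: np.ndarray, y: np.ndarray) -> list[int]:
    """Forward-backward AIC selection over candidate columns; the forced
    design ``z`` is never removed."""
    n = len(y)
    selected: list[int] = []
    pool = list(range(candidates.shape[1]))
    current = _aic(_ols_rss(z, y), n, z.shape[1])
    improved = True
    while improved:
        improved = False
        # forward
        best_add, best_aic = None, current
        for j in pool:
            x = np.column_stack([z, candidates[:, selected + [j]]])
            a = _aic(_ols_rss(x, y), n, x.shape[1])
            if a < best_aic - 1e-10:
                best_add, best_aic = j, a
        if best_add is not None:
            selected.append(best_add)
            pool.remove(best_add)
            current = best_aic
            improved = True
        # backward (candidates only)
        best_drop, best_aic = None, current
        for j in selected:
            keep = [s for s in selected if s != j]
            x = np.column_stack([z, candidates[:, keep]]) if keep else z
            a = _aic(_ols_rss(x, y), n, x.shape[1])
            if a < best_aic - 1e-10:
                best_drop, best_aic = j, a
        if best_drop is not None:
            selected.remove(best_drop)
            pool.append(best_drop)
            current = best_aic
            improved = True
    return sorted(selected)


def _fit_coefs(z: np.ndarray, candidates: np.ndarray, selected: list[int],
               y: np.ndarray) -> np.ndarray:
    x = np.column_stack([z, candidates[:, selected]]) if selected else z
    coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    return coef[z.shape[1]:]


def stepwise_bootstrap(
    pheno: pd.DataFrame,
    metabolites: pd.DataFrame,
    outcome: str,
    forced_covariates,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap stability of stepwise variable selection.

    Stepwise (forward-backward, AIC) linear regression of the outcome on
    the candidate metabolites with all forced covariates kept in the model,
    repeated on ``n_boot`` bootstrap resamples of individuals.  For each
    candidate the output counts how often it is selected and how often its
    coefficient's sign differs from the full-sample reference fit.

    Rank-deficient resamples are redrawn (and counted in the
    ``n_redrawn`` attribute of the returned frame).
    """
    if metabolites.shape[1] < 2:
        raise ValueError("need at least 2 candidate metabolites")
    z, _ = design_matrix(pheno, forced_covariates)
    y = pheno[outcome].to_numpy(dtype=float)
    cand = metabolites.to_numpy(dtype=float)
    cand = (cand - cand.mean(axis=0)) / cand.std(axis=0, ddof=0)
    mask = (np.isfinite(y) & np.all(np.isfinite(z), axis=1)
            & np.all(np.isfinite(cand), axis=1))
    z, y, cand = z[mask], y[mask], cand[mask]
    n = len(y)
    names = list(metabolites.columns)

    # full-sample reference: stepwise signs; variables never selected fall
    # back to the all-candidate forced fit for a reference sign
    ref_selected = _stepwise(z, cand, y)
    ref_signs = np.sign(_fit_coefs(z, cand, list(range(cand.shape[1])), y))
    ref_step_coefs = _fit_coefs(z, cand, ref_selected, y)
    for pos, j in enumerate(ref_selected):
        ref_signs[j] = np.sign(ref_step_coefs[pos])

    rng = np.random.default_rng(seed)
    n_sel = np.zeros(cand.shape[1], dtype=int)
    n_sign = np.zeros(cand.shape[1], dtype=int)
    n_redrawn = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, size=n)
        try:
            sel = _stepwise(z[idx], cand[idx], y[idx])
        except np.linalg.LinAlgError:
            n_redrawn += 1
            if n_redrawn > 50 * n_boot:
                raise RuntimeError("too many degenerate bootstrap resamples")
            continue
        coefs = _fit_coefs(z[idx], cand[idx], sel, y[idx])
        for pos, j in enumerate(sel):
            n_sel[j] += 1
            if np.sign(coefs[pos]) != ref_signs[j] and ref_signs[j] != 0:
                n_sign[j] += 1
        b += 1
    out = pd.DataFrame({
        "variable": names,
        "n_selected": n_sel,
        "selection_freq": n_sel / n_boot,
        "n_sign_change": n_sign,
        "reference_sign": ref_signs.astype(int),
        "selected_full_sample": [j in ref_selected for j in range(cand.shape[1])],
    })
    out.attrs["n_boot"] = n_boot
    out.attrs["n_redrawn"] = n_redrawn
    return out


# ----------------------------------------------------------------------
# Cox stage


@dataclass
class CoxResult:
    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float
    log_hr: float
    se_log_hr: float
    ph_test_p: float
    n_events: int
    n_used: int

    def summary(self) -> str:
        return (f"HR per SD = {self.hazard_ratio:.3f} "
                f"({self.ci_lower:.3f}-{self.ci_upper:.3f}), "
                f"p = {self.p_value:.3g}; PH test p = {self.ph_test_p:.3g}; "
                f"{self.n_events} events / {self.n_used} individuals")


def cox_association(
    pheno: pd.DataFrame,
    metabolite,
    covariates,
    duration_col: str = "followup_time",
    event_col: str = "event_status",
) -> CoxResult:
    """Cox proportional-hazards association of incident events with one
    metabolite, adjusted for the given covariates.

    Partial-likelihood fit with Efron tie handling; the hazard ratio is per
    SD of the metabolite.  The proportional-hazards assumption is tested on
    the scaled Schoenfeld residuals against the rank of event time.
    """
    from lifelines import CoxPHFitter
    from lifelines.statistics import proportional_hazard_test

    z, names = design_matrix(pheno, covariates)
    met = np.asarray(metabolite, dtype=float)
    dur = pheno[duration_col].to_numpy(dtype=float)
    ev = pheno[event_col].to_numpy(dtype=float)
    mask = (np.isfinite(met) & np.isfinite(dur) & np.isfinite(ev)
            & np.all(np.isfinite(z), axis=1))
    if np.nanmin(dur[mask]) <= 0:
        raise ValueError("non-positive follow-up time")
    if ev[mask].sum() < 10:
        raise ValueError("fewer than 10 events")
    met = met[mask]
    met = (met - met.mean()) / met.std(ddof=0)
    df = pd.DataFrame(z[mask, 1:], columns=names[1:])  # lifelines adds no intercept
    df["metabolite_sd"] = met
    df["T"] = dur[mask]
    df["E"] = ev[mask]
    cph = CoxPHFitter()
    cph.fit(df, duration_col="T", event_col="E")
    beta = float(cph.params_["metabolite_sd"])
    se = float(cph.standard_errors_["metabolite_sd"])
    ph = proportional_hazard_test(cph, df, time_transform="rank")
    ph_p = float(ph.summary.loc["metabolite_sd", "p"].iloc[0]
                 if hasattr(ph.summary.loc["metabolite_sd", "p"], "iloc")
                 else ph.summary.loc["metabolite_sd", "p"])
    zcrit = stats.norm.ppf(0.975)
    return CoxResult(
        hazard_ratio=math.exp(beta),
        ci_lower=math.exp(beta - zcrit * se),
        ci_upper=math.exp(beta + zcrit * se),
        p_value=float(cph.summary.loc["metabolite_sd", "p"]),
        log_hr=beta,
        se_log_hr=se,
        ph_test_p=ph_p,
        n_events=int(ev[mask].sum()),
        n_used=int(mask.sum()),
    )


# ----------------------------------------------------------------------
# PCA effective components


def pca_effective_components(matrix, variance_threshold: float = 0.95) -> int:
    """Smallest k such that the top-k principal components of the
    column-standardized matrix explain >= the variance threshold.

    Constant columns are removed first.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("need a matrix with >= 3 rows and >= 2 columns")
    sd = x.std(axis=0, ddof=0)
    x = x[:, sd > 0]
    if x.shape[1] < 1:
        raise ValueError("all columns constant")
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
    s = np.linalg.svd(x, compute_uv=False)
    var = s ** 2
    frac = np.cumsum(var) / var.sum()
    return int(np.searchsorted(frac, variance_threshold - 1e-12) + 1)


def bonferroni_level(alpha: float, k: int) -> float:
    """Bonferroni-corrected per-test level for k effective tests."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return alpha / k


# ----------------------------------------------------------------------
# adjusted correlation matrix with hierarchical reordering


def risk_factor_correlation_matrix(
    metabolites: pd.DataFrame,
    risk_factors: pd.DataFrame | None = None,
    pheno: pd.DataFrame | None = None,
    covariates=(),
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Covariate-adjusted Spearman correlation matrix, reordered by
    average-linkage hierarchical clustering on 1 - |r|.

    Returns (correlations, p-values, significance flags) as aligned
    DataFrames; flags mark Bonferroni significance at the given
    family-wise alpha over all distinct pairs.
    """
    blocks = [metabolites]
    if risk_factors is not None:
        blocks.append(risk_factors)
    data = pd.concat(blocks, axis=1)
    x = data.to_numpy(dtype=float)
    if covariates:
        if pheno is None:
            raise ValueError("pheno table required when adjusting for covariates")
        z, _ = design_matrix(pheno, covariates)
        rows = np.all(np.isfinite(x), axis=1) & np.all(np.isfinite(z), axis=1)
        x, z = x[rows], z[rows]
        u, s, _ = np.linalg.svd(z, full_matrices=False)
        q = u[:, : int((s > s[0] * 1e-10).sum())]
        x = x - q @ (q.T @ x)
        n_adj = q.shape[1]
    else:
        rows = np.all(np.isfinite(x), axis=1)
        x = x[rows]
        n_adj = 0
    n = x.shape[0]
    if n < 3:
        raise ValueError("fewer than 3 complete cases")
    ranks = stats.rankdata(x, axis=0)
    r = np.corrcoef(ranks, rowvar=False)
    np.fill_diagonal(r, 1.0)
    df = max(n - n_adj - 2, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / np.clip(1.0 - r ** 2, 1e-15, None))
    pmat = 2.0 * stats.t.sf(np.abs(t), df)
    np.fill_diagonal(pmat, 0.0)

    m = r.shape[0]
    dist = 1.0 - np.abs(r)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = hierarchy.leaves_list(link)
    cols = data.columns[order]
    corr = pd.DataFrame(r[np.ix_(order, order)], index=cols, columns=cols)
    pvals = pd.DataFrame(pmat[np.ix_(order, order)], index=cols, columns=cols)
    n_pairs = m * (m - 1) // 2
    flags = pvals < bonferroni_level(alpha, max(n_pairs, 1))
    return corr, pvals, flags
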