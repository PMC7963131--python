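"""Metabolome-wide association scans with permutation-based significance.

The central objects follow the model/results idiom: :class:`MWAS` is built
from a :class:`~nmrmwas.spectra.SpectrumSet`, a phenotype table and a
:class:`ModelSpec`; ``fit()`` returns an :class:`MWASResults` carrying one
row per spectral feature — standardized regression coefficient (per SD of
the feature), its standard error, two-sided p-value, and the partial
Spearman correlation — plus ``summary()`` and a Manhattan export.

Family-wise error over the tens of thousands of correlated features is
controlled by the metabolome-wide significance level (MWSL): the outcome
vector is permuted across participants (covariates stay attached to their
samples), the per-permutation minimum p-value over all features is
recorded, and the per-variable threshold alpha' is the k-th smallest of
these minima with k = ceil(alpha * n_perm) — the 500th of 10 000 at a 5%
family-wise error rate.  The effective number of tests is ENT = alpha /
alpha'.

Two-stage design: features significant at alpha' in the discovery cohort
are taken to replication; a hit replicates when its replication p-value is
below 0.05 with the same direction of association.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .spectra import SpectrumSet
from .srv import Cluster, ClusterMap

MODEL1_COVARIATES = ("age", "sex", "ethnicity", "phase")
MODEL2_COVARIATES = MODEL1_COVARIATES + (
    "ldl", "hdl", "sbp", "smoking", "diabetes", "lipid_treatment", "bp_treatment")
CONTINUOUS_OUTCOMES = ("ln_cac1", "log10_imt")


@dataclass(frozen=True)
class ModelSpec:
    """Outcome plus adjustment set for one association model."""

    outcome: str
    covariates: tuple[str, ...]
    standardize_features: bool = True

    def __post_init__(self) -> None:
        if self.outcome not in CONTINUOUS_OUTCOMES + ("event",):
            raise ValueError(f"unknown outcome {self.outcome!r}")

    @classmethod
    def model1(cls, outcome: str = "ln_cac1", pooled: bool = False) -> "ModelSpec":
        """Minimal adjustment: age, sex, ethnicity, measurement phase
        (+ cohort when pooling cohorts)."""
        cov = MODEL1_COVARIATES + (("cohort",) if pooled else ())
        return cls(outcome, cov)

    @classmethod
    def model2(cls, outcome: str = "ln_cac1", pooled: bool = False) -> "ModelSpec":
        """Model 1 plus LDL/HDL cholesterol, systolic blood pressure,
        smoking status, diabetes, and lipid / blood-pressure treatment."""
        cov = MODEL2_COVARIATES + (("cohort",) if pooled else ())
        return cls(outcome, cov)


def transform_outcomes(pheno: pd.DataFrame) -> pd.DataFrame:
    """Populate ln_cac1 = ln(CAC+1) and log10_imt = log10(IMT)."""
    out = pheno.copy()
    if "cac_agatston" in out:
        cac = out["cac_agatston"].to_numpy(dtype=float)
        if np.nanmin(cac) < 0:
            raise ValueError("negative CAC score")
        out["ln_cac1"] = np.log1p(cac)
    if "imt_mm" in out:
        imt = out["imt_mm"].to_numpy(dtype=float)
        if np.nanmin(imt) <= 0:
            raise ValueError("non-positive IMT")
        out["log10_imt"] = np.log10(imt)
    return out


def design_matrix(pheno: pd.DataFrame, covariates) -> tuple[np.ndarray, list[str]]:
    """Covariate design with intercept; categoricals are dummy-coded."""
    missing = [c for c in covariates if c not in pheno.columns]
    if missing:
        raise ValueError(f"covariates not in phenotype table: {missing}")
    cols: list[pd.Series | pd.DataFrame] = []
    names = ["intercept"]
    parts = [np.ones((len(pheno), 1))]
    for c in covariates:
        col = pheno[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
            parts.append(dummies.to_numpy())
            names.extend(dummies.columns.tolist())
        else:
            parts.append(col.to_numpy(dtype=float).reshape(-1, 1))
            names.append(c)
    return np.hstack(parts), names


@dataclass
class MWSLResult:
    """Permutation estimate of the metabolome-wide significance level."""

    alpha: float
    n_perm: int
    permutation_min_p: np.ndarray  # sorted ascending, length n_perm
    alpha_prime: float
    ent: float
    seed: int
    k: int

    def __repr__(self) -> str:
        return (f"MWSLResult(alpha={self.alpha}, n_perm={self.n_perm}, "
                f"alpha_prime={self.alpha_prime:.3g}, ent={self.ent:.1f})")


def effective_number_of_tests(alpha: float, alpha_prime: float) -> float:
    """ENT = alpha / alpha': the number of independent tests that would
    need Bonferroni correction to reach the same per-variable level."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if not (0.0 < alpha_prime <= 1.0):
        raise ValueError("alpha_prime must be in (0, 1]")
    return alpha / alpha_prime


class MWAS:
    """Per-feature association model of a phenotype on spectral features.

    Each spectral feature is standardized (mean-centred, unit variance) and
    regressed on the outcome by ordinary least squares with the model's
    covariates; the per-feature coefficient, its two-sided p-value and the
    partial Spearman correlation (on covariate-adjusted residual ranks) are
    reported.  The scan is vectorised through the Frisch–Waugh–Lovell
    residualisation, which makes the 10 000-permutation MWSL estimate
    tractable at full spectral resolution.

    Parameters
    ----------
    spectra : SpectrumSet
    pheno : DataFrame with a ``sample_id`` column (or matching index)
    model : ModelSpec with a continuous outcome
    """

    def __init__(self, spectra: SpectrumSet, pheno: pd.DataFrame, model: ModelSpec):
        if model.outcome not in CONTINUOUS_OUTCOMES:
            raise ValueError(
                "MWAS handles the continuous outcomes; use cox_association "
                "for incident events")
        self.spectra = spectra
        self.model = model
        if "sample_id" in pheno.columns:
            pheno = pheno.set_index("sample_id")
        missing = [s for s in spectra.sample_ids if s not in pheno.index]
        if missing:
            raise ValueError(f"samples without phenotype rows: {missing[:5]}...")
        self.pheno = pheno.loc[spectra.sample_ids]
        self._prepared = None

    @classmethod
    def from_tsv(cls, spectra_path, pheno_path, model: ModelSpec) -> "MWAS":
        spectra = SpectrumSet.from_tsv(spectra_path)
        pheno = pd.read_csv(pheno_path, sep="\t")
        return cls(spectra, transform_outcomes(pheno), model)

    # -- internals -------------------------------------------------------

    def _prepare(self):
        """Complete-case residualisation shared by fit() and the MWSL."""
        if self._prepared is not None:
            return self._prepared
        z_full, _ = design_matrix(self.pheno, self.model.covariates)
        y_full = self.pheno[self.model.outcome].to_numpy(dtype=float)
        mask = np.isfinite(y_full) & np.all(np.isfinite(z_full), axis=1)
        n = int(mask.sum())
        z = z_full[mask]
        if n < z.shape[1] + 3:
            raise ValueError(
                f"insufficient complete cases: {n} for {z.shape[1]} columns")
        u, s, _ = np.linalg.svd(z, full_matrices=False)
        rank = int((s > s[0] * 1e-10).sum())
        q = u[:, :rank]
        y = y_full[mask]

        x = self.spectra.intensities[mask]
        mu = x.mean(axis=0)
        sd = x.std(axis=0, ddof=0)
        constant = sd <= 0
        sd_safe = np.where(constant, 1.0, sd)
        if self.model.standardize_features:
            x = (x - mu) / sd_safe
        ex = x - q @ (q.T @ x)
        ey = y - q @ (q.T @ y)
        df = n - rank - 1
        self._prepared = dict(mask=mask, n=n, q=q, rank=rank, y=y, ey=ey,
                              ex=ex, constant=constant, df=df)
        return self._prepared

    # -- fitting ---------------------------------------------------------

    def fit(self) -> "MWASResults":
        p = self._prepare()
        ex, ey, df, constant = p["ex"], p["ey"], p["df"], p["constant"]
        sxx = np.einsum("ij,ij->j", ex, ex)
        syy = float(ey @ ey)
        sxy = ex.T @ ey
        with np.errstate(invalid="ignore", divide="ignore"):
            beta = sxy / sxx
            sigma2 = np.maximum(syy - beta ** 2 * sxx, 0.0) / df
            se = np.sqrt(sigma2 / sxx)
            tstat = beta / se
        pval = 2.0 * stats.t.sf(np.abs(tstat), df)
        pval = np.clip(pval, np.finfo(float).tiny, 1.0)

        ranks_y = stats.rankdata(ey)
        ranks_x = stats.rankdata(ex, axis=0)
        ry = ranks_y - ranks_y.mean()
        rx = ranks_x - ranks_x.mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = (rx.T @ ry) / np.sqrt(
                np.einsum("ij,ij->j", rx, rx) * float(ry @ ry))

        beta[constant] = np.nan
        se[constant] = np.nan
        pval = pval.astype(float)
        pval[constant] = np.nan
        rho[constant] = np.nan
        table = pd.DataFrame({
            "feature_index": np.arange(self.spectra.n_features),
            "ppm": self.spectra.ppm,
            "beta_per_sd": beta,
            "se": se,
            "p_value": pval,
            "partial_spearman_rho": rho,
            "n_used": p["n"],
            "direction": np.sign(np.nan_to_num(beta)).astype(int),
            "note": np.where(constant, "constant", ""),
        })
        return MWASResults(table, self.model, df_resid=df, n_used=p["n"],
                           model_obj=self)

    # -- permutation MWSL -------------------------------------------------

    def estimate_mwsl(self, alpha: float = 0.05, n_perm: int = 10000,
                      seed: int = 0, chunk_size: int = 256) -> MWSLResult:
        """Permutation estimate of the per-variable threshold alpha'.

        Per permutation the outcome is randomly re-allocated across
        participants (covariates stay attached), the scan is re-run and the
        minimum p over features recorded; alpha' is the k-th smallest
        minimum with k = ceil(alpha * n_perm), and ENT = alpha / alpha'.
        """
        if n_perm * alpha < 1:
            raise ValueError("n_perm must be at least 1/alpha")
        p = self._prepare()
        q, y, ex, constant, df = p["q"], p["y"], p["ex"], p["constant"], p["df"]
        n = p["n"]
        exn = ex[:, ~constant]
        norms = np.sqrt(np.einsum("ij,ij->j", exn, exn))
        exn = exn / norms
        rng = np.random.default_rng(seed)
        max_abs_r = np.empty(n_perm)
        done = 0
        while done < n_perm:
            b = min(chunk_size, n_perm - done)
            perm = np.empty((n, b))
            for k in range(b):
                perm[:, k] = y[rng.permutation(n)]
            eyp = perm - q @ (q.T @ perm)
            eyp /= np.sqrt(np.einsum("ij,ij->j", eyp, eyp))
            c = exn.T @ eyp
            max_abs_r[done:done + b] = np.abs(c).max(axis=0)
            done += b
        r = np.clip(max_abs_r, 0.0, 1.0 - 1e-15)
        tstat = r * np.sqrt(df / (1.0 - r ** 2))
        min_p = np.sort(2.0 * stats.t.sf(tstat, df))
        k = math.ceil(alpha * n_perm)
        alpha_prime = float(min_p[k - 1])
        return MWSLResult(alpha=alpha, n_perm=n_perm, permutation_min_p=min_p,
                          alpha_prime=alpha_prime,
                          ent=effective_number_of_tests(alpha, alpha_prime),
                          seed=seed, k=k)


class MWASResults:
    """Per-feature association estimates from an :class:`MWAS` fit."""

    def __init__(self, table: pd.DataFrame, model: ModelSpec, df_resid: int,
                 n_used: int, model_obj: MWAS | None = None):
        self.table = table
        self.model = model
        self.df_resid = df_resid
        self.n_used = n_used
        self._model_obj = model_obj

    @property
    def p_values(self) -> np.ndarray:
        return self.table["p_value"].to_numpy()

    def significant(self, threshold: float) -> pd.DataFrame:
        return self.table[self.table["p_value"] < threshold]

    def manhattan_table(self) -> pd.DataFrame:
        """Signed -log10 p per feature, the Manhattan-plot export."""
        t = self.table.copy()
        t["signed_log10_p"] = -np.log10(t["p_value"]) * t["direction"]
        return t

    def plot_manhattan(self, threshold: float | None = None, ax=None):
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        t = self.manhattan_table()
        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3.5))
        ax.plot(t["ppm"], t["signed_log10_p"], lw=0.5, color="0.4")
        if threshold is not None:
            sig = t["p_value"] < threshold
            ax.plot(t.loc[sig, "ppm"], t.loc[sig, "signed_log10_p"], ".",
                    color="k", ms=3)
            for y in (-math.log10(threshold), math.log10(threshold)):
                ax.axhline(y, color="r", lw=0.7, ls="--")
        ax.invert_xaxis()
        ax.set_xlabel("chemical shift (ppm)")
        ax.set_ylabel(r"signed $-\log_{10} P$")
        return ax

    def summary(self, top: int = 10) -> str:
        t = self.table.dropna(subset=["p_value"]).nsmallest(top, "p_value")
        lines = [
            "MWAS scan summary",
            f"  outcome:      {self.model.outcome}",
            f"  covariates:   {', '.join(self.model.covariates)}",
            f"  n samples:    {self.n_used}   residual df: {self.df_resid}",
            f"  n features:   {len(self.table)}",
            f"  top {top} features by p-value:",
            t[["feature_index", "ppm", "beta_per_sd", "se", "p_value",
               "partial_spearman_rho"]].to_string(index=False,
                                                  float_format="%.4g"),
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.manhattan_table().to_csv(path, sep="\t", index=False)


def mwas_scan(spectra: SpectrumSet, pheno: pd.DataFrame, model: ModelSpec) -> MWASResults:
    """Functional wrapper: build the model and fit in one call."""
    return MWAS(spectra, pheno, model).fit()


def estimate_mwsl(spectra: SpectrumSet, pheno: pd.DataFrame, model: ModelSpec,
                  alpha: float = 0.05, n_perm: int = 10000, seed: int = 0,
                  chunk_size: int = 256) -> MWSLResult:
    return MWAS(spectra, pheno, model).estimate_mwsl(alpha, n_perm, seed,
                                                     chunk_size)


def replicate_hits(discovery: MWASResults | pd.DataFrame,
                   replication: MWASResults | pd.DataFrame,
                   alpha_prime: float | MWSLResult,
                   replication_alpha: float = 0.05) -> pd.DataFrame:
    """Two-stage discovery -> replication filter.

    Discovery hits are features with discovery p < alpha'; each replicates
    when its replication p < 0.05 with a consistent direction of
    association.
    """
    if isinstance(discovery, MWASResults):
        discovery = discovery.table
    if isinstance(replication, MWASResults):
        replication = replication.table
    if isinstance(alpha_prime, MWSLResult):
        alpha_prime = alpha_prime.alpha_prime
    if not discovery["feature_index"].equals(replication["feature_index"]):
        raise ValueError("feature indices do not align between stages")
    hits = discovery["p_value"] < alpha_prime
    out = pd.DataFrame({
        "feature_index": discovery.loc[hits, "feature_index"],
        "ppm": discovery.loc[hits, "ppm"],
        "discovery_p": discovery.loc[hits, "p_value"],
        "discovery_direction": discovery.loc[hits, "direction"],
        "replication_p": replication.loc[hits, "p_value"],
        "replication_direction": replication.loc[hits, "direction"],
    })
    out["replicated"] = ((out["replication_p"] < replication_alpha)
                         & (out["replication_direction"]
                            == out["discovery_direction"]))
    return out.reset_index(drop=True)


def select_sentinels(results: MWASResults | pd.DataFrame,
                     cmap: ClusterMap) -> ClusterMap:
    """Fill each cluster's sentinel: the member feature with the lowest
    p-value (ties broken by the smaller feature index)."""
    from dataclasses import replace

    table = results.table if isinstance(results, MWASResults) else results
    pvals = table.set_index("feature_index")["p_value"]
    new: list[Cluster] = []
    for c in cmap.clusters:
        member_p = pvals.loc[c.start:c.end]
        valid = member_p.dropna()
        sentinel = int(valid.idxmin()) if len(valid) else None
        new.append(replace(c, sentinel_feature=sentinel))
    return ClusterMap(new, cmap.unassigned_features, cmap.n_features)
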