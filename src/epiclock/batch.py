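"""Empirical-Bayes location/scale batch adjustment with a reference-batch mode.

Methylation matrices pooled across studies carry study-level shifts that
dominate principal components and leak into penalized fits. The adjustment
implemented here is the standard parametric empirical-Bayes recipe: per
site, fit a linear model with batch indicators plus protected covariates
(covariates whose signal must survive the correction, e.g. age); standardize
the data to residual scale; estimate per-batch location (gamma) and scale
(delta^2) parameters; shrink them across sites with moment-matched normal /
inverse-gamma priors; and adjust each batch to the pooled (or reference)
level.

In reference mode all adjustments are expressed relative to one chosen
batch, whose samples pass through bit-identical -- the mode of practical
interest when a trained clock must travel to new cohorts that can be
mapped onto the reference study.

A PCA diagnostic quantifies batch signal as the one-way ANOVA F statistic
of batch labels on each principal component, before and after correction.

The variant for forensic use, where chronological age is unknown at
prediction time, protects the clock's own predicted age instead of the true
age.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import BetaMatrix, ClockModel, SampleSheet

__all__ = [
    "BatchModel",
    "fit_batch_model",
    "apply_batch_model",
    "correct_batches",
    "protect_with_predicted_age",
    "batch_pca",
]

logger = logging.getLogger(__name__)


@dataclass
class BatchModel:
    """Fitted standardization + per-batch EB adjustment parameters."""

    batches: list[str]
    reference: str | None
    protected: list[str]
    logit: bool
    # standardization fit (per site)
    grand_mean: np.ndarray            # (n_sites,)
    beta_covar: np.ndarray            # (n_covar, n_sites) protected-covariate coefs
    var_pooled: np.ndarray            # (n_sites,)
    covar_center: np.ndarray          # (n_covar,) training means of covariates
    # EB estimates (per batch x site)
    gamma_star: pd.DataFrame
    delta_star: pd.DataFrame
    site_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if (self.delta_star.to_numpy() <= 0).any():
            raise ValueError("delta_star must be positive")


_EPS = 1e-6


def _to_logit(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, _EPS, 1 - _EPS)
    return np.log(x / (1 - x))


def _from_logit(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _design(sheet: SampleSheet, batches: list[str], protected: list[str],
            covar_center: np.ndarray | None = None):
    """Batch one-hot design plus centered protected covariates."""
    lab = sheet.batches.to_numpy()
    B = np.column_stack([(lab == b).astype(float) for b in batches])
    cov_cols = []
    for name in protected:
        if name == "age":
            cov_cols.append(sheet.ages.to_numpy(dtype=float))
        elif name in sheet.table.columns:
            cov_cols.append(sheet.table[name].to_numpy(dtype=float))
        else:
            raise KeyError(f"protected covariate {name!r} not in sample sheet")
    C = np.column_stack(cov_cols) if cov_cols else np.empty((len(lab), 0))
    if covar_center is None:
        covar_center = C.mean(axis=0) if C.shape[1] else np.empty(0)
    C = C - covar_center
    return B, C, covar_center


def _eb_solve(z_batch: np.ndarray, gamma_hat: np.ndarray, delta_hat: np.ndarray,
              gamma_bar: float, tau2: float, a_prior: float, b_prior: float,
              conv: float = 1e-4) -> tuple[np.ndarray, np.ndarray]:
    """Iterative joint posterior-mode solve for one batch's (gamma*, delta*²)."""
    n = z_batch.shape[1]
    g_old = gamma_hat.copy()
    d_old = delta_hat.copy()
    change = 1.0
    while change > conv:
        g_new = (n * tau2 * gamma_hat + d_old * gamma_bar) / (n * tau2 + d_old)
        sse = ((z_batch - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sse + b_prior) / (n / 2.0 + a_prior - 1.0)
        # elementwise relative change, the classic stopping rule
        denom_g = np.where(np.abs(g_old) > 1e-12, np.abs(g_old), 1e-12)
        change = max(
            (np.abs(g_new - g_old) / denom_g).max(),
            (np.abs(d_new - d_old) / d_old).max(),
        )
        g_old, d_old = g_new, d_new
    return g_old, d_old


def fit_batch_model(bm: BetaMatrix, sheet: SampleSheet,
                    protected: list[str] | None = None,
                    reference: str | None = None,
                    parametric: bool = True,
                    logit: bool = False) -> BatchModel:
    """Fit per-batch EB location/scale adjustments.

    Requires >= 2 batches with >= 2 samples each. ``protected`` names sample
    sheet covariates whose association with methylation is preserved
    (``"age"`` uses the age column). With ``reference`` set, adjustments are
    relative to that batch and its samples are left untouched by
    :func:`apply_batch_model`.
    """
    if not parametric:
        raise NotImplementedError("only the parametric EB variant is provided")
    sheet = sheet.aligned_to(bm)
    protected = list(protected or [])
    labels = sheet.batches
    batch_names = list(pd.unique(labels))
    if len(batch_names) < 2:
        raise ValueError("need at least two batches")
    sizes = labels.value_counts()
    if (sizes < 2).any():
        bad = sizes[sizes < 2].index.tolist()
        raise ValueError(f"singleton batches not allowed: {bad}")
    if reference is not None and reference not in batch_names:
        raise ValueError(f"reference batch {reference!r} not present")

    Y = bm.values.to_numpy().copy()  # sites x samples
    if np.isnan(Y).any():
        raise ValueError("batch correction requires complete data (no missing betas)")
    if logit:
        Y = _to_logit(Y)

    B, C, covar_center = _design(sheet, batch_names, protected)
    X = np.hstack([B, C])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("collinear design: protected covariates confounded with batch")
    # per-site OLS, all sites at once
    coef, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (n_batch + n_covar, n_sites)
    n_batch = len(batch_names)
    batch_effects = coef[:n_batch]
    beta_covar = coef[n_batch:]

    n_samples = Y.shape[1]
    props = np.array([ (labels == b).sum() / n_samples for b in batch_names])
    if reference is None:
        grand_mean = props @ batch_effects
        resid = Y - (X @ coef).T
        var_pooled = (resid ** 2).mean(axis=1)
    else:
        ref_idx = batch_names.index(reference)
        grand_mean = batch_effects[ref_idx]
        mask = (labels == reference).to_numpy()
        resid_ref = (Y - (X @ coef).T)[:, mask]
        var_pooled = (resid_ref ** 2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, 1e-12)

    # standardize: remove grand mean and covariate effects, divide by pooled sd
    fitted_cov = (C @ beta_covar).T  # sites x samples
    Z = (Y - grand_mean[:, None] - fitted_cov) / np.sqrt(var_pooled)[:, None]

    gamma_star = {}
    delta_star = {}
    for b in batch_names:
        mask = (labels == b).to_numpy()
        Zb = Z[:, mask]
        gamma_hat = Zb.mean(axis=1)
        delta_hat = Zb.var(axis=1, ddof=1)
        delta_hat = np.maximum(delta_hat, 1e-12)
        gamma_bar = float(gamma_hat.mean())
        tau2 = float(gamma_hat.var(ddof=1))
        m, s2 = float(delta_hat.mean()), float(delta_hat.var(ddof=1))
        a_prior = (2 * s2 + m ** 2) / s2 if s2 > 0 else 2.0
        b_prior = (m * s2 + m ** 3) / s2 if s2 > 0 else m
        if tau2 > 0:
            g, d = _eb_solve(Zb, gamma_hat, delta_hat, gamma_bar, tau2, a_prior, b_prior)
        else:  # degenerate: no across-site spread to shrink with
            g, d = gamma_hat, delta_hat
        gamma_star[b] = g
        delta_star[b] = np.maximum(d, 1e-12)
    if reference is not None:
        gamma_star[reference] = np.zeros(Z.shape[0])
        delta_star[reference] = np.ones(Z.shape[0])

    return BatchModel(
        batches=batch_names,
        reference=reference,
        protected=protected,
        logit=logit,
        grand_mean=grand_mean,
        beta_covar=beta_covar,
        var_pooled=var_pooled,
        covar_center=covar_center,
        gamma_star=pd.DataFrame(gamma_star, index=bm.site_ids).T,
        delta_star=pd.DataFrame(delta_star, index=bm.site_ids).T,
        site_ids=list(bm.site_ids),
    )


def apply_batch_model(bm: BetaMatrix, model: BatchModel, sheet: SampleSheet) -> BetaMatrix:
    """Standardize, remove EB batch effects, restore scale; clip to [0, 1].

    Reference-batch samples are returned bit-identical. Unknown batch labels
    raise. The number of values clipped at the [0, 1] boundary is logged.
    """
    sheet = sheet.aligned_to(bm)
    if list(bm.site_ids) != model.site_ids:
        bm = bm.select_sites(model.site_ids)
    labels = sheet.batches
    unknown = set(labels) - set(model.batches)
    if unknown:
        raise ValueError(f"batches absent from model: {sorted(unknown)}")

    Y0 = bm.values.to_numpy()
    Y = _to_logit(Y0) if model.logit else Y0.copy()
    _, C, _ = _design(sheet, model.batches, model.protected, model.covar_center)
    fitted_cov = (C @ model.beta_covar).T
    sd = np.sqrt(model.var_pooled)[:, None]
    Z = (Y - model.grand_mean[:, None] - fitted_cov) / sd

    out = np.empty_like(Y)
    for b in model.batches:
        mask = (labels == b).to_numpy()
        if not mask.any():
            continue
        g = model.gamma_star.loc[b].to_numpy()
        d = model.delta_star.loc[b].to_numpy()
        Zadj = (Z[:, mask] - g[:, None]) / np.sqrt(d)[:, None]
        out[:, mask] = Zadj * sd + model.grand_mean[:, None] + fitted_cov[:, mask]

    if model.logit:
        out = _from_logit(out)
    if model.reference is not None:
        mask = (labels == model.reference).to_numpy()
        out[:, mask] = Y0[:, mask]  # bit-identical pass-through
    n_clip = int(((out < 0) | (out > 1)).sum())
    if n_clip:
        logger.info("batch adjustment clipped %d values to [0, 1]", n_clip)
    out = np.clip(out, 0.0, 1.0)
    return BetaMatrix(pd.DataFrame(out, index=bm.site_ids, columns=bm.sample_ids))


def correct_batches(bm: BetaMatrix, sheet: SampleSheet, **kwargs) -> BetaMatrix:
    """Convenience fit + apply on the same data."""
    model = fit_batch_model(bm, sheet, **kwargs)
    return apply_batch_model(bm, model, sheet)


def protect_with_predicted_age(bm: BetaMatrix, sheet: SampleSheet,
                               clock: ClockModel, reference: str) -> BetaMatrix:
    """Batch-correct using the clock's own predictions as the protected variable.

    For cohorts whose chronological age is unknown (the forensic setting),
    predicted age stands in for true age in the protected design.
    """
    from .report import predict_age

    pred = predict_age(clock, bm, missing_policy="impute_half")
    tab = sheet.aligned_to(bm).table.copy()
    tab["predicted_age"] = pred.set_index("sample_id").loc[tab["sample_id"], "predicted_age"].to_numpy()
    sheet_pred = SampleSheet(tab.reset_index(drop=True))
    protected = ["predicted_age"]
    if sheet_pred.table["predicted_age"].nunique() == 1:
        # constant prediction carries no signal to protect
        protected = []
    model = fit_batch_model(bm, sheet_pred, protected=protected, reference=reference)
    return apply_batch_model(bm, model, sheet_pred)


def batch_pca(bm: BetaMatrix, sheet: SampleSheet, n_components: int = 5) -> pd.DataFrame:
    """PCA of samples + per-component one-way batch ANOVA F statistic.

    Returns a DataFrame with one row per component: ``explained_variance_ratio``,
    ``batch_F`` and the sample scores as columns ``score_<sample_id>`` are
    attached in ``.attrs["scores"]`` (samples x components).
    """
    from sklearn.decomposition import PCA

    sheet = sheet.aligned_to(bm)
    labels = sheet.batches
    if labels.nunique() < 2:
        raise ValueError("need at least two batches for a batch diagnostic")
    max_nc = min(bm.n_sites, bm.n_samples) - 1
    if n_components > max_nc:
        raise ValueError(f"n_components must be <= {max_nc}")
    X = bm.values.to_numpy().T  # samples x sites
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("zero-variance data: PCA undefined")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X - X.mean(axis=0))
    rows = []
    groups = [scores[(labels == b).to_numpy()] for b in pd.unique(labels)]
    for k in range(n_components):
        F, _ = stats.f_oneway(*[g[:, k] for g in groups])
        rows.append({
            "component": k + 1,
            "explained_variance_ratio": float(pca.explained_variance_ratio_[k]),
            "batch_F": float(F),
        })
    out = pd.DataFrame(rows).set_index("component")
    out.attrs["scores"] = pd.DataFrame(
        scores, index=bm.sample_ids,
        columns=[f"PC{k + 1}" for k in range(n_components)],
    )
    return out
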