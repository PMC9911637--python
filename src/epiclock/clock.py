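"""Elastic-net age-clock training, lambda selection and repeated-split evaluation.

The clock is a penalized linear regression of (transformed) chronological
age on CpG beta values. With standardized predictors the objective is

    (1/2n) * sum_i (y_i - b0 - x_i.b)^2 + lambda * (alpha*|b|_1 + (1-alpha)/2*|b|_2^2)

with mixing parameter alpha (default 0.5, halfway between lasso and ridge)
and penalty lambda chosen by k-fold cross-validation over a geometric
lambda path. Two selection rules are supported: ``min`` (the lambda
minimizing mean CV squared error) and ``1se`` (the largest lambda whose
mean CV error stays within one standard error of that minimum -- a sparser
model at nearly the same error, and the rule that generalizes better to
truly independent cohorts).

Prediction error is summarized as MAD: the *median of absolute prediction
errors in years* -- not the median-absolute-deviation-from-median scale
estimator. The repeated-split evaluation draws ten random 2/3 - 1/3 splits
of the training cohort, fits a clock on each 2/3 with internal CV, and
records MAD on the held-out 1/3 and on an external cohort never touched by
training.

Organisation follows the model/results idiom: build an
:class:`EpigeneticClock` from a beta matrix + sample sheet + config, call
``.fit()`` and work with the returned :class:`ClockFit`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal
import warnings

import numpy as np
import pandas as pd
from sklearn.linear_model import enet_path

from .age_transform import TransformSpec, inverse_transform_age, transform_age
from .data import BetaMatrix, ClockModel, EvaluationResult, SampleSheet

__all__ = [
    "TrainingConfig",
    "CVCurve",
    "EpigeneticClock",
    "ClockFit",
    "train_clock",
    "select_lambda",
    "mad_error",
    "evaluate_repeated",
    "attach_cell_fractions",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Parameters of one clock fit / evaluation run.

    ``age_span`` restricts training to an age window in years (the narrow
    12-25 window is the default: clocks for adolescents generalize better
    when trained only on adolescents). ``subsample_n`` optionally
    down-samples the training cohort before splitting, for sample-size
    experiments.
    """

    alpha: float = 0.5
    n_folds: int = 10
    lambda_rule: Literal["min", "1se"] = "1se"
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    age_span: tuple[float, float] | None = (12.0, 25.0)
    use_transform: bool = True
    adult_age: float = 20.0
    include_cell_fractions: bool = False
    subsample_n: int | None = None
    seed: int = 0
    n_repeats: int = 10
    train_fraction: float = 2.0 / 3.0
    tol: float = 1e-4  # coordinate-descent duality-gap tolerance

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.lambda_rule not in ("min", "1se"):
            raise ValueError("lambda_rule must be 'min' or '1se'")

    @property
    def transform_spec(self) -> TransformSpec:
        return TransformSpec(adult_age=self.adult_age, enabled=self.use_transform)


@dataclass
class CVCurve:
    """Cross-validation loss along the lambda path (lambdas descending)."""

    lambdas: np.ndarray
    mean_loss: np.ndarray
    se_loss: np.ndarray
    n_nonzero: np.ndarray

    def __post_init__(self):
        n = len(self.lambdas)
        if not (len(self.mean_loss) == len(self.se_loss) == len(self.n_nonzero) == n):
            raise ValueError("curve columns must have equal length")
        if n == 0:
            raise ValueError("empty CV curve")
        if np.any(np.diff(self.lambdas) >= 0):
            raise ValueError("lambdas must be strictly decreasing")
        if np.any(self.se_loss < 0):
            raise ValueError("negative standard error")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "lambda": self.lambdas, "mean_loss": self.mean_loss,
            "se_loss": self.se_loss, "n_nonzero": self.n_nonzero,
        })


def select_lambda(curve: CVCurve, rule: str) -> float:
    """``min``: argmin of mean CV loss. ``1se``: largest lambda whose mean
    loss is within one standard error of the minimum (ties favour the larger,
    sparser lambda)."""
    i_min = int(np.argmin(curve.mean_loss))
    if rule == "min":
        return float(curve.lambdas[i_min])
    if rule == "1se":
        threshold = curve.mean_loss[i_min] + curve.se_loss[i_min]
        ok = np.flatnonzero(curve.mean_loss <= threshold)
        return float(curve.lambdas[ok[0]])  # lambdas descend: first ok is largest
    raise ValueError("rule must be 'min' or '1se'")


def mad_error(predicted, actual) -> float:
    """Median of absolute prediction errors, in years."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape or predicted.ndim != 1 or len(predicted) < 1:
        raise ValueError("predicted and actual must be equal-length 1-d arrays")
    return float(np.median(np.abs(predicted - actual)))


def attach_cell_fractions(bm: BetaMatrix, sheet: SampleSheet) -> pd.DataFrame:
    """Samples x predictors matrix: beta values plus ``cell:`` columns.

    Cell-fraction covariates enter the design like any site (standardized
    before penalization). Zero-variance fraction columns are dropped with a
    warning.
    """
    sheet = sheet.aligned_to(bm)
    X = bm.values.T.copy()  # samples x sites
    fracs = sheet.cell_fractions()
    if fracs.isna().any().any():
        bad = fracs.index[fracs.isna().any(axis=1)][0]
        raise ValueError(f"missing cell fractions for sample {bad!r}")
    for col in fracs.columns:
        v = fracs[col].to_numpy(dtype=float)
        if v.std() < 1e-12:
            warnings.warn(f"cell fraction column {col!r} has zero variance; dropped")
            continue
        X[f"cell:{col[len('cell_'):]}"] = v
    return X


def _lambda_path(Xs: np.ndarray, yc: np.ndarray, cfg: TrainingConfig) -> np.ndarray:
    """Geometric lambda grid from the all-zero lambda down by lambda_min_ratio."""
    n = Xs.shape[0]
    alpha_eff = max(cfg.alpha, 1e-3)  # ridge limit: finite path max
    lam_max = np.abs(Xs.T @ yc).max() / (n * alpha_eff)
    lam_max = max(lam_max, 1e-12)
    return np.geomspace(lam_max, lam_max * cfg.lambda_min_ratio, cfg.n_lambda)


def _enet_coefs(Xs: np.ndarray, yc: np.ndarray, lambdas: np.ndarray,
                alpha: float, tol: float = 1e-4) -> np.ndarray:
    """Coefficient matrix (n_features x n_lambda) on the standardized scale."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if alpha == 0.0:
            # closed-form ridge per lambda (coordinate descent is ill-suited)
            n, p = Xs.shape
            G = Xs.T @ Xs / n
            b = Xs.T @ yc / n
            coefs = np.empty((p, len(lambdas)))
            for j, lam in enumerate(lambdas):
                coefs[:, j] = np.linalg.solve(G + lam * np.eye(p), b)
            return coefs
        _, coefs, _ = enet_path(Xs, yc, l1_ratio=alpha, alphas=lambdas,
                                max_iter=20000, tol=tol)
    return coefs


class EpigeneticClock:
    """Model object: a cohort (beta matrix + sample sheet) plus a training config.

    Applies the configured age-span filter, optional down-sampling and
    optional cell-fraction covariates at construction; ``fit`` runs the
    cross-validated elastic net.
    """

    def __init__(self, bm: BetaMatrix, sheet: SampleSheet,
                 config: TrainingConfig = TrainingConfig()):
        self.config = config
        sheet = sheet.aligned_to(bm)
        if config.age_span is not None:
            lo, hi = config.age_span
            keep = sheet.table.index[(sheet.ages >= lo) & (sheet.ages <= hi)]
            if len(keep) == 0:
                raise ValueError("no samples left after age-span filtering")
            sheet = sheet.subset(keep)
            bm = bm.select_samples(keep)
        if config.subsample_n is not None and config.subsample_n < len(sheet):
            rng = np.random.default_rng(config.seed)
            pick = rng.choice(sheet.sample_ids, size=config.subsample_n, replace=False)
            sheet = sheet.subset(pick)
            bm = bm.select_samples(pick)
        self.sheet = sheet
        self.bm = bm
        if config.include_cell_fractions:
            self.X = attach_cell_fractions(bm, sheet)
        else:
            self.X = bm.values.T.copy()
        if self.X.isna().any().any():
            bad = self.X.columns[self.X.isna().any(axis=0)][:5].tolist()
            raise ValueError(
                f"missing beta values in training sites {bad}; impute or drop "
                "these sites before fitting"
            )
        ages = sheet.ages.to_numpy(dtype=float)
        self.y = np.asarray(transform_age(ages, config.transform_spec), dtype=float)
        if np.ptp(self.y) == 0:
            raise ValueError("constant response: all training ages identical")
        self.feature_names = list(self.X.columns)

    # -- internals -----------------------------------------------------

    def _standardize(self, X: np.ndarray):
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        return (X - mu) / sd, mu, sd

    def _cv_folds(self, n: int, rng: np.random.Generator):
        """Shuffle once, folds as contiguous blocks (no stratification)."""
        order = rng.permutation(n)
        return np.array_split(order, self.config.n_folds)

    # -- fitting -------------------------------------------------------

    def fit(self, lambda_: float | None = None) -> "ClockFit":
        """Cross-validate over the lambda path, select lambda, refit on all data.

        Passing ``lambda_`` skips CV and fits at that penalty (still
        reporting the full-data path for the coefficient counts).
        """
        cfg = self.config
        X = self.X.to_numpy(dtype=float)
        y = self.y
        Xs, mu, sd = self._standardize(X)
        ybar = y.mean()
        yc = y - ybar
        lambdas = _lambda_path(Xs, yc, cfg)

        coefs_full = _enet_coefs(Xs, yc, lambdas, cfg.alpha, cfg.tol)
        n_nonzero = (coefs_full != 0).sum(axis=0)

        curve = None
        if lambda_ is None:
            rng = np.random.default_rng(cfg.seed)
            folds = self._cv_folds(len(y), rng)
            fold_losses = np.empty((cfg.n_folds, len(lambdas)))
            for k, test_idx in enumerate(folds):
                train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
                Xt, mt, st = self._standardize(X[train_idx])
                yt = y[train_idx]
                ck = _enet_coefs(Xt, yt - yt.mean(), lambdas, cfg.alpha, cfg.tol)
                # predictions on the held-out fold, per lambda
                Xv = (X[test_idx] - mt) / st
                pred = Xv @ ck + yt.mean()
                fold_losses[k] = ((pred - y[test_idx, None]) ** 2).mean(axis=0)
            mean_loss = fold_losses.mean(axis=0)
            se_loss = fold_losses.std(axis=0, ddof=1) / np.sqrt(cfg.n_folds)
            curve = CVCurve(lambdas=lambdas, mean_loss=mean_loss,
                            se_loss=se_loss, n_nonzero=n_nonzero)
            lam = select_lambda(curve, cfg.lambda_rule)
            b_std = coefs_full[:, int(np.argmin(np.abs(lambdas - lam)))]
        else:
            lam = float(lambda_)
            if lam >= lambdas[0]:
                b_std = np.zeros(X.shape[1])
            else:
                b_std = _enet_coefs(Xs, yc, np.array([lam]), cfg.alpha, cfg.tol)[:, 0]

        b = b_std / sd
        intercept = float(ybar - b @ mu)
        coefficients = {name: float(w) for name, w in zip(self.feature_names, b)
                        if w != 0.0}
        model = ClockModel(
            intercept=intercept,
            coefficients=coefficients,
            transform_spec=cfg.transform_spec,
            meta={
                "alpha": cfg.alpha,
                "lambda": lam,
                "lambda_rule": cfg.lambda_rule if lambda_ is None else "fixed",
                "n_samples": len(y),
                "age_span": list(cfg.age_span) if cfg.age_span else None,
                "n_folds": cfg.n_folds,
                "seed": cfg.seed,
            },
        )
        return ClockFit(model=model, cv_curve=curve, clock=self, lambda_=lam)


@dataclass
class ClockFit:
    """Results object: the fitted sparse clock plus its CV diagnostics."""

    model: ClockModel
    cv_curve: CVCurve | None
    clock: EpigeneticClock
    lambda_: float

    @property
    def n_sites(self) -> int:
        return self.model.n_sites

    def predict(self, bm: BetaMatrix, missing_policy: str = "error") -> pd.DataFrame:
        from .report import predict_age

        return predict_age(self.model, bm, missing_policy=missing_policy)

    def predicted_ages(self, bm: BetaMatrix) -> pd.Series:
        pred = self.predict(bm, missing_policy="error")
        return pred.set_index("sample_id")["predicted_age"]

    def mad(self, bm: BetaMatrix, sheet: SampleSheet) -> float:
        sheet = sheet.aligned_to(bm)
        pred = self.predicted_ages(bm).loc[sheet.sample_ids]
        return mad_error(pred.to_numpy(), sheet.ages.to_numpy())

    def summary(self) -> str:
        cfg = self.clock.config
        lines = [
            "Elastic-net age clock",
            "=" * 42,
            f"training samples      {self.clock.X.shape[0]}",
            f"candidate predictors  {self.clock.X.shape[1]}",
            f"alpha (L1 mixing)     {cfg.alpha}",
            f"lambda ({self.model.meta.get('lambda_rule')})          {self.lambda_:.6g}",
            f"selected sites        {self.n_sites}",
            f"intercept             {self.model.intercept:.4f}",
            f"age transform         adult_age={cfg.adult_age}, enabled={cfg.use_transform}",
        ]
        if self.cv_curve is not None:
            i = int(np.argmin(np.abs(self.cv_curve.lambdas - self.lambda_)))
            lines.append(f"CV mean squared error {self.cv_curve.mean_loss[i]:.5f} "
                         f"(+/- {self.cv_curve.se_loss[i]:.5f})")
        return "\n".join(lines)

    def plot_cv(self, ax=None):
        """CV loss vs log10(lambda) with the 1-SE band and selected lambda."""
        import matplotlib.pyplot as plt

        if self.cv_curve is None:
            raise ValueError("no CV curve: the fit used a fixed lambda")
        if ax is None:
            _, ax = plt.subplots()
        c = self.cv_curve
        ax.errorbar(np.log10(c.lambdas), c.mean_loss, yerr=c.se_loss,
                    fmt="o", ms=3, lw=0.8, capsize=2)
        ax.axvline(np.log10(self.lambda_), ls="--", color="red")
        ax.set_xlabel("log10(lambda)")
        ax.set_ylabel("CV mean squared error")
        return ax


def train_clock(bm: BetaMatrix, sheet: SampleSheet,
                cfg: TrainingConfig = TrainingConfig()) -> tuple[ClockModel, CVCurve]:
    """Functional wrapper: fit one clock with CV and return (model, curve)."""
    fit = EpigeneticClock(bm, sheet, cfg).fit()
    return fit.model, fit.cv_curve


def evaluate_repeated(bm: BetaMatrix, sheet: SampleSheet,
                      external_bm: BetaMatrix | None,
                      external_sheet: SampleSheet | None,
                      cfg: TrainingConfig = TrainingConfig()) -> EvaluationResult:
    """Repeated random-split evaluation.

    Per repeat: a random ``train_fraction`` split of the (age-filtered,
    optionally down-sampled) cohort; a CV fit on the training part; MAD in
    years on the internal held-out part and, when given, on the external
    cohort. External sample ids must be disjoint from the training cohort.
    Seeds derive deterministically from ``cfg.seed`` plus the repeat index.
    """
    if external_bm is not None:
        overlap = set(bm.sample_ids) & set(external_bm.sample_ids)
        if overlap:
            raise ValueError(f"external samples overlap training: {sorted(overlap)[:5]}")
    records = []
    for r in range(cfg.n_repeats):
        seed_r = int((cfg.seed + 1000003 * (r + 1)) % (2**31 - 1))
        cfg_r = replace(cfg, seed=seed_r)
        # age filter + optional subsample happen inside the model object
        base = EpigeneticClock(bm, sheet, cfg_r)
        rng = np.random.default_rng(seed_r)
        ids = np.array(base.sheet.sample_ids)
        n_train = int(round(cfg.train_fraction * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        perm = rng.permutation(len(ids))
        train_ids = ids[perm[:n_train]]
        test_ids = ids[perm[n_train:]]
        fit = EpigeneticClock(
            base.bm.select_samples(train_ids),
            base.sheet.subset(train_ids),
            replace(cfg_r, age_span=None, subsample_n=None),
        ).fit()
        rec = {
            "repeat": r,
            "internal_mad": fit.mad(base.bm.select_samples(test_ids),
                                    base.sheet.subset(test_ids)),
            "n_sites": fit.n_sites,
            "lambda": fit.lambda_,
        }
        if external_bm is not None:
            rec["external_mad"] = fit.mad(external_bm, external_sheet)
        records.append(rec)
    return EvaluationResult(records=pd.DataFrame(records))
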