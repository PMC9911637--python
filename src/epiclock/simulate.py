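"""Seeded generator of synthetic methylation cohorts.

Emulates the statistical structure an adolescent blood 450K cohort presents
to the clock pipeline: a small fraction of CpGs whose mean beta follows a
logistic curve in transformed age, a majority of flat noise CpGs, a
fraction of SNP-like multimodal CpGs whose values fall into 2-3 discrete
clusters independent of age, study-level batch shifts applied additively on
the logit scale, and optional leukocyte-composition covariates. Everything
is driven by one integer seed; the same config reproduces the same matrices
bit for bit.

Signal sites place their age dependence on the *transformed* age scale, so
the piecewise log-linear transform is exactly the right link during
recovery tests; a ``linear_age`` mode generates linear-in-years means
instead, to probe robustness to link misspecification. A
``slope_change_at`` knot makes slopes differ between young and old age
segments, reproducing the situation where a clock trained on a narrow
adolescent span beats one trained on the full adult range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .age_transform import TransformSpec, transform_age
from .data import BetaMatrix, SampleSheet

__all__ = ["BatchSpec", "CellSpec", "SimConfig", "SimTruth",
           "simulate_dataset", "make_external_cohort"]


@dataclass(frozen=True)
class BatchSpec:
    label: str
    n: int
    shift: float = 0.0   # additive offset on the logit-beta scale
    scale: float = 1.0   # noise-variance multiplier


@dataclass(frozen=True)
class CellSpec:
    names: tuple[str, ...] = ("CD4T", "CD8T", "NK", "Bcell", "Mono", "Gran")
    concentration: tuple[float, ...] = (6.0, 4.0, 2.0, 2.0, 3.0, 20.0)
    effect_sd: float = 0.0  # per-type site effect on the logit scale; 0 = null


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-z))


def _logit(p):
    p = np.clip(p, 1e-6, 1 - 1e-6)
    return np.log(p / (1 - p))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of one synthetic cohort.

    Defaults describe an adolescent training cohort: 900 samples over ages
    12-25 y in three studies, 2000 CpGs of which 2% trend with age and 5%
    are SNP-like multimodal, residual beta noise sd 0.03.
    """

    n_samples: int = 900
    n_sites: int = 2000
    frac_signal: float = 0.02
    frac_multimodal: float = 0.05
    age_range: tuple[float, float] = (12.0, 25.0)
    slope_range: tuple[float, float] = (0.8, 2.0)  # |slope|, logit units per transformed-age unit
    noise_sd: float = 0.03
    batches: tuple[BatchSpec, ...] = (
        BatchSpec("study_A", 300, 0.0),
        BatchSpec("study_B", 300, +0.2),
        BatchSpec("study_C", 300, -0.2),
    )
    cell_types: CellSpec | None = None
    adult_age: float = 20.0
    linear_age: bool = False       # misspecified link: mean linear in years
    slope_change_at: float | None = None  # knot (years) where slopes change
    seed: int = 0

    def __post_init__(self):
        if self.frac_signal + self.frac_multimodal > 1:
            raise ValueError("signal + multimodal fractions exceed 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if sum(b.n for b in self.batches) != self.n_samples:
            raise ValueError("batch sizes must sum to n_samples")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("invalid age_range")


@dataclass
class SimTruth:
    """Per-site generating parameters; labels partition the sites."""

    site_labels: pd.Series          # site_id -> {signal, noise, multimodal}
    baseline: np.ndarray            # logit-scale intercept per site
    slope: np.ndarray               # logit-scale slope (0 for non-signal)
    slope_old: np.ndarray           # slope beyond the knot (equals slope if no knot)
    mm_means: dict[str, np.ndarray]   # multimodal site -> component means (beta)
    mm_probs: dict[str, np.ndarray]   # multimodal site -> component probabilities
    cell_effects: np.ndarray | None   # (n_sites, n_cell_types) logit effects
    batch_shifts: dict[str, float]
    ages: pd.Series                 # sample_id -> age (training draw)
    config: SimConfig = None

    def signal_sites(self) -> list[str]:
        return list(self.site_labels.index[self.site_labels == "signal"])

    def multimodal_sites(self) -> list[str]:
        return list(self.site_labels.index[self.site_labels == "multimodal"])


def _site_params(cfg: SimConfig, rng: np.random.Generator):
    n = cfg.n_sites
    n_sig = int(round(cfg.frac_signal * n))
    n_mm = int(round(cfg.frac_multimodal * n))
    site_ids = [f"cg{i:07d}" for i in range(n)]
    labels = np.array(["noise"] * n, dtype=object)
    labels[:n_sig] = "signal"
    labels[n_sig:n_sig + n_mm] = "multimodal"

    baseline = _logit(rng.uniform(0.25, 0.75, size=n))
    lo, hi = cfg.slope_range
    mag = rng.uniform(lo, hi, size=n)
    sign = rng.choice([-1.0, 1.0], size=n)
    slope = np.where(labels == "signal", mag * sign, 0.0)
    if cfg.slope_change_at is not None:
        mag2 = rng.uniform(lo, hi, size=n)
        sign2 = rng.choice([-1.0, 1.0], size=n)
        slope_old = np.where(labels == "signal", mag2 * sign2, 0.0)
    else:
        slope_old = slope.copy()

    mm_means: dict[str, np.ndarray] = {}
    mm_probs: dict[str, np.ndarray] = {}
    for i in range(n_sig, n_sig + n_mm):
        k = int(rng.integers(2, 4))  # 2 or 3 clusters
        if k == 2:
            m1 = rng.uniform(0.05, 0.35)
            m2 = m1 + rng.uniform(0.4, 0.6)
            means = np.array([m1, m2])
        else:
            means = np.array([0.1, 0.5, 0.9]) + rng.uniform(-0.05, 0.05, size=3)
        # allele-frequency-like mixing, floored so minor clusters stay visible
        p = rng.dirichlet(np.full(k, 4.0))
        p = np.maximum(p, 0.15)
        p /= p.sum()
        mm_means[site_ids[i]] = np.clip(means, 0.01, 0.99)
        mm_probs[site_ids[i]] = p

    cell_effects = None
    if cfg.cell_types is not None and cfg.cell_types.effect_sd > 0:
        cell_effects = rng.normal(0.0, cfg.cell_types.effect_sd,
                                  size=(n, len(cfg.cell_types.names)))
    return site_ids, labels, baseline, slope, slope_old, mm_means, mm_probs, cell_effects


def _mean_matrix(cfg: SimConfig, truth_parts, ages: np.ndarray,
                 cell_fracs: np.ndarray | None, rng: np.random.Generator):
    """Noise-free per-(site, sample) mean betas, before batch shift."""
    site_ids, labels, baseline, slope, slope_old, mm_means, mm_probs, cell_eff = truth_parts
    spec = TransformSpec(adult_age=cfg.adult_age)
    if cfg.linear_age:
        f = (ages - cfg.adult_age) / (cfg.adult_age + 1.0)  # comparable scale
    else:
        f = np.asarray(transform_age(ages, spec))
    if cfg.slope_change_at is None:
        lin = baseline[:, None] + slope[:, None] * f[None, :]
    else:
        f_knot = float(transform_age(cfg.slope_change_at, spec)) if not cfg.linear_age \
            else (cfg.slope_change_at - cfg.adult_age) / (cfg.adult_age + 1.0)
        below = np.minimum(f, f_knot)
        above = np.maximum(f - f_knot, 0.0)
        lin = baseline[:, None] + slope[:, None] * below[None, :] \
            + slope_old[:, None] * above[None, :]
    if cell_eff is not None and cell_fracs is not None:
        centered = cell_fracs - cell_fracs.mean(axis=0)
        lin = lin + cell_eff @ centered.T
    mean = _logistic(lin)
    # multimodal sites: cluster mean per sample, independent of age
    for i, sid in enumerate(site_ids):
        if labels[i] == "multimodal":
            comp = rng.choice(len(mm_probs[sid]), size=len(ages), p=mm_probs[sid])
            mean[i] = mm_means[sid][comp]
    return mean


def _assemble(cfg: SimConfig, mean: np.ndarray, batch_of: np.ndarray,
              shifts: dict[str, float], scales: dict[str, float],
              rng: np.random.Generator) -> np.ndarray:
    shift_vec = np.array([shifts[b] for b in batch_of])
    scale_vec = np.array([scales[b] for b in batch_of])
    shifted = _logistic(_logit(mean) + shift_vec[None, :])
    noise = rng.normal(0.0, 1.0, size=mean.shape) * (cfg.noise_sd * np.sqrt(scale_vec))[None, :]
    return np.clip(shifted + noise, 0.0, 1.0)


def simulate_dataset(cfg: SimConfig = SimConfig()) -> tuple[BetaMatrix, SampleSheet, SimTruth]:
    """One training cohort draw: (beta matrix, sample sheet, ground truth)."""
    rng = np.random.default_rng(cfg.seed)
    parts = _site_params(cfg, rng)
    site_ids, labels = parts[0], parts[1]

    sample_ids = [f"s{j:04d}" for j in range(cfg.n_samples)]
    ages = rng.uniform(*cfg.age_range, size=cfg.n_samples)
    batch_of = np.concatenate([[b.label] * b.n for b in cfg.batches])
    shifts = {b.label: b.shift for b in cfg.batches}
    scales = {b.label: b.scale for b in cfg.batches}
    sexes = rng.choice(["male", "female"], size=cfg.n_samples)

    cell_fracs = None
    sheet_cols = {
        "sample_id": sample_ids,
        "age": ages,
        "sex": sexes,
        "batch": batch_of,
    }
    if cfg.cell_types is not None:
        cs = cfg.cell_types
        cell_fracs = rng.dirichlet(np.asarray(cs.concentration), size=cfg.n_samples)
        for k, name in enumerate(cs.names):
            sheet_cols[f"cell_{name}"] = cell_fracs[:, k]

    mean = _mean_matrix(cfg, parts, ages, cell_fracs, rng)
    values = _assemble(cfg, mean, batch_of, shifts, scales, rng)

    bm = BetaMatrix(pd.DataFrame(values, index=site_ids, columns=sample_ids))
    sheet = SampleSheet(pd.DataFrame(sheet_cols))
    truth = SimTruth(
        site_labels=pd.Series(labels, index=site_ids, name="label"),
        baseline=parts[2], slope=parts[3], slope_old=parts[4],
        mm_means=parts[5], mm_probs=parts[6], cell_effects=parts[7],
        batch_shifts=shifts,
        ages=pd.Series(ages, index=sample_ids, name="age"),
        config=cfg,
    )
    return bm, sheet, truth


def make_external_cohort(cfg: SimConfig, truth: SimTruth, target_age: float = 18.5,
                         n: int = 200, age_jitter: float = 0.5,
                         batch: BatchSpec | None = None,
                         seed: int | None = None) -> tuple[BetaMatrix, SampleSheet]:
    """A validation cohort at (approximately) one target age.

    Reuses the per-site generating parameters of a training draw, so a
    clock trained on that draw faces the same biology in new individuals.
    By default the cohort carries no batch shift; pass ``batch`` to give it
    its own study label and logit shift.
    """
    if truth.config is None or truth.config.n_sites != cfg.n_sites:
        raise ValueError("truth does not match the supplied config")
    rng = np.random.default_rng(cfg.seed + 777_001 if seed is None else seed)
    site_ids = list(truth.site_labels.index)
    labels = truth.site_labels.to_numpy()
    parts = (site_ids, labels, truth.baseline, truth.slope, truth.slope_old,
             truth.mm_means, truth.mm_probs, truth.cell_effects)

    sample_ids = [f"e{j:04d}" for j in range(n)]
    ages = target_age + rng.uniform(-age_jitter, age_jitter, size=n)
    b = batch or BatchSpec("external", n, 0.0)
    batch_of = np.array([b.label] * n)

    cell_fracs = None
    sheet_cols = {
        "sample_id": sample_ids,
        "age": ages,
        "sex": rng.choice(["male", "female"], size=n),
        "batch": batch_of,
    }
    if cfg.cell_types is not None:
        cs = cfg.cell_types
        cell_fracs = rng.dirichlet(np.asarray(cs.concentration), size=n)
        for k, name in enumerate(cs.names):
            sheet_cols[f"cell_{name}"] = cell_fracs[:, k]

    mean = _mean_matrix(cfg, parts, ages, cell_fracs, rng)
    values = _assemble(cfg, mean, batch_of, {b.label: b.shift},
                       {b.label: b.scale}, rng)
    return (BetaMatrix(pd.DataFrame(values, index=site_ids, columns=sample_ids)),
            SampleSheet(pd.DataFrame(sheet_cols)))
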