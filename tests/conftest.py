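"""Shared fixtures: synthetic cohorts at the default study conditions.

Heavy objects (the default 900 x 2000 training draw, its external cohort
and one full cross-validated fit) are session-scoped so the acceptance
tests share them instead of recomputing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import epiclock as ec


@pytest.fixture(scope="session")
def default_cohort():
    """Training draw at default study conditions (900 samples, 2000 sites)."""
    cfg = ec.SimConfig(seed=2024)
    bm, sheet, truth = ec.simulate_dataset(cfg)
    return cfg, bm, sheet, truth


@pytest.fixture(scope="session")
def external_cohort(default_cohort):
    """Validation cohort of 18-year-olds drawn from the same site truth."""
    cfg, _, _, truth = default_cohort
    return ec.make_external_cohort(cfg, truth, target_age=18.5, n=200)


@pytest.fixture(scope="session")
def default_fit(default_cohort):
    """One cross-validated 1se fit on the multimodal-filtered training draw."""
    _, bm, sheet, _ = default_cohort
    report = ec.modality_scan(bm)
    filtered = ec.remove_multimodal(bm, report)
    fit = ec.EpigeneticClock(filtered, sheet, ec.TrainingConfig(seed=7)).fit()
    return filtered, report, fit


@pytest.fixture()
def tiny_bm():
    """3 sites x 4 samples, handy for IO and plumbing tests."""
    vals = pd.DataFrame(
        [[0.1, 0.2, 0.3, 0.4],
         [0.5, 0.6, 0.7, 0.8],
         [0.9, 0.15, 0.25, 0.35]],
        index=["cg000001", "cg000002", "cg000003"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ec.BetaMatrix(vals)


@pytest.fixture()
def tiny_sheet():
    return ec.SampleSheet(pd.DataFrame({
        "sample_id": ["s1", "s2", "s3", "s4"],
        "age": [12.0, 18.5, 25.0, 20.0],
        "sex": ["male", "female", "female", "male"],
        "batch": ["A", "A", "B", "B"],
    }))


def two_batch_cohort(seed=5, n_sites=80, n_per_batch=50, shift=0.1,
                     age_by_batch=None, slope_sd=0.015):
    """Small cohort with a planted additive batch shift on the beta scale.

    ``age_by_batch`` maps batch label -> (lo, hi) age range, letting tests
    confound age with batch on purpose.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_batch
    batch = np.array(["A"] * n_per_batch + ["B"] * n_per_batch)
    if age_by_batch is None:
        age = rng.uniform(12, 25, n)
    else:
        age = np.concatenate([
            rng.uniform(*age_by_batch["A"], n_per_batch),
            rng.uniform(*age_by_batch["B"], n_per_batch),
        ])
    base = rng.uniform(0.25, 0.65, (n_sites, 1))
    slope = rng.normal(0, slope_sd, (n_sites, 1))
    mean = base + slope * (age[None, :] - 18.0)
    vals = mean + np.where(batch == "B", shift, 0.0)[None, :]
    vals = np.clip(vals + rng.normal(0, 0.03, (n_sites, n)), 0.001, 0.999)
    ids = [f"cg{i:06d}" for i in range(n_sites)]
    samples = [f"s{j:03d}" for j in range(n)]
    bm = ec.BetaMatrix(pd.DataFrame(vals, index=ids, columns=samples))
    sheet = ec.SampleSheet(pd.DataFrame({
        "sample_id": samples, "age": age,
        "sex": rng.choice(["male", "female"], n), "batch": batch,
    }))
    return bm, sheet, slope.ravel()
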