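"""Beta-value computation, probe blacklisting and sample QC.

Methylation level at a site is the beta value

    beta = M / (M + U + offset)

with M/U the methylated/unmethylated fluorescence intensities and a small
stabilizing offset (default 100) that keeps near-zero-intensity probes from
blowing up. Probe blacklists (SNP-associated, cross-reactive, absent from
newer chips) are user-supplied plain-text id lists. Sample QC is flag-only:
samples are reported, never deleted automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import BetaMatrix

__all__ = [
    "ProbeBlacklist",
    "compute_beta",
    "filter_probes",
    "qc_samples",
]

DEFAULT_OFFSET = 100.0


@dataclass(frozen=True)
class ProbeBlacklist:
    name: str
    site_ids: frozenset[str]

    @classmethod
    def from_ids(cls, name: str, ids) -> "ProbeBlacklist":
        return cls(name=name, site_ids=frozenset(str(s) for s in ids))

    @classmethod
    def from_file(cls, path, name: str | None = None) -> "ProbeBlacklist":
        from .data import read_site_list
        from pathlib import Path

        ids = read_site_list(path)
        return cls.from_ids(name or Path(path).stem, ids)


def compute_beta(meth, unmeth, offset: float = DEFAULT_OFFSET,
                 site_ids=None, sample_ids=None) -> BetaMatrix:
    """Elementwise beta = meth / (meth + unmeth + offset).

    ``meth`` and ``unmeth`` are equally-shaped nonnegative intensity arrays
    (sites x samples). With offset > 0 the result is strictly below 1.
    """
    meth = np.atleast_2d(np.asarray(meth, dtype=float))
    unmeth = np.atleast_2d(np.asarray(unmeth, dtype=float))
    if meth.shape != unmeth.shape:
        raise ValueError("meth and unmeth must have identical shape")
    if offset < 0:
        raise ValueError("offset must be nonnegative")
    if np.any(meth < 0) or np.any(unmeth < 0):
        raise ValueError("negative intensity")
    denom = meth + unmeth + offset
    with np.errstate(invalid="ignore"):
        beta = np.where(denom > 0, meth / denom, 0.0)
    idx = site_ids if site_ids is not None else [f"site{i}" for i in range(meth.shape[0])]
    cols = sample_ids if sample_ids is not None else [f"sample{j}" for j in range(meth.shape[1])]
    return BetaMatrix(pd.DataFrame(beta, index=idx, columns=cols))


def filter_probes(bm: BetaMatrix, blacklists) -> tuple[BetaMatrix, pd.DataFrame]:
    """Drop blacklisted sites; return the filtered matrix and a removal log.

    A site present in several lists is removed once and attributed to the
    first list that names it (lists are applied in the order given).
    """
    removed: set[str] = set()
    log_rows = []
    present = set(bm.site_ids)
    for bl in blacklists:
        hit = (present & set(bl.site_ids)) - removed
        removed |= hit
        log_rows.append({"blacklist": bl.name, "n_removed": len(hit)})
    out = bm.drop_sites(removed) if removed else bm
    return out, pd.DataFrame(log_rows, columns=["blacklist", "n_removed"])


def qc_samples(bm: BetaMatrix, max_missing: float = 0.05,
               beta_median_range: tuple[float, float] = (0.2, 0.8)) -> pd.DataFrame:
    """Flag low-quality samples; never mutates the matrix.

    A sample is flagged when its missing fraction exceeds ``max_missing`` or
    its median beta falls outside ``beta_median_range``. Returns one row per
    sample with columns ``sample_id, missing_fraction, median_beta, flagged,
    reasons``.
    """
    if not (0.0 <= max_missing <= 1.0):
        raise ValueError("max_missing must be in [0, 1]")
    lo, hi = beta_median_range
    if not lo < hi:
        raise ValueError("beta_median_range must be a nonempty interval")
    df = bm.values
    rows = []
    for sample in df.columns:
        col = df[sample]
        miss = float(col.isna().mean())
        med = float(col.median())  # NaN-skipping
        reasons = []
        if miss > max_missing:
            reasons.append("missing")
        if np.isnan(med) or not (lo <= med <= hi):
            reasons.append("median")
        rows.append({
            "sample_id": sample,
            "missing_fraction": miss,
            "median_beta": med,
            "flagged": bool(reasons),
            "reasons": ";".join(reasons),
        })
    return pd.DataFrame(rows)
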