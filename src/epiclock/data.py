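"""Shared domain types and file formats.

The pipeline moves four kinds of objects around: beta-value matrices
(CpG sites x samples, methylation fractions in [0, 1]), sample sheets
(per-sample age / sex / batch / optional leukocyte fractions), sparse clock
coefficient tables (one intercept row plus CpG -> weight rows) and evaluation
tables. Beta matrices are TSV with sites as rows by default -- the convention
of GEO series matrices; coefficient tables are CSV with a reserved
``Intercept`` row so they stay interoperable with published supplementary
clock tables, and a JSON sidecar carries the age-transform parameters and
training provenance.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "SampleSheet",
    "ClockModel",
    "EvaluationResult",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_clock_model",
    "write_clock_model",
    "read_site_list",
]

_CPG_ID = re.compile(r"^[A-Za-z][A-Za-z0-9_.:-]*$")

INTERCEPT_LABEL = "Intercept"


def _check_unique(ids: Sequence[str], what: str) -> None:
    counts = pd.Index(ids).value_counts()
    dups = counts[counts > 1]
    if len(dups):
        raise ValueError(f"duplicate {what}: {', '.join(map(str, dups.index[:10]))}")


class BetaMatrix:
    """Methylation fractions, sites x samples.

    Wraps a float DataFrame whose index holds CpG ids and whose columns hold
    sample ids. Non-missing values must lie in [0, 1]; NaN marks missing and
    is carried through, never silently imputed.
    """

    def __init__(self, values: pd.DataFrame):
        if values.shape[0] == 0 or values.shape[1] == 0:
            raise ValueError("beta matrix must have at least one site and one sample")
        _check_unique(values.index, "site ids")
        _check_unique(values.columns, "sample ids")
        arr = values.to_numpy(dtype=float)
        bad = (arr < 0) | (arr > 1)
        if np.any(bad & ~np.isnan(arr)):
            r, c = np.argwhere(bad & ~np.isnan(arr))[0]
            raise ValueError(
                f"beta value out of [0, 1] at site {values.index[r]!r}, "
                f"sample {values.columns[c]!r}: {arr[r, c]}"
            )
        self._df = values.astype(float)
        self._df.index = self._df.index.astype(str)
        self._df.columns = self._df.columns.astype(str)

    @property
    def values(self) -> pd.DataFrame:
        return self._df

    @property
    def site_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def n_sites(self) -> int:
        return self._df.shape[0]

    @property
    def n_samples(self) -> int:
        return self._df.shape[1]

    def select_sites(self, sites: Iterable[str]) -> "BetaMatrix":
        sites = [s for s in sites]
        missing = set(sites) - set(self._df.index)
        if missing:
            raise KeyError(f"sites not in matrix: {sorted(missing)[:10]}")
        return BetaMatrix(self._df.loc[sites])

    def select_samples(self, samples: Iterable[str]) -> "BetaMatrix":
        samples = [s for s in samples]
        missing = set(samples) - set(self._df.columns)
        if missing:
            raise KeyError(f"samples not in matrix: {sorted(missing)[:10]}")
        return BetaMatrix(self._df[samples])

    def drop_sites(self, sites: Iterable[str]) -> "BetaMatrix":
        drop = set(sites)
        keep = [s for s in self._df.index if s not in drop]
        return BetaMatrix(self._df.loc[keep])

    def __repr__(self) -> str:  # pragma: no cover
        return f"BetaMatrix({self.n_sites} sites x {self.n_samples} samples)"


SEXES = ("male", "female", "unknown")


class SampleSheet:
    """Per-sample metadata: chronological age (years), sex, batch, cell fractions.

    ``cell_columns`` lists optional leukocyte-fraction columns (each in
    [0, 1]); any column named ``cell_<type>`` in an input CSV is picked up
    automatically.
    """

    REQUIRED = ("sample_id", "age")

    def __init__(self, table: pd.DataFrame):
        for col in self.REQUIRED:
            if col not in table.columns:
                raise ValueError(f"sample sheet missing required column {col!r}")
        table = table.copy()
        table["sample_id"] = table["sample_id"].astype(str)
        _check_unique(table["sample_id"], "sample ids")
        table["age"] = pd.to_numeric(table["age"], errors="raise").astype(float)
        if (table["age"] <= 0).any():
            bad = table.loc[table["age"] <= 0, "sample_id"].iloc[0]
            raise ValueError(f"non-positive age for sample {bad!r}")
        if "sex" in table.columns:
            table["sex"] = table["sex"].fillna("unknown").astype(str).str.lower()
            unknown = set(table["sex"]) - set(SEXES)
            if unknown:
                raise ValueError(f"unrecognised sex labels: {sorted(unknown)}")
        else:
            table["sex"] = "unknown"
        if "batch" in table.columns:
            table["batch"] = table["batch"].astype(str)
        for col in self.cell_columns_of(table):
            vals = pd.to_numeric(table[col], errors="raise").astype(float)
            if ((vals < 0) | (vals > 1)).any():
                raise ValueError(f"cell fraction column {col!r} outside [0, 1]")
            table[col] = vals
        self._df = table.set_index("sample_id", drop=False)

    @staticmethod
    def cell_columns_of(table: pd.DataFrame) -> list[str]:
        return [c for c in table.columns if c.startswith("cell_")]

    @property
    def table(self) -> pd.DataFrame:
        return self._df

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df["sample_id"])

    @property
    def ages(self) -> pd.Series:
        return self._df["age"]

    @property
    def batches(self) -> pd.Series:
        if "batch" not in self._df.columns:
            raise KeyError("sample sheet has no 'batch' column")
        return self._df["batch"]

    @property
    def cell_columns(self) -> list[str]:
        return self.cell_columns_of(self._df)

    def cell_fractions(self) -> pd.DataFrame:
        cols = self.cell_columns
        if not cols:
            raise KeyError("sample sheet has no cell-fraction columns")
        return self._df[cols]

    def subset(self, sample_ids: Iterable[str]) -> "SampleSheet":
        ids = [str(s) for s in sample_ids]
        missing = set(ids) - set(self._df.index)
        if missing:
            raise KeyError(f"samples not in sheet: {sorted(missing)[:10]}")
        return SampleSheet(self._df.loc[ids].reset_index(drop=True))

    def aligned_to(self, bm: BetaMatrix) -> "SampleSheet":
        """Subset and order to match a beta matrix's samples."""
        return self.subset(bm.sample_ids)

    def __len__(self) -> int:
        return len(self._df)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SampleSheet({len(self)} samples)"


@dataclass
class ClockModel:
    """A fitted linear age clock: intercept plus sparse CpG weights.

    The linear score ``intercept + sum_j coef_j * beta_j`` lives on the
    transformed-age scale described by ``transform_spec``; predictions in
    years are obtained through the inverse transform.
    """

    intercept: float
    coefficients: dict[str, float]
    transform_spec: "TransformSpec"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        from .age_transform import TransformSpec

        clean = {}
        for site, w in self.coefficients.items():
            if not _CPG_ID.match(str(site)):
                raise ValueError(f"invalid CpG identifier {site!r}")
            if w != 0.0:
                clean[str(site)] = float(w)
        self.coefficients = clean
        if self.transform_spec is None:
            self.transform_spec = TransformSpec()
        self.intercept = float(self.intercept)

    @property
    def sites(self) -> list[str]:
        return list(self.coefficients)

    @property
    def n_sites(self) -> int:
        return len(self.coefficients)


@dataclass
class EvaluationResult:
    """Per-repeat MAD records from the repeated-split evaluation."""

    records: pd.DataFrame  # columns: repeat, internal_mad, external_mad, n_sites

    def __post_init__(self):
        need = {"repeat", "internal_mad", "n_sites"}
        if not need <= set(self.records.columns):
            raise ValueError(f"evaluation records need columns {sorted(need)}")
        for col in ("internal_mad", "external_mad"):
            if col in self.records and (self.records[col].dropna() < 0).any():
                raise ValueError("MAD must be nonnegative")

    def summary(self) -> pd.DataFrame:
        cols = [c for c in ("internal_mad", "external_mad", "n_sites") if c in self.records]
        return self.records[cols].agg(["median", "min", "max"])

    def __repr__(self) -> str:  # pragma: no cover
        med = self.records["internal_mad"].median()
        return f"EvaluationResult({len(self.records)} repeats, median internal MAD {med:.3f} y)"


# ---------------------------------------------------------------------------
# Readers / writers


def read_beta_matrix(path, dialect: str = "sites-as-rows") -> BetaMatrix:
    """Read a beta matrix from TSV/CSV (one id header row, one id column).

    ``dialect`` chooses whether rows are sites (default, the GEO
    series-matrix layout) or samples. Empty cells become NaN; out-of-range
    or non-numeric cells raise with their location.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    df = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        try:
            df[col] = pd.to_numeric(raw[col].str.strip() if raw[col].dtype == object else raw[col])
        except (ValueError, TypeError):
            vals = pd.to_numeric(raw[col], errors="coerce")
            bad_rows = raw.index[vals.isna() & raw[col].notna() & (raw[col].str.strip() != "")]
            raise ValueError(
                f"non-numeric cell in column {col!r}, row {bad_rows[0]!r}"
            ) from None
    if dialect == "sites-as-columns":
        df = df.T
    elif dialect != "sites-as-rows":
        raise ValueError(f"unknown dialect {dialect!r}")
    return BetaMatrix(df)


def write_beta_matrix(bm: BetaMatrix, path, dialect: str = "sites-as-rows") -> None:
    df = bm.values if dialect == "sites-as-rows" else bm.values.T
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df.to_csv(path, sep=sep, float_format="%.6f", index_label="cpg_id")


def read_sample_sheet(path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path))


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.table.to_csv(path, index=False)


def read_clock_model(path) -> ClockModel:
    """Load a clock from a coefficient CSV plus optional JSON sidecar.

    The CSV has columns ``site,coefficient`` with a reserved ``Intercept``
    row. A sidecar ``<path>.json`` (if present) supplies the transform
    parameters and training metadata; without it the canonical adult-age-20
    transform is assumed.
    """
    from .age_transform import TransformSpec

    path = Path(path)
    tab = pd.read_csv(path)
    cols = {c.lower(): c for c in tab.columns}
    if "site" not in cols or "coefficient" not in cols:
        raise ValueError("clock table must have columns 'site' and 'coefficient'")
    sites = tab[cols["site"]].astype(str)
    coefs = pd.to_numeric(tab[cols["coefficient"]], errors="raise")
    is_int = sites == INTERCEPT_LABEL
    if is_int.sum() == 0:
        raise ValueError(f"clock table has no {INTERCEPT_LABEL!r} row")
    if is_int.sum() > 1:
        raise ValueError(f"clock table has multiple {INTERCEPT_LABEL!r} rows")
    _check_unique(sites[~is_int], "CpG ids in clock table")
    intercept = float(coefs[is_int].iloc[0])
    coefficients = dict(zip(sites[~is_int], coefs[~is_int].astype(float)))

    sidecar = path.with_suffix(path.suffix + ".json")
    spec = TransformSpec()
    meta: dict = {}
    if sidecar.exists():
        blob = json.loads(sidecar.read_text())
        ts = blob.get("transform_spec", {})
        spec = TransformSpec(
            adult_age=float(ts.get("adult_age", 20.0)),
            enabled=bool(ts.get("enabled", True)),
        )
        meta = blob.get("meta", {})
    return ClockModel(intercept=intercept, coefficients=coefficients,
                      transform_spec=spec, meta=meta)


def write_clock_model(model: ClockModel, path) -> None:
    path = Path(path)
    rows = [{"site": INTERCEPT_LABEL, "coefficient": model.intercept}]
    rows += [{"site": s, "coefficient": w} for s, w in model.coefficients.items()]
    pd.DataFrame(rows).to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    blob = {
        "transform_spec": {
            "adult_age": model.transform_spec.adult_age,
            "enabled": model.transform_spec.enabled,
        },
        "meta": model.meta,
    }
    sidecar.write_text(json.dumps(blob, indent=2, default=str))


def read_site_list(path) -> list[str]:
    """Plain-text CpG list, one id per line; '#' starts a comment."""
    out: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(line)
    return out
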