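"""Annual ADR count series: ingestion, validation, cumulation and tidy output.

The central container is :class:`ADRSeries`, one drug's annual spontaneous
adverse-drug-reaction (ADR) report counts on a regular calendar-year grid,
together with the running (cumulative) total that all downstream growth-model
fitting operates on.  Counts are treated as opaque annual totals, as exported
by the public FAERS and VigiAccess dashboards.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["ADRSeries", "ValidationError", "read_annual_counts", "cumulate", "write_series"]


class ValidationError(ValueError):
    """Raised when an input table or series violates the format contract."""


@dataclass(frozen=True)
class ADRSeries:
    """One drug's annual and cumulative ADR report counts.

    Parameters
    ----------
    drug_id : str
        Free-text drug label.
    years : np.ndarray
        Strictly increasing, consecutive calendar years (int).
    annual_counts : np.ndarray
        Non-negative counts (or exposure-normalized rates) aligned to
        ``years``.
    withdrawal_status : str, optional
        Free-text regulatory tag (e.g. ``"withdrawn"``, ``"regional"``,
        ``"partial"``, ``"active"``).
    withdrawal_year : int, optional
        Calendar year of market withdrawal, if any.

    Notes
    -----
    ``cumulative_counts`` are the prefix sums of ``annual_counts`` and
    ``time_index`` is the 1-based year index t = 1..n ("years since the
    series start"); every fitter in this package uses that convention.
    """

    drug_id: str
    years: np.ndarray
    annual_counts: np.ndarray
    withdrawal_status: str | None = None
    withdrawal_year: int | None = None
    cumulative_counts: np.ndarray = field(init=False, repr=False)
    time_index: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        annual = np.asarray(self.annual_counts, dtype=float)
        if years.ndim != 1 or annual.ndim != 1 or len(years) != len(annual):
            raise ValidationError("years and annual_counts must be 1-D and equal length")
        if len(years) == 0:
            raise ValidationError("empty series")
        if not np.all(np.diff(years) == 1):
            raise ValidationError(
                f"years must be consecutive; got gaps/reorder in {self.drug_id!r}"
            )
        if np.any(annual < 0):
            bad = years[annual < 0][0]
            raise ValidationError(f"negative annual count for {self.drug_id!r} in {bad}")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "annual_counts", annual)
        object.__setattr__(self, "cumulative_counts", np.cumsum(annual))
        object.__setattr__(self, "time_index", np.arange(1, len(years) + 1))

    @property
    def n_obs(self) -> int:
        return len(self.years)

    def scaled(self, c: float) -> "ADRSeries":
        """Return a copy with all counts multiplied by ``c`` > 0."""
        if c <= 0:
            raise ValidationError("scale factor must be positive")
        return replace(self, annual_counts=self.annual_counts * c)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ADRSeries):
            return NotImplemented
        return (
            self.drug_id == other.drug_id
            and np.array_equal(self.years, other.years)
            and np.allclose(self.annual_counts, other.annual_counts)
            and self.withdrawal_status == other.withdrawal_status
            and self.withdrawal_year == other.withdrawal_year
        )


def cumulate(annual_counts) -> np.ndarray:
    """Prefix-sum a vector of non-negative annual counts.

    Element ``i`` of the result is the sum of the first ``i + 1`` annual
    counts, so the output is non-decreasing.
    """
    annual = np.asarray(annual_counts, dtype=float)
    if np.any(annual < 0):
        raise ValidationError("annual counts must be non-negative")
    return np.cumsum(annual)


def read_annual_counts(source, metadata=None) -> list[ADRSeries]:
    """Read a long-format ``drug,year,count`` table into per-drug series.

    Rows sharing a (drug, year) key are summed (merged dashboard exports);
    missing interior years are zero-filled so every series sits on a
    consecutive annual grid.  An empty table yields an empty list.

    Parameters
    ----------
    source : path or file-like or DataFrame
        CSV with header ``drug,year,count`` or an equivalent DataFrame.
    metadata : path or DataFrame, optional
        CSV ``drug,withdrawal_status,withdrawal_year`` attaching regulatory
        tags to drugs.
    """
    df = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    required = {"drug", "year", "count"}
    if not required.issubset(df.columns):
        raise ValidationError(f"input table must have columns {sorted(required)}")
    if df.empty:
        return []

    years_num = pd.to_numeric(df["year"], errors="coerce")
    if years_num.isna().any() or (years_num % 1 != 0).any():
        row = df.index[years_num.isna() | (years_num % 1 != 0)][0]
        raise ValidationError(f"non-integer year at row {row}")
    counts_num = pd.to_numeric(df["count"], errors="coerce")
    if counts_num.isna().any():
        row = df.index[counts_num.isna()][0]
        raise ValidationError(f"unparseable count at row {row}")
    if (counts_num < 0).any():
        row = df.index[counts_num < 0][0]
        raise ValidationError(f"negative count at row {row}")
    # counts are usually integers, but exposure-normalized rates and
    # regenerated reference curves are real-valued; both are accepted
    df = df.assign(year=years_num.astype(int), count=counts_num.astype(float))

    meta: dict[str, tuple[str | None, int | None]] = {}
    if metadata is not None:
        mdf = metadata if isinstance(metadata, pd.DataFrame) else pd.read_csv(metadata)
        for _, r in mdf.iterrows():
            status = r.get("withdrawal_status")
            wyear = r.get("withdrawal_year")
            meta[str(r["drug"])] = (
                None if pd.isna(status) else str(status),
                None if pd.isna(wyear) else int(wyear),
            )

    out = []
    for drug, grp in df.groupby("drug", sort=True):
        per_year = grp.groupby("year")["count"].sum()
        full = np.arange(per_year.index.min(), per_year.index.max() + 1)
        annual = per_year.reindex(full, fill_value=0).to_numpy()
        status, wyear = meta.get(str(drug), (None, None))
        out.append(
            ADRSeries(
                drug_id=str(drug),
                years=full,
                annual_counts=annual,
                withdrawal_status=status,
                withdrawal_year=wyear,
            )
        )
    return out


def write_series(series: ADRSeries, destination) -> pd.DataFrame:
    """Write one series as tidy CSV ``drug,year,annual_count,cumulative_count``.

    Round-trips through :func:`read_annual_counts` (the ``annual_count``
    column is the canonical ``count``).  Withdrawal metadata, when present,
    travels as constant columns.
    """
    frame = pd.DataFrame(
        {
            "drug": series.drug_id,
            "year": series.years,
            "annual_count": series.annual_counts,
            "cumulative_count": series.cumulative_counts,
        }
    )
    if series.withdrawal_status is not None:
        frame["withdrawal_status"] = series.withdrawal_status
    if series.withdrawal_year is not None:
        frame["withdrawal_year"] = series.withdrawal_year
    frame.to_csv(destination, index=False)
    return frame


def read_tidy(source) -> list[ADRSeries]:
    """Read back a table produced by :func:`write_series`."""
    df = pd.read_csv(source)
    df = df.rename(columns={"annual_count": "count"})
    out = []
    for s in read_annual_counts(df[["drug", "year", "count"]]):
        sub = df[df["drug"] == s.drug_id]
        kwargs = {}
        if "withdrawal_status" in sub and sub["withdrawal_status"].notna().any():
            kwargs["withdrawal_status"] = str(sub["withdrawal_status"].iloc[0])
        if "withdrawal_year" in sub and sub["withdrawal_year"].notna().any():
            kwargs["withdrawal_year"] = int(sub["withdrawal_year"].iloc[0])
        out.append(replace(s, **kwargs) if kwargs else s)
    return out
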