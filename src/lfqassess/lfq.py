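"""Catch records, length-frequency matrices, and ELEFAN restructuring.

The substrate of every length-based analysis in this package is a
length-frequency (LFQ) matrix: counts of individuals per carapace-length
bin (uniform grid, default 2 mm) per monthly sample.  This module holds
the record-level data model (individual capture records and trap sets),
the binning step that turns records into an LFQ matrix, the "restructuring"
transform that converts raw counts into peak/trough scores for ELEFAN
growth scoring, and plain-CSV I/O for both representations.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CatchRecord",
    "TrapSet",
    "LengthFrequencyData",
    "RestructuredLFQ",
    "bin_lengths",
    "restructure",
    "read_catch_records_csv",
    "write_catch_records_csv",
    "read_lfq_csv",
    "write_lfq_csv",
]

_SEXES = ("male", "female", "unknown")
_SEX_CODE = {"male": "m", "female": "f", "unknown": "u"}
_SEX_DECODE = {v: k for k, v in _SEX_CODE.items()}


@dataclass(frozen=True)
class CatchRecord:
    """One captured individual: where, when, sex, size and (optional) weight."""

    set_id: str
    date: _dt.date
    depth_m: float
    sex: str
    cl_mm: float
    ww_g: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in _SEXES:
            raise ValueError(f"sex must be one of {_SEXES}, got {self.sex!r}")
        if not self.cl_mm > 0:
            raise ValueError(f"cl_mm must be positive, got {self.cl_mm}")
        if self.ww_g is not None and not self.ww_g > 0:
            raise ValueError(f"ww_g must be positive when present, got {self.ww_g}")
        if self.depth_m < 0:
            raise ValueError(f"depth_m must be non-negative, got {self.depth_m}")


@dataclass(frozen=True)
class TrapSet:
    """One fishing set: a string of traps soaked at one depth on one date."""

    set_id: str
    date: _dt.date
    depth_m: float
    n_traps: int = 15
    valid: bool = True

    def __post_init__(self) -> None:
        if self.n_traps < 1:
            raise ValueError(f"n_traps must be >= 1, got {self.n_traps}")


@dataclass
class LengthFrequencyData:
    """Binned counts on a uniform length grid, one column per sample date.

    Attributes
    ----------
    bin_midpoints_mm : ascending uniform grid of bin midpoints (mm).
    sample_dates : ascending calendar dates, one per column.
    counts : (n_bins, n_dates) non-negative matrix.
    bin_width_mm : constant bin width (mm).
    """

    bin_midpoints_mm: np.ndarray
    sample_dates: list[_dt.date]
    counts: np.ndarray
    bin_width_mm: float = 2.0

    def __post_init__(self) -> None:
        self.bin_midpoints_mm = np.asarray(self.bin_midpoints_mm, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D (bins x dates) matrix")
        if self.counts.shape != (self.bin_midpoints_mm.size, len(self.sample_dates)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{self.bin_midpoints_mm.size} bins x {len(self.sample_dates)} dates"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        diffs = np.diff(self.bin_midpoints_mm)
        if self.bin_midpoints_mm.size > 1 and not np.allclose(
            diffs, self.bin_width_mm, rtol=0, atol=1e-9
        ):
            raise ValueError(
                "bin midpoints must be strictly increasing with constant "
                f"spacing equal to bin_width_mm={self.bin_width_mm}"
            )
        if not self.bin_width_mm > 0:
            raise ValueError("bin_width_mm must be positive")
        dates = list(self.sample_dates)
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("sample_dates must be strictly ascending")

    @property
    def n_bins(self) -> int:
        return self.bin_midpoints_mm.size

    @property
    def n_samples(self) -> int:
        return len(self.sample_dates)

    @property
    def bin_lower_edges_mm(self) -> np.ndarray:
        return self.bin_midpoints_mm - self.bin_width_mm / 2.0

    @property
    def bin_upper_edges_mm(self) -> np.ndarray:
        return self.bin_midpoints_mm + self.bin_width_mm / 2.0

    def pooled(self) -> "LengthFrequencyData":
        """Sum counts across all sample dates into a single column."""
        return LengthFrequencyData(
            bin_midpoints_mm=self.bin_midpoints_mm.copy(),
            sample_dates=[self.sample_dates[-1]],
            counts=self.counts.sum(axis=1, keepdims=True),
            bin_width_mm=self.bin_width_mm,
        )


@dataclass
class RestructuredLFQ:
    """ELEFAN peak/trough scores on the same grid as the source LFQ."""

    bin_midpoints_mm: np.ndarray
    sample_dates: list[_dt.date]
    rvalues: np.ndarray
    bin_width_mm: float
    window: int = 5


def bin_lengths(
    records: Iterable[CatchRecord],
    bin_width_mm: float = 2.0,
    origin_mm: float | None = None,
    period: str = "monthly",
) -> LengthFrequencyData:
    """Bin individual lengths into a monthly length-frequency matrix.

    Bins are half-open ``[origin + i*w, origin + (i+1)*w)``.  The origin
    defaults to the smallest observed length floored to an even millimetre.
    Records are grouped by calendar month; the sample date of each column
    is the 15th of its month.

    Raises
    ------
    ValueError
        If no records are given, if ``period`` is not ``"monthly"``, or if
        a record lies below the binning origin.
    """
    if period != "monthly":
        raise ValueError(f"unsupported period {period!r}; only 'monthly'")
    if not bin_width_mm > 0:
        raise ValueError("bin_width_mm must be positive")
    records = list(records)
    if not records:
        raise ValueError("cannot bin an empty record set")

    lengths = np.array([r.cl_mm for r in records])
    if origin_mm is None:
        origin_mm = 2.0 * math.floor(lengths.min() / 2.0)
    below = np.nonzero(lengths < origin_mm)[0]
    if below.size:
        bad = records[below[0]]
        raise ValueError(
            f"record {bad.set_id!r} with cl_mm={bad.cl_mm} lies below the "
            f"binning origin {origin_mm}"
        )

    months = sorted({(r.date.year, r.date.month) for r in records})
    col_of = {ym: j for j, ym in enumerate(months)}
    sample_dates = [_dt.date(y, m, 15) for (y, m) in months]

    idx = np.floor((lengths - origin_mm) / bin_width_mm).astype(int)
    n_bins = int(idx.max()) + 1
    counts = np.zeros((n_bins, len(months)), dtype=float)
    for r, i in zip(records, idx):
        counts[i, col_of[(r.date.year, r.date.month)]] += 1

    midpoints = origin_mm + (np.arange(n_bins) + 0.5) * bin_width_mm
    return LengthFrequencyData(midpoints, sample_dates, counts, bin_width_mm)


def restructure(lfq: LengthFrequencyData, window: int = 5) -> RestructuredLFQ:
    """Transform raw counts into ELEFAN peak/trough scores.

    Per column: (1) a centred moving average of width ``window`` (edge
    windows average over the bins present on the grid); (2) the
    count/moving-average quotient ``q`` (zero
    where the moving average is zero); (3) ``r = q/q̄ − 1`` about the column
    mean quotient; (4) positive scores are de-weighted by the number of
    zero-count immediate neighbours, ``r / (nz + 1)``; (5) negative scores
    are rescaled by a single per-column factor so the column sums to zero
    (skipped when only one sign is present).  An all-zero column maps to an
    all-zero column.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    counts = lfq.counts
    n_bins, n_cols = counts.shape
    kernel = np.ones(window)
    # edge windows average over the bins actually on the grid, so a flat
    # column maps to q identically 1 and hence all-zero scores
    denom = np.convolve(np.ones(n_bins), kernel, mode="same")
    rvalues = np.zeros_like(counts, dtype=float)
    # number of zero-count immediate neighbours; off-grid neighbours count
    # as zero, consistent with the zero-padded moving average
    padded = np.pad(counts, ((1, 1), (0, 0)))
    nz = (padded[:-2] == 0).astype(int) + (padded[2:] == 0).astype(int)

    for j in range(n_cols):
        col = counts[:, j]
        if not np.any(col > 0):
            continue
        ma = np.convolve(col, kernel, mode="same") / denom
        q = np.divide(col, ma, out=np.zeros(n_bins), where=ma > 0)
        qbar = q.mean()
        if qbar == 0:
            continue
        r = q / qbar - 1.0
        pos = r > 0
        r[pos] = r[pos] / (nz[pos, j] + 1)
        neg = r < 0
        pos_sum = r[pos].sum()
        neg_sum = -r[neg].sum()
        if pos_sum > 0 and neg_sum > 0:
            r[neg] *= pos_sum / neg_sum
        rvalues[:, j] = r

    return RestructuredLFQ(
        bin_midpoints_mm=lfq.bin_midpoints_mm.copy(),
        sample_dates=list(lfq.sample_dates),
        rvalues=rvalues,
        bin_width_mm=lfq.bin_width_mm,
        window=window,
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_RECORD_COLUMNS = ["set_id", "date", "depth_m", "sex", "cl_mm", "ww_g"]
_SET_COLUMNS = ["set_id", "date", "depth_m", "n_traps", "valid"]


def write_catch_records_csv(
    records: Sequence[CatchRecord],
    sets: Sequence[TrapSet],
    records_path,
    sets_path,
) -> None:
    """Write records and trap sets as two CSV files (0.1 mm / 0.1 g precision)."""
    rec_rows = [
        {
            "set_id": r.set_id,
            "date": r.date.isoformat(),
            "depth_m": round(r.depth_m, 1),
            "sex": _SEX_CODE[r.sex],
            "cl_mm": round(r.cl_mm, 1),
            "ww_g": "" if r.ww_g is None else round(r.ww_g, 1),
        }
        for r in records
    ]
    pd.DataFrame(rec_rows, columns=_RECORD_COLUMNS).to_csv(records_path, index=False)
    set_rows = [
        {
            "set_id": s.set_id,
            "date": s.date.isoformat(),
            "depth_m": round(s.depth_m, 1),
            "n_traps": s.n_traps,
            "valid": int(s.valid),
        }
        for s in sets
    ]
    pd.DataFrame(set_rows, columns=_SET_COLUMNS).to_csv(sets_path, index=False)


def read_catch_records_csv(records_path, sets_path=None):
    """Read catch records (and optionally trap sets) from CSV.

    Returns ``(records, sets)``; ``sets`` is an empty list when no sets file
    is given.  Raises on missing mandatory columns or unparseable rows,
    naming the offender.
    """
    df = pd.read_csv(records_path, dtype={"set_id": str})
    for col in ["set_id", "date", "depth_m", "sex", "cl_mm"]:
        if col not in df.columns:
            raise ValueError(f"records file is missing mandatory column {col!r}")
    records: list[CatchRecord] = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):
        try:
            ww = getattr(row, "ww_g", None)
            ww = None if ww is None or (isinstance(ww, float) and math.isnan(ww)) else float(ww)
            records.append(
                CatchRecord(
                    set_id=str(row.set_id),
                    date=_dt.date.fromisoformat(str(row.date)),
                    depth_m=float(row.depth_m),
                    sex=_SEX_DECODE[str(row.sex).strip().lower()],
                    cl_mm=float(row.cl_mm),
                    ww_g=ww,
                )
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise ValueError(f"unparseable record at row {pos}: {exc}") from exc

    sets: list[TrapSet] = []
    if sets_path is not None:
        sf = pd.read_csv(sets_path, dtype={"set_id": str})
        for col in _SET_COLUMNS:
            if col not in sf.columns:
                raise ValueError(f"sets file is missing mandatory column {col!r}")
        for pos, row in enumerate(sf.itertuples(index=False), start=2):
            try:
                sets.append(
                    TrapSet(
                        set_id=str(row.set_id),
                        date=_dt.date.fromisoformat(str(row.date)),
                        depth_m=float(row.depth_m),
                        n_traps=int(row.n_traps),
                        valid=bool(int(row.valid)),
                    )
                )
            except (ValueError, TypeError) as exc:
                raise ValueError(f"unparseable set at row {pos}: {exc}") from exc
    return records, sets


def write_lfq_csv(lfq: LengthFrequencyData, path) -> None:
    """Write an LFQ matrix: midpoint column followed by one column per date."""
    df = pd.DataFrame(
        lfq.counts, columns=[d.isoformat() for d in lfq.sample_dates]
    )
    df.insert(0, "midpoint_mm", lfq.bin_midpoints_mm)
    df.to_csv(path, index=False)


def read_lfq_csv(path) -> LengthFrequencyData:
    """Read an LFQ matrix written by :func:`write_lfq_csv`."""
    df = pd.read_csv(path)
    if "midpoint_mm" not in df.columns:
        raise ValueError("LFQ file must have a 'midpoint_mm' first column")
    mid = df["midpoint_mm"].to_numpy(dtype=float)
    if mid.size > 1:
        diffs = np.diff(mid)
        if np.any(diffs <= 0) or not np.allclose(diffs, diffs[0], atol=1e-9):
            raise ValueError("bin midpoints must be increasing and uniform")
        width = float(diffs[0])
    else:
        width = 2.0
    date_cols = [c for c in df.columns if c != "midpoint_mm"]
    dates = [_dt.date.fromisoformat(c) for c in date_cols]
    counts = df[date_cols].to_numpy(dtype=float)
    if np.any(counts < 0):
        raise ValueError("LFQ counts must be non-negative")
    return LengthFrequencyData(mid, dates, counts, width)
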