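"""Neutrality functions and residual (epistasis) statistics.

A neutrality function predicts the fitness of a double mutant from the
fitnesses of the two single mutants under the null hypothesis that the two
mutations do not interact.  Fitness ``W`` is the growth rate of a mutant
relative to wild type (WT = 1).  Four laws are implemented:

``product``
    ``W_xy = W_x * W_y`` — a mutation's absolute effect scales with the
    fitness of the background it lands in (diminishing returns).
``additive``
    ``W_xy = W_x + W_y - 1`` — fitness *defects* add; a mutation's absolute
    effect is independent of the background.
``minimum``
    ``W_xy = min(W_x, W_y)`` — the most deleterious mutation is rate
    limiting and the milder one has no further effect.
``scott_hwa``
    ``W_xy = 1 / (1/W_x + 1/W_y - 1)`` — the exact double-mutant fitness of
    the growth-optimised two-sector proteome-allocation model (see
    :mod:`neutrality.scott_hwa`); a Product law with a correction term.

The epistasis residual of a record under a law is ``observed - predicted``
(``w_xy - law(w_x, w_y)``), so a law that predicts fitnesses that are too
high produces negative residuals.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "LAWS",
    "DivergenceError",
    "MutantPairRecord",
    "BinnedSummary",
    "predict",
    "residuals",
    "binned_summary",
    "records_to_frame",
]

logger = logging.getLogger(__name__)

#: Names of the supported neutrality laws.
LAWS = ("product", "additive", "minimum", "scott_hwa")

#: Canonical column order of a residual table.
RESIDUAL_COLUMNS = (
    "query_gene",
    "array_gene",
    "w_x",
    "w_y",
    "w_xy",
    "law",
    "predicted",
    "residual",
    "max_single",
)


class DivergenceError(ValueError):
    """The scott_hwa law diverges: ``1/w_x + 1/w_y - 1 <= 0``.

    This happens only for sufficiently beneficial mutation pairs (for
    example ``w_x = w_y = 2``); on deleterious inputs (``w <= 1``) the
    denominator is at least 1.
    """


@dataclass(frozen=True)
class MutantPairRecord:
    """One double mutant: gene identities and the three relative fitnesses."""

    query_gene: str
    array_gene: str
    w_x: float
    w_y: float
    w_xy: float
    subdataset_tag: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("w_x", "w_y", "w_xy"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")


def records_to_frame(records: Union[pd.DataFrame, Iterable[MutantPairRecord]]) -> pd.DataFrame:
    """Normalise a record sequence (or pass through a DataFrame) to the
    canonical columns ``query_gene, array_gene, w_x, w_y, w_xy``."""
    if isinstance(records, pd.DataFrame):
        missing = {"w_x", "w_y", "w_xy"} - set(records.columns)
        if missing:
            raise ValueError(f"record frame lacks columns {sorted(missing)}")
        df = records.copy()
        for col in ("query_gene", "array_gene"):
            if col not in df.columns:
                df[col] = ""
        return df
    rows = [
        (r.query_gene, r.array_gene, r.w_x, r.w_y, r.w_xy, r.subdataset_tag)
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=["query_gene", "array_gene", "w_x", "w_y", "w_xy", "subdataset_tag"],
    )


def _predict_arrays(law: str, w_x: np.ndarray, w_y: np.ndarray):
    """Vectorised prediction; returns (values, divergent_mask)."""
    if law == "product":
        return w_x * w_y, np.zeros(w_x.shape, dtype=bool)
    if law == "additive":
        return w_x + w_y - 1.0, np.zeros(w_x.shape, dtype=bool)
    if law == "minimum":
        return np.minimum(w_x, w_y), np.zeros(w_x.shape, dtype=bool)
    if law == "scott_hwa":
        with np.errstate(divide="ignore", invalid="ignore"):
            den = 1.0 / w_x + 1.0 / w_y - 1.0
            bad = ~(den > 0)
            out = np.where(bad, np.nan, 1.0 / np.where(bad, 1.0, den))
        return out, bad
    raise ValueError(f"unknown law {law!r}; expected one of {LAWS}")


def predict(law: str, w_x, w_y):
    """Predicted double-mutant fitness under ``law``.

    Accepts scalars or arrays.  Negative fitness inputs are rejected.  For
    the ``scott_hwa`` law a non-positive denominator raises
    :class:`DivergenceError` (use :func:`residuals` to flag-and-exclude
    divergent records instead).
    """
    wx = np.asarray(w_x, dtype=float)
    wy = np.asarray(w_y, dtype=float)
    if np.any(wx < 0) or np.any(wy < 0):
        raise ValueError("fitness inputs must be non-negative")
    values, bad = _predict_arrays(law, wx, wy)
    if np.any(bad):
        raise DivergenceError(
            "scott_hwa law diverges (1/w_x + 1/w_y - 1 <= 0) for "
            f"{int(np.sum(bad))} input(s)"
        )
    if np.isscalar(w_x) and np.isscalar(w_y):
        return float(values)
    return values


def residuals(
    records: Union[pd.DataFrame, Iterable[MutantPairRecord]],
    law: str,
) -> pd.DataFrame:
    """Epistasis residual table for ``records`` under ``law``.

    One row per record with columns ``query_gene, array_gene, w_x, w_y,
    w_xy, law, predicted, residual, max_single`` where ``residual = w_xy -
    predicted`` and ``max_single = max(w_x, w_y)``.  Records for which the
    law is undefined (scott_hwa divergence) are excluded; the excluded
    count is logged and stored in ``frame.attrs['n_divergent_excluded']``.
    """
    df = records_to_frame(records)
    wx = df["w_x"].to_numpy(dtype=float)
    wy = df["w_y"].to_numpy(dtype=float)
    if np.any(wx < 0) or np.any(wy < 0):
        raise ValueError("fitness inputs must be non-negative")
    predicted, bad = _predict_arrays(law, wx, wy)
    out = pd.DataFrame(
        {
            "query_gene": df["query_gene"].to_numpy(),
            "array_gene": df["array_gene"].to_numpy(),
            "w_x": wx,
            "w_y": wy,
            "w_xy": df["w_xy"].to_numpy(dtype=float),
            "law": law,
            "predicted": predicted,
            "max_single": np.maximum(wx, wy),
        }
    )
    out["residual"] = out["w_xy"] - out["predicted"]
    n_bad = int(np.sum(bad))
    if n_bad:
        logger.warning("excluding %d record(s) where the %s law diverges", n_bad, law)
        out = out.loc[~bad].reset_index(drop=True)
    out = out[list(RESIDUAL_COLUMNS)]
    out.attrs["n_divergent_excluded"] = n_bad
    return out


@dataclass
class BinnedSummary:
    """Median and quartiles of residuals per equal-width bin of
    ``max_single = max(w_x, w_y)``.

    Bins are half-open ``[lo, hi)`` except the last, which is closed so that
    ``max_single == hi`` (e.g. 1.0) is included.  Empty bins carry count 0
    and NaN statistics.
    """

    bin_edges: np.ndarray
    table: pd.DataFrame = field(repr=False)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def bin_index_containing(self, value: float) -> int:
        """Index of the bin whose interval contains ``value``."""
        edges = self.bin_edges
        if not (edges[0] <= value <= edges[-1]):
            raise ValueError(f"{value} outside [{edges[0]}, {edges[-1]}]")
        idx = int(np.searchsorted(edges, value, side="right")) - 1
        return min(idx, len(edges) - 2)

    def row_containing(self, value: float) -> pd.Series:
        """Summary row of the bin containing ``value``."""
        return self.table.iloc[self.bin_index_containing(value)]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json_dict(self) -> dict:
        return {
            "bin_edges": [float(e) for e in self.bin_edges],
            "bins": json.loads(self.table.to_json(orient="records")),
        }


def binned_summary(
    table: pd.DataFrame,
    n_bins: int = 10,
    lo: float = 0.5,
    hi: float = 1.0,
) -> BinnedSummary:
    """Bin a residual table by ``max_single`` and summarise residuals.

    Records with ``max_single`` outside ``[lo, hi]`` are excluded.  Per bin
    the count, median, and 25th/75th percentiles (linear interpolation
    between order statistics) of the residuals are reported.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if not lo < hi:
        raise ValueError("lo must be < hi")
    edges = np.linspace(lo, hi, n_bins + 1)
    ms = table["max_single"].to_numpy(dtype=float)
    res = table["residual"].to_numpy(dtype=float)
    inside = (ms >= lo) & (ms <= hi)
    ms, res = ms[inside], res[inside]
    width = (hi - lo) / n_bins
    idx = np.minimum(((ms - lo) / width).astype(int), n_bins - 1)

    counts = np.zeros(n_bins, dtype=int)
    med = np.full(n_bins, np.nan)
    q25 = np.full(n_bins, np.nan)
    q75 = np.full(n_bins, np.nan)
    order = np.argsort(idx, kind="stable")
    idx_sorted, res_sorted = idx[order], res[order]
    boundaries = np.searchsorted(idx_sorted, np.arange(n_bins + 1))
    for b in range(n_bins):
        chunk = res_sorted[boundaries[b] : boundaries[b + 1]]
        counts[b] = chunk.size
        if chunk.size:
            q25[b], med[b], q75[b] = np.percentile(chunk, [25, 50, 75])
    out = pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "bin_center": 0.5 * (edges[:-1] + edges[1:]),
            "count": counts,
            "median": med,
            "q25": q25,
            "q75": q75,
        }
    )
    return BinnedSummary(bin_edges=edges, table=out)
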