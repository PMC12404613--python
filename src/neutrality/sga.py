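"""Reading and preprocessing SGA-style double-mutant fitness tables.

Synthetic Genetic Array (SGA) screens cross a set of query mutants against
an ordered array of mutants and report colony-growth fitnesses for the two
singles and the double.  The released tables are tab-separated, one row per
query x array cross, with strain identifiers of the form
``<GENE>_<allele/annotation>`` (gene = substring before the first
underscore).

Preprocessing restricts the analysis to deleterious mutations:

1. drop records where either *single*-mutant fitness exceeds 1;
2. drop records where the Additive law would predict a negative fitness,
   i.e. ``w_x + w_y < 1`` (strict; the boundary sum = 1 is retained),

so all neutrality functions are compared on the same record set.  Note the
first filter applies to single-mutant fitnesses only: double-mutant
fitnesses above 1 are retained by default since the filter's purpose is to
restrict to deleterious *mutations*; pass ``strict=True`` to also drop
``w_xy > 1``.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Tuple, Union

import pandas as pd

__all__ = [
    "SgaColumnMap",
    "SubdatasetSelector",
    "PreprocessReport",
    "DEFAULT_COLUMN_MAP",
    "DRYAD_ACCESSION",
    "read_sga",
    "filter_deleterious",
    "filter_additive_domain",
    "preprocess",
    "select_subdataset",
]

logger = logging.getLogger(__name__)

#: Dryad accession of the published complete SGA dataset (for reference; the
#: package never downloads it and no test requires it).
DRYAD_ACCESSION = "10.5061/dryad.4291s"


@dataclass(frozen=True)
class SgaColumnMap:
    """Maps the five semantic fields to source column names."""

    query_id: str = "Query Strain ID"
    array_id: str = "Array Strain ID"
    query_smf: str = "Query single mutant fitness (SMF)"
    array_smf: str = "Array SMF"
    double_fitness: str = "Double mutant fitness"

    def as_dict(self) -> dict:
        return asdict(self)


DEFAULT_COLUMN_MAP = SgaColumnMap()


@dataclass(frozen=True)
class SubdatasetSelector:
    """One screen condition: query set x array x temperature.

    query_set: ``deletion_ts`` (nonessential deletions + temperature-
    sensitive alleles) or ``damp`` (hypomorphic DAmP alleles of essential
    genes); array: ``DMA`` or ``TSA``; temperature: 26 or 30 degC.
    """

    query_set: str
    array: str
    temperature: int

    _QUERY_SETS = ("deletion_ts", "damp")
    _ARRAYS = ("DMA", "TSA")
    _TEMPS = (26, 30)

    def __post_init__(self) -> None:
        if self.query_set not in self._QUERY_SETS:
            raise ValueError(f"query_set must be one of {self._QUERY_SETS}")
        if self.array not in self._ARRAYS:
            raise ValueError(f"array must be one of {self._ARRAYS}")
        if self.temperature not in self._TEMPS:
            raise ValueError(f"temperature must be one of {self._TEMPS}")


@dataclass
class PreprocessReport:
    """Row accounting for the preprocessing filters.

    Invariant: ``n_read == n_dropped_fitness_gt1 + n_dropped_additive_domain
    + n_retained``.
    """

    n_read: int = 0
    n_dropped_fitness_gt1: int = 0
    n_dropped_additive_domain: int = 0
    n_retained: int = 0

    def validate(self) -> "PreprocessReport":
        total = self.n_dropped_fitness_gt1 + self.n_dropped_additive_domain + self.n_retained
        if total != self.n_read:
            raise ValueError(f"report does not reconcile: {self}")
        return self

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _extract_gene(strain_id: pd.Series, pattern: str) -> pd.Series:
    return strain_id.astype(str).str.extract(pattern, expand=False).fillna(strain_id)


def read_sga(
    path,
    colmap: Optional[SgaColumnMap] = None,
    gene_pattern: str = r"^([^_]+)",
) -> pd.DataFrame:
    """Read a tab-separated SGA table into the canonical record frame.

    Gene identifiers are derived from strain IDs by ``gene_pattern``
    (default: substring before the first underscore).  Rows with missing or
    non-numeric fitness fields are dropped; the count is logged and stored
    in ``frame.attrs['n_dropped_unparseable']``.
    """
    cm = colmap or DEFAULT_COLUMN_MAP
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in cm.as_dict().values() if c not in raw.columns]
    if missing:
        raise KeyError(
            f"column(s) {missing} not found in {path}; header has {list(raw.columns)}"
        )
    if raw.empty:
        logger.warning("SGA file %s contains no data rows", path)
    df = pd.DataFrame(
        {
            "query_gene": _extract_gene(raw[cm.query_id], gene_pattern),
            "array_gene": _extract_gene(raw[cm.array_id], gene_pattern),
            "w_x": pd.to_numeric(raw[cm.query_smf], errors="coerce"),
            "w_y": pd.to_numeric(raw[cm.array_smf], errors="coerce"),
            "w_xy": pd.to_numeric(raw[cm.double_fitness], errors="coerce"),
        }
    )
    ok = df[["w_x", "w_y", "w_xy"]].notna().all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("dropped %d row(s) with missing/non-numeric fitness", n_dropped)
    df = df.loc[ok].reset_index(drop=True)
    df.attrs["n_dropped_unparseable"] = n_dropped
    return df


def filter_deleterious(
    records: pd.DataFrame, strict: bool = False
) -> Tuple[pd.DataFrame, PreprocessReport]:
    """Keep only deleterious mutations: drop records with ``w_x > 1`` or
    ``w_y > 1`` (and ``w_xy > 1`` too when ``strict``)."""
    n_read = len(records)
    keep = (records["w_x"] <= 1.0) & (records["w_y"] <= 1.0)
    if strict:
        keep &= records["w_xy"] <= 1.0
    out = records.loc[keep].reset_index(drop=True)
    report = PreprocessReport(
        n_read=n_read,
        n_dropped_fitness_gt1=n_read - len(out),
        n_retained=len(out),
    ).validate()
    return out, report


def filter_additive_domain(
    records: pd.DataFrame,
) -> Tuple[pd.DataFrame, PreprocessReport]:
    """Drop records where the Additive law predicts a negative fitness,
    i.e. ``w_x + w_y < 1`` (strict inequality; the boundary is retained)."""
    n_read = len(records)
    keep = records["w_x"] + records["w_y"] >= 1.0
    out = records.loc[keep].reset_index(drop=True)
    report = PreprocessReport(
        n_read=n_read,
        n_dropped_additive_domain=n_read - len(out),
        n_retained=len(out),
    ).validate()
    return out, report


def preprocess(
    records: pd.DataFrame, strict: bool = False
) -> Tuple[pd.DataFrame, PreprocessReport]:
    """Apply both filters and return a combined, reconciling report."""
    step1, rep1 = filter_deleterious(records, strict=strict)
    step2, rep2 = filter_additive_domain(step1)
    report = PreprocessReport(
        n_read=rep1.n_read,
        n_dropped_fitness_gt1=rep1.n_dropped_fitness_gt1,
        n_dropped_additive_domain=rep2.n_dropped_additive_domain,
        n_retained=rep2.n_retained,
    ).validate()
    return step2, report


def select_subdataset(
    catalog: Mapping[SubdatasetSelector, Union[str, pd.DataFrame]],
    sel: SubdatasetSelector,
    colmap: Optional[SgaColumnMap] = None,
    run_preprocess: bool = True,
    strict: bool = False,
) -> Tuple[pd.DataFrame, PreprocessReport]:
    """Load and preprocess one subdataset from a selector -> file catalog.

    Catalog values may be file paths (read with :func:`read_sga`) or
    already-loaded record frames.
    """
    if sel not in catalog:
        available = ", ".join(
            f"({s.query_set}, {s.array}, {s.temperature})" for s in catalog
        )
        raise KeyError(
            f"subdataset ({sel.query_set}, {sel.array}, {sel.temperature}) "
            f"not in catalog; available: {available or 'none'}"
        )
    source = catalog[sel]
    df = source.copy() if isinstance(source, pd.DataFrame) else read_sga(source, colmap)
    if not run_preprocess:
        n = len(df)
        return df, PreprocessReport(n_read=n, n_retained=n).validate()
    return preprocess(df, strict=strict)
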