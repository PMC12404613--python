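"""GO biological-process pair analysis of epistasis residuals.

Genes are annotated to biological processes (possibly several per gene).
The analysis keeps processes represented by at least ``min_count``
annotated genes in the fitness dataset, enumerates unordered pairs of
distinct processes whose (dataset-restricted) gene sets are disjoint, and
profiles the epistasis residuals of double mutants bridging the two
processes.  Pairs within a single process are compared against
between-process pairs via two-sided residual tail fractions: mutations in
the same process interact more often, so both tails are heavier there.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Set

import pandas as pd

from .laws import BinnedSummary, binned_summary

__all__ = [
    "ProcessPair",
    "read_annotation_tsv",
    "read_gaf",
    "select_processes",
    "enumerate_disjoint_pairs",
    "pair_residual_profile",
    "intra_vs_inter_tails",
]

logger = logging.getLogger(__name__)

#: gene identifier -> set of process identifiers
ProcessAnnotation = Mapping[str, Set[str]]


@dataclass(frozen=True)
class ProcessPair:
    """Two distinct processes with their dataset-restricted gene sets."""

    process_a: str
    process_b: str
    gene_set_a: frozenset
    gene_set_b: frozenset

    @property
    def disjoint(self) -> bool:
        return not (self.gene_set_a & self.gene_set_b)


def read_annotation_tsv(path) -> Dict[str, Set[str]]:
    """Read a two-column ``gene<TAB>process`` table (no header required).

    Lines starting with ``#`` are ignored.
    """
    annotation: Dict[str, Set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"annotation line lacks two columns: {line!r}")
            gene, process = parts[0], parts[1]
            annotation.setdefault(gene, set()).add(process)
    return annotation


def read_gaf(
    path,
    aspect: str = "P",
    evidence_codes: Optional[Set[str]] = None,
) -> Dict[str, Set[str]]:
    """Read a GAF 2.x association file into a gene -> processes mapping.

    Keeps only the requested aspect (default ``P``, biological process).
    Evidence-code filtering is off by default; pass a set of codes to
    restrict.  The object symbol (column 3) is used as the gene identifier.
    """
    annotation: Dict[str, Set[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            symbol, qualifier, go_id, evidence, asp = (
                cols[2],
                cols[3],
                cols[4],
                cols[6],
                cols[8],
            )
            if asp != aspect:
                continue
            if "NOT" in qualifier.split("|"):
                continue
            if evidence_codes is not None and evidence not in evidence_codes:
                continue
            annotation.setdefault(symbol, set()).add(go_id)
    return annotation


def _dataset_gene_sets(
    annotation: ProcessAnnotation, dataset_genes: Set[str]
) -> Dict[str, Set[str]]:
    by_process: Dict[str, Set[str]] = {}
    for gene, processes in annotation.items():
        if gene not in dataset_genes:
            continue
        for proc in processes:
            by_process.setdefault(proc, set()).add(gene)
    return by_process


def select_processes(
    annotation: ProcessAnnotation,
    dataset_genes: Set[str],
    min_count: int = 50,
) -> Set[str]:
    """Processes with at least ``min_count`` annotated genes present in the
    fitness dataset (counting unique genes, regardless of query/array
    role)."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if not annotation:
        logger.warning("empty annotation; no processes selected")
        return set()
    by_process = _dataset_gene_sets(annotation, dataset_genes)
    return {p for p, genes in by_process.items() if len(genes) >= min_count}


def enumerate_disjoint_pairs(
    processes: Set[str],
    annotation: ProcessAnnotation,
    dataset_genes: Set[str],
) -> Sequence[ProcessPair]:
    """All unordered pairs of distinct selected processes whose
    dataset-restricted gene sets share no gene.

    Pairs with shared genes are discarded; the discarded count is logged
    (and equals ``C(n,2) - len(result)``).
    """
    by_process = _dataset_gene_sets(annotation, dataset_genes)
    pairs = []
    n_discarded = 0
    for a, b in itertools.combinations(sorted(processes), 2):
        pair = ProcessPair(
            process_a=a,
            process_b=b,
            gene_set_a=frozenset(by_process.get(a, ())),
            gene_set_b=frozenset(by_process.get(b, ())),
        )
        if pair.disjoint:
            pairs.append(pair)
        else:
            n_discarded += 1
    logger.info(
        "enumerated %d disjoint process pairs (%d discarded for shared genes)",
        len(pairs),
        n_discarded,
    )
    return pairs


def pair_residual_profile(
    pair: ProcessPair,
    residual_table: pd.DataFrame,
    n_bins: int = 10,
    lo: float = 0.5,
    hi: float = 1.0,
) -> BinnedSummary:
    """Binned residual summary restricted to records bridging the pair.

    A record qualifies when one gene is annotated to ``process_a`` and the
    other to ``process_b`` (either role).  Pairs covering no records return
    all-empty bins.
    """
    q = residual_table["query_gene"]
    a = residual_table["array_gene"]
    in_a_q = q.isin(pair.gene_set_a)
    in_b_q = q.isin(pair.gene_set_b)
    in_a_a = a.isin(pair.gene_set_a)
    in_b_a = a.isin(pair.gene_set_b)
    mask = (in_a_q & in_b_a) | (in_b_q & in_a_a)
    return binned_summary(residual_table.loc[mask], n_bins=n_bins, lo=lo, hi=hi)


def intra_vs_inter_tails(
    residual_table: pd.DataFrame,
    annotation: ProcessAnnotation,
    threshold: float,
    processes: Optional[Set[str]] = None,
) -> pd.DataFrame:
    """Two-sided residual tail fractions for intra- vs inter-process pairs.

    A record is *intra* when its two genes share at least one (selected)
    process and *inter* when both are annotated but share none.  Records
    with a gene lacking any (selected) annotation are excluded; the count
    is stored in ``result.attrs['n_unannotated_excluded']``.

    Returns a frame with one row per class and columns ``class, n,
    frac_pos, frac_neg`` (fractions of residuals above ``+threshold`` and
    below ``-threshold``).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if processes is not None:
        annotation = {
            g: (ps & processes) for g, ps in annotation.items() if ps & processes
        }
    rows = {"intra": [], "inter": []}
    n_excluded = 0
    res = residual_table["residual"].to_numpy(dtype=float)
    qs = residual_table["query_gene"].to_numpy()
    ars = residual_table["array_gene"].to_numpy()
    for r, qg, ag in zip(res, qs, ars):
        pq = annotation.get(qg)
        pa = annotation.get(ag)
        if not pq or not pa:
            n_excluded += 1
            continue
        rows["intra" if pq & pa else "inter"].append(r)
    out_rows = []
    for cls in ("intra", "inter"):
        vals = pd.Series(rows[cls], dtype=float)
        n = len(vals)
        out_rows.append(
            {
                "class": cls,
                "n": n,
                "frac_pos": float((vals > threshold).mean()) if n else 0.0,
                "frac_neg": float((vals < -threshold).mean()) if n else 0.0,
            }
        )
    out = pd.DataFrame(out_rows)
    out.attrs["n_unannotated_excluded"] = n_excluded
    if n_excluded:
        logger.info("excluded %d record(s) with unannotated gene(s)", n_excluded)
    return out
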