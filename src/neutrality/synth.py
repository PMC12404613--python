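"""Synthetic double-mutant fitness data with known ground truth.

The generator emulates the statistical structure of an SGA-style screen:
single-mutant fitnesses drawn i.i.d. on (0, 1] (mutations generally
decrease fitness, so the default distribution piles mass near 1 with a
deleterious tail), double-mutant fitnesses produced by a chosen neutrality
law plus additive measurement noise (truncated at 0), and multi-process
gene annotations with controllable between-process overlap.  When
annotations are generated, records whose genes share a process ("intra"
pairs) can receive extra noise (``sigma_intra``), emulating the heavier
residual tails of same-process interactions.

It deliberately does *not* emulate colony geometry, plate/batch effects,
or the real screens' non-independence between records; see
docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Set, Tuple

import numpy as np
import pandas as pd

from .laws import LAWS, predict
from .sga import DEFAULT_COLUMN_MAP

__all__ = [
    "SynthConfig",
    "generate_fitness_table",
    "generate_annotations",
    "generate_dataset",
    "to_sga_tsv",
    "write_annotation_tsv",
]

#: Default single-mutant fitness distribution: a mixture of a near-1
#: component (weight 0.35, 1 minus a half-normal of scale 0.02) and a
#: Beta(1.4, 1.1)-shaped deleterious tail stretched over [0.35, 1].
DEFAULT_SINGLE_FITNESS = {"family": "sga_like"}


@dataclass(frozen=True)
class SynthConfig:
    """Ground-truth configuration for one synthetic dataset."""

    n_genes: int = 500
    n_pairs: int = 10_000
    law: str = "product"
    noise_sigma: float = 0.05
    noise_mode: str = "additive"  # or "multiplicative"
    single_fitness: dict = field(default_factory=lambda: dict(DEFAULT_SINGLE_FITNESS))
    sigma_intra: Optional[float] = None
    n_processes: int = 0
    genes_per_process: int = 0
    overlap_fraction: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.law not in LAWS:
            raise ValueError(f"law must be one of {LAWS}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.noise_mode not in ("additive", "multiplicative"):
            raise ValueError("noise_mode must be 'additive' or 'multiplicative'")
        if not 0 <= self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must be in [0, 1]")
        if self.n_pairs > self.n_genes * (self.n_genes - 1) // 2:
            raise ValueError("n_pairs exceeds C(n_genes, 2)")
        if self.sigma_intra is not None and self.n_processes == 0:
            raise ValueError("sigma_intra requires generated annotations")


def _gene_names(n: int) -> np.ndarray:
    return np.array([f"G{i:05d}" for i in range(n)])


def _draw_singles(rng: np.random.Generator, n: int, spec: dict) -> np.ndarray:
    family = spec.get("family", "sga_like")
    if family == "sga_like":
        near1 = 1.0 - np.abs(rng.normal(0.0, 0.02, n))
        tail = 0.35 + 0.65 * rng.beta(1.4, 1.1, n)
        w = np.where(rng.random(n) < 0.35, near1, tail)
    elif family == "uniform":
        w = rng.uniform(spec.get("low", 0.3), spec.get("high", 1.0), n)
    elif family == "beta":
        lo, hi = spec.get("low", 0.0), spec.get("high", 1.0)
        w = lo + (hi - lo) * rng.beta(spec.get("a", 2.0), spec.get("b", 2.0), n)
    else:
        raise ValueError(f"unknown single-fitness family {family!r}")
    return np.clip(w, np.nextafter(0.0, 1.0), 1.0)


def generate_annotations(config: SynthConfig) -> Dict[str, Set[str]]:
    """Assign genes to ``n_processes`` processes of size
    ``genes_per_process`` arranged in a chain: consecutive processes share
    ``round(overlap_fraction * genes_per_process)`` genes; non-consecutive
    processes are disjoint.  ``overlap_fraction = 0`` makes all processes
    pairwise disjoint; ``overlap_fraction = 1`` makes consecutive pairs
    identical (and hence always excluded from disjoint-pair enumeration).
    """
    if config.n_processes == 0:
        return {}
    gpp = config.genes_per_process
    if gpp < 1:
        raise ValueError("genes_per_process must be >= 1 when n_processes > 0")
    shared = int(round(config.overlap_fraction * gpp))
    stride = gpp - shared
    needed = gpp + stride * (config.n_processes - 1)
    if needed > config.n_genes:
        raise ValueError(
            f"n_genes={config.n_genes} too small for {config.n_processes} "
            f"processes of {gpp} genes with overlap {config.overlap_fraction} "
            f"(need {needed})"
        )
    genes = _gene_names(config.n_genes)
    annotation: Dict[str, Set[str]] = {}
    for i in range(config.n_processes):
        start = i * stride
        for g in genes[start : start + gpp]:
            annotation.setdefault(str(g), set()).add(f"P{i:03d}")
    return annotation


def generate_fitness_table(
    config: SynthConfig,
    annotation: Optional[Dict[str, Set[str]]] = None,
) -> pd.DataFrame:
    """Generate ``n_pairs`` double-mutant records under the configured law.

    ``w_x, w_y`` are i.i.d. from the configured single-fitness
    distribution; ``w_xy = law(w_x, w_y) + noise`` truncated at 0
    (multiplicative noise mode: ``law(w_x, w_y) * (1 + noise)``).  Gene
    pairs are sampled uniformly without self-pairs.  When ``annotation``
    (or a generated one, if ``config.n_processes > 0``) is available, an
    ``intra`` column records whether the two genes share a process, and
    intra records use ``sigma_intra`` when configured.  Byte-identical for
    a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    if annotation is None and config.n_processes > 0:
        annotation = generate_annotations(config)
    n = config.n_pairs
    genes = _gene_names(config.n_genes)
    qi = rng.integers(0, config.n_genes, n)
    ai = rng.integers(0, config.n_genes, n)
    clash = qi == ai
    while np.any(clash):
        ai[clash] = rng.integers(0, config.n_genes, int(clash.sum()))
        clash = qi == ai
    w_x = _draw_singles(rng, n, config.single_fitness)
    w_y = _draw_singles(rng, n, config.single_fitness)
    pred = predict(config.law, w_x, w_y)

    sigma = np.full(n, config.noise_sigma)
    intra: Optional[np.ndarray] = None
    if annotation:
        proc_sets = [annotation.get(str(g), set()) for g in genes]
        intra = np.fromiter(
            (bool(proc_sets[q] & proc_sets[a]) for q, a in zip(qi, ai)),
            dtype=bool,
            count=n,
        )
        if config.sigma_intra is not None:
            sigma = np.where(intra, config.sigma_intra, config.noise_sigma)
    eps = rng.normal(0.0, 1.0, n) * sigma
    if config.noise_mode == "additive":
        w_xy = pred + eps
    else:
        w_xy = pred * (1.0 + eps)
    w_xy = np.maximum(w_xy, 0.0)

    df = pd.DataFrame(
        {
            "query_gene": genes[qi],
            "array_gene": genes[ai],
            "w_x": w_x,
            "w_y": w_y,
            "w_xy": w_xy,
        }
    )
    if intra is not None:
        df["intra"] = intra
    df.attrs["law"] = config.law
    df.attrs["noise_sigma"] = config.noise_sigma
    return df


def generate_dataset(
    config: SynthConfig,
) -> Tuple[pd.DataFrame, Dict[str, Set[str]]]:
    """Annotations plus a fitness table generated against them."""
    annotation = generate_annotations(config)
    table = generate_fitness_table(config, annotation=annotation)
    return table, annotation


def to_sga_tsv(table: pd.DataFrame, path) -> None:
    """Write records in the SGA dialect read by :func:`neutrality.sga.read_sga`
    (strain IDs ``<gene>_sn<row>``, default column headers)."""
    cm = DEFAULT_COLUMN_MAP
    out = pd.DataFrame(
        {
            cm.query_id: [f"{g}_sn{i}" for i, g in enumerate(table["query_gene"])],
            cm.array_id: [f"{g}_sn{i}" for i, g in enumerate(table["array_gene"])],
            cm.query_smf: table["w_x"].to_numpy(),
            cm.array_smf: table["w_y"].to_numpy(),
            cm.double_fitness: table["w_xy"].to_numpy(),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def write_annotation_tsv(annotation: Dict[str, Set[str]], path) -> None:
    """Write a two-column ``gene<TAB>process`` file readable by
    :func:`neutrality.go.read_annotation_tsv`."""
    with open(path, "w") as fh:
        for gene in sorted(annotation):
            for proc in sorted(annotation[gene]):
                fh.write(f"{gene}\t{proc}\n")
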