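"""Differential-expression scores and expressed-gene filtering.

Each gene's fold change and adjusted p-value are combined into a single
non-negative score, the pi-value::

    pi = |log2FC| * (-log10 adj_p)

which later becomes the gene-side restart mass of the random walk, so both
up- and down-regulation contribute.  Genes not expressed above the
experimental background are removed from the interactome to give a
context-specific network; the microarray and RNA-seq rules used for that
decision live here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, SchemaError

__all__ = [
    "ExpressionScores",
    "ExpressedSet",
    "pi_value",
    "load_de_table",
    "expressed_microarray",
    "expressed_rnaseq",
]

#: adjusted p-values are floored here so that p printed as 0 keeps pi finite
P_FLOOR = 1e-300


def pi_value(log2fc: float, adj_p: float, floor: float = P_FLOOR) -> float:
    """Combined magnitude/significance score ``|log2fc| * (-log10 adj_p)``.

    ``adj_p`` must lie in (0, 1]; it is floored at ``floor`` before taking
    the log so that underflowed p-values stay finite.
    """
    if not 0.0 < adj_p <= 1.0:
        raise ValueError(f"adjusted p-value must be in (0, 1], got {adj_p}")
    return abs(log2fc) * (-math.log10(max(adj_p, floor)))


@dataclass(frozen=True)
class ExpressionScores:
    """Per-gene log2 fold change, adjusted p and pi-value."""

    frame: pd.DataFrame  # index: gene; columns: log2fc, adj_p, pi

    def __post_init__(self) -> None:
        missing = {"log2fc", "adj_p", "pi"} - set(self.frame.columns)
        if missing:
            raise SchemaError(f"ExpressionScores frame missing columns {missing}")
        if self.frame.index.has_duplicates:
            raise SchemaError("ExpressionScores index contains duplicate genes")

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "ExpressionScores":
        """Build from a (gene, log2fc, adj_p) table, computing pi.

        Duplicate gene rows are collapsed by keeping the row with the largest
        pi-value, which is conservative towards signal retention.
        """
        missing = {"gene", "log2fc", "adj_p"} - set(table.columns)
        if missing:
            raise SchemaError(f"DE table missing required columns {sorted(missing)}")
        df = table.copy()
        bad = ~((df["adj_p"] > 0) & (df["adj_p"] <= 1))
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} rows with adj_p outside (0, 1], e.g. gene "
                f"{df.loc[bad, 'gene'].iloc[0]!r}"
            )
        df["pi"] = [pi_value(fc, p) for fc, p in zip(df["log2fc"], df["adj_p"])]
        df = (
            df.sort_values(["pi", "gene"])
            .drop_duplicates(subset="gene", keep="last")
            .set_index("gene")[["log2fc", "adj_p", "pi"]]
            .sort_index()
        )
        return cls(df)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.frame.index)

    def pi(self, gene: str, default: float = 0.0) -> float:
        if gene in self.frame.index:
            return float(self.frame.at[gene, "pi"])
        return default

    def pi_vector(self, genes) -> np.ndarray:
        """pi-values for ``genes`` in order; genes without a score get 0."""
        return np.array([self.pi(g) for g in genes], dtype=float)

    def __len__(self) -> int:
        return len(self.frame)


def load_de_table(path) -> ExpressionScores:
    """Read a differential-expression TSV with columns gene, log2fc, adj_p."""
    try:
        table = pd.read_csv(path, sep="\t", dtype={"gene": str})
    except Exception as exc:
        raise SchemaError(f"could not read DE table {path}: {exc}") from exc
    missing = {"gene", "log2fc", "adj_p"} - set(table.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    for col in ("log2fc", "adj_p"):
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = coerced.isna() & table[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"{path}: line {row + 2}: unparseable {col} value "
                f"{table[col].iloc[row]!r}"
            )
        table[col] = coerced
    if table[["log2fc", "adj_p"]].isna().any().any():
        raise SchemaError(f"{path}: missing numeric values in log2fc/adj_p")
    return ExpressionScores.from_table(table)


@dataclass(frozen=True)
class ExpressedSet:
    """Genes deemed expressed above background, plus the rule that decided it."""

    genes: frozenset[str]
    rule: str

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __len__(self) -> int:
        return len(self.genes)


def expressed_microarray(
    intensity: pd.DataFrame, threshold: float = 5.0, fraction: float = 0.5
) -> ExpressedSet:
    """Microarray rule: expressed iff intensity > threshold in more than
    ``fraction`` of the samples (both comparisons strict).

    ``intensity`` is a gene x sample matrix.
    """
    if intensity.shape[0] == 0 or intensity.shape[1] == 0:
        raise ConfigurationError("intensity matrix is empty")
    n_samples = intensity.shape[1]
    counts = (intensity > threshold).sum(axis=1)
    kept = intensity.index[counts > fraction * n_samples]
    return ExpressedSet(
        genes=frozenset(kept),
        rule=f"microarray: intensity > {threshold} in > {fraction:g} of {n_samples} samples",
    )


def expressed_rnaseq(fpkm: Mapping[str, float], threshold: float = 2.0) -> ExpressedSet:
    """RNA-seq rule: expressed iff FPKM > threshold (strict)."""
    negative = [g for g, v in fpkm.items() if v < 0]
    if negative:
        raise ValueError(f"negative FPKM for genes {negative[:5]}")
    kept = frozenset(g for g, v in fpkm.items() if v > threshold)
    return ExpressedSet(genes=kept, rule=f"rnaseq: FPKM > {threshold}")
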