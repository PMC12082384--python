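"""Clonotype diversity indices per repertoire stratum.

Two indices summarize a stratum's clone-size distribution:

* the Gini-Simpson index, ``1 - sum_i (n_i/N)^2`` — the probability that two
  cells drawn (with replacement) carry *different* clonotypes; 0 for a
  monoclonal population, approaching ``1 - 1/K`` for K uniform clonotypes;
* Shannon entropy, ``-sum_i p_i ln p_i`` in nats, which weights clone sizes.

Strata are (donor, lineage, cluster, compartment) cells; strata below a
minimum cell count are flagged rather than dropped, mirroring the practice
of excluding very small clusters from repertoire statistics.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats


def _as_counts(counts: Iterable[int]) -> np.ndarray:
    arr = np.asarray(list(counts) if not isinstance(counts, np.ndarray) else counts)
    arr = arr.astype(np.int64)
    if arr.size == 0:
        raise ValueError("empty stratum: diversity is undefined")
    if (arr < 1).any():
        raise ValueError("clonotype counts must be >= 1")
    return arr


def simpson_index(counts: Iterable[int], unbiased: bool = False) -> float:
    """Gini-Simpson diversity of a multiset of per-clonotype cell counts.

    With ``unbiased=True`` the without-replacement estimator
    ``1 - sum_i n_i (n_i - 1) / (N (N - 1))`` is returned instead of the
    plug-in form (the two coincide as N grows).
    """
    n = _as_counts(counts)
    total = int(n.sum())
    if unbiased:
        if total < 2:
            raise ValueError("unbiased Simpson needs at least 2 cells")
        return float(1.0 - (n * (n - 1)).sum() / (total * (total - 1)))
    p = n / total
    return float(1.0 - (p @ p))


def shannon_entropy(counts: Iterable[int], base: float | None = None) -> float:
    """Shannon entropy of the clone-size distribution, in nats by default."""
    n = _as_counts(counts)
    return float(stats.entropy(n, base=base))


def diversity_table(
    cells: pd.DataFrame,
    min_cells: int = 20,
    unbiased_simpson: bool = False,
) -> pd.DataFrame:
    """Per-stratum diversity for every non-empty stratum.

    ``cells`` needs columns donor, lineage, cluster, compartment,
    clonotype_key (one row per cell).  Returns one row per stratum with cell
    and clonotype counts, both indices, and a flag marking strata whose cell
    count falls below ``min_cells`` as "insufficient".  The result is
    invariant to the order of input rows.
    """
    required = {"donor", "lineage", "cluster", "compartment", "clonotype_key"}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"cells table is missing columns {sorted(missing)}")
    rows = []
    grouped = cells.groupby(["donor", "lineage", "cluster", "compartment"], sort=True)
    for (donor, lineage, cluster, compartment), group in grouped:
        counts = group["clonotype_key"].value_counts().to_numpy()
        n_cells = int(counts.sum())
        rows.append(
            {
                "donor": donor,
                "lineage": lineage,
                "cluster": cluster,
                "compartment": compartment,
                "n_cells": n_cells,
                "n_clonotypes": int(counts.size),
                "simpson": simpson_index(counts, unbiased=unbiased_simpson),
                "shannon": shannon_entropy(counts),
                "flag": "ok" if n_cells >= min_cells else "insufficient",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "donor",
            "lineage",
            "cluster",
            "compartment",
            "n_cells",
            "n_clonotypes",
            "simpson",
            "shannon",
            "flag",
        ],
    )


def max_shannon(n_clonotypes: int) -> float:
    """Entropy of the uniform distribution over ``n_clonotypes`` clones."""
    return math.log(n_clonotypes)
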