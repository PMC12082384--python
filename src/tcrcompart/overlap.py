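"""Clonotype-overlap permutation test between two cell compartments.

The statistic is the number of *distinct* clonotypes present in both
compartments.  The null distribution is built by pooling the cells of the
two compartments (each cell keeps its clonotype) and reassigning compartment
labels uniformly at random while keeping the two group sizes fixed — i.e. a
label-shuffling test at the cell level, which preserves the pooled
clone-size structure exactly.  An observed overlap in the far lower tail of
the null argues that the two compartments hold distinct repertoires.

The Monte-Carlo p-value uses the +1 correction
``p = (1 + #{null <= observed}) / (1 + n_permutations)`` so it is never
exactly zero; with 1000 permutations the smallest attainable p is 1/1001.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence
from zlib import crc32

import numpy as np
import pandas as pd

#: Compartment pairs compared by default: blood vs resident and
#: non-resident bone-marrow subsets, and the two bone-marrow subsets.
DEFAULT_PAIRS: tuple[tuple[str, str], ...] = (
    ("Blood", "BM_CD69neg"),
    ("BM_CD69pos", "BM_CD69neg"),
    ("Blood", "BM_CD69pos"),
)

_PERMUTATION_CHUNK = 256  # rows of the permutation matrix held at once


@dataclass
class OverlapTestResult:
    """Observed overlap, permutation null summary and one-sided p-value."""

    compartment_a: str
    compartment_b: str
    scope: str  # "global" or a cluster identifier
    n_cells_a: int
    n_cells_b: int
    observed_overlap: int
    n_permutations: int
    seed: int
    p_value: float | None = None
    null_mean: float | None = None
    null_sd: float | None = None
    null_min: int | None = None
    null_max: int | None = None
    null_histogram: dict[int, int] = field(default_factory=dict)
    donor: str | None = None
    lineage: str | None = None
    skipped: bool = False
    skipped_reason: str | None = None


def observed_overlap(keys_a: Iterable[str], keys_b: Iterable[str]) -> int:
    """Number of distinct clonotype keys present in both groups."""
    return len(set(keys_a) & set(keys_b))


def _null_overlap_distribution(
    codes: np.ndarray, n_first: int, n_permutations: int, rng: np.random.Generator
) -> np.ndarray:
    """Distinct-clonotype overlap between the two blocks of each permutation.

    ``codes`` is the pooled, factorized clonotype vector; each permutation
    splits it into blocks of ``n_first`` and ``len - n_first`` cells.  The
    overlap statistic is symmetric in the two blocks, so which block is
    called "a" does not matter.
    """
    n = codes.size
    k = int(codes.max()) + 1
    pooled_counts = np.bincount(codes, minlength=k)
    null = np.empty(n_permutations, dtype=np.int64)
    done = 0
    while done < n_permutations:
        m = min(_PERMUTATION_CHUNK, n_permutations - done)
        perms = rng.permuted(np.broadcast_to(codes, (m, n)), axis=1)
        # each permutation must preserve the pooled clonotype multiset
        assert np.array_equal(np.bincount(perms[0], minlength=k), pooled_counts)
        in_a = np.zeros((m, k), dtype=bool)
        in_b = np.zeros((m, k), dtype=bool)
        rows_a = np.repeat(np.arange(m), n_first)
        rows_b = np.repeat(np.arange(m), n - n_first)
        in_a[rows_a, perms[:, :n_first].ravel()] = True
        in_b[rows_b, perms[:, n_first:].ravel()] = True
        null[done : done + m] = np.count_nonzero(in_a & in_b, axis=1)
        done += m
    return null


def permutation_overlap_test(
    keys_a: Sequence[str],
    keys_b: Sequence[str],
    n_permutations: int = 1000,
    seed: int = 0,
    min_cells: int = 0,
    alternative: str = "lower",
    ties: str = "inclusive",
    compartment_a: str = "a",
    compartment_b: str = "b",
    scope: str = "global",
) -> OverlapTestResult:
    """Size-preserving label-shuffling test for clonotype overlap.

    ``keys_a`` / ``keys_b`` are the per-cell clonotype keys of the two
    compartments.  ``alternative="lower"`` (default) asks whether the
    observed number of shared clonotypes is smaller than expected when
    labels are exchangeable; "two-sided" doubles the smaller tail.

    ``ties`` controls how null values equal to the observed overlap enter
    the p-value.  "inclusive" (default, the reported p) counts them fully
    and is conservative (super-uniform) because the overlap statistic is
    discrete; "mid" counts half of them; "randomized" counts a uniform
    fraction, giving an exactly uniform p under exchangeability.  The
    latter two are calibration diagnostics, not reporting defaults.

    A group below ``min_cells`` yields a result flagged ``skipped`` with no
    p-value.  The pooled multiset is canonicalized (sorted, smaller group
    first) before permuting, so swapping the two groups with the same seed
    reproduces the null distribution exactly.
    """
    if alternative not in ("lower", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if ties not in ("inclusive", "mid", "randomized"):
        raise ValueError(f"unknown tie-handling {ties!r}")
    keys_a = list(keys_a)
    keys_b = list(keys_b)
    n_a, n_b = len(keys_a), len(keys_b)
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty")
    obs = observed_overlap(keys_a, keys_b)
    result = OverlapTestResult(
        compartment_a=compartment_a,
        compartment_b=compartment_b,
        scope=scope,
        n_cells_a=n_a,
        n_cells_b=n_b,
        observed_overlap=obs,
        n_permutations=n_permutations,
        seed=seed,
    )
    if min(n_a, n_b) < min_cells:
        result.skipped = True
        result.skipped_reason = (
            f"group size {min(n_a, n_b)} below min_cells={min_cells}"
        )
        return result
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")

    pooled = np.sort(np.asarray(keys_a + keys_b, dtype=object))
    _, codes = np.unique(pooled, return_inverse=True)
    rng = np.random.default_rng(seed)
    null = _null_overlap_distribution(
        codes.astype(np.int64), min(n_a, n_b), n_permutations, rng
    )

    n_below = int((null < obs).sum())
    n_tied = int((null == obs).sum())
    if ties == "inclusive":
        lower = (1 + n_below + n_tied) / (1 + n_permutations)
        upper = (1 + n_permutations - n_below) / (1 + n_permutations)
    elif ties == "mid":
        lower = (1 + n_below + 0.5 * n_tied) / (1 + n_permutations)
        upper = (1 + n_permutations - n_below - 0.5 * n_tied) / (1 + n_permutations)
    else:  # randomized: exactly uniform under exchangeability
        u = float(rng.random())
        lower = (u + n_below + u * n_tied) / (1 + n_permutations)
        upper = 1.0 + 1.0 / (1 + n_permutations) - lower
    if alternative == "lower":
        p = lower
    else:
        p = min(1.0, 2.0 * min(lower, upper))
    values, counts = np.unique(null, return_counts=True)
    result.p_value = float(p)
    result.null_mean = float(null.mean())
    result.null_sd = float(null.std(ddof=0))
    result.null_min = int(null.min())
    result.null_max = int(null.max())
    result.null_histogram = {int(v): int(c) for v, c in zip(values, counts)}
    return result


def derive_seed(master_seed: int, stratum_id: str) -> int:
    """Stable per-test seed from the master seed and a stratum identifier.

    Uses a CRC32 of the identifier so adding or removing one stratum does
    not perturb the RNG stream of any other.  Result is < 2**31.
    """
    return (int(master_seed) * 2654435761 + crc32(stratum_id.encode())) % (2**31)


def run_overlap_suite(
    cells: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS,
    scopes: Sequence[str] = ("global", "cluster"),
    n_permutations: int = 1000,
    seed: int = 0,
    min_cells: int = 20,
    alternative: str = "lower",
    ties: str = "inclusive",
) -> list[OverlapTestResult]:
    """One overlap test per donor x lineage x compartment pair x scope.

    ``cells`` needs columns donor, lineage, cluster, compartment,
    clonotype_key (one row per cell).  Scope "global" pools all clusters;
    scope "cluster" runs the test separately within each transcriptional
    cluster.  Pairs whose compartments are absent or below ``min_cells`` in
    a stratum produce results flagged skipped.  Deterministic given ``seed``.
    """
    required = {"donor", "lineage", "cluster", "compartment", "clonotype_key"}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"cells table is missing columns {sorted(missing)}")
    results: list[OverlapTestResult] = []
    for (donor, lineage), stratum in cells.groupby(["donor", "lineage"], sort=True):
        scoped: list[tuple[str, pd.DataFrame]] = []
        if "global" in scopes:
            scoped.append(("global", stratum))
        if "cluster" in scopes:
            for cluster, sub in stratum.groupby("cluster", sort=True):
                scoped.append((str(cluster), sub))
        for scope, sub in scoped:
            by_comp = dict(list(sub.groupby("compartment")))
            for comp_a, comp_b in pairs:
                stratum_id = f"{donor}|{lineage}|{scope}|{comp_a}|{comp_b}"
                test_seed = derive_seed(seed, stratum_id)
                cells_a = by_comp.get(comp_a)
                cells_b = by_comp.get(comp_b)
                if cells_a is None or cells_b is None:
                    result = OverlapTestResult(
                        compartment_a=comp_a,
                        compartment_b=comp_b,
                        scope=scope,
                        n_cells_a=0 if cells_a is None else len(cells_a),
                        n_cells_b=0 if cells_b is None else len(cells_b),
                        observed_overlap=0,
                        n_permutations=n_permutations,
                        seed=test_seed,
                        skipped=True,
                        skipped_reason="compartment absent from stratum",
                    )
                else:
                    result = permutation_overlap_test(
                        cells_a["clonotype_key"].tolist(),
                        cells_b["clonotype_key"].tolist(),
                        n_permutations=n_permutations,
                        seed=test_seed,
                        min_cells=min_cells,
                        alternative=alternative,
                        ties=ties,
                        compartment_a=comp_a,
                        compartment_b=comp_b,
                        scope=scope,
                    )
                result.donor = str(donor)
                result.lineage = str(lineage)
                results.append(result)
    return results


def overlap_frame(results: Sequence[OverlapTestResult]) -> pd.DataFrame:
    """Tabular summary of overlap tests (null histograms omitted)."""
    return pd.DataFrame(
        [
            {
                "donor": r.donor,
                "lineage": r.lineage,
                "scope": r.scope,
                "compartment_a": r.compartment_a,
                "compartment_b": r.compartment_b,
                "n_cells_a": r.n_cells_a,
                "n_cells_b": r.n_cells_b,
                "observed_overlap": r.observed_overlap,
                "null_mean": r.null_mean,
                "null_sd": r.null_sd,
                "p_value": r.p_value,
                "n_permutations": r.n_permutations,
                "seed": r.seed,
                "skipped_reason": r.skipped_reason if r.skipped else "",
            }
            for r in results
        ]
    )
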