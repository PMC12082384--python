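"""Surface-marker gating of cells into T-cell subsets from CITE-seq counts.

Gating operates on log1p-transformed antibody counts for CD4, CD8 and CD69.
Together with the tissue of origin this defines six subsets: Blood CD4+,
BM CD4+CD69+, BM CD4+CD69-, Blood CD8+, BM CD8+CD69+, BM CD8+CD69-.  Blood
cells are not split on CD69 by default (blood memory T cells are treated as
the surface-CD69-negative reference population); CD4/CD8 double-positive
and double-negative barcodes are rejected as putative doublets / non-T
events.

Thresholds are configuration, not code: "manual" gates are inherently
dataset-specific, so fixed cutoffs come from the config and an automatic
valley-finding mode is available as an opt-in convenience.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import argrelextrema
from scipy.stats import gaussian_kde

from .errors import ConfigurationError

MARKERS = ("CD4", "CD8", "CD69")

#: default cutoffs on the log1p scale (~raw count 9), between a background
#: mode around a handful of counts and a positive mode in the tens-hundreds
DEFAULT_THRESHOLDS: dict[str, float] = {"CD4": 2.3, "CD8": 2.3, "CD69": 2.3}


@dataclass(frozen=True)
class GateConfig:
    """Thresholds (log1p scale) and mode for CITE gating."""

    thresholds: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS)
    )
    mode: str = "fixed"  # "fixed" | "auto-valley"
    split_blood_cd69: bool = False

    def validate(self) -> None:
        if self.mode not in ("fixed", "auto-valley"):
            raise ConfigurationError(f"gate mode {self.mode!r} is not recognized")
        for marker in MARKERS:
            if marker not in self.thresholds:
                raise ConfigurationError(f"thresholds: missing marker '{marker}'")
            t = self.thresholds[marker]
            if not np.isfinite(t) or t < 0:
                raise ConfigurationError(
                    f"thresholds[{marker}]: must be finite and >= 0, got {t!r}"
                )


@dataclass(frozen=True)
class CompartmentLabel:
    """Stratification of one cell: donor, lineage, tissue, surface CD69."""

    donor: str
    lineage: str  # "CD4" | "CD8"
    tissue: str  # "blood" | "BM"
    cd69_surface: str  # "pos" | "neg" | "na" (blood, unsplit)
    cluster: int | None = None

    @property
    def compartment(self) -> str:
        return subset_name(self.tissue, self.cd69_surface)


def subset_name(tissue: str, cd69_surface: str) -> str:
    """Canonical compartment name: Blood, BM_CD69pos or BM_CD69neg."""
    if tissue == "blood":
        return "Blood" if cd69_surface == "na" else f"Blood_CD69{cd69_surface}"
    return f"BM_CD69{cd69_surface}"


@dataclass(frozen=True)
class AutoThreshold:
    value: float
    fallback_used: bool


def _merged_modes(
    grid: np.ndarray, density: np.ndarray, min_separation: float
) -> list[int]:
    """Local density maxima, pruned of comb artifacts.

    Raw antibody counts are integers, so at the low end the KDE shows one
    spike per count value; maxima closer than ``min_separation`` (log1p
    units) are merged into the highest of their run, and maxima with
    negligible density are dropped.
    """
    maxima = argrelextrema(density, np.greater)[0]
    if density[0] > density[1]:  # a boundary mode at zero counts
        maxima = np.concatenate([[0], maxima])
    maxima = [int(m) for m in maxima if density[m] >= 0.02 * density.max()]
    merged: list[int] = []
    for m in maxima:
        if merged and grid[m] - grid[merged[-1]] < min_separation:
            if density[m] > density[merged[-1]]:
                merged[-1] = m
        else:
            merged.append(m)
    return merged


def auto_thresholds(
    cite: pd.DataFrame,
    fallbacks: Mapping[str, float] | None = None,
    min_cells: int = 100,
    grid_size: int = 512,
    min_mode_separation: float = 1.0,
    max_valley_ratio: float = 0.7,
) -> dict[str, AutoThreshold]:
    """Per-marker cutoff at the density valley between the two largest modes.

    A Gaussian KDE of the log1p counts is evaluated on a grid; the cutoff is
    the density minimum between the two highest well-separated local maxima,
    accepted only if that valley dips below ``max_valley_ratio`` times the
    smaller mode (a genuine bimodal split).  Unimodal marker distributions
    fall back to the configured default and are flagged.  Requires at least
    ``min_cells`` cells.
    """
    if len(cite) < min_cells:
        raise ValueError(f"auto_thresholds needs >= {min_cells} cells, got {len(cite)}")
    fallbacks = dict(DEFAULT_THRESHOLDS) | dict(fallbacks or {})
    out: dict[str, AutoThreshold] = {}
    for marker in MARKERS:
        x = np.log1p(cite[marker].to_numpy(dtype=float))
        grid = np.linspace(0.0, x.max() + 0.5, grid_size)
        density = gaussian_kde(x)(grid)
        modes = _merged_modes(grid, density, min_mode_separation)
        if len(modes) < 2:
            out[marker] = AutoThreshold(float(fallbacks[marker]), True)
            continue
        lo, hi = sorted(sorted(modes, key=lambda m: density[m])[-2:])
        valley = lo + int(np.argmin(density[lo : hi + 1]))
        if density[valley] > max_valley_ratio * min(density[lo], density[hi]):
            out[marker] = AutoThreshold(float(fallbacks[marker]), True)
            continue
        out[marker] = AutoThreshold(float(grid[valley]), False)
    return out


def gate_cells(
    cite: pd.DataFrame,
    tissue: Mapping[str, str] | pd.Series,
    config: GateConfig | None = None,
    donor: Mapping[str, str] | pd.Series | None = None,
) -> pd.DataFrame:
    """Assign each barcode a subset label or a rejection reason.

    ``cite`` is a barcode-indexed count table with CD4/CD8/CD69 columns;
    ``tissue`` maps barcode -> "blood"/"BM".  In "auto-valley" mode the
    thresholds are recomputed from the data with the configured values as
    fallback.  Returns a barcode-indexed frame with columns lineage, tissue,
    cd69_surface, compartment and reject_reason (empty string when gated).
    Every input barcode receives exactly one label or one reason.
    """
    config = config or GateConfig()
    config.validate()
    thresholds = dict(config.thresholds)
    if config.mode == "auto-valley":
        auto = auto_thresholds(cite, fallbacks=thresholds)
        thresholds = {m: a.value for m, a in auto.items()}

    tissue = pd.Series(tissue) if not isinstance(tissue, pd.Series) else tissue
    log_counts = np.log1p(cite[list(MARKERS)].astype(float))
    cd4_pos = log_counts["CD4"] > thresholds["CD4"]
    cd8_pos = log_counts["CD8"] > thresholds["CD8"]
    cd69_pos = log_counts["CD69"] > thresholds["CD69"]

    rows = []
    for barcode in cite.index:
        cell_tissue = tissue.get(barcode)
        if cell_tissue not in ("blood", "BM"):
            rows.append((barcode, "", "", "", "", "unknown tissue"))
            continue
        is4, is8 = bool(cd4_pos[barcode]), bool(cd8_pos[barcode])
        if is4 and is8:
            rows.append((barcode, "", cell_tissue, "", "", "CD4/CD8 double-positive"))
            continue
        if not is4 and not is8:
            rows.append((barcode, "", cell_tissue, "", "", "CD4/CD8 double-negative"))
            continue
        lineage = "CD4" if is4 else "CD8"
        if cell_tissue == "BM" or config.split_blood_cd69:
            cd69 = "pos" if bool(cd69_pos[barcode]) else "neg"
        else:
            cd69 = "na"
        rows.append(
            (barcode, lineage, cell_tissue, cd69, subset_name(cell_tissue, cd69), "")
        )
    labels = pd.DataFrame(
        rows,
        columns=["barcode", "lineage", "tissue", "cd69_surface", "compartment",
                 "reject_reason"],
    ).set_index("barcode")
    if donor is not None:
        donor = pd.Series(donor) if not isinstance(donor, pd.Series) else donor
        labels["donor"] = labels.index.map(donor)
    return labels
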