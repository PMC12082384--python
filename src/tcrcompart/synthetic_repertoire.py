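"""Synthetic multi-donor paired blood / bone-marrow TCR + CITE datasets.

The generator emulates the structure of a paired-tissue single-cell immune
profiling experiment: for each donor and lineage (CD4 / CD8) it builds, per
transcriptional cluster, clonotype pools for the three compartments (blood,
bone-marrow surface-CD69+, bone-marrow surface-CD69-) with a tunable
fraction of the pool shared between compartments.  Cells are then sampled
i.i.d. from a fixed, skewed clone-frequency vector (geometric or power-law
over clone ranks), so under full sharing the compartment labels of cells
are exactly exchangeable — the regime in which the label-shuffling overlap
test must be calibrated.  Outputs are written in the same dialects the
ingest module reads: a 10x-style contig annotation CSV (one productive TRA
and TRB row per cell), a barcode x marker CITE count CSV with bimodal
negative-binomial mixtures for CD4/CD8/CD69, and a per-barcode metadata
table.  Every assignment is recorded in a GroundTruth object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .gating import subset_name
from .ingest import make_clonotype_key

_AA = "ACDEFGHIKLMNPQRSTVWY"
#: one codon per residue, for plausible cdr3_nt strings
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "AGC", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

CONTIG_COLUMNS = [
    "barcode", "is_cell", "contig_id", "high_confidence", "length", "chain",
    "v_gene", "d_gene", "j_gene", "c_gene", "full_length", "productive",
    "cdr3", "cdr3_nt", "reads", "umis", "raw_clonotype_id",
]


@dataclass(frozen=True)
class CiteMarkerParams:
    """Two-component negative-binomial mixture for one marker's raw counts."""

    neg_mean: float = 1.0
    pos_mean: float = 60.0
    dispersion: float = 8.0  # NB size parameter; larger -> tighter modes


@dataclass(frozen=True)
class CompartmentSpec:
    tissue: str  # "blood" | "BM"
    cd69: str  # "pos" | "neg"  (surface status; blood compartments are neg)
    n_cells: int = 1000

    @property
    def name(self) -> str:
        # blood memory T cells are the surface-CD69-negative reference and
        # are not CD69-split, so the compartment is simply "Blood"
        return "Blood" if self.tissue == "blood" else subset_name(self.tissue, self.cd69)


@dataclass(frozen=True)
class ClusterSpec:
    """A transcriptional cluster and its frequency weight per compartment."""

    cluster_id: int
    weights: Mapping[str, float] | float = 1.0

    def weight_for(self, compartment: str) -> float:
        if isinstance(self.weights, Mapping):
            return float(self.weights.get(compartment, 0.0))
        return float(self.weights)


@dataclass(frozen=True)
class CloneSizeLaw:
    """Clone-frequency law over clone ranks 1..K.

    "geometric": freq(rank) proportional to (1-param)^(rank-1), param in (0,1).
    "power": freq(rank) proportional to rank^(-param), param > 0.
    """

    name: str = "geometric"
    param: float = 0.10

    def rank_probabilities(self, k: int) -> np.ndarray:
        ranks = np.arange(1, k + 1, dtype=float)
        if self.name == "geometric":
            if not 0.0 < self.param < 1.0:
                raise ConfigurationError(
                    f"clone_size_law.param: geometric p must be in (0,1), got {self.param}"
                )
            w = (1.0 - self.param) ** (ranks - 1.0)
        elif self.name == "power":
            if self.param <= 0:
                raise ConfigurationError(
                    f"clone_size_law.param: power-law exponent must be > 0, got {self.param}"
                )
            w = ranks ** (-self.param)
        else:
            raise ConfigurationError(
                f"clone_size_law.name: unknown law {self.name!r}"
            )
        return w / w.sum()


def default_compartments(n_cells: int = 1000) -> tuple[CompartmentSpec, ...]:
    return (
        CompartmentSpec("blood", "neg", n_cells),
        CompartmentSpec("BM", "neg", n_cells),
        CompartmentSpec("BM", "pos", n_cells),
    )


def default_clusters(n_clusters: int = 10) -> tuple[ClusterSpec, ...]:
    """Skewed cluster composition differing between compartments.

    Blood and non-resident bone-marrow cells decay geometrically from
    cluster 0; the surface-CD69+ bone-marrow compartment is tilted toward
    cluster 2 (the predominant resident cluster in this kind of data).
    """
    base = 0.75 ** np.arange(n_clusters)
    tilted = base.copy()
    if n_clusters > 2:
        tilted[2] = base.max() * 2.0
    clusters = []
    for k in range(n_clusters):
        clusters.append(
            ClusterSpec(
                cluster_id=k,
                weights={
                    "Blood": base[k] / base.sum(),
                    "BM_CD69neg": base[k] / base.sum(),
                    "BM_CD69pos": tilted[k] / tilted.sum(),
                },
            )
        )
    return tuple(clusters)


def default_cite_params() -> dict[str, CiteMarkerParams]:
    return {
        "CD4": CiteMarkerParams(),
        "CD8": CiteMarkerParams(),
        "CD69": CiteMarkerParams(),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Everything the generator needs; fully reproducible from ``seed``."""

    n_donors: int = 3
    lineages: tuple[str, ...] = ("CD4", "CD8")
    compartments: tuple[CompartmentSpec, ...] = field(
        default_factory=default_compartments
    )
    clusters: tuple[ClusterSpec, ...] = field(default_factory=default_clusters)
    clone_size_law: CloneSizeLaw = field(default_factory=CloneSizeLaw)
    n_clonotypes_per_pool: int = 100
    #: fraction of each cluster's clonotype pool common to all compartments;
    #: a scalar, or a mapping cluster id -> fraction
    sharing_fraction: float | Mapping[int, float] = 0.2
    cite_params: Mapping[str, CiteMarkerParams] = field(
        default_factory=default_cite_params
    )
    second_alpha_rate: float = 0.0
    nonproductive_rate: float = 0.0
    seed: int = 0

    def sharing_for(self, cluster_id: int) -> float:
        if isinstance(self.sharing_fraction, Mapping):
            return float(self.sharing_fraction.get(cluster_id, 0.0))
        return float(self.sharing_fraction)

    def validate(self) -> None:
        if self.n_donors < 1:
            raise ConfigurationError(f"n_donors: must be >= 1, got {self.n_donors}")
        if self.n_clonotypes_per_pool < 1:
            raise ConfigurationError(
                f"n_clonotypes_per_pool: must be >= 1, got {self.n_clonotypes_per_pool}"
            )
        if not self.compartments:
            raise ConfigurationError("compartments: at least one is required")
        names = [c.name for c in self.compartments]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"compartments: duplicate names in {names}")
        for comp in self.compartments:
            if comp.tissue not in ("blood", "BM"):
                raise ConfigurationError(
                    f"compartments.tissue: must be 'blood' or 'BM', got {comp.tissue!r}"
                )
            if comp.cd69 not in ("pos", "neg"):
                raise ConfigurationError(
                    f"compartments.cd69: must be 'pos' or 'neg', got {comp.cd69!r}"
                )
            if comp.n_cells < 1:
                raise ConfigurationError(
                    f"compartments.n_cells: must be >= 1, got {comp.n_cells}"
                )
        if not self.clusters:
            raise ConfigurationError("clusters: at least one is required")
        for comp in self.compartments:
            total = sum(c.weight_for(comp.name) for c in self.clusters)
            if total <= 0:
                raise ConfigurationError(
                    f"clusters: weights for compartment '{comp.name}' sum to 0"
                )
            if any(c.weight_for(comp.name) < 0 for c in self.clusters):
                raise ConfigurationError(
                    f"clusters: negative weight for compartment '{comp.name}'"
                )
        for c in self.clusters:
            s = self.sharing_for(c.cluster_id)
            if not 0.0 <= s <= 1.0:
                raise ConfigurationError(
                    f"sharing_fraction[{c.cluster_id}]: must be in [0,1], got {s}"
                )
        for rate_name in ("second_alpha_rate", "nonproductive_rate"):
            rate = getattr(self, rate_name)
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(
                    f"{rate_name}: must be in [0,1], got {rate}"
                )
        for marker in ("CD4", "CD8", "CD69"):
            if marker not in self.cite_params:
                raise ConfigurationError(f"cite_params: missing marker '{marker}'")
            p = self.cite_params[marker]
            if p.neg_mean <= 0 or p.pos_mean <= 0 or p.dispersion <= 0:
                raise ConfigurationError(
                    f"cite_params[{marker}]: means and dispersion must be > 0"
                )
        # the clone law validates its own parameters
        self.clone_size_law.rank_probabilities(2)


@dataclass
class GroundTruth:
    """Every assignment the generator made.

    ``cells``: one row per cell (barcode, donor, lineage, tissue, cd69,
    compartment, cluster, clonotype_key, alpha/beta CDR3).
    ``pools``: (donor, lineage, cluster) -> compartment -> frozenset of keys.
    ``clone_probabilities``: (donor, lineage, cluster) -> compartment ->
    key -> sampling probability (the fixed clone-frequency vector).
    ``cluster_counts``: (donor, lineage, compartment) -> per-cluster cell
    counts from the multinomial draw.
    """

    cells: pd.DataFrame
    pools: dict[tuple[str, str, int], dict[str, frozenset[str]]]
    clone_probabilities: dict[tuple[str, str, int], dict[str, dict[str, float]]]
    cluster_counts: dict[tuple[str, str, str], dict[int, int]]
    config: SimulationConfig


@dataclass
class SyntheticDataset:
    contigs: pd.DataFrame
    cite: pd.DataFrame
    metadata: pd.DataFrame
    truth: GroundTruth


def _random_cdr3(rng: np.random.Generator, prefix: str, taken: set[str]) -> str:
    """A fresh CDR3-aa string: C...F with 6-12 random inner residues."""
    while True:
        inner = "".join(
            _AA[i] for i in rng.integers(0, len(_AA), size=int(rng.integers(6, 13)))
        )
        cdr3 = f"{prefix}{inner}F"
        if cdr3 not in taken:
            taken.add(cdr3)
            return cdr3


def _random_barcode(rng: np.random.Generator, taken: set[str]) -> str:
    while True:
        bc = "".join("ACGT"[i] for i in rng.integers(0, 4, size=16)) + "-1"
        if bc not in taken:
            taken.add(bc)
            return bc


def _nt_for(aa: str) -> str:
    return "".join(_CODON.get(res, "NNN") for res in aa)


def _nb_counts(
    rng: np.random.Generator, mean: float, dispersion: float, size: int
) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Sample a complete paired-tissue TCR + CITE dataset.

    Per (donor, lineage, cluster) a master clone-frequency vector over clone
    ranks 1..K is drawn from the configured law; a shared subset of rank
    slots (``sharing_fraction`` of K, same slots in every compartment)
    carries common clonotypes, the remaining slots carry compartment-private
    ones.  Shared clones therefore occupy the same frequency rank in every
    compartment, and with full sharing the compartment pools and frequency
    vectors are identical, making cell labels exchangeable.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    k = config.n_clonotypes_per_pool
    comp_names = [c.name for c in config.compartments]

    taken_alpha: set[str] = set()
    taken_beta: set[str] = set()
    taken_barcodes: set[str] = set()

    pools: dict[tuple[str, str, int], dict[str, frozenset[str]]] = {}
    clone_probabilities: dict[tuple[str, str, int], dict[str, dict[str, float]]] = {}
    cluster_counts: dict[tuple[str, str, str], dict[int, int]] = {}
    cell_rows: list[dict] = []

    for donor_index in range(config.n_donors):
        donor = f"donor{donor_index + 1}"
        for lineage in config.lineages:
            # clonotype pools per cluster
            per_cluster_pool: dict[int, dict[str, list[str]]] = {}
            per_cluster_probs: dict[int, np.ndarray] = {}
            for cluster in config.clusters:
                cid = cluster.cluster_id
                probs = config.clone_size_law.rank_probabilities(k)
                # random rank slots carry the shared clonotypes
                n_shared = int(round(config.sharing_for(cid) * k))
                slots = rng.permutation(k)
                shared_slots = set(slots[:n_shared].tolist())
                shared_keys = {
                    slot: make_clonotype_key(
                        _random_cdr3(rng, "CA", taken_alpha),
                        _random_cdr3(rng, "CASS", taken_beta),
                    )
                    for slot in sorted(shared_slots)
                }
                comp_pools: dict[str, list[str]] = {}
                for name in comp_names:
                    keys = []
                    for slot in range(k):
                        if slot in shared_slots:
                            keys.append(shared_keys[slot])
                        else:
                            keys.append(
                                make_clonotype_key(
                                    _random_cdr3(rng, "CA", taken_alpha),
                                    _random_cdr3(rng, "CASS", taken_beta),
                                )
                            )
                    comp_pools[name] = keys
                per_cluster_pool[cid] = comp_pools
                per_cluster_probs[cid] = probs
                pools[(donor, lineage, cid)] = {
                    name: frozenset(keys) for name, keys in comp_pools.items()
                }
                clone_probabilities[(donor, lineage, cid)] = {
                    name: {key: float(probs[slot]) for slot, key in enumerate(keys)}
                    for name, keys in comp_pools.items()
                }

            # cells per compartment: multinomial cluster draw, then i.i.d.
            # clonotype sampling from the cluster's frequency vector
            for comp in config.compartments:
                weights = np.array(
                    [c.weight_for(comp.name) for c in config.clusters], dtype=float
                )
                weights = weights / weights.sum()
                draw = rng.multinomial(comp.n_cells, weights)
                cluster_counts[(donor, lineage, comp.name)] = {
                    c.cluster_id: int(n) for c, n in zip(config.clusters, draw)
                }
                for cluster, n_cluster_cells in zip(config.clusters, draw):
                    if n_cluster_cells == 0:
                        continue
                    cid = cluster.cluster_id
                    slots = rng.choice(
                        k, size=int(n_cluster_cells), p=per_cluster_probs[cid]
                    )
                    for slot in slots:
                        key = per_cluster_pool[cid][comp.name][int(slot)]
                        alpha = key.split("|")[0][len("TRA:") :]
                        beta = key.split("|")[1][len("TRB:") :]
                        cell_rows.append(
                            {
                                "barcode": _random_barcode(rng, taken_barcodes),
                                "donor": donor,
                                "lineage": lineage,
                                "tissue": comp.tissue,
                                "cd69": comp.cd69,
                                "compartment": comp.name,
                                "cluster": cid,
                                "clonotype_key": key,
                                "alpha_cdr3_aa": alpha,
                                "beta_cdr3_aa": beta,
                            }
                        )

    cells = pd.DataFrame(cell_rows)
    contigs = _build_contigs(cells, config, rng)
    cite = _build_cite(cells, config, rng)
    metadata = cells[["barcode", "donor", "tissue", "cluster"]].copy()
    truth = GroundTruth(
        cells=cells,
        pools=pools,
        clone_probabilities=clone_probabilities,
        cluster_counts=cluster_counts,
        config=config,
    )
    return SyntheticDataset(contigs=contigs, cite=cite, metadata=metadata, truth=truth)


def _contig_row(
    barcode: str, n: int, chain: str, cdr3: str, umis: int, productive: bool
) -> dict:
    v = f"{chain}V12-1"
    return {
        "barcode": barcode,
        "is_cell": "True",
        "contig_id": f"{barcode}_contig_{n}",
        "high_confidence": "True",
        "length": 450 + len(cdr3) * 3,
        "chain": chain,
        "v_gene": v,
        "d_gene": f"{chain}D1" if chain == "TRB" else "None",
        "j_gene": f"{chain}J2-3",
        "c_gene": f"{chain}C",
        "full_length": "True",
        "productive": "True" if productive else "False",
        "cdr3": cdr3,
        "cdr3_nt": _nt_for(cdr3),
        "reads": umis * 25,
        "umis": umis,
        "raw_clonotype_id": "None",
    }


def _build_contigs(
    cells: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    rows: list[dict] = []
    for cell in cells.itertuples(index=False):
        umi_a = int(rng.poisson(5)) + 2
        umi_b = int(rng.poisson(8)) + 2
        n = 1
        rows.append(_contig_row(cell.barcode, n, "TRA", cell.alpha_cdr3_aa, umi_a, True))
        n += 1
        rows.append(_contig_row(cell.barcode, n, "TRB", cell.beta_cdr3_aa, umi_b, True))
        if config.second_alpha_rate and rng.random() < config.second_alpha_rate:
            n += 1
            # a genuine secondary alpha chain with strictly fewer UMIs, so
            # the highest-UMI resolution rule keeps the primary chain
            taken: set[str] = {cell.alpha_cdr3_aa}
            secondary = _random_cdr3(rng, "CA", taken)
            rows.append(
                _contig_row(
                    cell.barcode, n, "TRA", secondary, int(rng.integers(1, umi_a)), True
                )
            )
        if config.nonproductive_rate and rng.random() < config.nonproductive_rate:
            n += 1
            chain = "TRA" if rng.random() < 0.5 else "TRB"
            rows.append(
                _contig_row(cell.barcode, n, chain, "CX*F", 1, False)
            )
    return pd.DataFrame(rows, columns=CONTIG_COLUMNS)


def _build_cite(
    cells: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    n = len(cells)
    counts = {}
    positive = {
        "CD4": (cells["lineage"] == "CD4").to_numpy(),
        "CD8": (cells["lineage"] == "CD8").to_numpy(),
        "CD69": ((cells["tissue"] == "BM") & (cells["cd69"] == "pos")).to_numpy(),
    }
    for marker in ("CD4", "CD8", "CD69"):
        params = config.cite_params[marker]
        neg = _nb_counts(rng, params.neg_mean, params.dispersion, n)
        pos = _nb_counts(rng, params.pos_mean, params.dispersion, n)
        counts[marker] = np.where(positive[marker], pos, neg)
    return pd.DataFrame(counts, index=pd.Index(cells["barcode"], name="barcode"))


def inject_incomplete_cells(
    contigs: pd.DataFrame, fraction: float, seed: int
) -> pd.DataFrame:
    """Delete one chain's contig rows for a fraction of cells.

    Exactly ``round(fraction * n_barcodes)`` barcodes (sampled without
    replacement) lose all rows of one randomly chosen locus, so downstream
    clonotype calling must exclude them.  ``fraction=0`` returns the table
    unchanged.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ConfigurationError(f"fraction: must be in [0,1], got {fraction}")
    if fraction == 0.0:
        return contigs.copy()
    rng = np.random.default_rng(seed)
    barcodes = contigs["barcode"].unique()
    n_hit = int(round(fraction * barcodes.size))
    hit = rng.choice(barcodes, size=n_hit, replace=False)
    drop_chain = pd.Series(
        np.where(rng.random(n_hit) < 0.5, "TRA", "TRB"), index=hit
    )
    mask = contigs["barcode"].map(drop_chain) == contigs["chain"]
    return contigs.loc[~mask].reset_index(drop=True)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the three input files in the dialects the ingest module reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "contigs": outdir / "filtered_contig_annotations.csv",
        "cite": outdir / "cite_counts.csv",
        "metadata": outdir / "cell_metadata.tsv",
    }
    dataset.contigs.to_csv(paths["contigs"], index=False)
    dataset.cite.to_csv(paths["cite"])
    dataset.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    return paths


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a per-barcode metadata table (barcode, donor, tissue, cluster)."""
    from .errors import FormatError

    table = pd.read_csv(path, sep="\t")
    for column in ("barcode", "donor", "tissue", "cluster"):
        if column not in table.columns:
            raise FormatError(f"metadata table {path} is missing column '{column}'")
    return table
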