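"""Generator: reproducibility, ground-truth bookkeeping, sharing structure,
clone-size law, and the incomplete-cell injector."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tcrcompart.errors import ConfigurationError
from tcrcompart.ingest import call_clonotypes, read_contigs
from tcrcompart.synthetic_repertoire import (
    CloneSizeLaw,
    ClusterSpec,
    CompartmentSpec,
    SimulationConfig,
    default_clusters,
    default_compartments,
    generate_dataset,
    inject_incomplete_cells,
    write_dataset,
)


def _tiny_config(**overrides):
    defaults = dict(
        n_donors=1,
        lineages=("CD4",),
        compartments=(
            CompartmentSpec("blood", "neg", 120),
            CompartmentSpec("BM", "neg", 120),
        ),
        clusters=(ClusterSpec(0, 1.0),),
        n_clonotypes_per_pool=40,
        sharing_fraction=0.5,
        seed=7,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def test_identical_config_and_seed_give_byte_identical_files(tmp_path):
    config = _tiny_config()
    paths1 = write_dataset(generate_dataset(config), tmp_path / "a")
    paths2 = write_dataset(generate_dataset(config), tmp_path / "b")
    for name in paths1:
        assert paths1[name].read_bytes() == paths2[name].read_bytes()


def test_different_seed_changes_output():
    cells1 = generate_dataset(_tiny_config(seed=1)).truth.cells
    cells2 = generate_dataset(_tiny_config(seed=2)).truth.cells
    assert not cells1["barcode"].equals(cells2["barcode"])


def test_compartment_cell_counts_match_config(small_dataset, small_config):
    cells = small_dataset.truth.cells
    for comp in small_config.compartments:
        for donor in cells["donor"].unique():
            for lineage in small_config.lineages:
                mask = (
                    (cells["compartment"] == comp.name)
                    & (cells["donor"] == donor)
                    & (cells["lineage"] == lineage)
                )
                assert mask.sum() == comp.n_cells
                assert cells.loc[mask, "barcode"].nunique() == comp.n_cells


def test_cluster_marginals_match_recorded_multinomial_draw(small_dataset):
    truth = small_dataset.truth
    cells = truth.cells
    for (donor, lineage, comp), expected in truth.cluster_counts.items():
        observed = (
            cells[
                (cells["donor"] == donor)
                & (cells["lineage"] == lineage)
                & (cells["compartment"] == comp)
            ]["cluster"]
            .value_counts()
            .to_dict()
        )
        assert {k: v for k, v in expected.items() if v > 0} == observed


@pytest.mark.parametrize("sharing,expect", [(0.0, "disjoint"), (1.0, "identical")])
def test_sharing_fraction_extremes_control_pool_structure(sharing, expect):
    truth = generate_dataset(_tiny_config(sharing_fraction=sharing)).truth
    for pools in truth.pools.values():
        blood, bm = pools["Blood"], pools["BM_CD69neg"]
        if expect == "disjoint":
            assert not blood & bm
        else:
            assert blood == bm


def test_every_cell_clonotype_comes_from_its_compartment_pool(small_dataset):
    truth = small_dataset.truth
    for cell in truth.cells.itertuples(index=False):
        pool = truth.pools[(cell.donor, cell.lineage, cell.cluster)][cell.compartment]
        assert cell.clonotype_key in pool


def test_clone_size_frequencies_follow_the_configured_law():
    """Pooled over replicates, per-rank cell counts match the geometric
    clone-frequency law (chi-square goodness of fit at 0.01)."""
    law = CloneSizeLaw("geometric", 0.10)
    k, n_cells = 30, 4000
    counts = np.zeros(k)
    expected_probs = law.rank_probabilities(k)
    for seed in range(5):
        config = _tiny_config(
            n_donors=1,
            compartments=(CompartmentSpec("blood", "neg", n_cells),),
            n_clonotypes_per_pool=k,
            sharing_fraction=1.0,
            clone_size_law=law,
            seed=100 + seed,
        )
        truth = generate_dataset(config).truth
        probs = truth.clone_probabilities[("donor1", "CD4", 0)]["Blood"]
        sizes = truth.cells["clonotype_key"].value_counts()
        # align clonotypes by their ground-truth frequency rank
        by_rank = sorted(probs, key=probs.get, reverse=True)
        counts += sizes.reindex(by_rank).fillna(0.0).to_numpy()
    chi2 = stats.chisquare(counts, f_exp=expected_probs * counts.sum())
    assert chi2.pvalue > 0.01


def test_power_law_probabilities_are_zipf_shaped():
    probs = CloneSizeLaw("power", 1.5).rank_probabilities(10)
    ranks = np.arange(1, 11)
    np.testing.assert_allclose(probs / probs[0], ranks**-1.5, rtol=1e-12)


def test_cite_counts_are_bimodal_by_design(small_dataset):
    cite = small_dataset.cite
    cells = small_dataset.truth.cells.set_index("barcode")
    cd4_cells = cite.loc[cells[cells["lineage"] == "CD4"].index]
    cd8_cells = cite.loc[cells[cells["lineage"] == "CD8"].index]
    assert cd4_cells["CD4"].median() > 10 * max(1, cd8_cells["CD4"].median())
    assert cd8_cells["CD8"].median() > 10 * max(1, cd4_cells["CD8"].median())
    cd69pos = cells[(cells["tissue"] == "BM") & (cells["cd69"] == "pos")].index
    cd69neg = cells[cells["cd69"] == "neg"].index
    assert cite.loc[cd69pos, "CD69"].median() > 10 * max(
        1, cite.loc[cd69neg, "CD69"].median()
    )


@pytest.mark.parametrize(
    "overrides,field",
    [
        (dict(n_donors=0), "n_donors"),
        (dict(sharing_fraction=1.5), "sharing_fraction"),
        (dict(n_clonotypes_per_pool=0), "n_clonotypes_per_pool"),
        (dict(clone_size_law=CloneSizeLaw("geometric", 1.5)), "clone_size_law"),
        (dict(clusters=(ClusterSpec(0, 0.0),)), "clusters"),
        (dict(second_alpha_rate=-0.1), "second_alpha_rate"),
    ],
)
def test_invalid_configuration_errors_name_the_field(overrides, field):
    with pytest.raises(ConfigurationError, match=field):
        _tiny_config(**overrides).validate()


class TestInjectIncompleteCells:
    def test_fraction_zero_is_identity(self, small_dataset):
        out = inject_incomplete_cells(small_dataset.contigs, 0.0, seed=0)
        pd.testing.assert_frame_equal(out, small_dataset.contigs)

    def test_fraction_one_leaves_every_cell_single_chain(self):
        contigs = generate_dataset(_tiny_config()).contigs
        out = inject_incomplete_cells(contigs, 1.0, seed=0)
        per_cell_loci = out.groupby("barcode")["chain"].nunique()
        assert (per_cell_loci == 1).all()
        assert call_clonotypes_count(out) == 0

    def test_exact_fraction_of_cells_become_single_chain(self):
        config = _tiny_config(
            compartments=(CompartmentSpec("blood", "neg", 100),),
            n_donors=1,
        )
        contigs = generate_dataset(config).contigs
        out = inject_incomplete_cells(contigs, 0.2, seed=3)
        single = (out.groupby("barcode")["chain"].nunique() == 1).sum()
        assert single == 20


def call_clonotypes_count(contigs: pd.DataFrame) -> int:
    from tcrcompart.ingest import ContigRecord

    records = [
        ContigRecord(
            barcode=r.barcode,
            chain=r.chain,
            cdr3_aa=r.cdr3,
            cdr3_nt=r.cdr3_nt,
            productive=r.productive == "True",
            umis=int(r.umis),
        )
        for r in contigs.itertuples(index=False)
    ]
    return len(call_clonotypes(records))


def test_noise_rows_do_not_change_resolved_clonotypes(tmp_path):
    clean = _tiny_config(seed=11)
    noisy = _tiny_config(seed=11, second_alpha_rate=0.3, nonproductive_rate=0.2)
    ds = generate_dataset(noisy)
    paths = write_dataset(ds, tmp_path)
    cells = call_clonotypes(read_contigs(paths["contigs"]))
    resolved = {c.barcode: c.clonotype_key for c in cells}
    truth = ds.truth.cells.set_index("barcode")["clonotype_key"].to_dict()
    assert resolved == truth
    # and the noisy table really contains extra rows
    assert len(ds.contigs) > 2 * len(ds.truth.cells)
    assert len(generate_dataset(clean).contigs) == 2 * len(ds.truth.cells)
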