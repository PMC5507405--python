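"""Signed-network derivation from perturbation fold-change tables."""

import numpy as np
import pytest

from dermapattern.network import (
    FoldChangeRecord,
    InvalidGroupingError,
    InvalidRecordError,
    SignedInteractionMatrix,
    SpeciesGrouping,
    collapse_to_species,
    default_grouping,
    default_matrix,
    derive_gene_network,
    ttest_fold_changes,
    validate_self_inhibition,
)
from dermapattern.synthetic import gen_foldchange_table
from dermapattern.network import records_from_frame


def rec(gene, pathway, direction, fc, p):
    return FoldChangeRecord(gene, pathway, direction, fc, p)


@pytest.mark.parametrize(
    "record, expect_edge",
    [
        (("geneA", "WNT", "stimulated", 2.5, 0.01), ("WNT", "geneA", +1)),
        (("geneB", "BMP", "stimulated", 1.5, 0.01), None),  # below 1.8-fold
        (("geneC", "FGF", "stimulated", 0.3, 0.20), None),  # p >= alpha
        (("geneD", "FGF", "stimulated", 0.3, 0.01), ("FGF", "geneD", -1)),
        # inhibited condition: downregulation implies positive regulation
        (("geneE", "WNT", "inhibited", 0.4, 0.01), ("WNT", "geneE", +1)),
        # exact threshold is inclusive (>= 1.8)
        (("geneF", "BMP", "stimulated", 1.8, 0.049), ("BMP", "geneF", +1)),
    ],
)
def test_threshold_rule(record, expect_edge):
    net = derive_gene_network([rec(*record)], fc_threshold=1.8, alpha=0.05)
    if expect_edge is None:
        assert net.edges == {}
    else:
        pathway, gene, sign = expect_edge
        assert net.edges == {(pathway, gene): sign}


def test_conflicting_conditions_drop_edge_with_warning():
    records = [
        rec("g", "WNT", "stimulated", 2.5, 0.01),
        rec("g", "WNT", "inhibited", 2.5, 0.01),  # implies the opposite call
    ]
    with pytest.warns(UserWarning, match="conflicting"):
        net = derive_gene_network(records)
    assert net.edges == {}
    assert ("WNT", "g") in net.conflicts


def test_invalid_inputs_raise():
    with pytest.raises(InvalidRecordError):
        FoldChangeRecord("g", "WNT", "stimulated", -1.0, 0.01)
    with pytest.raises(InvalidRecordError):
        FoldChangeRecord("g", "WNT", "stimulated", 2.0, 1.5)
    with pytest.raises(InvalidRecordError):
        derive_gene_network([rec("g", "HEDGEHOG", "stimulated", 2.0, 0.01)])
    with pytest.raises(InvalidRecordError):
        derive_gene_network([])


def test_monotonicity_in_thresholds():
    rng = np.random.default_rng(0)
    records = [
        rec(f"g{i}", "WNT", "stimulated", float(np.exp(rng.normal(0, 1))), float(rng.uniform(0, 0.2)))
        for i in range(100)
    ]
    base = set(derive_gene_network(records, 1.8, 0.05).edges)
    stricter_fc = set(derive_gene_network(records, 2.5, 0.05).edges)
    stricter_alpha = set(derive_gene_network(records, 1.8, 0.01).edges)
    assert stricter_fc <= base
    assert stricter_alpha <= base


def test_stimulated_inhibited_symmetry_on_noiseless_data(default_matrix):
    """On noiseless tables the stimulated-only edge set equals the
    sign-flipped inhibited-only set."""
    table, _ = gen_foldchange_table(default_matrix, noise_sd=0.0, seed=0)
    recs = records_from_frame(table)
    stim = derive_gene_network(
        [r for r in recs if r.direction == "stimulated"], pathways=default_matrix.species
    )
    inhib = derive_gene_network(
        [r for r in recs if r.direction == "inhibited"], pathways=default_matrix.species
    )
    assert stim.edges == inhib.edges  # implied signs already account for direction


def test_collapse_consensus_and_provenance():
    net = derive_gene_network(
        [
            rec("Dkk4", "WNT", "stimulated", 2.5, 0.01),
            rec("Dkk1", "WNT", "stimulated", 2.2, 0.02),
            rec("Nog", "BMP", "stimulated", 3.0, 0.001),
        ]
    )
    M = collapse_to_species(net, default_grouping())
    assert M[M.index("WNT_inhibitor"), M.index("WNT")] == 1
    assert M[M.index("BMP_inhibitor"), M.index("BMP")] == 1
    assert "Dkk4:+1" in M.provenance[("WNT_inhibitor", "WNT")]
    # untouched cells stay zero
    assert M[M.index("FGF"), M.index("FGF")] == 0


def test_collapse_empty_network_gives_zero_matrix():
    net = derive_gene_network([rec("g", "WNT", "stimulated", 1.0, 0.9)])
    M = collapse_to_species(net, default_grouping())
    assert (M.M == 0).all()


def test_collapse_gene_level_conflict_zeroes_cell():
    net = derive_gene_network(
        [
            rec("Dkk4", "WNT", "stimulated", 2.5, 0.01),
            rec("Dkk1", "WNT", "stimulated", 0.4, 0.01),
        ]
    )
    with pytest.warns(UserWarning, match="conflicting gene-level"):
        M = collapse_to_species(net, default_grouping())
    assert M[M.index("WNT_inhibitor"), M.index("WNT")] == 0


def test_grouping_rejects_double_assignment():
    with pytest.raises(InvalidGroupingError):
        SpeciesGrouping.from_lists({"WNT": ["Dkk4"], "WNT_inhibitor": ["Dkk4"]})


def test_self_inhibition_report():
    # WNT self-inhibits through its dedicated inhibitor 2-cycle
    M = np.zeros((5, 5), dtype=int)
    species = ("BMP", "WNT", "WNT_inhibitor", "BMP_inhibitor", "FGF")
    M[species.index("WNT_inhibitor"), species.index("WNT")] = 1
    M[species.index("WNT"), species.index("WNT_inhibitor")] = -1
    M[species.index("FGF"), species.index("FGF")] = -1
    rep = validate_self_inhibition(SignedInteractionMatrix(M, species))
    assert rep["WNT"]["self_inhibiting"] and rep["WNT"]["via_inhibitor"] == -1
    assert rep["FGF"]["self_inhibiting"] and rep["FGF"]["direct"] == -1
    assert not rep["BMP"]["self_inhibiting"]
    # all-zero matrix: nothing self-inhibits
    rep0 = validate_self_inhibition(SignedInteractionMatrix(np.zeros((5, 5)), species))
    assert not any(r["self_inhibiting"] for r in rep0.values())


def test_default_matrix_all_pathways_self_inhibit(default_matrix):
    rep = validate_self_inhibition(default_matrix)
    for pathway in ("BMP", "WNT", "FGF"):
        assert rep[pathway]["self_inhibiting"]


def test_matrix_csv_roundtrip(tmp_path, default_matrix):
    path = tmp_path / "m.csv"
    default_matrix.to_csv(path)
    back = SignedInteractionMatrix.from_csv(path)
    assert back.species == default_matrix.species
    assert (back.M == default_matrix.M).all()


def test_noiseless_recovery_is_exact(default_matrix):
    table, grouping = gen_foldchange_table(default_matrix, noise_sd=0.0, seed=1)
    net = derive_gene_network(records_from_frame(table), pathways=default_matrix.species)
    M = collapse_to_species(
        net, SpeciesGrouping(grouping), source_species=default_matrix.species
    )
    assert (M.M == default_matrix.M).all()


def test_noiseless_recovery_at_exact_threshold(default_matrix):
    """effect = 1.8 sits exactly on the inclusive fold-change threshold."""
    table, grouping = gen_foldchange_table(
        default_matrix, effect=1.8, noise_sd=0.0, seed=1
    )
    net = derive_gene_network(records_from_frame(table), pathways=default_matrix.species)
    M = collapse_to_species(net, SpeciesGrouping(grouping))
    assert (M.M == default_matrix.M).all()


def test_ttest_helper_matches_known_direction():
    fc, p = ttest_fold_changes(np.array([2.0, 2.1, 1.9]), np.array([1.0, 1.05, 0.95]))
    assert fc == pytest.approx(2.0, rel=0.05)
    assert p < 0.01
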