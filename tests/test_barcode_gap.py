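import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import barcodelim as bl
from barcodelim.alignment import SpeciesPartition, alignment_from_dict
from barcodelim.barcode_gap import (
    BarcodeGapError,
    bin_distances,
    distance_class,
    duplicate_and_recode,
    find_gaps,
    partition_distances,
)
from barcodelim.distances import DistanceMatrix, distance_matrix


# ----------------------------------------------------------------------
# binning
# ----------------------------------------------------------------------

def test_boundary_convention_closed_lower_open_upper():
    fd = bin_distances([0.000, 0.0049, 0.005])
    assert fd.counts == {1: 2, 2: 1}
    assert fd.n_total == 3


def test_class_58_covers_0287():
    assert distance_class(0.287) == 58
    assert distance_class(0.285) == 58  # lower bound closed
    assert distance_class(0.290) == 59  # upper bound open


def test_exact_multiples_are_robust_to_float_representation():
    # 0.015 / 0.005 is not exactly 3 in binary floating point
    for k in range(1, 200):
        assert distance_class(k * 0.005) == k + 1


def test_empty_and_invalid_inputs():
    fd = bin_distances([])
    assert fd.n_total == 0 and fd.counts == {}
    with pytest.raises(BarcodeGapError, match="index 1"):
        bin_distances([0.1, -0.2])
    with pytest.raises(BarcodeGapError, match="invalid"):
        bin_distances([float("inf")])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0,
                          allow_nan=False), max_size=300))
def test_binning_is_exhaustive_and_exclusive(values):
    fd = bin_distances(values)
    assert sum(fd.counts.values()) == len(values)
    for k in fd.counts:
        lo, hi = fd.bounds(k)
        members = [v for v in values if distance_class(v) == k]
        assert len(members) == fd.counts[k]


def test_frequency_table_tsv(tmp_path):
    fd = bin_distances([0.001, 0.002, 0.012], intra_values=[0.001])
    out = tmp_path / "freq.tsv"
    fd.write_tsv(out)
    lines = out.read_text().strip().splitlines()
    assert lines[0] == "class\tlower\tupper\tcount\tintra\tinter"
    assert lines[1].split("\t") == ["1", "0", "0.005", "2", "1", "1"]


# ----------------------------------------------------------------------
# intra/inter partitioning
# ----------------------------------------------------------------------

def test_partition_distances_small_example():
    vals = np.array([[0, 0.1, 0.2], [0.1, 0, 0.3], [0.2, 0.3, 0.0]])
    dm = DistanceMatrix(["a1", "a2", "b1"], vals)
    part = SpeciesPartition({"a1": "A", "a2": "A", "b1": "B"})
    intra, inter = partition_distances(dm, part)
    assert intra == [0.1]
    assert sorted(inter) == [0.2, 0.3]


def test_single_species_all_intra():
    n = 5
    vals = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) * 0.01
    dm = DistanceMatrix([f"t{i}" for i in range(n)], vals.astype(float))
    part = SpeciesPartition({f"t{i}": "S" for i in range(n)})
    intra, inter = partition_distances(dm, part)
    assert len(intra) == n * (n - 1) // 2 and inter == []


def test_unassigned_taxon_rejected():
    dm = DistanceMatrix(["a", "b"], np.array([[0, 0.1], [0.1, 0.0]]))
    with pytest.raises(BarcodeGapError, match="b"):
        partition_distances(dm, SpeciesPartition({"a": "A"}))


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=2, max_value=50), st.integers(min_value=1, max_value=6),
       st.integers(min_value=0, max_value=10 ** 6))
def test_intra_count_identity_against_brute_force(n, n_species, seed):
    rng = np.random.default_rng(seed)
    taxa = [f"t{i}" for i in range(n)]
    assignment = {t: f"S{rng.integers(0, n_species)}" for t in taxa}
    part = SpeciesPartition(assignment)
    vals = rng.random((n, n))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 0.0)
    dm = DistanceMatrix(taxa, vals)
    intra, inter = partition_distances(dm, part)
    brute = sum(
        1
        for i in range(n)
        for j in range(i + 1, n)
        if assignment[taxa[i]] == assignment[taxa[j]]
    )
    assert len(intra) == brute == part.intraspecific_pair_count()
    assert len(intra) + len(inter) == n * (n - 1) // 2


# ----------------------------------------------------------------------
# gap detection
# ----------------------------------------------------------------------

def test_interior_empty_class_reported():
    fd = bin_distances([0.001] * 5 + [0.006] * 3 + [0.016] * 7)
    report = find_gaps(fd)
    assert report.empty_classes == [3]


def test_unimodal_distribution_has_no_gaps():
    fd = bin_distances([0.001, 0.006, 0.006, 0.011, 0.011, 0.011, 0.016])
    report = find_gaps(fd)
    assert report.empty_classes == [] and report.minima == []


def test_trailing_zeros_are_not_gaps():
    fd = bin_distances([0.001] * 5)
    fd.counts.setdefault(2, 0)
    fd.counts.setdefault(3, 0)
    report = find_gaps(fd)
    assert report.empty_classes == []


def test_local_minimum_with_flanks():
    fd = bin_distances([0.001] * 5 + [0.006] * 2 + [0.011] * 7)
    report = find_gaps(fd)
    assert report.minima == [(2, 2, 5, 7)]


# ----------------------------------------------------------------------
# duplication experiment
# ----------------------------------------------------------------------

def test_duplicate_single_taxon_alignment():
    aln = alignment_from_dict({"a": "ACGT", "b": "AGGT"})
    part = SpeciesPartition({"a": "A", "b": "B"})
    mod, mpart, summary = duplicate_and_recode(aln, part, {"a": 1})
    assert summary.n_taxa == 3
    dm = distance_matrix(mod, method="p")
    assert dm.get("a", "a__dup1") == 0.0
    assert mpart.assignments["a__dup1"] == "A"


def test_duplicate_on_distance_matrix_copies_rows():
    vals = np.array([[0, 0.1, 0.4], [0.1, 0, 0.5], [0.4, 0.5, 0.0]])
    dm = DistanceMatrix(["a", "b", "c"], vals)
    part = SpeciesPartition({"a": "A", "b": "B", "c": "C"})
    mod, mpart, summary = duplicate_and_recode(dm, part, {"a": 2})
    assert summary.n_taxa == 5
    assert mod.get("a__dup1", "b") == pytest.approx(0.1)
    assert mod.get("a__dup1", "a__dup2") == 0.0
    assert mod.get("a__dup1", "a") == 0.0


def test_recode_only_leaves_data_unchanged():
    vals = np.array([[0, 0.1], [0.1, 0.0]])
    dm = DistanceMatrix(["a", "b"], vals)
    part = SpeciesPartition({"a": "A", "b": "A"})
    mod, mpart, summary = duplicate_and_recode(dm, part,
                                               recodings={"b": "B"})
    assert np.allclose(mod.values, dm.values)
    assert mpart.assignments["b"] == "B"
    assert summary.n_intra == 0


def test_duplicating_unassigned_taxon_rejected():
    aln = alignment_from_dict({"a": "ACGT", "b": "AGGT"})
    with pytest.raises(BarcodeGapError, match="not assigned"):
        duplicate_and_recode(aln, SpeciesPartition({"b": "B"}), {"a": 1})


def test_taxon_sampling_modification_arithmetic():
    """Duplicating two singletons x4 and splitting a 3-member species gives
    Delta intra = +18 on the 64-taxon fixture (114 -> 132)."""
    fx = bl.make_duplication_fixture(seed=3, n_sites=120)
    assert fx.alignment.n_taxa == 64
    assert fx.partition.intraspecific_pair_count() == 114
    mod, mpart, summary = duplicate_and_recode(
        fx.alignment, fx.partition, fx.duplications, fx.recodings)
    assert summary.n_taxa == 72
    assert summary.n_pairs == 2556
    assert summary.n_intra == 132
    assert summary.n_inter == 2424
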