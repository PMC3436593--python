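"""Barcode-gap analysis: distance-class frequency distributions, intra- vs
interspecific partitioning, gap detection, and the taxon-sampling
duplication experiment.

Distances are sorted into classes of fixed width (default 0.005) with
closed lower and open upper limits: class k covers [width*(k-1), width*k[,
1-based so class 1 is [0, width[. No means or standard deviations are ever
computed for the distributions — summary statistics of skewed intra- and
multimodal interspecific distance sets bias the apparent gap, so only raw
counts are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment, SpeciesPartition
from .distances import DistanceMatrix

DEFAULT_CLASS_WIDTH = 0.005


class BarcodeGapError(ValueError):
    pass


@dataclass
class FrequencyDistribution:
    """Distance-class counts; optionally split into intra/inter components."""

    class_width: float
    counts: dict[int, int]
    n_total: int
    intra: dict[int, int] | None = None
    inter: dict[int, int] | None = None

    def bounds(self, k: int) -> tuple[float, float]:
        return (self.class_width * (k - 1), self.class_width * k)

    def max_class(self) -> int:
        return max(self.counts) if self.counts else 0

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            header = "class\tlower\tupper\tcount"
            if self.intra is not None:
                header += "\tintra\tinter"
            fh.write(header + "\n")
            for k in range(1, self.max_class() + 1):
                lo, hi = self.bounds(k)
                row = f"{k}\t{lo:.6g}\t{hi:.6g}\t{self.counts.get(k, 0)}"
                if self.intra is not None:
                    row += f"\t{self.intra.get(k, 0)}\t{self.inter.get(k, 0)}"
                fh.write(row + "\n")


def distance_class(value: float, class_width: float = DEFAULT_CLASS_WIDTH) -> int:
    """1-based class index of a distance; exact multiples of the width fall
    in the upper class (closed-lower/open-upper convention)."""
    if not math.isfinite(value) or value < 0:
        raise BarcodeGapError(f"invalid distance: {value}")
    # relative epsilon guards against 0.015/0.005 -> 2.999... artefacts
    return int(math.floor(value / class_width + 1e-9)) + 1


def bin_distances(values, class_width: float = DEFAULT_CLASS_WIDTH,
                  intra_values=None) -> FrequencyDistribution:
    """Bin distances into the class grid; ``intra_values`` (a subset) splits
    the counts into parallel intra/inter vectors."""
    if class_width <= 0:
        raise BarcodeGapError("class width must be positive")
    values = list(values)
    counts: dict[int, int] = {}
    for i, v in enumerate(values):
        if not math.isfinite(v) or v < 0:
            raise BarcodeGapError(f"invalid distance at index {i}: {v}")
        k = distance_class(v, class_width)
        counts[k] = counts.get(k, 0) + 1
    fd = FrequencyDistribution(class_width, counts, n_total=len(values))
    if intra_values is not None:
        intra: dict[int, int] = {}
        for v in intra_values:
            k = distance_class(v, class_width)
            intra[k] = intra.get(k, 0) + 1
        inter = {k: counts.get(k, 0) - intra.get(k, 0) for k in counts}
        if any(c < 0 for c in inter.values()):
            raise BarcodeGapError("intra values are not a subset of values")
        fd.intra, fd.inter = intra, inter
    return fd


def partition_distances(dm: DistanceMatrix, part: SpeciesPartition
                        ) -> tuple[list[float], list[float]]:
    """Split the n(n-1)/2 pairwise distances into intra- and interspecific
    lists; every matrix taxon must be assigned."""
    missing = part.unassigned(dm.taxa)
    if missing:
        raise BarcodeGapError(
            f"taxa without species assignment: {', '.join(sorted(missing))}")
    intra: list[float] = []
    inter: list[float] = []
    for i in range(dm.n):
        sp_i = part.assignments[dm.taxa[i]]
        for j in range(i + 1, dm.n):
            v = float(dm.values[i, j])
            if sp_i == part.assignments[dm.taxa[j]]:
                intra.append(v)
            else:
                inter.append(v)
    return intra, inter


@dataclass
class GapReport:
    """Interior empty classes and interior local minima of a distribution.

    An empty class is reported only when flanked (not necessarily
    adjacently) by occupied classes; trailing or leading zeros are not gaps.
    """

    empty_classes: list[int]
    minima: list[tuple[int, int, int, int]]  # (class, count, left, right)
    notes: str = ""


def find_gaps(fd: FrequencyDistribution) -> GapReport:
    occupied = sorted(k for k, c in fd.counts.items() if c > 0)
    if len(occupied) < 2:
        return GapReport([], [], notes="fewer than two occupied classes")
    lo, hi = occupied[0], occupied[-1]
    dense = np.array([fd.counts.get(k, 0) for k in range(lo, hi + 1)])
    empty = [lo + i for i in range(len(dense)) if dense[i] == 0]
    minima: list[tuple[int, int, int, int]] = []
    for i in range(1, len(dense) - 1):
        if dense[i] > 0 and dense[i] < dense[i - 1] and dense[i] < dense[i + 1]:
            minima.append((lo + i, int(dense[i]),
                           int(dense[i - 1]), int(dense[i + 1])))
    notes = ""
    if empty:
        runs = _runs(empty)
        notes = "empty class runs: " + ", ".join(
            f"{a}" if a == b else f"{a}-{b}" for a, b in runs)
    return GapReport(empty, minima, notes)


def _runs(indices: list[int]) -> list[tuple[int, int]]:
    runs = []
    start = prev = indices[0]
    for k in indices[1:]:
        if k == prev + 1:
            prev = k
            continue
        runs.append((start, prev))
        start = prev = k
    runs.append((start, prev))
    return runs


# ----------------------------------------------------------------------
# taxon-sampling modification experiment
# ----------------------------------------------------------------------

@dataclass
class ModificationSummary:
    n_taxa: int
    n_pairs: int
    n_intra: int
    n_inter: int


def _dup_label(taxon: str, i: int) -> str:
    return f"{taxon}__dup{i}"


def duplicate_and_recode(data, part: SpeciesPartition,
                         duplications: dict[str, int] | None = None,
                         recodings: dict[str, str] | None = None):
    """Apply the sampling-modification experiment to an alignment or
    distance matrix plus its species partition.

    ``duplications`` maps a taxon to the number of extra identical copies
    (labelled ``taxon__dup1``, ...); copies inherit the source's sequence or
    distances (zero to the source) and its species. ``recodings`` reassigns
    taxa to new species identifiers without touching the data. Returns
    ``(modified data, modified partition, ModificationSummary)``.
    """
    duplications = duplications or {}
    recodings = recodings or {}
    for taxon in list(duplications) + list(recodings):
        if part.species_of(taxon) is None:
            raise BarcodeGapError(f"taxon not assigned to a species: {taxon}")
    assignments = dict(part.assignments)
    for taxon, sp in recodings.items():
        assignments[taxon] = sp

    if isinstance(data, Alignment):
        taxa = list(data.taxa)
        rows = [data.rows[i] for i in range(data.n_taxa)]
        for taxon, ncopies in sorted(duplications.items()):
            if taxon not in taxa:
                raise BarcodeGapError(f"unknown taxon: {taxon}")
            src = data.rows[data.taxa.index(taxon)]
            for i in range(1, ncopies + 1):
                label = _dup_label(taxon, i)
                taxa.append(label)
                rows.append(src.copy())
                assignments[label] = assignments[taxon]
        new_data = Alignment(taxa, np.vstack(rows),
                             data.included_columns.copy())
        n = len(taxa)
    elif isinstance(data, DistanceMatrix):
        taxa = list(data.taxa)
        values = data.values
        for taxon, ncopies in sorted(duplications.items()):
            if taxon not in data.taxa:
                raise BarcodeGapError(f"unknown taxon: {taxon}")
            src = taxa.index(taxon)
            for i in range(1, ncopies + 1):
                label = _dup_label(taxon, i)
                m = values.shape[0]
                values = np.pad(values, ((0, 1), (0, 1)))
                values[m, :m] = values[src, :m]
                values[:m, m] = values[:m, src]
                values[m, src] = values[src, m] = 0.0
                # distances among copies of the same source are zero
                for j, lab in enumerate(taxa):
                    if lab.startswith(f"{taxon}__dup"):
                        values[m, j] = values[j, m] = 0.0
                values[m, m] = 0.0
                taxa.append(label)
                assignments[label] = assignments[taxon]
        new_data = DistanceMatrix(taxa, values, model_tag=data.model_tag,
                                  units=data.units)
        n = len(taxa)
    else:
        raise BarcodeGapError("data must be an Alignment or DistanceMatrix")

    new_part = SpeciesPartition(assignments)
    present = SpeciesPartition(
        {t: sp for t, sp in assignments.items() if t in set(taxa)})
    n_intra = present.intraspecific_pair_count()
    n_pairs = n * (n - 1) // 2
    summary = ModificationSummary(n_taxa=n, n_pairs=n_pairs,
                                  n_intra=n_intra, n_inter=n_pairs - n_intra)
    return new_data, new_part, summary
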