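"""Synthetic data: Yule species trees, within-species coalescents, sequence
evolution and the taxon-duplication fixture.

The generative model matches the assumptions of the delimitation analysis:
a pure-birth (Yule) process above species boundaries, neutral Kingman
coalescents of constant population size within species, and reversible
substitution models (optionally +I and discrete-gamma) along the branches.
All simulators are bit-reproducible given a seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .alignment import Alignment, SpeciesPartition
from .models import SubstitutionModel


@dataclass
class SimulationSpec:
    """Study conditions of a species-sampling simulation."""

    n_species: int
    birth_rate: float
    samples_per_species: int | list[int]
    theta: float | list[float]
    n_sites: int
    model: SubstitutionModel
    seed: int

    def serialize(self) -> str:
        lines = [
            f"n_species={self.n_species}",
            f"birth_rate={self.birth_rate}",
            f"samples_per_species={self.samples_per_species}",
            f"theta={self.theta}",
            f"n_sites={self.n_sites}",
            f"model={self.model.family}",
            f"p_inv={self.model.p_inv}",
            f"alpha={self.model.alpha}",
            f"seed={self.seed}",
        ]
        return "\n".join(lines) + "\n"


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_yule_tree(n_species: int, birth_rate: float, seed) -> dendropy.Tree:
    """Pure-birth ultrametric species tree with tips S1..Sn.

    Construction runs forward from the root (2 lineages): with k lineages
    the waiting time to the next split is Exponential(k * birth_rate); after
    the n-lineage interval the present is reached.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = _rng(seed)
    ns = dendropy.TaxonNamespace([f"S{i + 1}" for i in range(n_species)])
    tree = dendropy.Tree(taxon_namespace=ns)
    root = tree.seed_node
    elapsed = 0.0
    split_time = {id(root): 0.0}
    active = []
    for _ in range(2):
        ch = dendropy.Node()
        root.add_child(ch)
        active.append(ch)
    for k in range(2, n_species + 1):
        elapsed += rng.exponential(1.0 / (k * birth_rate))
        if k == n_species:
            break
        idx = int(rng.integers(0, len(active)))
        nd = active[idx]
        split_time[id(nd)] = elapsed
        for _ in range(2):
            ch = dendropy.Node()
            nd.add_child(ch)
            active.append(ch)
        active.pop(idx)
    depth = elapsed
    # tips are the still-active lineages; assign labels deterministically
    for i, nd in enumerate(active):
        nd.taxon = ns.get_taxon(f"S{i + 1}")
    ages = {}
    for nd in tree.postorder_node_iter():
        ages[id(nd)] = 0.0 if nd.is_leaf() else depth - split_time[id(nd)]
        for ch in nd.child_nodes():
            ch.edge.length = ages[id(nd)] - ages[id(ch)]
    tree.is_rooted = True
    return tree


def _kingman_genealogy(labels: list[str], theta: float, ns,
                       rng: np.random.Generator):
    """Single-population coalescent over ``labels``; pair rate n(n-1)/2 per
    theta. Returns (root node, root height)."""
    nodes = []
    for lab in labels:
        nd = dendropy.Node(taxon=ns.get_taxon(lab))
        nd.sim_age = 0.0
        nodes.append(nd)
    t = 0.0
    while len(nodes) > 1:
        j = len(nodes)
        t += rng.exponential(2.0 * theta / (j * (j - 1)))
        a, b = rng.choice(len(nodes), size=2, replace=False)
        a, b = int(min(a, b)), int(max(a, b))
        parent = dendropy.Node()
        parent.sim_age = t
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        for ch in parent.child_nodes():
            ch.edge.length = t - ch.sim_age
        nodes = [nd for i, nd in enumerate(nodes) if i not in (a, b)] + [parent]
    return nodes[0], nodes[0].sim_age if len(labels) > 1 else 0.0


def simulate_species_coalescents(species_tree: dendropy.Tree,
                                 samples_per_species: int | list[int],
                                 theta: float | list[float],
                                 seed) -> tuple[dendropy.Tree, SpeciesPartition]:
    """Graft within-species Kingman genealogies onto a species tree.

    Each species tip with m >= 2 samples is replaced by a coalescent
    genealogy over tips ``<species>_1..m``; a genealogy deeper than 95% of
    the species' terminal branch is rescaled to fit (with a warning), so the
    output stays ultrametric. Species with one sample keep their label.
    """
    rng = _rng(seed)
    tree = species_tree.clone(depth=1)
    species = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if isinstance(samples_per_species, int):
        samples = {sp: samples_per_species for sp in species}
    else:
        samples = dict(zip(species, samples_per_species))
    if isinstance(theta, (int, float)):
        thetas = {sp: float(theta) for sp in species}
    else:
        thetas = dict(zip(species, theta))
    assignments: dict[str, str] = {}
    new_labels: list[str] = []
    for sp in species:
        m = samples[sp]
        if m >= 2:
            new_labels.extend(f"{sp}_{i + 1}" for i in range(m))
        else:
            new_labels.append(sp)
    ns = dendropy.TaxonNamespace(new_labels)
    for sp in species:
        m = samples[sp]
        tip = tree.find_node_with_taxon_label(sp)
        if m < 2:
            assignments[sp] = sp
            tip.taxon = ns.get_taxon(sp)
            continue
        labels = [f"{sp}_{i + 1}" for i in range(m)]
        for lab in labels:
            assignments[lab] = sp
        stem = tip.edge.length
        if stem is None or stem <= 0:
            raise ValueError(f"species {sp} has a zero-length terminal branch")
        groot, height = _kingman_genealogy(labels, thetas[sp], ns, rng)
        if height >= 0.95 * stem:
            factor = 0.9 * stem / height
            warnings.warn(
                f"coalescent of species {sp} (depth {height:.4g}) rescaled "
                f"by {factor:.3g} to fit its terminal branch ({stem:.4g})"
            )
            for nd in groot.preorder_iter():
                if nd.edge.length is not None:
                    nd.edge.length *= factor
            height *= factor
        parent = tip.parent_node
        parent.remove_child(tip)
        parent.add_child(groot)
        groot.edge.length = stem - height
    tree.taxon_namespace = ns
    tree.update_taxon_namespace()
    tree.is_rooted = True
    return tree, SpeciesPartition(assignments)


def simulate_coalescent_tree(n_samples: int, theta: float, seed) -> dendropy.Tree:
    """Single-population Kingman genealogy over tips t1..tn (the GMYC null)."""
    labels = [f"t{i + 1}" for i in range(n_samples)]
    ns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=ns)
    root, _ = _kingman_genealogy(labels, theta, ns, _rng(seed))
    tree.seed_node = root
    tree.is_rooted = True
    return tree


def simulate_delimitation_benchmark(seed, n_species: int = 5,
                                    samples_per_species: int = 5,
                                    separation: float = 100.0):
    """Species sample tree with controlled speciation/coalescent separation.

    A Yule species tree (birth rate 1) is drawn, then the within-species
    coalescent scale is set to ``shallowest species divergence /
    separation`` so that even the most recent speciation is ``separation``
    times deeper than the mean within-species pairwise coalescence. Returns
    ``(ultrametric sample tree, true SpeciesPartition)``.
    """
    rng = _rng(seed)
    sp_tree = simulate_yule_tree(n_species, 1.0, rng)
    ages = {}
    for nd in sp_tree.postorder_node_iter():
        ages[id(nd)] = 0.0 if nd.is_leaf() else max(
            ages[id(ch)] + ch.edge.length for ch in nd.child_nodes())
    min_div = min(a for a in ages.values() if a > 0)
    theta = min_div / separation
    return simulate_species_coalescents(sp_tree, samples_per_species, theta, rng)


def simulate_ultrametric_sample_tree(spec: SimulationSpec):
    """Yule species tree + grafted coalescents in one call."""
    rng = _rng(spec.seed)
    sp_tree = simulate_yule_tree(spec.n_species, spec.birth_rate, rng)
    return simulate_species_coalescents(
        sp_tree, spec.samples_per_species, spec.theta, rng)


_BASE_BYTES = np.frombuffer(b"ACGT", dtype="S1")


def simulate_alignment(tree: dendropy.Tree, model: SubstitutionModel,
                       n_sites: int, seed) -> Alignment:
    """Evolve sequences along a tree whose branch lengths are expected
    substitutions per site.

    Root states are drawn from pi; each site is invariable with probability
    p_inv, otherwise it evolves at one of the discrete-gamma category rates
    (chosen uniformly), using the same discretisation as the likelihood
    engine.
    """
    rng = _rng(seed)
    eigen = model.eigen()
    cat_rates = model.gamma_category_rates()
    n_cat = len(cat_rates)
    site_rates = cat_rates[rng.integers(0, n_cat, size=n_sites)]
    if model.p_inv > 0:
        invariant = rng.random(n_sites) < model.p_inv
        site_rates = np.where(invariant, 0.0, site_rates)
    states: dict[int, np.ndarray] = {}
    root = tree.seed_node
    states[id(root)] = rng.choice(4, size=n_sites, p=model.pi)
    unique_rates = np.unique(site_rates)
    for nd in tree.preorder_node_iter():
        if nd is root:
            continue
        t = nd.edge.length or 0.0
        parent_states = states[id(nd.parent_node)]
        child = parent_states.copy()
        for rho in unique_rates:
            if rho == 0.0 or t == 0.0:
                continue
            sel = site_rates == rho
            if not sel.any():
                continue
            pmat = model.transition_matrix(t * rho, eigen)
            cum = np.cumsum(pmat, axis=1)
            u = rng.random(int(sel.sum()))
            child[sel] = (u[:, None] > cum[parent_states[sel]]).sum(axis=1)
        states[id(nd)] = child
        if not nd.is_leaf():
            continue
    taxa = []
    rows = []
    for lf in tree.leaf_node_iter():
        taxa.append(lf.taxon.label)
        rows.append(_BASE_BYTES[states[id(lf)]])
    return Alignment(taxa, np.vstack(rows))


# ----------------------------------------------------------------------
# duplication fixture
# ----------------------------------------------------------------------

#: Species-size profile of the 64-taxon fixture: sum = 64 with
#: sum C(s,2) = 114 intraspecific pairs, three singletons (two of which are
#: the designated duplication targets) and several 3-member species (the
#: first of which is the recoding target).
FIXTURE_PROFILE = (8, 7, 5, 5, 5, 4, 4, 4, 3, 3, 3, 3, 3, 2, 2, 1, 1, 1)


@dataclass
class DuplicationFixture:
    """A 64-taxon surrogate data set for the taxon-sampling experiment."""

    alignment: Alignment
    partition: SpeciesPartition
    tree: dendropy.Tree
    duplications: dict[str, int]  # taxon -> extra copy count
    recodings: dict[str, str]  # taxon -> new species id
    spec: SimulationSpec = field(repr=False, default=None)  # type: ignore


def make_duplication_fixture(seed: int = 0, n_sites: int = 600) -> DuplicationFixture:
    """Simulated analogue of the 64-taxon barcode data set.

    The baseline has exactly 114 intraspecific pairs. The attached
    modification recipe duplicates the two designated singleton taxa four
    times each (two artificial 5-member species) and recodes one member of a
    3-member species as a separate species, yielding 72 taxa, 2556 pairwise
    distances, 132 intra- and 2424 interspecific ones.
    """
    profile = FIXTURE_PROFILE
    assert sum(profile) == 64
    assert sum(s * (s - 1) // 2 for s in profile) == 114
    model = SubstitutionModel.gtr(
        pi=[0.27, 0.23, 0.26, 0.24],
        rates=[1.2, 4.0, 0.8, 0.9, 5.0, 1.0], alpha=0.6)
    spec = SimulationSpec(
        n_species=len(profile), birth_rate=1.0,
        samples_per_species=list(profile), theta=0.005,
        n_sites=n_sites, model=model, seed=seed)
    rng = _rng(seed)
    sp_tree = simulate_yule_tree(spec.n_species, spec.birth_rate, rng)
    # scale so that species divergences dwarf within-species depths
    for nd in sp_tree.preorder_node_iter():
        if nd.edge.length is not None:
            nd.edge.length *= 0.2
    tree, part = simulate_species_coalescents(
        sp_tree, spec.samples_per_species, spec.theta, rng)
    aln = simulate_alignment(tree, model, n_sites, rng)
    singleton_species = [sp for sp, n in part.sizes.items() if n == 1]
    triple_species = [sp for sp, n in part.sizes.items() if n == 3]
    dup_targets = sorted(singleton_species)[:2]
    recode_member = sorted(part.species[sorted(triple_species)[0]])[0]
    duplications = {t: 4 for t in dup_targets}
    recodings = {recode_member: f"{part.assignments[recode_member]}_split"}
    return DuplicationFixture(alignment=aln, partition=part, tree=tree,
                              duplications=duplications, recodings=recodings,
                              spec=spec)
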