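"""Strain trees: construction, Newick IO, and topology comparison.

``StrainTree`` wraps a dendropy tree.  Simulation trees are ultrametric with
branch lengths in time units; sequence trees carry expected substitutions
per site.  Topology comparisons are unrooted Robinson-Foulds distances.
"""

from __future__ import annotations

import io

import dendropy
import numpy as np
from dendropy.calculate import treecompare


class StrainTree:
    def __init__(self, tree: dendropy.Tree, outgroup: str | None = None):
        self.tree = tree
        self.outgroup = outgroup
        names = self.leaf_names
        if len(names) != len(set(names)):
            raise ValueError("leaf names must be unique")
        if outgroup is not None and outgroup not in names:
            raise ValueError(f"outgroup {outgroup!r} is not a leaf of the tree")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("branch lengths must be >= 0")

    # -- construction ------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str, outgroup: str | None = None) -> "StrainTree":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
        return cls(tree, outgroup=outgroup)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True,
                                   unquoted_underscores=True).strip()

    # -- basic queries -----------------------------------------------------
    @property
    def leaf_names(self) -> list:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    def total_length(self) -> float:
        return sum(e.length or 0.0 for e in self.tree.preorder_edge_iter())

    def node_ages(self) -> dict:
        """Age (height above the leaves) of every node, assuming ultrametric."""
        depths = self.tree.calc_node_root_distances(return_leaf_distances_only=False)
        max_depth = max(depths)
        return {nd: max_depth - nd.root_distance for nd in self.tree.preorder_node_iter()}

    def leaf_distance_matrix(self) -> tuple:
        """(names, matrix) of patristic distances between leaves."""
        pdm = self.tree.phylogenetic_distance_matrix()
        taxa = sorted(self.tree.taxon_namespace, key=lambda t: t.label)
        names = [t.label for t in taxa]
        n = len(names)
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = pdm.patristic_distance(taxa[i], taxa[j])
                mat[i, j] = mat[j, i] = d
        return names, mat

    def scaled(self, factor: float) -> "StrainTree":
        t = self.tree.clone(depth=1)
        for e in t.preorder_edge_iter():
            if e.length is not None:
                e.length *= factor
        return StrainTree(t, outgroup=self.outgroup)

    # -- comparison --------------------------------------------------------
    def rf_distance(self, other: "StrainTree") -> int:
        """Unrooted Robinson-Foulds (symmetric difference) distance."""
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=self.to_newick(), schema="newick",
                               taxon_namespace=tns, preserve_underscores=True)
        t2 = dendropy.Tree.get(data=other.to_newick(), schema="newick",
                               taxon_namespace=tns, preserve_underscores=True)
        if set(lf.taxon.label for lf in t1.leaf_node_iter()) != set(
                lf.taxon.label for lf in t2.leaf_node_iter()):
            raise ValueError("trees have different leaf sets")
        for t in (t1, t2):
            t.is_rooted = False
            t.deroot()
            t.encode_bipartitions()
        return treecompare.symmetric_difference(t1, t2)


def random_strain_tree(strains: list, seed: int, depth: float = 1.0,
                       outgroup: str | None = None,
                       ingroup_depth_fraction: float = 0.8,
                       age_jitter: float = 0.015,
                       shape: str = "random") -> StrainTree:
    """Ultrametric strain tree with well-separated internal nodes.

    The designated outgroup splits off at the root (age ``depth``); the
    remaining strains coalesce at ages evenly spaced (with small jitter) up
    to ``ingroup_depth_fraction * depth``, so every internal branch has a
    guaranteed minimum time span.  ``shape="random"`` joins random lineage
    pairs; ``shape="ladder"`` builds a pectinate tree in the order the
    strains are listed (first strain shallowest), giving a spread of
    divergence times from the first strain, as in a panel of progressively
    more distant relatives.
    """
    if len(strains) < 2:
        raise ValueError("need at least 2 strains")
    if len(set(strains)) != len(strains):
        raise ValueError("strain names must be unique")
    if shape not in ("random", "ladder"):
        raise ValueError(f"unknown tree shape {shape!r}")
    rng = np.random.default_rng(seed)
    if outgroup is None:
        outgroup = strains[-1]
    if outgroup not in strains:
        raise ValueError(f"outgroup {outgroup!r} not among strains")
    ingroup = [s for s in strains if s != outgroup]

    # Newick assembled bottom-up: each lineage is (newick_fragment, age).
    lineages = [(name, 0.0) for name in ingroup]
    k = len(ingroup) - 1
    if k > 0:
        base_ages = np.linspace(depth * ingroup_depth_fraction / (k + 1),
                                depth * ingroup_depth_fraction, k)
        ages = base_ages + rng.uniform(-age_jitter, age_jitter, size=k)
    else:
        ages = []
    for age in ages:
        if shape == "ladder":
            i, j = 0, 1
        else:
            i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        (na, aa), (nb, ab) = lineages[i], lineages[j]
        merged = (f"({na}:{age - aa:.10f},{nb}:{age - ab:.10f})", float(age))
        lineages = [x for idx, x in enumerate(lineages) if idx not in (i, j)]
        if shape == "ladder":
            lineages.insert(0, merged)
        else:
            lineages.append(merged)
    (nin, ain) = lineages[0]
    newick = f"({nin}:{depth - ain:.10f},{outgroup}:{depth:.10f});"
    return StrainTree.from_newick(newick, outgroup=outgroup)
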