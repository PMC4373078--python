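"""Rooted trees with branch lengths, and tip -> geographic region codings.

Thin layer over dendropy: trees are parsed, validated (rooted, unique tip
labels, non-negative branch lengths with at least one positive) and indexed
into flat arrays for the likelihood machinery.  Internal nodes get stable
ids N0, N1, ... in preorder; tips keep their labels as ids.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import dendropy
import numpy as np


class TreeError(ValueError):
    pass


@dataclass
class PhyloTree:
    tree: dendropy.Tree
    # flat postorder index, built on construction
    node_ids: list[str] = field(default_factory=list)       # per postorder index
    parent: np.ndarray | None = None                        # postorder idx -> idx
    edge_len: np.ndarray | None = None
    children: list[list[int]] = field(default_factory=list)
    is_leaf: np.ndarray | None = None
    postorder: list[int] = field(default_factory=list)      # identity order
    root_index: int = -1

    def __post_init__(self) -> None:
        self._index()

    def _index(self) -> None:
        nodes = list(self.tree.postorder_node_iter())
        n = len(nodes)
        idx = {id(nd): i for i, nd in enumerate(nodes)}
        self.parent = np.full(n, -1, dtype=int)
        self.edge_len = np.zeros(n)
        self.is_leaf = np.zeros(n, dtype=bool)
        self.children = [[] for _ in range(n)]
        labels: set[str] = set()
        # preorder numbering for internal-node ids
        pre_ids: dict[int, str] = {}
        counter = 0
        for nd in self.tree.preorder_node_iter():
            if not nd.is_leaf():
                pre_ids[id(nd)] = f"N{counter}"
                counter += 1
        self.node_ids = [""] * n
        positive = False
        for i, nd in enumerate(nodes):
            if nd.is_leaf():
                self.is_leaf[i] = True
                if nd.taxon is None or not nd.taxon.label:
                    raise TreeError("unlabeled tip")
                label = nd.taxon.label
                if label in labels:
                    raise TreeError(f"duplicate tip label {label!r}")
                labels.add(label)
                self.node_ids[i] = label
            else:
                self.node_ids[i] = pre_ids[id(nd)]
            if nd.parent_node is not None:
                self.parent[i] = idx[id(nd.parent_node)]
                self.children[idx[id(nd.parent_node)]].append(i)
                if nd.edge.length is None:
                    raise TreeError(
                        f"missing branch length on edge to {self.node_ids[i]!r}")
                if nd.edge.length < 0:
                    raise TreeError(
                        f"negative branch length on edge to {self.node_ids[i]!r}")
                self.edge_len[i] = float(nd.edge.length)
                positive = positive or nd.edge.length > 0
            else:
                self.root_index = i
        if not positive:
            raise TreeError("all branch lengths are zero")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def tip_labels(self) -> list[str]:
        return [self.node_ids[i] for i in range(self.n_nodes) if self.is_leaf[i]]

    @property
    def n_tips(self) -> int:
        return int(self.is_leaf.sum())

    def height(self) -> float:
        depth = np.zeros(self.n_nodes)
        for i in reversed(range(self.n_nodes)):  # preorder over postorder array
            if self.parent[i] >= 0:
                depth[i] = depth[self.parent[i]] + self.edge_len[i]
        return float(depth[self.is_leaf].max())

    def tips_below(self) -> list[list[int]]:
        """Postorder-indexed list of descendant-tip indices per node."""
        below: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(self.n_nodes):
            if self.is_leaf[i]:
                below[i] = [i]
            else:
                for c in self.children[i]:
                    below[i].extend(below[c])
        return below

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def read_newick(path) -> PhyloTree:
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    return tree_from_string(text)


def tree_from_string(text: str) -> PhyloTree:
    if "[&U]" in text.replace(" ", ""):
        raise TreeError("tree is explicitly unrooted; a rooted tree is required")
    try:
        t = dendropy.Tree.get(data=text, schema="newick",
                              rooting="force-rooted",
                              suppress_internal_node_taxa=True)
    except Exception as e:  # dendropy raises several error types
        raise TreeError(f"malformed newick: {e}") from e
    return PhyloTree(t)


def write_newick(t: PhyloTree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(t.newick() + "\n")


@dataclass
class RegionCoding:
    states: list[str]
    assignment: dict[str, str]  # tip label -> region

    def __post_init__(self) -> None:
        bad = {r for r in self.assignment.values()} - set(self.states)
        if bad:
            raise ValueError(f"region(s) {sorted(bad)} not in state set")

    def validate_against(self, tree: PhyloTree) -> None:
        missing = [l for l in tree.tip_labels if l not in self.assignment]
        if missing:
            raise ValueError(f"uncoded tip(s): {missing[:5]}")


def read_regions_csv(path, states: list[str] | None = None) -> RegionCoding:
    """tip_label,region CSV; the state set defaults to the observed regions."""
    assignment: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if not reader.fieldnames or "tip_label" not in reader.fieldnames \
                or "region" not in reader.fieldnames:
            raise ValueError("regions CSV needs columns tip_label,region")
        for row in reader:
            tip = row["tip_label"].strip()
            if tip in assignment:
                raise ValueError(f"duplicate tip {tip!r} in regions CSV")
            assignment[tip] = row["region"].strip()
    if states is None:
        states = sorted(set(assignment.values()))
    return RegionCoding(states=list(states), assignment=assignment)


def write_regions_csv(coding: RegionCoding, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["tip_label", "region"])
        for tip, region in coding.assignment.items():
            w.writerow([tip, region])
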