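"""Synthetic inputs with the statistical structure the analyses assume.

Three generators, all pure functions of their configuration and seed:

* Yule trees with equal-rates Mk region evolution, optionally with a
  planted "camouflaged invasion": one clade's tips are relabeled to the
  focal region while the underlying lineage keeps its exotic source state.
* Clonal morph character matrices: each morph is a centroid in the shell
  scoring system and specimens scatter around it by adjacent-state
  perturbation with probability pi (the plasticity), occasionally recorded
  as a two-state border cell — tight clonal morphs at pi near 0, plastic
  morphs at larger pi.
* Population grids with a lognormal background and Gaussian urban hotspots
  (heavy right tail, emulating a gridded population-count product at ~21 km²
  resolution), a border-band mask, and invasion placement biased toward
  dense cells with probability proportional to (count + 1)^beta.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np

from .characters import (NA, CharacterMatrix, SpecimenScore,
                         canonical_character_set)
from .grid import InvasionSites, PopulationGrid
from .phylo import PhyloTree, RegionCoding

# defaults are the study conditions: a 200-tip tree with total branch length
# ~ (n-1)/birth_rate = 40 so that the default dispersal rate 0.1 yields only
# a handful of region shifts, as in real intercontinental snail phylogenies;
# lognormal(4.5, 2.2) puts ~7.7% of background cells above 2100 people/cell,
# the high-density fraction of the sub-Saharan grid the generator emulates.


@dataclass
class TreeConfig:
    n_tips: int = 200
    birth_rate: float = 5.0


@dataclass
class PlantedInvasion:
    clade_size: int = 5
    source: str = "Asia"
    focal: str = "Africa"
    force_root_source: bool = True


@dataclass
class RegionConfig:
    states: tuple[str, ...] = ("Africa", "Asia")
    q_true: float = 0.1
    planted: PlantedInvasion | None = None


@dataclass
class MorphConfig:
    n_morphs: int = 6
    specimens_per_morph: int = 8
    plasticity: float = 0.2
    border_cell_prob: float = 0.25  # P(record a perturbation as a border cell)


@dataclass
class GridConfig:
    nrows: int = 120
    ncols: int = 120
    n_hotspots: int = 12
    hotspot_intensity: float = 50000.0
    hotspot_sigma: float = 2.0       # cells
    lognormal_mu: float = 4.5
    lognormal_sigma: float = 2.2
    border: int = 3                  # masked-out border band, cells
    cell_area: float = 21.0


@dataclass
class PlacementConfig:
    k: int = 6
    beta: float = 2.0


@dataclass
class SimulationConfig:
    seed: int = 0
    tree: TreeConfig = field(default_factory=TreeConfig)
    regions: RegionConfig = field(default_factory=RegionConfig)
    morphs: MorphConfig = field(default_factory=MorphConfig)
    grid: GridConfig = field(default_factory=GridConfig)
    placement: PlacementConfig = field(default_factory=PlacementConfig)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        kw = {}
        if "seed" in raw:
            kw["seed"] = int(raw["seed"])
        for name, sub in (("tree", TreeConfig), ("morphs", MorphConfig),
                          ("grid", GridConfig), ("placement", PlacementConfig)):
            if name in raw:
                kw[name] = sub(**raw[name])
        if "regions" in raw:
            r = dict(raw["regions"])
            if r.get("planted"):
                r["planted"] = PlantedInvasion(**r["planted"])
            if "states" in r:
                r["states"] = tuple(r["states"])
            kw["regions"] = RegionConfig(**r)
        return cls(**kw)

    def to_jsonable(self) -> dict:
        return asdict(self)


def simulate_yule_tree(n_tips: int, birth_rate: float = 1.0,
                       seed: int = 0) -> PhyloTree:
    """Pure-birth tree conditioned on n_tips; branch lengths in 1/birth_rate units."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    r = random.Random(seed)
    t = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0, num_extant_tips=n_tips, rng=r)
    # the simulator stops at the n-th birth, leaving the newest tips with
    # zero pendant edges; extend all tips by the Exp(n*lambda) waiting time
    # to the (unrealized) next birth, as the Yule process prescribes
    extra = r.expovariate(n_tips * birth_rate)
    for i, leaf in enumerate(t.leaf_node_iter()):
        leaf.taxon.label = f"t{i + 1}"
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    return PhyloTree(t)


@dataclass
class MkTruth:
    node_states: dict[str, str]       # true state per node id (pre-relabel)
    n_changes: int
    invasion_tips: list[str]          # tips relabeled by the planted scenario
    planted_anchor: str | None        # node id of the planted clade's root
    root_state: str


def _evolve_branch(state_i: int, t: float, k: int, q: float,
                   rng: np.random.Generator) -> tuple[int, int]:
    """Gillespie simulation of the ER chain along one branch."""
    changes = 0
    remaining = t
    rate = (k - 1) * q
    if rate == 0:
        return state_i, 0
    while True:
        wait = rng.exponential(1.0 / rate)
        if wait >= remaining:
            return state_i, changes
        remaining -= wait
        others = [s for s in range(k) if s != state_i]
        state_i = others[rng.integers(0, k - 1)]
        changes += 1


def simulate_mk_states(tree: PhyloTree, q_true: float, states,
                       seed: int = 0,
                       planted: PlantedInvasion | None = None,
                       ) -> tuple[RegionCoding, MkTruth]:
    """Evolve regions along the tree; optionally plant a camouflaged clade.

    The root state is uniform (forced to the planted source when the
    scenario asks for an exotic backbone).  When planting, an internal node
    with the requested number of descendant tips whose parent truly carries
    the source state is chosen (seeded) and its tips are relabeled to the
    focal region; the truth table keeps the original states.
    """
    if q_true < 0:
        raise ValueError("q_true must be non-negative")
    states = list(states)
    k = len(states)
    rng = np.random.default_rng(seed)
    if planted and planted.force_root_source:
        root_i = states.index(planted.source)
    else:
        root_i = int(rng.integers(0, k))
    state_i = np.zeros(tree.n_nodes, dtype=int)
    n_changes = 0
    order = list(reversed(range(tree.n_nodes)))  # preorder
    state_i[tree.root_index] = root_i
    for v in order:
        p = tree.parent[v]
        if p < 0:
            continue
        s, ch = _evolve_branch(int(state_i[p]), float(tree.edge_len[v]),
                               k, q_true, rng)
        state_i[v] = s
        n_changes += ch

    assignment = {tree.node_ids[v]: states[state_i[v]]
                  for v in range(tree.n_nodes) if tree.is_leaf[v]}
    invasion_tips: list[str] = []
    anchor_id: str | None = None
    if planted is not None:
        below = tree.tips_below()
        src = states.index(planted.source)
        exact = [v for v in range(tree.n_nodes)
                 if not tree.is_leaf[v] and tree.parent[v] >= 0
                 and len(below[v]) == planted.clade_size
                 and state_i[tree.parent[v]] == src]
        if not exact:  # relax the size requirement, keep the source context
            cands = [v for v in range(tree.n_nodes)
                     if not tree.is_leaf[v] and tree.parent[v] >= 0
                     and state_i[tree.parent[v]] == src]
            if not cands:
                raise RuntimeError(
                    "no internal node with a source-state parent; cannot plant")
            sizes = np.array([abs(len(below[v]) - planted.clade_size)
                              for v in cands])
            exact = [c for c, s in zip(cands, sizes) if s == sizes.min()]
        prefer = [v for v in exact if state_i[v] == src]
        pool = prefer or exact
        chosen = pool[int(rng.integers(0, len(pool)))]
        anchor_id = tree.node_ids[chosen]
        for t in below[chosen]:
            label = tree.node_ids[t]
            assignment[label] = planted.focal
            invasion_tips.append(label)

    coding = RegionCoding(states=states, assignment=assignment)
    truth = MkTruth(
        node_states={tree.node_ids[v]: states[state_i[v]]
                     for v in range(tree.n_nodes)},
        n_changes=n_changes, invasion_tips=invasion_tips,
        planted_anchor=anchor_id, root_state=states[root_i])
    return coding, truth


# characters whose state gates another character's applicability must be
# drawn before their dependents
def _dependency_order(definitions):
    codes = [d.code for d in definitions]
    order = [d for d in definitions if d.na_rule is None]
    order += [d for d in definitions if d.na_rule is not None]
    assert len(order) == len(codes)
    return order


def simulate_character_matrix(cfg: MorphConfig, seed: int = 0,
                              definitions=None) -> CharacterMatrix:
    """Clonal morphs with adjacent-state plasticity.

    Each morph draws a centroid uniformly over valid states (respecting the
    inapplicability rules); each specimen perturbs each applicable character
    to an adjacent valid state with probability `plasticity`, occasionally
    recording the border cell {old, new}.  Controller characters perturb
    too; dependents are re-drawn or blanked to keep the record valid.
    """
    if not (0.0 <= cfg.plasticity <= 1.0):
        raise ValueError("plasticity must lie in [0, 1]")
    definitions = list(definitions) if definitions else canonical_character_set()
    rng = np.random.default_rng(seed)
    order = _dependency_order(definitions)
    dependents = {d.code: d for d in definitions if d.na_rule is not None}
    specimens = []
    groups = ("native", "invasive")
    for m in range(cfg.n_morphs):
        centroid: dict[str, int | None] = {}
        for d in order:
            if d.na_rule is not None:
                other = centroid[d.na_rule.other_code]
                if other is None or other in d.na_rule.states:
                    centroid[d.code] = None
                    continue
            centroid[d.code] = int(rng.choice(sorted(d.allowed_states)))
        for i in range(cfg.specimens_per_morph):
            scores: dict[str, frozenset[int] | None] = {}
            drawn: dict[str, int | None] = {}
            for d in order:
                if d.na_rule is not None:
                    other = drawn[d.na_rule.other_code]
                    if other is None or other in d.na_rule.states:
                        scores[d.code] = NA
                        drawn[d.code] = None
                        continue
                    if centroid[d.code] is None:
                        # applicable here though inapplicable at the centroid
                        val = int(rng.choice(sorted(d.allowed_states)))
                        scores[d.code] = frozenset({val})
                        drawn[d.code] = val
                        continue
                base = centroid[d.code]
                val = base
                border = None
                if rng.random() < cfg.plasticity:
                    allowed = sorted(d.allowed_states)
                    pos = allowed.index(base)
                    steps = [p for p in (pos - 1, pos + 1)
                             if 0 <= p < len(allowed)]
                    val = allowed[steps[int(rng.integers(0, len(steps)))]]
                    if rng.random() < cfg.border_cell_prob:
                        border = frozenset({base, val})
                scores[d.code] = border if border else frozenset({val})
                drawn[d.code] = val
            specimens.append(SpecimenScore(
                specimen_id=f"M{m + 1}_{i + 1}",
                population_code=f"M{m + 1}",
                group=groups[m % 2],
                scores=scores))
    matrix = CharacterMatrix(definitions, specimens)
    matrix.validate()
    return matrix


def simulate_population_grid(cfg: GridConfig, seed: int = 0) -> PopulationGrid:
    """Lognormal background counts plus Gaussian hotspot surges, border mask."""
    rng = np.random.default_rng(seed)
    values = rng.lognormal(cfg.lognormal_mu, cfg.lognormal_sigma,
                           size=(cfg.nrows, cfg.ncols))
    if cfg.n_hotspots > 0:
        rr, cc = np.mgrid[0:cfg.nrows, 0:cfg.ncols]
        for _ in range(cfg.n_hotspots):
            r0 = rng.uniform(0, cfg.nrows)
            c0 = rng.uniform(0, cfg.ncols)
            d2 = (rr - r0) ** 2 + (cc - c0) ** 2
            values += cfg.hotspot_intensity * np.exp(
                -d2 / (2 * cfg.hotspot_sigma ** 2))
    mask = np.zeros_like(values, dtype=bool)
    b = cfg.border
    mask[b:cfg.nrows - b, b:cfg.ncols - b] = True
    if not mask.any():
        raise ValueError("border band leaves no masked cells")
    return PopulationGrid(values=np.round(values, 3), mask=mask,
                          cell_area=cfg.cell_area)


def place_invasions(grid: PopulationGrid, k: int, beta: float,
                    seed: int = 0) -> InvasionSites:
    """k distinct masked cells sampled with probability ∝ (count + 1)^beta."""
    if beta < 0:
        raise ValueError("beta must be non-negative")
    rows, cols = np.nonzero(grid.mask)
    n = rows.size
    if k > n:
        raise ValueError(f"k = {k} exceeds the {n} masked cells")
    rng = np.random.default_rng(seed)
    logw = beta * np.log1p(grid.values[rows, cols])
    # Gumbel top-k trick: distinct weighted sample without replacement
    keys = logw + rng.gumbel(size=n)
    pick = np.argpartition(-keys, k - 1)[:k]
    cells = [(int(rows[i]), int(cols[i])) for i in pick]
    return InvasionSites.from_cells(cells)
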