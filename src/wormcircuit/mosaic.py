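"""Lineage-based extrachromosomal-array transmission model.

Extrachromosomal arrays in *C. elegans* are lost stochastically at mitosis.
If an array is observed to have survived ``D`` cell divisions in a fraction
``f`` of animals, the average per-division transmission probability is
``p = f**(1/D)``, and the probability that the array is retained through any
other ``k`` divisions is ``p**k``.  This module implements that closed-form
model on a lineage tree, the derived census arithmetic for programmed cell
death (PCD), and a Monte Carlo validator that simulates per-division array
loss on the same tree.

The shipped fixture tree (``data/rim_lineage.nwk``) is a reduced encoding of
the hermaphrodite lineage: the zygote P0 divides twice into the common
ancestor of the tracked lineages (labeled ``ABp``), from which the two RIM
sister cells each lie 8 divisions deep, and each other bilateral pair of
*inx-19*-expressing neurons with an undead relative lies ``k`` divisions
deep (counting the minimal subtree spanning both cells of the pair).  Edges
carry the division counts; untracked daughters are elided, so the tree has
pass-through (unary) divisions and a multifurcation at the divergence node.
"""

from __future__ import annotations

import decimal
import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientSampleError, UnknownCellError

__all__ = [
    "LineageTree",
    "TransmissionEstimate",
    "CensusTable",
    "load_rim_fixture_tree",
    "divisions_spanning",
    "estimate_transmission",
    "predict_retention",
    "predict_retention_table",
    "validate_by_simulation",
    "compute_census",
    "round_half_up",
    "RIM_PAIR",
    "FIXTURE_CELL_TYPES",
    "DIVERGENCE_NODE",
]

#: Node at which every tracked pair diverges in the fixture tree.
DIVERGENCE_NODE = "ABp"

#: Terminal labels of the two RIM sister cells (undead RIM-like neurons).
RIM_PAIR = ("RIMLU", "RIMRU")

#: Bilateral pairs covered by the fixture, in the conventional report order.
FIXTURE_CELL_TYPES = ("ASI", "ADL", "ASK", "ADA", "PHB", "PVQ", "RIC")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as report tables conventionally do."""
    q = decimal.Decimal(1).scaleb(-ndigits)
    return float(decimal.Decimal(repr(float(x))).quantize(
        q, rounding=decimal.ROUND_HALF_UP))


class LineageTree:
    """Rooted cell-division tree; every edge is one mitotic division.

    Thin wrapper around a :class:`dendropy.Tree` providing label lookup and
    division-count queries.  Terminal cells are named by taxon; internal
    nodes may carry labels (the root is conventionally ``P0``).
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._by_label: dict[str, dendropy.Node] = {}
        for node in tree.preorder_node_iter():
            label = node.taxon.label if node.taxon is not None else node.label
            if label:
                if label in self._by_label:
                    raise DomainError(f"duplicate node label {label!r}")
                self._by_label[label] = node

    @classmethod
    def from_newick(cls, source: str, *, is_path: bool = True) -> "LineageTree":
        kwargs = dict(schema="newick", suppress_internal_node_taxa=True,
                      preserve_underscores=True)
        if is_path:
            tree = dendropy.Tree.get(path=source, **kwargs)
        else:
            tree = dendropy.Tree.get(data=source, **kwargs)
        return cls(tree)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def labels(self) -> list[str]:
        return sorted(self._by_label)

    @property
    def leaf_labels(self) -> list[str]:
        return [nd.taxon.label for nd in self._tree.leaf_node_iter()
                if nd.taxon is not None]

    def node(self, label: str) -> dendropy.Node:
        try:
            return self._by_label[label]
        except KeyError:
            raise UnknownCellError(f"cell {label!r} not in lineage tree") from None

    def pair_leaves(self, cell_type: str) -> tuple[str, str]:
        """Terminal labels of a bilateral pair (``RIM`` maps to its sisters)."""
        if cell_type == "RIM":
            return RIM_PAIR
        left, right = f"{cell_type}L", f"{cell_type}R"
        for lab in (left, right):
            if lab not in self._by_label:
                raise UnknownCellError(f"cell {lab!r} not in lineage tree")
        return left, right

    def edges(self) -> list[tuple[dendropy.Node, dendropy.Node]]:
        """All (parent, child) division edges in preorder."""
        out = []
        for node in self._tree.preorder_node_iter():
            if node.parent_node is not None:
                out.append((node.parent_node, node))
        return out

    def root_path_edges(self, label: str) -> list[int]:
        """Indices into :meth:`edges` of the divisions from the root to a node."""
        index = {id(child): i for i, (_, child) in enumerate(self.edges())}
        path = []
        node = self.node(label)
        while node.parent_node is not None:
            path.append(index[id(node)])
            node = node.parent_node
        return path[::-1]


def load_rim_fixture_tree() -> LineageTree:
    """Load the reduced RIM-lineage fixture shipped with the package."""
    ref = importlib.resources.files("wormcircuit").joinpath("data/rim_lineage.nwk")
    return LineageTree.from_newick(ref.read_text(), is_path=False)


def divisions_spanning(tree: LineageTree, conditioning_node: str,
                       target_labels: Iterable[str]) -> int:
    """Number of divisions in the minimal subtree joining a node to targets.

    Counts the union of the edges on the paths from ``conditioning_node``
    down to each target.  The conditioning node must be an ancestor of (or
    equal to) every target.
    """
    cond = tree.node(conditioning_node)
    seen: set[int] = set()
    for label in target_labels:
        node = tree.node(label)
        path: set[int] = set()
        while node is not cond:
            path.add(id(node))
            node = node.parent_node
            if node is None:
                raise DomainError(
                    f"{conditioning_node!r} is not an ancestor of {label!r}")
        seen |= path
    return len(seen)


@dataclass(frozen=True)
class TransmissionEstimate:
    """Per-division transmission probability inferred from retention data.

    ``p_reported`` truncates to 4 decimals (the convention used when quoting
    the headline probability); ``p`` carries full precision.
    """

    f: float  # observed retention frequency
    D: int    # divisions the array survived
    p: float  # per-division transmission probability, f ** (1/D)

    @property
    def p_reported(self) -> float:
        return np.floor(self.p * 1e4) / 1e4

    @property
    def p_rounded(self) -> float:
        return round_half_up(self.p, 4)


def estimate_transmission(f: float, D: int) -> TransmissionEstimate:
    """Infer per-division transmission probability ``p = f**(1/D)``."""
    if not 0 < f <= 1:
        if f == 0:
            raise DomainError("retention frequency f=0 has no finite root")
        raise DomainError(f"retention frequency must be in (0, 1], got {f}")
    if D < 1:
        raise DomainError(f"division count must be >= 1, got {D}")
    return TransmissionEstimate(f=float(f), D=int(D), p=float(f) ** (1.0 / D))


def predict_retention(p: float, k: int) -> float:
    """Probability that the array survives ``k`` further divisions: ``p**k``."""
    if not 0 <= p <= 1:
        raise DomainError(f"transmission probability must be in [0, 1], got {p}")
    if k < 0:
        raise DomainError(f"division count must be >= 0, got {k}")
    return float(p) ** int(k)


def predict_retention_table(tree: LineageTree, p: float,
                            conditioning: str = "divergence",
                            cell_types: Sequence[str] = FIXTURE_CELL_TYPES,
                            divergence_node: str = DIVERGENCE_NODE,
                            root: str = "P0") -> pd.DataFrame:
    """Predicted retention fraction for each bilateral cell pair.

    conditioning="divergence": the array is known to be present along the
    whole RIM lineage (a 2-RIM animal), so only the ``k`` divisions of each
    pair's minimal subtree below the divergence node must succeed.

    conditioning="P0": the array is known to be present only in the zygote
    (a 4-RIM animal), so the shared divisions from the root down to the
    divergence node must succeed as well.
    """
    if conditioning not in ("divergence", "P0"):
        raise DomainError(f"conditioning must be 'divergence' or 'P0', "
                          f"got {conditioning!r}")
    shared = (0 if conditioning == "divergence"
              else divisions_spanning(tree, root, [divergence_node]))
    rows = []
    for cell in cell_types:
        k = divisions_spanning(tree, divergence_node, tree.pair_leaves(cell))
        frac = predict_retention(p, k + shared)
        rows.append({"cell_type": cell, "k": k, "shared_divisions": shared,
                     "conditioning": conditioning, "predicted_fraction": frac,
                     "predicted_fraction_2dp": round_half_up(frac, 2)})
    return pd.DataFrame(rows)


def validate_by_simulation(tree: LineageTree, p: float,
                           conditioning: str = "divergence",
                           n: int = 200_000, seed: int = 0,
                           cell_types: Sequence[str] = FIXTURE_CELL_TYPES,
                           rim_pair: Sequence[str] = RIM_PAIR) -> pd.DataFrame:
    """Monte Carlo check of the closed-form retention fractions.

    Simulates per-division array loss for ``n`` animals, conditions on the
    stated event (array retained in both RIM sisters for "divergence";
    always true for "P0", since the root retains by construction) and
    reports conditional retention frequencies with binomial standard errors.
    """
    from .synthetic import simulate_mosaic_population

    if n < 1000:
        raise DomainError(f"n must be >= 1000 for a meaningful check, got {n}")
    if conditioning not in ("divergence", "P0"):
        raise DomainError(f"conditioning must be 'divergence' or 'P0', "
                          f"got {conditioning!r}")
    retained, leaf_labels = simulate_mosaic_population(tree, p, n, seed)
    col = {lab: i for i, lab in enumerate(leaf_labels)}
    if conditioning == "divergence":
        mask = retained[:, col[rim_pair[0]]] & retained[:, col[rim_pair[1]]]
    else:
        mask = np.ones(n, dtype=bool)
    m = int(mask.sum())
    if m == 0:
        raise InsufficientSampleError(
            "conditioning event (array in both RIM sisters) never observed")
    rows = []
    for cell in cell_types:
        left, right = tree.pair_leaves(cell)
        both = retained[mask, col[left]] & retained[mask, col[right]]
        fhat = both.mean()
        se = float(np.sqrt(fhat * (1.0 - fhat) / m))
        rows.append({"cell_type": cell, "conditioning": conditioning,
                     "empirical_fraction": float(fhat), "se": se,
                     "n_conditional": m})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CensusTable:
    """Cell-death census of the hermaphrodite somatic lineage."""

    n_pcd: int                # programmed cell deaths in the lineage
    n_neural_proximate: int   # PCDs in branches making only neurons/glia
    n_neuronal_lineage: int   # PCDs in branches making only neurons
    n_neurons: int            # neurons in the mature animal
    n_cells: int              # somatic cells in the mature animal

    def __post_init__(self):
        for name in ("n_pcd", "n_neural_proximate", "n_neuronal_lineage",
                     "n_neurons", "n_cells"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        if self.n_neural_proximate > self.n_pcd:
            raise DomainError("neural-proximate deaths exceed total deaths")
        if self.n_neuronal_lineage > self.n_pcd:
            raise DomainError("neuronal-lineage deaths exceed total deaths")
        if self.n_neurons > self.n_cells:
            raise DomainError("neuron count exceeds total cell count")


#: Published hermaphrodite census: 131 deaths, 105 neural-proximate,
#: 94 in exclusively neuronal branches, 302 neurons among 959 somatic cells.
HERMAPHRODITE_CENSUS = CensusTable(131, 105, 94, 302, 959)


def compute_census(census: CensusTable) -> dict[str, int]:
    """Integer percentages summarizing where PCD falls in the lineage.

    ``undead_increase_pct`` is the growth of the neuron count if every death
    in an exclusively neuronal branch instead produced a surviving neuron.
    """
    if census.n_pcd == 0 or census.n_cells == 0 or census.n_neurons == 0:
        raise DomainError("census denominators must be positive")
    pct = lambda num, den: int(round_half_up(100.0 * num / den, 0))
    return {
        "neural_proximate_pct": pct(census.n_neural_proximate, census.n_pcd),
        "neuronal_lineage_pct": pct(census.n_neuronal_lineage, census.n_pcd),
        "neuron_pct": pct(census.n_neurons, census.n_cells),
        "undead_increase_pct": pct(census.n_neuronal_lineage, census.n_neurons),
    }
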