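"""Time-calibrated (ultrametric) trees and the quantities the likelihoods consume.

Time runs in Myr before present: t = 0 at the present, increasing into the
past.  A clade's crown age is the age of the most recent common ancestor of
its sampled species; branching times are the ages of the internal nodes of
the reconstructed tree, the data entering every birth-death likelihood.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "UltrametricTree",
    "BranchingTimes",
    "CladeRecord",
    "TreeValidationError",
    "parse_newick",
    "write_newick",
    "branching_times",
    "lineage_count_at",
    "truncation_age",
    "extract_neotropical_clades",
    "load_metadata_csv",
]

#: fixed vocabulary for clade metadata
TAXON_GROUPS = ("plant", "mammal", "bird", "squamate", "amphibian")
ELEVATION_CLASSES = ("lowland", "montane", "highland", "mixed")
REGIONS = (
    "Amazonia",
    "Atlantic Forest",
    "Bahama-Antilles",
    "Caatinga",
    "Central Andes",
    "Cerrado",
    "Chaco",
    "Choco",
    "Guiana Shield",
    "Mesoamerica",
    "Northern Andes",
    "temperate South America",
    "elsewhere",
)


class TreeValidationError(ValueError):
    """Raised when a tree violates the ultrametric-tree contract."""


@dataclass(frozen=True)
class UltrametricTree:
    """A validated, rooted, bifurcating, ultrametric time tree.

    ``node_ages`` maps each dendropy node to its age in Myr before present
    (tips at ~0, root at ``crown_age``).
    """

    tree: dendropy.Tree
    tip_names: tuple[str, ...]
    crown_age: float

    @property
    def n_tips(self) -> int:
        return len(self.tip_names)

    def node_age(self, node: dendropy.Node) -> float:
        return self.crown_age - self._depths()[node]

    def _depths(self) -> dict:
        d = getattr(self, "_depth_cache", None)
        if d is None:
            d = _node_depths(self.tree)
            object.__setattr__(self, "_depth_cache", d)
        return d


@dataclass(frozen=True)
class BranchingTimes:
    """Internal node ages of a reconstructed tree, sorted descending.

    ``ages[0]`` is the crown age; the vector has ``n_tips - 1`` entries.
    """

    ages: np.ndarray
    n_tips: int

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=float)
        object.__setattr__(self, "ages", ages)
        if len(ages) != self.n_tips - 1:
            raise ValueError(
                f"expected {self.n_tips - 1} branching times, got {len(ages)}"
            )
        if len(ages) and (np.any(np.diff(ages) > 0) or np.any(ages <= 0)):
            raise ValueError("branching times must be positive and sorted descending")

    @property
    def crown_age(self) -> float:
        return float(self.ages[0])


@dataclass
class CladeRecord:
    """Per-clade metadata: taxonomy, richness, sampling, elevation, geography."""

    clade_id: str
    taxon_group: str
    n_sampled: int
    n_described: int
    elevation_class: str = "mixed"
    region_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.taxon_group not in TAXON_GROUPS:
            raise ValueError(f"unknown taxon_group {self.taxon_group!r}")
        if self.elevation_class not in ELEVATION_CLASSES:
            raise ValueError(f"unknown elevation_class {self.elevation_class!r}")
        if not (0 < self.n_sampled <= self.n_described):
            raise ValueError("need 0 < n_sampled <= n_described")
        if any(v < 0 for v in self.region_counts.values()):
            raise ValueError("region counts must be >= 0")

    @property
    def sampling_fraction(self) -> float:
        return self.n_sampled / self.n_described


def load_metadata_csv(path) -> list[CladeRecord]:
    """Read clade metadata: clade_id, taxon_group, n_sampled, n_described,
    elevation_class, plus the 13 region-count columns (absent regions -> 0)."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"clade_id", "taxon_group", "n_sampled", "n_described"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata CSV missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        counts = {r: int(row[r]) for r in REGIONS if r in df.columns}
        records.append(
            CladeRecord(
                clade_id=str(row["clade_id"]),
                taxon_group=str(row["taxon_group"]),
                n_sampled=int(row["n_sampled"]),
                n_described=int(row["n_described"]),
                elevation_class=str(row.get("elevation_class", "mixed")),
                region_counts=counts,
            )
        )
    return records


def _node_depths(tree: dendropy.Tree) -> dict:
    """Distance of every node from the root, following edge lengths."""
    depths = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            el = node.edge.length
            if el is None:
                raise TreeValidationError("every non-root edge needs a branch length")
            if el < 0:
                raise TreeValidationError("negative edge length")
            depths[node] = depths[node.parent_node] + el
    return depths


def parse_newick(
    text: str,
    *,
    resolve_polytomies: bool = False,
    ultrametric_rtol: float = 1e-6,
) -> UltrametricTree:
    """Parse a rooted newick string into a validated :class:`UltrametricTree`.

    Polytomies are rejected unless ``resolve_polytomies`` is set, in which
    case they are broken into zero-length bifurcations (with a warning).
    Trees whose root-to-tip spans differ by more than ``ultrametric_rtol``
    relative to the crown age are rejected, naming the worst tip.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeValidationError(f"malformed newick: {exc}") from exc
    return _validate_tree(
        tree, resolve_polytomies=resolve_polytomies, ultrametric_rtol=ultrametric_rtol
    )


def _validate_tree(
    tree: dendropy.Tree,
    *,
    resolve_polytomies: bool = False,
    ultrametric_rtol: float = 1e-6,
) -> UltrametricTree:
    leaves = tree.leaf_nodes()
    if len(leaves) < 2:
        raise TreeValidationError("need at least 2 tips")
    names = []
    for lf in leaves:
        if lf.taxon is None or not lf.taxon.label:
            raise TreeValidationError("every tip needs a label")
        names.append(lf.taxon.label)
    if len(set(names)) != len(names):
        raise TreeValidationError("tip labels must be unique")

    for node in tree.preorder_internal_node_iter():
        nc = len(node.child_nodes())
        if nc > 2:
            if not resolve_polytomies:
                raise TreeValidationError(
                    f"polytomy with {nc} children (set resolve_polytomies=True)"
                )
            warnings.warn("resolving polytomy to zero-length bifurcations")
            tree.resolve_polytomies()
            break
        if nc == 1:
            raise TreeValidationError("unifurcation in tree")

    depths = _node_depths(tree)
    tip_depths = {lf.taxon.label: depths[lf] for lf in tree.leaf_nodes()}
    crown_age = max(tip_depths.values())
    if crown_age <= 0:
        raise TreeValidationError("crown age must be > 0")
    med = float(np.median(list(tip_depths.values())))
    worst = max(tip_depths, key=lambda k: abs(tip_depths[k] - med))
    if abs(tip_depths[worst] - crown_age) > ultrametric_rtol * crown_age or abs(
        tip_depths[worst] - med
    ) > ultrametric_rtol * crown_age:
        raise TreeValidationError(
            f"tree is not ultrametric: tip {worst!r} at depth "
            f"{tip_depths[worst]:.6g} vs crown age {crown_age:.6g}"
        )
    return UltrametricTree(
        tree=tree,
        tip_names=tuple(sorted(tip_depths)),
        crown_age=float(crown_age),
    )


def write_newick(ut: UltrametricTree) -> str:
    """Serialize back to newick (branch lengths at full precision)."""
    s = io.StringIO()
    ut.tree.write(file=s, schema="newick", suppress_rooting=True,
                  real_value_format_specifier=".17g")
    return s.getvalue().strip()


def branching_times(ut: UltrametricTree) -> BranchingTimes:
    """Ages of the internal nodes, sorted descending (crown age first)."""
    depths = ut._depths()
    ages = sorted(
        (ut.crown_age - depths[n] for n in ut.tree.preorder_internal_node_iter()),
        reverse=True,
    )
    return BranchingTimes(ages=np.asarray(ages), n_tips=ut.n_tips)


def lineage_count_at(bt: BranchingTimes, age: float) -> int:
    """Number of reconstructed lineages alive at ``age``.

    Half-open convention: a branching event at exactly ``age`` has *not yet*
    occurred, i.e. the count on (age, crown] is used.  At the crown age the
    two crown lineages are counted; at age 0 the count equals ``n_tips``.
    """
    if not (0 <= age <= bt.crown_age):
        raise ValueError(f"age {age} outside [0, {bt.crown_age}]")
    return 2 + int(np.sum(bt.ages[1:] > age))


def truncation_age(bt: BranchingTimes, min_lineages: int = 10) -> tuple[float, bool]:
    """Oldest age below which the lineage count exceeds ``min_lineages``.

    Returns ``(age, ok)``.  The age is that of the branching event creating
    the ``min_lineages + 1``-th lineage; below it the reconstructed tree has
    more than ``min_lineages`` lineages.  Trees that never exceed the bound
    return ``(0.0, False)`` — such clades cannot support a gridded pulled-rate
    fit and are flagged.
    """
    if min_lineages < 2:
        raise ValueError("min_lineages must be >= 2")
    if bt.n_tips <= min_lineages:
        return 0.0, False
    # descending ages: event k (1-based) brings the count to k + 1
    return float(bt.ages[min_lineages - 1]), True


def extract_neotropical_clades(
    ut: UltrametricTree,
    tip_flags: dict[str, str],
    threshold: float = 0.8,
    min_tips: int = 2,
) -> list[UltrametricTree]:
    """Most-inclusive clades whose fraction of "in"-flagged tips >= threshold.

    Walks the tree root-down and keeps the first (largest) clade on each path
    meeting the fraction and size requirements, so the returned clades are
    maximal and mutually non-nested.  ``tip_flags`` maps every tip label to
    ``"in"`` or ``"out"``.
    """
    if not tip_flags:
        raise ValueError("empty tip flag map")
    missing = set(ut.tip_names) - set(tip_flags)
    if missing:
        raise ValueError(f"tips without flags: {sorted(missing)[:5]}")
    bad = {v for v in tip_flags.values()} - {"in", "out"}
    if bad:
        raise ValueError(f"flags must be 'in'/'out', got {bad}")

    results: list[UltrametricTree] = []

    def walk(node):
        labels = [lf.taxon.label for lf in node.leaf_iter()]
        n_in = sum(tip_flags[x] == "in" for x in labels)
        if len(labels) >= min_tips and n_in / len(labels) >= threshold:
            results.append(_extract_subtree(ut, node))
            return
        for child in node.child_nodes():
            walk(child)

    walk(ut.tree.seed_node)
    return results


def _extract_subtree(ut: UltrametricTree, node) -> UltrametricTree:
    labels = {lf.taxon.label for lf in node.leaf_iter()}
    if len(labels) == ut.n_tips:
        return ut
    clone = ut.tree.extract_tree_with_taxa_labels(labels)
    return _validate_tree(clone)
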