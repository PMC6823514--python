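"""Time-calibrated species trees and male-mutation-bias branch-shortening scenarios.

A :class:`SpeciesTree` is a rooted tree whose branch lengths are either in
millions of years ("myr") or in expected substitutions per site ("subs"); the
unit is explicit metadata, never inferred.  Scenarios encode, per lineage, the
strength of male mutation bias (alpha, the male/female mutation-rate ratio)
and the number of Myr the lineage's focal sequences were X-linked before a
sex-chromosome turnover returned them to autosomal inheritance.  Applying a
scenario shortens branch lengths by the substitution deficit X-linked
sequences accumulate relative to autosomes while the system is in place.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import dendropy

logger = logging.getLogger(__name__)

MYR = "myr"
SUBS = "subs"

#: Average mammalian germ-line substitution rate used to convert Myr branch
#: lengths to expected substitutions (per site per year).
DEFAULT_MU = 2.22e-9

#: Per-10-Myr branch shortening at alpha = 6 in the linear calibration.
DEFAULT_C6 = 0.0227

#: Published per-10-Myr shortening constants, stored verbatim.  The alpha=1.8
#: squamate value and the mammal clade constants are not derivable from a
#: single linear calibration and are carried as configuration data only.
PUBLISHED_SHORTENING_CONSTANTS = {
    ("squamate_10myr", 1.8): 0.00683,
    ("squamate_10myr", 2.4): 0.0091,
    ("squamate_10myr", 4.0): 0.0151,
    ("squamate_10myr", 6.0): 0.0227,
    ("mammal_10myr", 2.9): 0.0113,
    ("mammal_total", 1.8): 0.122,   # alpha 1.6-2.0 clades
    ("mammal_total", 3.1): 0.198,   # alpha 2.9-3.3 clades
    ("mammal_total", 4.0): 0.27,    # alpha 3.9-4.0 clades
    ("mammal_total", 6.0): 0.39,    # alpha > 6 clades
}

#: Floor left on a branch when a scenario would over-shorten it (subs/site).
CLAMP_FLOOR = 1e-6


class TreeError(ValueError):
    pass


class UnitError(TreeError):
    pass


@dataclass
class Node:
    label: str | None = None
    length: float = 0.0
    lineage_tag: str | None = None
    parent: "Node | None" = None
    children: list = field(default_factory=list)
    #: original Myr length, preserved across unit conversion so scenario
    #: time windows can be located on a substitutions-unit tree
    myr_length: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


class SpeciesTree:
    """Rooted tree with explicit branch-length units and lineage tags."""

    def __init__(self, root: Node, unit: str = MYR):
        if unit not in (MYR, SUBS):
            raise UnitError(f"unknown unit {unit!r}")
        self.root = root
        self.unit = unit
        self._validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, unit: str = MYR,
                    lineage_tags: dict[str, str] | None = None) -> "SpeciesTree":
        """Parse a newick string (or path contents) with mandatory branch lengths.

        ``lineage_tags`` maps leaf labels to group names (e.g. ``"snake"``).
        """
        try:
            dt = dendropy.Tree.get(data=newick, schema="newick")
        except Exception as exc:
            raise TreeError(f"malformed newick: {exc}") from None
        root = cls._convert(dt.seed_node)
        tree = cls(root, unit=unit)
        if lineage_tags:
            missing = set(lineage_tags) - {lf.label for lf in tree.leaves()}
            if missing:
                raise TreeError(f"lineage tags for unknown leaves: {sorted(missing)}")
            for leaf in tree.leaves():
                leaf.lineage_tag = lineage_tags.get(leaf.label)
        return tree

    @staticmethod
    def _convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        node = Node(label=label, length=float(dnode.edge.length or 0.0))
        for child in dnode.child_nodes():
            cn = SpeciesTree._convert(child)
            cn.parent = node
            node.children.append(cn)
        return node

    def _validate(self):
        seen = set()
        for leaf in self.leaves():
            if leaf.label is None:
                raise TreeError("unlabeled leaf")
            if leaf.label in seen:
                raise TreeError(f"duplicate leaf label {leaf.label!r}")
            seen.add(leaf.label)
        for node in self.nodes():
            if node.length < 0:
                raise TreeError(f"negative branch length at {node.label!r}")

    # -- traversal ---------------------------------------------------------

    def nodes(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def leaves(self):
        return [n for n in self.nodes() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return sorted(n.label for n in self.leaves())

    def find(self, label: str) -> Node:
        for node in self.nodes():
            if node.label == label:
                return node
        raise TreeError(f"no node labeled {label!r}")

    def path_to_root(self, node: Node) -> list[Node]:
        """Nodes from ``node`` (inclusive) up to the root (inclusive)."""
        path = []
        while node is not None:
            path.append(node)
            node = node.parent
        return path

    def mrca(self, labels) -> Node:
        paths = [set(id(n) for n in self.path_to_root(self.find(lb))) for lb in labels]
        common = set.intersection(*paths)
        node = self.find(labels[0])
        while id(node) not in common or any(id(node) not in p for p in paths):
            node = node.parent
        return node

    def total_length(self) -> float:
        return sum(n.length for n in self.nodes() if n.parent is not None)

    def copy(self) -> "SpeciesTree":
        def rec(node, parent):
            nn = Node(label=node.label, length=node.length,
                      lineage_tag=node.lineage_tag, parent=parent,
                      myr_length=node.myr_length)
            nn.children = [rec(c, nn) for c in node.children]
            return nn
        return SpeciesTree(rec(self.root, None), unit=self.unit)

    # -- newick output ------------------------------------------------------

    def to_newick(self, precision: int = 10) -> str:
        def rec(node):
            if node.is_leaf:
                core = node.label
            else:
                core = "(" + ",".join(rec(c) for c in node.children) + ")"
                if node.label:
                    core += node.label
            if node.parent is None:
                return core
            return f"{core}:{node.length:.{precision}g}"
        return rec(self.root) + ";"

    # -- time geometry -------------------------------------------------------

    def depths_myr(self) -> dict[int, float]:
        """Depth from the root, in Myr, keyed by ``id(node)``.

        Uses ``myr_length`` when present (subs-unit trees converted from Myr),
        else the branch lengths themselves (Myr-unit trees).
        """
        depths = {id(self.root): 0.0}
        stack = [self.root]
        while stack:
            node = stack.pop()
            for child in node.children:
                ln = child.myr_length
                if ln is None:
                    if self.unit != MYR:
                        raise UnitError("tree lacks Myr metadata for time geometry")
                    ln = child.length
                depths[id(child)] = depths[id(node)] + ln
                stack.append(child)
        return depths


# -- calibration and scenarios --------------------------------------------

PAPER_LINEAR = "paper_linear"
MIYATA = "miyata"


@dataclass(frozen=True)
class RateCalibration:
    """Myr-to-substitutions conversion and shortening calibration.

    ``mu`` is substitutions per site per year; ``c6`` the per-10-Myr branch
    shortening at alpha = 6 anchoring the linear calibration.
    """

    mu: float = DEFAULT_MU
    c6: float = DEFAULT_C6
    shortening_mode: str = PAPER_LINEAR

    def __post_init__(self):
        if self.mu <= 0 or self.c6 <= 0:
            raise ValueError("mu and c6 must be positive")
        if self.shortening_mode not in (PAPER_LINEAR, MIYATA):
            raise ValueError(f"unknown shortening mode {self.shortening_mode!r}")

    @property
    def subs_per_myr(self) -> float:
        return self.mu * 1e6


@dataclass(frozen=True)
class LineageSpec:
    alpha: float
    retention_t: float  # Myr the lineage's sequences were X-linked

    def __post_init__(self):
        if self.alpha < 1:
            raise ValueError("alpha must be >= 1")
        if self.retention_t < 0:
            raise ValueError("retention time must be >= 0")


@dataclass(frozen=True)
class LineageScenario:
    """One point of the scenario grid: per-lineage alpha and retention time.

    ``system_age`` is the age of the ancestral sex-chromosome system in Myr
    before present; a lineage with retention time T was X-linked over
    [system_age - T, system_age] Myr before present and autosomal since.
    """

    lineages: dict  # name -> LineageSpec; name = leaf label or lineage_tag
    system_age: float
    scenario_id: str = ""

    def __post_init__(self):
        for name, spec in self.lineages.items():
            if spec.retention_t > self.system_age + 1e-9:
                raise ValueError(
                    f"lineage {name!r}: retention {spec.retention_t} exceeds "
                    f"system age {self.system_age}")


def myr_to_substitutions(tree: SpeciesTree, calib: RateCalibration) -> SpeciesTree:
    """Convert a Myr tree to expected substitutions per site.

    Every branch length is multiplied by mu x 1e6; the original Myr length is
    retained on each node so scenario time windows stay resolvable.
    """
    if tree.unit != MYR:
        raise UnitError("input tree must be in Myr units")
    out = tree.copy()
    for node in out.nodes():
        node.myr_length = node.length
        node.length = node.length * calib.subs_per_myr
    out.unit = SUBS
    return out


def mmb_shortening(alpha: float, duration_myr: float,
                   calib: RateCalibration) -> float:
    """Substitutions/site to subtract for ``duration_myr`` of X-linkage.

    paper_linear: Delta = (c6/6) * alpha * duration/10 — linear in alpha,
    anchored so alpha=6 gives c6 per 10 Myr (reproduces the published
    0.0091 and 0.0151 constants at alpha 2.4 and 4).

    miyata: Delta = mu * duration_yr * (alpha-1)/(3(1+alpha)) — the X-vs-
    autosome rate deficit implied by inverting the X/A relation
    X/A = 2(2+alpha)/(3(1+alpha)); zero at alpha=1 and always smaller than
    the autosomal length accumulated over the same window.
    """
    if alpha < 1:
        raise ValueError("alpha must be >= 1")
    if duration_myr < 0:
        raise ValueError("duration must be >= 0")
    if calib.shortening_mode == PAPER_LINEAR:
        return (calib.c6 / 6.0) * alpha * (duration_myr / 10.0)
    return calib.mu * duration_myr * 1e6 * (alpha - 1.0) / (3.0 * (1.0 + alpha))


@dataclass
class BranchAdjustment:
    branch: str          # leaf label or clade key of the child node
    delta_applied: float
    delta_requested: float
    clamped: bool


def _clade_key(node: Node) -> str:
    if node.is_leaf:
        return node.label
    leaves = sorted(lf.label for lf in _subtree_leaves(node))
    return "|".join(leaves)


def _subtree_leaves(node: Node) -> list[Node]:
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        else:
            stack.extend(n.children)
    return out


def resolve_lineage(tree: SpeciesTree, name: str) -> list[Node]:
    """Leaves selected by ``name``: a leaf label or a lineage tag."""
    tagged = [lf for lf in tree.leaves() if lf.lineage_tag == name]
    if tagged:
        return tagged
    try:
        node = tree.find(name)
    except TreeError:
        raise TreeError(f"scenario lineage {name!r} not found in tree") from None
    return _subtree_leaves(node) if not node.is_leaf else [node]


def apply_scenario(tree: SpeciesTree, scenario: LineageScenario,
                   calib: RateCalibration,
                   clamp_floor: float = CLAMP_FLOOR):
    """Shorten branches of a substitutions-unit tree per an X-linkage scenario.

    For each focal tip the total deficit mmb_shortening(alpha, T) is spread
    along its root-to-tip path in proportion to the Myr each branch overlaps
    the X-linked window [system_age - T, system_age] before present.  A
    branch ancestral to several focal tips is shortened once, using the mean
    alpha of its focal descendants and the mean window overlap (the tree-
    structure averaging applied to internal nodes).

    Returns ``(new_tree, adjustments)`` where adjustments is a list of
    :class:`BranchAdjustment` (one per touched branch).
    """
    if tree.unit != SUBS:
        raise UnitError("apply_scenario needs a substitutions-unit tree")
    out = tree.copy()
    depths = out.depths_myr()

    # per focal tip: (alpha, window) in Myr-before-present along its own path
    tip_info = {}
    for name, spec in scenario.lineages.items():
        for leaf in resolve_lineage(out, name):
            tip_info[id(leaf)] = (leaf, spec)

    # collect, per branch, the focal tips whose path crosses it plus their
    # overlap of the branch's time interval with their X-linked window
    contrib: dict[int, list[tuple[float, float]]] = {}
    node_by_id = {}
    for leaf, spec in tip_info.values():
        if spec.retention_t <= 0:
            continue
        tip_depth = depths[id(leaf)]
        lo = scenario.system_age - spec.retention_t  # window, Myr before present
        hi = scenario.system_age
        for node in out.path_to_root(leaf):
            if node.parent is None:
                continue
            # branch (parent -> node) spans before-present ages
            b_lo = tip_depth - depths[id(node)]
            b_hi = tip_depth - depths[id(node.parent)]
            overlap = max(0.0, min(hi, b_hi) - max(lo, b_lo))
            if overlap > 0:
                contrib.setdefault(id(node), []).append((spec.alpha, overlap))
                node_by_id[id(node)] = node

    adjustments = []
    for nid, entries in contrib.items():
        node = node_by_id[nid]
        alphas = [a for a, _ in entries]
        overlaps = [o for _, o in entries]
        alpha_bar = sum(alphas) / len(alphas)
        duration = sum(overlaps) / len(overlaps)
        delta = mmb_shortening(alpha_bar, duration, calib)
        applied = delta
        clamped = False
        if node.length - delta < clamp_floor:
            applied = max(0.0, node.length - clamp_floor)
            clamped = True
            logger.warning(
                "scenario %s over-shortens branch %s (requested %.4g, branch %.4g); "
                "clamped to floor %.1g", scenario.scenario_id or "<unnamed>",
                _clade_key(node), delta, node.length, clamp_floor)
        node.length -= applied
        adjustments.append(BranchAdjustment(
            branch=_clade_key(node), delta_applied=applied,
            delta_requested=delta, clamped=clamped))
    return out, adjustments


def scenario_grid(focal_lineages, alphas: dict, system_age: float,
                  step: float = 10.0, max_retention: float | None = None,
                  fixed: dict | None = None) -> list[LineageScenario]:
    """Null scenario plus one scenario per retention step.

    ``focal_lineages`` all take the same retention time T within a scenario,
    scanned over T in {0, step, ..., max_retention} (default up to the system
    age).  ``alphas`` maps each focal lineage to its alpha.  ``fixed`` maps
    background lineages to :class:`LineageSpec` held constant across the grid
    (e.g. an always-X-linked clade).
    """
    if max_retention is None:
        max_retention = system_age
    if step <= 0:
        raise ValueError("step must be positive")
    n_steps = round(max_retention / step)
    if abs(n_steps * step - max_retention) > 1e-9:
        raise ValueError("step must divide the scanned retention range")
    grid = []
    for i in range(n_steps + 1):
        t = i * step
        lineages = {name: LineageSpec(alpha=alphas[name], retention_t=t)
                    for name in focal_lineages}
        if fixed:
            lineages.update(fixed)
        grid.append(LineageScenario(lineages=lineages, system_age=system_age,
                                    scenario_id=f"T{int(round(t)):03d}"))
    return grid


def squamate_study_grid(focal_lineages, alphas, fixed=None) -> list[LineageScenario]:
    """The published squamate design: 170-Myr-old system, retention scanned
    to 150 Myr in 10-Myr steps — the null hypothesis plus 15 alternatives
    (16 scenarios)."""
    return scenario_grid(focal_lineages, alphas, system_age=170.0, step=10.0,
                         max_retention=150.0, fixed=fixed)


def mammal_study_grid(focal_lineages, alphas, fixed=None) -> list[LineageScenario]:
    """The published mammal design: 180-Myr-old system, retention scanned to
    170 Myr in 10-Myr steps — the null plus 17 alternatives (18 scenarios)."""
    return scenario_grid(focal_lineages, alphas, system_age=180.0, step=10.0,
                         max_retention=170.0, fixed=fixed)


def cumulative_length(tree: SpeciesTree, leaf: str, ancestor: Node | str) -> float:
    """Sum of branch lengths from ``ancestor`` (exclusive) to ``leaf`` (inclusive)."""
    leaf_node = tree.find(leaf) if isinstance(leaf, str) else leaf
    anc = tree.find(ancestor) if isinstance(ancestor, str) else ancestor
    total = 0.0
    node = leaf_node
    while node is not anc:
        if node.parent is None:
            raise TreeError(
                f"{getattr(anc, 'label', anc)!r} is not an ancestor of {leaf!r}")
        total += node.length
        node = node.parent
    return total


def grid_to_tsv(grid: list[LineageScenario]) -> str:
    """Scenario grid as TSV (scenario_id, lineage, alpha, retention_t)."""
    buf = io.StringIO()
    buf.write("scenario_id\tlineage\talpha\tretention_t\n")
    for sc in grid:
        for name, spec in sorted(sc.lineages.items()):
            buf.write(f"{sc.scenario_id}\t{name}\t{spec.alpha:g}\t{spec.retention_t:g}\n")
    return buf.getvalue()
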