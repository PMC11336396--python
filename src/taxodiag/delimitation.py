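"""Tree-based delimitation of higher taxa and alphanumeric coding.

Candidate taxa are clades on a support-annotated rooted tree satisfying
four criteria: monophyly, bootstrap support above a threshold (>95 by
default), phylogenetic breadth comparable to reference taxa of the same
rank, and minimality of the number of new taxa. Because clades of a tree
are laminar (nested or disjoint), accepting the qualifying clade closest
to the root on every path yields the unique minimal partition of the
coverable leaves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd


class TreeError(ValueError):
    """Unparseable or inconsistent tree input."""


@dataclass
class CladeCandidate:
    leafset: frozenset[str]
    support: float | None
    breadth: float           # max within-clade patristic distance
    depth: float             # max node-to-tip path length
    rank: str | None = None
    code: str | None = None
    swept_in: frozenset[str] = frozenset()
    node: object = None

    def to_dict(self) -> dict:
        return {
            "code": self.code,
            "rank": self.rank,
            "support": self.support,
            "breadth": self.breadth,
            "n_leaves": len(self.leafset),
            "leaves": sorted(self.leafset),
            "swept_in": sorted(self.swept_in),
        }


class PhyloTree:
    """Rooted tree with per-node support in [0, 100] and branch lengths."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self._leaf_by_label: dict[str, dendropy.Node] = {}
        for leaf in tree.leaf_node_iter():
            label = leaf.taxon.label if leaf.taxon else leaf.label
            if label in self._leaf_by_label:
                raise TreeError(f"duplicate leaf label {label!r}")
            self._leaf_by_label[label] = leaf
        self._annotate()

    # -- construction -------------------------------------------------
    @classmethod
    def read(cls, source: str | Path, support_dialect: str = "label",
             dialect_field: int = 1) -> "PhyloTree":
        """Parse Newick; internal-node labels carry support values.

        ``support_dialect="label"`` reads a plain number; ``"slash"``
        reads the *dialect_field*-th ``/``-separated component (e.g.
        "aLRT/UFboot"). Supports on a 0-1 scale are rescaled to 0-100.
        """
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        try:
            tree = dendropy.Tree.get(data=text, schema="newick",
                                     suppress_internal_node_taxa=True)
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeError(f"unparseable Newick: {exc}") from exc
        supports = []
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                continue
            node.support = _parse_support(node.label, support_dialect,
                                          dialect_field)
            if node.support is not None:
                supports.append(node.support)
        if supports and max(supports) <= 1.0:
            for node in tree.preorder_node_iter():
                if not node.is_leaf() and node.support is not None:
                    node.support *= 100.0
        return cls(tree)

    def write(self) -> str:
        for node in self.tree.preorder_node_iter():
            if not node.is_leaf():
                sup = getattr(node, "support", None)
                node.label = (f"{sup:g}" if sup is not None else None)
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    # -- annotation ---------------------------------------------------
    def _annotate(self) -> None:
        """Cache per-node leafsets, depths and breadths in one postorder pass."""
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                label = node.taxon.label if node.taxon else node.label
                node.leafset = frozenset([label])
                node.max_tip_depth = 0.0
                node.breadth = 0.0
            else:
                node.leafset = frozenset().union(
                    *(c.leafset for c in node.child_nodes()))
                arm = sorted(
                    ((c.max_tip_depth + (c.edge.length or 0.0))
                     for c in node.child_nodes()), reverse=True)
                node.max_tip_depth = arm[0]
                cross = arm[0] + arm[1] if len(arm) > 1 else 0.0
                node.breadth = max(cross,
                                   max(c.breadth for c in node.child_nodes()))

    # -- queries ------------------------------------------------------
    @property
    def leaves(self) -> list[str]:
        return sorted(self._leaf_by_label)

    def supports(self) -> list[float]:
        return [n.support for n in self.tree.preorder_node_iter()
                if not n.is_leaf() and getattr(n, "support", None) is not None]

    def mrca(self, accessions: Iterable[str]) -> dendropy.Node:
        accs = list(accessions)
        for a in accs:
            if a not in self._leaf_by_label:
                raise KeyError(f"accession {a!r} is not a leaf of the tree")
        node = self._leaf_by_label[accs[0]]
        query = frozenset(accs)
        while not query <= node.leafset:
            node = node.parent_node
        return node

    def candidate_from_node(self, node: dendropy.Node,
                            query: frozenset[str] = frozenset(),
                            rank: str | None = None) -> CladeCandidate:
        return CladeCandidate(
            leafset=node.leafset,
            support=getattr(node, "support", None),
            breadth=node.breadth,
            depth=node.max_tip_depth,
            rank=rank,
            swept_in=node.leafset - query if query else frozenset(),
            node=node,
        )


def _parse_support(label: str | None, dialect: str, field_idx: int) -> float | None:
    if not label:
        return None
    if dialect == "slash":
        parts = label.split("/")
        if field_idx >= len(parts):
            return None
        label = parts[field_idx]
    try:
        return float(label)
    except ValueError:
        return None


def read_tree(source: str | Path, support_dialect: str = "label",
              dialect_field: int = 1) -> PhyloTree:
    return PhyloTree.read(source, support_dialect, dialect_field)


def least_inclusive_clade(tree: PhyloTree,
                          accessions: Iterable[str],
                          rank: str | None = None) -> CladeCandidate:
    """The smallest clade containing all the named accessions.

    This is the convention used to delimit described taxa: the MRCA
    subtree of the anchoring accessions; leaves under the MRCA that were
    not named are reported as swept-in members.
    """
    query = frozenset(accessions)
    node = tree.mrca(query)
    return tree.candidate_from_node(node, query, rank)


def is_monophyletic(tree: PhyloTree,
                    leafset: Iterable[str]) -> tuple[bool, list[str]]:
    """True iff the MRCA of the leafset contains no other leaves."""
    query = frozenset(leafset)
    if not query:
        raise ValueError("empty leafset")
    node = tree.mrca(query)
    intruders = sorted(node.leafset - query)
    return not intruders, intruders


@dataclass
class DelimitationConfig:
    support_min: float = 95.0
    breadth_band: tuple[float, float] = (0.5, 2.0)
    missing_support_passes: bool = False
    allow_singletons: bool = True


@dataclass
class DelimitationResult:
    candidates: list[CladeCandidate]
    unassigned: list[str]
    reference_breadths: dict[str, float]
    breadth_limits: tuple[float, float]


def propose_taxa(tree: PhyloTree, rank: str,
                 reference_taxa: Mapping[str, Iterable[str]],
                 config: DelimitationConfig | None = None) -> DelimitationResult:
    """Partition unlabelled leaves into the fewest qualifying clades.

    A clade qualifies when it contains only unlabelled leaves, its
    support exceeds ``support_min`` (missing support fails unless
    configured otherwise; single leaves are trivially supported), and its
    breadth falls within ``breadth_band`` scaled by the range of the
    reference taxa's breadths. Acceptance is greedy from the root down,
    which is provably minimal because clades are nested or disjoint.
    Leaves in no qualifying clade are returned unassigned.
    """
    cfg = config or DelimitationConfig()
    ref_breadths = {}
    for name, accs in reference_taxa.items():
        ref_breadths[name] = tree.mrca(frozenset(accs)).breadth
    if not ref_breadths:
        raise ValueError("at least one reference taxon is required")
    lo = cfg.breadth_band[0] * min(ref_breadths.values())
    hi = cfg.breadth_band[1] * max(ref_breadths.values())
    labelled = frozenset().union(*(frozenset(v) for v in reference_taxa.values()))

    def qualifies(node) -> bool:
        if node.leafset & labelled:
            return False
        if node.is_leaf():
            if not cfg.allow_singletons:
                return False
        else:
            sup = getattr(node, "support", None)
            if sup is None:
                if not cfg.missing_support_passes:
                    return False
            elif sup <= cfg.support_min:
                return False
        return lo <= node.breadth <= hi

    candidates: list[CladeCandidate] = []
    unassigned: list[str] = []

    def visit(node) -> None:
        if not (node.leafset - labelled):
            return
        if qualifies(node):
            candidates.append(tree.candidate_from_node(node, rank=rank))
            return
        if node.is_leaf():
            unassigned.append(next(iter(node.leafset)))
            return
        for child in node.child_nodes():
            visit(child)

    visit(tree.tree.seed_node)
    return DelimitationResult(candidates, sorted(unassigned), ref_breadths,
                              (lo, hi))


DEFAULT_PREFIXES = {"species": "SP", "genus": "GEN", "family": "FAM",
                    "order": "ORD"}


def assign_codes(candidates: Sequence[CladeCandidate], rank: str,
                 scheme: Mapping[str, str] | None = None,
                 width: int = 2) -> list[CladeCandidate]:
    """Provisional alphanumeric codes for candidate taxa.

    Candidates are ordered by their smallest leaf accession so reruns on
    identical input reproduce identical codes; labels are
    ``<prefix><zero-padded index>`` (e.g. GEN01), with the prefix taken
    per rank from *scheme* (a bare "GS"-style prefix works by passing
    ``{rank: "GS"}``).
    """
    prefixes = dict(DEFAULT_PREFIXES)
    if scheme:
        prefixes.update(scheme)
    prefix = prefixes.get(rank, rank[:3].upper())
    ordered = sorted(candidates, key=lambda c: min(c.leafset))
    for i, cand in enumerate(ordered, start=1):
        cand.code = f"{prefix}{i:0{width}d}"
        cand.rank = rank
    return ordered


def candidates_table(candidates: Sequence[CladeCandidate]) -> pd.DataFrame:
    rows = [{
        "code": c.code,
        "rank": c.rank,
        "support": c.support,
        "n_leaves": len(c.leafset),
        "breadth": c.breadth,
        "leaves": ",".join(sorted(c.leafset)),
    } for c in candidates]
    return pd.DataFrame(rows, columns=["code", "rank", "support", "n_leaves",
                                       "breadth", "leaves"])


def candidates_json(candidates: Sequence[CladeCandidate]) -> str:
    return json.dumps([c.to_dict() for c in candidates], indent=2)
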