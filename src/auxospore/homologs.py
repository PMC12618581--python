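"""Identification of marker homologs in environmental sequence collections.

Profile-HMM hit tables (HMMER3 per-sequence tblout) are parsed and
filtered on bit score, E-value and source taxon; phylogenetic trees
carrying reference, outgroup and query tips are midpoint rooted and the
query sequences falling inside the reference marker clade are selected.

Trees are handled with dendropy; roles are attached to tips either via an
explicit mapping or via ``REF_`` / ``OUT_`` / ``Q_`` label prefixes.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import dendropy

ROLES = ("reference", "outgroup", "query")
ROLE_PREFIXES = {"REF_": "reference", "OUT_": "outgroup", "Q_": "query"}


@dataclass(frozen=True)
class HmmHit:
    """One profile-HMM hit: environmental target vs marker model."""

    target_id: str
    marker_label: str
    score: float
    evalue: float
    source_taxon: str | None = None


def parse_tblout(source, *, source_taxon: str | None = None) -> list[HmmHit]:
    """Parse a HMMER3 per-sequence tabular output (``--tblout``).

    Comment lines (leading ``#``) are skipped. Fields used: 1 (target
    name), 3 (query/marker name), 5 (full-sequence E-value), 6
    (full-sequence bit score). Domain tables are not supported.
    """
    if isinstance(source, str) and "\n" in source:
        lines: Iterable[str] = io.StringIO(source)
    elif isinstance(source, str):
        lines = open(source)
    else:
        lines = source
    hits: list[HmmHit] = []
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise ValueError(f"truncated tblout line {lineno}: {line!r}")
        try:
            evalue = float(fields[4])
            score = float(fields[5])
        except ValueError as exc:
            raise ValueError(
                f"non-numeric score/E-value on tblout line {lineno}: {line!r}"
            ) from exc
        if evalue < 0 or not math.isfinite(score):
            raise ValueError(f"invalid score/E-value on tblout line {lineno}")
        hits.append(
            HmmHit(
                target_id=fields[0],
                marker_label=fields[2],
                evalue=evalue,
                score=score,
                source_taxon=source_taxon,
            )
        )
    return hits


def write_tblout(hits: Iterable[HmmHit]) -> str:
    """Serialize hits in the minimal HMMER3 tblout dialect parsed above."""
    out = [
        "#                                  --- full sequence ----",
        "# target name  accession  query name  accession  E-value  score  bias",
    ]
    for h in hits:
        out.append(
            f"{h.target_id} - {h.marker_label} - {h.evalue:.3g} {h.score:.1f} 0.0"
        )
    return "\n".join(out) + "\n"


def filter_hits(
    hits: Iterable[HmmHit],
    min_score: float = 50.0,
    max_evalue: float = 1e-10,
    allowed_taxa: set[str] | None = None,
) -> list[HmmHit]:
    """Keep hits with score >= min_score AND evalue < max_evalue.

    The score bound is inclusive, the E-value bound strict. When
    ``allowed_taxa`` is given, the source taxon must be in it (hits
    without a source taxon are dropped in that case).
    """
    kept = []
    for h in hits:
        if h.score < min_score or not (h.evalue < max_evalue):
            continue
        if allowed_taxa is not None and h.source_taxon not in allowed_taxa:
            continue
        kept.append(h)
    return kept


# ---------------------------------------------------------------------------
# trees


def read_tree(newick: str) -> dendropy.Tree:
    """Read a newick string (support values as internal node labels)."""
    return dendropy.Tree.get(
        data=newick, schema="newick", suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )


def tip_roles(
    tree: dendropy.Tree, roles: Mapping[str, str] | None = None
) -> dict[str, str]:
    """Resolve the role of every tip, from a mapping or label prefixes."""
    out: dict[str, str] = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        if roles is not None:
            if label not in roles:
                raise ValueError(f"tip {label!r} has no role annotation")
            role = roles[label]
        else:
            role = next(
                (r for pre, r in ROLE_PREFIXES.items()
                 if label.replace(" ", "_").startswith(pre)),
                None,
            )
            if role is None:
                raise ValueError(f"cannot infer role from tip label {label!r}")
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r} for tip {label!r}")
        out[label] = role
    return out


def _path_edges(leaf_a, leaf_b):
    """Edges along the tip-to-tip path, ordered from leaf_a, with orientation.

    Each element is (edge, near_is_head): ``near_is_head`` is True when the
    edge's head node (child side) is the end closer to leaf_a.
    """
    anc_a = []
    node = leaf_a
    while node is not None:
        anc_a.append(node)
        node = node.parent_node
    anc_a_set = set(id(n) for n in anc_a)
    up_b = []
    node = leaf_b
    while id(node) not in anc_a_set:
        up_b.append(node)
        node = node.parent_node
    lca = node
    up_a = []
    node = leaf_a
    while node is not lca:
        up_a.append(node)
        node = node.parent_node
    path = [(n.edge, True) for n in up_a]           # climbing: near end = head
    path += [(n.edge, False) for n in reversed(up_b)]  # descending: near end = tail
    return path


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root a tree at the midpoint of its longest tip-to-tip path.

    The deepest pair of tips is found exhaustively; the root is placed on
    the edge where the half-diameter point falls, so that path lengths
    between tips are preserved. Returns a new tree.
    """
    if len(tree.leaf_nodes()) < 2:
        raise ValueError("midpoint rooting requires >= 2 tips")
    lengths = [e.length or 0.0 for e in tree.edges() if e.head_node is not tree.seed_node]
    if all(l == 0.0 for l in lengths):
        raise ValueError("all branch lengths are zero; midpoint undefined")
    rooted = tree.clone(depth=1)
    rooted.seed_node.edge.length = None  # a dangling root edge is meaningless

    pdm = rooted.phylogenetic_distance_matrix()
    taxa = list(rooted.taxon_namespace)
    best, diameter = None, -1.0
    for i, ta in enumerate(taxa):
        for tb in taxa[i + 1:]:
            d = pdm.distance(ta, tb)
            if d > diameter:
                diameter, best = d, (ta, tb)
    leaves = {lf.taxon.label: lf for lf in rooted.leaf_node_iter()}
    leaf_a, leaf_b = leaves[best[0].label], leaves[best[1].label]

    half = diameter / 2.0
    cum = 0.0
    for edge, near_is_head in _path_edges(leaf_a, leaf_b):
        elen = edge.length or 0.0
        if cum + elen >= half - 1e-12:
            offset = half - cum  # distance from the near end of this edge
            if near_is_head:
                length_head, length_tail = offset, elen - offset
            else:
                length_tail, length_head = offset, elen - offset
            rooted.reroot_at_edge(
                edge, length1=max(length_tail, 0.0), length2=max(length_head, 0.0),
                update_bipartitions=False,
            )
            rooted.is_rooted = True
            return rooted
        cum += elen
    raise AssertionError("midpoint not found on the diameter path")


@dataclass
class CladeSelection:
    """Outcome of the phylogenetic selection rule."""

    selected_queries: set[str]
    clades: list[dict]   # per selected clade: tips, n_reference, support


def select_marker_clade(
    tree: dendropy.Tree,
    roles: Mapping[str, str] | None = None,
    min_support: float = 0.0,
    *,
    midpoint: bool = True,
) -> CladeSelection:
    """Select query tips clustering within the reference marker clade.

    After (optional) midpoint rooting, the maximal clades containing at
    least one reference tip and no outgroup tip — and, when
    ``min_support`` > 0, whose subtending branch support is at least
    ``min_support`` (clades without a support value are not penalised) —
    are selected. Query tips inside their union are returned, except that
    with a support cutoff a query is dropped when any branch on its path
    from the selected clade's root has support below the cutoff (an
    unreliably attached query is not trusted even inside a good clade).
    """
    role_map = tip_roles(tree, roles)
    if "reference" not in role_map.values():
        raise ValueError("tree contains no reference tips")
    work = midpoint_root(tree) if midpoint else tree.clone(depth=1)

    selected: set[str] = set()
    clades: list[dict] = []

    def clade_tips(node) -> list[str]:
        return [lf.taxon.label for lf in node.leaf_iter()]

    def support_of(node) -> float | None:
        if node.label is not None:
            try:
                return float(node.label)
            except ValueError:
                return None
        return None

    def admissible(node) -> bool:
        tips = clade_tips(node)
        tip_roles_here = [role_map[t] for t in tips]
        if "outgroup" in tip_roles_here or "reference" not in tip_roles_here:
            return False
        if min_support > 0 and not node.is_leaf():
            sup = support_of(node)
            if sup is not None and sup < min_support:
                return False
        return True

    def collect_queries(node):
        """Query tips of an admissible clade, pruned at low-support branches."""
        if node.is_leaf():
            if role_map[node.taxon.label] == "query":
                selected.add(node.taxon.label)
            return
        for child in node.child_nodes():
            if min_support > 0 and not child.is_leaf():
                sup = support_of(child)
                if sup is not None and sup < min_support:
                    continue
            collect_queries(child)

    def walk(node):
        if admissible(node):
            tips = clade_tips(node)
            clades.append({
                "tips": tips,
                "n_reference": sum(role_map[t] == "reference" for t in tips),
                "support": support_of(node) if not node.is_leaf() else None,
            })
            collect_queries(node)
            return
        for child in node.child_nodes():
            walk(child)

    walk(work.seed_node)
    return CladeSelection(selected_queries=selected, clades=clades)


def selection_report(selection: CladeSelection, marker_label: str) -> list[dict]:
    """Flatten a clade selection into report rows (target, marker, clade, support)."""
    rows = []
    for i, clade in enumerate(selection.clades):
        for tip in clade["tips"]:
            rows.append({
                "target_id": tip,
                "marker_label": marker_label,
                "clade_id": f"clade_{i}",
                "support": clade["support"],
            })
    return rows
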