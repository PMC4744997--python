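"""Hierarchical composite niche codes, occupancy and vacancy accounting.

Per-dimension terminal-node groups are stacked in a fixed hierarchy
order into tuples ("niche codes"); the cross-product of group counts
defines the potential niche space, most of which is typically vacant.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

DEFAULT_HIERARCHY = ("habitat", "life_history", "trophic", "defence", "metabolic")


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class NicheClassification:
    """Summary of the discrete scheme for one assemblage."""

    hierarchy_order: tuple
    per_dimension_groups: dict        # dimension -> {species: group}
    codes: dict                       # species -> tuple of group labels
    leaf_counts: tuple                # per dimension, hierarchy order
    potential: int
    occupied: dict                    # code tuple -> sorted species list
    vacant_count: int

    @property
    def multi_occupied(self) -> dict:
        return {c: sp for c, sp in self.occupied.items() if len(sp) > 1}

    def to_json(self) -> str:
        payload = {
            "hierarchy_order": list(self.hierarchy_order),
            "leaf_counts": list(self.leaf_counts),
            "potential": self.potential,
            "occupied_count": len(self.occupied),
            "vacant_count": self.vacant_count,
            "occupied": {
                ",".join(map(str, code)): species
                for code, species in sorted(self.occupied.items())
            },
            "multi_occupied": {
                ",".join(map(str, code)): species
                for code, species in sorted(self.multi_occupied.items())
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def assign_niche_codes(groups_per_dimension: dict, hierarchy_order=None) -> dict:
    """Combine per-dimension group labels into one code tuple per species.

    ``groups_per_dimension`` maps dimension -> {species: group label}.
    Every dimension must cover every species.
    """
    if hierarchy_order is None:
        hierarchy_order = [d for d in DEFAULT_HIERARCHY if d in groups_per_dimension]
        hierarchy_order += [d for d in groups_per_dimension if d not in hierarchy_order]
    hierarchy_order = tuple(hierarchy_order)
    if not hierarchy_order:
        raise ClassificationError("empty hierarchy")
    for dim in hierarchy_order:
        if dim not in groups_per_dimension:
            raise ClassificationError(f"no group map for dimension {dim!r}")
    species = sorted(groups_per_dimension[hierarchy_order[0]])
    codes = {}
    for sp in species:
        code = []
        for dim in hierarchy_order:
            try:
                code.append(int(groups_per_dimension[dim][sp]))
            except KeyError:
                raise ClassificationError(
                    f"species {sp!r} missing from dimension {dim!r}"
                ) from None
        codes[sp] = tuple(code)
    for dim in hierarchy_order:
        extra = set(groups_per_dimension[dim]) - set(species)
        if extra:
            raise ClassificationError(
                f"dimension {dim!r} has species absent elsewhere: {sorted(extra)}"
            )
    return codes


def enumerate_niche_space(leaf_counts):
    """Potential niche count and lexicographic iterator over all codes.

    Returns ``(potential, iterator)`` where potential is the product of
    the per-dimension group counts.
    """
    leaf_counts = tuple(int(c) for c in leaf_counts)
    if any(c < 1 for c in leaf_counts):
        raise ClassificationError(f"group counts must be >= 1, got {leaf_counts}")
    potential = 1
    for c in leaf_counts:
        potential *= c
    codes = itertools.product(*(range(1, c + 1) for c in leaf_counts))
    return potential, codes


def occupancy(codes: dict, leaf_counts, hierarchy_order=None,
              per_dimension_groups=None) -> NicheClassification:
    """Occupied/vacant accounting over the cross-product niche space."""
    leaf_counts = tuple(int(c) for c in leaf_counts)
    potential, _ = enumerate_niche_space(leaf_counts)
    occupied: dict = {}
    for sp in sorted(codes):
        code = tuple(int(g) for g in codes[sp])
        if len(code) != len(leaf_counts):
            raise ClassificationError(
                f"code length {len(code)} != {len(leaf_counts)} dimensions"
            )
        for g, c in zip(code, leaf_counts):
            if not 1 <= g <= c:
                raise ClassificationError(f"group {g} out of range 1..{c} for {sp!r}")
        occupied.setdefault(code, []).append(sp)
    if hierarchy_order is None:
        hierarchy_order = tuple(f"dim{k + 1}" for k in range(len(leaf_counts)))
    return NicheClassification(
        hierarchy_order=tuple(hierarchy_order),
        per_dimension_groups=per_dimension_groups or {},
        codes={sp: tuple(codes[sp]) for sp in codes},
        leaf_counts=leaf_counts,
        potential=potential,
        occupied=occupied,
        vacant_count=potential - len(occupied),
    )


def build_composite_tree(leaf_counts, hierarchy_order, occupied=None,
                         include_vacant: bool = True):
    """Nested composite dendrogram over the cross-product niche space.

    Returns the root of a nested dict tree: internal levels follow
    ``hierarchy_order``; each tip is a full code annotated with its
    occupying species (or marked vacant).
    """
    hierarchy_order = tuple(hierarchy_order)
    if not hierarchy_order:
        raise ClassificationError("empty hierarchy")
    if len(hierarchy_order) != len(leaf_counts):
        raise ClassificationError("hierarchy_order and leaf_counts disagree")
    occupied = occupied or {}

    def build(level, prefix):
        if level == len(leaf_counts):
            species = occupied.get(prefix, [])
            if not species and not include_vacant:
                return None
            return {"code": prefix, "species": sorted(species),
                    "vacant": not species}
        children = []
        for g in range(1, leaf_counts[level] + 1):
            child = build(level + 1, prefix + (g,))
            if child is not None:
                children.append((g, child))
        if not children:
            return None
        return {"dimension": hierarchy_order[level],
                "children": dict(children)}

    root = build(0, ())
    return root if root is not None else {"dimension": hierarchy_order[0], "children": {}}


def composite_tips(tree):
    """Depth-first tips of a composite tree (code, species list, vacant)."""
    if "code" in tree:
        return [(tree["code"], tree["species"], tree["vacant"])]
    tips = []
    for g in sorted(tree["children"]):
        tips.extend(composite_tips(tree["children"][g]))
    return tips


def _tip_label(code, species, vacant, hierarchy_order):
    prefix = ".".join(
        f"{dim[0].upper()}{g}" for dim, g in zip(hierarchy_order, code)
    )
    payload = "VACANT" if vacant else ",".join(species)
    return f"{prefix}|{payload}"


def composite_to_newick(tree, hierarchy_order) -> str:
    """Labeled newick export; vacant tips keep a ``|VACANT`` payload."""

    def render(node):
        if "code" in node:
            label = _tip_label(node["code"], node["species"], node["vacant"],
                              hierarchy_order)
            return label.replace(" ", "_").replace(",", "+").replace("(", "").replace(")", "")
        parts = [render(node["children"][g]) for g in sorted(node["children"])]
        if len(parts) == 1:
            return parts[0]
        return "(" + ",".join(parts) + ")"

    return render(tree) + ";"


def composite_outline(tree, hierarchy_order, depth: int = 0) -> str:
    """Indented text rendering of the composite dendrogram."""
    if "code" in tree:
        return "  " * depth + _tip_label(
            tree["code"], tree["species"], tree["vacant"], hierarchy_order
        )
    lines = []
    if depth == 0:
        lines.append(f"composite niche tree ({' > '.join(hierarchy_order)})")
    for g in sorted(tree["children"]):
        child = tree["children"][g]
        if "code" not in child:
            lines.append("  " * (depth + 1) + f"{tree['dimension']}={g}")
            lines.append(composite_outline(child, hierarchy_order, depth + 1))
        else:
            lines.append(composite_outline(child, hierarchy_order, depth + 1))
    return "\n".join(lines)
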