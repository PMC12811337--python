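"""Exhaustive Venn-region decomposition of named sets.

A region is identified by the exact subset of input sets an element belongs
to; the 2^k - 1 non-empty membership patterns partition the union.
"""

from __future__ import annotations

from typing import Hashable, Mapping


def venn_regions(
    sets: Mapping[str, set[Hashable]],
) -> dict[frozenset[str], set[Hashable]]:
    """Map each non-empty membership pattern to its member elements."""
    regions: dict[frozenset[str], set] = {}
    universe = set().union(*sets.values()) if sets else set()
    for element in universe:
        pattern = frozenset(name for name, s in sets.items() if element in s)
        regions.setdefault(pattern, set()).add(element)
    return regions


def venn_region_counts(sets: Mapping[str, set[Hashable]]) -> dict[frozenset[str], int]:
    return {pattern: len(members) for pattern, members in venn_regions(sets).items()}
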