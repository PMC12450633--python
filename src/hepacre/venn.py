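"""Exclusive-region (Venn) counting over named sets."""

from __future__ import annotations

from collections.abc import Mapping
from itertools import combinations


def venn_counts(named_sets: Mapping[str, set]) -> dict[str, int]:
    """Exclusive region counts for every non-empty combination of sets.

    Keys are the member set names joined by "&" in the mapping's order
    (e.g. "A", "A&B"). Regions partition the union, so the counts sum to
    the union size (inclusion-exclusion consistency).
    """
    names = list(named_sets)
    sets = {k: set(v) for k, v in named_sets.items()}
    out: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[c] for c in combo)) if combo else set()
            for other in names:
                if other not in combo:
                    inside -= sets[other]
            out["&".join(combo)] = len(inside)
    return out
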