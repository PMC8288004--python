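"""Consensus partition of scanned loci into adaptive / neutral / single-method.

A locus counts once for a method if it is significant under any of that
method's variables.  Putatively adaptive loci are those flagged by at least
``min_methods`` (default 2) methods; putatively neutral loci are flagged by
none; the remainder (exactly one method) are excluded from both downstream
data sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

from .scans import ScanResult

__all__ = ["ConsensusPartition", "partition_loci"]


@dataclass
class ConsensusPartition:
    adaptive: list[str]
    neutral: list[str]
    single_method: list[str]
    per_method: dict[str, set[str]] = field(default_factory=dict)
    venn_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return len(self.adaptive) + len(self.neutral) + len(self.single_method)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "adaptive": self.adaptive,
                "neutral": self.neutral,
                "single_method": self.single_method,
                "per_method": {m: sorted(s) for m, s in self.per_method.items()},
                "venn_counts": self.venn_counts,
            }, fh, indent=2)


def partition_loci(scan_results: list[ScanResult],
                   min_methods: int = 2) -> ConsensusPartition:
    """Partition the common locus set by how many methods flagged each locus."""
    if len(scan_results) < 2:
        raise ValueError("need at least 2 scan results")
    base = scan_results[0].locus_ids
    base_set = set(base)
    for r in scan_results[1:]:
        if set(r.locus_ids) != base_set:
            raise ValueError(f"scan {r.method!r} covers a different locus set")
    per_method = {r.method: r.significant_ids for r in scan_results}
    if len(per_method) != len(scan_results):
        raise ValueError("duplicate method labels")

    hits = {lid: sum(lid in s for s in per_method.values()) for lid in base}
    adaptive = [lid for lid in base if hits[lid] >= min_methods]
    neutral = [lid for lid in base if hits[lid] == 0]
    single = [lid for lid in base if 0 < hits[lid] < min_methods]

    # exclusive Venn region counts (methods in input order)
    methods = list(per_method)
    venn: dict[str, int] = {}
    for r in range(1, len(methods) + 1):
        for combo in combinations(methods, r):
            inside = set.intersection(*(per_method[m] for m in combo))
            outside = set.union(set(), *(per_method[m] for m in methods
                                         if m not in combo))
            venn["&".join(combo)] = len(inside - outside)
    return ConsensusPartition(adaptive=adaptive, neutral=neutral,
                              single_method=single, per_method=per_method,
                              venn_counts=venn)
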