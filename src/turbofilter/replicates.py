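"""Cross-experiment (biological-replicate) concordance analyses.

Independent experiments performed on different dates rarely recover
identical candidate lists; these tools quantify that: how often each
filtered protein recurs across experiments, how much of the detection
overlap structure is driven by run-day batch effects rather than biology,
and how similar downstream term lists are (Jaccard index).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Hashable, Mapping

import pandas as pd

from ._venn import venn_regions
from .io import DataError

__all__ = [
    "OccurrenceTable",
    "occurrence_frequency",
    "batch_overlap",
    "term_set_jaccard",
]


@dataclass
class OccurrenceTable:
    """Per-protein recurrence across experiments plus the frequency
    histogram (number of proteins appearing in exactly 1, 2, ...
    experiments).  The histogram sums to the union size ``n``."""

    experiments: dict[str, set[str]]
    counts: dict[str, int]
    membership: dict[str, set[str]]
    histogram: dict[int, int]
    n: int

    def frame(self, colors: Mapping[str, Mapping[str, str]] | None = None) -> pd.DataFrame:
        """One row per protein with per-experiment membership flags and,
        optionally, per-experiment color labels."""
        exp_names = sorted(self.experiments)
        rows = []
        for pid in sorted(self.counts, key=lambda p: (-self.counts[p], p)):
            row: dict[str, object] = {"protein_id": pid, "occurrence_count": self.counts[pid]}
            for e in exp_names:
                row[f"in_{e}"] = pid in self.experiments[e]
                if colors is not None:
                    row[f"color_{e}"] = colors.get(e, {}).get(pid, "")
            rows.append(row)
        return pd.DataFrame(rows)


def occurrence_frequency(filter_sets: Mapping[str, set[str]]) -> OccurrenceTable:
    """Occurrence counts of proteins across >= 2 per-experiment filtered
    sets (by default the Filter-2 candidate lists)."""
    if len(filter_sets) < 2:
        raise DataError("need >= 2 experiments")
    counts: dict[str, int] = {}
    membership: dict[str, set[str]] = {}
    for name, proteins in filter_sets.items():
        for pid in proteins:
            counts[pid] = counts.get(pid, 0) + 1
            membership.setdefault(pid, set()).add(name)
    histogram = dict(Counter(counts.values()))
    return OccurrenceTable(
        experiments={k: set(v) for k, v in filter_sets.items()},
        counts=counts,
        membership=membership,
        histogram=histogram,
        n=len(counts),
    )


def batch_overlap(
    detection_sets: Mapping[Hashable, set[str]],
    up_sets: Mapping[Hashable, set[str]] | None = None,
) -> pd.DataFrame:
    """Venn-region decomposition of all-replicate detection sets across
    (strain, experiment) samples.

    ``detection_sets`` maps each sample to the proteins detected in *all*
    of its technical replicates, irrespective of fold change.  Large
    regions shared by different strains of the same experiment indicate
    batch effects.  When ``up_sets`` gives each sample's bait-enriched
    proteins (FC > 2), each region also reports the fraction of its
    proteins that are up; for regions spanning several samples the maximum
    across the member samples is reported.
    """
    if len(detection_sets) < 2:
        raise DataError("need >= 2 detection sets")
    named = {str(k): set(v) for k, v in detection_sets.items()}
    up_named = {str(k): set(v) for k, v in (up_sets or {}).items()}
    rows = []
    for pattern, proteins in sorted(
        venn_regions(named).items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
    ):
        row: dict[str, object] = {
            "members": "|".join(sorted(pattern)),
            "n_members": len(pattern),
            "count": len(proteins),
        }
        if up_named:
            fracs = [
                len(proteins & up_named[m]) / len(proteins)
                for m in pattern
                if m in up_named
            ]
            row["up_fraction"] = max(fracs) if fracs else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def term_set_jaccard(term_lists: Mapping[str, set[str]]) -> pd.DataFrame:
    """Pairwise shared-term counts and Jaccard indices for named term
    lists (e.g. enriched GO-term ids per dataset).

    Returns a long-form frame with columns (a, b, shared, jaccard);
    Jaccard is NaN for pairs involving an empty list with an empty union.
    """
    if len(term_lists) < 2:
        raise DataError("need >= 2 term lists")
    names = sorted(term_lists)
    rows = []
    for i, a in enumerate(names):
        for b in names[i:]:
            inter = len(term_lists[a] & term_lists[b])
            union = len(term_lists[a] | term_lists[b])
            rows.append(
                {
                    "a": a,
                    "b": b,
                    "shared": inter,
                    "jaccard": (inter / union) if union else float("nan"),
                }
            )
    return pd.DataFrame(rows)
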