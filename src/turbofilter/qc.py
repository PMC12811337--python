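"""Experiment-quality metrics for streptavidin-pulldown proteomics.

Four per-sample percentages summarize how well a pulldown enriched for
biotinylated material:

* **Up %** — among proteins differential versus the no-ligase control
  (fold change >= 2, adjusted p <= 0.05 by default), the share enriched on
  the bait side.
* **TurboID %** — among proteins detected exclusively in one sample class
  (all replicates of one, none of the other), the share on the bait side.
* **Carboxylase %** — share of total detected intensity carried by the
  endogenously biotinylated carboxylases (PYC-1, PCCA-1, MCCC-1, POD-2 in
  *C. elegans*); low values flag non-biotinylated "sticky" contamination.
* **Epidermal %** — share of final candidates present in a
  tissue-expression reference set.

Also here: technical-replicate agreement (detection Venn regions and
pairwise R^2 of log2 intensities) and cross-experiment metric regressions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from ._venn import venn_region_counts
from .enrichment import EnrichmentRecord
from .io import DataError, IntensityMatrix, ReferenceSet

__all__ = [
    "QCReport",
    "OverlapSummary",
    "up_down_counts",
    "up_percent",
    "turboid_percent",
    "carboxylase_percent",
    "epidermal_percent",
    "replicate_overlap",
    "replicate_r2",
    "metric_correlation",
]


@dataclass
class QCReport:
    """Per-(strain, experiment) metric panel; None marks an undefined
    percentage (zero denominator)."""

    strain_label: str
    experiment_id: str
    up_count: int = 0
    down_count: int = 0
    up_percent: float | None = None
    turboid_only_count: int = 0
    n2_only_count: int = 0
    turboid_percent: float | None = None
    carboxylase_percent: float | None = None
    epidermal_percent: float | None = None
    filter1_count: int | None = None
    filter2_count: int | None = None
    bait_cis_fc: float | None = None
    bait_fc_is_estimate: bool = False
    prey_trans_fcs: dict[str, float] = field(default_factory=dict)
    prey_fc_is_estimate: dict[str, bool] = field(default_factory=dict)


def up_down_counts(
    records: Iterable[EnrichmentRecord],
    fc_cut: float = 2.0,
    p_cut: float = 0.05,
) -> tuple[int, int]:
    """Counts of bait-enriched ("up": FC >= fc_cut, adj p <= p_cut) and
    control-enriched ("down": FC <= 1/fc_cut, adj p <= p_cut) proteins.

    Bounds are inclusive.  Records with an estimated fold change carry no
    p-value and are excluded by construction.
    """
    up = down = 0
    for r in records:
        if r.fold_change is None or r.adj_p is None or r.fc_is_estimate:
            continue
        if r.adj_p <= p_cut:
            if r.fold_change >= fc_cut:
                up += 1
            elif r.fold_change <= 1.0 / fc_cut:
                down += 1
    return up, down


def up_percent(up_count: int, down_count: int) -> float | None:
    """100 * up / (up + down); None when no differential proteins exist."""
    total = up_count + down_count
    if total == 0:
        return None
    return 100.0 * up_count / total


def turboid_percent(turboid_only_count: int, n2_only_count: int) -> float | None:
    """100 * bait-exclusive / (bait-exclusive + control-exclusive)."""
    total = turboid_only_count + n2_only_count
    if total == 0:
        return None
    return 100.0 * turboid_only_count / total


def carboxylase_percent(
    matrix: IntensityMatrix,
    runs: Sequence[str],
    carboxylase_set: ReferenceSet,
) -> float:
    """Carboxylase share of total detected intensity, pooled over runs.

    The pooled convention (sum of carboxylase intensities over all the
    sample's technical replicates divided by the total detected intensity)
    is robust to per-run dropout; it equals the mean of per-run ratios only
    when per-run totals are equal.
    """
    runs = list(runs)
    if not runs:
        raise DataError("run subset is empty")
    sub = matrix.data[runs]
    total = float(np.nansum(sub.to_numpy()))
    if total == 0:
        raise DataError("total detected intensity over the given runs is zero")
    in_set = [pid for pid in matrix.protein_ids if pid in carboxylase_set]
    carb = float(np.nansum(sub.loc[in_set].to_numpy())) if in_set else 0.0
    return 100.0 * carb / total


def epidermal_percent(
    protein_set: Iterable[str],
    tissue_reference: ReferenceSet,
) -> float:
    """Percentage of the candidate set present in a tissue reference."""
    proteins = set(protein_set)
    if not proteins:
        raise DataError("protein set is empty")
    hits = sum(1 for p in proteins if p in tissue_reference)
    return 100.0 * hits / len(proteins)


@dataclass
class OverlapSummary:
    """Detection Venn decomposition across the technical replicates of one
    sample: region counts keyed by the subset of runs in which the region's
    proteins are detected."""

    region_counts: dict[frozenset[str], int]
    n_union: int
    all_runs_fraction: float


def replicate_overlap(matrix: IntensityMatrix, runs: Sequence[str]) -> OverlapSummary:
    """Per-region counts of the detection Venn diagram over >= 2 runs."""
    runs = list(runs)
    if len(runs) < 2:
        raise DataError("need >= 2 runs for an overlap summary")
    detected = matrix.detected()[runs]
    sets = {rid: set(detected.index[detected[rid]]) for rid in runs}
    counts = venn_region_counts(sets)
    n_union = sum(counts.values())
    full = counts.get(frozenset(runs), 0)
    return OverlapSummary(
        region_counts=counts,
        n_union=n_union,
        all_runs_fraction=(full / n_union) if n_union else 0.0,
    )


def replicate_r2(
    matrix: IntensityMatrix, run_a: str, run_b: str
) -> float | None:
    """R^2 of ordinary least squares on log2 intensities of co-detected
    proteins; None with < 3 shared proteins.  Symmetric in its arguments."""
    a = matrix.data[run_a].to_numpy(float)
    b = matrix.data[run_b].to_numpy(float)
    mask = ~np.isnan(a) & ~np.isnan(b)
    if int(mask.sum()) < 3:
        return None
    res = stats.linregress(np.log2(a[mask]), np.log2(b[mask]))
    return float(res.rvalue**2)


def metric_correlation(
    reports: Sequence[QCReport], x_metric: str, y_metric: str
) -> tuple[float, float, float] | None:
    """Simple linear regression of one QC metric on another across
    experiments: returns (R^2, slope, p) or None when < 3 paired values or
    the x metric is degenerate (zero variance)."""
    xs, ys = [], []
    for rep in reports:
        x = getattr(rep, x_metric)
        y = getattr(rep, y_metric)
        if x is None or y is None:
            continue
        xs.append(float(x))
        ys.append(float(y))
    if len(xs) < 3:
        return None
    x_arr, y_arr = np.asarray(xs), np.asarray(ys)
    if np.ptp(x_arr) == 0:
        return None
    res = stats.linregress(x_arr, y_arr)
    return float(res.rvalue**2), float(res.slope), float(res.pvalue)
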