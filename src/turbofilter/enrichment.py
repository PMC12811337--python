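"""Per-protein bait vs negative-control enrichment summarization.

For each protein the bait and control group means are computed over the
technical replicates in which the protein was detected — an absence never
enters a mean, so intensities (13, ND, ND) average to 13.  The fold change
is the ratio of the two linear-scale means.  Significance comes from a
Welch (unequal-variance) t-test on log2 intensities over detected
replicates, corrected per contrast by Benjamini–Hochberg; precomputed
p-values from upstream DIA software can be ingested instead.

Proteins present in every bait replicate but absent from every control
replicate have no measurable denominator.  For those, a conservative fold
change is estimated against a detection-floor proxy: the mean of the k
lowest control group-means among proteins detected in *all* control
replicates (k = 10 by default).
"""

from __future__ import annotations

import contextlib
import enum
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import DataError, IntensityMatrix

__all__ = [
    "DetectionCategory",
    "EnrichmentRecord",
    "TestConfig",
    "group_mean",
    "classify_detection",
    "compute_enrichment",
    "estimate_missing_fc",
    "benjamini_hochberg",
    "records_frame",
]


class DetectionCategory(str, enum.Enum):
    BOTH = "both"
    BAIT_ONLY = "bait_only"
    CONTROL_ONLY = "control_only"
    NEITHER = "neither"
    PARTIAL = "partial"


@dataclass
class EnrichmentRecord:
    """One protein's summary for one bait-vs-control contrast.

    Undefined quantities are ``None``: e.g. ``control_mean`` when the
    protein was never detected in the control group, or ``p_value`` when
    fewer than ``min_replicates`` detections exist in either group.
    """

    protein_id: str
    bait_mean: float | None
    control_mean: float | None
    n_detected_bait: int
    n_detected_control: int
    n_bait_runs: int
    n_control_runs: int
    fold_change: float | None
    log2_fc: float | None
    p_value: float | None
    adj_p: float | None
    fc_is_estimate: bool
    detection_category: DetectionCategory


@dataclass(frozen=True)
class TestConfig:
    """Significance-test configuration for :func:`compute_enrichment`.

    ``test``: ``"welch"`` (default) or ``"ingest"`` to use p-values handed
    in via ``precomputed_p``.  ``min_replicates`` is the minimum number of
    detected values per group for a p-value.  ``estimate_missing`` enables
    the detection-floor fold-change estimator for bait-only proteins.
    """

    test: str = "welch"
    min_replicates: int = 2
    estimate_missing: bool = True
    estimate_k: int = 10

    def __post_init__(self) -> None:
        if self.test not in {"welch", "ingest"}:
            raise DataError(f"unknown test {self.test!r}; expected 'welch' or 'ingest'")
        if self.min_replicates < 2:
            raise DataError("min_replicates must be >= 2")


def group_mean(
    matrix: IntensityMatrix, runs: Sequence[str], protein_id: str
) -> float | None:
    """Arithmetic mean over the runs in which the protein was detected.

    Returns None (absent) when the protein was detected in none of them.
    """
    if not runs:
        raise DataError("run subset is empty")
    values = matrix.values_for(protein_id, runs)
    if np.all(np.isnan(values)):
        return None
    return float(np.nanmean(values))


def _categorize(n_b: int, n_c: int, r_b: int, r_c: int) -> DetectionCategory:
    if n_b == 0 and n_c == 0:
        return DetectionCategory.NEITHER
    if n_b > 0 and n_c > 0:
        return DetectionCategory.BOTH
    if n_b == r_b and n_c == 0:
        return DetectionCategory.BAIT_ONLY
    if n_c == r_c and n_b == 0:
        return DetectionCategory.CONTROL_ONLY
    return DetectionCategory.PARTIAL


def classify_detection(
    matrix: IntensityMatrix,
    bait_runs: Sequence[str],
    control_runs: Sequence[str],
    protein_id: str,
) -> DetectionCategory:
    """Detection category of one protein given the two run sets.

    bait_only / control_only require detection in *all* replicates of the
    one group and *none* of the other; both requires at least one detection
    per group; partial covers detection in a strict subset of exactly one
    group's replicates.  The five categories partition the protein universe.
    """
    if not bait_runs or not control_runs:
        raise DataError("both run sets must be non-empty")
    n_b = int(np.sum(~np.isnan(matrix.values_for(protein_id, bait_runs))))
    n_c = int(np.sum(~np.isnan(matrix.values_for(protein_id, control_runs))))
    return _categorize(n_b, n_c, len(bait_runs), len(control_runs))


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values; NaN entries stay NaN and do not count
    toward the number of tests."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


@contextlib.contextmanager
def _quiet_nan_stats():
    """Silence the all-NaN-slice warnings of nan-aware reductions; the
    affected entries are masked out explicitly afterwards."""
    with warnings.catch_warnings(), np.errstate(invalid="ignore", divide="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


def _welch_p(logb: np.ndarray, logc: np.ndarray, min_replicates: int) -> np.ndarray:
    """Vectorized Welch t-test p-values on log2 intensities (rows =
    proteins).  Rows with fewer than ``min_replicates`` detections in
    either group get NaN.  Zero-variance degenerate rows: p = 1 when the
    group means coincide, else p -> 0."""
    n_b = np.sum(~np.isnan(logb), axis=1)
    n_c = np.sum(~np.isnan(logc), axis=1)
    valid = (n_b >= min_replicates) & (n_c >= min_replicates)
    with _quiet_nan_stats():
        mb = np.nanmean(logb, axis=1)
        mc = np.nanmean(logc, axis=1)
        vb = _nanvar(logb, n_b)
        vc = _nanvar(logc, n_c)
        se2 = vb / n_b + vc / n_c
        t = (mb - mc) / np.sqrt(se2)
        df = se2**2 / (
            (vb / n_b) ** 2 / np.maximum(n_b - 1, 1)
            + (vc / n_c) ** 2 / np.maximum(n_c - 1, 1)
        )
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = valid & (se2 == 0)
    p[degenerate] = np.where(mb[degenerate] == mc[degenerate], 1.0, 0.0)
    p[~valid] = np.nan
    return p


def _nanvar(x: np.ndarray, n: np.ndarray) -> np.ndarray:
    with _quiet_nan_stats():
        v = np.nanvar(x, axis=1, ddof=1)
    return np.where(n > 1, v, np.nan)


def compute_enrichment(
    matrix: IntensityMatrix,
    bait_runs: Sequence[str],
    control_runs: Sequence[str],
    config: TestConfig = TestConfig(),
    precomputed_p: Mapping[str, float] | None = None,
) -> list[EnrichmentRecord]:
    """Summarize every protein of the matrix for one contrast.

    Fold change = bait_mean / control_mean on the linear scale.  BH
    adjustment runs over all proteins of the contrast with a defined
    p-value.  Bait-only proteins get an estimated fold change via
    :func:`estimate_missing_fc` when enough fully detected control proteins
    exist (otherwise their fold change stays undefined).
    """
    bait_runs = list(bait_runs)
    control_runs = list(control_runs)
    if not bait_runs or not control_runs:
        raise DataError("both run sets must be non-empty")
    if set(bait_runs) & set(control_runs):
        raise DataError(
            "bait and control run sets overlap: "
            + ", ".join(sorted(set(bait_runs) & set(control_runs)))
        )

    B = matrix.data[bait_runs].to_numpy(float)
    C = matrix.data[control_runs].to_numpy(float)
    r_b, r_c = len(bait_runs), len(control_runs)
    n_b = np.sum(~np.isnan(B), axis=1)
    n_c = np.sum(~np.isnan(C), axis=1)
    with _quiet_nan_stats():
        bait_mean = np.where(n_b > 0, np.nanmean(B, axis=1), np.nan)
        control_mean = np.where(n_c > 0, np.nanmean(C, axis=1), np.nan)

    if config.test == "ingest":
        if precomputed_p is None:
            raise DataError("test='ingest' requires precomputed_p")
        lut = {k.casefold().strip(): v for k, v in precomputed_p.items()}
        p = np.array(
            [lut.get(pid.casefold(), np.nan) for pid in matrix.protein_ids], dtype=float
        )
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            p = _welch_p(np.log2(B), np.log2(C), config.min_replicates)
    adj = benjamini_hochberg(p)

    fc = np.where((n_b > 0) & (n_c > 0), bait_mean / control_mean, np.nan)

    floor = None
    if config.estimate_missing:
        fully = n_c == r_c
        if int(fully.sum()) >= config.estimate_k:
            floor = float(
                np.mean(np.sort(control_mean[fully])[: config.estimate_k])
            )

    records: list[EnrichmentRecord] = []
    for i, pid in enumerate(matrix.protein_ids):
        cat = _categorize(int(n_b[i]), int(n_c[i]), r_b, r_c)
        this_fc = None if np.isnan(fc[i]) else float(fc[i])
        est = False
        if (
            this_fc is None
            and cat == DetectionCategory.BAIT_ONLY
            and floor is not None
        ):
            this_fc = float(bait_mean[i]) / floor
            est = True
        records.append(
            EnrichmentRecord(
                protein_id=pid,
                bait_mean=None if np.isnan(bait_mean[i]) else float(bait_mean[i]),
                control_mean=None if np.isnan(control_mean[i]) else float(control_mean[i]),
                n_detected_bait=int(n_b[i]),
                n_detected_control=int(n_c[i]),
                n_bait_runs=r_b,
                n_control_runs=r_c,
                fold_change=this_fc,
                log2_fc=None if this_fc is None else float(np.log2(this_fc)),
                p_value=None if np.isnan(p[i]) else float(p[i]),
                adj_p=None if np.isnan(adj[i]) else float(adj[i]),
                fc_is_estimate=est,
                detection_category=cat,
            )
        )
    return records


def estimate_missing_fc(
    bait_mean: float,
    control_matrix: IntensityMatrix,
    control_runs: Sequence[str],
    k: int = 10,
) -> float:
    """Conservative fold change for a protein absent from every control run.

    The denominator floor is the mean of the k lowest control group-means
    among proteins detected in all control replicates — a proxy for the
    control sample's limit of detection.
    """
    if bait_mean <= 0:
        raise DataError("bait_mean must be positive")
    control_runs = list(control_runs)
    if not control_runs:
        raise DataError("control run set is empty")
    C = control_matrix.data[control_runs].to_numpy(float)
    fully = np.sum(~np.isnan(C), axis=1) == len(control_runs)
    means = np.nanmean(C[fully], axis=1) if fully.any() else np.array([])
    if means.size < k:
        raise DataError(
            f"only {means.size} proteins are detected in every control run; "
            f"need >= k={k}. Consider a smaller k."
        )
    floor = float(np.mean(np.sort(means)[:k]))
    return bait_mean / floor


def records_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    """Tabular view of enrichment records (one row per protein)."""
    return pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in records],
            "bait_mean": [r.bait_mean for r in records],
            "control_mean": [r.control_mean for r in records],
            "n_detected_bait": [r.n_detected_bait for r in records],
            "n_detected_control": [r.n_detected_control for r in records],
            "fold_change": [r.fold_change for r in records],
            "fc_flag": ["estimated" if r.fc_is_estimate else "" for r in records],
            "log2_fc": [r.log2_fc for r in records],
            "p_value": [r.p_value for r in records],
            "adj_p": [r.adj_p for r in records],
            "detection_category": [r.detection_category.value for r in records],
        }
    )
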