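"""Two-step control-referenced removal of non-bait-specific targets.

A promiscuous, freely diffusing biotin-ligase strain (e.g. an epidermally
expressed mNG::TurboID fusion) biotinylates proteins regardless of bait
identity.  Its enrichment contrasts versus the no-ligase control define a
reusable reference of likely non-specific targets, each carrying the mean
control fold change and a provenance category:

* ``enriched_both`` — fully detected and significantly enriched (FC >= 2,
  adjusted p <= 0.05) in every control experiment; control FC is the mean
  of the per-experiment fold changes.
* ``enriched_single_<label>`` — significant in exactly one control
  experiment while absent from the other experiments' negative controls.
* ``control_only`` — present in all ligase replicates of every control
  experiment but never in a negative control; no fold change exists.

**Filter-1** keeps bait-contrast proteins with FC >= 2, adjusted p <= 0.05
and detection in every bait replicate, plus bait-exclusive proteins
(detected in all bait replicates, absent from all negative controls).

Filter-1 survivors are color-annotated by control fold change — red > 10,
orange (5, 10], yellow [2, 5], gray for control_only, green for declared
bait-complex members, white otherwise — and **Filter-2** then removes red
and orange outright and yellow proteins whose bait-to-control fold-change
ratio falls below 1.5.  Gray proteins stay in the retained set but remain
flagged by their color.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .enrichment import DetectionCategory, EnrichmentRecord
from .io import DataError, ReferenceSet, id_key
from ._venn import venn_regions

logger = logging.getLogger(__name__)

__all__ = [
    "ControlReferenceEntry",
    "ControlReference",
    "FilterAnnotation",
    "build_control_reference",
    "filter1",
    "annotate",
    "bait_control_ratio",
    "filter2",
    "cross_bait_overlap",
]

#: Color breakpoints for annotating control fold changes (Filter-1 labels).
RED_ABOVE = 10.0
ORANGE_ABOVE = 5.0
YELLOW_FROM = 2.0


@dataclass(frozen=True)
class ControlReferenceEntry:
    protein_id: str
    category: str  # enriched_both | enriched_single_<label> | control_only
    control_fc: float | None  # None iff control_only
    per_contrast_fcs: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if (self.control_fc is None) != (self.category == "control_only"):
            raise DataError(
                f"{self.protein_id}: control_fc must be defined exactly for "
                "enriched_* categories"
            )


class ControlReference:
    """Case-insensitive lookup of control-reference entries by protein id."""

    def __init__(self, entries: Iterable[ControlReferenceEntry]) -> None:
        self._entries: dict[str, ControlReferenceEntry] = {}
        for e in entries:
            self._entries[id_key(e.protein_id)] = e

    def get(self, protein_id: str) -> ControlReferenceEntry | None:
        return self._entries.get(id_key(protein_id))

    def __contains__(self, protein_id: str) -> bool:
        return id_key(protein_id) in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    @property
    def entries(self) -> list[ControlReferenceEntry]:
        return list(self._entries.values())

    def n_enriched(self) -> int:
        return sum(1 for e in self._entries.values() if e.category != "control_only")


@dataclass(frozen=True)
class FilterAnnotation:
    protein_id: str
    color: str  # red | orange | yellow | gray | white | green
    control_fc: float | None
    bait_control_ratio: float | None
    filter1_pass: bool
    filter2_pass: bool


def _contrast_labels(n: int) -> list[str]:
    return [chr(ord("a") + i) if i < 26 else str(i) for i in range(n)]


def build_control_reference(
    control_contrasts: Sequence[Sequence[EnrichmentRecord]],
    fc_cut: float = 2.0,
    p_cut: float = 0.05,
    labels: Sequence[str] | None = None,
) -> ControlReference:
    """Assemble the non-specific-target reference from >= 1 promiscuous-
    ligase contrasts (ligase strain vs no-ligase control).

    With k contrasts, ``enriched_both`` requires full detection in both
    groups plus significance in *every* contrast; ``enriched_single_x``
    requires significance in exactly contrast x, full ligase detection
    throughout, and absence from every other contrast's negative controls;
    ``control_only`` requires full ligase detection and zero negative-
    control detection everywhere.
    """
    if not control_contrasts:
        raise DataError("at least one control contrast is required")
    labels = list(labels) if labels is not None else _contrast_labels(len(control_contrasts))
    if len(labels) != len(control_contrasts):
        raise DataError("labels must match the number of contrasts")

    by_key: dict[str, dict[str, EnrichmentRecord]] = {}
    names: dict[str, str] = {}
    for label, records in zip(labels, control_contrasts):
        for r in records:
            k = id_key(r.protein_id)
            by_key.setdefault(k, {})[label] = r
            names.setdefault(k, r.protein_id)

    entries: list[ControlReferenceEntry] = []
    for k, per in by_key.items():
        def rec(lab: str) -> EnrichmentRecord | None:
            return per.get(lab)

        def sig(r: EnrichmentRecord | None) -> bool:
            return (
                r is not None
                and r.fold_change is not None
                and not r.fc_is_estimate
                and r.fold_change >= fc_cut
                and r.adj_p is not None
                and r.adj_p <= p_cut
            )

        def full_ligase(r: EnrichmentRecord | None) -> bool:
            return r is not None and r.n_detected_bait == r.n_bait_runs

        def full_both(r: EnrichmentRecord | None) -> bool:
            return full_ligase(r) and r.n_detected_control == r.n_control_runs

        def absent_neg(r: EnrichmentRecord | None) -> bool:
            return r is None or r.n_detected_control == 0

        recs = [rec(lab) for lab in labels]
        if all(full_both(r) and sig(r) for r in recs):
            fcs = tuple(float(r.fold_change) for r in recs)  # type: ignore[union-attr]
            entries.append(
                ControlReferenceEntry(
                    protein_id=names[k],
                    category="enriched_both",
                    control_fc=sum(fcs) / len(fcs),
                    per_contrast_fcs=fcs,
                )
            )
            continue
        sig_labels = [lab for lab, r in zip(labels, recs) if sig(r)]
        if (
            len(sig_labels) == 1
            and all(full_ligase(r) for r in recs)
            and all(
                absent_neg(r)
                for lab, r in zip(labels, recs)
                if lab != sig_labels[0]
            )
        ):
            r = per[sig_labels[0]]
            entries.append(
                ControlReferenceEntry(
                    protein_id=names[k],
                    category=f"enriched_single_{sig_labels[0]}",
                    control_fc=float(r.fold_change),  # type: ignore[arg-type]
                    per_contrast_fcs=(float(r.fold_change),),  # type: ignore[arg-type]
                )
            )
            continue
        if all(full_ligase(r) and r.n_detected_control == 0 for r in recs):
            entries.append(
                ControlReferenceEntry(
                    protein_id=names[k], category="control_only", control_fc=None
                )
            )
    return ControlReference(entries)


def filter1(
    records: Iterable[EnrichmentRecord],
    fc_cut: float = 2.0,
    p_cut: float = 0.05,
) -> set[str]:
    """Retain proteins with FC >= fc_cut, adjusted p <= p_cut and detection
    in every bait technical replicate, plus bait-exclusive proteins."""
    retained: set[str] = set()
    for r in records:
        if r.detection_category == DetectionCategory.BAIT_ONLY:
            retained.add(r.protein_id)
            continue
        if (
            r.fold_change is not None
            and not r.fc_is_estimate
            and r.fold_change >= fc_cut
            and r.adj_p is not None
            and r.adj_p <= p_cut
            and r.n_detected_bait == r.n_bait_runs
        ):
            retained.add(r.protein_id)
    return retained


def bait_control_ratio(bait_fc: float, control_fc: float) -> float:
    """Fold change in the bait contrast over fold change in the
    promiscuous-ligase control contrast."""
    if bait_fc <= 0 or control_fc <= 0:
        raise DataError("fold changes must be positive")
    return bait_fc / control_fc


def _color(
    entry: ControlReferenceEntry | None,
    is_complex_member: bool,
) -> str:
    if is_complex_member:
        return "green"
    if entry is None:
        return "white"
    if entry.category == "control_only":
        return "gray"
    fc = entry.control_fc
    assert fc is not None
    if fc > RED_ABOVE:
        return "red"
    if fc > ORANGE_ABOVE:
        return "orange"
    if fc >= YELLOW_FROM:
        return "yellow"
    return "white"


def annotate(
    filter1_set: Iterable[str],
    records: Iterable[EnrichmentRecord] | Mapping[str, EnrichmentRecord],
    control_reference: ControlReference | None,
    complex_members: ReferenceSet | None = None,
    ratio_cut: float = 1.5,
    remove_above_control_fc: float = 5.0,
) -> dict[str, FilterAnnotation]:
    """Color-annotate a Filter-1 set and precompute Filter-2 decisions.

    The bait-to-control ratio uses the record's fold change, estimated or
    measured — bait-exclusive proteins enter Filter-2 with their
    conservative estimate.  A protein both in the complex list and the
    control reference is annotated green and a conflict warning is logged.
    """
    if isinstance(records, Mapping):
        rec_by_key = {id_key(k): v for k, v in records.items()}
    else:
        rec_by_key = {id_key(r.protein_id): r for r in records}
    out: dict[str, FilterAnnotation] = {}
    for pid in filter1_set:
        rec = rec_by_key.get(id_key(pid))
        entry = control_reference.get(pid) if control_reference is not None else None
        is_member = complex_members is not None and pid in complex_members
        if is_member and entry is not None:
            logger.warning(
                "%s is both a declared complex member and a control-reference "
                "entry (%s); annotating green",
                pid,
                entry.category,
            )
        color = _color(entry, is_member)
        bait_fc = rec.fold_change if rec is not None else None
        ratio = None
        if (
            entry is not None
            and entry.control_fc is not None
            and bait_fc is not None
            and not is_member
        ):
            ratio = bait_control_ratio(bait_fc, entry.control_fc)
        removed = _filter2_removes(
            entry, ratio, is_member, ratio_cut, remove_above_control_fc
        )
        out[pid] = FilterAnnotation(
            protein_id=pid,
            color=color,
            control_fc=entry.control_fc if entry is not None else None,
            bait_control_ratio=ratio,
            filter1_pass=True,
            filter2_pass=not removed,
        )
    return out


def _filter2_removes(
    entry: ControlReferenceEntry | None,
    ratio: float | None,
    is_complex_member: bool,
    ratio_cut: float,
    remove_above_control_fc: float,
) -> bool:
    """Removal rule expressed on the numeric thresholds (so it is monotone
    when the thresholds move); at the defaults it is exactly "remove red and
    orange; remove yellow with ratio < 1.5"."""
    if is_complex_member or entry is None or entry.control_fc is None:
        return False  # green, white, gray are retained
    if entry.control_fc > remove_above_control_fc:
        return True
    if ratio is not None and ratio < ratio_cut:
        return True
    return False


def filter2(
    annotations: Mapping[str, FilterAnnotation],
    filter1_set: Iterable[str] | None = None,
) -> set[str]:
    """Apply Filter-2 to an annotated Filter-1 set; returns the retained
    protein ids.  Raises when a protein of the set has no annotation."""
    if filter1_set is None:
        filter1_set = list(annotations)
    retained: set[str] = set()
    for pid in filter1_set:
        ann = annotations.get(pid)
        if ann is None:
            raise DataError(f"no annotation for protein {pid!r}")
        if ann.filter2_pass:
            retained.add(pid)
    return retained


def cross_bait_overlap(
    filter_sets: Mapping[str, set[str]],
    annotations: Mapping[str, Mapping[str, FilterAnnotation]] | None = None,
) -> list[dict]:
    """Venn-region counts across bait datasets, with per-region color
    composition when annotations are supplied.

    Returns one row per non-empty region: ``members`` (the bait names whose
    sets contain the region), ``count``, ``proteins``, and ``colors`` (a
    Counter over annotation colors; a protein annotated differently by
    different baits contributes each of its colors once).
    """
    if len(filter_sets) < 2:
        raise DataError("need >= 2 named sets")
    rows = []
    for pattern, proteins in sorted(
        venn_regions(dict(filter_sets)).items(), key=lambda kv: sorted(kv[0])
    ):
        colors: Counter[str] = Counter()
        if annotations is not None:
            for pid in proteins:
                for bait in pattern:
                    ann = annotations.get(bait, {}).get(pid)
                    if ann is not None:
                        colors[ann.color] += 1
        rows.append(
            {
                "members": pattern,
                "count": len(proteins),
                "proteins": set(proteins),
                "colors": colors,
            }
        )
    return rows
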