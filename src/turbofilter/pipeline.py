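"""End-to-end orchestration: config -> enrichment -> QC -> filters -> report.

For each (bait strain, experiment) the pipeline contrasts the bait runs
against the experiment's negative-control runs, writes the annotated
per-protein table, and accumulates a QC summary row.  Non-specific-ligase
contrasts feed the control reference used by Filter-2.  All thresholds are
recorded in the manifest for provenance, and a rerun on identical inputs
produces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr
from . import filtering as flt
from . import qc
from .io import (
    ANNOTATED_COLUMNS,
    ConfigError,
    DataError,
    IntensityMatrix,
    QuantDialect,
    ReferenceSet,
    Role,
    SampleDescriptor,
    read_quant_table,
    read_reference_set,
    read_sample_sheet,
    write_annotated_table,
)
from .replicates import occurrence_frequency
from .enrichment import records_frame

logger = logging.getLogger(__name__)

__all__ = [
    "Thresholds",
    "PipelineConfig",
    "run_pipeline",
    "summarize_study",
    "filter_count_stats",
]


@dataclass(frozen=True)
class Thresholds:
    fc_cut: float = 2.0
    p_cut: float = 0.05
    ratio_cut: float = 1.5
    remove_above_control_fc: float = 5.0
    min_replicates: int = 2
    estimate_k: int = 10

    def __post_init__(self) -> None:
        for name in ("fc_cut", "p_cut", "ratio_cut", "remove_above_control_fc"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"threshold {name} must be positive")


@dataclass
class PipelineConfig:
    quant_table: Path
    sample_sheet: Path
    output_dir: Path
    carboxylase_set: Path | None = None
    epidermal_set: Path | None = None
    complex_members: Path | None = None
    bait_proteins: dict[str, str] = field(default_factory=dict)  # strain -> bait protein
    bait_partners: dict[str, list[str]] = field(default_factory=dict)
    thresholds: Thresholds = field(default_factory=Thresholds)
    dialect: QuantDialect = field(default_factory=QuantDialect)
    filter1_only: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        try:
            paths = raw.get("paths", {})
            base = Path(path).parent

            def resolve(key: str, required: bool = False) -> Path | None:
                value = paths.get(key)
                if value is None:
                    if required:
                        raise ConfigError(f"config lacks paths.{key}")
                    return None
                p = Path(value)
                return p if p.is_absolute() else base / p

            thr = Thresholds(**raw.get("thresholds", {}))
            dialect = QuantDialect(**raw.get("dialect", {}))
            baits = raw.get("baits", {}) or {}
            return cls(
                quant_table=resolve("quant_table", required=True),  # type: ignore[arg-type]
                sample_sheet=resolve("sample_sheet", required=True),  # type: ignore[arg-type]
                output_dir=resolve("output_dir", required=True),  # type: ignore[arg-type]
                carboxylase_set=resolve("carboxylase_set"),
                epidermal_set=resolve("epidermal_set"),
                complex_members=resolve("complex_members"),
                bait_proteins={
                    strain: spec.get("protein", "")
                    for strain, spec in baits.items()
                    if isinstance(spec, dict) and spec.get("protein")
                },
                bait_partners={
                    strain: list(spec.get("partners", []))
                    for strain, spec in baits.items()
                    if isinstance(spec, dict)
                },
                filter1_only=bool(raw.get("filter1_only", False)),
                thresholds=thr,
                dialect=dialect,
            )
        except TypeError as exc:  # unknown keys in thresholds/dialect blocks
            raise ConfigError(str(exc)) from exc


def _contrasts(
    samples: Sequence[SampleDescriptor], role: Role
) -> list[tuple[str, str, list[str], list[str]]]:
    """(strain, experiment, bait-side runs, negative-control runs) for every
    strain of the given role, per experiment."""
    out = []
    by_exp_neg: dict[str, list[str]] = {}
    for s in samples:
        if s.role == Role.NEGATIVE_CONTROL:
            by_exp_neg.setdefault(s.experiment_id, []).append(s.run_id)
    seen = []
    for s in samples:
        if s.role != role:
            continue
        key = (s.strain_label, s.experiment_id)
        if key in seen:
            continue
        seen.append(key)
        runs = [
            t.run_id
            for t in samples
            if t.strain_label == s.strain_label and t.experiment_id == s.experiment_id
        ]
        neg = by_exp_neg.get(s.experiment_id, [])
        out.append((s.strain_label, s.experiment_id, runs, neg))
    return out


def run_pipeline(
    config: PipelineConfig,
    matrix: IntensityMatrix | None = None,
    samples: Sequence[SampleDescriptor] | None = None,
) -> dict:
    """Run the full workflow; returns the artifact manifest.

    ``matrix``/``samples`` may be passed directly (e.g. straight from the
    simulator) to skip file loading.
    """
    thr = config.thresholds
    if samples is None:
        samples = read_sample_sheet(config.sample_sheet)
    if matrix is None:
        matrix = read_quant_table(
            config.quant_table, config.dialect, {s.run_id: s for s in samples}
        )
    elif not matrix.samples:
        matrix = matrix.with_samples(samples)

    carbox = (
        read_reference_set(config.carboxylase_set, "carboxylases")
        if config.carboxylase_set
        else None
    )
    epidermal = (
        read_reference_set(config.epidermal_set, "epidermal")
        if config.epidermal_set
        else None
    )
    members = (
        read_reference_set(config.complex_members, "complex_members")
        if config.complex_members
        else None
    )

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    test_config = enr.TestConfig(
        min_replicates=thr.min_replicates, estimate_k=thr.estimate_k
    )

    # --- control reference from non-specific-ligase contrasts -------------
    ns_contrasts = _contrasts(samples, Role.NONSPECIFIC_CONTROL)
    control_ref: flt.ControlReference | None = None
    if ns_contrasts:
        record_lists = []
        labels = []
        for strain, exp, runs, neg in ns_contrasts:
            if not neg:
                raise DataError(
                    f"experiment {exp!r} has no negative_control runs for the "
                    f"non-specific control contrast ({strain})"
                )
            record_lists.append(
                enr.compute_enrichment(matrix, runs, neg, test_config)
            )
            labels.append(exp)
        control_ref = flt.build_control_reference(
            record_lists, fc_cut=thr.fc_cut, p_cut=thr.p_cut, labels=labels
        )
        pd.DataFrame(
            [
                {
                    "protein_id": e.protein_id,
                    "category": e.category,
                    "control_fc": e.control_fc,
                }
                for e in control_ref.entries
            ]
        ).to_csv(out_dir / "control_reference.csv", index=False)
    elif not config.filter1_only:
        raise DataError(
            "no non-specific control runs present: Filter-2 needs a control "
            "reference. Rerun with filter1_only=true for Filter-1-only mode."
        )
    if config.filter1_only:
        logger.warning("Filter-1-only mode: filter2 columns will be absent")

    # --- bait contrasts ----------------------------------------------------
    bait_contrasts = _contrasts(samples, Role.BAIT)
    if not bait_contrasts:
        raise DataError("sample sheet defines no bait runs")
    qc_rows: list[qc.QCReport] = []
    filter2_sets: dict[tuple[str, str], set[str]] = {}
    manifest_files: list[dict] = []

    for strain, exp, runs, neg in sorted(bait_contrasts, key=lambda t: (t[1], t[0])):
        if not neg:
            raise DataError(
                f"experiment {exp!r} has bait runs ({strain}) but no "
                "negative_control runs; cannot form a contrast"
            )
        records = enr.compute_enrichment(matrix, runs, neg, test_config)
        rec_by_id = {r.protein_id: r for r in records}
        f1 = flt.filter1(records, fc_cut=thr.fc_cut, p_cut=thr.p_cut)
        annotations: dict[str, flt.FilterAnnotation] = {}
        f2: set[str] | None = None
        if not config.filter1_only:
            annotations = flt.annotate(
                f1,
                rec_by_id,
                control_ref,
                members,
                ratio_cut=thr.ratio_cut,
                remove_above_control_fc=thr.remove_above_control_fc,
            )
            f2 = flt.filter2(annotations, f1)
            filter2_sets[(strain, exp)] = f2

        table = records_frame(records)
        table["control_fc"] = [
            (control_ref.get(p).control_fc if control_ref and control_ref.get(p) else None)
            for p in table["protein_id"]
        ]
        table["color"] = [
            annotations[p].color if p in annotations else "" for p in table["protein_id"]
        ]
        table["bait_control_ratio"] = [
            annotations[p].bait_control_ratio if p in annotations else None
            for p in table["protein_id"]
        ]
        table["filter1_pass"] = table["protein_id"].isin(f1)
        if not config.filter1_only:
            table["filter2_pass"] = table["protein_id"].isin(f2 or set())
        slug = f"{strain}_{exp}".replace("::", "").replace("/", "-").replace("|", "-")
        table_path = out_dir / f"enrichment_{slug}.csv"
        out_cols = (
            [c for c in ANNOTATED_COLUMNS if c != "filter2_pass"]
            if config.filter1_only
            else ANNOTATED_COLUMNS
        )
        write_annotated_table(table, table_path, columns=out_cols)
        manifest_files.append({"path": table_path.name, "rows": len(table)})

        # --- QC row --------------------------------------------------------
        up, down = qc.up_down_counts(records, fc_cut=thr.fc_cut, p_cut=thr.p_cut)
        to_count = sum(
            1 for r in records if r.detection_category == enr.DetectionCategory.BAIT_ONLY
        )
        n2_count = sum(
            1 for r in records if r.detection_category == enr.DetectionCategory.CONTROL_ONLY
        )
        report = qc.QCReport(
            strain_label=strain,
            experiment_id=exp,
            up_count=up,
            down_count=down,
            up_percent=qc.up_percent(up, down),
            turboid_only_count=to_count,
            n2_only_count=n2_count,
            turboid_percent=qc.turboid_percent(to_count, n2_count),
            filter1_count=len(f1),
            filter2_count=len(f2) if f2 is not None else None,
        )
        if carbox is not None:
            report.carboxylase_percent = qc.carboxylase_percent(matrix, runs, carbox)
        if epidermal is not None:
            candidate = f2 if f2 is not None else f1
            if candidate:
                report.epidermal_percent = qc.epidermal_percent(candidate, epidermal)
        bait_protein = config.bait_proteins.get(strain)
        if bait_protein and bait_protein in matrix:
            rec = rec_by_id.get(matrix.resolve(bait_protein))
            if rec and rec.fold_change is not None:
                report.bait_cis_fc = rec.fold_change
                report.bait_fc_is_estimate = rec.fc_is_estimate
        for partner in config.bait_partners.get(strain, []):
            if partner in matrix:
                rec = rec_by_id.get(matrix.resolve(partner))
                if rec and rec.fold_change is not None:
                    report.prey_trans_fcs[partner] = rec.fold_change
                    report.prey_fc_is_estimate[partner] = rec.fc_is_estimate
        qc_rows.append(report)

    # --- cross-experiment occurrence --------------------------------------
    by_strain: dict[str, dict[str, set[str]]] = {}
    for (strain, exp), f2set in filter2_sets.items():
        by_strain.setdefault(strain, {})[exp] = f2set
    for strain, per_exp in by_strain.items():
        if len(per_exp) >= 2:
            occ = occurrence_frequency(per_exp)
            slug = strain.replace("::", "").replace("/", "-")
            occ_path = out_dir / f"occurrence_{slug}.csv"
            occ.frame().to_csv(occ_path, index=False)
            manifest_files.append({"path": occ_path.name, "rows": occ.n})

    # --- study summary ------------------------------------------------------
    summary = summarize_study(qc_rows)
    summary_path = out_dir / "qc_summary.csv"
    summary.to_csv(summary_path, index=False, na_rep="")
    manifest_files.append({"path": summary_path.name, "rows": len(summary)})

    manifest = {
        "thresholds": {
            "fc_cut": thr.fc_cut,
            "p_cut": thr.p_cut,
            "ratio_cut": thr.ratio_cut,
            "remove_above_control_fc": thr.remove_above_control_fc,
            "min_replicates": thr.min_replicates,
            "estimate_k": thr.estimate_k,
        },
        "filter1_only": config.filter1_only,
        "n_proteins": len(matrix.protein_ids),
        "n_runs": len(matrix.run_ids),
        "n_contrasts": len(bait_contrasts),
        "control_reference_size": len(control_ref) if control_ref else 0,
        "files": sorted(manifest_files, key=lambda f: f["path"]),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %d contrasts, outputs in %s", len(bait_contrasts), out_dir)
    return manifest


def summarize_study(
    qc_rows: Sequence[qc.QCReport],
    filter_counts: Mapping[tuple[str, str], tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Study-level metric table: one row per (strain, experiment) plus a
    trailing summary row with mean/SD/range of the Filter-1 and Filter-2
    counts.  Estimated fold changes carry an asterisk.  With a single
    contrast the SD is undefined and emitted empty.
    """
    if not qc_rows:
        raise DataError("no completed contrasts to summarize")

    def fmt_fc(value: float | None, est: bool) -> str:
        if value is None:
            return ""
        return f"{value:.3g}*" if est else f"{value:.3g}"

    rows = []
    for r in qc_rows:
        f1c, f2c = r.filter1_count, r.filter2_count
        if filter_counts is not None:
            f1c, f2c = filter_counts.get((r.strain_label, r.experiment_id), (f1c, f2c))
        rows.append(
            {
                "strain_label": r.strain_label,
                "experiment_id": r.experiment_id,
                "up_count": r.up_count,
                "down_count": r.down_count,
                "up_percent": r.up_percent,
                "turboid_only_count": r.turboid_only_count,
                "n2_only_count": r.n2_only_count,
                "turboid_percent": r.turboid_percent,
                "carboxylase_percent": r.carboxylase_percent,
                "epidermal_percent": r.epidermal_percent,
                "filter1_count": f1c,
                "filter2_count": f2c,
                "bait_cis_fc": fmt_fc(r.bait_cis_fc, r.bait_fc_is_estimate),
                "prey_trans_fcs": ";".join(
                    f"{p}:{fmt_fc(fc, r.prey_fc_is_estimate.get(p, False))}"
                    for p, fc in sorted(r.prey_trans_fcs.items())
                ),
            }
        )
    df = pd.DataFrame(rows)

    summary_row = {c: "" for c in df.columns}
    summary_row["strain_label"] = "STUDY_SUMMARY"
    parts = []
    for col, prefix in (("filter1_count", "filter1"), ("filter2_count", "filter2")):
        if col in df and df[col].notna().any():
            s = filter_count_stats(df[col].dropna().astype(float))
            sd = "" if s["sd"] is None else f"{s['sd']:.6g}"
            parts.append(
                f"{prefix}_mean={s['mean']:.6g};{prefix}_sd={sd};{prefix}_range={s['range']}"
            )
    summary_row["experiment_id"] = ";".join(parts)
    df = pd.concat([df, pd.DataFrame([summary_row])], ignore_index=True)
    return df


def filter_count_stats(counts: Sequence[float]) -> dict[str, object]:
    """Mean, sample SD and range of per-contrast filter counts.  SD is None
    (emitted empty) for a single contrast."""
    vals = np.asarray(list(counts), dtype=float)
    if vals.size == 0:
        raise DataError("no counts")
    return {
        "mean": float(np.mean(vals)),
        "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else None,
        "range": f"{int(vals.min())}-{int(vals.max())}",
    }
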