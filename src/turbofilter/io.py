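"""Core data model and delimited-text IO.

Protein quantification tables are wide matrices: one row per protein, one
column per MS run, cells holding non-negative intensities.  A cell may also
be *not detected* — a state distinct from any numeric value.  Upstream DIA
software conventionally exports zero or an empty cell for undetected
proteins; internally we keep not-detected as NaN inside a float DataFrame
and never as a literal zero, because downstream group means must skip (not
include) absences.

Run metadata lives in a sample sheet mapping each run to a strain, a
biological-replicate experiment, a technical-replicate index and a role
(bait, negative control, or non-specific promiscuous-ligase control).
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Role",
    "SampleDescriptor",
    "IntensityMatrix",
    "ReferenceSet",
    "QuantDialect",
    "DataError",
    "ConfigError",
    "normalize_id",
    "read_quant_table",
    "write_quant_table",
    "read_sample_sheet",
    "read_reference_set",
    "write_annotated_table",
    "experiments_without_negative_control",
]


class DataError(ValueError):
    """Malformed or inconsistent input data."""


class ConfigError(ValueError):
    """Invalid configuration."""


class Role(str, enum.Enum):
    BAIT = "bait"
    NEGATIVE_CONTROL = "negative_control"
    NONSPECIFIC_CONTROL = "nonspecific_control"


def normalize_id(identifier: str) -> str:
    """Trim surrounding whitespace; case is preserved."""
    return str(identifier).strip()


def id_key(identifier: str) -> str:
    """Canonical comparison key: case-insensitive, whitespace-trimmed."""
    return normalize_id(identifier).casefold()


@dataclass(frozen=True)
class SampleDescriptor:
    """One MS run and its experimental coordinates."""

    run_id: str
    strain_label: str
    experiment_id: str
    replicate_index: int
    role: Role

    def __post_init__(self) -> None:
        if self.replicate_index < 1:
            raise DataError(
                f"replicate_index must be a positive integer, got "
                f"{self.replicate_index!r} for run {self.run_id!r}"
            )


@dataclass(frozen=True)
class ReferenceSet:
    """A named list of protein identifiers (e.g. the four endogenously
    biotinylated carboxylases, or a tissue-expression reference)."""

    name: str
    protein_ids: frozenset[str]
    source_note: str = ""

    def __post_init__(self) -> None:
        if not self.protein_ids:
            raise DataError(f"reference set {self.name!r} is empty")
        object.__setattr__(
            self, "_keys", frozenset(id_key(p) for p in self.protein_ids)
        )

    def __contains__(self, protein_id: str) -> bool:
        return id_key(protein_id) in self._keys  # type: ignore[attr-defined]

    def __len__(self) -> int:
        return len(self._keys)  # type: ignore[attr-defined]


class IntensityMatrix:
    """Proteins x runs intensity matrix.

    ``data`` is a float DataFrame indexed by protein identifier with one
    column per run id; NaN encodes the not-detected state.  Stored
    intensities are strictly positive.  ``samples`` optionally maps run ids
    to :class:`SampleDescriptor` records.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        samples: Mapping[str, SampleDescriptor] | None = None,
    ) -> None:
        data = data.astype(float)
        data.index = pd.Index([normalize_id(p) for p in data.index], name="protein_id")
        data.columns = [str(c).strip() for c in data.columns]
        keys = [id_key(p) for p in data.index]
        dupes = pd.Index(keys)[pd.Index(keys).duplicated()].unique().tolist()
        if dupes:
            raise DataError(
                "duplicate protein identifiers after normalization: "
                + ", ".join(sorted(dupes))
            )
        with np.errstate(invalid="ignore"):
            if np.any(data.to_numpy() <= 0):
                bad = data.index[(data <= 0).any(axis=1)].tolist()
                raise DataError(
                    "non-positive stored intensity for: " + ", ".join(map(str, bad[:10]))
                )
        self.data = data
        self._key_to_id = {id_key(p): p for p in data.index}
        self.samples: dict[str, SampleDescriptor] = dict(samples or {})
        if self.samples:
            missing = [c for c in data.columns if c not in self.samples]
            if missing:
                raise DataError(
                    "runs present in the quantification table but absent from "
                    "the sample sheet: " + ", ".join(missing)
                )

    # -- basic accessors -------------------------------------------------
    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def run_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_detected_cells(self) -> int:
        return int(self.data.notna().to_numpy().sum())

    def resolve(self, protein_id: str) -> str:
        """Return the stored spelling of an identifier (case-insensitive)."""
        try:
            return self._key_to_id[id_key(protein_id)]
        except KeyError:
            raise KeyError(f"protein {protein_id!r} not in matrix") from None

    def __contains__(self, protein_id: str) -> bool:
        return id_key(protein_id) in self._key_to_id

    def value(self, protein_id: str, run_id: str) -> float | None:
        """Intensity, or None when not detected."""
        v = self.data.at[self.resolve(protein_id), run_id]
        return None if pd.isna(v) else float(v)

    def detected(self) -> pd.DataFrame:
        return self.data.notna()

    def values_for(self, protein_id: str, run_ids: Sequence[str]) -> np.ndarray:
        """Intensities over the given runs (NaN where not detected)."""
        return self.data.loc[self.resolve(protein_id), list(run_ids)].to_numpy(float)

    def runs_for(
        self,
        strain_label: str | None = None,
        experiment_id: str | None = None,
        role: Role | None = None,
    ) -> list[str]:
        """Run ids matching the given sample-sheet coordinates."""
        if not self.samples:
            raise DataError("no sample sheet attached to this matrix")
        out = []
        for rid in self.run_ids:
            s = self.samples[rid]
            if strain_label is not None and s.strain_label != strain_label:
                continue
            if experiment_id is not None and s.experiment_id != experiment_id:
                continue
            if role is not None and s.role != role:
                continue
            out.append(rid)
        return out

    def with_samples(self, samples: Iterable[SampleDescriptor]) -> "IntensityMatrix":
        return IntensityMatrix(self.data.copy(), {s.run_id: s for s in samples})

    def equals(self, other: "IntensityMatrix") -> bool:
        """Equality up to row/column order (and identifier case)."""
        a = self.data.copy()
        b = other.data.copy()
        a.index = [id_key(p) for p in a.index]
        b.index = [id_key(p) for p in b.index]
        if sorted(a.index) != sorted(b.index) or sorted(a.columns) != sorted(b.columns):
            return False
        b = b.loc[a.index, a.columns]
        na, nb = a.to_numpy(), b.to_numpy()
        return bool(np.all((np.isnan(na) & np.isnan(nb)) | (na == nb)))


@dataclass(frozen=True)
class QuantDialect:
    """How to interpret an upstream quantification export.

    ``missing_tokens`` are cell contents (case-insensitive) that denote
    not-detected; ``zero_is_missing`` additionally maps an exact zero to
    not-detected, matching the convention of DIA software exports where a
    zero intensity means the protein was not found in that run.
    """

    delimiter: str | None = None  # None: infer from file extension
    missing_tokens: tuple[str, ...] = ("", "na", "nd", "filtered", "nan")
    zero_is_missing: bool = True
    protein_column: str | None = None  # None: first column


def _infer_delimiter(path: Path, dialect: QuantDialect) -> str:
    if dialect.delimiter is not None:
        return dialect.delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".txt", ".tab"} else ","


def read_quant_table(
    path: str | Path,
    dialect: QuantDialect = QuantDialect(),
    samples: Mapping[str, SampleDescriptor] | None = None,
) -> IntensityMatrix:
    """Parse a wide protein-quantification table.

    First column: protein identifier; remaining columns: one per run.
    Raises :class:`DataError` on duplicate protein ids, negative
    intensities, or (when ``samples`` is given) runs missing from the
    sample sheet.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=_infer_delimiter(path, dialect), dtype=str)
    if raw.shape[1] < 2:
        raise DataError(f"{path}: expected a protein column plus >=1 run column")
    pcol = dialect.protein_column or raw.columns[0]
    raw = raw.set_index(pcol)
    tokens = {t.casefold() for t in dialect.missing_tokens}

    def parse_cell(cell: object) -> float:
        if cell is None or (isinstance(cell, float) and np.isnan(cell)):
            return np.nan
        text = str(cell).strip()
        if text.casefold() in tokens:
            return np.nan
        v = float(text)
        if v < 0:
            raise DataError(f"{path}: negative intensity {v!r}")
        if v == 0:
            if dialect.zero_is_missing:
                return np.nan
            raise DataError(
                f"{path}: zero intensity encountered with zero_is_missing=False; "
                "stored intensities must be strictly positive"
            )
        return v

    data = raw.map(parse_cell)
    matrix = IntensityMatrix(data, samples)
    logger.info(
        "read %s: %d proteins x %d runs, %d detected cells",
        path,
        len(matrix.protein_ids),
        len(matrix.run_ids),
        matrix.n_detected_cells,
    )
    return matrix


def write_quant_table(matrix: IntensityMatrix, path: str | Path) -> None:
    """Write a matrix back out; not-detected cells are emitted empty."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt", ".tab"} else ","
    matrix.data.to_csv(path, sep=sep, na_rep="", index_label="protein_id")


_SHEET_COLUMNS = ["run_id", "strain_label", "experiment_id", "replicate_index", "role"]


def read_sample_sheet(path: str | Path) -> list[SampleDescriptor]:
    """Parse and validate a sample sheet.

    An experiment referenced by bait runs but lacking any negative-control
    run is only *warned* about here; the error is deferred until a contrast
    for that experiment is actually requested.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in _SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: sample sheet lacks columns: {', '.join(missing)}")
    out: list[SampleDescriptor] = []
    seen_runs: set[str] = set()
    seen_coords: set[tuple[str, str, int]] = set()
    for _, row in df.iterrows():
        role_text = str(row["role"]).strip()
        try:
            role = Role(role_text)
        except ValueError:
            raise DataError(
                f"{path}: unknown role {role_text!r}; expected one of "
                + ", ".join(r.value for r in Role)
            ) from None
        try:
            rep = int(row["replicate_index"])
        except (TypeError, ValueError):
            raise DataError(
                f"{path}: non-integer replicate_index {row['replicate_index']!r}"
            ) from None
        s = SampleDescriptor(
            run_id=str(row["run_id"]).strip(),
            strain_label=str(row["strain_label"]).strip(),
            experiment_id=str(row["experiment_id"]).strip(),
            replicate_index=rep,
            role=role,
        )
        if s.run_id in seen_runs:
            raise DataError(f"{path}: duplicate run_id {s.run_id!r}")
        coords = (s.strain_label, s.experiment_id, s.replicate_index)
        if coords in seen_coords:
            raise DataError(
                f"{path}: duplicate (strain, experiment, replicate) {coords!r}"
            )
        seen_runs.add(s.run_id)
        seen_coords.add(coords)
        out.append(s)
    for exp in experiments_without_negative_control(out):
        msg = (
            f"experiment {exp!r} has bait runs but no negative_control run; "
            "contrasts for it will fail"
        )
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    return out


def experiments_without_negative_control(
    samples: Iterable[SampleDescriptor],
) -> list[str]:
    samples = list(samples)
    bait_exps = {s.experiment_id for s in samples if s.role == Role.BAIT}
    neg_exps = {s.experiment_id for s in samples if s.role == Role.NEGATIVE_CONTROL}
    return sorted(bait_exps - neg_exps)


def read_reference_set(path: str | Path, name: str) -> ReferenceSet:
    """One identifier per line; '#' starts a comment; blank lines ignored."""
    ids: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        ids.setdefault(id_key(line), normalize_id(line))
    if not ids:
        raise DataError(f"reference set file {path} contains no identifiers")
    return ReferenceSet(name=name, protein_ids=frozenset(ids.values()), source_note=str(path))


#: Stable column order of the annotated output table.
ANNOTATED_COLUMNS = [
    "protein_id",
    "bait_mean",
    "control_mean",
    "n_detected_bait",
    "n_detected_control",
    "fold_change",
    "fc_flag",
    "log2_fc",
    "p_value",
    "adj_p",
    "detection_category",
    "control_fc",
    "color",
    "bait_control_ratio",
    "filter1_pass",
    "filter2_pass",
]


def write_annotated_table(
    records: pd.DataFrame,
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write the per-protein annotated output with a stable column order.

    ``records`` must carry the columns of :data:`ANNOTATED_COLUMNS` (or of
    ``columns`` when given, e.g. to omit the filter2 column in
    Filter-1-only mode); missing optional columns are emitted empty.  An
    empty frame yields a header-only file.
    """
    if columns is None:
        columns = ANNOTATED_COLUMNS
    df = records.copy()
    for col in columns:
        if col not in df.columns:
            df[col] = pd.NA
    df = df[list(columns)]
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt", ".tab"} else ","
    df.to_csv(path, sep=sep, na_rep="", index=False)
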