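"""Synthetic proximity-labeling studies with ground truth.

The generator emulates the statistical structure of a streptavidin-pulldown
DIA experiment so that every pipeline stage is testable without real data:

* log-normal baseline protein abundances, with a handful of endogenously
  biotinylated carboxylases at a large multiple of baseline in every strain;
* bait strains add *cis* enrichment to the bait fusion protein and *trans*
  enrichment to its declared complex partners;
* a reproducible promiscuous-target set enriched in every ligase-bearing
  strain (bait strains and the non-specific control alike), with control
  fold changes spanning roughly 2- to 130-fold;
* a large sticky non-biotinylated background captured in proportion to a
  contamination fraction; a small competing subset of it is depleted (or
  fully outcompeted) on the ligase side, producing control-enriched and
  control-exclusive proteins;
* multiplicative log-normal technical-replicate noise, experiment-level
  batch shifts on a random protein subset, and a hard detection floor below
  which intensities become not-detected.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    ConfigError,
    IntensityMatrix,
    Role,
    SampleDescriptor,
    write_quant_table,
)

__all__ = [
    "ProteinClass",
    "BaitSpec",
    "SimConfig",
    "SimTruth",
    "SimulatedStudy",
    "simulate_study",
    "evaluate_recovery",
    "RecoveryReport",
    "write_study",
]

_CARBOXYLASE_NAMES = ("PYC-1", "PCCA-1", "MCCC-1", "POD-2")


class ProteinClass(str, enum.Enum):
    BAIT = "bait"
    COMPLEX_PARTNER = "complex_partner"
    PROMISCUOUS = "promiscuous"
    CARBOXYLASE = "carboxylase"
    BACKGROUND = "background"


@dataclass(frozen=True)
class BaitSpec:
    """One bait-fusion strain: its strain label, the bait protein it tags,
    the cis (self-biotinylation) fold enrichment, and trans fold
    enrichments for its complex partners."""

    name: str
    bait_protein: str
    cis_fc: float = 50.0
    partners: Mapping[str, float] = field(default_factory=dict)


def _default_baits() -> tuple[BaitSpec, ...]:
    # A strongly and a moderately expressed bait, mirroring the spread seen
    # between kinase and scaffold fusions in practice.
    return (
        BaitSpec(
            name="BAIT-A::TurboID",
            bait_protein="BAIT-A",
            cis_fc=200.0,
            partners={"PREY-A1": 30.0},
        ),
        BaitSpec(
            name="BAIT-B::TurboID",
            bait_protein="BAIT-B",
            cis_fc=10.0,
            partners={"PREY-B1": 8.0, "PREY-B2": 6.0},
        ),
    )


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for :func:`simulate_study`.

    Intensities are in arbitrary units on the scale of the DIA exports the
    pipeline ingests.  ``contamination`` scales the capture level of the
    sticky background; ``basal_capture`` is the (contamination-independent)
    carryover at which ligase-relevant proteins appear in the no-ligase
    control, giving them measurable fold changes.
    """

    n_proteins: int = 1000
    n_carboxylases: int = 4
    log2_abundance_mean: float = 13.0
    log2_abundance_sd: float = 1.5
    carboxylase_multiplier: float = 20.0
    baits: tuple[BaitSpec, ...] = field(default_factory=_default_baits)
    include_nonspecific_control: bool = True
    nonspecific_label: str = "mNG::TurboID"
    negative_control_label: str = "N2"
    n_promiscuous: int = 60
    promiscuous_fc_range: tuple[float, float] = (2.0, 132.0)
    promiscuous_log2_abundance_boost: float = 2.0
    contamination: float = 0.3
    basal_capture: float = 0.05
    basal_log2_sd: float = 2.0
    promiscuous_basal_log2_sd: float = 0.75
    background_down_fraction: float = 0.06
    background_exclusive_fraction: float = 0.015
    background_suppression: float = 0.4
    detection_floor: float = 600.0
    replicate_noise_log2_sd: float = 0.25
    batch_fraction: float = 0.10
    batch_shift_log2_sd: float = 1.0
    n_technical_replicates: int = 3
    n_experiments: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0 or self.n_technical_replicates <= 0 or self.n_experiments <= 0:
            raise ConfigError("sizes must be positive")
        for frac in (
            self.contamination,
            self.basal_capture,
            self.background_down_fraction,
            self.background_exclusive_fraction,
            self.background_suppression,
            self.batch_fraction,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"fractions must lie in [0, 1], got {frac}")
        if self.background_down_fraction + self.background_exclusive_fraction > 1.0:
            raise ConfigError("background subset fractions exceed 1")
        if self.promiscuous_fc_range[0] <= 0 or (
            self.promiscuous_fc_range[1] < self.promiscuous_fc_range[0]
        ):
            raise ConfigError("invalid promiscuous_fc_range")
        n_special = (
            len({b.bait_protein for b in self.baits})
            + len({p for b in self.baits for p in b.partners})
            + self.n_carboxylases
            + self.n_promiscuous
        )
        if n_special >= self.n_proteins:
            raise ConfigError(
                f"n_proteins={self.n_proteins} leaves no room for the "
                f"{n_special} bait/partner/carboxylase/promiscuous proteins"
            )


@dataclass
class SimTruth:
    """Ground-truth labels for one simulated study."""

    classes: dict[str, ProteinClass]
    effects: dict[str, dict[str, float]]  # protein -> strain -> fold multiplier
    promiscuous_fc: dict[str, float]
    batch_members: dict[str, set[str]]
    config: SimConfig

    def of_class(self, cls: ProteinClass) -> set[str]:
        return {p for p, c in self.classes.items() if c == cls}

    def partners_of(self, strain_label: str) -> set[str]:
        return {
            p
            for p, eff in self.effects.items()
            if strain_label in eff and self.classes[p] == ProteinClass.COMPLEX_PARTNER
        }

    def frame(self) -> pd.DataFrame:
        rows = []
        for pid, cls in self.classes.items():
            rows.append(
                {
                    "protein_id": pid,
                    "class": cls.value,
                    "promiscuous_fc": self.promiscuous_fc.get(pid, np.nan),
                    "effects": ";".join(
                        f"{s}:{fc:g}" for s, fc in sorted(self.effects.get(pid, {}).items())
                    ),
                    "batch_experiments": ";".join(
                        sorted(e for e, m in self.batch_members.items() if pid in m)
                    ),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class SimulatedStudy:
    matrix: IntensityMatrix
    samples: list[SampleDescriptor]
    truth: SimTruth


def simulate_study(config: SimConfig = SimConfig()) -> SimulatedStudy:
    """Generate a complete study: intensity matrix, sample sheet, truth."""
    rng = np.random.default_rng(config.seed)

    # --- protein universe ------------------------------------------------
    bait_proteins = list(dict.fromkeys(b.bait_protein for b in config.baits))
    partner_proteins = list(
        dict.fromkeys(p for b in config.baits for p in b.partners)
    )
    carboxylases = [
        _CARBOXYLASE_NAMES[i] if i < len(_CARBOXYLASE_NAMES) else f"CARB-{i + 1}"
        for i in range(config.n_carboxylases)
    ]
    promiscuous = [f"NSB-{i + 1:04d}" for i in range(config.n_promiscuous)]
    n_background = config.n_proteins - (
        len(bait_proteins) + len(partner_proteins) + len(carboxylases) + len(promiscuous)
    )
    background = [f"PROT-{i + 1:05d}" for i in range(n_background)]
    proteins = bait_proteins + partner_proteins + carboxylases + promiscuous + background
    n = len(proteins)
    index = {p: i for i, p in enumerate(proteins)}

    classes = {p: ProteinClass.BAIT for p in bait_proteins}
    classes.update({p: ProteinClass.COMPLEX_PARTNER for p in partner_proteins})
    classes.update({p: ProteinClass.CARBOXYLASE for p in carboxylases})
    classes.update({p: ProteinClass.PROMISCUOUS for p in promiscuous})
    classes.update({p: ProteinClass.BACKGROUND for p in background})

    base = 2.0 ** rng.normal(config.log2_abundance_mean, config.log2_abundance_sd, n)
    # Promiscuous targets skew abundant (accessible surface lysines on
    # plentiful proteins), which is what makes their enrichment reproducible
    # across control experiments.
    for p in promiscuous:
        base[index[p]] *= 2.0**config.promiscuous_log2_abundance_boost

    lo, hi = config.promiscuous_fc_range
    prom_fc = {
        p: float(np.exp(rng.uniform(np.log(lo), np.log(hi)))) for p in promiscuous
    }

    # Per-protein basal (no-ligase) bead carryover: stickiness spans orders
    # of magnitude for bait-specific targets, so some have measurable N2
    # levels while others are solidly absent from the no-ligase control.
    # Promiscuous targets draw from a narrower spread — their abundance and
    # stickiness is what makes their detection reproducible across control
    # experiments.
    basal_mult = {
        p: float(2.0 ** rng.normal(0.0, config.basal_log2_sd))
        for p in bait_proteins + partner_proteins
    }
    basal_mult |= {
        p: float(2.0 ** rng.normal(0.0, config.promiscuous_basal_log2_sd))
        for p in promiscuous
    }

    # Background capture on the ligase side: most sticky proteins bind
    # identically in every strain; a "competing" subset is depleted when
    # biotinylated material occupies the beads, and a further subset is
    # fully outcompeted (control-exclusive).
    n_down = int(round(config.background_down_fraction * n_background))
    n_excl = int(round(config.background_exclusive_fraction * n_background))
    order = rng.permutation(n_background)
    down_set = {background[i] for i in order[:n_down]}
    excl_set = {background[i] for i in order[n_down : n_down + n_excl]}

    # --- strains and runs -------------------------------------------------
    strains: list[tuple[str, Role]] = [(config.negative_control_label, Role.NEGATIVE_CONTROL)]
    strains += [(b.name, Role.BAIT) for b in config.baits]
    if config.include_nonspecific_control:
        strains.append((config.nonspecific_label, Role.NONSPECIFIC_CONTROL))
    experiments = [f"Exp{i + 1}" for i in range(config.n_experiments)]

    samples: list[SampleDescriptor] = []
    for exp in experiments:
        for strain, role in strains:
            for rep in range(1, config.n_technical_replicates + 1):
                run_id = f"{strain}|{exp}|r{rep}".replace("::", "~")
                samples.append(
                    SampleDescriptor(
                        run_id=run_id,
                        strain_label=strain,
                        experiment_id=exp,
                        replicate_index=rep,
                        role=role,
                    )
                )

    # --- expected capture level per (protein, strain) ---------------------
    effects: dict[str, dict[str, float]] = {}
    bait_by_name = {b.name: b for b in config.baits}
    level = np.empty((n, len(strains)))
    for j, (strain, role) in enumerate(strains):
        ligase = role in (Role.BAIT, Role.NONSPECIFIC_CONTROL)
        col = np.empty(n)
        for p, i in index.items():
            cls = classes[p]
            mult = 1.0
            if cls == ProteinClass.CARBOXYLASE:
                col[i] = base[i] * config.carboxylase_multiplier
            elif cls == ProteinClass.BACKGROUND:
                if ligase:
                    if p in excl_set:
                        mult = 0.0
                    elif p in down_set:
                        mult = config.background_suppression
                col[i] = base[i] * config.contamination * mult
            else:
                if ligase:
                    if cls == ProteinClass.PROMISCUOUS:
                        mult = prom_fc[p]
                    if role == Role.BAIT:
                        spec = bait_by_name[strain]
                        if p == spec.bait_protein:
                            mult = spec.cis_fc
                        elif p in spec.partners:
                            mult = spec.partners[p]
                col[i] = base[i] * config.basal_capture * basal_mult[p] * mult
                if ligase and mult != 1.0:
                    effects.setdefault(p, {})[strain] = float(mult)
        level[:, j] = col
    strain_col = {strain: j for j, (strain, _) in enumerate(strains)}

    # --- batch shifts ------------------------------------------------------
    batch_members: dict[str, set[str]] = {}
    batch_mult = np.ones((n, len(experiments)))
    n_batch = int(round(config.batch_fraction * n))
    for e, exp in enumerate(experiments):
        members = rng.permutation(n)[:n_batch]
        batch_members[exp] = {proteins[i] for i in members}
        batch_mult[members, e] = 2.0 ** rng.normal(
            0.0, config.batch_shift_log2_sd, n_batch
        )

    # --- per-run intensities ----------------------------------------------
    data = np.empty((n, len(samples)))
    exp_index = {exp: e for e, exp in enumerate(experiments)}
    for c, s in enumerate(samples):
        noise = 2.0 ** rng.normal(0.0, config.replicate_noise_log2_sd, n)
        data[:, c] = (
            level[:, strain_col[s.strain_label]]
            * batch_mult[:, exp_index[s.experiment_id]]
            * noise
        )
    data[data < config.detection_floor] = np.nan

    frame = pd.DataFrame(data, index=proteins, columns=[s.run_id for s in samples])
    matrix = IntensityMatrix(frame, {s.run_id: s for s in samples})
    truth = SimTruth(
        classes=classes,
        effects=effects,
        promiscuous_fc=prom_fc,
        batch_members=batch_members,
        config=config,
    )
    return SimulatedStudy(matrix=matrix, samples=samples, truth=truth)


@dataclass(frozen=True)
class RecoveryReport:
    """How well a filtered candidate set recovers the planted biology."""

    sensitivity: float  # fraction of relevant complex partners retained
    fdp_promiscuous: float  # fraction of the retained set that is promiscuous
    fdp_background: float  # fraction of the retained set that is background
    n_retained: int


def evaluate_recovery(
    truth: SimTruth,
    filter2_set: set[str],
    strain_label: str | None = None,
) -> RecoveryReport:
    """Score a retained set against the truth.

    With ``strain_label``, sensitivity is computed over that strain's
    declared complex partners; otherwise over all planted partners.
    """
    partners = (
        truth.partners_of(strain_label)
        if strain_label is not None
        else truth.of_class(ProteinClass.COMPLEX_PARTNER)
    )
    sens = (
        len(partners & filter2_set) / len(partners) if partners else float("nan")
    )
    n_ret = len(filter2_set)
    prom = truth.of_class(ProteinClass.PROMISCUOUS)
    bg = truth.of_class(ProteinClass.BACKGROUND)
    return RecoveryReport(
        sensitivity=sens,
        fdp_promiscuous=(len(filter2_set & prom) / n_ret) if n_ret else 0.0,
        fdp_background=(len(filter2_set & bg) / n_ret) if n_ret else 0.0,
        n_retained=n_ret,
    )


def write_study(study: SimulatedStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write the study as the same CSV formats the IO module reads, plus a
    ground-truth table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "quant_table": out / "quant.csv",
        "sample_sheet": out / "samples.csv",
        "truth": out / "truth.csv",
    }
    write_quant_table(study.matrix, paths["quant_table"])
    pd.DataFrame(
        [
            {
                "run_id": s.run_id,
                "strain_label": s.strain_label,
                "experiment_id": s.experiment_id,
                "replicate_index": s.replicate_index,
                "role": s.role.value,
            }
            for s in study.samples
        ]
    ).to_csv(paths["sample_sheet"], index=False)
    study.truth.frame().to_csv(paths["truth"], index=False)
    return paths
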