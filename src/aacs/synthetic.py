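"""Synthetic plasma cohorts: compositions, true signatures, plate reads.

Emulates the study design the measurement pipeline expects, without
claiming any real patient values: each synthetic patient draws a plasma
composition over the packaged ~10-protein panel (immunoglobulin molar
fraction near 38% in health, perturbed by disease-state class switching),
its true AACS is computed exactly, and 96-well plate fluorescence is
simulated through the same linear forward model the calibration module
inverts.  At zero technical noise the decode is exact, which anchors the
end-to-end round-trip tests.

Randomness is split into named substreams (composition, plate) derived
from one master seed, so biological and technical noise can be varied
independently and every table is reproducible bit-for-bit.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationCurve,
    ChannelConfig,
    DEFAULT_DILUTIONS,
    PLATE_COLUMNS,
)
from .channels import DEFAULT_CHANNELS, ChannelSet
from .composition import ProteinRecord, count_residues, packaged_panel
from .embedding import (
    AACSVector,
    PlasmaComponent,
    PlasmaComposition,
    embed,
    total_residue_concentrations,
)

GENERATOR_VERSION = "1"

IG_PANEL = ("IGG_SYN", "IGA_SYN", "IGM_SYN", "IGD_SYN", "IGE_SYN")
NON_IG_PANEL = ("ALB_SYN", "TF_SYN", "FIB_SYN", "HP_SYN", "A1AT_SYN")

#: molar proportions of the non-Ig pool (albumin-dominated), within-pool
BASE_NON_IG = {"ALB_SYN": 0.68, "TF_SYN": 0.11, "FIB_SYN": 0.05,
               "HP_SYN": 0.08, "A1AT_SYN": 0.08}

HEALTHY_IG_CLASSES = {"IGG_SYN": 0.74, "IGA_SYN": 0.15, "IGM_SYN": 0.08,
                      "IGD_SYN": 0.02, "IGE_SYN": 0.01}


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class DiseaseProfile:
    """Center of a disease state's plasma composition distribution.

    ``ig_fraction`` is the molar fraction of protein molecules that are
    immunoglobulins (c. 0.38 in health); ``ig_classes`` the within-Ig class
    proportions; ``non_ig_multipliers`` scale the baseline non-Ig pool
    (e.g. acute-phase fibrinogen) before renormalisation.  ``dispersion``
    is the Dirichlet precision of between-patient composition draws
    (``inf`` = point mass); total protein is uniform over
    ``total_protein_range`` mg/mL.  All effect sizes are generator
    constructs, not measured patient values.
    """

    label: str
    ig_fraction: float = 0.38
    ig_classes: dict[str, float] = field(default_factory=lambda: dict(HEALTHY_IG_CLASSES))
    non_ig_multipliers: dict[str, float] = field(default_factory=dict)
    total_protein_range: tuple[float, float] = (60.0, 80.0)
    dispersion: float = 500.0

    def __post_init__(self) -> None:
        if not 0 <= self.ig_fraction <= 1:
            raise GeneratorError("ig_fraction must lie in [0, 1]")
        s = sum(self.ig_classes.values())
        if abs(s - 1.0) > 1e-9:
            raise GeneratorError(f"Ig class proportions must sum to 1, got {s}")
        lo, hi = self.total_protein_range
        if not 0 < lo <= hi:
            raise GeneratorError("total protein range must be positive")
        if self.dispersion <= 0:
            raise GeneratorError("dispersion must be positive")

    def center_proportions(self) -> dict[str, float]:
        """Panel-wide molar proportions at the profile center (sum to 1)."""
        non_ig = {
            pid: BASE_NON_IG[pid] * self.non_ig_multipliers.get(pid, 1.0)
            for pid in NON_IG_PANEL
        }
        z = sum(non_ig.values())
        props = {pid: (1.0 - self.ig_fraction) * v / z for pid, v in non_ig.items()}
        for pid in IG_PANEL:
            props[pid] = self.ig_fraction * self.ig_classes.get(pid, 0.0)
        return props


def builtin_profiles() -> dict[str, DiseaseProfile]:
    """Documented default disease profiles (synthetic constructs)."""
    mk = DiseaseProfile
    return {
        "healthy": mk("healthy"),
        # breast and prostate form the "hormonal" cluster (similar class mix),
        # colorectal and pancreatic the IgA-rich "abdominal" cluster
        "breast": mk("breast", ig_fraction=0.47,
                     ig_classes={"IGG_SYN": 0.67, "IGA_SYN": 0.13, "IGM_SYN": 0.15,
                                 "IGD_SYN": 0.03, "IGE_SYN": 0.02}),
        "colorectal": mk("colorectal", ig_fraction=0.48,
                         ig_classes={"IGG_SYN": 0.55, "IGA_SYN": 0.30, "IGM_SYN": 0.10,
                                     "IGD_SYN": 0.03, "IGE_SYN": 0.02}),
        "prostate": mk("prostate", ig_fraction=0.50,
                       ig_classes={"IGG_SYN": 0.66, "IGA_SYN": 0.12, "IGM_SYN": 0.17,
                                   "IGD_SYN": 0.03, "IGE_SYN": 0.02}),
        "pancreatic": mk("pancreatic", ig_fraction=0.47,
                         ig_classes={"IGG_SYN": 0.54, "IGA_SYN": 0.28, "IGM_SYN": 0.11,
                                     "IGD_SYN": 0.04, "IGE_SYN": 0.03}),
        "autoimmune": mk("autoimmune", ig_fraction=0.55,
                         ig_classes={"IGG_SYN": 0.80, "IGA_SYN": 0.10, "IGM_SYN": 0.07,
                                     "IGD_SYN": 0.02, "IGE_SYN": 0.01}),
        "infection": mk("infection", ig_fraction=0.44,
                        ig_classes={"IGG_SYN": 0.55, "IGA_SYN": 0.15, "IGM_SYN": 0.25,
                                    "IGD_SYN": 0.03, "IGE_SYN": 0.02},
                        non_ig_multipliers={"FIB_SYN": 1.8, "HP_SYN": 1.5}),
        "cdki_responder": mk("cdki_responder", ig_fraction=0.47,
                             ig_classes={"IGG_SYN": 0.62, "IGA_SYN": 0.23,
                                         "IGM_SYN": 0.10, "IGD_SYN": 0.03,
                                         "IGE_SYN": 0.02}),
        "cdki_nonresponder": mk("cdki_nonresponder", ig_fraction=0.41,
                                ig_classes={"IGG_SYN": 0.70, "IGA_SYN": 0.17,
                                            "IGM_SYN": 0.09, "IGD_SYN": 0.02,
                                            "IGE_SYN": 0.02}),
    }


#: forward-model defaults: fluorescence slope (a.u. per uM residues),
#: shared intercept, and additive background levels per well role
DEFAULT_SLOPES = {"Lys": 120.0, "Trp": 300.0, "Tyr": 220.0,
                  "Cys_T": 180.0, "Cys_R": 400.0}
DEFAULT_INTERCEPT = 25.0
DEFAULT_BUFFER_LEVEL = 40.0
DEFAULT_LABEL_LEVEL = 120.0
DEFAULT_PLASMA_LEVEL = 60.0
N_STANDARD_POINTS = 6


@dataclass
class CohortConfig:
    """Cohort generation parameters (counts per disease profile + noise)."""

    counts: dict[str, int]
    replicates: int = 3
    technical_cv: float = 0.05
    seed: int = 0
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    dilutions: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_DILUTIONS))
    slopes: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SLOPES))
    intercept: float = DEFAULT_INTERCEPT
    profiles: dict[str, DiseaseProfile] = field(default_factory=builtin_profiles)

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.counts.values()):
            raise GeneratorError("patient counts must be >= 0")
        if sum(self.counts.values()) == 0:
            raise GeneratorError("cohort requires at least one patient")
        if self.replicates < 1:
            raise GeneratorError("replicates must be >= 1")
        if self.technical_cv < 0:
            raise GeneratorError("technical CV must be >= 0")
        unknown = set(self.counts) - set(self.profiles)
        if unknown:
            raise GeneratorError(f"no profile for labels {sorted(unknown)}")


@dataclass
class SyntheticPatient:
    id: str
    label: str
    composition: PlasmaComposition
    aacs_normalized: AACSVector
    aacs_absolute: AACSVector


@dataclass
class SyntheticCohort:
    patients: list[SyntheticPatient]
    plate: pd.DataFrame
    curves: dict[str, CalibrationCurve]
    config: CohortConfig

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": [p.id for p in self.patients],
             "label": [p.label for p in self.patients]}
        )

    def true_aacs_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            for mode, vec in (("normalized", p.aacs_normalized),
                              ("absolute", p.aacs_absolute)):
                rows.append({"sample_id": p.id, "mode": mode, **vec.as_dict()})
        return pd.DataFrame(rows)


_PANEL_CACHE: dict[str, ProteinRecord] | None = None


def _panel_records() -> dict[str, ProteinRecord]:
    global _PANEL_CACHE
    if _PANEL_CACHE is None:
        _PANEL_CACHE = {r.id: r for r in packaged_panel()}
    return _PANEL_CACHE


def sample_patient_composition(
    profile: DiseaseProfile,
    rng: np.random.Generator,
    panel: dict[str, ProteinRecord] | None = None,
    channels: ChannelSet | None = None,
    total_protein_mg_ml: float | None = None,
) -> PlasmaComposition:
    """Draw one patient's plasma composition from a disease profile.

    Total protein (mg/mL) is uniform over the profile range, converted to
    a total molar concentration via the panel's sequence-derived molecular
    weights; panel proportions are Dirichlet-distributed around the
    profile center with precision ``dispersion``.
    """
    panel = panel or _panel_records()
    channels = channels or ChannelSet()
    center = profile.center_proportions()
    missing = [pid for pid in center if pid not in panel]
    if missing:
        raise GeneratorError(f"panel proteins lacking sequences: {missing}")
    pids = list(center)
    p = np.array([center[pid] for pid in pids])
    if total_protein_mg_ml is None:
        lo, hi = profile.total_protein_range
        total_protein_mg_ml = float(rng.uniform(lo, hi))
    if np.isfinite(profile.dispersion):
        alpha = np.clip(profile.dispersion * p, 1e-9, None)
        p = rng.dirichlet(alpha)
    mws = np.array([panel[pid].molecular_weight for pid in pids])
    total_uM = total_protein_mg_ml * 1e6 / float(p @ mws)
    comps = []
    for pid, frac in zip(pids, p):
        counts = count_residues(panel[pid], channels)
        comps.append(PlasmaComponent(counts, total_uM * frac, pid, panel[pid]))
    return PlasmaComposition(tuple(comps))


def _make_curves(config: CohortConfig) -> dict[str, CalibrationCurve]:
    """The generator's true forward-model curves (also usable for decode)."""
    curves = {}
    for ch in config.channels:
        lo, hi = _standard_grid(config, ch)[[0, -1]]
        curves[ch] = CalibrationCurve(
            ch, config.slopes[ch], config.intercept, 1.0, (float(lo), float(hi))
        )
    return curves


_GRID_CACHE: dict = {}


def _standard_grid(config: CohortConfig, channel: str) -> np.ndarray:
    """Diluted residue-concentration grid for a channel's standard wells.

    Spans 0.2x-2x of the healthy-center diluted concentration so typical
    diluted patient wells fall inside the quantitative range.
    """
    healthy = config.profiles.get("healthy", DiseaseProfile("healthy"))
    key = (channel, config.dilutions[channel], healthy.ig_fraction,
           tuple(sorted(healthy.ig_classes.items())), config.channels)
    if key in _GRID_CACHE:
        return _GRID_CACHE[key]
    panel = _panel_records()
    profile = config.profiles.get("healthy", DiseaseProfile("healthy"))
    center = profile.center_proportions()
    chanset = ChannelSet(config.channels)
    mws = np.array([panel[pid].molecular_weight for pid in center])
    p = np.array(list(center.values()))
    total_uM = 70.0 * 1e6 / float(p @ mws)
    counts = np.array(
        [count_residues(panel[pid], chanset)[channel] for pid in center]
    )
    c_center = float((p * counts).sum() * total_uM) / config.dilutions[channel]
    grid = np.linspace(0.2 * c_center, 2.0 * c_center, N_STANDARD_POINTS)
    _GRID_CACHE[key] = grid
    return grid


def simulate_plate(
    true_absolute: dict[str, AACSVector],
    config: CohortConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate 96-well plate reads for a batch of patients.

    One plate per channel per batch of up to 29 patients: 3 blank wells,
    6 standard wells, then ``replicates`` sample wells per patient.
    Intensities follow mean x lognormal(0, technical_cv).
    """
    def noisy(mean: float) -> float:
        if config.technical_cv == 0:
            return float(mean)
        return float(mean * np.exp(rng.normal(0.0, config.technical_cv)))

    rows: list[dict] = []
    sample_ids = list(true_absolute)
    n_std_wells = N_STANDARD_POINTS * config.replicates
    per_plate = (96 - 3 - n_std_wells) // config.replicates
    if per_plate < 1:
        raise GeneratorError("replicate count leaves no sample wells on a plate")
    for ch in config.channels:
        slope, icept = config.slopes[ch], config.intercept
        dil = config.dilutions[ch]
        grid = _standard_grid(config, ch)
        for batch_i in range(0, len(sample_ids), per_plate):
            batch = sample_ids[batch_i : batch_i + per_plate]
            plate_id = f"{ch}_p{batch_i // per_plate}"
            wells = iter(f"{r}{c}" for r in "ABCDEFGH" for c in range(1, 13))

            def emit(role, sample_id, intensity, std_conc=np.nan, rep=0):
                rows.append({
                    "plate_id": plate_id, "well": next(wells),
                    "sample_id": sample_id, "channel": ch,
                    "replicate": rep, "role": role,
                    "intensity": noisy(intensity), "dilution": dil,
                    "standard_conc_uM": std_conc,
                })

            emit("label_blank", "", DEFAULT_BUFFER_LEVEL + DEFAULT_LABEL_LEVEL)
            emit("plasma_blank", "", DEFAULT_BUFFER_LEVEL + DEFAULT_PLASMA_LEVEL)
            emit("buffer_blank", "", DEFAULT_BUFFER_LEVEL)
            for conc in grid:
                for rep in range(config.replicates):
                    emit("standard", "STD",
                         slope * conc + icept
                         + DEFAULT_BUFFER_LEVEL + DEFAULT_LABEL_LEVEL,
                         std_conc=float(conc), rep=rep)
            for sid in batch:
                vec = true_absolute[sid]
                if ch not in vec.channels.channels:
                    raise GeneratorError(f"{sid}: AACS lacks channel {ch}")
                c_dil = vec[ch] / dil
                mean = (slope * c_dil + icept + DEFAULT_BUFFER_LEVEL
                        + DEFAULT_LABEL_LEVEL + DEFAULT_PLASMA_LEVEL)
                for rep in range(config.replicates):
                    rows.append({
                        "plate_id": plate_id, "well": next(wells),
                        "sample_id": sid, "channel": ch,
                        "replicate": rep, "role": "sample",
                        "intensity": noisy(mean), "dilution": dil,
                        "standard_conc_uM": np.nan,
                    })
    return pd.DataFrame(rows, columns=PLATE_COLUMNS)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a labelled cohort with true values and simulated plates."""
    seed_seq = np.random.SeedSequence(config.seed)
    rng_comp, rng_plate = (np.random.default_rng(s) for s in seed_seq.spawn(2))
    panel = _panel_records()
    chanset = ChannelSet(config.channels)
    patients: list[SyntheticPatient] = []
    true_abs: dict[str, AACSVector] = {}
    idx = 0
    for label in sorted(config.counts):
        profile = config.profiles[label]
        for _ in range(config.counts[label]):
            pid = f"S{idx:04d}"
            idx += 1
            comp = sample_patient_composition(profile, rng_comp, panel, chanset)
            norm = embed(comp)
            absolute = total_residue_concentrations(comp)
            patients.append(SyntheticPatient(pid, label, comp, norm, absolute))
            true_abs[pid] = absolute
    plate = simulate_plate(true_abs, config, rng_plate)
    return SyntheticCohort(patients, plate, _make_curves(config), config)


def _config_dict(config: CohortConfig) -> dict:
    d = asdict(config)
    d["profiles"] = {k: asdict(v) for k, v in config.profiles.items()}
    d["channels"] = list(config.channels)
    d["generator_version"] = GENERATOR_VERSION
    return d


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write plate/labels/true-AACS CSVs and the resolved config JSON."""
    directory = Path(directory)
    if not directory.exists():
        raise FileNotFoundError(f"output directory does not exist: {directory}")
    paths = {
        "plate": directory / "plate.csv",
        "labels": directory / "labels.csv",
        "true_aacs": directory / "true_aacs.csv",
        "config": directory / "config.json",
    }
    cohort.plate.to_csv(paths["plate"], index=False, float_format="%.17g")
    cohort.labels_frame().to_csv(paths["labels"], index=False)
    cohort.true_aacs_frame().to_csv(paths["true_aacs"], index=False,
                                    float_format="%.17g")
    cfg = _config_dict(cohort.config)
    cfg["curves"] = {ch: c.to_dict() for ch, c in cohort.curves.items()}
    paths["config"].write_text(json.dumps(cfg, indent=2, sort_keys=True))
    return paths


def cohort_checksums(directory: str | Path) -> dict[str, str]:
    directory = Path(directory)
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(directory.glob("*.csv"))
    }
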