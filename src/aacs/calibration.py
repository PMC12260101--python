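"""Fluorescence calibration: background correction, linear fits, inversion.

Each residue channel is measured by a fluorogenic label whose corrected
intensity is linear in the residue concentration of the (diluted) well.
Calibration curves are fit on protein standards of known sequence and
concentration (residue concentration = protein concentration x residue
count), then inverted to turn patient-well fluorescence into neat-plasma
residue concentrations via the channel's dilution factor.

Background model: a sample well contains the buffer baseline plus the
unreacted-label background plus the diluted-plasma autofluorescence plus
signal.  Subtracting the label-only and plasma-only blank wells removes
the buffer baseline twice, so it is restored once:

    corrected = raw - label_blank - plasma_blank + buffer_blank

Negative corrected intensities clip to zero with a QC flag.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import DEFAULT_CHANNELS

#: plasma dilution factors used for patient wells (1:60 for the four
#: abundant channels, 1:6 for the sparser free-cysteine channel)
DEFAULT_DILUTIONS: dict[str, int] = {
    "Lys": 60, "Trp": 60, "Tyr": 60, "Cys_T": 60, "Cys_R": 6,
}

DILUTION_LADDER = (1, 2, 6, 10, 20, 60, 120)

PLATE_COLUMNS = [
    "plate_id", "well", "sample_id", "channel", "replicate",
    "role", "intensity", "dilution", "standard_conc_uM",
]

ROLES = {"sample", "label_blank", "plasma_blank", "buffer_blank", "standard"}

_WELLS_96 = tuple(f"{r}{c}" for r in "ABCDEFGH" for c in range(1, 13))


class CalibrationError(ValueError):
    """Calibration fitting or inversion failure."""


class PlateError(ValueError):
    """Malformed or incomplete plate data."""


@dataclass(frozen=True)
class ChannelConfig:
    """Per-channel measurement configuration."""

    channel: str
    dilution: int
    excitation_nm: float | None = None
    emission_nm: float | None = None

    def __post_init__(self) -> None:
        if self.dilution < 1:
            raise ValueError("dilution factor must be >= 1")


def default_channel_configs() -> dict[str, ChannelConfig]:
    return {ch: ChannelConfig(ch, DEFAULT_DILUTIONS[ch]) for ch in DEFAULT_CHANNELS}


@dataclass(frozen=True)
class CalibrationCurve:
    """Accepted linear fluorescence<->concentration map for one channel."""

    channel: str
    slope: float  # a.u. per uM residues
    intercept: float  # a.u.
    r_squared: float
    conc_range: tuple[float, float]  # uM residues spanned by standards

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise CalibrationError(f"{self.channel}: slope must be positive")
        lo, hi = self.conc_range
        if not lo < hi:
            raise CalibrationError(f"{self.channel}: degenerate concentration range")

    def predict(self, conc: np.ndarray | float) -> np.ndarray | float:
        return self.slope * conc + self.intercept

    def to_dict(self) -> dict:
        return {
            "channel": self.channel,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "conc_range": list(self.conc_range),
        }


@dataclass
class MeasuredAACS:
    """Per-sample measured signature: mean neat-plasma uM and CV per channel."""

    sample_id: str
    concentrations: dict[str, float]
    cvs: dict[str, float]
    flags: dict[str, list[str]] = field(default_factory=dict)


def validate_well(well: str) -> str:
    if well not in _WELLS_96:
        raise PlateError(f"invalid 96-well name {well!r} (expected A1..H12)")
    return well


def correct_background(
    raw: float,
    label_blank: float,
    plasma_blank: float,
    buffer_blank: float | None = None,
) -> tuple[float, list[str]]:
    """Blank-subtract one read; returns (corrected, qc_flags).

    With ``buffer_blank=None`` plain two-blank subtraction is used
    (raw - label - plasma); otherwise the buffer baseline, present in both
    blanks, is restored once.
    """
    corrected = raw - label_blank - plasma_blank
    if buffer_blank is not None:
        corrected += buffer_blank
    flags: list[str] = []
    if corrected < 0:
        corrected = 0.0
        flags.append("negative_corrected")
    return float(corrected), flags


def fit_calibration(
    concentrations: np.ndarray,
    intensities: np.ndarray,
    channel: str,
    r2_threshold: float = 0.98,
    through_origin: bool = False,
) -> CalibrationCurve:
    """Ordinary least squares of corrected intensity on residue concentration.

    Free intercept by default; rejects curves with fewer than three distinct
    concentrations, non-positive slope, or R^2 below ``r2_threshold``.
    """
    conc = np.asarray(concentrations, dtype=float)
    intens = np.asarray(intensities, dtype=float)
    if conc.shape != intens.shape:
        raise CalibrationError("concentration/intensity arrays must align")
    if len(np.unique(conc)) < 3:
        raise CalibrationError(
            f"{channel}: need >= 3 distinct standard concentrations, "
            f"got {len(np.unique(conc))}"
        )
    if through_origin:
        slope = float(conc @ intens / (conc @ conc))
        intercept = 0.0
    else:
        slope, intercept = (float(v) for v in np.polyfit(conc, intens, 1))
    fitted = slope * conc + intercept
    ss_res = float(((intens - fitted) ** 2).sum())
    ss_tot = float(((intens - intens.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    r2 = min(max(r2, 0.0), 1.0)
    if slope <= 0:
        raise CalibrationError(f"{channel}: rejected, non-positive slope {slope:.4g}")
    if r2 < r2_threshold:
        raise CalibrationError(
            f"{channel}: rejected, R^2 {r2:.4f} < threshold {r2_threshold}"
        )
    return CalibrationCurve(
        channel, slope, intercept, r2, (float(conc.min()), float(conc.max()))
    )


def invert_calibration(
    curve: CalibrationCurve,
    intensity: float,
    dilution: float = 1.0,
    range_tolerance: float = 0.1,
) -> tuple[float, list[str]]:
    """Invert an accepted curve: (intensity - intercept)/slope x dilution.

    Returns (neat-plasma uM, qc_flags); diluted concentrations outside the
    standard range (± ``range_tolerance`` fraction of the span) are flagged
    ``extrapolated``.
    """
    if not np.isfinite(intensity):
        raise CalibrationError(f"{curve.channel}: non-finite intensity")
    c_diluted = (intensity - curve.intercept) / curve.slope
    flags: list[str] = []
    lo, hi = curve.conc_range
    pad = range_tolerance * (hi - lo)
    if not (lo - pad) <= c_diluted <= (hi + pad):
        flags.append("extrapolated")
    return float(c_diluted * dilution), flags


def recommend_dilution(
    expected_range: tuple[float, float],
    curve_range: tuple[float, float],
    ladder: tuple[int, ...] = DILUTION_LADDER,
) -> int:
    """Smallest ladder dilution placing the whole expected range in-curve."""
    lo, hi = expected_range
    clo, chi = curve_range
    if not (0 < lo <= hi) or not (0 < clo < chi):
        raise CalibrationError("expected and curve ranges must be positive")
    for d in sorted(ladder):
        if clo <= lo / d and hi / d <= chi:
            return d
    raise CalibrationError(
        f"no ladder dilution maps expected range [{lo}, {hi}] uM into "
        f"curve range [{clo}, {chi}] uM"
    )


def read_plate_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    return validate_plate(df)


def validate_plate(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(PLATE_COLUMNS) - {"standard_conc_uM"} - set(df.columns)
    if missing:
        raise PlateError(f"plate table missing columns {sorted(missing)}")
    bad_roles = set(df["role"]) - ROLES
    if bad_roles:
        raise PlateError(f"unknown plate roles {sorted(bad_roles)}")
    if not np.isfinite(df["intensity"]).all():
        raise PlateError("non-finite intensities in plate table")
    for well in df["well"].unique():
        validate_well(well)
    return df


def _blank_means(plate: pd.DataFrame, plate_id, channel: str) -> dict[str, float]:
    sel = plate[(plate["plate_id"] == plate_id) & (plate["channel"] == channel)]
    out = {}
    for role in ("label_blank", "plasma_blank", "buffer_blank"):
        reads = sel.loc[sel["role"] == role, "intensity"]
        if reads.empty:
            raise PlateError(
                f"plate {plate_id!r} channel {channel}: missing {role} well"
            )
        out[role] = float(reads.mean())
    return out


def fit_calibration_from_plate(
    plate: pd.DataFrame,
    channel: str,
    r2_threshold: float = 0.98,
    through_origin: bool = False,
) -> CalibrationCurve:
    """Fit a channel's curve from the plate's standard wells.

    Standard wells carry their diluted residue concentration in
    ``standard_conc_uM``; they are corrected with the label and buffer
    blanks (no plasma component in a standard well).  Replicate wells of
    one concentration on one plate are averaged before fitting.
    """
    stds = plate[(plate["channel"] == channel) & (plate["role"] == "standard")]
    if stds.empty:
        raise CalibrationError(f"{channel}: no standard wells on plate")
    conc, intens = [], []
    for plate_id, group in stds.groupby("plate_id"):
        blanks = _blank_means(plate, plate_id, channel)
        for std_conc, reads in group.groupby("standard_conc_uM"):
            vals = [
                correct_background(
                    row.intensity,
                    blanks["label_blank"],
                    blanks["buffer_blank"],  # stands in for the absent plasma blank
                    blanks["buffer_blank"],
                )[0]
                for row in reads.itertuples(index=False)
            ]
            conc.append(float(std_conc))
            intens.append(float(np.mean(vals)))
    return fit_calibration(
        np.array(conc), np.array(intens), channel, r2_threshold, through_origin
    )


def measure_aacs(
    plate: pd.DataFrame,
    curves: dict[str, CalibrationCurve],
    channel_configs: dict[str, ChannelConfig] | None = None,
    cv_threshold: float = 0.20,
    range_tolerance: float = 0.1,
) -> list[MeasuredAACS]:
    """Turn sample plate reads into per-sample mean AACS concentrations.

    Per sample and channel each replicate is background-corrected with its
    plate's blanks, inverted through the accepted curve, and scaled by the
    well's dilution; the triplicate (or n-licate) mean and CV are reported.
    CV above ``cv_threshold`` and extrapolated inversions are QC-flagged.
    """
    channel_configs = channel_configs or default_channel_configs()
    validate_plate(plate)
    samples = plate[plate["role"] == "sample"]
    results: list[MeasuredAACS] = []
    for sample_id, per_sample in samples.groupby("sample_id", sort=False):
        concs: dict[str, float] = {}
        cvs: dict[str, float] = {}
        flags: dict[str, list[str]] = {}
        for channel, group in per_sample.groupby("channel", sort=False):
            if channel not in curves:
                raise CalibrationError(f"no accepted curve for channel {channel}")
            dilutions = group["dilution"].unique()
            if len(dilutions) != 1:
                raise PlateError(
                    f"{sample_id}/{channel}: mixed dilution factors "
                    f"{sorted(dilutions)} within one replicate set"
                )
            ch_flags: list[str] = []
            values = []
            for plate_id, reads in group.groupby("plate_id"):
                blanks = _blank_means(plate, plate_id, channel)
                for row in reads.itertuples(index=False):
                    corrected, f1 = correct_background(
                        row.intensity,
                        blanks["label_blank"],
                        blanks["plasma_blank"],
                        blanks["buffer_blank"],
                    )
                    neat, f2 = invert_calibration(
                        curves[channel], corrected, row.dilution, range_tolerance
                    )
                    values.append(neat)
                    ch_flags.extend(f1 + f2)
            arr = np.array(values)
            mean = float(arr.mean())
            cv = 0.0 if mean == 0 else float(arr.std(ddof=1) / mean) if len(arr) > 1 else 0.0
            if cv > cv_threshold:
                ch_flags.append("high_cv")
            concs[channel] = mean
            cvs[channel] = cv
            if ch_flags:
                flags[channel] = sorted(set(ch_flags))
        results.append(MeasuredAACS(str(sample_id), concs, cvs, flags))
    return results


def measured_to_frame(measured: list[MeasuredAACS]) -> pd.DataFrame:
    """Wide per-sample table: one concentration and CV column per channel."""
    rows = []
    for m in measured:
        row: dict = {"sample_id": m.sample_id}
        for ch, v in m.concentrations.items():
            row[ch] = v
            row[f"{ch}_cv"] = m.cvs[ch]
            row[f"{ch}_flags"] = ";".join(m.flags.get(ch, []))
        rows.append(row)
    return pd.DataFrame(rows)
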