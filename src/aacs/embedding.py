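"""Mixture embedding: per-protein residue vectors and the plasma AACS.

A protein with residue counts a_1..a_n at molar concentration theta
contributes the vector <a_1 theta, ..., a_n theta> (residue micromolar).
A mixture of alpha proteins is embedded as the molar-fraction-weighted
sum E_n = sum_i a_n,i beta_i with beta_i = theta_i / sum(theta): the mean
number of channel-n residues per protein molecule ("normalized" mode).
Multiplying by the total molar concentration gives the absolute mode,
total residue concentrations in uM — the quantity the fluorescence
measurement pipeline reports.

All concentrations are micromolar throughout; unit conversions happen at
I/O edges only.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import ALL_CHANNELS, CYS_REDUCED, ChannelSet
from .composition import ProteinRecord, ResidueCountVector, count_residues

_ATOL = 1e-12


class CompositionError(ValueError):
    """Degenerate or inconsistent plasma composition."""


@dataclass(frozen=True)
class PlasmaComponent:
    """One protein of a plasma mixture: residue counts + molar concentration.

    ``record`` optionally keeps the source sequence so operations needing
    channels outside ``counts`` (axis ranking) can recount.
    """

    counts: ResidueCountVector
    molar_concentration: float  # uM
    protein_id: str = ""
    record: ProteinRecord | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if not np.isfinite(self.molar_concentration) or self.molar_concentration < 0:
            raise CompositionError(
                f"molar concentration must be finite and >= 0, "
                f"got {self.molar_concentration}"
            )


@dataclass(frozen=True)
class PlasmaComposition:
    """A mixture of plasma proteins (the summation domain of the embedding)."""

    components: tuple[PlasmaComponent, ...]

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        object.__setattr__(self, "components", comps)
        if len(comps) < 1:
            raise CompositionError("composition requires at least one component")
        chans = comps[0].counts.channels
        if any(c.counts.channels != chans for c in comps):
            raise CompositionError("all components must share one channel set")

    @property
    def channels(self) -> ChannelSet:
        return self.components[0].counts.channels

    @property
    def size(self) -> int:
        return len(self.components)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c.molar_concentration for c in self.components])

    @property
    def total_concentration(self) -> float:
        return float(self.concentrations.sum())

    def count_matrix(self) -> np.ndarray:
        """alpha x n_channels matrix of residue counts."""
        return np.vstack([c.counts.as_array() for c in self.components])


@dataclass(frozen=True)
class AACSVector:
    """Per-channel AACS values, normalized (residues/protein) or absolute (uM)."""

    channels: ChannelSet
    values: tuple[float, ...]
    mode: str  # "normalized" | "absolute"

    def __post_init__(self) -> None:
        if self.mode not in ("normalized", "absolute"):
            raise ValueError(f"unknown AACS mode {self.mode!r}")
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        if any(v < -_ATOL for v in vals):
            raise ValueError("AACS values must be non-negative")

    def __getitem__(self, channel: str) -> float:
        return self.values[self.channels.index(channel)]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.channels.channels, self.values))


def protein_vector(component: PlasmaComponent) -> np.ndarray:
    """Per-channel residue concentrations a_n * theta for one protein (uM)."""
    return component.counts.as_array() * component.molar_concentration


def molar_fractions(composition: PlasmaComposition) -> np.ndarray:
    """beta_i = theta_i / sum(theta); errors on an all-zero composition."""
    theta = composition.concentrations
    total = theta.sum()
    if total <= 0:
        raise CompositionError("degenerate composition: total molar concentration is 0")
    return theta / total


def embed(composition: PlasmaComposition) -> AACSVector:
    """Normalized-mode embedding: E_n = sum_i a_n,i beta_i.

    Invariant to uniform rescaling of all component concentrations.
    """
    beta = molar_fractions(composition)
    values = beta @ composition.count_matrix()
    return AACSVector(composition.channels, tuple(values), "normalized")


def total_residue_concentrations(composition: PlasmaComposition) -> AACSVector:
    """Absolute-mode AACS: channel n = sum_i a_n,i theta_i (uM residues)."""
    theta = composition.concentrations
    values = theta @ composition.count_matrix()
    return AACSVector(composition.channels, tuple(values), "absolute")


def read_composition_csv(path: str | Path) -> pd.DataFrame:
    """Composition table: columns protein_id, molar_concentration_uM."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    required = {"protein_id", "molar_concentration_uM"}
    missing = required - set(df.columns)
    if missing:
        raise CompositionError(f"composition table missing columns {sorted(missing)}")
    if (df["molar_concentration_uM"] < 0).any():
        raise CompositionError("negative molar concentrations in composition table")
    return df


def composition_from_records(
    table: pd.DataFrame,
    records: list[ProteinRecord],
    channels: ChannelSet | None = None,
    on_ambiguous: str = "error",
) -> PlasmaComposition:
    """Join a composition table with sequence records into a composition."""
    channels = channels or ChannelSet()
    by_id = {r.id: r for r in records}
    comps = []
    for row in table.itertuples(index=False):
        rec = by_id.get(row.protein_id)
        if rec is None:
            raise CompositionError(
                f"composition table id {row.protein_id!r} has no sequence"
            )
        counts = count_residues(rec, channels, on_ambiguous=on_ambiguous)
        comps.append(
            PlasmaComponent(counts, float(row.molar_concentration_uM), rec.id, rec)
        )
    return PlasmaComposition(tuple(comps))


def theoretical_aacs(
    table: pd.DataFrame,
    records: list[ProteinRecord],
    channels: ChannelSet | None = None,
) -> dict:
    """Theoretical AACS of a composition table (both modes + breakdown).

    Returns a dict with ``normalized`` and ``absolute`` AACSVectors and a
    per-protein ``contributions`` DataFrame (absolute uM per channel) whose
    column sums equal the absolute vector.
    """
    channels = channels or ChannelSet()
    comp = composition_from_records(table, records, channels)
    norm = embed(comp)
    absolute = total_residue_concentrations(comp)
    rows = {c.protein_id: protein_vector(c) for c in comp.components}
    contributions = pd.DataFrame.from_dict(
        rows, orient="index", columns=list(channels.channels)
    )
    return {"normalized": norm, "absolute": absolute, "contributions": contributions}


@dataclass(frozen=True)
class AxisSpread:
    channel: str
    spread: float
    class_values: tuple[float, ...] = field(default=(), compare=False)


def rank_axes(
    class_compositions: list[PlasmaComposition],
    candidate_channels: tuple[str, ...] = ALL_CHANNELS,
) -> list[AxisSpread]:
    """Rank candidate channels by between-class spread of the embedding.

    For each candidate channel the normalized-mode value is computed per
    class composition; the spread statistic is the coefficient of range
    (max - min) / mean across classes (0 when the mean is 0).  Channels are
    ordered by decreasing spread, alphabetical channel name breaking ties.
    """
    if len(class_compositions) < 2:
        raise CompositionError("axis ranking needs at least two class compositions")
    results = []
    for ch in candidate_channels:
        chanset = ChannelSet(("Cys_T", ch)) if ch == CYS_REDUCED else ChannelSet((ch,))
        vals = []
        for comp in class_compositions:
            rebuilt = []
            for c in comp.components:
                # recount on the requested channel; reuse annotations via counts
                rec = _component_record(c)
                counts = count_residues(rec, chanset)
                rebuilt.append(
                    PlasmaComponent(counts, c.molar_concentration, c.protein_id)
                )
            vals.append(embed(PlasmaComposition(tuple(rebuilt)))[ch])
        vals_arr = np.array(vals)
        mean = vals_arr.mean()
        spread = 0.0 if mean == 0 else float((vals_arr.max() - vals_arr.min()) / mean)
        results.append(AxisSpread(ch, spread, tuple(vals)))
    return sorted(results, key=lambda r: (-r.spread, r.channel))


def _component_record(component: PlasmaComponent) -> ProteinRecord:
    if component.record is None:
        raise CompositionError(
            "rank_axes requires sequence-backed compositions "
            "(build them via composition_from_records)"
        )
    return component.record


def rank_axes_from_records(
    class_tables: list[pd.DataFrame],
    records: list[ProteinRecord],
    candidate_channels: tuple[str, ...] = ALL_CHANNELS,
) -> list[AxisSpread]:
    """rank_axes over composition tables joined against sequence records."""
    if len(class_tables) < 2:
        raise CompositionError("axis ranking needs at least two class compositions")
    results = []
    for ch in candidate_channels:
        chanset = ChannelSet(("Cys_T", ch)) if ch == CYS_REDUCED else ChannelSet((ch,))
        vals = []
        for table in class_tables:
            comp = composition_from_records(table, records, chanset)
            vals.append(embed(comp)[ch])
        vals_arr = np.array(vals)
        mean = vals_arr.mean()
        spread = 0.0 if mean == 0 else float((vals_arr.max() - vals_arr.min()) / mean)
        results.append(AxisSpread(ch, spread, tuple(vals)))
    return sorted(results, key=lambda r: (-r.spread, r.channel))
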