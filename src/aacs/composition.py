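"""Protein sequence handling and residue-channel counting.

Reads FASTA sequence sets and disulfide-bond annotations, validates them
against the 20-letter canonical alphabet, and counts the residues feeding
each AACS channel.  The only non-trivial channel is Cys_R (free cysteine):
Cys_R = Cys_T - 2 x disulfide_bond_count, so it needs the bond annotation.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.SeqUtils import molecular_weight as _bio_mw

from .channels import CANONICAL_LETTERS, CYS_REDUCED, ChannelSet, channel_letter

AMBIGUOUS_LETTERS = set("BZXUO")


class SequenceError(ValueError):
    """Invalid or inconsistent sequence/annotation input."""


@dataclass
class ProteinRecord:
    """A protein sequence with optional disulfide-bond annotation.

    ``disulfide_bond_count`` is the number of S-S *bonds* (not residues);
    ``None`` means unknown.  ``flags`` carries provenance notes such as the
    unknown-disulfide policy having been applied.
    """

    id: str
    sequence: str
    disulfide_bond_count: int | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = "".join(self.sequence.split()).upper()
        if not self.id:
            raise SequenceError("protein record requires a non-empty id")
        if not self.sequence:
            raise SequenceError(f"empty sequence for record {self.id!r}")
        if self.disulfide_bond_count is not None:
            self._check_disulfides(self.disulfide_bond_count)

    def _check_disulfides(self, bonds: int) -> None:
        if bonds < 0:
            raise SequenceError(f"{self.id}: negative disulfide bond count {bonds}")
        n_cys = self.sequence.count("C")
        if 2 * bonds > n_cys:
            raise SequenceError(
                f"{self.id}: {bonds} disulfide bonds need {2 * bonds} Cys "
                f"but sequence has {n_cys}"
            )

    @property
    def molecular_weight(self) -> float:
        """Average molecular weight in daltons (residues + one water)."""
        seq = "".join(c for c in self.sequence if c in CANONICAL_LETTERS)
        return _bio_mw(seq, seq_type="protein")


@dataclass(frozen=True)
class ResidueCountVector:
    """Non-negative residue counts per channel of a ChannelSet."""

    channels: ChannelSet
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.channels):
            raise ValueError("counts length must match channels")
        if any(c < 0 for c in self.counts):
            raise ValueError("residue counts must be non-negative")
        chans = self.channels.channels
        if CYS_REDUCED in chans and "Cys_T" in chans:
            if self[CYS_REDUCED] > self["Cys_T"]:
                raise ValueError("Cys_R count cannot exceed Cys_T count")

    def __getitem__(self, channel: str) -> int:
        return self.counts[self.channels.index(channel)]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.channels.channels, self.counts))


def validate_sequence(record: ProteinRecord, on_ambiguous: str = "error") -> str:
    """Return the sequence with ambiguity policy applied.

    ``on_ambiguous='error'`` rejects non-canonical letters (B, Z, X, U, O or
    anything else), naming the offending position; ``'ignore'`` drops them
    from counting (they contribute to no channel) and flags the record.
    """
    seq = record.sequence
    bad = [(i, c) for i, c in enumerate(seq) if c not in CANONICAL_LETTERS]
    if not bad:
        return seq
    if on_ambiguous == "ignore":
        if "ambiguous_letters_ignored" not in record.flags:
            record.flags.append("ambiguous_letters_ignored")
        return "".join(c for c in seq if c in CANONICAL_LETTERS)
    pos, letter = bad[0]
    raise SequenceError(
        f"{record.id}: non-canonical residue {letter!r} at position {pos + 1}"
    )


def count_residues(
    record: ProteinRecord,
    channels: ChannelSet | None = None,
    on_ambiguous: str = "error",
    unknown_disulfides: str = "all_free",
) -> ResidueCountVector:
    """Count residues per channel; Cys_R = Cys_T - 2 x disulfide bonds.

    When Cys_R is requested but the bond count is unknown, the default
    policy treats every cysteine as free (conservative upper bound) and
    flags the record; ``unknown_disulfides='error'`` raises instead.
    """
    channels = channels or ChannelSet()
    seq = validate_sequence(record, on_ambiguous)
    counts: list[int] = []
    for ch in channels:
        letter = channel_letter(ch)
        if letter is not None:
            counts.append(seq.count(letter))
            continue
        cys_t = seq.count("C")
        bonds = record.disulfide_bond_count
        if bonds is None:
            if unknown_disulfides == "error":
                raise SequenceError(
                    f"{record.id}: Cys_R requested but disulfide bond count unknown"
                )
            if "disulfides_unknown_assumed_free" not in record.flags:
                record.flags.append("disulfides_unknown_assumed_free")
            bonds = 0
        counts.append(cys_t - 2 * bonds)
    return ResidueCountVector(channels, tuple(counts))


def read_fasta(path: str | Path, on_ambiguous: str = "error") -> list[ProteinRecord]:
    """Read a FASTA file into ProteinRecords (ids = header first token)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise SequenceError(f"duplicate FASTA id {entry.id!r} in {path}")
        seen.add(entry.id)
        if not str(entry.seq):
            raise SequenceError(f"empty sequence for FASTA entry {entry.id!r}")
        rec = ProteinRecord(id=entry.id, sequence=str(entry.seq))
        validate_sequence(rec, on_ambiguous)
        records.append(rec)
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_disulfide_table(path: str | Path) -> dict[str, int]:
    """Read an (id, bond count) two-column CSV/TSV into a validated map."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with path.open(newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if sample.count("\t") >= sample.count(",") else ","
        reader = csv.reader(fh, delimiter=delim)
        rows = [r for r in reader if r and r[0].strip()]
    out: dict[str, int] = {}
    for row in rows:
        key = row[0].strip()
        if key.lower() in {"protein_id", "id"}:
            continue
        try:
            bonds = int(row[1])
        except (IndexError, ValueError) as exc:
            raise SequenceError(f"bad disulfide table row {row!r}") from exc
        if bonds < 0:
            raise SequenceError(f"{key}: negative disulfide bond count {bonds}")
        out[key] = bonds
    return out


def attach_disulfides(
    records: list[ProteinRecord],
    table: dict[str, int],
    missing: str = "all_free",
) -> list[ProteinRecord]:
    """Join bond counts onto records; validates 2 x bonds <= #Cys.

    Table ids absent from the sequence set are an error (a typo would
    silently drop an annotation otherwise).  Records without an annotation
    follow the unknown-disulfide policy: flagged, Cys_R treated as Cys_T.
    """
    ids = {r.id for r in records}
    unknown = set(table) - ids
    if unknown:
        raise SequenceError(f"disulfide table ids not in sequence set: {sorted(unknown)}")
    for rec in records:
        if rec.id in table:
            rec._check_disulfides(table[rec.id])
            rec.disulfide_bond_count = table[rec.id]
        elif missing == "error":
            raise SequenceError(f"{rec.id}: no disulfide annotation")
        else:
            rec.flags.append("disulfides_unknown_assumed_free")
    return records


def _data_path(name: str):
    return resources.files("aacs.data").joinpath(name)


def packaged_panel() -> list[ProteinRecord]:
    """The packaged synthetic plasma panel + calibration standards.

    Sequences other than hen lysozyme (LYZ) are synthetic stand-ins with
    realistic lengths and channel residue counts; see the FASTA headers.
    """
    with resources.as_file(_data_path("plasma_panel.synthetic.fasta")) as p:
        records = read_fasta(p)
    with resources.as_file(_data_path("plasma_panel.synthetic_disulfides.tsv")) as p:
        table = read_disulfide_table(p)
    return attach_disulfides(records, table)
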