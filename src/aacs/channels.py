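"""Residue channel definitions.

A *channel* is one axis of the amino-acid concentration signature (AACS).
The default panel has five channels: total lysine (Lys), tryptophan (Trp),
tyrosine (Tyr), total cysteine (Cys_T) and reduced/free cysteine (Cys_R,
cysteines not engaged in disulfide bonds).  For axis ranking any of the 20
canonical amino acids can serve as a channel; Cys_T is the plain cysteine
count under another name, while Cys_R is derived from Cys_T and the
disulfide-bond annotation (Cys_R = Cys_T - 2 x bonds).
"""
from __future__ import annotations

from dataclasses import dataclass, field

CANONICAL_LETTERS = "ACDEFGHIKLMNPQRSTVWY"

THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}

#: channels counting a single residue letter (Cys_T is an alias for Cys)
_CHANNEL_LETTER = dict(THREE_TO_ONE)
_CHANNEL_LETTER["Cys_T"] = "C"

#: derived channel: free cysteine, Cys_T minus disulfide-engaged residues
CYS_REDUCED = "Cys_R"

DEFAULT_CHANNELS = ("Lys", "Trp", "Tyr", "Cys_T", CYS_REDUCED)

#: all channels usable for axis ranking: the 20 canonical residues
#: (cysteine spelled Cys_T) plus the derived free-cysteine channel
ALL_CHANNELS = tuple(
    sorted(name for name in THREE_TO_ONE if name != "Cys")
) + ("Cys_T", CYS_REDUCED)


def channel_letter(channel: str) -> str | None:
    """One-letter code counted by *channel*, or None for the derived Cys_R."""
    if channel == CYS_REDUCED:
        return None
    try:
        return _CHANNEL_LETTER[channel]
    except KeyError:
        raise ValueError(f"unknown residue channel {channel!r}") from None


@dataclass(frozen=True)
class ChannelSet:
    """Ordered, unique set of residue channels.

    Cys_R may only be requested alongside Cys_T, so that the free/total
    cysteine invariant (Cys_R <= Cys_T) is always checkable.
    """

    channels: tuple[str, ...] = field(default=DEFAULT_CHANNELS)

    def __post_init__(self) -> None:
        chans = tuple(self.channels)
        object.__setattr__(self, "channels", chans)
        if len(set(chans)) != len(chans):
            raise ValueError("channels must be unique")
        for ch in chans:
            channel_letter(ch)  # validates the name
        if CYS_REDUCED in chans and "Cys_T" not in chans:
            raise ValueError("Cys_R requires Cys_T in the same channel set")

    def __iter__(self):
        return iter(self.channels)

    def __len__(self) -> int:
        return len(self.channels)

    def index(self, channel: str) -> int:
        return self.channels.index(channel)
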