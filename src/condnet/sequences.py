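"""Sticker-spacer sequence construction and characterization.

Two sequence families are packaged: the low-complexity domains (LCDs) of four
phase-separating RNA-binding proteins (hnRNPA1, FUS, EWSR1, TIA1), and binary
tyrosine/serine ("YS") model sequences of length 150 in which the sticker
fraction f_h and the blockiness f_B are varied systematically.

Blockiness is defined from junction counting: f_B = 1 - B_act/B_max, where
B_act is the number of adjacent unlike (Y-S or S-Y) pairs and
B_max = min(2*min(n_Y, n_S), n - 1) is the largest junction count attainable
at the same composition.  The alternating sequence then has f_B = 0 and a
diblock has f_B -> 1.  The B_max convention is a documented choice of this
package; it reproduces both stated limits.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from io import StringIO
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Default sticker (aromatic) residues for natural LCD sequences.
AROMATIC_STICKERS = frozenset("FWY")

LCD_NAMES = ("A1-LCD", "FUS-LCD", "EWSR1-LCD", "TIA1-LCD")

#: The ten constructible YS variants (repeat-unit grammar) plus the packaged
#: scrambled sequence.  Patterns are tiled left to right to n = 150.
YS_VARIANTS = {
    "(S9Y)15": "(S9Y)15",
    "(S4Y)30": "(S4Y)30",
    "(SSY)50": "(SSY)50",
    "(YS)75": "(YS)75",
    "(YYS)50": "(YYS)50",
    "Y150": "Y150",
    "S150": "S150",
    "(S12Y3)10": "(S12Y3)10",
    "(S24Y6)5": "(S24Y6)5",
    "S120Y30": "S120Y30",
    "(S120Y30)scr": "scrambled",
}


@dataclass(frozen=True)
class ResidueSequence:
    """A named bead sequence over the 20-letter amino-acid alphabet."""

    name: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if len(self.residues) < 1:
            raise ValueError(f"{self.name}: empty sequence")
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise ValueError(f"{self.name}: invalid residue codes {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_binary_ys(self) -> bool:
        return set(self.residues) <= {"Y", "S"}


@dataclass(frozen=True)
class SequenceMetrics:
    """Composition and patterning metrics of a binary sticker-spacer sequence."""

    f_h: float
    f_B: float
    b_act: int
    b_max: int
    degenerate: bool = field(default=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_h <= 1.0 and 0.0 <= self.f_B <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        if not (0 <= self.b_act <= max(self.b_max, 0) or self.degenerate):
            raise ValueError("junction counts inconsistent")


def _packaged_fasta(filename: str) -> dict[str, str]:
    text = resources.files("condnet.data").joinpath(filename).read_text()
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(StringIO(text), "fasta")}


def build_lcd(name: str) -> ResidueSequence:
    """Return one of the four packaged LCD sequences by canonical name."""
    records = _packaged_fasta("lcd_sequences.fasta")
    if name not in records:
        raise KeyError(f"unknown LCD {name!r}; packaged: {sorted(records)}")
    return ResidueSequence(name, records[name])


_UNIT_RE = re.compile(r"([A-Z])(\d*)")
_PATTERN_RE = re.compile(r"^\((?P<unit>[A-Z0-9]+)\)x?(?P<rep>\d+)$")


def _expand_runs(spec: str) -> str:
    if not re.fullmatch(r"(?:[A-Z]\d*)+", spec):
        raise ValueError(f"cannot parse pattern unit {spec!r}")
    out = []
    for letter, count in _UNIT_RE.findall(spec):
        out.append(letter * (int(count) if count else 1))
    return "".join(out)


def build_ys_variant(pattern: str, expected_length: int | None = None) -> ResidueSequence:
    """Construct a binary YS sequence from a repeat-unit spec.

    ``pattern`` is either ``"scrambled"`` (returning the packaged scrambled
    (S120Y30)scr sequence verbatim), a parenthesized repeat like ``"(S4Y)30"``
    or ``"(S4Y)x30"``, or a plain run-length string like ``"S120Y30"`` or
    ``"Y150"``.  Repeats are tiled left to right.
    """
    if pattern == "scrambled" or pattern == "(S120Y30)scr":
        records = _packaged_fasta("ys_variants.fasta")
        seq = records["(S120Y30)scr"]
        name = "(S120Y30)scr"
    else:
        m = _PATTERN_RE.match(pattern)
        if m:
            seq = _expand_runs(m.group("unit")) * int(m.group("rep"))
        else:
            seq = _expand_runs(pattern)
        name = pattern
    if expected_length is not None and len(seq) != expected_length:
        raise ValueError(
            f"pattern {pattern!r} composes to length {len(seq)}, expected {expected_length}"
        )
    if not set(seq) <= {"Y", "S"}:
        raise ValueError(f"YS variant {pattern!r} contains non-YS residues")
    return ResidueSequence(name, seq)


def hydrophobic_fraction(seq: ResidueSequence, sticker_set: frozenset | set | None = None) -> float:
    """Fraction of sticker residues.

    The sticker set defaults to the aromatics {F, W, Y} for natural sequences
    and to {Y} for binary YS sequences.
    """
    if sticker_set is None:
        sticker_set = {"Y"} if seq.is_binary_ys else AROMATIC_STICKERS
    if not sticker_set:
        raise ValueError("empty sticker set")
    return sum(r in sticker_set for r in seq.residues) / len(seq)


def blockiness(seq: ResidueSequence) -> SequenceMetrics:
    """Junction-count blockiness of a binary YS sequence (see module docstring)."""
    if not seq.is_binary_ys:
        raise ValueError(f"{seq.name}: blockiness is defined on the {{Y,S}} alphabet only")
    s = seq.residues
    n = len(s)
    n_y = s.count("Y")
    n_s = n - n_y
    f_h = n_y / n
    if n_y == 0 or n_s == 0:
        return SequenceMetrics(f_h=f_h, f_B=1.0, b_act=0, b_max=0, degenerate=True)
    b_act = sum(a != b for a, b in zip(s, s[1:]))
    b_max = min(2 * min(n_y, n_s), n - 1)
    return SequenceMetrics(f_h=f_h, f_B=1.0 - b_act / b_max, b_act=b_act, b_max=b_max)


def load_packaged_ys_variants() -> list[ResidueSequence]:
    """All eleven YS variants (ten constructed, one scrambled) as packaged."""
    records = _packaged_fasta("ys_variants.fasta")
    return [ResidueSequence(name, res) for name, res in records.items()]


def read_fasta(path: str | Path) -> list[ResidueSequence]:
    return [ResidueSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(sequences: list[ResidueSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.name, description="") for s in sequences
    ]
    SeqIO.write(records, str(path), "fasta")
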