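"""In silico tryptic digestion and peptide masses.

Trypsin cleaves C-terminal to lysine (K) or arginine (R) unless the next
residue is proline (Keil rule).  Fragment size determines renal routing:
small peptides (<= 6 residues by default) bypass the early proximal tubule
and are reabsorbed downstream, whereas larger fragments trigger S1 uptake.

Masses are singly protonated monoisotopic ([M+H]+), computed with pyteomics;
the rounded integer dalton value is the conventional display form.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from pyteomics import mass as _ptmass

__all__ = [
    "PeptideFragment", "tryptic_digest", "peptide_mh", "rounded_mh",
    "classify_fragment", "digest_table", "digest_fasta",
    "SIZE_CUTOFF_AA", "VALID_RESIDUES",
]

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")
SIZE_CUTOFF_AA = 6  # inclusive: fragments up to this length are "small"

_CLEAVAGE_RE = re.compile(r"(?<=[KR])(?!P)")


def _validate_sequence(sequence: str) -> str:
    if not sequence:
        raise ValueError("empty peptide sequence")
    seq = sequence.upper()
    for i, ch in enumerate(seq):
        if ch not in VALID_RESIDUES:
            raise ValueError(
                f"invalid residue {ch!r} at position {i + 1} in {sequence!r}")
    return seq


def peptide_mh(sequence: str, adduct_mass: float = 0.0) -> float:
    """Singly protonated monoisotopic mass [M+H]+ in daltons.

    ``adduct_mass`` adds a fixed neutral modification (e.g. a dye), default 0.
    """
    seq = _validate_sequence(sequence)
    return float(_ptmass.calculate_mass(sequence=seq, ion_type="M", charge=1)
                 + adduct_mass)


def rounded_mh(sequence: str, adduct_mass: float = 0.0) -> int:
    """[M+H]+ rounded half-up to the nearest integer dalton (display form)."""
    return int(math.floor(peptide_mh(sequence, adduct_mass) + 0.5))


def classify_fragment(sequence: str, length_cutoff: int = SIZE_CUTOFF_AA) -> str:
    """Size class for renal routing: ``small`` iff length <= cutoff, else ``large``."""
    seq = _validate_sequence(sequence)
    return "small" if len(seq) <= length_cutoff else "large"


@dataclass(frozen=True)
class PeptideFragment:
    """A tryptic fragment with its [M+H]+ monoisotopic mass and size class."""

    sequence: str
    mh_mono: float
    size_class: str

    @classmethod
    def from_sequence(cls, sequence: str,
                      length_cutoff: int = SIZE_CUTOFF_AA) -> "PeptideFragment":
        seq = _validate_sequence(sequence)
        return cls(seq, peptide_mh(seq), classify_fragment(seq, length_cutoff))


def tryptic_digest(sequence: str, missed_cleavages: int = 0) -> list[str]:
    """Ordered tryptic fragments of ``sequence``.

    With ``missed_cleavages=0`` the fragments partition the input (they
    concatenate back to it).  ``missed_cleavages=k`` additionally yields every
    merge of up to k+1 adjacent fragments, appended after the fully cleaved
    set in N- to C-terminal order.
    """
    seq = _validate_sequence(sequence)
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    base = [f for f in _CLEAVAGE_RE.split(seq) if f]
    out = list(base)
    for span in range(2, missed_cleavages + 2):
        for i in range(len(base) - span + 1):
            out.append("".join(base[i:i + span]))
    return out


def digest_table(sequence: str, missed_cleavages: int = 0,
                 length_cutoff: int = SIZE_CUTOFF_AA) -> pd.DataFrame:
    """Fragment table: sequence, length, [M+H]+ (exact and rounded), size class."""
    rows = []
    for frag in tryptic_digest(sequence, missed_cleavages):
        mh = peptide_mh(frag)
        rows.append((frag, len(frag), mh, int(math.floor(mh + 0.5)),
                     classify_fragment(frag, length_cutoff)))
    return pd.DataFrame(rows, columns=["sequence", "length", "mh_mono",
                                       "mh_rounded_da", "size_class"])


def digest_fasta(path, missed_cleavages: int = 0,
                 length_cutoff: int = SIZE_CUTOFF_AA) -> pd.DataFrame:
    """Digest every record of a FASTA file; adds a ``record_id`` column."""
    from Bio import SeqIO

    frames = []
    for record in SeqIO.parse(str(path), "fasta"):
        tbl = digest_table(str(record.seq), missed_cleavages, length_cutoff)
        tbl.insert(0, "record_id", record.id)
        frames.append(tbl)
    if not frames:
        raise ValueError(f"no FASTA records in {path}")
    return pd.concat(frames, ignore_index=True)
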