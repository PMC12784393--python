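"""Peptide record container and tab-separated table I/O.

A record is one peptide/charge observation: sequence (one-letter codes),
charge state, measured collisional cross section (CCS, Å²), a free-text
modification annotation, and an optional protease label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

PROTEASES = ("trypsin", "lysc", "lysn", "unknown")


class AlphabetError(ValueError):
    """A sequence contains a character outside the 20-letter amino-acid code."""


def validate_sequence(sequence: str) -> None:
    """Raise :class:`AlphabetError` naming the first offending character."""
    if not sequence:
        raise AlphabetError("empty sequence")
    for pos, ch in enumerate(sequence, start=1):
        if ch not in _AA_SET:
            raise AlphabetError(
                f"invalid amino-acid code {ch!r} at position {pos} in {sequence!r}"
            )


@dataclass(frozen=True)
class PeptideRecord:
    """One peptide/charge observation.

    Parameters
    ----------
    sequence
        Peptide sequence in one-letter amino-acid codes.
    charge
        Positive integer charge state.
    ccs
        Collisional cross section in Å²; must be positive.
    modifications
        Free-text modification annotation (e.g. MaxQuant's
        ``"Acetyl (Protein N-term)"``). Empty string means unmodified.
    protease
        One of ``trypsin``, ``lysc``, ``lysn`` or ``unknown``.
    """

    sequence: str
    charge: int
    ccs: float
    modifications: str = ""
    protease: str = "unknown"

    def __post_init__(self) -> None:
        validate_sequence(self.sequence)
        if self.charge < 1:
            raise ValueError(f"charge must be positive, got {self.charge}")
        if not self.ccs > 0:
            raise ValueError(f"ccs must be positive, got {self.ccs}")
        if self.protease not in PROTEASES:
            raise ValueError(
                f"protease must be one of {PROTEASES}, got {self.protease!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


def read_peptide_table(path: str | Path) -> list[PeptideRecord]:
    """Read a tab-separated peptide table into records.

    Expects a header row with columns ``sequence``, ``charge``, ``ccs``;
    ``modifications`` and ``protease`` are optional. Malformed rows raise a
    ``ValueError`` naming the offending line number (1-based, header = line 1).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sequence", "charge", "ccs"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    records: list[PeptideRecord] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                PeptideRecord(
                    sequence=row.sequence,
                    charge=int(row.charge),
                    ccs=float(row.ccs),
                    modifications=getattr(row, "modifications", ""),
                    protease=getattr(row, "protease", "") or "unknown",
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: malformed record at line {idx}: {exc}") from exc
    return records


def to_frame(records: Iterable[PeptideRecord]) -> pd.DataFrame:
    rows = [
        (r.sequence, r.charge, r.ccs, r.modifications, r.protease) for r in records
    ]
    return pd.DataFrame(
        rows, columns=["sequence", "charge", "ccs", "modifications", "protease"]
    )


def write_peptide_table(records: Sequence[PeptideRecord], path: str | Path) -> None:
    """Write records as a UTF-8 tab-separated table with a header row."""
    to_frame(records).to_csv(path, sep="\t", index=False, lineterminator="\n")
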