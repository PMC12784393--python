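"""Sequence-derived physical and positional peptide features.

Everything the bimodality analysis stratifies on lives here: neutral
monoisotopic mass, basic-site positions and their distances to the
C-terminus, proline counts, protease classification, N-terminal-acetylation
detection, the shared relative-position coordinate, and the cohort filter
(charge, length, basic-site count, protease, modification state).

A *basic site* is a protonatable site: an arginine, lysine or histidine side
chain, or the N-terminal amine. The amine is always counted once and is
recorded as pseudo-position 0 so it can never be "internal"; internal sites
are basic residues at positions 2..n-1, and the distance of an internal site
at position p to the C-terminus is n - p (adjacent to the terminal residue
means distance 1).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .records import AMINO_ACIDS, AlphabetError, PeptideRecord, validate_sequence

WATER_MONOISOTOPIC = 18.0105646
CARBAMIDOMETHYL_DELTA = 57.02146

BASIC_RESIDUES = frozenset("RKH")

#: MaxQuant-style token marking N-terminal acetylation in the modification
#: annotation; configurable per call for other dialects.
NT_ACETYL_TOKEN = "Acetyl (Protein N-term)"


def _load_table(name: str, column: str) -> dict[str, float]:
    ref = importlib.resources.files("ccsbimodal.data").joinpath(name)
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    return dict(zip(df["code"], df[column]))


@dataclass(frozen=True)
class ResidueMassTable:
    """Monoisotopic residue masses (Da) for the 20 standard amino acids."""

    masses: dict[str, float]
    water: float = WATER_MONOISOTOPIC
    carbamidomethyl: float = CARBAMIDOMETHYL_DELTA

    def __post_init__(self) -> None:
        if set(self.masses) != set(AMINO_ACIDS):
            raise ValueError("residue mass table must cover exactly the 20 codes")
        if any(m <= 0 for m in self.masses.values()) or self.water <= 0:
            raise ValueError("all masses must be positive")

    @classmethod
    def default(cls) -> "ResidueMassTable":
        return cls(masses=_load_table("residue_masses.tsv", "monoisotopic_mass"))


_DEFAULT_MASSES: ResidueMassTable | None = None


def default_mass_table() -> ResidueMassTable:
    global _DEFAULT_MASSES
    if _DEFAULT_MASSES is None:
        _DEFAULT_MASSES = ResidueMassTable.default()
    return _DEFAULT_MASSES


def kyte_doolittle() -> dict[str, float]:
    """Kyte–Doolittle hydropathy values for the 20 standard amino acids."""
    return _load_table("kyte_doolittle.tsv", "hydropathy")


def monoisotopic_mass(
    sequence: str,
    cys_carbamidomethyl: bool = True,
    table: ResidueMassTable | None = None,
) -> float:
    """Neutral monoisotopic peptide mass in Da.

    Sum of residue monoisotopic masses plus one water; no proton masses are
    added. Cysteines carry the fixed carbamidomethyl modification
    (+57.02146 Da) by default, matching the alkylated form the CCS dataset
    reports.
    """
    validate_sequence(sequence)
    table = table or default_mass_table()
    mass = sum(table.masses[aa] for aa in sequence) + table.water
    if cys_carbamidomethyl:
        mass += table.carbamidomethyl * sequence.count("C")
    return mass


@dataclass(frozen=True)
class BasicSiteProfile:
    """Positions of a peptide's basic sites and their C-terminal distances.

    ``positions`` lists the N-terminal amine as pseudo-position 0 followed by
    the 1-based positions of R/K/H residues. ``internal_positions`` is the
    sublist at positions 2..n-1; ``cterm_distances[j]`` is n minus the j-th
    internal position (strictly positive, at most n-2).
    """

    length: int
    positions: tuple[int, ...]
    internal_positions: tuple[int, ...]
    cterm_distances: tuple[int, ...]

    @property
    def n_sites(self) -> int:
        return len(self.positions)


def find_basic_sites(sequence: str) -> BasicSiteProfile:
    """Locate all basic sites (R/K/H residues plus the N-terminal amine).

    The amine always counts as one site regardless of the identity of the
    first residue; a basic residue at position 1 contributes a second,
    distinct site. Internal sites are those at positions 2..n-1.
    """
    validate_sequence(sequence)
    n = len(sequence)
    if n < 2:
        raise ValueError(f"degenerate peptide of length {n}; need length >= 2")
    residue_positions = tuple(
        i for i, aa in enumerate(sequence, start=1) if aa in BASIC_RESIDUES
    )
    internal = tuple(p for p in residue_positions if 2 <= p <= n - 1)
    return BasicSiteProfile(
        length=n,
        positions=(0,) + residue_positions,
        internal_positions=internal,
        cterm_distances=tuple(n - p for p in internal),
    )


def internal_site_distance(profile: BasicSiteProfile, k: int) -> int:
    """Distance to the C-terminus of the k-th internal basic site.

    Internal sites are counted 1-based from the N- toward the C-terminus, so
    k=1 is the most N-terminal internal site.
    """
    if not 1 <= k <= len(profile.internal_positions):
        raise IndexError(
            f"internal site index {k} out of range; profile has "
            f"{len(profile.internal_positions)} internal site(s)"
        )
    return profile.cterm_distances[k - 1]


def classify_protease(record: PeptideRecord) -> str:
    """Protease attribution: the table's label if present, else terminus rules.

    Unlabeled records are inferred from cleavage-compatible termini with
    precedence trypsin > lysn > lysc: C-terminal R or K means tryptic,
    N-terminal K means LysN, a C-terminal K not already claimed means LysC,
    otherwise ``other``.
    """
    if record.protease != "unknown":
        return record.protease
    seq = record.sequence
    if seq[-1] in "RK":
        return "trypsin"
    if seq[0] == "K":
        return "lysn"
    return "other"


def is_nt_acetylated(record: PeptideRecord, token: str = NT_ACETYL_TOKEN) -> bool:
    """True iff the modification annotation carries the Nt-acetylation token."""
    return token in record.modifications


def count_prolines(sequence: str) -> int:
    validate_sequence(sequence)
    return sequence.count("P")


def relative_position(i: int, n: int) -> float:
    """Relative position (i-1)/(n-2) of residue i in a length-n peptide.

    Runs linearly from 0 at the N-terminal residue to 1 at the penultimate
    residue. The C-terminal residue (i = n) is modeled separately and must
    never be passed.
    """
    if n < 3:
        raise ValueError(f"peptide length {n} too short for a relative position")
    if i == n:
        raise ValueError("the C-terminal residue has no relative position")
    if not 1 <= i < n:
        raise ValueError(f"residue index {i} out of range for length {n}")
    return (i - 1) / (n - 2)


@dataclass
class FilterSummary:
    """Record counts before/after each rule of the cohort filter."""

    n_input: int = 0
    n_charge: int = 0
    n_length: int = 0
    n_not_acetylated: int = 0
    n_protease: int = 0
    n_basic_sites: int = 0

    def __str__(self) -> str:  # pragma: no cover - logging convenience
        return (
            f"input={self.n_input} charge={self.n_charge} length={self.n_length} "
            f"non-Nt-acetylated={self.n_not_acetylated} protease={self.n_protease} "
            f"basic-sites={self.n_basic_sites}"
        )


def filter_analysis_set(
    records: Sequence[PeptideRecord],
    min_length: int = 15,
    charge: int = 3,
    n_basic_sites: int | None = None,
    proteases: Iterable[str] = ("trypsin", "lysn"),
) -> tuple[list[PeptideRecord], FilterSummary]:
    """Apply the analysis cohort filter, preserving input order.

    A record survives when ALL hold: charge equals ``charge``; length is at
    least ``min_length``; it is not N-terminally acetylated; its (labeled or
    inferred) protease is in ``proteases``; and, when ``n_basic_sites`` is
    given, its basic-site count matches exactly. Returns the surviving subset
    plus a per-rule count summary.
    """
    allowed = set(proteases)
    summary = FilterSummary(n_input=len(records))
    out: list[PeptideRecord] = []
    for rec in records:
        if rec.charge != charge:
            continue
        summary.n_charge += 1
        if rec.length < min_length:
            continue
        summary.n_length += 1
        if is_nt_acetylated(rec):
            continue
        summary.n_not_acetylated += 1
        if classify_protease(rec) not in allowed:
            continue
        summary.n_protease += 1
        if n_basic_sites is not None:
            if find_basic_sites(rec.sequence).n_sites != n_basic_sites:
                continue
        summary.n_basic_sites += 1
        out.append(rec)
    return out, summary
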