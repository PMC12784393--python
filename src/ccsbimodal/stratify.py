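"""Binned mode-fraction maps and spline summary correlations.

The bimodality analysis asks how the fraction of peptides in the high CCS
mode varies over integer-valued positional features (peptide length, proline
count, distance of an internal basic site to the C-terminus). Bins holding
fewer than 8 peptides are masked. Spline summaries (position-averaged
per-amino-acid contributions) are correlated against standard residue
properties: Kyte–Doolittle hydropathy for the mode models, monoisotopic
residue mass for the absolute-CCS models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import pearsonr

from .features import (
    count_prolines,
    default_mass_table,
    find_basic_sites,
    internal_site_distance,
    kyte_doolittle,
)
from .gam import SharedSplineGam, aa_mean_contributions
from .modes import ModeAssignment
from .records import AMINO_ACIDS, PeptideRecord

#: Features usable as map axes. ``internal_site_distance_k`` counts internal
#: sites from the N-terminus; ``min_internal_site_distance`` is the distance
#: of the most C-terminal internal site.
def compute_feature(record: PeptideRecord, name: str) -> int | None:
    if name == "length":
        return record.length
    if name == "proline_count":
        return count_prolines(record.sequence)
    if name == "min_internal_site_distance":
        prof = find_basic_sites(record.sequence)
        return min(prof.cterm_distances) if prof.cterm_distances else None
    if name.startswith("internal_site_distance_"):
        k = int(name.rsplit("_", 1)[1])
        prof = find_basic_sites(record.sequence)
        if len(prof.internal_positions) < k:
            return None
        return internal_site_distance(prof, k)
    raise ValueError(f"unknown feature {name!r}")


@dataclass
class BinnedFractionMap:
    """2D integer-binned fraction-of-high-mode map with a count mask."""

    x_feature: str
    y_feature: str
    x_values: np.ndarray  # integer bin centers (unit-width bins)
    y_values: np.ndarray
    counts: np.ndarray  # (len(x), len(y))
    fraction_high: np.ndarray  # NaN where masked
    mask: np.ndarray  # True where count >= min_count
    min_count: int
    x_marginal: np.ndarray
    y_marginal: np.ndarray
    n_records: int

    def to_long_frame(self):
        import pandas as pd

        rows = []
        for i, xv in enumerate(self.x_values):
            for j, yv in enumerate(self.y_values):
                rows.append(
                    (
                        int(xv),
                        int(yv),
                        int(self.counts[i, j]),
                        self.fraction_high[i, j],
                        not self.mask[i, j],
                    )
                )
        return pd.DataFrame(
            rows, columns=["x_bin", "y_bin", "count", "fraction_high", "masked"]
        )


def fraction_high_map(
    records: Sequence[PeptideRecord],
    assignments: Sequence[ModeAssignment],
    x_feature: str,
    y_feature: str,
    min_count: int = 8,
) -> BinnedFractionMap:
    """Fraction of high-mode peptides per unit-width integer bin.

    Records whose feature is undefined (e.g. no k-th internal site) are
    dropped. Bins with fewer than ``min_count`` records carry no fraction
    (NaN) but still contribute to the counts and marginals.
    """
    xs, ys, highs = [], [], []
    for rec, asg in zip(records, assignments):
        xv = compute_feature(rec, x_feature)
        yv = compute_feature(rec, y_feature)
        if xv is None or yv is None:
            continue
        xs.append(xv)
        ys.append(yv)
        highs.append(asg.mode == "high")
    if not xs:
        x_vals = np.array([], dtype=int)
        y_vals = np.array([], dtype=int)
        empty2 = np.zeros((0, 0))
        return BinnedFractionMap(
            x_feature, y_feature, x_vals, y_vals, empty2, empty2,
            empty2.astype(bool), min_count, np.array([]), np.array([]), 0,
        )
    xs = np.asarray(xs, dtype=int)
    ys = np.asarray(ys, dtype=int)
    highs = np.asarray(highs, dtype=float)
    x_vals = np.arange(xs.min(), xs.max() + 1)
    y_vals = np.arange(ys.min(), ys.max() + 1)
    counts = np.zeros((len(x_vals), len(y_vals)))
    high_counts = np.zeros_like(counts)
    xi = xs - xs.min()
    yi = ys - ys.min()
    np.add.at(counts, (xi, yi), 1.0)
    np.add.at(high_counts, (xi, yi), highs)
    mask = counts >= min_count
    frac = np.full_like(counts, np.nan)
    frac[mask] = high_counts[mask] / counts[mask]
    return BinnedFractionMap(
        x_feature=x_feature,
        y_feature=y_feature,
        x_values=x_vals,
        y_values=y_vals,
        counts=counts,
        fraction_high=frac,
        mask=mask,
        min_count=min_count,
        x_marginal=counts.sum(axis=1),
        y_marginal=counts.sum(axis=0),
        n_records=len(xs),
    )


@dataclass(frozen=True)
class GroupFractions:
    n: int
    n_high: int
    n_low: int
    fraction_high: float | None
    fraction_low: float | None
    defined: bool


def mode_fraction_by_group(
    records: Sequence[PeptideRecord],
    assignments: Sequence[ModeAssignment],
    predicate: Callable[[PeptideRecord], bool],
) -> GroupFractions:
    """High/low mode fractions over the predicate-selected subset.

    An empty subset yields ``defined=False`` with ``None`` fractions rather
    than an error, so callers can distinguish absence from 0%.
    """
    n = n_high = 0
    for rec, asg in zip(records, assignments):
        if predicate(rec):
            n += 1
            n_high += asg.mode == "high"
    if n == 0:
        return GroupFractions(0, 0, 0, None, None, False)
    return GroupFractions(n, n_high, n - n_high, n_high / n, 1 - n_high / n, True)


@dataclass
class PropertyCorrelation:
    property_name: str
    amino_acids: tuple[str, ...]
    mean_contributions: np.ndarray
    property_values: np.ndarray
    pearson_r: float | None
    r_squared: float | None
    excluded: tuple[str, ...]
    defined: bool


def _property_values(name: str) -> dict[str, float]:
    if name == "hydropathy":
        return kyte_doolittle()
    if name == "residue_mass":
        return default_mass_table().masses
    raise ValueError(f"unknown property table {name!r}")


def spline_property_correlation(
    models: SharedSplineGam | Sequence[SharedSplineGam],
    property_table: str | dict[str, float],
    exclusions: Sequence[str] = ("C",),
) -> PropertyCorrelation:
    """Correlate per-amino-acid mean spline contributions with a residue property.

    The mean contribution of each amino acid is its spline averaged over a
    uniform grid of relative positions, then averaged across the supplied
    models when a pair is given (e.g. the two mode models, or the high/low
    CCS models). Cysteine is excluded by default because the dataset's
    cysteine is carbamidomethylated and not comparable on standard scales.
    Constant contributions (zero variance) make the correlation undefined;
    this is flagged, not raised.
    """
    if isinstance(models, SharedSplineGam):
        models = [models]
    name = property_table if isinstance(property_table, str) else "custom"
    table = (
        _property_values(property_table)
        if isinstance(property_table, str)
        else dict(property_table)
    )
    aas = tuple(a for a in AMINO_ACIDS if a not in set(exclusions))
    missing = [a for a in aas if a not in table]
    if missing:
        raise ValueError(f"property table missing residues: {missing}")
    per_model = [aa_mean_contributions(m) for m in models]
    contrib = np.array([np.mean([pm[a] for pm in per_model]) for a in aas])
    props = np.array([table[a] for a in aas])
    if np.ptp(contrib) < 1e-12 or np.ptp(props) < 1e-12:
        return PropertyCorrelation(
            name, aas, contrib, props, None, None, tuple(exclusions), False
        )
    r = float(pearsonr(contrib, props).statistic)
    return PropertyCorrelation(
        name, aas, contrib, props, r, r * r, tuple(exclusions), True
    )


def spline_pair_similarity(
    model_a: SharedSplineGam, model_b: SharedSplineGam
) -> float:
    """Pearson r between two models' per-amino-acid mean spline contributions."""
    ca = aa_mean_contributions(model_a)
    cb = aa_mean_contributions(model_b)
    if set(ca) != set(cb):
        raise ValueError("models do not share an amino-acid alphabet")
    aas = sorted(ca)
    va = np.array([ca[a] for a in aas])
    vb = np.array([cb[a] for a in aas])
    if np.ptp(va) < 1e-12 or np.ptp(vb) < 1e-12:
        return 1.0 if np.allclose(va, vb) else float("nan")
    return float(pearsonr(va, vb).statistic)
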