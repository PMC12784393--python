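"""End-to-end analysis pipeline: filter → mode separation → stratification →
shared-spline GAM fits → spline summary correlations.

Every artifact is plain text (TSV/JSON), stamped with the seed and a hash of
the configuration, so a rerun with the same config and seed is byte-identical
for the deterministic stages (which is all of them: the only randomness is
seeded).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .features import filter_analysis_set, find_basic_sites, monoisotopic_mass
from .gam import (
    GamTrainingSpec,
    Penalties,
    SharedSplineGam,
    auroc,
    fit_shared_spline_gam,
    partial_dependence,
)
from .modes import SeparationResult, separate_dataset
from .records import PeptideRecord, read_peptide_table, to_frame
from .stratify import (
    fraction_high_map,
    spline_pair_similarity,
    spline_property_correlation,
)

log = logging.getLogger("ccsbimodal")


@dataclass
class PipelineConfig:
    input: str
    output_dir: str
    seed: int = 0
    charge: int = 3
    min_length: int = 15
    proteases: tuple[str, ...] = ("trypsin", "lysn")
    n_basic_sites: int | None = 3
    separator_strategy: Literal["refit", "reference"] = "refit"
    min_bin_count: int = 8
    map_features: tuple[tuple[str, str], ...] = (
        ("length", "min_internal_site_distance"),
        ("length", "proline_count"),
    )
    gam_min_records: int = 200
    penalties: Penalties = field(default_factory=Penalties)

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib

        raw = tomllib.loads(Path(path).read_text())
        if "proteases" in raw:
            raw["proteases"] = tuple(raw["proteases"])
        if "map_features" in raw:
            raw["map_features"] = tuple(tuple(p) for p in raw["map_features"])
        if "penalties" in raw:
            raw["penalties"] = Penalties(**raw["penalties"])
        return cls(**raw)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _subset_records(
    records: Sequence[PeptideRecord], assignments, subset: str
) -> tuple[list[str], np.ndarray]:
    """Training sequences and targets for one GAM cohort.

    Mode cohorts split on the distance of the (sole) internal basic site:
    within five residues of the C-terminus versus at least seven away —
    distance-6 peptides belong to neither. CCS cohorts split on assigned mode.
    """
    seqs: list[str] = []
    targets: list[float] = []
    for rec, asg in zip(records, assignments):
        if rec.sequence[-1] not in "RK":
            continue  # GAM cohorts are tryptic: C-terminal R or K
        if subset in ("dist_le5", "dist_ge7"):
            dists = find_basic_sites(rec.sequence).cterm_distances
            if not dists:
                continue
            d = min(dists)
            if subset == "dist_le5" and d > 5:
                continue
            if subset == "dist_ge7" and d < 7:
                continue
            seqs.append(rec.sequence)
            targets.append(1.0 if asg.mode == "high" else 0.0)
        else:
            if subset == "mode_high" and asg.mode != "high":
                continue
            if subset == "mode_low" and asg.mode != "low":
                continue
            seqs.append(rec.sequence)
            targets.append(rec.ccs)
    return seqs, np.asarray(targets)


def fit_gam_for_subset(
    records: Sequence[PeptideRecord],
    assignments,
    spec: GamTrainingSpec,
) -> SharedSplineGam:
    """Fit one of the four study GAMs on its training cohort."""
    seqs, y = _subset_records(records, assignments, spec.subset)
    if len(seqs) < spec.min_records:
        raise ValueError(
            f"subset {spec.subset!r} has {len(seqs)} records; "
            f"need at least {spec.min_records}"
        )
    return fit_shared_spline_gam(seqs, y, spec.link, spec.penalties)


def write_assignments(
    records: Sequence[PeptideRecord], result: SeparationResult, path: Path
) -> None:
    df = to_frame(records)
    df["mass"] = [monoisotopic_mass(r.sequence) for r in records]
    df["delta_ccs"] = [a.delta_ccs for a in result.assignments]
    df["mode"] = [a.mode for a in result.assignments]
    df.to_csv(path, sep="\t", index=False, float_format="%.6f", lineterminator="\n")


def model_to_json(model: SharedSplineGam) -> dict:
    return {
        "link": model.link,
        "position_basis": {
            "n_basis": model.position_basis.n_basis,
            "degree": model.position_basis.degree,
            "domain": [model.position_basis.lo, model.position_basis.hi],
        },
        "length_basis": {
            "n_basis": model.length_basis.n_basis,
            "degree": model.length_basis.degree,
            "domain": [model.length_basis.lo, model.length_basis.hi],
        },
        "penalties": asdict(model.penalties),
        "coef": [float(c) for c in model.coef],
        "cov": [[float(v) for v in row] for row in model.cov],
        "diagnostics": {
            k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
            for k, v in model.diagnostics.items()
        },
        "beta_cterm_k": model.beta_cterm_k,
    }


def export_partial_dependence(model: SharedSplineGam, path: Path) -> None:
    grid = np.linspace(0, 1, 101)
    rows = []
    for aa in sorted(set("ACDEFGHIKLMNPQRSTVWY")):
        pd_curve = partial_dependence(model, aa, grid, center=True)
        for t, e, lo, hi in zip(grid, pd_curve.estimate, pd_curve.lo95, pd_curve.hi95):
            rows.append((aa, round(t, 4), e, lo, hi))
    pd.DataFrame(
        rows, columns=["amino_acid", "position", "estimate", "lo95", "hi95"]
    ).to_csv(path, sep="\t", index=False, float_format="%.6f", lineterminator="\n")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the whole analysis; returns the populated output directory.

    Stages: cohort filter, mode separation, binned fraction maps, the four
    shared-spline GAMs (two logistic mode models on the distance subsets, two
    identity-link CCS models on the mode subsets), and the spline summary
    correlations. Failures abort with the stage name; artifacts written so
    far are left in place.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.hash(), "seed": config.seed,
            "version": __version__, "config": asdict(config)}
    (out / "run_meta.json").write_text(json.dumps(meta, indent=1, default=str))
    report: dict = {"config_hash": config.hash(), "seed": config.seed}

    stage = "read_input"
    try:
        records = read_peptide_table(config.input)
        log.info("read %d records from %s", len(records), config.input)

        stage = "filter"
        cohort, summary = filter_analysis_set(
            records,
            min_length=config.min_length,
            charge=config.charge,
            n_basic_sites=config.n_basic_sites,
            proteases=config.proteases,
        )
        log.info("cohort filter: %s", summary)
        report["filter_counts"] = asdict(summary)

        stage = "mode_separation"
        sep = separate_dataset(
            cohort, strategy=config.separator_strategy, seed=config.seed
        )
        write_assignments(cohort, sep, out / "assignments.tsv")
        sep_json = {
            "strategy": config.separator_strategy,
            "slope": sep.separator.slope,
            "intercept": sep.separator.intercept,
            "n_low": sep.n_low,
            "n_high": sep.n_high,
        }
        (out / "separator.json").write_text(json.dumps(sep_json, indent=1))
        log.info(
            "separator: slope=%.6f intercept=%.3f low=%d high=%d",
            sep.separator.slope, sep.separator.intercept, sep.n_low, sep.n_high,
        )
        report["separator"] = sep_json

        stage = "stratification"
        report["maps"] = {}
        for x_feat, y_feat in config.map_features:
            fmap = fraction_high_map(
                cohort, sep.assignments, x_feat, y_feat,
                min_count=config.min_bin_count,
            )
            name = f"map_{x_feat}__{y_feat}.tsv"
            fmap.to_long_frame().to_csv(
                out / name, sep="\t", index=False, float_format="%.6f",
                lineterminator="\n",
            )
            report["maps"][name] = {
                "n_records": fmap.n_records,
                "n_unmasked_bins": int(fmap.mask.sum()),
            }

        stage = "gam_fits"
        gams: dict[str, SharedSplineGam] = {}
        report["gams"] = {}
        for subset, target in (
            ("dist_le5", "mode"),
            ("dist_ge7", "mode"),
            ("mode_high", "ccs"),
            ("mode_low", "ccs"),
        ):
            spec = GamTrainingSpec(
                subset=subset, target=target, penalties=config.penalties,
                seed=config.seed, min_records=config.gam_min_records,
            )
            model = fit_gam_for_subset(cohort, sep.assignments, spec)
            gams[subset] = model
            (out / f"gam_{subset}.json").write_text(
                json.dumps(model_to_json(model), indent=1)
            )
            export_partial_dependence(model, out / f"gam_{subset}_splines.tsv")
            report["gams"][subset] = {
                k: v for k, v in model.diagnostics.items()
                if isinstance(v, (int, float))
            }
            report["gams"][subset]["beta_cterm_k"] = model.beta_cterm_k
            log.info("GAM %s: %s", subset, report["gams"][subset])

        stage = "correlations"
        mode_corr = spline_property_correlation(
            [gams["dist_le5"], gams["dist_ge7"]], "hydropathy"
        )
        ccs_corr = spline_property_correlation(
            [gams["mode_high"], gams["mode_low"]], "residue_mass"
        )
        report["correlations"] = {
            "mode_splines_vs_hydropathy_r": mode_corr.pearson_r,
            "ccs_splines_vs_residue_mass_r2": ccs_corr.r_squared,
            "ccs_spline_pair_similarity_r": spline_pair_similarity(
                gams["mode_high"], gams["mode_low"]
            ),
        }
    except Exception as exc:  # noqa: BLE001 - annotate stage then re-raise
        (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
        raise StageError(stage, exc) from exc

    (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return out
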