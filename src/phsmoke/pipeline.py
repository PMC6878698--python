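"""End-to-end pipeline: harmonize -> fit -> calibrate -> cross-validate ->
small-area estimation -> economics -> export.

A run is fully determined by its config and seed: derived RNG streams are
[seed, 2] for cross-validation and [seed, 3, i] for the i-th development
(file order), so reruns with the same config are byte-identical. Partial
outputs are removed if a stage fails.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import io as io_mod
from .economics import read_economic_config, roi_table
from .errors import ValidationError
from .harmonize import harmonize_survey
from .microsim import aggregate_to_county, estimate_phd_smokers
from .model import SmokingModel, cross_validate

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    survey_path: str
    phd_path: str
    tax_path: str
    economics_path: str
    output_dir: str
    seed: int
    threshold_mode: str = "calibrate"  # "calibrate" to a target, or "fixed"
    target_prevalence: float = 0.33
    fixed_threshold: float = 0.33
    threshold_scale: str = "probability"
    cv_repeats: int = 100
    train_fraction: float = 0.75
    n_boot: int = 50
    min_residents: int = 1
    roster_mode: str = "resample"
    count_mode: str = "classify"

    def validate(self) -> None:
        if self.seed is None:
            raise ValidationError("pipeline config requires an explicit seed")
        if self.cv_repeats < 1 or self.n_boot < 1:
            raise ValidationError("cv_repeats and n_boot must be >= 1")
        if self.threshold_mode not in ("calibrate", "fixed"):
            raise ValidationError("threshold_mode must be 'calibrate' or 'fixed'")

    def config_hash(self) -> str:
        doc = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


OUTPUT_FILES = [
    "model.json",
    "cv_report.csv",
    "phd_estimates.csv",
    "county_estimates.csv",
    "roi.csv",
    "map.geojson",
]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; return (and write) the run manifest."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        raw = io_mod.read_survey_csv(config.survey_path)
        tax_table = io_mod.read_tax_csv(config.tax_path)
        phds = io_mod.read_phd_csv(config.phd_path)
        costs, interventions = read_economic_config(config.economics_path)
        log.info("loaded %d survey records, %d PHDs, %d states", len(raw), len(phds), len(tax_table))

        harm = harmonize_survey(raw, tax_table, drop_invalid=True)
        log.info("harmonized %d records (%d dropped)", len(harm), len(raw) - len(harm))

        results = SmokingModel.from_dataframe(harm).fit()
        if config.threshold_mode == "fixed":
            results.set_threshold(config.fixed_threshold, config.threshold_scale)
        else:
            results.calibrate_threshold(
                harm, config.target_prevalence, scale=config.threshold_scale
            )
        results.save(outdir / "model.json")
        written.append(outdir / "model.json")
        log.info("fitted model (threshold %.4f)", results.threshold)

        cv = cross_validate(
            harm,
            train_fraction=config.train_fraction,
            repeats=config.cv_repeats,
            seed=[config.seed, 2],
            target_prevalence=config.target_prevalence,
            fixed_threshold=(
                config.fixed_threshold if config.threshold_mode == "fixed" else None
            ),
        )
        cv.to_frame().to_csv(outdir / "cv_report.csv", index=False)
        written.append(outdir / "cv_report.csv")
        log.info("cross-validated: AUC %.3f (sd %.3f)", cv.auc_mean, cv.auc_sd)

        kept = [p for p in phds if p.n_residents >= config.min_residents]
        log.info("estimating %d PHDs (%d filtered out)", len(kept), len(phds) - len(kept))
        estimates = [
            estimate_phd_smokers(
                phd,
                results,
                tax_table,
                n_boot=config.n_boot,
                rng=np.random.default_rng([config.seed, 3, i]),
                roster_mode=config.roster_mode,
                count_mode=config.count_mode,
            )
            for i, phd in enumerate(kept)
        ]
        io_mod.write_estimates_csv(outdir / "phd_estimates.csv", estimates)
        written.append(outdir / "phd_estimates.csv")

        counties = aggregate_to_county(estimates, kept)
        io_mod.write_county_csv(outdir / "county_estimates.csv", counties)
        written.append(outdir / "county_estimates.csv")

        roi = roi_table(estimates, interventions, costs)
        roi.to_csv(outdir / "roi.csv", index=False)
        written.append(outdir / "roi.csv")

        doc = io_mod.export_geojson(counties, kept, estimates, roi if len(roi) else None)
        io_mod.write_geojson(outdir / "map.geojson", doc)
        written.append(outdir / "map.geojson")

        manifest = {
            "seed": config.seed,
            "config": asdict(config),
            "config_hash": config.config_hash(),
            "row_counts": {
                "survey": len(raw),
                "harmonized": len(harm),
                "phds_estimated": len(kept),
                "counties": len(counties),
                "roi_rows": len(roi),
            },
            "outputs": {f.name: _sha256(f) for f in written},
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        return manifest
    except Exception:
        for f in written:
            f.unlink(missing_ok=True)
        raise
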