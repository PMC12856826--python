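"""End-to-end pipeline: database -> normalize -> peaks -> segment -> fingerprint
-> annotate -> renormalize -> cohort statistics, with a seeded, manifest-backed
run record.

Two stages are orchestrated. The imaging stage takes one datacube (read from
disk or simulated) through TIC normalization, channel extraction, guide-steered
segmentation (or a manual mask), ROI fingerprinting, exact-mass annotation and
renormalization over identified species. The cohort stage samples or loads a
sample x species fingerprint table with its design, averages hemispheres, and
runs the Levene-gated comparison plus 0-1-scaled PCA. Every output file's
SHA-256 and every seed in play is recorded in ``manifest.json``; identical
config + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fingerprint_stats as fs
from . import lipid_db as ldb
from . import msi_core as mc
from . import segmentation as seg
from . import synthetic_data as sd

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    out_dir: str = "lipidmsi_run"
    seed: int = 0

    # imaging stage
    cube_path: str | None = None  # None -> simulate a packed-blob phantom
    guide_mask: str | None = None  # None + simulated cube -> use the truth mask
    manual_mask: str | None = None  # bypass segmentation entirely
    target_channels: int = 400
    threshold_fraction: float | None = None  # alternative to channel-count targeting
    resolving_power: float = mc.DEFAULT_RESOLVING_POWER
    tol_ppm: float = 10.0
    max_depth: int = 10
    n_restarts: int = seg.DEFAULT_RESTARTS

    # simulated phantom parameters (used when cube_path is None)
    grid: tuple[int, int] = (64, 64)
    noise_cv: float = 0.20
    mz_jitter_ppm: float = 5.0

    # cohort stage
    cohort: bool = True
    fingerprint_table: str | None = None  # CSV; None -> sample synthetically
    design_table: str | None = None
    animals_per_sex: int = 5
    class_effects: dict = field(default_factory=dict)
    factor: str = "sex"
    alpha: float = 0.05
    fdr: bool = False
    scale01: bool = True

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.tol_ppm <= 0 or self.resolving_power <= 0 or self.target_channels < 1:
            raise ValueError("tolerance, resolving power and target channels must be positive")

    def to_yaml(self, path) -> None:
        import yaml

        d = dataclasses.asdict(self)
        d["grid"] = list(self.grid)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "grid" in d:
            d["grid"] = tuple(d["grid"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the manifest dict.

    Any stage failure aborts with the stage name prefixed to the cause.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {**dataclasses.asdict(cfg), "grid": list(cfg.grid)},
        "seed": cfg.seed,
        "stages": {},
        "outputs": {},
    }
    stage = "db-build"
    try:
        db = ldb.build_database()
        manifest["stages"][stage] = {"entries": len(db)}

        stage = "load"
        truth = None
        if cfg.cube_path:
            cube = mc.read_datacube(cfg.cube_path)
        else:
            pcfg = sd.PhantomConfig(
                width=cfg.grid[0], height=cfg.grid[1], archetypes=(sd.lc_like(),),
                noise_cv=cfg.noise_cv, mz_jitter_ppm=cfg.mz_jitter_ppm, seed=cfg.seed,
            )
            cube, truth = sd.make_phantom(pcfg)
        manifest["stages"][stage] = {"pixels": cube.n_pixels, "peaks": int(len(cube.mz))}

        stage = "normalize"
        cube = mc.tic_normalize(cube)
        manifest["stages"][stage] = {"invalid_pixels": cube.metadata["invalid_pixels"]}

        stage = "peaks"
        mean = mc.mean_spectrum(cube, cfg.resolving_power)
        if cfg.threshold_fraction is not None:
            thr = cfg.threshold_fraction * float(np.max(mean[1]))
            frac = cfg.threshold_fraction
        else:
            thr, frac = mc.select_threshold(mean, cfg.target_channels, cfg.resolving_power)
        channels = mc.extract_channels(mean, thr, cfg.resolving_power)
        manifest["stages"][stage] = {
            "bins": int(len(mean[0])), "threshold": thr,
            "threshold_fraction_of_max": frac, "channels": len(channels),
        }

        stage = "feature-matrix"
        fm = mc.build_feature_matrix(cube, channels)
        manifest["stages"][stage] = {"shape": list(fm.values.shape)}

        stage = "segment"
        if cfg.manual_mask:
            roi = seg.manual_roi(cfg.manual_mask, fm)
            manifest["stages"][stage] = {"origin": "manual", "roi_pixels": len(roi)}
        else:
            if cfg.guide_mask:
                guide = seg.manual_roi(cfg.guide_mask, fm, label="guide")
            elif truth is not None:
                kind = next(iter(truth.masks))
                guide = seg.ROI(truth.masks[kind], label=kind)
            else:
                raise ValueError("a guide or manual mask is required for real data")
            tree = seg.supervised_segmentation(
                fm, guide, max_depth=cfg.max_depth, seed=cfg.seed, n_restarts=cfg.n_restarts
            )
            roi = tree.target
            manifest["stages"][stage] = {
                "origin": "segmentation",
                "roi_pixels": len(roi),
                "log": tree.log,
            }

        stage = "fingerprint"
        fp = seg.roi_fingerprint(fm, roi)

        stage = "annotate"
        anns = ldb.annotate_channels(channels.centers, db, cfg.tol_ppm)
        n_matched = sum(a.matched for a in anns)
        manifest["stages"][stage] = {"channels": len(anns), "matched": n_matched}

        stage = "renormalize"
        afp = fs.renormalize_annotated(fp, anns)
        fp_path = out / "roi_fingerprint.tsv"
        afp.as_series().rename("relative_abundance").to_csv(fp_path, sep="\t")
        manifest["stages"][stage] = {
            "species": len(afp.abundances), "sum": float(sum(afp.abundances.values())),
        }

        if cfg.cohort:
            stage = "cohort"
            if cfg.fingerprint_table and cfg.design_table:
                table = pd.read_csv(cfg.fingerprint_table, index_col=0)
                design = pd.read_csv(cfg.design_table)
            else:
                ccfg = sd.CohortConfig(
                    animals_per_sex=cfg.animals_per_sex,
                    class_effects=dict(cfg.class_effects),
                    seed=cfg.seed,
                )
                table, design = sd.sample_cohort_fingerprints(ccfg)
            manifest["stages"][stage] = {"samples": len(table), "species": table.shape[1]}

            stage = "average-hemispheres"
            avg = fs.average_hemispheres(table, design)
            avg_design = avg.attrs["design"]
            manifest["stages"][stage] = {"fingerprints": len(avg)}

            stage = "stats"
            classes = avg.T.groupby(
                pd.Index([ldb.species_class(s) for s in avg.columns], name="class")
            ).sum().T
            results = fs.compare_groups(classes, avg_design, cfg.factor, cfg.alpha, cfg.fdr)
            stats_path = out / "stats.tsv"
            fs.stat_results_frame(results).to_csv(stats_path, sep="\t", index=False)
            manifest["stages"][stage] = {
                "features": len(results),
                "significant": sum(
                    any(c.p < cfg.alpha for c in r.pairwise) for r in results if not r.skipped
                ),
            }

            stage = "pca"
            pres = fs.pca(avg, scale01=cfg.scale01)
            pca_path = out / "pca_scores.tsv"
            scores = pres.scores.copy()
            scores.insert(0, cfg.factor, avg_design[cfg.factor])
            scores.to_csv(pca_path, sep="\t")
            manifest["stages"][stage] = {
                "explained_variance_ratio": [float(v) for v in pres.explained_variance_ratio[:5]],
            }
            avg.to_csv(out / "fingerprints_avg.tsv", sep="\t")
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
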