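"""Synthetic MSI phantoms and cohorts with known ground truth.

The generator emulates the statistical structure of negative-mode MALDI-MSI
acquisitions of brain tissue at 10 µm/pixel: a background "tissue" lipidome of
~30 abundant glycerophospho- and sphingolipid species observed as [M-H]- (or
[M-CH3]- for choline-bearing classes), planted neuron-population regions with
species-specific fold changes (e.g. PI 38:4 up and PI 38:6 down in a
LC-like packed blob), multiplicative lognormal pixel noise, per-pixel total
ion current variation, ppm-scale centroid jitter, and sparse chemical-noise
peaks. Three ROI archetypes mirror the populations of interest: a densely
packed blob (LC-like), isolated large somas (Me5-like), and 1-4-pixel
micro-somas (SNc-like).

Cohorts add a study design on top: animals x sections x hemispheres with a
shared per-animal random effect (identical in the left and right hemisphere)
and multiplicative sex effects on configured lipid classes, recorded exactly
as applied so downstream statistics can be validated against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .lipid_db import ADDUCTS, DEFAULT_CLASSES, LipidSpecies, apply_adduct, species_class
from .msi_core import DEFAULT_MASS_WINDOW, DEFAULT_PIXEL_SIZE_UM, Datacube

__all__ = [
    "PhantomConfig",
    "ROIArchetype",
    "GroundTruth",
    "CohortConfig",
    "default_background",
    "species_mz",
    "make_phantom",
    "make_cohort",
    "sample_cohort_fingerprints",
    "write_fixture_suite",
]

# Background lipidome: (species label, mean relative abundance before
# normalization). Roughly the negative-mode brain profile: PC/PE dominate,
# then PI and the ether lipids, PS, SM, sulfatides, minor PG/PA/lyso species.
_DEFAULT_BACKGROUND: tuple[tuple[str, float], ...] = (
    ("PI 38:4", 0.085),
    ("PI 38:5", 0.030),
    ("PI 38:6", 0.020),
    ("PI 36:4", 0.015),
    ("PS 36:1", 0.080),
    ("PS 40:6", 0.070),
    ("PS 38:4", 0.020),
    ("PE 38:4", 0.085),
    ("PE 40:6", 0.070),
    ("PE 34:1", 0.040),
    ("PE 36:2", 0.030),
    ("PC 34:1", 0.075),
    ("PC 36:1", 0.030),
    ("PC 32:0", 0.025),
    ("PC 38:4", 0.020),
    ("PEe 38:4", 0.035),
    ("PEe 40:6", 0.030),
    ("PCe 34:1", 0.015),
    ("PCe 36:2", 0.010),
    ("PG 34:1", 0.015),
    ("PG 36:2", 0.010),
    ("PA 38:4", 0.010),
    ("SM 36:1", 0.050),
    ("SM 36:2", 0.015),
    ("SM 38:1", 0.020),
    ("SM 42:2", 0.030),
    ("SHexCer 42:2", 0.030),
    ("SHexCer 42:1", 0.020),
    ("HexCer 40:1", 0.015),
    ("Cer 36:1", 0.010),
    ("LPE 18:1", 0.005),
)


def default_background() -> dict[str, float]:
    """Default background lipidome, normalized to sum 1."""
    total = sum(v for _, v in _DEFAULT_BACKGROUND)
    return {k: v / total for k, v in _DEFAULT_BACKGROUND}


def species_mz(label: str) -> float:
    """Theoretical observed m/z of a species label.

    Choline-bearing classes (PC, PCe, LPC, SM...) are observed demethylated
    ([M-CH3]-), everything else deprotonated ([M-H]-).
    """
    cls_ab, comp = label.rsplit(" ", 1)
    c_t, d_t = (int(x) for x in comp.split(":"))
    lc = DEFAULT_CLASSES[cls_ab]
    adduct = ADDUCTS["[M-CH3]-"] if lc.choline else ADDUCTS["[M-H]-"]
    return apply_adduct(LipidSpecies(lc, c_t, d_t), adduct).mz


# Archetype fold-change defaults, after the populations they emulate.
LC_LIKE_FOLDS: Mapping[str, float] = {
    "PI 38:4": 3.0,
    "PI 38:5": 1.5,
    "PI 38:6": 0.4,
    "SM 36:1": 1.4,
    "PEe 38:4": 1.3,
}
ME5_LIKE_FOLDS: Mapping[str, float] = {
    "PI 38:6": 3.0,
    "PI 38:4": 0.5,
    "PE 38:4": 1.3,
    "PC 34:1": 1.2,
}
SNC_LIKE_FOLDS: Mapping[str, float] = {
    "PI 38:4": 2.5,
    "PS 40:6": 1.4,
    "PG 36:2": 1.5,
}


@dataclass(frozen=True)
class ROIArchetype:
    """Geometry + per-species fold changes of a planted neuron population."""

    kind: str  # packed-blob | isolated-soma | micro-soma
    fold_changes: Mapping[str, float] = field(default_factory=dict)
    # packed-blob
    radius: int = 15
    # isolated-soma / micro-soma
    n_somas: int = 6
    min_separation: int = 10

    def __post_init__(self) -> None:
        if self.kind not in ("packed-blob", "isolated-soma", "micro-soma"):
            raise ValueError(f"unknown archetype kind {self.kind!r}")
        if any(f <= 0 for f in self.fold_changes.values()):
            raise ValueError("fold changes must be positive")


def lc_like(radius: int = 15) -> ROIArchetype:
    return ROIArchetype("packed-blob", LC_LIKE_FOLDS, radius=radius)


def me5_like(n_somas: int = 6) -> ROIArchetype:
    return ROIArchetype("isolated-soma", ME5_LIKE_FOLDS, n_somas=n_somas, min_separation=10)


def snc_like(n_somas: int = 10) -> ROIArchetype:
    return ROIArchetype("micro-soma", SNC_LIKE_FOLDS, n_somas=n_somas, min_separation=5)


@dataclass(frozen=True)
class PhantomConfig:
    width: int = 64
    height: int = 64
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    background: Mapping[str, float] = field(default_factory=default_background)
    archetypes: tuple[ROIArchetype, ...] = ()
    noise_cv: float = 0.20  # lognormal multiplicative noise per pixel x species
    tic_cv: float = 0.15  # lognormal per-pixel TIC factor
    mz_jitter_ppm: float = 5.0  # centroid jitter SD
    baseline_fraction: float = 0.02  # chemical-noise intensity scale vs mean species signal
    baseline_peaks_per_pixel: int = 40
    mass_window: tuple[float, float] = DEFAULT_MASS_WINDOW
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.background.values()):
            raise ValueError("background abundances must be positive")
        if min(self.noise_cv, self.tic_cv, self.mz_jitter_ppm, self.baseline_fraction) < 0:
            raise ValueError("noise parameters must be non-negative")
        lo, hi = self.mass_window
        for label in self.background:
            mz = species_mz(label)
            if not lo <= mz <= hi:
                raise ValueError(f"species {label} at m/z {mz:.4f} outside window {self.mass_window}")


@dataclass
class GroundTruth:
    species: list[str]
    theoretical_mz: np.ndarray
    masks: dict[str, frozenset[int]]  # archetype kind -> pixel indices
    true_abundance: np.ndarray  # (n_pixels, n_species), noise-free proportions
    fold_changes: dict[str, Mapping[str, float]]
    seed: int


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean lognormal multiplicative factors with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def _place_components(
    rng: np.random.Generator, width: int, height: int, offsets_list: list[list[tuple[int, int]]],
    min_separation: int,
) -> set[int]:
    """Place disjoint pixel components with a minimum center separation."""
    centers: list[tuple[int, int]] = []
    mask: set[int] = set()
    margin = 3
    for offsets in offsets_list:
        for _ in range(1000):
            x = int(rng.integers(margin, width - margin))
            y = int(rng.integers(margin, height - margin))
            if all((x - cx) ** 2 + (y - cy) ** 2 >= min_separation**2 for cx, cy in centers):
                centers.append((x, y))
                for dx, dy in offsets:
                    px, py = x + dx, y + dy
                    if 0 <= px < width and 0 <= py < height:
                        mask.add(py * width + px)
                break
        else:
            raise ValueError("could not place ROI components; grid too small")
    return mask


_SOMA_OFFSETS = [(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (-1, -1)]
_MICRO_OFFSETS = [(0, 0), (1, 0), (0, 1), (1, 1)]


def _archetype_mask(rng: np.random.Generator, arch: ROIArchetype, width: int, height: int) -> set[int]:
    if arch.kind == "packed-blob":
        cx, cy = width // 2, height // 2
        ys, xs = np.mgrid[0:height, 0:width]
        inside = (xs - cx) ** 2 + (ys - cy) ** 2 <= arch.radius**2
        return set((ys[inside] * width + xs[inside]).tolist())
    if arch.kind == "isolated-soma":
        sizes = rng.integers(5, 8, size=arch.n_somas)  # 5-7 pixel somas
        comps = [_SOMA_OFFSETS[:s] for s in sizes]
        return _place_components(rng, width, height, comps, arch.min_separation + 4)
    # micro-soma: 1-4 pixel components
    sizes = rng.integers(1, 5, size=arch.n_somas)
    comps = [_MICRO_OFFSETS[:s] for s in sizes]
    return _place_components(rng, width, height, comps, arch.min_separation)


def _true_abundances(cfg: PhantomConfig, masks: dict[str, frozenset[int]]) -> np.ndarray:
    species = list(cfg.background)
    n_pix = cfg.width * cfg.height
    base = np.array([cfg.background[s] for s in species])
    base = base / base.sum()
    ab = np.tile(base, (n_pix, 1))
    for arch in cfg.archetypes:
        idx = np.fromiter(masks[arch.kind], dtype=np.int64)
        for sp, fold in arch.fold_changes.items():
            ab[idx, species.index(sp)] *= fold
    return ab / ab.sum(axis=1, keepdims=True)


def make_phantom(cfg: PhantomConfig) -> tuple[Datacube, GroundTruth]:
    """Generate one phantom datacube plus its ground truth.

    Noise-free limit (all CVs, jitter and baseline at 0): every pixel's
    TIC-normalized spectrum equals its true abundance vector exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    species = list(cfg.background)
    theo_mz = np.array([species_mz(s) for s in species])
    masks: dict[str, frozenset[int]] = {}
    for arch in cfg.archetypes:
        if arch.kind in masks:
            raise ValueError(f"duplicate archetype kind {arch.kind}")
        masks[arch.kind] = frozenset(_archetype_mask(rng, arch, cfg.width, cfg.height))
    ab = _true_abundances(cfg, masks)
    n_pix, n_sp = ab.shape

    noise = _lognormal_factor(rng, cfg.noise_cv, (n_pix, n_sp))
    tic = _lognormal_factor(rng, cfg.tic_cv, (n_pix, 1))
    inten = ab * noise * tic
    jitter = (
        rng.normal(0.0, cfg.mz_jitter_ppm * 1e-6, size=(n_pix, n_sp))
        if cfg.mz_jitter_ppm > 0
        else np.zeros((n_pix, n_sp))
    )
    mzs = theo_mz[None, :] * (1.0 + jitter)

    pix = np.repeat(np.arange(n_pix, dtype=np.int64), n_sp)
    mz_flat = mzs.ravel()
    it_flat = inten.ravel()

    if cfg.baseline_fraction > 0 and cfg.baseline_peaks_per_pixel > 0:
        k = cfg.baseline_peaks_per_pixel
        lo, hi = cfg.mass_window
        bl_pix = np.repeat(np.arange(n_pix, dtype=np.int64), k)
        bl_mz = rng.uniform(lo, hi, size=n_pix * k)
        scale = cfg.baseline_fraction * ab.mean()
        bl_it = rng.exponential(scale, size=n_pix * k)
        pix = np.concatenate([pix, bl_pix])
        mz_flat = np.concatenate([mz_flat, bl_mz])
        it_flat = np.concatenate([it_flat, bl_it])

    lo, hi = cfg.mass_window
    np.clip(mz_flat, lo, hi, out=mz_flat)
    cube = Datacube(
        cfg.width, cfg.height, pix, mz_flat, it_flat,
        pixel_size_um=cfg.pixel_size_um, mass_window=cfg.mass_window,
        metadata={"phantom_seed": cfg.seed},
    )
    truth = GroundTruth(
        species=species,
        theoretical_mz=theo_mz,
        masks=masks,
        true_abundance=ab,
        fold_changes={a.kind: dict(a.fold_changes) for a in cfg.archetypes},
        seed=cfg.seed,
    )
    return cube, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortConfig:
    """Study design for a synthetic cohort.

    ``class_effects`` multiplies the named lipid classes in *male* animals'
    ROI abundances (e.g. ``{"SM": 0.7}``); 1.0 everywhere yields a null
    cohort. The per-animal random effect is shared between hemispheres.
    """

    animals_per_sex: int = 5
    sections_per_animal: int = 1
    hemispheres: tuple[str, ...] = ("L", "R")
    nucleus: str = "LC"
    class_effects: Mapping[str, float] = field(default_factory=dict)
    between_animal_cv: float = 0.10
    residual_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.animals_per_sex < 1 or self.sections_per_animal < 1:
            raise ValueError("need at least one animal and one section per cell")
        if any(e <= 0 for e in self.class_effects.values()):
            raise ValueError("effects must be positive")


def _roi_base_abundance(phantom_cfg: PhantomConfig) -> tuple[list[str], np.ndarray]:
    """Noise-free ROI abundance vector (background x archetype fold changes)."""
    species = list(phantom_cfg.background)
    base = np.array([phantom_cfg.background[s] for s in species])
    base = base / base.sum()
    for arch in phantom_cfg.archetypes:
        for sp, fold in arch.fold_changes.items():
            base[species.index(sp)] *= fold
    return species, base


def _sample_design(cfg: CohortConfig) -> pd.DataFrame:
    rows = []
    for sex in ("F", "M"):
        for a in range(cfg.animals_per_sex):
            animal = f"{sex}{a + 1}"
            for s in range(cfg.sections_per_animal):
                for h in cfg.hemispheres:
                    rows.append(
                        {
                            "sample": f"{animal}-{cfg.nucleus}-s{s + 1}-{h}",
                            "animal": animal,
                            "sex": sex,
                            "nucleus": cfg.nucleus,
                            "section": s + 1,
                            "hemisphere": h,
                        }
                    )
    return pd.DataFrame(rows)


def _sample_factors(
    cfg: CohortConfig, species: list[str], design: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """Per-sample multiplicative factor matrix (samples x species):
    animal effect (shared L/R) x sex class effect x sample residual."""
    n_sp = len(species)
    cls = [species_class(s) for s in species]
    sex_f = np.array([cfg.class_effects.get(c, 1.0) for c in cls])
    animal_f = {
        a: _lognormal_factor(rng, cfg.between_animal_cv, n_sp)
        for a in design["animal"].unique()
    }
    rows = []
    for _, r in design.iterrows():
        f = animal_f[r["animal"]] * _lognormal_factor(rng, cfg.residual_cv, n_sp)
        if r["sex"] == "M":
            f = f * sex_f
        rows.append(f)
    return np.vstack(rows)


def sample_cohort_fingerprints(
    cfg: CohortConfig, phantom_cfg: PhantomConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample per-sample ROI fingerprints directly from the cohort model.

    This is the image-free counterpart of :func:`make_cohort`: the same ROI
    abundances and animal/sex/residual factor structure, skipping pixel-level
    rendering. Returns (fingerprint table indexed by sample, design table);
    fingerprints are renormalized to sum 1.
    """
    phantom_cfg = phantom_cfg or PhantomConfig(archetypes=(lc_like(),), seed=cfg.seed)
    species, base = _roi_base_abundance(phantom_cfg)
    design = _sample_design(cfg)
    rng = np.random.default_rng(cfg.seed)
    factors = _sample_factors(cfg, species, design, rng)
    ab = base[None, :] * factors
    ab = ab / ab.sum(axis=1, keepdims=True)
    table = pd.DataFrame(ab, index=design["sample"], columns=species)
    return table, design


def make_cohort(
    cfg: CohortConfig, phantom_cfg: PhantomConfig | None = None
) -> list[tuple[Datacube, GroundTruth, dict]]:
    """Render one phantom per animal x section x hemisphere.

    Sex and animal effects scale the ROI abundances before pixel noise; the
    applied factor vector is recorded in each sample's metadata and ground
    truth. Returns a list of (cube, truth, design-row dict).
    """
    phantom_cfg = phantom_cfg or PhantomConfig(archetypes=(lc_like(),), seed=cfg.seed)
    if not phantom_cfg.archetypes:
        raise ValueError("cohort phantoms need at least one ROI archetype")
    species = list(phantom_cfg.background)
    design = _sample_design(cfg)
    ss = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    factors = _sample_factors(cfg, species, design, rng)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(len(design))]
    out = []
    for i, (_, row) in enumerate(design.iterrows()):
        arch0 = phantom_cfg.archetypes[0]
        folds = dict(arch0.fold_changes)
        for j, sp in enumerate(species):
            f = float(factors[i, j])
            if f != 1.0:
                folds[sp] = folds.get(sp, 1.0) * f
        cfg_i = replace(
            phantom_cfg,
            archetypes=(replace(arch0, fold_changes=folds),) + phantom_cfg.archetypes[1:],
            seed=child_seeds[i],
        )
        cube, truth = make_phantom(cfg_i)
        cube.metadata.update(sample=row["sample"], cohort_seed=cfg.seed)
        out.append((cube, truth, row.to_dict()))
    return out


def write_fixture_suite(out_dir, seed: int = 0) -> dict:
    """Write the standard test-fixture suite and return its manifest.

    Produces the three archetype phantoms (imzML + truth-mask PNG), a null
    cohort and an SM x0.7 effect cohort (fingerprint + design CSVs), plus a
    ``manifest.json`` recording every file with the seed that generated it.
    Deterministic: re-running with the same seed reproduces the manifest.
    """
    import json
    from pathlib import Path

    from PIL import Image

    from .msi_core import write_datacube

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "files": []}

    archetypes = {"packed-blob": lc_like(), "isolated-soma": me5_like(), "micro-soma": snc_like()}
    for i, (kind, arch) in enumerate(archetypes.items()):
        cfg = PhantomConfig(archetypes=(arch,), seed=seed + i)
        cube, truth = make_phantom(cfg)
        stem = kind.replace("-", "_")
        write_datacube(cube, out / f"{stem}.imzML")
        mask = np.zeros(cfg.width * cfg.height, dtype=np.uint8)
        mask[list(truth.masks[kind])] = 255
        Image.fromarray(mask.reshape(cfg.height, cfg.width)).save(out / f"{stem}_mask.png")
        manifest["files"].append(
            {"path": f"{stem}.imzML", "seed": cfg.seed, "kind": kind,
             "roi_pixels": len(truth.masks[kind])}
        )
        manifest["files"].append({"path": f"{stem}_mask.png", "seed": cfg.seed, "kind": kind})

    cohorts = {
        "null_cohort": CohortConfig(seed=seed + 10),
        "effect_cohort": CohortConfig(class_effects={"SM": 0.7}, seed=seed + 11),
    }
    for name, ccfg in cohorts.items():
        table, design = sample_cohort_fingerprints(ccfg)
        table.to_csv(out / f"{name}_fingerprints.csv")
        design.to_csv(out / f"{name}_design.csv", index=False)
        manifest["files"].append(
            {"path": f"{name}_fingerprints.csv", "seed": ccfg.seed,
             "effects": dict(ccfg.class_effects), "samples": len(design)}
        )
        manifest["files"].append({"path": f"{name}_design.csv", "seed": ccfg.seed})

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
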