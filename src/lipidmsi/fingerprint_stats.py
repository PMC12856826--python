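"""Annotated-fingerprint statistics: renormalization, aggregation, group tests, PCA.

After annotating the extracted channels, unidentified channels are dropped and
the remaining abundances renormalized so that the identified species sum to 1.
Left/right hemisphere fingerprints of each animal are averaged; species are
aggregated to lipid classes or to fatty-acyl pools (e.g. all species carrying
20:4 or 22:6 chains, given acyl-level evidence). Group comparisons use a
Levene-gated one-way chain: homogeneous variances route to Tukey's HSD,
heterogeneous ones to Games-Howell; asterisks mark p < 0.05 / 0.01 / 0.001.
PCA operates on per-feature min-max-scaled (0-1) data.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .lipid_db import Annotation, species_class

__all__ = [
    "AnnotatedFingerprint",
    "StatResult",
    "PairwiseComparison",
    "PCAResult",
    "renormalize_annotated",
    "average_hemispheres",
    "class_abundance",
    "fa_pool_abundance",
    "levene_test",
    "anova_oneway",
    "tukey_hsd",
    "games_howell",
    "compare_groups",
    "pca",
    "stars",
]


@dataclass
class AnnotatedFingerprint:
    """Relative abundances over identified species, summing to 1."""

    abundances: dict[str, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = np.fromiter(self.abundances.values(), dtype=float)
        if np.any(vals < 0):
            raise ValueError("abundances must be non-negative")
        if len(vals) and abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"abundances must sum to 1 (got {vals.sum()!r})")

    def as_series(self) -> pd.Series:
        return pd.Series(self.abundances, dtype=float)


def renormalize_annotated(
    fingerprint: np.ndarray, annotations: list[Annotation]
) -> AnnotatedFingerprint:
    """Drop unannotated channels and renormalize so identified species sum to 1.

    ``fingerprint`` holds per-channel mean intensities aligned with
    ``annotations``. Channels resolving to the same species label are summed.
    """
    fingerprint = np.asarray(fingerprint, dtype=float)
    if len(fingerprint) != len(annotations):
        raise ValueError("fingerprint and annotation lengths differ")
    acc: dict[str, float] = {}
    for v, ann in zip(fingerprint, annotations):
        if ann.matched:
            acc[ann.label] = acc.get(ann.label, 0.0) + float(v)
    total = sum(acc.values())
    if not acc or total <= 0:
        raise ValueError("no annotated channel with positive intensity")
    return AnnotatedFingerprint({k: v / total for k, v in acc.items()})


def average_hemispheres(table: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Average matched left/right hemisphere fingerprints per (animal, nucleus, section).

    ``table`` is samples x species indexed by sample id; ``design`` has columns
    sample, animal, sex, nucleus, section, hemisphere. Samples missing their
    partner hemisphere pass through with a warning. Returns a fingerprint table
    indexed by "animal/nucleus/section" with the design columns carried along.
    """
    design = design.set_index("sample") if "sample" in design.columns else design
    rows, meta = [], []
    for (animal, nucleus, section), grp in design.loc[table.index].groupby(
        ["animal", "nucleus", "section"], sort=True
    ):
        if len(grp) == 1:
            warnings.warn(
                f"unmatched hemisphere for animal={animal} nucleus={nucleus} "
                f"section={section}; passing through"
            )
        elif len(grp) > 2:
            raise ValueError(f"more than two hemispheres for {(animal, nucleus, section)}")
        rows.append(table.loc[grp.index].mean(axis=0))
        meta.append(
            {
                "animal": animal,
                "nucleus": nucleus,
                "section": section,
                "sex": grp["sex"].iloc[0],
                "hemispheres": "".join(sorted(grp["hemisphere"])),
            }
        )
    out = pd.DataFrame(rows, index=[f"{m['animal']}/{m['nucleus']}/{m['section']}" for m in meta])
    out.attrs["design"] = pd.DataFrame(meta, index=out.index)
    return out


def class_abundance(
    fp: AnnotatedFingerprint | pd.Series, class_map: dict[str, str] | None = None
) -> pd.Series:
    """Sum species abundances per lipid class.

    Classes are parsed from the species labels ("PI 38:4" -> PI; joined labels
    resolve to their top-ranked species) unless an explicit map is given. The
    class sums preserve the fingerprint total.
    """
    s = fp.as_series() if isinstance(fp, AnnotatedFingerprint) else fp
    classes = [class_map[k] if class_map else species_class(k) for k in s.index]
    return s.groupby(pd.Index(classes, name="class")).sum().sort_index()


def fa_pool_abundance(
    fp: AnnotatedFingerprint | pd.Series,
    fatty_acid: str,
    evidence: dict[str, tuple[str, ...]],
) -> tuple[float, dict]:
    """Summed abundance of species whose acyl evidence contains ``fatty_acid``.

    ``evidence`` maps sum-composition labels to acyl constituents, e.g.
    ``{"PS 40:6": ("18:0", "22:6")}`` — the stand-in for an LC-MS/MS
    identification table. Species without evidence are excluded and counted in
    the coverage report.
    """
    s = fp.as_series() if isinstance(fp, AnnotatedFingerprint) else fp
    total, covered, uncovered = 0.0, [], []
    for label, v in s.items():
        chains = evidence.get(label) or evidence.get(label.split("/")[0])
        if chains is None:
            uncovered.append(label)
            continue
        covered.append(label)
        if fatty_acid in chains:
            total += float(v)
    report = {
        "fatty_acid": fatty_acid,
        "covered": covered,
        "uncovered": uncovered,
        "coverage": len(covered) / max(len(s), 1),
    }
    if not covered:
        warnings.warn(f"no acyl evidence covers any species; {fatty_acid} pool is 0")
    return total, report


# ---------------------------------------------------------------------------
# univariate test chain
# ---------------------------------------------------------------------------


def _check_groups(groups, min_n=2) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < min_n for g in gs):
        raise ValueError(f"each group needs n >= {min_n}")
    return gs


def levene_test(groups, center: str = "mean") -> tuple[float, float]:
    """Levene's homogeneity-of-variance test (classic mean-centered variant).

    ``center='median'`` selects the Brown-Forsythe variant. Returns (W, p)
    with p from F(k-1, N-k).
    """
    gs = _check_groups(groups)
    w, p = sps.levene(*gs, center=center)
    return float(w), float(p)


def anova_oneway(groups) -> tuple[float, float]:
    """One-way fixed-effects ANOVA; returns (F, p) with p from F(k-1, N-k)."""
    gs = _check_groups(groups)
    f, p = sps.f_oneway(*gs)
    return float(f), float(p)


def tukey_hsd(groups) -> dict[tuple[int, int], float]:
    """Tukey's HSD pairwise p-values (Tukey-Kramer under unequal n)."""
    gs = _check_groups(groups)
    res = sps.tukey_hsd(*gs)
    return {
        (i, j): float(res.pvalue[i, j])
        for i, j in itertools.combinations(range(len(gs)), 2)
    }


def games_howell(groups) -> dict[tuple[int, int], float]:
    """Games-Howell pairwise p-values (robust to unequal variances).

    For groups i, j: t = |mi - mj| / sqrt(si^2/ni + sj^2/nj) with
    Welch-Satterthwaite degrees of freedom; p = studentized-range survival at
    q = t * sqrt(2) with k groups.
    """
    gs = _check_groups(groups)
    k = len(gs)
    m = [g.mean() for g in gs]
    v = [g.var(ddof=1) for g in gs]
    n = [len(g) for g in gs]
    out: dict[tuple[int, int], float] = {}
    for i, j in itertools.combinations(range(k), 2):
        se2 = v[i] / n[i] + v[j] / n[j]
        if se2 == 0:
            out[(i, j)] = 1.0 if m[i] == m[j] else 0.0
            continue
        t = abs(m[i] - m[j]) / np.sqrt(se2)
        df = se2**2 / (
            (v[i] / n[i]) ** 2 / (n[i] - 1) + (v[j] / n[j]) ** 2 / (n[j] - 1)
        )
        p = float(sps.studentized_range.sf(t * np.sqrt(2.0), k, df))
        out[(i, j)] = min(1.0, max(0.0, p))
    return out


def stars(p: float) -> str:
    """Significance stars at 0.05 / 0.01 / 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    p: float
    stars: str


@dataclass
class StatResult:
    feature: str
    group_means: dict[str, float]
    levene_w: float
    levene_p: float
    anova_f: float
    anova_p: float
    posthoc: str  # "Tukey" | "Games-Howell"
    pairwise: list[PairwiseComparison]
    fdr_q: float | None = None
    skipped: str | None = None


def compare_groups(
    table: pd.DataFrame,
    design: pd.DataFrame,
    factor: str,
    alpha: float = 0.05,
    fdr: bool = False,
) -> list[StatResult]:
    """Levene-gated one-way comparison of every feature across factor levels.

    Per feature: Levene's test chooses the post hoc family — Games-Howell when
    Levene p < ``alpha`` (heterogeneous variances), Tukey's HSD otherwise —
    and a one-way ANOVA F/p is attached. Features with any level at n < 2 are
    skipped with a reason. ``fdr=True`` adds Benjamini-Hochberg q-values over
    the ANOVA p's (off by default; stars always reflect raw post hoc p's).
    """
    if factor not in design.columns:
        raise ValueError(f"factor {factor!r} not in design")
    labels = design.loc[table.index, factor]
    levels = sorted(labels.unique())
    results: list[StatResult] = []
    for feat in table.columns:
        groups = [table.loc[labels == lv, feat].to_numpy(dtype=float) for lv in levels]
        means = {lv: float(np.mean(g)) if len(g) else float("nan") for lv, g in zip(levels, groups)}
        if any(len(g) < 2 for g in groups):
            results.append(
                StatResult(feat, means, np.nan, np.nan, np.nan, np.nan, "", [],
                           skipped="a group has n < 2")
            )
            continue
        if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
            results.append(
                StatResult(feat, means, np.nan, np.nan, np.nan, np.nan, "", [],
                           skipped="feature is constant")
            )
            continue
        lw, lp = levene_test(groups)
        method = "Games-Howell" if lp < alpha else "Tukey"
        pmap = games_howell(groups) if method == "Games-Howell" else tukey_hsd(groups)
        f, p = anova_oneway(groups)
        pw = [
            PairwiseComparison(levels[i], levels[j], pij, stars(pij))
            for (i, j), pij in sorted(pmap.items())
        ]
        results.append(StatResult(feat, means, lw, lp, f, p, method, pw))
    if fdr:
        tested = [r for r in results if r.skipped is None]
        if tested:
            qs = _bh_fdr(np.array([r.anova_p for r in tested]))
            for r, q in zip(tested, qs):
                r.fdr_q = float(q)
    return results


def _bh_fdr(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    q = np.empty(n)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = n - rank_from_top
        running = min(running, p[idx] * n / rank)
        q[idx] = running
    return q


def stat_results_frame(results: list[StatResult]) -> pd.DataFrame:
    """Flatten StatResults to a tidy table (one row per pairwise comparison)."""
    rows = []
    for r in results:
        base = {
            "feature": r.feature,
            "levene_W": r.levene_w,
            "levene_p": r.levene_p,
            "anova_F": r.anova_f,
            "anova_p": r.anova_p,
            "posthoc": r.posthoc,
            "skipped": r.skipped or "",
        }
        if r.fdr_q is not None:
            base["fdr_q"] = r.fdr_q
        if not r.pairwise:
            rows.append(base)
        for c in r.pairwise:
            rows.append({**base, "group_a": c.group_a, "group_b": c.group_b,
                         "p": c.p, "stars": c.stars})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    explained_variance_ratio: np.ndarray
    feature_min: pd.Series
    feature_range: pd.Series


def pca(table: pd.DataFrame, scale01: bool = True, n_components: int | None = None) -> PCAResult:
    """PCA of a samples x features table after per-feature 0-1 scaling.

    Each feature is min-max scaled over the analyzed sample set (constant
    features map to 0), mean-centered, and the covariance eigendecomposition
    is taken via SVD. Component signs follow the convention that each
    component's largest-magnitude loading is positive.
    """
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 features")
    x = table.to_numpy(dtype=float)
    fmin = x.min(axis=0)
    frange = np.ptp(x, axis=0)
    if scale01:
        safe = np.where(frange > 0, frange, 1.0)
        x = np.where(frange > 0, (x - fmin) / safe, 0.0)
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    rank = min(xc.shape[0] - 1, xc.shape[1])
    k = rank if n_components is None else min(n_components, rank)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # deterministic signs: largest-|loading| positive per component
    for c in range(k):
        jmax = int(np.argmax(np.abs(vt[c])))
        if vt[c, jmax] < 0:
            vt[c] *= -1
            u[:, c] *= -1
    scores = u * s
    var = s**2
    total_var = (xc**2).sum()
    evr = var / total_var if total_var > 0 else np.zeros_like(var)
    comp = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=table.index, columns=comp),
        loadings=pd.DataFrame(vt.T, index=table.columns, columns=comp),
        explained_variance_ratio=evr,
        feature_min=pd.Series(fmin, index=table.columns),
        feature_range=pd.Series(frange, index=table.columns),
    )
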