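"""Supervised bisecting k-means segmentation of MSI feature matrices.

Segmentation starts from all valid pixels and repeatedly splits one segment in
two by k-means (k = 2) on the TIC-normalized feature rows: two distinct random
pixels seed the centroids, the remaining pixels are assigned to the nearest
centroid by Euclidean distance, and assignment/centroid updates iterate until
the labels stop changing. The split is steered by a guide mask marking the
neuron population of interest: at each depth the leaf overlapping the guide
most is bisected, and splitting stops when the best leaf's Dice overlap with
the guide stops improving. A manual mask path covers populations (such as the
large isolated Me5 somas) that the automatic segmentation fails to gather into
one segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .msi_core import FeatureMatrix

__all__ = [
    "ROI",
    "SegmentNode",
    "SegmentTree",
    "UnsplittableError",
    "bisect",
    "supervised_segmentation",
    "manual_roi",
    "roi_fingerprint",
    "dice",
]

DEFAULT_MAX_ITER = 100
DEFAULT_RESTARTS = 10


class UnsplittableError(ValueError):
    """All rows in the segment are identical; no 2-way split exists."""


@dataclass(frozen=True)
class ROI:
    """A set of pixel indices (row-major, 0-based) with provenance."""

    pixels: frozenset[int]
    label: str = "roi"
    origin: str = "segmentation"  # segmentation | manual

    def __post_init__(self) -> None:
        if not self.pixels:
            raise ValueError("ROI must be non-empty")

    def __len__(self) -> int:
        return len(self.pixels)

    def index_array(self) -> np.ndarray:
        return np.fromiter(sorted(self.pixels), dtype=np.int64)


def dice(a: frozenset[int] | set[int], b: frozenset[int] | set[int]) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|)."""
    if not a and not b:
        return 1.0
    return 2.0 * len(set(a) & set(b)) / (len(a) + len(b))


@dataclass
class SegmentNode:
    pixels: np.ndarray  # sorted pixel indices
    centroid: np.ndarray
    depth: int
    seed: int | None = None  # seed of the winning restart that split this node
    n_iter: int = 0
    children: tuple["SegmentNode", "SegmentNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None


@dataclass
class SegmentTree:
    root: SegmentNode
    target: ROI | None = None
    log: list[dict] = field(default_factory=list)

    def leaves(self) -> list[SegmentNode]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n)
            else:
                stack.extend(n.children)
        return sorted(out, key=lambda n: int(n.pixels[0]))


def _kmeans2(rows: np.ndarray, init: np.ndarray, max_iter: int) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Lloyd iterations for k=2 from explicit initial centroids.

    Returns (labels, centroids, within-cluster SS, iterations). Assignment
    ties go to cluster 0; an emptied cluster is re-seeded with the point
    farthest from the surviving centroid.
    """
    cents = init.astype(np.float64).copy()
    labels = None
    for it in range(1, max_iter + 1):
        d0 = ((rows - cents[0]) ** 2).sum(axis=1)
        d1 = ((rows - cents[1]) ** 2).sum(axis=1)
        new = (d1 < d0).astype(np.int8)  # tie -> cluster 0
        for k in (0, 1):
            if not np.any(new == k):
                far = int(np.argmax(d0 if k == 0 else d1))
                new[far] = k
        if labels is not None and np.array_equal(new, labels):
            labels = new
            break
        labels = new
        for k in (0, 1):
            cents[k] = rows[labels == k].mean(axis=0)
    d = np.where(labels == 0, ((rows - cents[0]) ** 2).sum(axis=1), ((rows - cents[1]) ** 2).sum(axis=1))
    return labels, cents, float(d.sum()), it


def bisect(
    fm: FeatureMatrix,
    pixels: np.ndarray,
    seed: int,
    n_restarts: int = DEFAULT_RESTARTS,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Split ``pixels`` in two by seeded k-means (k = 2) on feature rows.

    Initial centroids are the rows of two distinct random pixels; the best of
    ``n_restarts`` runs (lowest within-cluster sum of squares) wins. When the
    subset is small the restarts enumerate distinct index pairs without
    replacement, so small instances are searched near-exhaustively.

    Returns ``(pixels_a, pixels_b, centroids, info)``; raises
    :class:`UnsplittableError` when all rows are identical.
    """
    pixels = np.asarray(pixels, dtype=np.int64)
    if len(pixels) < 2:
        raise ValueError("need at least 2 pixels to bisect")
    rows = fm.values[pixels]
    if np.all(rows == rows[0]):
        raise UnsplittableError("all feature rows identical; segment cannot be split")
    rng = np.random.default_rng(seed)
    n = len(pixels)
    # candidate init pairs: enumerate when feasible, sample otherwise
    n_pairs = n * (n - 1) // 2
    if n_pairs <= 4 * n_restarts:
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        rng.shuffle(pairs)
        pairs = pairs[: max(n_restarts, min(len(pairs), n_restarts))]
        if len(pairs) > n_restarts:
            pairs = pairs[:n_restarts]
    else:
        pairs = []
        seen = set()
        while len(pairs) < n_restarts:
            i, j = map(int, rng.choice(n, size=2, replace=False))
            key = (min(i, j), max(i, j))
            if key not in seen:
                seen.add(key)
                pairs.append(key)
    best = None
    for r, (i, j) in enumerate(pairs):
        if np.all(rows[i] == rows[j]):
            continue
        labels, cents, wss, iters = _kmeans2(rows, rows[[i, j]], max_iter)
        if best is None or wss < best[2] - 1e-12:
            best = (labels, cents, wss, iters, r)
    if best is None:
        raise UnsplittableError("no distinct initialization pair found")
    labels, cents, wss, iters, r = best
    a, b = pixels[labels == 0], pixels[labels == 1]
    info = {"seed": seed, "restart": r, "wss": wss, "iterations": iters}
    return a, b, cents, info


def supervised_segmentation(
    fm: FeatureMatrix,
    guide: ROI,
    max_depth: int = 10,
    seed: int = 0,
    n_restarts: int = DEFAULT_RESTARTS,
    max_iter: int = DEFAULT_MAX_ITER,
) -> SegmentTree:
    """Guide-steered iterative bisection.

    At each depth the leaf with the largest overlap fraction with the guide
    mask is bisected; the leaf with the best Dice coefficient against the guide
    is tracked and splitting stops when that Dice stops improving (or at
    ``max_depth``). The best leaf becomes the tree's target ROI.
    """
    valid = np.flatnonzero(fm.valid)
    guide_set = set(guide.pixels) & set(valid.tolist())
    if not guide_set:
        raise ValueError("guide mask is disjoint from valid pixels")
    root = SegmentNode(valid, fm.values[valid].mean(axis=0), depth=0)
    tree = SegmentTree(root)
    rng = np.random.default_rng(seed)

    def leaf_dice(node: SegmentNode) -> float:
        return dice(set(node.pixels.tolist()), guide_set)

    best_leaf, best_dice = root, leaf_dice(root)
    for depth in range(max_depth):
        leaves = tree.leaves()
        overlaps = [len(guide_set & set(l.pixels.tolist())) / len(guide_set) for l in leaves]
        k = int(np.argmax(overlaps))
        leaf = leaves[k]
        if len(leaf.pixels) < 2:
            break
        split_seed = int(rng.integers(0, 2**31 - 1))
        try:
            a, b, cents, info = bisect(fm, leaf.pixels, split_seed, n_restarts, max_iter)
        except UnsplittableError:
            break
        leaf.children = (
            SegmentNode(np.sort(a), cents[0], leaf.depth + 1),
            SegmentNode(np.sort(b), cents[1], leaf.depth + 1),
        )
        leaf.seed, leaf.n_iter = split_seed, info["iterations"]
        tree.log.append({"depth": depth, **info, "leaf_size": len(leaf.pixels)})
        cand = max(tree.leaves(), key=leaf_dice)
        cand_dice = leaf_dice(cand)
        if cand_dice <= best_dice:
            # no improvement: discard the attempted split and stop
            leaf.children = None
            leaf.seed = None
            tree.log.pop()
            break
        best_leaf, best_dice = cand, cand_dice
    tree.target = ROI(frozenset(int(p) for p in best_leaf.pixels), label=guide.label)
    tree.log.append({"target_dice": best_dice, "target_size": len(best_leaf.pixels)})
    return tree


def manual_roi(mask: np.ndarray | str, fm: FeatureMatrix, label: str = "manual") -> ROI:
    """ROI from a mask image (nonzero = member), intersected with valid pixels.

    ``mask`` is a 2-D array or a path to an 8-bit PNG/PGM of the cube's exact
    height x width.
    """
    if isinstance(mask, (str, bytes)) or hasattr(mask, "__fspath__"):
        from PIL import Image

        mask = np.asarray(Image.open(mask).convert("L"))
    mask = np.asarray(mask)
    if mask.shape != (fm.height, fm.width):
        raise ValueError(
            f"mask shape {mask.shape} does not match cube geometry {(fm.height, fm.width)}"
        )
    members = np.flatnonzero(mask.ravel()) if mask.dtype != bool else np.flatnonzero(mask.ravel())
    members = members[fm.valid[members]]
    if len(members) == 0:
        raise ValueError("mask covers no valid (nonzero-TIC) pixels")
    return ROI(frozenset(int(p) for p in members), label=label, origin="manual")


def roi_fingerprint(fm: FeatureMatrix, roi: ROI) -> np.ndarray:
    """Per-channel arithmetic mean over the ROI pixels (the segment's lipid
    fingerprint)."""
    return fm.values[roi.index_array()].mean(axis=0)
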