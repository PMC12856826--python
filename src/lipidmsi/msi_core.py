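"""MSI datacube handling: I/O, TIC normalization, peak/channel extraction.

A datacube is a rectangular pixel grid (10 µm/pixel by default) holding one
sparse centroid spectrum per pixel, acquired in a fixed mass window
(300-1300 Da by default). Processing follows the minimal chain used for
high-stability centroided acquisitions: no baseline subtraction, no peak
alignment, no smoothing — just per-pixel total-ion-current normalization,
pooling of the mean spectrum into resolution-width bins, intensity
thresholding to ~400 channels, and construction of a pixels x channels
feature matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "Datacube",
    "ChannelSet",
    "FeatureMatrix",
    "read_datacube",
    "write_datacube",
    "tic_normalize",
    "mean_spectrum",
    "select_threshold",
    "extract_channels",
    "build_feature_matrix",
    "channel_image",
]

DEFAULT_MASS_WINDOW = (300.0, 1300.0)
DEFAULT_PIXEL_SIZE_UM = 10.0
DEFAULT_RESOLVING_POWER = 60_000.0


@dataclass
class Datacube:
    """Pixel grid of sparse centroid spectra.

    Peaks are stored flat: ``pix[i]`` is the row-major 0-based pixel index of
    peak i, with ``mz``/``intensity`` aligned. Arrays are kept sorted by
    (pixel, m/z).
    """

    width: int
    height: int
    pix: np.ndarray  # int64, row-major pixel index per peak
    mz: np.ndarray  # float64
    intensity: np.ndarray  # float64
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    mass_window: tuple[float, float] = DEFAULT_MASS_WINDOW
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pix = np.asarray(self.pix, dtype=np.int64)
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if not (len(self.pix) == len(self.mz) == len(self.intensity)):
            raise ValueError("pix/mz/intensity arrays must be aligned")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        lo, hi = self.mass_window
        if len(self.mz) and (self.mz.min() < lo or self.mz.max() > hi):
            raise ValueError("peaks outside the acquisition mass window")
        order = np.lexsort((self.mz, self.pix))
        self.pix, self.mz, self.intensity = self.pix[order], self.mz[order], self.intensity[order]

    @property
    def n_pixels(self) -> int:
        return self.width * self.height

    def tic(self) -> np.ndarray:
        """Per-pixel total ion current, length ``n_pixels``."""
        return np.bincount(self.pix, weights=self.intensity, minlength=self.n_pixels)

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of pixels with nonzero TIC."""
        return self.tic() > 0

    def spectrum(self, x: int, y: int) -> tuple[np.ndarray, np.ndarray]:
        """Sparse spectrum (mz, intensity) of pixel (x, y), 0-based."""
        idx = y * self.width + x
        sel = self.pix == idx
        return self.mz[sel], self.intensity[sel]


def _from_pixel_lists(
    coords: list[tuple[int, int]],
    spectra: list[tuple[np.ndarray, np.ndarray]],
    width: int,
    height: int,
    mass_window: tuple[float, float],
    **kw,
) -> Datacube:
    """Assemble a cube, dropping (and counting) peaks outside the mass window."""
    pix_l, mz_l, it_l = [], [], []
    dropped = 0
    lo, hi = mass_window
    for (x, y), (mzs, its) in zip(coords, spectra):
        mzs = np.asarray(mzs, dtype=np.float64)
        its = np.asarray(its, dtype=np.float64)
        keep = (mzs >= lo) & (mzs <= hi)
        dropped += int((~keep).sum())
        pix_l.append(np.full(keep.sum(), y * width + x, dtype=np.int64))
        mz_l.append(mzs[keep])
        it_l.append(its[keep])
    if dropped:
        log.warning("dropped %d peaks outside mass window %s", dropped, mass_window)
        warnings.warn(f"dropped {dropped} peaks outside mass window {mass_window}")
    cat = lambda xs, dt: np.concatenate(xs) if xs else np.empty(0, dt)
    return Datacube(
        width, height, cat(pix_l, np.int64), cat(mz_l, np.float64), cat(it_l, np.float64),
        mass_window=mass_window, **kw,
    )


def read_datacube(
    path,
    dialect: str | None = None,
    mass_window: tuple[float, float] = DEFAULT_MASS_WINDOW,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> Datacube:
    """Load a datacube from processed-mode imzML or the CSV fixture dialect.

    The dialect is inferred from the extension when not given. Peaks outside
    ``mass_window`` are dropped with a logged count. Continuous-mode imzML is
    rejected (this pipeline consumes centroided peak lists only).
    """
    path = str(path)
    if dialect is None:
        dialect = "imzml" if path.lower().endswith(".imzml") else "csv"
    if dialect == "imzml":
        return _read_imzml(path, mass_window, pixel_size_um)
    if dialect == "csv":
        return _read_csv(path, mass_window, pixel_size_um)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_imzml(path, mass_window, pixel_size_um) -> Datacube:
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(path)
    modes = parser.metadata.file_description.param_by_name
    if "continuous" in modes and "processed" not in modes:
        raise ValueError(f"{path}: continuous-mode imzML is unsupported; centroid the data first")
    coords, spectra = [], []
    for i, (x, y, *_z) in enumerate(parser.coordinates):
        mzs, its = parser.getspectrum(i)
        coords.append((x - 1, y - 1))  # imzML coordinates are 1-based
        spectra.append((mzs, its))
    width = max(c[0] for c in coords) + 1
    height = max(c[1] for c in coords) + 1
    return _from_pixel_lists(
        coords, spectra, width, height, mass_window, pixel_size_um=pixel_size_um
    )


def _read_csv(path, mass_window, pixel_size_um) -> Datacube:
    import pandas as pd

    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as err:  # noqa: BLE001 - re-raise with location
        raise ValueError(f"{path}: malformed CSV fixture ({err})") from err
    expected = ["x", "y", "mz", "intensity"]
    if list(df.columns[:4]) != expected:
        raise ValueError(f"{path}: CSV fixture must have header {','.join(expected)}")
    width = int(df["x"].max()) + 1 if len(df) else 1
    height = int(df["y"].max()) + 1 if len(df) else 1
    lo, hi = mass_window
    keep = (df["mz"] >= lo) & (df["mz"] <= hi)
    if (~keep).any():
        log.warning("dropped %d peaks outside mass window %s", int((~keep).sum()), mass_window)
        warnings.warn(f"dropped {int((~keep).sum())} peaks outside mass window {mass_window}")
    df = df[keep]
    return Datacube(
        width,
        height,
        (df["y"].to_numpy(np.int64) * width + df["x"].to_numpy(np.int64)),
        df["mz"].to_numpy(np.float64),
        df["intensity"].to_numpy(np.float64),
        pixel_size_um=pixel_size_um,
        mass_window=mass_window,
    )


def write_datacube(cube: Datacube, path, dialect: str | None = None) -> None:
    """Write a cube as processed-mode imzML or the CSV fixture dialect."""
    path = str(path)
    if dialect is None:
        dialect = "imzml" if path.lower().endswith(".imzml") else "csv"
    if dialect == "imzml":
        from pyimzml.ImzMLWriter import ImzMLWriter

        with ImzMLWriter(
            path, mode="processed", mz_dtype=np.float64, intensity_dtype=np.float64,
            polarity="negative",
        ) as w:
            for idx in range(cube.n_pixels):
                sel = cube.pix == idx
                x, y = idx % cube.width, idx // cube.width
                w.addSpectrum(cube.mz[sel], cube.intensity[sel], (x + 1, y + 1, 1))
    elif dialect == "csv":
        with open(path, "w") as fh:
            fh.write("x,y,mz,intensity\n")
            for p, m, i in zip(cube.pix, cube.mz, cube.intensity):
                fh.write(f"{p % cube.width},{p // cube.width},{float(m)!r},{float(i)!r}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def tic_normalize(cube: Datacube) -> Datacube:
    """Divide each pixel's intensities by that pixel's total ion current.

    Zero-TIC pixels are left at zero; ``metadata['invalid_pixels']`` records
    them. Idempotent on already-normalized cubes.
    """
    tic = cube.tic()
    scale = np.ones_like(tic)
    nz = tic > 0
    scale[nz] = tic[nz]
    out = Datacube(
        cube.width,
        cube.height,
        cube.pix.copy(),
        cube.mz.copy(),
        cube.intensity / scale[cube.pix],
        pixel_size_um=cube.pixel_size_um,
        mass_window=cube.mass_window,
        metadata=dict(cube.metadata),
    )
    out.metadata["tic_normalized"] = True
    out.metadata["invalid_pixels"] = int((~nz).sum())
    return out


def mean_spectrum(cube: Datacube, resolving_power: float = DEFAULT_RESOLVING_POWER):
    """Mean spectrum over valid pixels, pooled into resolution-width bins.

    Peaks from all pixels are sorted by m/z and merged greedily: a peak joins
    the current bin while its gap to the running intensity-weighted centroid is
    at most ``centroid / (2 R)`` (bin width m/R around the centroid). Bin
    intensity is the summed intensity divided by the number of valid pixels.

    Returns ``(centers, intensities)`` as float64 arrays sorted by m/z.
    """
    if resolving_power <= 0:
        raise ValueError("resolving power must be positive")
    n_valid = int(cube.valid_mask().sum())
    if len(cube.mz) == 0 or n_valid == 0:
        raise ValueError("empty datacube")
    order = np.argsort(cube.mz, kind="stable")
    mz = cube.mz[order]
    it = cube.intensity[order]
    centers: list[float] = []
    sums: list[float] = []
    c_mz, c_w = mz[0], it[0] if it[0] > 0 else 1e-300
    c_sum = it[0]
    for m, i in zip(mz[1:], it[1:]):
        if m - c_mz <= c_mz / (2.0 * resolving_power):
            w = i if i > 0 else 1e-300
            c_mz = (c_mz * c_w + m * w) / (c_w + w)
            c_w += w
            c_sum += i
        else:
            centers.append(c_mz)
            sums.append(c_sum)
            c_mz, c_w, c_sum = m, (i if i > 0 else 1e-300), i
    centers.append(c_mz)
    sums.append(c_sum)
    return np.asarray(centers), np.asarray(sums) / n_valid


def _local_maxima(
    centers: np.ndarray, intensities: np.ndarray, resolving_power: float
) -> np.ndarray:
    """Indices of local-maximum bins.

    A neighboring bin competes only if it lies within two bin-widths
    (2 m/R) of the candidate; isolated bins are local maxima by themselves.
    Plateau ties break toward lower m/z (strict > to the left, >= to the
    right).
    """
    n = len(centers)
    out = []
    for i in range(n):
        win = 2.0 * centers[i] / resolving_power
        ok = True
        if i > 0 and centers[i] - centers[i - 1] <= win and not intensities[i] > intensities[i - 1]:
            ok = False
        if (
            i < n - 1
            and centers[i + 1] - centers[i] <= win
            and not intensities[i] >= intensities[i + 1]
        ):
            ok = False
        if ok:
            out.append(i)
    return np.asarray(out, dtype=np.int64)


def select_threshold(
    mean: tuple[np.ndarray, np.ndarray],
    target_channels: int = 400,
    resolving_power: float = DEFAULT_RESOLVING_POWER,
) -> tuple[float, float]:
    """Largest intensity threshold keeping at least ``target_channels`` peaks.

    Returns ``(threshold, fraction_of_max)``; the fraction allows comparison
    with the ~0.5%-of-maximum convention. When fewer candidate peaks exist
    than requested, the smallest positive peak intensity is returned with a
    warning.
    """
    if target_channels < 1:
        raise ValueError("target_channels must be >= 1")
    centers, intensities = mean
    peaks = intensities[_local_maxima(np.asarray(centers), np.asarray(intensities), resolving_power)]
    peaks = peaks[peaks > 0]
    if len(peaks) == 0:
        raise ValueError("mean spectrum has no positive peaks")
    top = np.sort(peaks)[::-1]
    if len(top) < target_channels:
        warnings.warn(
            f"only {len(top)} candidate peaks for target {target_channels}; keeping all"
        )
        t = float(top[-1])
    else:
        t = float(top[target_channels - 1])
    return t, t / float(top[0])


@dataclass(frozen=True)
class ChannelSet:
    """Ordered channel centers with per-channel half-width ``center / (2 R)``."""

    centers: np.ndarray
    resolving_power: float = DEFAULT_RESOLVING_POWER

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, dtype=np.float64)
        if np.any(np.diff(c) <= 0):
            raise ValueError("channel centers must be strictly increasing")
        object.__setattr__(self, "centers", c)

    def __len__(self) -> int:
        return len(self.centers)

    @property
    def half_widths(self) -> np.ndarray:
        return self.centers / (2.0 * self.resolving_power)


def extract_channels(
    mean: tuple[np.ndarray, np.ndarray],
    threshold: float,
    resolving_power: float = DEFAULT_RESOLVING_POWER,
) -> ChannelSet:
    """Channels = local maxima of the binned mean spectrum with intensity >= threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    centers, intensities = np.asarray(mean[0]), np.asarray(mean[1])
    idx = _local_maxima(centers, intensities, resolving_power)
    idx = idx[intensities[idx] >= threshold]
    return ChannelSet(centers[idx], resolving_power)


@dataclass
class FeatureMatrix:
    """Pixels x channels matrix of TIC-normalized summed intensities."""

    values: np.ndarray  # (n_pixels, n_channels)
    channels: ChannelSet
    width: int
    height: int
    valid: np.ndarray  # boolean per pixel

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]


def build_feature_matrix(cube: Datacube, channels: ChannelSet) -> FeatureMatrix:
    """Sum each pixel's peaks into channel windows.

    Each peak is attributed to the nearest channel center (ties toward lower
    m/z) and kept only if it falls within that channel's half-width; peaks
    outside all windows are discarded. Expects a TIC-normalized cube.
    """
    if not cube.metadata.get("tic_normalized"):
        warnings.warn("building a feature matrix from a cube not marked TIC-normalized")
    c = channels.centers
    hw = channels.half_widths
    values = np.zeros((cube.n_pixels, len(c)))
    if len(cube.mz):
        # nearest center: index of right neighbor, then compare distances
        j = np.searchsorted(c, cube.mz)
        left = np.clip(j - 1, 0, len(c) - 1)
        right = np.clip(j, 0, len(c) - 1)
        d_left = np.abs(cube.mz - c[left])
        d_right = np.abs(cube.mz - c[right])
        nearest = np.where(d_left <= d_right, left, right)  # tie -> lower m/z
        dist = np.minimum(d_left, d_right)
        inside = dist <= hw[nearest]
        np.add.at(values, (cube.pix[inside], nearest[inside]), cube.intensity[inside])
    return FeatureMatrix(values, channels, cube.width, cube.height, cube.valid_mask())


def channel_image(fm: FeatureMatrix, mz: float, tol: float | None = None) -> np.ndarray:
    """2-D (height x width) image of the channel nearest ``mz``.

    ``tol`` defaults to the channel half-width; a query farther than that from
    every center raises, naming the nearest channels. Invalid pixels are 0.
    """
    c = fm.channels.centers
    if len(c) == 0:
        raise ValueError("feature matrix has no channels")
    k = int(np.argmin(np.abs(c - mz)))
    lim = fm.channels.half_widths[k] if tol is None else tol
    if abs(c[k] - mz) > lim:
        near = ", ".join(f"{v:.4f}" for v in c[max(0, k - 2) : k + 3])
        raise ValueError(f"no channel within {lim:.4g} Da of m/z {mz}; nearest: {near}")
    col = fm.values[:, k].copy()
    col[~fm.valid] = 0.0
    return col.reshape(fm.height, fm.width)
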