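"""Synthetic NIR seed spectra and miniature hypercubes with known truth.

The generator emulates the measurement design of a 7-variety maize
seed study: 105 seeds per variety, 224 bands evenly spanning
935.61-1720.23 nm.  Each variety's reflectance profile is a shared
smooth baseline minus Gaussian absorption dips at variety-specific
wavelengths; samples add multiplicative scatter (surface/geometry
effects, removed later by maximum normalization) and additive Gaussian
sensor noise.  Adjacent varieties share one dip centre (with different
depths), mimicking the spectral similarity of half-parent hybrids, so
wavelength selection is non-trivial but solvable.

Ground truth (the informative band indices per class) is carried
alongside the data so selector recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hypercube import Hypercube, RoiMask
from .spectra import SpectraTable

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "default_centers",
    "default_depths",
    "class_profile",
    "generate_dataset",
    "generate_mini_cube",
]


def default_centers(n_classes: int = 7) -> list[list[float]]:
    """Two dip centres per class from a shared pool; neighbours overlap.

    The pool staggers ``n_classes + 1`` centres over 1000-1630 nm and
    class c takes (pool[c], pool[c+1]), so consecutive classes share
    exactly one centre.
    """
    pool = np.linspace(1000.0, 1630.0, n_classes + 1)
    return [[float(pool[c]), float(pool[c + 1])] for c in range(n_classes)]


def default_depths(n_classes: int, depth_range: tuple[float, float]) -> list[list[float]]:
    """Deterministic per-class dip depths covering ``depth_range``.

    Chosen so that the (centre, depth) pairs of all classes are
    distinct — in particular a centre shared by two classes carries a
    different depth in each.
    """
    lo, hi = depth_range
    return [
        [lo + (hi - lo) * ((2 * c + 3 * j) % 7) / 6.0 for j in range(2)]
        for c in range(n_classes)
    ]


@dataclass
class SyntheticSpec:
    """Generator settings; the defaults define the study conditions."""

    n_classes: int = 7
    n_per_class: int = 105
    n_bands: int = 224
    wl_start: float = 935.61
    wl_end: float = 1720.23
    informative_centers: list[list[float]] | None = None
    peak_depth_range: tuple[float, float] = (0.10, 0.30)
    peak_depths: list[list[float]] | None = None
    peak_width: float = 40.0  # FWHM, nm
    scatter_range: tuple[float, float] = (0.8, 1.2)
    noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_classes, self.n_per_class, self.n_bands) < 1:
            raise ValueError("counts must be positive")
        if not self.wl_start < self.wl_end:
            raise ValueError("wl_start must be < wl_end")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.informative_centers is None:
            self.informative_centers = default_centers(self.n_classes)
        if len(self.informative_centers) != self.n_classes:
            raise ValueError("need one centre list per class")
        for centers in self.informative_centers:
            for c in centers:
                if not self.wl_start <= c <= self.wl_end:
                    raise ValueError(f"centre {c} nm outside the wavelength grid")
        if self.peak_depths is None:
            self.peak_depths = [
                [
                    self.peak_depth_range[0]
                    + (self.peak_depth_range[1] - self.peak_depth_range[0])
                    * ((2 * c + 3 * j) % 7)
                    / 6.0
                    for j in range(len(self.informative_centers[c]))
                ]
                for c in range(self.n_classes)
            ]

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.wl_start, self.wl_end, self.n_bands)

    def truth_bands(self) -> list[list[int]]:
        """Per-class indices of the bands nearest each dip centre."""
        wl = self.wavelengths
        return [
            [int(np.argmin(np.abs(wl - c))) for c in centers]
            for centers in self.informative_centers
        ]


@dataclass
class SyntheticDataset:
    table: SpectraTable
    truth_bands: list[list[int]]
    spec: SyntheticSpec

    @property
    def truth_band_set(self) -> np.ndarray:
        return np.unique([b for bands in self.truth_bands for b in bands])


def _baseline(wavelengths: np.ndarray, wl_start: float, wl_end: float) -> np.ndarray:
    # smooth quadratic falling from ~0.9 to ~0.4 across the grid
    t = (wavelengths - wl_start) / (wl_end - wl_start)
    return 0.9 - 0.2 * t - 0.3 * t**2


_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def class_profile(class_id: int, spec: SyntheticSpec) -> np.ndarray:
    """Noise-free reflectance profile of one variety (length n_bands)."""
    if not 0 <= class_id < spec.n_classes:
        raise ValueError(f"class_id {class_id} outside 0..{spec.n_classes - 1}")
    wl = spec.wavelengths
    profile = _baseline(wl, spec.wl_start, spec.wl_end)
    sigma = spec.peak_width * _FWHM_TO_SIGMA
    for center, depth in zip(spec.informative_centers[class_id], spec.peak_depths[class_id]):
        profile = profile - depth * np.exp(-((wl - center) ** 2) / (2.0 * sigma**2))
    return np.clip(profile, 1e-6, 1.0)


def generate_dataset(spec: SyntheticSpec = SyntheticSpec()) -> SyntheticDataset:
    """Balanced labelled spectra: scatter * class_profile + noise."""
    rng = np.random.default_rng(spec.seed)
    profiles = np.stack([class_profile(c, spec) for c in range(spec.n_classes)])
    labels = np.repeat(np.arange(spec.n_classes), spec.n_per_class)
    n = labels.size
    scatter = rng.uniform(*spec.scatter_range, size=n)
    values = scatter[:, None] * profiles[labels] + rng.normal(0.0, spec.noise_sd, size=(n, spec.n_bands))
    order = rng.permutation(n)
    table = SpectraTable(
        values=values[order],
        wavelengths=spec.wavelengths,
        labels=labels[order],
        sample_ids=[f"seed{i:04d}" for i in range(n)],
    )
    return SyntheticDataset(table=table, truth_bands=spec.truth_bands(), spec=spec)


def generate_mini_cube(
    spec: SyntheticSpec = SyntheticSpec(),
    n_seeds: int = 4,
    image_size: tuple[int, int] = (64, 64),
):
    """A small raw/white/dark cube triple with elliptical seeds.

    Seeds (cycling through the classes) are placed on a grid over a
    near-dark background; raw digital numbers are built from the very
    same white and dark reference frames the caller will calibrate
    with, so black/white correction recovers each seed's reflectance
    up to the configured sensor noise.

    Returns ``(raw, white, dark, truth_masks, labels)`` where the
    masks cover the full ellipses.
    """
    rows, cols = image_size
    grid = int(np.ceil(np.sqrt(n_seeds)))
    cell_r, cell_c = rows // grid, cols // grid
    ax_r, ax_c = int(cell_r * 0.32), int(cell_c * 0.32)
    if min(ax_r, ax_c) < 3:
        raise ValueError(
            f"image {image_size} too small for {n_seeds} non-overlapping seeds"
        )
    rng = np.random.default_rng(spec.seed)
    wl = spec.wavelengths
    b = spec.n_bands

    dark_level, white_level = 100.0, 4000.0
    dark = dark_level + rng.normal(0, 1.0, size=(rows, cols, b))
    white = white_level + rng.normal(0, 5.0, size=(rows, cols, b))
    span = white - dark

    reflectance = np.full((rows, cols, b), 0.02)  # black paper background
    rr, cc = np.mgrid[0:rows, 0:cols]
    masks, labels = [], []
    for k in range(n_seeds):
        gi, gj = divmod(k, grid)
        cy, cx = gi * cell_r + cell_r // 2, gj * cell_c + cell_c // 2
        ellipse = ((rr - cy) / ax_r) ** 2 + ((cc - cx) / ax_c) ** 2 <= 1.0
        cls = k % spec.n_classes
        scatter = rng.uniform(*spec.scatter_range)
        reflectance[ellipse, :] = scatter * class_profile(cls, spec)
        masks.append(RoiMask.from_mask(ellipse))
        labels.append(cls)

    raw = dark + reflectance * span + rng.normal(0, spec.noise_sd, size=(rows, cols, b)) * span
    mk = lambda d, kind: Hypercube(
        data=d.astype(np.float32), wavelengths=wl.copy(), kind=kind
    )
    return (
        mk(raw, "raw"),
        mk(white, "reference_white"),
        mk(dark, "reference_dark"),
        masks,
        labels,
    )
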