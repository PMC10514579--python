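"""Spectral pretreatment: Savitzky-Golay smoothing, then maximum normalization.

The two steps target different artefacts: SG smoothing suppresses
band-to-band sensor noise, while per-sample maximum normalization (MN)
removes the multiplicative scatter differences between seeds (surface
geometry, packing) by mapping every spectrum into [0, 1] relative to
its own maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

from .spectra import SpectraTable

__all__ = ["PreprocessConfig", "sg_smooth", "max_normalize", "preprocess"]


@dataclass(frozen=True)
class PreprocessConfig:
    """Settings for the SG + MN pretreatment.

    ``sg_window`` is the odd number of smoothing points (default 3);
    ``sg_polyorder`` the fitted polynomial degree (default 1 — with a
    3-point window an order-2 fit reproduces the input exactly, so
    order 1, i.e. a 3-point moving average, is the only choice under
    which a 3-point window actually smooths).  ``normalize`` is
    ``"max_normalization"`` or ``"none"``.
    """

    sg_window: int = 3
    sg_polyorder: int = 1
    normalize: str = "max_normalization"

    def __post_init__(self) -> None:
        if self.sg_window < 3 or self.sg_window % 2 == 0:
            raise ValueError("sg_window must be odd and >= 3")
        if not 0 <= self.sg_polyorder < self.sg_window:
            raise ValueError("sg_polyorder must be < sg_window")
        if self.normalize not in ("max_normalization", "none"):
            raise ValueError(f"unknown normalize mode {self.normalize!r}")


def sg_smooth(table: SpectraTable, cfg: PreprocessConfig = PreprocessConfig()) -> SpectraTable:
    """Savitzky-Golay least-squares smoothing along the wavelength axis.

    Edges are mirror-padded by (window-1)/2 points so the output keeps
    all B bands.
    """
    if cfg.sg_window >= table.n_bands:
        raise ValueError(
            f"sg_window {cfg.sg_window} must be smaller than band count {table.n_bands}"
        )
    smoothed = savgol_filter(
        table.values, cfg.sg_window, cfg.sg_polyorder, axis=1, mode="mirror"
    )
    return replace(table, values=smoothed)


def max_normalize(table: SpectraTable) -> SpectraTable:
    """Divide each spectrum by its own maximum so every row peaks at 1."""
    peaks = table.values.max(axis=1)
    bad = np.nonzero(peaks <= 0)[0]
    if bad.size:
        names = ", ".join(table.sample_ids[i] for i in bad[:5])
        raise ValueError(f"max normalization undefined for non-positive rows: {names}")
    return replace(table, values=table.values / peaks[:, None])


def preprocess(table: SpectraTable, cfg: PreprocessConfig = PreprocessConfig()) -> SpectraTable:
    """Full pretreatment in fixed order: SG smoothing, then MN."""
    out = sg_smooth(table, cfg)
    if cfg.normalize == "max_normalization":
        out = max_normalize(out)
    return out
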