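"""Tabular reflectance spectra: the central in-memory container.

A :class:`SpectraTable` holds one mean reflectance spectrum per seed
(rows) on a common wavelength grid in nanometres (columns), plus an
integer variety label per row.  All downstream stages (preprocessing,
wavelength selection, model training) operate on this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["SpectraTable", "crop_band_range"]


@dataclass
class SpectraTable:
    """N spectra on a shared, strictly increasing wavelength grid.

    Parameters
    ----------
    values : ndarray, shape (N, B)
        Reflectance values, one row per sample.
    wavelengths : ndarray, shape (B,)
        Band-centre wavelengths in nm, strictly increasing.
    labels : ndarray of int, shape (N,)
        Class label per row, coded ``0..q-1``.
    sample_ids : list of str
        One identifier per row; autogenerated when omitted.
    """

    values: np.ndarray
    wavelengths: np.ndarray
    labels: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (samples x bands) array")
        n, b = self.values.shape
        if self.wavelengths.shape != (b,):
            raise ValueError(
                f"wavelength grid length {self.wavelengths.size} != band count {b}"
            )
        if self.labels.shape != (n,):
            raise ValueError(f"label count {self.labels.size} != sample count {n}")
        if b > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectra contain non-finite values")
        if not self.sample_ids:
            self.sample_ids = [f"s{i:04d}" for i in range(n)]
        elif len(self.sample_ids) != n:
            raise ValueError("sample_ids length mismatch")

    # -- basic views ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def take_rows(self, idx: np.ndarray) -> "SpectraTable":
        idx = np.asarray(idx)
        return replace(
            self,
            values=self.values[idx],
            labels=self.labels[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
        )

    def take_bands(self, idx: np.ndarray) -> "SpectraTable":
        idx = np.asarray(idx)
        return replace(
            self,
            values=self.values[:, idx],
            wavelengths=self.wavelengths[idx],
        )

    # -- CSV round trip ------------------------------------------------
    def to_csv(self, path) -> None:
        """Write ``sample_id, label, <one column per band named by nm>``."""
        df = pd.DataFrame(self.values, columns=[f"{w:.2f}" for w in self.wavelengths])
        df.insert(0, "label", self.labels)
        df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectraTable":
        df = pd.read_csv(path)
        for col in ("sample_id", "label"):
            if col not in df.columns:
                raise ValueError(f"spectra CSV missing required column {col!r}")
        band_cols = [c for c in df.columns if c not in ("sample_id", "label")]
        wavelengths = np.array([float(c) for c in band_cols])
        return cls(
            values=df[band_cols].to_numpy(dtype=float),
            wavelengths=wavelengths,
            labels=df["label"].to_numpy(dtype=int),
            sample_ids=[str(s) for s in df["sample_id"]],
        )


def crop_band_range(table: SpectraTable, lo_nm: float, hi_nm: float) -> SpectraTable:
    """Keep exactly the bands with ``lo_nm <= wavelength <= hi_nm``.

    Both endpoints are inclusive so that a crop bound placed on a band
    centre retains that band.  Raises ``ValueError`` when the window
    contains no band.
    """
    if not lo_nm < hi_nm:
        raise ValueError(f"invalid crop window [{lo_nm}, {hi_nm}]")
    keep = np.nonzero((table.wavelengths >= lo_nm) & (table.wavelengths <= hi_nm))[0]
    if keep.size == 0:
        raise ValueError(
            f"no band inside [{lo_nm}, {hi_nm}] nm "
            f"(grid spans {table.wavelengths[0]:.2f}-{table.wavelengths[-1]:.2f})"
        )
    return table.take_bands(keep)
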