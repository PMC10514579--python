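"""Feature-wavelength selection: SPA, CARS, and their union.

Two complementary chemometric selectors reduce the full NIR grid to a
small informative band set:

* **SPA** (successive projections algorithm) greedily grows a chain of
  bands with minimal collinearity — each new band maximizes the
  residual norm after projection onto the orthogonal complement of the
  bands already chosen — and then sizes the chain by validation RMSE
  of a multiple linear regression on one-hot class codes.

* **CARS** (competitive adaptive reweighted sampling) runs N Monte
  Carlo iterations of PLS fitting on random 80% row subsamples,
  ranking bands by absolute PLS regression coefficient and retaining a
  fraction dictated by an exponentially decreasing function (EDF) that
  falls from 1 to 2/p; the subset with minimal cross-validated RMSECV
  wins.

Both selectors treat the classification task PLS-DA style: labels are
one-hot coded into q response columns and RMSE/RMSECV is pooled over
all q columns.  The final feature set is the union of the two
selections.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from math import ceil, exp, log
from pathlib import Path

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import KFold

from .spectra import SpectraTable

__all__ = [
    "SelectionResult",
    "CarsConfig",
    "one_hot",
    "spa_projection_chain",
    "spa_select",
    "edf_ratio",
    "cars_select",
    "union_bands",
]


def one_hot(labels: np.ndarray, n_classes: int | None = None) -> np.ndarray:
    """One-hot code integer labels into an N x q response matrix."""
    labels = np.asarray(labels, dtype=int)
    q = n_classes if n_classes is not None else int(labels.max()) + 1
    out = np.zeros((labels.size, q))
    out[np.arange(labels.size), labels] = 1.0
    return out


@dataclass
class SelectionResult:
    """Outcome of one selector run (or of a union of two).

    ``criterion_curve`` is a list of ``(step, criterion)`` pairs where
    the criterion is validation RMSE per subset size (SPA) or RMSECV
    per Monte Carlo run (CARS); ``subsets_per_step`` holds the
    candidate band subset at each step and ``chosen_step`` indexes the
    winner.
    """

    method: str
    selected_indices: np.ndarray
    grid_wavelengths: np.ndarray
    criterion_curve: list[tuple[int, float]] = field(default_factory=list)
    subsets_per_step: list[list[int]] = field(default_factory=list)
    chosen_step: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.selected_indices = np.asarray(self.selected_indices, dtype=int)
        self.grid_wavelengths = np.asarray(self.grid_wavelengths, dtype=float)
        if self.selected_indices.size:
            if not np.all(np.diff(self.selected_indices) > 0):
                raise ValueError("selected_indices must be strictly increasing")
            if self.selected_indices[0] < 0 or self.selected_indices[-1] >= self.grid_wavelengths.size:
                raise ValueError("selected_indices out of grid range")
        if any(v < 0 for _, v in self.criterion_curve):
            raise ValueError("criterion values must be nonnegative")
        if self.chosen_step is not None and self.subsets_per_step:
            chosen = sorted(self.subsets_per_step[self.chosen_step])
            if chosen != self.selected_indices.tolist():
                raise ValueError("selected_indices != sorted subset at chosen_step")

    @property
    def selected_wavelengths(self) -> np.ndarray:
        return self.grid_wavelengths[self.selected_indices]

    @property
    def n_selected(self) -> int:
        return int(self.selected_indices.size)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "seed": self.seed,
            "selected_indices": self.selected_indices.tolist(),
            "selected_wavelengths": self.selected_wavelengths.tolist(),
            "grid_wavelengths": self.grid_wavelengths.tolist(),
            "criterion_curve": [[int(s), float(v)] for s, v in self.criterion_curve],
            "subsets_per_step": [list(map(int, s)) for s in self.subsets_per_step],
            "chosen_step": self.chosen_step,
        }

    @classmethod
    def from_json(cls, path) -> "SelectionResult":
        d = json.loads(Path(path).read_text())
        return cls(
            method=d["method"],
            selected_indices=np.array(d["selected_indices"], dtype=int),
            grid_wavelengths=np.array(d["grid_wavelengths"], dtype=float),
            criterion_curve=[(int(s), float(v)) for s, v in d["criterion_curve"]],
            subsets_per_step=[list(map(int, s)) for s in d["subsets_per_step"]],
            chosen_step=d["chosen_step"],
            seed=d["seed"],
        )


# ----------------------------------------------------------------------
# SPA
# ----------------------------------------------------------------------

def spa_projection_chain(X: np.ndarray, start: int, k_max: int) -> list[int]:
    """Greedy orthogonal-projection chain of column indices.

    ``X`` is expected column mean-centered.  The chain begins at
    ``start``; each subsequent pick is the column with maximal
    Euclidean norm after projection onto the orthogonal complement of
    the span of the columns already chosen (ties broken toward the
    lowest index).
    """
    X = np.asarray(X, dtype=float)
    n, b = X.shape
    if not 1 <= k_max <= min(n, b):
        raise ValueError(f"k_max={k_max} infeasible for a {n}x{b} matrix (rank bound)")
    if not 0 <= start < b:
        raise ValueError(f"start column {start} out of range")
    resid = X.copy()
    chain = [int(start)]
    for _ in range(1, k_max):
        v = resid[:, chain[-1]]
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            raise ValueError(f"rank exhausted after {len(chain)} picks (k_max={k_max})")
        u = v / nv
        resid -= np.outer(u, u @ resid)
        norms = np.linalg.norm(resid, axis=0)
        norms[chain] = -1.0
        chain.append(int(np.argmax(norms)))  # argmax -> first max -> lowest index
    return chain


def _mlr_val_rmse(Xtr, Ytr, Xval, Yval) -> float:
    """Pooled validation RMSE of an intercept-augmented least-squares fit."""
    Atr = np.column_stack([np.ones(len(Xtr)), Xtr])
    Aval = np.column_stack([np.ones(len(Xval)), Xval])
    coef, *_ = np.linalg.lstsq(Atr, Ytr, rcond=None)
    err = Aval @ coef - Yval
    return float(np.sqrt(np.mean(err**2)))


def spa_select(
    train: SpectraTable, val: SpectraTable, k_max: int = 20
) -> SelectionResult:
    """SPA band selection sized by validation RMSE on one-hot labels.

    A projection chain of length ``k_max`` is grown from every start
    band; for each subset size k the best chain prefix (lowest
    validation RMSE of a multiple linear regression on the one-hot
    class codes) defines the criterion curve.  The chosen size is the
    smallest k whose best RMSE is within 5% of the curve's global
    minimum — the "no longer decreases significantly" elbow.
    """
    if not np.allclose(train.wavelengths, val.wavelengths):
        raise ValueError("train and val wavelength grids differ")
    if k_max >= train.n_samples:
        raise ValueError(f"k_max={k_max} must be < n_train={train.n_samples}")
    b = train.n_bands
    q = max(train.n_classes, val.n_classes)
    Xtr, Xval = train.values, val.values
    Ytr, Yval = one_hot(train.labels, q), one_hot(val.labels, q)
    Xc = Xtr - Xtr.mean(axis=0)

    k_max = min(k_max, train.n_samples - 1, b)
    best_rmse = np.full(k_max, np.inf)
    best_prefix: list[list[int]] = [[] for _ in range(k_max)]
    for start in range(b):
        chain = spa_projection_chain(Xc, start, k_max)
        for k in range(1, k_max + 1):
            prefix = chain[:k]
            rmse = _mlr_val_rmse(Xtr[:, prefix], Ytr, Xval[:, prefix], Yval)
            if rmse < best_rmse[k - 1]:  # strict: ties keep earliest start
                best_rmse[k - 1] = rmse
                best_prefix[k - 1] = prefix
    curve = [(k + 1, float(best_rmse[k])) for k in range(k_max)]
    rmin = float(best_rmse.min())
    chosen = int(np.nonzero(best_rmse <= 1.05 * rmin)[0][0])
    return SelectionResult(
        method="spa",
        selected_indices=np.array(sorted(best_prefix[chosen])),
        grid_wavelengths=train.wavelengths.copy(),
        criterion_curve=curve,
        subsets_per_step=best_prefix,
        chosen_step=chosen,
    )


# ----------------------------------------------------------------------
# CARS
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class CarsConfig:
    """CARS settings: N Monte Carlo runs, CV folds for RMSECV, PLS size."""

    n_runs: int = 50
    cv_folds: int = 5
    n_pls_components: int = 10
    mc_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.n_pls_components < 1:
            raise ValueError("n_pls_components must be >= 1")
        if not 0 < self.mc_fraction <= 1:
            raise ValueError("mc_fraction must be in (0, 1]")


def edf_ratio(i: int, N: int, p: int) -> float:
    """Exponentially decreasing retention fraction r_i = a*e^(-k*i).

    Calibrated so r_1 = 1 (all p bands retained on the first run) and
    r_N = 2/p (two bands on the last): a = (p/2)^(1/(N-1)),
    k = ln(p/2)/(N-1).
    """
    if not 1 <= i <= N:
        raise ValueError(f"run index {i} outside 1..{N}")
    if p < 2:
        raise ValueError("need at least 2 bands")
    a = (p / 2.0) ** (1.0 / (N - 1))
    k = log(p / 2.0) / (N - 1)
    return a * exp(-k * i)


def _pls_fit_weights(X, Y, n_components) -> np.ndarray:
    """|PLS regression coefficient| summed over response columns."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        pls = PLSRegression(n_components=n_components, scale=False)
        pls.fit(X, Y)
    return np.abs(pls.coef_).sum(axis=0)  # coef_ is (n_targets, n_features)


def _pls_rmsecv(X, Y, n_components, folds) -> float:
    """Pooled k-fold RMSECV of a PLS model on the given columns."""
    err = np.empty_like(Y)
    for tr, te in folds:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            pls = PLSRegression(n_components=min(n_components, X.shape[1], len(tr) - 1), scale=False)
            pls.fit(X[tr], Y[tr])
        err[te] = pls.predict(X[te]) - Y[te]
    return float(np.sqrt(np.mean(err**2)))


def cars_select(table: SpectraTable, cfg: CarsConfig = CarsConfig()) -> SelectionResult:
    """Competitive adaptive reweighted sampling over the band grid.

    Per Monte Carlo run i = 1..N: fit PLS on an ``mc_fraction`` row
    subsample restricted to the currently retained bands; weight each
    band by its absolute regression coefficient; retain the
    ceil(r_i * p) top-weighted bands (the EDF-enforced descent; the
    adaptive reweighted draw is taken without replacement at full
    count, so it reduces to this forced top-k selection and the
    stochastic competition comes from the row subsampling); record the
    pooled k-fold RMSECV of a PLS model on that subset.  The subset
    with minimal RMSECV wins (earliest run on ties).
    """
    n, p = table.values.shape
    if n < cfg.cv_folds:
        raise ValueError("fewer samples than CV folds")
    rng = np.random.default_rng(cfg.seed)
    X = table.values
    Y = one_hot(table.labels)
    kf = KFold(n_splits=cfg.cv_folds, shuffle=True, random_state=int(rng.integers(2**31)))
    folds = list(kf.split(X))
    n_sub = max(2, int(round(cfg.mc_fraction * n)))

    retained = np.arange(p)
    subsets: list[list[int]] = []
    rmsecv = np.empty(cfg.n_runs)
    clip_warned = False
    for i in range(1, cfg.n_runs + 1):
        rows = rng.choice(n, size=n_sub, replace=False)
        ncomp = min(cfg.n_pls_components, retained.size, n_sub - 1)
        if ncomp < cfg.n_pls_components and not clip_warned:
            warnings.warn(
                f"PLS components clipped to {ncomp} (retained bands: {retained.size})",
                stacklevel=2,
            )
            clip_warned = True
        w = _pls_fit_weights(X[np.ix_(rows, retained)], Y[rows], ncomp)
        n_keep = min(retained.size, ceil(edf_ratio(i, cfg.n_runs, p) * p))
        order = np.argsort(-w, kind="stable")  # ties -> lowest band index
        retained = np.sort(retained[order[:n_keep]])
        subsets.append(retained.tolist())
        rmsecv[i - 1] = _pls_rmsecv(X[:, retained], Y, cfg.n_pls_components, folds)

    winner = int(np.argmin(rmsecv))  # first minimum on ties
    return SelectionResult(
        method="cars",
        selected_indices=np.array(subsets[winner]),
        grid_wavelengths=table.wavelengths.copy(),
        criterion_curve=[(i + 1, float(v)) for i, v in enumerate(rmsecv)],
        subsets_per_step=subsets,
        chosen_step=winner,
        seed=cfg.seed,
    )


def union_bands(a: SelectionResult, b: SelectionResult) -> SelectionResult:
    """Sorted set-union of two selections on the same wavelength grid."""
    if a.grid_wavelengths.size != b.grid_wavelengths.size or not np.allclose(
        a.grid_wavelengths, b.grid_wavelengths
    ):
        raise ValueError("selections refer to different wavelength grids")
    merged = np.array(sorted(set(a.selected_indices) | set(b.selected_indices)))
    return SelectionResult(
        method="union",
        selected_indices=merged,
        grid_wavelengths=a.grid_wavelengths.copy(),
        subsets_per_step=[merged.tolist()],
        chosen_step=0,
        seed=a.seed if a.seed is not None else b.seed,
    )
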