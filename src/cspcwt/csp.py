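"""Common spatial pattern (CSP) filtering with a one-vs-rest multiclass extension.

CSP finds a linear spatial filter W that jointly diagonalizes the average
covariance matrices of two signal classes: projected variance is maximal for
one class exactly where it is minimal for the other.  The construction is the
classical whitening route: trace-normalize per-epoch covariances, average per
class, eigendecompose the composite covariance R1 + R2, whiten with
Pw = Δ^{-1/2} Uᵀ, then diagonalize the whitened class-1 covariance with common
eigenvectors V.  The paired eigenvalue spectra satisfy Δ1 + Δ2 = I, and
W = Vᵀ Pw with inverse W⁻¹ whose columns are the spatial patterns.

Six-class decoding uses one binary contrast per event against a balanced pool
of epochs drawn from the other five classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import linalg

from .io_gal import EVENT_NAMES, EpochSet

#: Relative eigenvalue threshold below which whitening refuses to proceed.
EIG_FLOOR = 1e-10


class DegenerateEpochError(ValueError):
    """An epoch (or covariance) carries no energy."""


class RankDeficiencyError(np.linalg.LinAlgError):
    """Composite covariance is (numerically) singular; consider shrinkage."""


class CoverageError(ValueError):
    """The epoch set does not contain every event class."""


def spatial_covariance(X: np.ndarray) -> np.ndarray:
    """Trace-normalized spatial covariance R = XXᵀ / trace(XXᵀ) of one epoch."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("epoch must be a (channels x samples) matrix")
    C = X @ X.T
    tr = np.trace(C)
    if tr <= 0:
        raise DegenerateEpochError("zero-energy epoch has no spatial covariance")
    return C / tr


def average_covariance(covs) -> np.ndarray:
    """Element-wise mean of trace-normalized covariances (trace stays 1)."""
    covs = list(covs)
    if not covs:
        raise ValueError("cannot average an empty covariance list")
    shapes = {c.shape for c in covs}
    if len(shapes) != 1:
        raise ValueError(f"covariance dimensions differ: {shapes}")
    return np.mean(covs, axis=0)


def shrink(R: np.ndarray, lam: float) -> np.ndarray:
    """Shrinkage regularization R ← (1-λ)R + λ·(trace(R)/N)·I."""
    n = R.shape[0]
    return (1 - lam) * R + lam * (np.trace(R) / n) * np.eye(n)


def whitening_transform(Rc: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigendecompose the composite covariance and build the whitening matrix.

    Returns ``(U, Delta, Pw)`` with eigenvalues in descending order and
    ``Pw = Delta^{-1/2} Uᵀ`` so that ``Pw Rc Pwᵀ = I``.  Eigenvalue ties keep
    their original order (stable sort); raises :class:`RankDeficiencyError`
    when the smallest eigenvalue falls below ``EIG_FLOOR`` times the largest.
    """
    Rc = np.asarray(Rc, dtype=float)
    evals, evecs = linalg.eigh(Rc)
    order = np.argsort(-evals, kind="stable")
    Delta, U = evals[order], evecs[:, order]
    if Delta[-1] < EIG_FLOOR * Delta[0]:
        raise RankDeficiencyError(
            "composite covariance is rank deficient; enable shrinkage regularization"
        )
    Pw = np.diag(Delta ** -0.5) @ U.T
    return U, Delta, Pw


def _fix_signs(V: np.ndarray) -> np.ndarray:
    # Deterministic sign convention: largest-magnitude entry of each column > 0.
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


@dataclass
class CSPModel:
    """Fitted CSP filter for one event-vs-rest contrast.

    ``W`` rows are ordered by descending event-class eigenvalue ``Delta1``, so
    row 0 captures the direction of maximal event variance (and minimal rest
    variance) and the last row the opposite extreme.  Columns of ``W_inv`` are
    the corresponding spatial patterns.
    """

    U: np.ndarray
    Delta: np.ndarray
    Pw: np.ndarray
    V: np.ndarray
    Delta1: np.ndarray
    Delta2: np.ndarray
    W: np.ndarray
    W_inv: np.ndarray
    contrast: tuple[str, str] = ("", "rest")

    @property
    def n_channels(self) -> int:
        return self.W.shape[0]

    def save(self, path) -> None:
        np.savez(
            path,
            U=self.U, Delta=self.Delta, Pw=self.Pw, V=self.V,
            Delta1=self.Delta1, Delta2=self.Delta2, W=self.W, W_inv=self.W_inv,
            contrast=np.array(self.contrast),
        )

    @classmethod
    def load(cls, path) -> "CSPModel":
        z = np.load(path)
        return cls(
            U=z["U"], Delta=z["Delta"], Pw=z["Pw"], V=z["V"],
            Delta1=z["Delta1"], Delta2=z["Delta2"], W=z["W"], W_inv=z["W_inv"],
            contrast=tuple(z["contrast"]),
        )


def csp_fit(epochs_event, epochs_rest, contrast: tuple[str, str] = ("event", "rest")) -> CSPModel:
    """Fit a two-class CSP model from raw epoch matrices.

    ``epochs_event`` and ``epochs_rest`` are iterables of (N x T) matrices.
    The whitened class covariances Q1, Q2 share common eigenvectors V with
    paired spectra summing to one; W = Vᵀ Pw is returned with rows sorted by
    descending Delta1.
    """
    covs1 = [spatial_covariance(X) for X in epochs_event]
    covs2 = [spatial_covariance(X) for X in epochs_rest]
    R1 = average_covariance(covs1)
    R2 = average_covariance(covs2)
    if R1.shape != R2.shape:
        raise ValueError("classes have different channel counts")
    U, Delta, Pw = whitening_transform(R1 + R2)
    Q1 = Pw @ R1 @ Pw.T
    d1, V = linalg.eigh((Q1 + Q1.T) / 2)
    order = np.argsort(-d1, kind="stable")
    d1, V = d1[order], _fix_signs(V[:, order])
    W = V.T @ Pw
    return CSPModel(
        U=U, Delta=Delta, Pw=Pw, V=V,
        Delta1=d1, Delta2=1.0 - d1,
        W=W, W_inv=np.linalg.inv(W),
        contrast=contrast,
    )


def csp_project(model: CSPModel, X: np.ndarray) -> np.ndarray:
    """Project an epoch onto the CSP components: Z = W X."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] != model.n_channels:
        raise ValueError(f"epoch has {X.shape[0]} rows, model expects {model.n_channels}")
    return model.W @ X


def csp_reconstruct(model: CSPModel, Z: np.ndarray) -> np.ndarray:
    """Invert the projection: X = W⁻¹ Z."""
    Z = np.asarray(Z, dtype=float)
    if Z.shape[0] != model.n_channels:
        raise ValueError(f"components have {Z.shape[0]} rows, model expects {model.n_channels}")
    return model.W_inv @ Z


def rest_pool_indices(
    labels: np.ndarray,
    event: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Balanced rest-pool epoch indices for a one-vs-rest contrast.

    Draws (seeded, without replacement where possible) an equal number of
    epochs from each of the five non-target event classes so the pool size
    matches the event-class count and no single class dominates the rest
    covariance.
    """
    labels = np.asarray(labels)
    n_event = int((labels == event).sum())
    others = [k for k in range(len(EVENT_NAMES)) if k != event]
    per_class = max(1, int(math.ceil(n_event / len(others))))
    chosen = []
    for k in others:
        idx = np.flatnonzero(labels == k)
        if idx.size == 0:
            raise CoverageError(f"no epochs for class {EVENT_NAMES[k]}")
        take = rng.choice(idx, size=per_class, replace=idx.size < per_class)
        chosen.append(take)
    return np.concatenate(chosen)


def one_vs_rest_fit(epochs: EpochSet, seed: int = 0) -> dict[str, CSPModel]:
    """Fit six CSP models, one per event against a balanced five-class rest pool."""
    present = set(np.unique(epochs.labels))
    missing = [n for k, n in enumerate(EVENT_NAMES) if k not in present]
    if missing:
        raise CoverageError(f"epoch set lacks classes: {missing}")
    rng = np.random.default_rng(seed)
    models = {}
    for k, name in enumerate(EVENT_NAMES):
        rest_idx = rest_pool_indices(epochs.labels, k, rng)
        models[name] = csp_fit(
            epochs.epochs_for(k),
            epochs.epochs[rest_idx],
            contrast=(name, "rest"),
        )
    return models


def rest_pool_orderings(event: str | int = "HS") -> int:
    """Number of distinct orderings of the five non-target classes in a rest pool.

    Enumerated explicitly (5! = 120) rather than assumed.
    """
    k = EVENT_NAMES.index(event) if isinstance(event, str) else int(event)
    others = [n for i, n in enumerate(EVENT_NAMES) if i != k]
    return sum(1 for _ in permutations(others))


def singular_energy_profile(Z_all: np.ndarray) -> np.ndarray:
    """Cumulative energy fraction captured by the leading singular vectors.

    Entry k is (Σ_{i<=k} σ_i²)/(Σ σ_i²) for singular values σ of the
    concatenated CSP feature matrix; CSP compresses most oriented energy into
    the first few components, so the profile saturates early.
    """
    Z_all = np.asarray(Z_all, dtype=float)
    if Z_all.size == 0:
        raise ValueError("empty feature matrix")
    s = np.linalg.svd(Z_all, compute_uv=False)
    energy = s**2
    total = energy.sum()
    if total == 0:
        raise DegenerateEpochError("zero feature matrix has no energy profile")
    return np.cumsum(energy) / total
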