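"""Muscle-synergy extraction.

Processed EMG epochs are stacked into an observations x 7 matrix (one column
per muscle, z-scored), decomposed by PCA on the correlation matrix, and the
retained principal components are rotated by FastICA (fixed-point log-cosh
negentropy) into statistically independent synergies.  Also provides the
variance-accounted metrics: per-PC variance fractions, the minimum number of
components reaching a variance threshold, and the rank-k reconstruction
residual RMS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .io import MUSCLES, TrialRecording
from .segmentation import EpochWindows


class IcaConvergenceError(RuntimeError):
    """FastICA did not converge within the iteration budget."""

    def __init__(self, n_iter: int, max_iter: int):
        self.n_iter = n_iter
        self.max_iter = max_iter
        super().__init__(f"ICA did not converge after {n_iter}/{max_iter} iterations")


@dataclass(frozen=True)
class SynergyDecomposition:
    """PCA + ICA decomposition of a pooled epoch matrix."""

    muscles: tuple[str, ...]
    pc_loadings: np.ndarray          # 7 x 7, columns orthonormal
    pc_variance_fractions: np.ndarray  # length 7, descending, sums to 1
    n_retained: int
    ica_unmixing: np.ndarray         # n x n, acts on whitened PC scores
    synergy_weights: np.ndarray      # 7 x n back-projected muscle weights
    synergy_waveforms: np.ndarray    # observations x n independent sources
    residual_rms: np.ndarray         # rank-k residual RMS for k = 1..7
    seed: int


def build_matrix(records: list[TrialRecording], windows: list[EpochWindows],
                 phase: str) -> np.ndarray:
    """Stack each trial's epoch samples into an observations x 7 matrix.

    Columns follow the montage order and are z-scored (mean 0, variance 1)
    over the pooled samples; a zero-variance column (a muscle flat across the
    whole pool) is rejected by name.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 trials to pool an epoch matrix")
    if len(records) != len(windows):
        raise ValueError("one epoch-window set per trial is required")
    blocks = []
    for rec, win in zip(records, windows):
        sl = win.slice_(phase)
        blocks.append(np.column_stack([rec.emg[m][sl] for m in MUSCLES]))
    x = np.vstack(blocks)
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    for j, m in enumerate(MUSCLES):
        if std[j] == 0:
            raise ValueError(f"zero-variance column for muscle {m!r}")
    return (x - mean) / std


def pca(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the column correlation matrix.

    Returns ``(loadings, fractions)``: loadings columns are unit eigenvectors
    ordered by descending eigenvalue, with the deterministic sign convention
    that each component's largest-magnitude loading is positive; fractions
    are eigenvalues normalized by their sum.
    """
    x = np.asarray(matrix, float)
    if not np.isfinite(x).all():
        raise ValueError("matrix contains non-finite entries")
    if x.shape[0] < x.shape[1]:
        raise ValueError("need at least as many observations as muscles")
    corr = (x.T @ x) / x.shape[0]
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    for j in range(eigvecs.shape[1]):
        k = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    return eigvecs, eigvals / eigvals.sum()


def min_components(fractions: np.ndarray, threshold: float = 0.75) -> int:
    """Smallest k whose leading-k cumulative variance fraction reaches the threshold."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    cum = np.cumsum(np.asarray(fractions, float))
    hits = np.flatnonzero(cum >= threshold - 1e-12)
    if hits.size == 0:
        raise ValueError("variance fractions do not reach the threshold")
    return int(hits[0]) + 1


def reconstruction_residual_rms(matrix: np.ndarray, k: int) -> float:
    """RMS of the rank-k PCA reconstruction residual, pooled over all entries."""
    x = np.asarray(matrix, float)
    if not 1 <= k <= x.shape[1]:
        raise ValueError(f"k must lie in 1..{x.shape[1]}")
    loadings, _ = pca(x)
    scores = x @ loadings[:, :k]
    resid = x - scores @ loadings[:, :k].T
    return float(np.sqrt(np.mean(resid ** 2)))


def extract_synergies(matrix: np.ndarray, n_components: int, seed: int = 0,
                      max_iter: int = 1000, tol: float = 1e-6,
                      restarts: int = 5) -> SynergyDecomposition:
    """Project onto the top PCs and rotate into independent synergies.

    The retained PC scores are whitened and unmixed by FastICA (parallel
    fixed-point iteration, log-cosh negentropy contrast) with a seeded
    initial rotation, so identical seeds give identical unmixing matrices.
    When a start fails to converge within ``max_iter`` the rotation is
    re-initialized deterministically (seed, seed+1, ...) up to ``restarts``
    times -- the fixed-point iteration is sensitive to its starting point on
    weakly non-Gaussian data; :class:`IcaConvergenceError` is raised after
    the final failed start.  Components are ordered by back-projected
    variance and sign-fixed like the PCA loadings.
    """
    if n_components not in (2, 3, 4):
        raise ValueError("n_components must be 2, 3 or 4")
    x = np.asarray(matrix, float)
    loadings, fractions = pca(x)
    eigvals = fractions * x.shape[1]  # correlation-matrix eigenvalues
    lam = eigvals[:n_components]
    if np.any(lam <= 0):
        raise ValueError("retained components have zero variance")
    scores = x @ loadings[:, :n_components]
    white = scores / np.sqrt(lam)

    # Deterministic restart schedule: symmetric (parallel) updates at the
    # strict tolerance, then at a 100x relaxed tolerance, then one-unit-at-a-
    # time deflation -- the symmetric update can cycle between equivalent
    # rotations on weakly non-Gaussian data where deflation still converges.
    sources = None
    for algorithm, level_tol in (("parallel", tol), ("parallel", 100 * tol),
                                 ("deflation", tol)):
        for attempt in range(max(restarts, 1)):
            rng = np.random.default_rng(seed + attempt)
            w_init = rng.standard_normal((n_components, n_components))
            ica = FastICA(algorithm=algorithm, fun="logcosh",
                          max_iter=max_iter, tol=level_tol, whiten=False,
                          w_init=w_init)
            with warnings.catch_warnings():
                warnings.simplefilter("error", ConvergenceWarning)
                try:
                    sources = ica.fit_transform(white)
                    break
                except ConvergenceWarning:
                    continue
        if sources is not None:
            break
    if sources is None:
        raise IcaConvergenceError(max_iter, max_iter)
    unmixing = ica.components_                       # white -> sources
    mixing = np.linalg.inv(unmixing)                 # sources -> white

    # Back-projected muscle weights: sources -> white -> PC scores -> muscles.
    weights = loadings[:, :n_components] @ (np.sqrt(lam)[:, None] * mixing)
    var = np.sum(weights ** 2, axis=0) * sources.var(axis=0)
    order = np.argsort(var)[::-1]
    weights = weights[:, order]
    sources = sources[:, order]
    unmixing = unmixing[order]
    for j in range(n_components):
        k = np.argmax(np.abs(weights[:, j]))
        if weights[k, j] < 0:
            weights[:, j] = -weights[:, j]
            sources[:, j] = -sources[:, j]
            unmixing[j] = -unmixing[j]

    residual = np.array([reconstruction_residual_rms(x, k)
                         for k in range(1, x.shape[1] + 1)])
    return SynergyDecomposition(
        muscles=MUSCLES, pc_loadings=loadings, pc_variance_fractions=fractions,
        n_retained=n_components, ica_unmixing=unmixing, synergy_weights=weights,
        synergy_waveforms=sources, residual_rms=residual, seed=seed)
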