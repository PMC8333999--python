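"""Common spatial patterns for two-class EEG enhancement.

CSP finds spatial filters W that maximize the variance of the projected
signal for one class while minimizing it for the other.  With per-class
covariances C_A and C_B (averages of trace-normalized per-trial covariances
G G^T / tr(G G^T)), the composite C = C_A + C_B = Z psi Z^T is whitened by
P = psi^{-1/2} Z^T, so that C'_A = P C_A P^T and C'_B = P C_B P^T share
eigenvectors U with eigenvalue matrices that sum to the identity.  The
projection is W = U^T P with rows sorted by descending class-A eigenvalue;
features are F = W G.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, TransformerMixin


def class_covariance(trials) -> np.ndarray:
    """Average of trace-normalized per-trial covariances G G^T / tr(G G^T).

    Symmetric positive semi-definite with unit trace.  Warns when the result
    is numerically rank-deficient.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("need at least one trial")
    M = np.asarray(trials[0]).shape[0]
    C = np.zeros((M, M))
    for G in trials:
        G = np.asarray(G, dtype=float)
        if G.shape[0] != M:
            raise ValueError("all trials must share the channel count")
        GG = G @ G.T
        tr = np.trace(GG)
        if tr <= 0:
            raise ValueError("trial with zero power cannot be covariance-"
                             "normalized")
        C += GG / tr
    C /= len(trials)
    C = 0.5 * (C + C.T)
    if linalg.eigvalsh(C)[0] < 1e-12:
        warnings.warn("class covariance is numerically rank-deficient")
    return C


def _shrink(C: np.ndarray, gamma: float) -> np.ndarray:
    M = C.shape[0]
    return (1.0 - gamma) * C + gamma * (np.trace(C) / M) * np.eye(M)


class CSP(BaseEstimator, TransformerMixin):
    """Sklearn-style CSP transformer.

    Parameters
    ----------
    n_components : int or None
        Number of spatial filters retained by :meth:`transform`.  ``None``
        keeps all M filters (the downstream attention model consumes the
        fully rotated signal); an even integer keeps the top/bottom pairs
        ranked by eigenvalue extremity.
    cond_threshold : float
        Condition number of the composite covariance above which scalar
        shrinkage toward the identity is applied (with a warning).

    Attributes
    ----------
    filters_ : ndarray [M x M]
        Full projection matrix W = U^T P, rows sorted by descending
        class-A eigenvalue.
    eigvals_a_, eigvals_b_ : ndarray [M]
        Whitened-space eigenvalues per class; they sum to one pairwise.
    whitening_ : ndarray [M x M]
        P = psi^{-1/2} Z^T.
    composite_eigvecs_, composite_eigvals_ : diagnostics (Z and psi).
    fitted_on_ : tuple of trial identifiers seen during fit (leakage audit).
    """

    def __init__(self, n_components=None, cond_threshold=1e10,
                 shrinkage="auto", rank_tol=1e-10):
        self.n_components = n_components
        self.cond_threshold = cond_threshold
        self.shrinkage = shrinkage
        self.rank_tol = rank_tol

    def fit(self, X, y, trial_ids=None):
        """Fit on trials ``X`` (iterable of [M x S] arrays or an
        [n, M, S] array) with binary labels ``y`` (0/'A' vs 1/'B')."""
        X = [np.asarray(x, dtype=float) for x in X]
        y = np.asarray(["AB".index(v) if isinstance(v, str) else int(v)
                        for v in y])
        classes = np.unique(y)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if set(classes) - {0, 1} or len(classes) != 2:
            raise ValueError("CSP requires exactly two classes (A/0 and B/1)")
        Ca = class_covariance([x for x, l in zip(X, y) if l == 0])
        Cb = class_covariance([x for x, l in zip(X, y) if l == 1])
        self._fit_covariances(Ca, Cb)
        self.fitted_on_ = tuple(trial_ids) if trial_ids is not None else \
            tuple(range(len(X)))
        return self

    def _fit_covariances(self, Ca: np.ndarray, Cb: np.ndarray):
        C = Ca + Cb
        psi, Z = linalg.eigh(C)
        # whitening is only defined on the span of the data: directions with
        # (numerically) zero composite variance - e.g. the exact linear
        # dependence introduced by mastoid re-referencing - are truncated
        keep = psi > self.rank_tol * psi[-1]
        if not keep.any():
            raise ValueError("composite covariance is numerically zero")
        if not keep.all():
            warnings.warn(
                f"composite covariance rank-deficient; retaining "
                f"{int(keep.sum())} of {len(psi)} dimensions")
            psi, Z = psi[keep], Z[:, keep]
        cond = psi[-1] / psi[0]
        if cond > self.cond_threshold:
            gamma = 1e-4 if self.shrinkage == "auto" else float(self.shrinkage)
            warnings.warn(
                f"composite covariance ill-conditioned (cond={cond:.3g}); "
                f"applying shrinkage gamma={gamma}")
            Ca, Cb = _shrink(Ca, gamma), _shrink(Cb, gamma)
            psi, Z = linalg.eigh(Ca + Cb)
            keep = psi > self.rank_tol * psi[-1]
            psi, Z = psi[keep], Z[:, keep]
        P = (Z / np.sqrt(psi)).T          # psi^{-1/2} Z^T, [r x M]
        Ca_w = P @ Ca @ P.T
        lam_a, U = linalg.eigh(Ca_w)
        order = np.argsort(lam_a)[::-1]
        lam_a, U = lam_a[order], U[:, order]
        self.whitening_ = P
        self.composite_eigvecs_ = Z
        self.composite_eigvals_ = psi
        self.eigvals_a_ = lam_a
        self.eigvals_b_ = 1.0 - lam_a
        self.filters_ = U.T @ P
        r = self.filters_.shape[0]
        self.n_components_ = r if self.n_components is None \
            else min(int(self.n_components), r)
        return self

    def _selected_rows(self) -> np.ndarray:
        M = self.filters_.shape[0]
        k = self.n_components_
        if k >= M:
            return np.arange(M)
        # alternate most extreme eigenvalues: top, bottom, 2nd top, ...
        idx, lo, hi = [], M - 1, 0
        while len(idx) < k:
            idx.append(hi); hi += 1
            if len(idx) < k:
                idx.append(lo); lo -= 1
        return np.array(idx)

    def transform(self, X):
        """Project trials (or a single [M x S] trial) through the retained
        spatial filters: F = W G."""
        if isinstance(X, np.ndarray) and X.ndim == 2:
            return self._apply_one(X)
        return [self._apply_one(np.asarray(x)) for x in X]

    def _apply_one(self, G: np.ndarray) -> np.ndarray:
        W = self.filters_
        if G.shape[0] != W.shape[1]:
            raise ValueError(
                f"trial has {G.shape[0]} channels, CSP was fitted on "
                f"{W.shape[1]}")
        return W[self._selected_rows()] @ G


# -- thin functional wrappers ------------------------------------------------

def fit_csp(trials_a, trials_b, n_components=None, trial_ids=None) -> CSP:
    """Fit CSP from two lists of [M x S] class-wise trials."""
    ta, tb = list(trials_a), list(trials_b)
    return CSP(n_components=n_components).fit(
        ta + tb, [0] * len(ta) + [1] * len(tb), trial_ids=trial_ids)


def apply_csp(model: CSP, eeg: np.ndarray) -> np.ndarray:
    """Apply fitted spatial filters to one [M x S] EEG matrix."""
    return model.transform(np.asarray(eeg))
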