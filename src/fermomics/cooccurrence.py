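"""Microbe-metabolite cooccurrence by low-rank conditional factorization.

The model treats each microbial read in a sample as an observation that
"emits" the sample's metabolite profile: the probability of metabolite j
conditioned on a read of microbe m is ``softmax_j(u_m . v_j + b_j)`` with
d-dimensional latent vectors u (microbes) and v (metabolites) and a
per-metabolite bias. Because the multinomial likelihood factorizes, the
sufficient statistic is the microbes-x-metabolites weight matrix
``C = Xrel^T Yrel`` (per-sample relative abundances, equal sample weight),
and training is deterministic full-batch Adam on the penalized
log-likelihood. The fitted ``conditional_`` matrix has one probability
distribution over metabolites per microbe row.

A biplot is obtained by SVD of the column-centered log conditional
matrix: microbe scores U.S, metabolite loadings V, axes sign-canonicalized
so the largest-magnitude metabolite loading on each axis is positive.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator


def _softmax_rows(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class CooccurrenceFactorizer(BaseEstimator):
    """Low-rank metabolite-given-microbe conditional probability model.

    Parameters
    ----------
    n_components : latent dimension d (must be < min(#microbes, #metabolites)).
    epochs, learning_rate : full-batch Adam training schedule.
    ridge : small L2 penalty on U and V for identifiability when there is
        no cooccurrence signal.
    seed : controls the latent initialization.

    Attributes set by ``fit``: ``U_`` (microbes x d), ``V_``
    (metabolites x d), ``bias_`` (metabolites), ``conditional_``
    (microbes x metabolites DataFrame, rows sum to 1), ``loss_curve_``.
    """

    def __init__(self, n_components=3, epochs=2000, learning_rate=0.05,
                 ridge=1e-4, seed=0):
        self.n_components = n_components
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.ridge = ridge
        self.seed = seed

    def fit(self, X: pd.DataFrame, Y: pd.DataFrame) -> "CooccurrenceFactorizer":
        """Fit on a microbe count table ``X`` and metabolite table ``Y``.

        Tables are aligned on the intersection of their sample IDs (at
        least two shared samples required; dropped samples are reported
        in ``n_dropped_samples_``).
        """
        shared = X.index.intersection(Y.index, sort=False)
        if len(shared) < 2:
            raise ValueError("need at least 2 shared samples")
        self.n_dropped_samples_ = (len(X) - len(shared)) + (len(Y) - len(shared))
        X = X.loc[shared]
        Y = Y.loc[shared]
        d = self.n_components
        D, M = X.shape[1], Y.shape[1]
        if d >= min(D, M):
            raise ValueError(
                f"n_components={d} must be < min(n_microbes={D}, "
                f"n_metabolites={M})")

        Xrel = X.to_numpy(float)
        Xrel /= np.maximum(Xrel.sum(axis=1, keepdims=True), 1e-12)
        Yrel = Y.to_numpy(float)
        Yrel /= np.maximum(Yrel.sum(axis=1, keepdims=True), 1e-12)
        C = Xrel.T @ Yrel  # microbes x metabolites cooccurrence weights
        total = C.sum()
        if total <= 0:
            raise ValueError("empty cooccurrence weights")
        w = C.sum(axis=1, keepdims=True)  # per-microbe weight

        rng = np.random.default_rng(self.seed)
        U = 0.1 * rng.standard_normal((D, d))
        V = 0.1 * rng.standard_normal((M, d))
        b = np.zeros(M)
        mo = [np.zeros_like(U), np.zeros_like(V), np.zeros_like(b)]
        vo = [np.zeros_like(U), np.zeros_like(V), np.zeros_like(b)]
        b1, b2, eps = 0.9, 0.999, 1e-8
        losses = []
        for step in range(1, self.epochs + 1):
            P = _softmax_rows(U @ V.T + b[None, :])
            Rerr = w * P - C  # gradient of -loglik wrt logits
            grads = [Rerr @ V / total + self.ridge * U,
                     Rerr.T @ U / total + self.ridge * V,
                     Rerr.sum(axis=0) / total]
            params = [U, V, b]
            for k in range(3):
                mo[k] = b1 * mo[k] + (1 - b1) * grads[k]
                vo[k] = b2 * vo[k] + (1 - b2) * grads[k]**2
                params[k] -= self.learning_rate * (
                    mo[k] / (1 - b1**step)
                    / (np.sqrt(vo[k] / (1 - b2**step)) + eps))
            with np.errstate(divide="ignore"):
                ll = (C * np.log(_softmax_rows(U @ V.T + b[None, :]))).sum()
            loss = float(-ll / total
                         + 0.5 * self.ridge * ((U**2).sum() + (V**2).sum()))
            if not np.isfinite(loss):
                raise RuntimeError(f"fit diverged at step {step}")
            losses.append(loss)

        self.U_, self.V_, self.bias_ = U, V, b
        self.microbe_ids_ = list(X.columns)
        self.metabolite_ids_ = list(Y.columns)
        self.conditional_ = pd.DataFrame(
            _softmax_rows(U @ V.T + b[None, :]),
            index=self.microbe_ids_, columns=self.metabolite_ids_)
        self.loss_curve_ = np.asarray(losses)
        return self

    def rank_microbes(self, metabolite_id: str,
                      top_n: int | None = None) -> pd.Series:
        """Microbes sorted by descending conditional probability of the
        target metabolite; ties broken by feature ID."""
        if metabolite_id not in self.conditional_.columns:
            raise KeyError(f"unknown metabolite {metabolite_id!r}")
        col = self.conditional_[metabolite_id]
        order = sorted(col.index, key=lambda f: (-col[f], f))
        ranked = col.loc[order]
        return ranked.head(top_n) if top_n is not None else ranked


def centered_log_conditional(model: CooccurrenceFactorizer) -> pd.DataFrame:
    """Column-centered log conditional matrix: the cooccurrence *deviation*
    structure, with the shared metabolite marginal (which carries no
    microbe-specific information) removed. This is the representation the
    biplot SVD consumes and the right surface for comparing against a
    planted affinity."""
    logc = np.log(model.conditional_.to_numpy())
    logc = logc - logc.mean(axis=0, keepdims=True)
    return pd.DataFrame(logc, index=model.microbe_ids_,
                        columns=model.metabolite_ids_)


class BiplotCoordinates(NamedTuple):
    microbe_scores: pd.DataFrame      # microbes x axes (U.S)
    metabolite_loadings: pd.DataFrame  # metabolites x axes (V)
    proportion_explained: np.ndarray


def biplot(model: CooccurrenceFactorizer, n_axes: int = 3) -> BiplotCoordinates:
    """SVD biplot of the column-centered log conditional matrix."""
    logc = centered_log_conditional(model).to_numpy()
    if np.allclose(logc, 0):
        raise ValueError("conditional matrix has no variance")
    u, s, vt = np.linalg.svd(logc, full_matrices=False)
    n_axes = min(n_axes, int((s > s[0] * 1e-12).sum()))
    prop = s[:n_axes] ** 2 / (s**2).sum()
    scores = u[:, :n_axes] * s[:n_axes]
    loadings = vt[:n_axes].T
    for a in range(n_axes):  # canonical orientation per axis
        j = int(np.argmax(np.abs(loadings[:, a])))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1
            scores[:, a] *= -1
    axes = [f"PC{a + 1}" for a in range(n_axes)]
    return BiplotCoordinates(
        pd.DataFrame(scores, index=model.microbe_ids_, columns=axes),
        pd.DataFrame(loadings, index=model.metabolite_ids_, columns=axes),
        prop,
    )


def fit_cooccurrence(microbes: pd.DataFrame, metabolites: pd.DataFrame,
                     d: int = 3, **params) -> CooccurrenceFactorizer:
    """Convenience wrapper over :class:`CooccurrenceFactorizer`."""
    return CooccurrenceFactorizer(n_components=d, **params).fit(
        microbes, metabolites)


def rank_cooccurring_microbes(model: CooccurrenceFactorizer,
                              metabolite_id: str, top_n: int) -> list[str]:
    """Ordered list of the top_n microbes for a target metabolite."""
    return list(model.rank_microbes(metabolite_id, top_n).index)


def axis_vs_differentials(
    coords: BiplotCoordinates,
    ranks: pd.DataFrame | pd.Series,
    covariate: str | None = None,
    axis: str = "PC1",
) -> tuple[float, float, int]:
    """Pearson correlation between microbe axis-1 scores and the
    covariate's differentials over the shared microbe set."""
    series = ranks[covariate] if isinstance(ranks, pd.DataFrame) else ranks
    shared = coords.microbe_scores.index.intersection(series.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared microbes")
    x = coords.microbe_scores.loc[shared, axis].to_numpy(float)
    y = series.loc[shared].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), len(shared)


def write_ordination(coords: BiplotCoordinates, path) -> None:
    """Write biplot coordinates as a plain-text ordination file with
    eigenvalue, proportion-explained, loading, and score blocks."""
    with open(path, "w") as fh:
        n_axes = len(coords.proportion_explained)
        fh.write(f"Proportion explained\t{n_axes}\n")
        fh.write("\t".join(f"{v:.6f}" for v in coords.proportion_explained)
                 + "\n\n")
        fh.write(f"Metabolite loadings\t{coords.metabolite_loadings.shape[0]}"
                 f"\t{n_axes}\n")
        coords.metabolite_loadings.to_csv(fh, sep="\t", header=False)
        fh.write("\n")
        fh.write(f"Microbe scores\t{coords.microbe_scores.shape[0]}"
                 f"\t{n_axes}\n")
        coords.microbe_scores.to_csv(fh, sep="\t", header=False)
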