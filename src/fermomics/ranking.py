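"""Regularized multinomial log-linear regression of counts on covariates.

The model is ``counts_i ~ Multinomial(n_i, softmax(x_i B))`` with an
independent normal(0, prior_sd^2) penalty on the coefficients, fitted in
additive-log-ratio (ALR) coordinates against a reference feature and then
re-expressed as centered (CLR) *differentials*: per covariate, a vector
over features that sums to zero and whose ordering ranks features by their
log fold change with respect to that covariate. Absolute differentials are
not identifiable from relative data; only their ranking and ratios are
interpretable, which is why downstream analysis consumes them through
extreme-rank feature sets and log ratios.

Every sample contributes its count *proportions* with equal weight, so the
fitted differentials are exactly invariant to per-sample count scaling.
The optimizer is first-order stochastic gradient (Adam); at desk scale the
default is deterministic full-batch training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .logratio import FeatureSetPair


@dataclass(frozen=True)
class RegressionSpec:
    """Fit configuration for :func:`fit_differentials`.

    ``covariates`` name numeric metadata columns (a 0/1 consumption
    indicator is the primary use). ``batch_size=None`` trains full batch.
    ``min_sample_count`` / ``min_feature_count`` are pre-fit gates on
    sample and feature totals.
    """

    covariates: tuple[str, ...] = ("consumer",)
    epochs: int = 2000
    batch_size: int | None = None
    learning_rate: float = 0.05
    prior_sd: float = 1.0
    nominal_depth: float = 1000.0
    n_test_samples: int = 10
    min_sample_count: int = 0
    min_feature_count: int = 0
    reference_feature: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.prior_sd <= 0:
            raise ValueError("prior_sd must be > 0")


def published_spec(**overrides) -> RegressionSpec:
    """The historical reference configuration for this class of model:
    5,000 epochs of minibatch (size 5) gradient steps at learning rate
    1e-4, a 1,000-read sample gate, and 10 random held-out samples."""
    base = dict(epochs=5000, batch_size=5, learning_rate=1e-4,
                min_sample_count=1000, min_feature_count=0,
                n_test_samples=10)
    base.update(overrides)
    return RegressionSpec(**base)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class MultinomialDifferentialRegressor(BaseEstimator):
    """Scikit-learn style estimator for compositional differentials.

    Parameters mirror :class:`RegressionSpec`. ``fit`` takes the count
    table as ``X`` (samples x features DataFrame) and the covariate values
    as ``y`` (Series or DataFrame aligned on sample IDs, numeric).

    Attributes set by ``fit``:

    ``differentials_`` : DataFrame (features x terms, first term
        "Intercept") of CLR-centered coefficients — each column sums to 0.
    ``reference_feature_`` : the ALR reference actually used (defaults to
        the most prevalent feature).
    ``loss_curve_`` : per-epoch penalized loss on the full data.
    ``n_iter_`` : number of epochs run.
    """

    def __init__(self, epochs=2000, batch_size=None, learning_rate=0.05,
                 prior_sd=1.0, nominal_depth=1000.0, min_sample_count=0,
                 min_feature_count=0, reference_feature=None, seed=0):
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.prior_sd = prior_sd
        self.nominal_depth = nominal_depth
        self.min_sample_count = min_sample_count
        self.min_feature_count = min_feature_count
        self.reference_feature = reference_feature
        self.seed = seed

    # -- data preparation ---------------------------------------------------

    def _gate(self, X: pd.DataFrame) -> pd.DataFrame:
        X = X.loc[X.sum(axis=1) >= self.min_sample_count]
        X = X.loc[:, X.sum(axis=0) >= self.min_feature_count]
        if X.shape[1] < 2:
            raise ValueError("need at least 2 features after gating")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 samples after gating")
        return X

    @staticmethod
    def _design(y, index) -> pd.DataFrame:
        if isinstance(y, pd.Series):
            y = y.to_frame()
        y = y.reindex(index)
        if y.isna().any().any():
            raise ValueError("covariates missing for some table samples")
        design = pd.DataFrame({"Intercept": 1.0}, index=index)
        for col in y.columns:
            vals = pd.to_numeric(y[col])
            if vals.nunique() < 2:
                raise ValueError(f"covariate {col!r} is constant")
            design[col] = vals.astype(float)
        return design

    def _pick_reference(self, X: pd.DataFrame) -> str:
        if self.reference_feature is not None:
            if self.reference_feature not in X.columns:
                raise KeyError(
                    f"reference feature {self.reference_feature!r} not in table")
            return self.reference_feature
        prevalence = (X > 0).sum(axis=0)
        totals = X.sum(axis=0)
        order = sorted(X.columns,
                       key=lambda f: (-prevalence[f], -totals[f], f))
        return order[0]

    # -- fitting ------------------------------------------------------------

    def fit(self, X: pd.DataFrame, y) -> "MultinomialDifferentialRegressor":
        X = self._gate(X)
        design = self._design(y, X.index)
        ref = self._pick_reference(X)
        features = list(X.columns)
        ref_idx = features.index(ref)
        keep = [j for j in range(len(features)) if j != ref_idx]

        counts = X.to_numpy(float)
        R = counts / counts.sum(axis=1, keepdims=True)  # proportions
        Xd = design.to_numpy(float)
        n, p = Xd.shape
        D = len(features)

        rng = np.random.default_rng(self.seed)
        B = np.zeros((p, D - 1))
        m = np.zeros_like(B)
        v = np.zeros_like(B)
        b1, b2, eps = 0.9, 0.999, 1e-8
        # prior strength relative to a proportion likelihood carrying a
        # fixed nominal multinomial depth per sample (keeps the fit exactly
        # invariant to per-sample count scaling)
        lam = 1.0 / (self.prior_sd**2 * n * self.nominal_depth)
        batch = self.batch_size or n
        step = 0
        losses = []
        for epoch in range(self.epochs):
            if batch >= n:
                batches = [np.arange(n)]
            else:
                perm = rng.permutation(n)
                batches = [perm[i:i + batch] for i in range(0, n, batch)]
            for idx in batches:
                logits = np.insert(Xd[idx] @ B, ref_idx, 0.0, axis=1)
                P = _softmax(logits)
                G = Xd[idx].T @ (P - R[idx]) / len(idx)
                grad = G[:, keep] + lam * B
                step += 1
                m = b1 * m + (1 - b1) * grad
                v = b2 * v + (1 - b2) * grad**2
                mh = m / (1 - b1**step)
                vh = v / (1 - b2**step)
                B -= self.learning_rate * mh / (np.sqrt(vh) + eps)
            losses.append(self._loss(Xd, R, B, ref_idx, lam))
            if not np.isfinite(losses[-1]):
                raise RuntimeError(
                    f"fit diverged at epoch {epoch}: loss={losses[-1]}")

        full = np.insert(B, ref_idx, 0.0, axis=1)  # p x D, ref column = 0
        clr = full - full.mean(axis=1, keepdims=True)
        self.differentials_ = pd.DataFrame(
            clr.T, index=features, columns=design.columns)
        self.differentials_.index.name = "featureid"
        self.reference_feature_ = ref
        self.loss_curve_ = np.asarray(losses)
        self.n_iter_ = self.epochs
        self.feature_names_in_ = np.asarray(features, dtype=object)
        self.design_columns_ = list(design.columns)
        return self

    @staticmethod
    def _loss(Xd, R, B, ref_idx, lam) -> float:
        logits = np.insert(Xd @ B, ref_idx, 0.0, axis=1)
        logZ = np.log(np.exp(logits - logits.max(1, keepdims=True))
                      .sum(1)) + logits.max(1)
        ll = (R * logits).sum(1) - logZ
        return float(-ll.mean() + 0.5 * lam * (B**2).sum())

    # -- prediction ---------------------------------------------------------

    def predict_proba(self, y) -> pd.DataFrame:
        """Predicted composition for covariate rows ``y`` (DataFrame with
        the fitted covariate columns, or a design with Intercept)."""
        if not hasattr(self, "differentials_"):
            raise RuntimeError("estimator is not fitted")
        if isinstance(y, pd.Series):
            y = y.to_frame()
        design = pd.DataFrame({"Intercept": 1.0}, index=y.index)
        for col in self.design_columns_[1:]:
            design[col] = pd.to_numeric(y[col]).astype(float)
        logits = design.to_numpy(float) @ self.differentials_.to_numpy().T
        return pd.DataFrame(_softmax(logits), index=y.index,
                            columns=self.differentials_.index)


def fit_differentials(
    table: pd.DataFrame, meta: pd.DataFrame, spec: RegressionSpec
) -> MultinomialDifferentialRegressor:
    """Fit differentials for ``spec.covariates`` drawn from ``meta``."""
    missing = set(table.index) - set(meta.index)
    if missing:
        raise KeyError(f"table samples absent from metadata: "
                       f"{sorted(missing)[:3]}")
    est = MultinomialDifferentialRegressor(
        epochs=spec.epochs, batch_size=spec.batch_size,
        learning_rate=spec.learning_rate, prior_sd=spec.prior_sd,
        nominal_depth=spec.nominal_depth,
        min_sample_count=spec.min_sample_count,
        min_feature_count=spec.min_feature_count,
        reference_feature=spec.reference_feature, seed=spec.seed)
    return est.fit(table, meta.loc[table.index, list(spec.covariates)])


def q2_score(actual: np.ndarray, predicted: np.ndarray,
             baseline: np.ndarray) -> float:
    """Q^2 = 1 - MAE(predicted)/MAE(baseline) on held-out counts.

    1 for perfect predictions, 0 when the model does no better than the
    baseline, negative when it does worse.
    """
    actual = np.asarray(actual, float)
    mae_model = float(np.abs(np.asarray(predicted, float) - actual).mean())
    mae_base = float(np.abs(np.asarray(baseline, float) - actual).mean())
    if mae_base == 0:
        return 1.0 if mae_model == 0 else -np.inf
    return 1.0 - mae_model / mae_base


def evaluate_q2(
    table: pd.DataFrame, meta: pd.DataFrame, spec: RegressionSpec
) -> float:
    """Q^2 of the covariate model against an intercept-only baseline.

    ``spec.n_test_samples`` held-out samples are chosen once by seed; both
    models are fitted on the remainder and predict held-out counts as
    ``n_i * softmax(x_i B)``. Q^2 = 1 - MAE(model)/MAE(baseline); values
    at or below zero indicate no predictive gain over the baseline.
    """
    n = table.shape[0]
    n_test = min(spec.n_test_samples, n - 2)
    if n_test < 1:
        raise ValueError("held-out set is empty")
    rng = np.random.default_rng(spec.seed)
    test_idx = table.index[rng.choice(n, size=n_test, replace=False)]
    train_idx = table.index.difference(test_idx, sort=False)

    train_t, test_t = table.loc[train_idx], table.loc[test_idx]
    model = fit_differentials(train_t, meta, spec)
    totals = test_t.sum(axis=1).to_numpy(float)[:, None]

    pred = model.predict_proba(meta.loc[test_t.index, list(spec.covariates)])
    pred = (pred * totals).reindex(columns=test_t.columns).fillna(0.0)

    # intercept-only baseline: mean training proportions
    p_base = (train_t.to_numpy(float)
              / train_t.sum(axis=1).to_numpy(float)[:, None]).mean(0)
    baseline = totals * p_base[None, :]

    return q2_score(test_t.to_numpy(float), pred.to_numpy(), baseline)


def select_extreme_features(
    ranks: pd.DataFrame | pd.Series, covariate: str | None = None,
    k: int = 20,
) -> FeatureSetPair:
    """Numerator = k largest differentials, denominator = k smallest.

    One consistent ordering (value descending, ties by lexicographically
    smaller feature ID first) is used for both ends, so the sets can
    never overlap: at a tied numerator boundary the smaller ID wins the
    slot, at a tied denominator boundary the larger ID does.
    """
    series = ranks[covariate] if isinstance(ranks, pd.DataFrame) else ranks
    if 2 * k > len(series):
        raise ValueError(f"2k={2 * k} exceeds feature count {len(series)}")
    df = series.rename("value").reset_index()
    df.columns = ["featureid", "value"]
    ordered = df.sort_values(["value", "featureid"],
                             ascending=[False, True],
                             kind="mergesort")["featureid"]
    top = ordered.head(k)
    bottom = ordered.tail(k)
    return FeatureSetPair(frozenset(top), frozenset(bottom),
                          provenance="ranked",
                          note=f"top/bottom {k} by differential")


def write_differentials(ranks: pd.DataFrame, path) -> None:
    """Write differentials TSV: 'featureid', then one column per term
    (including 'Intercept') — the layout rank-plot visualizers consume."""
    ranks.to_csv(path, sep="\t", index_label="featureid")
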