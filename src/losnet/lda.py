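"""Supervised compression of the centrality feature block.

Linear discriminant analysis treats the integer LOS values of the training
rows as class labels and projects the wide multi-hot centrality block onto
at most K − 1 discriminant directions (K = number of distinct training LOS
values), maximizing between-class relative to within-class scatter.  The
output dimension is selected on the validation split: each candidate is
fitted, a fixed fast probe regressor is trained on the projected training
rows, and the candidate with the lowest validation MAE wins (ties go to the
smaller dimension).

The scatter solve is delegated to scikit-learn's eigen solver with a ridge
shrinkage on the within-class scatter, which survives the rank-deficient
blocks that sparse multi-hot features produce on small cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingRegressor


@dataclass
class LdaProjection:
    estimator: LinearDiscriminantAnalysis
    n_components: int
    n_classes: int
    n_features: int
    n_train_rows: int

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} columns, got "
                f"{X.shape[1] if X.ndim == 2 else X.ndim}"
            )
        return self.estimator.transform(X)[:, : self.n_components]


def fit_lda(X, y, n_components: int, shrinkage: float | str = 0.1
            ) -> LdaProjection:
    """Fit the discriminant projection on training rows.

    ``y`` holds integer class labels (here: LOS day values).  Raises when
    fewer than two classes are present or ``n_components`` exceeds the
    K − 1 bound or the block width.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    k = len(classes)
    if k < 2:
        raise ValueError("LDA needs at least two distinct label values")
    max_dim = min(k - 1, X.shape[1])
    if n_components > max_dim:
        raise ValueError(
            f"n_components={n_components} exceeds the bound min(K−1, width) "
            f"= {max_dim} (K = {k} distinct labels)"
        )
    est = LinearDiscriminantAnalysis(
        solver="eigen", shrinkage=shrinkage, n_components=n_components
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")   # variable collinearity warnings
        est.fit(X, y)
    return LdaProjection(est, n_components, k, X.shape[1], X.shape[0])


def default_probe() -> GradientBoostingRegressor:
    """Small fixed boosted-tree probe used to score candidate dimensions."""
    return GradientBoostingRegressor(
        n_estimators=50, max_depth=3, random_state=0
    )


def select_components(
    candidates,
    X_train, y_train,
    X_val, y_val,
    probe_factory=default_probe,
    shrinkage: float | str = 0.1,
) -> tuple[int, dict[int, float]]:
    """Pick the projection dimension with the lowest validation MAE.

    Candidates above the K − 1 / width bound are dropped with a warning.
    Returns (best dimension, per-candidate validation MAE); exact ties go
    to the smallest dimension.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train)
    k = len(np.unique(y_train))
    max_dim = min(k - 1, X_train.shape[1])
    feasible = sorted({int(c) for c in candidates if 1 <= c <= max_dim})
    dropped = sorted(set(int(c) for c in candidates) - set(feasible))
    if dropped:
        warnings.warn(
            f"candidate dimensions {dropped} exceed the bound {max_dim} "
            f"and were dropped"
        )
    if not feasible:
        raise ValueError(
            f"no feasible candidate dimension (bound min(K−1, width) = {max_dim})"
        )
    scores: dict[int, float] = {}
    for dim in feasible:
        proj = fit_lda(X_train, y_train, dim, shrinkage)
        probe = probe_factory()
        probe.fit(proj.transform(X_train), y_train)
        pred = probe.predict(proj.transform(X_val))
        scores[dim] = float(np.mean(np.abs(np.asarray(y_val) - pred)))
    best = min(feasible, key=lambda d: (scores[d], d))
    return best, scores
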