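"""Random-forest regression with inner cross-validated grid search.

The ensemble size M and maximum tree depth are tuned by an inner
five-fold cross-validation on the training fold only (mean squared
error), then the forest is refit on the whole training fold with the
selected pair.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.utils.validation import check_array, check_is_fitted


class GridSearchForestRegressor(RegressorMixin, BaseEstimator):
    """Random forest with (n_trees, max_depth) chosen by inner CV.

    ``grid_trees`` and ``grid_depth`` default to M in {100, 300, 500} and
    depth in {5, 10, unlimited}; both are configurable.
    """

    def __init__(self, grid_trees=(100, 300, 500), grid_depth=(5, 10, None),
                 inner_folds=5, random_state=0, n_jobs=1):
        self.grid_trees = grid_trees
        self.grid_depth = grid_depth
        self.inner_folds = inner_folds
        self.random_state = random_state
        self.n_jobs = n_jobs

    def fit(self, X, y):
        X = check_array(X, dtype=float)
        y = check_array(y, ensure_2d=False, dtype=float)
        if any(m < 1 for m in self.grid_trees):
            raise ValueError("all candidate ensemble sizes must be >= 1")
        inner = KFold(n_splits=self.inner_folds, shuffle=True,
                      random_state=self.random_state)
        search = GridSearchCV(
            RandomForestRegressor(random_state=self.random_state, n_jobs=self.n_jobs),
            param_grid={
                "n_estimators": list(self.grid_trees),
                "max_depth": list(self.grid_depth),
            },
            cv=inner,
            scoring="neg_mean_squared_error",
            n_jobs=1,
            refit=True,
        )
        search.fit(X, y)
        self.model_ = search.best_estimator_
        self.best_params_ = search.best_params_
        self.best_inner_mse_ = -float(search.best_score_)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(check_array(X, dtype=float))
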