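"""The 28-configuration regression registry.

Eight families, mirroring a standard regression-learner toolbox: linear
(4), tree (3), SVM (6), efficient linear (2), ensemble (2), Gaussian
process (4), neural network (5) and kernel (2).  Every hyperparameter is
pinned here so the whole comparison is reproducible from this one file.

Models that are scale-sensitive (SVM, efficient linear, neural networks,
kernel expansions) standardise the predictor internally and fit on a
standardised target; tree and linear families work on raw grams.
"""

from __future__ import annotations

from typing import List

from sklearn.compose import TransformedTargetRegressor
from sklearn.ensemble import BaggingRegressor, GradientBoostingRegressor
from sklearn.feature_selection import SequentialFeatureSelector
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process import kernels as gpk
from sklearn.kernel_approximation import RBFSampler
from sklearn.linear_model import HuberRegressor, LinearRegression, Ridge, SGDRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler
from sklearn.svm import SVR, LinearSVR
from sklearn.tree import DecisionTreeRegressor

from .types import ModelSpec

__all__ = ["model_registry", "build_estimator", "FAMILY_ORDER"]

FAMILY_ORDER = (
    "linear",
    "tree",
    "svm",
    "efficient_linear",
    "ensemble",
    "gpr",
    "neural_network",
    "kernel",
)

_SEED = 0  # estimator-internal randomness; the data split carries the run seed

_REGISTRY = [
    # id, family, variant name, interpretability, hyperparameters
    ("2.1", "linear", "Linear", "easy", ()),
    ("2.2", "linear", "Interactions Linear", "easy", (("interaction_only", True),)),
    ("2.3", "linear", "Robust Linear", "easy", (("epsilon", 1.35),)),
    ("2.4", "linear", "Stepwise Linear", "easy", (("max_degree", 3),)),
    ("2.5", "tree", "Fine Tree", "easy", (("min_samples_leaf", 4),)),
    ("2.6", "tree", "Medium Tree", "easy", (("min_samples_leaf", 12),)),
    ("2.7", "tree", "Coarse Tree", "easy", (("min_samples_leaf", 36),)),
    ("2.8", "svm", "Linear SVM", "easy", (("kernel", "linear"),)),
    ("2.9", "svm", "Quadratic SVM", "hard", (("kernel", "poly"), ("degree", 2))),
    ("2.10", "svm", "Cubic SVM", "hard", (("kernel", "poly"), ("degree", 3))),
    # Gaussian kernel scales sqrt(P)/4, sqrt(P), 4*sqrt(P) with P=1 feature
    ("2.11", "svm", "Fine Gaussian SVM", "hard", (("kernel", "rbf"), ("kernel_scale", 0.25))),
    ("2.12", "svm", "Medium Gaussian SVM", "hard", (("kernel", "rbf"), ("kernel_scale", 1.0))),
    ("2.13", "svm", "Coarse Gaussian SVM", "hard", (("kernel", "rbf"), ("kernel_scale", 4.0))),
    ("2.14", "efficient_linear", "Efficient Linear Least Squares", "easy", (("loss", "squared_error"),)),
    ("2.15", "efficient_linear", "Efficient Linear SVM", "easy", (("loss", "epsilon_insensitive"),)),
    ("2.16", "ensemble", "Boosted Trees", "hard", (("n_estimators", 30), ("learning_rate", 0.1))),
    ("2.17", "ensemble", "Bagged Trees", "hard", (("n_estimators", 30),)),
    ("2.18", "gpr", "Squared Exponential GPR", "hard", (("kernel", "rbf"),)),
    ("2.19", "gpr", "Matern 5/2 GPR", "hard", (("kernel", "matern52"),)),
    ("2.20", "gpr", "Exponential GPR", "hard", (("kernel", "exponential"),)),
    ("2.21", "gpr", "Rational Quadratic", "hard", (("kernel", "rational_quadratic"),)),
    ("2.22", "neural_network", "Narrow Neural Network", "hard", (("hidden", (10,)),)),
    ("2.23", "neural_network", "Medium Neural Network", "hard", (("hidden", (25,)),)),
    ("2.24", "neural_network", "Wide Neural Network", "hard", (("hidden", (100,)),)),
    ("2.25", "neural_network", "Bilayered Neural Network", "hard", (("hidden", (10, 10)),)),
    ("2.26", "neural_network", "Trilayered Neural Network", "hard", (("hidden", (10, 10, 10)),)),
    ("2.27", "kernel", "SVM Kernel", "hard", (("n_components", 256),)),
    ("2.28", "kernel", "Least Squares Kernel Regression", "hard", (("n_components", 256),)),
]


def model_registry() -> List[ModelSpec]:
    """All 28 model specifications, ordered by id."""
    return [
        ModelSpec(mid, fam, name, interp, hyper)
        for mid, fam, name, interp, hyper in _REGISTRY
    ]


def _standardised(estimator):
    """Standardise X and y around a scale-sensitive estimator."""
    return TransformedTargetRegressor(
        regressor=make_pipeline(StandardScaler(), estimator),
        transformer=StandardScaler(),
    )


def _gpr_kernel(name: str):
    base = {
        "rbf": gpk.RBF(length_scale=1.0),
        "matern52": gpk.Matern(length_scale=1.0, nu=2.5),
        "exponential": gpk.Matern(length_scale=1.0, nu=0.5),
        "rational_quadratic": gpk.RationalQuadratic(length_scale=1.0, alpha=1.0),
    }[name]
    return gpk.ConstantKernel(1.0) * base + gpk.WhiteKernel(
        noise_level=1e-2, noise_level_bounds=(1e-12, 1e1)
    )


def build_estimator(spec: ModelSpec):
    """Instantiate the scikit-learn estimator behind one registry entry."""
    hp = spec.hyper_dict
    mid = spec.model_id

    if spec.family == "linear":
        if mid == "2.1":
            return LinearRegression()
        if mid == "2.2":
            # interaction expansion; with a single predictor this reduces
            # to the plain linear model
            return make_pipeline(
                PolynomialFeatures(degree=2, interaction_only=True, include_bias=False),
                LinearRegression(),
            )
        if mid == "2.3":
            return make_pipeline(StandardScaler(), HuberRegressor(epsilon=hp["epsilon"]))
        if mid == "2.4":
            return make_pipeline(
                PolynomialFeatures(degree=hp["max_degree"], include_bias=False),
                StandardScaler(),
                SequentialFeatureSelector(
                    LinearRegression(), n_features_to_select="auto", tol=1e-4, cv=3
                ),
                LinearRegression(),
            )
    if spec.family == "tree":
        return DecisionTreeRegressor(
            min_samples_leaf=hp["min_samples_leaf"], random_state=_SEED
        )
    if spec.family == "svm":
        if hp["kernel"] == "rbf":
            svr = SVR(kernel="rbf", gamma=1.0 / hp["kernel_scale"] ** 2, C=1.0)
        elif hp["kernel"] == "poly":
            # coef0=1 gives the full inhomogeneous polynomial (constant and
            # linear terms included), not just the pure power
            svr = SVR(kernel="poly", degree=hp["degree"], coef0=1.0, C=1.0)
        else:
            svr = SVR(kernel="linear", C=1.0)
        return _standardised(svr)
    if spec.family == "efficient_linear":
        sgd = SGDRegressor(
            loss=hp["loss"], max_iter=1000, tol=1e-4, random_state=_SEED
        )
        return _standardised(sgd)
    if spec.family == "ensemble":
        if mid == "2.16":
            return GradientBoostingRegressor(
                n_estimators=hp["n_estimators"],
                learning_rate=hp["learning_rate"],
                random_state=_SEED,
            )
        return BaggingRegressor(
            DecisionTreeRegressor(random_state=_SEED),
            n_estimators=hp["n_estimators"],
            random_state=_SEED,
        )
    if spec.family == "gpr":
        # standardised inputs keep the unit initial length scale in the
        # basin of attraction of the marginal-likelihood optimiser
        return make_pipeline(
            StandardScaler(),
            GaussianProcessRegressor(
                kernel=_gpr_kernel(hp["kernel"]),
                normalize_y=True,
                alpha=1e-10,
                random_state=_SEED,
            ),
        )
    if spec.family == "neural_network":
        mlp = MLPRegressor(
            hidden_layer_sizes=hp["hidden"],
            activation="relu",
            solver="lbfgs",
            max_iter=1000,
            random_state=_SEED,
        )
        return _standardised(mlp)
    if spec.family == "kernel":
        sampler = RBFSampler(
            gamma=1.0, n_components=hp["n_components"], random_state=_SEED
        )
        if mid == "2.27":
            head = LinearSVR(C=1.0, max_iter=10000, random_state=_SEED)
        else:
            head = Ridge(alpha=1e-3)
        return TransformedTargetRegressor(
            regressor=Pipeline(
                [("scale", StandardScaler()), ("rff", sampler), ("head", head)]
            ),
            transformer=StandardScaler(),
        )
    raise ValueError(f"no estimator for spec {spec.model_id} ({spec.family})")
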