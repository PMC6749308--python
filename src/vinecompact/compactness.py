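"""Gaussian-process regression of cluster compactness on the OIV 1-9 scale.

The rating model is g(x) = f(x) + h(x)^T beta, where f is a zero-mean
Gaussian process with an exponential covariance

    k(x, x') = sigma_f^2 * exp(-||x - x'|| / kernel_scale)

over the standardised 14-feature vector, h is a constant (intercept) basis
by default, and observations carry Gaussian noise with standard deviation
``sigma`` in rating units.  The posterior is computed exactly (Cholesky);
the signal variance sigma_f^2 is fitted by marginal likelihood when not
supplied.  Predictions report the posterior mean (clamped to the OIV span
[1, 9] for reporting, with the raw value retained so evaluation can see
out-of-span behaviour) and the predictive standard deviation.

Hyperparameters (``sigma`` and ``kernel_scale`` for the GP, box constraint
and kernel scale for the detection SVM) can be tuned by a sequential
model-based (Bayesian) optimiser: a surrogate GP with an ARD Matern 5/2
kernel models the cross-validated loss and an expected-improvement-plus
acquisition proposes each next evaluation inside the bounded search space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import cdist
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

__all__ = [
    "DEFAULT_GPR_KERNEL_SCALE",
    "DEFAULT_GPR_SIGMA",
    "GPRModel",
    "GPR_SEARCH_SPACE",
    "HyperparameterSearchSpace",
    "SVM_SEARCH_SPACE",
    "optimize_hyperparameters",
    "predict_compactness",
    "train_gpr",
]

#: Tuned GPR operating point (Bayesian optimisation; sigma searched in
#: [1e-4, 22.5184], kernel scale in [0.1216, 121.6122]).
DEFAULT_GPR_SIGMA = 0.83194
DEFAULT_GPR_KERNEL_SCALE = 91.5821

OIV_SPAN = (1.0, 9.0)


@dataclass
class GPRModel:
    """Exact Gaussian-process regressor with exponential covariance."""

    sigma: float
    kernel_scale: float
    signal_variance: float
    basis: str  # "constant" or "none"
    beta: float
    train_features: np.ndarray  # standardised (n, d)
    train_targets: np.ndarray
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    _alpha: np.ndarray = field(repr=False, default=None)
    _cho: tuple = field(repr=False, default=None)
    _ones_solve: np.ndarray = field(repr=False, default=None)

    def kernel(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        d = cdist(np.atleast_2d(a), np.atleast_2d(b))
        return self.signal_variance * np.exp(-d / self.kernel_scale)


def _standardize(x):
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale == 0] = 1.0
    return (x - mean) / scale, mean, scale


def train_gpr(
    features: np.ndarray,
    targets: np.ndarray,
    sigma: float = DEFAULT_GPR_SIGMA,
    kernel_scale: float = DEFAULT_GPR_KERNEL_SCALE,
    *,
    signal_variance: float | None = None,
    basis: str = "constant",
) -> GPRModel:
    """Fit the exact GP posterior for compactness regression.

    Parameters
    ----------
    features : (n, d) array of compactness features (d = 14 in the pipeline;
        any d >= 1 is accepted for the regression itself).
    targets : (n,) ratings in [1, 9] (panel means).
    sigma : observation noise standard deviation, rating units.
    kernel_scale : exponential-covariance length scale over the
        standardised features (dimensionless).
    signal_variance : prior variance sigma_f^2 of the latent process; fitted
        by maximising the marginal likelihood when None.
    basis : "constant" fits an intercept by generalised least squares;
        "none" uses a strict zero-mean process.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    if x.ndim != 2:
        raise ValueError("features must be 2-d (n, d)")
    if y.shape != (x.shape[0],):
        raise ValueError("targets must be 1-d matching features")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("features and targets must be finite")
    if sigma < 0 or kernel_scale <= 0:
        raise ValueError("sigma must be >= 0 and kernel_scale > 0")
    if basis not in ("constant", "none"):
        raise ValueError("basis must be 'constant' or 'none'")

    z, mean, scale = _standardize(x)
    dists = cdist(z, z)
    corr = np.exp(-dists / kernel_scale)
    n = z.shape[0]

    def fit_for(sf2):
        kmat = sf2 * corr + (sigma**2 + 1e-10) * np.eye(n)
        cho = cho_factor(kmat, lower=True)
        ones = np.ones(n)
        if basis == "constant":
            kinv_1 = cho_solve(cho, ones)
            beta = float(ones @ cho_solve(cho, y) / (ones @ kinv_1))
        else:
            kinv_1 = cho_solve(cho, ones)
            beta = 0.0
        resid = y - beta
        alpha = cho_solve(cho, resid)
        logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
        lml = -0.5 * (resid @ alpha) - 0.5 * logdet - 0.5 * n * np.log(2 * np.pi)
        return beta, alpha, cho, kinv_1, lml

    if signal_variance is None:
        res = minimize_scalar(
            lambda logsf2: -fit_for(np.exp(logsf2))[4],
            bounds=(np.log(1e-6), np.log(1e6)),
            method="bounded",
            options={"xatol": 1e-3},
        )
        signal_variance = float(np.exp(res.x))
    beta, alpha, cho, kinv_1, _ = fit_for(signal_variance)

    return GPRModel(
        sigma=float(sigma),
        kernel_scale=float(kernel_scale),
        signal_variance=float(signal_variance),
        basis=basis,
        beta=beta,
        train_features=z,
        train_targets=y,
        feature_mean=mean,
        feature_scale=scale,
        _alpha=alpha,
        _cho=cho,
        _ones_solve=kinv_1,
    )


def predict_compactness(model: GPRModel, features: np.ndarray):
    """Posterior mean and standard deviation of the rating at new features.

    Returns ``(mean, sd, raw_mean)``: the mean clamped to the OIV span
    [1, 9] for reporting, the predictive SD of the latent rating, and the
    unclamped mean (used by all evaluation metrics so systematic over- or
    under-estimation near the span edges stays visible).
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] != model.train_features.shape[1]:
        raise ValueError(
            f"feature length {x.shape[1]} != "
            f"model dimension {model.train_features.shape[1]}"
        )
    z = (x - model.feature_mean) / model.feature_scale
    kstar = model.kernel(z, model.train_features)  # (m, n)
    raw_mean = model.beta + kstar @ model._alpha
    kinv_kstar = cho_solve(model._cho, kstar.T)  # (n, m)
    var = model.signal_variance - np.sum(kstar.T * kinv_kstar, axis=0)
    if model.basis == "constant":
        ones = np.ones(model.train_features.shape[0])
        r = 1.0 - kstar @ model._ones_solve
        var = var + r**2 / (ones @ model._ones_solve)
    sd = np.sqrt(np.clip(var, 0.0, None))
    mean = np.clip(raw_mean, *OIV_SPAN)
    return mean, sd, raw_mean


# ---------------------------------------------------------------------------
# Bayesian hyperparameter optimisation


@dataclass(frozen=True)
class HyperparameterSearchSpace:
    """A bounded box of hyperparameters with an evaluation budget.

    ``bounds`` maps each hyperparameter name to finite (lo, hi) with
    lo < hi; names in ``log_scale`` are searched on a log10 axis.
    """

    bounds: dict
    budget: int = 30
    seed: int = 0
    log_scale: tuple = ()

    def __post_init__(self) -> None:
        if self.budget < 10:
            raise ValueError("budget must be >= 10")
        for name, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"invalid bounds for {name!r}: ({lo}, {hi})")
            if name in self.log_scale and lo <= 0:
                raise ValueError(f"log-scale bounds for {name!r} must be > 0")


#: Hyperparameter search ranges used to tune the operating points.
GPR_SEARCH_SPACE = HyperparameterSearchSpace(
    bounds={"sigma": (1e-4, 22.5184), "kernel_scale": (0.1216, 121.6122)},
    log_scale=("sigma",),
)
SVM_SEARCH_SPACE = HyperparameterSearchSpace(
    bounds={"box_constraint": (1e-3, 1e3), "kernel_scale": (1e-3, 1e3)},
    log_scale=("box_constraint", "kernel_scale"),
)


def _to_unit(space, params):
    u = []
    for name, (lo, hi) in space.bounds.items():
        v = params[name]
        if name in space.log_scale:
            u.append((np.log10(v) - np.log10(lo)) / (np.log10(hi) - np.log10(lo)))
        else:
            u.append((v - lo) / (hi - lo))
    return np.array(u)


def _from_unit(space, u):
    params = {}
    for (name, (lo, hi)), v in zip(space.bounds.items(), u):
        if name in space.log_scale:
            params[name] = 10 ** (np.log10(lo) + v * (np.log10(hi) - np.log10(lo)))
        else:
            params[name] = lo + v * (hi - lo)
    return params


def optimize_hyperparameters(space: HyperparameterSearchSpace, objective):
    """Minimise a (cross-validated) loss over a bounded hyperparameter box.

    Sequential model-based optimisation: after an initial random design,
    a Gaussian-process surrogate with an ARD Matern 5/2 kernel is fitted to
    the evaluations (on the unit cube, log axes where declared) and an
    expected-improvement acquisition with an exploration floor
    ("expected-improvement-plus": proposals that coincide with already
    evaluated points are pushed to the best remaining exploratory
    candidate) selects each next point.  Exactly ``space.budget``
    evaluations are performed; non-finite objective values are recorded in
    the trace as failures and excluded from the surrogate.

    Returns
    -------
    (best_params, trace)
        ``best_params`` is the evaluated point with the lowest finite loss;
        ``trace`` is the list of (params, loss) in evaluation order.
    """
    rng = np.random.default_rng(space.seed)
    d = len(space.bounds)
    n_init = max(5, space.budget // 4)
    n_init = min(n_init, space.budget)
    trace: list[tuple[dict, float]] = []
    units: list[np.ndarray] = []
    values: list[float] = []

    def evaluate(u):
        params = _from_unit(space, np.clip(u, 0.0, 1.0))
        try:
            val = float(objective(params))
        except FloatingPointError:
            val = np.nan
        trace.append((params, val))
        units.append(np.clip(u, 0.0, 1.0))
        values.append(val)

    for _ in range(n_init):
        evaluate(rng.uniform(size=d))

    while len(trace) < space.budget:
        finite = np.isfinite(values)
        if finite.sum() < 2:
            evaluate(rng.uniform(size=d))
            continue
        x_obs = np.asarray(units)[finite]
        y_obs = np.asarray(values)[finite]
        kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
            length_scale=np.full(d, 0.3),
            length_scale_bounds=(1e-2, 1e2),
            nu=2.5,
        ) + WhiteKernel(1e-6, (1e-10, 1e-1))
        surrogate = GaussianProcessRegressor(
            kernel=kernel,
            normalize_y=True,
            n_restarts_optimizer=1,
            random_state=int(rng.integers(2**31 - 1)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            surrogate.fit(x_obs, y_obs)
        cand = rng.uniform(size=(1500, d))
        mu, sd = surrogate.predict(cand, return_std=True)
        best = y_obs.min()
        sd = np.maximum(sd, 1e-12)
        imp = best - mu - 1e-3 * max(np.std(y_obs), 1e-12)
        zscore = imp / sd
        ei = imp * norm.cdf(zscore) + sd * norm.pdf(zscore)
        order = np.argsort(-ei)
        chosen = None
        for idx in order[:50]:  # exploration floor: skip near-duplicates
            if np.min(cdist(cand[idx][None], np.asarray(units))) > 1e-6:
                chosen = cand[idx]
                break
        if chosen is None:
            chosen = rng.uniform(size=d)
        evaluate(chosen)

    finite = np.isfinite(values)
    if not finite.any():
        raise RuntimeError("all objective evaluations failed")
    best_idx = int(np.arange(len(values))[finite][np.argmin(np.asarray(values)[finite])])
    return trace[best_idx][0], trace
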