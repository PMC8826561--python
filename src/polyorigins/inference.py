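"""ABC model choice, parameter estimation, and Bayes-factor arithmetic.

Model choice follows the rejection-plus-regression recipe: retain the
fraction of reference-table rows closest to the observed statistics
(Euclidean distance over MAD-scaled statistics), weight them with the
Epanechnikov kernel, and regress the model indicator on the statistics with
an ensemble of single-hidden-layer feed-forward networks (default 35 nets,
10 hidden units).  Parameter posteriors use the same ensemble for nonlinear
regression adjustment on logit-transformed parameters, which guarantees the
adjusted samples respect their prior bounds.  Robustness of a model pair is
assessed on pseudo-observed datasets, and log-marginal likelihoods (e.g.
Bezier approximations from migrate-n runs) are converted to equal-prior
model probabilities by max-shifted exponentiation.

The hidden-unit weights of the kernel enter the network fits through
weight-proportional bootstrap resampling (one resample per ensemble
member), since the regression backend takes no per-row weights.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import gaussian_kde
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor

from .sumstats import StatVector

logger = logging.getLogger(__name__)

_MAX_SEED = 2**31 - 1


@dataclass
class ReferenceTable:
    """Simulated (model, parameters, statistics) rows for ABC."""

    models: np.ndarray  # model label per row
    params: pd.DataFrame  # one column per parameter
    stats: np.ndarray  # rows x statistics
    manifest: list[str]

    def __post_init__(self):
        n = len(self.models)
        if not (len(self.params) == n and self.stats.shape[0] == n):
            raise ValueError("models, params and stats must have equal row counts")
        if self.stats.shape[1] != len(self.manifest):
            raise ValueError("stats width does not match the manifest")

    @property
    def n_rows(self) -> int:
        return len(self.models)

    def scales(self) -> np.ndarray:
        """Per-statistic median absolute deviation, floored at machine-eps."""
        med = np.nanmedian(self.stats, axis=0)
        mad = np.nanmedian(np.abs(self.stats - med), axis=0)
        floor = np.finfo(float).eps
        if (mad <= floor).any():
            logger.warning("%d statistic scales floored at eps", int((mad <= floor).sum()))
        return np.maximum(mad, floor)

    def restrict(self, model: str) -> "ReferenceTable":
        keep = self.models == model
        if not keep.any():
            raise ValueError(f"no rows for model {model!r}")
        return ReferenceTable(
            self.models[keep], self.params.loc[keep].reset_index(drop=True),
            self.stats[keep], list(self.manifest),
        )

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.stats, columns=self.manifest)
        out = pd.concat([pd.Series(self.models, name="model"), self.params, df], axis=1)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, manifest: list[str]) -> "ReferenceTable":
        df = pd.read_csv(path, sep="\t")
        stats = df[manifest].to_numpy(float)
        params = df.drop(columns=["model", *manifest])
        return cls(df["model"].to_numpy(str), params, stats, list(manifest))


@dataclass
class ABCModelPosterior:
    probabilities: dict[str, float]
    rejection_probabilities: dict[str, float]
    method: str
    tolerance: float
    n_retained: int


@dataclass
class ParameterPosterior:
    parameter: str
    samples: np.ndarray  # regression-adjusted, back-transformed
    weights: np.ndarray
    pdv: float  # peak distribution value (weighted-density mode)
    ci90: tuple[float, float]  # weighted 5% / 95% quantiles


@dataclass
class RobustnessReport:
    models: tuple[str, str]
    mean_posterior: np.ndarray  # [true, assigned] mean posterior probabilities
    robustness: float  # P(M1|M1) / (P(M1|M1) + P(M1|M2))
    n_pseudo: int
    seed: int | None


def model_probabilities_from_lnml(lnml: dict[str, float] | list) -> dict[str, float]:
    """Equal-prior model probabilities from log-marginal likelihoods.

    p_i = exp(lnML_i - max) / sum_j exp(lnML_j - max); invariant to adding
    a constant to every input.
    """
    items = list(lnml.items()) if isinstance(lnml, dict) else list(lnml)
    if len(items) < 2:
        raise ValueError("need >= 2 models")
    values = np.array([v for _, v in items], dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("log-marginal likelihoods must be finite")
    shifted = np.exp(values - values.max())
    probs = shifted / shifted.sum()
    return {name: float(p) for (name, _), p in zip(items, probs)}


def abc_reject(
    observed: np.ndarray | StatVector,
    table: ReferenceTable,
    tolerance: float = 0.005,
):
    """Retain the ``tolerance`` fraction of nearest rows, with weights.

    Distance is Euclidean over MAD-scaled statistics; the retained rows get
    Epanechnikov weights 1 - (d/d_max)^2 where d_max is the largest retained
    distance.  Boundary ties resolve by row order.  Returns
    ``(indices, distances, weights)``.
    """
    if not 0 < tolerance <= 1:
        raise ValueError("tolerance must be in (0, 1]")
    if table.n_rows == 0:
        raise ValueError("empty reference table")
    obs = observed.as_array() if isinstance(observed, StatVector) else np.asarray(observed, float)
    if obs.shape != (len(table.manifest),):
        raise ValueError("observed vector does not match the table manifest")
    scales = table.scales()
    diff = (table.stats - obs) / scales
    dist = np.sqrt(np.nansum(diff**2, axis=1))
    n_keep = int(np.ceil(tolerance * table.n_rows))
    order = np.argsort(dist, kind="stable")
    idx = order[:n_keep]
    d = dist[idx]
    d_max = d.max()
    weights = 1.0 - (d / d_max) ** 2 if d_max > 0 else np.ones_like(d)
    if weights.sum() == 0:  # all retained rows sit exactly at d_max
        weights = np.ones_like(d)
    return idx, d, weights


def _fit_ensemble_predict(
    x_train: np.ndarray,
    y_train: np.ndarray,
    weights: np.ndarray,
    x_eval: np.ndarray,
    n_nets: int,
    n_hidden: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Median prediction of weight-resampled single-hidden-layer nets."""
    p = weights / weights.sum()
    preds = np.empty((n_nets, x_eval.shape[0], y_train.shape[1]))
    n = len(x_train)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for k in range(n_nets):
            rows = rng.choice(n, size=n, replace=True, p=p)
            net = MLPRegressor(
                hidden_layer_sizes=(n_hidden,),
                solver="lbfgs",
                max_iter=500,
                alpha=1e-3,
                random_state=int(rng.integers(0, _MAX_SEED)),
            )
            y_fit = y_train[rows]
            net.fit(x_train[rows], y_fit.ravel() if y_fit.shape[1] == 1 else y_fit)
            out = net.predict(x_eval)
            preds[k] = out.reshape(x_eval.shape[0], -1)
    return np.median(preds, axis=0)


def abc_model_choice(
    observed,
    table: ReferenceTable,
    tolerance: float = 0.005,
    n_nets: int = 35,
    n_hidden: int = 10,
    seed: int | None = None,
) -> ABCModelPosterior:
    """Posterior model probabilities by neural-network regression.

    The model indicator (one-hot) is regressed on the MAD-scaled retained
    statistics; ensemble-median predictions at the observed point are
    clipped to [0, 1] and renormalized.  The rejection-only estimate
    (kernel-weighted model frequencies among retained rows) is reported
    alongside.  A model absent from the retained rows gets probability 0.
    """
    idx, _, weights = abc_reject(observed, table, tolerance)
    model_names = sorted(set(table.models.tolist()))
    if len(model_names) < 2:
        raise ValueError("need >= 2 models in the reference table")
    retained_models = table.models[idx]
    rejection = {
        m: float(weights[retained_models == m].sum() / weights.sum()) for m in model_names
    }
    missing = [m for m in model_names if (retained_models == m).sum() == 0]
    if missing:
        logger.warning("models absent from retained rows: %s", missing)

    obs = observed.as_array() if isinstance(observed, StatVector) else np.asarray(observed, float)
    scales = table.scales()
    x = np.nan_to_num((table.stats[idx] - obs) / scales)
    y = np.stack([(retained_models == m).astype(float) for m in model_names], axis=1)
    rng = np.random.default_rng(seed)
    pred = _fit_ensemble_predict(x, y, weights, np.zeros((1, x.shape[1])), n_nets, n_hidden, rng)[0]
    pred = np.clip(pred, 0.0, 1.0)
    for j, m in enumerate(model_names):
        if m in missing:
            pred[j] = 0.0
    if pred.sum() == 0:
        probs = dict(rejection)
    else:
        probs = {m: float(p / pred.sum()) for m, p in zip(model_names, pred)}
    return ABCModelPosterior(probs, rejection, "neural_network", tolerance, len(idx))


def _logit(y: np.ndarray, lo: float, hi: float) -> np.ndarray:
    eps = 1e-12 * (hi - lo)
    z = np.clip((y - lo) / (hi - lo), eps, 1 - eps)
    return np.log(z / (1 - z))


def _inv_logit(z: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return lo + (hi - lo) * expit(z)


def weighted_quantile(samples: np.ndarray, weights: np.ndarray, q) -> np.ndarray:
    order = np.argsort(samples)
    s, w = samples[order], weights[order]
    cdf = (np.cumsum(w) - 0.5 * w) / w.sum()
    return np.interp(np.atleast_1d(q), cdf, s)


def _weighted_mode(samples: np.ndarray, weights: np.ndarray) -> float:
    """Mode of the weighted kernel density (Silverman bandwidth)."""
    if np.ptp(samples) == 0:
        return float(samples[0])
    kde = gaussian_kde(samples, bw_method="silverman", weights=weights)
    grid = np.linspace(samples.min(), samples.max(), 512)
    return float(grid[int(np.argmax(kde(grid)))])


def abc_parameter_posterior(
    observed,
    table: ReferenceTable,
    prior_bounds: dict[str, tuple[float, float]],
    n_keep: int = 1000,
    n_nets: int = 35,
    n_hidden: int = 10,
    seed: int | None = None,
) -> dict[str, ParameterPosterior]:
    """Regression-adjusted posteriors for one model's parameters.

    The ``n_keep`` nearest rows of the (single-model) table are logit-
    transformed to their prior bounds, adjusted by the ensemble regression
    (prediction at the observed point plus weighted residuals) and back-
    transformed.  Parameters constant across retained rows come back as
    point masses.
    """
    if n_keep > table.n_rows:
        raise ValueError(f"n_keep={n_keep} exceeds table rows ({table.n_rows})")
    tolerance = n_keep / table.n_rows
    idx, _, weights = abc_reject(observed, table, tolerance)
    obs = observed.as_array() if isinstance(observed, StatVector) else np.asarray(observed, float)
    scales = table.scales()
    x = np.nan_to_num((table.stats[idx] - obs) / scales)
    rng = np.random.default_rng(seed)

    names = [p for p in prior_bounds if p in table.params.columns]
    live, z_cols, const = [], [], {}
    for p in names:
        y = table.params[p].to_numpy(float)[idx]
        if np.ptp(y) == 0:
            const[p] = float(y[0])
            continue
        live.append(p)
        z_cols.append(_logit(y, *prior_bounds[p]))
    out: dict[str, ParameterPosterior] = {}
    if live:
        z = np.stack(z_cols, axis=1)
        pred = _fit_ensemble_predict(
            x, z, weights, np.vstack([np.zeros(x.shape[1]), x]), n_nets, n_hidden, rng
        )
        at_obs, at_rows = pred[0], pred[1:]
        z_adj = at_obs + (z - at_rows)
        for j, p in enumerate(live):
            samples = _inv_logit(z_adj[:, j], *prior_bounds[p])
            lo, hi = weighted_quantile(samples, weights, [0.05, 0.95])
            out[p] = ParameterPosterior(
                p, samples, weights, _weighted_mode(samples, weights), (float(lo), float(hi))
            )
    for p, v in const.items():
        out[p] = ParameterPosterior(p, np.full(len(idx), v), weights, v, (v, v))
    return out


def robustness_from_probs(p_m1_given_m1: float, p_m1_given_m2: float) -> float:
    """R = P(M1|M1) / (P(M1|M1) + P(M1|M2))."""
    return p_m1_given_m1 / (p_m1_given_m1 + p_m1_given_m2)


def robustness_assessment(
    model_pair: tuple[str, str],
    simulate_pseudo,
    table: ReferenceTable,
    n_pseudo: int = 1000,
    tolerance: float = 0.005,
    n_nets: int = 35,
    n_hidden: int = 10,
    seed: int | None = None,
) -> RobustnessReport:
    """Mean posterior matrix over pseudo-observed datasets for a model pair.

    ``simulate_pseudo(model_name, seed) -> StatVector`` generates one
    pseudo-observed dataset under the named model (parameters drawn from
    the priors).  ``n_pseudo`` datasets are simulated per model.
    """
    if n_pseudo < 10:
        raise ValueError("n_pseudo must be >= 10")
    m1, m2 = model_pair
    rng = np.random.default_rng(seed)
    mean_post = np.zeros((2, 2))
    for row, true_model in enumerate(model_pair):
        acc = np.zeros(2)
        for _ in range(n_pseudo):
            sv = simulate_pseudo(true_model, int(rng.integers(1, _MAX_SEED)))
            post = abc_model_choice(
                sv, table, tolerance, n_nets, n_hidden, seed=int(rng.integers(0, _MAX_SEED))
            )
            pair_mass = post.probabilities.get(m1, 0.0) + post.probabilities.get(m2, 0.0)
            if pair_mass == 0:
                acc += 0.5
            else:
                acc[0] += post.probabilities.get(m1, 0.0) / pair_mass
                acc[1] += post.probabilities.get(m2, 0.0) / pair_mass
        mean_post[row] = acc / n_pseudo
    r = robustness_from_probs(mean_post[0, 0], mean_post[1, 0])
    return RobustnessReport(model_pair, mean_post, float(r), n_pseudo, seed)


def build_reference_table(
    scenarios,
    priors,
    simulate_stats,
    n_sims_per_model: int,
    seed: int | None = None,
) -> ReferenceTable:
    """Simulate the ABC reference table.

    ``simulate_stats(scenario, params, seed) -> StatVector`` runs one
    multilocus simulation and summarises it.  Rows are labeled by the
    scenario key.
    """
    from .coalsim import sample_prior  # deferred: avoid import cycle

    rng = np.random.default_rng(seed)
    models, stats, param_rows = [], [], []
    manifest = StatVector.manifest()
    for scenario in scenarios:
        for _ in range(n_sims_per_model):
            n_range = None
            if scenario.inheritance == "heterosomic":
                n_range = (0, getattr(simulate_stats, "n_loci", 50))
            params = sample_prior(priors, int(rng.integers(1, _MAX_SEED)), n_range)
            sv = simulate_stats(scenario, params, int(rng.integers(1, _MAX_SEED)))
            models.append(scenario.key)
            stats.append(sv.as_array())
            row = {
                k: getattr(params, k)
                for k in (
                    "N_dip", "N_ext", "N_tet", "N_anc", "T_split", "T_WGD",
                    "m_dip_to_A", "m_dip_to_B", "m_A_to_dip", "m_B_to_dip",
                )
            }
            param_rows.append(row)
    return ReferenceTable(
        np.array(models), pd.DataFrame(param_rows), np.vstack(stats), manifest
    )
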