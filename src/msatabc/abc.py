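"""Approximate Bayesian Computation: reference tables, rejection, scenario
choice, local-linear parameter adjustment, model checking.

The workflow mirrors the standard rejection + regression ABC used for
microsatellite demographic inference:

1. a *reference table* of (scenario, parameters, summary statistics) rows is
   simulated from the priors;
2. statistics are robustly standardised (median/MAD of the table) and the
   rows closest to the observed vector in Euclidean distance are retained;
3. scenario posterior probabilities come from the retained-set proportions
   (direct estimate) and from a distance-weighted multinomial logistic
   regression of the scenario indicator on the standardised statistic
   offsets, evaluated at offset zero (logistic estimate);
4. parameter posteriors come from Beaumont-style local-linear regression:
   each parameter is logit-transformed to its prior interval, regressed on
   the statistic offsets with Epanechnikov weights, residual-adjusted to
   offset zero and back-transformed — adjusted draws therefore can never
   leave the prior support;
5. goodness of fit is assessed by posterior-predictive simulation with
   per-statistic two-sided tail probabilities and Bonferroni correction,
   and by projecting the observed vector into a PCA of the reference table.

The user-facing entry point is :class:`DemographicABC` (model object) whose
``fit`` returns an :class:`ABCResults`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression

from .dataset import MicrosatDataset
from .scenarios import (
    ALL_SYMBOLS,
    DemographicScenario,
    ParameterDraw,
    PriorSpec,
    SCENARIOS,
    default_priors,
    required_symbols,
    sample_parameters,
)
from .simulate import simulate_dataset
from .sumstats import summary_stat_names, summary_vector

__all__ = [
    "ReferenceTable",
    "build_reference_table",
    "RetainedSet",
    "select_closest",
    "ScenarioProbabilities",
    "model_choice",
    "ParameterPosterior",
    "estimate_posteriors",
    "convert_to_years",
    "bottleneck_ratio",
    "model_check",
    "pca_preevaluation",
    "DemographicABC",
    "ABCResults",
    "weighted_quantile",
]

_TIME_SYMBOLS = ("t1", "t2", "db")


# ---------------------------------------------------------------------------
# reference table
# ---------------------------------------------------------------------------

@dataclass
class ReferenceTable:
    """Rows of (scenario id, parameter draw, summary statistics)."""

    df: pd.DataFrame
    stat_names: tuple
    meta: dict = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return len(self.df)

    @property
    def scenario_ids(self) -> np.ndarray:
        return self.df["scenario"].to_numpy()

    def stats(self) -> np.ndarray:
        return self.df.loc[:, list(self.stat_names)].to_numpy(dtype=float)

    def filter_scenario(self, scenario_id: int) -> "ReferenceTable":
        sub = self.df[self.df["scenario"] == scenario_id].reset_index(drop=True)
        return ReferenceTable(sub, self.stat_names, dict(self.meta))

    def to_csv(self, path) -> None:
        import json

        with open(path, "w") as fh:
            fh.write("# " + json.dumps({"stat_names": list(self.stat_names),
                                        **self.meta}) + "\n")
            self.df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "ReferenceTable":
        import json

        with open(path) as fh:
            first = fh.readline()
            meta = json.loads(first.lstrip("# ")) if first.startswith("#") else {}
            df = pd.read_csv(fh)
        stat_names = tuple(meta.pop("stat_names", [c for c in df.columns
                                                   if c not in ("scenario",) + ALL_SYMBOLS]))
        return cls(df, stat_names, meta)


def build_reference_table(
    scenarios: Sequence[DemographicScenario],
    priors: Mapping[str, PriorSpec],
    n_per_scenario: int,
    n_loci: int,
    sample_sizes: Sequence[int],
    seed: int,
    pop_names: Sequence[str] | None = None,
    **sim_kwargs,
) -> ReferenceTable:
    """Simulate the ABC reference table (reproducible from ``seed``)."""
    if n_per_scenario < 1:
        raise ValueError("n_per_scenario must be >= 1")
    rng = np.random.default_rng(seed)
    stat_names = None
    rows_param = []
    rows_stat = []
    rows_scen = []
    for sc in scenarios:
        for i in range(n_per_scenario):
            try:
                draw = sample_parameters(priors, sc, rng)
                ds = simulate_dataset(sc, draw, n_loci, sample_sizes, rng,
                                      pop_names=pop_names, **sim_kwargs)
                sv = summary_vector(ds)
            except Exception as err:  # pragma: no cover - defensive
                raise RuntimeError(
                    f"simulation failed at scenario {sc.id}, row {i}: {err}"
                ) from err
            if stat_names is None:
                stat_names = summary_stat_names(ds.pop_names)
            rows_scen.append(sc.id)
            rows_param.append([draw.as_dict()[s] for s in ALL_SYMBOLS])
            rows_stat.append(sv)
    df = pd.DataFrame(rows_param, columns=list(ALL_SYMBOLS))
    df.insert(0, "scenario", rows_scen)
    df = pd.concat(
        [df, pd.DataFrame(rows_stat, columns=list(stat_names))], axis=1
    )
    meta = {
        "seed": int(seed),
        "n_per_scenario": int(n_per_scenario),
        "n_loci": int(n_loci),
        "sample_sizes": [int(x) for x in sample_sizes],
    }
    return ReferenceTable(df, stat_names, meta)


# ---------------------------------------------------------------------------
# rejection
# ---------------------------------------------------------------------------

@dataclass
class RetainedSet:
    """Closest reference-table rows to the observed statistics.

    ``X`` holds the standardised statistic offsets (row statistics minus
    observed, in median/MAD units over the kept statistics); ``weights``
    are Epanechnikov kernel weights ``1 - (d/d_max)^2`` with the bandwidth
    at the largest retained distance.
    """

    table: ReferenceTable
    indices: np.ndarray
    distances: np.ndarray
    X: np.ndarray
    kept_stats: tuple
    center: np.ndarray
    scale: np.ndarray

    @property
    def scenario_ids(self) -> np.ndarray:
        return self.table.scenario_ids[self.indices]

    @property
    def params(self) -> pd.DataFrame:
        return self.table.df.iloc[self.indices][list(ALL_SYMBOLS)]

    @property
    def weights(self) -> np.ndarray:
        dmax = self.distances.max()
        if dmax == 0:
            return np.ones_like(self.distances)
        w = 1.0 - (self.distances / dmax) ** 2
        # the farthest retained row gets weight 0; keep it infinitesimally
        # positive so degenerate two-row sets stay usable
        return np.maximum(w, 1e-12)


def select_closest(
    table: ReferenceTable, observed: np.ndarray, fraction: float = 0.01
) -> RetainedSet:
    """Retain the ``ceil(fraction * n)`` rows closest to ``observed``.

    Statistics are standardised by the table's median and MAD; statistics
    with zero MAD are dropped from the distance with a warning.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    S = table.stats()
    obs = np.asarray(observed, dtype=float)
    if obs.shape[0] != S.shape[1]:
        raise ValueError("observed vector has wrong length")
    center = np.median(S, axis=0)
    scale = np.median(np.abs(S - center), axis=0)
    keep = scale > 0
    if not keep.all():
        dropped = [n for n, k in zip(table.stat_names, keep) if not k]
        warnings.warn(f"dropping zero-MAD statistics from distance: {dropped}")
    if not keep.any():
        raise ValueError("all statistics have zero MAD")
    Z = (S[:, keep] - center[keep]) / scale[keep]
    z_obs = (obs[keep] - center[keep]) / scale[keep]
    offsets = Z - z_obs
    d = np.sqrt((offsets**2).sum(axis=1))
    n_keep = int(math.ceil(fraction * len(d)))
    idx = np.argpartition(d, n_keep - 1)[:n_keep]
    idx = idx[np.argsort(d[idx], kind="stable")]
    return RetainedSet(
        table=table,
        indices=idx,
        distances=d[idx],
        X=offsets[idx],
        kept_stats=tuple(n for n, k in zip(table.stat_names, keep) if k),
        center=center,
        scale=scale,
    )


# ---------------------------------------------------------------------------
# scenario choice
# ---------------------------------------------------------------------------

@dataclass
class ScenarioProbabilities:
    """Posterior scenario probabilities by both estimators."""

    table: pd.DataFrame  # scenario, p_direct, p_logistic[, ci_low, ci_high]
    method_flags: dict

    @property
    def best_scenario(self) -> int:
        return int(self.table.loc[self.table["p_logistic"].idxmax(), "scenario"])

    def __repr__(self) -> str:  # pragma: no cover
        return self.table.to_string(index=False)


def _fit_logistic(X, y, w, classes, lda: bool = True):
    if lda and X.shape[1] > len(np.unique(y)) - 1:
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        proj = LinearDiscriminantAnalysis()
        Xt = proj.fit_transform(X, y)
        x0 = proj.transform(np.zeros((1, X.shape[1])))
    else:
        Xt, x0 = X, np.zeros((1, X.shape[1]))
    clf = LogisticRegression(C=1e4, max_iter=2000, tol=1e-8)
    clf.fit(Xt, y, sample_weight=w)
    p_at_zero = clf.predict_proba(x0)[0]
    probs = dict(zip(clf.classes_, p_at_zero))
    return np.array([probs.get(c, 0.0) for c in classes])


def model_choice(
    retained: RetainedSet,
    scenario_ids: Sequence[int] | None = None,
    n_bootstrap: int = 0,
    rng: np.random.Generator | None = None,
    lda: bool = True,
) -> ScenarioProbabilities:
    """Scenario posterior probabilities from the retained set.

    Direct estimate: retained-set proportions.  Logistic estimate:
    Epanechnikov-weighted multinomial logistic regression of the scenario
    indicator on the standardised statistic offsets, evaluated at offset
    zero.  With ``lda`` (default) the offsets are first projected onto
    their linear-discriminant axes, the low-dimensional stabilisation the
    reference ABC engine applies before its logistic step; set
    ``lda=False`` to regress on the raw standardised offsets.  Optional
    nonparametric bootstrap of the retained set gives 95% CIs on the
    logistic probabilities.
    """
    y = retained.scenario_ids
    if scenario_ids is None:
        scenario_ids = np.unique(retained.table.scenario_ids)
    scenario_ids = np.asarray(sorted(scenario_ids))
    if len(scenario_ids) < 2:
        raise ValueError("model choice needs at least two scenarios")
    flags: dict = {}

    counts = np.array([(y == c).sum() for c in scenario_ids], dtype=float)
    absent = scenario_ids[counts == 0]
    if absent.size:
        warnings.warn(f"scenarios absent from retained set: {absent.tolist()}")
        flags["absent"] = absent.tolist()
    p_direct = counts / counts.sum()

    present = scenario_ids[counts > 0]
    if len(present) == 1:
        p_logistic = (scenario_ids == present[0]).astype(float)
        flags["logistic"] = "single-class"
    else:
        try:
            p_logistic = _fit_logistic(retained.X, y, retained.weights,
                                       scenario_ids, lda=lda)
        except Exception as err:
            warnings.warn(f"logistic regression failed ({err}); using direct")
            p_logistic = p_direct.copy()
            flags["logistic"] = "fallback-direct"

    out = pd.DataFrame(
        {"scenario": scenario_ids, "p_direct": p_direct, "p_logistic": p_logistic}
    )
    if n_bootstrap > 0:
        if rng is None:
            rng = np.random.default_rng()
        boot = np.empty((n_bootstrap, len(scenario_ids)))
        n = len(y)
        for b in range(n_bootstrap):
            take = rng.integers(0, n, n)
            yb = y[take]
            if len(np.unique(yb)) < 2:
                boot[b] = (scenario_ids == yb[0]).astype(float)
                continue
            try:
                boot[b] = _fit_logistic(
                    retained.X[take], yb, retained.weights[take],
                    scenario_ids, lda=lda,
                )
            except Exception:
                boot[b] = np.nan
        out["ci_low"] = np.nanpercentile(boot, 2.5, axis=0)
        out["ci_high"] = np.nanpercentile(boot, 97.5, axis=0)
    return ScenarioProbabilities(out, flags)


# ---------------------------------------------------------------------------
# parameter posteriors
# ---------------------------------------------------------------------------

def weighted_quantile(values: np.ndarray, q, weights: np.ndarray):
    """Weighted quantiles by the cumulative-midpoint rule."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    cw = (np.cumsum(w) - 0.5 * w) / w.sum()
    return np.interp(q, cw, v)


@dataclass
class ParameterPosterior:
    """Adjusted posterior samples for one scenario's parameters."""

    scenario: DemographicScenario
    samples: pd.DataFrame  # one column per symbol, one row per retained sim
    weights: np.ndarray
    slopes: pd.DataFrame  # regression slopes per symbol x statistic
    flags: dict

    def summary(self) -> pd.DataFrame:
        """median / q050 / q950 per parameter (weighted)."""
        rows = {}
        for sym in self.samples.columns:
            med, lo, hi = weighted_quantile(
                self.samples[sym].to_numpy(), [0.5, 0.05, 0.95], self.weights
            )
            rows[sym] = {"median": med, "q050": lo, "q950": hi}
        return pd.DataFrame(rows).T[["median", "q050", "q950"]]


def estimate_posteriors(
    retained: RetainedSet,
    priors: Mapping[str, PriorSpec],
    scenario: DemographicScenario,
) -> ParameterPosterior:
    """Logit-transformed local-linear regression adjustment.

    Each parameter is mapped to the real line by the logit of its position
    in the prior interval, linearly regressed on the standardised statistic
    offsets with Epanechnikov weights, and residual-adjusted to offset
    zero; the inverse transform guarantees adjusted draws stay inside the
    prior bounds.
    """
    symbols = required_symbols(scenario)
    X = retained.X
    w = retained.weights
    n, k = X.shape
    flags: dict = {}
    if n <= k + 1:
        # an exact-interpolation regime would collapse the posterior to a
        # point mass; fall back to the plain rejection sample
        warnings.warn(
            f"only {n} retained simulations for {k} statistics: skipping "
            "the regression adjustment (rejection sample returned)"
        )
        flags["adjustment"] = "skipped: retained set smaller than design"
        X = np.zeros_like(X)
    D = np.column_stack([np.ones(n), X])
    sw = np.sqrt(w)
    rank = np.linalg.matrix_rank(D * sw[:, None])
    if rank < k + 1 and "adjustment" not in flags:
        flags["design"] = "rank-deficient; minimum-norm solution"
    adj = {}
    slopes = {}
    eps = 1e-10
    params = retained.params
    for sym in symbols:
        a, b = priors[sym].low, priors[sym].high
        theta = params[sym].to_numpy(dtype=float)
        if b == a:
            adj[sym] = np.full(n, a)
            slopes[sym] = np.zeros(k)
            continue
        u = np.clip((theta - a) / (b - a), eps, 1 - eps)
        z = logit(u)
        beta, *_ = np.linalg.lstsq(D * sw[:, None], z * sw, rcond=None)
        z_adj = z - X @ beta[1:]
        adj[sym] = a + (b - a) * expit(z_adj)
        slopes[sym] = beta[1:]
    samples = pd.DataFrame(adj)
    # hard invariant: the logit transform keeps draws inside the prior
    for sym in symbols:
        lo, hi = priors[sym].low, priors[sym].high
        assert samples[sym].between(lo, hi).all(), f"{sym} left prior bounds"
    return ParameterPosterior(
        scenario=scenario,
        samples=samples,
        weights=w,
        slopes=pd.DataFrame(slopes, index=list(retained.kept_stats)).T,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# unit conversion and derived quantities
# ---------------------------------------------------------------------------

def convert_to_years(generations, generation_time: float = 3.0):
    """Generations -> years (wolf generation time: 3 years)."""
    if generation_time <= 0:
        raise ValueError("generation_time must be > 0")
    return np.asarray(generations, dtype=float) * generation_time if not np.isscalar(
        generations
    ) else float(generations) * generation_time


def bottleneck_ratio(pre_size: float, post_size: float) -> float:
    """Bottleneck severity R = Nb / N, reported to one decimal."""
    if post_size <= 0:
        raise ValueError("post-bottleneck size must be > 0")
    return round(pre_size / post_size, 1)


# ---------------------------------------------------------------------------
# model checking and PCA pre-evaluation
# ---------------------------------------------------------------------------

def model_check(
    posterior: ParameterPosterior,
    observed: np.ndarray,
    n_loci: int,
    sample_sizes: Sequence[int],
    n_ppc: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    stat_names: Sequence[str] | None = None,
    **sim_kwargs,
) -> pd.DataFrame:
    """Posterior-predictive goodness-of-fit check.

    Simulates ``n_ppc`` datasets at parameter vectors resampled from the
    adjusted posterior (weight-proportional) and reports, per summary
    statistic, the two-sided tail probability of the observed value within
    the predictive distribution, with the Bonferroni threshold
    ``alpha / n_statistics``.
    """
    if n_ppc < 100:
        warnings.warn("n_ppc < 100 gives coarse tail probabilities")
    if rng is None:
        rng = np.random.default_rng()
    sc = posterior.scenario
    samples = posterior.samples
    n_rows = len(samples)

    # the marginal adjustment can break joint ordering constraints
    # (db < t1 < t2); draw only from rows that still satisfy them, or
    # repair the offending times when no row does (tiny retained sets)
    draws = []
    for i in range(n_rows):
        d = {s: float("nan") for s in ALL_SYMBOLS}
        d.update({k: float(v) for k, v in samples.iloc[i].items()})
        draws.append(ParameterDraw.from_dict(d))
    valid = np.zeros(n_rows, dtype=bool)
    for i, dr in enumerate(draws):
        try:
            dr.validate(sc)
            valid[i] = True
        except Exception:
            pass
    if valid.any():
        w = posterior.weights * valid
    else:
        warnings.warn(
            "no adjusted draw satisfies the ordering constraints; "
            "repairing times for posterior-predictive simulation"
        )
        for dr in draws:
            if sc.bottleneck and not dr.db < dr.t1:
                dr.db = 0.999 * dr.t1
            if sc.sequential and not dr.t1 < dr.t2:
                dr.t2 = 1.001 * dr.t1
        w = posterior.weights.copy()
    w = w / w.sum()
    sims = np.empty((n_ppc, len(observed)))
    for j in range(n_ppc):
        i = rng.choice(n_rows, p=w)
        ds = simulate_dataset(sc, draws[i], n_loci, sample_sizes, rng,
                              **sim_kwargs)
        sims[j] = summary_vector(ds)
    obs = np.asarray(observed, dtype=float)
    p_low = ((sims <= obs).sum(axis=0) + 1.0) / (n_ppc + 1.0)
    p_high = ((sims >= obs).sum(axis=0) + 1.0) / (n_ppc + 1.0)
    tail = np.minimum(1.0, 2.0 * np.minimum(p_low, p_high))
    n_stats = len(obs)
    thresh = alpha / n_stats
    if stat_names is None:
        stat_names = [f"stat{i}" for i in range(n_stats)]
    return pd.DataFrame(
        {
            "statistic": list(stat_names),
            "observed": obs,
            "predictive_median": np.median(sims, axis=0),
            "tail_prob": tail,
            "significant": tail < thresh,
        }
    )


def pca_preevaluation(
    table: ReferenceTable,
    observed: np.ndarray,
    n_points: int = 10_000,
    rng: np.random.Generator | None = None,
):
    """Project a reference-table subsample and the observed vector on PCs.

    Statistics are z-standardised on the subsample; returns a DataFrame of
    PC1/PC2 coordinates with scenario labels (the observed point has
    scenario 0) and the fitted PCA object.
    """
    if table.n_rows < 2:
        raise ValueError("PCA needs at least two reference rows")
    if rng is None:
        rng = np.random.default_rng()
    n_sub = min(n_points, table.n_rows)
    take = rng.choice(table.n_rows, size=n_sub, replace=False)
    S = table.stats()[take]
    mean = S.mean(axis=0)
    std = S.std(axis=0)
    std[std == 0] = 1.0
    Z = (S - mean) / std
    z_obs = (np.asarray(observed, dtype=float) - mean) / std
    pca = PCA()
    coords = pca.fit_transform(Z)
    obs_coords = pca.transform(z_obs[None, :])
    df = pd.DataFrame(
        {
            "PC1": np.concatenate([coords[:, 0], obs_coords[:, 0]]),
            "PC2": np.concatenate([coords[:, 1], obs_coords[:, 1]]),
            "scenario": np.concatenate([table.scenario_ids[take], [0]]),
        }
    )
    return df, pca


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class DemographicABC:
    """ABC model for multi-population microsatellite demography.

    Parameters
    ----------
    observed : MicrosatDataset or 1-D array
        Observed dataset, or a precomputed summary-statistic vector (then
        ``n_loci`` and ``sample_sizes`` are required).
    scenarios : sequence of DemographicScenario, default all four
    priors : mapping symbol -> PriorSpec, default :func:`default_priors`
    fraction : float
        Fraction of simulations retained by rejection (the classic 1%).
    generation_time : float
        Years per generation for time conversions.
    sim_kwargs : extra options forwarded to the simulator
        (``motif_lengths``, ``ladder_bounds``, ``gamma_rate_shape``).

    Examples
    --------
    >>> model = DemographicABC(observed_dataset)
    >>> res = model.fit(n_per_scenario=5000, seed=7)
    >>> res.scenario_probabilities
    >>> res.posterior_summary(units="years")
    """

    def __init__(
        self,
        observed,
        scenarios: Sequence[DemographicScenario] | None = None,
        priors: Mapping[str, PriorSpec] | None = None,
        n_loci: int | None = None,
        sample_sizes: Sequence[int] | None = None,
        fraction: float = 0.01,
        generation_time: float = 3.0,
        **sim_kwargs,
    ):
        if isinstance(observed, MicrosatDataset):
            self.observed_dataset = observed
            self.observed_stats = summary_vector(observed)
            n_loci = n_loci if n_loci is not None else observed.n_loci
            if sample_sizes is None:
                sample_sizes = observed.sample_sizes.tolist()
        else:
            self.observed_dataset = None
            self.observed_stats = np.asarray(observed, dtype=float)
            if n_loci is None or sample_sizes is None:
                raise ValueError(
                    "n_loci and sample_sizes are required when observed is a "
                    "statistic vector"
                )
        self.n_loci = int(n_loci)
        self.sample_sizes = [int(x) for x in sample_sizes]
        self.scenarios = list(scenarios) if scenarios else [SCENARIOS[i] for i in (1, 2, 3, 4)]
        self.priors = dict(priors) if priors else default_priors()
        self.fraction = float(fraction)
        self.generation_time = float(generation_time)
        self.sim_kwargs = sim_kwargs

    # -- simulation ----------------------------------------------------------
    def simulate_reference_table(self, n_per_scenario: int, seed: int) -> ReferenceTable:
        return build_reference_table(
            self.scenarios, self.priors, n_per_scenario, self.n_loci,
            self.sample_sizes, seed, **self.sim_kwargs,
        )

    # -- fitting -------------------------------------------------------------
    def fit(
        self,
        n_per_scenario: int = 10_000,
        seed: int = 0,
        reference_table: ReferenceTable | None = None,
        fraction: float | None = None,
        n_bootstrap: int = 0,
        posterior_scenario: int | None = None,
    ) -> "ABCResults":
        """Run rejection, scenario choice and parameter adjustment.

        Pass ``reference_table`` to reuse simulations (e.g. across several
        observed datasets); otherwise a fresh table of ``n_per_scenario``
        rows per scenario is simulated from ``seed``.
        ``posterior_scenario`` forces parameter estimation under a given
        scenario instead of the best one.
        """
        fraction = self.fraction if fraction is None else float(fraction)
        table = reference_table or self.simulate_reference_table(n_per_scenario, seed)
        rng = np.random.default_rng(seed + 1)

        retained = select_closest(table, self.observed_stats, fraction)
        if len(self.scenarios) > 1:
            probs = model_choice(
                retained,
                scenario_ids=[s.id for s in self.scenarios],
                n_bootstrap=n_bootstrap,
                rng=rng,
            )
            best_id = probs.best_scenario
        else:
            only = self.scenarios[0].id
            probs = ScenarioProbabilities(
                pd.DataFrame({"scenario": [only], "p_direct": [1.0],
                              "p_logistic": [1.0]}),
                {"logistic": "single-scenario"},
            )
            best_id = only
        if posterior_scenario is not None:
            best_id = int(posterior_scenario)
        best = SCENARIOS[best_id]
        retained_best = select_closest(
            table.filter_scenario(best_id), self.observed_stats, fraction
        )
        posterior = estimate_posteriors(retained_best, self.priors, best)
        return ABCResults(
            model=self,
            reference_table=table,
            retained=retained,
            scenario_probabilities=probs.table,
            scenario_flags=probs.method_flags,
            best_scenario=best,
            retained_best=retained_best,
            posterior=posterior,
            seed=seed,
        )


@dataclass
class ABCResults:
    """Fitted ABC results: scenario choice, posteriors, diagnostics."""

    model: DemographicABC
    reference_table: ReferenceTable
    retained: RetainedSet
    scenario_probabilities: pd.DataFrame
    scenario_flags: dict
    best_scenario: DemographicScenario
    retained_best: RetainedSet
    posterior: ParameterPosterior
    seed: int

    # -- posterior summaries -------------------------------------------------
    def posterior_summary(self, units: str = "generations") -> pd.DataFrame:
        """median / q050 / q950 per parameter.

        With ``units="years"`` the time parameters (t1, t2, db) are
        converted at the model's generation time; sizes and rates are
        unchanged.
        """
        summ = self.posterior.summary()
        if units == "generations":
            return summ
        if units != "years":
            raise ValueError("units must be 'generations' or 'years'")
        out = summ.copy()
        g = self.model.generation_time
        for sym in _TIME_SYMBOLS:
            if sym in out.index:
                out.loc[sym] *= g
        return out

    def bottleneck_ratios(self) -> pd.DataFrame:
        """R = Nb/N per population from posterior medians (1 decimal)."""
        if not self.best_scenario.bottleneck:
            raise ValueError("best scenario has no bottleneck")
        med = self.posterior.summary()["median"]
        rows = []
        for i, label in enumerate(self.best_scenario.pop_labels, start=1):
            rows.append(
                {
                    "population": label,
                    "N": med[f"N{i}"],
                    "Nb": med[f"N{i}b"],
                    "R": bottleneck_ratio(med[f"N{i}b"], med[f"N{i}"]),
                }
            )
        return pd.DataFrame(rows)

    # -- diagnostics ---------------------------------------------------------
    def model_check(self, n_ppc: int = 1000, alpha: float = 0.05,
                    seed: int | None = None) -> pd.DataFrame:
        rng = np.random.default_rng(self.seed + 2 if seed is None else seed)
        return model_check(
            self.posterior,
            self.model.observed_stats,
            self.model.n_loci,
            self.model.sample_sizes,
            n_ppc=n_ppc,
            alpha=alpha,
            rng=rng,
            stat_names=self.reference_table.stat_names,
            **self.model.sim_kwargs,
        )

    def pca_preevaluation(self, n_points: int = 10_000, seed: int | None = None):
        rng = np.random.default_rng(self.seed + 3 if seed is None else seed)
        return pca_preevaluation(
            self.reference_table, self.model.observed_stats, n_points, rng
        )

    # -- reporting -----------------------------------------------------------
    def summary(self) -> str:
        """Human-readable report of the fit."""
        meta = self.reference_table.meta
        lines = [
            "Approximate Bayesian Computation results",
            "========================================",
            f"reference table : {self.reference_table.n_rows} rows "
            f"({meta.get('n_per_scenario', '?')} per scenario), "
            f"{meta.get('n_loci', '?')} loci, samples {meta.get('sample_sizes', '?')}",
            f"retained        : {len(self.retained.indices)} rows "
            f"(fraction {self.model.fraction})",
            "",
            "Scenario posterior probabilities",
            "--------------------------------",
            self.scenario_probabilities.to_string(index=False,
                                                  float_format=lambda x: f"{x:.4f}"),
            "",
            f"Parameter posteriors under scenario {self.best_scenario.id} "
            f"(generations / diploid sizes)",
            "-" * 60,
            self.posterior_summary().to_string(float_format=lambda x: f"{x:.4g}"),
            "",
            f"Time parameters in years (generation time "
            f"{self.model.generation_time:g} y)",
            "-" * 60,
            self.posterior_summary(units="years")
            .loc[[s for s in _TIME_SYMBOLS
                  if s in self.posterior.samples.columns]]
            .to_string(float_format=lambda x: f"{x:.4g}"),
        ]
        if self.best_scenario.bottleneck:
            lines += [
                "",
                "Bottleneck severity (posterior medians)",
                "---------------------------------------",
                self.bottleneck_ratios().to_string(
                    index=False, float_format=lambda x: f"{x:.3g}"
                ),
            ]
        return "\n".join(lines)
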