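"""Statistical layer: null-ensemble comparisons, rankings, outliers, regimes.

The central inference compares communication metrics of a focal node on
the empirical network against a surrogate ensemble: the ensemble mean of
R simulations on the real network is expressed as a z-score relative to
the distribution of one-simulation values over S surrogate networks.  A
large positive z for, say, arrivals means the node attracts more traffic
than degree alone can explain.

The *convergence excess* statistic packages this against degree-
preserving rewired surrogates of the evaluated network itself, so it can
be applied equally to an empirical network and to its direction-reversed
counterpart: a genuine topological funnel shows a large excess that
vanishes after reversal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .metrics import METRICS, node_metrics
from .network import DegreeProfile, DirectedNetwork
from .nulls import surrogate_ensemble
from .simulate import SimParams, SimResult, simulate
from .utils import derive_seed

__all__ = [
    "zscore_vs_null",
    "rank_nodes",
    "top_k_edges",
    "degree_outlier_scores",
    "phase_map",
    "run_ensemble",
    "null_ensemble_report",
    "convergence_excess",
    "NullEnsembleReport",
    "PhaseMap",
]


def zscore_vs_null(
    empirical: np.ndarray, null: np.ndarray, ddof: int = 1
) -> tuple[float, float]:
    """z of the empirical ensemble mean against a null distribution.

    ``z = (mean(empirical) - mean(null)) / sd(null)`` with a two-sided
    normal-approximation p-value.
    """
    empirical = np.asarray(empirical, dtype=float)
    null = np.asarray(null, dtype=float)
    if empirical.size < 2 or null.size < 2:
        raise ValueError("need at least 2 empirical and 2 null values")
    sd = float(null.std(ddof=ddof))
    if sd == 0:
        raise ValueError("null distribution has zero variance")
    z = float((empirical.mean() - null.mean()) / sd)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return z, p


def empirical_percentile_p(empirical: np.ndarray, null: np.ndarray) -> float:
    """Two-sided empirical percentile p-value (add-one correction)."""
    m = float(np.mean(empirical))
    null = np.asarray(null, dtype=float)
    hi = np.sum(null >= m) + 1
    lo = np.sum(null <= m) + 1
    return float(min(1.0, 2.0 * min(hi, lo) / (null.size + 1)))


def rank_nodes(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Rank nodes on one metric, descending; rank 1 is the largest value.

    Ties get the average rank.  The returned frame is sorted by rank
    with label order as the final tie-break, and keeps the metric value.
    """
    if metric not in table.columns:
        raise KeyError(f"unknown metric {metric!r}; table has {list(table.columns)}")
    ranks = table[metric].rank(ascending=False, method="average")
    out = pd.DataFrame({metric: table[metric], "rank": ranks})
    # stable sort keeps canonical label order as the final tie-break
    return out.sort_values("rank", kind="stable")


def top_k_edges(
    traffic: np.ndarray, node_labels: tuple[str, ...], k: int
) -> list[tuple[tuple[str, str], int]]:
    """The k most-traversed directed edges, descending by count.

    Ties are broken by (source, target) label order.  If fewer than k
    edges carried traffic, all of them are returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    src, dst = np.nonzero(traffic)
    entries = [
        ((node_labels[i], node_labels[j]), int(traffic[i, j])) for i, j in zip(src, dst)
    ]
    entries.sort(key=lambda e: (-e[1], e[0]))
    return entries[:k]


def degree_outlier_scores(
    table: pd.DataFrame,
    degree_profile: DegreeProfile,
    metric: str = "arrivals",
    threshold: float = 3.0,
) -> pd.DataFrame:
    """Studentized residuals of a metric regressed on in-degree.

    Ordinary least squares of ``metric ~ k_in`` across nodes; nodes with
    internally studentized residual above ``threshold`` in absolute
    value are flagged as communication outliers — traffic beyond what
    in-degree alone predicts.
    """
    deg = degree_profile.to_frame().reindex(table.index)
    if deg["in_degree"].nunique() < 2 or len(table) < 3:
        raise ValueError("need >= 3 nodes with variance in in-degree")
    y = table[metric].to_numpy(dtype=float)
    X = sm.add_constant(deg["in_degree"].to_numpy(dtype=float))
    fit = sm.OLS(y, X).fit()
    if fit.ssr <= 1e-12 * max(1.0, float(np.sum(y**2))):
        resid = np.zeros(len(y))  # perfect fit: studentization is 0/0
    else:
        resid = fit.get_influence().resid_studentized_internal
    out = pd.DataFrame(
        {
            "in_degree": deg["in_degree"],
            metric: table[metric],
            "studentized_residual": resid,
        },
        index=table.index,
    )
    out["outlier"] = np.abs(out["studentized_residual"]) > threshold
    return out


# ---------------------------------------------------------------------------
# Ensembles and null-model reports
# ---------------------------------------------------------------------------


def run_ensemble(
    net: DirectedNetwork,
    params: SimParams,
    n_runs: int,
    base_seed: int,
    stage: str = "ensemble",
) -> list[SimResult]:
    """R independent seeded simulations on one network."""
    return [
        simulate(net, _with_seed(params, derive_seed(base_seed, stage, r)))
        for r in range(n_runs)
    ]


def ensemble_metric_table(results: list[SimResult]) -> pd.DataFrame:
    """Per-node metrics averaged over an ensemble of runs."""
    frames = [node_metrics(r) for r in results]
    return sum(frames[1:], frames[0]) / len(frames)


def ensemble_edge_traffic(results: list[SimResult]) -> np.ndarray:
    """Summed edge traversal counts over an ensemble of runs."""
    return np.sum([r.edge_counts for r in results], axis=0)


@dataclass
class NullEnsembleReport:
    """z-scores of a focal node's metrics against one surrogate family."""

    focal: str
    null_kind: str
    n_empirical: int
    n_surrogates: int
    z: dict[str, float] = field(default_factory=dict)
    p: dict[str, float] = field(default_factory=dict)
    p_empirical: dict[str, float] = field(default_factory=dict)
    empirical_mean: dict[str, float] = field(default_factory=dict)
    null_mean: dict[str, float] = field(default_factory=dict)
    null_sd: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "focal": self.focal,
            "null_kind": self.null_kind,
            "R": self.n_empirical,
            "S": self.n_surrogates,
            "metrics": {
                m: {
                    "z": self.z[m],
                    "p_normal": self.p[m],
                    "p_empirical": self.p_empirical[m],
                    "empirical_mean": self.empirical_mean[m],
                    "null_mean": self.null_mean[m],
                    "null_sd": self.null_sd[m],
                }
                for m in self.z
            },
        }


def _with_seed(params: SimParams, seed: int) -> SimParams:
    fields = {k: getattr(params, k) for k in params.__dataclass_fields__}
    fields["seed"] = seed
    return SimParams(**fields)


def null_ensemble_report(
    net: DirectedNetwork,
    focal: str,
    params: SimParams,
    n_empirical: int,
    n_surrogates: int,
    base_seed: int,
    null_kind: str = "rewired",
    reversal_fraction: float | None = None,
    empirical_results: list[SimResult] | None = None,
) -> NullEnsembleReport:
    """Compare a focal node's metrics on ``net`` against a surrogate family.

    R simulations on the empirical network (reused if supplied) against
    one simulation on each of S surrogates, per the standard surrogate-
    ensemble design.
    """
    i = net.index_of(focal)
    if empirical_results is None:
        empirical_results = run_ensemble(net, params, n_empirical, base_seed, "empirical")
    surrogates = surrogate_ensemble(
        net,
        null_kind,
        n_surrogates,
        derive_seed(base_seed, f"null-{null_kind}", 0),
        reversal_fraction=reversal_fraction,
    )
    null_results = [
        simulate(s_net, _with_seed(params, derive_seed(spec.seed, "null-sim", 0)))
        for s_net, spec in surrogates
    ]
    report = NullEnsembleReport(
        focal=focal,
        null_kind=null_kind,
        n_empirical=len(empirical_results),
        n_surrogates=n_surrogates,
    )
    for m in METRICS:
        emp = np.array([node_metrics(r)[m].iloc[i] for r in empirical_results])
        nul = np.array([node_metrics(r)[m].iloc[i] for r in null_results])
        z, p = zscore_vs_null(emp, nul)
        report.z[m] = z
        report.p[m] = p
        report.p_empirical[m] = empirical_percentile_p(emp, nul)
        report.empirical_mean[m] = float(emp.mean())
        report.null_mean[m] = float(nul.mean())
        report.null_sd[m] = float(nul.std(ddof=1))
    return report


def convergence_excess(
    net: DirectedNetwork,
    focal: str,
    params: SimParams,
    n_empirical: int,
    n_surrogates: int,
    base_seed: int,
) -> NullEnsembleReport:
    """Traffic excess of a node beyond its degree sequence.

    z of the node's metrics on ``net`` against degree-preserving rewired
    surrogates *of that same network*.  Applied to an empirical network
    it measures how much of the node's traffic is due to higher-order
    topology; applied to the direction-reversed network it tests whether
    the excess survives reversal.
    """
    return null_ensemble_report(
        net,
        focal,
        params,
        n_empirical,
        n_surrogates,
        base_seed,
        null_kind="rewired",
    )


# ---------------------------------------------------------------------------
# Phase regime mapping
# ---------------------------------------------------------------------------


@dataclass
class PhaseMap:
    """Steady/jammed classification over a grid of generation rates."""

    rates: list[float]
    regimes: list[str]
    slopes: list[float]
    mean_contents: list[float]
    capacity: float  # N * (K + 1), the absolute contents bound

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rate_gen": self.rates,
                "regime": self.regimes,
                "slope": self.slopes,
                "mean_total_contents": self.mean_contents,
            }
        )

    def transition_rate(self) -> float | None:
        """Smallest jammed rate, or None if no jammed point was found."""
        for r, reg in zip(self.rates, self.regimes):
            if reg == "jammed":
                return r
        return None


def _trend_is_significant(t: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """OLS slope of y on t with an AR(1)-corrected significance call.

    Total-contents series are strongly autocorrelated, so the plain OLS
    standard error of the slope is far too small; it is inflated by the
    usual AR(1) effective-sample-size factor sqrt((1+rho)/(1-rho))
    before asking whether the trend exceeds 3 standard errors.
    """
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (intercept + slope * t)
    n = y.size
    if n < 8 or resid.std() == 0:
        return float(slope), False
    rho = float(np.corrcoef(resid[:-1], resid[1:])[0, 1])
    rho = min(max(rho, -0.99), 0.99)
    tc = t - t.mean()
    se = resid.std(ddof=2) / np.sqrt(float(np.sum(tc**2)))
    se *= np.sqrt((1 + rho) / (1 - rho))
    return float(slope), bool(abs(slope) > 3 * se)


def phase_map(
    net: DirectedNetwork,
    rate_gens: list[float],
    params: SimParams,
    base_seed: int,
    slope_tol: float = 0.2,
    saturation_fraction: float = 0.9,
    sample_interval: float | None = None,
) -> PhaseMap:
    """Classify each generation rate as steady or jammed.

    A rate is *jammed* when the network has lost stationarity: either
    the post-transient mean total contents sit above
    ``saturation_fraction`` of the absolute capacity N(K+1) (every
    buffer essentially full — the terminal state of a jam), or total
    contents still climb through the window (positive trend that is both
    statistically significant under an AR(1) noise model and larger than
    ``slope_tol`` of the mean level over the window).  Everything else
    is steady.
    """
    if list(rate_gens) != sorted(rate_gens):
        raise ValueError("rate_gens must be sorted ascending")
    dt = sample_interval or params.duration / 2_000
    capacity = net.n_nodes * (params.buffer_capacity + 1)
    rates, regimes, slopes, means = [], [], [], []
    for r_idx, lam in enumerate(rate_gens):
        p = _with_seed(params, derive_seed(base_seed, "phase", r_idx))
        p = SimParams(**{**{k: getattr(p, k) for k in p.__dataclass_fields__}, "rate_gen": lam})
        res = simulate(net, p, sample_interval=dt)
        t, series = res.total_contents_series
        keep = t > p.transient_or_default()
        tw, yw = t[keep], series[keep].astype(float)
        mean_c = float(yw.mean())
        window = float(tw[-1] - tw[0])
        if tw.size > 2:
            slope, significant = _trend_is_significant(tw, yw)
        else:
            slope, significant = 0.0, False
        drift = slope * window  # signed: only growth indicates a jam
        saturated = mean_c > saturation_fraction * capacity
        climbing = significant and drift > slope_tol * max(mean_c, 1.0)
        rates.append(lam)
        regimes.append("jammed" if (saturated or climbing) else "steady")
        slopes.append(slope)
        means.append(mean_c)
    return PhaseMap(rates, regimes, slopes, means, capacity)
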