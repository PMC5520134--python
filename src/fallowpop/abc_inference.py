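"""Rejection-plus-regression approximate Bayesian computation.

The workflow mirrors the classic DIYABC pipeline: a reference table of
(scenario, parameters, summary statistics) rows is simulated from the
priors; the rows nearest the observed summary vector (Euclidean distance on
MAD-normalised statistics) are accepted; scenario posterior probabilities
come from the acceptance frequencies ("direct") and from a weighted
multinomial logistic regression of scenario on summary differences evaluated
at zero difference ("logistic"); parameter posteriors are sharpened by
local-linear regression adjustment, positive parameters on the log scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .coalescent_sim import (
    ParameterDraw,
    PriorSet,
    SampleConfig,
    ScenarioSpec,
    draw_parameters,
    simulate_dataset,
)
from .popgen_stats import SummaryVector, build_summary_vector

logger = logging.getLogger(__name__)

#: parameter columns adjusted on the log scale (all strictly positive)
PARAM_COLUMNS = ("n_iberia", "n_italia", "n_anatolia", "n_ancestral",
                 "t", "tb", "mean_msat_rate", "mtdna_rate")


@dataclass
class ReferenceTable:
    """Simulated (scenario, parameters, summaries) rows plus the robust
    per-statistic scale used to normalise distances."""

    params: pd.DataFrame             # scenario_id + PARAM_COLUMNS
    summaries: np.ndarray            # n_rows x n_stats
    names: tuple[str, ...]
    scale: np.ndarray                # MAD per statistic (retained ones)
    retained: np.ndarray             # boolean mask over names
    provenance: dict = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return self.summaries.shape[0]

    def normalised(self, values: np.ndarray) -> np.ndarray:
        return values[..., self.retained] / self.scale


def _mad(x: np.ndarray) -> np.ndarray:
    med = np.median(x, axis=0)
    return np.median(np.abs(x - med), axis=0)


def build_reference_table(scenarios: list[ScenarioSpec], priors: PriorSet,
                          n_sims: int, samples: SampleConfig,
                          seed: int, with_mtdna: bool = True,
                          stream_path=None) -> ReferenceTable:
    """Simulate a reference table with equal prior probability on scenarios.

    Statistics with zero median absolute deviation carry no distance
    information and are dropped (logged as a warning).  ``stream_path``
    additionally writes each (parameters, summaries) row as CSV while the
    table is being built, so long runs survive interruption.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be at least 1")
    rng = np.random.default_rng(seed)
    recs, rows = [], []
    names: tuple[str, ...] | None = None
    pops = [p for p, v in samples.msat_samples.items() if v > 0]
    if not with_mtdna and any(samples.mtdna_samples.values()):
        from dataclasses import replace as _replace
        samples = _replace(
            samples, mtdna_samples={k: 0 for k in samples.mtdna_samples})
    stream = open(stream_path, "w") if stream_path is not None else None
    try:
        for _ in range(n_sims):
            scenario = scenarios[rng.integers(len(scenarios))]
            draw = draw_parameters(priors, scenario, rng,
                                   n_loci=samples.n_loci)
            dataset, alignment = simulate_dataset(scenario, draw, samples,
                                                  rng)
            vec = build_summary_vector(dataset,
                                       alignment if with_mtdna else None,
                                       pops=pops)
            if names is None:
                names = vec.names
                if stream is not None:
                    header = list(draw.as_record()) + list(names)
                    stream.write(",".join(header) + "\n")
            recs.append(draw.as_record())
            rows.append(vec.values)
            if stream is not None:
                vals = list(recs[-1].values()) + vec.values.tolist()
                stream.write(",".join(repr(v) for v in vals) + "\n")
    finally:
        if stream is not None:
            stream.close()
    summaries = np.asarray(rows)
    scale = _mad(summaries)
    retained = scale > 0
    if not retained.all():
        dropped = [n for n, keep in zip(names, retained) if not keep]
        logger.warning("dropping %d zero-variance statistics: %s",
                       len(dropped), dropped[:10])
    return ReferenceTable(
        params=pd.DataFrame(recs),
        summaries=summaries,
        names=names,
        scale=scale[retained],
        retained=retained,
        provenance={"seed": seed, "n_sims": n_sims,
                    "generation_time_years": priors.generation_time_years},
    )


def nearest_records(observed: SummaryVector, table: ReferenceTable,
                    n_keep: int) -> np.ndarray:
    """Indices of the ``n_keep`` rows closest to the observation (Euclidean
    distance on MAD-normalised statistics; ties break on row index)."""
    if n_keep > table.n_rows:
        raise ValueError(f"n_keep={n_keep} exceeds table of {table.n_rows}")
    if tuple(observed.names) != tuple(table.names):
        raise ValueError("summary names do not match the reference table")
    z = table.normalised(table.summaries) - table.normalised(observed.values)
    d = np.sqrt((z * z).sum(axis=1))
    return np.argsort(d, kind="stable")[:n_keep]


def _distances(observed: SummaryVector, table: ReferenceTable,
               idx: np.ndarray) -> np.ndarray:
    z = (table.normalised(table.summaries[idx])
         - table.normalised(observed.values))
    return np.sqrt((z * z).sum(axis=1))


def _epanechnikov(d: np.ndarray) -> np.ndarray:
    dmax = d.max() * (1 + 1e-9) if d.size else 1.0
    if dmax == 0:
        return np.ones_like(d)
    return 1.0 - (d / dmax) ** 2


@dataclass
class ABCModelChoice:
    scenario_ids: list[int]
    direct: np.ndarray | None = None
    direct_ci: np.ndarray | None = None      # (k, 2)
    logistic: np.ndarray | None = None
    logistic_ci: np.ndarray | None = None
    n_closest: int = 0

    def to_frame(self) -> pd.DataFrame:
        rec = {"scenario": self.scenario_ids}
        if self.direct is not None:
            rec["direct"] = self.direct
            rec["direct_lo"] = self.direct_ci[:, 0]
            rec["direct_hi"] = self.direct_ci[:, 1]
        if self.logistic is not None:
            rec["logistic"] = self.logistic
            rec["logistic_lo"] = self.logistic_ci[:, 0]
            rec["logistic_hi"] = self.logistic_ci[:, 1]
        return pd.DataFrame(rec)


def direct_model_probabilities(scenario_ids: np.ndarray,
                               all_ids: list[int] | None = None
                               ) -> ABCModelChoice:
    """Scenario frequencies among accepted rows with binomial 95% CIs."""
    scenario_ids = np.asarray(scenario_ids)
    if scenario_ids.size == 0:
        raise ValueError("no accepted rows")
    ids = sorted(set(scenario_ids.tolist())
                 if all_ids is None else all_ids)
    n = scenario_ids.size
    probs, cis = [], []
    for sid in ids:
        p = float((scenario_ids == sid).mean())
        half = 1.96 * np.sqrt(max(p * (1 - p), 0.0) / n)
        probs.append(p)
        cis.append((max(p - half, 0.0), min(p + half, 1.0)))
    return ABCModelChoice(ids, direct=np.array(probs),
                          direct_ci=np.array(cis), n_closest=n)


# ---------------------------------------------------------------------------
# weighted multinomial logistic regression


def _softmax(eta: np.ndarray) -> np.ndarray:
    m = eta.max(axis=1, keepdims=True)
    e = np.exp(eta - m)
    return e / e.sum(axis=1, keepdims=True)


def _fit_weighted_multinomial(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                              ridge: float = 1e-6):
    """Weighted multinomial logit with intercept; class 0 is the reference.

    Returns (beta matrix (k-1, p+1), covariance of the flattened beta).
    """
    n, p = X.shape
    k = int(y.max()) + 1
    Xd = np.hstack([np.ones((n, 1)), X])
    pd_ = p + 1

    def unpack(theta):
        return theta.reshape(k - 1, pd_)

    def nll(theta):
        B = unpack(theta)
        eta = np.hstack([np.zeros((n, 1)), Xd @ B.T])
        m = eta.max(axis=1)
        lse = m + np.log(np.exp(eta - m[:, None]).sum(axis=1))
        ll = (w * (eta[np.arange(n), y] - lse)).sum()
        pen = 0.5 * ridge * (theta @ theta)
        P = _softmax(eta)
        G = np.empty((k - 1, pd_))
        for c in range(1, k):
            r = w * ((y == c).astype(float) - P[:, c])
            G[c - 1] = -(r[:, None] * Xd).sum(axis=0)
        return -ll + pen, G.ravel() + ridge * theta

    theta0 = np.zeros((k - 1) * pd_)
    res = optimize.minimize(nll, theta0, jac=True, method="L-BFGS-B",
                            options={"maxiter": 500})
    B = unpack(res.x)
    # observed information (weighted) for the delta-method CIs
    eta = np.hstack([np.zeros((n, 1)), Xd @ B.T])
    P = _softmax(eta)
    H = np.zeros(((k - 1) * pd_, (k - 1) * pd_))
    for c in range(1, k):
        for d in range(1, k):
            wcd = w * (P[:, c] * ((c == d) - P[:, d]))
            block = (Xd * wcd[:, None]).T @ Xd
            H[(c - 1) * pd_:(c) * pd_, (d - 1) * pd_:(d) * pd_] = block
    H += ridge * np.eye(H.shape[0])
    cov = np.linalg.pinv(H)
    return B, cov, res


def logistic_model_probabilities(observed: SummaryVector,
                                 table: ReferenceTable,
                                 n_fit: int) -> ABCModelChoice:
    """Scenario probabilities from a weighted multinomial logistic
    regression of scenario on normalised summary differences over the
    ``n_fit`` closest rows, evaluated at zero difference; Epanechnikov
    distance weights; delta-method CIs.  Complete separation (a divergent
    fit) falls back to the direct estimate with a warning."""
    idx = nearest_records(observed, table, n_fit)
    sids = table.params["scenario_id"].to_numpy()[idx].astype(int)
    ids = sorted(set(sids.tolist()))
    if len(ids) < 2:
        warnings.warn("fewer than 2 scenarios among closest rows; "
                      "falling back to direct estimate")
        return direct_model_probabilities(sids)
    d = _distances(observed, table, idx)
    w = _epanechnikov(d)
    X = (table.normalised(table.summaries[idx])
         - table.normalised(observed.values))
    y = np.array([ids.index(s) for s in sids])
    k = len(ids)
    # guard against overfitting: cap the design so the parameter count stays
    # well below the number of fitted rows (leading principal components)
    max_feats = max(1, n_fit // (3 * (k - 1)) - 1)
    if X.shape[1] > max_feats:
        from sklearn.decomposition import PCA

        # project onto leading directions without re-centring, so the
        # observation still sits at the origin of the reduced design
        W = PCA(n_components=max_feats, svd_solver="full").fit(X).components_
        X = X @ W.T
    B, cov, res = _fit_weighted_multinomial(X, y, w)
    if not np.isfinite(B).all() or np.abs(B).max() > 1e4:
        warnings.warn("logistic fit diverged (complete separation?); "
                      "falling back to direct estimate")
        mc = direct_model_probabilities(sids)
        return mc

    k = len(ids)
    pdim = X.shape[1] + 1
    intercepts = np.concatenate([[0.0], B[:, 0]])
    probs = _softmax(intercepts[None, :])[0]
    # delta method: dp/db0 for the intercept block only
    J = np.zeros((k, (k - 1) * pdim))
    for c in range(k):
        for m in range(1, k):
            J[c, (m - 1) * pdim] = probs[c] * ((c == m) - probs[m])
    pvar = np.clip(np.diag(J @ cov @ J.T), 0.0, None)
    half = 1.96 * np.sqrt(pvar)
    cis = np.stack([np.clip(probs - half, 0, 1),
                    np.clip(probs + half, 0, 1)], axis=1)
    return ABCModelChoice(ids, logistic=probs, logistic_ci=cis,
                          n_closest=n_fit)


def model_choice(observed: SummaryVector, table: ReferenceTable,
                 n_keep: int) -> ABCModelChoice:
    """Direct and logistic scenario probabilities on the same accepted set."""
    idx = nearest_records(observed, table, n_keep)
    sids = table.params["scenario_id"].to_numpy()[idx].astype(int)
    all_ids = sorted(set(table.params["scenario_id"].astype(int)))
    direct = direct_model_probabilities(sids, all_ids=all_ids)
    logistic = logistic_model_probabilities(observed, table, n_keep)
    merged = ABCModelChoice(all_ids, n_closest=n_keep)
    merged.direct = direct.direct
    merged.direct_ci = direct.direct_ci
    lg = np.zeros(len(all_ids))
    lgci = np.zeros((len(all_ids), 2))
    if logistic.logistic is not None:
        for i, sid in enumerate(logistic.scenario_ids):
            j = all_ids.index(sid)
            lg[j] = logistic.logistic[i]
            lgci[j] = logistic.logistic_ci[i]
    else:
        for i, sid in enumerate(logistic.scenario_ids):
            j = all_ids.index(sid)
            lg[j] = logistic.direct[i]
            lgci[j] = logistic.direct_ci[i]
    merged.logistic = lg
    merged.logistic_ci = lgci
    return merged


# ---------------------------------------------------------------------------
# parameter posteriors


@dataclass
class PosteriorSample:
    """Accepted and regression-adjusted parameter draws with weights."""

    parameters: list[str]
    raw: pd.DataFrame
    adjusted: pd.DataFrame
    weights: np.ndarray


def adjust_posterior(table: ReferenceTable, accepted: np.ndarray,
                     observed: SummaryVector,
                     parameters: tuple[str, ...] = PARAM_COLUMNS
                     ) -> PosteriorSample:
    """Local-linear regression adjustment of accepted parameter draws.

    Each parameter (log scale, all supports are positive) is regressed on
    the normalised summary differences with Epanechnikov weights; residuals
    are transported to the observation (zero difference).  A singular
    design falls back to a ridge-stabilised fit with a warning.
    """
    if accepted.size == 0:
        raise ValueError("no accepted rows")
    X = (table.normalised(table.summaries[accepted])
         - table.normalised(observed.values))
    if accepted.size < X.shape[1] + 1:
        warnings.warn("fewer accepted rows than statistics; adjustment will "
                      "be ridge-stabilised")
    d = np.sqrt((X * X).sum(axis=1))
    w = _epanechnikov(d)
    Xd = np.hstack([np.ones((X.shape[0], 1)), X])
    sw = np.sqrt(w)
    A = Xd * sw[:, None]
    cols = [p for p in parameters if p in table.params.columns]
    raw = table.params.iloc[accepted][cols].reset_index(drop=True)
    adj = {}
    for p in cols:
        y = raw[p].to_numpy(dtype=float)
        ok = np.isfinite(y)
        if not ok.any():
            adj[p] = y
            continue
        ly = np.log(np.clip(y[ok], 1e-300, None))
        Ao, Xo, swo = A[ok], Xd[ok], sw[ok]
        b, *_ = np.linalg.lstsq(Ao, ly * swo, rcond=None)
        if not np.isfinite(b).all():
            warnings.warn(f"singular design for {p}; using ridge fit")
            AtA = Ao.T @ Ao + 1e-8 * np.eye(Ao.shape[1])
            b = np.linalg.solve(AtA, Ao.T @ (ly * swo))
        out = np.full(y.shape, np.nan)
        out[ok] = np.exp(b[0] + (ly - Xo @ b))
        adj[p] = out
    return PosteriorSample(cols, raw, pd.DataFrame(adj), w)


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q) -> np.ndarray:
    order = np.argsort(x)
    x, w = x[order], w[order]
    cw = np.cumsum(w) - 0.5 * w
    cw /= w.sum()
    return np.interp(np.atleast_1d(q), cw, x)


def posterior_summary(sample: PosteriorSample,
                      generation_time_years: float = 1.0,
                      time_parameters: tuple[str, ...] = ("t", "tb")
                      ) -> pd.DataFrame:
    """Weighted median and central 95% interval per parameter; split times
    are reported in years (generations x generation time)."""
    if sample.adjusted.empty:
        raise ValueError("empty posterior sample")
    rows = []
    for p in sample.parameters:
        x = sample.adjusted[p].to_numpy(dtype=float)
        ok = np.isfinite(x)
        if not ok.any():
            rows.append({"parameter": p, "median": np.nan,
                         "q2.5": np.nan, "q97.5": np.nan})
            continue
        w = sample.weights[ok]
        lo, med, hi = _weighted_quantile(x[ok], w, [0.025, 0.5, 0.975])
        if p in time_parameters:
            lo, med, hi = (v * generation_time_years for v in (lo, med, hi))
        rows.append({"parameter": p, "median": med, "q2.5": lo, "q97.5": hi})
    return pd.DataFrame(rows)


def rescale_time(generations: float, generation_time_years: float) -> float:
    """Convert a split-time estimate from generations to years."""
    return generations * generation_time_years


# ---------------------------------------------------------------------------
# posterior predictive check


@dataclass
class FitReport:
    depth_percentile: float
    mahalanobis: float
    pc_observed: np.ndarray
    pc_predictive: np.ndarray


def posterior_predictive_check(observed: SummaryVector,
                               posterior: PosteriorSample,
                               scenario: ScenarioSpec,
                               samples: SampleConfig,
                               n_rep: int,
                               rng: np.random.Generator,
                               with_mtdna: bool = True,
                               generation_time_years: float = 1.0
                               ) -> FitReport:
    """Simulate datasets from the adjusted posterior, project the predictive
    summary cloud and the observation onto its first two principal
    components, and report where the observation sits (fraction of
    replicates at least as far from the cloud centre, by Mahalanobis
    distance in PC space)."""
    from sklearn.decomposition import PCA

    if n_rep < 10:
        raise ValueError("n_rep must be at least 10")
    draws = posterior.adjusted
    w = posterior.weights / posterior.weights.sum()
    pops = [p for p, v in samples.msat_samples.items() if v > 0]
    sims = []
    for _ in range(n_rep):
        row = draws.iloc[int(rng.choice(len(draws), p=w))]
        n_loci = samples.n_loci
        params = ParameterDraw(
            scenario_id=scenario.scenario_id,
            sizes={"iberia": row["n_iberia"], "italia": row["n_italia"],
                   "anatolia": row["n_anatolia"],
                   "ancestral": row["n_ancestral"]},
            t=None if scenario.is_trifurcation or np.isnan(row.get("t", np.nan))
            else float(row["t"]),
            tb=float(row["tb"]),
            msat_locus_rates=np.full(n_loci, row["mean_msat_rate"]),
            mtdna_rate=float(row["mtdna_rate"]),
            generation_time_years=generation_time_years,
        )
        if params.t is not None and params.t >= params.tb:
            params.t = 0.99 * params.tb
        ds, aln = simulate_dataset(scenario, params, samples, rng)
        sims.append(build_summary_vector(ds, aln if with_mtdna else None,
                                         pops=pops).values)
    sims = np.asarray(sims)
    keep = sims.std(axis=0) > 0
    pca = PCA(n_components=2)
    pcs = pca.fit_transform(sims[:, keep])
    obs_pc = pca.transform(observed.values[None, keep])[0]
    cov = np.cov(pcs.T) + 1e-12 * np.eye(2)
    icov = np.linalg.inv(cov)
    centre = pcs.mean(axis=0)

    def maha(v):
        dv = v - centre
        return float(np.sqrt(dv @ icov @ dv))

    d_obs = maha(obs_pc)
    d_rep = np.array([maha(v) for v in pcs])
    depth = float((d_rep >= d_obs).mean())
    return FitReport(depth, d_obs, obs_pc, pcs)
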