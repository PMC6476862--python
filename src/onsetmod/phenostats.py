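"""Descriptive analyses of the onset-age distribution.

Covers the three phenotype-level questions asked of a founder cohort
before any genetics: is the onset distribution a mixture of hidden
subgroups (univariate Gaussian-mixture EM with BIC model choice); how
do early and late onset split around the cohort mean (dichotomization
at 48 years, late inclusive); and do sex, education group or years of
education predict onset (two-sample t, one-way ANOVA, simple
regression).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .rng import substream


@dataclass
class MixtureFit:
    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    bic: float
    responsibilities: np.ndarray  # (n, k), rows sum to 1
    converged: bool
    n_iter: int
    seed: int

    def to_json_dict(self) -> dict:
        return {
            "k": self.k,
            "weights": [float(w) for w in self.weights],
            "means": [float(m) for m in self.means],
            "sds": [float(s) for s in self.sds],
            "loglik": float(self.loglik),
            "bic": float(self.bic),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
        }


def _em_once(y: np.ndarray, k: int, rng: np.random.Generator,
             var_floor: float, max_iter: int, tol: float):
    n = len(y)
    means = np.sort(rng.choice(y, size=k, replace=False).astype(float))
    sds = np.full(k, max(y.std(), np.sqrt(var_floor)))
    weights = np.full(k, 1.0 / k)
    ll_prev = -np.inf
    converged = False
    resp = np.full((n, k), 1.0 / k)
    log_2pi = np.log(2 * np.pi)
    for it in range(1, max_iter + 1):
        z = (y[:, None] - means[None, :]) / sds[None, :]
        logpdf = (-0.5 * z * z - np.log(sds)[None, :] - 0.5 * log_2pi
                  + np.log(weights)[None, :])
        mx = logpdf.max(axis=1, keepdims=True)
        dens = np.exp(logpdf - mx)
        tot = dens.sum(axis=1, keepdims=True)
        resp = dens / tot
        ll = float(np.sum(mx.ravel() + np.log(tot.ravel())))
        # EM guarantees monotone log-likelihood; enforce as an invariant
        assert ll >= ll_prev - 1e-8, "EM log-likelihood decreased"
        if ll - ll_prev < tol:
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
        nk = resp.sum(axis=0)
        weights = nk / n
        means = (resp * y[:, None]).sum(axis=0) / nk
        var = (resp * (y[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.sqrt(np.maximum(var, var_floor))
    order = np.argsort(means)
    return weights[order], means[order], sds[order], ll_prev, resp[:, order], converged, it


def fit_mixture(
    adaoo: np.ndarray,
    k: int,
    n_starts: int = 20,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-7,
) -> MixtureFit:
    """Fit a k-component univariate Gaussian mixture by EM.

    Multiple random restarts (seed-expanded substreams), best
    log-likelihood kept; variances floored at (0.01 * sd(y))² to block
    degenerate spikes; components reported sorted by mean.  k = 1 is
    the closed-form MLE.  BIC (3k - 1 free parameters) is reported for
    model choice across k.
    """
    y = np.asarray(adaoo, dtype=float)
    n = len(y)
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < 2 * k:
        raise ValueError(f"need at least {2 * k} observations for k={k}")
    if k == 1:
        mu, sd = float(y.mean()), float(y.std())  # MLE sd (ddof=0)
        ll = float(stats.norm.logpdf(y, mu, sd).sum())
        bic = -2 * ll + 2 * np.log(n)
        return MixtureFit(1, np.array([1.0]), np.array([mu]), np.array([sd]),
                          ll, bic, np.ones((n, 1)), True, 0, seed)
    var_floor = (0.01 * y.std()) ** 2
    best = None
    for s in range(n_starts):
        rng = substream(seed, "mixture", k, s)
        out = _em_once(y, k, rng, var_floor, max_iter, tol)
        if best is None or out[3] > best[3]:
            best = out
    weights, means, sds, ll, resp, converged, n_iter = best
    bic = -2 * ll + (3 * k - 1) * np.log(n)
    if not converged:
        import warnings

        warnings.warn("mixture EM did not converge in any start; "
                      "returning best partial fit", stacklevel=2)
    return MixtureFit(k, weights, means, sds, ll, bic, resp, converged, n_iter, seed)


def select_mixture(adaoo: np.ndarray, k_values=(1, 2, 3), n_starts: int = 20,
                   seed: int = 0) -> tuple[MixtureFit, dict[int, float]]:
    """Fit each k and return the BIC-best fit plus the BIC table."""
    fits = {k: fit_mixture(adaoo, k, n_starts=n_starts, seed=seed) for k in k_values}
    bics = {k: f.bic for k, f in fits.items()}
    best_k = min(bics, key=bics.get)
    return fits[best_k], bics


@dataclass
class OnsetDichotomy:
    labels: pd.Series  # 'early' / 'late'
    cutoff: float
    summary: pd.DataFrame  # per-group n, mean, sd
    comparison: "GroupComparison | None"


@dataclass
class GroupComparison:
    test: str
    statistic: float
    df: float | tuple
    p: float
    effect: dict


def dichotomize_onset(adaoo: np.ndarray, cutoff: float = 48.0) -> OnsetDichotomy:
    """Split onset at the cutoff: early < cutoff <= late (late inclusive).

    Returns labels, per-group n/mean/sd, and a two-sample comparison
    (omitted when one group is empty).
    """
    y = np.asarray(adaoo, dtype=float)
    if not (y.min() <= cutoff <= y.max()):
        raise ValueError("cutoff outside the data range")
    labels = pd.Series(np.where(y < cutoff, "early", "late"))
    rows = []
    for lab in ("early", "late"):
        v = y[labels == lab]
        rows.append({"group": lab, "n": len(v),
                     "mean": float(v.mean()) if len(v) else np.nan,
                     "sd": float(v.std(ddof=1)) if len(v) > 1 else np.nan})
    summary = pd.DataFrame(rows).set_index("group")
    early, late = y[labels == "early"], y[labels == "late"]
    comp = None
    if len(early) >= 2 and len(late) >= 2:
        comp = group_tests_two_sample(early, late)
    return OnsetDichotomy(labels, cutoff, summary, comp)


def group_tests_two_sample(g1: np.ndarray, g2: np.ndarray,
                           pooled: bool = True) -> GroupComparison:
    """Two-sample t test on onset (pooled variance by default).

    Pooled df = n1 + n2 - 2 matches the classical bookkeeping; Welch
    available with ``pooled=False``.  Returns the mean difference with
    a 95% CI.
    """
    g1 = np.asarray(g1, float)
    g2 = np.asarray(g2, float)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need >= 2 observations per group")
    if g1.std() == 0 and g2.std() == 0:
        if float(g1.mean()) == float(g2.mean()):
            return GroupComparison("two-sample t (pooled)", 0.0,
                                   len(g1) + len(g2) - 2, 1.0,
                                   {"mean_diff": 0.0, "ci": (0.0, 0.0),
                                    "note": "degenerate variance"})
        raise ValueError("degenerate variance: both groups constant but unequal")
    res = stats.ttest_ind(g1, g2, equal_var=pooled)
    n1, n2 = len(g1), len(g2)
    diff = float(g1.mean() - g2.mean())
    if pooled:
        df = n1 + n2 - 2
        sp2 = (((n1 - 1) * g1.var(ddof=1) + (n2 - 1) * g2.var(ddof=1)) / df)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        name = "two-sample t (pooled)"
    else:
        df = float(res.df)
        se = np.sqrt(g1.var(ddof=1) / n1 + g2.var(ddof=1) / n2)
        name = "two-sample t (Welch)"
    tcrit = stats.t.ppf(0.975, df)
    return GroupComparison(name, float(res.statistic), df, float(res.pvalue),
                           {"mean_diff": diff,
                            "ci": (diff - tcrit * se, diff + tcrit * se)})


def group_tests(phenotypes: pd.DataFrame, design: str,
                pooled: bool = True, carrier: np.ndarray | None = None) -> GroupComparison:
    """Phenotype-level association test chosen by ``design``.

    design='sex' or 'carrier': two-sample t on onset; 'edu_group':
    one-way ANOVA across education groups; 'edu_years': OLS of onset on
    years of education (slope, R², p).
    """
    y = phenotypes["adaoo"].to_numpy(dtype=float)
    if design == "sex":
        g = phenotypes["sex"].to_numpy()
        return group_tests_two_sample(y[g == "F"], y[g == "M"], pooled=pooled)
    if design == "carrier":
        if carrier is None:
            raise ValueError("design='carrier' requires a carrier flag vector")
        carrier = np.asarray(carrier, dtype=bool)
        return group_tests_two_sample(y[carrier], y[~carrier], pooled=pooled)
    if design == "edu_group":
        groups = [y[phenotypes["edu_group"] == lv]
                  for lv in phenotypes["edu_group"].cat.categories
                  if (phenotypes["edu_group"] == lv).sum() >= 2]
        if len(groups) < 2:
            raise ValueError("need >= 2 education groups with >= 2 observations")
        f, p = stats.f_oneway(*groups)
        k = len(groups)
        n = sum(len(g) for g in groups)
        return GroupComparison("one-way ANOVA", float(f), (k - 1, n - k), float(p),
                               {"group_means": [float(g.mean()) for g in groups]})
    if design == "edu_years":
        x = phenotypes["edu_years"].to_numpy(dtype=float)
        if len(x) < 3:
            raise ValueError("need >= 3 points for regression")
        if x.std() == 0:
            raise ValueError("degenerate predictor: edu_years is constant")
        res = stats.linregress(x, y)
        return GroupComparison("simple linear regression", float(res.slope) / max(res.stderr, 1e-300),
                               len(x) - 2, float(res.pvalue),
                               {"slope": float(res.slope), "r2": float(res.rvalue ** 2)})
    raise ValueError(f"unknown design {design!r}")
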