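"""Kinship-corrected association models for age of onset.

The workhorse is a linear mixed model

    y = X b + u + e,   u ~ N(0, sigma_g2 * K),   e ~ N(0, sigma_e2 * I)

fitted by REML after a single spectral decomposition of the kinship
matrix K: with K = U L U', the profile (restricted) likelihood is a
one-dimensional function of the variance ratio delta = sigma_e2 /
sigma_g2, and every evaluation reduces to a weighted least-squares
solve in the rotated coordinates U'y, U'X.  Coefficient tests are Wald
t-tests; because plug-in variance components make the naive
n - rank(X) reference anticonservative in small related samples, the
denominator degrees of freedom default to the Satterthwaite
approximation computed from the REML information matrix (exact
residual df is used when the components are supplied as known).

On top of the fitter sit the single-locus scan under a chosen genetic
coding, Benjamini-Hochberg and extreme-value multiple-testing
adjustments, stepwise forward/backward multi-locus model selection,
variance-explained accounting, and covariate-specificity
(heterogeneity) likelihood-ratio tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

from .coding import code_genotype
from .containers import EmptyPanelError, GenotypeMatrix, KinshipMatrix, check_phenotypes
from .qc import estimate_frequencies
from .rng import substream

_LOG2PI = np.log(2 * np.pi)


# ---------------------------------------------------------------------------
# Design construction


def build_design(
    phenotypes: pd.DataFrame,
    covariates: tuple[str, ...] = ("sex", "edu_years"),
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Return (y, X, names) for the fixed-effect design.

    ``sex`` enters as an indicator for male (female reference);
    ``edu_years`` as a continuous covariate; ``edu_group`` as dummy
    columns against the lowest level.  An intercept is always first.
    """
    phen = check_phenotypes(phenotypes)
    y = phen["adaoo"].to_numpy(dtype=float)
    cols = [np.ones(len(phen))]
    names = ["intercept"]
    for cov in covariates:
        if cov == "sex":
            cols.append((phen["sex"] == "M").to_numpy(dtype=float))
            names.append("sex[M]")
        elif cov == "edu_years":
            cols.append(phen["edu_years"].to_numpy(dtype=float))
            names.append("edu_years")
        elif cov == "edu_group":
            levels = [lv for lv in phen["edu_group"].cat.categories]
            for lv in levels[1:]:
                cols.append((phen["edu_group"] == lv).to_numpy(dtype=float))
                names.append(f"edu_group[{lv}]")
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    return y, np.column_stack(cols), names


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via pivoted QR diagnostics
        from scipy.linalg import qr as _qr

        _, R, piv = _qr(X, pivoting=True)
        diag = np.abs(np.diag(R))
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] < 1e-10 * diag[0]]
        bad += [names[p] for p in piv[len(diag):]]
        raise ValueError(f"rank-deficient fixed-effect design; collinear columns: {bad}")


# ---------------------------------------------------------------------------
# REML fitter


@dataclass
class LMEMFit:
    beta: np.ndarray
    se_beta: np.ndarray
    p_values: np.ndarray
    names: list[str]
    sigma_g2: float
    sigma_e2: float
    pseudo_h2: float
    loglik_reml: float
    loglik_ml: float
    n_used: int
    delta: float  # sigma_e2 / sigma_g2 at the optimum
    df: np.ndarray | None = None  # per-coefficient denominator df

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta": self.beta, "se": self.se_beta, "p": self.p_values},
            index=self.names,
        )


def _eig_kinship(K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lam, U = np.linalg.eigh(K)
    return np.clip(lam, 0.0, None), U


def _profile(delta: float, lam: np.ndarray, yt: np.ndarray, Xt: np.ndarray,
             logdet_xx: float) -> dict:
    """Profile quantities at a fixed variance ratio delta = s_e2/s_g2."""
    n, p = Xt.shape
    w = lam + delta
    Xw = Xt / w[:, None]
    XtWX = Xt.T @ Xw
    beta = np.linalg.solve(XtWX, Xw.T @ yt)
    r = yt - Xt @ beta
    rss = float(np.sum(r * r / w))
    sg2_reml = rss / (n - p)
    sg2_ml = rss / n
    sum_logw = float(np.sum(np.log(w)))
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    ll_reml = -0.5 * ((n - p) * (_LOG2PI + np.log(sg2_reml) + 1.0)
                      + sum_logw + logdet_xwx - logdet_xx)
    ll_ml = -0.5 * (n * (_LOG2PI + np.log(sg2_ml) + 1.0) + sum_logw)
    return dict(beta=beta, rss=rss, sg2_reml=sg2_reml, sg2_ml=sg2_ml,
                XtWX=XtWX, ll_reml=ll_reml, ll_ml=ll_ml, w=w)


def _small_sample_adjust(lam: np.ndarray, Xt: np.ndarray, sg2: float, se2: float,
                         n: int, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Kenward-Roger-type covariance adjustment and Satterthwaite df.

    Plug-in REML variance components understate Cov(beta_hat) and make
    naive residual-df t-tests anticonservative in small related
    samples.  In the rotated basis V = diag(sg2*lam + se2), so the REML
    projection matrix and the information matrix of (sg2, se2) need
    only elementwise O(n^2 p) work.  Returns (adjusted covariance of
    beta_hat, per-coefficient Satterthwaite df).
    """
    d = sg2 * lam + se2
    Dinv = 1.0 / d
    XD = Xt * Dinv[:, None]
    Phi = np.linalg.inv(Xt.T @ XD)  # plug-in Cov(beta_hat)
    Pm = np.diag(Dinv) - XD @ Phi @ XD.T
    P2 = Pm * Pm
    info = 0.5 * np.array([
        [(lam[:, None] * lam[None, :] * P2).sum(), (lam[:, None] * P2).sum()],
        [(lam[None, :] * P2).sum(), P2.sum()],
    ])
    W = np.linalg.pinv(info)  # approx Cov of (sg2_hat, se2_hat)
    vdiags = (lam, np.ones(n))
    Pmat = [(XD * v[:, None]).T @ XD for v in vdiags]
    Qmat = [[(XD * (vi * vj * Dinv)[:, None]).T @ XD for vj in vdiags]
            for vi in vdiags]
    # Kackar-Harville correction (V linear in the components, so the
    # second-derivative terms vanish)
    Lam = np.zeros((p, p))
    for i in range(2):
        for j in range(2):
            Lam += W[i, j] * (Qmat[i][j] - Pmat[i] @ Phi @ Pmat[j])
    Phi_adj = Phi + 2.0 * Phi @ Lam @ Phi
    dfs = np.empty(p)
    for c in range(p):
        v = Phi_adj[c, c]
        g = np.array([(Phi @ Pmat[i] @ Phi)[c, c] for i in range(2)])
        var_v = float(g @ W @ g)
        dfs[c] = 2.0 * v * v / var_v if var_v > 0 else n - p
    return Phi_adj, np.clip(dfs, 1.0, n - p)


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray | KinshipMatrix | None = None,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
    names: list[str] | None = None,
    fix_components: tuple[float, float] | None = None,
    df_method: str = "satterthwaite",
) -> LMEMFit:
    """REML fit of the one-random-effect mixed model.

    Pass ``eig = (eigenvalues, eigenvectors)`` of K to amortize the
    decomposition across a scan.  ``fix_components = (sigma_g2,
    sigma_e2)`` skips estimation and returns the GLS solution at the
    given variance components (used by oracle tests).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if len(y) != n:
        raise ValueError("y and X are not aligned")
    names = names or [f"x{j}" for j in range(p)]
    _check_rank(X, names)
    if eig is None:
        if K is None:
            raise ValueError("provide K or its eigendecomposition")
        Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
        if Kv.shape != (n, n):
            raise ValueError("kinship matrix is not aligned with y")
        eig = _eig_kinship(Kv)
    lam, U = eig
    yt = U.T @ y
    Xt = U.T @ X
    _, logdet_xx = np.linalg.slogdet(Xt.T @ Xt)

    if fix_components is not None:
        sg2, se2 = fix_components
        if sg2 < 0 or se2 <= 0:
            raise ValueError("fixed components require sigma_g2 >= 0, sigma_e2 > 0")
        v = sg2 * lam + se2  # eigenvalues of V = sg2*K + se2*I
        Xw = Xt / v[:, None]
        XtVX = Xt.T @ Xw
        beta = np.linalg.solve(XtVX, Xw.T @ yt)
        r = yt - Xt @ beta
        quad = float(np.sum(r * r / v))
        sum_logv = float(np.sum(np.log(v)))
        _, logdet_xvx = np.linalg.slogdet(XtVX)
        ll_ml = -0.5 * (n * _LOG2PI + sum_logv + quad)
        ll_reml = -0.5 * ((n - p) * _LOG2PI + sum_logv + quad
                          + logdet_xvx - logdet_xx)
        cov = np.linalg.inv(XtVX)
        se = np.sqrt(np.diag(cov))
        # components known -> exact GLS, residual df applies
        pvals = 2 * stats.t.sf(np.abs(beta / se), df=n - p)
        h2 = sg2 / (sg2 + se2)
        delta = se2 / sg2 if sg2 > 0 else np.inf
        return LMEMFit(beta, se, pvals, names, sg2, se2, h2,
                       ll_reml, ll_ml, n, float(delta),
                       df=np.full(p, float(n - p)))

    # profile REML over log10(delta): coarse grid, then local refinement
    grid = np.linspace(-4.0, 4.0, 17)
    nll = [-_profile(10.0 ** g, lam, yt, Xt, logdet_xx)["ll_reml"] for g in grid]
    i0 = int(np.argmin(nll))
    lo = grid[max(i0 - 1, 0)]
    hi = grid[min(i0 + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda g: -_profile(10.0 ** g, lam, yt, Xt, logdet_xx)["ll_reml"],
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6},
    )
    g_opt = res.x if res.fun <= min(nll) else grid[i0]
    delta = float(10.0 ** g_opt)
    prof = _profile(delta, lam, yt, Xt, logdet_xx)
    sg2 = prof["sg2_reml"]
    se2 = delta * sg2
    if df_method == "satterthwaite":
        cov, dfs = _small_sample_adjust(lam, Xt, sg2, se2, n, p)
    elif df_method == "residual":
        cov = np.linalg.inv(prof["XtWX"]) * sg2
        dfs = np.full(p, float(n - p))
    else:
        raise ValueError(f"unknown df_method {df_method!r}")
    se = np.sqrt(np.diag(cov))
    tstat = prof["beta"] / se
    pvals = 2 * stats.t.sf(np.abs(tstat), df=dfs)
    h2 = 1.0 / (1.0 + delta)
    return LMEMFit(prof["beta"], se, pvals, names, sg2, se2, h2,
                   prof["ll_reml"], prof["ll_ml"], n, delta, df=dfs)


# ---------------------------------------------------------------------------
# Multiple-testing adjustments


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN passed through).

    adjusted p_(i) = min_{j >= i} min(1, m * p_(j) / j) over the sorted
    p-values; implemented directly so the output agrees with the
    step-up definition bit-for-bit.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.sum() == 0:
        return out
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(pv)
    order = np.argsort(pv, kind="stable")
    stepup = np.minimum(1.0, pv[order] * m / np.arange(1, m + 1))
    stepup = np.minimum.accumulate(stepup[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = stepup
    out[ok] = adj
    return out


@dataclass
class EVTAdjustment:
    p_adjusted: np.ndarray
    p_empirical: np.ndarray
    maxima: np.ndarray
    gev_params: tuple[float, float, float] | None
    converged: bool
    n_perm: int


def _marker_t_stats(yt_cols: np.ndarray, Gt: np.ndarray, X0t: np.ndarray,
                    w: np.ndarray, df_resid: int) -> np.ndarray:
    """Wald-type t statistics for each marker column against each phenotype
    column, with covariates partialled out under the 1/w GLS metric."""
    s = 1.0 / np.sqrt(w)
    Ys = yt_cols * s[:, None]
    Gs = Gt * s[:, None]
    X0s = X0t * s[:, None]
    Q, _ = np.linalg.qr(X0s)
    Yr = Ys - Q @ (Q.T @ Ys)
    Gr = Gs - Q @ (Q.T @ Gs)
    gnorm2 = np.sum(Gr * Gr, axis=0)
    gnorm2 = np.where(gnorm2 <= 0, np.nan, gnorm2)
    A = Gr.T @ Yr                      # (m, k) inner products
    yy = np.sum(Yr * Yr, axis=0)       # (k,)
    T = A / np.sqrt(gnorm2)[:, None]
    resid2 = np.clip(yy[None, :] - T**2, 1e-12, None)
    return T / np.sqrt(resid2 / df_resid)


def evt_adjust(
    y: np.ndarray,
    X0: np.ndarray,
    G: np.ndarray,
    K: np.ndarray | None = None,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> EVTAdjustment:
    """Extreme-value multiple-testing adjustment by residual permutation.

    Covariate-model residuals are permuted across samples; each
    permutation records the maximum absolute marker t statistic over
    the panel (variance components held at the covariate-only REML
    estimates).  A generalized-extreme-value distribution fitted to the
    maxima supplies the adjusted upper-tail probability of each
    observed statistic; if the GEV fit fails, the empirical permutation
    p is used and flagged.
    """
    if n_perm < 200:
        raise ValueError("n_perm must be >= 200")
    y = np.asarray(y, dtype=float)
    X0 = np.atleast_2d(np.asarray(X0, dtype=float))
    G = np.atleast_2d(np.asarray(G, dtype=float))
    n, p0 = X0.shape
    if eig is None:
        eig = _eig_kinship(np.asarray(K, dtype=float))
    lam, U = eig
    null = reml_fit(y, X0, eig=eig)
    w = lam + null.delta
    # GLS residuals of the covariate-only model, permuted in sample space
    e = y - X0 @ null.beta
    fitted = X0 @ null.beta
    rng = substream(seed, "evt")
    perms = np.array([rng.permutation(n) for _ in range(n_perm)]).T  # (n, n_perm)
    Ystar = fitted[:, None] + e[perms]
    Yall = np.column_stack([y, Ystar])
    Yt = U.T @ Yall
    Gt = U.T @ G
    X0t = U.T @ X0
    T = _marker_t_stats(Yt, Gt, X0t, w, df_resid=n - p0 - 1)
    t_obs = np.abs(T[:, 0])
    maxima = np.nanmax(np.abs(T[:, 1:]), axis=0)
    p_emp = (1.0 + np.sum(maxima[None, :] >= t_obs[:, None], axis=1)) / (n_perm + 1.0)
    gev_params, converged = None, False
    p_adj = p_emp.copy()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            c, loc, scale = stats.genextreme.fit(maxima)
        if np.isfinite([c, loc, scale]).all() and scale > 0:
            sf = stats.genextreme.sf(t_obs, c, loc=loc, scale=scale)
            if np.isfinite(sf).all():
                gev_params, converged = (float(c), float(loc), float(scale)), True
                # GEV extrapolates below the empirical floor; never exceed it
                p_adj = np.minimum(sf, p_emp)
    except Exception:
        warnings.warn("GEV fit to permutation maxima failed; "
                      "falling back to empirical permutation p-values", stacklevel=2)
    p_adj = np.clip(p_adj, 0.0, 1.0)
    return EVTAdjustment(p_adj, p_emp, maxima, gev_params, converged, n_perm)


# ---------------------------------------------------------------------------
# Single-locus scan


@dataclass
class ScanResult:
    table: pd.DataFrame
    coding: str
    reference: str
    covariates: tuple[str, ...]
    n_samples: int
    evt: EVTAdjustment | None = None


def single_locus_scan(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    K: KinshipMatrix,
    coding: str = "dominant",
    reference: str = "minor",
    covariates: tuple[str, ...] = ("sex", "edu_years"),
    evt_perms: int = 0,
    seed: int = 0,
) -> ScanResult:
    """Marker-by-marker mixed-model association scan.

    Each marker is coded per the genetic model, samples missing at that
    marker are dropped for that marker only, and the marker term is
    added to the covariate design.  Markers whose coded genotype is
    constant in the analyzed subsample get NA statistics and a reason.
    Raw p-values are FDR-adjusted over the scan; an extreme-value
    adjustment is appended when ``evt_perms > 0``.
    """
    if genotypes.n_markers == 0:
        raise EmptyPanelError("no markers in panel (did QC remove everything?)")
    phen = check_phenotypes(phenotypes)
    if list(phen["sample_id"]) != list(genotypes.samples):
        raise ValueError("phenotype sample order does not match genotype samples")
    K = K.align(genotypes.samples)
    y, X0, names0 = build_design(phen, covariates)
    eig_full = _eig_kinship(K.values)
    freqs = estimate_frequencies(genotypes)

    rows = []
    complete_cols = []
    complete_idx = []
    for j, mk in enumerate(genotypes.markers):
        g = genotypes.dosage[:, j]
        code = code_genotype(g, coding, reference)
        okmask = ~np.isnan(code)
        row = dict(
            chr=mk.chrom, snp=mk.id, pos=mk.pos, gene=mk.gene or "",
            ref_alt=f"{mk.ref_allele}/{mk.alt_allele}",
            ma_freq=float(freqs.iloc[j]["maf"]),
            call_rate=float(np.mean(okmask)),
            coding=coding, n_used=int(okmask.sum()),
            beta=np.nan, se=np.nan, p=np.nan, note="",
        )
        if okmask.sum() < X0.shape[1] + 2 or np.nanstd(code[okmask]) == 0:
            row["note"] = "constant_coded_genotype" if okmask.sum() else "all_missing"
            rows.append(row)
            continue
        if okmask.all():
            eig = eig_full
            ysub, Xsub = y, np.column_stack([X0, code])
        else:
            sub = np.flatnonzero(okmask)
            eig = _eig_kinship(K.values[np.ix_(sub, sub)])
            ysub = y[sub]
            Xsub = np.column_stack([X0[sub], code[sub]])
        try:
            fit = reml_fit(ysub, Xsub, eig=eig, names=names0 + [mk.id])
        except ValueError as exc:
            row["note"] = f"fit_failed:{exc}"
            rows.append(row)
            continue
        row.update(beta=fit.beta[-1], se=fit.se_beta[-1], p=fit.p_values[-1])
        rows.append(row)
        if okmask.all():
            complete_cols.append(code)
            complete_idx.append(len(rows) - 1)

    table = pd.DataFrame(rows)
    table["p_fdr"] = fdr_adjust(table["p"].to_numpy())
    table["p_evt"] = np.nan
    evt = None
    if evt_perms > 0 and complete_cols:
        evt = evt_adjust(y, X0, np.column_stack(complete_cols), eig=eig_full,
                         n_perm=evt_perms, seed=seed)
        raw = table.loc[complete_idx, "p"].to_numpy()
        table.loc[complete_idx, "p_evt"] = np.maximum(evt.p_adjusted, raw)
    return ScanResult(table, coding, reference, tuple(covariates), genotypes.n_samples, evt)


# ---------------------------------------------------------------------------
# Multi-locus stepwise selection


@dataclass
class MultiLocusModel:
    markers: list[str]
    coding: str
    reference: str
    fit: LMEMFit | None
    beta: dict[str, float]
    se: dict[str, float]
    p: dict[str, float]
    pve_per_marker: dict[str, float]
    total_pve: float
    trace: list[dict]
    criterion: str
    n_samples: int

    def to_json_dict(self) -> dict:
        return {
            "markers": self.markers,
            "coding": self.coding,
            "reference": self.reference,
            "beta": self.beta,
            "se": self.se,
            "p": self.p,
            "pve_per_marker": self.pve_per_marker,
            "total_pve": self.total_pve,
            "pseudo_h2": self.fit.pseudo_h2 if self.fit else None,
            "sigma_g2": self.fit.sigma_g2 if self.fit else None,
            "sigma_e2": self.fit.sigma_e2 if self.fit else None,
            "trace": self.trace,
            "criterion": self.criterion,
            "n_samples": self.n_samples,
        }


def _ebic(ll: float, k: int, n: int, m: int, gamma: float) -> float:
    pen = k * np.log(n)
    if 0 < k <= m:
        pen += 2.0 * gamma * (gammaln(m + 1) - gammaln(k + 1) - gammaln(m - k + 1))
    return -2.0 * ll + pen


def multilocus_select(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    K: KinshipMatrix,
    coding: str = "dominant",
    reference: str = "minor",
    covariates: tuple[str, ...] = ("sex", "edu_years"),
    max_steps: int = 10,
    criterion: str = "ebic",
    ebic_gamma: float = 0.5,
) -> MultiLocusModel:
    """Forward/backward stepwise multi-locus mixed model.

    Each step adds the marker that most improves the selection
    criterion (extended BIC on the ML profile likelihood by default),
    then removes any included marker whose exclusion improves it.
    Stops after ``max_steps`` forward additions or when no admissible
    move remains.  Coded-genotype columns collinear with the current
    design are skipped (ties broken by input marker order).  Missing
    coded genotypes are mean-imputed during the search; the reported
    final fit (joint REML, Wald tests, PVE accounting) uses complete
    cases for the selected markers.
    """
    if genotypes.n_markers == 0:
        raise EmptyPanelError("no markers in panel")
    if criterion != "ebic":
        raise ValueError(f"unknown selection criterion {criterion!r}")
    phen = check_phenotypes(phenotypes)
    if list(phen["sample_id"]) != list(genotypes.samples):
        raise ValueError("phenotype sample order does not match genotype samples")
    K = K.align(genotypes.samples)
    y, X0, names0 = build_design(phen, covariates)
    n, m = genotypes.n_samples, genotypes.n_markers
    eig = _eig_kinship(K.values)

    C = np.empty((n, m))
    usable = np.ones(m, dtype=bool)
    for j in range(m):
        col = code_genotype(genotypes.dosage[:, j], coding, reference)
        nan = np.isnan(col)
        if nan.all() or np.nanstd(col) == 0:
            usable[j] = False
            C[:, j] = 0.0
            continue
        if nan.any():
            col = np.where(nan, np.nanmean(col), col)
        C[:, j] = col

    def crit_of(sel: list[int]) -> float:
        X = np.column_stack([X0] + [C[:, j] for j in sel]) if sel else X0
        # selection only consumes the ML log-likelihood; skip df corrections
        fit = reml_fit(y, X, eig=eig, df_method="residual",
                       names=names0 + [genotypes.markers[j].id for j in sel])
        return _ebic(fit.loglik_ml, len(sel), n, m, ebic_gamma)

    def collinear(j: int, sel: list[int]) -> bool:
        X = np.column_stack([X0] + [C[:, k] for k in sel])
        g = C[:, j]
        resid = g - X @ np.linalg.lstsq(X, g, rcond=None)[0]
        return float(resid @ resid) < 1e-10 * float(g @ g + 1.0)

    selected: list[int] = []
    trace: list[dict] = []
    current = crit_of(selected)
    for step in range(max_steps):
        best_j, best_c = None, current - 1e-9
        for j in range(m):
            if not usable[j] or j in selected or collinear(j, selected):
                continue
            c = crit_of(selected + [j])
            if c < best_c - 1e-12:
                best_j, best_c = j, c
        if best_j is None:
            break
        selected.append(best_j)
        current = best_c
        trace.append({"action": "add", "marker": genotypes.markers[best_j].id,
                      "criterion": float(current)})
        # backward sweep
        changed = True
        while changed and len(selected) > 1:
            changed = False
            for j in list(selected):
                cand = [k for k in selected if k != j]
                c = crit_of(cand)
                if c < current - 1e-9:
                    selected = cand
                    current = c
                    trace.append({"action": "drop",
                                  "marker": genotypes.markers[j].id,
                                  "criterion": float(current)})
                    changed = True
                    break

    if not selected:
        return MultiLocusModel([], coding, reference, None, {}, {}, {}, {}, 0.0,
                               trace, criterion, n)

    ids = [genotypes.markers[j].id for j in selected]
    raw = np.column_stack(
        [code_genotype(genotypes.dosage[:, j], coding, reference) for j in selected]
    )
    ok = ~np.isnan(raw).any(axis=1)
    sub = np.flatnonzero(ok)
    eig_sub = eig if ok.all() else _eig_kinship(K.values[np.ix_(sub, sub)])
    Xj = np.column_stack([X0[sub], raw[sub]])
    fit = reml_fit(y[sub], Xj, eig=eig_sub, names=names0 + ids)
    k0 = X0.shape[1]
    beta = {mid: float(fit.beta[k0 + i]) for i, mid in enumerate(ids)}
    se = {mid: float(fit.se_beta[k0 + i]) for i, mid in enumerate(ids)}
    pv = {mid: float(fit.p_values[k0 + i]) for i, mid in enumerate(ids)}
    pve_marker, total = pve(raw[sub], ids, y[sub], X0[sub])
    return MultiLocusModel(ids, coding, reference, fit, beta, se, pv,
                           pve_marker, total, trace, criterion, n)


def pve(
    codes: np.ndarray,
    marker_ids: list[str],
    y: np.ndarray,
    X_covariates: np.ndarray,
) -> tuple[dict[str, float], float]:
    """Variance explained per marker (sequential) and jointly.

    The phenotype is first residualized on the covariates; markers then
    enter in selection order, each credited with the reduction in
    residual variance it achieves given the earlier markers, expressed
    as a fraction of the covariate-adjusted phenotypic variance.  The
    total is the joint R² of all coded marker terms, which the
    sequential shares sum to exactly.
    """
    y = np.asarray(y, dtype=float)
    codes = np.atleast_2d(np.asarray(codes, dtype=float))
    r = y - X_covariates @ np.linalg.lstsq(X_covariates, y, rcond=None)[0]
    var_y = float(r @ r)
    if var_y == 0:
        return {mid: 0.0 for mid in marker_ids}, 0.0
    out = {}
    cur = r.copy()
    Xacc = X_covariates
    for i, mid in enumerate(marker_ids):
        Xacc = np.column_stack([Xacc, codes[:, i]])
        nxt = y - Xacc @ np.linalg.lstsq(Xacc, y, rcond=None)[0]
        out[mid] = max(0.0, float(cur @ cur - nxt @ nxt) / var_y)
        cur = nxt
    total = float(r @ r - cur @ cur) / var_y
    return out, min(max(total, 0.0), 1.0)


# ---------------------------------------------------------------------------
# Covariate-specificity (heterogeneity) tests


@dataclass
class HeterogeneityTest:
    marker: str
    grouping: str
    chi2: float
    df: int
    p: float
    levels_used: list[str]
    note: str = ""


def heterogeneity_test(
    marker_id: str,
    grouping: str,
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    K: KinshipMatrix,
    coding: str = "dominant",
    reference: str = "minor",
) -> HeterogeneityTest:
    """Likelihood-ratio test for group-specific marker effects.

    Compares the mixed model with marker x group interaction terms
    against marker + group main effects (ML likelihoods, chi-square
    with (levels - 1) x 1 df).  Groups without minor-allele carriers
    are excluded, reducing the df, and noted in the output.
    """
    if grouping not in ("sex", "edu_group"):
        raise ValueError("grouping must be 'sex' or 'edu_group'")
    phen = check_phenotypes(phenotypes)
    K = K.align(genotypes.samples)
    j = genotypes.marker_index(marker_id)
    code = code_genotype(genotypes.dosage[:, j], coding, reference)
    grp = phen[grouping].astype(str).to_numpy()
    ok = ~np.isnan(code)
    note = ""
    levels = [lv for lv in pd.unique(grp[ok]) if (code[ok][grp[ok] == lv] > 0).any()]
    if len(levels) < 2:
        return HeterogeneityTest(marker_id, grouping, np.nan, 0, np.nan, levels,
                                 "interaction inestimable: fewer than 2 groups with carriers")
    use = ok & np.isin(grp, levels)
    if not use.all():
        note = f"excluded groups without carriers; kept {levels}"
    sub = np.flatnonzero(use)
    ysub = phen["adaoo"].to_numpy(dtype=float)[sub]
    gsub, csub = grp[sub], code[sub]
    eig = _eig_kinship(K.values[np.ix_(sub, sub)])
    other = "edu_years" if grouping == "sex" else "sex"
    _, Xother, _ = build_design(phen.iloc[sub].reset_index(drop=True), (other,))
    grp_dum = np.column_stack([(gsub == lv).astype(float) for lv in levels[1:]]) \
        if len(levels) > 1 else np.empty((len(sub), 0))
    X_red = np.column_stack([Xother, grp_dum, csub])
    inter = np.column_stack([csub * (gsub == lv) for lv in levels[1:]])
    X_full = np.column_stack([X_red, inter])
    try:
        fit_red = reml_fit(ysub, X_red, eig=eig)
        fit_full = reml_fit(ysub, X_full, eig=eig)
    except ValueError as exc:
        return HeterogeneityTest(marker_id, grouping, np.nan, 0, np.nan, levels,
                                 f"interaction inestimable: {exc}")
    chi2 = max(0.0, 2.0 * (fit_full.loglik_ml - fit_red.loglik_ml))
    df = len(levels) - 1
    p = float(stats.chi2.sf(chi2, df))
    return HeterogeneityTest(marker_id, grouping, chi2, df, p, levels, note)
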