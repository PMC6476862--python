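"""Two-locus interaction analysis of onset age.

The question is whether the joint effect of two modifier SNPs exceeds
that of either marker alone.  Onset age is residualized on covariates
(least squares, grand mean re-added), compared across the up-to-nine
two-locus genotype cells, and decomposed into additive, dominance and
epistatic (aa, ad, da, dd) terms by weighted least squares on
orthogonal marker scores.  Because per-cell sample sizes are small in
a pedigree cohort, inference for cell-mean contrasts is resampling
based: percentile bootstrap for confidence intervals, label
permutation (add-one estimator) for p-values — two distinct schemes,
since a bootstrap null for a mean difference is ill-defined without a
null-imposing device.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .coding import code_genotype
from .containers import GenotypeMatrix, KinshipMatrix, check_phenotypes
from .lmem import build_design
from .rng import substream

EPI_TERMS = ("a1", "d1", "a2", "d2", "aa", "ad", "da", "dd")


@dataclass
class TwoLocusDesign:
    """Covariate-adjusted genotype-cell summary for a marker pair.

    ``cells`` is a DataFrame with one row per genotype combination
    (g_a, g_b in {0,1,2}): count, adjusted mean, within-cell SS.
    ``data`` retains the analysis-set individual-level records needed
    by the resampling procedures.
    """

    marker_a: str
    marker_b: str
    cells: pd.DataFrame
    data: pd.DataFrame  # columns: y_adj, y_raw, g_a, g_b
    covariates: tuple[str, ...]
    X_cov: np.ndarray | None = None  # covariate design on the analysis set
    min_cell_n: int = 3

    def cell_mean(self, ga: int, gb: int) -> float:
        row = self.cells[(self.cells.g_a == ga) & (self.cells.g_b == gb)]
        return float(row["adj_mean"].iloc[0]) if len(row) else np.nan

    def cell_n(self, ga: int, gb: int) -> int:
        row = self.cells[(self.cells.g_a == ga) & (self.cells.g_b == gb)]
        return int(row["n"].iloc[0]) if len(row) else 0


@dataclass(frozen=True)
class ContrastSpec:
    """Carrier-vs-non-carrier contrast within a stratum of the other marker.

    ``target`` names which marker of the pair is contrasted ('a' or
    'b'); carriers are defined by a genetic coding of its dosage
    (dominant by default); the stratum fixes the other marker's
    genotype.  ``stratum=None`` pools all strata (marginal contrast).
    """

    target: str = "a"
    stratum: int | None = None
    carrier_coding: str = "dominant"
    carrier_reference: str = "minor"

    def describe(self, marker_a: str, marker_b: str) -> str:
        tgt, other = (marker_a, marker_b) if self.target == "a" else (marker_b, marker_a)
        strat = "all" if self.stratum is None else str(self.stratum)
        return f"{tgt} {self.carrier_coding}-carrier vs non-carrier | {other}={strat}"


@dataclass
class EpistasisResult:
    marker_a: str
    marker_b: str
    contrast: str
    stratum: str
    n_carrier: int
    n_noncarrier: int
    delta_years: float
    ci_level: float
    ci_low: float
    ci_high: float
    p_perm: float
    B: int
    seed: int
    flag: str = ""  # '' | 'inconclusive:<why>'


def _residualize(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    return y - X @ beta + float(np.mean(y))


def adjusted_cell_means(
    pair: tuple[str, str],
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    covariates: tuple[str, ...] = ("sex", "edu_years"),
    min_cell_n: int = 3,
) -> TwoLocusDesign:
    """Per-cell covariate-adjusted mean onset for a marker pair.

    Onset is residualized on the covariates by least squares with the
    grand mean re-added; cells are formed on complete cases for both
    markers.  Cells below ``min_cell_n`` are flagged ``small``; empty
    cells are simply absent from the table.
    """
    phen = check_phenotypes(phenotypes)
    if list(phen["sample_id"]) != list(genotypes.samples):
        raise ValueError("phenotype sample order does not match genotype samples")
    ga = genotypes.column(pair[0])
    gb = genotypes.column(pair[1])
    ok = ~np.isnan(ga) & ~np.isnan(gb)
    if not ok.any():
        raise ValueError("no complete cases for this marker pair")
    if np.nanstd(ga[ok]) == 0 and np.nanstd(gb[ok]) == 0:
        raise ValueError(f"both markers {pair} are monomorphic in the analysis set")
    y, X, _ = build_design(phen, covariates)
    sub = np.flatnonzero(ok)
    y_adj = _residualize(y[sub], X[sub])
    data = pd.DataFrame({"y_adj": y_adj, "y_raw": y[sub],
                         "g_a": ga[sub].astype(int), "g_b": gb[sub].astype(int)})
    grp = data.groupby(["g_a", "g_b"], sort=True)
    cells = grp["y_adj"].agg(n="size", adj_mean="mean").reset_index()
    cells["ss_within"] = grp["y_adj"].apply(lambda v: float(((v - v.mean()) ** 2).sum())).values
    cells["small"] = cells["n"] < min_cell_n
    return TwoLocusDesign(pair[0], pair[1], cells, data, tuple(covariates),
                          X_cov=X[sub], min_cell_n=min_cell_n)


@dataclass
class TwoLocusFit:
    estimates: dict[str, float]
    dropped: list[str]
    f_epistasis: float
    df_num: int
    df_den: int
    p_epistasis: float


def full_two_locus_fit(design: TwoLocusDesign) -> TwoLocusFit:
    """Orthogonal decomposition of the two-locus cell-mean surface.

    Weighted least squares (weights = cell n) of the adjusted cell
    means on additive scores (-1, 0, 1), centered heterozygosity
    dominance scores, and their four products (aa, ad, da, dd).
    Unidentifiable terms (collinear on the occupied cells) are dropped
    and reported.  The joint test of the epistatic terms is an F test
    against the pooled within-cell variance.
    """
    cells = design.cells
    a1 = cells["g_a"].to_numpy() - 1.0
    a2 = cells["g_b"].to_numpy() - 1.0
    d1 = (cells["g_a"] == 1).to_numpy(float) - 0.5
    d2 = (cells["g_b"] == 1).to_numpy(float) - 0.5
    terms = {"a1": a1, "d1": d1, "a2": a2, "d2": d2,
             "aa": a1 * a2, "ad": a1 * d2, "da": d1 * a2, "dd": d1 * d2}
    w = cells["n"].to_numpy(dtype=float)
    ybar = cells["adj_mean"].to_numpy()
    sw = np.sqrt(w)

    kept, dropped = ["_const"], []
    Xcols = [np.ones(len(cells))]
    for name in EPI_TERMS:
        cand = np.column_stack(Xcols + [terms[name]]) * sw[:, None]
        if np.linalg.matrix_rank(cand) > len(Xcols):
            Xcols.append(terms[name])
            kept.append(name)
        else:
            dropped.append(name)
    X = np.column_stack(Xcols)
    beta = np.linalg.lstsq(X * sw[:, None], ybar * sw, rcond=None)[0]
    est = {name: float(b) for name, b in zip(kept, beta) if name != "_const"}

    # F test of the kept epistatic terms against pooled within-cell MS
    epi_kept = [t for t in ("aa", "ad", "da", "dd") if t in kept]
    n_tot = int(w.sum())
    df_den = n_tot - len(cells)
    ss_within = float(cells["ss_within"].sum())
    if epi_kept and df_den > 0 and ss_within > 0:
        keep_red = [i for i, name in enumerate(kept) if name not in epi_kept]
        Xr = X[:, keep_red]
        rss_full = float(np.sum(w * (ybar - X @ beta) ** 2))
        br = np.linalg.lstsq(Xr * sw[:, None], ybar * sw, rcond=None)[0]
        rss_red = float(np.sum(w * (ybar - Xr @ br) ** 2))
        df_num = len(epi_kept)
        ms_within = ss_within / df_den
        f = max(0.0, (rss_red - rss_full) / df_num) / ms_within
        from scipy import stats as _st

        p = float(_st.f.sf(f, df_num, df_den))
    else:
        f, df_num, p = np.nan, len(epi_kept), np.nan
    return TwoLocusFit(est, dropped, f, df_num, df_den, p)


def _contrast_groups(ga: np.ndarray, gb: np.ndarray, spec: ContrastSpec):
    """Boolean (carrier, noncarrier) masks for a contrast spec."""
    tgt, other = (ga, gb) if spec.target == "a" else (gb, ga)
    carrier = code_genotype(tgt.astype(float), spec.carrier_coding,
                            spec.carrier_reference) > 0
    if spec.stratum is None:
        strat = np.ones(len(tgt), dtype=bool)
    else:
        strat = other == spec.stratum
    return strat & carrier, strat & ~carrier


def _delta(y: np.ndarray, grp1: np.ndarray, grp0: np.ndarray) -> float:
    if grp1.sum() == 0 or grp0.sum() == 0:
        return np.nan
    return float(y[grp1].mean() - y[grp0].mean())


def interaction_contrast(
    design: TwoLocusDesign,
    spec: ContrastSpec,
    B: int = 10_000,
    seed: int = 0,
    ci_level: float = 0.95,
    B_boot: int | None = None,
) -> EpistasisResult:
    """Point estimate, bootstrap CI and permutation p for one contrast.

    The estimate is the difference of covariate-adjusted mean onset
    between carriers and non-carriers of the target marker's allele
    within the given stratum of the other marker.  The CI resamples
    individuals with replacement (re-running the covariate adjustment
    each time); the p-value permutes the target marker's genotype
    labels against the (other genotype, covariates, phenotype) tuples,
    with the add-one estimator p = (1 + #{|perm| >= |obs|}) / (B + 1).
    """
    B_boot = B if B_boot is None else B_boot
    d = design.data
    ga = d["g_a"].to_numpy()
    gb = d["g_b"].to_numpy()
    y_adj = d["y_adj"].to_numpy()
    grp1, grp0 = _contrast_groups(ga, gb, spec)
    n1, n0 = int(grp1.sum()), int(grp0.sum())
    desc = spec.describe(design.marker_a, design.marker_b)
    strat = "all" if spec.stratum is None else str(spec.stratum)
    if min(n1, n0) < design.min_cell_n:
        return EpistasisResult(design.marker_a, design.marker_b, desc, strat,
                               n1, n0, np.nan, ci_level, np.nan, np.nan, np.nan,
                               B, seed, flag=f"inconclusive:min_cell_n<{design.min_cell_n}")
    obs = _delta(y_adj, grp1, grp0)

    # permutation p: shuffle the target marker's genotype labels.  The
    # carrier code is elementwise in the genotype, so permuting genotypes
    # and permuting the precomputed carrier indicator are equivalent --
    # which makes the whole null distribution one masked matmul.
    rng_p = substream(seed, "perm", design.marker_a, design.marker_b, spec.target,
                      -1 if spec.stratum is None else spec.stratum)
    n = len(d)
    tgt = ga if spec.target == "a" else gb
    oth = gb if spec.target == "a" else ga
    carrier = code_genotype(tgt.astype(float), spec.carrier_coding,
                            spec.carrier_reference) > 0
    in_strat = np.ones(n, dtype=bool) if spec.stratum is None else oth == spec.stratum
    Cperm = rng_p.permuted(np.tile(carrier, (B, 1)), axis=1).T  # (n, B)
    ys = y_adj[in_strat]
    Cs = Cperm[in_strat].astype(float)
    k1 = Cs.sum(axis=0)
    m_s = in_strat.sum()
    sum1 = ys @ Cs
    with np.errstate(invalid="ignore", divide="ignore"):
        dperm = sum1 / k1 - (ys.sum() - sum1) / (m_s - k1)
    ok_perm = (k1 > 0) & (k1 < m_s)
    valid = int(ok_perm.sum())
    exceed = int((np.abs(dperm[ok_perm]) >= abs(obs) - 1e-12).sum())
    p_perm = (1.0 + exceed) / (valid + 1.0)

    # bootstrap CI: resample individuals, redo adjustment and cell means
    rng_b = substream(seed, "boot", design.marker_a, design.marker_b, spec.target,
                      -1 if spec.stratum is None else spec.stratum)
    Xcov = design.X_cov
    if Xcov is None:
        raise ValueError("design lacks the covariate matrix needed for bootstrap")
    y_raw = d["y_raw"].to_numpy()
    boots = []
    for _ in range(B_boot):
        idx = rng_b.integers(0, n, size=n)
        Xb = Xcov[idx]
        yb_raw = y_raw[idx]
        beta = np.linalg.solve(Xb.T @ Xb, Xb.T @ yb_raw)
        yb = yb_raw - Xb @ beta + yb_raw.mean()
        g1 = in_strat[idx] & carrier[idx]
        g0 = in_strat[idx] & ~carrier[idx]
        db = _delta(yb, g1, g0)
        if not np.isnan(db):
            boots.append(db)
    if len(boots) >= max(10, B_boot // 2):
        alpha = 1.0 - ci_level
        lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        flag = ""
    else:
        lo = hi = np.nan
        flag = "inconclusive:bootstrap_groups_empty"
    return EpistasisResult(design.marker_a, design.marker_b, desc, strat,
                           n1, n0, obs, ci_level, float(lo), float(hi),
                           float(p_perm), B, seed, flag=flag)


def pairwise_screen(
    selected_markers: list[str],
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    B: int = 10_000,
    seed: int = 0,
    covariates: tuple[str, ...] = ("sex", "edu_years"),
    min_cell_n: int = 3,
) -> pd.DataFrame:
    """Screen every unordered pair of selected markers for interaction.

    For each pair, contrasts carrier-vs-non-carrier of each marker
    within each genotype stratum of the other; strata violating the
    minimum cell size are flagged and the rest still reported.  A
    per-pair verdict ('interaction detected' at F-test p < 0.05, else
    'no interaction detected') accompanies the contrast rows.
    """
    if len(selected_markers) < 2:
        raise ValueError("need at least 2 selected markers to screen pairs")
    rows = []
    for ma, mb in combinations(selected_markers, 2):
        design = adjusted_cell_means((ma, mb), genotypes, phenotypes,
                                     covariates, min_cell_n)
        fit = full_two_locus_fit(design)
        verdict = ("no interaction detected" if not np.isfinite(fit.f_epistasis)
                   or fit.p_epistasis >= 0.05 else "interaction detected")
        for target, other_col in (("a", "g_b"), ("b", "g_a")):
            for stratum in sorted(design.data[other_col].unique()):
                res = interaction_contrast(
                    design, ContrastSpec(target=target, stratum=int(stratum)),
                    B=B, seed=seed)
                rows.append({
                    "marker_a": res.marker_a, "marker_b": res.marker_b,
                    "contrast": res.contrast, "stratum": res.stratum,
                    "n_a": res.n_carrier, "n_b": res.n_noncarrier,
                    "delta_years": res.delta_years,
                    "ci_low": res.ci_low, "ci_high": res.ci_high,
                    "p_perm": res.p_perm, "B": res.B, "flag": res.flag,
                    "pair_epistasis_F": fit.f_epistasis,
                    "pair_epistasis_p": fit.p_epistasis,
                    "verdict": verdict,
                })
    return pd.DataFrame(rows)
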