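"""Marker quality control, frequency estimation, and relatedness.

QC mirrors the candidate-panel protocol: markers are excluded for
(i) Hardy-Weinberg departure at P < 0.05/m (m = markers entering QC),
(ii) call rate below 90%, (iii) not exactly two declared alleles, and
(iv) minor allele frequency below 1%.  Boundaries are inclusive on the
passing side (call rate exactly 0.90 passes, MAF exactly 0.01 passes,
HWE p exactly 0.05/m passes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix, KinshipMatrix


@dataclass
class QCThresholds:
    hwe_alpha: float | None = None  # None -> 0.05 / m at apply time
    min_call_rate: float = 0.90
    min_maf: float = 0.01

    def resolved_hwe_alpha(self, m: int) -> float:
        return 0.05 / m if self.hwe_alpha is None else self.hwe_alpha


@dataclass
class QCReport:
    table: pd.DataFrame  # one row per marker entering QC
    thresholds: QCThresholds
    hwe_alpha_used: float

    @property
    def n_pass(self) -> int:
        return int(self.table["pass"].sum())

    @property
    def n_fail(self) -> int:
        return len(self.table) - self.n_pass

    def to_json_dict(self) -> dict:
        return {
            "n_markers": int(len(self.table)),
            "n_pass": self.n_pass,
            "n_fail": self.n_fail,
            "hwe_alpha": self.hwe_alpha_used,
            "min_call_rate": self.thresholds.min_call_rate,
            "min_maf": self.thresholds.min_maf,
            "failures": {
                str(idx): row["reasons"].split(";")
                for idx, row in self.table.iterrows()
                if not row["pass"]
            },
        }


def genotype_counts(dosage_col: np.ndarray) -> tuple[int, int, int]:
    """(hom-major, het, hom-minor) counts from a minor-allele dosage column."""
    d = dosage_col[~np.isnan(dosage_col)]
    return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())


def estimate_frequencies(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker ML genotype and allele frequencies.

    With complete biallelic data the maximum-likelihood estimator is
    the counting estimator: counted-allele frequency
    (2*hom + het) / (2*called); genotype frequencies are the observed
    proportions among called samples.  All-missing markers are reported
    with NaN frequencies (undefined, not zero).
    """
    rows = []
    for j, mk in enumerate(genotypes.markers):
        n0, n1, n2 = genotype_counts(genotypes.dosage[:, j])
        n_called = n0 + n1 + n2
        if n_called == 0:
            rows.append(dict(marker=mk.id, n_called=0, freq_counted=np.nan,
                             maf=np.nan, minor_allele=None,
                             f_hom_major=np.nan, f_het=np.nan, f_hom_minor=np.nan))
            continue
        f = (2 * n2 + n1) / (2 * n_called)
        maf = min(f, 1 - f)
        minor = mk.counted_allele if f <= 0.5 else (
            mk.ref_allele if mk.counted_allele == mk.alt_allele else mk.alt_allele
        )
        rows.append(dict(marker=mk.id, n_called=n_called, freq_counted=f, maf=maf,
                         minor_allele=minor, f_hom_major=n0 / n_called,
                         f_het=n1 / n_called, f_hom_minor=n2 / n_called))
    return pd.DataFrame(rows).set_index("marker")


def format_ma_freq(minor_allele: str | None, maf: float) -> str:
    """Render the 'MA (Freq)' column, e.g. ``T (0.046)``."""
    if minor_allele is None or np.isnan(maf):
        return "NA"
    return f"{minor_allele} ({maf:.3f})"


def hwe_test(n_hom_major: int, n_het: int, n_hom_minor: int, method: str = "chi2") -> float:
    """Hardy-Weinberg goodness-of-fit p-value from genotype counts.

    ``chi2`` (default): 1-df chi-square of observed counts against HWE
    expectations at the ML allele frequency.  ``exact``: conditional
    exact test enumerating heterozygote counts given the allele counts.
    Monomorphic markers return p = 1 (no departure is testable).
    """
    n = n_hom_major + n_het + n_hom_minor
    if n == 0:
        raise ValueError("no called genotypes")
    q = (2 * n_hom_minor + n_het) / (2 * n)
    if q == 0.0 or q == 1.0:
        return 1.0
    if method == "chi2":
        p = 1 - q
        exp = np.array([p * p, 2 * p * q, q * q]) * n
        obs = np.array([n_hom_major, n_het, n_hom_minor], dtype=float)
        chi2 = float(((obs - exp) ** 2 / exp).sum())
        return float(stats.chi2.sf(chi2, df=1))
    if method == "exact":
        return _hwe_exact(n_hom_major, n_het, n_hom_minor)
    raise ValueError(f"unknown HWE method {method!r}")


def hwe_chi2_statistic(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    n = n_hom_major + n_het + n_hom_minor
    q = (2 * n_hom_minor + n_het) / (2 * n)
    if q in (0.0, 1.0):
        return 0.0
    p = 1 - q
    exp = np.array([p * p, 2 * p * q, q * q]) * n
    obs = np.array([n_hom_major, n_het, n_hom_minor], dtype=float)
    return float(((obs - exp) ** 2 / exp).sum())


def _hwe_exact(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact HWE test: sums probabilities of heterozygote counts no more
    probable than the observed one, conditional on allele counts."""
    n = n_aa + n_ab + n_bb
    n_b = 2 * n_bb + n_ab  # rarer-allele count assumed; symmetric otherwise
    n_b = min(n_b, 2 * n - n_b)
    hets = np.arange(n_b % 2, n_b + 1, 2)
    logp = np.zeros(len(hets))
    from scipy.special import gammaln

    def lfac(x):
        return gammaln(np.asarray(x) + 1.0)

    homb = (n_b - hets) // 2
    homa = n - hets - homb
    logp = (lfac(n) - lfac(homa) - lfac(hets) - lfac(homb)
            + hets * np.log(2.0) + lfac(n_b) + lfac(2 * n - n_b) - lfac(2 * n))
    pr = np.exp(logp - logp.max())
    pr /= pr.sum()
    obs_het = n_ab
    p_obs = pr[hets == obs_het]
    if p_obs.size == 0:
        raise ValueError("observed heterozygote count inconsistent with allele counts")
    return float(min(1.0, pr[pr <= p_obs[0] + 1e-12].sum()))


def hwe_test_from_dosage(dosage_col: np.ndarray, method: str = "chi2") -> float:
    return hwe_test(*genotype_counts(dosage_col), method=method)


def apply_qc(
    genotypes: GenotypeMatrix,
    thresholds: QCThresholds | None = None,
    hwe_method: str = "chi2",
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter markers by the four QC rules; report every violation.

    The Bonferroni HWE bound uses m = number of markers entering QC.
    Sample order is unchanged.  The call is idempotent: a panel that
    passed once passes unchanged (the HWE bound can only loosen as m
    shrinks).
    """
    thresholds = thresholds or QCThresholds()
    m = genotypes.n_markers
    hwe_alpha = thresholds.resolved_hwe_alpha(max(m, 1))
    freqs = estimate_frequencies(genotypes)
    rows = []
    keep = []
    for j, mk in enumerate(genotypes.markers):
        col = genotypes.dosage[:, j]
        call_rate = float(np.mean(~np.isnan(col)))
        maf = float(freqs.iloc[j]["maf"])
        if mk.n_alleles == 2 and not np.isnan(maf):
            hwe_p = hwe_test_from_dosage(col, method=hwe_method) if call_rate > 0 else np.nan
        else:
            hwe_p = np.nan
        reasons = []
        if mk.n_alleles != 2:
            reasons.append("n_alleles")
        if call_rate < thresholds.min_call_rate:
            reasons.append("call_rate")
        if np.isnan(maf) or maf < thresholds.min_maf:
            reasons.append("maf")
        if not np.isnan(hwe_p) and hwe_p < hwe_alpha:
            reasons.append("hwe")
        ok = not reasons
        keep.append(ok)
        rows.append(dict(marker=mk.id, call_rate=call_rate, maf=maf, hwe_p=hwe_p,
                         n_alleles=mk.n_alleles, **{"pass": ok},
                         reasons=";".join(reasons)))
    table = pd.DataFrame(rows).set_index("marker")
    report = QCReport(table, thresholds, hwe_alpha)
    return genotypes.subset_markers(np.array(keep, dtype=bool)), report


def estimate_kinship(genotypes: GenotypeMatrix, min_markers: int = 2) -> KinshipMatrix:
    """Standardized-genotype relationship matrix (GRM), PSD-stabilized.

    K = Z Z' / m with Z the per-marker centered (2p) and scaled
    (sqrt(2p(1-p))) dosage; missing dosages are mean-imputed for this
    computation only.  Negative eigenvalues are floored at zero.
    Monomorphic or all-missing markers are skipped.
    """
    import warnings

    X = genotypes.dosage.copy()
    cols = []
    for j in range(X.shape[1]):
        col = X[:, j]
        called = ~np.isnan(col)
        if called.sum() == 0:
            continue
        p = col[called].mean() / 2
        if p <= 0 or p >= 1:
            continue
        col = np.where(called, col, 2 * p)
        cols.append((col - 2 * p) / np.sqrt(2 * p * (1 - p)))
    if len(cols) < min_markers:
        warnings.warn(
            f"only {len(cols)} usable markers for kinship estimation; "
            "estimates will be unstable",
            stacklevel=2,
        )
    if not cols:
        raise ValueError("no polymorphic markers available for kinship estimation")
    Z = np.column_stack(cols)
    K = Z @ Z.T / Z.shape[1]
    w, V = np.linalg.eigh(K)
    if w.min() < 0:
        K = (V * np.clip(w, 0, None)) @ V.T
    K = 0.5 * (K + K.T)
    return KinshipMatrix(K, list(genotypes.samples))
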