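"""Non-random-mating and relatedness diagnostics.

Mate-PGS and transmitted/non-transmitted PGS correlations (computed on
PC-residualized scores, with Fisher-z confidence intervals), and a
frequency-standardized method-of-moments estimator of the genome-wide
IBD-sharing proportion (pi-hat) with relationship-degree classification.
Under assortative mating with cross-mate score correlation r, the
expected transmitted/non-transmitted score correlation is
(r/2) / (1 + r/2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MISSING = -1

# Degree bins: geometric midpoints between the expected pi-hat of adjacent
# degrees (1, 1/2, 1/4, 1/8, 1/16), i.e. powers of 1/sqrt(2).
_DEGREE_BINS = [
    ("duplicate/MZ", 2 ** -0.5, np.inf),
    ("1st", 2 ** -1.5, 2 ** -0.5),
    ("2nd", 2 ** -2.5, 2 ** -1.5),
    ("3rd", 2 ** -3.5, 2 ** -2.5),
    ("4th", 2 ** -4.5, 2 ** -3.5),
    ("unrelated", -np.inf, 2 ** -4.5),
]


@dataclass
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    n: int


def _pearson_with_ci(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    r = float(np.corrcoef(x[ok], y[ok])[0, 1])
    if abs(r) >= 1.0:
        return CorrelationResult(r, r, r, n)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    lo, hi = np.tanh(z - 1.959963984540054 * se), np.tanh(z + 1.959963984540054 * se)
    return CorrelationResult(r, float(lo), float(hi), n)


def mate_correlation(mother_scores: np.ndarray, father_scores: np.ndarray) -> CorrelationResult:
    """Pearson correlation between paired mothers' and fathers' scores.

    Intended for PC-residualized scores; Fisher-z 95% CI.
    """
    return _pearson_with_ci(mother_scores, father_scores)


def t_nt_correlation(t_scores: np.ndarray, nt_scores: np.ndarray) -> CorrelationResult:
    """Correlation between transmitted and non-transmitted (pseudo-control)
    scores; nonzero values indicate assortative mating or consanguinity."""
    return _pearson_with_ci(t_scores, nt_scores)


def expected_t_nt_correlation(r_am: float) -> float:
    """Closed-form corr(T, NT) implied by cross-mate score correlation r."""
    return (r_am / 2.0) / (1.0 + r_am / 2.0)


def estimate_pi_hat(
    x: np.ndarray,
    y: np.ndarray,
    allele_freq: np.ndarray,
    maf_filter: float = 0.05,
) -> float:
    """Method-of-moments genome-wide IBD-sharing proportion for one pair.

    pi_hat = mean_j (x_j - 2p_j)(y_j - 2p_j) / (2 p_j (1 - p_j)) over
    non-missing SNPs with frequency in [maf_filter, 1 - maf_filter]
    (a standardized-genotype kinship estimate times two).  Warns below
    1000 usable SNPs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    p = np.asarray(allele_freq, dtype=float)
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    keep = (
        (x != MISSING)
        & (y != MISSING)
        & np.isfinite(x)
        & np.isfinite(y)
        & (p >= maf_filter)
        & (p <= 1.0 - maf_filter)
    )
    m = int(keep.sum())
    if m == 0:
        raise ValueError("no usable SNPs after missingness and frequency filters")
    if m < 1000:
        warnings.warn(f"only {m} SNPs used for pi-hat; estimate may be noisy", stacklevel=2)
    num = (x[keep] - 2 * p[keep]) * (y[keep] - 2 * p[keep])
    den = 2 * p[keep] * (1 - p[keep])
    return float(np.mean(num / den))


def pairwise_pi_hat(
    genotypes_a: np.ndarray,
    genotypes_b: np.ndarray,
    allele_freq: np.ndarray,
    maf_filter: float = 0.05,
) -> np.ndarray:
    """Vectorized pi-hat for row-paired genotype matrices."""
    a = np.asarray(genotypes_a, dtype=float)
    b = np.asarray(genotypes_b, dtype=float)
    p = np.asarray(allele_freq, dtype=float)
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    snp_ok = (p >= maf_filter) & (p <= 1.0 - maf_filter)
    a, b, p = a[:, snp_ok], b[:, snp_ok], p[snp_ok]
    am = (a == MISSING) | ~np.isfinite(a)
    bm = (b == MISSING) | ~np.isfinite(b)
    ok = ~(am | bm)
    num = np.where(ok, (a - 2 * p) * (b - 2 * p) / (2 * p * (1 - p)), 0.0)
    return num.sum(axis=1) / ok.sum(axis=1)


def classify_degree(pi_hat: float) -> str:
    """Relationship degree from pi-hat via powers-of-sqrt(2) midpoint bins."""
    if not np.isfinite(pi_hat):
        raise ValueError("pi_hat must be finite")
    for name, lo, hi in _DEGREE_BINS:
        if lo < pi_hat <= hi or (name == "unrelated" and pi_hat <= hi):
            return name
    return "unrelated"


def relatedness_table(
    ids_a: list[str],
    ids_b: list[str],
    genotypes_a: np.ndarray,
    genotypes_b: np.ndarray,
    allele_freq: np.ndarray,
    maf_filter: float = 0.05,
) -> pd.DataFrame:
    """Pairwise relatedness table: id1, id2, pi_hat, degree."""
    pis = pairwise_pi_hat(genotypes_a, genotypes_b, allele_freq, maf_filter)
    return pd.DataFrame(
        {
            "id1": ids_a,
            "id2": ids_b,
            "pi_hat": pis,
            "degree": [classify_degree(p) for p in pis],
        }
    )


def mating_diagnostics(
    scores_by_class: dict[str, np.ndarray], phenotype: str
) -> pd.DataFrame:
    """Mate and T/NT correlation summary for one PGS phenotype.

    ``scores_by_class`` must provide residualized scores keyed by
    'mother', 'father', and optionally 'T' and 'NT'.
    """
    rows = []
    pairs = [("mother", "father", "mate_correlation")]
    if "T" in scores_by_class and "NT" in scores_by_class:
        pairs.append(("T", "NT", "t_nt_correlation"))
    for a, b, label in pairs:
        c = _pearson_with_ci(scores_by_class[a], scores_by_class[b])
        rows.append(
            {
                "phenotype": phenotype,
                "statistic": label,
                "r": c.r,
                "ci_low": c.ci_low,
                "ci_high": c.ci_high,
                "n_pairs": c.n,
            }
        )
    return pd.DataFrame(rows)
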