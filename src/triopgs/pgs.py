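"""Polygenic score construction from external weight files.

Reads PRS-CS-style weight tables (CHR SNP BP A1 A2 BETA), aligns effect
alleles to cohort variants (direct match, allele swap, strand flip;
palindromic SNPs dropped by default), and computes raw, standardized and
PC-residualized scores for children, parents and pseudo-controls.

Swapped-allele weights are folded into an equivalent alt-allele weight
plus an additive offset (w * (2 - d) = 2w - w*d), so scoring is exactly
invariant to the representation of the weight file.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

MISSING = -1
_VALID_ALLELES = {"A", "C", "G", "T"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
WEIGHT_COLUMNS = ["CHR", "SNP", "BP", "A1", "A2", "BETA"]


def read_weights(path) -> pd.DataFrame:
    """Read and validate a variant-weight TSV (CHR SNP BP A1 A2 BETA).

    A1 is the effect allele.  Raises on malformed rows, invalid alleles,
    A1 == A2, non-finite weights, or duplicate SNP ids.  An empty table
    with a valid header is returned as-is.
    """
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str, "SNP": str, "A1": str, "A2": str})
    missing_cols = [c for c in WEIGHT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"weight file {path} missing columns {missing_cols}")
    df = df[WEIGHT_COLUMNS].copy()
    if df.empty:
        return df
    df["BETA"] = pd.to_numeric(df["BETA"], errors="raise")
    for col in ("A1", "A2"):
        bad = ~df[col].isin(_VALID_ALLELES)
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(
                f"row {row} ({df.loc[row, 'SNP']}): invalid {col} allele {df.loc[row, col]!r}"
            )
    same = df["A1"] == df["A2"]
    if same.any():
        row = df.index[same][0]
        raise ValueError(f"row {row} ({df.loc[row, 'SNP']}): A1 equals A2")
    if not np.isfinite(df["BETA"]).all():
        raise ValueError("non-finite BETA values in weight file")
    dup = df["SNP"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate SNP ids: {sorted(df.loc[dup, 'SNP'].unique())}")
    return df


@dataclass
class AlignedWeights:
    """Weights mapped onto the cohort variant axis.

    ``alt_weight[j]`` multiplies the alt-allele dosage of cohort variant j
    (zero where unscored); ``offset`` collects the constants from
    swapped-allele weights; ``dropped`` maps SNP id -> reason.
    """

    alt_weight: np.ndarray
    offset: float
    scored_mask: np.ndarray
    n_scored: int
    dropped: dict[str, str] = field(default_factory=dict)


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT[a1] == a2


def align_alleles(
    weights: pd.DataFrame,
    variants: pd.DataFrame,
    drop_palindromic: bool = True,
) -> AlignedWeights:
    """Match weight-file alleles to cohort variants (keyed by variant id).

    Exact A1/A2 = alt/ref match keeps the weight on the alt dosage; a
    swap (A1 = ref) applies the weight to 2 - dosage; strand-flipped
    records are complemented first.  Palindromic (A/T, C/G) SNPs are
    dropped by default since their strand cannot be verified.  Unmatched
    or mismatched variants are dropped with reason codes; this never
    raises.
    """
    n = len(variants)
    alt_weight = np.zeros(n, dtype=float)
    scored = np.zeros(n, dtype=bool)
    offset = 0.0
    dropped: dict[str, str] = {}
    var_index = {vid: j for j, vid in enumerate(variants["id"])}
    ref = variants["ref"].to_numpy()
    alt = variants["alt"].to_numpy()

    for row in weights.itertuples(index=False):
        a1, a2, w = row.A1, row.A2, float(row.BETA)
        j = var_index.get(row.SNP)
        if j is None:
            dropped[row.SNP] = "unmatched"
            continue
        if drop_palindromic and _is_palindromic(a1, a2):
            dropped[row.SNP] = "palindromic"
            continue
        r, a = ref[j], alt[j]
        if (a1, a2) == (a, r):
            pass  # effect allele is alt
        elif (a1, a2) == (r, a):
            # effect allele is ref: w*(2-d) = 2w - w*d
            offset += 2.0 * w
            w = -w
        elif (_COMPLEMENT[a1], _COMPLEMENT[a2]) == (a, r):
            pass  # strand flip, effect allele is alt
        elif (_COMPLEMENT[a1], _COMPLEMENT[a2]) == (r, a):
            offset += 2.0 * w
            w = -w
        else:
            dropped[row.SNP] = "allele_mismatch"
            continue
        alt_weight[j] = w
        scored[j] = True
    return AlignedWeights(
        alt_weight=alt_weight,
        offset=offset,
        scored_mask=scored,
        n_scored=int(scored.sum()),
        dropped=dropped,
    )


def score(
    genotypes: np.ndarray,
    aligned: AlignedWeights,
    missing_policy: str = "mean_impute",
    allele_freq: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Raw polygenic scores: offset + sum_j alt_weight_j * dosage_ij.

    Missing dosages are replaced by 2 * alt-allele frequency
    (``mean_impute``, default; frequency estimated in the scoring cohort
    unless given) or the variant is skipped for that sample
    (``drop_variant_for_sample``).  Samples missing at every scored
    variant get NaN with a warning.
    """
    if missing_policy not in ("mean_impute", "drop_variant_for_sample"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if aligned.n_scored == 0:
        return np.full(genotypes.shape[0], aligned.offset)
    g = genotypes.astype(float)
    miss = genotypes == MISSING
    g[miss] = np.nan
    if allele_freq is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            allele_freq = np.nanmean(g, axis=0) / 2.0
        allele_freq = np.nan_to_num(allele_freq, nan=0.0)
    if missing_policy == "mean_impute":
        g = np.where(np.isnan(g), 2.0 * allele_freq, g)
        raw = aligned.offset + g @ aligned.alt_weight
    else:
        g = np.where(np.isnan(g), 0.0, g)
        raw = aligned.offset + g @ aligned.alt_weight
    all_missing = miss[:, aligned.scored_mask].all(axis=1) if aligned.n_scored else (
        np.ones(genotypes.shape[0], dtype=bool)
    )
    if aligned.n_scored and all_missing.any():
        warnings.warn(
            f"{int(all_missing.sum())} sample(s) missing at every scored variant; "
            "scores set to NaN",
            stacklevel=2,
        )
        raw = raw.copy()
        raw[all_missing] = np.nan
    return raw


@dataclass
class ScoreSet:
    """Raw, standardized and PC-residualized scores for one phenotype/class."""

    phenotype: str
    transmission_class: str  # child/T, mother, father, pseudo-control/NT
    raw: np.ndarray
    z: np.ndarray
    residualized: np.ndarray
    n_variants_scored: int
    n_variants_dropped: int
    drop_reasons: dict[str, str] = field(default_factory=dict)


def standardize_and_residualize(
    raw: np.ndarray,
    pcs: np.ndarray,
    phenotype: str = "score",
    transmission_class: str = "child/T",
    group: Optional[np.ndarray] = None,
    n_variants_scored: int = 0,
    drop_reasons: Optional[dict[str, str]] = None,
) -> ScoreSet:
    """Z-score within group and residualize on the PCs (plus intercept).

    The residual is the least-squares projection residual of the z-score
    on [1, PCs]; by construction its correlation with every PC is zero to
    numerical precision.  Raises if the PC design is rank-deficient,
    naming the collinear columns.
    """
    raw = np.asarray(raw, dtype=float)
    z = np.full_like(raw, np.nan)
    groups = np.zeros(raw.shape[0], dtype=int) if group is None else np.asarray(group)
    for gval in np.unique(groups):
        m = (groups == gval) & np.isfinite(raw)
        if m.sum() >= 2 and raw[m].std() > 0:
            z[m] = (raw[m] - raw[m].mean()) / raw[m].std()
        elif m.any():
            z[m] = 0.0

    pcs = np.asarray(pcs, dtype=float)
    if pcs.ndim != 2 or pcs.shape[0] != raw.shape[0]:
        raise ValueError("PC matrix must be (n_samples, n_pcs), row-aligned with scores")
    nonzero = pcs.std(axis=0) > 0
    design = np.column_stack([np.ones(raw.shape[0]), pcs[:, nonzero]])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by incremental rank
        collinear = []
        cols = [np.ones(raw.shape[0])]
        for k in np.where(nonzero)[0]:
            trial = np.column_stack(cols + [pcs[:, k]])
            if np.linalg.matrix_rank(trial) == len(cols):
                collinear.append(k)
            else:
                cols.append(pcs[:, k])
        raise ValueError(f"rank-deficient PC matrix; collinear columns: {collinear}")
    ok = np.isfinite(z)
    resid = np.full_like(z, np.nan)
    beta, *_ = np.linalg.lstsq(design[ok], z[ok], rcond=None)
    resid[ok] = z[ok] - design[ok] @ beta
    return ScoreSet(
        phenotype=phenotype,
        transmission_class=transmission_class,
        raw=raw,
        z=z,
        residualized=resid,
        n_variants_scored=n_variants_scored,
        n_variants_dropped=len(drop_reasons or {}),
        drop_reasons=dict(drop_reasons or {}),
    )
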