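"""Synthetic trio-cohort generator.

Produces trio genotype/phenotype data with known direct-genetic and
genetic-nurture effects, configurable assortative mating, consanguinity,
and phenotype-dependent attrition, in the same file formats the analysis
pipeline consumes.  The generative model is a liability-threshold model:

    L_age = delta_age * Z(PGS_child)
          + eta_age   * (Z(PGS_mother) + Z(PGS_father))
          + sex_effect * I(female) + ses_effect * SES + noise

with the noise variance chosen so that Var(L_age) = 1 in the simulated
cohort.  Ordinal symptom scores (SDQ-E, SMFQ, KMH) are produced by
thresholding item-level liabilities that load on L_age.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

SUPPORTED_AGES = (3, 5, 7, 11, 14, 17)
SELF_REPORT_AGES = (11, 14, 17)
MISSING = -1

_DEFAULT_DELTA = {3: 0.05, 5: 0.12, 7: 0.14, 11: 0.16, 14: 0.18, 17: 0.20}
_DEFAULT_ETA = {a: 0.0 for a in SUPPORTED_AGES}

# Non-complementary ref/alt pairs, so every simulated SNP survives strand
# checks; palindromic (A/T, C/G) sites are only emitted on request.
_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SimulationConfig:
    """Parameters of one simulated trio cohort.

    Effect sizes are on the liability scale: ``delta_by_age`` is the direct
    effect per SD of the child's own score; ``eta_by_age`` is the nurture
    effect per SD of each parent's score (applied to the sum of the two
    z-scored parental scores, so the joint trio model's per-parent
    coefficient equals eta).
    """

    n_trios: int = 5000
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    weight_sparsity: float = 1.0
    delta_by_age: dict[int, float] = field(default_factory=lambda: dict(_DEFAULT_DELTA))
    eta_by_age: dict[int, float] = field(default_factory=lambda: dict(_DEFAULT_ETA))
    eta_mother_by_age: Optional[dict[int, float]] = None
    eta_father_by_age: Optional[dict[int, float]] = None
    r_am: float = 0.0
    consang_fraction: float = 0.0
    consang_degree: int = 3
    sex_effect: float = 0.5
    ses_effect: float = -0.15
    rater_reliability: float = 0.7
    item_loading: float = 0.5
    attrition_intercept: float = 0.43
    attrition_beta: float = 0.5
    attrition_ses: float = 0.3
    ages: tuple[int, ...] = SUPPORTED_AGES
    include_palindromic: bool = False
    match_on_observed_pgs: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trios < 1:
            raise ValueError("n_trios must be >= 1")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if not (0.0 <= self.r_am < 1.0):
            raise ValueError(f"r_am must be in [0, 1), got {self.r_am}")
        if not (0.0 <= self.consang_fraction <= 1.0):
            raise ValueError("consang_fraction must be in [0, 1]")
        if self.consang_degree not in (3, 4):
            raise ValueError("consang_degree must be 3 or 4")
        if not (0.0 <= self.weight_sparsity <= 1.0):
            raise ValueError("weight_sparsity must be in [0, 1]")
        if not set(self.ages) <= set(SUPPORTED_AGES):
            raise ValueError(f"ages must be a subset of {SUPPORTED_AGES}")
        for name in ("delta_by_age", "eta_by_age"):
            d = getattr(self, name)
            for a in self.ages:
                if a not in d:
                    raise ValueError(f"{name} missing age {a}")
                if not np.isfinite(d[a]):
                    raise ValueError(f"{name}[{a}] is not finite")
        if not (0.0 < self.attrition_intercept < 1.0):
            raise ValueError("attrition_intercept must be a probability in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["maf_range"] = list(self.maf_range)
        d["ages"] = list(self.ages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        if "ages" in d:
            d["ages"] = tuple(int(a) for a in d["ages"])
        for key in ("delta_by_age", "eta_by_age", "eta_mother_by_age", "eta_father_by_age"):
            if d.get(key):
                d[key] = {int(k): float(v) for k, v in d[key].items()}
        return cls(**d)


@dataclass
class FounderPool:
    """Parent genotype pool with per-parent true (causal-weight) score."""

    genotypes: np.ndarray  # (n_parents, n_snps) int8 dosage of alt allele
    allele_freq: np.ndarray  # (n_snps,)
    weights: np.ndarray  # (n_snps,) causal weight per alt allele
    raw_score: np.ndarray  # (n_parents,)
    z_score: np.ndarray  # (n_parents,)


@dataclass
class TrioCohort:
    """In-memory trio cohort: genotypes, pedigree, phenotypes, and truth."""

    variants: pd.DataFrame  # chrom, pos, id, ref, alt, af, weight
    child: np.ndarray  # (n_trios, n_snps) int8, -1 = missing
    mother: np.ndarray
    father: np.ndarray
    child_ids: list[str]
    mother_ids: list[str]
    father_ids: list[str]
    transmission_truth: Optional[dict[str, np.ndarray]] = None  # t_m, t_f alt counts
    phenotypes: Optional[pd.DataFrame] = None
    config: Optional[SimulationConfig] = None

    @property
    def n_trios(self) -> int:
        return self.child.shape[0]

    @property
    def n_snps(self) -> int:
        return self.child.shape[1]

    @property
    def pedigree(self) -> dict[str, tuple[str, str]]:
        return {
            c: (m, f)
            for c, m, f in zip(self.child_ids, self.mother_ids, self.father_ids)
        }


# ---------------------------------------------------------------------------
# founders and mating
# ---------------------------------------------------------------------------


def _draw_weights(n_snps: int, sparsity: float, rng: np.random.Generator) -> np.ndarray:
    w = rng.normal(0.0, 1.0, n_snps)
    if sparsity < 1.0:
        n_zero = int(round((1.0 - sparsity) * n_snps))
        if n_zero > 0:
            zero_idx = rng.choice(n_snps, size=n_zero, replace=False)
            w[zero_idx] = 0.0
    return w


def _draw_genotypes(afs: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    # Binomial(2, p) drawn as two Bernoulli haplotypes; much faster than
    # rng.binomial with a broadcast p vector.
    m = afs.shape[0]
    g = (rng.random((n, m)) < afs).view(np.int8) + (rng.random((n, m)) < afs)
    return g.astype(np.int8)


def simulate_founders(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    n_parents: Optional[int] = None,
) -> FounderPool:
    """Draw unrelated founder parents in Hardy-Weinberg proportions.

    Allele frequencies are Uniform over ``maf_range``; genotypes are
    Binomial(2, p) per SNP; the true score is the causal-weighted allele
    sum, returned both raw and z-scored within the pool.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if n_parents is None:
        n_parents = 2 * config.n_trios
    lo, hi = config.maf_range
    afs = rng.uniform(lo, hi, config.n_snps)
    weights = _draw_weights(config.n_snps, config.weight_sparsity, rng)
    genotypes = _draw_genotypes(afs, n_parents, rng)
    raw = genotypes.astype(float) @ weights
    sd = raw.std() if raw.size else 0.0
    z = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)
    return FounderPool(genotypes, afs, weights, raw, z)


def _copula_pair_order(
    mother_scores: np.ndarray, father_scores: np.ndarray, r_am: float, rng: np.random.Generator
) -> np.ndarray:
    """Return, for each mother index, the father index she is paired with.

    Gaussian-copula rank matching: mothers' score ranks are mapped to normal
    scores u, a target v = r*u + sqrt(1-r^2)*e is drawn, and the father whose
    score rank matches the rank of v is assigned.  Achieves cross-mate score
    correlation ~ r_am for near-Gaussian scores.
    """
    n = mother_scores.shape[0]
    from scipy.stats import rankdata, norm

    u = norm.ppf((rankdata(mother_scores) - 0.5) / n)
    # exact in-sample calibration: the noise is orthogonalized against u so
    # that corr(u, v) equals r_am up to rank-mapping error, not sampling error
    e = rng.standard_normal(n)
    e = e - e.mean() - u * (u @ e) / (u @ u)
    e = e / e.std() * u.std()
    v = r_am * u + np.sqrt(1.0 - r_am**2) * e
    father_sorted = np.argsort(father_scores, kind="stable")
    v_rank = rankdata(v, method="ordinal").astype(int) - 1
    return father_sorted[v_rank]


def _mate_pair(
    mothers: np.ndarray, fathers: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Transmit one allele from each parent; returns (t_m, t_f) alt counts."""
    out = []
    for g in (mothers, fathers):
        het = g == 1
        t = (g == 2).astype(np.int8)
        t[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
        t[g == MISSING] = MISSING
        out.append(t)
    return out[0], out[1]


def transmit(
    mother: np.ndarray, father: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mendelian segregation: child genotypes plus transmission truth.

    One allele is sampled uniformly from each parent independently per SNP.
    Missing parental sites propagate to missing child sites.  Returns
    ``(child, t_m, t_f)`` where ``t_m``/``t_f`` are the transmitted
    alt-allele counts (0/1, -1 where missing).
    """
    t_m, t_f = _mate_pair(mother, father, rng)
    child = t_m + t_f
    child[(t_m == MISSING) | (t_f == MISSING)] = MISSING
    return child.astype(np.int8), t_m, t_f


def simulate_relative_pair(
    afs: np.ndarray, degree: int, n_pairs: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate pairs of relatives via explicit mini-pedigrees.

    degree 3: first cousins (expected genome-wide IBD proportion 0.125) —
    two siblings from one founder couple each have a child with an
    unrelated spouse.  degree 4: first cousins once removed (expected
    0.0625) — one additional meiosis on one side.
    Returns two (n_pairs, n_snps) genotype matrices.
    """
    if degree not in (3, 4):
        raise ValueError("degree must be 3 or 4")

    def founders(n):
        return _draw_genotypes(afs, n, rng)

    g1, g2 = founders(n_pairs), founders(n_pairs)
    sib1, _, _ = transmit(g1, g2, rng)
    sib2, _, _ = transmit(g1, g2, rng)
    cousin1, _, _ = transmit(sib1, founders(n_pairs), rng)
    cousin2, _, _ = transmit(sib2, founders(n_pairs), rng)
    if degree == 3:
        return cousin1, cousin2
    removed, _, _ = transmit(cousin2, founders(n_pairs), rng)
    return cousin1, removed


def pair_mates(
    pool: FounderPool,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Form mother/father genotype matrices for ``config.n_trios`` pairs.

    Non-consanguineous pairs come from the pool via Gaussian-copula rank
    matching on the true score (or the observed score when
    ``match_on_observed_pgs``; with independent SNPs the two coincide).
    Consanguineous pairs are generated de novo from explicit mini-pedigrees
    rather than drawn from the pool.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    n = config.n_trios
    n_consang = int(round(config.consang_fraction * n))
    n_random = n - n_consang
    if pool.genotypes.shape[0] < 2 * n_random:
        raise ValueError(
            f"pool of {pool.genotypes.shape[0]} parents cannot form {n_random} pairs"
        )
    if n_random > 0:
        mothers_idx = np.arange(n_random)
        fathers_idx = np.arange(n_random, 2 * n_random)
        scores = pool.z_score
        pairing = _copula_pair_order(
            scores[mothers_idx], scores[fathers_idx], config.r_am, rng
        )
        mother_g = pool.genotypes[mothers_idx]
        father_g = pool.genotypes[fathers_idx][pairing]
    else:
        mother_g = np.empty((0, config.n_snps), dtype=np.int8)
        father_g = np.empty((0, config.n_snps), dtype=np.int8)
    if n_consang > 0:
        cm, cf = simulate_relative_pair(
            pool.allele_freq, config.consang_degree, n_consang, rng
        )
        mother_g = np.vstack([mother_g, cm])
        father_g = np.vstack([father_g, cf])
    return mother_g, father_g


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x, dtype=float)


def _ordinal_items(
    liability: np.ndarray,
    n_items: int,
    cutpoints: np.ndarray,
    loading: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Threshold item liabilities sharing a common factor into ordinal items."""
    n = liability.shape[0]
    lam = np.sqrt(loading)
    eps = rng.standard_normal((n, n_items))
    item_liab = lam * liability[:, None] + np.sqrt(1.0 - loading) * eps
    return (item_liab[:, :, None] > cutpoints[None, None, :]).sum(axis=2).astype(np.int16)


# Item thresholds on the (unit-variance) item liability scale, shared by
# parent and self report; chosen to give a realistic right-skewed symptom
# distribution with a meaningful high-score tail.
_SDQE_CUTS = np.array([0.9, 1.7])
_SMFQ_CUTS = np.array([1.0, 1.8])
_KMH_CUTS = np.array([0.4, 1.0, 1.6, 2.2])
SDQE_DISORDER_CUTOFF = 7


def simulate_phenotypes(
    cohort: TrioCohort,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Simulate the phenotype table for a cohort with known genetic truth.

    Per age, a unit-variance liability combines the child's direct genetic
    effect, the parental nurture effect, sex, SES, and scaled noise; SDQ-E
    (five items, 0-2), SMFQ at 14 (13 items, 0-2) and KMH at 17 (6 items,
    0-4) totals are generated by thresholding item liabilities with a
    common factor.  ``emotional_disorder`` flags any SDQ-E total >= 7.
    Latent liabilities are retained as ``liability_<age>`` columns (ground
    truth available in simulated cohorts only).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    n = cohort.n_trios
    w = cohort.variants["weight"].to_numpy()

    def score(g):
        gf = g.astype(float)
        gf[g == MISSING] = np.nan
        af = np.nanmean(gf, axis=0) / 2.0
        gf = np.where(np.isnan(gf), 2.0 * af, gf)
        return gf @ w

    z_child = _zscore(score(cohort.child))
    z_mother = _zscore(score(cohort.mother))
    z_father = _zscore(score(cohort.father))

    sex_female = rng.integers(0, 2, n)  # 1:1 split
    ses = rng.standard_normal(n)
    pcs = rng.standard_normal((n, 10))

    eta_m = config.eta_mother_by_age or config.eta_by_age
    eta_f = config.eta_father_by_age or config.eta_by_age

    data: dict[str, np.ndarray] = {
        "iid": np.array(cohort.child_ids),
        "sex": np.where(sex_female == 1, "female", "male"),
        "ses": ses,
    }
    for k in range(10):
        data[f"pc{k + 1}"] = pcs[:, k]

    sdqe_totals = []
    for age in config.ages:
        systematic = (
            config.delta_by_age[age] * z_child
            + eta_m[age] * z_mother
            + eta_f[age] * z_father
            + config.sex_effect * sex_female
            + config.ses_effect * ses
        )
        var_sys = systematic.var()
        if var_sys >= 0.95:
            raise ValueError(
                f"systematic liability variance {var_sys:.3f} at age {age} "
                "leaves no room for unit-variance noise scaling"
            )
        liability = systematic + np.sqrt(1.0 - var_sys) * rng.standard_normal(n)
        data[f"liability_age{age}"] = liability

        raters = ["parent"] + (["self"] if age in SELF_REPORT_AGES else [])
        for rater in raters:
            rel = np.sqrt(config.rater_reliability)
            rater_liab = rel * liability + np.sqrt(
                1.0 - config.rater_reliability
            ) * rng.standard_normal(n)
            items = _ordinal_items(rater_liab, 5, _SDQE_CUTS, config.item_loading, rng)
            total = items.sum(axis=1)
            data[f"sdqe_{rater}_age{age}"] = total
            sdqe_totals.append(total)
        if age == 14 and 14 in config.ages:
            rater_liab = np.sqrt(config.rater_reliability) * liability + np.sqrt(
                1.0 - config.rater_reliability
            ) * rng.standard_normal(n)
            data["smfq_self_age14"] = _ordinal_items(
                rater_liab, 13, _SMFQ_CUTS, config.item_loading, rng
            ).sum(axis=1)
        if age == 17 and 17 in config.ages:
            rater_liab = np.sqrt(config.rater_reliability) * liability + np.sqrt(
                1.0 - config.rater_reliability
            ) * rng.standard_normal(n)
            data["kmh_self_age17"] = _ordinal_items(
                rater_liab, 6, _KMH_CUTS, config.item_loading, rng
            ).sum(axis=1)

    any_high = np.zeros(n, dtype=bool)
    for total in sdqe_totals:
        any_high |= total >= SDQE_DISORDER_CUTOFF
    data["emotional_disorder"] = any_high.astype(int)
    data["in_trio_subset"] = np.ones(n, dtype=int)
    return pd.DataFrame(data)


def apply_attrition(
    cohort: TrioCohort,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Flag the trio-complete subset under liability/SES-dependent dropout.

    P(trio complete) = sigmoid(logit(attrition_intercept)
                               - attrition_beta * mean liability
                               + attrition_ses * SES),
    so higher-liability children are less likely, and higher-SES families
    more likely, to remain in the complete-trio subset.
    """
    if cohort.phenotypes is None:
        raise ValueError("phenotypes must be simulated before attrition")
    rng = rng if rng is not None else np.random.default_rng(config.seed + 3)
    phen = cohort.phenotypes
    liab_cols = [c for c in phen.columns if c.startswith("liability_age")]
    mean_liab = phen[liab_cols].to_numpy().mean(axis=1)
    logit0 = np.log(config.attrition_intercept / (1.0 - config.attrition_intercept))
    eta = logit0 - config.attrition_beta * mean_liab + config.attrition_ses * phen["ses"].to_numpy()
    p_complete = 1.0 / (1.0 + np.exp(-eta))
    phen = phen.copy()
    phen["in_trio_subset"] = (rng.random(len(phen)) < p_complete).astype(int)
    cohort.phenotypes = phen
    return phen


def completeness_probability(liability: float, ses: float, config: SimulationConfig) -> float:
    """Probability a trio stays complete at the given liability and SES."""
    logit0 = np.log(config.attrition_intercept / (1.0 - config.attrition_intercept))
    eta = logit0 - config.attrition_beta * liability + config.attrition_ses * ses
    return float(1.0 / (1.0 + np.exp(-eta)))


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------


def _variant_table(
    afs: np.ndarray, weights: np.ndarray, include_palindromic: bool, rng: np.random.Generator
) -> pd.DataFrame:
    n = afs.shape[0]
    pairs = _NONPALINDROMIC_PAIRS + (_PALINDROMIC_PAIRS if include_palindromic else [])
    alleles = [pairs[i] for i in rng.integers(0, len(pairs), n)]
    chrom = (np.arange(n) % 22) + 1
    pos = np.arange(n) // 22 * 1000 + 10_000 + (np.arange(n) % 22)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "id": [f"snp{i}" for i in range(n)],
            "ref": [a[0] for a in alleles],
            "alt": [a[1] for a in alleles],
            "af": afs,
            "weight": weights,
        }
    )


def simulate_cohort(config: SimulationConfig) -> TrioCohort:
    """End-to-end cohort simulation: founders, mating, transmission,
    phenotypes and attrition, fully determined by ``config`` (incl. seed)."""
    rng = np.random.default_rng(config.seed)
    n_consang = int(round(config.consang_fraction * config.n_trios))
    pool = simulate_founders(config, rng, n_parents=2 * (config.n_trios - n_consang))
    mother_g, father_g = pair_mates(pool, config, rng)
    child_g, t_m, t_f = transmit(mother_g, father_g, rng)

    variants = _variant_table(pool.allele_freq, pool.weights, config.include_palindromic, rng)
    n = config.n_trios
    cohort = TrioCohort(
        variants=variants,
        child=child_g,
        mother=mother_g,
        father=father_g,
        child_ids=[f"C{i:05d}" for i in range(n)],
        mother_ids=[f"M{i:05d}" for i in range(n)],
        father_ids=[f"F{i:05d}" for i in range(n)],
        transmission_truth={"t_m": t_m, "t_f": t_f},
        config=config,
    )
    cohort.phenotypes = simulate_phenotypes(cohort, config, rng)
    apply_attrition(cohort, config, rng)
    return cohort
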