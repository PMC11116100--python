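"""End-to-end orchestration: simulate -> resolve -> score -> associate -> diagnose.

Each stage is seedable and file-based, so a whole run is reproducible
from a config; ``recovery_experiment`` wraps repeated simulation + fit
cycles for parameter-recovery and calibration studies.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import association, diagnostics, io, pgs, transmission
from .simulate import MISSING, SimulationConfig, TrioCohort, simulate_cohort

log = logging.getLogger("triopgs")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_simulate(config: SimulationConfig, out_dir) -> dict:
    """Simulate a cohort, write it, and record a manifest with file hashes."""
    out_dir = Path(out_dir)
    cohort = simulate_cohort(config)
    paths = io.write_cohort(cohort, out_dir)
    manifest = {
        "truth": config.to_dict(),
        "files": {k: {"path": p.name, "sha256": _sha256(p)} for k, p in paths.items()},
        "n_trios": cohort.n_trios,
        "n_snps": cohort.n_snps,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("simulated %d trios x %d SNPs into %s", cohort.n_trios, cohort.n_snps, out_dir)
    return manifest


@dataclass
class ScoredCohort:
    """Cohort with resolved transmissions and standardized score sets."""

    cohort: TrioCohort
    resolution: transmission.TransmissionResolution
    pseudo: transmission.PseudoControlGenotypes
    scores: dict[str, pgs.ScoreSet]  # keys: child/T, mother, father, pseudo-control/NT


def score_cohort(
    cohort: TrioCohort,
    weights: Optional[pd.DataFrame] = None,
    phenotype_label: str = "emotional",
    ambiguous_policy: str = "set_missing",
    seed: Optional[int] = None,
    drop_palindromic: bool = True,
) -> ScoredCohort:
    """Resolve transmissions and build T / NT / parental score sets.

    When ``weights`` is None the cohort's own (causal) weight table is
    used.  Pseudo-control scores use the child allele frequencies for
    mean imputation at unresolved sites, keeping T and NT on one scale.
    """
    if weights is None:
        nz = cohort.variants[cohort.variants["weight"] != 0.0]
        weights = pd.DataFrame(
            {
                "CHR": nz["chrom"].values,
                "SNP": nz["id"].values,
                "BP": nz["pos"].values,
                "A1": nz["alt"].values,
                "A2": nz["ref"].values,
                "BETA": nz["weight"].values,
            }
        )
    res = transmission.resolve_cohort(
        cohort.child, cohort.mother, cohort.father, ambiguous_policy, seed
    )
    pseudo = transmission.build_pseudo_control(res)
    aligned = pgs.align_alleles(weights, cohort.variants, drop_palindromic)

    gf = cohort.child.astype(float)
    gf[cohort.child == MISSING] = np.nan
    child_af = np.nanmean(gf, axis=0) / 2.0

    phen = cohort.phenotypes
    pcs = (
        phen[[f"pc{k}" for k in range(1, 11)]].to_numpy()
        if phen is not None
        else np.zeros((cohort.n_trios, 1))
    )
    raw = {
        "child/T": pgs.score(cohort.child, aligned, allele_freq=child_af),
        "mother": pgs.score(cohort.mother, aligned),
        "father": pgs.score(cohort.father, aligned),
        "pseudo-control/NT": pgs.score(pseudo.dosage, aligned, allele_freq=child_af),
    }
    scores = {
        cls: pgs.standardize_and_residualize(
            r,
            pcs,
            phenotype=phenotype_label,
            transmission_class=cls,
            n_variants_scored=aligned.n_scored,
            drop_reasons=aligned.dropped,
        )
        for cls, r in raw.items()
    }
    return ScoredCohort(cohort, res, pseudo, scores)


def run_analysis(
    cohort_dir,
    out_dir,
    seed: int = 0,
    ambiguous_policy: str = "set_missing",
    analyses: Sequence[str] = (
        "transmitted",
        "non_transmitted",
        "per_age",
        "interaction",
        "trio_joint",
        "diagnostics",
    ),
) -> dict[str, Path]:
    """Run the association battery on a cohort directory and write tables.

    Transmitted-score models use every genotyped child; non-transmitted
    models are restricted to the trio-complete subset.  Outputs:
    ``table_transmitted.tsv``, ``table_non_transmitted.tsv``,
    ``per_age_results.tsv``, ``diagnostics.tsv`` and ``run_report.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = io.read_cohort(cohort_dir)
    if cohort.phenotypes is None:
        raise ValueError(f"no phenotype table in {cohort_dir}")
    scored = score_cohort(cohort, ambiguous_policy=ambiguous_policy, seed=seed)
    phen = cohort.phenotypes
    pcs = phen[[f"pc{k}" for k in range(1, 11)]].to_numpy()
    y = phen["emotional_disorder"].to_numpy(dtype=float)
    trio = phen["in_trio_subset"].to_numpy(dtype=bool)
    written: dict[str, Path] = {}

    def _table(cls: str, mask: np.ndarray) -> pd.DataFrame:
        res = association.fit_univariate(
            scored.scores[cls].z[mask], y[mask], pcs[mask], family="logistic",
            label="emotional",
        )
        association.attach_fdr([res])
        return association.results_table([res], transmission_class=cls)

    if "transmitted" in analyses:
        t = _table("child/T", np.ones(len(phen), dtype=bool))
        p = out_dir / "table_transmitted.tsv"
        t.to_csv(p, sep="\t", index=False)
        written["transmitted"] = p
    if "non_transmitted" in analyses:
        t = _table("pseudo-control/NT", trio)
        p = out_dir / "table_non_transmitted.tsv"
        t.to_csv(p, sep="\t", index=False)
        written["non_transmitted"] = p
    if "per_age" in analyses:
        rows = []
        score_cols = [c for c in phen.columns if c.startswith(("sdqe_", "smfq_", "kmh_"))]
        for cls, mask in (("child/T", np.ones(len(phen), bool)), ("pseudo-control/NT", trio)):
            results = []
            for col in score_cols:
                results.append(
                    association.fit_univariate(
                        scored.scores[cls].z[mask],
                        phen[col].to_numpy(dtype=float)[mask],
                        pcs[mask],
                        family="linear",
                        label=col,
                    )
                )
            association.attach_fdr(results)
            rows.append(association.results_table(results, transmission_class=cls))
        p = out_dir / "per_age_results.tsv"
        pd.concat(rows).to_csv(p, sep="\t", index=False)
        written["per_age"] = p
    if "interaction" in analyses:
        sex01 = (phen["sex"].to_numpy() == "female").astype(float)
        inter = association.fit_interaction(
            scored.scores["child/T"].z, y, sex01, pcs, family="logistic", label="emotional"
        )
        rows = [inter["interaction"].to_dict()]
        for key in sorted(k for k in inter if k.startswith("stratum")):
            d = inter[key].to_dict()
            d["model"] = f"{d['model']}:{'female' if key.endswith('1') else 'male'}"
            rows.append(d)
        p = out_dir / "table_interaction.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        written["interaction"] = p
    if "trio_joint" in analyses:
        joint = association.fit_trio_joint(
            scored.scores["child/T"].residualized[trio],
            scored.scores["mother"].residualized[trio],
            scored.scores["father"].residualized[trio],
            y[trio],
            pcs[trio],
            family="logistic",
        )
        p = out_dir / "table_trio_joint.tsv"
        association.results_table(list(joint.values())).to_csv(p, sep="\t", index=False)
        written["trio_joint"] = p
    if "diagnostics" in analyses:
        sc = scored.scores
        diag = diagnostics.mating_diagnostics(
            {
                "mother": sc["mother"].residualized[trio],
                "father": sc["father"].residualized[trio],
                "T": sc["child/T"].residualized[trio],
                "NT": sc["pseudo-control/NT"].residualized[trio],
            },
            phenotype="emotional",
        )
        p = out_dir / "diagnostics.tsv"
        diag.to_csv(p, sep="\t", index=False)
        written["diagnostics"] = p

    report = {
        "cohort_dir": str(cohort_dir),
        "seed": seed,
        "analyses": list(analyses),
        "n_children": int(len(phen)),
        "n_complete_trios": int(trio.sum()),
        "outputs": {k: p.name for k, p in written.items()},
    }
    with open(out_dir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    written["report"] = out_dir / "run_report.json"
    return written


def recovery_experiment(
    delta: float,
    eta: float,
    n_trios: int,
    reps: int,
    seed: int,
    n_snps: int = 500,
    r_am: float = 0.0,
    family: str = "linear",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Repeated simulate-and-fit cycles for estimand recovery.

    Each replicate simulates a cohort at the given direct (delta) and
    nurture (eta) liability effects with sex/SES effects off, fits the
    joint trio model and the univariate transmitted / non-transmitted
    models on the latent liability, and records estimates and p-values.
    Returns one row per replicate; summarize across rows for recovery
    means and rejection rates.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    rows = []
    for rep in range(reps):
        cfg = SimulationConfig(
            n_trios=n_trios,
            n_snps=n_snps,
            delta_by_age={11: delta},
            eta_by_age={11: eta},
            r_am=r_am,
            sex_effect=0.0,
            ses_effect=0.0,
            attrition_beta=0.0,
            ages=(11,),
            seed=seed + rep,
        )
        cohort = simulate_cohort(cfg)
        scored = score_cohort(
            cohort, ambiguous_policy="random_split", seed=cfg.seed + 10_000
        )
        phen = cohort.phenotypes
        y = phen["liability_age11"].to_numpy()
        pcs = phen[[f"pc{k}" for k in range(1, 11)]].to_numpy()
        sc = scored.scores
        joint = association.fit_trio_joint(
            sc["child/T"].z, sc["mother"].z, sc["father"].z, y, pcs, family=family
        )
        uni_t = association.fit_univariate(sc["child/T"].z, y, pcs, family=family)
        uni_nt = association.fit_univariate(sc["pseudo-control/NT"].z, y, pcs, family=family)
        rows.append(
            {
                "rep": rep,
                "child_hat": joint["child"].estimate,
                "mother_hat": joint["mother"].estimate,
                "father_hat": joint["father"].estimate,
                "t_slope": uni_t.estimate,
                "t_p": uni_t.p,
                "nt_slope": uni_nt.estimate,
                "nt_p": uni_nt.p,
                "t_reject": uni_t.p < alpha,
                "nt_reject": uni_nt.p < alpha,
            }
        )
    return pd.DataFrame(rows)


def summarize_recovery(df: pd.DataFrame) -> dict[str, float]:
    """Means, Monte-Carlo SEs, and rejection rates across replicates."""
    out = {}
    for col in ("child_hat", "mother_hat", "father_hat", "t_slope", "nt_slope"):
        out[f"{col}_mean"] = float(df[col].mean())
        out[f"{col}_mcse"] = float(df[col].std(ddof=1) / np.sqrt(len(df)))
    for col in ("t_reject", "nt_reject"):
        out[f"{col}_rate"] = float(df[col].mean())
    out["n_reps"] = int(len(df))
    return out
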