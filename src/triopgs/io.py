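"""Cohort file I/O: VCF 4.2 + PLINK-style FAM + TSV tables.

Writes a simulated trio cohort as plain-text files (genotypes as GT-only
VCF with ``./.`` for missing; pedigree as 6-column FAM; weights and
phenotypes as TSV) and reads them back into the in-memory containers.
Output contains no timestamps, so identical cohorts produce
byte-identical files.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .simulate import MISSING, SimulationConfig, TrioCohort

_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}

VCF_NAME = "cohort.vcf"
FAM_NAME = "cohort.fam"
WEIGHTS_NAME = "weights.tsv"
PHENO_NAME = "phenotypes.tsv"
DICT_NAME = "data_dictionary.tsv"
CONFIG_NAME = "simulation_config.yaml"


def write_cohort(cohort: TrioCohort, directory) -> dict[str, Path]:
    """Write a cohort to ``directory``; returns the paths written.

    Files: cohort.vcf (children, mothers, fathers as sample columns),
    cohort.fam, weights.tsv (CHR SNP BP A1 A2 BETA, nonzero causal
    weights), phenotypes.tsv, data_dictionary.tsv and, for simulated
    cohorts, simulation_config.yaml.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    samples = cohort.child_ids + cohort.mother_ids + cohort.father_ids
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids across children and parents")

    paths = {}
    vcf_path = directory / VCF_NAME
    geno = np.hstack([cohort.child.T, cohort.mother.T, cohort.father.T])  # variant x sample
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in sorted(cohort.variants["chrom"].unique()):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for j, v in enumerate(cohort.variants.itertuples(index=False)):
            gts = "\t".join(_GT[int(d)] for d in geno[j])
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t{gts}\n")
    paths["vcf"] = vcf_path

    fam_path = directory / FAM_NAME
    with open(fam_path, "w") as fh:
        for i, (c, m, f) in enumerate(
            zip(cohort.child_ids, cohort.mother_ids, cohort.father_ids)
        ):
            fam = f"FAM{i:05d}"
            fh.write(f"{fam}\t{c}\t{f}\t{m}\t0\t-9\n")
            fh.write(f"{fam}\t{f}\t0\t0\t1\t-9\n")
            fh.write(f"{fam}\t{m}\t0\t0\t2\t-9\n")
    paths["fam"] = fam_path

    w_path = directory / WEIGHTS_NAME
    nz = cohort.variants[cohort.variants["weight"] != 0.0]
    pd.DataFrame(
        {
            "CHR": nz["chrom"].values,
            "SNP": nz["id"].values,
            "BP": nz["pos"].values,
            "A1": nz["alt"].values,
            "A2": nz["ref"].values,
            "BETA": nz["weight"].values,
        }
    ).to_csv(w_path, sep="\t", index=False, float_format="%.10g")
    paths["weights"] = w_path

    if cohort.phenotypes is not None:
        p_path = directory / PHENO_NAME
        cohort.phenotypes.to_csv(p_path, sep="\t", index=False, float_format="%.10g")
        paths["phenotypes"] = p_path
        d_path = directory / DICT_NAME
        _write_data_dictionary(cohort.phenotypes, d_path)
        paths["data_dictionary"] = d_path

    if cohort.config is not None:
        import yaml

        c_path = directory / CONFIG_NAME
        with open(c_path, "w") as fh:
            yaml.safe_dump(cohort.config.to_dict(), fh, sort_keys=True)
        paths["config"] = c_path
    return paths


_DICT_DESCRIPTIONS = [
    ("iid", "child sample id (matches VCF and FAM)"),
    ("sex", "child sex: male or female"),
    ("ses", "family socio-economic status, z-score"),
    ("pc", "simulated genetic principal component (covariate)"),
    ("sdqe_parent", "SDQ emotional subscale total (0-10), parent report"),
    ("sdqe_self", "SDQ emotional subscale total (0-10), self report"),
    ("smfq_self", "SMFQ depressive symptoms total (0-26), self report, age 14"),
    ("kmh_self", "Kessler psychological distress total (0-24), self report, age 17"),
    ("liability", "latent liability (simulation ground truth)"),
    ("emotional_disorder", "1 if any SDQ-E total (any age/rater) >= 7"),
    ("in_trio_subset", "1 if trio complete after attrition"),
]


def _write_data_dictionary(phen: pd.DataFrame, path: Path) -> None:
    rows = []
    for col in phen.columns:
        desc = next((d for k, d in _DICT_DESCRIPTIONS if col.startswith(k)), "")
        rows.append({"column": col, "description": desc})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_cohort(directory) -> TrioCohort:
    """Read a cohort directory written by :func:`write_cohort`.

    Genotypes are read from the VCF via cyvcf2 as hard-call dosages;
    trio links come from the FAM file; phenotypes, weights and (when
    present) the simulation config are restored from their TSV/YAML.
    """
    directory = Path(directory)
    vcf_path = directory / VCF_NAME
    if not vcf_path.exists():
        raise FileNotFoundError(vcf_path)

    vcf = VCF(os.fspath(vcf_path), gts012=True)
    samples = list(vcf.samples)
    rows, dosages = [], []
    for v in vcf:
        rows.append(
            {
                "chrom": int(v.CHROM),
                "pos": v.POS,
                "id": v.ID,
                "ref": v.REF,
                "alt": v.ALT[0],
            }
        )
        # gts012: 0/1/2 = alt dosage, 3 = unknown
        d = v.gt_types.astype(np.int8)
        d[d == 3] = MISSING
        dosages.append(d)
    vcf.close()
    variants = pd.DataFrame(rows)
    geno = np.vstack(dosages).T  # sample x variant

    fam = pd.read_csv(
        directory / FAM_NAME,
        sep="\t",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype=str,
    )
    children = fam[(fam["father"] != "0") & (fam["mother"] != "0")]
    missing_parents = children[
        ~children["father"].isin(fam["iid"]) | ~children["mother"].isin(fam["iid"])
    ]
    if len(missing_parents):
        raise ValueError(
            f"children with parent ids absent from FAM: {missing_parents['iid'].tolist()}"
        )
    child_ids = children["iid"].tolist()
    mother_ids = children["mother"].tolist()
    father_ids = children["father"].tolist()
    sidx = {s: i for i, s in enumerate(samples)}
    child = geno[[sidx[s] for s in child_ids]]
    mother = geno[[sidx[s] for s in mother_ids]]
    father = geno[[sidx[s] for s in father_ids]]

    gf = child.astype(float)
    gf[child == MISSING] = np.nan
    variants["af"] = np.nanmean(np.vstack([gf, _to_nan(mother), _to_nan(father)]), axis=0) / 2.0

    weights = np.zeros(len(variants))
    w_path = directory / WEIGHTS_NAME
    if w_path.exists():
        w = pd.read_csv(w_path, sep="\t")
        wmap = dict(zip(w["SNP"], w["BETA"]))
        weights = np.array([wmap.get(i, 0.0) for i in variants["id"]])
    variants["weight"] = weights

    phen = None
    p_path = directory / PHENO_NAME
    if p_path.exists():
        phen = pd.read_csv(p_path, sep="\t")
        phen = phen.set_index("iid").loc[child_ids].reset_index()

    config = None
    c_path = directory / CONFIG_NAME
    if c_path.exists():
        import yaml

        with open(c_path) as fh:
            config = SimulationConfig.from_dict(yaml.safe_load(fh))

    return TrioCohort(
        variants=variants,
        child=child,
        mother=mother,
        father=father,
        child_ids=child_ids,
        mother_ids=mother_ids,
        father_ids=father_ids,
        phenotypes=phen,
        config=config,
    )


def _to_nan(g: np.ndarray) -> np.ndarray:
    gf = g.astype(float)
    gf[g == MISSING] = np.nan
    return gf
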