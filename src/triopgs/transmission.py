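"""Resolve transmitted / non-transmitted parental alleles in trios.

For each trio and biallelic SNP, determines which allele each parent
transmitted to the child, flags Mendelian errors and the one genuinely
ambiguous configuration (all three members heterozygous), and assembles
the "pseudo-control" genotype carrying the two non-transmitted parental
alleles.  At every resolved site the allele-conservation identity

    child dosage + pseudo-control dosage = mother dosage + father dosage

holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Optional

import numpy as np
import pandas as pd

MISSING = -1


class Status(IntEnum):
    RESOLVED = 0
    AMBIGUOUS = 1
    MENDEL_ERROR = 2
    MISSING = 3


def resolve_site(
    child: int, mother: int, father: int
) -> tuple[int, int, int, int, Status]:
    """Resolve one trio site from hard-call alt-allele dosages.

    Returns ``(t_m, nt_m, t_f, nt_f, status)`` with alt-allele indicators
    (0/1) for the transmitted and non-transmitted allele of each parent,
    or -1 where unresolved.  Deterministic for every Mendelian-consistent
    triple except the triple heterozygote, which is AMBIGUOUS.
    """
    for name, d in (("child", child), ("mother", mother), ("father", father)):
        if d not in (0, 1, 2, MISSING):
            raise ValueError(f"{name} dosage {d!r} not in {{0, 1, 2, missing}}")
    if MISSING in (child, mother, father):
        return MISSING, MISSING, MISSING, MISSING, Status.MISSING
    if child == mother == father == 1:
        return MISSING, MISSING, MISSING, MISSING, Status.AMBIGUOUS

    # Enumerate each parent's possible transmitted alt counts and keep the
    # combinations consistent with the child dosage.
    options_m = (0, 1) if mother == 1 else (mother // 2,)
    options_f = (0, 1) if father == 1 else (father // 2,)
    consistent = [
        (tm, tf) for tm in options_m for tf in options_f if tm + tf == child
    ]
    if not consistent:
        return MISSING, MISSING, MISSING, MISSING, Status.MENDEL_ERROR
    # Outside the triple heterozygote the consistent assignment is unique.
    (t_m, t_f) = consistent[0]
    return t_m, mother - t_m, t_f, father - t_f, Status.RESOLVED


def _build_lookup() -> dict[str, np.ndarray]:
    """4x4x4 lookup over (child, mother, father) with index 3 = missing."""
    shape = (4, 4, 4)
    tables = {k: np.full(shape, MISSING, dtype=np.int8) for k in ("t_m", "nt_m", "t_f", "nt_f")}
    status = np.full(shape, int(Status.MISSING), dtype=np.int8)
    dosages = (0, 1, 2, MISSING)
    for ci, c in enumerate(dosages):
        for mi, m in enumerate(dosages):
            for fi, f in enumerate(dosages):
                t_m, nt_m, t_f, nt_f, st = resolve_site(c, m, f)
                tables["t_m"][ci, mi, fi] = t_m
                tables["nt_m"][ci, mi, fi] = nt_m
                tables["t_f"][ci, mi, fi] = t_f
                tables["nt_f"][ci, mi, fi] = nt_f
                status[ci, mi, fi] = int(st)
    tables["status"] = status
    return tables


_LOOKUP = _build_lookup()


@dataclass
class TransmissionResolution:
    """Per trio x variant transmitted/non-transmitted alt-allele indicators."""

    t_m: np.ndarray  # (n_trios, n_snps) int8, -1 unresolved
    nt_m: np.ndarray
    t_f: np.ndarray
    nt_f: np.ndarray
    status: np.ndarray  # Status codes
    n_ambiguous_split: int = 0  # triple-het sites filled by random_split


@dataclass
class PseudoControlGenotypes:
    """Non-transmitted ("pseudo-control") dosages with resolution summaries."""

    dosage: np.ndarray  # (n_trios, n_snps) int8, -1 where unresolved
    per_trio_resolution_rate: np.ndarray
    per_variant_resolution_rate: np.ndarray


def resolve_cohort(
    child: np.ndarray,
    mother: np.ndarray,
    father: np.ndarray,
    ambiguous_policy: str = "set_missing",
    seed: Optional[int] = None,
) -> TransmissionResolution:
    """Vectorized transmission resolution for dosage matrices.

    ``ambiguous_policy`` is ``set_missing`` (default: triple-het sites stay
    unresolved) or ``random_split`` (the maternal transmitted allele is
    drawn fairly, mirroring a random phase assignment).
    """
    if ambiguous_policy not in ("set_missing", "random_split"):
        raise ValueError(f"unknown ambiguous_policy {ambiguous_policy!r}")
    for name, g in (("child", child), ("mother", mother), ("father", father)):
        vals = np.unique(g)
        if not np.isin(vals, [MISSING, 0, 1, 2]).all():
            if np.issubdtype(g.dtype, np.floating) and not np.isin(
                vals[np.isfinite(vals)], [MISSING, 0, 1, 2]
            ).all():
                raise ValueError(
                    f"{name} matrix contains fractional dosages; transmission "
                    "resolution requires hard calls in {0, 1, 2, missing}"
                )
            raise ValueError(f"{name} matrix has dosages outside {{0, 1, 2, missing}}")

    idx = lambda g: np.where(g == MISSING, 3, g).astype(np.intp)
    ci, mi, fi = idx(child), idx(mother), idx(father)
    res = TransmissionResolution(
        t_m=_LOOKUP["t_m"][ci, mi, fi],
        nt_m=_LOOKUP["nt_m"][ci, mi, fi],
        t_f=_LOOKUP["t_f"][ci, mi, fi],
        nt_f=_LOOKUP["nt_f"][ci, mi, fi],
        status=_LOOKUP["status"][ci, mi, fi],
    )
    if ambiguous_policy == "random_split":
        amb = res.status == int(Status.AMBIGUOUS)
        n_amb = int(amb.sum())
        if n_amb:
            rng = np.random.default_rng(seed)
            b = rng.integers(0, 2, size=n_amb, dtype=np.int8)
            res.t_m[amb] = b
            res.nt_m[amb] = 1 - b
            res.t_f[amb] = 1 - b
            res.nt_f[amb] = b
            res.status[amb] = int(Status.RESOLVED)
        res.n_ambiguous_split = n_amb
    return res


def build_pseudo_control(resolution: TransmissionResolution) -> PseudoControlGenotypes:
    """Assemble pseudo-control dosages (nt_m + nt_f) at resolved sites."""
    resolved = resolution.status == int(Status.RESOLVED)
    dosage = np.full(resolution.t_m.shape, MISSING, dtype=np.int8)
    dosage[resolved] = resolution.nt_m[resolved] + resolution.nt_f[resolved]
    return PseudoControlGenotypes(
        dosage=dosage,
        per_trio_resolution_rate=resolved.mean(axis=1),
        per_variant_resolution_rate=resolved.mean(axis=0),
    )


def mendel_summary(resolution: TransmissionResolution) -> dict[str, pd.DataFrame]:
    """Per-variant and per-trio fractions of each resolution status."""
    out = {}
    for axis, key in ((0, "per_variant"), (1, "per_trio")):
        rows = {
            st.name.lower(): (resolution.status == int(st)).mean(axis=axis)
            for st in Status
        }
        out[key] = pd.DataFrame(rows)
    return out


def drop_high_error_variants(
    resolution: TransmissionResolution, max_error_rate: float = 0.01
) -> np.ndarray:
    """Boolean keep-mask over variants with trio Mendel-error rate <= cutoff."""
    err_rate = (resolution.status == int(Status.MENDEL_ERROR)).mean(axis=0)
    return err_rate <= max_error_rate
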