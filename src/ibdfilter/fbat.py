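"""Family-based association score test with empirical (robust) variance.

The statistic compares affected offspring genotypes with their Mendelian
expectation given the parents.  With additive coding X = minor-allele
dosage, each nuclear family f contributes

    U_f = sum over affected offspring of (X - E[X | parents]),

where E[X | parents] = g_f/2 + g_m/2 from independent transmission of
one allele per parent.  The total score is U = sum_f U_f and

    model variance      V = sum_f sum_aff Var(X | parents),
    empirical variance  V = sum_f U_f**2        (the "-e" option),

with Z = U / sqrt(V) and a two-sided normal p-value.  The empirical
variance is robust when several nuclear families come from the same
extended pedigree and are therefore correlated.

Only families with both parental genotypes observed contribute; a
family is informative for a marker when at least one parent is
heterozygous and at least one affected offspring is genotyped.  A
marker is screened only in replicates where it is informative in at
least ``min_pedigrees`` extended pedigrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .pedigree import Pedigree


@dataclass(frozen=True)
class NuclearFamily:
    """A mated pair and their common offspring inside an extended pedigree."""

    pedigree_id: str
    father: str
    mother: str
    offspring: tuple[str, ...]

    def __post_init__(self):
        if not self.offspring:
            raise ValueError("nuclear family must have at least one offspring")


def split_nuclear(pedigree: Pedigree) -> list[NuclearFamily]:
    """One nuclear family per mated pair with children; an individual may
    be offspring in one family and parent in another."""
    fams = []
    for (fa, mo), kids in pedigree.couples():
        fams.append(
            NuclearFamily(
                pedigree_id=pedigree.individual(fa).family,
                father=fa,
                mother=mo,
                offspring=kids,
            )
        )
    return fams


def mendelian_moments(g_father: float, g_mother: float) -> tuple[float, float]:
    """Mean and variance of offspring minor-allele dosage given parents.

    Each parent transmits its minor allele with probability g/2,
    independently, so E[X] = gf/2 + gm/2 and Var[X] is the sum of the
    two Bernoulli variances.
    """
    pf, pm = g_father / 2.0, g_mother / 2.0
    return pf + pm, pf * (1.0 - pf) + pm * (1.0 - pm)


def is_informative(
    family: NuclearFamily,
    dosages: pd.DataFrame,
    snp: str,
    affected: Iterable[str],
) -> bool:
    """True when the family can contribute: both parents genotyped, at
    least one heterozygous, and at least one affected genotyped offspring."""
    col = dosages[snp]
    gf = col.get(family.father)
    gm = col.get(family.mother)
    if gf is None or gm is None or pd.isna(gf) or pd.isna(gm):
        return False
    aff = set(affected)
    has_affected = any(
        kid in aff and kid in col.index and not pd.isna(col[kid])
        for kid in family.offspring
    )
    return has_affected and (gf == 1 or gm == 1)


@dataclass(frozen=True)
class FbatResult:
    snp: str
    n_informative_families: int
    n_informative_pedigrees: int
    U: float
    V: float
    Z: float  # nan when not testable
    p: float  # nan when not testable
    testable: bool
    variance: str  # "empirical" | "model"


def fbat_score(
    families: Sequence[NuclearFamily],
    snp: str,
    dosages: pd.DataFrame,
    affected: Iterable[str],
    empirical_variance: bool = True,
) -> FbatResult:
    """Score test over the informative families for one marker."""
    aff = set(affected)
    col = dosages[snp]
    U = 0.0
    V = 0.0
    peds = set()
    n_inf = 0
    for fam in families:
        if not is_informative(fam, dosages, snp, aff):
            continue
        gf, gm = float(col[fam.father]), float(col[fam.mother])
        e, v = mendelian_moments(gf, gm)
        u_f = 0.0
        n_aff = 0
        for kid in fam.offspring:
            if kid in aff and kid in col.index and not pd.isna(col[kid]):
                u_f += float(col[kid]) - e
                n_aff += 1
        U += u_f
        V += u_f * u_f if empirical_variance else n_aff * v
        n_inf += 1
        peds.add(fam.pedigree_id)
    variance = "empirical" if empirical_variance else "model"
    if n_inf == 0 or V <= 0.0:
        return FbatResult(snp, n_inf, len(peds), U, V, float("nan"), float("nan"),
                          testable=False, variance=variance)
    Z = U / math.sqrt(V)
    p = 2.0 * float(norm.sf(abs(Z)))
    return FbatResult(snp, n_inf, len(peds), U, V, Z, p, testable=True,
                      variance=variance)


# -- replicate screen --------------------------------------------------


class _FamilyIndex:
    """Flat array view of the nuclear families for vectorised screening."""

    def __init__(self, families: Sequence[NuclearFamily], id_index: dict[str, int]):
        self.father = np.array([id_index[f.father] for f in families])
        self.mother = np.array([id_index[f.mother] for f in families])
        peds = sorted({f.pedigree_id for f in families})
        self.ped_code = np.array(
            [peds.index(f.pedigree_id) for f in families], dtype=np.int32
        )
        self.n_pedigrees = len(peds)
        child_idx, child_fam = [], []
        for fi, f in enumerate(families):
            for kid in f.offspring:
                child_idx.append(id_index[kid])
                child_fam.append(fi)
        self.child = np.array(child_idx)
        self.child_fam = np.array(child_fam, dtype=np.int64)
        self.n_families = len(families)


def run_fbat_screen(
    pedigree: Pedigree,
    dosages: pd.DataFrame,
    affection: pd.DataFrame,
    snps: Sequence[str],
    min_pedigrees: int = 3,
    alpha: float = 0.05,
    empirical_variance: bool = True,
) -> pd.DataFrame:
    """Screen markers across phenotype replicates.

    For each marker, the test runs in every replicate where it is
    informative in at least ``min_pedigrees`` extended pedigrees; the
    minimum p across tested replicates is recorded and the marker is
    flagged when it falls below ``alpha``.  Markers never reaching
    ``min_pedigrees`` are excluded with a reason.

    ``affection`` is a boolean individuals x replicates frame.
    """
    if min_pedigrees < 1:
        raise ValueError("min_pedigrees must be >= 1")
    families = split_nuclear(pedigree)
    ids = list(dosages.index)
    id_index = {iid: i for i, iid in enumerate(ids)}
    fx = _FamilyIndex(families, id_index)
    dos = dosages.to_numpy(dtype=float)
    aff = affection.reindex(ids).to_numpy(dtype=bool)
    rep_ids = list(affection.columns)
    col_of = {s: j for j, s in enumerate(dosages.columns)}

    rows = []
    for snp in snps:
        x = dos[:, col_of[snp]]
        gf, gm = x[fx.father], x[fx.mother]
        ok_parents = ~(np.isnan(gf) | np.isnan(gm))
        het = ok_parents & ((gf == 1) | (gm == 1))
        pf = np.where(ok_parents, gf / 2.0, 0.0)
        pm = np.where(ok_parents, gm / 2.0, 0.0)
        e = pf + pm
        v = pf * (1 - pf) + pm * (1 - pm)
        xc = x[fx.child]
        resid = xc - e[fx.child_fam]
        child_ok = ~np.isnan(xc)

        min_p = np.inf
        min_rep = None
        n_tested = 0
        best_n_ped = 0
        for r, rep in enumerate(rep_ids):
            use = aff[fx.child, r] & child_ok
            n_aff = np.bincount(fx.child_fam, weights=use, minlength=fx.n_families)
            informative = het & (n_aff > 0)
            n_ped = len(np.unique(fx.ped_code[informative]))
            best_n_ped = max(best_n_ped, n_ped)
            if n_ped < min_pedigrees:
                continue
            u_f = np.bincount(
                fx.child_fam, weights=np.where(use, resid, 0.0), minlength=fx.n_families
            )
            U = float(u_f[informative].sum())
            if empirical_variance:
                V = float((u_f[informative] ** 2).sum())
            else:
                V = float((n_aff * v)[informative].sum())
            if V <= 0.0:
                continue
            p = 2.0 * float(norm.sf(abs(U) / math.sqrt(V)))
            n_tested += 1
            if p < min_p:
                min_p, min_rep = p, rep
        if n_tested == 0:
            rows.append(
                {
                    "snp": snp,
                    "n_replicates_tested": 0,
                    "best_n_informative_pedigrees": best_n_ped,
                    "min_p": float("nan"),
                    "min_p_replicate": None,
                    "flagged": False,
                    "reason": "insufficient informative pedigrees",
                }
            )
        else:
            rows.append(
                {
                    "snp": snp,
                    "n_replicates_tested": n_tested,
                    "best_n_informative_pedigrees": best_n_ped,
                    "min_p": min_p,
                    "min_p_replicate": min_rep,
                    "flagged": bool(min_p < alpha),
                    "reason": "",
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "snp",
            "n_replicates_tested",
            "best_n_informative_pedigrees",
            "min_p",
            "min_p_replicate",
            "flagged",
            "reason",
        ],
    )
    return out.set_index("snp")
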