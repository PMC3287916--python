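"""Kinship, relationship degree, and expected vs realized genome sharing.

Distant affected relatives share little of their genome identical by
descent, so IBD regions they do share are a small search space for risk
alleles.  The expected genome fraction shared by a relative pair of
degree *m* is ``(1/2)**m``: 50% for parent-offspring, 25% for
second-degree pairs (avuncular, grandparental), 12.5% for first cousins,
6.25% for fourth- and 3.13% for fifth-degree pairs.  Degree is defined
through the kinship coefficient phi (``g = 2*phi``) rather than raw path
meioses, so two-common-ancestor relationships such as first cousins
(four path meioses, g = 1/8) land on the conventional degree 3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, TYPE_CHECKING

import pandas as pd

from .pedigree import Pedigree, PedigreeError

if TYPE_CHECKING:  # pragma: no cover
    from .ibd import IbdMatrix


def expected_sharing(degree: int) -> float:
    """Expected genome fraction shared IBD by outbred relatives of ``degree``."""
    if not isinstance(degree, int) or isinstance(degree, bool):
        raise TypeError(f"degree must be an integer, got {degree!r}")
    if degree < 1:
        raise ValueError(f"degree must be >= 1, got {degree}")
    return 0.5**degree


def kinship(pedigree: Pedigree, id1: str, id2: str) -> float:
    """Kinship coefficient phi: probability that one allele drawn at random
    from each individual is identical by descent.

    Standard recursion: distinct founders have phi 0; phi(x, x) is
    (1 + F_x)/2 with F_x the kinship of x's parents; for a non-founder
    whose generation rank is >= the other's, phi is the mean of the
    parental kinships with the other individual.
    """
    pedigree.individual(id1)
    pedigree.individual(id2)
    memo: dict[tuple[str, str], float] = {}
    return _kin(pedigree, id1, id2, memo)


def _kin(ped: Pedigree, a: str, b: str, memo: dict[tuple[str, str], float]) -> float:
    key = (a, b) if a <= b else (b, a)
    hit = memo.get(key)
    if hit is not None:
        return hit
    ia, ib = ped.individual(a), ped.individual(b)
    if a == b:
        if ia.is_founder:
            phi = 0.5
        else:
            phi = 0.5 * (1.0 + _kin(ped, ia.father, ia.mother, memo))
    else:
        # recurse on the individual with the larger generation rank, which
        # is guaranteed not to be an ancestor of the other
        if ped.generation(a) < ped.generation(b):
            a, b, ia, ib = b, a, ib, ia
        if ia.is_founder:
            phi = 0.0
        else:
            phi = 0.5 * (_kin(ped, ia.father, b, memo) + _kin(ped, ia.mother, b, memo))
    memo[key] = phi
    return phi


@dataclass(frozen=True)
class RelationshipDegree:
    """Degree band of a relative pair.

    ``degree`` is ``None`` for unrelated pairs and 0 for self; ``exact``
    is False when 2*phi is not a power of 1/2 (e.g. three-quarter sibs),
    in which case ``degree`` is the nearest integer band.
    """

    degree: Optional[int]
    exact: bool


def relationship_degree(pedigree: Pedigree, id1: str, id2: str) -> RelationshipDegree:
    phi = kinship(pedigree, id1, id2)
    if phi == 0.0:
        return RelationshipDegree(degree=None, exact=True)
    g = 2.0 * phi
    degree = max(0, round(-math.log2(g)))
    exact = math.isclose(g, 0.5**degree, rel_tol=0.0, abs_tol=1e-12)
    return RelationshipDegree(degree=degree, exact=exact)


def realized_sharing(ibd: "IbdMatrix", pair: tuple[str, str]) -> float:
    """Genome fraction shared by ``pair``: unweighted mean of per-gene IBD scores."""
    return ibd.realized_sharing(pair)


def relationship_table(
    pedigree: Pedigree, ibd: Optional["IbdMatrix"] = None
) -> pd.DataFrame:
    """Pairwise within-family relationship summary.

    Columns: id1, id2, kinship, degree (NaN if unrelated), exact,
    expected_sharing, realized_sharing (NaN without an IBD matrix).
    """
    rows = []
    for fam in pedigree.families:
        ids = sorted(pedigree.members_of(fam))
        memo: dict[tuple[str, str], float] = {}
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                phi = _kin(pedigree, a, b, memo)
                deg = relationship_degree(pedigree, a, b)
                exp = float("nan") if deg.degree in (None, 0) else 0.5**deg.degree
                real = float("nan")
                if ibd is not None and (a, b) in ibd:
                    real = ibd.realized_sharing((a, b))
                rows.append(
                    {
                        "id1": a,
                        "id2": b,
                        "kinship": phi,
                        "degree": deg.degree,
                        "exact": deg.exact,
                        "expected_sharing": exp,
                        "realized_sharing": real,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "id1",
            "id2",
            "kinship",
            "degree",
            "exact",
            "expected_sharing",
            "realized_sharing",
        ],
    )
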