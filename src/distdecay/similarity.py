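"""Incidence-based pairwise similarity indices.

For a pair of sites, with ``a`` the number of shared species and ``b``,
``c`` the numbers unique to each site:

* Jaccard similarity  J = a / (a + b + c) — sensitive to richness
  differences (a nested pair scores < 1);
* Simpson similarity  S = a / (a + min(b, c)) — the complement of the
  beta-sim turnover measure, equal to 1 whenever one assemblage nests in
  the other, hence independent of richness gradients.

Both range over [0, 1] and S >= J for every pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import OccurrenceMatrix, PairwiseMatrix

INDICES = ("jaccard", "simpson")


@dataclass(frozen=True)
class PairCounts:
    """Shared/unique species counts for one site pair."""

    a: int  # present at both sites
    b: int  # only at site 1
    c: int  # only at site 2

    def __post_init__(self):
        if min(self.a, self.b, self.c) < 0:
            raise ValueError("counts must be non-negative")


def jaccard(counts: PairCounts) -> float:
    """Jaccard similarity a / (a + b + c)."""
    denom = counts.a + counts.b + counts.c
    if denom == 0:
        raise ValueError("Jaccard undefined for two empty assemblages (a+b+c = 0)")
    return counts.a / denom


def simpson(counts: PairCounts) -> float:
    """Simpson similarity a / (a + min(b, c)); 1 for nested assemblages."""
    denom = counts.a + min(counts.b, counts.c)
    if denom == 0:
        raise ValueError("Simpson undefined when a = 0 and min(b, c) = 0")
    return counts.a / denom


def pair_counts(occ: OccurrenceMatrix, i: int, j: int) -> PairCounts:
    """Counts a, b, c for the sites at row positions i and j."""
    x = occ.incidence[i].astype(bool)
    y = occ.incidence[j].astype(bool)
    a = int(np.sum(x & y))
    return PairCounts(a=a, b=int(x.sum()) - a, c=int(y.sum()) - a)


def similarity_matrix(occ: OccurrenceMatrix, index: str = "jaccard") -> PairwiseMatrix:
    """All-pairs similarity matrix for the chosen index.

    Computed via the incidence cross-product: A = X X^T gives the shared
    counts, from which b and c follow from row sums.
    """
    if index not in INDICES:
        raise ValueError(f"index must be one of {INDICES}, got {index!r}")
    x = occ.incidence.astype(np.int64)
    shared = x @ x.T
    rich = x.sum(axis=1)
    b = rich[:, None] - shared
    c = rich[None, :] - shared
    if index == "jaccard":
        denom = shared + b + c
    else:
        denom = shared + np.minimum(b, c)
    if (denom == 0).any():
        raise ValueError("undefined similarity: a site pair with zero denominator")
    values = shared / denom
    return PairwiseMatrix(list(occ.site_ids), values, "similarity")
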