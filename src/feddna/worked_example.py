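"""The three-site worked example used to illustrate greedy tree matching.

Three sites each hold three neurons — Site 1 = {A, B, C}, Site 2 = {a, b, c},
Site 3 = {alpha, beta, gamma} — and only the pairwise cross-site distances
are given, as three 3x3 blocks.  The globally closest pair is (B, a) at
0.11, which seeds the first matching tree; Site 3's node alpha then joins at
distance 0.13 (its distance to both current members), completing the first
tree {a, B, alpha}.  The example is executable directly from the distance
blocks via :class:`~feddna.matching.TableDistanceSource`.
"""

from __future__ import annotations

import numpy as np

from .matching import DistanceTable, TableDistanceSource, tables_to_source

__all__ = [
    "SITE_LABELS",
    "three_site_tables",
    "three_site_source",
    "label_of",
]

#: node labels per site, index order matching the distance blocks
SITE_LABELS = (
    ("A", "B", "C"),
    ("a", "b", "c"),
    ("alpha", "beta", "gamma"),
)

# Site 1 rows (A, B, C) x Site 2 cols (a, b, c)
_SITE1_SITE2 = [
    [0.12, 0.15, 0.16],
    [0.11, 0.13, 0.17],
    [0.16, 0.14, 0.18],
]
# Site 3 rows (alpha, beta, gamma) x Site 1 cols (A, B, C)
_SITE3_SITE1 = [
    [0.27, 0.13, 0.19],
    [0.23, 0.14, 0.18],
    [0.21, 0.16, 0.21],
]
# Site 3 rows (alpha, beta, gamma) x Site 2 cols (a, b, c)
_SITE3_SITE2 = [
    [0.13, 0.24, 0.18],
    [0.14, 0.19, 0.21],
    [0.21, 0.21, 0.25],
]


def three_site_tables() -> list[DistanceTable]:
    """The three printed distance blocks as labeled :class:`DistanceTable`s."""
    return [
        DistanceTable(0, 1, list(SITE_LABELS[0]), list(SITE_LABELS[1]),
                      np.array(_SITE1_SITE2)),
        DistanceTable(2, 0, list(SITE_LABELS[2]), list(SITE_LABELS[0]),
                      np.array(_SITE3_SITE1)),
        DistanceTable(2, 1, list(SITE_LABELS[2]), list(SITE_LABELS[1]),
                      np.array(_SITE3_SITE2)),
    ]


def three_site_source() -> TableDistanceSource:
    """Distance source over the worked example's three sites."""
    return tables_to_source(three_site_tables(), n_sites=3)


def label_of(site: int, node: int) -> str:
    """Human-readable node label for a (site, node) pair of the example."""
    return SITE_LABELS[site][node]
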