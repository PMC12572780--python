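"""Published field-survey count data bundled for the association analyses.

These are the printed colony-level tallies from the queen-size-dimorphic
ant survey the pipeline is modeled on (31 colonies from southern Finland):
queen censuses per colony type, supergene genotype classes of resident
queens, and estimated matriline counts from worker microsatellites. They
are inputs to the exact tests, not outputs of this package.
"""

from __future__ import annotations

import pandas as pd

#: Queens captured per sampling round: 11 queens from the first 7 colonies,
#: 78 from the remaining 24 colonies.
N_QUEENS_CAPTURED = (11, 78)
N_COLONIES = 31

#: Colony type x colony genotype class (AA if any resident queen AA):
#: 20 single-queen colonies (14 AA / 6 non-AA), 11 multiple-queen colonies
#: (0 AA / 11 non-AA).
COLONY_TYPE_BY_GENOTYPE = pd.DataFrame(
    [[14, 6], [0, 11]],
    index=["single-queen", "multiple-queen"],
    columns=["AA", "non-AA"],
)

#: Queen genotype class x estimated matriline count for the colonies with
#: worker microsatellite data: 12 AA colonies (10 single-matriline / 2
#: multiple), 6 non-AA single-queen colonies plus 4 multiple-queen control
#: colonies (1 single / 9 multiple).
MATRILINES_BY_GENOTYPE = pd.DataFrame(
    [[10, 2], [1, 9]],
    index=["AA", "non-AA"],
    columns=["single-matriline", "multiple-matriline"],
)


def mean_queens_per_colony() -> float:
    """Mean captured adult queens per colony across the survey."""
    return sum(N_QUEENS_CAPTURED) / N_COLONIES
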