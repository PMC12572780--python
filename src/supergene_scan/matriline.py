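"""Parsimony matriline estimation from worker microsatellite genotypes.

Under haplodiploidy a mother is diploid and her (single) mate haploid, so
all full sisters share the paternal allele at every locus and carry one of
at most two maternal alleles. A set of workers is *family-consistent* under
monandry when such a father/mother configuration exists at every locus; the
polyandry relaxation only requires a shared diploid mother (every worker
carries at least one maternal allele). The number of matrilines in a colony
is estimated as the minimum number of family-consistent blocks partitioning
its workers — a deterministic, auditable stand-in for likelihood-based
sibship reconstruction. Missing data at a locus is uninformative and never
falsifies a family.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, combinations_with_replacement
from typing import Optional, Sequence

import numpy as np
import pandas as pd

MODES = ("monandry", "polyandry")


@dataclass(frozen=True)
class WorkerGenotype:
    worker_id: str
    colony_id: str
    #: per-locus unordered allele pair; None marks a missing locus
    loci: tuple[Optional[tuple[int, int]], ...]


@dataclass
class MatrilinePartition:
    colony_id: str
    blocks: list[list[str]]  # worker ids per matriline
    mode: str
    exact: bool  # True when found by exhaustive partition search

    @property
    def n_matrilines(self) -> int:
        return len(self.blocks)


def workers_from_table(table: pd.DataFrame) -> list[WorkerGenotype]:
    """Parse a microsatellite TSV with worker_id, colony_id and L<k>_a1/_a2
    columns; non-finite allele values mark a missing locus."""
    loci_names = sorted(
        {c.rsplit("_", 1)[0] for c in table.columns if c.endswith("_a1")},
        key=lambda s: int(s[1:]),
    )
    out = []
    for _, row in table.iterrows():
        pairs = []
        for loc in loci_names:
            a1, a2 = row[f"{loc}_a1"], row[f"{loc}_a2"]
            if pd.isna(a1) or pd.isna(a2):
                pairs.append(None)
            else:
                pairs.append(tuple(sorted((int(a1), int(a2)))))
        out.append(
            WorkerGenotype(str(row["worker_id"]), str(row["colony_id"]), tuple(pairs))
        )
    return out


def _locus_pairs(workers: Sequence[WorkerGenotype], locus: int):
    return [w.loci[locus] for w in workers if w.loci[locus] is not None]


def _monandry_locus_ok(pairs: Sequence[tuple[int, int]]) -> bool:
    """Is there a paternal allele f and mother {m1, m2} explaining every
    pair as {f, m}?"""
    candidates = set(pairs[0])
    for pair in pairs[1:]:
        candidates &= set(pair)
        if not candidates:
            return False
    for f in candidates:
        maternal = set()
        for a, b in pairs:
            maternal.add(b if a == f else a)  # {f,f} contributes f itself
        if len(maternal) <= 2:
            return True
    return False


def _polyandry_locus_ok(pairs: Sequence[tuple[int, int]]) -> bool:
    """Is there a diploid mother {m1, m2} with every worker carrying at
    least one maternal allele?"""
    alleles = sorted({a for pair in pairs for a in pair})
    for m1, m2 in combinations_with_replacement(alleles, 2):
        if all(m1 in pair or m2 in pair for pair in pairs):
            return True
    return False


def family_consistent(workers: Sequence[WorkerGenotype], mode: str = "monandry") -> bool:
    """Can these workers be one matriline under the given mating mode?"""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if not workers:
        raise ValueError("need >= 1 worker")
    n_loci = len(workers[0].loci)
    if n_loci == 0:
        raise ValueError("no loci")
    check = _monandry_locus_ok if mode == "monandry" else _polyandry_locus_ok
    any_data = False
    for locus in range(n_loci):
        pairs = _locus_pairs(workers, locus)
        if not pairs:
            continue
        any_data = True
        if not check(pairs):
            return False
    if not any_data:
        raise ValueError("no locus with data")
    return True


def _exact_min_partition(
    workers: list[WorkerGenotype], mode: str
) -> list[list[int]]:
    """Branch-and-bound over set partitions (workers in fixed order)."""
    best: list[list[int]] = [[i] for i in range(len(workers))]

    def recurse(i: int, blocks: list[list[int]]):
        nonlocal best
        if len(blocks) >= len(best):
            return
        if i == len(workers):
            best = [list(b) for b in blocks]
            return
        for b in blocks:
            members = [workers[k] for k in b] + [workers[i]]
            if family_consistent(members, mode):
                b.append(i)
                recurse(i + 1, blocks)
                b.pop()
        blocks.append([i])
        recurse(i + 1, blocks)
        blocks.pop()

    recurse(0, [])
    return best


def _greedy_partition(workers: list[WorkerGenotype], mode: str) -> list[list[int]]:
    """Seed each block with the unassigned worker having fewest pairwise-
    compatible peers, then grow while the block stays consistent."""
    n = len(workers)
    compat = np.zeros((n, n), dtype=int)
    for i, j in combinations(range(n), 2):
        if family_consistent([workers[i], workers[j]], mode):
            compat[i, j] = compat[j, i] = 1
    unassigned = set(range(n))
    blocks = []
    while unassigned:
        seed = min(
            unassigned, key=lambda i: (compat[i, sorted(unassigned)].sum(), i)
        )
        block = [seed]
        unassigned.discard(seed)
        for j in sorted(unassigned):
            if family_consistent([workers[k] for k in block + [j]], mode):
                block.append(j)
                unassigned.discard(j)
        blocks.append(sorted(block))
    return blocks


def min_matrilines(
    workers: Sequence[WorkerGenotype],
    mode: str = "monandry",
    exact_limit: int = 9,
) -> MatrilinePartition:
    """Minimum number of family-consistent blocks for one colony's workers.

    Exhaustive partition search when the colony has at most ``exact_limit``
    workers; otherwise a greedy cover whose block count is an upper bound on
    the exact minimum.
    """
    workers = list(workers)
    if not workers:
        raise ValueError("need >= 1 worker")
    colony = workers[0].colony_id
    exact = len(workers) <= exact_limit
    blocks_idx = (
        _exact_min_partition(workers, mode)
        if exact
        else _greedy_partition(workers, mode)
    )
    blocks = [[workers[i].worker_id for i in b] for b in blocks_idx]
    return MatrilinePartition(colony_id=colony, blocks=blocks, mode=mode, exact=exact)


def colony_matriline_counts(
    table: pd.DataFrame, mode: str = "monandry", exact_limit: int = 9
) -> pd.DataFrame:
    """Estimated matriline count per colony from a microsatellite table."""
    workers = workers_from_table(table)
    rows = []
    by_colony: dict[str, list[WorkerGenotype]] = {}
    for w in workers:
        by_colony.setdefault(w.colony_id, []).append(w)
    for colony in sorted(by_colony):
        part = min_matrilines(by_colony[colony], mode=mode, exact_limit=exact_limit)
        rows.append(
            {
                "colony_id": colony,
                "n_workers": len(by_colony[colony]),
                "n_matrilines": part.n_matrilines,
                "mode": mode,
                "exact": part.exact,
            }
        )
    return pd.DataFrame(rows)
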