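"""Graded taxon-subsampling design.

Datamatrices are built at increasing per-family sampling levels (by
default 100, 200, 300, 400 and 500 species per family) with independent
replicate draws at each level. Within a family, species are drawn
uniformly at random without replacement; a family smaller than the level
is kept whole. Every job's random stream is derived deterministically
from the scheme's master seed via ``numpy.random.SeedSequence`` spawn
keys, so replicates are independent and the whole design is reproducible
from a single integer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .congruence import ConcordanceGroup
from .treekit import Alignment

__all__ = ["SamplingScheme", "Job", "subsample_matrix", "enumerate_datamatrices"]

DEFAULT_LEVELS = (100, 200, 300, 400, 500)


@dataclass(frozen=True)
class SamplingScheme:
    levels: tuple = DEFAULT_LEVELS
    replicates: int = 2
    master_seed: int = 0

    def __post_init__(self):
        levels = tuple(int(l) for l in self.levels)
        if not levels or any(l <= 0 for l in levels):
            raise ValueError("levels must be positive integers")
        if list(levels) != sorted(set(levels)):
            raise ValueError("levels must be strictly increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        object.__setattr__(self, "levels", levels)


@dataclass(frozen=True)
class Job:
    level: int
    replicate: int
    seed: int


def enumerate_datamatrices(scheme: SamplingScheme) -> list[Job]:
    """All (level, replicate) jobs with distinct derived seeds.

    5 levels x 2 replicates gives the design's 10 datamatrices.
    """
    jobs = []
    for li, level in enumerate(scheme.levels):
        for ri in range(scheme.replicates):
            ss = np.random.SeedSequence(scheme.master_seed,
                                        spawn_key=(li, ri))
            seed = int(ss.generate_state(1)[0] & 0x7FFFFFFF)
            jobs.append(Job(level=level, replicate=ri + 1, seed=seed))
    if len({j.seed for j in jobs}) != len(jobs):  # astronomically unlikely
        raise RuntimeError("derived seed collision; change master_seed")
    return jobs


def subsample_matrix(alignment: Alignment,
                     groups: Sequence[ConcordanceGroup],
                     level: int,
                     seed: int) -> tuple[Alignment, list[ConcordanceGroup]]:
    """Random per-group subsample of at most ``level`` taxa per group.

    Groups with at most ``level`` members are retained whole. The draw is
    uniform without replacement and deterministic given ``seed``
    (independent of group ordering). Taxa outside every group are
    dropped.
    """
    if level <= 0:
        raise ValueError("level must be positive")
    aln_taxa = set(alignment.ids)
    kept_groups = []
    kept_taxa: set = set()
    for gi, g in enumerate(sorted(groups, key=lambda g: g.name)):
        members = sorted(g.members & aln_taxa)
        if not members:
            raise ValueError(f"group {g.name!r} has no taxa in the alignment")
        if len(members) > level:
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(gi,)))
            members = sorted(rng.choice(members, size=level, replace=False))
        kept_groups.append(ConcordanceGroup(g.name, frozenset(members)))
        kept_taxa.update(members)
    return alignment.subset(kept_taxa), kept_groups
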