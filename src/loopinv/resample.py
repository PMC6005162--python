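"""Character subsampling: interleaved dataset duplication and
delete-fraction jackknife.

Two ways of probing how much signal a reduced character sample carries:
duplicating one fast region K times (which multiplies every site pattern
without adding new ones), and drawing a fixed fraction of columns without
replacement from a large heterogeneous compartment (which can occasionally
pick up the rare sites informative for short branches).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .msa import Msa
from .ranges import RangeSet


class ResampleError(ValueError):
    pass


@dataclass
class ResampleConfig:
    """Jackknife settings: retained fraction f, replicate count R, seed.

    ``fraction`` is the fraction of columns *retained* per replicate
    (sampling without replacement), matching the 4/8/16% usage.
    """

    fraction: float = 0.16
    replicates: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fraction <= 1):
            raise ResampleError("fraction must be in (0, 1]")
        if self.replicates < 1:
            raise ResampleError("replicates must be >= 1")


def duplicate_interleaved(msa: Msa, copies: int) -> Msa:
    """Concatenate ``copies`` identical copies of every row (K-fold
    duplication of the character matrix)."""
    if copies < 1:
        raise ResampleError("copies must be >= 1")
    return Msa((t, msa.rows[t] * copies) for t in msa.taxa)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def jackknife_replicates(msa: Msa, config: ResampleConfig,
                         restrict_to: RangeSet | None = None
                         ) -> tuple[list[Msa], dict]:
    """Delete-fraction jackknife: R alignments each retaining
    round(f * L) distinct columns, drawn uniformly without replacement.

    Each replicate draws fresh from a generator seeded deterministically by
    (seed, replicate index); columns are emitted in ascending original
    order.  ``restrict_to`` limits the sampled universe to a column subset
    (e.g. non-coding columns after exclusions).  Returns the replicates and
    a manifest recording seed, fraction and the 1-based columns per
    replicate.
    """
    if restrict_to is not None:
        restrict_to.check_bounds(msa.length)
        universe = np.fromiter(restrict_to.columns(), dtype=np.int64)
    else:
        universe = np.arange(msa.length, dtype=np.int64)
    n = len(universe)
    k = _round_half_up(config.fraction * n)
    if k < 1:
        raise ResampleError(
            f"fraction {config.fraction} of {n} columns rounds to zero")
    reps: list[Msa] = []
    manifest: dict = {"seed": config.seed, "fraction": config.fraction,
                      "replicates": config.replicates, "columns_per_replicate": k,
                      "universe_size": n, "columns": []}
    for r in range(config.replicates):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, r]))
        chosen = np.sort(rng.choice(universe, size=k, replace=False))
        reps.append(msa.take_columns(chosen.tolist()))
        manifest["columns"].append([int(c) + 1 for c in chosen])
    return reps, manifest
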