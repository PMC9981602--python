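"""Age -> stage probability tables and stage imputation.

A host dissected after parasitoid attack reveals its developmental stage
through the number of molted head capsules recovered; an unparasitized
host's stage at exposure is unobserved.  This module estimates, from
reference development data, the probability a host of a given seed
quality is in each stage on each day of its development, and uses those
distributions to impute stages for unparasitized hosts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import STAGES, STAGE_INDEX


class InvalidCapsuleCountError(ValueError):
    """More molted head capsules than a four-instar host can shed."""


class MissingCellError(KeyError):
    """A (quality, age) combination has no estimated stage distribution."""


def stage_from_head_capsules(n_capsules: int, is_pupa_or_adult: bool = False) -> str:
    """Map a molted-head-capsule count to a developmental stage.

    Hosts molt once per instar transition, so ``n`` recovered capsules
    place a larva in instar ``n + 1``; four capsules mean the host had
    left the larval stages, and morphology separates pupa from adult.
    """
    n = int(n_capsules)
    if n < 0 or n > 4:
        raise InvalidCapsuleCountError(f"head-capsule count must be in 0..4, got {n}")
    if n < 4:
        if is_pupa_or_adult:
            # Morphology is authoritative for post-larval hosts.
            return "A" if n == 4 else "P"
        return STAGES[n]
    return "A" if is_pupa_or_adult else "P"


@dataclass
class StageDistributionTable:
    """Per (quality, age) probability vector over the six stages.

    ``probs`` has one row per cell in ``cells`` order; rows are
    nonnegative and sum to one.  ``counts`` records the number of
    reference observations behind each row.  The table conditions on
    hosts still present (alive, inside the seed) at the given age.
    """

    cells: list[tuple[int, int]]  # (quality, age)
    probs: np.ndarray  # (n_cells, 6)
    counts: np.ndarray  # (n_cells,)
    provenance: str = ""
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, float)
        if self.probs.ndim != 2 or self.probs.shape[1] != len(STAGES):
            raise ValueError("probs must be (n_cells, 6)")
        if np.any(self.probs < -1e-15):
            raise ValueError("negative stage probability")
        sums = self.probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-12):
            raise ValueError("stage probability rows must sum to 1")
        self._index = {cell: i for i, cell in enumerate(self.cells)}

    def lookup(self, quality: int, age: int, nearest_age_fallback: bool = False) -> np.ndarray:
        """Probability vector for a cell; optionally borrow the nearest
        age with data within the same quality (ties -> younger age)."""
        key = (int(quality), int(age))
        i = self._index.get(key)
        if i is not None:
            return self.probs[i]
        if nearest_age_fallback:
            ages = sorted(a for (q, a) in self.cells if q == key[0])
            if ages:
                nearest = min(ages, key=lambda a: (abs(a - key[1]), a))
                return self.probs[self._index[(key[0], nearest)]]
        raise MissingCellError(f"no stage distribution for quality={quality}, age={age}")

    def sample(self, quality: int, age: int, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        """Inverse-CDF sample of stage names for one cell."""
        cum = np.cumsum(self.lookup(quality, age))
        u = rng.random(size)
        return np.array(STAGES)[np.searchsorted(cum, u, side="right")]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.cells, columns=["quality", "age"])
        for j, s in enumerate(STAGES):
            df[f"p_{s}"] = self.probs[:, j]
        df["n"] = self.counts
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "") -> "StageDistributionTable":
        cells = list(zip(df["quality"].astype(int), df["age"].astype(int)))
        probs = df[[f"p_{s}" for s in STAGES]].to_numpy(float)
        counts = df["n"].to_numpy(int)
        return cls(cells=cells, probs=probs, counts=counts, provenance=provenance)

    @classmethod
    def from_csv(cls, path) -> "StageDistributionTable":
        return cls.from_frame(pd.read_csv(path), provenance=str(path))


def estimate_stage_distribution(
    reference: pd.DataFrame, provenance: str = "reference"
) -> StageDistributionTable:
    """Relative stage frequencies per (quality, age) reference cell.

    Cells with no reference records are simply absent from the table;
    lookups for them fail loudly unless the caller opts into the
    nearest-age fallback.
    """
    if reference.empty:
        raise ValueError("reference table is empty")
    ref = reference.copy()
    ref["_stage_code"] = ref["stage"].map(STAGE_INDEX)
    if ref["_stage_code"].isna().any():
        bad = ref.loc[ref["_stage_code"].isna(), "stage"].unique()
        raise ValueError(f"unknown stage labels in reference table: {bad}")
    grouped = (
        ref.groupby(["quality", "age", "_stage_code"]).size().unstack("_stage_code", fill_value=0)
    )
    counts = np.zeros((len(grouped), len(STAGES)), int)
    for code in grouped.columns:
        counts[:, int(code)] = grouped[code].to_numpy()
    totals = counts.sum(axis=1)
    probs = counts / totals[:, None]
    cells = [(int(q), int(a)) for q, a in grouped.index]
    return StageDistributionTable(cells=cells, probs=probs, counts=totals, provenance=provenance)


def impute_stages(
    records: pd.DataFrame,
    table: StageDistributionTable,
    rng: np.random.Generator,
    nearest_age_fallback: bool = False,
) -> pd.DataFrame:
    """Fill in stages for unparasitized hosts by sampling their cell.

    Parasitized hosts keep their observed (head-capsule) stage untouched;
    every other field is left unchanged and row order is preserved.
    Fails loudly, naming the (quality, age) cell, when an unparasitized
    host has no distribution to draw from.
    """
    out = records.copy()
    unpar = ~records["parasitized"].astype(bool).to_numpy()
    if not unpar.any():
        return out
    quality = records["quality"].to_numpy(int)[unpar]
    age = records["age_at_exposure"].to_numpy(int)[unpar]
    cum = np.empty((unpar.sum(), len(STAGES)))
    for i, (q, a) in enumerate(zip(quality, age)):
        cum[i] = np.cumsum(table.lookup(q, a, nearest_age_fallback=nearest_age_fallback))
    u = rng.random(len(cum))
    codes = (cum < u[:, None]).sum(axis=1)
    stages = np.array(STAGES)[codes]
    col = out["stage_at_parasitism"]
    if not isinstance(col.dtype, pd.StringDtype):
        out["stage_at_parasitism"] = col.astype("string")
    out.loc[unpar, "stage_at_parasitism"] = stages
    return out
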