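"""Pedigree coancestry and inbreeding for haplodiploid honeybee pedigrees.

Two layers live here.

``Pedigree`` is the *realized* drone-level pedigree: every queen records her
dam and the actual father drone, every drone records his mother.  Coancestry
is computed by exact recursion: drones are single meiotic gametes, so the
kinship of a drone with itself is 1 and his kinship with anything else equals
his mother's.  This is the ground truth used for individual inbreeding
coefficients and as an oracle for the sparse BLUP relationship machinery.

``expected_relationship`` computes *average* additive relationships on an
entity pedigree in which paternity is only known at the mating-station level
(the situation of a real breeding program): the sire of a mating is the pooled
drone production of eight drone-producing queens, and each offspring's
paternal gamete is an independent draw from that (infinite) pool.  It is a
pair-recursive implementation, deliberately independent of the forward
T-D-T' construction in :mod:`hivesim.blup`, and serves as its oracle.

The module also houses the generational inbreeding-rate transform
``delta_f`` and Wright's heuristic ``wright_delta_f`` comparator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "delta_f",
    "effective_population_size",
    "wright_delta_f",
    "InbreedingSummary",
    "EntityRecord",
    "expected_relationship",
    "save_pedigree",
    "load_pedigree",
]


class Pedigree:
    """Realized queen/drone pedigree with exact recursive coancestry.

    Individuals are added in topological (birth) order; parents must already
    be present.  Identifiers are arbitrary hashables.
    """

    QUEEN = "queen"
    DRONE = "drone"

    def __init__(self):
        self._kind: dict = {}
        self._parents: dict = {}  # queen -> (dam, father_drone); drone -> mother
        self._order: dict = {}
        self._memo: dict = {}

    # -- construction ---------------------------------------------------

    def add_queen(self, qid, dam=None, father_drone=None) -> None:
        if qid in self._kind:
            raise ValueError(f"duplicate individual {qid!r}")
        if (dam is None) != (father_drone is None):
            raise ValueError("non-base queens need both dam and father drone")
        for p in (dam, father_drone):
            if p is not None and p not in self._kind:
                raise KeyError(f"unknown parent {p!r}")
        self._kind[qid] = self.QUEEN
        self._parents[qid] = (dam, father_drone)
        self._order[qid] = len(self._order)

    def add_drone(self, did, mother) -> None:
        if did in self._kind:
            raise ValueError(f"duplicate individual {did!r}")
        if mother not in self._kind or self._kind[mother] != self.QUEEN:
            raise KeyError(f"drone mother {mother!r} is not a known queen")
        self._kind[did] = self.DRONE
        self._parents[did] = mother
        self._order[did] = len(self._order)

    def __contains__(self, xid) -> bool:
        return xid in self._kind

    # -- coancestry -----------------------------------------------------

    def coancestry(self, x, y) -> float:
        """Kinship f(x, y): probability that random alleles from x and y are IBD."""
        for z in (x, y):
            if z not in self._kind:
                raise KeyError(f"unknown individual {z!r}")
        return self._f(x, y)

    def _f(self, x, y) -> float:
        if x == y:
            if self._kind[x] == self.DRONE:
                return 1.0
            return 0.5 * (1.0 + self.inbreeding(x))
        key = (x, y) if self._order[x] <= self._order[y] else (y, x)
        hit = self._memo.get(key)
        if hit is not None:
            return hit
        older, younger = key
        if self._kind[younger] == self.DRONE:
            val = self._f(self._parents[younger], older)
        else:
            dam, father = self._parents[younger]
            if dam is None:
                val = 0.0
            else:
                val = 0.5 * (self._f(dam, older) + self._f(father, older))
        self._memo[key] = val
        return val

    def inbreeding(self, qid) -> float:
        """Pedigree inbreeding coefficient: coancestry of dam and father drone."""
        if self._kind.get(qid) == self.DRONE:
            # a drone carries a single genome copy; F is defined via his mother
            return self.inbreeding(self._parents[qid])
        dam, father = self._parents[qid]
        if dam is None:
            return 0.0
        return self._f(dam, father)

    def relationship(self, x, y) -> float:
        """Additive relationship a(x, y) = 2 f(x, y)."""
        return 2.0 * self.coancestry(x, y)

    # -- gene-dropping oracle -------------------------------------------

    def gene_drop(self, pairs, n_drops: int, rng: np.random.Generator) -> dict:
        """Monte-Carlo IBD frequencies for (x, y) pairs over ``n_drops`` drops.

        Founder queens get unique allele labels; inheritance follows the
        pedigree exactly.  Returns estimated coancestries.
        """
        ids = sorted(self._kind, key=self._order.get)
        est = {pair: 0.0 for pair in pairs}
        for _ in range(n_drops):
            alleles: dict = {}
            label = 0
            for xid in ids:
                if self._kind[xid] == self.DRONE:
                    m = alleles[self._parents[xid]]
                    alleles[xid] = (m[rng.integers(2)],)
                else:
                    dam, father = self._parents[xid]
                    if dam is None:
                        alleles[xid] = (label, label + 1)
                        label += 2
                    else:
                        alleles[xid] = (
                            alleles[dam][rng.integers(2)],
                            alleles[father][0],
                        )
            for x, y in pairs:
                ax, ay = alleles[x], alleles[y]
                matches = sum(a == b for a in ax for b in ay)
                est[(x, y)] += matches / (len(ax) * len(ay))
        return {pair: v / n_drops for pair, v in est.items()}

    # -- export ----------------------------------------------------------


PEDIGREE_COLUMNS = [
    "queen_id",
    "birth_year",
    "dam_id",
    "father_dpq_id",
    "station_id",
    "apiary_id",
    "F",
]


def save_pedigree(frame: pd.DataFrame, path) -> None:
    """Write a pedigree table (1-based identifiers, 0 for missing parents)."""
    frame.to_csv(path, sep="\t", index=False, columns=PEDIGREE_COLUMNS)


def load_pedigree(path) -> pd.DataFrame:
    """Read a pedigree table written by :func:`save_pedigree`."""
    frame = pd.read_csv(path, sep="\t")
    missing = set(PEDIGREE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"pedigree table lacks columns {sorted(missing)}")
    return frame[PEDIGREE_COLUMNS]


def delta_f(f_final: float, elapsed_years: float = 99.0, generation_interval: float = 2.5) -> float:
    """Generational inbreeding rate from the terminal mean inbreeding.

    ``dF = 1 - (1 - F)^(L/T)`` with generation interval L (default 2.5 years:
    two on the maternal and three on the paternal path) and T elapsed years.
    """
    if not 0.0 <= f_final < 1.0:
        raise ValueError("terminal inbreeding must lie in [0, 1)")
    return 1.0 - (1.0 - f_final) ** (generation_interval / elapsed_years)


def effective_population_size(rate: float) -> float:
    """Ne = 1 / (2 dF) for a positive generational inbreeding rate."""
    if rate <= 0:
        raise ValueError("delta F must be positive")
    return 1.0 / (2.0 * rate)


def wright_delta_f(n_sires: int, n_dams: int) -> float:
    """Wright's idealized-population inbreeding rate (F + M) / (8 M F).

    A heuristic comparator only; it ignores the honeybee mating structure.
    """
    if n_sires < 1 or n_dams < 1:
        raise ValueError("parent counts must be at least 1")
    return (n_dams + n_sires) / (8.0 * n_sires * n_dams)


@dataclass
class InbreedingSummary:
    """Cohort-mean inbreeding trajectory and derived rate/effective size."""

    f_by_year: pd.Series
    elapsed_years: float = 99.0
    generation_interval: float = 2.5
    f_final: float = field(init=False)
    delta_f: float = field(init=False)
    n_e: float = field(init=False)

    def __post_init__(self):
        self.f_final = float(self.f_by_year.iloc[-1])
        self.delta_f = delta_f(self.f_final, self.elapsed_years, self.generation_interval)
        self.n_e = float("inf") if self.delta_f == 0 else effective_population_size(self.delta_f)


# ---------------------------------------------------------------------------
# Average relationships on the entity pedigree (station-level paternity)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EntityRecord:
    """One node of the evaluation-entity pedigree.

    kind is one of ``base_queen``, ``queen``, ``base_pool``, ``pool``,
    ``worker_group``.  ``queen`` has parents (dam, sire pool of the dam's
    mating); ``pool`` (a mating station's drone pool) has parents (founder
    queen, sire pool of the founder's mating) and implicitly consists of the
    founder's eight drone-producing daughters; ``worker_group`` has parents
    (its own queen, the queen's mating pool).  ``base_pool`` is the pooled
    drone production of ``n_members`` unrelated, non-inbred queens outside the
    recorded population.
    """

    kind: str
    dam: int | None = None
    sire: int | None = None
    n_members: int = 12
    members: tuple = ()  # explicit DPQ entity ids for "pool", optional


def expected_relationship(entities: list[EntityRecord]) -> np.ndarray:
    """Dense average additive-relationship matrix by pair recursion.

    Paternal gametes are independent draws from the (infinite) pool of the
    recorded mating; a worker group averages twelve such draws.  Entities must
    be listed parents-first.  Complexity is O(n^2) with memoization — intended
    for oracle-sized pedigrees.
    """
    n = len(entities)
    memo: dict = {}

    def diag(i: int) -> float:
        rec = entities[i]
        if rec.kind == "base_queen":
            return 1.0
        if rec.kind == "base_pool":
            # pooled (infinite) drone production of n unrelated queens
            return 1.0 / rec.n_members
        if rec.kind == "queen":
            return 1.0 + 0.5 * pair(rec.dam, rec.sire)
        if rec.kind == "pool":
            if rec.members:
                m = rec.members
                return sum(pair(a, b) for a in m for b in m) / len(m) ** 2
            a_pp, a_ss = pair(rec.dam, rec.dam), pair(rec.sire, rec.sire)
            a_ps = pair(rec.dam, rec.sire)
            half_sib = 0.25 * (a_pp + 2.0 * a_ps + a_ss)
            d_dpq = 1.0 - 0.25 * (a_pp + a_ss)
            return half_sib + d_dpq / 8.0
        if rec.kind == "worker_group":
            a_qq, a_ss = pair(rec.dam, rec.dam), pair(rec.sire, rec.sire)
            a_qs = pair(rec.dam, rec.sire)
            return 0.25 * a_qq + 0.5 * a_qs + 0.25 * (a_ss + (2.0 - a_ss) / 12.0)
        raise ValueError(f"unknown entity kind {rec.kind!r}")

    def pair(i: int, j: int) -> float:
        if i == j:
            key = (i, i)
            if key not in memo:
                memo[key] = diag(i)
            return memo[key]
        key = (min(i, j), max(i, j))
        if key in memo:
            return memo[key]
        older, younger = key
        rec = entities[younger]
        if rec.kind in ("base_queen", "base_pool"):
            val = 0.0
        elif rec.kind == "pool" and rec.members:
            val = sum(pair(m, older) for m in rec.members) / len(rec.members)
        else:
            val = 0.5 * pair(rec.dam, older) + 0.5 * pair(rec.sire, older)
        memo[key] = val
        return val

    out = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            out[i, j] = out[j, i] = pair(i, j)
    return out
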