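"""Sliding-window relationship trackers used by the yearly simulator.

Parents of any individual created in year t were born in years t-2 or t-3, so
exact kinships can be maintained generation-by-generation on a dense matrix
restricted to the last few birth cohorts instead of the full pedigree.

``KinshipWindow`` tracks *realized* coancestries on the drone-level pedigree
(actual father drones recorded); it supplies individual inbreeding
coefficients.  Offspring rows are parent averages with the father drone
represented by his mother, plus a correction of ``(1 - F_M)/8`` for every pair
of offspring sharing the same father drone (a drone's kinship with himself is
1, not his mother's self-kinship).

``EntityWindow`` tracks *average* relationships among evaluation entities
(queens and pseudo-sire drone pools) under station-level paternity, providing
the pairwise values needed for the closed-form Mendelian sampling
coefficients of the sparse BLUP relationship inverse.
"""

from __future__ import annotations

import numpy as np

from .blup import mendelian_d_pool, mendelian_d_queen, mendelian_d_worker_group

_CHUNK = 512


class _Window:
    """Dense symmetric matrix over a pruned set of members."""

    def __init__(self):
        self._mat = np.zeros((_CHUNK, _CHUNK))
        self._ids: dict = {}
        self._years: list[int] = []
        self._keys: list = []
        self.n = 0

    def _ensure_capacity(self):
        if self.n < self._mat.shape[0]:
            return
        cap = self._mat.shape[0] + _CHUNK
        mat = np.zeros((cap, cap))
        mat[: self.n, : self.n] = self._mat[: self.n, : self.n]
        self._mat = mat

    def index(self, xid) -> int:
        return self._ids[xid]

    def __contains__(self, xid) -> bool:
        return xid in self._ids

    def _push(self, xid, year: int, key=None) -> int:
        self._ensure_capacity()
        i = self.n
        self._ids[xid] = i
        self._years.append(year)
        self._keys.append(key)
        self.n += 1
        return i

    def prune(self, min_year: int) -> None:
        keep = [i for i, y in enumerate(self._years) if y >= min_year]
        if len(keep) == self.n:
            return
        keep_arr = np.array(keep)
        old_ids = {i: xid for xid, i in self._ids.items()}
        self._mat[: len(keep), : len(keep)] = self._mat[np.ix_(keep_arr, keep_arr)]
        self._ids = {old_ids[i]: j for j, i in enumerate(keep)}
        self._years = [self._years[i] for i in keep]
        self._keys = [self._keys[i] for i in keep]
        self.n = len(keep)


class KinshipWindow(_Window):
    """Realized drone-level coancestries (f-scale) over recent cohorts."""

    def __init__(self):
        super().__init__()
        self.inbreeding: dict = {}
        self._drone_groups: dict = {}

    def add_base_queen(self, qid, year: int) -> None:
        i = self._push(qid, year, key=None)
        self._mat[i, : i + 1] = 0.0
        self._mat[: i + 1, i] = 0.0
        self._mat[i, i] = 0.5
        self.inbreeding[qid] = 0.0

    def add_queen(
        self,
        qid,
        year: int,
        dam,
        drone_mother,
        father_drone_key,
        drone_mother_f: float,
    ) -> float:
        """Insert a queen; returns her realized inbreeding coefficient.

        ``drone_mother`` is the queen whose gamete the father drone is
        (``None`` for drones of unrelated hidden base queens);
        ``father_drone_key`` identifies the individual drone so that repeat
        use of one drone is detected across offspring.
        """
        m = self._mat
        di = self._ids[dam]
        if drone_mother is None:
            # father drone stems from an unrelated queen outside the window;
            # her kinship is zero with everything except children of this very
            # drone, handled below
            f_q = 0.0
            row = 0.5 * m[di, : self.n]
            corr = 0.125 * (1.0 - drone_mother_f) + 0.25 * (1.0 + drone_mother_f) * 0.5
        else:
            mi = self._ids[drone_mother]
            f_q = m[di, mi]
            row = 0.5 * (m[di, : self.n] + m[mi, : self.n])
            # shared father drone: f gains (1 - F_M)/8 over the row average
            corr = 0.125 * (1.0 - drone_mother_f)
        for j in self._drone_groups.get(father_drone_key, ()):
            row[j] += corr

        i = self._push(qid, year, key=father_drone_key)
        self._drone_groups.setdefault(father_drone_key, []).append(i)
        m = self._mat  # _push may have reallocated
        m[i, : self.n - 1] = row
        m[: self.n - 1, i] = row
        m[i, i] = 0.5 * (1.0 + f_q)
        self.inbreeding[qid] = f_q
        return f_q

    def coancestry(self, x, y) -> float:
        return float(self._mat[self._ids[x], self._ids[y]])

    def prune(self, min_year: int) -> None:
        super().prune(min_year)
        groups: dict = {}
        for j, k in enumerate(self._keys):
            if k is not None:
                groups.setdefault(k, []).append(j)
        self._drone_groups = groups


class EntityWindow(_Window):
    """Average relationships (a-scale) among queen and pool entities."""

    def add_base_queen(self, eid, year: int) -> float:
        i = self._push(eid, year)
        self._mat[i, : i + 1] = 0.0
        self._mat[: i + 1, i] = 0.0
        self._mat[i, i] = 1.0
        return 1.0  # d

    def add_base_pool(self, eid, year: int, n_members: int = 12) -> float:
        i = self._push(eid, year)
        self._mat[i, : i + 1] = 0.0
        self._mat[: i + 1, i] = 0.0
        self._mat[i, i] = 1.0 / n_members
        return 1.0 / n_members

    def add_queen(self, eid, year: int, dam_eid, sire_eid) -> float:
        m = self._mat
        p, s = self._ids[dam_eid], self._ids[sire_eid]
        d = mendelian_d_queen(m[p, p], m[s, s])
        diag = 1.0 + 0.5 * m[p, s]
        row = 0.5 * (m[p, : self.n] + m[s, : self.n])
        i = self._push(eid, year)
        m = self._mat  # _push may have reallocated
        m[i, : self.n - 1] = row
        m[: self.n - 1, i] = row
        m[i, i] = diag
        return d

    def add_pool(self, eid, year: int, founder_eid, founder_pool_eid) -> float:
        m = self._mat
        p, s = self._ids[founder_eid], self._ids[founder_pool_eid]
        d = mendelian_d_pool(m[p, p], m[s, s])
        diag = 0.25 * (m[p, p] + 2.0 * m[p, s] + m[s, s]) + d
        row = 0.5 * (m[p, : self.n] + m[s, : self.n])
        i = self._push(eid, year)
        m = self._mat  # _push may have reallocated
        m[i, : self.n - 1] = row
        m[: self.n - 1, i] = row
        m[i, i] = diag
        return d

    def worker_group_d(self, pool_eid) -> float:
        s = self._ids[pool_eid]
        return mendelian_d_worker_group(self._mat[s, s])
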