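"""Yearly driver for a closed honeybee breeding scheme.

One scheme ``S^{ks}_{kd}`` maintains a constant census of N breeding queens
per year.  Each year, BLUP breeding values are estimated from all historical
colony records; the best two-year-old queens are selected as dams (floor(N/kd)
of them, each producing kd daughters) and the best ks% of three-year-old
queens each found one isolated mating station, stocked with eight
drone-producing daughter colonies.  Every virgin queen is mated on a random
station to twelve drones, is assigned an apiary (her dam's with probability
0.7), and generates one performance record in her birth year.

Inbreeding is tracked on the realized drone-level pedigree; the evaluator's
relationship matrix uses station-level (pseudo-sire) paternity — see
:mod:`hivesim.kinship` and :mod:`hivesim.blup`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import blup as _blup
from ._windows import EntityWindow, KinshipWindow
from .architecture import TraitArchitecture
from .kinship import delta_f as _delta_f

__all__ = ["SchemeConfig", "Simulation", "SimulationResult", "run_scheme_once"]

_BASE_YEARS = (-2, -1, 0)  # founder cohorts so years 1-3 have candidates aged 1-3


@dataclass(frozen=True)
class SchemeConfig:
    """Parameters of one breeding scheme.

    ``sister_group_size`` is k_d (reciprocal dam selection rate);
    ``sire_rate_percent`` is k_s, the percentage of three-year-old queens
    founding a mating station each year.
    """

    n_queens: int = 200
    sister_group_size: int = 3
    sire_rate_percent: float = 10.0
    years: int = 100
    n_dpq_per_station: int = 8
    n_mates_per_queen: int = 12
    apiary_inherit_prob: float = 0.7
    reestimate_interval: int = 5
    n_drones_reestimate: int = 100
    selection: str = "blup"  # "blup", "random" (null model) or "true_bv" (oracle)
    solver: str = "cg"
    solver_tol: float = 1e-8

    def __post_init__(self):
        if self.n_queens < 2:
            raise ValueError("population size N must be at least 2")
        if self.n_queens < self.n_mates_per_queen:
            raise ValueError("N must be at least the number of mates per queen")
        if self.sister_group_size < 1:
            raise ValueError("sister group size k_d must be at least 1")
        if not 1 <= self.sire_rate_percent <= 100:
            raise ValueError("sire rate k_s must lie in [1, 100] percent")
        if self.selection not in ("blup", "random", "true_bv"):
            raise ValueError("selection must be 'blup', 'random' or 'true_bv'")
        if self.years < 1:
            raise ValueError("horizon must be at least one year")

    @property
    def n_apiaries(self) -> int:
        """7N/100 apiaries, rounded to nearest, at least 1."""
        return max(1, round(7 * self.n_queens / 100))

    @property
    def n_dams(self) -> int:
        return self.n_queens // self.sister_group_size

    @property
    def n_stations(self) -> int:
        return max(1, round(self.n_queens * self.sire_rate_percent / 100))


@dataclass
class _Cohort:
    """Per-birth-year arrays for the N breeding queens of one cohort."""

    ids: np.ndarray
    dam_id: np.ndarray
    father_dpq_id: np.ndarray
    station_id: np.ndarray
    apiary: np.ndarray
    inbreeding: np.ndarray
    tbv: np.ndarray  # (n, 2) maternal/direct true breeding values
    wg_direct: np.ndarray
    phenotype: np.ndarray
    entity: np.ndarray
    sire_pool_entity: np.ndarray  # pool entity of each queen's own mating
    # heavyweight fields, pruned once the cohort ages out of reproduction
    genotypes: np.ndarray | None = None
    mates_hap: np.ndarray | None = None
    mates_dpq_id: np.ndarray | None = None
    mates_dpq_f: np.ndarray | None = None


@dataclass
class SimulationResult:
    """Outputs of one replicate: per-year summaries plus the full pedigree."""

    config: SchemeConfig
    arch: TraitArchitecture
    summaries: pd.DataFrame
    pedigree: pd.DataFrame
    base_inheritance_variance: float

    @property
    def f_final(self) -> float:
        return float(self.summaries["mean_f"].iloc[-1])

    def delta_f(self) -> float:
        """Generational inbreeding rate from the final cohort's mean F."""
        elapsed = max(float(self.summaries["year"].iloc[-1]) - 1.0, 1.0)
        return _delta_f(self.f_final, elapsed_years=elapsed)

    def gain(self, year: int) -> float:
        row = self.summaries.loc[self.summaries["year"] == year, "performance_criterion"]
        return float(row.iloc[0])

    def relative_variance(self, year: int | None = None) -> float:
        """Inheritance-criterion variance relative to the base population."""
        s = self.summaries
        row = s.iloc[-1] if year is None else s.loc[s["year"] == year].iloc[0]
        return float(row["inheritance_variance"]) / self.base_inheritance_variance

    def save(self, directory: str | Path, stem: str = "run") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.summaries.to_csv(directory / f"{stem}_summary.tsv", sep="\t", index=False)
        self.pedigree.to_csv(directory / f"{stem}_pedigree.tsv", sep="\t", index=False)


class Simulation:
    """Stateful single-replicate simulation of one breeding scheme."""

    def __init__(
        self,
        config: SchemeConfig,
        arch: TraitArchitecture,
        rng: np.random.Generator | np.random.SeedSequence | int,
    ):
        self.config = config
        self.arch = arch
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.rng = rng

        self._next_id = 1
        self.cohorts: dict[int, _Cohort] = {}
        self.kin = KinshipWindow()
        self.ent = EntityWindow()

        # global entity pedigree (grows monotonically; -1 = founder)
        self.ent_p: list[int] = []
        self.ent_s: list[int] = []
        self.ent_d: list[float] = []
        self.ent_kind: list[str] = []
        self._last_ebv: tuple[int, np.ndarray] | None = None  # (year, u)

        # performance records
        self._levels: dict[tuple[int, int], int] = {}
        self.rec_level: list[int] = []
        self.rec_qent: list[int] = []
        self.rec_went: list[int] = []
        self.rec_y: list[float] = []

        self.sigma_hat = arch.sigma_a.copy()
        self._warm: np.ndarray | None = None
        self._summaries: list[dict] = []
        self._ped_rows: list[tuple] = []
        #: (queen_id, dam_id, drone_mother_id, father_drone_key) in insertion
        #: order, for every queen incl. DPQs — feeds the exact-recursion oracle
        self.kin_log: list[tuple] = []
        # DPQ bookkeeping for the current year's stations
        self._stations: list[dict] = []
        self._station_counter = 0

    # -- id and entity helpers ------------------------------------------

    def _take_ids(self, n: int) -> np.ndarray:
        ids = np.arange(self._next_id, self._next_id + n, dtype=np.int64)
        self._next_id += n
        return ids

    def _add_entity(self, p: int, s: int, d: float, kind: str = "queen") -> int:
        self.ent_p.append(p)
        self.ent_s.append(s)
        self.ent_d.append(d)
        self.ent_kind.append(kind)
        return len(self.ent_d) - 1

    def entity_frame(self) -> pd.DataFrame:
        """Evaluation-entity pedigree as a delimited-text-ready table."""
        return pd.DataFrame(
            {
                "entity_id": np.arange(len(self.ent_d)),
                "kind": self.ent_kind,
                "dam": self.ent_p,
                "sire": self.ent_s,
                "d": self.ent_d,
            }
        )

    def ebv_frame(self) -> pd.DataFrame:
        """Latest estimated breeding values per entity (maternal, direct)."""
        if self._last_ebv is None:
            raise ValueError("no evaluation has been run yet")
        year, u = self._last_ebv
        return pd.DataFrame(
            {
                "entity_id": np.arange(u.shape[0]),
                "maternal_ebv": u[:, 0],
                "direct_ebv": u[:, 1],
                "year": year,
            }
        )

    def _level(self, year: int, apiary: int) -> int:
        key = (year, int(apiary))
        if key not in self._levels:
            self._levels[key] = len(self._levels)
        return self._levels[key]

    # -- phenotype machinery --------------------------------------------

    def _tbv(self, genotypes: np.ndarray) -> np.ndarray:
        counts = genotypes.sum(axis=1).astype(float)
        return (counts - 2.0 * self.arch.allele_freq) @ self.arch.effects.T

    def _wg_direct(self, genotypes: np.ndarray, mates_hap: np.ndarray) -> np.ndarray:
        p = self.arch.allele_freq
        counts = genotypes.sum(axis=1).astype(float)
        mean_counts = 0.5 * (counts - 2.0 * p) + (mates_hap.mean(axis=1) - p)
        return mean_counts @ self.arch.effects[1]

    # -- base population -------------------------------------------------

    def initialize_base(self) -> None:
        """Three unrelated founder cohorts of N queens each.

        Every base queen mates with twelve drones of twelve distinct unrelated
        queens outside the recorded population (so base pseudo-sires are
        founder entities with pool diagonal 1/12), and is assigned a random
        apiary.
        """
        cfg, arch, rng = self.config, self.arch, self.rng
        n, L = cfg.n_queens, arch.n_loci
        nm = cfg.n_mates_per_queen
        for year in _BASE_YEARS:
            ids = self._take_ids(n)
            genotypes = (rng.random((n, 2, L)) < arch.allele_freq).astype(np.uint8)
            # a gamete of an unrelated Hardy-Weinberg queen is Bernoulli(p)
            mates_hap = (rng.random((n, nm, L)) < arch.allele_freq).astype(np.uint8)
            apiary = rng.integers(cfg.n_apiaries, size=n)

            entity = np.empty(n, dtype=np.int64)
            pool_entity = np.empty(n, dtype=np.int64)
            for i, qid in enumerate(ids):
                self.kin.add_base_queen(qid, year)
                self.kin_log.append((int(qid), None, None, None))
                qe = self._add_entity(-1, -1, 1.0, "base_queen")
                self.ent.add_base_queen(qe, year)
                pe = self._add_entity(-1, -1, 1.0 / nm, "base_pool")
                self.ent.add_base_pool(pe, year, n_members=nm)
                entity[i] = qe
                pool_entity[i] = pe

            tbv = self._tbv(genotypes)
            wg = self._wg_direct(genotypes, mates_hap)
            pheno = tbv[:, 0] + wg + rng.normal(0.0, np.sqrt(arch.sigma_e2), size=n)

            cohort = _Cohort(
                ids=ids,
                dam_id=np.zeros(n, dtype=np.int64),
                father_dpq_id=np.zeros(n, dtype=np.int64),
                station_id=np.zeros(n, dtype=np.int64),
                apiary=apiary,
                inbreeding=np.zeros(n),
                tbv=tbv,
                wg_direct=wg,
                phenotype=pheno,
                entity=entity,
                sire_pool_entity=pool_entity,
                genotypes=genotypes,
                mates_hap=mates_hap,
                mates_dpq_id=np.full((n, nm), -1, dtype=np.int64),
                mates_dpq_f=np.zeros((n, nm)),
            )
            self.cohorts[year] = cohort
            self._record_cohort(year, cohort)

    def _record_cohort(self, year: int, cohort: _Cohort) -> None:
        for i in range(cohort.ids.size):
            we = self._add_entity(
                int(cohort.entity[i]),
                int(cohort.sire_pool_entity[i]),
                self.ent.worker_group_d(int(cohort.sire_pool_entity[i])),
                "worker_group",
            )
            self.rec_level.append(self._level(year, cohort.apiary[i]))
            self.rec_qent.append(int(cohort.entity[i]))
            self.rec_went.append(we)
            self.rec_y.append(float(cohort.phenotype[i]))
        for i in range(cohort.ids.size):
            self._ped_rows.append(
                (
                    int(cohort.ids[i]),
                    year,
                    int(cohort.dam_id[i]),
                    int(cohort.father_dpq_id[i]),
                    int(cohort.station_id[i]),
                    int(cohort.apiary[i]) + 1,
                    float(cohort.inbreeding[i]),
                )
            )

    # -- yearly steps -----------------------------------------------------

    def _evaluate(self, year: int) -> np.ndarray:
        """Run BLUP on all historical records; returns per-entity EBV sums."""
        cfg = self.config
        ainv = _blup.sparse_a_inverse(
            np.asarray(self.ent_p), np.asarray(self.ent_s), np.asarray(self.ent_d)
        )
        mme = _blup.MixedModelEquations.assemble(
            np.asarray(self.rec_level),
            len(self._levels),
            np.asarray(self.rec_qent),
            np.asarray(self.rec_went),
            np.asarray(self.rec_y),
            ainv,
            self.sigma_hat,
            self.arch.sigma_e2,
        )
        warm = None
        if self._warm is not None:
            nf_old, x_old = self._warm
            warm = np.zeros(mme.rhs.size)
            warm[:nf_old] = x_old[:nf_old]
            warm[mme.n_fixed : mme.n_fixed + x_old.size - nf_old] = x_old[nf_old:]
        _, u, x = _blup.solve_mme(
            mme, tol=cfg.solver_tol, warm_start=warm, solver=cfg.solver
        )
        self._warm = (mme.n_fixed, x)
        self._last_ebv = (year, u)
        return u[:, 0] + u[:, 1]

    def _truncate(self, cohort: _Cohort, crit: np.ndarray | None, n_sel: int) -> np.ndarray:
        """Indices of the n_sel best candidates (ties broken by queen id)."""
        if crit is None:  # random (null-model) selection
            return self.rng.choice(cohort.ids.size, size=n_sel, replace=False)
        scores = crit[cohort.entity]
        order = np.lexsort((cohort.ids, -scores))
        return order[:n_sel]

    def _build_stations(self, year: int, founders_idx: np.ndarray, cohort: _Cohort) -> None:
        """Each founder's colony supplies 8 drone-producing daughter queens."""
        cfg, rng = self.config, self.rng
        n_dpq = cfg.n_dpq_per_station
        self._stations = []
        for j, fi in enumerate(founders_idx):
            fid = int(cohort.ids[fi])
            slots = rng.integers(cfg.n_mates_per_queen, size=n_dpq)
            pick = rng.integers(0, 2, size=(n_dpq, self.arch.n_loci))
            geno = cohort.genotypes[fi]
            gam = np.where(pick == 0, geno[0][None, :], geno[1][None, :])
            dpq_geno = np.stack([gam, cohort.mates_hap[fi, slots]], axis=1)
            dpq_ids = self._take_ids(n_dpq)
            dpq_f = np.empty(n_dpq)
            for k in range(n_dpq):
                mom = int(cohort.mates_dpq_id[fi, slots[k]])
                key = fid * 16 + int(slots[k])
                dpq_f[k] = self.kin.add_queen(
                    int(dpq_ids[k]),
                    year,
                    fid,
                    mom if mom >= 0 else None,
                    key,
                    float(cohort.mates_dpq_f[fi, slots[k]]),
                )
                self.kin_log.append((int(dpq_ids[k]), fid, mom if mom >= 0 else None, key))
            pool_entity = self._add_entity(
                int(cohort.entity[fi]), int(cohort.sire_pool_entity[fi]), 0.0, "pool"
            )
            self.ent_d[pool_entity] = self.ent.add_pool(
                pool_entity, year, int(cohort.entity[fi]), int(cohort.sire_pool_entity[fi])
            )
            self._station_counter += 1
            self._stations.append(
                {
                    "id": self._station_counter,
                    "founder": fid,
                    "dpq_ids": dpq_ids,
                    "dpq_geno": dpq_geno,
                    "dpq_f": dpq_f,
                    "pool_entity": pool_entity,
                }
            )

    def run_year(self, year: int) -> None:
        cfg, arch, rng = self.config, self.arch, self.rng
        n, L = cfg.n_queens, arch.n_loci
        nm = cfg.n_mates_per_queen

        crit = None
        if cfg.selection == "true_bv":
            # oracle selection on true breeding values (diagnostic upper bound
            # for EBV accuracy effects)
            crit = np.zeros(len(self.ent_d))
            for c in self.cohorts.values():
                crit[c.entity] = c.tbv.sum(axis=1)
        if cfg.selection == "blup":
            if (
                cfg.reestimate_interval > 0
                and year >= cfg.reestimate_interval
                and year % cfg.reestimate_interval == 0
            ):
                prev = self.cohorts[year - 1]
                est = _blup.reestimate_variance(
                    prev.genotypes,
                    prev.inbreeding,
                    arch,
                    rng,
                    n_drones=cfg.n_drones_reestimate,
                    year=year,
                )
                self.sigma_hat = _blup.nearest_psd(est.sigma_hat)
            crit = self._evaluate(year)

        dam_cohort = self.cohorts[year - 2]
        sire_cohort = self.cohorts[year - 3]
        dams_idx = self._truncate(dam_cohort, crit, cfg.n_dams)
        founders_idx = self._truncate(sire_cohort, crit, cfg.n_stations)
        self._build_stations(year, founders_idx, sire_cohort)

        # dam assignment: k_d daughters per selected dam, remainder at random
        quota = np.repeat(dams_idx, cfg.sister_group_size)
        n_rest = n - quota.size
        if n_rest > 0:
            quota = np.concatenate([quota, rng.choice(dams_idx, size=n_rest, replace=True)])
        dam_of = quota[:n]

        # paternal gamete: one of the dam's twelve stored mates, per daughter
        father_slot = rng.integers(nm, size=n)
        pick = rng.integers(0, 2, size=(n, L))
        dam_geno = dam_cohort.genotypes[dam_of]
        maternal_gam = np.take_along_axis(dam_geno, pick[:, None, :], axis=1)[:, 0, :]
        paternal_hap = dam_cohort.mates_hap[dam_of, father_slot]
        genotypes = np.stack([maternal_gam, paternal_hap], axis=1)

        # mating: a random station, twelve drones from its eight DPQ colonies
        st_of = rng.integers(len(self._stations), size=n)
        dpq_pick = rng.integers(cfg.n_dpq_per_station, size=(n, nm))
        all_dpq_geno = np.stack([s["dpq_geno"] for s in self._stations])
        all_dpq_ids = np.stack([s["dpq_ids"] for s in self._stations])
        all_dpq_f = np.stack([s["dpq_f"] for s in self._stations])
        sel_geno = all_dpq_geno[st_of[:, None], dpq_pick]  # (n, nm, 2, L)
        pick2 = rng.integers(0, 2, size=(n, nm, L))
        mates_hap = np.take_along_axis(sel_geno, pick2[:, :, None, :], axis=2)[:, :, 0, :]
        mates_dpq_id = all_dpq_ids[st_of[:, None], dpq_pick]
        mates_dpq_f = all_dpq_f[st_of[:, None], dpq_pick]

        apiary = np.where(
            rng.random(n) < cfg.apiary_inherit_prob,
            dam_cohort.apiary[dam_of],
            rng.integers(cfg.n_apiaries, size=n),
        )

        ids = self._take_ids(n)
        inbreeding = np.empty(n)
        entity = np.empty(n, dtype=np.int64)
        pool_entity = np.empty(n, dtype=np.int64)
        for i in range(n):
            di = int(dam_of[i])
            dam_id = int(dam_cohort.ids[di])
            mom = int(dam_cohort.mates_dpq_id[di, father_slot[i]])
            key = dam_id * 16 + int(father_slot[i])
            inbreeding[i] = self.kin.add_queen(
                int(ids[i]),
                year,
                dam_id,
                mom if mom >= 0 else None,
                key,
                float(dam_cohort.mates_dpq_f[di, father_slot[i]]),
            )
            self.kin_log.append((int(ids[i]), dam_id, mom if mom >= 0 else None, key))
            st = self._stations[st_of[i]]
            qe = self._add_entity(
                int(dam_cohort.entity[di]), int(dam_cohort.sire_pool_entity[di]), 0.0
            )
            self.ent_d[qe] = self.ent.add_queen(
                qe, year, int(dam_cohort.entity[di]), int(dam_cohort.sire_pool_entity[di])
            )
            entity[i] = qe
            pool_entity[i] = st["pool_entity"]

        tbv = self._tbv(genotypes)
        wg = self._wg_direct(genotypes, mates_hap)
        pheno = tbv[:, 0] + wg + rng.normal(0.0, np.sqrt(arch.sigma_e2), size=n)

        cohort = _Cohort(
            ids=ids,
            dam_id=dam_cohort.ids[dam_of],
            father_dpq_id=np.array(
                [
                    int(dam_cohort.mates_dpq_id[int(dam_of[i]), father_slot[i]])
                    for i in range(n)
                ],
                dtype=np.int64,
            ).clip(min=0),
            station_id=np.array([self._stations[s]["id"] for s in st_of], dtype=np.int64),
            apiary=apiary,
            inbreeding=inbreeding,
            tbv=tbv,
            wg_direct=wg,
            phenotype=pheno,
            entity=entity,
            sire_pool_entity=pool_entity,
            genotypes=genotypes,
            mates_hap=mates_hap,
            mates_dpq_id=mates_dpq_id,
            mates_dpq_f=mates_dpq_f,
        )
        self.cohorts[year] = cohort
        self._record_cohort(year, cohort)

        # selection differential bookkeeping + cohort summary
        sel_tbv = dam_cohort.tbv[dams_idx].sum(axis=1).mean()
        self._summaries.append(
            {
                "year": year,
                "mean_f": float(inbreeding.mean()),
                "performance_criterion": float((tbv[:, 0] + wg).mean()),
                "inheritance_mean": float(tbv.sum(axis=1).mean()),
                "inheritance_variance": float(tbv.sum(axis=1).var(ddof=1)),
                "sigma_hat_m2": float(self.sigma_hat[0, 0]),
                "sigma_hat_d2": float(self.sigma_hat[1, 1]),
                "sigma_hat_md": float(self.sigma_hat[0, 1]),
                "dam_selection_differential": float(
                    sel_tbv - dam_cohort.tbv.sum(axis=1).mean()
                ),
                "delta_f_to_date": (
                    _delta_f(float(inbreeding.mean()), elapsed_years=max(year - 1, 1))
                ),
            }
        )

        # windows and heavy per-cohort data are only needed for ~3 years back
        self.kin.prune(year - 3)
        self.ent.prune(year - 3)
        old = year - 4
        if old in self.cohorts:
            c = self.cohorts[old]
            c.genotypes = c.mates_hap = None
            c.mates_dpq_id = c.mates_dpq_f = None

    # -- orchestration ----------------------------------------------------

    def run(self) -> SimulationResult:
        self.initialize_base()
        for year in range(1, self.config.years + 1):
            self.run_year(year)
        summaries = pd.DataFrame(self._summaries)
        pedigree = pd.DataFrame(
            self._ped_rows,
            columns=[
                "queen_id",
                "birth_year",
                "dam_id",
                "father_dpq_id",
                "station_id",
                "apiary_id",
                "F",
            ],
        )
        return SimulationResult(
            config=self.config,
            arch=self.arch,
            summaries=summaries,
            pedigree=pedigree,
            base_inheritance_variance=self.arch.sigma_ic**2,
        )


def run_scheme_once(
    config: SchemeConfig,
    arch: TraitArchitecture,
    seed: np.random.SeedSequence | int,
) -> SimulationResult:
    """Convenience wrapper: one replicate, fresh RNG stream."""
    return Simulation(config, arch, seed).run()
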