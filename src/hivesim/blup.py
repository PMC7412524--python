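"""Honeybee-specific BLUP: entity pedigree, sparse relationship inverse,
maternal/direct mixed-model equations, and the drone-based variance
re-estimator.

Evaluation entities are queens, worker groups, and *pseudo-sires*.  A
pseudo-sire stands for the pooled drone production of a mating station's eight
drone-producing queens (the honeybee analogue of a sire); its genetic value is
the mean value of the eight drone-producing queens, so the expectation of any
offspring equals the usual half-dam plus half-sire parent average and the
standard Henderson machinery applies.  Each entity carries a Mendelian
sampling-variance coefficient ``d_i`` derived in closed form from the model's
own drone-level kinship rules (eight drone-producing queens per station,
twelve mates per queen, infinitely many drones per drone-producing queen):

* base queen                      ``d = 1``
* base pool of n unrelated queens ``d = 1/n``
* queen                           ``d = 1 - (a_pp + a_ss)/4``
* station pool                    ``d = (1 - (a_pp + a_ss)/4) / 8``
* worker group                    ``d = (2 - a_ss)/48``

where ``a_pp``/``a_ss`` are the diagonal relationship entries of the dam-side
and sire-side parent entities.  With these, ``A = T D T'`` reproduces the
average relationship matrix exactly and ``A^{-1}`` is sparse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .architecture import TraitArchitecture, make_gametes
from .kinship import EntityRecord

__all__ = [
    "mendelian_d_queen",
    "mendelian_d_pool",
    "mendelian_d_worker_group",
    "DenseEntityPedigree",
    "sparse_a_inverse",
    "MixedModelEquations",
    "solve_mme",
    "VarianceEstimate",
    "reestimate_variance",
    "nearest_psd",
]

N_DPQ = 8
N_MATES = 12


# -- closed-form Mendelian sampling coefficients ------------------------


def mendelian_d_queen(a_pp: float, a_ss: float) -> float:
    """d for a queen from dam diagonal ``a_pp`` and sire-pool diagonal ``a_ss``."""
    return 1.0 - 0.25 * (a_pp + a_ss)


def mendelian_d_pool(a_pp: float, a_ss: float, n_dpq: int = N_DPQ) -> float:
    """d for a station pool: the drone-producing-queen d shrunk by pool size."""
    return (1.0 - 0.25 * (a_pp + a_ss)) / n_dpq


def mendelian_d_worker_group(a_ss: float, n_mates: int = N_MATES) -> float:
    """d for a worker group: finite-mate sampling of the paternal pool mean."""
    return (2.0 - a_ss) / (4.0 * n_mates)


class DenseEntityPedigree:
    """Entity pedigree with a forward-built dense relationship matrix.

    Intended for oracle-sized problems and tests; the simulator maintains the
    same quantities in a sliding window.  ``add_*`` methods return the entity
    index; parents must already exist.
    """

    def __init__(self):
        self.kinds: list[str] = []
        self.parent_p: list[int] = []
        self.parent_s: list[int] = []
        self.d: list[float] = []
        self.records: list[EntityRecord] = []
        self._a = np.zeros((0, 0))

    def __len__(self) -> int:
        return len(self.kinds)

    @property
    def a(self) -> np.ndarray:
        """Dense average additive-relationship matrix A = T D T'."""
        return self._a

    def _grow(self) -> int:
        n = len(self.kinds)
        a = np.zeros((n, n))
        a[: n - 1, : n - 1] = self._a
        self._a = a
        return n - 1

    def _check_parents(self, *parents) -> None:
        for parent in parents:
            if parent is not None and not 0 <= parent < len(self.kinds):
                raise ValueError(f"dangling parent reference {parent!r}")

    def _append(self, kind, p, s, rec) -> int:
        self._check_parents(p, s)
        self.kinds.append(kind)
        self.parent_p.append(-1 if p is None else p)
        self.parent_s.append(-1 if s is None else s)
        self.records.append(rec)
        return self._grow()

    def add_base_queen(self) -> int:
        i = self._append("base_queen", None, None, EntityRecord("base_queen"))
        self.d.append(1.0)
        self._a[i, i] = 1.0
        return i

    def add_base_pool(self, n_members: int = N_MATES) -> int:
        i = self._append(
            "base_pool", None, None, EntityRecord("base_pool", n_members=n_members)
        )
        self.d.append(1.0 / n_members)
        self._a[i, i] = 1.0 / n_members
        return i

    def add_queen(self, dam: int, sire_pool: int) -> int:
        self._check_parents(dam, sire_pool)
        a = self._a
        d = mendelian_d_queen(a[dam, dam], a[sire_pool, sire_pool])
        i = self._append("queen", dam, sire_pool, EntityRecord("queen", dam, sire_pool))
        self.d.append(d)
        a = self._a
        row = 0.5 * (a[dam, :i] + a[sire_pool, :i])
        a[i, :i] = a[:i, i] = row
        a[i, i] = 1.0 + 0.5 * a[dam, sire_pool]
        return i

    def add_pool(self, founder: int, founder_pool: int) -> int:
        self._check_parents(founder, founder_pool)
        a = self._a
        app, ass = a[founder, founder], a[founder_pool, founder_pool]
        aps = a[founder, founder_pool]
        d = mendelian_d_pool(app, ass)
        i = self._append("pool", founder, founder_pool, EntityRecord("pool", founder, founder_pool))
        self.d.append(d)
        a = self._a
        row = 0.5 * (a[founder, :i] + a[founder_pool, :i])
        a[i, :i] = a[:i, i] = row
        a[i, i] = 0.25 * (app + 2.0 * aps + ass) + d
        return i

    def add_worker_group(self, queen: int, pool: int) -> int:
        self._check_parents(queen, pool)
        a = self._a
        aqq, ass, aqs = a[queen, queen], a[pool, pool], a[queen, pool]
        d = mendelian_d_worker_group(ass)
        i = self._append(
            "worker_group", queen, pool, EntityRecord("worker_group", queen, pool)
        )
        self.d.append(d)
        a = self._a
        row = 0.5 * (a[queen, :i] + a[pool, :i])
        a[i, :i] = a[:i, i] = row
        a[i, i] = 0.25 * (aqq + 2.0 * aqs + ass) + d
        return i

    def a_inverse(self) -> sp.csr_matrix:
        return sparse_a_inverse(
            np.asarray(self.parent_p), np.asarray(self.parent_s), np.asarray(self.d)
        )


def sparse_a_inverse(
    parent_p: np.ndarray, parent_s: np.ndarray, d: np.ndarray
) -> sp.csr_matrix:
    """Sparse inverse of A = T D T' by Henderson's rules, vectorized.

    ``parent_p``/``parent_s`` hold entity indices (-1 for unknown), ``d`` the
    Mendelian sampling-variance coefficients.
    """
    n = d.size
    if np.any(d <= 0):
        raise ValueError("Mendelian sampling coefficients must be positive")
    alpha = 1.0 / d
    idx = np.arange(n)
    rows = [idx]
    cols = [idx]
    vals = [alpha]
    for par in (parent_p, parent_s):
        m = par >= 0
        rows += [par[m], idx[m]]
        cols += [idx[m], par[m]]
        vals += [-0.5 * alpha[m], -0.5 * alpha[m]]
    for pa in (parent_p, parent_s):
        for pb in (parent_p, parent_s):
            m = (pa >= 0) & (pb >= 0)
            rows.append(pa[m])
            cols.append(pb[m])
            vals.append(0.25 * alpha[m])
    coo = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return coo.tocsr()


# -- mixed-model equations ----------------------------------------------


@dataclass
class MixedModelEquations:
    """Assembled MME for the maternal/direct colony model.

    Records follow ``y = year-x-apiary fixed level + queen maternal +
    worker-group direct + residual``; each entity has a (maternal, direct)
    pair of random effects with covariance ``A (x) Sigma_A``.
    """

    lhs: sp.csr_matrix
    rhs: np.ndarray
    n_fixed: int
    n_entities: int
    ainv_diag: np.ndarray
    ginv: np.ndarray
    sigma_e2: float

    @classmethod
    def assemble(
        cls,
        level_idx: np.ndarray,
        n_levels: int,
        queen_entity: np.ndarray,
        wg_entity: np.ndarray,
        y: np.ndarray,
        ainv: sp.spmatrix,
        sigma_hat: np.ndarray,
        sigma_e2: float,
    ) -> "MixedModelEquations":
        n_rec = y.size
        if n_rec == 0:
            raise ValueError("at least one performance record is required")
        n_ent = ainv.shape[0]
        ginv = np.linalg.inv(sigma_hat)

        rows = np.repeat(np.arange(n_rec), 3)
        cols = np.stack(
            [level_idx, n_levels + 2 * queen_entity, n_levels + 2 * wg_entity + 1],
            axis=1,
        ).ravel()
        w = sp.csr_matrix(
            (np.ones(3 * n_rec), (rows, cols)), shape=(n_rec, n_levels + 2 * n_ent)
        )
        lhs = (w.T @ w).tocoo()

        pen = ainv.tocoo()
        lam = ginv * sigma_e2
        prow, pcol, pval = [], [], []
        for a in range(2):
            for b in range(2):
                prow.append(n_levels + 2 * pen.row + a)
                pcol.append(n_levels + 2 * pen.col + b)
                pval.append(pen.data * lam[a, b])
        lhs = sp.coo_matrix(
            (
                np.concatenate([lhs.data] + pval),
                (
                    np.concatenate([lhs.row] + prow),
                    np.concatenate([lhs.col] + pcol),
                ),
            ),
            shape=lhs.shape,
        ).tocsr()
        rhs = w.T @ y
        return cls(lhs, rhs, n_levels, n_ent, ainv.diagonal(), ginv, sigma_e2)

    def preconditioner(self) -> spla.LinearOperator:
        """2x2 block-Jacobi on the random part, scalar Jacobi on fixed levels."""
        diag = self.lhs.diagonal()
        nf, ne = self.n_fixed, self.n_entities
        fixed_inv = 1.0 / diag[:nf]
        b11 = diag[nf + 0 :: 2]
        b22 = diag[nf + 1 :: 2]
        b12 = self.ainv_diag * self.ginv[0, 1] * self.sigma_e2
        det = b11 * b22 - b12 * b12
        det = np.where(np.abs(det) < 1e-300, 1.0, det)

        def apply(r):
            out = np.empty_like(r)
            out[:nf] = r[:nf] * fixed_inv
            r1, r2 = r[nf::2], r[nf + 1 :: 2]
            out[nf::2] = (b22 * r1 - b12 * r2) / det
            out[nf + 1 :: 2] = (b11 * r2 - b12 * r1) / det
            return out

        n = diag.size
        return spla.LinearOperator((n, n), matvec=apply)


def solve_mme(
    mme: MixedModelEquations,
    tol: float = 1e-8,
    warm_start: np.ndarray | None = None,
    solver: str = "cg",
    maxiter: int = 20000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Solve the MME; returns (fixed estimates, EBV array (n_ent, 2), raw x).

    ``solver="cg"`` uses block-Jacobi preconditioned conjugate gradients with
    an optional warm start (relative residual below ``tol``); ``"direct"``
    uses a sparse LU factorization.
    """
    if solver == "direct":
        x = spla.splu(mme.lhs.tocsc()).solve(mme.rhs)
    elif solver == "cg":
        x0 = None
        if warm_start is not None and warm_start.size == mme.rhs.size:
            x0 = warm_start
        x, info = spla.cg(
            mme.lhs,
            mme.rhs,
            x0=x0,
            rtol=tol,
            atol=0.0,
            maxiter=maxiter,
            M=mme.preconditioner(),
        )
        if info != 0:
            res = np.linalg.norm(mme.rhs - mme.lhs @ x) / np.linalg.norm(mme.rhs)
            raise RuntimeError(
                f"MME solver did not converge (info={info}, rel. residual={res:.3e}, "
                f"n={mme.rhs.size})"
            )
    else:
        raise ValueError(f"unknown solver {solver!r}")
    beta = x[: mme.n_fixed]
    u = x[mme.n_fixed :].reshape(mme.n_entities, 2)
    return beta, u, x


# -- five-yearly variance re-estimation ---------------------------------


def nearest_psd(mat: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to PSD by clipping eigenvalues at ``eps``."""
    sym = 0.5 * (mat + mat.T)
    vals, vecs = np.linalg.eigh(sym)
    if vals[0] >= eps:
        return sym
    return (vecs * np.maximum(vals, eps)) @ vecs.T


@dataclass
class VarianceEstimate:
    """Re-estimated additive covariance from simulated drone production."""

    sigma_hat: np.ndarray
    year: int
    n_queens: int
    n_drones_per_queen: int


def reestimate_variance(
    genotypes: np.ndarray,
    inbreeding: np.ndarray,
    arch: TraitArchitecture,
    rng: np.random.Generator,
    n_drones: int = 100,
    year: int = 0,
) -> VarianceEstimate:
    """Within-family variance estimator from virtual drone production.

    Every queen i (genotype ``(2, n_loci)``, pedigree inbreeding ``F_i``)
    produces ``n_drones`` virtual drones.  With Mendelian-sampling deviations
    ``delta_ij = TBV(Q_i) - TBV(D_ij)`` (drones on the doubled-homozygous
    scale), ``var(delta) = (1 - F_i) Sigma_A``, so

        Sigma_hat = (n N - 1)^{-1} sum_i (1 - F_i)^{-1} sum_j delta delta'

    estimates the additive covariance free of Bulmer-effect bias.  Queens with
    F within 1e-6 of 1 are excluded with a warning; the result is projected to
    the nearest PSD matrix if needed.
    """
    genotypes = np.asarray(genotypes)
    f = np.asarray(inbreeding, dtype=float)
    keep = f < 1.0 - 1e-6
    if not np.all(keep):
        warnings.warn(
            f"excluding {int((~keep).sum())} fully inbred queens from variance "
            "re-estimation"
        )
        genotypes, f = genotypes[keep], f[keep]
    if genotypes.shape[0] == 0:
        raise ValueError("no queens available for variance re-estimation")

    n = genotypes.shape[0]
    counts = genotypes.sum(axis=1).astype(float)  # (n, L)
    q_tbv = (counts - 2.0 * arch.allele_freq) @ arch.effects.T  # (n, 2)
    gametes = make_gametes(genotypes, n_drones, rng).astype(float)  # (n, nd, L)
    d_tbv = (2.0 * gametes - 2.0 * arch.allele_freq) @ arch.effects.T  # (n, nd, 2)
    delta = q_tbv[:, None, :] - d_tbv
    weights = 1.0 / (1.0 - f)
    scatter = np.einsum("i,ija,ijb->ab", weights, delta, delta)
    sigma = scatter / (n * n_drones - 1.0)
    if np.linalg.eigvalsh(sigma)[0] < 0:
        sigma = nearest_psd(sigma)
    return VarianceEstimate(sigma, year, n, n_drones)
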