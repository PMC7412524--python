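"""Finite-locus trait architecture for honeybee breeding simulations.

The selection trait is controlled by ``n_loci`` unlinked, biallelic, purely
additive loci.  Every locus carries a pair of substitution effects — one on the
*maternal* (queen) component of colony performance and one on the *direct*
(worker group) component.  Base-population allele frequencies follow a U-shaped
Beta(0.5, 0.5) distribution and raw effect pairs are drawn from an equal-weight
mixture of a bivariate Laplace and a bivariate Normal distribution.  A final
whitening/recoloring transform of the two effect rows makes the additive
covariance implied by the base population equal to the requested ``sigma_a``
*exactly*, so simulated true breeding values start at mean zero with a known
covariance.

Drones are haploid; for breeding-value bookkeeping they are interpreted as
diploid but fully homozygous, i.e. their allele counts are twice their single
haplotype.  Worker groups are modeled as the expectation over an infinite
worker cohort fathered equally by the queen's twelve mates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "TraitArchitecture",
    "sample_architecture",
    "make_gamete",
    "make_gametes",
    "queen_tbv",
    "drone_tbv",
    "worker_group_tbv",
]

#: frequencies closer than this to 0/1 are resampled so 2p(1-p) stays positive
_FREQ_MARGIN = 1e-6
#: tolerance of the exact post-correction contract
_EXACTNESS_TOL = 1e-10


def _as_sigma_a(sigma_a) -> np.ndarray:
    """Coerce ``(var_m, var_d, cov_md)`` or a 2x2 array to a 2x2 float array."""
    arr = np.asarray(sigma_a, dtype=float)
    if arr.shape == (3,):
        vm, vd, c = arr
        arr = np.array([[vm, c], [c, vd]])
    if arr.shape != (2, 2):
        raise ValueError("sigma_a must be a 2x2 matrix or (var_m, var_d, cov_md)")
    if not np.allclose(arr, arr.T):
        raise ValueError("sigma_a must be symmetric")
    if np.linalg.eigvalsh(arr)[0] <= 0:
        raise ValueError("sigma_a must be positive definite")
    return arr


@dataclass(frozen=True)
class TraitArchitecture:
    """Immutable description of one selection trait.

    Attributes
    ----------
    allele_freq
        Base-population frequencies of the "1" allele, shape ``(n_loci,)``,
        strictly inside (0, 1).
    effects
        Per-allele-copy substitution effects, shape ``(2, n_loci)``; row 0 is
        the maternal effect, row 1 the direct effect.
    sigma_a
        Target 2x2 additive covariance matrix of (maternal, direct) breeding
        values in the base population.
    sigma_e2
        Residual variance of colony performance records.
    """

    allele_freq: np.ndarray
    effects: np.ndarray
    sigma_a: np.ndarray
    sigma_e2: float
    seed: int | None = field(default=None, compare=False)

    def __post_init__(self):
        p = np.asarray(self.allele_freq, dtype=float)
        e = np.asarray(self.effects, dtype=float)
        s = _as_sigma_a(self.sigma_a)
        if p.ndim != 1 or p.size < 2:
            raise ValueError("allele_freq must be a vector with at least 2 loci")
        if np.any(p <= 0.0) or np.any(p >= 1.0):
            raise ValueError("allele frequencies must lie strictly inside (0, 1)")
        if e.shape != (2, p.size):
            raise ValueError("effects must have shape (2, n_loci)")
        if self.sigma_e2 < 0:
            raise ValueError("sigma_e2 must be non-negative")
        object.__setattr__(self, "allele_freq", p)
        object.__setattr__(self, "effects", e)
        object.__setattr__(self, "sigma_a", s)
        implied = self.implied_sigma_a()
        if np.max(np.abs(implied - s)) > 1e-8:
            raise ValueError("effects do not reproduce sigma_a (post-correction violated)")

    @property
    def n_loci(self) -> int:
        return self.allele_freq.size

    @property
    def sigma_ic(self) -> float:
        """Total genetic SD of the inheritance criterion (maternal + direct)."""
        s = self.sigma_a
        v = s[0, 0] + s[1, 1] + 2.0 * s[0, 1]
        return float(np.sqrt(max(v, 0.0)))

    @property
    def r_md(self) -> float:
        """Correlation between maternal and direct effects."""
        s = self.sigma_a
        return float(s[0, 1] / np.sqrt(s[0, 0] * s[1, 1]))

    def implied_sigma_a(self) -> np.ndarray:
        """Base additive covariance implied by frequencies and effects.

        Equals ``sum_l 2 p_l (1 - p_l) e_l e_l^T`` under Hardy-Weinberg and
        linkage equilibrium.
        """
        w = 2.0 * self.allele_freq * (1.0 - self.allele_freq)
        return (self.effects * w) @ self.effects.T

    # -- serialization --------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write a delimited per-locus table with a reproducibility header."""
        s = self.sigma_a
        header = (
            f"# sigma_a_m2={float(s[0, 0])!r}\tsigma_a_d2={float(s[1, 1])!r}\t"
            f"sigma_a_md={float(s[0, 1])!r}\tsigma_e2={float(self.sigma_e2)!r}\tseed={self.seed}\n"
            "locus\tfrequency\tmaternal_effect\tdirect_effect\n"
        )
        body = "\n".join(
            "\t".join(
                [
                    str(i + 1),
                    repr(float(self.allele_freq[i])),
                    repr(float(self.effects[0, i])),
                    repr(float(self.effects[1, i])),
                ]
            )
            for i in range(self.n_loci)
        )
        Path(path).write_text(header + body + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TraitArchitecture":
        lines = Path(path).read_text().strip().splitlines()
        meta = {}
        for kv in lines[0].lstrip("# ").split("\t"):
            k, v = kv.split("=")
            meta[k] = v
        rows = [ln.split("\t") for ln in lines[2:]]
        p = np.array([float(r[1]) for r in rows])
        e = np.array([[float(r[2]) for r in rows], [float(r[3]) for r in rows]])
        sig = (float(meta["sigma_a_m2"]), float(meta["sigma_a_d2"]), float(meta["sigma_a_md"]))
        seed = None if meta["seed"] == "None" else int(meta["seed"])
        return cls(p, e, _as_sigma_a(sig), float(meta["sigma_e2"]), seed=seed)


def sample_architecture(
    n_loci: int,
    sigma_a,
    sigma_e2: float,
    rng: np.random.Generator,
    laplace_weight: float = 0.5,
) -> TraitArchitecture:
    """Draw a random trait architecture with exactly the requested covariance.

    Frequencies are i.i.d. Beta(0.5, 0.5), resampled while within 1e-6 of the
    boundary.  Raw per-locus effect pairs come from an equal-weight mixture of
    a bivariate Laplace and a bivariate Normal, both scaled so that every locus
    contributes ``sigma_a / n_loci`` in expectation; a single 2x2 transform
    (target Cholesky times inverse achieved Cholesky) then makes the implied
    base covariance exact.
    """
    if n_loci < 2:
        raise ValueError("n_loci must be at least 2")
    target = _as_sigma_a(sigma_a)

    p = rng.beta(0.5, 0.5, size=n_loci)
    bad = (p < _FREQ_MARGIN) | (p > 1.0 - _FREQ_MARGIN)
    while np.any(bad):
        p[bad] = rng.beta(0.5, 0.5, size=int(bad.sum()))
        bad = (p < _FREQ_MARGIN) | (p > 1.0 - _FREQ_MARGIN)

    chol = np.linalg.cholesky(target)
    z = chol @ rng.standard_normal((2, n_loci))
    # elliptical bivariate Laplace: Gaussian scaled by sqrt of an Exp(1) mixing
    # variable; E[W] = 1 keeps the covariance at sigma_a
    is_laplace = rng.random(n_loci) < laplace_weight
    w = np.where(is_laplace, rng.exponential(1.0, size=n_loci), 1.0)
    z *= np.sqrt(w)

    # effect sizes are drawn independently of allele frequency (each locus has
    # covariance sigma_a / n_loci before correction); rare alleles therefore
    # contribute little variance, as in a neutral-architecture base population
    effects = z / np.sqrt(n_loci)

    het = 2.0 * p * (1.0 - p)
    achieved = (effects * het) @ effects.T
    transform = chol @ np.linalg.inv(np.linalg.cholesky(achieved))
    effects = transform @ effects

    arch = TraitArchitecture(p, effects, target, float(sigma_e2))
    assert np.max(np.abs(arch.implied_sigma_a() - target)) < _EXACTNESS_TOL
    return arch


def make_gamete(genotype: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One meiotic gamete of a queen: per locus, either haplotype with prob 1/2."""
    genotype = np.asarray(genotype)
    if genotype.ndim != 2 or genotype.shape[0] != 2:
        raise ValueError("genotype must have shape (2, n_loci)")
    pick = rng.integers(0, 2, size=genotype.shape[1])
    return genotype[pick, np.arange(genotype.shape[1])]


def make_gametes(genotypes: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Vectorized gametes.

    ``genotypes`` has shape ``(m, 2, n_loci)``; returns ``(m, n, n_loci)``
    with ``n`` independent gametes per queen.  No linkage, no mutation.
    """
    m, two, L = genotypes.shape
    assert two == 2
    pick = rng.integers(0, 2, size=(m, n, L))
    h0 = genotypes[:, 0, :][:, None, :]
    h1 = genotypes[:, 1, :][:, None, :]
    return np.where(pick == 0, h0, h1)


def _check_length(counts: np.ndarray, arch: TraitArchitecture) -> None:
    if counts.shape[-1] != arch.n_loci:
        raise ValueError(
            f"genotype has {counts.shape[-1]} loci, architecture has {arch.n_loci}"
        )


def queen_tbv(genotype: np.ndarray, arch: TraitArchitecture) -> np.ndarray:
    """(maternal, direct) true breeding value of a diploid queen.

    Linear in allele counts centered at base frequencies, so the base cohort
    expectation is the zero vector.
    """
    genotype = np.asarray(genotype, dtype=float)
    counts = genotype.sum(axis=-2)
    _check_length(counts, arch)
    return (counts - 2.0 * arch.allele_freq) @ arch.effects.T


def drone_tbv(haplotype: np.ndarray, arch: TraitArchitecture) -> np.ndarray:
    """(maternal, direct) TBV of a drone on the doubled-homozygous scale."""
    haplotype = np.asarray(haplotype, dtype=float)
    _check_length(haplotype, arch)
    return (2.0 * haplotype - 2.0 * arch.allele_freq) @ arch.effects.T


def worker_group_tbv(
    queen_genotype: np.ndarray,
    mates_haplotypes: np.ndarray,
    arch: TraitArchitecture,
) -> float:
    """Direct TBV of the (infinite) worker group of one colony.

    A worker carries one maternal gamete plus its father drone's haplotype;
    with the queen's mates contributing equally, the expectation over workers
    is ``e_direct . [ (queen counts - 2p)/2 + mean_k(haplotype_k - p) ]``.
    """
    mates = np.asarray(mates_haplotypes, dtype=float)
    if mates.ndim != 2 or mates.shape[0] == 0:
        raise ValueError("mates_haplotypes must be a non-empty (n_mates, n_loci) array")
    q = np.asarray(queen_genotype, dtype=float).sum(axis=0)
    _check_length(q, arch)
    _check_length(mates, arch)
    mean_counts = 0.5 * (q - 2.0 * arch.allele_freq) + (mates.mean(axis=0) - arch.allele_freq)
    return float(mean_counts @ arch.effects[1])
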