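"""Scheme-level metrics, replicate aggregation, and grid experiments.

Two criteria summarize a cohort: the *performance criterion* (mean of queen
maternal plus worker-group direct true breeding values — realized genetic
gain over the base population) and the *inheritance criterion* variance
(variance of queen maternal-plus-direct TBV — the selectable variance left in
the population).  Schemes are compared within one (population size, trait)
cell: a scheme is *competitive* (CBS) when its 100-year gain is within 5% of
the cell's best, and FAO sustainability thresholds of 0.5%/1% generational
inbreeding classify each scheme's long-term risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .architecture import TraitArchitecture, sample_architecture
from .config import TraitParams, seed_replicates
from .scheme import SchemeConfig, Simulation

__all__ = [
    "performance_criterion",
    "inheritance_variance",
    "classify_sustainability",
    "competitive_schemes",
    "SchemeResult",
    "run_scheme",
    "run_grid",
    "summarize_cell",
]

FAO_STRICT = 0.005
FAO_SUSTAINABLE = 0.01
CBS_TOLERANCE = 0.05


def performance_criterion(maternal_tbv: np.ndarray, wg_direct_tbv: np.ndarray) -> float:
    """Cohort mean of queen maternal + worker-group direct breeding values."""
    m = np.asarray(maternal_tbv, dtype=float)
    w = np.asarray(wg_direct_tbv, dtype=float)
    if m.size == 0:
        raise ValueError("cohort is empty")
    return float((m + w).mean())


def inheritance_variance(queen_tbv: np.ndarray) -> float:
    """Cohort variance of queen maternal + direct breeding values."""
    t = np.asarray(queen_tbv, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2:
        raise ValueError("need at least two queens with (maternal, direct) TBVs")
    return float(t.sum(axis=1).var(ddof=1))


def classify_sustainability(rate: float) -> str:
    """FAO classification of a generational inbreeding rate (fraction scale).

    Boundary inclusive: 0.5% is 'strict', 1% is 'sustainable'.
    """
    if rate < 0:
        raise ValueError("inbreeding rate must be non-negative")
    if rate <= FAO_STRICT:
        return "strict"
    if rate <= FAO_SUSTAINABLE:
        return "sustainable"
    return "unsustainable"


def competitive_schemes(gains: dict, tolerance: float = CBS_TOLERANCE) -> set:
    """Schemes whose gain is within ``tolerance`` of the best in the cell."""
    if not gains:
        raise ValueError("at least one scheme is required")
    best = max(gains.values())
    return {k for k, g in gains.items() if g >= (1.0 - tolerance) * best}


@dataclass
class SchemeResult:
    """Replicate-level outcomes of one scheme in one cell."""

    n: int
    k_d: int
    k_s: float
    trait: TraitParams
    gain_15: list[float] = field(default_factory=list)
    gain_final: list[float] = field(default_factory=list)
    var_final_relative: list[float] = field(default_factory=list)
    delta_f: list[float] = field(default_factory=list)

    @property
    def n_replicates(self) -> int:
        return len(self.delta_f)

    def mean(self, attr: str) -> float:
        return float(np.mean(getattr(self, attr)))

    def sd(self, attr: str) -> float:
        vals = getattr(self, attr)
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")


def run_scheme(
    config: SchemeConfig,
    trait: TraitParams,
    n_replicates: int,
    master_seed: int,
) -> SchemeResult:
    """Run independent seeded replicates of one scheme and collect metrics."""
    result = SchemeResult(config.n_queens, config.sister_group_size, config.sire_rate_percent, trait)
    for ss in seed_replicates(master_seed, n_replicates):
        arch_seed, sim_seed = ss.spawn(2)
        arch = sample_architecture(
            trait.n_loci, trait.sigma_a(), trait.sigma_e2, np.random.default_rng(arch_seed)
        )
        res = Simulation(config, arch, sim_seed).run()
        s = res.summaries
        if (s["year"] == 15).any():
            result.gain_15.append(res.gain(15))
        result.gain_final.append(float(s["performance_criterion"].iloc[-1]))
        result.var_final_relative.append(res.relative_variance())
        result.delta_f.append(res.delta_f())
    return result


def run_grid(
    n: int,
    kd_values,
    ks_values,
    trait: TraitParams,
    n_replicates: int,
    master_seed: int,
    years: int = 100,
    selection: str = "blup",
    on_error: str = "report",
) -> pd.DataFrame:
    """Sweep a k_d x k_s grid; one tidy row per scheme x replicate.

    Cell failures are reported and skipped (``on_error="report"``) so a long
    sweep survives isolated numerical problems, or re-raised
    (``on_error="raise"``).
    """
    rows = []
    for i_kd, kd in enumerate(kd_values):
        for i_ks, ks in enumerate(ks_values):
            config = SchemeConfig(
                n_queens=n,
                sister_group_size=int(kd),
                sire_rate_percent=float(ks),
                years=years,
                selection=selection,
            )
            cell_seed = master_seed + 100_003 * i_kd + 1009 * i_ks
            try:
                res = run_scheme(config, trait, n_replicates, cell_seed)
            except Exception as exc:  # pragma: no cover - defensive
                if on_error == "raise":
                    raise
                print(f"scheme kd={kd} ks={ks} failed: {exc}")
                continue
            for r in range(res.n_replicates):
                rows.append(
                    {
                        "n": n,
                        "k_d": kd,
                        "k_s": ks,
                        "replicate": r,
                        "gain_final": res.gain_final[r],
                        "gain_15": res.gain_15[r] if r < len(res.gain_15) else np.nan,
                        "var_final_relative": res.var_final_relative[r],
                        "delta_f": res.delta_f[r],
                    }
                )
    return pd.DataFrame(rows)


def summarize_cell(grid: pd.DataFrame) -> dict:
    """Table-style summary of one (population size, trait) cell.

    Returns CBS count, counts under the FAO thresholds, and the lowest- and
    highest-inbreeding competitive schemes with their retained variance.
    """
    agg = (
        grid.groupby(["k_d", "k_s"])
        .agg(
            gain=("gain_final", "mean"),
            delta_f=("delta_f", "mean"),
            var_rel=("var_final_relative", "mean"),
        )
        .reset_index()
    )
    gains = {(r.k_d, r.k_s): r.gain for r in agg.itertuples()}
    cbs = competitive_schemes(gains)
    sub = agg[[(r.k_d, r.k_s) in cbs for r in agg.itertuples()]]
    lo = sub.loc[sub["delta_f"].idxmin()]
    hi = sub.loc[sub["delta_f"].idxmax()]
    return {
        "n_cbs": len(cbs),
        "n_cbs_1pct": int((sub["delta_f"] <= FAO_SUSTAINABLE).sum()),
        "n_cbs_05pct": int((sub["delta_f"] <= FAO_STRICT).sum()),
        "lowest": {
            "k_d": int(lo.k_d),
            "k_s": float(lo.k_s),
            "delta_f": float(lo.delta_f),
            "var_rel": float(lo.var_rel),
        },
        "highest": {
            "k_d": int(hi.k_d),
            "k_s": float(hi.k_s),
            "delta_f": float(hi.delta_f),
            "var_rel": float(hi.var_rel),
        },
    }
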