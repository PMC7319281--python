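"""Monte-Carlo driver: empirical size/power tables and null diagnostics.

Seeding is counter-based: every (cell, replicate) pair maps to
``SeedSequence(master_seed, spawn_key=(cell_index, replicate))``, so each
table cell is reproducible in isolation and results do not depend on
execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .basis import CoefficientSet
from .functional import CalibrationError, flute_test
from .scalar import scalar_test
from .simulate import SimulationDesign, gen_functional_data, gen_scalar_data

__all__ = [
    "PowerTable",
    "run_cell",
    "size_power_table",
    "null_distribution_sample",
    "bootstrap_statistic_distribution",
    "TABLE_PRESETS",
    "run_table",
]


@dataclass
class PowerTable:
    """Empirical rejection rates, one row per |beta|^2 level.

    ``frame`` has a row per (cell label, betasq, alpha) with the rejection
    rate, its binomial Monte-Carlo standard error, the replicate count, and
    the number of replicates dropped to calibration failures.
    """

    frame: pd.DataFrame
    reps: int
    master_seed: int
    meta: dict = field(default_factory=dict)


def _replicate_rng(master_seed: int, cell_index: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(cell_index, rep))
    )


def _cell_rng(master_seed: int, cell_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(cell_index,))
    )


def run_cell(design: SimulationDesign, master_seed: int | None = None,
             cell_index: int = 0, collect_z: bool = False) -> dict:
    """Run one design cell: rejection rate per alpha level.

    Calibration failures (degenerate variance plug-ins) are counted and
    excluded from the denominator rather than silently dropped.
    """
    seed = design.seed if master_seed is None else master_seed
    cell_rng = _cell_rng(seed, cell_index)
    rejections = {a: 0 for a in design.alpha_levels}
    zs: list[float] = []
    failures = 0
    ref_alpha = min(design.alpha_levels)
    for rep in range(design.reps):
        rng = _replicate_rng(seed, cell_index, rep)
        try:
            if design.response == "functional":
                X, Y, _ = gen_functional_data(design, rng, cell_rng)
                res = flute_test(X, Y, beta0=None, alpha=ref_alpha)
            else:
                X, y, _ = gen_scalar_data(design, rng, cell_rng)
                res = scalar_test(X, y, beta0=None, alpha=ref_alpha)
        except CalibrationError:
            failures += 1
            continue
        zs.append(res.z)
        for a in design.alpha_levels:
            rejections[a] += res.z >= stats.norm.ppf(1.0 - a)
    valid = design.reps - failures
    rates = {a: (rejections[a] / valid if valid else np.nan)
             for a in design.alpha_levels}
    out = {"rates": rates, "valid": valid, "failures": failures}
    if collect_z:
        out["z"] = np.asarray(zs)
    return out


def size_power_table(designs: dict[str, SimulationDesign],
                     betasq_levels: list[float],
                     master_seed: int = 0) -> PowerTable:
    """Empirical rejection-rate table over design cells x |beta|^2 levels."""
    rows = []
    cell_index = 0
    reps = 0
    for label, design in designs.items():
        for betasq in betasq_levels:
            cell = design.with_betasq(betasq)
            reps = cell.reps
            result = run_cell(cell, master_seed, cell_index)
            for a, rate in result["rates"].items():
                se = np.sqrt(rate * (1.0 - rate) / result["valid"]) if result["valid"] else np.nan
                rows.append({
                    "cell": label, "betasq": betasq, "alpha": a,
                    "rate": rate, "mc_se": se,
                    "valid": result["valid"], "failures": result["failures"],
                    "cell_index": cell_index,
                })
            cell_index += 1
    return PowerTable(pd.DataFrame(rows), reps=reps, master_seed=master_seed)


def null_distribution_sample(design: SimulationDesign, reps: int | None = None,
                             master_seed: int = 0, cell_index: int = 0) -> dict:
    """Standardized statistics under the null plus a KS check against N(0,1)."""
    if design.betasq != 0.0:
        raise ValueError("null diagnostics require betasq = 0")
    if reps is not None:
        design = SimulationDesign(**{**design.__dict__, "reps": reps})
    result = run_cell(design, master_seed, cell_index, collect_z=True)
    z = result["z"]
    ks_stat, ks_p = stats.kstest(z, "norm")
    return {
        "z": z,
        "ks_statistic": float(ks_stat),
        "ks_p_value": float(ks_p),
        "rates": result["rates"],
        "valid": result["valid"],
        "failures": result["failures"],
    }


def bootstrap_statistic_distribution(X: CoefficientSet, Y, beta0=None,
                                     n_boot: int = 1000,
                                     rng: np.random.Generator | None = None,
                                     scalar: bool | None = None,
                                     indices: np.ndarray | None = None) -> dict:
    """Standardized statistics over subject resamples (with replacement).

    Resamples with fewer than four distinct subjects are redrawn and counted.
    ``indices`` injects explicit resample index rows (shape ``(n_boot, n)``),
    mainly so an identity resample can be checked against the plain test.
    """
    rng = rng or np.random.default_rng()
    n = X.n
    if scalar is None:
        scalar = not isinstance(Y, CoefficientSet)
    zs = np.empty(n_boot)
    redraws = 0
    for b in range(n_boot):
        while True:
            idx = (indices[b] if indices is not None
                   else rng.integers(0, n, size=n))
            if np.unique(idx).size >= 4:
                break
            redraws += 1
        Xb = CoefficientSet(X.coeffs[idx], X.basis)
        if scalar:
            res = scalar_test(Xb, np.asarray(Y)[idx], beta0)
        else:
            Yb = CoefficientSet(Y.coeffs[idx], Y.basis)
            res = flute_test(Xb, Yb, beta0)
        zs[b] = res.z
    return {"z": zs, "redraws": redraws}


def _functional_cells(n_K_pairs, **kw) -> dict[str, SimulationDesign]:
    return {
        f"K=L={K}, n={n}": SimulationDesign(n=n, K=K, L=K, response="functional", **kw)
        for K, n in n_K_pairs
    }


#: Preset Monte-Carlo grids mirroring the published size/power tables.
TABLE_PRESETS: dict[str, dict] = {
    # four (K, n) settings, |beta|^2 from 0 to 0.5, alpha = 0.05 and 0.1
    "table2": {
        "designs": lambda reps: _functional_cells(
            [(5, 40), (11, 40), (5, 100), (11, 100)], T=5, reps=reps),
        "levels": [0.0, 0.02, 0.04, 0.06, 0.08, 0.1, 0.2, 0.3, 0.4, 0.5],
    },
    # weak vs strong loading correlation at K=L=11, n=40
    "table4": {
        "designs": lambda reps: {
            f"T={T}": SimulationDesign(n=40, K=11, L=11, T=T, reps=reps)
            for T in (5, 11)
        },
        "levels": [0.0, 0.1, 0.2, 0.3, 0.4, 0.5],
    },
    # heteroscedastic error loadings Var(eps_l) = 1/l
    "table5": {
        "designs": lambda reps: {
            f"K=L={K}": SimulationDesign(
                n=40, K=K, L=K, T=5, reps=reps,
                error_cov="heteroscedastic_1_over_l")
            for K in (5, 11)
        },
        "levels": [0.0, 0.1, 0.2, 0.3, 0.4, 0.5],
    },
    # scalar response, N(0,1) errors
    "table6": {
        "designs": lambda reps: {
            f"K={K}, n={n}": SimulationDesign(
                n=n, K=K, L=1, T=5, reps=reps, response="scalar")
            for K, n in [(5, 40), (11, 40), (5, 100), (11, 100)]
        },
        "levels": [0.0, 0.02, 0.04, 0.06, 0.08, 0.1, 0.2, 0.3, 0.4, 0.5],
    },
    # pure-noise scalar model Y = eps
    "table8": {
        "designs": lambda reps: {
            f"n={n}": SimulationDesign(n=n, K=11, L=1, T=5, reps=reps,
                                       response="scalar")
            for n in (40, 100)
        },
        "levels": [0.0],
    },
}
TABLE_PRESETS["table3"] = TABLE_PRESETS["table2"]  # alpha = 0.1 column
TABLE_PRESETS["table7"] = TABLE_PRESETS["table6"]


def run_table(name: str, reps: int = 1000, master_seed: int = 0) -> PowerTable:
    """Run one preset table grid at the requested replicate count."""
    try:
        preset = TABLE_PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown table {name!r}; choose from {sorted(TABLE_PRESETS)}"
        ) from None
    table = size_power_table(preset["designs"](reps), preset["levels"], master_seed)
    table.meta["table"] = name
    return table
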