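"""Per-day fixed-effects model for greenhouse block and genotype effects.

For each imaging day t and each holistic response h (aerial density,
bi-angular convex-hull area ratio, aspect ratio) the observations are
modeled as

    y_{h,ij,t} = mu_{h,t} + alpha_{h,i,t} + gamma_{h,nu(i,j),t} + eps_{h,ij,t}

with i the greenhouse block, j the plant within the block and nu(i,j) its
genotype. Days are fitted independently by ordinary least squares under
reference ("benchmark") coding: the first block and the first genotype are
the baselines, their effects fixed at exactly zero. Confidence intervals
use the t distribution with the residual degrees of freedom; no
multiple-testing correction is applied.

Input is a long-format table with columns
``plant_id, block, genotype, day, response, value``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import AliasedEffectsError, InvalidArgumentError

TABLE_COLUMNS = ["plant_id", "block", "genotype", "day", "response", "value"]


@dataclass
class DayFit:
    """OLS fit of one (day, response) slice under reference coding."""

    day: int
    response: str
    intercept: float
    block_effects: dict  # label -> alpha (reference label -> 0.0)
    genotype_effects: dict  # label -> gamma (reference label -> 0.0)
    block_se: dict
    genotype_se: dict
    resid_var: float
    df_resid: float
    benchmark_block: object
    benchmark_genotype: object
    _params: np.ndarray = None
    _cov: np.ndarray = None
    _columns: list = None

    def fitted_and_residuals(self, table: pd.DataFrame):
        """Reproduce fitted values + residuals for the original rows."""
        sub = _day_slice(table, self.day, self.response)
        X, _, _ = _design(sub, self.benchmark_block, self.benchmark_genotype)
        fitted = X @ self._params
        return fitted, sub["value"].to_numpy() - fitted


def _day_slice(table: pd.DataFrame, day: int, response: str) -> pd.DataFrame:
    sub = table[(table["day"] == day) & (table["response"] == response)]
    if sub.empty:
        raise InvalidArgumentError(
            f"no rows for day={day}, response={response!r}"
        )
    return sub.sort_index()


def _design(sub: pd.DataFrame, benchmark_block, benchmark_genotype):
    """Reference-coded design matrix with deterministic column order."""
    blocks = sorted(sub["block"].unique(), key=str)
    genos = sorted(sub["genotype"].unique(), key=str)
    if benchmark_block is None:
        benchmark_block = blocks[0]
    if benchmark_genotype is None:
        benchmark_genotype = genos[0]
    if benchmark_block not in blocks:
        raise InvalidArgumentError(f"benchmark block {benchmark_block!r} absent")
    if benchmark_genotype not in genos:
        raise InvalidArgumentError(
            f"benchmark genotype {benchmark_genotype!r} absent"
        )
    cols = [("intercept", None)]
    cols += [("block", b) for b in blocks if b != benchmark_block]
    cols += [("genotype", g) for g in genos if g != benchmark_genotype]
    n = len(sub)
    X = np.zeros((n, len(cols)))
    X[:, 0] = 1.0
    block_vals = sub["block"].to_numpy()
    geno_vals = sub["genotype"].to_numpy()
    for j, (kind, label) in enumerate(cols):
        if kind == "block":
            X[:, j] = block_vals == label
        elif kind == "genotype":
            X[:, j] = geno_vals == label
    return X, cols, (benchmark_block, benchmark_genotype)


def fit_day_model(
    table: pd.DataFrame,
    day: int,
    response: str,
    benchmark_block=None,
    benchmark_genotype=None,
) -> DayFit:
    """OLS block + genotype effects for one day under reference coding."""
    sub = _day_slice(table, day, response)
    if sub["block"].nunique() < 2 or sub["genotype"].nunique() < 2:
        raise InvalidArgumentError(
            "need >= 2 blocks and >= 2 genotypes represented on the day"
        )
    X, cols, (ref_block, ref_geno) = _design(sub, benchmark_block,
                                             benchmark_genotype)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the confounded columns: those whose removal restores full rank
        aliased = []
        for j in range(1, X.shape[1]):
            Xr = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(Xr) == rank:
                aliased.append(cols[j])
        raise AliasedEffectsError(
            f"design is rank deficient; confounded effects: {aliased}"
        )
    y = sub["value"].to_numpy(dtype=float)
    res = sm.OLS(y, X).fit()
    params = res.params
    bse = res.bse
    block_effects = {ref_block: 0.0}
    genotype_effects = {ref_geno: 0.0}
    block_se = {ref_block: 0.0}
    genotype_se = {ref_geno: 0.0}
    for j, (kind, label) in enumerate(cols):
        if kind == "block":
            block_effects[label] = float(params[j])
            block_se[label] = float(bse[j])
        elif kind == "genotype":
            genotype_effects[label] = float(params[j])
            genotype_se[label] = float(bse[j])
    return DayFit(
        day=day,
        response=response,
        intercept=float(params[0]),
        block_effects=block_effects,
        genotype_effects=genotype_effects,
        block_se=block_se,
        genotype_se=genotype_se,
        resid_var=float(res.mse_resid),
        df_resid=float(res.df_resid),
        benchmark_block=ref_block,
        benchmark_genotype=ref_geno,
        _params=np.asarray(res.params),
        _cov=np.asarray(res.cov_params()),
        _columns=cols,
    )


def _contrast(fit: DayFit, kind: str, a, b, level: float):
    cols = fit._columns
    c = np.zeros(len(cols))
    known = {lab for k, lab in cols if k == kind}
    ref = fit.benchmark_block if kind == "block" else fit.benchmark_genotype
    for lab, sign in ((a, 1.0), (b, -1.0)):
        if lab == ref:
            continue
        if (kind, lab) not in cols:
            raise InvalidArgumentError(f"unknown {kind} {lab!r}")
        c[cols.index((kind, lab))] += sign
    est = float(c @ fit._params)
    se = float(np.sqrt(c @ fit._cov @ c))
    tcrit = stats.t.ppf(0.5 + level / 2, fit.df_resid)
    return est, se, (est - tcrit * se, est + tcrit * se)


def block_contrast(fit: DayFit, block_a, block_b, level: float = 0.95):
    """alpha_a - alpha_b with a t-based confidence interval.

    Returns ``(estimate, se, (lo, hi))``.
    """
    for lab in (block_a, block_b):
        if lab not in fit.block_effects:
            raise InvalidArgumentError(f"unknown block {lab!r}")
    return _contrast(fit, "block", block_a, block_b, level)


def genotype_contrast(fit: DayFit, geno_a, geno_b, level: float = 0.95):
    """gamma_a - gamma_b with a t-based confidence interval."""
    for lab in (geno_a, geno_b):
        if lab not in fit.genotype_effects:
            raise InvalidArgumentError(f"unknown genotype {lab!r}")
    return _contrast(fit, "genotype", geno_a, geno_b, level)


def genotype_series(
    table: pd.DataFrame,
    response: str,
    benchmark=None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-day adjusted genotype effects relative to the benchmark genotype.

    Returns a tidy frame (day, genotype, effect, se, ci_low, ci_high)
    suitable for effect-trajectory plots; rank-deficient days are skipped
    with a warning.
    """
    if table[table["response"] == response]["genotype"].nunique() < 2:
        raise InvalidArgumentError("need >= 2 genotypes for a contrast")
    rows = []
    days = sorted(table.loc[table["response"] == response, "day"].unique())
    for day in days:
        try:
            fit = fit_day_model(table, day, response,
                                benchmark_genotype=benchmark)
        except (AliasedEffectsError, InvalidArgumentError) as exc:
            warnings.warn(f"day {day} skipped: {exc}", stacklevel=2)
            continue
        tcrit = stats.t.ppf(0.5 + level / 2, fit.df_resid)
        for geno, eff in sorted(fit.genotype_effects.items(), key=lambda t: str(t[0])):
            se = fit.genotype_se[geno]
            rows.append(
                {
                    "day": day,
                    "genotype": geno,
                    "effect": eff,
                    "se": se,
                    "ci_low": eff - tcrit * se,
                    "ci_high": eff + tcrit * se,
                }
            )
    return pd.DataFrame(rows, columns=["day", "genotype", "effect", "se",
                                       "ci_low", "ci_high"])


# ---------------------------------------------------------------------------
# Synthetic phenotype tables (for validation and power checks)
# ---------------------------------------------------------------------------


def simulate_phenotype_table(
    rng: np.random.Generator,
    n_blocks: int = 4,
    n_genotypes: int = 8,
    plants_per_cell: int = 2,
    days: tuple[int, ...] = (1,),
    response: str = "pad",
    block_effects: np.ndarray | None = None,
    genotype_effects: np.ndarray | None = None,
    intercept: float = 1.0,
    sigma: float = 0.1,
) -> tuple[pd.DataFrame, dict]:
    """Long-format table drawn from the per-day fixed-effects model.

    Every (block, genotype) cell holds ``plants_per_cell`` plants. Effects
    default to evenly spread values with the first level fixed at 0
    (reference coding truth). Returns ``(table, truth)`` with truth holding
    the exact ``intercept``, ``alpha`` and ``gamma`` used.
    """
    if block_effects is None:
        block_effects = np.linspace(0.0, 0.5, n_blocks)
    if genotype_effects is None:
        genotype_effects = np.linspace(0.0, 1.0, n_genotypes)
    block_effects = np.asarray(block_effects, dtype=float)
    genotype_effects = np.asarray(genotype_effects, dtype=float)
    rows = []
    pid = 0
    for i in range(n_blocks):
        for j in range(n_genotypes):
            for _ in range(plants_per_cell):
                pid += 1
                for day in days:
                    noise = rng.normal(0.0, sigma) if sigma > 0 else 0.0
                    rows.append(
                        {
                            "plant_id": f"plant_{pid:04d}",
                            "block": f"B{i + 1:02d}",
                            "genotype": f"G{j + 1:02d}",
                            "day": day,
                            "response": response,
                            "value": intercept + block_effects[i]
                            + genotype_effects[j] + noise,
                        }
                    )
    truth = {
        "intercept": intercept,
        "alpha": {f"B{i + 1:02d}": float(block_effects[i]) for i in range(n_blocks)},
        "gamma": {f"G{j + 1:02d}": float(genotype_effects[j])
                  for j in range(n_genotypes)},
    }
    return pd.DataFrame(rows, columns=TABLE_COLUMNS), truth
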