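"""Scenario grids, replicate orchestration and the factorial screen.

The study design crosses selection strength sigma_s {0.15, 0.45, 1},
mating tolerance sigma_a {0.05, 0.1}, loci per trait L {4, 8} and
selective-vs-neutral middle habitat — 24 cells per mating scheme, 48
with the cost dimension — with (by default) 20 replicates per cell.
The relative contribution of each factor to a response is screened with
a fixed-effects factorial ANOVA: per-term partial eta-squared
SS_effect / (SS_effect + SS_error), normalised to percentages of the
summed etas so different responses are comparable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .lifecycle import SimParams, run_replicate

__all__ = [
    "ScenarioGrid",
    "run_grid",
    "eta_squared_anova",
    "aggregate_report",
    "DESK_SCALE_PRESET",
    "FULL_SCALE_PRESET",
]

#: Reduced-scale preset for desk experiments: carrying capacities and
#: duration both compressed tenfold (scale 0.1, T = 2,000).  The trait
#: mutation rate is raised by 1/(scale * T_desk/T_full) = 100x so the
#: compressed run receives the same total adaptive mutational input as
#: the full 20,000-generation experiment (total drift T/N is preserved
#: automatically); the microsatellite rate is raised by 1/scale only,
#: preserving the standing neutral diversity theta ~ 4 N mu0 that F_ST
#: is computed from.  See docs/methods.md for the rescaling model.
DESK_SCALE_PRESET = dict(scale=0.1, T=2_000, thin=50, mu=1e-3, mu0=1e-2)

#: The full-scale study configuration.
FULL_SCALE_PRESET = dict(scale=1.0, T=20_000, thin=100)

FACTORS = ("sigma_s", "sigma_a", "L", "middle_selective")


def middle_habitat_comparison(landscape_kind: str, base_seed: int,
                              replicates: int = 20) -> pd.DataFrame:
    """The asymmetry experiment: desk-scale replicates of one landscape.

    Runs ``replicates`` independent replicates (seeds base_seed,
    base_seed+1, ...) of the L = 4, sigma_s = 0.45, neutral-middle,
    no-cost scenario under the requested landscape at the desk-scale
    preset, and returns one summary row per replicate.  Averaging the
    ``x_middle`` column contrasts the Galician layout (middle habitat
    dragged toward the exposed-shore optimum by the denser lower shore)
    against the symmetric control (middle near 0.5).
    """
    rows = []
    for j in range(replicates):
        params = SimParams(sigma_s=0.45, sigma_a=0.1, L=4,
                           middle_selective=False, cost=False,
                           landscape_kind=landscape_kind,
                           seed=base_seed + j, **DESK_SCALE_PRESET)
        res = run_replicate(params)
        row = res.summary.to_dict()
        row["seed"] = params.seed
        # stationary tail average (last 500 generations of snapshots):
        # a lower-variance estimator of the equilibrium habitat mean than
        # the single final-generation value
        tail = res.series[res.series["generation"]
                          >= res.series["generation"].max() - 500]
        row["x_middle_tail"] = float(tail["x_middle"].mean(skipna=True))
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ScenarioGrid:
    """Orthogonal factor grid; the default no-cost grid has 24 cells."""

    sigma_s: Sequence[float] = (0.15, 0.45, 1.0)
    sigma_a: Sequence[float] = (0.05, 0.1)
    L: Sequence[int] = (4, 8)
    middle_selective: Sequence[bool] = (False, True)
    cost: Sequence[bool] = (False,)
    replicates: int = 20

    def cells(self) -> list[dict]:
        out = []
        for ss, sa, ell, mid, co in itertools.product(
                self.sigma_s, self.sigma_a, self.L, self.middle_selective, self.cost):
            out.append(dict(sigma_s=ss, sigma_a=sa, L=ell,
                            middle_selective=mid, cost=co))
        return out

    @property
    def n_cells(self) -> int:
        return len(self.cells())


def _run_one(params: SimParams, cell: dict, rep: int) -> dict:
    res = run_replicate(params)
    row = dict(cell)
    row["replicate"] = rep
    row["seed"] = params.seed
    row.update(res.summary.to_dict())
    return row


def run_grid(grid: ScenarioGrid, base_params: Optional[SimParams] = None,
             n_jobs: int = 1, base_seed: Optional[int] = None,
             out_csv=None) -> pd.DataFrame:
    """Run every (cell, replicate) of the grid and return one row each.

    Seeds are deterministic: replicate j of cell i runs with
    base_seed + i * replicates + j, so grids are reproducible and
    embarrassingly parallel (``n_jobs`` hands cells to joblib workers).
    If ``out_csv`` is given the table is also persisted incrementally.
    """
    if base_params is None:
        base_params = SimParams()
    if base_seed is None:
        base_seed = base_params.seed
    tasks = []
    for i, cell in enumerate(grid.cells()):
        for j in range(grid.replicates):
            seed = base_seed + i * grid.replicates + j
            tasks.append((replace(base_params, seed=seed, **cell), cell, j))
    if n_jobs == 1:
        rows = []
        for task in tasks:
            rows.append(_run_one(*task))
            if out_csv is not None:
                pd.DataFrame(rows).to_csv(out_csv, index=False)
    else:
        from joblib import Parallel, delayed
        rows = Parallel(n_jobs=n_jobs)(delayed(_run_one)(*t) for t in tasks)
        if out_csv is not None:
            pd.DataFrame(rows).to_csv(out_csv, index=False)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# eta-squared factorial ANOVA


def eta_squared_anova(records: pd.DataFrame, response: str,
                      factors: Sequence[str] = FACTORS,
                      alpha: float = 0.001) -> pd.DataFrame:
    """Factorial fixed-effects screen of one response column.

    Fits an OLS model with all main effects and all two-way interactions
    of the (categorical) factors, computes each term's partial
    eta-squared SS_term / (SS_term + SS_error), expresses it as % of the
    sum of all terms' etas, and flags significance at ``alpha`` (0.001).
    Requires a balanced (orthogonal) table, which the grid runner
    produces by construction.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if response not in records.columns:
        raise ValueError(f"response column {response!r} not in records")
    df = records.dropna(subset=[response]).copy()
    counts = df.groupby(list(factors), observed=True).size()
    if counts.nunique() != 1:
        raise ValueError(
            "unbalanced design: replicate counts per cell differ "
            f"({counts.min()}..{counts.max()}); the factorial screen "
            "requires the orthogonal grid")
    df["_resp"] = df[response].astype(float)
    mains = [f"C({f})" for f in factors]
    formula = "_resp ~ (" + " + ".join(mains) + ") ** 2"
    fit = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    ss_err = float(table.loc["Residual", "sum_sq"])
    terms = table.drop(index="Residual")
    eta = terms["sum_sq"] / (terms["sum_sq"] + ss_err)
    pct = 100.0 * eta / eta.sum()
    out = pd.DataFrame({
        "term": [t.replace("C(", "").replace(")", "") for t in terms.index],
        "sum_sq": terms["sum_sq"].to_numpy(),
        "partial_eta_sq": eta.to_numpy(),
        "pct_eta": pct.to_numpy(),
        "p_value": terms["PR(>F)"].to_numpy(),
    })
    out["significant"] = out["p_value"] < alpha
    return out.reset_index(drop=True)


def top_interactions(anova_table: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """The k interaction terms with the largest eta-squared share."""
    inter = anova_table[anova_table["term"].str.contains(":")]
    return inter.nlargest(k, "pct_eta").reset_index(drop=True)


# ----------------------------------------------------------------------
# headline aggregates


def aggregate_report(records: pd.DataFrame) -> dict:
    """Headline aggregates of a completed grid table.

    Percent of replicates adapted (lower-shore mean x < 0.25) overall
    and by middle-habitat scenario; percent reaching ecological
    speciation (middle c >= 0.9 and Q_ST >= 0.9); mean positive-regime
    choosiness |C| per shore by (cost, middle scenario), with
    negative-choice replicates excluded; mean mating correlation per
    shore; mean Q_ST by middle scenario.
    """
    rec = records
    n = len(rec)
    report: dict = {"n_runs": n}
    report["pct_adapted"] = 100.0 * rec["adapted"].mean()
    report["pct_speciation"] = 100.0 * rec["speciation"].mean()
    report["pct_extinct"] = 100.0 * rec["extinct"].mean()
    by_mid = rec.groupby("middle_selective")["adapted"].mean() * 100.0
    report["pct_adapted_by_middle"] = {
        ("selective" if k else "neutral"): float(v) for k, v in by_mid.items()}
    for s in ("lower", "middle", "upper"):
        col = rec[f"r_{s}"]
        report[f"mean_r_{s}"] = float(col.mean(skipna=True))
    choosiness = {}
    for (cost, mid), sub in rec.groupby(["cost", "middle_selective"]):
        key = f"{'cost' if cost else 'no_cost'}/{'selective' if mid else 'neutral'}_middle"
        vals = {}
        for s in ("lower", "middle", "upper"):
            keep = sub[sub[f"choice_{s}"] != "negative"]
            vals[s] = float(keep[f"choosiness_{s}"].mean(skipna=True)) if len(keep) else float("nan")
        choosiness[key] = vals
    report["mean_positive_choosiness"] = choosiness
    qst_by_mid = rec.groupby("middle_selective")["qst"].mean()
    report["mean_qst_by_middle"] = {
        ("selective" if k else "neutral"): float(v) for k, v in qst_by_mid.items()}
    report["mean_fst"] = float(rec["fst"].mean(skipna=True))
    return report
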