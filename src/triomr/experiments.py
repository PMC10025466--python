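"""Monte-Carlo study of type-I error and bias for the three MR estimators.

Each scenario is replicated many times; on every replicate dataset all three
estimators are fit (a paired design, so method contrasts are not confounded
by simulation noise).  Null runs (generative X→Y effect of 0) summarise the
rejection rate at the 0.05 level; effect runs (generative effect 1.0 by
default) summarise the bias, mean(β̂) − β.  Monte-Carlo standard errors
accompany every summary.

Seed discipline: replicate r of a sweep point uses seed ``base_seed + r``,
and successive sweep points are offset by 10^6 so their replicate streams
never overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import estimators
from .estimators import EstimationError, METHODS, fit_all
from .simulate import simulate_scenario, SCENARIOS

__all__ = [
    "ScenarioSpec",
    "MethodSummary",
    "ScenarioResult",
    "run_scenario",
    "sweep_assortative",
    "sweep_stratification",
    "results_to_frame",
    "write_results",
    "read_results",
    "plot_results",
    "DegenerateScenarioError",
    "ALPHA",
    "SWEEP_SEED_STRIDE",
]

ALPHA = 0.05
SWEEP_SEED_STRIDE = 10**6
MAX_DEGENERATE_FRACTION = 0.10

RESULT_COLUMNS = ["scenario", "sweep_value", "method", "metric",
                  "estimate", "mc_se", "n_reps_effective"]


class DegenerateScenarioError(RuntimeError):
    """More than 10% of replicates failed to fit: misconfigured scenario."""


@dataclass(frozen=True)
class ScenarioSpec:
    """One Monte-Carlo cell: a scenario, a sweep coordinate, and a mode.

    ``sweep_value`` is the assortative proportion for ``sim1-assortative`` and
    the subpopulation-2 allele frequency for ``sim2-stratified``.  A zero
    ``beta_xy`` selects the type-I-error mode; a positive value selects the
    bias mode.
    """

    scenario: str
    sweep_value: float
    beta_xy: float = 0.0
    n_reps: int = 1000
    base_seed: int = 0
    n_trios: int | None = None
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.n_reps < 1:
            raise ValueError("n_reps must be at least 1")
        if self.beta_xy < 0:
            raise ValueError("beta_xy must be non-negative")

    @property
    def metric(self) -> str:
        return "type1_error" if self.beta_xy == 0 else "bias"


@dataclass
class MethodSummary:
    """Per-method aggregate over effective replicates."""

    estimate: float
    mc_se: float
    n_reps_effective: int
    mean_beta_hat: float
    n_degenerate: int = 0


@dataclass
class ScenarioResult:
    """Aggregates for one scenario cell, keyed by estimator name."""

    scenario: str
    sweep_value: float
    metric: str
    methods: dict[str, MethodSummary]
    beta_xy: float
    n_reps: int
    base_seed: int

    def to_rows(self) -> list[dict]:
        return [{
            "scenario": self.scenario,
            "sweep_value": self.sweep_value,
            "method": m,
            "metric": self.metric,
            "estimate": s.estimate,
            "mc_se": s.mc_se,
            "n_reps_effective": s.n_reps_effective,
        } for m, s in self.methods.items()]


def _simulate_replicate(spec: ScenarioSpec, seed: int):
    kw = dict(spec.overrides)
    if spec.scenario == "sim1-assortative":
        return simulate_scenario(spec.scenario, seed=seed, beta_xy=spec.beta_xy,
                                 p_assort=spec.sweep_value,
                                 n_trios=spec.n_trios, **kw)
    return simulate_scenario(spec.scenario, seed=seed, beta_xy=spec.beta_xy,
                             freq2=spec.sweep_value,
                             n_trios=spec.n_trios, **kw)


def run_scenario(spec: ScenarioSpec,
                 keep_replicates: bool = False) -> ScenarioResult | tuple:
    """Run one Monte-Carlo cell: simulate, fit all three estimators, aggregate.

    Replicate r uses seed ``base_seed + r``.  Replicates on which an estimator
    raises a degeneracy error are excluded for that estimator and counted —
    never redrawn or imputed.  If more than 10% of replicates are degenerate
    for any estimator the run aborts with :class:`DegenerateScenarioError`.

    With ``keep_replicates=True`` also returns the per-replicate table of
    estimates and p-values (columns ``<method>_beta`` / ``<method>_p``).
    """
    betas = {m: np.full(spec.n_reps, np.nan) for m in METHODS}
    pvals = {m: np.full(spec.n_reps, np.nan) for m in METHODS}
    for r in range(spec.n_reps):
        data = _simulate_replicate(spec, spec.base_seed + r)
        for m in METHODS:
            try:
                fit = estimators._FITTERS[m](data)
            except EstimationError:
                continue
            betas[m][r] = fit.beta_xy_hat
            pvals[m][r] = fit.p_value

    methods: dict[str, MethodSummary] = {}
    for m in METHODS:
        ok = ~np.isnan(betas[m])
        n_eff = int(ok.sum())
        n_bad = spec.n_reps - n_eff
        if n_bad > MAX_DEGENERATE_FRACTION * spec.n_reps:
            raise DegenerateScenarioError(
                f"{n_bad}/{spec.n_reps} replicates degenerate for estimator "
                f"{m!r} in scenario {spec.scenario} at sweep value "
                f"{spec.sweep_value}")
        b = betas[m][ok]
        mean_b = float(b.mean()) if n_eff else np.nan
        if spec.metric == "type1_error":
            rej = float((pvals[m][ok] < ALPHA).mean()) if n_eff else np.nan
            mc_se = float(np.sqrt(rej * (1 - rej) / n_eff)) if n_eff else np.nan
            est = rej
        else:
            est = mean_b - spec.beta_xy
            mc_se = (float(b.std(ddof=1) / np.sqrt(n_eff)) if n_eff > 1 else 0.0)
        methods[m] = MethodSummary(estimate=est, mc_se=mc_se,
                                   n_reps_effective=n_eff,
                                   mean_beta_hat=mean_b, n_degenerate=n_bad)

    result = ScenarioResult(scenario=spec.scenario, sweep_value=spec.sweep_value,
                            metric=spec.metric, methods=methods,
                            beta_xy=spec.beta_xy, n_reps=spec.n_reps,
                            base_seed=spec.base_seed)
    if keep_replicates:
        rep = pd.DataFrame(
            {f"{m}_beta": betas[m] for m in METHODS}
            | {f"{m}_p": pvals[m] for m in METHODS})
        return result, rep
    return result


def _sweep(scenario: str, grid, beta_xy, n_reps, base_seed,
           n_trios=None, overrides=None) -> list[ScenarioResult]:
    results = []
    for i, v in enumerate(grid):
        spec = ScenarioSpec(scenario=scenario, sweep_value=float(v),
                            beta_xy=beta_xy, n_reps=n_reps,
                            base_seed=base_seed + i * SWEEP_SEED_STRIDE,
                            n_trios=n_trios, overrides=overrides or {})
        results.append(run_scenario(spec))
    return results


def sweep_assortative(p_grid, beta_xy: float = 0.0, n_reps: int = 1000,
                      base_seed: int = 0, n_trios: int | None = None,
                      overrides: dict | None = None) -> list[ScenarioResult]:
    """Sweep the assortative-mating proportion (grid values in [0, 1])."""
    for p in p_grid:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"assortative proportion {p} outside [0, 1]")
    return _sweep("sim1-assortative", p_grid, beta_xy, n_reps, base_seed,
                  n_trios, overrides)


def sweep_stratification(freq2_grid, beta_xy: float = 0.0, n_reps: int = 1000,
                         base_seed: int = 0, n_trios: int | None = None,
                         overrides: dict | None = None) -> list[ScenarioResult]:
    """Sweep the subpopulation-2 allele frequency (applied to both loci)."""
    for q in freq2_grid:
        if not 0.0 < q < 1.0:
            raise ValueError(f"allele frequency {q} outside (0, 1)")
    return _sweep("sim2-stratified", freq2_grid, beta_xy, n_reps, base_seed,
                  n_trios, overrides)


def results_to_frame(results) -> pd.DataFrame:
    rows = [row for res in results for row in res.to_rows()]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(results, path) -> None:
    """Write the canonical results table (one row per scenario×sweep×method)."""
    results_to_frame(results).to_csv(path, index=False, lineterminator="\n")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path)


def plot_results(results, path) -> None:
    """Summary figure: metric vs sweep coordinate, one line per estimator.

    Type-I-error panels carry a dotted reference line at the 0.05 level, bias
    panels at 0.  The output format follows the path extension (png/svg/pdf).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = results_to_frame(results)
    panels = list(frame.groupby(["scenario", "metric"], sort=True))
    fig, axes = plt.subplots(1, max(len(panels), 1),
                             figsize=(5 * max(len(panels), 1), 4), squeeze=False)
    markers = {"conventional": "s", "parental_genotype": "^", "mating_type": "o"}
    for ax, ((scenario, metric), sub) in zip(axes[0], panels):
        for m in METHODS:
            sm = sub[sub["method"] == m].sort_values("sweep_value")
            ax.errorbar(sm["sweep_value"], sm["estimate"], yerr=sm["mc_se"],
                        marker=markers[m], mfc="none", label=m)
        ref = ALPHA if metric == "type1_error" else 0.0
        ax.axhline(ref, color="gray", linestyle=":")
        xlabel = ("assortative proportion p" if scenario == "sim1-assortative"
                  else "subpopulation-2 allele frequency")
        ax.set_xlabel(xlabel)
        ax.set_ylabel("type I error rate" if metric == "type1_error" else "bias")
        ax.set_title(scenario)
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
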