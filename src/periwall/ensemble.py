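"""Two-stage Monte-Carlo workflow over the wall-model parameter space.

Stage 1 draws parameter sets from the initial (healthy) distributions, solves
the flow model for each, and records the mass-balance deviation Λ together
with the outer adventitial pressure ``p_ap``.  Because ``p_ap`` falls almost
linearly with Λ, the preimage of the physiologic pressure interval under the
fitted line defines the physiologic Λ interval.

Stage 2 re-samples parameter sets from the stage-1 pool whose Λ fell in that
interval (preserving the joint distribution the condition induces), draws Λ
uniformly on the refined interval, sets the per-vessel lymphatic drainage
rate by inverting the Λ formula, optionally applies the atherosclerotic
factors, and solves flow, tracer and the configured solute-transport cases.
Failures are recorded and counted, never silently dropped.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fluid import (
    FlowSolution,
    FlowSolverError,
    SolverOptions,
    luminal_fraction,
    solve_radial_flow,
)
from .metrics import MetricsRecord, flow_metrics, solute_metrics
from .parameters import (
    ATHEROSCLEROTIC,
    HEALTHY,
    ParameterRegistry,
    ParameterSet,
    apply_athero_factors,
    sample_parameter_sets,
)
from .refine import (
    DEFAULT_P_TEST,
    DEFAULT_PHYSIOLOGIC_INTERVAL,
    LambdaContext,
    mass_balance_deviation,
    refine_lambda_interval,
    with_imposed_lambda,
)
from .solute import SoluteParams, SoluteSolverError, solve_solute
from .units import pa_to_mmhg

logger = logging.getLogger(__name__)


class EnsembleError(RuntimeError):
    """Raised when an ensemble run is statistically unusable."""


@dataclass(frozen=True)
class EnsembleConfig:
    """Controls for ensemble runs.

    ``diffusivities`` (m²/s) and ``sources`` define the solute grid run per
    sample; the diffusive flux ratio ``R_d`` is drawn once per sample from a
    log-uniform range.  ``max_failure_fraction`` aborts a run whose solver
    failure rate suggests a broken parameterisation.
    """

    n_samples: int = 10_000
    seed: int = 0
    p_test: float = DEFAULT_P_TEST
    physiologic_interval: tuple[float, float] = DEFAULT_PHYSIOLOGIC_INTERVAL
    diffusivities: tuple[float, ...] = (100e-12, 10e-12, 1e-12)
    r_d_range: tuple[float, float] = (0.01, 10.0)
    sources: tuple[str, ...] = ("lumen", "eel")
    solver: SolverOptions = field(default_factory=SolverOptions)
    solute_solver: SolverOptions = field(
        default_factory=lambda: SolverOptions(rel_tol=1e-6, abs_tol=1e-8)
    )
    max_failure_fraction: float = 0.05
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if any(d <= 0 for d in self.diffusivities):
            raise ValueError("diffusivities must be positive")


@dataclass
class EnsembleResult:
    """Per-sample metrics table plus provenance.

    ``table`` has one row per attempted sample; failed solves carry a
    ``failure`` code and NaN metrics.  ``summary()`` recomputes aggregate
    statistics from the table.
    """

    table: pd.DataFrame
    condition: str
    seed: int
    n_failed: int
    provenance: dict = field(default_factory=dict)
    pool: list[ParameterSet] = field(default_factory=list)

    @property
    def ok(self) -> pd.DataFrame:
        return self.table[self.table["failure"].isna()]

    def summary(self, quantiles: tuple[float, ...] = (0.25, 0.5, 0.75)) -> pd.DataFrame:
        num = self.ok.select_dtypes(include=[np.number])
        rows = {"mean": num.mean(), "sd": num.std(ddof=1)}
        for q in quantiles:
            rows[f"q{q:g}"] = num.quantile(q)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def _sample_seeds(seed: int, n: int, stream: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(stream + 1)[stream].spawn(n)


# --------------------------------------------------------------------------
# stage 1
# --------------------------------------------------------------------------


def run_initial_ensemble(
    registry: ParameterRegistry, cfg: EnsembleConfig
) -> tuple[EnsembleResult, LambdaContext]:
    """Stage 1: solve the flow model over the initial healthy distributions.

    Returns the per-sample table (Λ, boundary pressures, failure codes) and
    the fitted :class:`LambdaContext` carrying the physiologic Λ interval and
    the quality of the p_ap–Λ regression.  The accepted parameter pool (Λ in
    the refined interval) is attached to the result for stage 2.
    """
    sets = sample_parameter_sets(registry, cfg.n_samples, cfg.seed)
    rows = []
    lambdas, paps, accepted_candidates = [], [], []
    n_failed = 0
    for ps in sets:
        row: dict = {"sample_id": ps.sample_id, "failure": None}
        try:
            lam = mass_balance_deviation(ps, cfg.p_test)
            flow = solve_radial_flow(ps, cfg.solver)
            g = ps.geometry
            row.update(
                lam=lam,
                p_ia_mmhg=pa_to_mmhg(float(flow.p_at(g.r_ia))),
                p_ap_mmhg=pa_to_mmhg(float(flow.p_at(g.r_ap))),
                u_mid_um_s=float(flow.u_at(g.r_lu + g.t_i / 2)) * 1e6,
                residual=flow.residual,
            )
            lambdas.append(lam)
            paps.append(float(flow.p_at(g.r_ap)))
            accepted_candidates.append((ps, lam))
        except (FlowSolverError, ValueError) as exc:
            n_failed += 1
            row["failure"] = type(exc).__name__
            logger.warning("stage-1 sample %d failed: %s", ps.sample_id, exc)
        rows.append(row)

    if n_failed > cfg.max_failure_fraction * cfg.n_samples:
        raise EnsembleError(
            f"{n_failed}/{cfg.n_samples} stage-1 solves failed; "
            "parameterisation suspect"
        )

    ctx = refine_lambda_interval(
        lambdas, paps, cfg.physiologic_interval, p_test=cfg.p_test
    )
    lo, hi = ctx.lambda_interval
    pool = [ps for ps, lam in accepted_candidates if lo <= lam <= hi]
    if not pool:
        raise EnsembleError("no stage-1 sample falls in the refined Λ interval")

    result = EnsembleResult(
        table=pd.DataFrame(rows),
        condition=HEALTHY,
        seed=cfg.seed,
        n_failed=n_failed,
        provenance=_provenance(cfg, stage="initial"),
        pool=pool,
    )
    return result, ctx


# --------------------------------------------------------------------------
# stage 2
# --------------------------------------------------------------------------


def run_refined_ensemble(
    cfg: EnsembleConfig,
    ctx: LambdaContext,
    pool: list[ParameterSet],
    condition: str = HEALTHY,
    registry: ParameterRegistry | None = None,
    n_samples: int | None = None,
    with_solute: bool = True,
) -> EnsembleResult:
    """Stage 2: refined ensemble under a condition.

    Per sample: resample a parameter set from the accepted stage-1 ``pool``,
    draw Λ uniformly on the refined interval, impose it by setting q̃_ℓ
    through the inversion (on the healthy parameters), then — for the
    atherosclerotic condition — apply the multiplicative factors from
    ``registry`` and solve.  The tracer and the configured solute cases run on
    every successful flow solve.
    """
    if ctx.lambda_interval is None:
        raise ValueError("LambdaContext has no refined interval")
    if condition == ATHEROSCLEROTIC and registry is None:
        raise ValueError("atherosclerotic runs need the registry's athero factors")
    n = n_samples if n_samples is not None else cfg.n_samples
    lo, hi = ctx.lambda_interval
    seeds = _sample_seeds(cfg.seed, n, stream=1 if condition == HEALTHY else 2)

    rows = []
    n_failed = 0
    for i, child in enumerate(seeds):
        rng = np.random.default_rng(child)
        base = pool[int(rng.integers(len(pool)))]
        lam = float(rng.uniform(lo, hi))
        row: dict = {"sample_id": i, "lam": lam, "failure": None}
        try:
            ps = with_imposed_lambda(base, lam, ctx.p_test)
            if condition == ATHEROSCLEROTIC:
                ps = apply_athero_factors(ps, registry.athero, rng)
            flow = solve_radial_flow(ps, cfg.solver)
            luminal_fraction(flow)
            rec = flow_metrics(flow)
            row.update(_record_to_row(rec))
            row["sink_rate"] = ps.lymph.sink_rate
            row["t_a"] = ps.geometry.t_a
            row["t_p"] = ps.geometry.t_p
            row["u_reversal"] = flow.u_reversal
            if with_solute:
                r_d = float(
                    np.exp(
                        rng.uniform(
                            np.log(cfg.r_d_range[0]), np.log(cfg.r_d_range[1])
                        )
                    )
                )
                row["r_d_draw"] = r_d
                for D in cfg.diffusivities:
                    for source in cfg.sources:
                        sp = SoluteParams(D=D, R_d=r_d, source=source)
                        key = f"{source}_D{D * 1e12:g}"
                        try:
                            sol = solve_solute(ps, flow, sp, cfg.solute_solver)
                            rec_s = solute_metrics(MetricsRecord(), sol)
                            row[f"Pe_D{D * 1e12:g}"] = sol.numbers.Pe
                            row[f"Da_l_D{D * 1e12:g}"] = sol.numbers.Da_l
                            row[f"Da_v_D{D * 1e12:g}"] = sol.numbers.Da_v
                            if source == "lumen":
                                row[f"c_ia_{key}"] = rec_s.c_ia
                            else:
                                row[f"max_grad_{key}"] = rec_s.max_grad
                                row[f"dc_distance_{key}"] = rec_s.dc_distance
                                row[f"t_star_{key}"] = rec_s.t_star_dc_pvat
                                row[f"profile_{key}"] = rec_s.profile_class
                        except SoluteSolverError as exc:
                            row[f"failure_{key}"] = type(exc).__name__
                            logger.warning(
                                "sample %d solute case %s failed: %s", i, key, exc
                            )
        except (FlowSolverError, ValueError) as exc:
            n_failed += 1
            row["failure"] = type(exc).__name__
            logger.warning("stage-2 sample %d failed: %s", i, exc)
        rows.append(row)

    if n_failed > cfg.max_failure_fraction * n:
        raise EnsembleError(
            f"{n_failed}/{n} stage-2 solves failed; parameterisation suspect"
        )
    return EnsembleResult(
        table=pd.DataFrame(rows),
        condition=condition,
        seed=cfg.seed,
        n_failed=n_failed,
        provenance=_provenance(cfg, stage=f"refined-{condition}", ctx=ctx),
    )


def _record_to_row(rec: MetricsRecord) -> dict:
    return {
        "u_mid_um_s": rec.u_mid,
        "p_ia_mmhg": rec.p_ia,
        "p_ap_mmhg": rec.p_ap,
        "vasa_fraction": rec.vasa_fraction,
        "dilution_distance": rec.dilution_distance,
        "dilution_from_endothelium": rec.dilution_from_endothelium,
        "dilution_frac_adventitia": rec.dilution_frac_adventitia,
    }


# --------------------------------------------------------------------------
# summaries
# --------------------------------------------------------------------------


def summarize(
    res: EnsembleResult,
    fractions: dict[str, tuple[str, str, float]] | None = None,
) -> pd.DataFrame:
    """Aggregate an ensemble: mean ± sd per metric plus requested fractions.

    ``fractions`` maps an output name to ``(column, op, threshold)`` with op
    one of ``>``, ``>=``, ``<``, ``<=``, producing the fraction of successful
    samples satisfying the predicate (NaNs excluded).
    """
    if res.ok.empty:
        raise EnsembleError("no successful samples to summarise")
    out = res.summary()
    if fractions:
        for name, (col, op, thr) in fractions.items():
            out.loc[name, "mean"] = fraction_of(res, col, op, thr)
    return out


def fraction_of(res: EnsembleResult, col: str, op: str, thr: float) -> float:
    """Fraction of successful samples with ``col op thr`` (NaNs excluded)."""
    ops = {
        ">": np.greater,
        ">=": np.greater_equal,
        "<": np.less,
        "<=": np.less_equal,
    }
    vals = res.ok[col].to_numpy(dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return math.nan
    return float(np.mean(ops[op](vals, thr)))


def profile_class_proportions(res: EnsembleResult, D: float) -> dict[str, float]:
    """Convex/accumulative/neither proportions for the EEL source at one D."""
    col = f"profile_eel_D{D * 1e12:g}"
    if col not in res.table:
        return {}
    vals = res.ok[col].dropna()
    vals = vals[vals != ""]
    if vals.empty:
        return {}
    counts = vals.value_counts(normalize=True)
    return {k: float(counts.get(k, 0.0)) for k in ("convex", "accumulative", "neither")}


def _provenance(cfg: EnsembleConfig, stage: str, ctx: LambdaContext | None = None) -> dict:
    prov = {
        "stage": stage,
        "seed": cfg.seed,
        "n_samples": cfg.n_samples,
        "package_version": "0.1.0",
    }
    if ctx is not None and ctx.lambda_interval is not None:
        prov["lambda_interval"] = list(ctx.lambda_interval)
        prov["r_squared"] = ctx.r_squared
    return prov


def write_refinement_report(ctx: LambdaContext, path: str | Path) -> None:
    """JSON report of the fitted Λ interval and regression quality."""
    payload = {
        "p_test_mmhg": pa_to_mmhg(ctx.p_test),
        "physiologic_interval_mmhg": [
            pa_to_mmhg(ctx.physiologic_interval[0]),
            pa_to_mmhg(ctx.physiologic_interval[1]),
        ],
        "lambda_interval": list(ctx.lambda_interval) if ctx.lambda_interval else None,
        "slope_mmhg_per_lambda": pa_to_mmhg(ctx.slope) if ctx.slope else None,
        "intercept_mmhg": pa_to_mmhg(ctx.intercept) if ctx.intercept else None,
        "r_squared": ctx.r_squared,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
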