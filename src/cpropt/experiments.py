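"""Patient-group sweep, trajectory reporting, and synthetic patient cohorts.

The sweep runs the optimization schemes across a range of patient maximum
blood flows (default Q_max ∈ {700, 800, 900, 1000, 1100} mL/min, spanning
the patient groups the model targets) and tabulates the optimized delivery
versus Q_max together with the per-cycle series of the compression ratio,
ventilation time, compression speed and tidal volume.  The optimized total
delivery must increase strictly with Q_max within each scheme — higher
achievable flow always buys more delivery in this model — and the sweep
asserts it.

A separate, clearly non-blocking "trend report" records whether each
sequential trajectory shows the qualitative dynamics of interest (ratio
non-increasing after the first cycle, compression speed non-decreasing,
ventilation time constant within its narrow bounds).  These trends are
reported rather than asserted: a static objective gives the optimizers no
reason to produce them, so their absence is informative, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model_core import DomainError, ParameterBounds, PatientParams
from .schemes import (
    OptimizationOutcome,
    SchemeConfig,
    global_optimize,
    sequential_optimize,
)

__all__ = [
    "SweepConfig",
    "SweepResult",
    "generate_patient_cohort",
    "run_sweep",
    "trajectory_report",
    "trend_report",
    "plot_sweep",
]

DEFAULT_QMAX_GRID = (700.0, 800.0, 900.0, 1000.0, 1100.0)
# Representative patient groups for per-cycle trajectory figures:
# endpoints and midpoint of the swept range.
REPRESENTATIVE_QMAX = (700.0, 900.0, 1100.0)


@dataclass(frozen=True)
class SweepConfig:
    """Patient-group sweep configuration.

    ``q_max_values`` lists the patient groups (mL/min); ``schemes`` selects
    which protocols to run; ``seeds`` gives one replicate per entry.
    """

    q_max_values: tuple[float, ...] = DEFAULT_QMAX_GRID
    schemes: tuple[str, ...] = ("global", "sequential")
    scheme_config: SchemeConfig = field(default_factory=SchemeConfig)
    bounds: ParameterBounds = field(default_factory=ParameterBounds)
    seeds: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        if not self.q_max_values:
            raise DomainError("q_max_values must be nonempty")
        if any(q <= 0 for q in self.q_max_values):
            raise DomainError("every Q_max must be > 0")
        if not self.schemes:
            raise DomainError("at least one scheme required")
        for s in self.schemes:
            if s not in ("global", "sequential"):
                raise DomainError(f"unknown scheme {s!r}")
        if not self.seeds:
            raise DomainError("at least one seed required")

    @classmethod
    def from_range(cls, low: float, high: float, step: float, **kw) -> "SweepConfig":
        if low > high or step <= 0:
            raise DomainError("invalid Q_max range")
        values = tuple(np.arange(low, high + 0.5 * step, step, dtype=float))
        return cls(q_max_values=values, **kw)


@dataclass
class SweepResult:
    """Outcomes keyed by (Q_max, scheme, seed), plus tabular summaries."""

    outcomes: dict[tuple[float, str, int], OptimizationOutcome]
    summary: pd.DataFrame
    config: SweepConfig


def generate_patient_cohort(
    n: int, q_range: tuple[float, float] = (700.0, 1100.0), seed: int = 0
) -> list[PatientParams]:
    """Sample ``n`` synthetic patients with Q_max uniform on ``q_range``.

    Deterministic under ``seed``.
    """
    low, high = q_range
    if n < 1:
        raise DomainError("cohort size must be >= 1")
    if low > high or low <= 0:
        raise DomainError(f"invalid Q_max range ({low}, {high})")
    rng = np.random.default_rng(seed)
    return [PatientParams(Q_max=float(q)) for q in rng.uniform(low, high, size=n)]


def _run_one(scheme: str, patient, bounds, cfg: SchemeConfig) -> OptimizationOutcome:
    if scheme == "global":
        return global_optimize(patient, bounds, replace(cfg, scheme="global"))
    return sequential_optimize(patient, bounds, replace(cfg, scheme="sequential"))


def run_sweep(config: SweepConfig = SweepConfig()) -> SweepResult:
    """Run every scheme at every (Q_max, seed); tabulate final optima.

    The summary table is sorted by Q_max and carries one row per
    (scheme, Q_max, seed).  Within each scheme (per seed) the final total
    delivery is checked to be strictly increasing in Q_max.
    """
    outcomes: dict[tuple[float, str, int], OptimizationOutcome] = {}
    rows = []
    for seed in config.seeds:
        for scheme in config.schemes:
            base = replace(
                config.scheme_config,
                annealing=replace(config.scheme_config.annealing, seed=seed),
            )
            for q in config.q_max_values:
                patient = PatientParams(Q_max=float(q))
                try:
                    outcome = _run_one(scheme, patient, config.bounds, base)
                except Exception as exc:
                    raise type(exc)(
                        f"{exc} [Q_max={q}, scheme={scheme}, seed={seed}]"
                    ) from exc
                outcomes[(float(q), scheme, seed)] = outcome
                fin = outcome.final
                rows.append(
                    {
                        "scheme": scheme,
                        "q_max": float(q),
                        "seed": seed,
                        "cycles_run": outcome.cycles_run,
                        "converged": outcome.converged,
                        "final_x": fin.rescuer.x,
                        "final_T": fin.rescuer.T,
                        "final_t": fin.rescuer.t,
                        "final_vt": fin.rescuer.v_t,
                        "final_fio2": fin.rescuer.f_I_O2,
                        "final_fico2": fin.rescuer.f_I_CO2,
                        "final_D_O2": fin.snapshot.D_O2,
                        "final_D_CO2": fin.snapshot.D_CO2,
                        "final_D_total": fin.snapshot.D_total,
                    }
                )
    summary = pd.DataFrame(rows).sort_values(
        ["scheme", "seed", "q_max"], kind="stable"
    ).reset_index(drop=True)

    for (scheme, seed), grp in summary.groupby(["scheme", "seed"]):
        d = grp.sort_values("q_max")["final_D_total"].to_numpy()
        if not np.all(np.diff(d) > 0):
            raise RuntimeError(
                f"optimized D_total not strictly increasing in Q_max for "
                f"scheme={scheme}, seed={seed}: {d}"
            )
    return SweepResult(outcomes=outcomes, summary=summary, config=config)


def trajectory_report(result: SweepResult) -> pd.DataFrame:
    """Per-cycle series of x, T, t, 1/t, v_t and the deliveries.

    One row per (Q_max, scheme, seed, cycle, phase).  Compression speed is
    reported as 1/t per minute.
    """
    rows = []
    for (q, scheme, seed), outcome in result.outcomes.items():
        for rec in outcome.trajectory:
            r = rec.rescuer
            rows.append(
                {
                    "scheme": scheme,
                    "q_max": q,
                    "seed": seed,
                    "cycle": rec.cycle_index,
                    "phase": rec.phase,
                    "x": r.x,
                    "T": r.T,
                    "t": r.t,
                    "compression_speed": 1.0 / r.t,
                    "v_t": r.v_t,
                    "f_I_O2": r.f_I_O2,
                    "f_I_CO2": r.f_I_CO2,
                    "Q_bar": rec.snapshot.Q_bar,
                    "D_O2": rec.snapshot.D_O2,
                    "D_CO2": rec.snapshot.D_CO2,
                    "D_total": rec.snapshot.D_total,
                }
            )
    if not rows:
        raise DomainError("empty sweep result")
    # stable sort without the phase column: within a cycle the emission
    # order (ratio_step before others_step) is the meaningful one
    return pd.DataFrame(rows).sort_values(
        ["scheme", "q_max", "seed", "cycle"], kind="stable"
    ).reset_index(drop=True)


def trend_report(result: SweepResult, rtol: float = 1e-9) -> pd.DataFrame:
    """Qualitative per-trajectory trend check — recorded, never asserted.

    For each sequential outcome, reports whether the per-cycle ratio series
    is non-increasing after the first cycle, the compression-speed series
    non-decreasing, and the ventilation time within its bounds.  A static
    delivery objective does not force the first two, so failures here are
    findings, not errors.
    """
    traj = trajectory_report(result)
    rows = []
    bounds = result.config.bounds
    for (q, scheme, seed), grp in traj.groupby(["q_max", "scheme", "seed"]):
        if scheme != "sequential":
            continue
        ratio = grp[grp["phase"] == "ratio_step"].sort_values("cycle")
        x = ratio["x"].to_numpy()
        speed = ratio["compression_speed"].to_numpy()
        t_series = grp["T"].to_numpy()
        slack = rtol * np.abs(x).max() if x.size else 0.0
        rows.append(
            {
                "q_max": q,
                "seed": seed,
                "ratio_non_increasing": bool(np.all(np.diff(x) <= slack)) if x.size > 1 else True,
                "speed_non_decreasing": bool(
                    np.all(np.diff(speed) >= -rtol * np.abs(speed).max())
                ) if speed.size > 1 else True,
                "ventilation_time_in_bounds": bool(
                    np.all((t_series >= bounds.T[0]) & (t_series <= bounds.T[1]))
                ),
            }
        )
    return pd.DataFrame(rows)


def plot_sweep(result: SweepResult, out_dir) -> list[str]:
    """Optional figures: D_total vs Q_max and per-cycle trajectories.

    Side-effect-only; returns the written file paths.  Imported lazily so
    headless use without a plotting stack never pays for it.
    """
    import pathlib

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    fig, ax = plt.subplots()
    for scheme, grp in result.summary.groupby("scheme"):
        g = grp.groupby("q_max")["final_D_total"].mean()
        ax.plot(g.index, g.values, marker="o", label=scheme)
    ax.set_xlabel("Q_max (mL/min)")
    ax.set_ylabel("optimized D_total (mL/min)")
    ax.legend()
    path = out / "delivery_vs_qmax.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(str(path))

    traj = trajectory_report(result)
    seq = traj[traj["scheme"] == "sequential"]
    if not seq.empty:
        for col, fname in [("x", "ratio_vs_cycle.png"),
                           ("T", "ventilation_time_vs_cycle.png"),
                           ("compression_speed", "compression_speed_vs_cycle.png")]:
            fig, ax = plt.subplots()
            for q, grp in seq[seq["phase"] == "ratio_step"].groupby("q_max"):
                g = grp.sort_values("cycle")
                ax.plot(g["cycle"], g[col], marker=".", label=f"Q_max={q:g}")
            ax.set_xlabel("CPR cycle")
            ax.set_ylabel(col)
            ax.legend()
            path = out / fname
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(str(path))
    return written
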