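"""In-silico inhibition experiments on patterned RD systems.

Two inhibition mechanisms mirror the pharmacology: *response* inhibition
(receptor-level block: every regulatory input from the target morphogen is
scaled by ``1 - alpha``) and *production* inhibition (ligand-synthesis
block: the target's whole clamped production term is scaled by
``1 - alpha``).  Perturbed runs restart from the established unperturbed
pattern, modelling acute inhibitor addition to a patterned explant; the
inhibition strength is calibrated by reducing ``alpha`` by a factor of
0.25 from complete inhibition until the pattern survives with its
whole-wave count intact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rd_core import RDParameterSet, InhibitionSpec
from .stability import rescale_for_domain
from . import simulate as sim

__all__ = [
    "PerturbationOutcome",
    "apply_response_inhibition",
    "apply_production_inhibition",
    "inhibited_model",
    "calibrate_alpha_max",
    "classify_wave_shift",
    "run_inhibition",
    "simulate_to_pattern",
    "perturbation_screen",
]

#: calibration ladder: alpha reduced by a factor of 0.25 from complete inhibition
ALPHA_LADDER = (1.0, 0.25, 0.0625, 0.015625)
#: peak/trough movements below this fraction of the amplitude are "not noticeable"
SHIFT_TOL = 0.05
WAVE_RANGE = (2.0, 4.5)


@dataclass
class PerturbationOutcome:
    spec: InhibitionSpec
    alpha_used: float  # None if no ladder level preserved the pattern
    mean_change: np.ndarray  # percent change of spatial mean, per component
    peak_shift: np.ndarray
    trough_shift: np.ndarray
    shift_class: list  # per component: "up" | "down" | "mixed" | "none"
    wave_count_preserved: bool


def apply_response_inhibition(params: RDParameterSet, target: int, alpha: float) -> RDParameterSet:
    """Scale every regulatory input from the target (column ``target`` of the
    weight matrix, self-weight included) by ``1 - alpha``."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if not 0 <= target < params.n:
        raise IndexError("bad component index")
    a = params.a.copy()
    a[:, target] *= 1.0 - alpha
    return params.with_(a=a)


def apply_production_inhibition(params: RDParameterSet, target: int, alpha: float):
    """Scale the target's whole production term by ``1 - alpha``; returns the
    (unchanged) parameter set together with the production-scale vector the
    integrator applies to the clamped production."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if not 0 <= target < params.n:
        raise IndexError("bad component index")
    scale = np.ones(params.n)
    scale[target] = 1.0 - alpha
    return params, scale


def inhibited_model(params: RDParameterSet, spec: InhibitionSpec):
    """(parameter set, production-scale) implementing the inhibition."""
    if spec.mode == "response":
        return apply_response_inhibition(params, spec.target, spec.alpha), None
    return apply_production_inhibition(params, spec.target, spec.alpha)


def simulate_to_pattern(
    params: RDParameterSet,
    seed=None,
    domain_length: float = sim.DEFAULT_GRID,
    target_wave_count: float = 3.25,
    target_growth_rate: float = 0.1,
    t_growth: float = 40.0,
):
    """Rescale for the simulation domain and integrate from noise until a
    stable pattern can be assessed.  Returns (rescaled params, field,
    verdict dict)."""
    scaled = rescale_for_domain(
        params, domain_length, target_wave_count, target_growth_rate
    )
    T = t_growth / target_growth_rate
    field = sim.integrate_rd(scaled, T=T, seed=seed, grid_size=int(domain_length))
    verdict = sim.detect_stable_pattern(field)
    return scaled, field, verdict


def _whole_waves(metrics) -> int:
    return int(math.floor(metrics.wave_count))


def classify_wave_shift(before, after, amplitude=None, tol: float = SHIFT_TOL) -> list:
    """Per-component bounded-shift class between two wave-metric sets.

    "up": the mean rose and the troughs rose beyond tolerance; "down": the
    mean fell and the peaks fell; "mixed"/"none" otherwise.  Tolerance is a
    fraction of the pre-perturbation amplitude.
    """
    if _whole_waves(before) != _whole_waves(after):
        raise ValueError("wave-count mismatch; shift comparison invalid")
    n = len(before.mean_level)
    out = []
    for i in range(n):
        amp = amplitude[i] if amplitude is not None else max(before.amplitude[i], 1e-12)
        d_mean = after.mean_level[i] - before.mean_level[i]
        d_trough = _level_change(before.trough_levels[i], after.trough_levels[i])
        d_peak = _level_change(before.peak_levels[i], after.peak_levels[i])
        up = d_mean > 0 and d_trough is not None and d_trough > tol * amp
        down = d_mean < 0 and d_peak is not None and d_peak < -tol * amp
        if up and not down:
            out.append("up")
        elif down and not up:
            out.append("down")
        elif abs(d_mean) <= tol * amp:
            out.append("none")
        else:
            out.append("mixed")
    return out


def _level_change(before_levels, after_levels):
    if len(before_levels) == 0 or len(after_levels) == 0:
        return None
    return float(np.mean(after_levels) - np.mean(before_levels))


def run_inhibition(
    params: RDParameterSet,
    spec: InhibitionSpec,
    baseline_field: sim.SimulationField,
    baseline_metrics,
    T: float,
) -> PerturbationOutcome:
    """Apply the inhibition to the established pattern at the given (or
    ladder-calibrated) strength and measure the outcome."""
    alphas = [spec.alpha] if spec.alpha is not None else list(ALPHA_LADDER)
    init = baseline_field.final
    for alpha in alphas:
        trial = InhibitionSpec(target=spec.target, mode=spec.mode, alpha=alpha)
        p2, scale = inhibited_model(params, trial)
        field = sim.integrate_rd(
            p2, T=T, init_state=init, grid_size=init.shape[0], production_scale=scale
        )
        verdict = sim.detect_stable_pattern(field)
        m = verdict["metrics"]
        if not (verdict["stable"] and verdict["patterned"]):
            continue
        if _whole_waves(m) != _whole_waves(baseline_metrics):
            continue
        base_mean = baseline_metrics.mean_level
        mean_change = 100.0 * (m.mean_level - base_mean) / base_mean
        peak_shift = np.array(
            [
                (_level_change(baseline_metrics.peak_levels[i], m.peak_levels[i]) or 0.0)
                for i in range(params.n)
            ]
        )
        trough_shift = np.array(
            [
                (_level_change(baseline_metrics.trough_levels[i], m.trough_levels[i]) or 0.0)
                for i in range(params.n)
            ]
        )
        shift = classify_wave_shift(baseline_metrics, m)
        return PerturbationOutcome(
            spec=trial,
            alpha_used=alpha,
            mean_change=mean_change,
            peak_shift=peak_shift,
            trough_shift=trough_shift,
            shift_class=shift,
            wave_count_preserved=True,
        )
    return PerturbationOutcome(
        spec=spec,
        alpha_used=None,
        mean_change=np.full(params.n, np.nan),
        peak_shift=np.full(params.n, np.nan),
        trough_shift=np.full(params.n, np.nan),
        shift_class=["none"] * params.n,
        wave_count_preserved=False,
    )


def calibrate_alpha_max(
    params: RDParameterSet,
    spec: InhibitionSpec,
    baseline_field: sim.SimulationField,
    baseline_metrics,
    T: float,
):
    """Strongest ladder inhibition preserving a stable pattern with the same
    whole-wave count; None when even alpha = 0.25 destroys it."""
    out = run_inhibition(
        params,
        InhibitionSpec(target=spec.target, mode=spec.mode, alpha=None),
        baseline_field,
        baseline_metrics,
        T,
    )
    return out.alpha_used


# ---------------------------------------------------------------------------
# batched screening


def sample_ddi_sets(
    topology,
    n_sets: int,
    seed,
    phase=None,
    max_attempts: int = 400_000,
    batch: int = 1024,
):
    """Random parameter sets conditioned on stationary non-oscillating DDI
    (optionally with a required phase signature), drawn in vectorised
    batches."""
    from .rd_core import sample_parameter_batch, materialize_parameter_set
    from .stability import classify_ddi_batch

    rng = np.random.default_rng(seed)
    want = None
    if phase is not None:
        want = np.sign(np.asarray(phase)).astype(int)
        if want[0] < 0:
            want = -want
    out = []
    attempts = 0
    n = topology.n
    while attempts < max_attempts and len(out) < n_sets:
        bt = sample_parameter_batch(topology, batch, rng.integers(2**31))
        attempts += batch
        J = bt["a"] - bt["c"][:, None, :] * np.eye(n)
        cls = classify_ddi_batch(J, bt["D"])
        ok = cls["ddi"] & ~cls["oscillatory"]
        if want is not None:
            ok &= np.all(cls["phase"] == want[None, :], axis=1)
        for i in np.where(ok)[0]:
            out.append(materialize_parameter_set(topology, bt, int(i)))
            if len(out) >= n_sets:
                break
    return out


def _batched_runs(param_list, T, init_states, production_scales=None, group=64, tol=1e-2):
    """Integrate many same-size systems, grouping by step-size so one slow
    diffusivity does not throttle the whole screen.  Returns final states."""
    n = param_list[0].n
    order = np.argsort([np.max(p.D) for p in param_list])
    finals = [None] * len(param_list)
    stables = [False] * len(param_list)
    for start in range(0, len(order), group):
        idx = order[start : start + group]
        a = np.stack([param_list[i].a for i in idx])
        b = np.stack([param_list[i].b for i in idx])
        c = np.stack([param_list[i].c for i in idx])
        fmax = np.stack([param_list[i].fmax for i in idx])
        D = np.stack([param_list[i].D for i in idx])
        init = np.stack([init_states[i] for i in idx])
        scale = (
            None
            if production_scales is None
            else np.stack([production_scales[i] for i in idx])
        )
        snaps, times = sim.integrate_batch(
            a, b, c, fmax, D, T, init, n_snapshots=24, production_scale=scale,
            early_stop_tol=tol / 5.0,
        )
        for pos, i in enumerate(idx):
            field = sim.SimulationField(
                state=snaps[:, pos], times=times, dx=1.0, dt=float("nan")
            )
            verdict = sim.detect_stable_pattern(field, tol=tol)
            finals[i] = (field, verdict)
            stables[i] = verdict["stable"]
    return finals


def perturbation_screen(
    topology,
    inhibitions,
    n_sets: int = 1000,
    seed=0,
    phase=None,
    domain_length: float = sim.DEFAULT_GRID,
    target_wave_count: float = 3.5,
    target_growth_rate: float = 0.1,
    t_growth: float = 30.0,
    oversample: float = 2.5,
    max_steps: int = 60_000,
    raw_sets: int = None,
) -> dict:
    """Screen random DDI parameterisations of a topology under a list of
    inhibitions (InhibitionSpec with alpha None -> ladder calibration).

    Sets whose rescaled dynamics would not fit the integration budget
    (marginal growth rates relative to their diffusive stiffness) are
    excluded, mirroring the workflow requirement that scaled sets fit the
    simulation space and time.  Returns per-set outcomes and a long-format
    summary table with the fraction of valid parameter sets in which each
    component's mean level increased.
    """
    rng = np.random.default_rng(seed)
    n_raw = raw_sets if raw_sets is not None else int(np.ceil(n_sets * oversample))
    raw = sample_ddi_sets(topology, n_raw, rng.integers(2**31), phase=phase)
    if raw_sets is not None:
        n_sets = len(raw)
    T = t_growth / target_growth_rate
    scaled, inits = [], []
    for p in raw:
        try:
            s = rescale_for_domain(
                p, domain_length, target_wave_count, target_growth_rate
            )
        except Exception:
            continue
        dt = sim._stable_dt(s.a[None], s.c[None], s.D[None], 1.0)
        if T / dt > max_steps:
            continue
        scaled.append(s)
        from .rd_core import uniform_steady_state

        center = uniform_steady_state(s)
        inits.append(
            sim.initial_noise(
                rng.integers(2**31), 1, int(domain_length), p.n, center=center
            )[0]
        )
    base = [None] * len(scaled)
    valid = []
    for start in range(0, len(scaled), 64):
        ids = list(range(start, min(start + 64, len(scaled))))
        runs = _batched_runs([scaled[i] for i in ids], T, [inits[i] for i in ids])
        for pos, i in enumerate(ids):
            base[i] = runs[pos]
            m = runs[pos][1]["metrics"]
            if (
                runs[pos][1]["stable"]
                and runs[pos][1]["patterned"]
                and WAVE_RANGE[0] <= m.wave_count <= WAVE_RANGE[1]
            ):
                valid.append(i)
        if len(valid) >= n_sets:
            break
    valid = valid[:n_sets]

    outcomes = {}
    for spec in inhibitions:
        per_set = [None] * len(valid)
        pending = list(range(len(valid)))
        for alpha in ALPHA_LADDER if spec.alpha is None else [spec.alpha]:
            if not pending:
                break
            trial = InhibitionSpec(target=spec.target, mode=spec.mode, alpha=alpha)
            plist, slist, init_states = [], [], []
            for j in pending:
                i = valid[j]
                p2, scale = inhibited_model(scaled[i], trial)
                plist.append(p2)
                slist.append(scale if scale is not None else np.ones(p2.n))
                init_states.append(base[i][0].final)
            runs = _batched_runs(plist, T, init_states, production_scales=slist)
            still = []
            for pos, j in enumerate(pending):
                i = valid[j]
                field, verdict = runs[pos]
                m = verdict["metrics"]
                bm = base[i][1]["metrics"]
                if (
                    verdict["stable"]
                    and verdict["patterned"]
                    and _whole_waves(m) == _whole_waves(bm)
                ):
                    mean_change = 100.0 * (m.mean_level - bm.mean_level) / bm.mean_level
                    per_set[j] = PerturbationOutcome(
                        spec=trial,
                        alpha_used=alpha,
                        mean_change=mean_change,
                        peak_shift=np.zeros(m.mean_level.size),
                        trough_shift=np.zeros(m.mean_level.size),
                        shift_class=classify_wave_shift(bm, m),
                        wave_count_preserved=True,
                    )
                else:
                    still.append(j)
            pending = still
        outcomes[(spec.target, spec.mode)] = per_set

    rows = []
    for (target, mode), per_set in outcomes.items():
        ok = [o for o in per_set if o is not None]
        for comp in range(topology.n):
            inc = sum(1 for o in ok if o.mean_change[comp] > 0)
            rows.append(
                {
                    "target": topology.labels[target],
                    "mode": mode,
                    "component": topology.labels[comp],
                    "fraction_increase": inc / len(ok) if ok else np.nan,
                    "n_valid_sets": len(ok),
                }
            )
    return {
        "summary": pd.DataFrame(rows),
        "outcomes": outcomes,
        "n_valid": len(valid),
        "params": [scaled[i] for i in valid],
    }
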