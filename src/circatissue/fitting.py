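"""Evolutionary parameter estimation for the core clock model.

Free parameters are the regulatory strength constants and fold changes;
degradation rates, delays and promoter-element counts stay fixed at
their literature-scale values.  Each optimization round samples
parameter vectors log-uniformly inside per-parameter ranges, scores the
resulting limit cycles against target rhythm descriptors, and narrows
the ranges around the elite before the next round — the score is a
weighted sum of squared deviations (period, peak phase, relative
amplitude, peak width) normalized by per-descriptor tolerances, with
circular phase distances on the 24 h clock face.

`control_analysis` quantifies how the fitted oscillator responds to
small relative perturbations of every scalar parameter (logarithmic
sensitivities of period and peak phases by central differences).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import (
    GENES,
    ClockParameters,
    IntegrationError,
    RhythmDescriptors,
    extract_rhythm_descriptors,
    simulate_clock,
)

__all__ = [
    "FitTargets",
    "FitResult",
    "FitError",
    "FREE_PARAMETERS",
    "score_model",
    "default_ranges",
    "evolutionary_fit",
    "control_analysis",
    "NON_OSCILLATING_PENALTY",
]

logger = logging.getLogger(__name__)

#: Score assigned to parameter vectors whose model does not sustain
#: oscillations (a large declared penalty rather than infinity).
NON_OSCILLATING_PENALTY = 1.0e6

#: Parameters sampled by the evolutionary strategy (all strictly
#: positive; sampled log-uniformly).  Rates, delays and site counts are
#: excluded by construction.
FREE_PARAMETERS = (
    "rre_strength_bmal1", "rre_strength_cry1",
    "per_repression_reverb", "per_repression_per2",
    "per_repression_cry1", "per_repression_dbp",
    "cry_repression_reverb", "cry_repression_per2",
    "cry_repression_cry1", "cry_repression_dbp",
    "ebox_strength_reverb", "ebox_strength_per2",
    "ebox_strength_cry1", "ebox_strength_dbp",
    "ebox_fold_reverb", "ebox_fold_per2", "ebox_fold_cry1", "ebox_fold_dbp",
    "dbox_strength_reverb", "dbox_strength_per2", "dbox_strength_cry1",
    "dbox_fold_reverb", "dbox_fold_per2", "dbox_fold_cry1",
)


class FitError(RuntimeError):
    """Raised when the evolutionary strategy cannot build a viable elite."""


def circular_difference(a: float, b: float, period: float = 24.0) -> float:
    """Shortest arc between two phases on a circle of the given period."""
    d = (a - b) % period
    return min(d, period - d)


@dataclass
class FitTargets:
    """Target rhythm descriptors with tolerances and score weights.

    ``phases``/``relative_amplitudes``/``peak_widths`` map gene names to
    target values; phase and width tolerances are absolute hours, the
    amplitude tolerance is relative (a fraction of the target).  The
    four weight entries scale whole descriptor classes.
    """

    phases: dict
    relative_amplitudes: dict
    peak_widths: dict
    period: float = 24.0
    phase_tolerance: float = 1.0
    relamp_tolerance: float = 0.2
    width_tolerance: float = 1.0
    period_tolerance: float = 0.5
    weights: dict = field(default_factory=lambda: {
        "period": 1.0, "phase": 1.0, "relamp": 1.0, "width": 1.0})

    def __post_init__(self) -> None:
        for tol in (self.phase_tolerance, self.relamp_tolerance,
                    self.width_tolerance, self.period_tolerance):
            if tol <= 0:
                raise ValueError("tolerances must be positive")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")

    @classmethod
    def liver_default(cls) -> "FitTargets":
        """Canonical liver-like descriptor targets.

        Phase ordering of the mouse liver clock: Rev-erba peaking sharply
        in the subjective morning (CT 6), Dbp before midday (CT 11),
        Per2 in the early subjective night (CT 12), Cry1 at night
        (CT 18) and Bmal1 in the late night (CT 22); high-amplitude
        Rev-erba and Dbp, moderate Bmal1/Per2, low-amplitude Cry1.

        Peak phases are the primary constraint (weight 3): they are the
        best-determined descriptors of profiling data, whereas relative
        amplitudes and especially peak widths vary substantially between
        platforms, so widths get half weight.
        """
        return cls(
            phases={"Bmal1": 22.0, "Rev-erba": 6.0, "Per2": 12.0,
                    "Cry1": 18.0, "Dbp": 11.0},
            relative_amplitudes={"Bmal1": 0.6, "Rev-erba": 0.9, "Per2": 0.7,
                                 "Cry1": 0.4, "Dbp": 0.9},
            peak_widths={"Bmal1": 12.0, "Rev-erba": 7.0, "Per2": 9.0,
                         "Cry1": 12.0, "Dbp": 8.0},
            weights={"period": 1.0, "phase": 3.0, "relamp": 1.0,
                     "width": 0.5},
        )

    @classmethod
    def from_descriptors(cls, desc: RhythmDescriptors,
                         **kwargs) -> "FitTargets":
        """Targets equal to an existing model's descriptors (self-target)."""
        return cls(phases=dict(desc.phases),
                   relative_amplitudes=dict(desc.relative_amplitudes),
                   peak_widths=dict(desc.peak_widths),
                   period=desc.period, **kwargs)


def score_model(descriptors: RhythmDescriptors, targets: FitTargets) -> float:
    """Weighted squared deviation of descriptors from targets.

    Zero iff every descriptor is exactly on target; non-oscillating (or
    incomplete) solutions receive :data:`NON_OSCILLATING_PENALTY`.
    """
    if not descriptors.oscillation_sustained:
        return NON_OSCILLATING_PENALTY
    if not math.isfinite(descriptors.period):
        return NON_OSCILLATING_PENALTY
    w = targets.weights
    s = w.get("period", 1.0) * (
        (descriptors.period - targets.period) / targets.period_tolerance) ** 2
    for g in GENES:
        ph = descriptors.phases.get(g, float("nan"))
        ra = descriptors.relative_amplitudes.get(g, float("nan"))
        pw = descriptors.peak_widths.get(g, float("nan"))
        if not (math.isfinite(ph) and math.isfinite(ra) and math.isfinite(pw)):
            return NON_OSCILLATING_PENALTY
        if g in targets.phases:
            dev = circular_difference(ph, targets.phases[g])
            s += w.get("phase", 1.0) * (dev / targets.phase_tolerance) ** 2
        if g in targets.relative_amplitudes:
            tgt = targets.relative_amplitudes[g]
            tol = targets.relamp_tolerance * tgt
            s += w.get("relamp", 1.0) * ((ra - tgt) / tol) ** 2
        if g in targets.peak_widths:
            s += w.get("width", 1.0) * (
                (pw - targets.peak_widths[g]) / targets.width_tolerance) ** 2
    return float(s)


def within_tolerances(descriptors: RhythmDescriptors,
                      targets: FitTargets) -> bool:
    """True when every targeted descriptor lies inside its tolerance."""
    if not descriptors.oscillation_sustained:
        return False
    if abs(descriptors.period - targets.period) > targets.period_tolerance:
        return False
    for g in GENES:
        if g in targets.phases and circular_difference(
                descriptors.phases[g],
                targets.phases[g]) > targets.phase_tolerance:
            return False
        if g in targets.relative_amplitudes:
            tgt = targets.relative_amplitudes[g]
            if abs(descriptors.relative_amplitudes[g] - tgt) \
                    > targets.relamp_tolerance * tgt:
                return False
        if g in targets.peak_widths and abs(
                descriptors.peak_widths[g]
                - targets.peak_widths[g]) > targets.width_tolerance:
            return False
    return True


def default_ranges(base: ClockParameters | None = None,
                   span: float = 4.0) -> dict:
    """Initial sampling ranges: a symmetric log-span around the defaults.

    Fold-change lower bounds are floored at 1 (activation folds cannot
    dip below basal).
    """
    base = base or ClockParameters()
    ranges = {}
    for name in FREE_PARAMETERS:
        v = getattr(base, name)
        lo, hi = v / span, v * span
        if "fold" in name:
            lo = max(lo, 1.0)
        ranges[name] = (lo, hi)
    return ranges


@dataclass
class FitResult:
    """Outcome of an evolutionary fit, with per-round provenance."""

    best_params: ClockParameters
    best_score: float
    best_descriptors: RhythmDescriptors
    round_history: list
    range_history: list
    seed: int
    targets: FitTargets

    def to_json_dict(self) -> dict:
        return {
            "best_score": self.best_score,
            "best_params": self.best_params.to_dict(),
            "best_descriptors": self.best_descriptors.as_dict(),
            "round_best_scores": [r["best_score"] for r in self.round_history],
            "seed": self.seed,
        }


def _evaluate(params: ClockParameters, targets: FitTargets, dt: float,
              t_end: float, transient: float):
    try:
        traj = simulate_clock(params, t_end=t_end, dt=dt, transient=transient)
    except (IntegrationError, ValueError):
        return NON_OSCILLATING_PENALTY, None
    desc = extract_rhythm_descriptors(traj)
    return score_model(desc, targets), desc


def evolutionary_fit(targets: FitTargets,
                     initial_ranges: dict | None = None,
                     rounds: int = 10,
                     population: int = 2000,
                     elite_fraction: float = 0.05,
                     seed: int = 0,
                     base_params: ClockParameters | None = None,
                     dt: float = 0.1,
                     transient: float = 240.0,
                     n_cycles: float = 5.0,
                     shrink: float = 0.8,
                     include_initial: bool = True,
                     final_dt: float = 0.05) -> FitResult:
    """Fit the free regulatory parameters by an elitist random strategy.

    Each round draws ``population`` log-uniform samples from the current
    per-parameter ranges, keeps the ``elite_fraction`` best oscillating
    vectors, and contracts the ranges to the elite span pulled ``shrink``
    of the way toward the round's best vector (in log space).  A round
    whose elite is empty is restarted with doubled ranges; three
    consecutive failures raise :class:`FitError`.  The best-ever vector
    is re-simulated at ``final_dt`` for the reported descriptors.
    Deterministic for a fixed seed and configuration.
    """
    if rounds < 1 or population < 1:
        raise ValueError("rounds and population must be >= 1")
    if not 0 < elite_fraction <= 1:
        raise ValueError("elite_fraction must be in (0, 1]")
    base = base_params or ClockParameters()
    ranges = dict(initial_ranges or default_ranges(base))
    for name in FREE_PARAMETERS:
        lo, hi = ranges[name]
        if not 0 < lo <= hi:
            raise ValueError(f"invalid range for {name}: ({lo}, {hi})")

    rng = np.random.default_rng(seed)
    t_end = transient + n_cycles * targets.period
    n_elite = max(1, int(round(population * elite_fraction)))

    best_score = math.inf
    best_params = None
    best_desc = None
    round_history = []
    range_history = [dict(ranges)]
    failures = 0
    rnd = 0
    while rnd < rounds:
        samples = []
        for k in range(population):
            if include_initial and rnd == 0 and k == 0:
                vec = {n: float(getattr(base, n)) for n in FREE_PARAMETERS}
            else:
                vec = {}
                for n in FREE_PARAMETERS:
                    lo, hi = ranges[n]
                    vec[n] = float(np.exp(
                        rng.uniform(np.log(lo), np.log(hi))))
            samples.append(vec)

        scored = []
        for vec in samples:
            params = base.with_updates(**vec)
            s, desc = _evaluate(params, targets, dt, t_end, transient)
            scored.append((s, vec, desc))
        scored.sort(key=lambda t: t[0])
        elite = [e for e in scored[:n_elite]
                 if e[0] < NON_OSCILLATING_PENALTY]

        if not elite:
            failures += 1
            logger.warning("round %d: empty elite, widening ranges "
                           "(failure %d/3)", rnd, failures)
            if failures >= 3:
                raise FitError("no oscillating candidate found in three "
                               "consecutive widened rounds")
            ranges = {n: (lo / 2.0, hi * 2.0)
                      for n, (lo, hi) in ranges.items()}
            for n in FREE_PARAMETERS:
                if "fold" in n:
                    lo, hi = ranges[n]
                    ranges[n] = (max(lo, 1.0), hi)
            continue
        failures = 0

        round_best_score, round_best_vec, round_best_desc = elite[0]
        if round_best_score < best_score:
            best_score = round_best_score
            best_params = base.with_updates(**round_best_vec)
            best_desc = round_best_desc
        round_history.append({
            "round": rnd,
            "best_score": best_score,
            "round_best_score": round_best_score,
            "n_oscillating": sum(
                1 for s, _, _ in scored if s < NON_OSCILLATING_PENALTY),
        })

        # next ranges: elite min-max shrunk toward the elite best (log space)
        new_ranges = {}
        for n in FREE_PARAMETERS:
            vals = np.log([vec[n] for _, vec, _ in elite])
            b = math.log(round_best_vec[n])
            lo = b - shrink * (b - vals.min())
            hi = b + shrink * (vals.max() - b)
            lo_v, hi_v = math.exp(lo), math.exp(hi)
            if "fold" in n:
                lo_v = max(lo_v, 1.0)
            if hi_v <= lo_v:
                hi_v = lo_v * 1.0001
            new_ranges[n] = (lo_v, hi_v)
        ranges = new_ranges
        range_history.append(dict(ranges))
        rnd += 1

    # refined descriptors of the winner at the finer step
    final_score, final_desc = _evaluate(best_params, targets, final_dt,
                                        transient + n_cycles * targets.period,
                                        transient)
    if final_desc is not None and final_score < NON_OSCILLATING_PENALTY:
        best_desc = final_desc
        best_score = min(best_score, final_score)
    return FitResult(best_params, best_score, best_desc, round_history,
                     range_history, seed, targets)


# --------------------------------------------------------------------------
# Control (sensitivity) analysis
# --------------------------------------------------------------------------

#: All scalar parameters probed by control analysis.
CONTROL_PARAMETERS = tuple(
    n for n in (
        "d_bmal1", "d_reverb", "d_per2", "d_cry1", "d_dbp",
        "tau_bmal1", "tau_reverb", "tau_per2", "tau_cry1", "tau_dbp",
    ) + FREE_PARAMETERS
)


def control_analysis(params: ClockParameters,
                     perturbation: float = 0.05,
                     dt: float = 0.05,
                     transient: float = 240.0,
                     n_cycles: float = 5.0) -> pd.DataFrame:
    """Logarithmic sensitivities of period and phases to each parameter.

    Every scalar parameter is scaled by ``1 +/- perturbation``; the
    table reports central-difference estimates of d(period)/d(ln p) and
    per-gene d(phase)/d(ln p), sorted by absolute period control.
    Perturbations that kill the oscillation are flagged, not dropped.
    Phase differences are taken on the circle to avoid wrap artifacts.
    """
    if not 0 < perturbation < 1:
        raise ValueError("perturbation must be a relative value in (0, 1)")
    t_end = transient + n_cycles * 24.0

    def descriptors_for(p: ClockParameters):
        try:
            traj = simulate_clock(p, t_end=t_end, dt=dt, transient=transient)
        except (IntegrationError, ValueError):
            return None
        d = extract_rhythm_descriptors(traj)
        return d if d.oscillation_sustained else None

    base_desc = descriptors_for(params)
    if base_desc is None:
        raise ValueError("control analysis requires a sustained oscillation "
                         "at the reference parameters")

    dlog = math.log(1.0 + perturbation) - math.log(1.0 - perturbation)
    rows = []
    for name in CONTROL_PARAMETERS:
        v = getattr(params, name)
        row = {"parameter": name, "value": v, "oscillating": True}
        if v == 0:
            # an inactive slot (e.g. zero delay) has no log-derivative
            row.update({"period_control": 0.0,
                        **{f"phase_control_{g}": 0.0 for g in GENES}})
            rows.append(row)
            continue
        try:
            up = descriptors_for(params.with_updates(
                **{name: v * (1.0 + perturbation)}))
            dn = descriptors_for(params.with_updates(
                **{name: v * (1.0 - perturbation)}))
        except ValueError:
            # perturbation leaves the valid parameter domain (e.g. a fold
            # sitting at its basal bound); flagged like a lost oscillation
            up = dn = None
        if up is None or dn is None:
            row["oscillating"] = False
            row.update({"period_control": float("nan"),
                        **{f"phase_control_{g}": float("nan")
                           for g in GENES}})
            rows.append(row)
            continue
        row["period_control"] = (up.period - dn.period) / dlog
        for g in GENES:
            diff = (up.phases[g] - dn.phases[g] + 12.0) % 24.0 - 12.0
            row[f"phase_control_{g}"] = diff / dlog
        rows.append(row)

    df = pd.DataFrame(rows)
    df["abs_period_control"] = df["period_control"].abs()
    df = df.sort_values("abs_period_control", ascending=False,
                        kind="mergesort").drop(columns="abs_period_control")
    return df.reset_index(drop=True)
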