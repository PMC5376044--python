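"""Clock-controlled genes driven by the core clock's modulation factors.

A clock-controlled gene (CCG) is modelled exactly like a core gene —

    dC/dt = d_CCG * (M_C(t) - C)

— except that its production term ``M_C`` is built from modulators
evaluated on the *simulated core clock* rather than feeding back into
it.  ``M_C`` is the product of any subset of an RRE repression factor
(driven by delayed Rev-erba), an E-box factor (delayed Bmal1 activation
against delayed Per2/Cry1 repression) and a D-box factor (delayed Dbp).
Because the driver is a known function of time the CCG equation is
linear and is integrated with an exact exponential scheme on the clock
grid (piecewise-linear production).

Population simulations sample gene-to-gene variability of the promoter
strength ``a_CCG``, the mRNA degradation rate ``d_CCG`` (0.2-0.6 1/h)
and the regulator delays, and summarize the resulting peak phases by a
circular mode over overlapping 4 h bins.

The module also contains the multiplicative two-sinusoid "harmonics"
construction: the product of out-of-phase regulatory oscillations
cancels the fundamental and leaves a 12 h component, the mechanism
behind harmonic transcripts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

from .core_model import (
    GENES,
    ClockParameters,
    RhythmDescriptors,
    Trajectory,
    dbox_modulator,
    ebox_modulator,
    rre_modulator,
    _gene_peaks,
)
from .rhythm_analysis import circular_mode

__all__ = [
    "RREDrive",
    "EboxDrive",
    "DboxDrive",
    "CCGParameters",
    "HarmonicSpec",
    "simulate_ccg",
    "ccg_modulation",
    "ccg_peak_phase",
    "sample_ccg_population",
    "PopulationResult",
    "fit_ccg_to_target",
    "CCGFitResult",
    "harmonic_product",
    "harmonic_expansion",
    "dominant_period",
]

#: Default lag between Dbp mRNA and D-box induction of targets (hours).
DEFAULT_DBOX_DELAY = 2.0

#: Relative-amplitude floor below which a CCG counts as flat.
FLAT_RELAMP = 1e-3


# --------------------------------------------------------------------------
# Driver configuration
# --------------------------------------------------------------------------

@dataclass
class RREDrive:
    """RRE repression of a CCG by delayed Rev-erba."""
    strength: float = 5.0
    site_count: int = 1
    delay: float = 2.0

    def validate(self):
        if self.strength <= 0 or self.site_count < 1 or self.delay < 0:
            raise ValueError("invalid RRE drive")


@dataclass
class EboxDrive:
    """E-box activation by delayed Bmal1 with Per2/Cry1 repression."""
    activator_strength: float = 5.0
    per_strength: float = 5.0
    cry_strength: float = 5.0
    fold: float = 10.0
    site_count: int = 1
    delay_bmal1: float = 8.0
    delay_per2: float = 4.0
    delay_cry1: float = 8.0

    def validate(self):
        if min(self.activator_strength, self.per_strength,
               self.cry_strength) <= 0:
            raise ValueError("E-box strengths must be positive")
        if self.fold < 1 or self.site_count < 1:
            raise ValueError("invalid E-box fold/site count")
        if min(self.delay_bmal1, self.delay_per2, self.delay_cry1) < 0:
            raise ValueError("delays must be non-negative")


@dataclass
class DboxDrive:
    """D-box activation by delayed Dbp."""
    strength: float = 5.0
    fold: float = 10.0
    site_count: int = 1
    delay: float = DEFAULT_DBOX_DELAY

    def validate(self):
        if self.strength <= 0 or self.fold < 1 or self.site_count < 1 \
                or self.delay < 0:
            raise ValueError("invalid D-box drive")


@dataclass
class CCGParameters:
    """Degradation rate and driver set of one clock-controlled gene."""

    d_ccg: float = 0.4
    rre: RREDrive | None = None
    ebox: EboxDrive | None = None
    dbox: DboxDrive | None = None

    def __post_init__(self):
        if not 0 < self.d_ccg <= 2.0:
            raise ValueError("d_ccg must lie in (0, 2] 1/h")
        if self.rre is None and self.ebox is None and self.dbox is None:
            raise ValueError("a CCG needs at least one driver")
        for drv in (self.rre, self.ebox, self.dbox):
            if drv is not None:
                drv.validate()


# --------------------------------------------------------------------------
# Driving and integration
# --------------------------------------------------------------------------

def _delayed_series(traj: Trajectory, gene: str, delay: float) -> np.ndarray:
    """Regulator level at ``t - delay`` on the trajectory grid.

    Times before the grid clamp to the initial value; the clock's own
    transient (still present in the grid) absorbs the edge effect.
    """
    x = traj.column(gene)
    return np.interp(traj.time - delay, traj.time, x,
                     left=float(x[0]), right=float(x[-1]))


def ccg_modulation(clock_traj: Trajectory, ccg: CCGParameters) -> np.ndarray:
    """Production term ``M_C(t)`` of the CCG on the clock grid."""
    for gene in ("Bmal1", "Rev-erba", "Per2", "Cry1", "Dbp"):
        if gene not in clock_traj.species:
            raise ValueError(f"driver species {gene!r} absent from trajectory")
    m = np.ones_like(clock_traj.time)
    if ccg.rre is not None:
        r = _delayed_series(clock_traj, "Rev-erba", ccg.rre.delay)
        m = m * rre_modulator(r, ccg.rre.strength, ccg.rre.site_count)
    if ccg.ebox is not None:
        e = ccg.ebox
        b = _delayed_series(clock_traj, "Bmal1", e.delay_bmal1)
        p = _delayed_series(clock_traj, "Per2", e.delay_per2)
        c = _delayed_series(clock_traj, "Cry1", e.delay_cry1)
        m = m * ebox_modulator(b, p, c,
                               activator_strength=e.activator_strength,
                               per_strength=e.per_strength,
                               cry_strength=e.cry_strength,
                               fold=e.fold, site_count=e.site_count)
    if ccg.dbox is not None:
        d = _delayed_series(clock_traj, "Dbp", ccg.dbox.delay)
        m = m * dbox_modulator(d, strength=ccg.dbox.strength,
                               fold=ccg.dbox.fold,
                               site_count=ccg.dbox.site_count)
    return m


def _drive_linear(m: np.ndarray, d: float, dt: float,
                  c0: float | None = None) -> np.ndarray:
    """Exact exponential-integrator solution of ``dC/dt = d (M(t) - C)``.

    ``M`` is treated as piecewise linear between grid points, for which
    the update ``C_{n+1} = a C_n + b1 M_{n+1} + b0 M_n`` is exact.
    """
    a = math.exp(-d * dt)
    e = 1.0 - a
    b1 = 1.0 - e / (d * dt)
    b0 = e - b1
    if c0 is None:
        c0 = float(m[0])
    # recursion via lfilter: y[n] = a y[n-1] + b1 m[n] + b0 m[n-1]
    zi = np.array([a * c0 + b0 * m[0]])
    y, _ = lfilter([b1, b0], [1.0, -a], m[1:], zi=zi)
    return np.concatenate(([c0], y))


def simulate_ccg(clock_traj: Trajectory, ccg: CCGParameters) -> Trajectory:
    """Integrate one CCG on the clock grid; returns a one-species trajectory."""
    m = ccg_modulation(clock_traj, ccg)
    c = _drive_linear(m, ccg.d_ccg, clock_traj.dt)
    return Trajectory(clock_traj.time, c, ("CCG",), clock_traj.dt,
                      dict(clock_traj.meta))


def ccg_peak_phase(ccg_traj: Trajectory, clock_desc: RhythmDescriptors,
                   transient: float | None = None) -> float:
    """CT of the CCG's expression peak, or NaN for flat profiles.

    Flatness is a post-transient relative amplitude below
    :data:`FLAT_RELAMP`.
    """
    tr = ccg_traj.after(ccg_traj.transient if transient is None
                        else transient)
    x = tr.column("CCG")
    hi, lo = float(x.max()), float(x.min())
    if hi + lo <= 0 or (hi - lo) / (hi + lo) < FLAT_RELAMP:
        return float("nan")
    pk_t, _ = _gene_peaks(tr.time, x, tr.dt)
    if len(pk_t) == 0:
        return float("nan")
    return float(clock_desc.ct(pk_t[-1]))


def ccg_relative_amplitude(ccg_traj: Trajectory, clock_desc: RhythmDescriptors,
                           transient: float | None = None) -> float:
    tr = ccg_traj.after(ccg_traj.transient if transient is None
                        else transient)
    t_last = tr.time[-1]
    sel = tr.time >= t_last - clock_desc.period
    x = tr.column("CCG")[sel]
    hi, lo = float(x.max()), float(x.min())
    return (hi - lo) / (hi + lo) if hi + lo > 0 else float("nan")


# --------------------------------------------------------------------------
# Population sampling
# --------------------------------------------------------------------------

@dataclass
class PopulationResult:
    """Peak phases of a simulated CCG population (flat genes excluded)."""

    phases: np.ndarray
    n_requested: int
    n_excluded: int
    driver: str
    seed: int

    def mode(self, bin_width: float = 4.0, overlap: float = 3.0) -> float:
        """Circular-mode peak phase over overlapping histogram bins."""
        return circular_mode(self.phases, bin_width=bin_width,
                             overlap=overlap)


#: Gene-to-gene spread of a regulator's effective action delay, as a
#: fraction of the core model's delay (the scale on which fitted delays
#: vary between tissue/condition-specific core models).
DELAY_SPREAD = 0.2

#: Default PER2/CRY1 inhibition constants of an output gene's E-box.
#: CRY1 — the long-lived, broadly bound E-box repressor — dominates on
#: typical output promoters; PER2 contributes weakly.
CCG_EBOX_PER_STRENGTH = 0.5
CCG_EBOX_CRY_STRENGTH = 2.0


def _delay_window(tau_core: float, spread: float = DELAY_SPREAD) -> tuple:
    return (max(0.0, (1.0 - spread) * tau_core), (1.0 + spread) * tau_core)


def _class_range(values, spread: float = 2.0) -> tuple:
    """Log-range spanned by a class of core-model constants, widened a
    factor ``spread`` at both ends (gene-to-gene promoter variability)."""
    lo, hi = min(values), max(values)
    return (lo / spread, hi * spread)


def _core_strength_ranges(core: ClockParameters) -> dict:
    """Per-element-class sampling ranges for CCG promoter constants.

    Output-gene strengths are drawn from the range their element class
    occupies in the fitted core model: the core promoters set the
    physiological scale of each regulator (absolute regulator levels
    differ widely between species, so a single shared range would let
    one element class saturate while another barely registers).
    """
    return {
        "rre": _class_range([core.rre_strength_bmal1,
                             core.rre_strength_cry1]),
        "ebox": _class_range([core.ebox_strength_reverb,
                              core.ebox_strength_per2,
                              core.ebox_strength_cry1,
                              core.ebox_strength_dbp]),
        "dbox": _class_range([core.dbox_strength_reverb,
                              core.dbox_strength_per2,
                              core.dbox_strength_cry1]),
        "ebox_fold": _class_range([core.ebox_fold_reverb,
                                   core.ebox_fold_per2,
                                   core.ebox_fold_cry1,
                                   core.ebox_fold_dbp], spread=1.0),
        "dbox_fold": _class_range([core.dbox_fold_reverb,
                                   core.dbox_fold_per2,
                                   core.dbox_fold_cry1], spread=1.0),
    }


def sample_ccg_population(clock_traj: Trajectory,
                          clock_desc: RhythmDescriptors,
                          driver: str = "rre",
                          n: int = 250,
                          seed: int = 0,
                          core_params: ClockParameters | None = None,
                          d_range: tuple = (0.2, 0.6),
                          strength_range: tuple | None = None,
                          fold_range: tuple | None = None,
                          delay_range: tuple | None = None,
                          vary_repressors: bool = False) -> PopulationResult:
    """Simulate ``n`` CCGs with sampled parameters; collect peak phases.

    ``driver`` is ``"rre"``, ``"ebox"``, ``"dbox"`` or ``"ebox+rre"``.
    Degradation rates are uniform in ``d_range`` (default the typical
    mRNA turnover window 0.2-0.6 1/h); promoter strengths and fold
    changes are log-uniform over the range their element class spans in
    the fitted core model (each class has its own physiological scale
    because absolute regulator levels differ between species); each
    regulator's action delay is uniform in a +/-20% window around the
    core model's fitted delay for that regulator — except for D-box
    drives, whose ~2 h induction lag is kept fixed.  Explicit
    ``strength_range``/``fold_range``/``delay_range`` substitute one
    shared range.  With ``vary_repressors`` the E-box PER/CRY repressor
    strengths are sampled as well, otherwise they stay at the declared
    output-promoter context.  Flat outputs are excluded from the phase
    list and counted.
    """
    if driver not in ("rre", "ebox", "dbox", "ebox+rre"):
        raise ValueError(f"unknown driver configuration {driver!r}")
    core = core_params or ClockParameters()
    rng = np.random.default_rng(seed)
    phases = []
    n_excluded = 0
    for _ in range(n):
        ccg = _sample_single_ccg(driver, int(rng.integers(2 ** 31)), core,
                                 d_range=d_range,
                                 strength_range=strength_range,
                                 fold_range=fold_range,
                                 delay_range=delay_range,
                                 vary_repressors=vary_repressors)
        ph = ccg_peak_phase(simulate_ccg(clock_traj, ccg), clock_desc)
        if math.isnan(ph):
            n_excluded += 1
        else:
            phases.append(ph)
    return PopulationResult(np.array(phases), n, n_excluded, driver, seed)


# --------------------------------------------------------------------------
# Fitting a single CCG to a target phase/amplitude
# --------------------------------------------------------------------------

@dataclass
class CCGFitResult:
    params: CCGParameters | None
    phase: float
    relative_amplitude: float
    no_fit: bool

    def __bool__(self) -> bool:  # truthy iff a fit was found
        return not self.no_fit


def fit_ccg_to_target(clock_traj: Trajectory,
                      clock_desc: RhythmDescriptors,
                      target_phase: float,
                      target_relamp: float,
                      drivers: Sequence[str] = ("rre",),
                      n_candidates: int = 500,
                      seed: int = 0,
                      core_params: ClockParameters | None = None,
                      max_phase_error: float = 3.0,
                      **sample_kwargs) -> CCGFitResult:
    """Random search for CCG parameters matching a phase/amplitude target.

    Candidates are drawn with the same gene-to-gene variability scheme
    as the population simulations (one driver set per call, e.g.
    ``("rre",)`` or ``("ebox", "rre")``); the best candidate minimizes
    circular phase error (per hour) plus relative-amplitude error (per
    0.1).  If no candidate comes within ``max_phase_error`` hours of the
    target phase the result carries the ``no_fit`` flag.
    """
    driver = "+".join(sorted(drivers)) if len(drivers) > 1 else drivers[0]
    core = core_params or ClockParameters()
    rng = np.random.default_rng(seed)
    best_score = math.inf
    best_result = None
    for _ in range(n_candidates):
        sub_seed = int(rng.integers(2 ** 31))
        params = _sample_single_ccg(driver, sub_seed, core, **sample_kwargs)
        traj = simulate_ccg(clock_traj, params)
        ph = ccg_peak_phase(traj, clock_desc)
        if math.isnan(ph):
            continue
        ra = ccg_relative_amplitude(traj, clock_desc)
        dphi = abs((ph - target_phase + 12.0) % 24.0 - 12.0)
        s = (dphi / 1.0) ** 2 + ((ra - target_relamp) / 0.1) ** 2
        if s < best_score:
            best_score = s
            best_result = CCGFitResult(params, ph, ra, False)
    if best_result is None or abs(
            (best_result.phase - target_phase + 12.0) % 24.0 - 12.0
            ) > max_phase_error:
        return CCGFitResult(None, float("nan"), float("nan"), True)
    return best_result


def _sample_single_ccg(driver: str, seed: int, core: ClockParameters,
                       d_range=(0.2, 0.6), strength_range=None,
                       fold_range=None, delay_range=None,
                       vary_repressors: bool = False) -> CCGParameters:
    """One CCG parameter draw, mirroring `sample_ccg_population`.

    Promoter strengths and folds default to the range their element
    class spans in the fitted core model; each regulator's action delay
    is drawn around the core model's fitted delay for that regulator
    (``strength_range``/``fold_range``/``delay_range`` override with
    one shared range).  The D-box lag stays at its ~2 h default.
    """
    rng = np.random.default_rng(seed)
    class_ranges = _core_strength_ranges(core)

    def log_draw(lo, hi):
        return float(np.exp(rng.uniform(math.log(lo), math.log(hi))))

    def strengths(cls):
        return strength_range if strength_range is not None \
            else class_ranges[cls]

    def folds(cls):
        lo, hi = fold_range if fold_range is not None \
            else class_ranges[cls + "_fold"]
        return (max(lo, 1.0), max(hi, 1.0 + 1e-9))

    def window(tau_core):
        return delay_range if delay_range is not None \
            else _delay_window(tau_core)

    d_ccg = float(rng.uniform(*d_range))
    rre = ebox = dbox = None
    if "rre" in driver:
        rre = RREDrive(strength=log_draw(*strengths("rre")),
                       site_count=1,
                       delay=float(rng.uniform(*window(core.tau_reverb))))
    if "ebox" in driver:
        if vary_repressors:
            p_s = log_draw(*strengths("ebox"))
            c_s = log_draw(*strengths("ebox"))
        else:
            p_s = CCG_EBOX_PER_STRENGTH
            c_s = CCG_EBOX_CRY_STRENGTH
        ebox = EboxDrive(
            activator_strength=log_draw(*strengths("ebox")),
            per_strength=p_s, cry_strength=c_s,
            fold=log_draw(*folds("ebox")), site_count=1,
            delay_bmal1=float(rng.uniform(*window(core.tau_bmal1))),
            delay_per2=float(rng.uniform(*window(core.tau_per2))),
            delay_cry1=float(rng.uniform(*window(core.tau_cry1))))
    if driver == "dbox":
        dbox = DboxDrive(strength=log_draw(*strengths("dbox")),
                         fold=log_draw(*folds("dbox")),
                         site_count=1, delay=DEFAULT_DBOX_DELAY)
    return CCGParameters(d_ccg=d_ccg, rre=rre, ebox=ebox, dbox=dbox)


def rre_release_phase(clock_traj: Trajectory,
                      clock_desc: RhythmDescriptors,
                      params: ClockParameters) -> float:
    """CT at which the RRE repressive modulator is maximal.

    Evaluates ``(1 + a*R(t - tau))**(-n)`` (the Bmal1-promoter RRE factor)
    with the model's Rev-erb delay over the last post-transient cycle;
    its maximum marks the release of REV-ERB repression.
    """
    r = _delayed_series(clock_traj, "Rev-erba", params.tau_reverb)
    m = rre_modulator(r, params.rre_strength_bmal1, params.rre_sites_bmal1)
    t = clock_traj.time
    sel = t >= t[-1] - clock_desc.period
    tt, mm = t[sel], m[sel]
    pk_t, _ = _gene_peaks(tt, mm, clock_traj.dt)
    t_max = pk_t[-1] if len(pk_t) else tt[np.argmax(mm)]
    return float(clock_desc.ct(t_max))


# --------------------------------------------------------------------------
# Multiplicative harmonics
# --------------------------------------------------------------------------

@dataclass
class HarmonicSpec:
    """Two multiplied sinusoidal regulations: ``(1+sin wt)(1+A sin(wt+a))``."""

    amplitude: float = 1.0
    phase_shift_deg: float = 180.0
    omega: float = 2.0 * math.pi / 24.0

    def __post_init__(self):
        if not 0.0 <= self.amplitude <= 1.0:
            raise ValueError("amplitude must lie in [0, 1]")


def harmonic_product(spec: HarmonicSpec, t) -> np.ndarray:
    """Product form of the two-sinusoid regulation."""
    t = np.asarray(t, dtype=float)
    a = math.radians(spec.phase_shift_deg)
    return (1.0 + np.sin(spec.omega * t)) \
        * (1.0 + spec.amplitude * np.sin(spec.omega * t + a))


def harmonic_expansion(spec: HarmonicSpec, t) -> np.ndarray:
    """Trigonometric expansion of :func:`harmonic_product`.

    ``1 + sin wt + A sin(wt+a) + (A/2)[cos a - cos(2wt + a)]`` — equal to
    the product to machine precision; the last term is the 12 h
    harmonic, which survives alone when ``A -> 1`` and ``a = 180°``.
    """
    t = np.asarray(t, dtype=float)
    a = math.radians(spec.phase_shift_deg)
    A = spec.amplitude
    return (1.0 + np.sin(spec.omega * t) + A * np.sin(spec.omega * t + a)
            + 0.5 * A * (math.cos(a) - np.cos(2.0 * spec.omega * t + a)))


def dominant_period(signal: Trajectory | tuple,
                    base_period: float = 24.0,
                    max_harmonic: int = 6) -> float:
    """Period (h) of the strongest Fourier component among ``base/k``.

    Requires at least four base cycles of uniformly sampled data.  A
    flat signal has no defined period and yields NaN.
    """
    if isinstance(signal, Trajectory):
        t = signal.time
        x = signal.values[:, 0]
    else:
        t, x = signal
        t = np.asarray(t, dtype=float)
        x = np.asarray(x, dtype=float)
    span = t[-1] - t[0]
    if span < 4 * base_period:
        raise ValueError("need at least four base cycles of data")
    x = x - x.mean()
    if float(np.max(np.abs(x))) < 1e-12:
        return float("nan")
    powers = []
    for k in range(1, max_harmonic + 1):
        w = 2.0 * math.pi * k / base_period
        c = np.trapezoid(x * np.cos(w * t), t)
        s = np.trapezoid(x * np.sin(w * t), t)
        powers.append(c * c + s * s)
    k_best = int(np.argmax(powers)) + 1
    return base_period / k_best
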