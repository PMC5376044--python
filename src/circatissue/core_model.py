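"""Minimal gene-regulatory model of the mammalian core circadian clock.

Five genes --- *Bmal1*, *Rev-erba* (lumping the redundant Rev-erb/Ror
nuclear-receptor paralogs), *Per2*, *Cry1* and *Dbp* --- are coupled
through the three canonical circadian promoter elements: E-boxes
(activated by BMAL1, repressed by PER2 and CRY1), D-boxes (activated by
DBP) and ROR elements / RREs (repressed by REV-ERB).  Each mRNA species
``x`` obeys

    dx/dt = d_x * (M_x(t) - x)

where ``M_x``, the product of the gene's *modulation factors*, is
evaluated on regulator mRNA levels a fixed number of hours in the past:
one explicit delay ``tau`` per regulator gene merges translation,
post-translational modification and nuclear import into a single lag.
Production is pre-multiplied by the degradation rate ``d_x`` so every
species is dimensionless and relaxes to its modulation factor whenever
regulation is frozen.

The modulation factors come in two shapes:

* repression through an RRE carrying ``n`` functional elements:
  ``(1 + a*R)**(-n)``;
* activation through ``n`` E-boxes or D-boxes with basal-to-full fold
  change ``f``: ``((1 + f*Xhat) / (1 + Xhat))**n`` where ``Xhat`` is the
  scaled activator level, competitively diminished by PER2/CRY1 in the
  E-box case (``Xhat = b*B / (1 + p*P + c*C)``).

Integration uses a fixed-step RK4 method-of-steps scheme; delayed
look-ups interpolate the stored solution with a 4-point Lagrange cubic.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, fields, replace
from typing import Mapping

import numpy as np
from numba import njit
from scipy.signal import find_peaks

__all__ = [
    "GENES",
    "CT_ANCHOR_OFFSET",
    "ClockParameters",
    "Trajectory",
    "RhythmDescriptors",
    "rre_modulator",
    "ebox_modulator",
    "dbox_modulator",
    "clock_rhs",
    "simulate_clock",
    "extract_rhythm_descriptors",
    "IntegrationError",
]

#: Model species, in integration order.
GENES = ("Bmal1", "Rev-erba", "Per2", "Cry1", "Dbp")

#: Circadian time assigned to the upward mean-crossing of Bmal1 that
#: precedes its expression peak.  A single declared constant: with the
#: default fit targets (Bmal1 peaking late subjective night) this anchor
#: places the fitted Rev-erba peak near CT 6.
CT_ANCHOR_OFFSET = 16.0

#: Plausibility bounds used for validation and for control analysis.
DEGRADATION_BOUNDS = (0.05, 2.0)   # per hour
DELAY_BOUNDS = (0.0, 12.0)         # hours


class IntegrationError(RuntimeError):
    """Raised when the DDE integration produces invalid concentrations."""


# --------------------------------------------------------------------------
# Parameters
# --------------------------------------------------------------------------

# Order of the scalar parameters inside the flat vector handed to the
# compiled integrator.  Degradation rates and delays first, then the
# regulatory constants (the free parameters of the evolutionary fit).
PARAMETER_ORDER = (
    "d_bmal1", "d_reverb", "d_per2", "d_cry1", "d_dbp",
    "tau_bmal1", "tau_reverb", "tau_per2", "tau_cry1", "tau_dbp",
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

SITE_COUNT_ORDER = (
    "rre_sites_bmal1",
    "ebox_sites_reverb", "ebox_sites_per2", "ebox_sites_cry1", "ebox_sites_dbp",
    "dbox_sites_reverb", "dbox_sites_per2", "dbox_sites_cry1",
    "rre_sites_cry1",
)


@dataclass
class ClockParameters:
    """All rates, delays, regulatory strengths and site counts of the model.

    Degradation rates ``d_*`` are in 1/h, delays ``tau_*`` in hours; the
    regulatory strength constants and fold changes are dimensionless.
    Site counts are the number of functional promoter elements (the
    exponents of the modulation factors) and are held fixed during
    fitting, as are degradation rates and delays.

    The defaults describe a liver-like model: they place the system in
    its self-sustained ~24 h oscillatory regime with the canonical phase
    ordering (Rev-erba peaking in the subjective morning, Dbp near
    midday, Per2 in the early evening, Cry1 at night and Bmal1 in the
    late night).
    """

    # degradation rates (1/h)
    d_bmal1: float = 0.711
    d_reverb: float = 0.848
    d_per2: float = 1.51
    d_cry1: float = 0.304
    d_dbp: float = 1.5
    # regulatory-protein delays (h), mRNA peak -> protein action
    tau_bmal1: float = 10.6
    tau_reverb: float = 2.0
    tau_per2: float = 1.83
    tau_cry1: float = 7.96
    tau_dbp: float = 0.408
    # RRE repression strengths
    rre_strength_bmal1: float = 0.0376
    rre_strength_cry1: float = 0.0779
    # competitive E-box repression by PER2 / CRY1, per target promoter
    # (promoter context sets how strongly each repressor acts there)
    per_repression_reverb: float = 3.28
    per_repression_per2: float = 0.463
    per_repression_cry1: float = 23.7
    per_repression_dbp: float = 0.0265
    cry_repression_reverb: float = 0.625
    cry_repression_per2: float = 0.237
    cry_repression_cry1: float = 22.9
    cry_repression_dbp: float = 1.55
    # E-box activation strength (scaling of BMAL1) per target promoter
    ebox_strength_reverb: float = 9.08
    ebox_strength_per2: float = 0.108
    ebox_strength_cry1: float = 9.05
    ebox_strength_dbp: float = 0.814
    # E-box fold changes per target promoter
    ebox_fold_reverb: float = 8.67
    ebox_fold_per2: float = 1.21
    ebox_fold_cry1: float = 3.71
    ebox_fold_dbp: float = 26.7
    # D-box activation strengths / folds per target promoter
    dbox_strength_reverb: float = 1.43
    dbox_strength_per2: float = 0.0051
    dbox_strength_cry1: float = 0.0359
    dbox_fold_reverb: float = 1.01
    dbox_fold_per2: float = 54.6
    dbox_fold_cry1: float = 22.1
    # site counts (number of functional promoter elements)
    rre_sites_bmal1: int = 3
    ebox_sites_reverb: int = 3
    dbox_sites_reverb: int = 1
    ebox_sites_per2: int = 2
    dbox_sites_per2: int = 1
    ebox_sites_cry1: int = 2
    dbox_sites_cry1: int = 1
    rre_sites_cry1: int = 2
    ebox_sites_dbp: int = 3

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        lo_d, hi_d = DEGRADATION_BOUNDS
        lo_t, hi_t = DELAY_BOUNDS
        for g in ("bmal1", "reverb", "per2", "cry1", "dbp"):
            d = getattr(self, f"d_{g}")
            if not lo_d <= d <= hi_d:
                raise ValueError(f"d_{g}={d} outside [{lo_d}, {hi_d}] 1/h")
            t = getattr(self, f"tau_{g}")
            if not lo_t <= t <= hi_t:
                raise ValueError(f"tau_{g}={t} outside [{lo_t}, {hi_t}] h")
        for name in PARAMETER_ORDER[10:]:
            v = getattr(self, name)
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
            if "fold" in name and v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        for name in SITE_COUNT_ORDER:
            n = getattr(self, name)
            if not (isinstance(n, (int, np.integer)) and n >= 1):
                raise ValueError(f"{name} must be a positive integer, got {n!r}")

    # -- flat-vector plumbing for the compiled integrator ------------------

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAMETER_ORDER], dtype=float)

    def site_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in SITE_COUNT_ORDER], dtype=float)

    def with_updates(self, **updates: float) -> "ClockParameters":
        return replace(self, **updates)

    # -- config round trip --------------------------------------------------

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ClockParameters":
        return cls(**dict(d))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ClockParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def digest(self) -> str:
        """Short stable hash of the parameter values (trajectory metadata)."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


# --------------------------------------------------------------------------
# Modulation factors (public, validated forms)
# --------------------------------------------------------------------------

def rre_modulator(regulator_level, strength, site_count):
    """Repressive ROR-element modulation factor ``(1 + a*R)**(-n)``.

    Equals 1 with no repressor and decreases strictly with the
    (delay-evaluated) REV-ERB level ``R``; the exponent ``n`` is the
    number of functional ROR elements on the promoter.
    """
    level = np.asarray(regulator_level, dtype=float)
    if np.any(level < 0):
        raise ValueError("regulator_level must be non-negative")
    if strength <= 0:
        raise ValueError("strength must be positive")
    if site_count < 1:
        raise ValueError("site_count must be a positive integer")
    out = (1.0 + strength * level) ** (-float(site_count))
    return float(out) if np.isscalar(regulator_level) else out


def ebox_modulator(activator_level, per_level, cry_level, *,
                   activator_strength, per_strength, cry_strength,
                   fold, site_count):
    """E-box modulation factor: BMAL1 activation under PER2/CRY1 repression.

    The effective activator is ``Bhat = b*B / (1 + p*P + c*C)``; the
    factor is ``((1 + f*Bhat) / (1 + Bhat))**n``, rising from 1 (basal
    transcription) to ``f**n`` at saturation.
    """
    b = np.asarray(activator_level, dtype=float)
    p = np.asarray(per_level, dtype=float)
    c = np.asarray(cry_level, dtype=float)
    if np.any(b < 0) or np.any(p < 0) or np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    if activator_strength <= 0 or per_strength <= 0 or cry_strength <= 0:
        raise ValueError("strength constants must be positive")
    if fold < 1:
        raise ValueError("activation fold must be >= 1")
    if site_count < 1:
        raise ValueError("site_count must be a positive integer")
    bhat = activator_strength * b / (1.0 + per_strength * p + cry_strength * c)
    out = ((1.0 + fold * bhat) / (1.0 + bhat)) ** float(site_count)
    scalar = all(np.isscalar(x) for x in (activator_level, per_level, cry_level))
    return float(out) if scalar else out


def dbox_modulator(dbp_level, *, strength, fold, site_count,
                   repressor_level=0.0, repressor_strength=0.0):
    """D-box modulation factor driven by DBP.

    Same activating form as the E-box factor with DBP as sole activator.
    The optional competing repressor slot covers E4BP4-like inputs and is
    off by default (``repressor_strength = 0``).
    """
    d = np.asarray(dbp_level, dtype=float)
    if np.any(d < 0):
        raise ValueError("dbp_level must be non-negative")
    if np.any(np.asarray(repressor_level) < 0) or repressor_strength < 0:
        raise ValueError("repressor terms must be non-negative")
    if strength <= 0:
        raise ValueError("strength must be positive")
    if fold < 1:
        raise ValueError("activation fold must be >= 1")
    if site_count < 1:
        raise ValueError("site_count must be a positive integer")
    dhat = strength * d / (1.0 + repressor_strength * np.asarray(repressor_level))
    out = ((1.0 + fold * dhat) / (1.0 + dhat)) ** float(site_count)
    return float(out) if np.isscalar(dbp_level) else out


# --------------------------------------------------------------------------
# Compiled right-hand side and integrator
# --------------------------------------------------------------------------
# Flat parameter vector layout (see PARAMETER_ORDER):
#   p[0:5]   d          p[5:10]  tau
#   p[10]    a_RRE(Bmal1)        p[11]  a_RRE(Cry1)
#   p[12:16] PER2 repression per promoter (Rev-erba, Per2, Cry1, Dbp)
#   p[16:20] CRY1 repression per promoter
#   p[20:24] E-box strengths (Rev-erba, Per2, Cry1, Dbp)
#   p[24:28] E-box folds
#   p[28:31] D-box strengths (Rev-erba, Per2, Cry1)
#   p[31:34] D-box folds
# Site counts s (floats for numba pow):
#   s[0] RRE(Bmal1); s[1:5] E-box (R,P,C,D); s[5:8] D-box (R,P,C); s[8] RRE(Cry1)


@njit(cache=True)
def _rhs(state, delayed, p, s):
    B = state[0]; R = state[1]; P = state[2]; C = state[3]; D = state[4]
    Bd = delayed[0]; Rd = delayed[1]; Pd = delayed[2]; Cd = delayed[3]; Dd = delayed[4]

    m_b = (1.0 + p[10] * Rd) ** (-s[0])

    bh = p[20] * Bd / (1.0 + p[12] * Pd + p[16] * Cd)
    m_r = ((1.0 + p[24] * bh) / (1.0 + bh)) ** s[1]
    xh = p[28] * Dd
    m_r *= ((1.0 + p[31] * xh) / (1.0 + xh)) ** s[5]

    bh = p[21] * Bd / (1.0 + p[13] * Pd + p[17] * Cd)
    m_p = ((1.0 + p[25] * bh) / (1.0 + bh)) ** s[2]
    xh = p[29] * Dd
    m_p *= ((1.0 + p[32] * xh) / (1.0 + xh)) ** s[6]

    bh = p[22] * Bd / (1.0 + p[14] * Pd + p[18] * Cd)
    m_c = ((1.0 + p[26] * bh) / (1.0 + bh)) ** s[3]
    xh = p[30] * Dd
    m_c *= ((1.0 + p[33] * xh) / (1.0 + xh)) ** s[7]
    m_c *= (1.0 + p[11] * Rd) ** (-s[8])

    bh = p[23] * Bd / (1.0 + p[15] * Pd + p[19] * Cd)
    m_d = ((1.0 + p[27] * bh) / (1.0 + bh)) ** s[4]

    out = np.empty(5)
    out[0] = p[0] * (m_b - B)
    out[1] = p[1] * (m_r - R)
    out[2] = p[2] * (m_p - P)
    out[3] = p[3] * (m_c - C)
    out[4] = p[4] * (m_d - D)
    return out


@njit(cache=True)
def _lookup(y, hist, g, x, imax):
    """Value of species g at fractional grid index x (cubic Lagrange)."""
    if x <= 0.0:
        return hist[g]
    if x >= imax:
        return y[imax, g]
    j = int(math.floor(x))
    if j < 1 or j + 2 > imax:
        # linear near the boundaries (transient region, discarded later)
        a = x - j
        return (1.0 - a) * y[j, g] + a * y[j + 1, g]
    a = x - j
    wm1 = -a * (a - 1.0) * (a - 2.0) / 6.0
    w0 = (a + 1.0) * (a - 1.0) * (a - 2.0) / 2.0
    w1 = -(a + 1.0) * a * (a - 2.0) / 2.0
    w2 = (a + 1.0) * a * (a - 1.0) / 6.0
    return (wm1 * y[j - 1, g] + w0 * y[j, g]
            + w1 * y[j + 1, g] + w2 * y[j + 2, g])


@njit(cache=True)
def _delayed_states(y, hist, stage_state, ts, tau, dt, imax):
    out = np.empty(5)
    for g in range(5):
        if tau[g] <= 0.0:
            out[g] = stage_state[g]
        else:
            out[g] = _lookup(y, hist, g, (ts - tau[g]) / dt, imax)
    return out


@njit(cache=True)
def _integrate(p, s, hist, n_steps, dt):
    tau = p[5:10]
    y = np.empty((n_steps + 1, 5))
    for g in range(5):
        y[0, g] = hist[g]
    ok = True
    for i in range(n_steps):
        t = i * dt
        yi = y[i]

        dl = _delayed_states(y, hist, yi, t, tau, dt, i)
        k1 = _rhs(yi, dl, p, s)

        y2 = yi + 0.5 * dt * k1
        dl = _delayed_states(y, hist, y2, t + 0.5 * dt, tau, dt, i)
        k2 = _rhs(y2, dl, p, s)

        y3 = yi + 0.5 * dt * k2
        dl = _delayed_states(y, hist, y3, t + 0.5 * dt, tau, dt, i)
        k3 = _rhs(y3, dl, p, s)

        y4 = yi + dt * k3
        dl = _delayed_states(y, hist, y4, t + dt, tau, dt, i)
        k4 = _rhs(y4, dl, p, s)

        for g in range(5):
            v = yi[g] + dt / 6.0 * (k1[g] + 2.0 * k2[g] + 2.0 * k3[g] + k4[g])
            if v < 0.0:
                if v < -1e-8:
                    ok = False
                v = 0.0
            y[i + 1, g] = v
        if not ok:
            break
    return y, ok


# --------------------------------------------------------------------------
# Trajectory container
# --------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Uniform-grid time courses of model species (dimensionless units)."""

    time: np.ndarray
    values: np.ndarray              # shape (n_times, n_species)
    species: tuple
    dt: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.time.shape[0] != self.values.shape[0]:
            raise ValueError("time and values length mismatch")
        steps = np.diff(self.time)
        if steps.size and (np.any(steps <= 0)
                           or not np.allclose(steps, steps[0], rtol=1e-9)):
            raise ValueError("time grid must be strictly increasing and uniform")

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.species.index(name)]

    def after(self, t0: float) -> "Trajectory":
        i = int(np.searchsorted(self.time, t0 - 1e-9))
        return Trajectory(self.time[i:], self.values[i:], self.species,
                          self.dt, dict(self.meta))

    @property
    def transient(self) -> float:
        return float(self.meta.get("transient", 0.0))

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"time_h": self.time,
                             **{g: self.values[:, k]
                                for k, g in enumerate(self.species)}})

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.6g")

    @classmethod
    def read_tsv(cls, path) -> "Trajectory":
        import pandas as pd
        df = pd.read_csv(path, sep="\t")
        t = df["time_h"].to_numpy(float)
        species = tuple(c for c in df.columns if c != "time_h")
        dt = float(t[1] - t[0]) if len(t) > 1 else 0.0
        return cls(t, df[list(species)].to_numpy(float), species, dt)


# --------------------------------------------------------------------------
# Public simulation API
# --------------------------------------------------------------------------

def clock_rhs(state_now, delayed_states, params: ClockParameters) -> np.ndarray:
    """Time derivatives of the five mRNA species.

    ``delayed_states`` holds each regulator's level at ``t - tau`` of its
    gene, in :data:`GENES` order.
    """
    state = np.asarray(state_now, dtype=float)
    delayed = np.asarray(delayed_states, dtype=float)
    if state.shape != (5,) or delayed.shape != (5,):
        raise ValueError("state_now and delayed_states must be 5-vectors")
    return _rhs(state, delayed, params.to_vector(), params.site_vector())


def _history_vector(history) -> np.ndarray:
    if np.isscalar(history):
        return np.full(5, float(history))
    if isinstance(history, Mapping):
        return np.array([float(history[g]) for g in GENES])
    h = np.asarray(history, dtype=float)
    if h.shape != (5,):
        raise ValueError("history must be scalar, mapping or 5-vector")
    return h


def simulate_clock(params: ClockParameters, history=1.0,
                   t_end: float = 480.0, dt: float = 0.05,
                   transient: float = 240.0) -> Trajectory:
    """Integrate the clock DDE by the method of steps.

    ``history`` is the constant pre-``t=0`` state (scalar, mapping or
    5-vector).  The returned trajectory covers the full ``[0, t_end]``
    grid; the declared ``transient`` (discarded by the descriptor
    extraction) is recorded in its metadata.  ``dt`` must not exceed
    0.1 h, nor a quarter of the smallest positive delay so delayed
    look-ups never leave the computed past.
    """
    if dt <= 0 or dt > 0.1 + 1e-12:
        raise ValueError("dt must be in (0, 0.1] h")
    taus = [getattr(params, f"tau_{g}")
            for g in ("bmal1", "reverb", "per2", "cry1", "dbp")]
    pos = [t for t in taus if t > 0]
    if pos and dt > min(pos) / 4 + 1e-12:
        raise ValueError("dt must be <= min(positive delay)/4")
    if t_end <= transient:
        raise ValueError("t_end must exceed the transient length")

    hist = _history_vector(history)
    n_steps = int(round(t_end / dt))
    y, ok = _integrate(params.to_vector(), params.site_vector(),
                       hist, n_steps, dt)
    if not ok:
        raise IntegrationError(
            "negative concentrations beyond tolerance; reduce dt")
    t = np.arange(n_steps + 1) * dt
    meta = {"dt": dt, "transient": transient, "params": params.digest()}
    return Trajectory(t, y, GENES, dt, meta)


# --------------------------------------------------------------------------
# Rhythm descriptors
# --------------------------------------------------------------------------

@dataclass
class RhythmDescriptors:
    """Period, peak phase, relative amplitude and peak width per gene.

    Phases are circadian hours in ``[0, 24)``; the CT scale is anchored
    at the upward mean-crossing of Bmal1 preceding its peak, which is
    assigned :data:`CT_ANCHOR_OFFSET`.
    """

    period: float
    phases: dict
    relative_amplitudes: dict
    peak_widths: dict
    peak_times: dict
    oscillation_sustained: bool
    anchor_time: float = float("nan")
    ct_offset: float = CT_ANCHOR_OFFSET

    def ct(self, t):
        """Map simulation time (h) to circadian time (CT h in [0, 24))."""
        return ((np.asarray(t, float) - self.anchor_time) / self.period * 24.0
                + self.ct_offset) % 24.0

    def as_dict(self) -> dict:
        return {
            "period": self.period,
            "phases": dict(self.phases),
            "relative_amplitudes": dict(self.relative_amplitudes),
            "peak_widths": dict(self.peak_widths),
            "oscillation_sustained": self.oscillation_sustained,
            "anchor_time": self.anchor_time,
            "ct_offset": self.ct_offset,
        }


def _refine_peak(t: np.ndarray, x: np.ndarray, i: int):
    """Quadratic interpolation of a discrete maximum; earliest-tie wins."""
    if i <= 0 or i >= len(x) - 1:
        return t[i], x[i]
    denom = x[i - 1] - 2.0 * x[i] + x[i + 1]
    if denom >= 0:
        return t[i], x[i]
    delta = 0.5 * (x[i - 1] - x[i + 1]) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    dt = t[1] - t[0]
    tp = t[i] + delta * dt
    xp = x[i] - 0.25 * (x[i - 1] - x[i + 1]) * delta
    return tp, xp


def _gene_peaks(t: np.ndarray, x: np.ndarray, dt: float):
    rng = float(x.max() - x.min())
    if rng <= 1e-12 * max(1.0, abs(float(x.max()))):
        return np.array([]), np.array([])
    idx, _ = find_peaks(x, distance=max(2, int(6.0 / dt)),
                        prominence=0.05 * rng)
    times = []
    heights = []
    for i in idx:
        tp, xp = _refine_peak(t, x, i)
        times.append(tp)
        heights.append(xp)
    return np.array(times), np.array(heights)


def _not_oscillating() -> RhythmDescriptors:
    nangenes = {g: float("nan") for g in GENES}
    return RhythmDescriptors(float("nan"), dict(nangenes), dict(nangenes),
                             dict(nangenes), dict(nangenes), False)


def extract_rhythm_descriptors(traj: Trajectory,
                               transient: float | None = None
                               ) -> RhythmDescriptors:
    """Summarize the post-transient limit cycle of a clock trajectory.

    The period is the mean inter-peak interval of Bmal1; each gene's
    peak phase is its last refined peak mapped to CT through the Bmal1
    mean-crossing anchor.  Relative amplitude is (max-min)/(max+min)
    over the cycle around the peak and peak width is the contiguous time
    the signal stays above the half-range level.  Fewer than two Bmal1
    peaks yields a not-oscillating result (flag, not an exception).
    """
    if transient is None:
        transient = traj.transient
    tr = traj.after(transient)
    t = tr.time
    dt = tr.dt

    xb = tr.column("Bmal1")
    pk_t, pk_h = _gene_peaks(t, xb, dt)
    if len(pk_t) < 2:
        return _not_oscillating()
    period = float(np.mean(np.diff(pk_t)))
    if not (math.isfinite(period) and period > 0):
        return _not_oscillating()
    if t[-1] - t[0] < 3 * period:
        return _not_oscillating()

    # sustained: consecutive Bmal1 cycle amplitudes within 1%
    sustained = True
    troughs = []
    for a, b in zip(pk_t[:-1], pk_t[1:]):
        seg = xb[(t >= a) & (t <= b)]
        troughs.append(float(seg.min()))
    amps = pk_h[1:] - np.array(troughs)
    if len(amps) >= 2:
        ratios = amps[1:] / np.where(amps[:-1] == 0, np.nan, amps[:-1])
        if np.any(~np.isfinite(ratios)) or np.any(np.abs(ratios - 1) > 0.01):
            sustained = False

    # CT anchor: last upward mean-crossing of Bmal1 before its last peak
    last_peak = pk_t[-1]
    win = (t >= last_peak - period) & (t <= last_peak)
    mean_b = float(xb[win].mean())
    anchor = None
    upward = np.nonzero((xb[:-1] < mean_b) & (xb[1:] >= mean_b))[0]
    for i in reversed(upward):
        if t[i] <= last_peak:
            # linear interpolation of the crossing time
            frac = (mean_b - xb[i]) / (xb[i + 1] - xb[i])
            anchor = float(t[i] + frac * dt)
            break
    if anchor is None:
        return _not_oscillating()

    phases = {}
    relamps = {}
    widths = {}
    peak_times = {}
    for g in GENES:
        x = tr.column(g)
        gpk_t, gpk_h = _gene_peaks(t, x, dt)
        if len(gpk_t) == 0:
            phases[g] = float("nan")
            relamps[g] = float("nan")
            widths[g] = float("nan")
            peak_times[g] = float("nan")
            continue
        # last peak with a full cycle of data around it
        k = len(gpk_t) - 1
        while k >= 0 and gpk_t[k] + period / 2 > t[-1]:
            k -= 1
        if k < 0:
            k = len(gpk_t) - 1
        tp, xp = gpk_t[k], gpk_h[k]
        peak_times[g] = float(tp)
        phase = ((tp - anchor) / period * 24.0 + CT_ANCHOR_OFFSET) % 24.0
        phases[g] = float(phase)

        lo = max(t[0], tp - period / 2)
        hi = min(t[-1], tp + period / 2)
        wsel = (t >= lo) & (t <= hi)
        xmin = float(x[wsel].min())
        xmax = max(float(x[wsel].max()), xp)
        relamps[g] = ((xmax - xmin) / (xmax + xmin)
                      if xmax + xmin > 0 else float("nan"))

        thr = xmin + 0.5 * (xmax - xmin)
        ip = int(np.argmin(np.abs(t - tp)))
        left = ip
        while left > 0 and x[left - 1] >= thr and t[left - 1] >= tp - period:
            left -= 1
        right = ip
        nmax = len(x) - 1
        while right < nmax and x[right + 1] >= thr and t[right + 1] <= tp + period:
            right += 1
        # linear sub-grid refinement of the two threshold crossings
        tl = t[left]
        if left > 0 and x[left - 1] < thr:
            tl = t[left] - dt * (x[left] - thr) / (x[left] - x[left - 1])
        trgt = t[right]
        if right < nmax and x[right + 1] < thr:
            trgt = t[right] + dt * (x[right] - thr) / (x[right] - x[right + 1])
        widths[g] = float(min(trgt - tl, period))

    return RhythmDescriptors(period, phases, relamps, widths, peak_times,
                             sustained, anchor_time=anchor)
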