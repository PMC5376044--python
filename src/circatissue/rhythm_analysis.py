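"""Rhythm detection and phase statistics for expression time courses.

The workhorse is a biharmonic (24 h + 12 h) harmonic regression

    y(t) = m + a1 cos wt + b1 sin wt + a2 cos 2wt + b2 sin 2wt,

with ``w = 2*pi/24``, tested for rhythmicity by an F-test of the four
rhythm coefficients against the intercept-only model.  A probe counts
as rhythmic when it clears three strict filters: F-test p < 0.01,
relative amplitude > 0.3 and maximum expression above a platform cutoff
(600 for liver-like arrays, 500 for the adrenal set).  Peak phase is
the argmax of the full fitted curve so that 12 h-dominated profiles
still receive a meaningful peak; relative amplitude is the fitted
peak-to-trough range over twice the fitted mean.

The module also covers qPCR preprocessing (efficiency-weighted Cp
transformation, normalization by the geometric mean of three reference
genes) and circular phase histograms with overlapping bins (4 h bins
stepping every 1 h, so each phase lands in exactly four bins).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionDataset",
    "BiharmonicFit",
    "biharmonic_fit",
    "biharmonic_fit_matrix",
    "classify_rhythmic",
    "top_by_amplitude",
    "set_overlap",
    "circular_phase_histogram",
    "circular_mode",
    "normalize_qpcr",
]

_OMEGA = 2.0 * math.pi / 24.0


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------

@dataclass
class ExpressionDataset:
    """Probes x samples expression matrix on a linear scale.

    ``times`` holds the sampling time (h) of every column; replicate
    columns repeat the same time with distinct ``replicates`` labels.
    """

    probes: list
    times: np.ndarray
    values: np.ndarray
    replicates: list | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probes), len(self.times)):
            raise ValueError("values must be probes x samples")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        if self.replicates is None:
            self.replicates = [""] * len(self.times)

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    def max_expression(self) -> pd.Series:
        return pd.Series(self.values.max(axis=1), index=self.probes)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"t{t:g}{('_' + r) if r else ''}"
                for t, r in zip(self.times, self.replicates)]
        return pd.DataFrame(self.values, index=pd.Index(self.probes,
                                                        name="probe"),
                            columns=cols)

    def write_tsv(self, path) -> None:
        # header cells are t<time> with an optional _<replicate> suffix so
        # replicate columns stay distinguishable
        self.to_frame().to_csv(path, sep="\t", float_format="%.6g")

    @classmethod
    def read_tsv(cls, path) -> "ExpressionDataset":
        df = pd.read_csv(path, sep="\t", index_col=0)
        times, reps = [], []
        for c in df.columns:
            stem, _, rep = str(c).partition("_")
            times.append(float(stem.lstrip("t")))
            reps.append(rep)
        return cls(list(df.index), np.array(times), df.to_numpy(float),
                   replicates=reps)


@dataclass
class BiharmonicFit:
    """Result of the 24 h + 12 h harmonic regression for one probe."""

    mean: float
    a1: float
    b1: float
    a2: float
    b2: float
    amplitude24: float
    phase: float
    phase24: float
    relative_amplitude: float
    f_statistic: float
    p_value: float

    def fitted(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (self.mean + self.a1 * np.cos(_OMEGA * t)
                + self.b1 * np.sin(_OMEGA * t)
                + self.a2 * np.cos(2 * _OMEGA * t)
                + self.b2 * np.sin(2 * _OMEGA * t))


# --------------------------------------------------------------------------
# Harmonic regression
# --------------------------------------------------------------------------

def _design(times: np.ndarray, base_period: float) -> np.ndarray:
    w = 2.0 * math.pi / base_period
    return np.column_stack([np.ones_like(times),
                            np.cos(w * times), np.sin(w * times),
                            np.cos(2 * w * times), np.sin(2 * w * times)])

#: grid on which the fitted curve is maximized for phase/amplitude
_PHASE_GRID = np.arange(0.0, 24.0, 0.01)


def _fit_matrix(times: np.ndarray, values: np.ndarray,
                base_period: float) -> pd.DataFrame:
    times = np.asarray(times, dtype=float)
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = times.size
    if n <= 5:
        raise ValueError("biharmonic fit needs at least 6 samples")
    if np.allclose(times, times[0]):
        raise ValueError("sampling times must not all coincide")
    X = _design(times, base_period)
    coef, *_ = np.linalg.lstsq(X, values.T, rcond=None)
    resid = values.T - X @ coef
    rss = np.sum(resid ** 2, axis=0)
    tss = np.sum((values - values.mean(axis=1, keepdims=True)) ** 2, axis=1)
    df_num, df_den = 4, n - 5
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((tss - rss) / df_num) / (rss / df_den)
    f = np.where(rss <= 0, np.inf, f)
    p = stats.f.sf(f, df_num, df_den)
    p = np.where(np.isinf(f), 0.0, p)

    G = _design(_PHASE_GRID * base_period / 24.0, base_period)
    curves = G @ coef                       # grid x probes
    imax = np.argmax(curves, axis=0)        # earliest tie via argmax
    phase = _PHASE_GRID[imax]
    cmax = curves.max(axis=0)
    cmin = curves.min(axis=0)
    m = coef[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        relamp = np.where(m > 0, (cmax - cmin) / (2.0 * m), np.nan)
    amp24 = np.hypot(coef[1], coef[2])
    # peak time of the 24 h component alone (robust phase for
    # fundamental-dominated profiles)
    phase24 = (np.arctan2(coef[2], coef[1]) / (2 * math.pi) * 24.0) % 24.0
    return pd.DataFrame({
        "mean": m, "a1": coef[1], "b1": coef[2],
        "a2": coef[3], "b2": coef[4],
        "amplitude24": amp24, "phase": phase, "phase24": phase24,
        "relative_amplitude": relamp,
        "f_statistic": f, "p_value": p,
    })


def biharmonic_fit(times, values, base_period: float = 24.0) -> BiharmonicFit:
    """Least-squares 24 h + 12 h harmonic regression of one profile.

    The F-test compares the four rhythm coefficients against the
    intercept-only model (df 4, N-5).  Non-positive fitted means leave
    the relative amplitude undefined (NaN).
    """
    row = _fit_matrix(np.asarray(times, float),
                      np.asarray(values, float)[None, :],
                      base_period).iloc[0]
    return BiharmonicFit(*(float(row[c]) for c in (
        "mean", "a1", "b1", "a2", "b2", "amplitude24", "phase", "phase24",
        "relative_amplitude", "f_statistic", "p_value")))


def biharmonic_fit_matrix(dataset: ExpressionDataset,
                          base_period: float = 24.0) -> pd.DataFrame:
    """Vectorized biharmonic fits for every probe of a dataset."""
    df = _fit_matrix(dataset.times, dataset.values, base_period)
    df.index = pd.Index(dataset.probes, name="probe")
    df["max_expression"] = dataset.values.max(axis=1)
    return df


# --------------------------------------------------------------------------
# Filters, ranking, overlaps
# --------------------------------------------------------------------------

def classify_rhythmic(fits: pd.DataFrame,
                      expression_cutoff: float = 600.0,
                      p_cutoff: float = 0.01,
                      relamp_cutoff: float = 0.3) -> list:
    """Probes passing all three strict filters, in input order.

    Requires a fit table from :func:`biharmonic_fit_matrix` (columns
    ``p_value``, ``relative_amplitude``, ``max_expression``).  All
    cutoffs are strict inequalities: a probe at exactly the cutoff is
    excluded.
    """
    sel = ((fits["max_expression"] > expression_cutoff)
           & (fits["p_value"] < p_cutoff)
           & (fits["relative_amplitude"] > relamp_cutoff))
    return list(fits.index[sel.fillna(False)])


def top_by_amplitude(fits: pd.DataFrame, rhythmic: list, k: int = 500) -> list:
    """The ``k`` largest-amplitude rhythmic probes, deterministically.

    Sorted by relative amplitude descending; ties broken by probe
    identifier (lexicographic).  A set smaller than ``k`` is returned
    whole.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    sub = fits.loc[rhythmic]
    order = np.lexsort((np.asarray(sub.index.astype(str)),
                        -sub["relative_amplitude"].to_numpy()))
    return list(sub.index[order][:k])


def set_overlap(set_a, set_b) -> list:
    """Sorted identifier intersection of two probe sets (symmetric)."""
    return sorted(set(set_a) & set(set_b))


# --------------------------------------------------------------------------
# Circular phase statistics
# --------------------------------------------------------------------------

def circular_phase_histogram(phases,
                             bin_width: float = 4.0,
                             overlap: float = 3.0,
                             period: float = 24.0) -> pd.DataFrame:
    """Overlapping circular histogram of peak phases.

    Bin centers step by ``bin_width - overlap`` (default 1 h) around the
    clock face; each bin is the half-open interval
    ``[center - width/2, center + width/2)`` taken circularly, so with
    the defaults every phase is counted in exactly four bins and the
    total count is ``4 * n``.
    """
    if not 0 <= overlap < bin_width:
        raise ValueError("need 0 <= overlap < bin_width")
    phases = np.asarray(phases, dtype=float) % period
    step = bin_width - overlap
    n_bins = int(round(period / step))
    if abs(n_bins * step - period) > 1e-9:
        raise ValueError("bin step must divide the period")
    centers = np.arange(n_bins) * step
    counts = np.empty(n_bins, dtype=int)
    for i, c in enumerate(centers):
        rel = (phases - (c - bin_width / 2.0)) % period
        counts[i] = int(np.sum(rel < bin_width))
    return pd.DataFrame({"bin_center_CT": centers, "count": counts})


def circular_mode(phases, bin_width: float = 4.0, overlap: float = 3.0,
                  period: float = 24.0) -> float:
    """Center of the fullest overlapping bin (ties: earliest center)."""
    hist = circular_phase_histogram(phases, bin_width, overlap, period)
    i = int(hist["count"].to_numpy().argmax())
    return float(hist["bin_center_CT"].iloc[i])


# --------------------------------------------------------------------------
# qPCR normalization
# --------------------------------------------------------------------------

def normalize_qpcr(cp_table: pd.DataFrame,
                   efficiencies,
                   reference_genes,
                   rescale: str = "max") -> pd.DataFrame:
    """Reference-gene normalization of a genes x samples Cp table.

    Cp values become quantities ``efficiency**(-Cp)`` (efficiency is the
    per-cycle amplification factor, at most 2); every sample is then
    divided by the geometric mean of its three reference-gene
    quantities, and each gene is rescaled to its maximum (or mean)
    across samples.  Samples missing a reference gene are dropped with a
    warning.
    """
    if rescale not in ("max", "mean", "none"):
        raise ValueError("rescale must be 'max', 'mean' or 'none'")
    reference_genes = list(reference_genes)
    missing = [g for g in reference_genes if g not in cp_table.index]
    if missing:
        raise ValueError(f"reference genes absent from table: {missing}")
    eff = pd.Series(efficiencies, dtype=float)
    for g in cp_table.index:
        if g not in eff.index:
            raise ValueError(f"no efficiency for gene {g!r}")
        if not 0.0 < eff[g] <= 2.0:
            raise ValueError(
                f"efficiency for {g!r} must be in (0, 2], got {eff[g]}")

    bad = cp_table.loc[reference_genes].isna().any(axis=0)
    if bad.any():
        dropped = list(cp_table.columns[bad])
        warnings.warn(f"dropping samples missing a reference gene: {dropped}")
        cp_table = cp_table.loc[:, ~bad]

    quantities = eff.loc[cp_table.index].to_numpy()[:, None] \
        ** (-cp_table.to_numpy(float))
    q = pd.DataFrame(quantities, index=cp_table.index,
                     columns=cp_table.columns)
    norm_factor = np.exp(np.log(q.loc[reference_genes]).mean(axis=0))
    out = q.div(norm_factor, axis=1)
    if rescale == "max":
        out = out.div(out.max(axis=1), axis=0)
    elif rescale == "mean":
        out = out.div(out.mean(axis=1), axis=0)
    return out
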