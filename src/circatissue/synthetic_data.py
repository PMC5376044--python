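"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate the data shapes the analysis consumes:

* expression matrices shaped like 2 h-resolution circadian microarray
  series (24 h span, >= 4 replicates per time point) with a configurable
  rhythmic fraction, a bimodal von Mises peak-phase mixture, an optional
  12 h-harmonic subpopulation and multiplicative lognormal noise;
* qPCR Cp tables produced by inverting the efficiency transformation on
  known abundance profiles, with per-sample loading drift that the
  reference-gene normalization must remove;
* gene annotations plus ChIP-seq peak files in which planted target
  genes carry peaks whose scores clear the TFAS cutoff at their
  (exponentially distributed) peak-to-gene distances.

All generators are deterministic for a fixed seed, and each returns the
ground truth needed to score the downstream stage without external
resources.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rhythm_analysis import ExpressionDataset

__all__ = [
    "SyntheticSpec",
    "generate_expression_matrix",
    "generate_qpcr_dataset",
    "generate_annotation_and_peaks",
    "write_peaks_bed",
    "write_annotation_bed",
]


@dataclass
class SyntheticSpec:
    """Design of a synthetic circadian expression matrix.

    The defaults mirror a liver-like circadian profiling design:
    samples every 2 h over 24 h with 4 replicates per time point,
    multiplicative lognormal noise of 10% CV, a bimodal phase mixture
    with von Mises components near CT 0 and CT 10, and roughly 1% of
    rhythmic probes carrying a dominant 12 h harmonic.
    """

    seed: int = 0
    n_probes: int = 1000
    rhythmic_fraction: float = 0.3
    phase_modes: tuple = ((0.0, 2.0), (10.0, 2.0))   # (CT mean, concentration)
    phase_weights: tuple = (0.5, 0.5)
    uniform_phases: bool = False
    relamp_range: tuple = (0.3, 0.8)
    harmonic_fraction: float = 0.01
    noise_cv: float = 0.10
    baseline_log_mean: float = math.log(1500.0)
    baseline_log_sd: float = 1.0
    start: float = 0.0
    step: float = 2.0
    span: float = 24.0
    replicates: int = 4

    def __post_init__(self):
        for frac in (self.rhythmic_fraction, self.harmonic_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.replicates < 1 or self.step <= 0 or self.span <= 0:
            raise ValueError("invalid sampling design")
        if abs((self.span / self.step) - round(self.span / self.step)) > 1e-9:
            raise ValueError("step must divide span")

    def sample_times(self) -> np.ndarray:
        base = np.arange(self.start, self.start + self.span, self.step)
        return np.repeat(base, self.replicates)

    def replicate_labels(self) -> list:
        n_t = int(round(self.span / self.step))
        return [f"r{k + 1}" for _ in range(n_t)
                for k in range(self.replicates)]


def _sample_phases(spec: SyntheticSpec, n: int,
                   rng: np.random.Generator) -> np.ndarray:
    if spec.uniform_phases or n == 0:
        return rng.uniform(0.0, 24.0, size=n)
    comp = rng.choice(len(spec.phase_modes), size=n,
                      p=np.asarray(spec.phase_weights, float)
                      / np.sum(spec.phase_weights))
    phases = np.empty(n)
    for i, c in enumerate(comp):
        mu_ct, kappa = spec.phase_modes[c]
        ang = rng.vonmises(mu_ct / 24.0 * 2 * math.pi, kappa)
        phases[i] = (ang / (2 * math.pi) * 24.0) % 24.0
    return phases


def generate_expression_matrix(spec: SyntheticSpec):
    """Expression matrix plus per-probe ground truth.

    Rhythmic probes follow ``baseline * (1 + relamp*cos(w(t-phi)) [+
    harmonic])`` with lognormal multiplicative noise; the remainder are
    noisy constants.  Harmonic probes replace half of the fundamental
    with a 12 h cosine peaking at the same phase.  Returns
    ``(ExpressionDataset, ground_truth DataFrame)``.
    """
    rng = np.random.default_rng(spec.seed)
    times = spec.sample_times()
    n = spec.n_probes
    probes = [f"probe_{i:05d}" for i in range(n)]

    n_rhythmic = int(round(spec.rhythmic_fraction * n))
    rhythmic = np.zeros(n, dtype=bool)
    rhythmic[rng.choice(n, size=n_rhythmic, replace=False)] = True
    phases = np.full(n, np.nan)
    phases[rhythmic] = _sample_phases(spec, n_rhythmic, rng)
    relamps = np.full(n, np.nan)
    relamps[rhythmic] = rng.uniform(*spec.relamp_range, size=n_rhythmic)
    harmonic = np.zeros(n, dtype=bool)
    idx_r = np.nonzero(rhythmic)[0]
    n_harm = int(round(spec.harmonic_fraction * n_rhythmic))
    if n_harm:
        harmonic[rng.choice(idx_r, size=n_harm, replace=False)] = True

    baseline = np.exp(rng.normal(spec.baseline_log_mean,
                                 spec.baseline_log_sd, size=n))
    w = 2 * math.pi / 24.0
    signal = np.ones((n, times.size))
    tt = times[None, :]
    ph = phases[:, None]
    ra = relamps[:, None]
    fundamental = np.where(harmonic[:, None], 0.5, 1.0)
    rows = rhythmic[:, None]
    signal = np.where(
        rows,
        1.0 + np.nan_to_num(ra) * (
            fundamental * np.cos(w * (tt - np.nan_to_num(ph)))
            + np.where(harmonic[:, None],
                       0.5 * np.cos(2 * w * (tt - np.nan_to_num(ph))), 0.0)),
        1.0)
    values = baseline[:, None] * signal
    if spec.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + spec.noise_cv ** 2))
        values = values * rng.lognormal(-0.5 * sigma ** 2, sigma,
                                        size=values.shape)
    values = np.clip(values, 0.0, None)

    dataset = ExpressionDataset(probes, times, values,
                                spec.replicate_labels())
    truth = pd.DataFrame({
        "probe": probes,
        "rhythmic": rhythmic,
        "phase": phases,
        "relative_amplitude": relamps,
        "harmonic": harmonic,
        "baseline": baseline,
    }).set_index("probe")
    return dataset, truth


def generate_qpcr_dataset(true_profiles: pd.DataFrame,
                          efficiencies,
                          reference_genes,
                          reference_drift=None,
                          noise_sd_cycles: float = 0.0,
                          seed: int = 0) -> pd.DataFrame:
    """Cp table realizing known abundances (inverse of normalization).

    ``true_profiles`` is genes x samples relative quantities; reference
    genes are appended with constant unit abundance.  Every quantity is
    multiplied by the per-sample ``reference_drift`` factor (loading /
    efficiency drift, default none) before conversion to cycles:
    ``Cp = -log_eff(quantity * drift) + noise``.
    """
    rng = np.random.default_rng(seed)
    reference_genes = list(reference_genes)
    eff = pd.Series(efficiencies, dtype=float)
    samples = true_profiles.columns
    profiles = true_profiles.copy()
    for g in reference_genes:
        if g not in profiles.index:
            profiles.loc[g] = 1.0
    if reference_drift is None:
        drift = np.ones(len(samples))
    else:
        drift = np.asarray(reference_drift, dtype=float)
        if drift.shape != (len(samples),):
            raise ValueError("reference_drift must have one entry per sample")
    q = profiles.to_numpy(float) * drift[None, :]
    if np.any(q <= 0):
        raise ValueError("true profiles must be strictly positive")
    log_eff = np.log(eff.loc[profiles.index].to_numpy(float))[:, None]
    cp = -np.log(q) / log_eff
    if noise_sd_cycles > 0:
        cp = cp + rng.normal(0.0, noise_sd_cycles, size=cp.shape)
    return pd.DataFrame(cp, index=profiles.index, columns=samples)


def generate_annotation_and_peaks(n_genes: int = 200,
                                  n_a_only: int = 20,
                                  n_b_only: int = 20,
                                  n_both: int = 10,
                                  chrom: str = "chr1",
                                  gene_spacing: int = 20000,
                                  distance_mean: float = 1000.0,
                                  max_distance: float = 5000.0,
                                  cutoff_a: float = 10.0,
                                  cutoff_b: float = 0.5,
                                  decoy_fraction: float = 0.1,
                                  seed: int = 0):
    """Annotation plus two factor peak sets with planted target genes.

    Genes sit every ``gene_spacing`` bp on one chromosome (spacing must
    exceed twice the association distance so planted peaks are
    unambiguous).  Planted targets of a factor receive one or two peaks
    at exponential(``distance_mean``) distances (truncated below
    ``max_distance``) whose scores guarantee the TFAS cutoff is cleared
    even for a single peak; a ``decoy_fraction`` of non-targets gets a
    sub-cutoff decoy peak near the distance limit.  Returns ``(genes,
    peaks_a, peaks_b, truth)`` DataFrames.
    """
    if gene_spacing <= 2 * max_distance:
        raise ValueError("gene_spacing must exceed 2*max_distance")
    if n_a_only + n_b_only + n_both > n_genes:
        raise ValueError("chromosome too short for the requested genes")
    rng = np.random.default_rng(seed)
    gene_ids = [f"gene_{i:04d}" for i in range(n_genes)]
    positions = gene_spacing * (1 + np.arange(n_genes))
    strands = rng.choice(["+", "-"], size=n_genes)
    genes = pd.DataFrame({"gene": gene_ids, "chrom": chrom,
                          "strand": strands, "start_codon": positions})

    members = rng.permutation(n_genes)
    both_set = set(members[n_a_only:n_a_only + n_both])
    a_set = set(members[:n_a_only]) | both_set
    b_set = both_set | set(
        members[n_a_only + n_both:n_a_only + n_both + n_b_only])

    def _plant(target_idx: set, cutoff: float) -> pd.DataFrame:
        rows = []
        k = 0
        for gi in sorted(target_idx):
            for _ in range(int(rng.integers(1, 3))):
                d = float(rng.exponential(distance_mean))
                while d >= max_distance:
                    d = float(rng.exponential(distance_mean))
                side = -1 if rng.random() < 0.5 else 1
                center = positions[gi] + side * d
                # score high enough that this single peak clears the cutoff
                score = 2.0 * cutoff * math.exp(d / 500.0) \
                    * float(rng.uniform(1.0, 2.0))
                half = 150
                rows.append((chrom, int(center - half), int(center + half),
                             f"peak_{k:05d}", score))
                k += 1
        # sub-cutoff decoys near non-target genes
        non_targets = [i for i in range(n_genes) if i not in target_idx]
        n_decoy = int(round(decoy_fraction * len(non_targets)))
        for gi in rng.choice(non_targets, size=n_decoy, replace=False):
            d = float(rng.uniform(0.8 * max_distance, 0.98 * max_distance))
            side = -1 if rng.random() < 0.5 else 1
            center = positions[gi] + side * d
            score = 0.5 * cutoff * math.exp(-d / 500.0)  # far below cutoff
            half = 150
            rows.append((chrom, int(center - half), int(center + half),
                         f"decoy_{k:05d}", score))
            k += 1
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                         "score"])
        df["center"] = (df["start"] + df["end"]) / 2.0
        return df

    peaks_a = _plant(a_set, cutoff_a)
    peaks_b = _plant(b_set, cutoff_b)
    truth = pd.DataFrame({
        "gene": gene_ids,
        "a_target": [i in a_set for i in range(n_genes)],
        "b_target": [i in b_set for i in range(n_genes)],
    }).set_index("gene")
    return genes, peaks_a, peaks_b, truth


# --------------------------------------------------------------------------
# File writers (round-trip with the tfas readers)
# --------------------------------------------------------------------------

def write_peaks_bed(peaks: pd.DataFrame, path) -> None:
    peaks[["chrom", "start", "end", "name", "score"]].to_csv(
        path, sep="\t", header=False, index=False)


def write_annotation_bed(genes: pd.DataFrame, path) -> None:
    df = pd.DataFrame({
        "chrom": genes["chrom"],
        "start": genes["start_codon"].astype(int),
        "end": genes["start_codon"].astype(int) + 1,
        "gene": genes["gene"],
        "score": 0,
        "strand": genes["strand"],
    })
    df.to_csv(path, sep="\t", header=False, index=False)
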