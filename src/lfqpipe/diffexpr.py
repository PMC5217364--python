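"""Mode normalization, expression ratios, and Monte Carlo significance.

Normalization divides each replicate's protein intensities by that
replicate's mode — the most commonly occurring intensity, located by a
log10 histogram — which is insensitive to the extreme minimum and maximum
intensities that vary strongly between replicates.  The between-condition
ratio of a protein is the mean normalized intensity of condition A over
condition B.  Its significance is assessed by resampling: each iteration
draws one uniform random intensity per replicate between the minimum
noise level and maximum observed intensity, recomputes the ratio, and
records whether it falls above or below the experimental one; the
two-sided p-value follows from those counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quant import IntensityMatrix

_MC_CHUNK = 100_000


@dataclass
class NormalizationReport:
    mode_value: dict[str, float]   # replicate -> mode on the raw scale
    bin_width: float               # log10 units
    normalized: IntensityMatrix


@dataclass
class DifferentialResult:
    accession: str
    ratio: float                   # condition A over condition B, normalized
    count_above: int
    count_below: int
    n_iterations: int
    p_value: float
    significant: bool
    seed: int


def replicate_mode(intensities, bin_width: float = 0.1) -> float:
    """Most commonly occurring intensity of one replicate.

    Intensities are histogrammed on a log10 grid of the given bin width
    anchored at 0; the mode is 10**(center of the most populated bin),
    ties broken toward the lower bin.
    """
    values = np.asarray(intensities, dtype=float)
    if values.size == 0:
        raise ValueError("empty intensity vector")
    if np.any(values <= 0):
        raise ValueError("all intensities must be > 0 for log-binning")
    idx = np.floor(np.log10(values) / bin_width).astype(np.int64)
    uniq, counts = np.unique(idx, return_counts=True)
    best = uniq[counts == counts.max()].min()
    return float(10.0 ** ((best + 0.5) * bin_width))


def normalize(matrix: IntensityMatrix, bin_width: float = 0.1) -> NormalizationReport:
    """Divide each replicate column by that replicate's own mode."""
    if (matrix.intensity.values <= 0).any():
        raise ValueError("intensity matrix must be strictly positive (impute first)")
    modes = {r: replicate_mode(matrix.intensity[r].values, bin_width) for r in matrix.replicates}
    if any(m == 0 for m in modes.values()):
        raise ValueError("zero mode")
    normed = matrix.intensity / pd.Series(modes)
    return NormalizationReport(
        mode_value=modes,
        bin_width=bin_width,
        normalized=IntensityMatrix(
            intensity=normed,
            imputed=matrix.imputed.copy(),
            noise_level=matrix.noise_level / pd.Series(modes),
            conditions=dict(matrix.conditions),
        ),
    )


def expression_ratio(row: pd.Series, replicates_a, replicates_b) -> float:
    """mean(normalized A) / mean(normalized B)."""
    a = np.asarray([row[r] for r in replicates_a], dtype=float)
    b = np.asarray([row[r] for r in replicates_b], dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("each condition needs at least one replicate")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("normalized intensities must be positive")
    return float(a.mean() / b.mean())


def monte_carlo_p(
    accession: str,
    ratio: float,
    n_a: int,
    n_b: int,
    noise_min: float,
    intensity_max: float,
    n_iterations: int = 1_000_000,
    seed: int = 0,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> DifferentialResult:
    """Resampling significance of an observed between-condition ratio.

    Each iteration draws one uniform intensity in
    ``[noise_min, intensity_max]`` for every replicate, forms the random
    A/B ratio of means, and counts whether it lies strictly above or below
    the experimental ratio (ties count as neither).  The two-sided p-value
    is ``min(1, 2 * (min(above, below) + 1) / (n_iterations + 1))``; the
    +1 guard keeps p strictly positive.  Deterministic given the seed.
    """
    if noise_min <= 0:
        raise ValueError("noise_min must be > 0")
    if intensity_max < noise_min:
        raise ValueError("intensity_max must be >= noise_min")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    above = below = 0
    remaining = n_iterations
    while remaining > 0:
        m = min(remaining, _MC_CHUNK)
        draws = rng.uniform(noise_min, intensity_max, size=(m, n_a + n_b))
        rand_ratio = draws[:, :n_a].mean(axis=1) / draws[:, n_a:].mean(axis=1)
        above += int((rand_ratio > ratio).sum())
        below += int((rand_ratio < ratio).sum())
        remaining -= m
    p = min(1.0, 2.0 * (min(above, below) + 1) / (n_iterations + 1))
    return DifferentialResult(
        accession=accession,
        ratio=ratio,
        count_above=above,
        count_below=below,
        n_iterations=n_iterations,
        p_value=p,
        significant=p <= alpha,
        seed=seed,
    )


def run_differential(
    matrix: IntensityMatrix,
    condition_a: str,
    condition_b: str,
    n_iterations: int = 1_000_000,
    seed: int = 0,
    alpha: float = 0.05,
    bin_width: float = 0.1,
    bounds: str = "per-protein",
) -> tuple[list[DifferentialResult], NormalizationReport]:
    """Normalize, then test every protein of the matrix A vs B.

    ``bounds='per-protein'`` draws random intensities between that
    protein's minimum replicate noise level and maximum observed cell;
    ``'global'`` uses the bounds of the whole normalized matrix.  One
    random stream per run (seeded) serves all proteins in matrix order.
    """
    report = normalize(matrix, bin_width)
    normed = report.normalized
    reps_a = normed.replicates_for(condition_a)
    reps_b = normed.replicates_for(condition_b)
    if not reps_a or not reps_b:
        raise ValueError(f"no replicates for condition {condition_a!r} or {condition_b!r}")
    reps = reps_a + reps_b
    noise = normed.noise_level[reps]
    if bounds not in ("per-protein", "global"):
        raise ValueError(f"unknown bounds mode: {bounds!r}")
    global_lo = float(noise.min())
    global_hi = float(normed.intensity[reps].values.max())
    rng = np.random.default_rng(seed)
    results = []
    for acc in normed.proteins:
        row = normed.intensity.loc[acc]
        ratio = expression_ratio(row, reps_a, reps_b)
        if bounds == "per-protein":
            lo = global_lo
            hi = float(row[reps].max())
        else:
            lo, hi = global_lo, global_hi
        results.append(
            monte_carlo_p(
                acc, ratio, len(reps_a), len(reps_b), lo, max(hi, lo),
                n_iterations=n_iterations, seed=seed, alpha=alpha, rng=rng,
            )
        )
    return results, report


def call_differential(results, alpha: float = 0.05):
    """Partition results into (up in A, down in A, unchanged).

    Significant means p <= alpha (inclusive); direction comes from the
    ratio relative to 1.  A ratio of exactly 1 cannot be directional and
    is classified unchanged with a warning even if nominally significant.
    """
    up, down, unchanged = [], [], []
    for res in results:
        if res.p_value <= alpha and res.ratio > 1:
            up.append(res)
        elif res.p_value <= alpha and res.ratio < 1:
            down.append(res)
        else:
            if res.p_value <= alpha and res.ratio == 1:
                warnings.warn(f"{res.accession}: significant p with ratio exactly 1; kept unchanged")
            unchanged.append(res)
    return up, down, unchanged


def results_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "accession": [r.accession for r in results],
            "ratio": [r.ratio for r in results],
            "count_above": [r.count_above for r in results],
            "count_below": [r.count_below for r in results],
            "n_iterations": [r.n_iterations for r in results],
            "p_value": [r.p_value for r in results],
            "significant": [r.significant for r in results],
            "direction": [
                "up" if (r.significant and r.ratio > 1)
                else "down" if (r.significant and r.ratio < 1)
                else "unchanged"
                for r in results
            ],
        }
    )
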