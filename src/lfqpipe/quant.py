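"""MS1 elution-profile quantification (extracted ion chromatograms).

For every retained peptide-spectrum match the ion current at its precursor
m/z (within a narrow channel, default total width 1 Da) is summed scan by
scan, walking outward in both directions from the identification's scan
until the chromatogram noise level or a maximum extent (default 250 scans)
is reached — effectively integrating the elution profile.  PSM traces with
the same precursor m/z are integrated once; per-protein, per-replicate
areas are summed into an intensity matrix, with the replicate's noise
level substituted for proteins absent from a replicate so downstream
ratios never divide by zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .identifications import PeptideSpectrumMatch, ProteinIdentification
from .ms1io import MS1Run


@dataclass
class ElutionTrace:
    """One integrated m/z channel around an identification's scan."""

    precursor_mz: float
    channel_halfwidth: float
    start_scan: int
    low_scan: int
    high_scan: int
    area: float
    stopped_by: tuple[str, str]    # (backward, forward): noise | extent-limit | chromatogram-edge


@dataclass
class IntensityMatrix:
    """Protein x replicate integrated intensities with imputation mask."""

    intensity: pd.DataFrame        # index accessions, columns replicate_ids
    imputed: pd.DataFrame          # same shape, bool
    noise_level: pd.Series         # per replicate
    conditions: dict[str, str]     # replicate_id -> condition_id

    @property
    def proteins(self) -> list[str]:
        return list(self.intensity.index)

    @property
    def replicates(self) -> list[str]:
        return list(self.intensity.columns)

    def replicates_for(self, condition_id: str) -> list[str]:
        return [r for r in self.replicates if self.conditions[r] == condition_id]

    def to_tsv(self, intensity_path, mask_path=None) -> None:
        self.intensity.to_csv(intensity_path, sep="\t", index_label="accession")
        if mask_path is not None:
            self.imputed.to_csv(mask_path, sep="\t", index_label="accession")

    @classmethod
    def from_tsv(cls, intensity_path, mask_path, noise_level, conditions) -> "IntensityMatrix":
        intensity = pd.read_csv(intensity_path, sep="\t", index_col="accession")
        imputed = pd.read_csv(mask_path, sep="\t", index_col="accession").astype(bool)
        return cls(intensity, imputed, pd.Series(noise_level), dict(conditions))


def estimate_noise(run: MS1Run, quantile: float = 0.05) -> float:
    """Noise level of a chromatogram: a low quantile of its nonzero peak
    intensities (linear-interpolation percentile convention).

    One scalar per replicate serves trace termination, missing-value
    substitution and the Monte Carlo lower bound.  An all-zero run yields
    0 with a warning.
    """
    if run.scans:
        allint = np.concatenate([s.intensity for s in run.scans]) if run.scans else np.array([])
    else:
        allint = np.array([])
    nonzero = allint[allint > 0] if allint.size else allint
    if nonzero.size == 0:
        warnings.warn(f"run {run.replicate_id!r} has no nonzero intensities; noise = 0")
        return 0.0
    return float(np.percentile(nonzero, 100.0 * quantile))


def _channel_intensity(scan, precursor_mz: float, halfwidth: float) -> float:
    mask = np.abs(scan.mz - precursor_mz) <= halfwidth
    return float(scan.intensity[mask].sum())


def extract_trace(
    run: MS1Run,
    precursor_mz: float,
    start_scan: int,
    noise: float,
    halfwidth: float = 0.5,
    max_extent: int = 250,
) -> ElutionTrace:
    """Integrate one m/z channel outward from ``start_scan``.

    The channel intensity of a scan is the sum of its peaks within
    ``halfwidth`` Th of ``precursor_mz``.  Walking backward and forward,
    each scan with channel intensity strictly above ``noise`` is included;
    the walk stops (exclusively) at the first scan at or below the noise,
    after ``max_extent`` scans, or at the chromatogram edge.  The start
    scan is always included.
    """
    idx = run.scan_index(start_scan)
    n = len(run.scans)
    included = [idx]
    stopped = {}
    for label, step in (("backward", -1), ("forward", +1)):
        j = idx
        dist = 0
        while True:
            j += step
            dist += 1
            if j < 0 or j >= n:
                stopped[label] = "chromatogram-edge"
                break
            if dist > max_extent:
                stopped[label] = "extent-limit"
                break
            if _channel_intensity(run.scans[j], precursor_mz, halfwidth) <= noise:
                stopped[label] = "noise"
                break
            included.append(j)
    area = sum(_channel_intensity(run.scans[j], precursor_mz, halfwidth) for j in included)
    lows = min(included)
    highs = max(included)
    return ElutionTrace(
        precursor_mz=precursor_mz,
        channel_halfwidth=halfwidth,
        start_scan=start_scan,
        low_scan=run.scans[lows].number,
        high_scan=run.scans[highs].number,
        area=area,
        stopped_by=(stopped["backward"], stopped["forward"]),
    )


def dedupe_psms_by_mz(psms, tolerance: float = 0.01) -> list:
    """Collapse PSMs sharing a precursor m/z so an integral is counted once.

    Classes are formed greedily on ascending m/z by chaining: a PSM joins
    the open class while within ``tolerance`` of the previous m/z, so each
    class is a maximal run of tolerance-linked values.  The earliest-scan
    PSM of each class is kept (scan ties broken by lower m/z).  Chaining
    keeps representatives of distinct classes more than ``tolerance``
    apart, which makes the operation idempotent.
    """
    if not psms:
        return []
    by_mz = sorted(psms, key=lambda p: (p.precursor_mz, p.scan_number))
    classes: list[list] = [[by_mz[0]]]
    prev = by_mz[0].precursor_mz
    for p in by_mz[1:]:
        if p.precursor_mz - prev <= tolerance:
            classes[-1].append(p)
        else:
            classes.append([p])
        prev = p.precursor_mz
    return [min(cls, key=lambda p: (p.scan_number, p.precursor_mz)) for cls in classes]


def quantify_proteins(
    runs: dict[str, MS1Run],
    proteins: list[ProteinIdentification],
    conditions: dict[str, str],
    noise_levels: dict[str, float] | None = None,
    halfwidth: float = 0.5,
    max_extent: int = 250,
    dedupe_tolerance: float = 0.01,
    noise_quantile: float = 0.05,
) -> IntensityMatrix:
    """Build the protein x replicate intensity matrix.

    Per replicate and protein: deduplicate that replicate's PSMs by
    precursor m/z, integrate one elution trace per retained PSM starting at
    its scan, and sum the areas.  A protein with no PSMs in a replicate —
    or whose summed area is zero — receives the replicate's noise level
    and is flagged imputed, so every cell is strictly positive whenever
    the noise level is.
    """
    replicate_ids = list(runs)
    if noise_levels is None:
        noise_levels = {r: estimate_noise(runs[r], noise_quantile) for r in replicate_ids}
    accs = [p.accession for p in proteins]
    intensity = pd.DataFrame(0.0, index=accs, columns=replicate_ids)
    imputed = pd.DataFrame(False, index=accs, columns=replicate_ids)
    for prot in proteins:
        by_rep: dict[str, list[PeptideSpectrumMatch]] = {}
        for psm in prot.psms:
            by_rep.setdefault(psm.replicate_id, []).append(psm)
        for rep in replicate_ids:
            rep_psms = dedupe_psms_by_mz(by_rep.get(rep, []), dedupe_tolerance)
            if not rep_psms:
                intensity.loc[prot.accession, rep] = noise_levels[rep]
                imputed.loc[prot.accession, rep] = True
                continue
            total = 0.0
            for psm in rep_psms:
                trace = extract_trace(
                    runs[rep], psm.precursor_mz, psm.scan_number,
                    noise_levels[rep], halfwidth, max_extent,
                )
                total += trace.area
            if total <= 0:
                intensity.loc[prot.accession, rep] = noise_levels[rep]
                imputed.loc[prot.accession, rep] = True
            else:
                intensity.loc[prot.accession, rep] = total
    return IntensityMatrix(
        intensity=intensity,
        imputed=imputed,
        noise_level=pd.Series(noise_levels),
        conditions=dict(conditions),
    )
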