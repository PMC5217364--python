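"""Ground-truth synthetic data: protein database, MS1 runs, PSM tables.

The generator emulates a multi-replicate, two-condition label-free
experiment: random protein sequences (with shuffled decoy copies and
cross-species duplicate entries), tryptic peptides with computed precursor
m/z, Gaussian elution peaks riding on a uniform-positive noise floor, and
E-value distributions in which target PSMs overwhelmingly pass — and decoy
PSMs overwhelmingly fail — the downstream 0.05 filter.  All randomness
flows from one top-level seed; an identical seed reproduces byte-identical
files.

Defaults model the study conditions the pipeline assumes: 3 replicates per
condition, 10% replicate coefficient of variation, detected peptide apexes
at least ~50x the chromatogram noise level.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from pyteomics import mass as _mass
from pyteomics import parser as _parser

from .identifications import DECOY_PREFIX, write_psm_table, PeptideSpectrumMatch
from .ms1io import MS1Run, Scan, write_ms1

AA20 = "ACDEFGHIKLMNPQRSTVWY"

SPECIES_MIX_DEFAULT = {
    "Gossypium hirsutum": 0.5,
    "Gossypium arboreum": 0.3,
    "Gossypium raimondii": 0.2,
}

# apex ion counts per unit abundance; with the default uniform(50, 150)
# noise floor this puts a unit-abundance peptide apex ~200x the floor
RESPONSE_FACTOR = 20_000.0
DETECTION_THRESHOLD = 5_000.0    # ~50x the mean noise floor


@dataclass
class SyntheticPeptide:
    sequence: str
    charge: int
    mz: float
    apex_scan: int = 0
    width_scans: float = 4.0
    apex_intensity: dict[str, float] = field(default_factory=dict)  # replicate -> apex


@dataclass
class SyntheticProtein:
    accession: str
    species: str
    sequence: str
    is_decoy: bool = False
    duplicate_of: str | None = None
    abundance: dict[str, float] = field(default_factory=dict)       # condition -> abundance
    fold_change: float = 1.0                                        # condition A over B
    peptides: list[SyntheticPeptide] = field(default_factory=list)


@dataclass
class SyntheticTruth:
    seed: int
    proteins: list[SyntheticProtein] = field(default_factory=list)
    replicates: dict[str, str] = field(default_factory=dict)        # replicate -> condition
    conditions: tuple[str, str] = ("A", "B")
    n_scans: int = 600
    noise_low: float = 50.0
    noise_high: float = 150.0
    noise_density: float = 0.5     # fraction of scans carrying a floor peak per channel
    cv: float = 0.10
    response_factor: float = RESPONSE_FACTOR
    detection_threshold: float = DETECTION_THRESHOLD

    def targets(self) -> list[SyntheticProtein]:
        return [p for p in self.proteins if not p.is_decoy]

    def decoys(self) -> list[SyntheticProtein]:
        return [p for p in self.proteins if p.is_decoy]


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), stream])


def digest(
    sequence: str,
    missed_cleavages: int = 2,
    min_length: int = 6,
    max_length: int = 30,
) -> list[str]:
    """Tryptic peptides: cleave after K or R (no proline exception), all
    fragments with up to ``missed_cleavages`` internal sites, length-filtered."""
    if not sequence:
        raise ValueError("sequence must be nonempty")
    peps = _parser.cleave(sequence, r"[KR]", missed_cleavages=missed_cleavages)
    return sorted(p for p in peps if min_length <= len(p) <= max_length)


def peptide_mz(peptide: str, charge: int) -> float:
    """Monoisotopic (M + z*H)/z for the bare peptide."""
    return float(_mass.fast_mass(peptide, charge=charge))


def generate_database(
    n_proteins: int,
    length_range: tuple[int, int] = (150, 300),
    species_mix: dict[str, float] | None = None,
    decoy_fraction: float = 0.0,
    duplicate_pairs: int = 0,
    seed: int = 0,
) -> tuple[str, SyntheticTruth]:
    """Random protein database with shuffled decoys and duplicate entries.

    Of ``n_proteins`` entries, ``round(n * decoy_fraction)`` are decoys —
    residue-shuffled copies of targets, accession-prefixed ``DECOY_`` and
    flagged in the truth record.  ``duplicate_pairs`` extra entries copy a
    target's sequence under a new accession and an independently drawn
    species, to exercise identical-evidence grouping.  Returns the FASTA
    text and the truth skeleton (no abundances yet).
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    if not 0.0 <= decoy_fraction <= 1.0:
        raise ValueError("decoy_fraction must be in [0, 1]")
    species_mix = species_mix or SPECIES_MIX_DEFAULT
    names = list(species_mix)
    probs = np.array([species_mix[s] for s in names], dtype=float)
    probs = probs / probs.sum()
    rng = _rng(seed, 0)

    n_decoy = int(round(n_proteins * decoy_fraction))
    n_target = n_proteins - n_decoy
    truth = SyntheticTruth(seed=int(seed) % (2**31))
    for i in range(n_target):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(rng.choice(list(AA20), size=length))
        species = names[int(rng.choice(len(names), p=probs))]
        truth.proteins.append(
            SyntheticProtein(accession=f"G{i:04d}", species=species, sequence=seq)
        )
    for j in range(n_decoy):
        src = truth.proteins[j % n_target]
        shuffled = "".join(rng.permutation(list(src.sequence)))
        truth.proteins.append(
            SyntheticProtein(
                accession=f"{DECOY_PREFIX}{src.accession}",
                species=src.species,
                sequence=shuffled,
                is_decoy=True,
            )
        )
    targets = truth.targets()
    for k in range(min(duplicate_pairs, n_target)):
        src = targets[k]
        species = names[int(rng.choice(len(names), p=probs))]
        truth.proteins.append(
            SyntheticProtein(
                accession=f"{src.accession}D",
                species=species,
                sequence=src.sequence,
                duplicate_of=src.accession,
            )
        )
    fasta = "".join(
        f">{p.accession} synthetic protein OS={p.species}\n{p.sequence}\n"
        for p in truth.proteins
    )
    return fasta, truth


def plan_experiment(
    truth: SyntheticTruth,
    n_replicates: int = 3,
    conditions: tuple[str, str] = ("A", "B"),
    fold_changes: dict[str, float] | float | None = None,
    base_abundance: float = 1.0,
    abundance_sigma_log10: float = 0.0,
    max_peptides_per_protein: int = 5,
) -> SyntheticTruth:
    """Assign condition abundances and elution-peak parameters.

    ``fold_changes`` maps accession to condition-A/condition-B ratio (a
    scalar applies to every target; default 1, the null).  Abundances are
    lognormal around ``base_abundance`` (condition B), with the A
    abundance scaled by the fold change.  Each target receives up to
    ``max_peptides_per_protein`` tryptic peptides with a random charge
    (2 or 3), Gaussian width 3-6 scans, apex away from the chromatogram
    edges, and per-replicate lognormal apex variation at the stated CV.
    """
    rng = _rng(truth.seed, 1)
    truth.conditions = tuple(conditions)
    truth.replicates = {
        f"{cond}{r+1}": cond for cond in conditions for r in range(n_replicates)
    }
    if fold_changes is None:
        fc_of = {}
    elif isinstance(fold_changes, dict):
        fc_of = dict(fold_changes)
    else:
        fc_of = {p.accession: float(fold_changes) for p in truth.targets()}
    cond_a, cond_b = truth.conditions
    # lognormal multiplier with unit mean at the stated CV
    sigma_cv = float(np.sqrt(np.log1p(truth.cv**2)))
    for prot in truth.proteins:
        if prot.is_decoy:
            continue
        if prot.duplicate_of is not None:
            src = next(p for p in truth.proteins if p.accession == prot.duplicate_of)
            prot.abundance = dict(src.abundance)
            prot.fold_change = src.fold_change
            prot.peptides = src.peptides   # shared evidence: same peaks, same spectra
            continue
        fc = float(fc_of.get(prot.accession, 1.0))
        if fc <= 0:
            raise ValueError(f"fold_change must be > 0, got {fc} for {prot.accession}")
        ab_b = base_abundance * 10.0 ** (rng.normal(0.0, abundance_sigma_log10))
        prot.abundance = {cond_a: ab_b * fc, cond_b: ab_b}
        prot.fold_change = fc
        peps = digest(prot.sequence)
        if len(peps) > max_peptides_per_protein:
            idx = rng.choice(len(peps), size=max_peptides_per_protein, replace=False)
            peps = [peps[i] for i in sorted(idx)]
        prot.peptides = []
        for pep in peps:
            charge = int(rng.choice([2, 3]))
            sp = SyntheticPeptide(
                sequence=pep,
                charge=charge,
                mz=peptide_mz(pep, charge),
                apex_scan=int(rng.integers(60, truth.n_scans - 60)),
                width_scans=float(rng.uniform(3.0, 6.0)),
            )
            for rep, cond in truth.replicates.items():
                mult = float(np.exp(rng.normal(-0.5 * sigma_cv**2, sigma_cv)))
                sp.apex_intensity[rep] = (
                    prot.abundance[cond] * truth.response_factor * mult
                )
            prot.peptides.append(sp)
    return truth


def detected(truth: SyntheticTruth, peptide: SyntheticPeptide, replicate: str) -> bool:
    return peptide.apex_intensity.get(replicate, 0.0) >= truth.detection_threshold


def generate_ms1(truth: SyntheticTruth, out_dir=None) -> dict[str, MS1Run]:
    """Simulate one MS1 chromatogram per replicate.

    Every peptide m/z channel carries a uniform-positive noise floor —
    present in a ``noise_density`` fraction of scans, mimicking the
    sparseness of real survey scans — and a detected peptide adds a
    Gaussian elution profile
    ``apex * exp(-(scan - apex_scan)^2 / (2 width^2))`` on top.  Scans
    store only nonzero peaks.  Files are written in MS1 text format when
    ``out_dir`` is given.
    """
    if truth.n_scans < 100:
        raise ValueError("n_scans must be >= 100")
    channels = sorted(
        {
            (round(sp.mz, 6))
            for p in truth.targets()
            if p.duplicate_of is None
            for sp in p.peptides
        }
    )
    mz_arr = np.asarray(channels, dtype=float)
    col = {m: i for i, m in enumerate(channels)}
    scans_axis = np.arange(1, truth.n_scans + 1)
    runs: dict[str, MS1Run] = {}
    for k, (rep, _cond) in enumerate(sorted(truth.replicates.items())):
        rng = _rng(truth.seed, 100 + k)
        grid = rng.uniform(
            truth.noise_low, truth.noise_high, size=(truth.n_scans, len(channels))
        )
        grid *= rng.random(size=grid.shape) < truth.noise_density
        for prot in truth.targets():
            if prot.duplicate_of is not None:
                continue
            for sp in prot.peptides:
                apex = sp.apex_intensity.get(rep, 0.0)
                if apex <= 0:
                    continue
                profile = apex * np.exp(
                    -((scans_axis - sp.apex_scan) ** 2) / (2.0 * sp.width_scans**2)
                )
                grid[:, col[round(sp.mz, 6)]] += profile
        # detector floor: sub-single-ion signals are not recorded, so the
        # far tails of elution peaks vanish instead of lingering at ~1e-200
        grid[grid < 1.0] = 0.0
        scans = []
        for i, s in enumerate(scans_axis):
            nz = grid[i] > 0
            scans.append(
                Scan(
                    number=int(s),
                    retention_time=float(s),
                    mz=mz_arr[nz],
                    intensity=grid[i][nz],
                )
            )
        run = MS1Run(replicate_id=rep, scans=scans)
        runs[rep] = run
        if out_dir is not None:
            os.makedirs(out_dir, exist_ok=True)
            write_ms1(run, os.path.join(out_dir, f"{rep}.ms1"))
    return runs


def generate_psms(
    truth: SyntheticTruth,
    target_evalue_scale: float = 0.005,
    decoy_evalue_scale: float = 10.0,
    max_decoy_peptides: int = 10,
    path=None,
) -> list[PeptideSpectrumMatch]:
    """PSM table: one row per (detected peptide, replicate, accession).

    Target E-values are Exponential(``target_evalue_scale``), decoy
    E-values Exponential(``decoy_evalue_scale``): with the defaults the
    closed-form pass probability at the 0.05 filter is ~1 for targets and
    ``1 - exp(-0.05/10) ~ 0.005`` for decoys.  Duplicate entries re-emit
    their source's rows under their own accession (identical spectrum
    ids), exercising the grouping stage.  Decoy peptides get random scans:
    they represent matches against the shuffled database, not real peaks.
    """
    rng = _rng(truth.seed, 2)
    psms: list[PeptideSpectrumMatch] = []
    dup_of: dict[str, list[str]] = {}
    for p in truth.proteins:
        if p.duplicate_of is not None:
            dup_of.setdefault(p.duplicate_of, []).append(p.accession)
    for prot in truth.proteins:
        if prot.duplicate_of is not None:
            continue
        if prot.is_decoy:
            # decoy matches are chance events: a sparse peptide subset,
            # each matched in one random replicate
            peps = digest(prot.sequence)
            if len(peps) > max_decoy_peptides:
                idx = rng.choice(len(peps), size=max_decoy_peptides, replace=False)
                peps = [peps[i] for i in sorted(idx)]
            reps = sorted(truth.replicates)
            for pep in peps:
                charge = int(rng.choice([2, 3]))
                rep = reps[int(rng.integers(len(reps)))]
                psms.append(
                    PeptideSpectrumMatch(
                        spectrum_id=f"{rep}:{prot.accession}:{pep[:8]}",
                        replicate_id=rep,
                        condition_id=truth.replicates[rep],
                        scan_number=int(rng.integers(1, truth.n_scans + 1)),
                        precursor_mz=peptide_mz(pep, charge),
                        peptide=pep,
                        accession=prot.accession,
                        e_value=float(rng.exponential(decoy_evalue_scale)),
                    )
                )
            continue
        for sp in prot.peptides:
            for rep, cond in sorted(truth.replicates.items()):
                if not detected(truth, sp, rep):
                    continue
                sid = f"{rep}:{prot.accession}:{sp.sequence[:8]}"
                e_val = float(rng.exponential(target_evalue_scale))
                row = PeptideSpectrumMatch(
                    spectrum_id=sid,
                    replicate_id=rep,
                    condition_id=cond,
                    scan_number=sp.apex_scan,
                    precursor_mz=sp.mz,
                    peptide=sp.sequence,
                    accession=prot.accession,
                    e_value=e_val,
                )
                psms.append(row)
                for dup_acc in dup_of.get(prot.accession, []):
                    psms.append(
                        PeptideSpectrumMatch(
                            spectrum_id=sid,
                            replicate_id=rep,
                            condition_id=cond,
                            scan_number=sp.apex_scan,
                            precursor_mz=sp.mz,
                            peptide=sp.sequence,
                            accession=dup_acc,
                            e_value=e_val,
                        )
                    )
    if path is not None:
        write_psm_table(psms, path)
    return psms


def generate_intensity_matrix(truth: SyntheticTruth, seed_offset: int = 3):
    """Draw a protein x replicate matrix directly from the abundance model.

    Bypasses chromatogram simulation: each cell is
    ``abundance[condition] * response_factor * lognormal(CV)``.  Noise
    levels mimic a low quantile of the uniform floor.  Useful for testing
    the statistics stage at scale.
    """
    from .quant import IntensityMatrix

    rng = _rng(truth.seed, seed_offset)
    reps = sorted(truth.replicates)
    prots = [p for p in truth.targets() if p.duplicate_of is None]
    accs = [p.accession for p in prots]
    sigma_cv = float(np.sqrt(np.log1p(truth.cv**2)))
    data = np.empty((len(prots), len(reps)))
    for i, prot in enumerate(prots):
        for j, rep in enumerate(reps):
            cond = truth.replicates[rep]
            mult = float(np.exp(rng.normal(-0.5 * sigma_cv**2, sigma_cv)))
            data[i, j] = prot.abundance[cond] * truth.response_factor * mult
    noise = truth.noise_low + 0.05 * (truth.noise_high - truth.noise_low)
    intensity = pd.DataFrame(data, index=accs, columns=reps)
    return IntensityMatrix(
        intensity=intensity,
        imputed=pd.DataFrame(False, index=accs, columns=reps),
        noise_level=pd.Series({r: noise for r in reps}),
        conditions=dict(truth.replicates),
    )


def write_truth_table(truth: SyntheticTruth, path) -> None:
    cond_a, cond_b = truth.conditions
    rows = [
        {
            "accession": p.accession,
            "species": p.species,
            f"abundance_{cond_a}": p.abundance.get(cond_a, 0.0),
            f"abundance_{cond_b}": p.abundance.get(cond_b, 0.0),
            "fold_change": p.fold_change,
            "is_decoy": p.is_decoy,
            "duplicate_of": p.duplicate_of or "",
        }
        for p in truth.proteins
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


DEFAULT_CONFIG = dict(
    n_proteins=40,
    length_range=(150, 300),
    decoy_fraction=0.0,
    duplicate_pairs=2,
    n_replicates=3,
    conditions=("A", "B"),
    fold_changes=None,
    base_abundance=1.0,
    abundance_sigma_log10=0.0,
    n_scans=600,
    seed=0,
)


def generate_dataset(out_dir, **params) -> SyntheticTruth:
    """Write a complete synthetic dataset (FASTA, PSM TSV, MS1 dir, truth).

    Parameters default to :data:`DEFAULT_CONFIG`; unknown keys are
    rejected.  Deterministic for a given seed.
    """
    cfg = dict(DEFAULT_CONFIG)
    unknown = set(params) - set(cfg)
    if unknown:
        raise ValueError(f"unknown generator parameter(s): {sorted(unknown)}")
    cfg.update(params)
    os.makedirs(out_dir, exist_ok=True)
    fasta, truth = generate_database(
        cfg["n_proteins"],
        tuple(cfg["length_range"]),
        decoy_fraction=cfg["decoy_fraction"],
        duplicate_pairs=cfg["duplicate_pairs"],
        seed=cfg["seed"],
    )
    truth.n_scans = int(cfg["n_scans"])
    with open(os.path.join(out_dir, "database.fasta"), "w") as fh:
        fh.write(fasta)
    plan_experiment(
        truth,
        n_replicates=cfg["n_replicates"],
        conditions=tuple(cfg["conditions"]),
        fold_changes=cfg["fold_changes"],
        base_abundance=cfg["base_abundance"],
        abundance_sigma_log10=cfg["abundance_sigma_log10"],
    )
    generate_ms1(truth, out_dir=os.path.join(out_dir, "ms1"))
    generate_psms(truth, path=os.path.join(out_dir, "psms.tsv"))
    write_truth_table(truth, os.path.join(out_dir, "truth.tsv"))
    with open(os.path.join(out_dir, "generator_config.yaml"), "w") as fh:
        yaml.safe_dump(
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg.items()},
            fh, sort_keys=True,
        )
    return truth


def generate_dataset_from_yaml(config_path, out_dir) -> SyntheticTruth:
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "fold_changes" in cfg and isinstance(cfg["fold_changes"], dict):
        cfg["fold_changes"] = {str(k): float(v) for k, v in cfg["fold_changes"].items()}
    return generate_dataset(out_dir, **cfg)
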