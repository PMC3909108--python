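"""Ground-truth phosphopeptide MS/MS simulation.

The generator emits spectra for peptides with a *known* phosphate placement:
every theoretical ion of the true configuration appears with a configurable
presence probability, with intensity drawn from a positive law and m/z
jittered by a small Gaussian; on top of that a uniform noise floor is added,
its intensity ceiling held below the true-peak law's median divided by the
signal-to-noise ratio so that the noise specifically exercises the ζ floor
and the matching window rather than realistic fragmentation chemistry.

Peptide families of increasing difficulty mirror a synthetic phosphopeptide
library design: the distance between the true site and neighbouring decoy
S/T/Y residues shrinks from family 1 to family 3 (family 3 has consecutive
phosphorylatable residues), which reduces the number of site-determining
ions available for discrimination.

Replicate spectra per peptide drive the redundancy criterion downstream.  The
emitted identification records mimic a search engine: correct sequence and
phosphate count, but a random site placement as the "first hit".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .configurations import PhosphoConfiguration, format_label
from .io import (
    IdentificationRecord,
    Spectrum,
    write_identifications,
    write_mgf,
    write_truth,
)
from .masses import DEFAULT_MASS_TABLE, MassTable, ModifiedPeptide, fragment_ladder

__all__ = [
    "SimulationParameters",
    "SimulatedDataset",
    "default_intensity_law",
    "family_peptide",
    "family_peptides",
    "simulate_spectrum",
    "simulate_dataset",
]

#: Residue alphabets of the library-style peptide families.
FAMILY_X = "ADEFGLSTVY"
FAMILY_Z = "SDLFGHP"


def default_intensity_law(rng: np.random.Generator, n: int) -> np.ndarray:
    """Log-normal fragment intensities with median 1000 (σ = 0.6 in log)."""
    return rng.lognormal(mean=np.log(1000.0), sigma=0.6, size=n)


@dataclass
class SimulationParameters:
    """Study conditions for one simulated dataset.

    ``peptides`` holds ``(sequence, true phospho positions)`` pairs; when
    empty, :func:`family_peptides` supplies them.  ``site_determining_snr``
    is the ratio between the true-peak intensity scale (the law's median) and
    the noise intensity ceiling.
    """

    peptides: tuple[tuple[str, tuple[int, ...]], ...] = ()
    precursor_charge: int = 2
    fragmentation: str = "HCD"
    fragment_intensity_law: Callable[[np.random.Generator, int], np.ndarray] = (
        default_intensity_law
    )
    site_determining_snr: float = 10.0
    peak_presence_prob: float = 0.9
    n_noise_peaks: int = 50
    noise_mz_range: tuple[float, float] = (100.0, 1500.0)
    replicates_per_peptide: int = 7
    mz_jitter_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.peak_presence_prob <= 1:
            raise ValueError("peak_presence_prob must lie in [0, 1]")
        if self.site_determining_snr <= 0:
            raise ValueError("site_determining_snr must be > 0")
        if self.replicates_per_peptide < 1:
            raise ValueError("replicates_per_peptide must be >= 1")
        if self.n_noise_peaks < 0:
            raise ValueError("n_noise_peaks must be >= 0")


@dataclass
class SimulatedDataset:
    """In-memory result of :func:`simulate_dataset`."""

    spectra: list[Spectrum]
    identifications: list[IdentificationRecord]
    truth: dict[str, tuple[int, ...]]


def _law_median(params: SimulationParameters) -> float:
    # estimated once per dataset from a fixed internal draw so that custom
    # laws need not expose an analytic median
    probe = np.random.default_rng(190733)
    return float(np.median(params.fragment_intensity_law(probe, 1001)))


def family_peptide(
    family: int, rng: np.random.Generator
) -> tuple[str, tuple[int, ...]]:
    """Draw one mono-phosphorylated peptide from a library-style family.

    Family 1 keeps the true site far from decoys, family 2 brings a decoy
    closer, family 3 places the true site inside a run of consecutive S/S/T.
    The X and Z alphabets may themselves contribute extra decoy sites.
    """
    X = lambda: rng.choice(list(FAMILY_X))
    Z = lambda: rng.choice(list(FAMILY_Z))
    if family == 1:
        seq = f"AS P {X()} P {X()} A {X()} F E A".replace(" ", "")
        return seq, (2,)
    if family == 2:
        seq = f"G A P {X()} P {X()} S {X()} F E A".replace(" ", "")
        return seq, (7,)
    if family == 3:
        seq = f"A D {Z()} {Z()} S S T {Z()} {Z()} F E A K".replace(" ", "")
        return seq, (5,)
    raise ValueError(f"unknown family {family}; choose 1, 2 or 3")


def family_peptides(
    n: int, rng: np.random.Generator, families: Sequence[int] = (1, 2, 3)
) -> tuple[tuple[str, tuple[int, ...]], ...]:
    """Cycle the requested families to draw ``n`` peptides."""
    out = []
    for i in range(n):
        out.append(family_peptide(families[i % len(families)], rng))
    return tuple(out)


def simulate_spectrum(
    config: PhosphoConfiguration,
    params: SimulationParameters,
    rng: np.random.Generator,
    scan_id: str,
    table: MassTable = DEFAULT_MASS_TABLE,
) -> tuple[Spectrum, tuple[int, ...]]:
    """Simulate one spectrum of ``config`` plus its truth record.

    The configuration's full theoretical ladder is emitted peak by peak (each
    present with ``peak_presence_prob``, jittered, intensity from the law),
    followed by ``n_noise_peaks`` uniform noise peaks whose intensities stay
    below ``median(law) / site_determining_snr``.
    """
    peptide = config.peptide.with_phospho(config.phospho_positions)
    peptide = ModifiedPeptide(
        sequence=peptide.sequence,
        precursor_charge=params.precursor_charge,
        fixed_mods=peptide.fixed_mods,
        variable_mods=peptide.variable_mods,
        phospho_positions=peptide.phospho_positions,
    )
    ladder = fragment_ladder(peptide, table=table)
    theo_mz = np.array([ion.mz for ion in ladder])
    present = rng.random(theo_mz.size) < params.peak_presence_prob
    n_true = int(present.sum())
    true_mz = theo_mz[present]
    if params.mz_jitter_sd > 0:
        true_mz = true_mz + rng.normal(0.0, params.mz_jitter_sd, n_true)
    true_intensity = np.asarray(params.fragment_intensity_law(rng, n_true), dtype=float)

    noise_ceiling = _law_median(params) / params.site_determining_snr
    noise_mz = rng.uniform(*params.noise_mz_range, params.n_noise_peaks)
    noise_intensity = rng.uniform(0.0, noise_ceiling, params.n_noise_peaks)

    spectrum = Spectrum(
        scan_id=scan_id,
        precursor_neutral_mass=peptide.neutral_mass(table),
        precursor_charge=params.precursor_charge,
        mz=np.concatenate([true_mz, noise_mz]),
        intensity=np.concatenate([true_intensity, noise_intensity]),
        fragmentation=params.fragmentation,
    )
    return spectrum, tuple(config.phospho_positions)


def simulate_dataset(
    params: SimulationParameters,
    out_dir: str | Path | None = None,
    table: MassTable = DEFAULT_MASS_TABLE,
) -> SimulatedDataset:
    """Simulate a full dataset: spectra, identifications and ground truth.

    Each peptide is fragmented ``replicates_per_peptide`` times (one spectrum
    per replicate, all sharing the same truth).  The identification table
    reports the correct sequence and phosphate count but a random placement,
    as a search engine would.  When ``out_dir`` is given, ``spectra.mgf``,
    ``identifications.tsv`` and ``truth.tsv`` are written there.
    """
    rng = np.random.default_rng(params.seed)
    peptides = params.peptides or family_peptides(30, rng)

    spectra: list[Spectrum] = []
    identifications: list[IdentificationRecord] = []
    truth: dict[str, tuple[int, ...]] = {}
    scan_no = 0
    for sequence, true_positions in peptides:
        base = ModifiedPeptide(
            sequence=sequence,
            precursor_charge=params.precursor_charge,
            phospho_positions=(),
        )
        config = PhosphoConfiguration(base=base, phospho_positions=tuple(true_positions))
        sites = base.site_positions
        p = len(true_positions)
        for _ in range(params.replicates_per_peptide):
            scan_id = f"scan{scan_no:06d}"
            scan_no += 1
            spectrum, true_pos = simulate_spectrum(
                config, params, rng, scan_id=scan_id, table=table
            )
            spectra.append(spectrum)
            truth[scan_id] = true_pos
            # search-engine emulation: random placement of the phosphates
            hit_positions = tuple(
                sorted(rng.choice(len(sites), size=p, replace=False))
            )
            hit = base.with_phospho(tuple(sites[i] for i in hit_positions))
            identifications.append(
                IdentificationRecord(
                    scan_id=scan_id,
                    peptide=hit,
                    search_engine="synthetic",
                    fragmentation=params.fragmentation,
                )
            )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_mgf(spectra, out_dir / "spectra.mgf", table=table)
        write_identifications(identifications, out_dir / "identifications.tsv")
        write_truth(truth, out_dir / "truth.tsv")
    return SimulatedDataset(
        spectra=spectra, identifications=identifications, truth=truth
    )
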