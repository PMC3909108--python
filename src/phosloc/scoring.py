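"""Windowed peak matching and the dynamic-programming Φ score.

For each candidate configuration, the observed spectrum is matched against
that configuration's surviving site-determining scoring targets: the
maximum-intensity observed peak inside the closed window
``[target - δ/2, target + δ/2]`` is the candidate match (δ defaults to the
instrument mass accuracy, 0.05 Da for an Orbitrap).  A match is admitted only
if it reaches the noise floor ζ, a fraction of the spectrum's tallest peak
(3% for HCD, 5% for CID).

The Φ score is built by the recursion

    Φ(j) = max(I[M(j)]_max + Φ(j-1), Φ(j-1)),   Φ(0) = 0

over targets in canonical ladder order; because intensities are non-negative
this includes every admissible match.  Each observed peak may contribute at
most once per configuration (the first claimant in ladder order wins), which
prevents a single dense spectral region from inflating Φ through several
near-coincident targets.

The localization confidence is dCn = (Φ_best − Φ_second) / Φ_best.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .configurations import ConfigurationSet, PhosphoConfiguration, ScoringTarget
from .io import Spectrum

__all__ = [
    "MatchParameters",
    "ScoredConfiguration",
    "max_peak_in_window",
    "zeta_threshold",
    "phi_score",
    "rank_configurations",
    "delta_cn",
    "top_is_tied",
]


@dataclass(frozen=True)
class MatchParameters:
    """Tunable matching parameters.

    ``window_delta`` is the *full* window width in Th.  ``min_rel_intensity``
    overrides the per-fragmentation ζ basis when set; otherwise 3% (HCD) or
    5% (CID) of the tallest peak is used.  ``max_fragment_charge`` defaults to
    the precursor charge.  ``score_full_ladder`` scores every surviving
    target instead of site-determining targets only.
    """

    window_delta: float = 0.05
    min_rel_intensity: float | None = None
    min_rel_intensity_hcd: float = 0.03
    min_rel_intensity_cid: float = 0.05
    max_fragment_charge: int | None = None
    score_full_ladder: bool = False

    def __post_init__(self) -> None:
        if self.window_delta <= 0:
            raise ValueError("window_delta must be > 0")
        for name in ("min_rel_intensity", "min_rel_intensity_hcd", "min_rel_intensity_cid"):
            v = getattr(self, name)
            if v is not None and not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1)")


@dataclass
class ScoredConfiguration:
    """A configuration with its Φ score and matched-peak evidence."""

    configuration: PhosphoConfiguration
    phi: float
    matched: list[tuple[ScoringTarget, float, float]]  # (target, obs m/z, intensity)
    n_evaluations: int = 0

    @property
    def label(self) -> str:
        return self.configuration.label


def max_peak_in_window(
    spectrum: Spectrum, target_mz: float, delta: float
) -> tuple[float, float] | None:
    """Maximum-intensity peak within ``[target - δ/2, target + δ/2]``.

    Returns ``(intensity, observed m/z)`` or ``None``; the lookup is
    logarithmic in the peak count (binary search on the sorted m/z array).
    """
    lo = int(np.searchsorted(spectrum.mz, target_mz - delta / 2, side="left"))
    hi = int(np.searchsorted(spectrum.mz, target_mz + delta / 2, side="right"))
    if lo == hi:
        return None
    idx = lo + int(np.argmax(spectrum.intensity[lo:hi]))
    return float(spectrum.intensity[idx]), float(spectrum.mz[idx])


def zeta_threshold(spectrum: Spectrum, params: MatchParameters) -> float:
    """Minimum peak intensity ζ considered for matching.

    A fraction of the whole spectrum's tallest peak, resolved by fragmentation
    method unless ``params.min_rel_intensity`` overrides it.  An empty
    spectrum yields +inf (nothing can match).
    """
    if spectrum.is_empty:
        return float("inf")
    if params.min_rel_intensity is not None:
        frac = params.min_rel_intensity
    elif spectrum.fragmentation == "CID":
        frac = params.min_rel_intensity_cid
    else:
        frac = params.min_rel_intensity_hcd
    return frac * float(spectrum.intensity.max())


def _best_unclaimed(
    spectrum: Spectrum,
    target_mz: float,
    delta: float,
    zeta: float,
    claimed: set[int],
) -> tuple[float, float, int] | None:
    lo = int(np.searchsorted(spectrum.mz, target_mz - delta / 2, side="left"))
    hi = int(np.searchsorted(spectrum.mz, target_mz + delta / 2, side="right"))
    best: tuple[float, float, int] | None = None
    for idx in range(lo, hi):
        if idx in claimed:
            continue
        inten = float(spectrum.intensity[idx])
        if inten < zeta:
            continue
        if best is None or inten > best[0]:
            best = (inten, float(spectrum.mz[idx]), idx)
    return best


def phi_score(
    spectrum: Spectrum,
    targets: Sequence[ScoringTarget],
    params: MatchParameters,
    configuration: PhosphoConfiguration | None = None,
    zeta: float | None = None,
) -> ScoredConfiguration:
    """Run the Φ recursion over one configuration's scoring targets.

    ``targets`` must already be the surviving, ordered scoring targets of the
    configuration (site-determining only unless ``score_full_ladder``); the
    caller may pass a precomputed ζ to avoid recomputation.
    """
    if zeta is None:
        zeta = zeta_threshold(spectrum, params)
    phi = 0.0  # Φ(0) = 0
    matched: list[tuple[ScoringTarget, float, float]] = []
    claimed: set[int] = set()
    n_eval = 0
    for target in targets:
        n_eval += 1
        best = _best_unclaimed(spectrum, target.mz, params.window_delta, zeta, claimed)
        if best is None:
            continue  # Φ(j) = Φ(j-1)
        intensity, obs_mz, idx = best
        if intensity + phi >= phi:  # always true for non-negative intensities
            phi += intensity
            claimed.add(idx)
            matched.append((target, obs_mz, intensity))
    return ScoredConfiguration(
        configuration=configuration, phi=phi, matched=matched, n_evaluations=n_eval
    )


def rank_configurations(
    cset: ConfigurationSet, spectrum: Spectrum, params: MatchParameters
) -> list[ScoredConfiguration]:
    """Score every configuration and order them by descending Φ.

    Ties are broken by lexicographic configuration label so the ordering is
    deterministic; a tie at the top is visible via :func:`top_is_tied`.
    """
    if cset.scoring_targets is None:
        raise ValueError("scoring targets not built; apply coincidence rules first")
    zeta = zeta_threshold(spectrum, params)
    scored = []
    for config, targets in zip(cset.configurations, cset.scoring_targets):
        if not params.score_full_ladder:
            targets = [t for t in targets if t.site_determining]
        scored.append(
            phi_score(spectrum, targets, params, configuration=config, zeta=zeta)
        )
    scored.sort(key=lambda s: (-s.phi, s.label))
    return scored


def top_is_tied(ranked: Sequence[ScoredConfiguration]) -> bool:
    """True when the two best configurations score identically."""
    return len(ranked) > 1 and ranked[0].phi == ranked[1].phi


def delta_cn(ranked: Sequence[ScoredConfiguration]) -> float:
    """Relative gap between the best and second-best Φ.

    Degenerate cases: a singleton candidate set returns 1.0 (a lone candidate
    site has nothing to be confused with); Φ_best = 0 with several candidates
    returns 0.0.
    """
    if not ranked:
        raise ValueError("no scored configurations")
    if len(ranked) == 1:
        return 1.0
    best = ranked[0].phi
    if best == 0.0:
        return 0.0
    return (best - ranked[1].phi) / best
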