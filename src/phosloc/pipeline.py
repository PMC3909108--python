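"""End-to-end site assignment: spectra + identifications -> report records."""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .configurations import (
    apply_coincidence_rules,
    build_ladders,
    enumerate_configurations,
    flag_site_determining,
)
from .io import AssignmentRecord, IdentificationRecord, Spectrum
from .masses import DEFAULT_MASS_TABLE, MassTable
from .postprocess import QualityParameters, RedundancyKey, redundancy_counts, verdict
from .scoring import (
    MatchParameters,
    ScoredConfiguration,
    delta_cn,
    rank_configurations,
    top_is_tied,
)

__all__ = ["ScanResult", "PipelineResult", "assign_spectra"]

logger = logging.getLogger(__name__)


@dataclass
class ScanResult:
    """Per-scan scoring detail kept alongside the final report record."""

    scan_id: str
    ranked: list[ScoredConfiguration]
    dcn: float
    top_tie: bool
    n_evaluations: int


@dataclass
class PipelineResult:
    """Everything one invocation produced."""

    records: list[AssignmentRecord]
    scans: list[ScanResult]
    total_evaluations: int
    skipped: list[str]


def assign_spectra(
    spectra: Iterable[Spectrum] | Mapping[str, Spectrum],
    identifications: Sequence[IdentificationRecord],
    match_params: MatchParameters = MatchParameters(),
    quality_params: QualityParameters = QualityParameters(),
    table: MassTable = DEFAULT_MASS_TABLE,
) -> PipelineResult:
    """Assign phosphosites for every identified spectrum.

    For each identification the candidate configurations are enumerated from
    the first-hit sequence and phosphate count, their ladders built at the
    matching charge ceiling, site-determining ions flagged, coincidences
    resolved, and the configurations ranked by Φ.  Redundancy is then counted
    across the whole batch and the pass/ambiguous verdicts issued.

    A scan id in the identifications with no matching spectrum is skipped
    with a log entry (and recorded in ``skipped``).
    """
    if isinstance(spectra, Mapping):
        by_scan = dict(spectra)
    else:
        by_scan = {s.scan_id: s for s in spectra}

    scans: list[ScanResult] = []
    tops: dict[str, RedundancyKey] = {}
    skipped: list[str] = []
    total_evaluations = 0
    for ident in identifications:
        spectrum = by_scan.get(ident.scan_id)
        if spectrum is None:
            logger.warning("no spectrum for scan %s; skipped", ident.scan_id)
            skipped.append(ident.scan_id)
            continue
        if ident.fragmentation and ident.fragmentation != spectrum.fragmentation:
            spectrum = replace(spectrum, fragmentation=ident.fragmentation)
        peptide = replace(ident.peptide, precursor_charge=spectrum.precursor_charge)
        cset = enumerate_configurations(peptide)
        build_ladders(cset, max_fragment_charge=match_params.max_fragment_charge, table=table)
        flag_site_determining(cset, tolerance=match_params.window_delta)
        apply_coincidence_rules(cset, tolerance=match_params.window_delta)
        ranked = rank_configurations(cset, spectrum, match_params)
        n_eval = sum(s.n_evaluations for s in ranked)
        total_evaluations += n_eval
        scans.append(
            ScanResult(
                scan_id=ident.scan_id,
                ranked=ranked,
                dcn=delta_cn(ranked),
                top_tie=top_is_tied(ranked),
                n_evaluations=n_eval,
            )
        )
        # a scan whose best Φ is 0 matched nothing: its deterministically
        # tie-broken top carries no localization evidence and must not pool
        # into (or draw on) the redundancy criterion
        if ranked[0].phi > 0:
            tops[ident.scan_id] = RedundancyKey.from_configuration(
                ranked[0].configuration
            )

    counts = redundancy_counts(tops)
    records = []
    for scan in scans:
        key = tops.get(scan.scan_id)
        redundancy = counts[key] if key is not None else 0
        records.append(
            AssignmentRecord(
                scan_id=scan.scan_id,
                assigned_label=scan.ranked[0].label,
                dcn=scan.dcn,
                redundancy=redundancy,
                verdict=verdict(scan.dcn, redundancy, quality_params, scan.top_tie),
            )
        )
    return PipelineResult(
        records=records,
        scans=scans,
        total_evaluations=total_evaluations,
        skipped=skipped,
    )
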