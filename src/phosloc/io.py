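"""Spectrum, identification and report input/output.

Supported formats:

* ``.dta`` — one spectrum per file; the first line holds the singly protonated
  precursor mass (M+H)+ and charge, subsequent lines hold ``m/z intensity``
  pairs.  The scan id is the file-name stem.
* MGF — via :mod:`pyteomics.mgf`; the TITLE (or block ordinal) becomes the
  scan id.
* Identification tables — a tab-separated file with columns ``scan_id``,
  ``peptide`` (``'*'`` label dialect), ``charge`` and ``fragmentation``,
  or a minimal legacy Sequest ``.out`` dialect from which only the rank-1
  peptide and the charge are extracted.
* The 5-column assignment report — tab-separated ``scan_id``, assigned
  peptide, dCn (4 decimals), redundancy, verdict.

Precursor masses are normalized to neutral mass + charge on read.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from pyteomics import mgf as _pt_mgf

from .configurations import format_label, parse_label
from .masses import DEFAULT_MASS_TABLE, MassTable, ModifiedPeptide

__all__ = [
    "Spectrum",
    "IdentificationRecord",
    "AssignmentRecord",
    "read_dta",
    "read_spectra",
    "read_mgf",
    "write_mgf",
    "read_identifications",
    "write_identifications",
    "write_report",
    "read_report",
    "write_truth",
    "read_truth",
]

logger = logging.getLogger(__name__)

REPORT_COLUMNS = ("scan_id", "peptide", "dcn", "redundancy", "verdict")


@dataclass
class Spectrum:
    """One MS/MS spectrum: a sorted peak list plus precursor metadata."""

    scan_id: str
    precursor_neutral_mass: float
    precursor_charge: int
    mz: np.ndarray
    intensity: np.ndarray
    fragmentation: str = "HCD"

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise ValueError("negative peak intensity")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if self.fragmentation not in ("CID", "HCD"):
            raise ValueError(f"fragmentation must be CID or HCD, got {self.fragmentation!r}")
        if self.is_empty:
            logger.warning("spectrum %s has no peaks; it will not score", self.scan_id)

    @property
    def is_empty(self) -> bool:
        return self.mz.size == 0

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))

    @property
    def precursor_mh(self) -> float:
        """Singly protonated precursor mass, the legacy .dta convention."""
        return self.precursor_neutral_mass + DEFAULT_MASS_TABLE.proton_mass


@dataclass(frozen=True)
class IdentificationRecord:
    """A search engine's first-hit peptide for one scan."""

    scan_id: str
    peptide: ModifiedPeptide
    search_engine: str = "tsv"
    fragmentation: str | None = None


@dataclass(frozen=True)
class AssignmentRecord:
    """Final per-spectrum result: best configuration plus quality metrics."""

    scan_id: str
    assigned_label: str
    dcn: float
    redundancy: int
    verdict: str

    def __post_init__(self) -> None:
        if self.verdict not in ("passed", "ambiguous"):
            raise ValueError(f"verdict must be passed/ambiguous, got {self.verdict!r}")
        if not 0.0 <= self.dcn <= 1.0:
            raise ValueError(f"dCn {self.dcn} outside [0, 1]")
        if self.redundancy < 0:
            raise ValueError("negative redundancy")


def read_dta(
    path: str | Path,
    fragmentation: str = "HCD",
    table: MassTable = DEFAULT_MASS_TABLE,
) -> Spectrum:
    """Read one legacy ``.dta`` spectrum.

    The first line is ``(M+H)+ charge``; the (M+H)+ value is converted to a
    neutral mass.  Peaks are sorted on read; a malformed numeric line raises
    with its 1-based line number.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty .dta file")
    mzs: list[float] = []
    intens: list[float] = []
    for lineno, line in enumerate(lines, start=1):
        tokens = line.split()
        if len(tokens) != 2:
            raise ValueError(f"{path}: line {lineno}: expected two columns")
        try:
            a, b = float(tokens[0]), float(tokens[1])
        except ValueError:
            raise ValueError(
                f"{path}: line {lineno}: non-numeric token in {line!r}"
            ) from None
        if lineno == 1:
            mh, charge = a, int(b)
        else:
            mzs.append(a)
            intens.append(b)
    return Spectrum(
        scan_id=path.stem,
        precursor_neutral_mass=mh - table.proton_mass,
        precursor_charge=charge,
        mz=np.array(mzs),
        intensity=np.array(intens),
        fragmentation=fragmentation,
    )


def read_mgf(
    path: str | Path,
    fragmentation: str = "HCD",
    default_charge: int | None = None,
    table: MassTable = DEFAULT_MASS_TABLE,
) -> list[Spectrum]:
    """Read all spectra from an MGF file (TITLE or ordinal becomes scan id)."""
    spectra: list[Spectrum] = []
    with _pt_mgf.MGF(str(path)) as reader:
        for ordinal, entry in enumerate(reader):
            params = entry["params"]
            scan_id = str(params.get("title", f"spectrum_{ordinal}")).strip()
            charges = params.get("charge")
            if charges:
                charge = int(charges[0])
            elif default_charge is not None:
                charge = default_charge
            else:
                raise ValueError(
                    f"{path}: spectrum {scan_id!r} has no CHARGE and no default "
                    "charge is configured"
                )
            pepmass = params["pepmass"][0]
            neutral = pepmass * charge - charge * table.proton_mass
            spectra.append(
                Spectrum(
                    scan_id=scan_id,
                    precursor_neutral_mass=neutral,
                    precursor_charge=charge,
                    mz=np.asarray(entry["m/z array"], dtype=float),
                    intensity=np.asarray(entry["intensity array"], dtype=float),
                    fragmentation=fragmentation,
                )
            )
    return spectra


def write_mgf(
    spectra: Iterable[Spectrum],
    path: str | Path,
    table: MassTable = DEFAULT_MASS_TABLE,
) -> None:
    """Write spectra to MGF (PEPMASS as precursor m/z, CHARGE, TITLE)."""
    entries = []
    for s in spectra:
        mz_prec = (s.precursor_neutral_mass + s.precursor_charge * table.proton_mass) / (
            s.precursor_charge
        )
        entries.append(
            {
                "m/z array": s.mz,
                "intensity array": s.intensity,
                "params": {
                    "title": s.scan_id,
                    "pepmass": mz_prec,
                    "charge": s.precursor_charge,
                },
            }
        )
    _pt_mgf.write(entries, str(path), file_mode="w")


def read_spectra(
    path: str | Path,
    fragmentation: str = "HCD",
    default_charge: int | None = None,
) -> list[Spectrum]:
    """Read spectra from an MGF file or a directory of ``.dta`` files."""
    path = Path(path)
    if path.is_dir():
        return [
            read_dta(p, fragmentation=fragmentation)
            for p in sorted(path.glob("*.dta"))
        ]
    return read_mgf(path, fragmentation=fragmentation, default_charge=default_charge)


_OUT_CHARGE = re.compile(r"charge(?:\s*state)?\s*[=:]\s*\+?(\d+)", re.IGNORECASE)
_OUT_RANK1 = re.compile(r"^\s*1\.\s")
_OUT_PEPTIDE = re.compile(r"(?:[A-Z-]\.)?([A-Z][A-Z*#@]*)(?:\.[A-Z-])?$")


def _parse_out_file(path: Path) -> IdentificationRecord | None:
    """Extract the rank-1 peptide and charge from a minimal Sequest .out file.

    Only the rank-1 peptide line and the charge are guaranteed to be parsed;
    ``#`` and ``@`` phospho markers are normalized to ``'*'`` and flanking
    residues (``K.PEPTIDE.A``) are stripped.
    """
    charge = None
    peptide_token = None
    for line in path.read_text().splitlines():
        if charge is None:
            m = _OUT_CHARGE.search(line)
            if m:
                charge = int(m.group(1))
        if peptide_token is None and _OUT_RANK1.match(line):
            for token in reversed(line.split()):
                m = _OUT_PEPTIDE.match(token)
                if m and any(c.isalpha() for c in m.group(1)):
                    peptide_token = m.group(1)
                    break
        if charge is not None and peptide_token is not None:
            break
    if peptide_token is None:
        raise ValueError(f"{path}: no rank-1 peptide line found")
    label = peptide_token.replace("#", "*").replace("@", "*")
    peptide = parse_label(label, precursor_charge=charge if charge else 2)
    if not peptide.phospho_positions:
        logger.info("%s: rank-1 peptide %s carries no phosphate; skipped", path, label)
        return None
    return IdentificationRecord(
        scan_id=path.stem, peptide=peptide, search_engine="sequest_out"
    )


def read_identifications(
    path: str | Path, dialect: str = "tsv"
) -> list[IdentificationRecord]:
    """Read first-hit identifications.

    ``tsv``: header ``scan_id  peptide  charge  fragmentation``; peptides use
    the ``'*'`` dialect.  Records without a phosphate are skipped with a log
    entry; duplicate scan ids are an error.

    ``sequest_out``: ``path`` is a ``.out`` file or a directory of them.
    """
    path = Path(path)
    if dialect == "sequest_out":
        files = sorted(path.glob("*.out")) if path.is_dir() else [path]
        records = [_parse_out_file(p) for p in files]
        out = [r for r in records if r is not None]
    elif dialect == "tsv":
        import pandas as pd

        frame = pd.read_csv(path, sep="\t", dtype={"scan_id": str})
        required = {"scan_id", "peptide", "charge", "fragmentation"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        out = []
        for row in frame.itertuples(index=False):
            try:
                peptide = parse_label(str(row.peptide), precursor_charge=int(row.charge))
            except ValueError as err:
                raise ValueError(f"{path}: scan {row.scan_id}: {err}") from None
            if not peptide.phospho_positions:
                logger.info(
                    "scan %s: peptide %s carries no phosphate; skipped",
                    row.scan_id,
                    row.peptide,
                )
                continue
            out.append(
                IdentificationRecord(
                    scan_id=str(row.scan_id),
                    peptide=peptide,
                    search_engine="tsv",
                    fragmentation=str(row.fragmentation),
                )
            )
    else:
        raise ValueError(f"unknown identification dialect {dialect!r}")
    seen: set[str] = set()
    for r in out:
        if r.scan_id in seen:
            raise ValueError(f"ambiguous identification: duplicate scan id {r.scan_id!r}")
        seen.add(r.scan_id)
    return out


def write_identifications(records: Iterable[IdentificationRecord], path: str | Path) -> None:
    """Write identifications in the canonical TSV dialect."""
    lines = ["scan_id\tpeptide\tcharge\tfragmentation"]
    for r in records:
        lines.append(
            f"{r.scan_id}\t{format_label(r.peptide)}\t{r.peptide.precursor_charge}"
            f"\t{r.fragmentation or 'HCD'}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_report(records: Sequence[AssignmentRecord], path: str | Path) -> None:
    """Write the 5-column assignment report (rows sorted by scan id)."""
    lines = ["\t".join(REPORT_COLUMNS)]
    for r in sorted(records, key=lambda r: r.scan_id):
        lines.append(
            f"{r.scan_id}\t{r.assigned_label}\t{r.dcn:.4f}\t{r.redundancy}\t{r.verdict}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_report(path: str | Path) -> list[AssignmentRecord]:
    """Read a 5-column assignment report back into records."""
    lines = Path(path).read_text().splitlines()
    if not lines or tuple(lines[0].split("\t")) != REPORT_COLUMNS:
        raise ValueError(f"{path}: not a 5-column assignment report")
    records = []
    for line in lines[1:]:
        scan_id, label, dcn, redundancy, verdict = line.split("\t")
        records.append(
            AssignmentRecord(
                scan_id=scan_id,
                assigned_label=label,
                dcn=float(dcn),
                redundancy=int(redundancy),
                verdict=verdict,
            )
        )
    return records


def write_truth(truth: Mapping[str, tuple[int, ...]], path: str | Path) -> None:
    """Write ground-truth site placements (scan_id, comma-joined positions)."""
    lines = ["scan_id\tphospho_positions"]
    for scan_id in sorted(truth):
        lines.append(f"{scan_id}\t{','.join(map(str, truth[scan_id]))}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_truth(path: str | Path) -> dict[str, tuple[int, ...]]:
    """Read a ground-truth table written by :func:`write_truth`."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != ["scan_id", "phospho_positions"]:
        raise ValueError(f"{path}: not a truth table")
    truth = {}
    for line in lines[1:]:
        scan_id, positions = line.split("\t")
        truth[scan_id] = tuple(int(p) for p in positions.split(",") if p)
    return truth
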