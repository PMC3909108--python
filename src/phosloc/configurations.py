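"""Candidate phosphopeptide configurations and site-determining ions.

A search engine reports a peptide sequence and how many phosphates it carries,
but its placement of those phosphates is unreliable.  This module enumerates
every possible placement (one *configuration* per combination of S/T/Y
positions), builds each configuration's theoretical ion ladder, and works out
which ions are *site-determining* — those whose m/z distinguishes at least one
pair of configurations and can therefore carry evidence about the true site.

Because theoretical ions of different identity can coincide in m/z, three
filtering rules are applied to pooled ions that fall within a coincidence
tolerance of each other:

1. a coincident group with no site-determining member is dropped from scoring;
2. a group mixing site-determining and non-site-determining ions is dropped
   entirely (the observed peak cannot be attributed);
3. a group of site-determining ions all belonging to the same configuration is
   merged into a single scoring target at the group's mean m/z; groups of
   site-determining ions spanning several configurations are dropped, since a
   shared m/z cannot discriminate between those configurations.

Labels use the ``'*'`` dialect: ``PQS*VLTK`` marks a phosphate on S3; other
modifications are written as a signed shift after the residue, e.g.
``AM(+15.995)DS*K``.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace

from .masses import (
    DEFAULT_MASS_TABLE,
    IonSpec,
    MassTable,
    ModifiedPeptide,
    PHOSPHORYLATABLE,
    TheoreticalIon,
    fragment_ladder,
)

__all__ = [
    "PhosphoConfiguration",
    "ScoringTarget",
    "ConfigurationSet",
    "format_label",
    "parse_label",
    "enumerate_configurations",
    "build_ladders",
    "flag_site_determining",
    "apply_coincidence_rules",
]


@dataclass(frozen=True)
class PhosphoConfiguration:
    """One specific placement of the phosphates on a base peptide."""

    base: ModifiedPeptide  # phospho_positions == ()
    phospho_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.base.phospho_positions:
            raise ValueError("base peptide must carry no phospho placement")
        object.__setattr__(
            self, "phospho_positions", tuple(sorted(self.phospho_positions))
        )
        # delegate position validation to ModifiedPeptide
        self.base.with_phospho(self.phospho_positions)

    @property
    def peptide(self) -> ModifiedPeptide:
        return self.base.with_phospho(self.phospho_positions)

    @property
    def label(self) -> str:
        return format_label(self.peptide)


@dataclass(frozen=True)
class ScoringTarget:
    """One m/z position to be matched against the observed spectrum.

    Usually a single theoretical ion; after coincidence rule 3 it may merge
    several same-configuration site-determining ions at their mean m/z.
    """

    mz: float
    specs: tuple[IonSpec, ...]
    site_determining: bool

    @property
    def sort_key(self) -> tuple:
        return min(spec.sort_key for spec in self.specs)


@dataclass
class ConfigurationSet:
    """All candidate configurations for one spectrum, plus derived state."""

    configurations: list[PhosphoConfiguration]
    ladders: list[list[TheoreticalIon]] | None = None
    scoring_targets: list[list[ScoringTarget]] | None = None
    discarded_ions: list[tuple[int, IonSpec]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.configurations:
            raise ValueError("empty configuration set")
        first = self.configurations[0]
        seen = set()
        for c in self.configurations:
            if c.base != first.base:
                raise ValueError("configurations must share the same base peptide")
            if len(c.phospho_positions) != len(first.phospho_positions):
                raise ValueError("configurations must share the phosphate count")
            if c.phospho_positions in seen:
                raise ValueError("duplicate configuration")
            seen.add(c.phospho_positions)


_LABEL_TOKEN = re.compile(r"([A-Z])(\*)?((?:\([+-]\d+(?:\.\d+)?\))*)")
_MOD_TOKEN = re.compile(r"\(([+-]\d+(?:\.\d+)?)\)")


def format_label(peptide: ModifiedPeptide) -> str:
    """Render a peptide in the ``'*'`` label dialect (mods at 3 decimals)."""
    mods_at: dict[int, list[float]] = {}
    for p, shift in (*peptide.fixed_mods, *peptide.variable_mods):
        mods_at.setdefault(p, []).append(shift)
    phospho = set(peptide.phospho_positions)
    out = []
    for i, aa in enumerate(peptide.sequence, start=1):
        out.append(aa)
        if i in phospho:
            out.append("*")
        for shift in mods_at.get(i, ()):
            out.append(f"({shift:+.3f})")
    return "".join(out)


def parse_label(
    label: str, precursor_charge: int = 2
) -> ModifiedPeptide:
    """Parse a ``'*'``-dialect peptide string into a :class:`ModifiedPeptide`.

    Non-phospho modifications are returned as ``variable_mods`` (the label
    dialect does not distinguish fixed from variable shifts).
    """
    sequence: list[str] = []
    phospho: list[int] = []
    mods: list[tuple[int, float]] = []
    pos = 0
    for m in _LABEL_TOKEN.finditer(label):
        if m.start() != pos:
            break
        pos = m.end()
        sequence.append(m.group(1))
        here = len(sequence)
        if m.group(2):
            phospho.append(here)
        for mod in _MOD_TOKEN.finditer(m.group(3)):
            mods.append((here, float(mod.group(1))))
    if pos != len(label) or not sequence:
        raise ValueError(f"unparseable peptide string {label!r}")
    return ModifiedPeptide(
        sequence="".join(sequence),
        precursor_charge=precursor_charge,
        variable_mods=tuple(mods),
        phospho_positions=tuple(phospho),
    )


def enumerate_configurations(hit: ModifiedPeptide) -> ConfigurationSet:
    """Enumerate all placements of the hit's phosphates over its S/T/Y sites.

    The search engine's own placement is ignored beyond the phosphate count;
    placements are returned in lexicographic order of their position tuples.
    """
    p = len(hit.phospho_positions)
    if p < 1:
        raise ValueError("peptide carries no phosphates; nothing to localize")
    sites = hit.site_positions
    if p > len(sites):
        raise ValueError(
            f"more phosphates ({p}) than phosphorylatable residues ({len(sites)})"
        )
    base = hit.with_phospho(())
    configurations = [
        PhosphoConfiguration(base=base, phospho_positions=combo)
        for combo in itertools.combinations(sites, p)
    ]
    return ConfigurationSet(configurations=configurations)


def build_ladders(
    cset: ConfigurationSet,
    max_fragment_charge: int | None = None,
    table: MassTable = DEFAULT_MASS_TABLE,
) -> ConfigurationSet:
    """Generate each configuration's theoretical ion ladder in place."""
    cset.ladders = [
        fragment_ladder(c.peptide, max_fragment_charge=max_fragment_charge, table=table)
        for c in cset.configurations
    ]
    return cset


def flag_site_determining(
    cset: ConfigurationSet, tolerance: float = 0.05
) -> ConfigurationSet:
    """Mark ions whose m/z discriminates between configurations.

    An ion of configuration ``c`` is site-determining iff some other
    configuration either lacks an ion of identical (series, index, loss,
    charge) identity — which happens exactly when the fragment's phosphate
    content differs and the loss is phosphoric-acid-type — or carries one at
    an m/z differing by more than ``tolerance``.
    """
    if cset.ladders is None:
        raise ValueError("ladders not built; call build_ladders first")
    n = len(cset.configurations)
    by_spec: dict[IonSpec, dict[int, TheoreticalIon]] = {}
    for ci, ladder in enumerate(cset.ladders):
        for ion in ladder:
            by_spec.setdefault(ion.spec, {})[ci] = ion
    for holders in by_spec.values():
        missing_somewhere = len(holders) < n
        for ci, ion in holders.items():
            ion.site_determining = missing_somewhere or any(
                abs(ion.mz - other.mz) > tolerance
                for cj, other in holders.items()
                if cj != ci
            )
    return cset


def apply_coincidence_rules(
    cset: ConfigurationSet, tolerance: float = 0.05
) -> ConfigurationSet:
    """Resolve theoretical ions that coincide in m/z into scoring targets.

    Ions are pooled over all configurations, grouped by single-linkage
    chaining on sorted m/z (gap <= ``tolerance`` joins a group), and the three
    coincidence rules are applied per group.  Surviving ions become per-
    configuration :class:`ScoringTarget` lists in canonical ladder order;
    removed ions are recorded in ``discarded_ions``.
    """
    if cset.ladders is None:
        raise ValueError("ladders not built; call build_ladders first")
    pooled: list[tuple[float, int, TheoreticalIon]] = sorted(
        ((ion.mz, ci, ion) for ci, ladder in enumerate(cset.ladders) for ion in ladder),
        key=lambda item: item[0],
    )
    targets: list[list[ScoringTarget]] = [[] for _ in cset.configurations]
    discarded: list[tuple[int, IonSpec]] = []

    def close_group(group: list[tuple[float, int, TheoreticalIon]]) -> None:
        # The same logical ion (identical identity, hence identical m/z) may
        # appear in several configurations' ladders; copies of one identity
        # are one group member, not a coincidence with themselves.
        members: dict[IonSpec, list[tuple[int, TheoreticalIon]]] = {}
        for _mz, ci, ion in group:
            members.setdefault(ion.spec, []).append((ci, ion))
        if len(members) == 1:
            for ci, ion in next(iter(members.values())):
                targets[ci].append(
                    ScoringTarget(
                        mz=ion.mz,
                        specs=(ion.spec,),
                        site_determining=ion.site_determining,
                    )
                )
            return
        flags = [copies[0][1].site_determining for copies in members.values()]
        if all(flags):
            owners = {ci for copies in members.values() for ci, _ion in copies}
            if len(owners) == 1:
                ci = owners.pop()
                targets[ci].append(
                    ScoringTarget(
                        mz=sum(item[0] for item in group) / len(group),
                        specs=tuple(sorted(members, key=lambda s: s.sort_key)),
                        site_determining=True,
                    )
                )
                return
        # rule 1 (no SD member), rule 2 (mixed), or SD identities spanning
        # multiple configurations: a shared m/z cannot attribute intensity.
        discarded.extend((ci, ion.spec) for _mz, ci, ion in group)

    group: list[tuple[float, int, TheoreticalIon]] = []
    for item in pooled:
        if group and item[0] - group[-1][0] > tolerance:
            close_group(group)
            group = []
        group.append(item)
    if group:
        close_group(group)

    cset.scoring_targets = [
        sorted(per_config, key=lambda t: t.sort_key) for per_config in targets
    ]
    cset.discarded_ions = discarded
    return cset
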