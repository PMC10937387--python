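"""Pedigree data model and extended PED/LINKAGE-style I/O.

Families are directed graphs of individuals carrying, besides the classic
six LINKAGE columns, observed status at two loci (an X-linked locus, here
the SRPK3 kinase, and an autosomal locus, here TTN) plus an X-inactivation
covariate for females and a proband flag.

File dialect (whitespace-separated, ``#`` comments ignored)::

    FID IID FAT MOT SEX PHENO S_OBS T_OBS XI PROBAND

    SEX    1=male 2=female
    PHENO  0=unknown 1=unaffected 2=affected
    S_OBS  0=unknown 1=wt 2=het_carrier 3=hemi_mut      (X locus)
    T_OBS  0=unknown 1=hom_wt 2=het_mut                 (autosomal locus)
    XI     0=unknown 1=random 2=skewed_mut_active 3=skewed_mut_silenced
    PROBAND 0/1

The first six columns are a superset of the classic pre-makeped LINKAGE
layout, so standard pedigree tooling can read them unchanged.  Founder
parent marker is ``0``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

FOUNDER = "0"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class Affection(str, Enum):
    UNKNOWN = "unknown"
    UNAFFECTED = "unaffected"
    AFFECTED = "affected"


class XObs(str, Enum):
    """Observed status at the X-linked locus."""

    UNKNOWN = "unknown"
    WT = "wt"                 # no mutant allele (hom wt female / hemi wt male)
    HET_CARRIER = "het_carrier"
    HEMI_MUT = "hemi_mut"


class TObs(str, Enum):
    """Observed status at the autosomal locus."""

    UNKNOWN = "unknown"
    HOM_WT = "hom_wt"
    HET_MUT = "het_mut"


class XInactivation(str, Enum):
    """Categorical X-inactivation call for females.

    ``skewed_mut_active`` means the X carrying the mutant allele is
    predominantly active; ``skewed_mut_silenced`` the opposite.
    """

    UNKNOWN = "unknown"
    RANDOM = "random"
    SKEWED_MUT_ACTIVE = "skewed_mut_active"
    SKEWED_MUT_SILENCED = "skewed_mut_silenced"


_SEX_CODE = {"1": Sex.MALE, "2": Sex.FEMALE}
_PHENO_CODE = {"0": Affection.UNKNOWN, "1": Affection.UNAFFECTED, "2": Affection.AFFECTED}
_SOBS_CODE = {"0": XObs.UNKNOWN, "1": XObs.WT, "2": XObs.HET_CARRIER, "3": XObs.HEMI_MUT}
_TOBS_CODE = {"0": TObs.UNKNOWN, "1": TObs.HOM_WT, "2": TObs.HET_MUT}
_XI_CODE = {
    "0": XInactivation.UNKNOWN,
    "1": XInactivation.RANDOM,
    "2": XInactivation.SKEWED_MUT_ACTIVE,
    "3": XInactivation.SKEWED_MUT_SILENCED,
}


def _inv(d):
    return {v: k for k, v in d.items()}


class PedigreeError(ValueError):
    """Malformed pedigree file or structurally invalid pedigree."""


@dataclass
class Individual:
    id: str
    father_id: str = FOUNDER
    mother_id: str = FOUNDER
    sex: Sex = Sex.MALE
    affection: Affection = Affection.UNKNOWN
    s_obs: XObs = XObs.UNKNOWN
    t_obs: TObs = TObs.UNKNOWN
    xi_status: XInactivation = XInactivation.UNKNOWN
    proband: bool = False

    def __post_init__(self) -> None:
        # XI is a female-only covariate; silently forced to unknown for males.
        if self.sex is Sex.MALE:
            self.xi_status = XInactivation.UNKNOWN

    @property
    def is_founder(self) -> bool:
        return self.father_id == FOUNDER and self.mother_id == FOUNDER


@dataclass
class Issue:
    severity: str  # "error" | "warning"
    individual_id: str | None
    message: str
    kind: str = "structure"  # "structure" | "observation"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        who = f" [{self.individual_id}]" if self.individual_id else ""
        return f"{self.severity}{who}: {self.message}"


@dataclass
class Pedigree:
    family_id: str
    members: list[Individual] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index = {m.id: m for m in self.members}
        if len(self._index) != len(self.members):
            seen, dup = set(), None
            for m in self.members:
                if m.id in seen:
                    dup = m.id
                    break
                seen.add(m.id)
            raise PedigreeError(f"family {self.family_id}: duplicate individual id {dup!r}")

    def __getitem__(self, iid: str) -> Individual:
        return self._index[iid]

    def __contains__(self, iid: str) -> bool:
        return iid in self._index

    def __len__(self) -> int:
        return len(self.members)

    @property
    def founders(self) -> list[Individual]:
        return [m for m in self.members if m.is_founder]

    @property
    def proband(self) -> Individual | None:
        for m in self.members:
            if m.proband:
                return m
        return None

    def nuclear_units(self) -> list[tuple[str, str, tuple[str, ...]]]:
        """Nuclear families as (father_id, mother_id, children ids), sorted."""
        units: dict[tuple[str, str], list[str]] = {}
        for m in self.members:
            if not m.is_founder:
                units.setdefault((m.father_id, m.mother_id), []).append(m.id)
        return sorted(
            (f, mo, tuple(sorted(kids))) for (f, mo), kids in units.items()
        )

    def strip_observations(self, keep_proband_affection: bool = False) -> "Pedigree":
        """Copy with all phenotype/genotype observations removed.

        With ``keep_proband_affection`` the proband's affection status is
        retained; used to compute ascertainment-correction denominators.
        """
        out = []
        for m in self.members:
            keep = keep_proband_affection and m.proband
            out.append(
                replace(
                    m,
                    affection=m.affection if keep else Affection.UNKNOWN,
                    s_obs=XObs.UNKNOWN,
                    t_obs=TObs.UNKNOWN,
                )
            )
        return Pedigree(self.family_id, out)


def validate_pedigree(ped: Pedigree) -> list[Issue]:
    """Check structural and observational invariants; returns issues.

    An empty list means the pedigree is valid.  Mendelian impossibilities
    that are decidable from single parent-child observations are reported
    as errors; deeper inconsistencies surface as a zero likelihood in the
    engine.
    """
    issues: list[Issue] = []

    def err(iid, msg, kind="structure"):
        issues.append(Issue("error", iid, msg, kind))

    for m in ped.members:
        for pid, role, want in ((m.father_id, "father", Sex.MALE), (m.mother_id, "mother", Sex.FEMALE)):
            if pid == FOUNDER:
                continue
            if pid not in ped:
                err(m.id, f"{role} {pid!r} not present in family {ped.family_id}")
            elif ped[pid].sex is not want:
                err(m.id, f"{role} {pid!r} is not {want.value}")
        if (m.father_id == FOUNDER) != (m.mother_id == FOUNDER):
            err(m.id, "individuals must have both parents in the family or neither")
        if m.sex is Sex.MALE and m.s_obs is XObs.HET_CARRIER:
            err(m.id, "males cannot be heterozygous carriers at the X-linked locus")
        if m.sex is Sex.FEMALE and m.s_obs is XObs.HEMI_MUT:
            err(m.id, "females cannot be hemizygous at the X-linked locus")

    if sum(m.proband for m in ped.members) > 1:
        err(None, "more than one proband flagged")

    # ancestry cycles (someone their own ancestor)
    parent_graph = nx.DiGraph()
    parent_graph.add_nodes_from(m.id for m in ped.members)
    for m in ped.members:
        for pid in (m.father_id, m.mother_id):
            if pid != FOUNDER and pid in ped:
                parent_graph.add_edge(pid, m.id)
    try:
        cycle = nx.find_cycle(parent_graph)
        err(None, "ancestry cycle: " + " -> ".join(e[0] for e in cycle))
    except nx.NetworkXNoCycle:
        pass

    # inbreeding / marriage loops: the bipartite graph of nuclear units and
    # individuals must be a forest for exact peeling without loop-breaking
    if not any(i.severity == "error" for i in issues):
        g = nx.Graph()
        for unit in ped.nuclear_units():
            f, mo, kids = unit
            unode = ("U",) + unit[:2] + (kids,)
            for iid in (f, mo, *kids):
                g.add_edge(unode, ("I", iid))
        if g.number_of_nodes() and not nx.is_forest(g):
            cyc = nx.cycle_basis(g)[0]
            people = sorted(n[1] for n in cyc if n[0] == "I")
            err(None, "pedigree loop (inbreeding or marriage loop) involving: " + ", ".join(people))

        # local Mendelian checks from direct observations
        for m in ped.members:
            if m.is_founder or m.father_id not in ped or m.mother_id not in ped:
                continue
            fa, mo = ped[m.father_id], ped[m.mother_id]
            if m.sex is Sex.MALE and m.s_obs is XObs.HEMI_MUT and mo.s_obs is XObs.WT:
                err(m.id, "hemizygous mutant son of a mother observed wild type at the X locus", "observation")
            if m.sex is Sex.FEMALE and m.s_obs is XObs.WT and fa.s_obs is XObs.HEMI_MUT:
                err(m.id, "daughter of a hemizygous mutant father must carry his X allele", "observation")
            if (
                m.sex is Sex.FEMALE
                and m.s_obs is XObs.HET_CARRIER
                and fa.s_obs is XObs.WT
                and mo.s_obs is XObs.WT
            ):
                err(m.id, "carrier daughter of parents both observed wild type at the X locus", "observation")
            if m.t_obs is TObs.HET_MUT and fa.t_obs is TObs.HOM_WT and mo.t_obs is TObs.HOM_WT:
                err(m.id, "heterozygous child of parents both observed hom wt at the autosomal locus", "observation")

    return issues


def _require_valid(peds: Iterable[Pedigree]) -> None:
    """Raise on structural errors; observation conflicts are left to the
    likelihood engine, which reports them as a zero likelihood."""
    for ped in peds:
        errors = [i for i in validate_pedigree(ped) if i.severity == "error" and i.kind == "structure"]
        if errors:
            raise PedigreeError(
                f"family {ped.family_id}: "
                + "; ".join(
                    (f"{i.individual_id}: {i.message}" if i.individual_id else i.message)
                    for i in errors
                )
            )


# ---------------------------------------------------------------------------
# extended PED I/O

_N_COLS = 10
_HEADER = "#FID IID FAT MOT SEX PHENO S_OBS T_OBS XI PROBAND"


def read_pedigrees(path: str | Path) -> list[Pedigree]:
    """Read an extended-PED file; one validated Pedigree per family id."""
    rows: dict[str, list[Individual]] = {}
    order: list[str] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) != _N_COLS:
                raise PedigreeError(f"{path}:{lineno}: expected {_N_COLS} columns, got {len(cols)}")
            fid, iid, fat, mot, sex, pheno, sobs, tobs, xi, prob = cols
            try:
                ind = Individual(
                    id=iid,
                    father_id=fat,
                    mother_id=mot,
                    sex=_SEX_CODE[sex],
                    affection=_PHENO_CODE[pheno],
                    s_obs=_SOBS_CODE[sobs],
                    t_obs=_TOBS_CODE[tobs],
                    xi_status=_XI_CODE[xi],
                    proband=prob == "1",
                )
            except KeyError as exc:
                raise PedigreeError(f"{path}:{lineno}: bad code {exc.args[0]!r}") from None
            if fid not in rows:
                order.append(fid)
            rows.setdefault(fid, []).append(ind)
    peds = [Pedigree(fid, rows[fid]) for fid in order]
    _require_valid(peds)
    return peds


def write_pedigrees(peds: Sequence[Pedigree], path: str | Path) -> None:
    """Write pedigrees in the extended-PED dialect (round-trips exactly)."""
    _require_valid(peds)
    sex_i, ph_i, so_i, to_i, xi_i = map(_inv, (_SEX_CODE, _PHENO_CODE, _SOBS_CODE, _TOBS_CODE, _XI_CODE))
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(_HEADER + "\n")
        for ped in peds:
            for m in ped.members:
                fh.write(
                    " ".join(
                        (
                            ped.family_id,
                            m.id,
                            m.father_id,
                            m.mother_id,
                            sex_i[m.sex],
                            ph_i[m.affection],
                            so_i[m.s_obs],
                            to_i[m.t_obs],
                            xi_i[m.xi_status],
                            "1" if m.proband else "0",
                        )
                    )
                    + "\n"
                )


def pedigrees_to_json(peds: Sequence[Pedigree]) -> str:
    """JSON rendering of pedigrees for programmatic use."""
    doc = [
        {
            "family_id": p.family_id,
            "members": [
                {
                    "id": m.id,
                    "father_id": m.father_id,
                    "mother_id": m.mother_id,
                    "sex": m.sex.value,
                    "affection": m.affection.value,
                    "s_obs": m.s_obs.value,
                    "t_obs": m.t_obs.value,
                    "xi_status": m.xi_status.value,
                    "proband": m.proband,
                }
                for m in p.members
            ],
        }
        for p in peds
    ]
    return json.dumps(doc, indent=2)


def pedigrees_from_json(text: str) -> list[Pedigree]:
    peds = []
    for fam in json.loads(text):
        members = [
            Individual(
                id=m["id"],
                father_id=m.get("father_id", FOUNDER),
                mother_id=m.get("mother_id", FOUNDER),
                sex=Sex(m["sex"]),
                affection=Affection(m.get("affection", "unknown")),
                s_obs=XObs(m.get("s_obs", "unknown")),
                t_obs=TObs(m.get("t_obs", "unknown")),
                xi_status=XInactivation(m.get("xi_status", "unknown")),
                proband=bool(m.get("proband", False)),
            )
            for m in fam["members"]
        ]
        peds.append(Pedigree(fam["family_id"], members))
    _require_valid(peds)
    return peds
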