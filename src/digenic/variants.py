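"""Variant cohort tables and truncating-consequence classification.

A variant is *truncating* when it is a stop gain, a frameshift or an
essential splice-site change — the definition used to count truncating TTN
variants (TTNtv) per family.  The printed effect column of the cohort table
is authoritative; HGVS pattern heuristics are only a fallback for rows
without a stated effect.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd


class ConsequenceClass(str, Enum):
    STOP_GAIN = "stop_gain"
    FRAMESHIFT = "frameshift"
    ESSENTIAL_SPLICE = "essential_splice"
    OTHER_SPLICE_REGION = "other_splice_region"
    MISSENSE = "missense"
    INFRAME_INDEL = "inframe_indel"
    UNKNOWN = "unknown"

    @property
    def truncating(self) -> bool:
        return self in _TRUNCATING


_TRUNCATING = {
    ConsequenceClass.STOP_GAIN,
    ConsequenceClass.FRAMESHIFT,
    ConsequenceClass.ESSENTIAL_SPLICE,
}


@dataclass(frozen=True)
class VariantRecord:
    family_id: str
    gene: str
    hgvs_c: str = ""
    hgvs_p: str = ""
    stated_effect: str = ""
    exon_or_intron: str = ""
    band: str = ""
    control_freq: float | None = None

    def __post_init__(self):
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")
        if self.control_freq is not None and not (0.0 <= self.control_freq <= 1.0):
            raise ValueError(f"control_freq {self.control_freq} outside [0, 1]")


@dataclass(frozen=True)
class CohortCounts:
    """Per-cohort carrier counts of truncating TTN variants."""

    cohort_id: str
    n_units: int
    n_ttn_truncating: int
    unit: str = "family"

    def __post_init__(self):
        if not (0 <= self.n_ttn_truncating <= self.n_units):
            raise ValueError("need 0 <= n_ttn_truncating <= n_units")


class TableFormatError(ValueError):
    """Configuration/format problem in a variant table."""


_REQUIRED_COLUMNS = ("family_id", "gene", "hgvs_c", "hgvs_p", "effect", "exon", "band", "control_freq")

# stated-effect keywords, checked in order; any printed splice label counts
# as essential: the published tallies treat stated splice-site variants as
# truncating even when the position is beyond the +/-2 dinucleotide
_EFFECT_PATTERNS = (
    ("stop gain", ConsequenceClass.STOP_GAIN),
    ("stopgain", ConsequenceClass.STOP_GAIN),
    ("nonsense", ConsequenceClass.STOP_GAIN),
    ("frameshift", ConsequenceClass.FRAMESHIFT),
    ("splice", ConsequenceClass.ESSENTIAL_SPLICE),
    ("missense", ConsequenceClass.MISSENSE),
    ("inframe", ConsequenceClass.INFRAME_INDEL),
)

_INTRON_OFFSET = re.compile(r"[-+](\d+)(?:_[-+]?\d+)?(?:del|dup|ins|[ACGT]>)", re.IGNORECASE)


def classify_consequence(record: VariantRecord) -> ConsequenceClass:
    """Deterministic consequence class for one variant record.

    The stated effect takes precedence.  Without one, light HGVS pattern
    matching is used: ``*``/``Ter`` in the protein change means stop gain,
    ``fs`` frameshift, intronic positions at +/-1 or +/-2 essential splice
    (deeper intronic positions are ``other_splice_region``), and frame
    preserving del/dup/delins are inframe indels.  Unparseable input yields
    ``unknown`` with a warning, never a silent guess.
    """
    effect = record.stated_effect.strip().lower()
    if effect:
        for key, cls in _EFFECT_PATTERNS:
            if key in effect:
                return cls

    p = record.hgvs_p.strip()
    if re.search(r"fs", p):
        return ConsequenceClass.FRAMESHIFT
    if p.endswith("*") or p.endswith("Ter") or re.search(r"(\*|Ter)\d*$", p):
        return ConsequenceClass.STOP_GAIN

    c = record.hgvs_c.strip()
    m = _INTRON_OFFSET.search(c)
    if m:
        off = int(m.group(1))
        return ConsequenceClass.ESSENTIAL_SPLICE if off <= 2 else ConsequenceClass.OTHER_SPLICE_REGION
    if re.search(r"delins|del|dup", c) or re.search(r"delins|del|dup", p):
        # protein-level del/dup with no fs/Ter token preserves the frame
        if p and not re.search(r"fs|\*|Ter", p):
            return ConsequenceClass.INFRAME_INDEL
    if re.fullmatch(r"p\.[A-Z][a-z]{2}\d+[A-Z][a-z]{2}", p):
        return ConsequenceClass.MISSENSE

    warnings.warn(
        f"could not classify variant {record.gene} {record.hgvs_c!r} / {record.hgvs_p!r}; "
        "class set to unknown",
        stacklevel=2,
    )
    return ConsequenceClass.UNKNOWN


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read a tab-separated variant cohort table into records.

    The header must carry the columns ``family_id gene hgvs_c hgvs_p effect
    exon band control_freq``; empty cells mean "absent".  Records preserve
    input order; malformed rows raise :class:`TableFormatError` naming the
    row.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise TableFormatError(f"{path}: file has no header row") from None
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    if df.empty:
        warnings.warn(f"{path}: variant table has a header but no data rows", stacklevel=2)
        return []

    records: list[VariantRecord] = []
    for idx, row in df.iterrows():
        rowno = idx + 2  # header is line 1
        fam, gene = row["family_id"].strip(), row["gene"].strip()
        if not fam:
            raise TableFormatError(f"{path}: row {rowno}: missing value in column 'family_id'")
        if not gene:
            raise TableFormatError(f"{path}: row {rowno}: missing value in column 'gene'")
        freq_text = row["control_freq"].strip()
        freq: float | None = None
        if freq_text:
            try:
                freq = float(freq_text)
            except ValueError:
                raise TableFormatError(
                    f"{path}: row {rowno}: bad control_freq {freq_text!r}"
                ) from None
        try:
            records.append(
                VariantRecord(
                    family_id=fam,
                    gene=gene,
                    hgvs_c=row["hgvs_c"].strip(),
                    hgvs_p=row["hgvs_p"].strip(),
                    stated_effect=row["effect"].strip(),
                    exon_or_intron=row["exon"].strip(),
                    band=row["band"].strip(),
                    control_freq=freq,
                )
            )
        except ValueError as exc:
            raise TableFormatError(f"{path}: row {rowno}: {exc}") from None
    return records


def summarize_cohort(
    records: Iterable[VariantRecord],
    unit: str = "family",
    cohort_id: str = "cohort",
    gene: str = "TTN",
) -> CohortCounts:
    """Count units carrying at least one truncating variant in ``gene``.

    ``unit="family"`` groups records by family id (a family with two TTN
    variants counts once); ``unit="individual"`` treats each family's
    genotyped index case as one individual, which coincides with the family
    count for one-proband-per-family tables.
    """
    if unit not in ("family", "individual"):
        raise ValueError(f"unknown unit {unit!r}; expected 'family' or 'individual'")
    families: dict[str, bool] = {}
    for rec in records:
        families.setdefault(rec.family_id, False)
        if rec.gene == gene and classify_consequence(rec).truncating:
            families[rec.family_id] = True
    return CohortCounts(
        cohort_id=cohort_id,
        n_units=len(families),
        n_ttn_truncating=sum(families.values()),
        unit=unit,
    )


def load_study_cohort() -> list[VariantRecord]:
    """The packaged SRPK3/TTN 25-family cohort table."""
    with resources.as_file(resources.files("digenic.data") / "srpk3_ttn_cohort.tsv") as p:
        return read_variant_table(p)
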