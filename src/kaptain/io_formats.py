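"""Tabular input/output for the post-classification workflow.

Three table kinds are handled, all TSV with a header row:

* per-template classifier hits (a normalized dialect of KMA ``.res``-style
  output),
* reference metadata mapping template -> genome -> species with plasmid and
  superkingdom annotation,
* mock-community ground truths (species with optional sequence abundance).

All percentages are carried on the 0-100 scale throughout the package.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

SUPERKINGDOMS = frozenset(
    {"bacteria", "archaea", "fungi", "protozoa", "virus", "other"}
)


class SchemaError(ValueError):
    """A required column is missing or a table dialect is unknown."""


class ValidationError(ValueError):
    """A row violates a field invariant (range, consistency, uniqueness)."""


@dataclass(frozen=True)
class TemplateHit:
    """One classifier result row for a single reference template.

    ``template_identity_pct`` is the classifier's per-template identity:
    the number of bases of the read consensus identical to the template,
    divided by the full template length.  It therefore conflates breadth of
    coverage with similarity of the covered region: a 100-base template
    covered over 75 bases can reach at most 75%, and 5 mismatches inside the
    covered span lower it to 70%.

    ``identical_bases`` (the numerator) is reconstructed as
    ``round(identity / 100 * length)`` when the input table does not carry
    it explicitly; the relation is exactly invertible up to rounding.
    """

    template_id: str
    mapped_reads: int
    template_length: int
    template_identity_pct: float
    template_coverage_pct: float = 100.0
    identical_bases: int | None = None

    def __post_init__(self) -> None:
        if self.mapped_reads < 0:
            raise ValidationError(
                f"{self.template_id}: mapped_reads must be >= 0, "
                f"got {self.mapped_reads}"
            )
        if self.template_length <= 0:
            raise ValidationError(
                f"{self.template_id}: template_length must be positive, "
                f"got {self.template_length}"
            )
        for name in ("template_identity_pct", "template_coverage_pct"):
            value = getattr(self, name)
            if not 0.0 <= value <= 100.0:
                raise ValidationError(
                    f"{self.template_id}: {name} must lie in [0, 100], got {value}"
                )
        if self.identical_bases is None:
            object.__setattr__(
                self,
                "identical_bases",
                int(round(self.template_identity_pct / 100.0 * self.template_length)),
            )
        ib = self.identical_bases
        if not 0 <= ib <= self.template_length:
            raise ValidationError(
                f"{self.template_id}: identical_bases={ib} outside "
                f"[0, {self.template_length}]"
            )
        # rounding bound: the stated identity may be off by half a base
        tol = 0.5 / self.template_length * 100.0 + 1e-9
        implied = 100.0 * ib / self.template_length
        if abs(implied - self.template_identity_pct) > tol:
            raise ValidationError(
                f"{self.template_id}: identical_bases={ib} implies identity "
                f"{implied:.4f}% but table states "
                f"{self.template_identity_pct:.4f}% (tolerance {tol:.4f})"
            )

    @classmethod
    def from_alignment(
        cls,
        template_id: str,
        template_length: int,
        covered_bases: int,
        mismatches: int = 0,
        mapped_reads: int = 1,
    ) -> "TemplateHit":
        """Build a hit from an explicit alignment summary.

        ``covered_bases`` is the breadth of the template touched by the read
        consensus and ``mismatches`` the non-identical positions within that
        span, so ``identical_bases = covered_bases - mismatches``.
        """
        if not 0 <= covered_bases <= template_length:
            raise ValidationError(
                f"covered_bases={covered_bases} outside [0, {template_length}]"
            )
        if not 0 <= mismatches <= covered_bases:
            raise ValidationError(
                f"mismatches={mismatches} outside [0, {covered_bases}]"
            )
        identical = covered_bases - mismatches
        return cls(
            template_id=template_id,
            mapped_reads=mapped_reads,
            template_length=template_length,
            template_identity_pct=100.0 * identical / template_length,
            template_coverage_pct=100.0 * covered_bases / template_length,
            identical_bases=identical,
        )

    @property
    def covered_bases(self) -> int:
        """Breadth of the covered template span, never below identical_bases."""
        implied = int(round(self.template_coverage_pct / 100.0 * self.template_length))
        return max(implied, int(self.identical_bases))


@dataclass(frozen=True)
class GroundTruthEntry:
    """One expected species of a mock community.

    ``sequence_abundance_pct`` is the fraction of sequencing reads attributed
    to the species (sequence abundance, not cell counts); it is optional
    because some communities only publish a species list.  ``in_database``
    records whether the species has any genome in the reference metadata;
    species missing from the database still count as false negatives for
    precision/recall but are excluded from limit-of-detection analysis.
    """

    species_name: str
    sequence_abundance_pct: float | None = None
    in_database: bool = True

    def __post_init__(self) -> None:
        a = self.sequence_abundance_pct
        if a is not None and not 0.0 < a <= 100.0:
            raise ValidationError(
                f"{self.species_name}: sequence_abundance_pct must lie in "
                f"(0, 100], got {a}"
            )


@dataclass
class ReferenceMetadata:
    """Template -> genome -> species mapping with non-target annotation.

    Wraps a DataFrame indexed by ``template_id`` with columns
    ``genome_accession``, ``species_name``, ``taxid`` (nullable),
    ``is_plasmid`` and ``superkingdom``.
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("template_id", "genome_accession", "species_name",
                "is_plasmid", "superkingdom")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns
                   and c != "template_id"]
        if self.table.index.name != "template_id":
            if "template_id" not in self.table.columns:
                missing.append("template_id")
            else:
                self.table = self.table.set_index("template_id")
        if missing:
            raise SchemaError(f"reference metadata missing columns: {missing}")
        if "taxid" not in self.table.columns:
            self.table["taxid"] = pd.array([pd.NA] * len(self.table),
                                           dtype="Int64")
        dup = self.table.index[self.table.index.duplicated()].unique().tolist()
        if dup:
            raise ValidationError(f"duplicate template_id entries: {dup}")
        bad_sk = sorted(set(self.table["superkingdom"]) - SUPERKINGDOMS)
        if bad_sk:
            raise ValidationError(f"unknown superkingdom values: {bad_sk}")
        per_genome = self.table.groupby("genome_accession")["species_name"].nunique()
        conflicted = per_genome[per_genome > 1].index.tolist()
        if conflicted:
            raise ValidationError(
                f"genomes mapped to more than one species: {conflicted}"
            )

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, template_id: str) -> bool:
        return template_id in self.table.index

    def genome_of(self, template_id: str) -> str:
        return self.table.at[template_id, "genome_accession"]

    def species_of_genome(self, genome_accession: str) -> str:
        rows = self.table[self.table["genome_accession"] == genome_accession]
        return rows["species_name"].iloc[0]

    def is_plasmid(self, template_id: str) -> bool:
        return bool(self.table.at[template_id, "is_plasmid"])

    def is_viral(self, template_id: str) -> bool:
        return self.table.at[template_id, "superkingdom"] == "virus"


def flag_plasmid_from_description(description: str) -> bool:
    """Heuristic plasmid flag: the word 'plasmid' in a sequence description."""
    return "plasmid" in description.lower()


# ---------------------------------------------------------------------------
# per-template hit tables

#: canonical internal column names
_HIT_COLUMNS = ("template_id", "mapped_reads", "template_length",
                "template_identity_pct", "template_coverage_pct",
                "identical_bases")

#: column aliases per dialect; KMA versions differ in the exact header set,
#: so mapped-read counts accept several historical names.
_HIT_DIALECTS: dict[str, dict[str, tuple[str, ...]]] = {
    "kaptain": {
        "template_id": ("template_id",),
        "mapped_reads": ("mapped_reads",),
        "template_length": ("template_length",),
        "template_identity_pct": ("template_identity_pct",),
        "template_coverage_pct": ("template_coverage_pct",),
        "identical_bases": ("identical_bases",),
    },
    "kma": {
        "template_id": ("#Template", "Template"),
        "mapped_reads": ("Num_reads", "readCount", "readCountAln",
                         "fragmentCount", "fragmentCountAln"),
        "template_length": ("Template_length", "Template_Length"),
        "template_identity_pct": ("Template_Identity",),
        "template_coverage_pct": ("Template_Coverage",),
        "identical_bases": ("Identical_bases",),
    },
}

_OPTIONAL_HIT_FIELDS = frozenset({"identical_bases", "template_coverage_pct"})


def read_hits(path: str | Path, schema: str = "kaptain") -> list[TemplateHit]:
    """Read a per-template hit table in the given dialect.

    Rows failing a field invariant are rejected with their row number.
    Extra columns are ignored.
    """
    if schema not in _HIT_DIALECTS:
        raise SchemaError(
            f"unknown hit-table dialect {schema!r}; "
            f"known: {sorted(_HIT_DIALECTS)}"
        )
    aliases = _HIT_DIALECTS[schema]
    df = pd.read_csv(path, sep="\t", dtype=str)
    resolved: dict[str, str] = {}
    for canonical, names in aliases.items():
        found = next((n for n in names if n in df.columns), None)
        if found is None and canonical not in _OPTIONAL_HIT_FIELDS:
            raise SchemaError(
                f"{path}: missing required column {canonical!r} "
                f"(accepted names: {list(names)})"
            )
        if found is not None:
            resolved[canonical] = found

    hits: list[TemplateHit] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header=1
        rec = dict(zip(df.columns, row))
        try:
            kwargs: dict = {
                "template_id": str(rec[resolved["template_id"]]),
                "mapped_reads": int(rec[resolved["mapped_reads"]]),
                "template_length": int(rec[resolved["template_length"]]),
                "template_identity_pct": float(
                    rec[resolved["template_identity_pct"]]),
            }
            if "template_coverage_pct" in resolved:
                kwargs["template_coverage_pct"] = float(
                    rec[resolved["template_coverage_pct"]])
            if "identical_bases" in resolved:
                raw = rec[resolved["identical_bases"]]
                if raw is not None and not (isinstance(raw, float) and math.isnan(raw)):
                    kwargs["identical_bases"] = int(float(raw))
            hits.append(TemplateHit(**kwargs))
        except (ValueError, TypeError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValidationError(
            f"{path}: {len(errors)} invalid row(s):\n" + "\n".join(errors)
        )
    return hits


def write_hits(path: str | Path, hits: Iterable[TemplateHit]) -> None:
    """Write hits in the canonical dialect (all six columns)."""
    df = pd.DataFrame(
        [{c: getattr(h, c) for c in _HIT_COLUMNS} for h in hits],
        columns=list(_HIT_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reference metadata

def read_reference_metadata(path: str | Path) -> ReferenceMetadata:
    df = pd.read_csv(
        path, sep="\t",
        dtype={"template_id": str, "genome_accession": str,
               "species_name": str, "superkingdom": str},
    )
    missing = [c for c in ReferenceMetadata.REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    df["is_plasmid"] = df["is_plasmid"].map(_parse_bool)
    if "taxid" in df.columns:
        df["taxid"] = df["taxid"].astype("Int64")
    return ReferenceMetadata(df)


def write_reference_metadata(path: str | Path, meta: ReferenceMetadata) -> None:
    meta.table.reset_index().to_csv(path, sep="\t", index=False)


def _parse_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in {"true", "1", "yes", "t"}:
        return True
    if text in {"false", "0", "no", "f"}:
        return False
    raise ValidationError(f"cannot parse boolean value {value!r}")


# ---------------------------------------------------------------------------
# ground truths

def read_ground_truth(
    path: str | Path, sum_tolerance_pct: float = 1.0
) -> list[GroundTruthEntry]:
    """Read a mock-community composition table.

    The ``species_name`` column is mandatory; ``sequence_abundance_pct`` and
    ``in_database`` are optional.  When every entry carries an abundance the
    values are expected to sum to 100; deviations are rescaled to exactly
    100, with a warning when the deviation exceeds ``sum_tolerance_pct``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"species_name": str})
    if "species_name" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'species_name'")
    entries: list[GroundTruthEntry] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        abundance = rec.get("sequence_abundance_pct")
        if abundance is not None and (
            isinstance(abundance, float) and math.isnan(abundance)
        ):
            abundance = None
        try:
            entries.append(
                GroundTruthEntry(
                    species_name=str(rec["species_name"]),
                    sequence_abundance_pct=(
                        float(abundance) if abundance is not None else None
                    ),
                    in_database=_parse_bool(rec.get("in_database", True)),
                )
            )
        except ValueError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return normalize_abundances(entries, sum_tolerance_pct=sum_tolerance_pct)


def normalize_abundances(
    entries: Sequence[GroundTruthEntry], sum_tolerance_pct: float = 1.0
) -> list[GroundTruthEntry]:
    """Rescale abundances to sum to exactly 100 when all are present."""
    entries = list(entries)
    abundances = [e.sequence_abundance_pct for e in entries]
    if not entries or any(a is None for a in abundances):
        return entries
    total = sum(abundances)
    if abs(total - 100.0) < 1e-9:
        return entries
    if abs(total - 100.0) > sum_tolerance_pct:
        logger.warning(
            "ground-truth abundances sum to %.4f%% (deviation beyond "
            "tolerance %.2f); rescaling to 100%%", total, sum_tolerance_pct,
        )
    return [
        replace(e, sequence_abundance_pct=e.sequence_abundance_pct * 100.0 / total)
        for e in entries
    ]


def write_ground_truth(path: str | Path, entries: Iterable[GroundTruthEntry]) -> None:
    df = pd.DataFrame(
        [
            {
                "species_name": e.species_name,
                "sequence_abundance_pct": e.sequence_abundance_pct,
                "in_database": e.in_database,
            }
            for e in entries
        ],
        columns=["species_name", "sequence_abundance_pct", "in_database"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# species-name synonyms

def read_synonyms(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (old name -> harmonized name)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["old", "new"], dtype=str)
    if df.isna().any().any():
        raise ValidationError(f"{path}: synonym table must have two columns per row")
    return dict(zip(df["old"], df["new"]))


def apply_synonyms(names: Iterable[str], synonyms: Mapping[str, str] | None) -> set[str]:
    """Harmonize species names through an optional synonym table."""
    if not synonyms:
        return set(names)
    return {synonyms.get(n, n) for n in names}
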