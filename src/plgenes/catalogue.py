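"""Literature-derived pregnancy-loss variant catalogue: model, I/O, strata.

The catalogue aggregates published case reports of euploid pregnancy loss
attributed to point mutations. One :class:`CatalogueRecord` is one reported
case; a compound-heterozygous pair reported for a single fetus is a single
record carrying two variant strings. :func:`summarize` reproduces the
headline catalogue statistics (distinct genes and variants, genes reported
by multiple independent studies, genes with multiple distinct variants) and
:func:`stratify` splits records by recurrence (RPL vs non-RPL) or by
pregnancy outcome.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .symbols import normalize_symbol


class CatalogueError(ValueError):
    """Base class for catalogue schema/parse failures."""


class SchemaError(CatalogueError):
    """The file header does not provide the required columns."""


class ParseError(CatalogueError):
    """A row holds a token that cannot be mapped onto the record schema."""


class Origin(str, enum.Enum):
    """Parental origin of the reported variant(s).

    ``UNCERTAIN`` marks cases where parental genotypes were not evaluated
    but the variant was homozygous or compound heterozygous in the fetus;
    ``UNKNOWN`` marks cases where origin was simply not reported.
    """

    INHERITED = "inherited"
    DE_NOVO = "de_novo"
    UNCERTAIN = "uncertain"
    UNKNOWN = "unknown"


class Outcome(str, enum.Enum):
    MISCARRIAGE = "miscarriage"
    TERMINATION = "termination"
    FETAL_DEMISE = "fetal_demise"
    STILLBIRTH = "stillbirth"
    NEONATAL_DEATH = "neonatal_death"
    FETAL_DEATH = "fetal_death"
    RPL = "rpl"


# Case-insensitive source-token normalization. Unknown tokens raise; nothing
# is silently mapped.
_ORIGIN_TOKENS: dict[str, Origin] = {
    "inherited": Origin.INHERITED,
    "de novo": Origin.DE_NOVO,
    "de_novo": Origin.DE_NOVO,
    "denovo": Origin.DE_NOVO,
    "uncertain": Origin.UNCERTAIN,
    "n.a.": Origin.UNKNOWN,
    "na": Origin.UNKNOWN,
    "unknown": Origin.UNKNOWN,
    "": Origin.UNKNOWN,
}

_OUTCOME_TOKENS: dict[str, Outcome] = {
    "miscarriage": Outcome.MISCARRIAGE,
    "spontaneous abortion": Outcome.MISCARRIAGE,
    "termination": Outcome.TERMINATION,
    "fetal demise": Outcome.FETAL_DEMISE,
    "fetal_demise": Outcome.FETAL_DEMISE,
    "stillbirth": Outcome.STILLBIRTH,
    "neonatal death": Outcome.NEONATAL_DEATH,
    "neonatal_death": Outcome.NEONATAL_DEATH,
    "fetal death": Outcome.FETAL_DEATH,
    "fetal_death": Outcome.FETAL_DEATH,
    "rpl": Outcome.RPL,
}

_BOOL_TOKENS: dict[str, bool | None] = {
    "true": True,
    "false": False,
    "yes": True,
    "no": False,
    "1": True,
    "0": False,
    "": None,
    "unknown": None,
    "na": None,
    "n.a.": None,
}


def parse_origin(token: str) -> Origin:
    try:
        return _ORIGIN_TOKENS[token.strip().lower()]
    except KeyError:
        raise ParseError(f"unknown variant-origin token: {token!r}") from None


def parse_outcome(token: str) -> Outcome:
    try:
        return _OUTCOME_TOKENS[token.strip().lower()]
    except KeyError:
        raise ParseError(f"unknown pregnancy-outcome token: {token!r}") from None


@dataclass(frozen=True)
class CatalogueRecord:
    """One reported pregnancy-loss case attributed to coding variant(s).

    ``variants`` holds one HGVS-like string, or two for a compound-
    heterozygous pair reported as a single case. ``recurrent`` is True for
    cases from recurrent pregnancy loss, False for explicitly sporadic
    ones, and None when recurrence was not reported. A record with outcome
    RPL is forced to ``recurrent=True``.
    """

    gene: str
    variants: tuple[str, ...]
    origin: Origin = Origin.UNKNOWN
    outcome: Outcome = Outcome.MISCARRIAGE
    recurrent: bool | None = None
    study_id: str = ""
    transcript: str | None = None
    gestational_age_weeks: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", normalize_symbol(self.gene))
        variants = tuple(str(v).strip() for v in self.variants if str(v).strip())
        if not 1 <= len(variants) <= 2:
            raise CatalogueError(
                f"{self.gene}: a case carries 1 or 2 variants, got {len(variants)}"
            )
        object.__setattr__(self, "variants", variants)
        if not isinstance(self.origin, Origin):
            object.__setattr__(self, "origin", parse_origin(str(self.origin)))
        if not isinstance(self.outcome, Outcome):
            object.__setattr__(self, "outcome", parse_outcome(str(self.outcome)))
        if self.outcome is Outcome.RPL:
            object.__setattr__(self, "recurrent", True)

    @property
    def normalized_variants(self) -> tuple[str, ...]:
        """Variant strings with any transcript prefix and spacing stripped.

        This is the identity used for distinct-variant counting, so the
        same change reported against two transcript versions collapses.
        """
        out = []
        for v in self.variants:
            v = v.split(":", 1)[-1].strip()
            out.append(" ".join(v.split()))
        return tuple(out)


@dataclass(frozen=True)
class Stratum:
    """Records and distinct-gene set of one stratum."""

    genes: frozenset[str]
    records: tuple[CatalogueRecord, ...]

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def n_distinct_variants(self) -> int:
        return len({v for r in self.records for v in r.normalized_variants})


@dataclass(frozen=True)
class CatalogueSummary:
    """Headline counts over a catalogue.

    ``n_variant_entries`` counts every variant string (a compound-het pair
    contributes 2); ``n_distinct_variants`` deduplicates the transcript-
    stripped strings — both are exposed because recurrent variants may be
    reported by more than one study.
    """

    n_records: int
    n_variant_entries: int
    n_distinct_variants: int
    n_genes: int
    multi_study_genes: frozenset[str]
    multi_variant_genes: frozenset[str]
    strata: Mapping[str, Stratum] = field(default_factory=dict)


#: Canonical TSV dialect: header names and the variant-join separator.
CANONICAL_COLUMNS = (
    "gene",
    "transcript",
    "variants",
    "origin",
    "outcome",
    "recurrent",
    "study_id",
    "gestational_age_weeks",
)
VARIANT_SEPARATOR = ";"


@dataclass(frozen=True)
class CatalogueDialect:
    """Maps file columns onto the record schema.

    Only ``gene`` and ``variants`` are mandatory in the file; every other
    column falls back to the record default when absent.
    """

    gene: str = "gene"
    variants: str = "variants"
    origin: str = "origin"
    outcome: str = "outcome"
    recurrent: str = "recurrent"
    study_id: str = "study_id"
    transcript: str = "transcript"
    gestational_age_weeks: str = "gestational_age_weeks"
    variant_separator: str = VARIANT_SEPARATOR


CANONICAL_DIALECT = CatalogueDialect()


def load_catalogue(
    path: str | Path,
    dialect: CatalogueDialect = CANONICAL_DIALECT,
    alias_map: Mapping[str, str] | None = None,
) -> list[CatalogueRecord]:
    """Read a catalogue TSV into a list of records.

    Raises :class:`SchemaError` when the gene or variants column is
    missing, and :class:`ParseError` (naming the offending row) for
    unmappable origin/outcome tokens.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for required in (dialect.gene, dialect.variants):
            if required not in header:
                raise SchemaError(f"{path}: missing required column {required!r}")
        records: list[CatalogueRecord] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                gene = normalize_symbol(row[dialect.gene], alias_map)
                variants = tuple(
                    v.strip()
                    for v in (row[dialect.variants] or "").split(dialect.variant_separator)
                    if v.strip()
                )
                ga_raw = (row.get(dialect.gestational_age_weeks) or "").strip()
                rec_raw = (row.get(dialect.recurrent) or "").strip().lower()
                if rec_raw not in _BOOL_TOKENS:
                    raise ParseError(f"unknown recurrence token: {rec_raw!r}")
                records.append(
                    CatalogueRecord(
                        gene=gene,
                        variants=variants,
                        origin=parse_origin(row.get(dialect.origin) or ""),
                        outcome=parse_outcome(row.get(dialect.outcome) or ""),
                        recurrent=_BOOL_TOKENS[rec_raw],
                        study_id=(row.get(dialect.study_id) or "").strip(),
                        transcript=(row.get(dialect.transcript) or "").strip() or None,
                        gestational_age_weeks=float(ga_raw) if ga_raw else None,
                    )
                )
            except CatalogueError as exc:
                raise type(exc)(f"{path}: row {lineno}: {exc}") from None
            except ValueError as exc:
                raise ParseError(f"{path}: row {lineno}: {exc}") from None
    return records


def write_catalogue(
    records: Iterable[CatalogueRecord],
    path: str | Path,
    dialect: CatalogueDialect = CANONICAL_DIALECT,
) -> None:
    """Serialize records in the canonical TSV dialect (round-trip safe)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CANONICAL_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.gene,
                    r.transcript or "",
                    dialect.variant_separator.join(r.variants),
                    r.origin.value,
                    r.outcome.value,
                    "" if r.recurrent is None else str(r.recurrent).lower(),
                    r.study_id,
                    "" if r.gestational_age_weeks is None else f"{r.gestational_age_weeks:g}",
                ]
            )


RECURRENCE_SCHEME = "recurrence"
OUTCOME_SCHEME = "outcome"

# Outcome-scheme labels. RPL cases are recurrent miscarriages, so they fold
# into the miscarriage/stillbirth group; neonatal death is kept apart so the
# scheme partitions every record.
_OUTCOME_GROUPS: dict[Outcome, str] = {
    Outcome.MISCARRIAGE: "miscarriage_stillbirth",
    Outcome.STILLBIRTH: "miscarriage_stillbirth",
    Outcome.FETAL_DEATH: "miscarriage_stillbirth",
    Outcome.RPL: "miscarriage_stillbirth",
    Outcome.TERMINATION: "termination",
    Outcome.FETAL_DEMISE: "demise_or_termination",
    Outcome.NEONATAL_DEATH: "neonatal_death",
}


def stratify(
    records: Sequence[CatalogueRecord], scheme: str = RECURRENCE_SCHEME
) -> dict[str, Stratum]:
    """Partition records by recurrence or by pregnancy outcome.

    The recurrence scheme yields ``rpl`` (recurrent=True) and ``non_rpl``
    (False or not reported). The outcome scheme yields the groups of
    ``_OUTCOME_GROUPS``; every record lands in exactly one stratum.
    """
    if scheme == RECURRENCE_SCHEME:
        labeller = lambda r: "rpl" if r.recurrent else "non_rpl"  # noqa: E731
        labels = ["rpl", "non_rpl"]
    elif scheme == OUTCOME_SCHEME:
        labeller = lambda r: _OUTCOME_GROUPS[r.outcome]  # noqa: E731
        labels = list(dict.fromkeys(_OUTCOME_GROUPS.values()))
    else:
        raise ValueError(f"unknown stratification scheme: {scheme!r}")

    buckets: dict[str, list[CatalogueRecord]] = {label: [] for label in labels}
    for record in records:
        buckets[labeller(record)].append(record)
    return {
        label: Stratum(
            genes=frozenset(r.gene for r in recs), records=tuple(recs)
        )
        for label, recs in buckets.items()
    }


def summarize(records: Sequence[CatalogueRecord]) -> CatalogueSummary:
    """Compute the headline catalogue counts.

    Multi-study membership requires >=2 distinct non-empty ``study_id``
    values for a gene; multi-variant membership requires >=2 distinct
    transcript-stripped variant strings. The two sets are not nested: one
    study may report the same recurrent variant in two cases.
    """
    genes: set[str] = set()
    variants: set[str] = set()
    n_entries = 0
    studies_by_gene: dict[str, set[str]] = {}
    variants_by_gene: dict[str, set[str]] = {}
    for r in records:
        genes.add(r.gene)
        n_entries += len(r.variants)
        variants.update(r.normalized_variants)
        variants_by_gene.setdefault(r.gene, set()).update(r.normalized_variants)
        if r.study_id:
            studies_by_gene.setdefault(r.gene, set()).add(r.study_id)

    def canonical(stratum: Stratum) -> Stratum:
        # summaries are permutation-invariant, so strata store records in
        # a canonical order rather than input order
        key = lambda r: (r.gene, r.variants, r.study_id, r.outcome.value, r.origin.value)  # noqa: E731
        return Stratum(genes=stratum.genes, records=tuple(sorted(stratum.records, key=key)))

    strata = {k: canonical(s) for k, s in stratify(records, RECURRENCE_SCHEME).items()}
    strata.update(
        {k: canonical(s) for k, s in stratify(records, OUTCOME_SCHEME).items()}
    )
    return CatalogueSummary(
        n_records=len(records),
        n_variant_entries=n_entries,
        n_distinct_variants=len(variants),
        n_genes=len(genes),
        multi_study_genes=frozenset(
            g for g, studies in studies_by_gene.items() if len(studies) >= 2
        ),
        multi_variant_genes=frozenset(
            g for g, vs in variants_by_gene.items() if len(vs) >= 2
        ),
        strata=strata,
    )
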