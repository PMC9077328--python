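"""Population variant tables: parsing, HGVS protein consequences, filtering.

This module ingests per-gene variant tables in the CSV dialect exported by
the gnomAD browser (one row per variant; protein consequence in HGVS ``p.``
notation; VEP consequence class; optional ClinVar clinical significance;
allele count / number / frequency) and reduces them to a putatively neutral
missense set: VEP class must be missense, and variants carrying a ClinVar
classification in the pathogenic / likely-pathogenic / conflicting /
uncertain classes are removed.  Benign-class and unannotated variants are
kept — absence of a ClinVar record is the common case for rare alleles and
does not argue against neutrality.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, DataError

__all__ = [
    "AA_THREE_TO_ONE",
    "VariantRecord",
    "HgvsParseFailure",
    "FilterPolicy",
    "FilterResult",
    "ParseResult",
    "ConstraintMetrics",
    "DEFAULT_COLUMNS",
    "parse_hgvs_protein",
    "parse_variant_table",
    "records_from_frame",
    "filter_neutral_missense",
    "write_variant_table",
    "read_constraint_metrics",
]

# Three-letter to one-letter amino-acid codes, plus the stop codon ("Ter").
AA_THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "*",
}

#: Default gnomAD v2 browser export column names.
DEFAULT_COLUMNS = {
    "hgvs_p": "Protein Consequence",
    "vep": "VEP Annotation",
    "clinvar": "ClinVar Clinical Significance",
    "allele_count": "Allele Count",
    "allele_number": "Allele Number",
    "allele_frequency": "Allele Frequency",
    "chromosome": "Chromosome",
    "position": "Position",
    "reference": "Reference",
    "alternate": "Alternate",
}

_MANDATORY = ("hgvs_p", "vep", "allele_count", "allele_number", "allele_frequency")


@dataclass(frozen=True)
class HgvsParseFailure:
    """Typed parse failure for a protein consequence string.

    Returned (never raised) by :func:`parse_hgvs_protein` for consequences
    that are not simple substitutions — frameshifts, deletions, duplications,
    unknown effects ("?"), synonymous-equals notation — or malformed text.
    """

    text: str
    reason: str

    def __bool__(self) -> bool:  # a failure is falsy
        return False


_HGVS_SUB = re.compile(
    r"^p\.\(?([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})\)?$"
)
_HGVS_REJECT = re.compile(r"(fs|del|dup|ins|ext|=|\?)")


def parse_hgvs_protein(s: str) -> tuple[str, int, str] | HgvsParseFailure:
    """Parse an HGVS ``p.`` substitution into ``(ref_aa, position, alt_aa)``.

    Residues are given in three-letter code and returned in one-letter code
    (the stop codon ``Ter`` maps to ``*``).  Non-substitution consequences
    (frameshift, del, dup, ins, extension, ``p.Met1?``, ``p.X123=``) and
    malformed strings yield an :class:`HgvsParseFailure` carrying the text.

    >>> parse_hgvs_protein("p.Arg123Cys")
    ('R', 123, 'C')
    """
    text = s.strip()
    if not text.startswith("p."):
        return HgvsParseFailure(s, "does not start with 'p.'")
    if _HGVS_REJECT.search(text):
        return HgvsParseFailure(s, "not a simple substitution")
    m = _HGVS_SUB.match(text)
    if m is None:
        return HgvsParseFailure(s, "unrecognised protein consequence")
    ref3, pos, alt3 = m.groups()
    try:
        ref = AA_THREE_TO_ONE[ref3]
        alt = AA_THREE_TO_ONE[alt3]
    except KeyError:
        return HgvsParseFailure(s, "unknown residue code")
    position = int(pos)
    if position < 1:
        return HgvsParseFailure(s, "position must be >= 1")
    return ref, position, alt


@dataclass(frozen=True)
class VariantRecord:
    """One row of a population variant table.

    ``position`` is the 1-based residue index on the UniProt canonical
    sequence; ``clinvar_significance`` is ``None`` when the variant has no
    ClinVar entry (or the table has no ClinVar column).
    """

    protein_id: str
    hgvs_p: str
    ref_aa: str
    position: int
    alt_aa: str
    vep_annotation: str
    allele_count: int
    allele_number: int
    allele_frequency: float
    clinvar_significance: str | None = None
    genomic_locus: tuple[str, int, str, str] | None = None
    source_row: int | None = field(default=None, compare=False)


@dataclass
class ParseResult:
    """Records plus a parse report (rows skipped and why)."""

    records: list[VariantRecord]
    n_rows: int = 0
    n_skipped_consequence: int = 0   # empty or non-substitution HGVS p.
    n_skipped_malformed: int = 0     # AN = 0, AF outside [0,1], bad numbers
    clinvar_column_present: bool = True

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _resolve_columns(
    header: Sequence[str], column_map: Mapping[str, str] | None
) -> dict[str, str]:
    names = dict(DEFAULT_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(DEFAULT_COLUMNS)
        if unknown:
            raise ConfigurationError(
                f"unknown column_map keys: {sorted(unknown)}; "
                f"valid keys: {sorted(DEFAULT_COLUMNS)}"
            )
        names.update(column_map)
    for key in _MANDATORY:
        if names[key] not in header:
            raise ConfigurationError(
                f"mandatory column {names[key]!r} (for {key}) not found in header"
            )
    return names


def records_from_frame(
    df: pd.DataFrame,
    protein_id: str = "protein",
    column_map: Mapping[str, str] | None = None,
) -> ParseResult:
    """Build :class:`VariantRecord` objects from an in-memory table.

    Shares all parsing rules with :func:`parse_variant_table`; rows whose
    protein consequence is empty or not a substitution are skipped and
    counted, as are rows with unusable allele statistics.
    """
    cols = _resolve_columns(list(df.columns), column_map)
    has_clinvar = cols["clinvar"] in df.columns
    has_locus = all(
        cols[k] in df.columns for k in ("chromosome", "position", "reference", "alternate")
    )
    result = ParseResult(records=[], clinvar_column_present=has_clinvar)

    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        result.n_rows += 1
        hgvs = str(row[cols["hgvs_p"]]).strip()
        parsed = parse_hgvs_protein(hgvs) if hgvs else HgvsParseFailure(hgvs, "empty")
        if isinstance(parsed, HgvsParseFailure):
            result.n_skipped_consequence += 1
            continue
        ref_aa, position, alt_aa = parsed
        try:
            ac = int(row[cols["allele_count"]])
            an = int(row[cols["allele_number"]])
            af = float(row[cols["allele_frequency"]])
        except (TypeError, ValueError):
            result.n_skipped_malformed += 1
            continue
        if ac < 0 or an <= 0 or not (0.0 <= af <= 1.0):
            result.n_skipped_malformed += 1
            continue
        # The table's AF column is typically a rounded rendition of AC/AN;
        # recompute so the stored frequency is exactly consistent.  A gross
        # mismatch (>1e-3 relative, i.e. beyond rounding) marks the row malformed.
        exact = ac / an
        if af > 0 and abs(af - exact) > 1e-3 * max(af, exact):
            result.n_skipped_malformed += 1
            continue
        locus = None
        if has_locus:
            try:
                locus = (
                    str(row[cols["chromosome"]]),
                    int(row[cols["position"]]),
                    str(row[cols["reference"]]),
                    str(row[cols["alternate"]]),
                )
            except (TypeError, ValueError):
                locus = None
        clinvar = None
        if has_clinvar:
            raw = str(row[cols["clinvar"]]).strip()
            clinvar = raw if raw else None
        result.records.append(
            VariantRecord(
                protein_id=protein_id,
                hgvs_p=hgvs,
                ref_aa=ref_aa,
                position=position,
                alt_aa=alt_aa,
                vep_annotation=str(row[cols["vep"]]).strip(),
                allele_count=ac,
                allele_number=an,
                allele_frequency=exact,
                clinvar_significance=clinvar,
                genomic_locus=locus,
                source_row=i,
            )
        )
    return result


def parse_variant_table(
    path: str | Path,
    protein_id: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> ParseResult:
    """Read a gnomAD-style CSV export into :class:`VariantRecord` objects.

    ``column_map`` overrides the default gnomAD v2 column names (keys are the
    logical names in :data:`DEFAULT_COLUMNS`).  A missing mandatory column
    raises :class:`~missensemap.errors.ConfigurationError` naming it; rows
    with an empty or non-substitution protein consequence are skipped and
    counted in the returned report.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except OSError:
        raise
    except Exception as exc:  # pandas parser errors -> DataError
        raise DataError(f"cannot parse CSV {path}: {exc}") from exc
    return records_from_frame(
        df, protein_id=protein_id or path.stem, column_map=column_map
    )


def _normalise_token(s: str) -> str:
    return re.sub(r"\s+", " ", s.strip().lower())


@dataclass(frozen=True)
class FilterPolicy:
    """Which VEP classes are accepted and which ClinVar classes are excluded.

    ClinVar matching is case- and whitespace-insensitive; multi-valued cells
    such as ``"Pathogenic/Likely pathogenic"`` are split on ``/`` and ``;``
    and excluded if any token matches an excluded class.
    """

    required_vep: frozenset[str] = frozenset({"missense_variant", "missense"})
    excluded_clinvar: frozenset[str] = frozenset(
        {
            "pathogenic",
            "likely pathogenic",
            "conflicting interpretations of pathogenicity",
            "uncertain significance",
        }
    )
    keep_unannotated_clinvar: bool = True

    def __post_init__(self) -> None:
        if not self.required_vep:
            raise ConfigurationError("FilterPolicy.required_vep must be non-empty")
        object.__setattr__(
            self, "required_vep", frozenset(_normalise_token(v) for v in self.required_vep)
        )
        object.__setattr__(
            self,
            "excluded_clinvar",
            frozenset(_normalise_token(v) for v in self.excluded_clinvar),
        )

    def vep_accepted(self, annotation: str) -> bool:
        return _normalise_token(annotation) in self.required_vep

    def clinvar_accepted(self, significance: str | None) -> bool:
        if significance is None or not significance.strip():
            return self.keep_unannotated_clinvar
        tokens = re.split(r"[/;]", significance)
        return not any(_normalise_token(t) in self.excluded_clinvar for t in tokens if t.strip())


@dataclass
class FilterResult:
    """Retained records plus counts removed per rule."""

    records: list[VariantRecord]
    n_input: int = 0
    n_removed_vep: int = 0
    n_removed_clinvar: int = 0
    n_removed_duplicate: int = 0

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def filter_neutral_missense(
    records: Iterable[VariantRecord],
    policy: FilterPolicy | None = None,
    deduplicate: bool = False,
) -> FilterResult:
    """Reduce parsed records to the neutral missense set.

    A record is retained iff its VEP class is accepted by the policy and its
    ClinVar significance is absent, benign-class, or otherwise not excluded.
    Input order is preserved and the operation is idempotent.  With
    ``deduplicate=True``, repeated genomic loci (or, lacking a locus, repeated
    (hgvs_p, allele_count, allele_number) triples) keep only the first copy.
    """
    policy = policy or FilterPolicy()
    result = FilterResult(records=[])
    seen: set = set()
    for rec in records:
        result.n_input += 1
        if not policy.vep_accepted(rec.vep_annotation):
            result.n_removed_vep += 1
            continue
        if not policy.clinvar_accepted(rec.clinvar_significance):
            result.n_removed_clinvar += 1
            continue
        if deduplicate:
            key = rec.genomic_locus or (rec.hgvs_p, rec.allele_count, rec.allele_number)
            if key in seen:
                result.n_removed_duplicate += 1
                continue
            seen.add(key)
        result.records.append(rec)
    return result


def write_variant_table(
    path: str | Path,
    records: Sequence[VariantRecord],
    retained: Sequence[bool] | None = None,
) -> None:
    """Write records back out in the same CSV dialect that is parsed.

    With ``retained`` given (one flag per record), an extra boolean
    ``retained`` column is appended — the audit-mode output.
    """
    cols = DEFAULT_COLUMNS
    has_locus = any(r.genomic_locus for r in records)
    header = [cols["hgvs_p"], cols["vep"], cols["clinvar"],
              cols["allele_count"], cols["allele_number"], cols["allele_frequency"]]
    if has_locus:
        header = [cols["chromosome"], cols["position"], cols["reference"],
                  cols["alternate"]] + header
    if retained is not None:
        header = header + ["retained"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for i, rec in enumerate(records):
            row = []
            if has_locus:
                locus = rec.genomic_locus or ("", "", "", "")
                row += [str(locus[0]), str(locus[1]), str(locus[2]), str(locus[3])]
            row += [
                rec.hgvs_p,
                rec.vep_annotation,
                rec.clinvar_significance or "",
                str(rec.allele_count),
                str(rec.allele_number),
                repr(rec.allele_frequency),
            ]
            if retained is not None:
                row.append(str(bool(retained[i])))
            writer.writerow(row)


@dataclass(frozen=True)
class ConstraintMetrics:
    """Externally supplied gene-level constraint scores (metadata only)."""

    protein_id: str
    missense_z: float
    loeuf: float
    pli: float | None = None
    rvis: float | None = None


def read_constraint_metrics(path: str | Path) -> dict[str, ConstraintMetrics]:
    """Read a per-gene constraint-metric CSV (gene, missense_z, loeuf[, pli, rvis])."""
    df = pd.read_csv(path)
    lower = {c.lower().strip(): c for c in df.columns}
    try:
        gene_col = lower.get("gene") or lower["protein_id"]
        z_col = lower["missense_z"]
        loeuf_col = lower["loeuf"]
    except KeyError as exc:
        raise ConfigurationError(f"constraint table missing column: {exc}") from exc
    out: dict[str, ConstraintMetrics] = {}
    for _, row in df.iterrows():
        out[str(row[gene_col])] = ConstraintMetrics(
            protein_id=str(row[gene_col]),
            missense_z=float(row[z_col]),
            loeuf=float(row[loeuf_col]),
            pli=float(row[lower["pli"]]) if "pli" in lower else None,
            rvis=float(row[lower["rvis"]]) if "rvis" in lower else None,
        )
    return out
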