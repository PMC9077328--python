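"""Per-residue aggregation of allele frequencies and the 6-bin log scale.

Several distinct substitutions can report at the same residue position
(multiallelic sites).  Treating the alleles as disjoint events, their
frequencies are summed into one per-residue frequency, which is then placed
on a base-10 log scale and sorted into 6 bins:

    bin 1: AF <= 1e-5   (everything below 1e-5, including AF < 1e-6)
    bin k: 10^(k-6) < AF <= 10^(k-5)   for k = 2..6

Intervals are half-open on the left and closed on the right, so AF = 1e-4
falls in bin 2 and AF = 1 in bin 6.  The whole-protein variant density Vp is
the fraction of residues carrying at least one retained missense variant.
"""

from __future__ import annotations

import bisect
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import DataError
from .variants import VariantRecord

__all__ = [
    "BIN_EDGES",
    "N_BINS",
    "ResidueAggregate",
    "ResidueProfile",
    "AggregationReport",
    "assign_frequency_bin",
    "aggregate_by_residue",
    "write_profile_tsv",
    "read_profile_tsv",
]

N_BINS = 6
#: Upper edges of bins 1..5; bin 6 is capped by AF = 1.
BIN_EDGES = (1e-5, 1e-4, 1e-3, 1e-2, 1e-1)


def assign_frequency_bin(af: float) -> int:
    """Assign a summed allele frequency in (0, 1] to its bin (1..6).

    Monotone non-decreasing in ``af``; exact powers of ten sit at the top of
    their bin (closed right edge).
    """
    if not (0.0 < af <= 1.0):
        raise ValueError(f"allele frequency must be in (0, 1], got {af!r}")
    # number of edges strictly below af; bisect_left returns the first index
    # with edge >= af, i.e. edges equal to af are not counted.
    return bisect.bisect_left(BIN_EDGES, af) + 1


@dataclass(frozen=True)
class ResidueAggregate:
    """Aggregated variation at one residue position."""

    position: int
    summed_af: float
    n_variants: int
    bin_index: int


@dataclass
class AggregationReport:
    """Records dropped or adjusted while aggregating."""

    n_records: int = 0
    n_dropped_zero_af: int = 0
    n_out_of_range: int = 0
    n_capped: int = 0


@dataclass
class ResidueProfile:
    """Per-residue aggregates over one protein.

    ``vp`` is |variable positions| / protein_length — the average density of
    missense-variable residues used as the whole-protein normaliser of the
    Vd/Vp ratio.
    """

    protein_id: str
    protein_length: int
    aggregates: dict[int, ResidueAggregate]
    report: AggregationReport = field(default_factory=AggregationReport, compare=False)

    @property
    def n_variable_positions(self) -> int:
        return len(self.aggregates)

    @property
    def vp(self) -> float:
        return len(self.aggregates) / self.protein_length

    def positions(self) -> list[int]:
        return sorted(self.aggregates)


def aggregate_by_residue(
    records: Iterable[VariantRecord],
    protein_length: int,
    protein_id: str | None = None,
) -> ResidueProfile:
    """Sum allele frequencies of filtered records per residue position.

    Applies the disjoint-event addition rule at multiallelic positions; the
    per-residue sum is capped at 1 (frequencies are probabilities) with the
    cap counted in the report.  Records with zero allele frequency (log-scale
    binning is undefined at 0) or a position beyond ``protein_length``
    (isoform or numbering mismatch) are dropped with a report count rather
    than aborting a batch run.
    """
    if protein_length < 1:
        raise ValueError(f"protein_length must be >= 1, got {protein_length}")
    report = AggregationReport()
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    pid = protein_id
    for rec in records:
        report.n_records += 1
        if pid is None:
            pid = rec.protein_id
        if rec.allele_frequency <= 0.0:
            report.n_dropped_zero_af += 1
            continue
        if rec.position > protein_length:
            report.n_out_of_range += 1
            continue
        sums[rec.position] = sums.get(rec.position, 0.0) + rec.allele_frequency
        counts[rec.position] = counts.get(rec.position, 0) + 1
    aggregates: dict[int, ResidueAggregate] = {}
    for pos in sorted(sums):
        af = sums[pos]
        if af > 1.0:
            af = 1.0
            report.n_capped += 1
        aggregates[pos] = ResidueAggregate(
            position=pos,
            summed_af=af,
            n_variants=counts[pos],
            bin_index=assign_frequency_bin(af),
        )
    return ResidueProfile(
        protein_id=pid or "protein",
        protein_length=protein_length,
        aggregates=aggregates,
        report=report,
    )


def write_profile_tsv(profile: ResidueProfile, path: str | Path) -> None:
    """Serialise a profile as TSV with ``# key=value`` header comments."""
    with open(path, "w") as fh:
        fh.write(f"# protein_id={profile.protein_id}\n")
        fh.write(f"# protein_length={profile.protein_length}\n")
        fh.write(f"# vp={profile.vp!r}\n")
        fh.write("position\tsummed_af\tn_variants\tbin_index\n")
        for pos in profile.positions():
            agg = profile.aggregates[pos]
            fh.write(f"{agg.position}\t{agg.summed_af!r}\t{agg.n_variants}\t{agg.bin_index}\n")


def read_profile_tsv(path: str | Path) -> ResidueProfile:
    """Inverse of :func:`write_profile_tsv` (round-trip exact)."""
    meta: dict[str, str] = {}
    aggregates: dict[int, ResidueAggregate] = {}
    header_seen = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*(\w+)=(.*)", line)
                if m:
                    meta[m.group(1)] = m.group(2)
                continue
            if not header_seen:
                header_seen = True  # column header line
                continue
            pos_s, af_s, n_s, bin_s = line.split("\t")
            pos = int(pos_s)
            aggregates[pos] = ResidueAggregate(
                position=pos,
                summed_af=float(af_s),
                n_variants=int(n_s),
                bin_index=int(bin_s),
            )
    try:
        return ResidueProfile(
            protein_id=meta["protein_id"],
            protein_length=int(meta["protein_length"]),
            aggregates=aggregates,
        )
    except KeyError as exc:
        raise DataError(f"profile TSV {path} missing header comment {exc}") from exc
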