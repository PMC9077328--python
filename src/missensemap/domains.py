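"""Domain boundaries and the Vd/Vp depletion ratio.

For a domain spanning residues [start, end] of a protein of length L:

    Vd    = (variable residue positions in domain) / (end - start + 1)
    Vp    = (variable residue positions in protein) / L
    Vd/Vp = Vd / Vp

A "variable residue position" is a residue with at least one retained
neutral missense variant — distinct positions, not variant counts, so
multiallelic sites are not double-counted.  Ratios below 1 indicate
domain-level missense depletion relative to the rest of the protein.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .errors import ConfigurationError, DomainFileError
from .profile import ResidueProfile

__all__ = [
    "DomainDefinition",
    "VdVpResult",
    "read_domain_table",
    "compute_vdvp",
    "write_vdvp_tsv",
]


@dataclass(frozen=True)
class DomainDefinition:
    """A named sequence interval, 1-based inclusive."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"domain {self.name!r}: need 1 <= start <= end, got ({self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class VdVpResult:
    """Vd/Vp of one domain; ``vdvp_ratio`` is None when Vp = 0 (undefined)."""

    domain: DomainDefinition
    variable_in_domain: int
    domain_length: int
    variable_in_protein: int
    protein_length: int
    vd: float
    vdvp_ratio: float | None

    @property
    def undefined(self) -> bool:
        return self.vdvp_ratio is None


def read_domain_table(path: str | Path) -> list[DomainDefinition]:
    """Read a plain-text domain file: whitespace-delimited ``name start end``.

    Lines beginning with ``#`` and blank lines are ignored; definitions are
    returned in file order and may overlap.  Malformed lines raise
    :class:`~missensemap.errors.DomainFileError` naming the line number.
    """
    out: list[DomainDefinition] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise DomainFileError(
                    f"line {lineno}: expected 'name start end', got {line!r}", lineno
                )
            name, start_s, end_s = parts
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise DomainFileError(
                    f"line {lineno}: non-integer bounds in {line!r}", lineno
                ) from None
            try:
                out.append(DomainDefinition(name, start, end))
            except ValueError as exc:
                raise DomainFileError(f"line {lineno}: {exc}", lineno) from None
    return out


def compute_vdvp(
    profile: ResidueProfile, domains: Sequence[DomainDefinition]
) -> list[VdVpResult]:
    """Score each domain's missense depletion against the whole protein.

    Results follow the input domain order.  A domain outside
    ``1..protein_length`` raises
    :class:`~missensemap.errors.ConfigurationError` naming the domain.
    """
    positions = profile.positions()
    n_protein = len(positions)
    vp = profile.vp
    results: list[VdVpResult] = []
    for dom in domains:
        if dom.end > profile.protein_length:
            raise ConfigurationError(
                f"domain {dom.name!r} ({dom.start}-{dom.end}) exceeds protein "
                f"length {profile.protein_length}"
            )
        lo = bisect.bisect_left(positions, dom.start)
        hi = bisect.bisect_right(positions, dom.end)
        in_domain = hi - lo
        vd = in_domain / dom.length
        ratio = vd / vp if vp > 0 else None
        results.append(
            VdVpResult(
                domain=dom,
                variable_in_domain=in_domain,
                domain_length=dom.length,
                variable_in_protein=n_protein,
                protein_length=profile.protein_length,
                vd=vd,
                vdvp_ratio=ratio,
            )
        )
    return results


def write_vdvp_tsv(results: Sequence[VdVpResult], path: str | Path) -> None:
    """Write Vd/Vp results as TSV.

    ``vdvp`` is printed to 2 decimal places (the figure-label convention);
    ``vdvp_full`` carries full precision.  Undefined ratios print ``NA``.
    """
    with open(path, "w") as fh:
        fh.write(
            "name\tstart\tend\tdomain_length\tvariable_in_domain\tvd\t"
            "variable_in_protein\tprotein_length\tvp\tvdvp\tvdvp_full\n"
        )
        for r in results:
            vp = r.variable_in_protein / r.protein_length
            ratio2 = "NA" if r.vdvp_ratio is None else f"{r.vdvp_ratio:.2f}"
            ratio_full = "NA" if r.vdvp_ratio is None else repr(r.vdvp_ratio)
            fh.write(
                f"{r.domain.name}\t{r.domain.start}\t{r.domain.end}\t"
                f"{r.domain_length}\t{r.variable_in_domain}\t{r.vd!r}\t"
                f"{r.variable_in_protein}\t{r.protein_length}\t{vp!r}\t"
                f"{ratio2}\t{ratio_full}\n"
            )
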