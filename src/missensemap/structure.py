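"""Mapping residue profiles onto structures and emitting PyMOL scripts.

A profile position ``p`` maps to structure residue ``p + offset`` on one
chain.  Positions that are absent from the structure, lack a Cα atom, or —
for predicted models, where the B-factor column carries the per-residue
pLDDT confidence — fall at or below the confidence threshold are reported
as unmapped with a reason.  Mapped positions are rendered as Cα spheres
whose radius and shade of blue grow with the allele-frequency bin, with an
optional pathogenic-variant overlay in a visually distinct style.

Structures are read with gemmi (PDB and mmCIF, auto-detected).  The script
emitter targets PyMOL command syntax (.pml) and is a pure function of its
inputs: byte-identical output across runs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import gemmi

from .errors import ConfigurationError, DataError
from .profile import N_BINS, ResidueProfile

__all__ = [
    "ResidueRecord",
    "StructureModel",
    "StructureAnnotation",
    "StyleSpec",
    "PLDDT_BACKBONE_CUTOFF",
    "load_structure",
    "map_profile",
    "overlay_pathogenic",
    "emit_viewer_script",
    "parse_viewer_script",
    "write_mapping_report",
    "read_pathogenic_table",
]

#: pLDDT above which a predicted backbone is considered generally correct.
PLDDT_BACKBONE_CUTOFF = 70.0

UNMAPPED_ABSENT = "absent_residue"
UNMAPPED_NO_CA = "no_CA"
UNMAPPED_PLDDT = "plddt_below_threshold"


@dataclass(frozen=True)
class ResidueRecord:
    """One residue of a parsed structure."""

    chain: str
    seqid: int
    icode: str
    name: str
    has_ca: bool
    b_factor: float


@dataclass
class StructureModel:
    """Indexed residues of the first model of a PDB/mmCIF file."""

    path: Path
    chains: list[str]
    residues: dict[tuple[str, int], ResidueRecord]
    has_insertion_codes: dict[str, bool]

    def residue(self, chain: str, seqid: int) -> ResidueRecord | None:
        return self.residues.get((chain, seqid))


def load_structure(path: str | Path) -> StructureModel:
    """Read a PDB or mmCIF file and index its residues.

    The format is auto-detected (extension first, then content).  The
    B-factor of the Cα atom (or, failing that, the first atom) is recorded
    per residue; for AlphaFold-style models this column holds the pLDDT.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError) as exc:
        raise DataError(f"cannot parse structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise DataError(f"structure file {path} contains no models")
    model = st[0]
    if sum(len(chain) for chain in model) == 0:
        raise DataError(f"structure file {path} contains no residues")
    residues: dict[tuple[str, int], ResidueRecord] = {}
    chains: list[str] = []
    has_icodes: dict[str, bool] = {}
    for chain in model:
        chains.append(chain.name)
        has_icodes.setdefault(chain.name, False)
        for res in chain:
            icode = res.seqid.icode.strip()
            if icode:
                has_icodes[chain.name] = True
            ca = res.find_atom("CA", "\0")
            b = ca.b_iso if ca is not None else (res[0].b_iso if len(res) else 0.0)
            key = (chain.name, res.seqid.num)
            if key not in residues or icode == "":  # prefer the blank-icode copy
                residues[key] = ResidueRecord(
                    chain=chain.name,
                    seqid=res.seqid.num,
                    icode=icode,
                    name=res.name,
                    has_ca=ca is not None,
                    b_factor=b,
                )
    return StructureModel(
        path=path, chains=chains, residues=residues, has_insertion_codes=has_icodes
    )


@dataclass
class StructureAnnotation:
    """Resolved mapping from profile positions to structure residues.

    ``mapped`` holds (profile position, structure residue number, bin index)
    in ascending position order; ``unmapped_positions`` holds (position,
    reason).  Every profile position appears in exactly one of the two.
    """

    chain: str
    offset: int
    structure_path: Path
    mapped: list[tuple[int, int, int]] = field(default_factory=list)
    unmapped_positions: list[tuple[int, str]] = field(default_factory=list)
    pathogenic_mapped: list[tuple[int, int, str]] = field(default_factory=list)
    pathogenic_unmapped: list[tuple[int, str]] = field(default_factory=list)


def _resolve(
    model: StructureModel, chain: str, seqid: int, plddt_min: float | None
) -> str | None:
    """Mapping verdict for one target residue: None if mappable, else reason."""
    res = model.residue(chain, seqid)
    if res is None:
        return UNMAPPED_ABSENT
    if not res.has_ca:
        return UNMAPPED_NO_CA
    if plddt_min is not None and res.b_factor <= plddt_min:
        return UNMAPPED_PLDDT
    return None


def map_profile(
    profile: ResidueProfile,
    model: StructureModel,
    chain: str,
    offset: int = 0,
    plddt_min: float | None = None,
) -> StructureAnnotation:
    """Map every profile position onto ``chain`` of the structure.

    ``plddt_min`` enables confidence masking for predicted models: residues
    whose B-factor (pLDDT) is <= the threshold are unmapped with a reason.
    Leave it unset for experimental structures.
    """
    if chain not in model.chains:
        raise ConfigurationError(
            f"chain {chain!r} not in structure {model.path.name} "
            f"(chains: {sorted(set(model.chains))})"
        )
    if model.has_insertion_codes.get(chain):
        raise ConfigurationError(
            f"chain {chain!r} of {model.path.name} uses insertion codes; "
            "integer-offset mapping would be ambiguous — renumber the chain "
            "or supply an explicit per-residue mapping"
        )
    ann = StructureAnnotation(chain=chain, offset=offset, structure_path=model.path)
    for pos in profile.positions():
        seqid = pos + offset
        reason = _resolve(model, chain, seqid, plddt_min)
        if reason is None:
            ann.mapped.append((pos, seqid, profile.aggregates[pos].bin_index))
        else:
            ann.unmapped_positions.append((pos, reason))
    return ann


def overlay_pathogenic(
    annotation: StructureAnnotation,
    pathogenic: Sequence[tuple[int, str]],
    model: StructureModel,
    chain: str,
    offset: int = 0,
    plddt_min: float | None = None,
) -> StructureAnnotation:
    """Resolve pathogenic positions with the same mapping rules.

    Returns a new annotation; unmappable pathogenic positions are reported
    in ``pathogenic_unmapped``, never fatal.  An empty list is a no-op.
    """
    ann = replace(
        annotation,
        mapped=list(annotation.mapped),
        unmapped_positions=list(annotation.unmapped_positions),
        pathogenic_mapped=list(annotation.pathogenic_mapped),
        pathogenic_unmapped=list(annotation.pathogenic_unmapped),
    )
    for pos, label in sorted(pathogenic):
        seqid = pos + offset
        reason = _resolve(model, chain, seqid, plddt_min)
        if reason is None:
            ann.pathogenic_mapped.append((pos, seqid, label))
        else:
            ann.pathogenic_unmapped.append((pos, reason))
    return ann


def _default_blue_ramp() -> tuple[tuple[float, float, float], ...]:
    # light -> dark blue, one step per bin
    return (
        (0.82, 0.88, 0.97),
        (0.65, 0.78, 0.92),
        (0.46, 0.66, 0.86),
        (0.29, 0.53, 0.79),
        (0.16, 0.40, 0.68),
        (0.06, 0.28, 0.55),
    )


@dataclass(frozen=True)
class StyleSpec:
    """Bin -> (sphere radius, colour) encoding.

    Radii (Å) must be non-decreasing with bin index so that common alleles
    read as larger spheres; the default colours form a light-to-dark blue
    ramp.  Pathogenic positions use a separate, contrasting style (red).
    """

    radii: tuple[float, ...] = (0.8, 1.2, 1.6, 2.0, 2.4, 2.8)
    colors: tuple[tuple[float, float, float], ...] = field(
        default_factory=_default_blue_ramp
    )
    pathogenic_color: tuple[float, float, float] = (0.80, 0.10, 0.10)
    pathogenic_radius: float = 2.0

    def __post_init__(self) -> None:
        if len(self.radii) != N_BINS or len(self.colors) != N_BINS:
            raise ValueError(f"StyleSpec needs exactly {N_BINS} radii and colors")
        if any(r <= 0 for r in self.radii) or self.pathogenic_radius <= 0:
            raise ValueError("sphere radii must be positive")
        if any(b < a for a, b in zip(self.radii, self.radii[1:])):
            raise ValueError("radii must be non-decreasing with bin index")


_BIN_LABELS = (
    "af_le_1e-05",
    "af_1e-05_to_1e-04",
    "af_1e-04_to_1e-03",
    "af_1e-03_to_1e-02",
    "af_1e-02_to_1e-01",
    "af_1e-01_to_1",
)


def _resi_list(seqids: Sequence[int]) -> str:
    return "+".join(str(n) for n in sorted(seqids))


def emit_viewer_script(
    annotation: StructureAnnotation,
    style: StyleSpec,
    structure_path: str | Path,
    out: str | Path,
    object_name: str = "target",
) -> Path:
    """Write a PyMOL command script rendering the annotation.

    One named selection is created per non-empty frequency bin (plus one for
    pathogenic positions); each shows Cα spheres with the bin's radius and
    colour.  Output ordering is stable (ascending residue number), so the
    script is byte-identical for identical inputs.
    """
    out = Path(out)
    by_bin: dict[int, list[int]] = {}
    for _pos, seqid, bin_index in annotation.mapped:
        by_bin.setdefault(bin_index, []).append(seqid)
    chain = annotation.chain
    lines: list[str] = []
    lines.append(f"load {Path(structure_path).as_posix()}, {object_name}")
    lines.append(f"hide everything, {object_name}")
    lines.append(f"show cartoon, {object_name}")
    lines.append(f"color grey80, {object_name}")
    lines.append(f"set cartoon_transparency, 0.2, {object_name}")
    for bin_index in sorted(by_bin):
        seqids = by_bin[bin_index]
        sel = f"bin{bin_index}_{_BIN_LABELS[bin_index - 1]}"
        r, g, b = style.colors[bin_index - 1]
        lines.append(f"set_color color_bin{bin_index}, [{r:.3f}, {g:.3f}, {b:.3f}]")
        lines.append(
            f"select {sel}, {object_name} and chain {chain} "
            f"and resi {_resi_list(seqids)} and name CA"
        )
        lines.append(f"show spheres, {sel}")
        lines.append(f"color color_bin{bin_index}, {sel}")
        lines.append(f"alter {sel}, vdw={style.radii[bin_index - 1]:.2f}")
    if annotation.pathogenic_mapped:
        seqids = [s for _p, s, _l in annotation.pathogenic_mapped]
        r, g, b = style.pathogenic_color
        lines.append(f"set_color color_pathogenic, [{r:.3f}, {g:.3f}, {b:.3f}]")
        lines.append(
            f"select pathogenic, {object_name} and chain {chain} "
            f"and resi {_resi_list(seqids)} and name CA"
        )
        lines.append("show spheres, pathogenic")
        lines.append("color color_pathogenic, pathogenic")
        lines.append(f"alter pathogenic, vdw={style.pathogenic_radius:.2f}")
    lines.append("rebuild")
    lines.append("deselect")
    out.write_text("\n".join(lines) + "\n")
    return out


_SELECT_RE = re.compile(r"^select (\S+), \S+ and chain \S+ and resi (\S+) and name CA$")


def parse_viewer_script(path: str | Path) -> dict[str, set[int]]:
    """Extract selection-name -> residue-number sets from an emitted script."""
    out: dict[str, set[int]] = {}
    for line in Path(path).read_text().splitlines():
        m = _SELECT_RE.match(line.strip())
        if m:
            out[m.group(1)] = {int(x) for x in m.group(2).split("+")}
    return out


def write_mapping_report(annotation: StructureAnnotation, path: str | Path) -> None:
    """TSV report: one row per profile position with status and reason."""
    with open(path, "w") as fh:
        fh.write("position\tstructure_residue\tstatus\tbin_index\treason\n")
        rows = [
            (pos, str(seqid), "mapped", str(b), "")
            for pos, seqid, b in annotation.mapped
        ] + [
            (pos, "", "unmapped", "", reason)
            for pos, reason in annotation.unmapped_positions
        ]
        for pos, seqid, status, b, reason in sorted(rows, key=lambda r: r[0]):
            fh.write(f"{pos}\t{seqid}\t{status}\t{b}\t{reason}\n")


def read_pathogenic_table(path: str | Path) -> list[tuple[int, str]]:
    """Read a pathogenic-position TSV: ``position label`` per line, # comments."""
    out: list[tuple[int, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            try:
                pos = int(parts[0])
            except ValueError:
                raise DataError(
                    f"pathogenic table line {lineno}: non-integer position {parts[0]!r}"
                ) from None
            label = parts[1].strip() if len(parts) > 1 else ""
            out.append((pos, label))
    return out
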