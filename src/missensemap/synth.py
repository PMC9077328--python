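"""Synthetic gnomAD-style variant tables and toy structures with ground truth.

The generator emulates a per-gene gnomAD v2 browser export well enough to
exercise the whole pipeline without downloads: each residue is missense-
variable with a region-dependent probability, allele frequencies are drawn
log-uniform (populating all six frequency bins, with allele counts
integerised against a realistic allele number so AF = AC/AN holds exactly),
a fraction of variable residues is multiallelic, and decoy rows carry
non-missense VEP classes or excluded ClinVar labels so the neutral filter
has real work to do.  A sidecar table records the ground truth — the true
variable positions per region with their summed frequencies and bins —
which by construction equals what the filter + aggregation pipeline must
recover.

Defaults are chosen to resemble a constrained human gene: background
variable-residue density 0.35, allele number 251,496 (2 x 125,748 exomes),
~1.5% of rows carrying excluded ClinVar classes and 25% non-missense.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
import pandas as pd

from .profile import assign_frequency_bin

__all__ = [
    "SyntheticSpec",
    "GroundTruthPosition",
    "GroundTruth",
    "synthesize_variants",
    "generate_variant_table",
    "write_ground_truth",
    "read_ground_truth",
    "generate_toy_structure",
]

#: 2 alleles x 125,748 exomes — the allele number of a fully-called gnomAD v2 site.
DEFAULT_ALLELE_NUMBER = 251_496

_AA1 = "ACDEFGHIKLMNPQRSTVWY"
_AA_ONE_TO_THREE = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}

_EXCLUDED_CLINVAR_LABELS = (
    "Pathogenic",
    "Likely pathogenic",
    "Uncertain significance",
    "Conflicting interpretations of pathogenicity",
    "Pathogenic/Likely pathogenic",
)
_BENIGN_CLINVAR_LABELS = ("Benign", "Likely benign", "Benign/Likely benign")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic per-gene variant table."""

    protein_length: int = 1000
    density_background: float = 0.35
    depleted_regions: tuple[tuple[int, int, float], ...] = ()
    af_log10_range: tuple[float, float] = (-6.0, 0.0)
    fraction_pathogenic: float = 0.015
    fraction_non_missense: float = 0.25
    multiallelic_rate: float = 0.15
    benign_label_rate: float = 0.15
    allele_number: int = DEFAULT_ALLELE_NUMBER
    protein_id: str = "SYNTH1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.protein_length < 1:
            raise ValueError("protein_length must be >= 1")
        if not (0.0 <= self.density_background <= 1.0):
            raise ValueError("density_background must be in [0, 1]")
        lo, hi = self.af_log10_range
        if not (-7.0 <= lo < hi <= 0.0):
            raise ValueError("af_log10_range must satisfy -7 <= lo < hi <= 0")
        for start, end, dens in self.depleted_regions:
            if not (1 <= start <= end <= self.protein_length):
                raise ValueError(f"region ({start}, {end}) outside 1..{self.protein_length}")
            if not (0.0 <= dens <= 1.0):
                raise ValueError(f"region density {dens} must be in [0, 1]")
        for frac in (self.fraction_pathogenic, self.fraction_non_missense):
            if not (0.0 <= frac < 1.0):
                raise ValueError("decoy fractions must be in [0, 1)")
        if self.fraction_pathogenic + self.fraction_non_missense >= 1.0:
            raise ValueError("decoy fractions must sum to < 1")
        if not (0.0 <= self.multiallelic_rate < 1.0):
            raise ValueError("multiallelic_rate must be in [0, 1)")


@dataclass(frozen=True)
class GroundTruthPosition:
    position: int
    region: str
    n_variants: int
    summed_af: float
    bin_index: int


@dataclass
class GroundTruth:
    """True post-filter variable positions, keyed by generating region."""

    spec: SyntheticSpec
    positions: list[GroundTruthPosition] = field(default_factory=list)

    def positions_in_region(self, region: str) -> list[int]:
        return [p.position for p in self.positions if p.region == region]

    def variable_positions(self) -> list[int]:
        return [p.position for p in self.positions]


def _region_name(index: int, start: int, end: int) -> str:
    return f"region{index}_{start}_{end}"


def _density_and_region(spec: SyntheticSpec) -> tuple[np.ndarray, list[str]]:
    density = np.full(spec.protein_length, spec.density_background)
    region = ["background"] * spec.protein_length
    for i, (start, end, dens) in enumerate(spec.depleted_regions, start=1):
        density[start - 1 : end] = dens
        name = _region_name(i, start, end)
        for p in range(start - 1, end):
            region[p] = name
    return density, region


def _draw_af(rng: np.random.Generator, spec: SyntheticSpec) -> tuple[int, float]:
    """Draw one allele count/frequency pair with AF = AC/AN exactly."""
    lo, hi = spec.af_log10_range
    af = 10.0 ** rng.uniform(lo, hi)
    ac = max(1, round(af * spec.allele_number))
    ac = min(ac, spec.allele_number)
    return ac, ac / spec.allele_number


def synthesize_variants(spec: SyntheticSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a variant table (gnomAD CSV dialect) and its ground truth.

    Fully reproducible from ``spec.seed``.  Neutral missense rows define the
    ground-truth variable positions; decoy rows (non-missense VEP classes,
    excluded ClinVar classes) are guaranteed to be removed by the default
    filter policy and therefore never perturb the truth.
    """
    rng = np.random.default_rng(spec.seed)
    density, region = _density_and_region(spec)
    variable = rng.random(spec.protein_length) < density

    truth = GroundTruth(spec=spec)
    rows: list[dict] = []

    def add_row(pos: int, ref: str, alt: str, vep: str, clinvar: str,
                ac: int, af: float) -> None:
        rows.append(
            {
                "Chromosome": "1",
                "Position": 1_000_000 + 3 * pos,
                "Reference": "C",
                "Alternate": "T",
                "Protein Consequence": f"p.{_AA_ONE_TO_THREE[ref]}{pos}"
                + (_AA_ONE_TO_THREE[alt] if alt != "*" else "Ter"),
                "VEP Annotation": vep,
                "ClinVar Clinical Significance": clinvar,
                "Allele Count": ac,
                "Allele Number": spec.allele_number,
                "Allele Frequency": af,
            }
        )

    ref_aa = rng.choice(list(_AA1), size=spec.protein_length)
    n_neutral = 0
    for pos0 in range(spec.protein_length):
        if not variable[pos0]:
            continue
        pos = pos0 + 1
        ref = str(ref_aa[pos0])
        n_sub = 2 if rng.random() < spec.multiallelic_rate else 1
        summed = 0.0
        for _ in range(n_sub):
            alt = ref
            while alt == ref:
                alt = _AA1[rng.integers(0, len(_AA1))]
            ac, af = _draw_af(rng, spec)
            clinvar = ""
            if rng.random() < spec.benign_label_rate:
                clinvar = _BENIGN_CLINVAR_LABELS[int(rng.integers(0, len(_BENIGN_CLINVAR_LABELS)))]
            add_row(pos, ref, alt, "missense_variant", clinvar, ac, af)
            summed += af
            n_neutral += 1
        summed = min(summed, 1.0)
        truth.positions.append(
            GroundTruthPosition(
                position=pos,
                region=region[pos0],
                n_variants=n_sub,
                summed_af=summed,
                bin_index=assign_frequency_bin(summed),
            )
        )

    # decoy rows so the requested fractions hold over the whole table
    f_p, f_nm = spec.fraction_pathogenic, spec.fraction_non_missense
    total = n_neutral / (1.0 - f_p - f_nm) if n_neutral else 0.0
    n_path = round(total * f_p)
    n_nonmis = round(total * f_nm)
    for i in range(n_path):
        pos = int(rng.integers(1, spec.protein_length + 1))
        ref = str(ref_aa[pos - 1])
        alt = ref
        while alt == ref:
            alt = _AA1[rng.integers(0, len(_AA1))]
        ac, af = _draw_af(rng, spec)
        label = _EXCLUDED_CLINVAR_LABELS[i % len(_EXCLUDED_CLINVAR_LABELS)]
        add_row(pos, ref, alt, "missense_variant", label, ac, af)
    for i in range(n_nonmis):
        pos = int(rng.integers(1, spec.protein_length + 1))
        ref = str(ref_aa[pos - 1])
        ac, af = _draw_af(rng, spec)
        if i % 3 == 2:
            alt = ref
            while alt == ref:
                alt = _AA1[rng.integers(0, len(_AA1))]
            add_row(pos, ref, "*", "stop_gained", "", ac, af)
        else:
            add_row(pos, ref, ref, "synonymous_variant", "", ac, af)

    df = pd.DataFrame(
        rows,
        columns=[
            "Chromosome", "Position", "Reference", "Alternate",
            "Protein Consequence", "VEP Annotation",
            "ClinVar Clinical Significance",
            "Allele Count", "Allele Number", "Allele Frequency",
        ],
    )
    df = df.sort_values(["Position", "Protein Consequence"], kind="stable").reset_index(
        drop=True
    )
    return df, truth


def generate_variant_table(
    spec: SyntheticSpec,
    csv_path: str | Path,
    sidecar_path: str | Path | None = None,
) -> tuple[Path, GroundTruth]:
    """Write the synthetic table as CSV (byte-identical per seed) + sidecar."""
    df, truth = synthesize_variants(spec)
    csv_path = Path(csv_path)
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(df.columns))
        for row in df.itertuples(index=False):
            formatted = [
                repr(v) if isinstance(v, float) else str(v) for v in row
            ]
            writer.writerow(formatted)
    if sidecar_path is not None:
        write_ground_truth(truth, sidecar_path)
    return csv_path, truth


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    spec = truth.spec
    with open(path, "w") as fh:
        fh.write(f"# protein_id={spec.protein_id}\n")
        fh.write(f"# protein_length={spec.protein_length}\n")
        fh.write(f"# seed={spec.seed}\n")
        fh.write("position\tregion\tn_variants\tsummed_af\tbin_index\n")
        for p in truth.positions:
            fh.write(
                f"{p.position}\t{p.region}\t{p.n_variants}\t{p.summed_af!r}\t{p.bin_index}\n"
            )


def read_ground_truth(path: str | Path) -> list[GroundTruthPosition]:
    out: list[GroundTruthPosition] = []
    header_seen = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                header_seen = True
                continue
            pos, region, n, af, b = line.split("\t")
            out.append(
                GroundTruthPosition(
                    position=int(pos), region=region, n_variants=int(n),
                    summed_af=float(af), bin_index=int(b),
                )
            )
    return out


# -- toy structures ---------------------------------------------------------

#: Ideal-helix parameters: 1.5 Å rise and 100° twist per residue; the radius
#: is chosen so consecutive Cα–Cα distances come out at ~3.8 Å.
_HELIX_RISE = 1.5
_HELIX_TWIST_DEG = 100.0
_HELIX_RADIUS = 2.28


def generate_toy_structure(
    n_residues: int,
    plddt_profile: Sequence[float] | None = None,
    chain: str = "A",
    out: str | Path = "toy.pdb",
    first_seqid: int = 1,
) -> Path:
    """Write a Cα-only poly-alanine ideal helix as a PDB file.

    The B-factor column is filled from ``plddt_profile`` when given (one
    value per residue; short profiles are padded with the last value), which
    lets downstream code treat the file as a predicted model with pLDDT
    confidences.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    st = gemmi.Structure()
    st.name = "toy-helix"
    model = gemmi.Model("1")
    ch = gemmi.Chain(chain)
    for i in range(n_residues):
        theta = math.radians(_HELIX_TWIST_DEG * i)
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(first_seqid + i, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(
            _HELIX_RADIUS * math.cos(theta),
            _HELIX_RADIUS * math.sin(theta),
            _HELIX_RISE * i,
        )
        atom.occ = 1.0
        if plddt_profile is not None:
            idx = min(i, len(plddt_profile) - 1)
            atom.b_iso = float(plddt_profile[idx])
        else:
            atom.b_iso = 0.0
        res.add_atom(atom)
        ch.add_residue(res)
    model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    out = Path(out)
    if out.suffix.lower() in (".cif", ".mmcif"):
        st.make_mmcif_document().write_file(str(out))
    else:
        st.write_pdb(str(out))
    return out
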