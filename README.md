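# missensemap

Map population missense variants onto protein sequences (1D) and structures
(3D), and quantify domain-level missense depletion.

Human population exome data (gnomAD-style per-gene exports) lists the
missense variants observed in ~10⁵ healthy adults, with allele frequencies.
Protein regions that are *depleted* of such neutral missense variation are
under purifying selection and are therefore likely to be functionally
important — enzyme active sites, interaction interfaces, nucleic-acid
binding surfaces. `missensemap` is a small toolkit for structural
biologists who want to inspect one protein at a time:

- **filter** a variant table to a neutral missense set: keep VEP class
  `missense_variant`, drop variants whose ClinVar classification is
  pathogenic, likely pathogenic, conflicting, or of uncertain significance;
- **aggregate** per residue: allele frequencies of distinct substitutions at
  the same residue are summed (addition rule for disjoint events), compressed
  on a base-10 log scale, and sorted into 6 frequency bins
  (AF ≤ 10⁻⁵, 10⁻⁵–10⁻⁴, …, 10⁻¹–10⁰);
- **quantify** depletion per domain with the Vd/Vp ratio

  ```
  Vd/Vp = (variable residue positions in domain / domain length)
        / (variable residue positions in protein / protein length)
  ```

  where a *variable residue position* is a residue with ≥ 1 retained
  missense variant, and Vp is the whole-protein variant density.
  Ratios < 1 flag missense-depleted domains;
- **render** the result as a 1D plot (positional ticks, domain diagram,
  Vd/Vp labels) or as a PyMOL script that draws Cα spheres whose radius and
  shade of blue grow with the frequency bin, with optional pathogenic-variant
  overlay (red) and pLDDT > 70 confidence masking for predicted models.

A synthetic-data module generates gnomAD-style tables and toy structures
with known ground truth, so the entire pipeline is testable offline.

## Worked example

Generate a 300-residue synthetic gene with an engineered depleted domain
(residues 120–200 at 8% variable-residue density against a 35% background),
then score domains and map the variants onto a toy structure:

```sh
missensemap synth --seed 11 --protein-length 300 --region 120:200:0.08 \
    --structure-residues 300 --out-dir fixtures
printf 'DEP 120 200\nNTD 1 100\n' > fixtures/domains.txt
missensemap vdvp --variants fixtures/variants.csv \
    --domains fixtures/domains.txt --protein-length 300 --out-dir vdvp_out
missensemap map3d --variants fixtures/variants.csv \
    --structure fixtures/toy.pdb --chain A --protein-length 300 \
    --out-dir map_out
```

which prints

```
wrote fixtures/variants.csv (88 variable positions)
DEP     120-200 Vd/Vp=0.21
NTD     1-100   Vd/Vp=1.53
wrote map_out/variants.pml (88 mapped, 0 unmapped)
```

The engineered domain scores Vd/Vp = 0.21 — strongly depleted, close to the
generating density ratio 0.08/0.35 ≈ 0.23 — while the unconstrained
N-terminal window scores above 1. `vdvp_out/vdvp.tsv` carries the full
arithmetic per domain (variable positions in domain and protein, Vd, Vp,
the ratio at display and full precision):

```
name  start  end  domain_length  variable_in_domain  vd       ...  vdvp
DEP   120    200  81             5                   0.0617   ...  0.21
NTD   1      100  100            45                  0.45     ...  1.53
```

`map_out/variants.pml`, loaded into PyMOL, shows the structure in grey
cartoon with one selection per populated frequency bin, e.g.

```
select bin1_af_le_1e-05, target and chain A and resi 15+58+72+... and name CA
show spheres, bin1_af_le_1e-05
alter bin1_af_le_1e-05, vdw=0.80
```

— rare variants as small pale-blue spheres, common variants as large dark
ones; the depleted domain stands out as a sphere-free surface. Real inputs
work the same way: pass a per-gene CSV exported from the gnomAD browser as
`--variants`, a PDB/mmCIF file as `--structure` (add `--predicted` for
AlphaFold models so residues with pLDDT ≤ 70 are masked), `--offset` if
structure numbering differs from UniProt numbering, and
`--pathogenic positions.tsv` to overlay clinically observed variants.

`missensemap filter --audit` re-emits the input table with a boolean
`retained` column; `missensemap plot1d` writes the 1D figure as SVG or PNG.
Every run writes a `run_report.json` with inputs, counts, seed and version.

## Scope

The tool trusts the protein consequences in the input table (no VEP
re-annotation or transcript selection), does not query gnomAD/ClinVar
services, does not normalise for codon mutability, and attaches no
statistical significance to depletion — Vd/Vp is a descriptive ratio whose
interpretation rests on the user's domain boundaries. See
`docs/methods.md` for the model, parameter choices, and limitations.
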