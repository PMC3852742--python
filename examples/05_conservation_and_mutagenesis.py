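"""Alignment conservation around the tau arginine, and primer verification.

Profiles the packaged (synthetic stand-in) CK1 kinase-domain alignment,
shows that the tau-mutation arginine column is invariant and maps to residue
200 of the O. tauri row, and verifies the R200C circular-mutagenesis primer
pair: reverse-complementarity and the encoded codon change.
"""

from importlib import resources

from circaphos import column_profiles, map_column_to_position, verify_mutagenic_primers
from circaphos.conservation import read_alignment

source = resources.files("circaphos.data").joinpath("ck1_alignment_synthetic.fasta")
with resources.as_file(source) as p:
    aln = read_alignment(p)

profiles = column_profiles(aln)
col = profiles[199]  # alignment column 200
print(f"alignment: {len(aln)} sequences x {len(profiles)} columns")
print(f"column {col.column}: consensus {col.consensus}, invariant={col.invariant}, "
      f"information {col.information_bits:.2f} bits")
pos = map_column_to_position(aln, "Otauri_CK1_synthetic", 200)
print(f"column 200 corresponds to O. tauri residue {pos}")

fwd = "gacgggaacggcgTGTtacgcgagtatcaacacg"
rev = "cgtgttgatactcgcgtaACAcgccgttcccgtc"
template = "gacgggaacggcgCGTtacgcgagtatcaacacg"  # wild-type codon CGT at position 200
report = verify_mutagenic_primers(template, fwd, rev, frame=1, first_codon_number=196)
print(f"primers reverse-complementary: {report.primers_complementary}")
print(f"substitution: {report.codon_before} -> {report.codon_after} "
      f"({report.aa_before}{report.protein_position}{report.aa_after})")
# An invariant arginine across isoforms plus a verified R->C primer design is
# exactly the checklist for porting the tau gain-of-function allele into a
# new species' CK1.
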