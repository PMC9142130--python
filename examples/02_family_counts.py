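"""Sort unique peptides into grain protein families.

Each unique peptide is assigned to exactly one family from its protein
descriptions (keyword table, fixed precedence: omega > alpha > gamma
gliadins > HMW > LMW glutenins > non-gluten classes), so family counts
always sum to the number of unique peptides.
"""

from glutenscan import PeptideRecord, count_family_peptides, filter_peptides

rows = [
    ("QPQLPYAQA", "A1", "alpha-gliadin"),
    ("PQQPFPQQC", "A1", "alpha-gliadin"),
    ("QQPGQGQQL", "H1", "high molecular weight glutenin subunit"),
    ("SQQQQPPFS", "H1", "high molecular weight glutenin subunit"),
    # shared peptide: alpha-gliadin outranks gamma-gliadin, counted once
    ("QPQQPYPQQ", "A1", "alpha-gliadin"),
    ("QPQQPYPQQ", "G1", "gamma-gliadin"),
    ("YYPTSPQQS", "G1", "gamma-gliadin"),
]
records = [
    PeptideRecord(seq, acc, desc, "Triticum aestivum", 0.001, "chymotrypsin")
    for seq, acc, desc in rows
]

unique = filter_peptides(records, sample_label="toy_flour")
counts = count_family_peptides(unique)
for family, n in counts.items():
    if n:
        print(f"{family.value:<15} {n} unique peptide(s)")
print(f"total {sum(counts.values())} == {len(unique)} unique peptides")
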