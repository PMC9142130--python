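"""In silico digestion of a gliadin-like protein.

Trypsin cuts after K/R and chymotrypsin after F/W/Y/L, both unless the next
residue is proline (Keil rules). Gliadin repeats are poor in K/R, which is
why chymotrypsin releases far more gluten peptides than trypsin.
"""

from glutenscan import DigestSpec, cleavage_sites, digest

PROTEIN = "VRVPVPQLQPQNPSQQQPQEQVPLVQQQQFPGQQQPFPPQQPYPQPQPFPSQQPYLQLQPF"

for enzyme in ("trypsin", "chymotrypsin"):
    sites = cleavage_sites(PROTEIN, enzyme)
    spec = DigestSpec(enzyme=enzyme, missed_cleavages=0, min_length=1,
                      max_length=100)
    frags = digest(PROTEIN, spec)
    print(f"{enzyme}: {len(sites)} cleavage sites -> {len(frags)} fragments")
    for f in frags:
        print(f"  [{f.start:>2}:{f.end:>2}] {f.peptide}")
    print()
print("fragments concatenate to the input protein (conservation):",
      "".join(f.peptide for f in digest(
          PROTEIN, DigestSpec(enzyme='chymotrypsin', min_length=1,
                              max_length=100))) == PROTEIN)
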