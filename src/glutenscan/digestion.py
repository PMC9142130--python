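"""Deterministic in silico protease digestion.

Implements the classical Keil specificities for the two proteases used to
digest flour protein extracts:

* trypsin — cleaves C-terminally of K or R, unless the next residue is P;
* chymotrypsin (high specificity) — cleaves C-terminally of F, W, Y or L,
  unless the next residue is P.

The rules live in a small regex table (``CLEAVAGE_RULES``) so users can
override or extend them. Digestion with ``missed_cleavages = m`` emits every
run of up to ``m + 1`` adjacent zero-missed fragments; the length filter is
applied last. With no missed cleavages and no length filter the fragments
tile the protein exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

__all__ = [
    "DigestSpec",
    "Fragment",
    "CLEAVAGE_RULES",
    "cleavage_sites",
    "digest",
    "write_digest_tsv",
]

#: Enzyme name -> cleavage-site regex. A match at index i means "cut after
#: residue i". Lookahead keeps matches overlap-safe (KK, RK runs all cut).
CLEAVAGE_RULES: dict[str, re.Pattern] = {
    "trypsin": re.compile(r"[KR](?!P)"),
    "chymotrypsin": re.compile(r"[FWYL](?!P)"),
}


@dataclass(frozen=True)
class DigestSpec:
    """Digestion parameters.

    ``missed_cleavages`` is the maximum number of internal uncut sites per
    emitted peptide; peptides outside ``[min_length, max_length]`` are
    dropped (set ``min_length=1`` and a large ``max_length`` to disable).
    """

    enzyme: str = "chymotrypsin"
    missed_cleavages: int = 0
    min_length: int = 5
    max_length: int = 50

    def __post_init__(self) -> None:
        if self.enzyme not in CLEAVAGE_RULES:
            raise ValueError(
                f"unknown enzyme {self.enzyme!r}; known: {sorted(CLEAVAGE_RULES)}"
            )
        if not (0 <= self.missed_cleavages <= 5):
            raise ValueError("missed_cleavages must be in [0, 5]")
        if not (1 <= self.min_length <= self.max_length):
            raise ValueError("need 1 <= min_length <= max_length")


@dataclass(frozen=True)
class Fragment:
    """One digestion product with parent coordinates (0-based, half-open)."""

    peptide: str
    start: int
    end: int
    missed: int


def cleavage_sites(protein: str, enzyme: str) -> list[int]:
    """0-based positions i such that the enzyme cuts between i and i+1.

    A potential site at the very last residue is not a cut (the protein ends
    there anyway), so positions are strictly inside the chain.
    """
    rule = CLEAVAGE_RULES[enzyme]
    return [m.start() for m in rule.finditer(protein) if m.start() < len(protein) - 1]


def digest(protein: str, spec: DigestSpec = DigestSpec()) -> list[Fragment]:
    """Digest ``protein`` under ``spec``, returning fragments with coordinates.

    Fragments are emitted in order of start position, then missed-cleavage
    count; each carries exactly ``missed`` internal cleavage sites by
    construction.
    """
    protein = protein.upper()
    sites = cleavage_sites(protein, spec.enzyme)
    bounds = [0] + [s + 1 for s in sites] + [len(protein)]
    out: list[Fragment] = []
    for i in range(len(bounds) - 1):
        for m in range(spec.missed_cleavages + 1):
            j = i + m + 1
            if j >= len(bounds):
                break
            start, end = bounds[i], bounds[j]
            if spec.min_length <= end - start <= spec.max_length:
                out.append(Fragment(protein[start:end], start, end, m))
    return out


def digest_no_filter(protein: str, enzyme: str, missed_cleavages: int = 0) -> list[Fragment]:
    """Digest with the length filter disabled (fragments tile the protein
    when ``missed_cleavages == 0``)."""
    spec = DigestSpec(
        enzyme=enzyme,
        missed_cleavages=missed_cleavages,
        min_length=1,
        max_length=10**9,
    )
    return digest(protein, spec)


def write_digest_tsv(
    fragments_by_protein: dict[str, Iterable[Fragment]],
    path: Union[str, Path],
    header_lines: Iterable[str] = (),
) -> None:
    """Write digestion products as TSV: protein_id, peptide, start, end."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("protein_id\tpeptide\tstart\tend\tmissed\n")
        for pid, frags in fragments_by_protein.items():
            for f in frags:
                fh.write(f"{pid}\t{f.peptide}\t{f.start}\t{f.end}\t{f.missed}\n")
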