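# Methods

## Pipeline model

`glutenscan` models immunogenic-load profiling of a flour sample as four
deterministic stages over peptide identification data:

1. **Ingest & filter.** A report row is one (peptide, protein) assignment
   with an expectation score. Filters are applied in a fixed order: score
   (`pep_expect < max_pep_expect`, strict, default 0.05), taxon
   (case-insensitive substring match against the allowed patterns, default
   *Triticum aestivum* / *Triticum turgidum* / *Hordeum*, so that
   "Hordeum" covers any *Hordeum* species), then protein support
   (accessions backed by at least `min_peptides_per_protein = 2` *distinct
   surviving peptide sequences*). Support is deliberately evaluated after
   the score and taxon filters and on distinct sequences, not spectra: the
   report format carries no spectral counts. The survivors are deduplicated
   into a unique-peptide set; the output is row-order independent
   (sequences sorted) and filtering is idempotent.
2. **Family sorting.** Each unique peptide is assigned to exactly one grain
   protein family from the free-text descriptions of its contributing
   proteins, via a keyword table (shipped as an editable TSV) scanned in a
   fixed precedence order: ω > α > γ gliadins > HMW > LMW glutenins > ATI >
   avenin > LTP > serpin > globulin > other. The precedence makes counts of
   multi-assigned peptides deterministic; each peptide is counted once, so
   family counts always sum to the set size. "α-gliadin" keywords cover the
   α/β-gliadin class.
3. **Motif scanning.** Every (unique peptide, motif) pair is scanned at
   every window offset; an event is a window whose Hamming distance to the
   motif equals the mode target — 0 (`perfect`), exactly 1
   (`one_mismatch`), or ≤ 1 (`at_most_one`, for sensitivity analysis).
   Overlapping windows each count, a peptide may contribute many events,
   and two motifs of the same category matching the same window are two
   events. Mismatches are substitutions only: with fixed-length windows the
   "one mismatch" notion is unambiguous, which an edit-distance variant
   would not be. I and L are distinct; no Q≈E deamidation equivalence is
   applied (the inventory stores native glutamine forms). Offsets are
   0-based, windows half-open. Events are counted per unique peptide
   sequence, not weighted by how many proteins share the peptide.
4. **Two-flour comparison.** Per category and mode, the fold-ratio
   reference/comparator is reported rounded half-up to one decimal
   (full-precision values are retained in `exact_ratios`); a zero
   comparator yields an explicit undefined sentinel (`None`, rendered
   `NA`), never a number.

Exact-distance semantics for `one_mismatch` are a deliberate design choice:
aggregated tables in this field can show one-mismatch counts *below*
perfect counts, which is only possible if the two modes are disjoint.
`at_most_one` is provided so users can recover inclusive semantics, and the
identity `at_most_one = perfect + one_mismatch` is enforced by tests.

## Motif inventory

The packaged default (`data/motifs.tsv`) covers six categories: CD T-cell
epitope 9-mer cores (native Q forms, DQ2.5/DQ8 restricted, from the Sollid
et al. catalogue), the α-gliadin p31–43 innate peptide, recognition sites
of the R5, G12 and A1 monoclonal antibodies used in gluten ELISAs, and
IgE-binding sites associated with WDEIA, baker's asthma and atopic
dermatitis. It is a literature-curated reconstruction — each row carries a
source tag — and is explicitly user-replaceable: any tab-separated file
with the same four columns can be passed everywhere a database is accepted.
Duplicate (category, sequence) pairs are rejected at load; the same
sequence may appear under two categories (R5's QQPFP pentamer, for
instance, also occurs inside CD epitopes), in which case it produces one
event per category, matching per-category summation. Degenerate/wildcard
positions in motifs are not supported; published sites with wildcards must
be expanded into their concrete variants by the user.

## In silico digestion

Classical Keil specificities: trypsin cuts after K/R, chymotrypsin (high
specificity) after F/W/Y/L, both suppressed when the next residue is
proline. The rules are a small regex table (`CLEAVAGE_RULES`) that users
can override. A potential site at the protein's final residue is not a cut.
With `missed_cleavages = m` every run of up to `m + 1` adjacent fragments
is emitted; the `[min_length, max_length]` filter (default 5–50, a rough
window of LC-MS/MS-detectable peptides) is applied last. Invariants
enforced by tests: zero-missed fragments tile the protein exactly; each
emitted fragment contains exactly its declared number of internal sites;
the digestion agrees with an independent implementation (pyteomics
`icleave` driven by the same rule) up to that library's convention of also
counting a cut at the protein terminus.

## Synthetic proteomes and ground truth

The generator emulates the study conditions this pipeline targets: a flour
proteome dominated by gliadin-like repetitive proteins, digested and
exported as a scored identification report.

* **Background.** Residues are i.i.d. from a Q/P-enriched composition
  (Q ≈ 0.37, P ≈ 0.16, then L, S, F, …) mimicking gliadin repeat regions.
  A Q/P-rich background *will* contain chance motif matches, especially for
  short motifs; correctness is therefore always defined against brute-force
  oracle enumeration over the generated peptides, never against the planted
  positions alone.
* **Families.** Protein family labels are drawn from a gliadin-heavy mix
  (α 0.25, γ 0.15, ω 0.08, HMW/LMW 0.10 each, remainder non-gluten),
  chosen as a plausible wheat-flour composition; the labels drive the
  report's description/taxon fields so the classification stage has real
  work to do.
* **Plants.** Per protein and category, the number of planted motifs is
  Poisson with the specified per-protein density (defaults: CD 1.0,
  R5/G12/IgE 0.4, A1 0.2, p31–43 0.1). Plants are placed uniformly at
  non-overlapping positions (rejection sampling; a placement failure after
  200 tries raises a generation error rather than silently dropping
  plants). Plants never straddle protein termini but may straddle cleavage
  sites — that is tracked, not prevented, because it exercises the
  coordinate bookkeeping: a plant is "contained" only if some emitted
  fragment covers its whole window and that fragment survives the filters.
  With probability `substitution_rate` a plant receives exactly one random
  substitution at a recorded motif position.
* **Scores.** True fragments draw `pep_expect` uniformly from
  [10⁻⁴, 0.04]; decoy rows (shuffled sequence, own accession) are injected
  with probability 0.1 per true row and scored from [0.05, 0.5], so the
  default decoys always fail the score filter and the filter stage is
  genuinely exercised.
* **Determinism.** All randomness flows from the single spec seed through
  numpy `default_rng` child streams (`[seed, 0]` proteome, `[seed, 1]`
  report); identical specs give byte-identical FASTA/TSV outputs.

What the generator does **not** emulate: real spectral acquisition and
search-engine scoring, homology structure between proteins (each synthetic
protein is independent), shared peptides across proteins, deamidation, or
realistic protein-level abundance. Passing the recovery tests therefore
shows that the pipeline's bookkeeping (filters, digestion coordinates,
window scanning, event aggregation) is exact under controlled input — it
does not validate identification quality on real LC-MS/MS data.

## Bundled published counts

`data/reference_counts/*.tsv` holds the published category × mode event
counts for white wheat and tritordeum flours under both digestions. The
underlying peptide identifications are not publicly deposited, so absolute
counts cannot be recomputed here; the bundled tables make the two-flour
fold-ratio computation reproducible (CD 49/14 → 3.5, G12 22/4 → 5.5 under
chymotrypsin; A1 1/1 → 1.0 under trypsin). Note that rounding is half-up:
31/8 prints as 3.9.

## Numerical and problem-size choices

* Ratio rounding uses decimal half-up on the repr of the float (avoids
  binary-float round-half-even surprises like 1.25 → 1.2).
* The scanner encodes sequences as uint8 arrays and uses numpy sliding
  windows; the reference oracle is a literal pure-Python enumeration kept
  intentionally naive and independent.
* Test/acceptance problem sizes — 10⁴ randomized scan cases, 100-protein
  recovery proteomes, 200-protein × 10-seed contrast runs, 1000-protein
  digestion sweeps — are chosen so the whole suite completes in well under
  a minute per property while keeping sampling error small (the contrast
  check tolerates ±0.5 around the planted 3.5-fold, about 3 standard
  errors of the 10-seed mean).
* Degenerate inputs: an empty survivor set yields an all-zero count table
  (with a warning at the CLI); a motif longer than a peptide yields no
  events; an empty category in a database is legal and counts zero.

## Known limitations

* The default motif inventory is a best-effort curation, not the exact
  historical list behind any published table; absolute event counts depend
  on the inventory and should only be compared across samples scanned with
  the same inventory.
* Family classification is keyword-based over free-text descriptions;
  exports with unusual nomenclature need an adapted keyword table.
* No deamidation-aware matching: deamidated epitope variants (E for Q) are
  only found if added to the inventory explicitly.
* Digestion is fully specific; semi-specific or non-specific cleavage
  products are not modeled.
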