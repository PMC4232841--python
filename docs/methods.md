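# Methods

## Scope and model

`splicevar` implements a database-driven strategy for finding splice
variants at the protein level. The object of study is a *variant
protein*: the ab-initio translation of a reference transcript whose
splice pattern has been modified by one or more events observed in
transcriptome data. Evidence for an event is a *variant-unique tryptic
peptide* — a peptide identified by a search engine that maps to the
variant protein but cannot arise from the unmodified reference proteome
under the same digestion rules.

The pipeline makes three modelling commitments:

1. **Largest-ORF translation.** The protein product of a variant mRNA is
   the translation of its longest ATG-initiated open reading frame.
   Non-ATG initiation is out of scope. By default the ORF must be
   stop-terminated (`allow_open_ended=False`): a predicted full-length
   cDNA is expected to encode a complete ORF, and admitting open-ended
   ORFs would make the length comparison sensitive to arbitrary 3'
   truncation. Ties in nucleotide length (stop codon included) break to
   the 5'-most start, matching conventional longest-ORF finders and
   favouring canonical initiation.
2. **Tryptic-universe uniqueness.** A peptide "exists" in the reference
   proteome only if it is itself a tryptic product there (cleavage
   C-terminal to K/R with no proline restriction, ≤2 missed cleavages,
   ≥7 residues — the digestion settings of the emulated searches). A
   stricter mode (`template_substring`) additionally rejects peptides
   occurring anywhere inside the variant's own template protein,
   guarding against semi-tryptic coincidences; it is off by default
   because search engines only observe fully tryptic peptides, so the
   tryptic universe is the operative definition.
3. **Peptide-first TIS calling.** An event is an alternative-TIS event
   when (i) a supporting peptide matches the variant protein's beginning
   (residue 1, or residue 2 of a Met-initiated protein when initiator-Met
   cleavage is considered — N-terminal acetylation co-occurs with Met
   removal, flag `nterm_met_cleavage`, default on) and (ii) the variant's
   ORF actually initiates away from the mapped reference start. The
   second condition prevents an N-terminal junction peptide of an
   unmoved start from being mistaken for a TIS event.

## Splice-event semantics

Events edit the exon/intron block list of a transcript; all coordinates
are 0-based half-open in spliced-mRNA space.

- `EXON_SKIP [i, j]`: remove exons i..j (contiguous).
- `ALT_3SS exon=i, shift=s`: s < 0 prepends the last |s| nt of intron
  i−1 to exon i (acceptor moved into the intron); s > 0 deletes the
  first s nt of exon i. The sign convention (negative = intronic
  extension) is a toolkit definition, documented in the event-TSV spec.
- `ALT_5SS exon=i, shift=s`: mirror image on the donor side.
- `INTRON_RETAIN k`: insert intron k between exons k and k+1.
- `DUAL_SPECIFIC`: taxonomy label only; never generated or applied.

Combined events (CASEs) apply all constituents in a *single pass* over
the block list, never sequentially on remapped coordinates, so the
result is order-independent by construction. Constituents must have
pairwise-disjoint footprints (our conservative reading; whether two
events may share an exon is not settled by the source catalogues).
Truncating shifts do not claim the flanking intron, so opposite-side
truncations around one intron can co-occur.

Alongside the variant mRNA the engine emits a strictly monotone partial
coordinate map (reference position → variant position; deleted positions
unmapped) and the *modified regions*: inserted intervals for retained
introns and splice-site extensions, and zero-length junction marks at
pure deletions. The junction marks let downstream logic ask whether a
codon spans a deletion even though the deletion has no extent in variant
coordinates.

Sequences may contain N; codons containing N translate to X and never
terminate an ORF — only exact TAA/TAG/TGA do. This keeps ingestion
permissive and translation deterministic.

## TIS classification rules

Let `r` be the image of the reference CDS start under the coordinate map
(possibly unmapped) and `s` the variant ORF start.

- **C (upstream)**: `r` mapped and `s < r`.
- **A vs B (downstream)**: the *variant-specific N-terminal span* runs
  from `s` to the point where the variant protein re-synchronizes with
  the reference protein. Re-synchronization is formalized as the longest
  exactly-matching C-terminal run of the two proteins: under the report
  aligner's scoring (match +1, mismatch −1, gap −5 −1/residue), the
  optimal global alignment always ends with that identical suffix
  aligned, so the suffix run equals the alignment's terminal match run
  while costing O(n) instead of O(nm). If no region of the event
  intersects the span (with a codon spanning a zero-length junction
  counting as intersecting, and the start codon always considered), the
  category is A; otherwise B.
- **first_atg_downstream**: `s` is the 5'-most ATG at or after the
  3'-most modified-region boundary. The scan is frame-agnostic by
  default (`first_atg_in_frame` restricts it to the ORF's frame); the
  source material does not settle which reading is intended, so both are
  supported.
- **wilson_model** (amino-terminus-only isoform difference): the event's
  net length change within the reference CDS is ≡ 0 (mod 3), no in-frame
  stop is introduced between the mapped reference start and the shared
  region, and variant and reference proteins are identical from the
  first residue encoded fully downstream of all modified regions to
  their C-termini. This is a machine-checkable formalization of a
  criterion originally applied by visual inspection.
  `orf_disrupting` is defined as its complement.

When `r` is mapped and `s == r` the variant is not an alternative-TIS
case and classification returns all-absent flags.

## Support calling

Stage 1 uses protein-assignment evidence: any non-variant accession in
the peptide's protein list rejects it (protein-group evidence outranks
recomputation); when the list is absent, membership is recomputed
against the database. Stage 2 requires absence from the reference
tryptic universe. Peptides shared between variants of different events
are attributed to every matching event and flagged `shared_variant`.
Variants whose sequences collide exactly are stored once but retain all
merged event ids, and support is credited to each.

## Synthetic data: what it emulates and what it does not

`generate_cohort` builds seeded toy genes (3–6 exons of 30–120 nt,
introns 9–60 nt) with a constructed CDS: ATG at a sampled start, random
non-stop body codons, in-frame stop in the final exon, and ATG-free,
stop-free UTR filler so the annotated CDS is the reference mRNA's
largest ORF. Constructed regions (planted introns, novel N-termini) use
a closed codon set with no stop and no ATG in any reading frame, plus
planted AAA lysines, so tryptic boundaries of novel peptides are
controlled.

The `tis-rich` preset cycles six gene archetypes so every TIS category
is well populated at n=200: start-exon skips resolved by a downstream
in-frame ATG (category A; alternating frame-preserving and
frame-shifting deletions), retained early-CDS introns carrying an
in-frame stop plus the new start (category B), retained 5'UTR introns
with an upstream in-frame ATG reading through into the CDS (category
C), two internal (start-preserving) simple events, and one internal
CASE. The `default` preset plants only internal events at the
transcriptome-like type mix (35/29/25/11% skip / alt-3' / alt-5' /
retention).

Ground truth is computed by oracles that share no code with the engines
they validate: a token-stream block rewriter for variant mRNAs, a
regex-driven brute-force ATG→stop scan, Biopython translation, and an
O(n²) all-substring digestion enumerator. Truth uniqueness is judged
against the whole cohort's reference tryptic universe, exactly as the
pipeline will see it.

The simulated identification table emulates a *filtered* search-engine
output: every tryptic peptide of every database entry appears with
probability `detect_prob`, protein assignments are computed honestly
from the database, decoy rows carry reversed sequences and `+` Reverse
flags, contaminants a `+` flag, intensities are log-normal around 1e7
(σ one decade, matching the several-orders-of-magnitude span of real
data) and scores uniform on [40, 160]. Intensity and score are report
plumbing only and never influence classification. The generator does
not model spectra, retention times, FDR, missing-value structure,
modified peptides, or I/L ambiguity (an `il_equivalence` fold is
available but off by default) — so passing tests demonstrate the
correctness of the database/uniqueness/classification logic, not
robustness to search-engine noise.

## Numerical and formatting choices

- FASTA output wraps at 60 columns, uppercase; variants sorted by event
  id, then reference records verbatim in input order — build output is
  byte-identical across runs.
- De-duplication keeps the lexicographically first event id; collisions
  between variant and reference sequences are retained on both sides
  (accession-level classification still works) and flagged in the build
  report.
- Frequency percentages are integers, round-half-up; percentages of a
  set sum to 100 ± 2 by rounding.
- The report aligner (Gotoh, affine gaps) breaks score ties
  diagonal > up > left, making text and HTML reports byte-stable.
- The acceptance script uses a 200-gene TIS-rich study; all suites run
  in seconds on one CPU at these sizes, which were chosen to exercise
  every archetype at least ten times.

## Known limitations

- Only ATG-initiated ORFs are considered; non-canonical starts are
  invisible to the TIS analysis.
- The CASE non-overlap constraint rejects some biologically conceivable
  same-exon combinations.
- Genome-backed ingestion takes CDS features verbatim; annotations whose
  CDS length is not a multiple of three are kept with the start only.
- `classify`/`report` CLI commands rebuild the database from transcripts
  and events rather than reading the database FASTA, because coordinate
  maps cannot be carried in FASTA; the deterministic build guarantees
  the rebuilt database matches the written one.
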