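# splicevar

Proteogenomic detection of alternative-splicing events (ASEs) in shotgun
proteomics data. `splicevar` builds custom protein search databases from
splice variants of reference transcripts, determines which tryptic
peptides are unique to each variant, classifies externally identified
peptides as ASE-supporting, and categorizes alternative translation
initiation sites (TIS).

It is written for proteogenomics practitioners who have (i) reference
transcript models, (ii) a catalogue of splice events called from
transcriptome data (exon skipping, alternative 3'/5' splice sites,
intron retention, and combinations thereof), (iii) a reference proteome
FASTA, and (iv) peptide identification tables from a search engine
(MaxQuant `peptides.txt` or any TSV with a `Sequence` column).

## The method

1. **Variant mRNA construction.** Each splice event is applied to its
   template transcript's exon/intron block structure in a single pass,
   yielding the variant mRNA plus a reference→variant coordinate map and
   the modified regions (inserted intronic sequence, or zero-length
   junction marks at deletions).
2. **Ab-initio translation.** The variant protein is the translation of
   the *largest* ATG-initiated, stop-terminated open reading frame of the
   variant mRNA (ties break 5'-most). Products identical to the
   template's annotated CDS translation are discarded.
3. **Database construction.** Surviving variants are de-duplicated by
   exact sequence, tagged `NAME# (TYPE:ID)` in the FASTA header
   (`ES`/`A3SS`/`A5SS`/`IR`/`CASE`), and merged with the reference
   proteome (reference headers preserved verbatim). Events supported by
   fewer than two expressed sequences are excluded by default.
4. **ASE-supporting peptides.** An identified peptide supports an event
   when its protein assignments contain only variant-tagged accessions
   *and* the peptide is absent from the reference tryptic-peptide
   universe (trypsin cutting after K/R with no proline restriction,
   ≤2 missed cleavages, ≥7 residues).
5. **TIS classification.** Events supported by a peptide matching the
   protein's beginning, whose variant initiates away from the mapped
   reference start, are alternative-TIS events:
   - **A** — new start downstream of (or replacing a deleted) reference
     start, with the variant-specific N-terminus clear of the modified
     region;
   - **B** — as A, but the modified region directly shapes the protein's
     beginning;
   - **C** — new start upstream of the intact reference start.

   Each TIS event also carries two flags: whether the chosen ATG is the
   first one downstream of the event, and whether the isoform pair fits
   the amino-terminus-only difference model (frame-preserving event, no
   introduced in-frame stop, identical sequence downstream of the
   modification).

## Worked example

```python
import splicevar as sv
from splicevar.digest import DigestParams
from splicevar.model import EventType
from splicevar.pipeline import IdentifiedPeptide

t = sv.Transcript(
    transcript_id="NM_EX1", gene_id="EX1",
    exons=("ATGGCTAAAGAGGAA", "GATTTTGGGCAT", "TGCGCTCGTTCTGAATAA"),
    introns=("GTAAGTACAG", "GTGAGTGCAG"),
    cds_start=0, cds_end=45,
)
e = sv.SpliceEvent("SP001", "NM_EX1", EventType.EXON_SKIP,
                   {"skip": (1, 1)}, support_count=4)

v = sv.predict_variant_protein(t, e)
reference = [("sp|EX1|REF example reference", sv.reference_protein(t))]
db = sv.build_database({"NM_EX1": t}, [e], reference)
index = sv.build_peptide_index(reference, DigestParams())

print(sv.reference_protein(t))                     # MAKEEDFGHCARSE
print(v.sequence)                                  # MAKEECARSE
print(v.accession)                                 # NM_EX1# (ES:SP001)
print([p.sequence for p in sv.variant_unique_peptides(v, index)])
# ['MAKEECAR', 'MAKEECARSE', 'EECARSE']

records, _ = sv.call_ase_support(
    [IdentifiedPeptide("MAKEECAR", accessions=(v.accession,))], db, index)
print(records[0].event_id, records[0].event_type, records[0].is_tis)
# SP001 ES False
```

Skipping the middle exon joins `...GAGGAA` to `TGCGCT...`, removing the
residues `DFGH` and creating the junction peptides `MAKEECAR`,
`MAKEECARSE` and `EECARSE` — tryptic peptides of the variant that do not
exist as tryptic peptides of the reference proteome. Observing any of
them in an MS search supports the skip. The event is not a TIS event:
the variant still initiates at the reference start codon.

The same steps are available from the shell (`splicevar build-db`,
`digest`, `classify`, `merge`, `report`), and `splicevar simulate`
writes a complete seeded synthetic study — transcripts, events,
reference proteome, identification table and ground truth — for testing
without any external data.

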