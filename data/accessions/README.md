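# Deposited reference records

Place local copies of the public records here to enable
`analysis/06_accession_checks.py` and the corresponding acceptance test
(`phamily.accession` documents how each file is used):

| file | content |
| --- | --- |
| `OR671924.gb` | CRP-810 phage genome, GenBank flat file with CDS features |
| `HTVC023P_TerL.faa` | pelagiphage HTVC023P terminase large subunit (protein FASTA) |
| `HTVC025P_tail_fiber.faa` | pelagiphage HTVC025P tail fiber protein (protein FASTA) |
| `PP816027.fasta` | host FZCC0198 16S rRNA gene (nucleotide FASTA) |
| `HKCCA1288_16S.fasta` | CHUG strain HKCCA1288 16S rRNA gene (nucleotide FASTA) |

These are ordinary NCBI downloads; nothing here modifies them.
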