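# data/

`deposited_alleles.fasta` (not redistributed): the archived loggerhead MHC
class I allele sequences, GenBank accessions KF021627-KF021666. Fetch them
on a networked machine with

    python scripts/fetch_deposited_alleles.py

The deposited-allele acceptance test
(`tests/test_acceptance.py::test_deposited_allele_statistics`) reads this
file and deduplicates identical sequences before computing population
statistics.
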