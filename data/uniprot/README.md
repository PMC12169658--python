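# Reference sequences (user-supplied)

Place the canonical UniProt FASTA files here to enable the reference
sequence-statistics checks:

* `Q9UBB5.fasta` — human MBD2 (expected net charge +23)
* `O95983.fasta` — human MBD3 (expected net charge −10)
* `P51608.fasta` — human MeCP2 (expected charged-residue fraction ≈33%)

e.g. `curl -O https://rest.uniprot.org/uniprotkb/Q9UBB5.fasta`. Fetching
them is the only step of the test suite that requires network access; they
are not bundled.
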