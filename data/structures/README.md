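# Deposited coordinate files

Place mmCIF (or PDB) files for the analyzed accessions here, named by
accession:

    9o8e.cif   9o8h.cif   7sp1.cif   5o3l.cif

e.g. `curl -O https://files.rcsb.org/download/9O8E.cif && mv 9O8E.cif 9o8e.cif`.

No coordinates are bundled: the environment this repository was built in had
no network route to the PDB archive. With the files in place,
`tests/test_acceptance.py` (criteria 5-8) and `scripts/acceptance.py`
(targets t1-t8) run the full computation against them; without the files the
tests fail with an explanatory message and the report omits those targets.
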