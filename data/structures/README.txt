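Place deposited coordinate files here to enable the crystal-structure
regression test (tests/test_acceptance.py::test_table1_crossover_regression).

One file per benchmark entry, named by NDB accession (case-insensitive),
PDB or mmCIF format:

    BD0022.pdb   BD0015.pdb   BDJ060.pdb   BD0028.pdb
    BDJ069.pdb   BD0047.pdb   BD0084.pdb   PD0287.cif

Files can be downloaded from the Nucleic Acid Database
(http://ndbserver.rutgers.edu) by searching the accession.  This directory
ships empty: the test requires network-obtained data and reports the missing
entries explicitly when run offline.
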