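# Reference coordinate files

One acceptance test superposes the deposited crystal structures of the
BAF A12T-lamin A/C Ig-fold complex on the wild-type complex and checks the
Ca RMSD. It expects the two PDB entries here as plain-text files:

    tests/data/7z21.pdb
    tests/data/6ghd.pdb

Fetch them with, e.g.:

    curl -o tests/data/7z21.pdb https://files.rcsb.org/download/7Z21.pdb
    curl -o tests/data/6ghd.pdb https://files.rcsb.org/download/6GHD.pdb

The files are not redistributed with the package; without them that test
fails with an explanatory message.
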