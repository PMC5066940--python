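# Deposited coordinate files (not bundled)

The deposited-ensemble checks in `tests/test_acceptance.py` analyse the two
solution-NMR ensembles of the lesion-bearing Drew–Dickerson duplexes,
deposited in the Protein Data Bank as **5IV1** (lesion at position 4,
13 models) and **5IZP** (lesion at position 10, 14 models). Coordinate
files are not redistributed with this package and cannot be fetched in an
offline environment.

To run those checks, download the entries and place them here as:

    data/deposited/5IV1.pdb
    data/deposited/5IZP.pdb

e.g. `curl -O https://files.rcsb.org/download/5IV1.pdb` (likewise 5IZP).
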