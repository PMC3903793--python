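# Deposited coordinate files

The worked-example acceptance tests and `scripts/acceptance.py` read
plain-text PDB files from this directory, named `<pdbid>.pdb` in
lowercase:

    1vkg.pdb  1t64.pdb  1bre.pdb  43c9.pdb  3ab2.pdb  3o6t.pdb  1w22.pdb  3rqd.pdb

They are not bundled (no redistribution, and the build environment had
no route to a PDB mirror). To populate:

    for id in 1vkg 1t64 1bre 43c9 3ab2 3o6t 1w22 3rqd; do
        curl -o data/pdb/$id.pdb https://files.rcsb.org/download/${id^^}.pdb
    done

Without these files the dependent acceptance targets are omitted from
the report and the corresponding tests fail with an explicit message;
everything else in the package is self-contained.
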