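# Crystal-structure inputs (not bundled)

The worked-example acceptance tests evaluate two structure-derived
quantities on the deposited Bcl-X_L_ coordinates:

* helical content of the apo (1PQ0) and holo (1PQ1) crystal structures
  under the dihedral-window criterion (expected near 80%);
* the union contact census over 1PQ0, 1BXL, 1G5J and 1PQ1 with the 4 A
  heavy-atom rule and the shipped region map (expected 174 pairs, with the
  sensitivity to the minimum-sequence-separation setting reported).

The coordinate files are not redistributed with this package. To run those
tests, download the entries from the PDB, reduce each to the Bcl-X_L_ chain
(for the complexes, this removes the bound BH3 peptide), and place them here
as:

    1pq0_bclxl.pdb
    1bxl_bclxl.pdb   (first NMR model)
    1g5j_bclxl.pdb
    1pq1_bclxl.pdb

`groovetraj.read_structure(path, chain="A")` + `write_structure` is enough
to produce the chain-reduced files.
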