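# Bcl-X_L_ helix/loop region map (residue numbering per UniProt Q64373).
# Helix ranges are the helical regions common to the 1PQ0 and 1PQ1 crystal
# structures of the loop-deleted construct, in which residue 44 is covalently
# linked to residue 85 (hence the two H2 intervals).  Loop LB is the long
# H2-H3 connector that wraps around the hydrophobic groove; LC and LD are the
# short H3-H4 and H4-H5 connectors.  Regions are kept disjoint: overlaps
# across regions are reported by RegionMap.overlapping_regions().
regions:
  H1: [[3, 20]]
  H2: [[42, 44], [85, 100]]
  H3: [[120, 133]]
  H4: [[137, 157]]
  H5: [[159, 185]]
  H6: [[188, 195]]
  LB: [[101, 119]]
  LC: [[134, 136]]
  LD: [[158, 158]]
helices: [H1, H2, H3, H4, H5, H6]
loops: [LB, LC, LD]
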