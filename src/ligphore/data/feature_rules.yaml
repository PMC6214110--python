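# Pharmacophore feature perception rules, version 1.
#
# The four feature classes follow the standard public definitions used by
# ligand-based pharmacophore tools:
#   HBD  N-H / O-H donors, excluding anions that have already lost the proton
#   HBA  N / O with an available lone pair, excluding amide N, pyrrole-type
#        aromatic N-H, oxidized N, and protonated N
#   HY   contiguous clusters (>= min_cluster_size) of non-polar carbons and
#        halogens not adjacent to charged or polar atoms; a ring is one cluster
#   RA   5- and 6-membered fully aromatic rings (centroid + ring normal)
version: 1
hbd:
  patterns:
    - "[N;!H0;!$([N-])]"
    - "[O;!H0;!$([O-])]"
hba:
  patterns:
    - "[OX2;!$([O-]);!$(O=*)]"
    - "[OX1;!$([OX1]~[NX3+])]"
    - "[O-;!$([O-][N+])]"
    - "[nX2;H0]"
    - "[NX3;v3;+0;!$([NX3][CX3]=[OX1]);!$([NX3]~[OX1]);!$([NX3]=*);!$([N;a])]"
    - "[NX2;+0;$([NX2]=[#6])]"
hy:
  min_cluster_size: 2
  atom_patterns:
    - "[#6;+0;!$([#6]~[#7,#8,#15,#16]);!$([#6]~[*;+1,+2,-1,-2])]"
    - "[F,Cl,Br,I;+0;$([*][#6])]"
ra:
  ring_sizes: [5, 6]
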