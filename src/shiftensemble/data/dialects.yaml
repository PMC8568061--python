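# Column mappings for supported chemical-shift predictor output dialects.
# layout: wide  -> one row per residue, one column per atom
# layout: long  -> one row per (residue, atom)
# layout: sparta-> whitespace table with a "VARS ..." header line
ucbshift:
  layout: wide
  residue_number: RESNUM
  residue_name: RESNAME
  nuclei:
    HN: H
    NH: N
    CA: CA
    CB: CB
shiftx2:
  layout: long
  residue_number: NUM
  residue_name: RES
  nucleus: ATOMNAME
  shift: SHIFT
  atom_map:
    H: HN
    HN: HN
    N: NH
    CA: CA
    CB: CB
spartaplus:
  layout: sparta
  residue_number: RESID
  residue_name: RESNAME
  nucleus: ATOMNAME
  shift: SHIFT
  atom_map:
    HN: HN
    H: HN
    N: NH
    CA: CA
    CB: CB
generic-csv:
  layout: long
  residue_number: residue_number
  residue_name: residue_name
  nucleus: nucleus
  shift: shift
  atom_map:
    HN: HN
    NH: NH
    H: HN
    N: NH
    CA: CA
    CB: CB
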