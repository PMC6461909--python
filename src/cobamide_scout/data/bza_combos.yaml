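# Mapping from anaerobic benzimidazole gene complements to the predicted
# lower-ligand compound.  The first committed step (AIR -> 5-OHBza) is
# carried out either by BzaF alone or by BzaA together with BzaB; BzaC,
# BzaD and BzaE extend the product stepwise:
#   5-OHBza --BzaC--> 5-OMeBza --BzaD--> 5-OMe-6-MeBza --BzaE--> DMB
# Each combo row lists a full gene set; every row must contain a first-step
# route (bzaF, or bzaA and bzaB).  A genome whose complement passes the
# first-step requirement but matches no row is reported as "unresolved".
combos:
  - {genes: [bzaF], compound: 5-OHBza}
  - {genes: [bzaA, bzaB], compound: 5-OHBza}
  - {genes: [bzaF, bzaC], compound: 5-OMeBza}
  - {genes: [bzaA, bzaB, bzaC], compound: 5-OMeBza}
  - {genes: [bzaF, bzaC, bzaD], compound: 5-OMe-6-MeBza}
  - {genes: [bzaA, bzaB, bzaC, bzaD], compound: 5-OMe-6-MeBza}
  - {genes: [bzaF, bzaC, bzaD, bzaE], compound: DMB}
  - {genes: [bzaA, bzaB, bzaC, bzaD, bzaE], compound: DMB}
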