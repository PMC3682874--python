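# Bundled default group configuration.
#
# predicate_groups: seven groups of SemRep predicates expressing related content.
# metapredications: the allowed <semantic group> <predicate group> <semantic group>
#   triples, grouped into eight display families; list order is the canonical
#   tie-break order for cluster labeling.
# semantic_types: UMLS semantic-type abbreviations mapped to the 15 coarse
#   semantic groups (McCray-style aggregation). The map is total on this declared
#   vocabulary only; users supply their own file to extend it.
# generic_concepts: Metathesaurus concepts too high in the hierarchy to carry
#   summary-worthy information; predications touching them are filtered out.

predicate_groups:
  Physical: [PART_OF, LOCATION_OF]
  Interaction: [INHIBITS, STIMULATES, INTERACTS_WITH]
  Therapy: [TREATS, PREVENTS, COMPARED_WITH, USES]
  Causation: [ASSOCIATED_WITH, CAUSES, PREDISPOSES]
  Diagnosis: [DIAGNOSES, MEASURES]
  Affects: [AFFECTS, AUGMENTS, DISRUPTS]
  Comorbidity: [COEXISTS_WITH]

metapredications:
  - display_name: Body location
    triples:
      - [Anatomy, Physical, Anatomy]
      - [Anatomy, Physical, Chemicals & Drugs]
      - [Anatomy, Physical, Disorders]
  - display_name: Substance interaction
    triples:
      - [Chemicals & Drugs, Interaction, Chemicals & Drugs]
      - [Chemicals & Drugs, Interaction, Genes & Molecular Sequences]
  - display_name: Drug treatment
    triples:
      - [Chemicals & Drugs, Therapy, Disorders]
      - [Chemicals & Drugs, Therapy, Chemicals & Drugs]
  - display_name: Procedure treatment
    triples:
      - [Procedures, Therapy, Disorders]
      - [Procedures, Therapy, Chemicals & Drugs]
  - display_name: Etiology
    triples:
      - [Genes & Molecular Sequences, Causation, Disorders]
      - [Chemicals & Drugs, Causation, Disorders]
      - [Disorders, Causation, Disorders]
  - display_name: Diagnosis
    triples:
      - [Procedures, Diagnosis, Disorders]
      - [Procedures, Diagnosis, Chemicals & Drugs]
  - display_name: Affect
    triples:
      - [Disorders, Affects, Disorders]
      - [Chemicals & Drugs, Affects, Disorders]
      - [Chemicals & Drugs, Affects, Physiology]
  - display_name: Disease comorbidities
    triples:
      - [Disorders, Comorbidity, Disorders]

semantic_types:
  # Anatomy
  anst: Anatomy
  blor: Anatomy
  bpoc: Anatomy
  bsoj: Anatomy
  cell: Anatomy
  celc: Anatomy
  emst: Anatomy
  ffas: Anatomy
  tisu: Anatomy
  # Chemicals & Drugs
  aapp: Chemicals & Drugs
  antb: Chemicals & Drugs
  bacs: Chemicals & Drugs
  bodm: Chemicals & Drugs
  chem: Chemicals & Drugs
  chvf: Chemicals & Drugs
  chvs: Chemicals & Drugs
  clnd: Chemicals & Drugs
  elii: Chemicals & Drugs
  enzy: Chemicals & Drugs
  hops: Chemicals & Drugs
  horm: Chemicals & Drugs
  imft: Chemicals & Drugs
  inch: Chemicals & Drugs
  irda: Chemicals & Drugs
  lipd: Chemicals & Drugs
  nnon: Chemicals & Drugs
  opco: Chemicals & Drugs
  orch: Chemicals & Drugs
  phsu: Chemicals & Drugs
  rcpt: Chemicals & Drugs
  strd: Chemicals & Drugs
  vita: Chemicals & Drugs
  # Disorders
  acab: Disorders
  anab: Disorders
  cgab: Disorders
  comd: Disorders
  dsyn: Disorders
  emod: Disorders
  fndg: Disorders
  inpo: Disorders
  mobd: Disorders
  neop: Disorders
  patf: Disorders
  sosy: Disorders
  # Genes & Molecular Sequences
  amas: Genes & Molecular Sequences
  crbs: Genes & Molecular Sequences
  gngm: Genes & Molecular Sequences
  mosq: Genes & Molecular Sequences
  nusq: Genes & Molecular Sequences
  # Physiology
  celf: Physiology
  clna: Physiology
  genf: Physiology
  menp: Physiology
  moft: Physiology
  orgf: Physiology
  ortf: Physiology
  phsf: Physiology
  # Procedures
  diap: Procedures
  edac: Procedures
  hlca: Procedures
  lbpr: Procedures
  mbrt: Procedures
  resa: Procedures
  topp: Procedures
  # Living Beings
  aggp: Living Beings
  amph: Living Beings
  anim: Living Beings
  arch: Living Beings
  bact: Living Beings
  bird: Living Beings
  euka: Living Beings
  fish: Living Beings
  fngs: Living Beings
  grup: Living Beings
  humn: Living Beings
  mamm: Living Beings
  orgm: Living Beings
  plnt: Living Beings
  podg: Living Beings
  popg: Living Beings
  prog: Living Beings
  rept: Living Beings
  virs: Living Beings
  vtbt: Living Beings
  # Activities & Behaviors
  acty: Activities & Behaviors
  bhvr: Activities & Behaviors
  dora: Activities & Behaviors
  evnt: Activities & Behaviors
  gora: Activities & Behaviors
  inbe: Activities & Behaviors
  mcha: Activities & Behaviors
  ocac: Activities & Behaviors
  socb: Activities & Behaviors
  # Concepts & Ideas
  clas: Concepts & Ideas
  cnce: Concepts & Ideas
  ftcn: Concepts & Ideas
  grpa: Concepts & Ideas
  idcn: Concepts & Ideas
  inpr: Concepts & Ideas
  lang: Concepts & Ideas
  qlco: Concepts & Ideas
  qnco: Concepts & Ideas
  rnlw: Concepts & Ideas
  spco: Concepts & Ideas
  tmco: Concepts & Ideas
  # Devices
  drdd: Devices
  medd: Devices
  resd: Devices
  # Objects
  enty: Objects
  food: Objects
  mnob: Objects
  sbst: Objects
  # Occupations
  bmod: Occupations
  ocdi: Occupations
  # Organizations
  hcro: Organizations
  orgt: Organizations
  pros: Organizations
  shro: Organizations
  # Phenomena
  eehu: Phenomena
  hcpp: Phenomena
  lbtr: Phenomena
  npop: Phenomena
  phpr: Phenomena
  # Geographic Areas
  geoa: Geographic Areas

generic_concepts:
  - C0030705   # Patients
  - C0013227   # Pharmaceutical Preparations
  - C0012634   # Disease
  - C0087111   # Therapeutic procedure
  - C1254351   # Pharmacologic Substance
  - C0332307   # Type of (qualifier-like placeholder concept)
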