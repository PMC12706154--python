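# CYP2D6 StarTRAC allele matrix and multiplex panel.
#
# Coordinates are 1-based on the NG_008376.4 RefSeq with ATG = +1.
# Statuses encode only what validated genotyping data force: omitted
# allele/target combinations are UNKNOWN and raise MatrixIncompleteError
# when queried, rather than being guessed.
#
# Hybrid alleles carry CYP2D7-derived gene regions (d7_regions, or
# d7_after: <region> meaning every region downstream of it). CYP2D6-specific
# assays produce no signal from CYP2D7-derived sequence.

targets:
  g.100C>T:  {position: 100,  ref: C, var: T, region: exon1,   rsid: rs1065852,  dyes: {ref: FAM, var: VIC}}
  g.1022C>T: {position: 1022, ref: C, var: T, region: exon2,   rsid: rs28371706, dyes: {ref: VIC, var: FAM}}
  g.1847G>A: {position: 1847, ref: G, var: A, region: exon4,   rsid: rs3892097,  dyes: {ref: VIC, var: FAM}}
  g.2851C>T: {position: 2851, ref: C, var: T, region: exon6,   rsid: rs16947,    dyes: {ref: FAM, var: VIC}}
  g.2989G>A: {position: 2989, ref: G, var: A, region: intron6, rsid: rs28371725, dyes: {ref: VIC, var: FAM}}
  g.3184G>A: {position: 3184, ref: G, var: A, region: exon7,   rsid: rs59421388, dyes: {ref: VIC, var: FAM}}
  # Variant-only exon-9 target: the assay detects only the C (variant) allele.
  g.4181G>C: {position: 4181, ref: G, var: C, region: exon9,   rsid: rs1135840,  dyes: {var: JUN}}

plexes:
  CN_100:  {gt: g.100C>T,  reference: RNaseP}
  CN_1022: {gt: g.1022C>T, reference: RNaseP}
  CN_1847: {gt: g.1847G>A, reference: RNaseP}
  CN_2851: {gt: g.2851C>T, reference: RNaseP}
  CN_2989: {gt: g.2989G>A, reference: RNaseP}
  CN_3184: {gt: g.3184G>A, reference: RNaseP}

alleles:
  "*1":
    targets: {g.100C>T: REF, g.1022C>T: REF, g.1847G>A: REF, g.2851C>T: REF,
              g.2989G>A: REF, g.3184G>A: REF, g.4181G>C: REF}
  "*2":
    targets: {g.100C>T: REF, g.1022C>T: REF, g.1847G>A: REF, g.2851C>T: VAR,
              g.2989G>A: REF, g.3184G>A: REF, g.4181G>C: VAR}
  "*4":
    targets: {g.100C>T: VAR, g.1022C>T: REF, g.1847G>A: VAR, g.2851C>T: REF,
              g.2989G>A: REF, g.3184G>A: REF, g.4181G>C: VAR}
    # Present on most but not all suballeles; may or may not be informative
    # depending on which *4 suballele a sample carries.
    hatched: [g.100C>T, g.4181G>C]
  "*10":
    targets: {g.100C>T: VAR, g.1022C>T: REF, g.1847G>A: REF, g.2851C>T: REF,
              g.2989G>A: REF, g.3184G>A: REF, g.4181G>C: VAR}
  "*17":
    targets: {g.100C>T: REF, g.1022C>T: VAR, g.1847G>A: REF, g.2851C>T: VAR,
              g.2989G>A: REF, g.3184G>A: REF, g.4181G>C: VAR}
  "*29":
    targets: {g.100C>T: REF, g.1022C>T: REF, g.1847G>A: REF, g.2851C>T: VAR,
              g.2989G>A: REF, g.3184G>A: VAR, g.4181G>C: VAR}
    annotations: ["core SNV g.1660G>A+g.1662G>A (p.V136I) not targeted by this panel"]
  "*41":
    targets: {g.100C>T: REF, g.1022C>T: REF, g.1847G>A: REF, g.2851C>T: VAR,
              g.2989G>A: VAR, g.3184G>A: REF, g.4181G>C: VAR}
  "*45":
    # Only the combinations exercised by validated samples are encoded.
    targets: {g.1022C>T: REF, g.4181G>C: VAR}
    annotations: ["core SNV g.1717G>A (p.E155K) not targeted by this panel"]
  "*154":
    targets: {g.1022C>T: VAR, g.3184G>A: REF, g.4181G>C: VAR}
    annotations:
      - "core SNV g.4046G>A (p.R411H) not targeted by this panel"
      - "g.1022T carriage by *154 (rather than *29) is figure-derived"
  "*158":
    targets: {g.2989G>A: VAR, g.4181G>C: VAR}
    annotations: ["core SNV g.3187A>C (p.I339L) not targeted by this panel"]
  "*36":
    # As *10 but with the exon-9 region CYP2D7-derived: the g.4181C assay
    # gives no signal from this copy.
    targets: {g.100C>T: VAR, g.1022C>T: REF, g.1847G>A: REF, g.2851C>T: REF,
              g.2989G>A: REF, g.3184G>A: REF, g.4181G>C: VAR}
    d7_regions: [exon9]
  "*68":
    # CYP2D6::CYP2D7 hybrid converting after intron 1; only exon-1 targets
    # (g.100) remain CYP2D6-specific.
    targets: {g.100C>T: VAR}
    d7_after: intron1
  "*5":
    # Whole-gene deletion: no CYP2D6 signal at any target.
    deletion: true
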