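# Default study profile: three plant accessions (C1 Jeddah, C2 Jizan,
# C3 Riyadh) characterized with 10 ISSR primers, 11 SCoT primers, one
# SDS-PAGE protein profile, two barcode loci, three target genes and a
# panel of phytochemical / antioxidant-enzyme traits.
accessions: [C1, C2, C3]

markers:
  ISSR:
    unique_allocation: {C1: 8, C2: 4, C3: 12}
    primers:
      - {id: ISSR1, MB: 4, UB: 4, NB: 1}
      - {id: ISSR2, MB: 5, UB: 3, NB: 1}
      - {id: ISSR3, MB: 6, UB: 0, NB: 1}
      - {id: ISSR4, MB: 3, UB: 0, NB: 1}
      - {id: ISSR5, MB: 4, UB: 4, NB: 3}
      - {id: ISSR6, MB: 2, UB: 0, NB: 3}
      - {id: ISSR7, MB: 1, UB: 2, NB: 0}
      - {id: ISSR8, MB: 3, UB: 2, NB: 2}
      - {id: ISSR9, MB: 2, UB: 3, NB: 1}
      - {id: ISSR10, MB: 1, UB: 6, NB: 2}
  SCoT:
    unique_allocation: {C1: 23, C2: 7, C3: 29}
    primers:
      - {id: SCoT1, MB: 6, UB: 0, NB: 3}
      - {id: SCoT2, MB: 2, UB: 11, NB: 0}
      - {id: SCoT3, MB: 3, UB: 2, NB: 2}
      - {id: SCoT4, MB: 3, UB: 1, NB: 1}
      - {id: SCoT5, MB: 5, UB: 7, NB: 8}
      - {id: SCoT6, MB: 1, UB: 8, NB: 5}
      - {id: SCoT7, MB: 0, UB: 12, NB: 7}
      - {id: SCoT8, MB: 3, UB: 10, NB: 4}
      - {id: SCoT9, MB: 4, UB: 3, NB: 5}
      - {id: SCoT10, MB: 5, UB: 2, NB: 5}
      - {id: SCoT11, MB: 2, UB: 3, NB: 5}
  PROTEIN:
    unique_allocation: {C1: 2, C2: 0, C3: 0}
    primers:
      - {id: SDS-PAGE, MB: 5, UB: 2, NB: 0}

# published PIC values per primer (the computing path of such columns is
# usually unstated; supplied as overrides so MI can use them)
published_pic:
  ISSR1: 0.46
  ISSR2: 0.36
  ISSR3: 0.08
  ISSR4: 0.14
  ISSR5: 0.47
  ISSR6: 0.33
  ISSR7: 0.59
  ISSR8: 0.41
  ISSR9: 0.54
  ISSR10: 0.72
  SCoT1: 0.19
  SCoT2: 0.75
  SCoT3: 0.41
  SCoT4: 0.29
  SCoT5: 0.53
  SCoT6: 0.71
  SCoT7: 0.77
  SCoT8: 0.66
  SCoT9: 0.45
  SCoT10: 0.41
  SCoT11: 0.54

barcode:
  length: 600
  close_pair: [C1, C2]          # sister accessions
  divergence_close: 0.01        # target p-distance within the close pair
  divergence_far: 0.15          # target p-distance of C3 to either

expression:
  reference_gene: Actin
  calibrator: C1
  n_replicates: 3
  ct_sigma: 0.2                 # per-well CT noise, cycles
  baseline_ct: 20.0             # reference-gene CT level
  delta_ct_base: 5.0            # calibrator dCt per gene, cycles
  folds:                        # truth relative to the calibrator
    PAL1: {C1: 1.0, C2: 3.0, C3: 7.3}
    PR12: {C1: 1.0, C2: 4.0, C3: 14.6}
    AFPRT: {C1: 1.0, C2: 5.0, C3: 13.8}

traits:
  n_replicates: 3
  # per accession: [mean, sd]; units follow each assay's convention
  values:
    TPC: {C1: [55.0, 2.8], C2: [70.0, 3.5], C3: [92.54, 4.6]}
    TFC: {C1: [48.0, 2.4], C2: [60.0, 3.0], C3: [77.13, 3.9]}
    Alkaloids: {C1: [0.87, 0.04], C2: [0.60, 0.03], C3: [0.35, 0.02]}
    Saponins: {C1: [30.0, 1.5], C2: [43.65, 2.2], C3: [49.67, 2.5]}
    Tannins: {C1: [0.95, 0.05], C2: [1.43, 0.07], C3: [1.87, 0.09]}
    SOD: {C1: [9.5, 0.5], C2: [12.4, 0.6], C3: [16.87, 0.8]}
    POD: {C1: [38.0, 1.9], C2: [47.0, 2.4], C3: [60.87, 3.0]}
    CAT: {C1: [20.0, 1.0], C2: [27.0, 1.4], C3: [35.76, 1.8]}
    APX: {C1: [15.0, 0.8], C2: [21.0, 1.1], C3: [27.98, 1.4]}
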