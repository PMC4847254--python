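# Default functional-profiling configuration for Oenococcus oeni-style
# analyses.  Editable: pathway "required" entries are lists of groups; a
# group is satisfied by any one of its members (alternative enzymes or
# alternative KEGG module variants).
#
# Note: one published listing of the malate-to-aspartate route carries the
# identifier "K014454", an apparent typo for K14454 (aspartate
# aminotransferase, consistent with the lactate and citrate routes); this
# config uses K14454.

pathways:
  # -------------------------------------------------- complete pathways (T1)
  - id: gln_from_glu
    label: "Glutamate to Glutamine"
    amino_acid: Glutamine
    table: T1
    required: [[K01915]]
  - id: gly_from_ser
    label: "Serine to Glycine"
    amino_acid: Glycine
    table: T1
    required: [[K00600]]
  - id: ser_from_gly
    label: "Glycine to Serine"
    amino_acid: Serine
    table: T1
    required: [[K00600]]
  - id: cys_from_ser
    label: "Serine to Cysteine"
    amino_acid: Cysteine
    table: T1
    required: [[M00021]]
  - id: pro_from_glu
    label: "Glutamate to Proline"
    amino_acid: Proline
    table: T1
    required: [[M00015]]
  - id: asp_from_asn
    label: "Asparagine to Aspartate"
    amino_acid: Aspartate
    table: T1
    required: [[K01424]]
  - id: asp_from_lactate
    label: "Lactate to Aspartate"
    amino_acid: Aspartate
    table: T1
    required: [[K00016], [K01006], [K01595], [K14454]]
  - id: asp_from_citrate
    label: "Citrate to Aspartate"
    amino_acid: Aspartate
    table: T1
    required: [[K01643], [K01644], [K01646], [K14454]]
  - id: asp_from_malate
    label: "Malate to Aspartate"
    amino_acid: Aspartate
    table: T1
    required: [[K00027], [K01006], [K01595], [K14454]]
  - id: thr_from_asp
    label: "Aspartate to Threonine"
    amino_acid: Threonine
    table: T1
    required: [[M00018]]
  - id: arg_from_gln
    label: "Glutamine to Arginine"
    amino_acid: Arginine
    table: T1
    required: [[K01955], [K01956], [K00611], [K01940], [K01755]]
  - id: leu_from_val
    label: "Valine to Leucine"
    amino_acid: Leucine
    table: T1
    required: [[M00432]]
  # ------------------------------------------------ incomplete pathways (T2)
  - id: asn_from_asp
    label: "Aspartate to Asparagine"
    amino_acid: Asparagine
    table: T2
    required: [[K01914]]
  - id: glu_from_pyruvate
    label: "Pyruvate to Glutamate"
    amino_acid: Glutamate
    table: T2
    required: [[K01958], [K01647], [K01681], [K00031], [K14454]]
  - id: glu_from_his
    label: "Histidine to Glutamate"
    amino_acid: Glutamate
    table: T2
    required: [[M00045]]
  - id: his_from_prpp
    label: "Phosphoribosyl to Histidine"
    amino_acid: Histidine
    table: T2
    required: [[M00026]]
  - id: ile_from_thr
    label: "Threonine to Isoleucine"
    amino_acid: Isoleucine
    table: T2
    required: [[M00570]]
  - id: lys_from_asp
    label: "Aspartate to Lysine"
    amino_acid: Lysine
    table: T2
    # KEGG module variants of the aspartate-to-lysine route; any one route
    # suffices.
    required: [[M00525, M00527, M00526, M00016]]
  - id: met_from_asp
    label: "Aspartate to Methionine"
    amino_acid: Methionine
    table: T2
    required: [[M00017]]
  - id: phe_from_chorismate
    label: "Chorismate to Phenylalanine"
    amino_acid: Phenylalanine
    table: T2
    required: [[M00024]]
  - id: trp_from_chorismate
    label: "Chorismate to Tryptophan"
    amino_acid: Tryptophan
    table: T2
    required: [[M00023]]
  - id: tyr_from_chorismate
    label: "Chorismate to Tyrosine"
    amino_acid: Tyrosine
    table: T2
    required: [[M00025]]
  - id: val_from_pyruvate
    label: "Pyruvate to Valine"
    amino_acid: Valine
    table: T2
    required: [[M00019]]

# PTS enzyme II transporters: completeness is assessed over the subunit set
# (typically IIA, IIB, IIC and occasionally IID).
subunit_systems:
  - id: pts_mannose
    label: "Mannose-specific PTS II"
    subunits: [PTS-man-IIA, PTS-man-IIB, PTS-man-IIC, PTS-man-IID]
  - id: pts_galactitol
    label: "Galactitol-specific PTS II"
    subunits: [PTS-gat-IIA, PTS-gat-IIB, PTS-gat-IIC]
  - id: pts_cellobiose
    label: "Cellobiose-specific PTS II"
    subunits: [PTS-cel-IIA, PTS-cel-IIB, PTS-cel-IIC]
  - id: pts_beta_glucoside
    label: "Beta-glucoside-specific PTS II"
    subunits: [PTS-bgl-IIA, PTS-bgl-IIB, PTS-bgl-IIC]
  - id: pts_fructose
    label: "Fructose-specific PTS II"
    subunits: [PTS-fru-IIA, PTS-fru-IIB, PTS-fru-IIC]
  - id: pts_ascorbate
    label: "Ascorbate-specific PTS II"
    subunits: [PTS-asc-IIA, PTS-asc-IIB, PTS-asc-IIC]
  - id: pts_sucrose
    label: "Sucrose-specific PTS II"
    subunits: [PTS-scr-IIA, PTS-scr-IIBC]
  - id: pts_lactose
    label: "Lactose-specific PTS II"
    subunits: [PTS-lac-IIA, PTS-lac-IIB, PTS-lac-IIC]

# Five-carbon sugar utilisation enzyme sets (per-enzyme strain counts are
# reported on a square-root shading scale).
enzyme_sets:
  - id: xylose
    label: "D-xylose utilisation"
    functions: ["EC 5.3.1.5", "EC 2.7.1.17"]
  - id: arabinose
    label: "L-arabinose utilisation"
    functions: ["EC 5.3.1.4", "EC 2.7.1.16", "EC 5.1.3.1", "EC 3.2.1.55"]
  - id: xylulose
    label: "L-xylulose utilisation"
    functions: ["EC 5.1.3.4", "EC 5.-.-.-", "EC 2.7.1.53"]

# Natural competence machinery assessed per strain.
competence_genes: [ComEA, ComEC, ComGC, ComFA, ComG]
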