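# Pathway signature rules for SQ degradation gene clusters.
#
# Each pathway is recognised by groups of accepted domain tags that must be
# found within the ±k-ORF neighbourhood of the seed SQase gene.  Tags are
# symbolic enzyme-role labels carried in feature annotations (domain_tags in
# TSV, `domain=` attributes in GFF3); swap in PFAM accessions here if your
# annotations carry them — rules are data, not code.
#
# min_groups_satisfied: all groups for multi-enzyme pathways; 1 for the
# single-signature sulfolytic/transaldolase pathways.  cooccurrence_tags is an
# optional extra requirement for single-signature pathways (off by default,
# enabled with require_cooccurrence=True) to keep single-gene calls honest.
pathways:
  - pathway: sulfo-EMP
    min_groups_satisfied: 4
    groups:
      - name: isomerase
        tags: [SQ_isomerase]
      - name: kinase
        tags: [SF_kinase]
      - name: aldolase
        tags: [SFP_aldolase]
      - name: sla_dehydrogenase
        tags: [SLA_dehydrogenase]
  - pathway: sulfo-ED
    min_groups_satisfied: 4
    groups:
      - name: sq_dehydrogenase
        tags: [SQ_dehydrogenase]
      - name: lactonase
        tags: [SGL_lactonase]
      - name: dehydratase
        tags: [SG_dehydratase]
      - name: aldolase
        tags: [KDSG_aldolase]
  - pathway: sulfo-SFT
    min_groups_satisfied: 1
    groups:
      - name: transaldolase
        tags: [SF_transaldolase]
    cooccurrence_tags: [SQ_transporter, sulfoglycolysis_regulator]
  - pathway: sulfo-SMO
    min_groups_satisfied: 1
    groups:
      - name: monooxygenase
        tags: [SQ_monooxygenase]
    cooccurrence_tags: [SQ_transporter, sulfolysis_regulator]
  - pathway: sulfo-SDO
    min_groups_satisfied: 1
    groups:
      - name: dioxygenase
        tags: [SQ_dioxygenase]
    cooccurrence_tags: [SQ_transporter, sulfolysis_regulator]
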