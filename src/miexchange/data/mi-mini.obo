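format-version: 1.2
ontology: mi-mini
remark: Synthetic excerpt of the PSI-MI controlled vocabulary shipped with miexchange. It mirrors the real ontology's structure (roots for detection methods, interaction types, roles, interactor types, expansion methods) with standard accessions, so generated fixtures and validation tests run hermetically; it is not a substitute for the full ontology.

[Term]
id: MI:0000
name: molecular interaction

[Term]
id: MI:0001
name: interaction detection method
is_a: MI:0000 ! molecular interaction

[Term]
id: MI:0045
name: experimental interaction detection
is_a: MI:0001 ! interaction detection method

[Term]
id: MI:0401
name: biochemical
is_a: MI:0045 ! experimental interaction detection

[Term]
id: MI:0004
name: affinity chromatography technology
is_a: MI:0401 ! biochemical

[Term]
id: MI:0007
name: anti tag coimmunoprecipitation
is_a: MI:0004 ! affinity chromatography technology

[Term]
id: MI:0096
name: pull down
is_a: MI:0004 ! affinity chromatography technology

[Term]
id: MI:0013
name: biophysical
is_a: MI:0045 ! experimental interaction detection

[Term]
id: MI:0114
name: x-ray crystallography
is_a: MI:0013 ! biophysical

[Term]
id: MI:0018
name: two hybrid
is_a: MI:0045 ! experimental interaction detection

[Term]
id: MI:0686
name: unspecified method
is_a: MI:0001 ! interaction detection method

[Term]
id: MI:0190
name: interaction type
is_a: MI:0000 ! molecular interaction

[Term]
id: MI:0914
name: association
is_a: MI:0190 ! interaction type

[Term]
id: MI:0915
name: physical association
is_a: MI:0914 ! association

[Term]
id: MI:0407
name: direct interaction
is_a: MI:0915 ! physical association

[Term]
id: MI:0403
name: colocalization
is_a: MI:0190 ! interaction type

[Term]
id: MI:0500
name: biological role
is_a: MI:0000 ! molecular interaction

[Term]
id: MI:0499
name: unspecified role
is_a: MI:0500 ! biological role
is_a: MI:0495 ! experimental role

[Term]
id: MI:0501
name: enzyme
is_a: MI:0500 ! biological role

[Term]
id: MI:0502
name: enzyme target
is_a: MI:0500 ! biological role

[Term]
id: MI:0495
name: experimental role
is_a: MI:0000 ! molecular interaction

[Term]
id: MI:0496
name: bait
is_a: MI:0495 ! experimental role

[Term]
id: MI:0498
name: prey
is_a: MI:0495 ! experimental role

[Term]
id: MI:0497
name: neutral component
is_a: MI:0495 ! experimental role

[Term]
id: MI:0313
name: interactor type
is_a: MI:0000 ! molecular interaction

[Term]
id: MI:0383
name: biopolymer
is_a: MI:0313 ! interactor type

[Term]
id: MI:0326
name: protein
is_a: MI:0383 ! biopolymer

[Term]
id: MI:0320
name: ribonucleic acid
is_a: MI:0383 ! biopolymer

[Term]
id: MI:0319
name: deoxyribonucleic acid
is_a: MI:0383 ! biopolymer

[Term]
id: MI:0328
name: small molecule
is_a: MI:0313 ! interactor type

[Term]
id: MI:0314
name: complex
is_a: MI:0313 ! interactor type

[Term]
id: MI:0329
name: unknown participant
is_a: MI:0313 ! interactor type

[Term]
id: MI:1059
name: complex expansion
is_a: MI:0000 ! molecular interaction

[Term]
id: MI:1060
name: spoke expansion
is_a: MI:1059 ! complex expansion

[Term]
id: MI:1061
name: matrix expansion
is_a: MI:1059 ! complex expansion

[Term]
id: MI:1062
name: bipartite expansion
is_a: MI:1059 ! complex expansion

[Term]
id: MI:0116
name: feature type
is_a: MI:0000 ! molecular interaction

[Term]
id: MI:0117
name: binding-associated region
is_a: MI:0116 ! feature type

[Term]
id: MI:0505
name: experimental feature
is_a: MI:0116 ! feature type

[Term]
id: MI:0507
name: tag
is_a: MI:0116 ! feature type

[Term]
id: MI:0333
name: feature range status
is_a: MI:0000 ! molecular interaction

[Term]
id: MI:0335
name: certain
is_a: MI:0333 ! feature range status

[Term]
id: MI:0339
name: undetermined
is_a: MI:0333 ! feature range status

[Term]
id: MI:0340
name: ragged n-terminus
is_a: MI:0333 ! feature range status

[Term]
id: MI:0444
name: database citation
is_a: MI:0000 ! molecular interaction

[Term]
id: MI:0486
name: uniprot knowledge base
is_a: MI:0444 ! database citation

[Term]
id: MI:0474
name: chebi
is_a: MI:0444 ! database citation

[Term]
id: MI:0446
name: pubmed
is_a: MI:0444 ! database citation

[Term]
id: MI:0488
name: psi-mi
is_a: MI:0444 ! database citation

[Term]
id: MI:0469
name: intact
is_a: MI:0444 ! database citation

[Term]
id: MI:0574
name: digital object identifier
is_a: MI:0444 ! database citation

[Term]
id: MI:0300
name: alias type
is_a: MI:0000 ! molecular interaction

[Term]
id: MI:0301
name: gene name
is_a: MI:0300 ! alias type

[Term]
id: MI:0302
name: gene name synonym
is_a: MI:0300 ! alias type

[Term]
id: MI:0353
name: cross-reference type
is_a: MI:0000 ! molecular interaction

[Term]
id: MI:0356
name: identity
is_a: MI:0353 ! cross-reference type

[Term]
id: MI:0360
name: secondary-ac
is_a: MI:0353 ! cross-reference type

[Term]
id: MI:0002
name: participant identification method
is_a: MI:0000 ! molecular interaction

[Term]
id: MI:0396
name: predetermined participant
is_a: MI:0002 ! participant identification method

[Term]
id: MI:0102
name: sequence tag identification
is_a: MI:0002 ! participant identification method

[Term]
id: MI:0590
name: attribute name
is_a: MI:0000 ! molecular interaction

[Term]
id: MI:0612
name: comment
is_a: MI:0590 ! attribute name
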