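# Default CV-usage rules: each rule names a model slot, the ontology term
# every CV term used in that slot must descend from (transitive is_a
# closure, self included), and the severity of a violation.
#
# This is a representative subset of the full semantic-validator catalogue;
# the mechanism is general and rule files like this one can be swapped in
# with the --rules option.
rules:
  - location: experiment.detection_method
    required_ancestor: "MI:0001"   # interaction detection method
    severity: error
  - location: interaction.interaction_type
    required_ancestor: "MI:0190"   # interaction type
    severity: error
  - location: participant.biological_role
    required_ancestor: "MI:0500"   # biological role
    severity: error
  - location: participant.experimental_role
    required_ancestor: "MI:0495"   # experimental role
    severity: error
  - location: interactor.interactor_type
    required_ancestor: "MI:0313"   # interactor type
    severity: error
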