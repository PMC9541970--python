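# Template bank for the synthetic-corpus generator.
#
# Every positive wrapper is cue-free (no negation or history cue appears
# before the embedded mention), which is what guarantees that in-lexicon
# positives are machine-recoverable by construction. Benign sentences avoid
# all lexicon vocabulary so no phrase can form, even across stripped
# punctuation. Distractor sentences deliberately contain in-lexicon phrases
# used in a non-IPV sense. Negated / history sentences wrap an in-lexicon
# phrase in a scope the detector must suppress.

benign_sentences:
  - "pt presents with ankle pain after a fall at work."
  - "seen for cough and fever, symptomatic treatment advised."
  - "laceration to left forearm repaired with sutures."
  - "headache, nausea, no focal neurologic deficits on exam."
  - "follow up with primary care in one week."
  - "medication list reviewed and reconciled."
  - "vitals stable throughout the visit."
  - "discharged home in good condition."

positive_wrappers:
  - "pt states she was {m}."
  - "chief complaint: {m}."
  - "she reports {m} this visit."
  - "seen by social work for {m}."
  - "{m} reported by patient on arrival."

negated_sentences:
  - "patient denies any domestic violence or abuse at home."
  - "pt states no ipv."
  - "denies intimate partner violence."
  - "no domestic dispute per pt."
  - "not a victim of domestic abuse."

history_sentences:
  - "hx of domestic violence in 2015, resolved."
  - "reports history of ipv during previous pregnancy but not currently."
  - "h/o ipv with prior partner."
  - "history of spouse abuse years ago."
  - "ho of domestic abuse, none current."

distractor_sentences:
  - "domestic dispute between mother and child reported by ems."
  - "ipv vaccine administered in left thigh."
  - "domestic violence pamphlet provided at discharge."

template_blocks:
  - "ipv screening questions:\ndo you feel safe at home? {a}\nhas your partner ever hit you? {a}\ndomestic violence screen: {a}"
  - "domestic violence screen completed by nursing: {a}\ndo you feel safe at home? {a}"

template_answers: ["___", "no", "declined"]

benign_codes_icd10: ["I10", "J45.909", "S93.401A", "R51.9", "K52.9", "Z23"]
benign_codes_icd9: ["401.9", "786.50", "845.00"]
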