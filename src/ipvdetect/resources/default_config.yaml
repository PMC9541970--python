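# Default scoping and normalization configuration.
#
# scoping.termination_tokens is the faithful published set; by default the
# loader DROPS "and" from it so that negation scopes extend through "and",
# matching the canonical worked example ("... use_neg and_neg intimate_neg ...").
# Pass faithful_table3=true to keep "and" as a terminator.
scoping:
  negation_cues: ["denies", "denied", "deny", "no", "non", "not", "without", "unable"]
  termination_tokens: ["?", ".", "-", "−", ";", ":", "+", "and", "but",
                       "complains", "did", "except", "has", "per", "pt",
                       "reports", "secondary", "states"]
  # matched longest-first so "h/o of" is never shadowed by "h/o"
  history_cues: ["history of", "hx of", "h/x of", "ho of", "h/o of",
                 "hx", "h/x", "h/o", "ho"]

normalization:
  min_word_length: 2
  stemming_suffixes: ["ed", "ing", "s"]
  temporal_stopwords: ["last", "night", "tonight", "yesterday", "today",
                       "tomorrow", "ago", "day", "days", "week", "weeks",
                       "month", "months", "year", "years", "am", "pm",
                       "morning", "evening", "afternoon", "overnight",
                       "recently"]
  # articles and conjunctions ride along with the prepositions; words that
  # occur inside lexicon phrases or scoping cues are protected at pipeline
  # build time and survive regardless of this list
  preposition_stopwords: ["of", "in", "on", "at", "by", "to", "with", "from",
                          "for", "into", "onto", "upon", "over", "under",
                          "about", "around", "near", "after", "before",
                          "between", "through", "across", "against", "and",
                          "or", "the", "a", "an"]
  pronoun_stopwords: ["i", "you", "he", "she", "it", "we", "they", "me",
                      "him", "her", "us", "them", "my", "your", "his", "its",
                      "our", "their", "hers", "theirs", "mine", "yours",
                      "herself", "himself"]

# Lines matching any pattern (shell-style wildcards, case-insensitive) are
# removed before tokenization: auto-populated screening blocks, completed or
# blank, must never trigger a label.
template_patterns:
  - "*do you feel safe at home*"
  - "*domestic violence screen*"
  - "*ipv screening*"
  - "*partner ever hit*"
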