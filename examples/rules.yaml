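# Editable harmonization rules fixture.
#
# The full rule set used for the original corpus was produced manually by a
# panel and is not published; this file illustrates the format and the three
# rule classes (synonyms, category grouping, keep-list) so pipelines can run
# end to end. Extend freely.
synonyms:
  shoes: shoe
  corona-virus: corona
  coronavirus: corona
  overcrowded: overcrowding
  crowding: overcrowding
categories:
  aunt: relative
  uncle: relative
  cousin: relative
  nephew: relative
  helsinki: city
  paris: city
  london: city
keep:
  - father
  - mother
  - grandfather
  - grandmother
  - daughter
  - son
  - finland
  - sweden
notes: >-
  Synonyms are applied before category grouping; keep-listed tokens are
  exempt from category grouping only.
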