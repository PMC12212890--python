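# Default cause lexicon, version-pinned.  Patterns are written as plain
# words/phrases; they are stemmed with the package stemmer at load time.
# Single words match any stemmed token; phrases match adjacent stems after
# stop-word removal.  "other" carries no patterns: it is the fallback for
# descriptions matching no named cause (homicide and most violent deaths
# land there by design).
version: "1.0"
stopwords: [a, an, the, of, and, to, his, her, their, with, by, from, after, while, during]
patterns:
  heart:
    - heart attack
    - heart failure
    - heart disease
    - cardiac
    - coronary
    - myocardial
  cancer:
    - cancer
    - tumor
    - tumour
    - leukemia
    - lymphoma
    - carcinoma
    - malignant
    - chemotherapy
  covid19:
    - covid
    - coronavirus
  accidents:
    - accident
    - accidental
    - car crash
    - plane crash
    - train crash
    - drowns
    - drowning
    - falls
    - fell
    - overdose
    - electrocuted
  cerebrovascular:
    - stroke
    - aneurysm
    - brain hemorrhage
    - brain haemorrhage
    - cerebral
  chronic_lower_respiratory:
    - emphysema
    - copd
    - chronic bronchitis
    - asthma
  alzheimer:
    - alzheimer
    - dementia
  diabetes:
    - diabetes
    - diabetic
  chronic_liver:
    - cirrhosis
    - liver failure
    - liver disease
  nephritis:
    - nephritis
    - kidney failure
    - renal failure
    - kidney disease
  suicide:
    - suicide
    - kills himself
    - kills herself
    - hangs himself
    - hangs herself
    - shoots himself
    - shoots herself
    - slits his wrists
    - slits her wrists
    - jumps to his death
    - jumps to her death
  hypertension:
    - hypertension
    - hypertensive
  other: []
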