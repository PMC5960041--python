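# Default HIV terminology corpus.
#
# This file is a RECONSTRUCTION: the categories and member terms are the ones
# named in published trend analyses of International AIDS Conference
# abstracts; the full curated term list behind those analyses is not publicly
# distributed, so this set covers the documented categories only.  Replace or
# extend it with your own file (same layout) for real analyses.
#
# Layout: terms -> list of {canonical, category, variants?, acronyms?}.
# Variants and canonical forms are matched case-insensitively after
# normalization; plural surface forms are generated automatically.
terms:
  - canonical: aids carrier
    category: living with HIV
  - canonical: aids victim
    category: living with HIV
  - canonical: hiv carrier
    category: living with HIV
  - canonical: hiv victim
    category: living with HIV
  - canonical: hiv positive
    category: living with HIV
  - canonical: hiv infected
    category: living with HIV
  - canonical: aids patient
    category: living with HIV
  - canonical: hiv/aids patient
    category: living with HIV
  - canonical: people living with hiv
    category: living with HIV
    variants: [person living with hiv]

  - canonical: gay
    category: homosexual
  - canonical: homosexual
    category: homosexual

  - canonical: men who have sex with men
    category: MSM
    acronyms: [msm]

  - canonical: sex worker
    category: sex worker
  - canonical: prostitute
    category: sex worker

  - canonical: drug addict
    category: alcohol and drug use
  - canonical: drug abuser
    category: alcohol and drug use
  - canonical: drug abuse
    category: alcohol and drug use
  - canonical: drug user
    category: alcohol and drug use
  - canonical: people who use drugs
    category: alcohol and drug use
  - canonical: people who inject drugs
    category: alcohol and drug use
    acronyms: [pwid]

  - canonical: senior
    category: older adults
  - canonical: older patient
    category: older adults
  - canonical: older adult
    category: older adults

  - canonical: antiretroviral therapy
    category: antiretroviral therapy
    acronyms: [art]
  - canonical: combination antiretroviral therapy
    category: antiretroviral therapy
  - canonical: highly active antiretroviral therapy
    category: antiretroviral therapy
    acronyms: [haart]
  - canonical: aids cocktail
    category: antiretroviral therapy
  - canonical: hiv cocktail
    category: antiretroviral therapy
  - canonical: drug holiday
    category: antiretroviral therapy

  - canonical: pre-exposure prophylaxis
    category: pre-exposure prophylaxis and post-exposure prophylaxis
    acronyms: [prep]
  - canonical: post-exposure prophylaxis
    category: pre-exposure prophylaxis and post-exposure prophylaxis
    acronyms: [pep]
  - canonical: treatment as prevention
    category: pre-exposure prophylaxis and post-exposure prophylaxis

  - canonical: aids epidemic
    category: epidemic descriptors
  - canonical: hiv epidemic
    category: epidemic descriptors

  - canonical: treatment experienced
    category: treatment history
  - canonical: treatment interruption
    category: treatment history
  - canonical: structured treatment interruption
    category: treatment history
  - canonical: stopping treatment
    category: treatment history
  - canonical: continuum of care
    category: treatment history
  - canonical: hiv care continuum
    category: treatment history
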