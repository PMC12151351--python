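# Two-letter reporter-country codes to display names (codes seen in FAERS
# demographics for the second-generation androgen receptor antagonist cohort,
# plus common others). Codes absent from this table render as
# "COUNTRY NOT SPECIFIED".
country_codes:
  JP: Japan
  US: United States of America
  FR: France
  TW: Taiwan (Province of China)
  GB: United Kingdom
  BR: Brazil
  IT: Italy
  CN: China
  DE: Germany
  KR: Republic of Korea
  IE: Ireland
  FI: Finland
  CH: Switzerland
  BE: Belgium
  NL: Netherlands
  RO: Romania
  CA: Canada
  AU: Australia
  ES: Spain
  SE: Sweden
  DK: Denmark
  NO: Norway
  PT: Portugal
  AT: Austria
  PL: Poland
  GR: Greece
  TR: Turkey
  IN: India
  MX: Mexico
  AR: Argentina
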