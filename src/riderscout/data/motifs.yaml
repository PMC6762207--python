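# Cis-regulatory element catalogue scanned in LTR promoter (U3/R) regions.
# CTGTTG / CTGTTA are the two MYB core variants observed in the reference
# element's 5' LTR. The CGCG box, ABRE-like, CE3 and CBF consensi follow
# PLACE-style definitions; their exact strings are catalogue defaults of this
# package, not experimentally re-derived.
- name: CGCGBOXAT
  pattern: VCGCGB
  source: PLACE-style consensus (calmodulin-binding transcription activator site)
- name: MYBCORE_G
  pattern: CTGTTG
  source: MYB recognition core, G variant
- name: MYBCORE_A
  pattern: CTGTTA
  source: MYB recognition core, A variant (R2R3-MYB)
- name: ABRE_like
  pattern: ACGTGK
  source: PLACE-style ABA-responsive element-like consensus
- name: CE3
  pattern: ACGCGTGTC
  source: PLACE-style coupling element 3 consensus
- name: CBF_site
  pattern: RYCGAC
  source: PLACE-style C-repeat / dehydration-responsive element core
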