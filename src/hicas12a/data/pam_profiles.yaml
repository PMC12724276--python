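# PAM compatibility registry for Cas12a variants (4-nt PAMs, 5' of the
# protospacer). Editable: classification picks matching exclusions first,
# then the most specific matching entry (fewest concrete 4-mers), ties
# broken by the higher efficiency class; unmatched 4-mers are "none".
#
# provenance:
#   yeast_benchmarked  - editing outcome measured in S. cerevisiae
#   reported_mammalian - activity reported in mammalian cells only
#   reported_in_vitro  - activity reported in vitro only
#
# dr: mature direct-repeat used when building crRNA cassettes. The
# canonical 20-nt LbCas12a DR is shipped as the default; override per
# variant in a run config if a different repeat is required.
default_dr: AATTTCTACTAAGTGTAGAT
profiles:
  LbCas12a:
    entries:
      - {pattern: TTTV, class: high, provenance: yeast_benchmarked}
    exclusions: []
  impLbCas12a:
    notes: >-
      Broadest-compatibility LbCas12a variant (D156R/G532R/K538V/Y542R/K595R).
      TNTN recognition is yeast-benchmarked as a family; per-4-mer efficiencies
      within TNTN are not individually encoded. TTTT is covered by the TNTN
      family claim rather than by a dedicated measurement.
    entries:
      - {pattern: TTTV, class: high, provenance: yeast_benchmarked}
      - {pattern: TNTN, class: high, provenance: yeast_benchmarked}
      - {pattern: TACC, class: high, provenance: yeast_benchmarked}
      - {pattern: TTCC, class: high, provenance: yeast_benchmarked}
      - {pattern: TCCC, class: high, provenance: yeast_benchmarked}
      - {pattern: CTCC, class: high, provenance: yeast_benchmarked}
      - {pattern: CTCA, class: high, provenance: yeast_benchmarked}
      - {pattern: CCCC, class: high, provenance: yeast_benchmarked}
      - {pattern: TACV, class: moderate, provenance: reported_mammalian}
      - {pattern: TTCV, class: moderate, provenance: reported_mammalian}
      - {pattern: TCCV, class: moderate, provenance: reported_mammalian}
      - {pattern: CTCV, class: moderate, provenance: reported_mammalian}
      - {pattern: CCCV, class: moderate, provenance: reported_mammalian}
    exclusions:
      - {pattern: TVTT, class: low, provenance: yeast_benchmarked}
      - {pattern: TSTG, class: low, provenance: yeast_benchmarked}
  LbCas12a-RR:
    entries:
      - {pattern: TTTV, class: high, provenance: reported_mammalian}
      - {pattern: TCTV, class: high, provenance: yeast_benchmarked}
      - {pattern: TYYV, class: moderate, provenance: reported_mammalian}
    exclusions: []
  LbCas12a-RVR:
    entries:
      - {pattern: TTTV, class: high, provenance: reported_mammalian}
      - {pattern: TWTV, class: moderate, provenance: reported_mammalian}
    exclusions:
      - {pattern: TATM, class: none, provenance: yeast_benchmarked}
  LbCas12a-3Rv:
    entries:
      - {pattern: ATTA, class: high, provenance: yeast_benchmarked}
      - {pattern: CTTA, class: high, provenance: yeast_benchmarked}
      - {pattern: TTTV, class: high, provenance: reported_mammalian}
      - {pattern: TTYN, class: moderate, provenance: reported_mammalian}
      - {pattern: VTTV, class: moderate, provenance: reported_mammalian}
      - {pattern: TRTV, class: moderate, provenance: reported_mammalian}
    exclusions:
      - {pattern: TGTM, class: none, provenance: yeast_benchmarked}
      - {pattern: TATM, class: none, provenance: yeast_benchmarked}
  FnCas12a-EP16:
    notes: >-
      NNYN and NTAC PAMs reported in vitro; editing in yeast was negligible,
      so every 4-mer classifies as none for design purposes.
    entries:
      - {pattern: NNYN, class: none, provenance: reported_in_vitro}
      - {pattern: NTAC, class: none, provenance: reported_in_vitro}
    exclusions: []
  PrCas12a-3Rv:
    notes: Negligible editing in yeast; every 4-mer classifies as none.
    entries: []
    exclusions: []
  AsCas12a-RR:
    entries:
      - {pattern: TTTV, class: moderate, provenance: reported_mammalian}
      - {pattern: TYCV, class: moderate, provenance: reported_mammalian}
    exclusions: []
  AsCas12a-RVR:
    entries:
      - {pattern: TTTV, class: moderate, provenance: reported_mammalian}
      - {pattern: TATV, class: moderate, provenance: reported_mammalian}
    exclusions: []
  enAsCas12a:
    entries:
      - {pattern: TTTV, class: moderate, provenance: reported_mammalian}
      - {pattern: TTYN, class: moderate, provenance: reported_mammalian}
      - {pattern: VTTV, class: moderate, provenance: reported_mammalian}
      - {pattern: TRTV, class: moderate, provenance: reported_mammalian}
    exclusions: []
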