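# Hard-filter threshold tables (community-standard germline cutoffs).
# A call FAILS when a populated annotation violates its rule:
#   comparator "<"  -> fail if value <  cutoff
#   comparator ">"  -> fail if value >  cutoff
# Missing annotations never fail a call. Edit freely and pass via --hard-filters.
SNV:
  QD: {comparator: "<", cutoff: 2.0}
  FS: {comparator: ">", cutoff: 60.0}
  MQ: {comparator: "<", cutoff: 40.0}
  MQRankSum: {comparator: "<", cutoff: -12.5}
  ReadPosRankSum: {comparator: "<", cutoff: -8.0}
  SOR: {comparator: ">", cutoff: 3.0}
INDEL:
  QD: {comparator: "<", cutoff: 2.0}
  FS: {comparator: ">", cutoff: 200.0}
  ReadPosRankSum: {comparator: "<", cutoff: -20.0}
  SOR: {comparator: ">", cutoff: 10.0}
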