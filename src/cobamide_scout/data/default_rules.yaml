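# Default phenotype classification thresholds.
#
# CR = number of merged corrin-ring ortholog groups detected (chelatases and
# other excluded steps not counted; the shipped catalog has 12 scoreable
# groups, so very_likely_min = 12 means "all of them").  Markers are the
# three core corrin-ring groups of the catalog's marker set.  The nucleotide
# loop is complete when all four core assembly groups are present.
# These thresholds are deliberately editable: they encode the verbal category
# definitions (a non-producer has fewer than five corrin-ring genes; a Cbi
# salvager keeps nucleotide-loop assembly but little of the ring) and should
# be replaced wholesale if you maintain your own criteria table.
version: default-0.1
corrin_ring:
  very_likely_min: 12
  likely_min: 9
  possible_min: 5          # producer floor; "fewer than five" ring genes -> non-producer
  likely_nonproducer_min: 3
nucleotide_loop:
  core_groups: [adoT, cobU/cobP, cobS/cobV, cbiB]
  likely_min_fraction: 0.5
markers:
  very_likely_min: 3
  likely_min: 2
# Core annotation groups of interest (three ring markers + four core
# nucleotide-loop groups + the legacy cbiA/cobB marker); reported alongside
# calls, not used by the default decision rules.
core_groups:
  [cbiL/cobI, cbiF/cobM, cbiC/cobH, adoT, cobU/cobP, cobS/cobV, cbiB, cbiA/cobB]
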