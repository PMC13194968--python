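# Classification schemes for the geochemical pollution indices.
#
# Each scheme is an ordered list of [lower, upper, label] intervals covering the
# whole real line (use .inf / -.inf).  Intervals are left-closed: a value equal
# to a boundary belongs to the upper class.  Bounds are kept in this config so
# they can be corrected against alternative published schemes without touching
# code.
igeo:  # Muller seven-class geo-accumulation scale
  - [-.inf, 0, "uncontaminated"]
  - [0, 1, "uncontaminated to moderately contaminated"]
  - [1, 2, "moderately contaminated"]
  - [2, 3, "moderately to heavily contaminated"]
  - [3, 4, "heavily contaminated"]
  - [4, 5, "heavily to extremely contaminated"]
  - [5, .inf, "extremely contaminated"]
ef:  # five enrichment groups
  - [-.inf, 2, "deficiency to minimal enrichment"]
  - [2, 5, "moderate enrichment"]
  - [5, 20, "significant enrichment"]
  - [20, 40, "very high enrichment"]
  - [40, .inf, "extremely high enrichment"]
cf:  # four contamination groups
  - [-.inf, 1, "low contamination"]
  - [1, 3, "moderate contamination"]
  - [3, 6, "considerable contamination"]
  - [6, .inf, "very high contamination"]
pli:  # four pollution-load groups (>1 means the site is polluted)
  - [-.inf, 1, "unpolluted"]
  - [1, 2, "moderately polluted"]
  - [2, 3, "heavily polluted"]
  - [3, .inf, "extremely polluted"]
hi:  # non-carcinogenic hazard index
  - [-.inf, 1, "no significant non-carcinogenic risk"]
  - [1, .inf, "adverse non-carcinogenic risk"]
tcr:  # lifetime carcinogenic risk bands
  - [-.inf, 1.0e-6, "insignificant risk"]
  - [1.0e-6, 1.0e-4, "tolerable risk"]
  - [1.0e-4, .inf, "unacceptable carcinogenic risk"]
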