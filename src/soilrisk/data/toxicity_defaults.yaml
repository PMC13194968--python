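# Default toxicity registry (mg/kg/day for RfD; (mg/kg/day)^-1 for CSF).
#
# Conventions: where no inhalation value exists the oral RfD is route-
# extrapolated; where an RfC (mg/m3) exists it is converted with 20 m3/day and
# 70 kg (RfD_inh = RfC x 20/70); dermal values follow RAGS Part E
# (RfD_derm = RfD_ing x GIABS, CSF_derm = CSF_ing / GIABS).  `abs_derm` is the
# dermal absorption fraction.  Metals without a slope factor for any route are
# non-carcinogenic-only and are excluded from TCR tables with a notice.
# Every entry carries a provenance tag; all values are overridable via config.
As:
  rfd_ing: 3.0e-4
  rfd_inh: 4.3e-6
  rfd_derm: 3.0e-4
  csf_ing: 1.5
  csf_inh: 15.1
  csf_derm: 1.5
  abs_derm: 0.03
  gi_abs: 1.0
  provenance: "IRIS oral RfD/CSF; RfC 1.5e-5 mg/m3 converted; IUR 4.3e-3 (ug/m3)^-1 converted; RAGS-E ABS 0.03"
Pb:
  rfd_ing: 3.5e-3
  rfd_inh: 3.5e-3
  rfd_derm: 3.5e-3
  csf_ing: 8.5e-3
  csf_inh: 4.2e-2
  csf_derm: 8.5e-3
  abs_derm: 0.001
  gi_abs: 1.0
  provenance: "WHO-derived oral RfD as commonly tabulated; CalEPA oral SF 8.5e-3 and IUR 1.2e-5 converted; oral values route-extrapolated to inhalation RfD"
Zn:
  rfd_ing: 0.3
  rfd_inh: 0.3
  rfd_derm: 0.3
  csf_ing: null
  csf_inh: null
  csf_derm: null
  abs_derm: 0.001
  gi_abs: 1.0
  provenance: "IRIS oral RfD; route-extrapolated; no slope factor (non-carcinogenic-only)"
Fe:
  rfd_ing: 0.7
  rfd_inh: 0.7
  rfd_derm: 0.7
  csf_ing: null
  csf_inh: null
  csf_derm: null
  abs_derm: 0.001
  gi_abs: 1.0
  provenance: "PPRTV provisional oral RfD; route-extrapolated; no slope factor (non-carcinogenic-only)"
Cd:
  rfd_ing: 1.0e-3
  rfd_inh: 2.86e-6
  rfd_derm: 2.5e-5
  csf_ing: 6.1
  csf_inh: 6.3
  csf_derm: 244.0
  csf_derm_note: "csf_ing / GIABS per RAGS-E"
  abs_derm: 0.001
  gi_abs: 0.025
  provenance: "IRIS oral RfD (diet); RfC 1e-5 mg/m3 converted; oral SF 6.1 as widely used in soil HHRA (no IRIS oral SF); IUR 1.8e-3 converted"
Cu:
  rfd_ing: 0.04
  rfd_inh: 0.04
  rfd_derm: 0.04
  csf_ing: null
  csf_inh: null
  csf_derm: null
  abs_derm: 0.001
  gi_abs: 1.0
  provenance: "HEAST oral RfD; route-extrapolated; no slope factor (non-carcinogenic-only)"
Cr:
  rfd_ing: 3.0e-3
  rfd_inh: 2.86e-5
  rfd_derm: 7.5e-5
  csf_ing: 0.5
  csf_inh: 42.0
  csf_derm: 20.0
  abs_derm: 0.001
  gi_abs: 0.025
  provenance: "Hexavalent Cr assumed (conservative): IRIS oral RfD 3e-3, RfC 1e-4 mg/m3 converted, oral SF 0.5 (NJDEP, common in soil HHRA), IUR 1.2e-2 converted"
Ni:
  rfd_ing: 0.02
  rfd_inh: 2.57e-5
  rfd_derm: 8.0e-4
  csf_ing: 0.91
  csf_inh: 0.84
  csf_derm: 22.75
  abs_derm: 0.001
  gi_abs: 0.04
  provenance: "IRIS oral RfD (soluble salts); RfC 9e-5 mg/m3 converted; oral SF 0.91 literature value used in soil HHRA (no IRIS oral SF); IUR 2.4e-4 converted"
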