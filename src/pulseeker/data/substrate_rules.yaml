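# Substrate classification rules for called PULs.
#
# Each rule lists the minimal CAZyme-family / role composition ("required",
# a multiset: "GH92: 3" means at least three genes confirmed as GH92) that a
# locus must contain, optionally families that commonly co-occur ("optional",
# reported as matched evidence only), and compositions that exclude the rule
# ("forbidden"). Family names without a subfamily suffix accept any
# subfamily (GH30 matches GH30_1); names with a suffix require it exactly.
# The token "sulfatase" counts genes carrying the sulfatase role.
#
# Rules are evaluated in ascending priority order, most-constrained first,
# and the first match wins; loci matching no rule are labelled unknown.
rules:
  - name: sulfated_xylan_2
    label: sulfated xylan
    priority: 10
    required: {GH30: 1, GH10: 1, GH43_1: 1, sulfatase: 3}
    optional: {PL9: 1, CBM22: 1}
  - name: mannose_sulfated
    label: alpha-mannose-rich
    priority: 20
    required: {GH92: 3, sulfatase: 2}
    optional: {GH2: 1, GH3: 1, GH43_2: 1}
  - name: beta_glucan_B
    label: beta-glucan/laminarin
    priority: 30
    required: {GH16: 1, GH30_1: 1, GH17: 1}
    optional: {GH17: 2}
  - name: mannose_sulfatase_free
    label: alpha-mannose-rich
    priority: 40
    required: {GH92: 1, GH130: 1, GH20: 1, GH18: 1}
    optional: {CBM9: 1, GH3: 1, GH2: 1, CE2: 1}
    forbidden: [sulfatase]
  - name: sulfated_xylan_1
    label: sulfated xylan
    priority: 50
    required: {GH10: 1, GH3: 1, sulfatase: 2}
  - name: alpha_glucan_complex
    label: alpha-glucan
    priority: 60
    required: {GH13: 2}
    optional: {GH65: 1, GH43_12: 1, sulfatase: 1}
  - name: beta_glucan_C
    label: beta-glucan/laminarin
    priority: 70
    required: {GH5_46: 1, GH16: 1}
    optional: {CBM6: 1}
  - name: beta_glucan_C_relaxed
    label: beta-glucan/laminarin
    priority: 75
    required: {GH5_46: 1, GH30_1: 1}
    enabled: false
  - name: beta_glucan_A
    label: beta-glucan/laminarin
    priority: 80
    required: {GH16: 1, GH3: 1}
    optional: {GH2: 1, GH30_1: 1}
  - name: alpha_glucan_simple
    label: alpha-glucan
    priority: 90
    required: {GH65: 1, GH13: 1}
    optional: {CBM48: 1}
  - name: alginate
    label: alginate
    priority: 100
    any_of:
      families: [PL6, PL7, PL17]
      min_distinct: 2
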