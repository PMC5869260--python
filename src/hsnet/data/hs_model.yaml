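places:
- id: p0
  label: Heparan sulfate
  initial: 0.0
  constant: true
- id: p1
  label: ph-ERK 1/2
  initial: 1.0
  constant: false
- id: p2
  label: Cytochrome C
  initial: 1.0
  constant: false
- id: p3
  label: Cleaved caspase 3
  initial: 1.0
  constant: false
- id: p4
  label: Cleaved PARP
  initial: 1.0
  constant: false
- id: p5
  label: ERK1/2
  initial: 1.0
  constant: true
- id: p6
  label: Caspase 3
  initial: 1.0
  constant: true
- id: p7
  label: PARP
  initial: 1.0
  constant: true
- id: p8
  label: TNF-alpha
  initial: 1.0
  constant: false
- id: p9
  label: pRIP3
  initial: 1.0
  constant: false
- id: p10
  label: RIP3
  initial: 1.0
  constant: true
transitions:
- id: t_act_perk
  law: mass_action
  params:
    rate: k_hs_perk
- id: t_act_tnf
  law: mass_action
  params:
    rate: k_hs_tnf
- id: t_conv_cytc
  law: mass_action
  params:
    rate: k_perk_cytc
- id: t_mm_casp3
  law: mm_competitive_inhibition
  params:
    ki: ki_casp3
    km: km_casp3
    vmax: v_casp3
  inhibitor: p8
- id: t_mm_parp
  law: mm_competitive_inhibition
  params:
    ki: ki_parp
    km: km_parp
    vmax: v_parp
  inhibitor: p8
- id: t_act_prip3
  law: mass_action
  params:
    rate: k_tnf_prip3
- id: t_src_perk
  law: constant_source
  params:
    rate: b_perk
- id: t_dec_perk
  law: first_order
  params:
    rate: d_perk
- id: t_src_cytc
  law: constant_source
  params:
    rate: b_cytc
- id: t_dec_cytc
  law: first_order
  params:
    rate: d_cytc
- id: t_src_casp3
  law: constant_source
  params:
    rate: b_casp3
- id: t_dec_casp3
  law: first_order
  params:
    rate: d_casp3
- id: t_src_parp
  law: constant_source
  params:
    rate: b_parp
- id: t_dec_parp
  law: first_order
  params:
    rate: d_parp
- id: t_src_tnf
  law: constant_source
  params:
    rate: b_tnf
- id: t_dec_tnf
  law: first_order
  params:
    rate: d_tnf
- id: t_src_prip3
  law: constant_source
  params:
    rate: b_prip3
- id: t_dec_prip3
  law: first_order
  params:
    rate: d_prip3
arcs:
- source: p0
  target: t_act_perk
  weight: 1.0
  kind: standard
- source: t_act_perk
  target: p1
  weight: 1.0
  kind: standard
- source: p5
  target: t_act_perk
  weight: 1.0
  kind: read
- source: p0
  target: t_act_tnf
  weight: 1.0
  kind: standard
- source: t_act_tnf
  target: p8
  weight: 1.0
  kind: standard
- source: p1
  target: t_conv_cytc
  weight: 1.0
  kind: standard
- source: t_conv_cytc
  target: p2
  weight: 1.0
  kind: standard
- source: p2
  target: t_mm_casp3
  weight: 1.0
  kind: standard
- source: t_mm_casp3
  target: p3
  weight: 1.0
  kind: standard
- source: p8
  target: t_mm_casp3
  weight: 1.0
  kind: read
- source: p6
  target: t_mm_casp3
  weight: 1.0
  kind: read
- source: p3
  target: t_mm_parp
  weight: 1.0
  kind: standard
- source: t_mm_parp
  target: p4
  weight: 1.0
  kind: standard
- source: p8
  target: t_mm_parp
  weight: 1.0
  kind: read
- source: p7
  target: t_mm_parp
  weight: 1.0
  kind: read
- source: p8
  target: t_act_prip3
  weight: 1.0
  kind: standard
- source: t_act_prip3
  target: p9
  weight: 1.0
  kind: standard
- source: p10
  target: t_act_prip3
  weight: 1.0
  kind: read
- source: t_src_perk
  target: p1
  weight: 1.0
  kind: standard
- source: p1
  target: t_dec_perk
  weight: 1.0
  kind: standard
- source: t_src_cytc
  target: p2
  weight: 1.0
  kind: standard
- source: p2
  target: t_dec_cytc
  weight: 1.0
  kind: standard
- source: t_src_casp3
  target: p3
  weight: 1.0
  kind: standard
- source: p3
  target: t_dec_casp3
  weight: 1.0
  kind: standard
- source: t_src_parp
  target: p4
  weight: 1.0
  kind: standard
- source: p4
  target: t_dec_parp
  weight: 1.0
  kind: standard
- source: t_src_tnf
  target: p8
  weight: 1.0
  kind: standard
- source: p8
  target: t_dec_tnf
  weight: 1.0
  kind: standard
- source: t_src_prip3
  target: p9
  weight: 1.0
  kind: standard
- source: p9
  target: t_dec_prip3
  weight: 1.0
  kind: standard
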