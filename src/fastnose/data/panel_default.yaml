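schema_version: 1
# Four food-odor compounds diluted in odorless mineral oil, plus the pure
# solvent ("blank") control.  Vapor pressures in mmHg at 25 C.
odorants:
  - name: IA
    full_name: isoamyl acetate
    odor_class: ester
    molecular_weight: 130.18
    vapor_pressure_mmhg: 5.6
    dilution: 0.20
  - name: EB
    full_name: ethyl butyrate
    odor_class: ester
    molecular_weight: 116.16
    vapor_pressure_mmhg: 11.3
    dilution: 0.20
  - name: Eu
    full_name: eucalyptol (cineole)
    odor_class: ether
    molecular_weight: 154.25
    vapor_pressure_mmhg: 1.9
    dilution: 0.20
  - name: "2H"
    full_name: 2-heptanone
    odor_class: ketone
    molecular_weight: 114.19
    vapor_pressure_mmhg: 3.85
    dilution: 0.05
  - name: blank
    full_name: mineral oil
    odor_class: solvent
    molecular_weight: 400.0
    vapor_pressure_mmhg: 0.0
    dilution: 1.0
    is_blank: true
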