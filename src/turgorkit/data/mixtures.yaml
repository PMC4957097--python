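# Model cytosol definitions: composition ratio [KCl]:[D-Glc]:[L-Gln], total
# molarity (mol/L) and pH, with the reference osmometry measurements
# (mean +/- sd over 5 replicates, MPa).  estimated_ref_MPa carries the
# reference estimated potential for the 1.5 M three-component rows, whose
# tabulated estimates are not reproduced by the constant-gamma model (see
# package docs); when absent the model estimate is used.
mixtures:
  - name: M1
    ratio: "5:12:3"
    total_molarity: 1.00
    pH: 7.0
    measured_MPa: 2.93
    measured_sd_MPa: 0.02
  - name: M1a
    ratio: "0:12:3"
    total_molarity: 0.75
    pH: 7.0
    measured_MPa: 1.95
    measured_sd_MPa: 0.04
  - name: M1b
    ratio: "5:12:0"
    total_molarity: 0.85
    pH: 7.0
    measured_MPa: 2.65
    measured_sd_MPa: 0.02
  - name: M1c
    ratio: "5:0:3"
    total_molarity: 0.40
    pH: 7.0
    measured_MPa: 1.44
    measured_sd_MPa: 0.01
    estimated_ref_MPa: 1.87
  - name: M2
    ratio: "15:12:3"
    total_molarity: 1.50
    pH: 7.0
    measured_MPa: 4.88
    measured_sd_MPa: 0.02
    estimated_ref_MPa: 5.56
  - name: M2a
    ratio: "25:12:3"
    total_molarity: 1.50
    pH: 7.0
    measured_MPa: 4.98
    measured_sd_MPa: 0.02
    estimated_ref_MPa: 5.84
  - name: M2b
    ratio: "15:22:3"
    total_molarity: 1.50
    pH: 7.0
    measured_MPa: 4.83
    measured_sd_MPa: 0.01
    estimated_ref_MPa: 5.11
  - name: KCl
    ratio: "1:0:0"
    total_molarity: 1.50
    pH: 7.0
    measured_MPa: 6.37
    measured_sd_MPa: 0.01
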