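# Named distance presets keyed by generic residue labels.
#
# galpha_interface: polar interactions between the receptor's intracellular
# face and the Galpha helix 5. Salt bridges are measured between charged-group
# heavy atoms; the 3.50 pair targets the backbone carbonyl O of G.H5.23.
# activation_switches: interhelical activation distances plus the CWxP
# alkyl-pi pair (min heavy-atom convention, no atom-name restriction).

galpha_interface:
  - name: "3.50-G.H5.23_backbone"
    a_label: "3.50"
    a_atoms: [NE, NH1, NH2]
    b_label: "G.H5.23"
    b_atoms: [O]
  - name: "3.56-G.H5.22_saltbridge"
    a_label: "3.56"
    a_atoms: [NE, NH1, NH2]
    b_label: "G.H5.22"
    b_atoms: [OD1, OD2]
  - name: "8.49-G.H5.22_saltbridge"
    a_label: "8.49"
    a_atoms: [NZ]
    b_label: "G.H5.22"
    b_atoms: [OD1, OD2]
  - name: "3.56-G.H5.19_polar"
    a_label: "3.56"
    a_atoms: [NE, NH1, NH2]
    b_label: "G.H5.19"
    b_atoms: [OD1, ND2]

activation_switches:
  - name: "TM3-TM6"
    a_label: "3.46"
    b_label: "6.37"
  - name: "TM3-TM7"
    a_label: "3.46"
    b_label: "7.53"
  - name: "TM1-TM7"
    a_label: "1.53"
    b_label: "7.53"
  - name: "ionic_lock_3.49-3.50"
    a_label: "3.49"
    b_label: "3.50"
  - name: "6.33-3.50"
    a_label: "6.33"
    b_label: "3.50"
  - name: "cwxp_alkyl_pi_6.48-3.36"
    a_label: "6.48"
    b_label: "3.36"
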