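# Default VSE calibration and per-variant Pfr anchors for the Agp2
# cyanophenylalanine variants.  Anchor fields and Pfr-ensemble TDMs come from
# the QM/MM stage and enter this package as constants only.
calibration:
  nu0: 2234.5              # cm-1, zero-field nitrile frequency (gas-phase benzonitrile)
  tuning_rate: 0.268       # cm-1 per MV/cm, Stark tuning rate for H-bond-free nitriles
  k_hbond: -0.2            # cm-1 per MV/cm, H-bond field sensitivity (rescaled Deb slope)
  tdm_slope: -0.047        # (km mol)^1/2 per MV/cm, slope A of mu = mu0 + A*E
  mu0_oCNF: 4.44           # (km mol)^1/2, zero-field TDM, ortho label
  mu0_pCNF: 7.04           # (km mol)^1/2, zero-field TDM, para label
  deb_D_reference: -0.317  # cm-1 per MV/cm, original Deb et al. slope (provenance only)
  hbond_threshold: 2228.0  # cm-1, RT-normalized frequency above which a band is H-bonded

variants:
  Y165oCNF: {label_type: oCNF, e_pfr_total: -53.41, mu_pfr: 7.767, i_pfr_rt: 7.64}
  F192oCNF: {label_type: oCNF, e_pfr_total: -45.40, mu_pfr: 6.196, i_pfr_rt: 12.86}
  Y165pCNF: {label_type: pCNF, e_pfr_total: -73.84, mu_pfr: 9.564, i_pfr_rt: 2.642}
  F192pCNF: {label_type: pCNF, e_pfr_total: -28.76, mu_pfr: 8.829, i_pfr_rt: 1.516}

# States whose substate system is underdetermined (two H-bonded components,
# no H-bond-free reference) and where a mole fraction is pinned to reproduce
# the published solution.  Key is the role of the first H-bonded component.
pins:
  Y165pCNF:
    Pr: {P2: 0.36}
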