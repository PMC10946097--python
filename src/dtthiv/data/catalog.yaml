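# Antiretroviral drug catalog.
#
# Codes follow common clinical abbreviations. `booster` marks pharmacokinetic
# enhancers (ritonavir used as booster, cobicistat): these are never counted
# when sizing a regimen.
drugs:
  # Nucleos(t)ide reverse transcriptase inhibitors
  - {code: ABC, name: abacavir, class: NRTI}
  - {code: AZT, name: zidovudine, class: NRTI}
  - {code: D4T, name: stavudine, class: NRTI}
  - {code: DDI, name: didanosine, class: NRTI}
  - {code: FTC, name: emtricitabine, class: NRTI}
  - {code: 3TC, name: lamivudine, class: NRTI}
  - {code: TDF, name: tenofovir disoproxil, class: NRTI}
  - {code: TAF, name: tenofovir alafenamide, class: NRTI}
  # Non-nucleoside reverse transcriptase inhibitors
  - {code: DOR, name: doravirine, class: NNRTI}
  - {code: EFV, name: efavirenz, class: NNRTI}
  - {code: ETR, name: etravirine, class: NNRTI}
  - {code: NVP, name: nevirapine, class: NNRTI}
  - {code: RPV, name: rilpivirine, class: NNRTI}
  # Protease inhibitors
  - {code: ATV, name: atazanavir, class: PI}
  - {code: DRV, name: darunavir, class: PI}
  - {code: FPV, name: fosamprenavir, class: PI}
  - {code: IDV, name: indinavir, class: PI}
  - {code: LPV, name: lopinavir, class: PI}
  - {code: NFV, name: nelfinavir, class: PI}
  - {code: SQV, name: saquinavir, class: PI}
  - {code: TPV, name: tipranavir, class: PI}
  # Integrase strand transfer inhibitors
  - {code: BIC, name: bictegravir, class: INSTI}
  - {code: CAB, name: cabotegravir, class: INSTI}
  - {code: DTG, name: dolutegravir, class: INSTI}
  - {code: EVG, name: elvitegravir, class: INSTI}
  - {code: RAL, name: raltegravir, class: INSTI}
  # Entry inhibitors
  - {code: ENF, name: enfuvirtide, class: ENTRY}
  - {code: FTR, name: fostemsavir, class: ENTRY}
  - {code: IBA, name: ibalizumab, class: ENTRY}
  - {code: MVC, name: maraviroc, class: ENTRY}
  # Capsid inhibitors
  - {code: LEN, name: lenacapavir, class: CAPSID}
  # Pharmacokinetic boosters
  - {code: RTV, name: ritonavir, class: PI, booster: true}
  - {code: COBI, name: cobicistat, class: OTHER, booster: true}
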