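# Molar extinction coefficients of haemoglobin in water, standard compiled
# values (cm^-1 per mol/L); linearly interpolated between tabulated
# wavelengths. Columns: wavelength_nm, eps_hbo2, eps_hhb.
wavelength_nm,eps_hbo2,eps_hhb
690,276.0,2051.96
720,398.0,1540.48
750,518.0,1405.24
760,586.0,1548.52
780,735.4,1102.2
800,816.0,761.72
830,974.0,693.04
850,1058.0,691.32
880,1154.8,736.0
900,1198.0,761.84
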