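# Molar extinction coefficients of human hemoglobin, cm^-1 M^-1 (per heme).
# Values from the Prahl/Oregon Medical Laser Center compilation of
# hemoglobin optical absorption (tabulated from Gratzer & Kollias data),
# restricted to the two near-infrared wavelengths used by dual-wavelength
# photoacoustic oximetry on either side of the ~800 nm isosbestic point.
wavelength_nm,eps_hbo2,eps_hb
750,518.0,1405.24
850,1058.0,691.32
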