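# glycodvp default chromophore spectra, v1
# molar_absorption_M_cm: molar absorption coefficient [M^-1 cm^-1] (hemoglobin species only)
# absorption_cm: bulk absorption coefficient [cm^-1]; for hemoglobin species this is the
#   molar value scaled by the whole-blood hemoglobin concentration 150/64500 mol/L and is
#   stored as a rounded literal on purpose (both views are asserted independently).
species,wavelength_nm,molar_absorption_M_cm,absorption_cm
HbA1c,465,549024.7353,1276.8017
HbA1c,525,455139.5677,1058.4641
HbA1c,615,170555.4218,396.6405
HbO,465,38440.2,89.3958
HbO,525,30882.8,71.8205
HbO,615,1166.4,2.7126
HHb,465,18701.6,43.4921
HHb,525,35170.8,81.7926
HHb,615,7553.4,17.5660
skin_baseline,465,,1.6279
skin_baseline,525,,1.0966
skin_baseline,615,,0.6552
water,465,,0.00020277
water,525,,0.0003927
water,615,,0.0027167
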