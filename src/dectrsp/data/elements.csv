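# Elemental constants: atomic number Z, standard atomic weight A (g/mol),
# and mean excitation energy I (eV) from the ICRU Report 37 recommendations
# (as tabulated in the NIST ESTAR/PSTAR material database).
symbol,name,atomic_number,atomic_mass,i_value_ev
H,Hydrogen,1,1.008,19.2
C,Carbon,6,12.011,78.0
N,Nitrogen,7,14.007,82.0
O,Oxygen,8,15.999,95.0
F,Fluorine,9,18.998,115.0
Na,Sodium,11,22.990,149.0
Mg,Magnesium,12,24.305,156.0
Al,Aluminium,13,26.982,166.0
Si,Silicon,14,28.085,173.0
P,Phosphorus,15,30.974,173.0
S,Sulfur,16,32.060,180.0
Cl,Chlorine,17,35.450,174.0
Ar,Argon,18,39.948,188.0
K,Potassium,19,39.098,190.0
Ca,Calcium,20,40.078,191.0
Ti,Titanium,22,47.867,233.0
Fe,Iron,26,55.845,286.0
Zn,Zinc,30,65.380,330.0
I,Iodine,53,126.904,491.0
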