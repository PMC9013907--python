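subject_id,age,sex,hair_length_cm,hair_color,cosmetic_treatment,declared_class,etg
CB1,54,M,6,Grizzled,No,Social,14.9
CB2,58,M,5,Grizzled,No,Moderate,<LOD
CB3,37,F,6,Brown,Yes,Moderate,<LOD
CB4,46,F,6,Brown,Yes,Light,<LOD
CB5,55,F,6,Brown,Yes,Moderate,23.4
CB6,55,M,6,Grizzled,No,Heavy,127.9
CB7,56,M,5,Grizzled,No,Heavy,199.8
CB8,36,M,5,Brown,No,Moderate,93.2
CB10,45,M,6,Grizzled,No,Heavy,58.3
CB11,54,M,6,Grizzled,No,Light,<LOQ
A,14,F,4.5,Brown,No,Teetotal,<LOD
B,46,F,6,Black,Yes,Light,<LOD
C,44,F,6,Black,No,Social,19.3
D,49,M,4.5,Dark brown,No,Moderate,62.1
E,18,M,3,Brown,No,Social,<LOD
1 FRA,57,F,6,Brown,No,Teetotal,<LOD
1 FIL,17,M,6,Blond,Yes,Teetotal,<LOD
1 GIA,17,M,6,Brown,No,Teetotal,<LOD
F,13,M,2,Dark brown,No,Teetotal,<LOD
G,48,F,6,Dark brown,Yes,Light,<LOD
H,16,F,6,Brown,No,Teetotal,<LOD
I,52,M,3,Grizzled,No,Light,<LOD
AA,59,F,6,Grizzled,No,Light,<LOD
BB,59,M,3,Brown,No,Social,13.3
M,53,M,5,Grizzled,No,Moderate,69.1
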