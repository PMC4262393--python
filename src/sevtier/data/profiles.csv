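disease_id,characteristic_id
canavan,le_childhood_adolescence
canavan,intellectual_disability
canavan,impaired_mobility
canavan,vision
canavan,hearing
canavan,sensory_other
canavan,dysmorphic_features
slos,le_infancy
slos,intellectual_disability
slos,impaired_mobility
slos,internal_malformation
slos,mental_illness
slos,dysmorphic_features
citrullinemia_1,le_infancy
citrullinemia_1,intellectual_disability
citrullinemia_1,impaired_mobility
citrullinemia_1,internal_malformation
citrullinemia_1,vision
citrullinemia_1,sensory_other
pompe,le_childhood_adolescence
pompe,intellectual_disability
pompe,impaired_mobility
pompe,internal_malformation
pompe,immunodeficiency_cancer
pompe,dysmorphic_features
galactosemia,le_infancy
galactosemia,intellectual_disability
galactosemia,impaired_mobility
galactosemia,vision
galactosemia,immunodeficiency_cancer
galactosemia,mental_illness
homocystinuria,intellectual_disability
homocystinuria,le_premature_adulthood
homocystinuria,impaired_mobility
homocystinuria,internal_malformation
homocystinuria,vision
homocystinuria,sensory_other
homocystinuria,mental_illness
homocystinuria,dysmorphic_features
cystic_fibrosis,le_childhood_adolescence
cystic_fibrosis,impaired_mobility
cystic_fibrosis,internal_malformation
cystic_fibrosis,immunodeficiency_cancer
scad_deficiency,le_childhood_adolescence
scad_deficiency,impaired_mobility
scad_deficiency,mental_illness
scad_deficiency,dysmorphic_features
wilson,intellectual_disability
wilson,le_premature_adulthood
wilson,impaired_mobility
wilson,internal_malformation
wilson,mental_illness
bardet_biedl,intellectual_disability
bardet_biedl,internal_malformation
bardet_biedl,vision
bardet_biedl,mental_illness
bardet_biedl,dysmorphic_features
fragile_x,intellectual_disability
fragile_x,impaired_mobility
fragile_x,vision
fragile_x,immunodeficiency_cancer
fragile_x,mental_illness
fragile_x,dysmorphic_features
beta_thal_scd,le_premature_adulthood
beta_thal_scd,impaired_mobility
beta_thal_scd,internal_malformation
beta_thal_scd,immunodeficiency_cancer
beta_thal_scd,sensory_other
usher_1f,impaired_mobility
usher_1f,vision
usher_1f,hearing
usher_1f,sensory_other
gjb2_deafness,hearing
a1at_deficiency,impaired_mobility
a1at_deficiency,internal_malformation
a1at_deficiency,immunodeficiency_cancer
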