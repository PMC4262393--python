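disease_id,name,survey_set,group,mean,median,min,max,acmg_acog,assessed_nbs,included_nbs
beta_thal_scd,Beta-thalassemia/sickle cell disease,A,Severe,2.79,3,2,4,true,true,true
citrullinemia_1,Citrullinemia type 1,A,Profound,3.54,4,2,4,false,true,true
gjb2_deafness,GJB2-related nonsyndromic hearing loss and deafness,A,Moderate,1.85,2,1,4,false,true,true
scad_deficiency,Short-chain acyl-CoA dehydrogenase deficiency,A,Severe,2.92,3,1,4,false,true,false
usher_1f,Usher syndrome type 1F,A,Severe,2.65,3,1,4,false,false,false
bardet_biedl,Bardet-Biedl syndrome,B,Severe,2.83,3,1,4,false,false,false
cystic_fibrosis,Cystic fibrosis,B,Severe,2.98,3,2,4,true,true,true
fragile_x,Fragile X syndrome,B,Severe,2.83,3,1,4,false,true,false
homocystinuria,Homocystinuria caused by CBS deficiency,B,Severe,3.13,3,2,4,false,true,true
slos,Smith-Lemli-Opitz syndrome,B,Profound,3.54,4,2,4,false,true,false
a1at_deficiency,Alpha-1 antitrypsin deficiency,C,Moderate,1.84,2,1,4,false,true,false
canavan,Canavan disease,C,Profound,3.66,4,2,4,true,false,false
galactosemia,Galactosemia,C,Profound,3.46,4,2,4,false,true,true
pompe,Pompe disease,C,Profound,3.48,4,2,4,false,true,false
wilson,Wilson disease,C,Severe,2.86,3,2,4,false,true,false
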