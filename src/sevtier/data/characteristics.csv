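id,name,category,lifespan_flag,tier,mean,median,min,max,n
le_infancy,Shortened life span: infancy,core,true,1,9.53,10,1,10,192
le_childhood_adolescence,Shortened life span: childhood/adolescence,core,true,1,9.17,9,2,10,192
intellectual_disability,Intellectual disability,core,false,1,9.07,9,5,10,192
le_premature_adulthood,Shortened life span: premature adulthood,core,true,2,8.01,8,1,10,192
impaired_mobility,Impaired mobility,core,false,2,7.98,8,2,10,192
internal_malformation,Internal physical malformation,core,false,2,7.71,8,3,10,192
vision,Sensory impairment: vision,core,false,3,6.98,7,1,10,192
immunodeficiency_cancer,Immunodeficiency/cancer,core,false,3,6.76,7,1,10,192
hearing,Sensory impairment: hearing,core,false,3,6.67,7,1,10,192
sensory_other,"Sensory impairment: touch, other (including pain)",core,false,3,6.65,7,1,10,192
mental_illness,Mental illness,core,false,3,6.54,7,1,10,192
dysmorphic_features,Dysmorphic features,core,false,3,6.43,7,1,10,192
reduced_fertility,Reduced fertility,core,false,4,3.97,3,1,10,192
availability_of_treatment,Availability of treatment,modifier,false,2,8.07,9,1,10,192
variable_expressivity,Variable expressivity,modifier,false,3,6.14,6,1,10,192
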