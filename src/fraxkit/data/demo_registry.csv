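patient_id,region,sex,age_years,admission_date,icd10_code,hip_surgery,neoplasia,refused_hospitalization,source
P001,region_a,female,72,2012-02-10,S72.0,false,false,false,hospital
P002,region_a,male,65,2012-03-05,S72.1,false,false,false,hospital
P003,region_a,female,81,2012-03-15,S72.2,false,false,false,hospital
P001,region_a,female,72,2012-02-20,S72.0,false,false,false,hospital
P004,region_a,female,78,2012-04-01,S72.0,false,true,false,hospital
P005,region_a,male,70,2012-05-10,S72.9,false,false,false,hospital
P006,region_a,female,84,2012-06-12,S72.9,true,false,false,hospital
P007,region_a,male,59,2012-07-04,S72.0,false,false,true,ambulance
P003,region_a,female,80,2011-08-28,S72.2,false,false,false,hospital
P008,region_a,female,66,2012-08-19,S73.0,false,false,false,hospital
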