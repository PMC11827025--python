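alias,canonical
SEQN,person_id
RIDAGEYR,age_y
RIAGENDR,sex
RIDRETH1,race_ethnicity
INDFMPIR,pir
SDMVSTRA,stratum
SDMVPSU,psu
WTDRD1,weight_day1_diet
FSDCH,hfssm_child_category
FSD652CW,hfssm_child_affirmed
DR1DAY,intake_day_of_week
DRDINT,n_recall_days
DR1DRSTZ,recall_status_day1
DR2DRSTZ,recall_status_day2
DR1IFDCD,food_code
DR1IGRMS,grams
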