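variable,role,category,mapping,missing_codes,binarize_rule
often_lonely,target,none,no=0;yes=1,Prefer not to answer|Do not know,yes
confide_frequency,target,none,never=0;1-3 times a month=1;weekly=2;2-4 times a week=3;daily or almost daily=4,Prefer not to answer,never|1-3 times a month|weekly|2-4 times a week
age,confound,none,,,
sex,confound,none,,,
current_tobacco_smoking,risk_trait,lifestyle,no=0;occasionally=1;yes=2,Prefer not to answer,
alcohol_intake_frequency,risk_trait,lifestyle,never=0;special occasions only=1;one to three times a month=2;once or twice a week=3;daily or almost daily=4,Prefer not to answer,
sleep_duration,risk_trait,lifestyle,,Prefer not to answer|Do not know,
tv_time,risk_trait,lifestyle,,,
gym_attendance,risk_trait,lifestyle,no=0;yes=1,,
high_blood_pressure,risk_trait,physical,no=0;yes=1,Prefer not to answer,
diabetes,risk_trait,physical,no=0;yes=1,Prefer not to answer,
hearing_difficulty,risk_trait,physical,no=0;yes=1,Do not know,
vision_aid_user,risk_trait,physical,no=0;yes=1,,
neuroticism_score,risk_trait,mental,,,
felt_happy,risk_trait,mental,never=0;rarely=1;sometimes=2;often=3;always=4,Prefer not to answer,
depression_diagnosis,risk_trait,mental,no=0;yes=1,Prefer not to answer,
household_size,risk_trait,societal,,,
income_band,risk_trait,societal,less than 18k=0;18k to 31k=1;31k to 52k=2;52k to 100k=3;greater than 100k=4,Prefer not to answer|Do not know,
urban_residence,risk_trait,societal,no=0;yes=1,,
close_friends,risk_trait,societal,,,
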