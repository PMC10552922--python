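case_label,sex,age_band,drug,indications,history,combined_drugs,onset_band,symptoms,nadir_plt_band,plt_decrease_band,anti_pf4,four_t_band,d_dimer_elevated,liver_kidney_abnormal,treatments,alt_anticoagulants,recovery_band,outcome
case-01,male,>60,enoxaparin,traffic accident,hypertension,,5-10,dyspnea;thrombus,20-49,>50%,positive,,,,withdrawal,,5-10,recovery
case-02,male,18-60,enoxaparin,infection,hypertension,,>10,cerebral infarction;thrombus,50-100,>50%,positive,4-5,,,withdrawal,acenocoumarol,5-10,recovery
case-03,female,>60,enoxaparin,dialysis,surgery,,>10,acute renal failure;skin lesions;thrombus,10-19,>50%,positive,6-8,no,,withdrawal,apixaban;fondaparinux,,recovery
case-04,male,18-60,enoxaparin,embolism,,,5-10,hemorrhage;thrombus,50-100,30-50%,positive,6-8,yes,,withdrawal,fondaparinux;warfarin,5-10,recovery
case-05,female,18-60,enoxaparin,heart failure,chronic renal insufficiency;diabetes,antihypertensive drugs,<5,hemorrhage;thrombus,20-49,>50%,positive,,,,withdrawal,fondaparinux;rivaroxaban,5-10,recovery
case-06,male,<18,enoxaparin,tumor,surgery,,5-10,hemorrhage;thrombus,20-49,>50%,,,,,withdrawal,fondaparinux;warfarin,,recovery
case-07,female,>60,enoxaparin,joint operation,surgery,,5-10,limb necrosis;skin lesions;thrombus,20-49,>50%,,,yes,,surgical thrombectomy;withdrawal,argatroban,5-10,worse
case-08,female,18-60,enoxaparin,joint operation,,,>10,limb necrosis;skin lesions;thrombus,>100,>50%,positive,,,,withdrawal,argatroban,,recovery
case-09,female,>60,enoxaparin,tumor,diabetes;thrombus history,,5-10,cerebral infarction;thrombus,50-100,>50%,positive,6-8,,no,withdrawal,lepirudin,5-10,recovery
case-10,female,18-60,enoxaparin,surgery,,,5-10,dyspnea;thrombus,50-100,>50%,positive,6-8,,,emergency treatment;withdrawal,acenocoumarol;fondaparinux,<5,recovery
case-11,male,>60,enoxaparin,heart failure,obesity,antibiotics,5-10,heart failure;skin lesions,>100,>50%,positive,,,,withdrawal,lepirudin,>10,recovery
case-12,male,>60,enoxaparin,surgery,,,<5,limb necrosis;skin lesions;thrombus,>100,>50%,positive,6-8,,,withdrawal,lepirudin,5-10,death
case-13,male,18-60,enoxaparin,surgery,obesity,,>10,fever;skin lesions;thrombus,50-100,>50%,positive,,yes,,withdrawal,lepirudin,,recovery
case-14,female,>60,enoxaparin,traffic accident,hypertension,,5-10,dyspnea;thrombus,50-100,>50%,,,,,withdrawal,lepirudin,,recovery
case-15,female,>60,enoxaparin,embolism,diabetes;immune-related diseases,,5-10,skin lesions;thrombus,>100,>50%,,,,,withdrawal,argatroban,5-10,recovery
case-16,female,>60,enoxaparin,dialysis,,,>10,hemorrhage;thrombus,20-49,>50%,positive,,no,yes,withdrawal,fondaparinux;warfarin,>10,recovery
case-17,female,>60,enoxaparin,tumor,surgery,,5-10,heart failure;skin lesions,20-49,>50%,positive,,,,withdrawal,lepirudin,<5,recovery
case-18,female,>60,enoxaparin,embolism,surgery,antidiabetic drugs,5-10,hemorrhage;thrombus,20-49,>50%,positive,6-8,,yes,withdrawal,lepirudin,<5,recovery
case-19,female,>60,enoxaparin,joint operation,surgery,,5-10,dyspnea;thrombus,20-49,>50%,positive,,,,withdrawal,fondaparinux,5-10,recovery
case-20,female,>60,enoxaparin,joint operation,surgery,,<5,heart failure;skin lesions,>100,30-50%,positive,,,,withdrawal,acenocoumarol,5-10,recovery
case-21,female,18-60,enoxaparin,embolism,diabetes;tumor,,5-10,shock;skin lesions;thrombus,50-100,>50%,positive,,no,,withdrawal,dabigatran;fondaparinux,5-10,recovery
case-22,female,18-60,nadroparin,embolism,diabetes;myocardial disease,,5-10,hemorrhage;thrombus,50-100,,positive,6-8,,,withdrawal,acenocoumarol,5-10,recovery
case-23,female,18-60,nadroparin,fracture,diabetes;myocardial disease,,5-10,acute renal failure;skin lesions;thrombus,>100,>50%,positive,,,,platelet transfusion;withdrawal,fondaparinux,<5,recovery
case-24,male,>60,nadroparin,surgery,obesity,,5-10,dyspnea;thrombus,50-100,>50%,positive,,,,thrombolytic agent;withdrawal,lepirudin,<5,recovery
case-25,female,18-60,nadroparin,fracture,surgery,,5-10,cerebral infarction;thrombus,20-49,>50%,positive,,yes,,withdrawal,,5-10,recovery
case-26,female,>60,nadroparin,embolism,tumor,,5-10,dyspnea;thrombus,>100,>50%,positive,6-8,,no,surgical thrombectomy;withdrawal,lepirudin,>10,recovery
case-27,female,>60,nadroparin,embolism;pregnancy,chronic renal insufficiency;diabetes,,5-10,dyspnea;thrombus,,,positive,,,,platelet transfusion;withdrawal,fondaparinux;rivaroxaban,5-10,recovery
case-28,female,18-60,nadroparin,fracture,tumor,,5-10,hemorrhage;thrombus,50-100,,positive,6-8,,,withdrawal,fondaparinux;warfarin,<5,recovery
case-29,male,>60,nadroparin,fracture,hypertension,,5-10,heart failure;skin lesions,20-49,,,,,no,surgical thrombectomy;withdrawal,apixaban;fondaparinux,>10,recovery
case-30,female,>60,nadroparin,heart failure,hypertension,,>10,dyspnea;thrombus,50-100,>50%,positive,6-8,,,withdrawal,,>10,recovery
case-31,female,18-60,nadroparin,joint operation,,,>10,heart failure;thrombus,<10,>50%,positive,6-8,,,withdrawal,acenocoumarol,>10,recovery
case-32,male,>60,nadroparin,joint operation,,antihypertensive drugs;other anticoagulants,>10,dyspnea;thrombus,,>50%,,6-8,,,surgical thrombectomy;withdrawal,clopidogrel;fondaparinux,<5,recovery
case-33,female,18-60,nadroparin,embolism,chronic renal insufficiency;diabetes,,5-10,limb necrosis;skin lesions;thrombus,50-100,30-50%,positive,6-8,,,withdrawal,argatroban,5-10,recovery
case-34,male,>60,nadroparin,fracture,cholecystectomy;diabetes,antihypertensive drugs;chemotherapeutic drugs,5-10,dyspnea;thrombus,,,positive,6-8,yes,,withdrawal,,>10,recovery
case-35,female,>60,nadroparin,embolism,obesity,,<5,limb necrosis;skin lesions;thrombus,10-19,>50%,positive,6-8,no,yes,glucocorticoid;withdrawal,fondaparinux;rivaroxaban,,recovery
case-36,female,18-60,dalteparin,embolism,tumor,,>10,cerebral infarction;thrombus,50-100,>50%,positive,4-5,no,,surgical thrombectomy;withdrawal,argatroban,<5,recovery
case-37,female,18-60,dalteparin,joint operation,,,>10,dyspnea;thrombus,10-19,,positive,,,,withdrawal,lepirudin,<5,recovery
case-38,female,>60,dalteparin,surgery,diabetes;myocardial disease,,>10,hemorrhage;thrombus,20-49,>50%,positive,,,,withdrawal,lepirudin,,recovery
case-39,female,>60,dalteparin,dialysis,obesity,antidiabetic drugs;antihypertensive drugs,>10,skin lesions;thrombus,>100,>50%,positive,4-5,,,withdrawal,fondaparinux;warfarin,,recovery
case-40,male,>60,tinzaparin,dialysis,obesity,,>10,cerebral infarction;thrombus,>100,>50%,positive,6-8,,,withdrawal,fondaparinux,5-10,recovery
case-41,female,>60,tinzaparin,joint operation,hypertension,,<5,dyspnea;thrombus,20-49,<30%,,,,yes,surgical thrombectomy;withdrawal,argatroban,,recovery
case-42,female,>60,bemiparin,infection,,,>10,hemorrhage;thrombus,50-100,>50%,positive,6-8,,,withdrawal,fondaparinux;rivaroxaban,5-10,recovery
case-43,female,>60,bemiparin,joint operation,surgery,antibiotics,5-10,dyspnea;thrombus,20-49,>50%,positive,6-8,no,yes,withdrawal,argatroban,>10,recovery
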