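subject_id,group,sex,smm,dms
Healthy-1,healthy,M,0.88,0.07
Healthy-2,healthy,M,0.94,0.07
Healthy-3,healthy,M,0.94,0.10
Healthy-4,healthy,M,0.97,0.06
Healthy-5,healthy,F,0.98,0.09
Healthy-6,healthy,M,0.96,0.16
Healthy-7,healthy,M,0.98,0.03
Healthy-8,healthy,M,0.99,0.05
Healthy-9,healthy,M,0.95,0.04
Healthy-10,healthy,M,0.96,0.07
Healthy-11,healthy,F,0.97,0.06
Healthy-12,healthy,M,0.95,0.09
Healthy-13,healthy,F,0.99,0.10
Healthy-14,healthy,M,0.98,0.06
Healthy-15,healthy,M,0.97,0.06
Healthy-16,healthy,M,0.96,0.06
Healthy-17,healthy,M,0.97,0.09
Healthy-18,healthy,M,0.88,0.07
Healthy-19,healthy,M,0.89,0.05
Healthy-20,healthy,M,0.99,0.06
Mild-1,mild,F,0.74,0.12
Mild-2,mild,F,0.92,0.09
Mild-3,mild,F,0.89,0.13
Mild-4,mild,M,0.95,0.12
Mild-5,mild,F,0.97,0.06
Mild-6,mild,M,0.98,0.10
Mild-7,mild,F,0.82,0.10
Mild-8,mild,F,0.96,0.10
Mild-9,mild,M,0.95,0.10
Mild-10,mild,F,0.86,0.07
Severe-1,severe,M,0.73,0.27
Severe-2,severe,M,0.82,0.18
Severe-3,severe,M,0.93,0.19
Severe-4,severe,F,0.93,0.19
Severe-5,severe,M,0.79,0.27
Severe-6,severe,M,0.78,0.08
Severe-7,severe,M,0.76,0.12
Severe-8,severe,F,0.85,0.22
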