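virus_id,host_id,assay,titer
HRTV-10,Halorubrum sp. B2-2,plaque,1.2e9
HRTV-10,LR2-5,plaque,6.8e3
HRTV-18,Halorubrum sp. SS10-3,plaque,7.5e9
HRTV-18,LR2-5,plaque,-
HRTV-20,Halorubrum sp. SS10-9,plaque,7.0e10
HRTV-20,LR2-5,plaque,-
HRTV-22,Halorubrum sp. SS10-9,plaque,1.1e10
HRTV-22,LR2-5,plaque,-
HRTV-26,Halorubrum sp. SS10-9,plaque,1.4e9
HRTV-26,LR2-5,plaque,4.3e6
HRTV-5,Halorubrum sp. s5a-3,plaque,2.0e10
HRTV-5,LR2-5,plaque,-
HCTV-7,Haloarcula californiae,plaque,4.8e10
HCTV-7,LR2-5,plaque,-
HCTV-12,Haloarcula californiae,plaque,1.3e10
HCTV-12,LR2-5,plaque,-
HCTV-9,Haloarcula californiae,plaque,2.8e10
HCTV-9,LR2-5,plaque,-
HCTV-11,Haloarcula californiae,plaque,4.0e10
HCTV-11,LR2-5,plaque,-
HRTV-9,Halorubrum sp. B2-2,plaque,5.3e9
HRTV-9,LR2-5,plaque,-
HRTV-16,Haloterrigena sp. SS13-7,plaque,nd
HRTV-16,LR2-5,plaque,nd
HCTV-8,Haloarcula californiae,plaque,2.3e10
HCTV-8,LR2-5,plaque,3.1e5
HCTV-10,Halorubrum sodomense,plaque,2.3e9
HCTV-10,LR2-5,plaque,-
HJTV-1,Haloarcula japonica,plaque,1.6e9
HJTV-1,LR2-5,plaque,-
HRTV-13,Halorubrum sp. SS8-2,plaque,5.1e9
HRTV-13,LR2-5,plaque,-
HRTV-21,Halorubrum sp. SS10-9,plaque,2.8e9
HRTV-21,LR2-5,plaque,-
HSTV-2,Halorubrum sodomense,plaque,8.2e9
HSTV-2,LR2-5,plaque,2.3e10
HRTV-7,Halorubrum sp. B2-2,plaque,2.1e9
HRTV-7,LR2-5,plaque,7.9e5
HRTV-2,Halorubrum sp. s1-2,plaque,2.0e10
HRTV-2,LR2-5,plaque,4.6e10
HRTV-11,Halorubrum sp. SL-5,plaque,4.7e10
HRTV-11,LR2-5,plaque,-
HCTV-6,Haloarcula californiae,plaque,1.6e10
HCTV-6,LR2-5,plaque,3.9e9
HCTV-13,Haloarcula californiae,plaque,2.5e9
HCTV-13,LR2-5,plaque,1.3e7
HCTV-15,Halorubrum sp. SS6-2,plaque,1.9e10
HCTV-15,LR2-5,plaque,9.6e6
HFTV1,LR2-5,plaque,2.9e12
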