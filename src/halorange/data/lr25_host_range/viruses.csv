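virus_id,family,genus,morphology,own_host
HRTV-10,Hafunaviridae,Haloferacalesvirus,myovirus,Halorubrum sp. B2-2
HRTV-18,Hafunaviridae,Haloferacalesvirus,myovirus,Halorubrum sp. SS10-3
HRTV-20,Hafunaviridae,Haloferacalesvirus,myovirus,Halorubrum sp. SS10-9
HRTV-22,Hafunaviridae,Haloferacalesvirus,myovirus,Halorubrum sp. SS10-9
HRTV-26,Hafunaviridae,Haloferacalesvirus,myovirus,Halorubrum sp. SS10-9
HRTV-5,Hafunaviridae,Haloferacalesvirus,myovirus,Halorubrum sp. s5a-3
HCTV-7,Hafunaviridae,Haloferacalesvirus,myovirus,Haloarcula californiae
HCTV-12,Hafunaviridae,Haloferacalesvirus,myovirus,Haloarcula californiae
HCTV-9,Hafunaviridae,Haloferacalesvirus,myovirus,Haloarcula californiae
HCTV-11,Hafunaviridae,Haloferacalesvirus,myovirus,Haloarcula californiae
HRTV-9,Hafunaviridae,Haloferacalesvirus,myovirus,Halorubrum sp. B2-2
HRTV-16,Hafunaviridae,Haloferacalesvirus,myovirus,Haloterrigena sp. SS13-7
HCTV-8,Hafunaviridae,Haloferacalesvirus,myovirus,Haloarcula californiae
HCTV-10,Hafunaviridae,Haloferacalesvirus,myovirus,Halorubrum sodomense
HJTV-1,Hafunaviridae,Haloferacalesvirus,myovirus,Haloarcula japonica
HRTV-13,Hafunaviridae,Haloferacalesvirus,myovirus,Halorubrum sp. SS8-2
HRTV-21,Hafunaviridae,Haloferacalesvirus,myovirus,Halorubrum sp. SS10-9
HSTV-2,Hafunaviridae,Mincapvirus,myovirus,Halorubrum sodomense
HRTV-7,Hafunaviridae,Mincapvirus,myovirus,Halorubrum sp. B2-2
HRTV-2,Hafunaviridae,Mincapvirus,myovirus,Halorubrum sp. s1-2
HRTV-11,Hafunaviridae,Mincapvirus,myovirus,Halorubrum sp. SL-5
HCTV-6,Hafunaviridae,Mincapvirus,myovirus,Haloarcula californiae
HCTV-13,Hafunaviridae,Mincapvirus,myovirus,Haloarcula californiae
HCTV-15,Hafunaviridae,Mincapvirus,myovirus,Halorubrum sp. SS6-2
HFTV1,Haloferuviridae,Retbasiphovirus,siphovirus,LR2-5
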