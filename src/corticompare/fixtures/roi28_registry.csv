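roi_id,name,lobe
3,"Superior Frontal Gyrus",Frontal
4,"Middle Frontal Gyrus",Frontal
5,"Inferior Frontal Gyrus, pars triangularis",Frontal
6,"Inferior Frontal Gyrus, pars opercularis",Frontal
33,"Frontal Orbital Cortex",Frontal
18,"Superior Parietal Lobule",Parietal
19,"Supramarginal Gyrus, anterior division",Parietal
20,"Supramarginal Gyrus, posterior division",Parietal
31,"Precuneus Cortex",Parietal
22,"Lateral Occipital Cortex, superior division",Occipital
23,"Lateral Occipital Cortex, inferior division",Occipital
29,"Cingulate Gyrus, anterior division",Limbic
30,"Cingulate Gyrus, posterior division",Limbic
8,"Temporal Pole",Temporal
9,"Superior Temporal Gyrus, anterior division",Temporal
10,"Superior Temporal Gyrus, posterior division",Temporal
11,"Middle Temporal Gyrus, anterior division",Temporal
12,"Middle Temporal Gyrus, posterior division",Temporal
13,"Middle Temporal Gyrus, temporo occipital part",Temporal
14,"Inferior Temporal Gyrus, anterior division",Temporal
15,"Inferior Temporal Gyrus, posterior division",Temporal
16,"Inferior Temporal Gyrus, temporo occipital part",Temporal
34,"Parahippocampal Gyrus, anterior division",Temporal
35,"Parahippocampal Gyrus, posterior division",Temporal
37,"Temporal Fusiform Cortex, anterior division",Temporal
38,"Temporal Fusiform Cortex, posterior division",Temporal
45,"Heschl's Gyrus (includes H1 and H2)",Temporal
46,"Temporal Planum",Temporal
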