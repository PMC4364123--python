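numeral,name,restored
I,"Sylvian Fissure",0
II,"Central Sulcus",0
III,"Postcentral Sulcus",0
IV,"Precentral Sulcus",0
V,"Superior Temporal Sulcus",0
VI,"Superior Frontal Sulcus",1
VII,"Intraparietal Sulcus",0
VIII,"Primary Intermediate Sulcus",0
IX,"Secondary Intermediate Sulcus",0
X,"Transverse Occipital Sulcus",0
XI,"Inferior Temporal Sulcus",0
XII,"Inferior Frontal Sulcus",0
XIII,"Middle Frontal Sulcus",0
XIV,"Olfactory Sulcus",0
XV,"Occipital-Temporal Sulcus",0
XVI,"Collateral Sulcus",0
XVII,"Olfactory Control Line",0
XVIII,"Olfactory-Middle Frontal Control Line",0
XIX,"Middle Frontal-Precentral Control Line",0
XX,"Precentral-Central Control Line",0
XXI,"Central-Postcentral Control Line",0
XXII,"Postcentral-Transverse Occipital Control Line",0
XXIII,"Occipital Control Line",0
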